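"""Micro-homology scanning against a brute-force oracle, plus the
disruption/switch sequence edits used as specificity controls."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from recascan.sequences import (
    IntervalError,
    MicroHomologyDomain,
    SequenceInputError,
    SequenceSet,
    disrupt_domain,
    domains_from_tsv,
    domains_to_tsv,
    find_microhomology,
    read_fasta,
    switch_domain,
    write_fasta,
)

BASES = "ACGT"


# ---------------------------------------------------------------------------
# the brute-force substring-pair oracle lives in oracles.py (shared with the
# end-to-end suite)

from oracles import oracle_scan


def as_tuples(domains):
    return sorted(
        (d.target_start, d.length, d.probe_start, d.sequence) for d in domains
    )


dna = st.text(alphabet=BASES, min_size=1, max_size=64)


@settings(max_examples=250, deadline=None, derandomize=True)
@given(probe=st.text(alphabet=BASES, min_size=1, max_size=20), target=dna,
       min_len=st.integers(1, 4))
def test_scanner_matches_bruteforce_oracle(probe, target, min_len):
    got = as_tuples(find_microhomology(probe, target, min_len=min_len))
    assert got == oracle_scan(probe, target, min_len)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(probe=st.text(alphabet=BASES, min_size=3, max_size=20), target=dna)
def test_reported_domains_are_maximal(probe, target):
    for d in find_microhomology(probe, target, min_len=3):
        i, j, L = d.probe_start - 1, d.target_start - 1, d.length
        assert probe[i : i + L] == target[j : j + L] == d.sequence
        if i > 0 and j > 0:
            assert probe[i - 1] != target[j - 1]
        if i + L < len(probe) and j + L < len(target):
            assert probe[i + L] != target[j + L]


def test_identity_case():
    doms = find_microhomology("ACGTACGT", "ACGTACGT", min_len=3)
    assert len(doms) == 1
    assert doms[0].target_start == 1 and doms[0].length == 8


def test_disjoint_alphabets():
    assert find_microhomology("AAA", "CCCCCC", min_len=3) == []


def test_min_len_longer_than_inputs_gives_empty():
    assert find_microhomology("ACG", "ACGT", min_len=5) == []


def test_non_acgt_character_names_position():
    with pytest.raises(SequenceInputError, match="position 3"):
        find_microhomology("ACNTT", "ACGT")


def test_exclude_masks_only_overlapping_domains():
    rng = random.Random(0)
    for _ in range(25):
        probe = "".join(rng.choice(BASES) for _ in range(15))
        target = "".join(rng.choice(BASES) for _ in range(60))
        full = find_microhomology(probe, target, min_len=3)
        excl = (20, 35)
        masked = find_microhomology(probe, target, min_len=3, exclude=excl)
        # agrees with the oracle under the same mask
        assert as_tuples(masked) == oracle_scan(probe, target, 3, exclude=excl)
        # nothing inside the mask; every clear locus survives the mask
        assert not any(d.overlaps(*excl) for d in masked)
        kept = as_tuples(d for d in full if not d.overlaps(*excl))
        assert set(kept) <= set(as_tuples(masked))


def test_exclude_interval_validation():
    with pytest.raises(IntervalError):
        find_microhomology("ACGT", "ACGT", exclude=(0, 2))
    with pytest.raises(IntervalError):
        find_microhomology("ACGT", "ACGT", exclude=(3, 99))


# ---------------------------------------------------------------------------
# disruption and switching


def _random_case(rng):
    probe = "".join(rng.choice(BASES) for _ in range(20))
    target = "".join(rng.choice(BASES) for _ in range(80))
    return probe, target


def test_disrupt_domain_clears_locus_and_preserves_others():
    rng = random.Random(7)
    done = 0
    while done < 50:
        probe, target = _random_case(rng)
        doms = find_microhomology(probe, target, min_len=3)
        if not doms:
            continue
        d = doms[rng.randrange(len(doms))]
        res = disrupt_domain(target, d, probe, rng_seed=done)
        assert len(res.target) == len(target)
        after = find_microhomology(probe, res.target, min_len=3)
        assert not any(a.overlaps(d.target_start, d.target_end) for a in after)
        # untouched loci: every original domain clear of the edit window is
        # still reported identically
        window = (d.target_start - 3, d.target_end + 3)
        before_far = [x for x in doms if not x.overlaps(*window)]
        after_far = [x for x in after if not x.overlaps(*window)]
        assert as_tuples(before_far) == as_tuples(after_far)
        done += 1


def test_disrupt_out_of_bounds_raises():
    d = MicroHomologyDomain(target_start=70, length=20, probe_start=1,
                            sequence="A" * 20)
    with pytest.raises(IntervalError):
        disrupt_domain("ACGT" * 20, d, "ACGTACGT", rng_seed=0)


def test_switch_to_self_is_noop(sim_sequences):
    seqs, domains = sim_sequences
    d = domains[0]
    out = switch_domain(seqs.reaction_top, d, d.sequence, seqs.npf_ssdna)
    assert out == seqs.reaction_top


def test_switch_replacement_must_be_in_probe(sim_sequences):
    seqs, domains = sim_sequences
    probe = seqs.npf_ssdna
    foreign = "AAA" if "AAA" not in probe else ("CCC" if "CCC" not in probe else "GGG")
    with pytest.raises(SequenceInputError):
        switch_domain(seqs.reaction_top, domains[0], foreign, probe)


def test_seeded_switches_relocate_domain():
    """Replacing one domain's sequence with another's keeps a domain at the
    same locus carrying the new sequence, with total length conserved."""
    from recascan.synthetic import SimulationConfig, simulate_sequences

    n_ok = 0
    for seed in range(10):
        seqs, domains = simulate_sequences(SimulationConfig(rng_seed=seed))
        probe = seqs.npf_ssdna
        long_doms = [d for d in domains if d.length >= 4]
        short_doms = [d for d in domains if d.length == 3]
        if not long_doms or not short_doms:
            continue
        d, repl = long_doms[0], short_doms[0].sequence
        out = switch_domain(seqs.reaction_top, d, repl, probe, rng_seed=seed)
        assert len(out) == len(seqs.reaction_top)
        after = find_microhomology(probe, out, min_len=3)
        hits = [a for a in after
                if a.target_start == d.target_start and a.sequence == repl]
        assert hits, "switched domain not found at the original locus"
        assert not any(
            a.target_start == d.target_start and a.sequence == d.sequence
            for a in after
        ), "original sequence still reported at the locus"
        n_ok += 1
    assert n_ok >= 8


# ---------------------------------------------------------------------------
# SequenceSet invariants and I/O


def test_sequence_set_requires_homology_match(sim_sequences):
    seqs, _ = sim_sequences
    bad = seqs.reaction_top[:45] + ("A" if seqs.reaction_top[45] != "A" else "C") \
        + seqs.reaction_top[46:]
    with pytest.raises(SequenceInputError):
        SequenceSet(seqs.npf_ssdna, bad, seqs.control_top, seqs.homology_start)


def test_sequence_set_rejects_homologous_control(sim_sequences):
    seqs, _ = sim_sequences
    # plant an 8-nt probe match into the control
    bad_control = seqs.control_top[:50] + seqs.npf_ssdna[:8] + seqs.control_top[58:]
    with pytest.raises(SequenceInputError, match="heterologous"):
        SequenceSet(seqs.npf_ssdna, seqs.reaction_top, bad_control,
                    seqs.homology_start)


def test_fasta_round_trip(tmp_path, sim_sequences):
    seqs, _ = sim_sequences
    path = tmp_path / "strands.fasta"
    write_fasta(seqs, path)
    back = read_fasta(path)
    assert back.npf_ssdna == seqs.npf_ssdna
    assert back.reaction_top == seqs.reaction_top
    assert back.control_top == seqs.control_top
    assert back.homology_start == seqs.homology_start


def test_domains_tsv_round_trip(tmp_path, sim_sequences):
    _, domains = sim_sequences
    path = tmp_path / "domains.tsv"
    domains_to_tsv(domains, path)
    back = domains_from_tsv(path)
    assert as_tuples(back) == as_tuples(domains)
    header = path.read_text().splitlines()[0]
    assert "1-based" in header and "closed" in header
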