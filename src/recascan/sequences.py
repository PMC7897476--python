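"""Strand sequences and micro-homology scanning.

A RecA monomer engages three nucleotides, so any observable contact between
a nucleoprotein filament and a duplex requires at least 3 nt of shared
sequence. This module finds every *maximal* exact shared substring (>= 3 nt
by default) between the filament's ssDNA probe and a target duplex strand,
and provides the two sequence edits used as controls: shuffling a domain's
nucleotides to destroy the micro-homology (``disrupt_domain``) and replacing
one domain's sequence with another's (``switch_domain``).

Matching is exact and orientation-preserving: the probe is compared against
the identical top strand of the duplex (parallel orientation). No
reverse-complement matching, mismatches or gaps are considered.

Coordinates are 1-based closed intervals counted from the duplex end
furthest from the origami frame's polarity marker.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceSet",
    "MicroHomologyDomain",
    "DisruptionResult",
    "find_microhomology",
    "disrupt_domain",
    "switch_domain",
    "read_fasta",
    "write_fasta",
    "domains_to_tsv",
]

_BASES = "ACGT"

#: Minimum shared length for a stable pairing seed; anything shorter is
#: transient micro-homology. Used to validate the heterologous control.
STABLE_SEED_NT = 8


class SequenceInputError(ValueError):
    """Raised for malformed sequence input (non-ACGT characters, bad intervals)."""


class IntervalError(ValueError):
    """Raised when a domain interval falls outside its target strand."""


class SwitchError(RuntimeError):
    """Raised when a domain switch cannot be realised at the requested locus."""


def _validate_dna(seq: str, name: str) -> None:
    if not seq:
        raise SequenceInputError(f"{name}: sequence is empty")
    for pos, ch in enumerate(seq, start=1):
        if ch not in _BASES:
            raise SequenceInputError(
                f"{name}: non-ACGT character {ch!r} at position {pos}"
            )


@dataclass(frozen=True)
class MicroHomologyDomain:
    """One maximal shared substring between probe and target.

    ``target_start`` and ``probe_start`` are 1-based; the domain occupies the
    closed interval ``[target_start, target_start + length - 1]`` on the
    target strand.
    """

    target_start: int
    length: int
    probe_start: int
    sequence: str

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("domain length must be >= 1")
        if len(self.sequence) != self.length:
            raise ValueError("domain sequence length disagrees with length field")
        if self.target_start < 1 or self.probe_start < 1:
            raise ValueError("domain coordinates are 1-based (must be >= 1)")

    @property
    def target_end(self) -> int:
        """Last (1-based, inclusive) target position of the domain."""
        return self.target_start + self.length - 1

    def overlaps(self, start: int, end: int) -> bool:
        """True if the domain's target interval intersects closed [start, end]."""
        return self.target_start <= end and start <= self.target_end


@dataclass(frozen=True)
class SequenceSet:
    """The three internal strands of the origami frame experiment.

    ``npf_ssdna`` is the 30-nt probe on which RecA polymerises; its sequence
    is repeated identically (parallel orientation) on ``reaction_top``
    starting at ``homology_start``. ``control_top`` is the heterologous
    control and must not share any >= 8 nt match with the probe. Positions
    are counted from the duplex end furthest from the polarity marker.
    """

    npf_ssdna: str
    reaction_top: str
    control_top: str
    homology_start: int
    origin_convention: str = "furthest_from_polarity_marker"
    probe_len: int = 30
    strand_len: int = 128

    def __post_init__(self) -> None:
        _validate_dna(self.npf_ssdna, "npf_ssdna")
        _validate_dna(self.reaction_top, "reaction_top")
        _validate_dna(self.control_top, "control_top")
        if len(self.npf_ssdna) != self.probe_len:
            raise SequenceInputError(
                f"npf_ssdna must be {self.probe_len} nt, got {len(self.npf_ssdna)}"
            )
        if len(self.reaction_top) != self.strand_len:
            raise SequenceInputError(
                f"reaction_top must be {self.strand_len} nt, got {len(self.reaction_top)}"
            )
        if len(self.control_top) != self.strand_len:
            raise SequenceInputError(
                f"control_top must be {self.strand_len} nt, got {len(self.control_top)}"
            )
        hs, he = self.homology_interval
        if hs < 1 or he > len(self.reaction_top):
            raise IntervalError(
                f"homology region [{hs}, {he}] outside reaction strand"
            )
        region = self.reaction_top[hs - 1 : he]
        if region != self.npf_ssdna:
            raise SequenceInputError(
                "reaction_top does not carry the probe sequence at homology_start"
            )
        long_matches = find_microhomology(
            self.npf_ssdna, self.control_top, min_len=STABLE_SEED_NT
        )
        if long_matches:
            raise SequenceInputError(
                f"control_top shares a >= {STABLE_SEED_NT} nt match with the probe "
                f"(at target position {long_matches[0].target_start}); it must be "
                "heterologous"
            )

    @property
    def homology_interval(self) -> Tuple[int, int]:
        """1-based closed interval of the designed homology region on reaction_top."""
        return (self.homology_start, self.homology_start + len(self.npf_ssdna) - 1)

    def scan_reaction(self, min_len: int = 3, mask_homology: bool = True
                      ) -> List[MicroHomologyDomain]:
        """Micro-homology domains on the reaction strand, by default with the
        designed homology region masked out."""
        exclude = self.homology_interval if mask_homology else None
        return find_microhomology(
            self.npf_ssdna, self.reaction_top, min_len=min_len, exclude=exclude
        )

    def scan_control(self, min_len: int = 3) -> List[MicroHomologyDomain]:
        """Micro-homology domains on the control strand."""
        return find_microhomology(self.npf_ssdna, self.control_top, min_len=min_len)


def _maximal_matches(probe: str, target: str, min_len: int
                     ) -> List[Tuple[int, int, int]]:
    """All maximal exact matches as (target_start, length, probe_start), 0-based
    starts internally converted to 1-based by the caller's wrapper.

    A match at (i, j) of length L is maximal iff it cannot be extended by one
    nucleotide on either side. Uses a suffix-extension table; O(|probe| *
    |target|) time and memory, ample for the <= few-hundred-nt strands here.
    """
    n, m = len(probe), len(target)
    # ext[i][j] = length of longest common prefix of probe[i:] and target[j:]
    ext = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n - 1, -1, -1):
        row = ext[i]
        nxt = ext[i + 1]
        pi = probe[i]
        for j in range(m - 1, -1, -1):
            if pi == target[j]:
                row[j] = nxt[j + 1] + 1
    out: List[Tuple[int, int, int]] = []
    for i in range(n):
        for j in range(m):
            length = ext[i][j]
            if length < min_len:
                continue
            # left-maximal: no identical base immediately before both
            if i > 0 and j > 0 and probe[i - 1] == target[j - 1]:
                continue
            # right-maximality is implied: ext already ran to the first mismatch
            out.append((j, length, i))
    return out


def _collapse_to_loci(matches: Sequence[Tuple[int, int, int]]
                      ) -> List[Tuple[int, int, int]]:
    """Merge maximal matches whose target intervals overlap into single loci.

    Domains are reported as target loci, not probe pairings: within each
    cluster of mutually overlapping target intervals the longest match is
    kept; ties break to the smallest target_start, then smallest probe_start.
    """
    if not matches:
        return []
    by_start = sorted(matches)  # (t_start, length, p_start)
    clusters: List[List[Tuple[int, int, int]]] = []
    cur = [by_start[0]]
    cur_end = by_start[0][0] + by_start[0][1] - 1
    for mt in by_start[1:]:
        t, ln, _ = mt
        if t <= cur_end:
            cur.append(mt)
            cur_end = max(cur_end, t + ln - 1)
        else:
            clusters.append(cur)
            cur = [mt]
            cur_end = t + ln - 1
    clusters.append(cur)
    kept = []
    for cluster in clusters:
        kept.append(min(cluster, key=lambda mt: (-mt[1], mt[0], mt[2])))
    return kept


def find_microhomology(
    probe: str,
    target: str,
    min_len: int = 3,
    exclude: Optional[Tuple[int, int]] = None,
) -> List[MicroHomologyDomain]:
    """Find maximal exact shared substrings of length >= ``min_len``.

    Parameters
    ----------
    probe, target : str
        Uppercase ACGT sequences (probe = NPF ssDNA, target = duplex top
        strand).
    min_len : int
        Minimum match length; default 3, the footprint of one RecA monomer.
    exclude : (start, end), optional
        1-based closed interval on the target to mask; any match whose
        target interval overlaps it is discarded. Used to mask the designed
        homology region so that only micro-homology outside it is reported.

    Returns
    -------
    list of MicroHomologyDomain
        Sorted by target_start. A longer match subsumes its shorter
        sub-matches, and overlapping matches at the same target locus are
        reported once (longest representative).
    """
    _validate_dna(probe, "probe")
    _validate_dna(target, "target")
    if min_len < 1:
        raise SequenceInputError(f"min_len must be >= 1, got {min_len}")
    if exclude is not None:
        xs, xe = exclude
        if xs < 1 or xe > len(target) or xs > xe:
            raise IntervalError(
                f"exclude interval [{xs}, {xe}] invalid on target of length {len(target)}"
            )
    if min_len > min(len(probe), len(target)):
        return []
    raw = _maximal_matches(probe, target, min_len)
    if exclude is not None:
        xs, xe = exclude
        raw = [
            (t, ln, p)
            for (t, ln, p) in raw
            if not (t + 1 <= xe and xs <= t + ln)  # closed-interval overlap
        ]
    loci = _collapse_to_loci(raw)
    loci.sort()
    return [
        MicroHomologyDomain(
            target_start=t + 1,
            length=ln,
            probe_start=p + 1,
            sequence=target[t : t + ln],
        )
        for (t, ln, p) in loci
    ]


def _probe_kmers(probe: str, k: int = 3) -> set:
    return {probe[i : i + k] for i in range(len(probe) - k + 1)}


def _fill_avoiding(
    kmers: set,
    left_ctx: str,
    right_ctx: str,
    length: int,
    rng: random.Random,
    forbid: Optional[set] = None,
) -> Optional[str]:
    """Fill ``length`` positions so that no 3-mer spanning the window (with up
    to 2 nt of fixed context on each side) belongs to ``kmers``. Randomised
    DFS with backtracking; returns None only if genuinely infeasible."""
    forbid = forbid or set()
    chosen: List[str] = []

    def ok(idx: int, base: str) -> bool:
        # check every 3-mer ending at this newly placed base
        win = left_ctx + "".join(chosen) + base
        for k in (3,):
            if len(win) >= k and win[-k:] in kmers:
                return False
        return True

    def final_ok(filled: str) -> bool:
        win = left_ctx + filled + right_ctx
        for i in range(len(win) - 2):
            if win[i : i + 3] in kmers:
                return False
        return True

    def dfs(idx: int) -> Optional[str]:
        if idx == length:
            filled = "".join(chosen)
            return filled if final_ok(filled) else None
        bases = [b for b in _BASES if b not in forbid]
        rng.shuffle(bases)
        for b in bases:
            if ok(idx, b):
                chosen.append(b)
                res = dfs(idx + 1)
                if res is not None:
                    return res
                chosen.pop()
        return None

    return dfs(0)


@dataclass(frozen=True)
class DisruptionResult:
    """Outcome of a micro-homology disruption.

    ``target`` is the edited strand. ``method`` is ``"shuffle"`` when a
    composition-preserving permutation sufficed and ``"substitution"`` when
    non-probe bases had to be introduced (deviating from pure shuffling).
    """

    target: str
    method: str
    attempts: int

    def __str__(self) -> str:  # allow use where a plain sequence is expected
        return self.target


def _overlapping_domains(
    probe: str, target: str, start: int, end: int, min_len: int = 3
) -> List[MicroHomologyDomain]:
    return [
        d for d in find_microhomology(probe, target, min_len=min_len)
        if d.overlaps(start, end)
    ]


def disrupt_domain(
    target: str,
    domain: MicroHomologyDomain,
    probe: str,
    rng_seed: int,
    max_shuffle_attempts: int = 200,
) -> DisruptionResult:
    """Destroy a micro-homology domain by permuting its nucleotides.

    The domain's bases are shuffled (same base composition) until a
    re-scan reports no >= 3 nt match overlapping the original interval.
    If no composition-preserving permutation achieves this within
    ``max_shuffle_attempts``, bases absent from the conflicting probe
    3-mers are substituted instead and the result is marked accordingly.
    Deterministic for a given ``rng_seed``.
    """
    _validate_dna(target, "target")
    _validate_dna(probe, "probe")
    s, e = domain.target_start, domain.target_end
    if s < 1 or e > len(target):
        raise IntervalError(
            f"domain interval [{s}, {e}] outside target of length {len(target)}"
        )
    rng = random.Random(rng_seed)
    original = list(target[s - 1 : e])
    for attempt in range(1, max_shuffle_attempts + 1):
        perm = original[:]
        rng.shuffle(perm)
        candidate = target[: s - 1] + "".join(perm) + target[e:]
        if not _overlapping_domains(probe, candidate, s, e):
            return DisruptionResult(candidate, "shuffle", attempt)
    # Fallback: substitute bases so that no probe 3-mer spans the interval.
    kmers = _probe_kmers(probe)
    left_ctx = target[max(0, s - 3) : s - 1]
    right_ctx = target[e : e + 2]
    filled = _fill_avoiding(kmers, left_ctx, right_ctx, e - s + 1, rng)
    if filled is None:
        raise SwitchError(
            f"cannot disrupt domain at [{s}, {e}]: no base assignment avoids "
            "all probe 3-mers"
        )
    candidate = target[: s - 1] + filled + target[e:]
    if _overlapping_domains(probe, candidate, s, e):
        raise SwitchError(f"substitution at [{s}, {e}] failed to clear the locus")
    return DisruptionResult(candidate, "substitution", max_shuffle_attempts)


def switch_domain(
    target: str,
    at: MicroHomologyDomain,
    replacement: str,
    probe: str,
    rng_seed: int = 0,
    max_attempts: int = 100,
) -> str:
    """Replace one micro-homology domain's sequence with another's.

    ``replacement`` must occur in the probe and be >= 3 nt. It is written at
    the domain's target_start; if shorter than the original domain the
    remaining 3' positions are padded with bases that match nothing in the
    probe, so total strand length is conserved. A re-scan of the returned
    strand reports a domain at the same locus whose sequence is
    ``replacement``. If the existing 5' flank would extend the new match
    (shifting the reported locus), the two bases immediately 5' of the
    locus are rewritten to non-matching ones as a last resort.
    """
    _validate_dna(target, "target")
    _validate_dna(probe, "probe")
    _validate_dna(replacement, "replacement")
    if len(replacement) < 3:
        raise SequenceInputError("replacement must be >= 3 nt")
    if replacement not in probe:
        raise SequenceInputError(
            f"replacement {replacement!r} is not a substring of the probe"
        )
    s = at.target_start
    e_old = at.target_end
    if s < 1 or e_old > len(target):
        raise IntervalError("domain outside target")
    if s - 1 + len(replacement) > len(target):
        raise IntervalError("replacement runs past the end of the target")
    pad_len = max(0, at.length - len(replacement))
    rng = random.Random(rng_seed)
    kmers = _probe_kmers(probe)
    e_new = s - 1 + len(replacement)  # 0-based exclusive end of replacement
    for repair_left in (False, True):
        base = target
        if repair_left:
            if s < 3:
                continue
            left = _fill_avoiding(
                kmers, target[max(0, s - 5) : s - 3], replacement[:2], 2, rng
            )
            if left is None:
                continue
            base = target[: s - 3] + left + target[s - 1 :]
        for extra in (0, 1, 2):
            # the 3' repair may extend a little past the old interval when
            # the minimal pad cannot avoid probe 3-mers
            fill_len = pad_len + extra
            if e_new + fill_len > len(target):
                continue
            for _ in range(max_attempts):
                if fill_len:
                    pad = _fill_avoiding(
                        kmers, replacement[-2:],
                        base[e_old + extra : e_old + extra + 2], fill_len, rng,
                    )
                    if pad is None:
                        break
                else:
                    pad = ""
                candidate = (base[: s - 1] + replacement + pad
                             + base[e_new + fill_len :])
                if len(candidate) != len(target):
                    raise AssertionError("switch changed sequence length")
                found = [
                    d
                    for d in find_microhomology(probe, candidate, min_len=3)
                    if d.target_start == s and d.sequence == replacement
                ]
                if found:
                    return candidate
                if not fill_len:
                    break  # nothing random to retry
    raise SwitchError(
        f"could not realise switch to {replacement!r} at position {s}: flanking "
        "sequence extends or masks the intended domain"
    )


# ---------------------------------------------------------------------------
# I/O

FASTA_IDS = ("NPF", "REACTION_TOP", "CONTROL_TOP")


def write_fasta(seqs: SequenceSet, path: str | Path) -> None:
    """Write the three strands as FASTA records NPF / REACTION_TOP /
    CONTROL_TOP; the homology start is recorded in the REACTION_TOP
    description."""
    records = [
        SeqRecord(Seq(seqs.npf_ssdna), id="NPF", description="npf ssdna probe"),
        SeqRecord(
            Seq(seqs.reaction_top),
            id="REACTION_TOP",
            description=f"homology_start={seqs.homology_start}",
        ),
        SeqRecord(Seq(seqs.control_top), id="CONTROL_TOP",
                  description="heterologous control"),
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path, homology_start: Optional[int] = None) -> SequenceSet:
    """Read a SequenceSet written by :func:`write_fasta`. ``homology_start``
    may be given explicitly or parsed from the REACTION_TOP description."""
    records = {r.id: r for r in SeqIO.parse(str(path), "fasta")}
    missing = [rid for rid in FASTA_IDS if rid not in records]
    if missing:
        raise SequenceInputError(f"FASTA missing records: {', '.join(missing)}")
    if homology_start is None:
        desc = records["REACTION_TOP"].description
        for token in desc.split():
            if token.startswith("homology_start="):
                homology_start = int(token.split("=", 1)[1])
        if homology_start is None:
            raise SequenceInputError(
                "homology_start not given and not found in REACTION_TOP description"
            )
    return SequenceSet(
        npf_ssdna=str(records["NPF"].seq).upper(),
        reaction_top=str(records["REACTION_TOP"].seq).upper(),
        control_top=str(records["CONTROL_TOP"].seq).upper(),
        homology_start=homology_start,
    )


def domains_from_tsv(path: str | Path) -> List[MicroHomologyDomain]:
    """Read domains written by :func:`domains_to_tsv`."""
    out = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("target\t"):
                continue
            _, start, _end, length, sequence, probe_start = line.rstrip("\n").split("\t")
            out.append(
                MicroHomologyDomain(
                    target_start=int(start),
                    length=int(length),
                    probe_start=int(probe_start),
                    sequence=sequence,
                )
            )
    return out


def domains_to_tsv(domains: Iterable[MicroHomologyDomain], path: str | Path,
                   target_name: str = "REACTION_TOP") -> None:
    """Export domains as BED-like TSV (1-based closed intervals, stated in
    the header)."""
    with open(path, "w") as fh:
        fh.write("# coordinates: 1-based, closed intervals, origin at the "
                 "duplex end furthest from the polarity marker\n")
        fh.write("target\tstart\tend\tlength\tsequence\tprobe_start\n")
        for d in sorted(domains, key=lambda d: d.target_start):
            fh.write(
                f"{target_name}\t{d.target_start}\t{d.target_end}\t"
                f"{d.length}\t{d.sequence}\t{d.probe_start}\n"
            )
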