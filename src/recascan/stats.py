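"""Positional enrichment of transient sampling events at micro-homology.

The qualitative observation that transient NPF-duplex contacts cluster at
micro-homology domains is formalised as a permutation test. The statistic
is the fraction of transient events whose sequence position lies within a
tolerance (default 6 nt, the upper end of the 1-2 nm measurement
uncertainty) of any micro-homology domain. The null distribution is built
by circularly shifting all event positions by a single uniform offset per
permutation, keeping the domains fixed: this preserves the clustering
structure of the events and conditions on the domain layout, whose lengths
and spacings are constrained by sequence composition. Events inside the
designed homology region are excluded by default, since the claim under
test concerns sampling outside the intended homologous sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from recascan.events import SamplingEvent
from recascan.sequences import MicroHomologyDomain

__all__ = ["EnrichmentResult", "enrichment_test", "power_curve",
           "domain_indicator"]


@dataclass(frozen=True)
class EnrichmentResult:
    """Result of the positional enrichment permutation test."""

    statistic: float
    null_mean: float
    null_sd: float
    n_perm: int
    p_value: float
    tolerance_nt: int
    n_events: int
    #: tie-corrected (mid-p) variant: half weight on null draws exactly equal
    #: to the observed statistic. The primary p_value counts ties fully and
    #: is therefore valid but conservative for this discrete statistic; the
    #: mid-p is the one to use when checking distributional calibration.
    p_value_mid: float = 1.0
    null_distribution: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.statistic <= 1.0:
            raise ValueError("statistic must lie in [0, 1]")
        if not 0.0 < self.p_value <= 1.0:
            raise ValueError("permutation p-value must lie in (0, 1]")

    def to_report(self, path: str | Path) -> None:
        """Write a small key: value text report."""
        with open(path, "w") as fh:
            fh.write(f"statistic: {self.statistic:.6f}\n")
            fh.write(f"null_mean: {self.null_mean:.6f}\n")
            fh.write(f"null_sd: {self.null_sd:.6f}\n")
            fh.write(f"n_perm: {self.n_perm}\n")
            fh.write(f"p_value: {self.p_value:.6g}\n")
            fh.write(f"p_value_mid: {self.p_value_mid:.6g}\n")
            fh.write(f"tolerance_nt: {self.tolerance_nt}\n")
            fh.write(f"n_events: {self.n_events}\n")

    def null_to_tsv(self, path: str | Path) -> None:
        """Dump the full null distribution for plotting."""
        if self.null_distribution is None:
            raise ValueError("null distribution was not retained")
        with open(path, "w") as fh:
            fh.write("null_statistic\n")
            for v in self.null_distribution:
                fh.write(f"{v:.6f}\n")


def domain_indicator(
    domains: Sequence[MicroHomologyDomain],
    strand_len: int,
    tolerance: int,
) -> np.ndarray:
    """Boolean array over positions 1..strand_len (index 0 = nt 1): True
    where a position lies within ``tolerance`` nt of any domain interval.

    The expansion wraps circularly, matching the circular-shift null, so the
    statistic is exactly equivariant under joint circular shifts of events
    and domains.
    """
    ind = np.zeros(strand_len, dtype=bool)
    for d in domains:
        start = d.target_start - 1 - tolerance
        stop = d.target_end - 1 + tolerance
        idx = np.arange(start, stop + 1) % strand_len
        ind[idx] = True
    return ind


def _event_positions_nt(
    events: Iterable[SamplingEvent],
    exclude_region: Optional[Tuple[int, int]],
    strand_len: int,
) -> np.ndarray:
    pos = []
    for ev in events:
        if ev.kind != "transient":
            continue
        nt = ev.position_nt
        if nt is None:
            nt = ev.with_position_nt().position_nt
        nt = min(max(nt, 1), strand_len)
        if exclude_region is not None and exclude_region[0] <= nt <= exclude_region[1]:
            continue
        pos.append(nt)
    return np.asarray(pos, dtype=np.int64)


def enrichment_test(
    events: Sequence[SamplingEvent],
    domains: Sequence[MicroHomologyDomain],
    tolerance: int = 6,
    n_perm: int = 10_000,
    rng_seed: int = 0,
    strand_len: int = 128,
    exclude_region: Optional[Tuple[int, int]] = None,
    keep_null: bool = False,
    null: str = "circular",
) -> EnrichmentResult:
    """Permutation test for enrichment of transient events at micro-homology.

    Parameters
    ----------
    events : sequence of SamplingEvent
        Only transient events are used; events inside ``exclude_region``
        (1-based closed, typically the designed homology region) are
        dropped first.
    domains : sequence of MicroHomologyDomain
        Micro-homology loci on the same strand coordinate system.
    tolerance : int
        Positional tolerance in nt (default 6, the upper measurement
        uncertainty).
    n_perm : int
        Number of circular-shift permutations (default 10_000).
    rng_seed : int
        Seed; results are bit-reproducible given the seed.
    null : str
        ``"circular"`` (default): one shared uniform circular shift of all
        event positions per permutation, preserving event clustering and
        conditioning on the domain layout. ``"uniform"``: independent
        uniform resampling of each event position. With many domains and a
        wide tolerance the indicator approaches saturation and the
        circular-shift null becomes conservative (only ~strand_len distinct
        shifts exist); the uniform null retains power there.

    Returns
    -------
    EnrichmentResult
        With p = (1 + #{null >= observed}) / (1 + n_perm), never zero.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not domains:
        raise ValueError("domains must be non-empty")
    if null not in ("circular", "uniform"):
        raise ValueError(f"unknown null model {null!r}")
    positions = _event_positions_nt(events, exclude_region, strand_len)
    if positions.size == 0:
        raise ValueError(
            "no transient events outside the excluded region; nothing to test"
        )
    ind = domain_indicator(domains, strand_len, tolerance)
    observed = float(ind[positions - 1].mean())
    # null positions are drawn from the same support as the observed events:
    # the excluded (homology) region is out of bounds for both
    all_nt = np.arange(1, strand_len + 1)
    if exclude_region is not None:
        xs, xe = exclude_region
        allowed = all_nt[(all_nt < xs) | (all_nt > xe)]
    else:
        allowed = all_nt
    rng = np.random.default_rng(rng_seed)
    if null == "circular":
        # one shared offset per permutation, on the circle of allowed
        # positions: preserves event clustering
        rank = np.searchsorted(allowed, positions)
        offsets = rng.integers(0, allowed.size, size=n_perm)
        shifted = allowed[(rank[None, :] + offsets[:, None]) % allowed.size]
        null_stats = ind[shifted - 1].mean(axis=1)
    else:
        resampled = allowed[
            rng.integers(0, allowed.size, size=(n_perm, positions.size))
        ]
        null_stats = ind[resampled - 1].mean(axis=1)
    n_gt = float(np.sum(null_stats > observed + 1e-12))
    n_eq = float(np.sum(np.abs(null_stats - observed) <= 1e-12))
    p = (1.0 + n_gt + n_eq) / (1.0 + n_perm)
    p_mid = (1.0 + n_gt + 0.5 * n_eq) / (1.0 + n_perm)
    return EnrichmentResult(
        statistic=observed,
        null_mean=float(null_stats.mean()),
        null_sd=float(null_stats.std(ddof=0)),
        n_perm=n_perm,
        p_value=p,
        p_value_mid=p_mid,
        tolerance_nt=tolerance,
        n_events=int(positions.size),
        null_distribution=null_stats if keep_null else None,
    )


def power_curve(
    domains: Sequence[MicroHomologyDomain],
    effect: float,
    n_events: int = 50,
    n_reps: int = 200,
    rng_seed: int = 0,
    tolerance: int = 6,
    n_perm: int = 500,
    strand_len: int = 128,
    alpha: float = 0.05,
    null: str = "uniform",
) -> float:
    """Monte-Carlo power of the enrichment test at significance ``alpha``.

    A fraction ``effect`` of events is generated at (uniformly chosen)
    domain centres, the rest uniformly over the strand; power is the
    fraction of replicates with p <= alpha. Monotone non-decreasing in
    ``effect`` and ``n_events`` up to Monte-Carlo error; at effect 0 it
    estimates the type-I error rate (~alpha). The default null is
    ``uniform``, matching the independent draws of this generator.
    """
    if not 0.0 <= effect <= 1.0:
        raise ValueError("effect must lie in [0, 1]")
    if not domains:
        raise ValueError("domains must be non-empty")
    rng = np.random.default_rng(rng_seed)
    centres = np.array(
        [(d.target_start + d.target_end) // 2 for d in domains], dtype=np.int64
    )
    hits = 0
    for _ in range(n_reps):
        at_domain = rng.random(n_events) < effect
        pos = np.empty(n_events, dtype=np.int64)
        k = int(at_domain.sum())
        pos[at_domain] = rng.choice(centres, size=k)
        pos[~at_domain] = rng.integers(1, strand_len + 1, size=n_events - k)
        evs = [
            SamplingEvent(frame_id=i, onset_s=0.0, dwell_s=1.0,
                          position_nm=0.0, position_nt=int(p))
            for i, p in enumerate(pos)
        ]
        res = enrichment_test(
            evs, domains, tolerance=tolerance, n_perm=n_perm,
            rng_seed=int(rng.integers(0, 2**31 - 1)), strand_len=strand_len,
            null=null,
        )
        if res.p_value <= alpha:
            hits += 1
    return hits / n_reps
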