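"""Spatial <-> sequence coordinate conversions for RecA-bound DNA.

Distances along a duplex are converted to nucleotide positions assuming a
B-form helical rise of 0.34 nm per basepair. RecA extends the DNA it binds:
a fully decorated filament is stretched to about 1.5x its B-form contour
length, so a 30-nt filament spans anywhere between 10.2 nm (bare B-form) and
15.3 nm (fully extended, the axial equivalent of 45 B-form nt) depending on
the degree of RecA coverage. Each RecA monomer engages three nucleotides.

All conversions are pure scalar arithmetic; they are independent of where
the coordinate origin sits on the strand.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Tuple

__all__ = ["GeometryModel", "B_FORM_RISE_NM", "UNDERWINDING_MAX", "MONOMER_FOOTPRINT_NT"]

#: Axial rise of canonical B-form DNA, nm per nucleotide (basepair).
B_FORM_RISE_NM = 0.34

#: Maximal RecA-induced axial extension factor (dimensionless).
UNDERWINDING_MAX = 1.5

#: Nucleotides bound per RecA monomer.
MONOMER_FOOTPRINT_NT = 3

Rounding = Literal["nearest", "floor", "ceil"]


@dataclass(frozen=True)
class GeometryModel:
    """Geometric model of (RecA-extended) duplex DNA.

    Parameters
    ----------
    bform_rise : float
        Axial rise per nucleotide of bare B-form DNA, in nm. Default 0.34.
    underwinding_max : float
        Maximal axial extension factor imposed by a saturated RecA filament.
        Default 1.5 (30 nt occupy the length of 45 B-form nt).
    monomer_footprint : int
        Nucleotides bound per RecA monomer. Default 3.
    """

    bform_rise: float = B_FORM_RISE_NM
    underwinding_max: float = UNDERWINDING_MAX
    monomer_footprint: int = MONOMER_FOOTPRINT_NT

    def __post_init__(self) -> None:
        if self.bform_rise <= 0:
            raise ValueError(f"bform_rise must be positive, got {self.bform_rise}")
        if self.underwinding_max < 1.0:
            raise ValueError(
                f"underwinding_max must be >= 1.0, got {self.underwinding_max}"
            )
        if self.monomer_footprint < 1:
            raise ValueError(
                f"monomer_footprint must be >= 1, got {self.monomer_footprint}"
            )

    def _check_extension(self, extension: float) -> None:
        if not 1.0 <= extension <= self.underwinding_max:
            raise ValueError(
                f"extension factor {extension} outside [1.0, {self.underwinding_max}]"
            )

    def nt_to_nm(self, n: float, extension: float = 1.0) -> float:
        """Axial length in nm of ``n`` nucleotides at a given extension factor.

        ``extension=1.0`` is bare B-form DNA; ``extension=1.5`` a saturated
        RecA filament.
        """
        if n < 0:
            raise ValueError(f"nucleotide count must be non-negative, got {n}")
        self._check_extension(extension)
        return n * self.bform_rise * extension

    def nm_to_nt(
        self, d: float, extension: float = 1.0, rounding: Rounding = "nearest"
    ) -> int:
        """Nucleotide count spanned by an axial distance ``d`` (nm).

        The continuous quotient ``d / (rise * extension)`` is discretised per
        ``rounding`` (``nearest`` | ``floor`` | ``ceil``). The measurement
        uncertainty of the AFM experiments (1-2 nm) maps to 3-6 nt only under
        mixed rounding -- floor at the lower endpoint, ceil at the upper --
        so both modes are exposed.
        """
        if d < 0:
            raise ValueError(f"distance must be non-negative, got {d}")
        self._check_extension(extension)
        q = d / (self.bform_rise * extension)
        if rounding == "nearest":
            return int(round(q))
        if rounding == "floor":
            return math.floor(q)
        if rounding == "ceil":
            return math.ceil(q)
        raise ValueError(f"unknown rounding mode {rounding!r}")

    def filament_length_bounds(self, n_nt: int) -> Tuple[float, float]:
        """(lower, upper) nm bounds for an ``n_nt`` nucleoprotein filament.

        Lower bound assumes no RecA-induced extension (partial or absent
        polymerisation); upper bound assumes full extension. For the 30-nt
        probe used in the frame experiments this is (10.2, 15.3) nm.
        """
        return (
            self.nt_to_nm(n_nt, 1.0),
            self.nt_to_nm(n_nt, self.underwinding_max),
        )

    def max_monomers(self, n_nt: int) -> int:
        """Maximum number of RecA monomers accommodated by ``n_nt`` nucleotides."""
        if n_nt < 0:
            raise ValueError(f"nucleotide count must be non-negative, got {n_nt}")
        return n_nt // self.monomer_footprint

    @classmethod
    def from_config(cls, cfg: dict) -> "GeometryModel":
        """Build from a config mapping (keys ``bform_rise_nm``,
        ``underwinding_max``, ``monomer_footprint_nt``; all optional)."""
        return cls(
            bform_rise=float(cfg.get("bform_rise_nm", B_FORM_RISE_NM)),
            underwinding_max=float(cfg.get("underwinding_max", UNDERWINDING_MAX)),
            monomer_footprint=int(cfg.get("monomer_footprint_nt", MONOMER_FOOTPRINT_NT)),
        )


#: Module-level default model (0.34 nm/nt, 1.5x extension, 3 nt/monomer).
DEFAULT_MODEL = GeometryModel()


def nt_to_nm(n: float, extension: float = 1.0) -> float:
    """See :meth:`GeometryModel.nt_to_nm` (default model)."""
    return DEFAULT_MODEL.nt_to_nm(n, extension)


def nm_to_nt(d: float, extension: float = 1.0, rounding: Rounding = "nearest") -> int:
    """See :meth:`GeometryModel.nm_to_nt` (default model)."""
    return DEFAULT_MODEL.nm_to_nt(d, extension, rounding)


def filament_length_bounds(n_nt: int) -> Tuple[float, float]:
    """See :meth:`GeometryModel.filament_length_bounds` (default model)."""
    return DEFAULT_MODEL.filament_length_bounds(n_nt)


def max_monomers(n_nt: int) -> int:
    """See :meth:`GeometryModel.max_monomers` (default model)."""
    return DEFAULT_MODEL.max_monomers(n_nt)
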