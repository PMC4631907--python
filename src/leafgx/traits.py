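"""Leaf economics and composition traits.

Specific leaf area (SLA, cm² g⁻¹) is leaf area over dry mass; nitrogen per
unit leaf area converts a mass-based concentration through SLA,

    Narea [g m⁻²] = 10 · Nmass [mg g⁻¹] / SLA [cm² g⁻¹]

(the factor 10 reconciles mg→g and cm²→m²); photosynthetic nitrogen use
efficiency relates assimilation to areal nitrogen,

    PNUE [µmol mol⁻¹ s⁻¹] = A · 14 / Narea

with 14 g mol⁻¹ the atomic mass of nitrogen; and the carbon isotope
composition of leaf tissue is expressed against the Pee Dee Belemnite
standard, δ¹³C = (Rsample/Rstandard − 1) reported in ‰.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "NITROGEN_ATOMIC_MASS",
    "R_PDB",
    "IsotopeSample",
    "LeafTraits",
    "specific_leaf_area",
    "nitrogen_per_area",
    "pnue",
    "delta13c",
]

#: Atomic mass of nitrogen, g mol⁻¹.
NITROGEN_ATOMIC_MASS = 14.0

#: ¹³C/¹²C ratio of the Pee Dee Belemnite standard.
R_PDB = 0.0112372

#: Plausible δ¹³C range for C3 leaf tissue (‰); values outside warn only.
_C3_DELTA13C_RANGE = (-35.0, -20.0)


def specific_leaf_area(area_cm2: float, dry_mass_g: float) -> float:
    """SLA (cm² g⁻¹): leaf area over leaf dry mass."""
    if area_cm2 <= 0 or dry_mass_g <= 0:
        raise ValueError(
            f"area and dry mass must be > 0, got {area_cm2!r} cm², {dry_mass_g!r} g"
        )
    return area_cm2 / dry_mass_g


def nitrogen_per_area(n_mass_mg_g: float, sla_cm2_g: float) -> float:
    """Areal nitrogen (g m⁻²) from mass-based concentration and SLA."""
    if n_mass_mg_g <= 0 or sla_cm2_g <= 0:
        raise ValueError(
            f"n_mass and sla must be > 0, got {n_mass_mg_g!r}, {sla_cm2_g!r}"
        )
    return 10.0 * n_mass_mg_g / sla_cm2_g


def pnue(a_umol_m2_s: float, n_area_g_m2: float) -> float:
    """Photosynthetic nitrogen use efficiency (µmol CO2 mol⁻¹ N s⁻¹).

    Computed per leaf and averaged afterwards when summarising groups — a
    ratio of group means differs slightly from the mean of per-leaf ratios.
    """
    if n_area_g_m2 <= 0:
        raise ValueError(f"n_area must be > 0, got {n_area_g_m2!r}")
    return a_umol_m2_s * NITROGEN_ATOMIC_MASS / n_area_g_m2


@dataclass(frozen=True)
class IsotopeSample:
    """A ¹³C/¹²C measurement against the Pee Dee Belemnite standard."""

    r_sample: float
    r_standard: float = R_PDB

    def __post_init__(self) -> None:
        if self.r_sample <= 0 or self.r_standard <= 0:
            raise ValueError("isotope ratios must be strictly positive")


def delta13c(sample: IsotopeSample) -> float:
    """δ¹³C (‰ vs PDB): 1000·(Rsample/Rstandard − 1).

    The ratio form is a pure number; the conventional reporting scale is per
    mil, so the result is multiplied by 1000.  C3 leaves fall around −35 to
    −20 ‰; values outside that range trigger a warning, not an error.
    """
    value = (sample.r_sample / sample.r_standard - 1.0) * 1000.0
    lo, hi = _C3_DELTA13C_RANGE
    if not (lo <= value <= hi):
        warnings.warn(
            f"delta13c {value:.2f} permil outside the usual C3 leaf range "
            f"[{lo:.0f}, {hi:.0f}]",
            stacklevel=2,
        )
    return value


@dataclass(frozen=True)
class LeafTraits:
    """Trait record of one leaf; derived fields are filled on construction
    when their inputs are present, and cross-checked when supplied redundantly.
    """

    leaf_id: str
    area_cm2: float | None = None
    dry_mass_g: float | None = None
    sla: float | None = None
    n_mass: float | None = None       # mg g⁻¹
    n_area: float | None = None       # g m⁻²
    delta13c_permil: float | None = None
    a: float | None = None            # µmol m⁻² s⁻¹, paired gas-exchange A
    pnue: float | None = None

    def __post_init__(self) -> None:
        if self.area_cm2 is not None and self.dry_mass_g is not None:
            sla = specific_leaf_area(self.area_cm2, self.dry_mass_g)
            if self.sla is None:
                object.__setattr__(self, "sla", sla)
            elif not math.isclose(self.sla, sla, rel_tol=1e-9):
                raise ValueError(
                    f"leaf {self.leaf_id}: supplied SLA {self.sla} inconsistent "
                    f"with area/dry mass ({sla:.6g})"
                )
        if self.n_mass is not None and self.sla is not None:
            n_area = nitrogen_per_area(self.n_mass, self.sla)
            if self.n_area is None:
                object.__setattr__(self, "n_area", n_area)
            elif not math.isclose(self.n_area, n_area, rel_tol=1e-6):
                raise ValueError(
                    f"leaf {self.leaf_id}: supplied Narea {self.n_area} inconsistent "
                    f"with 10·Nmass/SLA ({n_area:.6g})"
                )
        if self.pnue is None and self.a is not None and self.n_area is not None:
            object.__setattr__(self, "pnue", pnue(self.a, self.n_area))
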