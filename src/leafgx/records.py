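"""Point gas-exchange + fluorescence records.

One :class:`GasExchangeRecord` is a single instantaneous cuvette measurement:
net assimilation, CO2 mole fractions, stomatal conductance (with an explicit
water/CO2 basis flag), light, leaf temperature, site pressure and the pair of
fluorescence signals needed for the variable-J mesophyll-conductance
estimate.  Validation is collected as reason strings so readers can drop and
report bad rows instead of failing wholesale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

from .conductance import gs_water_to_co2

__all__ = ["GasExchangeRecord", "validate_record"]


@dataclass(frozen=True)
class GasExchangeRecord:
    leaf_id: str
    species: str
    elevation_m: float
    a: float                 # net assimilation, µmol m⁻² s⁻¹
    ca: float                # ambient CO2, µmol mol⁻¹
    ci: float                # intercellular CO2, µmol mol⁻¹
    gs: float                # stomatal conductance, mol m⁻² s⁻¹
    gs_basis: Literal["co2", "water"]
    ppfd: float              # µmol m⁻² s⁻¹
    tleaf_c: float
    patm_kpa: float
    f: float                 # steady-state fluorescence, a.u.
    fm_prime: float          # maximal fluorescence in the light, a.u.
    rn: float                # dark respiration of the same leaf, µmol m⁻² s⁻¹

    @property
    def gs_co2(self) -> float:
        """Stomatal conductance on a CO2 basis, converting once if the
        instrument logged the water-vapour value."""
        return self.gs if self.gs_basis == "co2" else gs_water_to_co2(self.gs)


def validate_record(rec: GasExchangeRecord) -> list[str]:
    """Return the list of invariant violations (empty = usable record)."""
    reasons: list[str] = []
    if rec.fm_prime <= 0 or not (0 <= rec.f <= rec.fm_prime):
        reasons.append("fluorescence bounds")
    if rec.ca <= 0 or rec.ci <= 0 or rec.ci > rec.ca:
        reasons.append("co2 mole fractions")
    if rec.gs <= 0:
        reasons.append("non-positive gs")
    if rec.gs_basis not in ("co2", "water"):
        reasons.append("unknown gs basis")
    if rec.ppfd < 0:
        reasons.append("negative ppfd")
    if not (40 < rec.patm_kpa <= 110):
        reasons.append("pressure out of range")
    if rec.rn < 0:
        reasons.append("negative dark respiration")
    return reasons
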