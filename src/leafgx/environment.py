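"""Elevation physics for gas-exchange work.

Every quantity a gas-exchange instrument reports as a mole fraction
(µmol mol⁻¹) corresponds, at a given site, to a partial pressure that falls
with elevation.  This module provides the international standard-atmosphere
barometric profile, the mean tropospheric temperature lapse, the mole-fraction
to partial-pressure conversion, and a :class:`SiteEnvironment` container that
keeps the three mutually consistent for one field site.

Units follow instrument conventions: pressure in kPa, CO2 partial pressure in
Pa, mole fractions in µmol mol⁻¹, elevation in metres above sea level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "STANDARD_PRESSURE_KPA",
    "DEFAULT_LAPSE_C_PER_KM",
    "barometric_pressure",
    "lapse_temperature",
    "partial_pressure",
    "relative_change_pco2",
    "SiteEnvironment",
]

#: Sea-level pressure of the international standard atmosphere (kPa).
STANDARD_PRESSURE_KPA = 101.325

#: ICAO standard-atmosphere constants.
_LAPSE_K_PER_M = 0.0065   # tropospheric temperature gradient
_T0_K = 288.15            # sea-level standard temperature
_BAROMETRIC_EXPONENT = 5.25588  # g·M/(R·L)

#: Mean decline of air temperature per km of elevation gain (°C km⁻¹).
DEFAULT_LAPSE_C_PER_KM = 5.5

_MAX_ELEVATION_M = 9000.0


def barometric_pressure(elevation_m: float) -> float:
    """Standard-atmosphere pressure (kPa) at an elevation (m a.s.l.).

    Evaluates ``P0 · (1 − L·h/T0)^(g·M/(R·L))`` with ICAO constants; strictly
    decreasing in elevation, 101.325 kPa at sea level and ≈74.7 kPa at 2500 m.

    Raises
    ------
    ValueError
        If elevation is outside [0, 9000] m (the troposphere layer the
        constants describe).
    """
    if not (0.0 <= elevation_m <= _MAX_ELEVATION_M):
        raise ValueError(
            f"elevation {elevation_m!r} m outside supported range "
            f"[0, {_MAX_ELEVATION_M:.0f}] m"
        )
    base = 1.0 - _LAPSE_K_PER_M * elevation_m / _T0_K
    return STANDARD_PRESSURE_KPA * base ** _BAROMETRIC_EXPONENT


def lapse_temperature(
    base_temperature_c: float,
    elevation_gain_m: float,
    lapse_c_per_km: float = DEFAULT_LAPSE_C_PER_KM,
) -> float:
    """Air temperature (°C) after an elevation gain, via a linear lapse rate.

    The default 5.5 °C km⁻¹ is the mean free-air lapse used in montane
    ecophysiology; pass ``lapse_c_per_km`` to override.
    """
    return base_temperature_c - lapse_c_per_km * elevation_gain_m / 1000.0


def partial_pressure(mole_fraction_umol_mol: float, pressure_kpa: float) -> float:
    """Partial pressure (Pa) of a gas at a mole fraction and total pressure.

    ``p = x·10⁻⁶ · P·10³`` — linear in both arguments.  380 µmol mol⁻¹ at
    101.325 kPa gives 38.5 Pa, the canonical sea-level CO2 partial pressure.
    """
    if mole_fraction_umol_mol < 0:
        raise ValueError(f"mole fraction must be >= 0, got {mole_fraction_umol_mol!r}")
    if pressure_kpa <= 0:
        raise ValueError(f"pressure must be > 0, got {pressure_kpa!r}")
    return mole_fraction_umol_mol * 1e-6 * pressure_kpa * 1e3


def relative_change_pco2(p_low_site_pa: float, p_high_site_pa: float) -> float:
    """Percent reduction in CO2 partial pressure between two sites.

    ``100·(p_low − p_high)/p_low``: positive when the high site has the lower
    partial pressure.  27.7 Pa → 24.6 Pa is an 11.2 % reduction.
    """
    if p_low_site_pa <= 0:
        raise ValueError(f"reference pCO2 must be > 0, got {p_low_site_pa!r}")
    return 100.0 * (p_low_site_pa - p_high_site_pa) / p_low_site_pa


@dataclass(frozen=True)
class SiteEnvironment:
    """Atmospheric context of one field site.

    ``atmospheric_pressure_kpa`` defaults to the standard-atmosphere value for
    the elevation but can be overridden with an instrument-sensed pressure —
    field barometers, not the formula, define the true site pressure; the
    formula is the fallback when no sensor value is recorded.  ``p_co2_pa`` is
    always derived from the effective pressure so the container cannot go
    internally inconsistent.
    """

    elevation_m: float
    ca_umol_mol: float = 380.0
    measured_pressure_kpa: float | None = None
    air_temperature_c: float | None = None
    atmospheric_pressure_kpa: float = field(init=False)
    p_co2_pa: float = field(init=False)

    def __post_init__(self) -> None:
        if self.elevation_m < 0:
            raise ValueError("site elevation must be >= 0 m")
        pressure = (
            self.measured_pressure_kpa
            if self.measured_pressure_kpa is not None
            else barometric_pressure(self.elevation_m)
        )
        if not (40.0 < pressure <= 110.0):
            raise ValueError(
                f"atmospheric pressure {pressure:.2f} kPa outside plausible "
                "site range (40, 110] kPa"
            )
        object.__setattr__(self, "atmospheric_pressure_kpa", pressure)
        object.__setattr__(
            self, "p_co2_pa", partial_pressure(self.ca_umol_mol, pressure)
        )
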