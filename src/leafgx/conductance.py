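"""Fluorescence-derived electron transport and the variable-J mesophyll
conductance estimator.

The variable-J method locates the chloroplast CO2 mole fraction of a leaf by
combining gas exchange (A, Ci) with a chlorophyll-fluorescence measurement of
the actual electron transport rate J.  Inverting the RuBP-regeneration
equation Aj = J·(Cc − Γ*)/(4Cc + 8Γ*) − Rd for Cc gives

    Cc = Γ*·(J + 8(A + Rd)) / (J − 4(A + Rd))

and hence the mesophyll conductance Gm = A/(Ci − Cc).  J itself comes from
the PSII operating quantum yield, J = ΦPSII·PPFD·α·β, with leaf absorptance α
and PSII partitioning β from a calibration (the field-standard values are
α = 0.85, β = 0.5 when a leaf-specific calibration under non-photorespiratory
conditions is impossible).

The estimator is undefined when J ≤ 4(A + Rd) — electron transport too small
to support the observed assimilation — and such records are rejected, never
imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "FluorescenceCalibration",
    "ConductanceSet",
    "GmEstimationError",
    "phi_psii",
    "electron_transport",
    "gm_variable_j",
    "variable_j_sensitivity",
    "cc_from_gm",
    "total_conductance",
    "pressure_ratios",
    "gs_water_to_co2",
]

#: Ratio of diffusivities of water vapour and CO2 in air.
H2O_CO2_DIFFUSIVITY_RATIO = 1.6

#: Upper bound on |dCc/dJ| beyond which a variable-J estimate is considered
#: hypersensitive to electron-transport error and unusable (the sensitivity
#: criterion that accompanies the method in its source literature).
SENSITIVITY_LIMIT = 50.0


class GmEstimationError(ValueError):
    """A record violates the validity region of the variable-J estimator."""


@dataclass(frozen=True)
class FluorescenceCalibration:
    """Electron-transport calibration: leaf absorptance α and the fraction of
    absorbed quanta reaching PSII, β.  Defaults are the standard field
    calibration α = 0.85, β = 0.5."""

    alpha: float = 0.85
    beta: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0) or not (0.0 < self.beta <= 1.0):
            raise ValueError("alpha and beta must lie in (0, 1]")


@dataclass(frozen=True)
class ConductanceSet:
    """Conductances of one leaf (mol m⁻² s⁻¹) and the partial-pressure ratios
    that index diffusional CO2 drawdown."""

    leaf_id: str
    gs: float
    gm: float
    gtot: float
    pi_pa: float
    pc_pa: float


def phi_psii(steady_f: float, fm_prime: float) -> float:
    """PSII operating quantum yield ΦPSII = (Fm′ − F)/Fm′, dimensionless in [0, 1].

    ``steady_f`` is the steady-state fluorescence in the light and
    ``fm_prime`` the maximal fluorescence under a saturating pulse.
    """
    if fm_prime <= 0:
        raise ValueError(f"fm_prime must be > 0, got {fm_prime!r}")
    if not (0.0 <= steady_f <= fm_prime):
        raise ValueError(
            f"steady-state fluorescence {steady_f!r} outside [0, fm_prime={fm_prime!r}]"
        )
    return (fm_prime - steady_f) / fm_prime


def electron_transport(
    phi: float, ppfd: float, cal: FluorescenceCalibration | None = None
) -> float:
    """Linear electron transport rate J = ΦPSII·PPFD·α·β (µmol m⁻² s⁻¹)."""
    if not (0.0 <= phi <= 1.0):
        raise ValueError(f"phi must lie in [0, 1], got {phi!r}")
    if ppfd < 0:
        raise ValueError(f"ppfd must be >= 0, got {ppfd!r}")
    cal = cal or FluorescenceCalibration()
    return phi * ppfd * cal.alpha * cal.beta


def gm_variable_j(
    a: float, ci: float, j: float, gamma_star: float, rd: float
) -> float:
    """Mesophyll conductance (mol m⁻² s⁻¹) by the variable-J method.

    Exact algebraic inverse of the forward chain Gm → Cc = Ci − A/Gm →
    J from the RuBP-regeneration equation, so a roundtrip through the forward
    construction reproduces Gm to machine precision.

    Raises
    ------
    GmEstimationError
        When J ≤ 4(A + Rd) (estimator undefined) or the implied mesophyll
        drawdown Ci − Cc is not positive.
    """
    if a <= 0:
        raise GmEstimationError(f"assimilation must be > 0 for Gm estimation, got {a!r}")
    denom = j - 4.0 * (a + rd)
    if denom <= 0:
        raise GmEstimationError(
            f"electron transport insufficient: J={j:.3f} <= 4(A+Rd)={4*(a+rd):.3f}"
        )
    cc = gamma_star * (j + 8.0 * (a + rd)) / denom
    drawdown = ci - cc
    if drawdown <= 0:
        raise GmEstimationError(
            f"implied chloroplast CO2 {cc:.2f} not below Ci {ci:.2f}"
        )
    return a / drawdown


def variable_j_sensitivity(a: float, j: float, rd: float, gamma_star: float) -> float:
    """|dCc/dJ| of the variable-J inversion: 12·Γ*·(A+Rd)/(J − 4(A+Rd))².

    Measures how strongly an error in the fluorescence-derived electron
    transport propagates into the located chloroplast CO2.  Estimates with
    sensitivity above :data:`SENSITIVITY_LIMIT` are conventionally discarded
    as unreliable.
    """
    denom = j - 4.0 * (a + rd)
    if denom <= 0:
        raise GmEstimationError(
            f"electron transport insufficient: J={j:.3f} <= 4(A+Rd)={4*(a+rd):.3f}"
        )
    return 12.0 * gamma_star * (a + rd) / denom**2


def cc_from_gm(a: float, ci: float, gm: float) -> float:
    """Chloroplast CO2 mole fraction from Fick's law: Cc = Ci − A/Gm."""
    if gm <= 0:
        raise ValueError(f"gm must be > 0, got {gm!r}")
    cc = ci - a / gm
    if cc <= 0:
        raise GmEstimationError(
            f"implied chloroplast CO2 {cc:.2f} <= 0 (A={a}, Ci={ci}, Gm={gm})"
        )
    return cc


def total_conductance(gs: float, gm: float) -> float:
    """Series combination of stomatal and mesophyll conductance,
    Gtot = Gs·Gm/(Gs + Gm); symmetric and never above min(Gs, Gm)."""
    if gs <= 0 or gm <= 0:
        raise ValueError(f"conductances must be > 0, got gs={gs!r}, gm={gm!r}")
    return gs * gm / (gs + gm)


def pressure_ratios(ci: float, cc: float, ca: float) -> tuple[float, float]:
    """(Pi/Pa, Pc/Pa): intercellular and chloroplast to ambient CO2 ratios.

    At a common total pressure the mole-fraction ratios equal the partial-
    pressure ratios, so no pressure argument is needed.
    """
    if ca <= 0:
        raise ValueError(f"ambient CO2 must be > 0, got {ca!r}")
    return ci / ca, cc / ca


def gs_water_to_co2(gsw: float) -> float:
    """Convert stomatal conductance to water vapour into conductance to CO2
    (divide by the diffusivity ratio 1.6).  Apply exactly once, and only to
    water-basis values."""
    if gsw < 0:
        raise ValueError(f"conductance must be >= 0, got {gsw!r}")
    return gsw / H2O_CO2_DIFFUSIVITY_RATIO
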