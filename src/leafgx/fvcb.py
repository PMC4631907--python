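"""Farquhar–von Caemmerer–Berry (FvCB) C3 photosynthesis model and A/Ci fitting.

Net assimilation of a C3 leaf is the minimum of a Rubisco-limited rate

    Ac = Vcmax · (C − Γ*) / (C + Kc·(1 + O/Ko)) − Rd

and an RuBP-regeneration (electron-transport) limited rate

    Aj = J · (C − Γ*) / (4·C + 8·Γ*) − Rd

where C is the CO2 mole fraction at the carboxylation site, Γ* the CO2
compensation point to photorespiration, Kc/Ko the Michaelis constants of
Rubisco for CO2/O2, O the oxygen mole fraction and Rd mitochondrial
respiration continuing in the light.  Fitting the model to a measured CO2
response curve yields the leaf's carboxylation capacity Vcmax and maximum
electron transport Jmax.

Curves are fitted in mole-fraction units (µmol mol⁻¹), matching the
instrument log; conversion to partial pressure is a display-layer concern
(see :mod:`leafgx.environment`).  Respiration defaults to the dark
respiration measured on the same leaf; co-fitting Rd is available but off by
default.  Triose-phosphate limitation is not modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "KineticConstants",
    "SPECIES_KINETICS",
    "FvCBParams",
    "ResponseCurve",
    "FitOptions",
    "FitError",
    "AciFit",
    "rubisco_limited_rate",
    "rubp_limited_rate",
    "net_assimilation",
    "fit_aci",
    "vcmax_slope_estimate",
]

#: Slope-method window on the CO2 setpoint axis (µmol mol⁻¹): the region of a
#: CO2 response curve where assimilation is Rubisco-limited in C3 leaves.
SLOPE_WINDOW = (40.0, 200.0)


class FitError(RuntimeError):
    """Raised when an A/Ci curve cannot be fitted (degenerate or insufficient data)."""


@dataclass(frozen=True)
class KineticConstants:
    """Biochemical constants the FvCB model is evaluated against.

    Defaults are the widely used tobacco-derived C3 values at 25 °C
    (Kc = 404.9 µmol mol⁻¹, Ko = 278.4 mmol mol⁻¹, O = 210 mmol mol⁻¹).
    Γ* has no universal default — it is species-specific and must be chosen;
    presets for the three montane study species are in
    :data:`SPECIES_KINETICS`.
    """

    gamma_star: float
    kc: float = 404.9
    ko: float = 278.4
    o: float = 210.0
    reference_temperature_c: float = 25.0

    def __post_init__(self) -> None:
        for name in ("gamma_star", "kc", "ko", "o"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.gamma_star >= self.kc:
            raise ValueError("gamma_star must be smaller than kc")

    @property
    def km_effective(self) -> float:
        """Effective Michaelis constant Kc·(1 + O/Ko), µmol mol⁻¹."""
        return self.kc * (1.0 + self.o / self.ko)


#: Species presets: photorespiratory compensation points (µmol mol⁻¹) derived
#: from Rubisco specificity factors for the three montane study species.
SPECIES_KINETICS: dict[str, KineticConstants] = {
    "Quercus spinosa": KineticConstants(gamma_star=52.513),
    "Salix atopantha": KineticConstants(gamma_star=54.145),
    "Rumex dentatus": KineticConstants(gamma_star=52.512),
}


@dataclass(frozen=True)
class FvCBParams:
    """Photosynthetic capacity parameters of one leaf (µmol m⁻² s⁻¹)."""

    vcmax: float
    jmax: float
    rd: float
    amax: float | None = None

    def __post_init__(self) -> None:
        if self.vcmax <= 0 or self.jmax <= 0 or self.rd <= 0:
            raise ValueError("vcmax, jmax and rd must all be > 0")

    @property
    def jmax_vcmax_ratio(self) -> float:
        return self.jmax / self.vcmax

    @property
    def amax_ceiling(self) -> float:
        """RuBP-regeneration ceiling on net assimilation, Jmax/4 − Rd."""
        return self.jmax / 4.0 - self.rd


@dataclass(frozen=True)
class ResponseCurve:
    """One leaf's CO2 response curve: net assimilation over an ascending
    ladder of cuvette CO2 setpoints at fixed temperature and saturating light.
    """

    leaf_id: str
    species: str
    elevation_m: float
    ca_set: np.ndarray    # cuvette setpoints, µmol mol⁻¹, strictly increasing
    a: np.ndarray         # net assimilation, µmol m⁻² s⁻¹
    ci: np.ndarray        # intercellular CO2, µmol mol⁻¹
    leaf_temperature_c: float = 25.0
    ppfd: float = 1200.0
    patm_kpa: float | None = None

    def __post_init__(self) -> None:
        ca = np.asarray(self.ca_set, dtype=float)
        a = np.asarray(self.a, dtype=float)
        ci = np.asarray(self.ci, dtype=float)
        object.__setattr__(self, "ca_set", ca)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "ci", ci)
        if not (ca.shape == a.shape == ci.shape):
            raise ValueError("ca_set, a and ci must have identical shapes")
        if ca.size < 5:
            raise ValueError(f"a response curve needs >= 5 records, got {ca.size}")
        if not np.all(np.diff(ca) > 0):
            raise ValueError("CO2 setpoints must be strictly increasing")

    def __len__(self) -> int:
        return int(self.ca_set.size)


def rubisco_limited_rate(cc, params: FvCBParams, constants: KineticConstants):
    """Rubisco-limited net assimilation Ac at chloroplast CO2 ``cc``.

    Saturates at Vcmax − Rd as cc → ∞ and crosses −Rd at cc = Γ*.
    Accepts scalars or arrays.
    """
    cc = np.asarray(cc, dtype=float)
    out = (
        params.vcmax * (cc - constants.gamma_star) / (cc + constants.km_effective)
        - params.rd
    )
    return out if out.ndim else float(out)


def rubp_limited_rate(cc, j: float, gamma_star: float, rd: float):
    """RuBP-regeneration-limited net assimilation Aj at electron transport ``j``.

    Saturates at J/4 − Rd as cc → ∞ and crosses −Rd at cc = Γ*.
    """
    cc = np.asarray(cc, dtype=float)
    out = j * (cc - gamma_star) / (4.0 * cc + 8.0 * gamma_star) - rd
    return out if out.ndim else float(out)


def _carboxylation_rates(cc, params: FvCBParams, constants: KineticConstants):
    """Gross carboxylation rates (Wc, Wj) at chloroplast CO2 ``cc``."""
    cc = np.asarray(cc, dtype=float)
    wc = params.vcmax * cc / (cc + constants.km_effective)
    wj = params.jmax * cc / (4.0 * cc + 8.0 * constants.gamma_star)
    return wc, wj


def net_assimilation(
    cc, params: FvCBParams, constants: KineticConstants, smoothing: float = 0.0
):
    """Net assimilation A = (1 − Γ*/cc)·min(Wc, Wj) − Rd at chloroplast CO2
    ``cc``, with gross carboxylation Wc = Vcmax·cc/(cc + Km) and
    Wj = J·cc/(4cc + 8Γ*).

    Above Γ* this equals min(Ac, Aj) of the two net branch rates; taking the
    minimum on the gross rates also keeps the correct (least-negative) branch
    below the compensation point, where the photorespiratory factor flips
    sign.  ``smoothing`` > 0 replaces the minimum of the gross rates with the
    hyperbolic-minimum root ``(Wc+Wj − sqrt((Wc+Wj)² − 4θ·Wc·Wj))/2θ``; the
    default 0 keeps the sharp transition.
    """
    cc = np.asarray(cc, dtype=float)
    wc, wj = _carboxylation_rates(cc, params, constants)
    if smoothing <= 0.0:
        w = np.minimum(wc, wj)
    else:
        s = wc + wj
        disc = np.maximum(s * s - 4.0 * smoothing * wc * wj, 0.0)
        w = (s - np.sqrt(disc)) / (2.0 * smoothing)
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(cc > 0, 1.0 - constants.gamma_star / cc, 1.0)
    out = factor * w - params.rd
    # cc -> 0: carboxylation stops, photorespiratory efflux saturates at the
    # finite Rubisco-branch limit
    floor = -params.vcmax * constants.gamma_star / constants.km_effective - params.rd
    out = np.where(np.asarray(cc) > 0, out, floor)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class FitOptions:
    """Options for :func:`fit_aci`.

    rd : fixed respiration (dark respiration of the same leaf).  Required
        unless ``fit_rd`` is true.
    fit_rd : co-estimate Rd alongside Vcmax and Jmax.
    amax_setpoint : CO2 mole fraction at which the fitted model is evaluated
        to report Amax (the saturating end of the setpoint ladder).
    smoothing : hyperbolic-minimum shape factor passed to
        :func:`net_assimilation`; 0 = sharp minimum.
    """

    rd: float | None = None
    fit_rd: bool = False
    amax_setpoint: float = 2000.0
    smoothing: float = 0.0


@dataclass(frozen=True)
class AciFit:
    """Result of one A/Ci fit: estimated parameters plus diagnostics."""

    params: FvCBParams
    rmse: float
    residuals: np.ndarray
    limiting: np.ndarray          # per point: "rubisco" | "rubp"
    n_points: int
    vcmax_slope: float | None     # slope-window estimate, when computable
    slope_estimate_divergent: bool
    jmax_identified: bool = True   # False: no clearly RuBP-limited points, so
    #                                the reported Jmax is only a lower bound
    vcmax_identified: bool = True  # analogous for Vcmax
    status: str = "ok"


# multi-start (Vcmax, Jmax) scale pairs applied to the initial guesses;
# fixed order keeps fits reproducible
_START_SCALES = ((1.0, 1.0), (0.5, 2.0), (2.0, 0.5))


def _initial_vcmax(curve: ResponseCurve, rd: float, constants: KineticConstants) -> float:
    """Closed-form least-squares Vcmax from the Rubisco-limited window,
    falling back to the full curve when the window is empty.  Ac is linear in
    Vcmax at fixed Rd, so no iteration is needed."""
    lo, hi = SLOPE_WINDOW
    mask = (curve.ca_set >= lo) & (curve.ca_set <= hi)
    if mask.sum() < 2:
        mask = np.ones(len(curve), dtype=bool)
    x = (curve.ci[mask] - constants.gamma_star) / (
        curve.ci[mask] + constants.km_effective
    )
    y = curve.a[mask] + rd
    denom = float(np.dot(x, x))
    if denom <= 0:
        return 50.0
    return max(float(np.dot(x, y) / denom), 1.0)


def fit_aci(
    curve: ResponseCurve,
    constants: KineticConstants,
    options: FitOptions | None = None,
) -> AciFit:
    """Estimate Vcmax and Jmax (optionally Rd) from a CO2 response curve.

    Least-squares fit of min(Ac, Aj) against the measured intercellular CO2,
    started from a deterministic multi-start grid (Vcmax seeded by the
    Rubisco-window slope estimate, Jmax by 4·(max A + Rd)), so repeated fits
    of the same curve are bitwise identical.  Amax is reported as the model
    prediction at the saturating setpoint.

    Raises
    ------
    FitError
        For degenerate curves (flat response), missing Rd, or solver failure.
    """
    options = options or FitOptions()
    if options.rd is None and not options.fit_rd:
        raise FitError("options.rd is required when fit_rd is disabled")
    if np.ptp(curve.a) < 1e-9:
        raise FitError(f"curve {curve.leaf_id}: flat response, nothing to fit")

    rd0 = options.rd if options.rd is not None else max(0.01 * np.max(curve.a), 0.1)
    v0 = _initial_vcmax(curve, rd0, constants)
    j0 = max(4.0 * (float(np.max(curve.a)) + rd0), 4.0)

    ci = curve.ci

    def predict(theta: np.ndarray) -> np.ndarray:
        if options.fit_rd:
            vc, jm, rd = theta
        else:
            vc, jm, rd = theta[0], theta[1], rd0
        p = FvCBParams(vcmax=vc, jmax=jm, rd=rd)
        return np.asarray(net_assimilation(ci, p, constants, options.smoothing))

    def residual(theta: np.ndarray) -> np.ndarray:
        return predict(theta) - curve.a

    def jacobian(theta: np.ndarray) -> np.ndarray:
        # the model is piecewise linear in (Vcmax, Jmax[, Rd]): each point's
        # gradient is the active gross-rate branch's coefficient
        if options.fit_rd:
            vc, jm, rd = theta
        else:
            vc, jm, rd = theta[0], theta[1], rd0
        p = FvCBParams(vcmax=vc, jmax=jm, rd=rd)
        wc, wj = _carboxylation_rates(ci, p, constants)
        on_wc = wc <= wj
        col_v = np.where(
            on_wc, (ci - constants.gamma_star) / (ci + constants.km_effective), 0.0
        )
        col_j = np.where(
            ~on_wc,
            (ci - constants.gamma_star) / (4.0 * ci + 8.0 * constants.gamma_star),
            0.0,
        )
        cols = [col_v, col_j]
        if options.fit_rd:
            cols.append(np.full_like(ci, -1.0))
        return np.column_stack(cols)

    use_jac = jacobian if options.smoothing <= 0 else "2-point"

    if options.fit_rd:
        bounds = ([1e-3, 1e-3, 1e-4], [1500.0, 3000.0, 50.0])
        base = np.array([v0, j0, rd0])
    else:
        bounds = ([1e-3, 1e-3], [1500.0, 3000.0])
        base = np.array([v0, j0])

    candidates = []
    for sv, sj in _START_SCALES:
        x0 = base.copy()
        x0[0] = np.clip(base[0] * sv, bounds[0][0], bounds[1][0])
        x0[1] = np.clip(base[1] * sj, bounds[0][1], bounds[1][1])
        sol = least_squares(
            residual, x0, jac=use_jac, bounds=bounds, method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=1000,
        )
        if sol.success:
            candidates.append(sol)
    if not candidates:
        raise FitError(f"curve {curve.leaf_id}: optimiser did not converge")
    # the capacity parameters have flat (unidentified) directions when one
    # branch never limits; among near-tied candidates prefer the smallest
    # capacity so degenerate single-branch solutions cannot run away
    best_cost = min(sol.cost for sol in candidates)
    best = min(
        (s for s in candidates if s.cost <= best_cost * 1.01 + 1e-12),
        key=lambda s: s.x[0] + s.x[1] / 4.0,
    )

    if options.fit_rd:
        vc, jm, rd = (float(v) for v in best.x)
    else:
        vc, jm = (float(v) for v in best.x)
        rd = float(rd0)

    # a capacity parameter whose gross-rate branch never limits anywhere on
    # the curve is unidentified (flat cost direction); report the smallest
    # value consistent with the data — the boundary where its branch just
    # touches the active one — instead of an initialisation-dependent number
    if options.smoothing <= 0:
        gs_ = constants.gamma_star
        km = constants.km_effective
        p0 = FvCBParams(vcmax=vc, jmax=jm, rd=rd)
        wc0, wj0 = _carboxylation_rates(ci, p0, constants)
        if not (wj0 < wc0 - 1e-9).any():  # RuBP never limits: Jmax flat
            jb = vc * float(np.max((4.0 * ci + 8.0 * gs_) / (ci + km)))
            jm = float(min(jm, max(jb, bounds[0][1])))
        if not (wc0 < wj0 - 1e-9).any():  # Rubisco never limits: Vcmax flat
            vb = jm * float(np.max((ci + km) / (4.0 * ci + 8.0 * gs_)))
            vc = float(min(vc, max(vb, bounds[0][0])))

    fitted = FvCBParams(vcmax=vc, jmax=jm, rd=rd)
    theta = np.array([vc, jm, rd] if options.fit_rd else [vc, jm])
    resid = residual(theta)
    rmse = float(np.sqrt(np.mean(resid**2)))

    wc, wj = _carboxylation_rates(ci, fitted, constants)
    limiting = np.where(wc <= wj, "rubisco", "rubp")
    # capacity parameters count as identified only when their branch clearly
    # limits somewhere on the curve, by a net-rate margin; otherwise the
    # reported value is a lower bound (common for high Jmax/Vcmax ratios,
    # where the whole measured range stays Rubisco-limited)
    net_gap = (1.0 - constants.gamma_star / ci) * (wc - wj)
    jmax_identified = bool(np.sum(net_gap > 0.05) >= 2)
    vcmax_identified = bool(np.sum(net_gap < -0.05) >= 2)

    amax = float(
        net_assimilation(options.amax_setpoint, fitted, constants, options.smoothing)
    )
    fitted = replace(fitted, amax=amax)

    try:
        v_slope = vcmax_slope_estimate(curve, constants, rd=rd)
    except FitError:
        v_slope = None
    divergent = v_slope is not None and abs(v_slope - vc) > 0.10 * vc

    return AciFit(
        params=fitted,
        rmse=rmse,
        residuals=resid,
        limiting=limiting,
        n_points=len(curve),
        vcmax_slope=v_slope,
        slope_estimate_divergent=bool(divergent),
        jmax_identified=jmax_identified,
        vcmax_identified=vcmax_identified,
    )


def vcmax_slope_estimate(
    curve: ResponseCurve,
    constants: KineticConstants,
    rd: float,
    window: tuple[float, float] = SLOPE_WINDOW,
) -> float:
    """Vcmax from the initial slope region of the CO2 response curve.

    Fits only the Rubisco-limited branch to points whose setpoint lies in
    ``window`` (default 40–200 µmol mol⁻¹).  Ac is linear in Vcmax at fixed
    Rd, so the estimate is closed-form.  If the true curve is electron-
    transport-limited anywhere in the window the estimate is biased low; the
    full fit flags that case via ``slope_estimate_divergent``.

    Raises
    ------
    FitError
        If fewer than 3 curve points fall inside the window.
    """
    lo, hi = window
    mask = (curve.ca_set >= lo) & (curve.ca_set <= hi)
    if mask.sum() < 3:
        raise FitError(
            f"curve {curve.leaf_id}: only {int(mask.sum())} points in the "
            f"[{lo:.0f}, {hi:.0f}] µmol mol⁻¹ slope window (need >= 3)"
        )
    x = (curve.ci[mask] - constants.gamma_star) / (
        curve.ci[mask] + constants.km_effective
    )
    y = curve.a[mask] + rd
    denom = float(np.dot(x, x))
    if denom <= 0:
        raise FitError(f"curve {curve.leaf_id}: degenerate slope window")
    return float(np.dot(x, y) / denom)
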