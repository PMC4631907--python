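"""Pipeline driver: chain simulate → fit-aci → conductance → traits → compare
into one reproducible run with a manifest.

Stage outputs are plain CSV; the manifest (JSON) records the config hash,
seed, package version, per-stage record counts with exclusion reasons, and
the output file list, so identical inputs reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .conductance import (
    SENSITIVITY_LIMIT,
    FluorescenceCalibration,
    GmEstimationError,
    cc_from_gm,
    electron_transport,
    gm_variable_j,
    phi_psii,
    pressure_ratios,
    total_conductance,
    variable_j_sensitivity,
)
from .fvcb import SPECIES_KINETICS, FitError, FitOptions, KineticConstants, ResponseCurve, fit_aci
from .records import GasExchangeRecord
from .stats import GroupSample, one_way_anova, relative_effect
from .synthetic import CampaignConfig, default_paper_scenario, simulate_campaign
from .traits import IsotopeSample, LeafTraits, delta13c

__all__ = [
    "RunManifest",
    "fit_curve_table",
    "conductance_table",
    "traits_table",
    "tidy_parameters",
    "compare_groups",
    "run_pipeline",
]

log = logging.getLogger("leafgx")

#: parameters carried into the group comparison, with their source stage
COMPARE_PARAMETERS = (
    "a", "gs", "gm", "gtot", "rn", "pi_pa", "pc_pa",
    "vcmax", "jmax", "jmax_vcmax", "amax",
    "sla", "narea", "delta13c", "pnue",
)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stage_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    exclusions: dict[str, list] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


def _kinetics_for(species: str) -> KineticConstants:
    try:
        return SPECIES_KINETICS[species]
    except KeyError:
        raise KeyError(
            f"no kinetic preset for species {species!r}; register one in "
            "SPECIES_KINETICS or pass constants explicitly"
        ) from None


def fit_curve_table(
    curves: list[ResponseCurve],
    rd_by_leaf: dict[str, float] | None = None,
    fit_rd: bool = False,
) -> pd.DataFrame:
    """Fit every response curve; one row per leaf.

    ``rd_by_leaf`` supplies the dark respiration measured on each leaf (the
    default respiration mode); leaves without an entry fall back to co-fitted
    Rd.  Fit failures become status rows, never silent drops.
    """
    rows = []
    for curve in curves:
        constants = _kinetics_for(curve.species)
        rd = None if fit_rd else (rd_by_leaf or {}).get(curve.leaf_id)
        options = FitOptions(rd=rd, fit_rd=fit_rd or rd is None)
        try:
            fit = fit_aci(curve, constants, options)
            p = fit.params
            rows.append({
                "leaf_id": curve.leaf_id, "species": curve.species,
                "elevation_m": curve.elevation_m,
                "vcmax": p.vcmax, "jmax": p.jmax, "rd": p.rd,
                "amax": p.amax, "jmax_vcmax": p.jmax_vcmax_ratio,
                "vcmax_slope": fit.vcmax_slope,
                "jmax_identified": fit.jmax_identified,
                "vcmax_identified": fit.vcmax_identified,
                "rmse": fit.rmse, "n_points": fit.n_points,
                "status": fit.status,
            })
        except FitError as err:
            log.warning("fit-aci: %s", err)
            rows.append({
                "leaf_id": curve.leaf_id, "species": curve.species,
                "elevation_m": curve.elevation_m,
                "vcmax": np.nan, "jmax": np.nan, "rd": np.nan,
                "amax": np.nan, "jmax_vcmax": np.nan, "vcmax_slope": np.nan,
                "rmse": np.nan, "n_points": len(curve),
                "status": f"failed: {err}",
            })
    return pd.DataFrame(rows)


def conductance_table(
    records: list[GasExchangeRecord],
    calibration: FluorescenceCalibration | None = None,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Per-leaf conductance sets from point measurements.

    Computes ΦPSII → J → variable-J Gm → Gtot and the Pi/Pa, Pc/Pa ratios.
    Records outside the estimator's validity region are excluded with a
    reason, never imputed.
    """
    cal = calibration or FluorescenceCalibration()
    rows, excluded = [], []
    for rec in records:
        constants = _kinetics_for(rec.species)
        try:
            phi = phi_psii(rec.f, rec.fm_prime)
            j = electron_transport(phi, rec.ppfd, cal)
            sensitivity = variable_j_sensitivity(
                rec.a, j, rec.rn, constants.gamma_star
            )
            if sensitivity > SENSITIVITY_LIMIT:
                raise GmEstimationError(
                    f"variable-J sensitivity |dCc/dJ|={sensitivity:.1f} above "
                    f"{SENSITIVITY_LIMIT:.0f}: estimate unreliable"
                )
            gm = gm_variable_j(rec.a, rec.ci, j, constants.gamma_star, rec.rn)
            cc = cc_from_gm(rec.a, rec.ci, gm)
            gs_co2 = rec.gs_co2
            gtot = total_conductance(gs_co2, gm)
            pi_pa, pc_pa = pressure_ratios(rec.ci, cc, rec.ca)
        except (GmEstimationError, ValueError) as err:
            log.warning("conductance: excluded leaf %s: %s", rec.leaf_id, err)
            excluded.append((rec.leaf_id, str(err)))
            continue
        rows.append({
            "leaf_id": rec.leaf_id, "species": rec.species,
            "elevation_m": rec.elevation_m,
            "a": rec.a, "phi_psii": phi, "j": j,
            "gs": gs_co2, "gm": gm, "gtot": gtot,
            "ci": rec.ci, "cc": cc, "pi_pa": pi_pa, "pc_pa": pc_pa,
            "rn": rec.rn, "dcc_dj": sensitivity,
        })
    return pd.DataFrame(rows), excluded


def traits_table(traits_df: pd.DataFrame) -> pd.DataFrame:
    """Derived leaf traits (SLA, Narea, δ¹³C, PNUE) per leaf from the raw
    trait inputs."""
    rows = []
    for _, row in traits_df.iterrows():
        lt = LeafTraits(
            leaf_id=str(row["leaf_id"]),
            area_cm2=float(row["area_cm2"]),
            dry_mass_g=float(row["dry_mass_g"]),
            n_mass=float(row["n_mass_mg_g"]),
            a=float(row["a_umol_m2_s"]) if pd.notna(row.get("a_umol_m2_s")) else None,
        )
        d13c = delta13c(
            IsotopeSample(float(row["r_sample"]), float(row["r_standard"]))
        )
        rows.append({
            "leaf_id": lt.leaf_id, "species": row["species"],
            "elevation_m": float(row["elevation_m"]),
            "area_cm2": lt.area_cm2, "dry_mass_g": lt.dry_mass_g,
            "sla": lt.sla, "n_mass": lt.n_mass, "narea": lt.n_area,
            "delta13c": d13c, "pnue": lt.pnue,
        })
    return pd.DataFrame(rows)


def tidy_parameters(
    conductance_df: pd.DataFrame,
    fits_df: pd.DataFrame,
    traits_out_df: pd.DataFrame,
) -> pd.DataFrame:
    """Long per-leaf table (leaf_id, species, elevation_m, parameter, value)
    pooling all comparison parameters from the three stage outputs.

    Vcmax enters the comparison via the 40–200 µmol mol⁻¹ slope-window
    estimate — the operational definition of carboxylation capacity in this
    workflow, and much more stable than the full-fit value when the branch
    structure of a curve is ambiguous; the full-fit Vcmax stays available in
    the fits table.  Jmax/Vcmax is recomputed against the same Vcmax.
    """
    fits_df = fits_df.copy()
    if "vcmax_slope" in fits_df.columns:
        slope = fits_df["vcmax_slope"]
        fits_df["vcmax"] = slope.where(slope.notna(), fits_df["vcmax"])
        fits_df["jmax_vcmax"] = fits_df["jmax"] / fits_df["vcmax"]
    pieces = []

    def melt(df: pd.DataFrame, cols: list[str]) -> None:
        present = [c for c in cols if c in df.columns]
        if df.empty or not present:
            return
        long = df.melt(
            id_vars=["leaf_id", "species", "elevation_m"],
            value_vars=present, var_name="parameter", value_name="value",
        )
        pieces.append(long.dropna(subset=["value"]))

    melt(conductance_df, ["a", "gs", "gm", "gtot", "rn", "pi_pa", "pc_pa"])
    melt(fits_df[fits_df["status"] == "ok"] if "status" in fits_df else fits_df,
         ["vcmax", "jmax", "jmax_vcmax", "amax"])
    melt(traits_out_df, ["sla", "narea", "delta13c", "pnue"])
    if not pieces:
        raise ValueError("no parameters available for comparison")
    return pd.concat(pieces, ignore_index=True)


def compare_groups(
    tidy: pd.DataFrame, alpha: float = 0.05, protected: bool = True
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Species × elevation group comparison for every parameter.

    Returns (anova, letters, effects): the omnibus ANOVA table, the LSD
    compact letter display, and the per-species elevation relative effects
    (percent change of the high-elevation mean with delta-method SE).
    """
    anova_rows, letter_rows, effect_rows = [], [], []
    for parameter, sub in tidy.groupby("parameter", sort=False):
        groups = []
        for (species, elev), grp in sub.groupby(["species", "elevation_m"], sort=True):
            if len(grp) >= 2:
                groups.append(
                    GroupSample(label=f"{species} @ {elev:.0f} m",
                                values=grp["value"].to_numpy(float))
                )
        if len(groups) < 2:
            continue
        res = one_way_anova(groups, alpha=alpha, protected=protected)
        anova_rows.append({
            "parameter": parameter, "f_stat": res.f_stat,
            "df_between": res.df_between, "df_within": res.df_within,
            "p_value": res.p_value, "ms_within": res.ms_within,
            "lsd": res.lsd_value,
        })
        for label, letters in res.group_letters.items():
            letter_rows.append({
                "parameter": parameter, "group": label,
                "mean": res.group_means[label], "n": res.group_ns[label],
                "letters": letters,
            })

        elevations = sorted(sub["elevation_m"].unique())
        if len(elevations) == 2:
            low_e, high_e = elevations
            for species, sp_grp in sub.groupby("species", sort=True):
                low = sp_grp.loc[sp_grp["elevation_m"] == low_e, "value"]
                high = sp_grp.loc[sp_grp["elevation_m"] == high_e, "value"]
                if len(low) < 2 or len(high) < 2 or low.mean() == 0:
                    continue
                eff = relative_effect(
                    parameter, str(species),
                    float(low.mean()), float(low.sem()),
                    float(high.mean()), float(high.sem()),
                )
                effect_rows.append({
                    "parameter": parameter, "species": species,
                    "low_mean": eff.low_mean, "high_mean": eff.high_mean,
                    "percent_change": eff.percent_change,
                    "se_percent": eff.se_percent,
                })
    return (
        pd.DataFrame(anova_rows),
        pd.DataFrame(letter_rows),
        pd.DataFrame(effect_rows),
    )


def _config_hash(config: CampaignConfig) -> str:
    """Stable hash of the campaign configuration."""
    def default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if hasattr(obj, "__dict__"):
            return obj.__dict__
        return str(obj)

    blob = json.dumps(asdict_like(config), sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def asdict_like(obj):
    """dataclasses.asdict that tolerates frozen dataclasses holding arrays."""
    if hasattr(obj, "__dataclass_fields__"):
        return {k: asdict_like(getattr(obj, k)) for k in obj.__dataclass_fields__}
    if isinstance(obj, dict):
        return {k: asdict_like(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [asdict_like(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


@dataclass
class CampaignAnalysis:
    """All stage outputs of one campaign analysis, in memory."""

    points: pd.DataFrame
    curves: pd.DataFrame
    traits_raw: pd.DataFrame
    truth: pd.DataFrame
    fits: pd.DataFrame
    conductance: pd.DataFrame
    traits: pd.DataFrame
    tidy: pd.DataFrame
    anova: pd.DataFrame
    letters: pd.DataFrame
    effects: pd.DataFrame
    point_exclusions: list
    conductance_exclusions: list
    n_resampled: int


def analyze_campaign(config: CampaignConfig) -> CampaignAnalysis:
    """Simulate a campaign and run every analysis stage in memory."""
    result = simulate_campaign(config)

    from .io import _curves_from_frame, _records_from_frame

    records, point_excl = _records_from_frame(result.points)
    curves = _curves_from_frame(result.curves)

    rd_by_leaf = {r.leaf_id: r.rn for r in records}
    fits = fit_curve_table(curves, rd_by_leaf=rd_by_leaf)
    cond, cond_excl = conductance_table(records, config.calibration)
    traits_out = traits_table(result.traits)
    tidy = tidy_parameters(cond, fits, traits_out)
    anova, letters, effects = compare_groups(tidy)

    return CampaignAnalysis(
        points=result.points, curves=result.curves, traits_raw=result.traits,
        truth=result.truth, fits=fits, conductance=cond, traits=traits_out,
        tidy=tidy, anova=anova, letters=letters, effects=effects,
        point_exclusions=point_excl, conductance_exclusions=cond_excl,
        n_resampled=result.n_resampled,
    )


def run_pipeline(
    out_dir: str | Path,
    config: CampaignConfig | None = None,
    seed: int | None = None,
) -> RunManifest:
    """Simulate a campaign and run every analysis stage, writing all outputs
    and a manifest under ``out_dir``."""
    if config is None:
        config = default_paper_scenario(seed=seed if seed is not None else 0)
    elif seed is not None:
        from dataclasses import replace
        config = replace(config, seed=seed)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        config_hash=_config_hash(config), seed=config.seed, version=__version__
    )

    analysis = analyze_campaign(config)
    tables = (
        ("points", analysis.points), ("curves", analysis.curves),
        ("traits", analysis.traits_raw), ("params_true", analysis.truth),
        ("aci_fits", analysis.fits), ("conductance", analysis.conductance),
        ("traits_derived", analysis.traits), ("tidy", analysis.tidy),
        ("anova", analysis.anova), ("letters", analysis.letters),
        ("effects", analysis.effects),
    )
    for name, df in tables:
        path = out / f"{name}.csv"
        df.to_csv(path, index=False)
        manifest.outputs.append(path.name)

    n_records = len(analysis.points) - len(analysis.point_exclusions)
    n_ok = int((analysis.fits["status"] == "ok").sum())
    manifest.stage_counts = {
        "simulate": {"leaves": len(analysis.points),
                     "resampled": analysis.n_resampled},
        "read_points": {"read": len(analysis.points), "used": n_records,
                        "excluded": len(analysis.point_exclusions)},
        "fit_aci": {"curves": len(analysis.fits), "ok": n_ok,
                    "failed": len(analysis.fits) - n_ok},
        "conductance": {"records": n_records, "used": len(analysis.conductance),
                        "excluded": len(analysis.conductance_exclusions)},
        "traits": {"leaves": len(analysis.traits)},
        "compare": {"parameters": len(analysis.anova),
                    "effects": len(analysis.effects)},
    }
    manifest.exclusions = {
        "points": [list(e) for e in analysis.point_exclusions],
        "conductance": [list(e) for e in analysis.conductance_exclusions],
    }

    manifest.write(out / "manifest.json")
    manifest.outputs.append("manifest.json")
    return manifest
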