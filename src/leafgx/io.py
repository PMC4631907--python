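"""CSV schemas, column mapping and validated readers/writers.

All tables are plain UTF-8 CSV with dot decimals and unit-bearing canonical
headers.  Instrument exports differ in naming, so readers accept a
:class:`ColumnMap` that renames input headers onto the canonical schema at
the boundary; everything downstream sees canonical names only.  Rows that
fail validation are dropped and reported with a reason — never imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .fvcb import ResponseCurve
from .records import GasExchangeRecord, validate_record

__all__ = [
    "ColumnMap",
    "SchemaError",
    "POINTS_COLUMNS",
    "CURVES_COLUMNS",
    "TRAITS_COLUMNS",
    "read_points",
    "read_curves",
    "read_traits",
]

log = logging.getLogger("leafgx")

POINTS_COLUMNS = (
    "leaf_id", "species", "elevation_m", "a_umol_m2_s", "ca_umol_mol",
    "ci_umol_mol", "gs_mol_m2_s", "gs_basis", "ppfd_umol_m2_s", "tleaf_c",
    "patm_kpa", "f_au", "fm_prime_au", "rn_umol_m2_s",
)
CURVES_COLUMNS = (
    "leaf_id", "species", "elevation_m", "ca_set_umol_mol", "a_umol_m2_s",
    "ci_umol_mol", "tleaf_c", "ppfd_umol_m2_s", "patm_kpa",
)
TRAITS_COLUMNS = (
    "leaf_id", "species", "elevation_m", "area_cm2", "dry_mass_g",
    "n_mass_mg_g", "r_sample", "r_standard", "a_umol_m2_s",
)


class SchemaError(ValueError):
    """An input table does not resolve to the canonical schema."""


@dataclass(frozen=True)
class ColumnMap:
    """Mapping from canonical column names to the headers of an input file.

    Only non-identity renames need listing.  ``apply`` renames a frame onto
    the canonical schema and raises :class:`SchemaError` for any required
    canonical column that cannot be resolved.
    """

    renames: dict[str, str] = field(default_factory=dict)

    def apply(self, df: pd.DataFrame, required: tuple[str, ...]) -> pd.DataFrame:
        inverse = {src: canon for canon, src in self.renames.items()}
        df = df.rename(columns=inverse)
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise SchemaError(f"missing mapped column(s): {', '.join(missing)}")
        return df


def _load_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    return df


def read_points(
    path: str | Path, column_map: ColumnMap | None = None
) -> tuple[list[GasExchangeRecord], list[tuple[str, str]]]:
    """Read and validate point measurements.

    Returns (records, exclusions) where exclusions is a list of
    (leaf_id, reason) for dropped rows, preserving input order for the kept
    records.
    """
    df = (column_map or ColumnMap()).apply(_load_csv(path), POINTS_COLUMNS)
    return _records_from_frame(df)


def _records_from_frame(
    df: pd.DataFrame,
) -> tuple[list[GasExchangeRecord], list[tuple[str, str]]]:
    records: list[GasExchangeRecord] = []
    excluded: list[tuple[str, str]] = []
    for _, row in df.iterrows():
        rec = GasExchangeRecord(
            leaf_id=str(row["leaf_id"]),
            species=str(row["species"]),
            elevation_m=float(row["elevation_m"]),
            a=float(row["a_umol_m2_s"]),
            ca=float(row["ca_umol_mol"]),
            ci=float(row["ci_umol_mol"]),
            gs=float(row["gs_mol_m2_s"]),
            gs_basis=str(row["gs_basis"]),
            ppfd=float(row["ppfd_umol_m2_s"]),
            tleaf_c=float(row["tleaf_c"]),
            patm_kpa=float(row["patm_kpa"]),
            f=float(row["f_au"]),
            fm_prime=float(row["fm_prime_au"]),
            rn=float(row["rn_umol_m2_s"]),
        )
        reasons = validate_record(rec)
        if reasons:
            for reason in reasons:
                log.warning("points: excluded leaf %s: %s", rec.leaf_id, reason)
            excluded.append((rec.leaf_id, "; ".join(reasons)))
        else:
            records.append(rec)
    return records, excluded


def read_curves(
    path: str | Path, column_map: ColumnMap | None = None
) -> list[ResponseCurve]:
    """Read response curves, one :class:`ResponseCurve` per leaf_id, records
    sorted by ascending CO2 setpoint."""
    df = (column_map or ColumnMap()).apply(_load_csv(path), CURVES_COLUMNS)
    return _curves_from_frame(df)


def _curves_from_frame(df: pd.DataFrame) -> list[ResponseCurve]:
    curves: list[ResponseCurve] = []
    for leaf_id, grp in df.groupby("leaf_id", sort=False):
        grp = grp.sort_values("ca_set_umol_mol")
        curves.append(
            ResponseCurve(
                leaf_id=str(leaf_id),
                species=str(grp["species"].iloc[0]),
                elevation_m=float(grp["elevation_m"].iloc[0]),
                ca_set=grp["ca_set_umol_mol"].to_numpy(float),
                a=grp["a_umol_m2_s"].to_numpy(float),
                ci=grp["ci_umol_mol"].to_numpy(float),
                leaf_temperature_c=float(grp["tleaf_c"].iloc[0]),
                ppfd=float(grp["ppfd_umol_m2_s"].iloc[0]),
                patm_kpa=float(grp["patm_kpa"].iloc[0]),
            )
        )
    return curves


def read_traits(
    path: str | Path, column_map: ColumnMap | None = None
) -> pd.DataFrame:
    """Read the leaf-trait table onto the canonical schema."""
    return (column_map or ColumnMap()).apply(_load_csv(path), TRAITS_COLUMNS)
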