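"""Delimited intensity tables and structured results records.

Intensity tables are plain tab-separated text with a header
(``experiment_id, replicate_id, ligand_total_molar, intensity,
is_control``), concentrations in molar — the form densitometry exports are
handed off in practice. Results and truth sidecars are JSON; every results
record carries the tool version, the resolved configuration, and the seed,
so a run can be reproduced bit-identically.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .depletion import EnergySummary, IntensityRecord, TitrationSeries
from .errors import SchemaError

TABLE_COLUMNS = [
    "experiment_id",
    "replicate_id",
    "ligand_total_molar",
    "intensity",
    "is_control",
]

SCHEMA_VERSION = "1"


def series_to_frame(series_list: Sequence[TitrationSeries]) -> pd.DataFrame:
    rows = [
        {
            "experiment_id": r.experiment_id,
            "replicate_id": r.replicate_id,
            "ligand_total_molar": r.ligand_total,
            "intensity": r.intensity,
            "is_control": r.is_control,
        }
        for s in series_list
        for r in s.records
    ]
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def frame_to_series(df: pd.DataFrame) -> dict[str, list[TitrationSeries]]:
    """Group a validated table into one TitrationSeries per replicate,
    keyed by experiment id. Points are ordered by descending ligand."""
    out: dict[str, list[TitrationSeries]] = {}
    for (exp_id, rep_id), grp in df.groupby(
        ["experiment_id", "replicate_id"], sort=True
    ):
        grp = grp.sort_values("ligand_total_molar", ascending=False)
        try:
            records = tuple(
                IntensityRecord(
                    experiment_id=str(exp_id),
                    replicate_id=str(rep_id),
                    ligand_total=float(r.ligand_total_molar),
                    intensity=float(r.intensity),
                    is_control=bool(r.is_control),
                )
                for r in grp.itertuples()
            )
            series = TitrationSeries(records=records)
        except Exception as exc:
            raise SchemaError(
                f"experiment {exp_id!r} replicate {rep_id!r}: {exc}"
            ) from exc
        out.setdefault(str(exp_id), []).append(series)
    return out


def write_intensity_table(
    table: pd.DataFrame | Sequence[TitrationSeries], path: str | Path
) -> None:
    df = table if isinstance(table, pd.DataFrame) else series_to_frame(table)
    # %.17g round-trips any float64 exactly
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_intensity_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a delimited intensity table."""
    try:
        df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    except Exception as exc:
        raise SchemaError(f"cannot parse intensity table {path}: {exc}") from exc
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"intensity table {path} missing columns {missing}")
    if df[TABLE_COLUMNS[:4]].isna().any().any():
        bad = df[df[TABLE_COLUMNS[:4]].isna().any(axis=1)].index[0]
        raise SchemaError(f"intensity table {path}: missing value at row {bad}")
    if df["is_control"].dtype != bool:
        mapped = df["is_control"].astype(str).str.strip().str.lower()
        if not mapped.isin(["true", "false", "0", "1"]).all():
            raise SchemaError(f"intensity table {path}: is_control must be boolean")
        df["is_control"] = mapped.isin(["true", "1"])
    return df


def summary_to_record(summary: EnergySummary, extra: dict | None = None) -> dict:
    rec = {
        "label": summary.label,
        "n": summary.n,
        "per_replicate_dg_kcal_mol": list(summary.per_replicate_dg),
        "mean_dg_kcal_mol": summary.mean_dg,
        "sd_dg_kcal_mol": summary.sd_dg,
        "ci_low_kcal_mol": summary.ci_low,
        "ci_high_kcal_mol": summary.ci_high,
        "apparent": summary.apparent,
        "below_detection_count": summary.below_detection_count,
        "sd_defined": summary.sd_defined,
        "ci_method": summary.ci_method,
        "temperature_K": summary.conditions.temperature,
        "gas_constant_kcal_mol_K": summary.conditions.gas_constant,
    }
    if extra:
        rec.update(extra)
    return rec


def results_payload(kind: str, config: dict, seed: int | None, body: dict) -> dict:
    from . import __version__

    return {
        "tool": "supdep",
        "version": __version__,
        "schema_version": SCHEMA_VERSION,
        "kind": kind,
        "seed": seed,
        "config": config,
        **body,
    }


def write_json(payload: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")


def read_json(path: str | Path) -> dict:
    try:
        return json.loads(Path(path).read_text())
    except Exception as exc:
        raise SchemaError(f"cannot parse JSON results {path}: {exc}") from exc
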