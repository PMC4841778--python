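"""Reading and writing the tabular formats the pipeline consumes.

The MID table dialect is one row per (sample, metabolite) with columns::

    sample_id, condition, metabolite, fragment_formula, backbone_carbons,
    m0, m1, ..., mN

``m0..mN`` hold raw (or corrected) isotopologue intensities; missing
trailing isotopologue columns are read as zero.  Seahorse-style flux series
use long-format CSV (well, condition, time_min, ocr, ecar, protein_ug) and
injection schedules a small YAML list.
"""

from __future__ import annotations

import re

import numpy as np
import pandas as pd
import yaml

from .bioenergetics import FluxTimeSeries, InjectionSchedule
from .correction import FragmentFormula, build_correction_matrix, correct_natural_abundance
from .mid import IsotopologueVector, normalize_mid

__all__ = [
    "read_mid_table",
    "write_mid_table",
    "iter_mids",
    "mids_to_frame",
    "correct_mid_table",
    "read_flux_series",
    "read_injection_schedule",
]

_META_COLS = ["sample_id", "condition", "metabolite", "fragment_formula", "backbone_carbons"]
_M_COL = re.compile(r"^m(\d+)$")


def read_mid_table(path) -> pd.DataFrame:
    """Read a MID table CSV; missing trailing isotopologue columns become 0."""
    df = pd.read_csv(path)
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"MID table missing columns: {missing}")
    m_cols = sorted(
        (c for c in df.columns if _M_COL.match(c)), key=lambda c: int(c[1:])
    )
    if not m_cols:
        raise ValueError("MID table has no m0..mN intensity columns")
    n_max = int(df["backbone_carbons"].max())
    for i in range(n_max + 1):
        col = f"m{i}"
        if col not in df.columns:
            df[col] = 0.0
    df[[f"m{i}" for i in range(n_max + 1)]] = (
        df[[f"m{i}" for i in range(n_max + 1)]].fillna(0.0).astype(float)
    )
    return df[_META_COLS + [f"m{i}" for i in range(n_max + 1)]]


def write_mid_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def iter_mids(df: pd.DataFrame, *, normalized: bool = False, corrected: bool = False):
    """Yield (row metadata, IsotopologueVector) for each MID table row.

    Rows are auto-normalized to unit sum unless ``normalized`` claims they
    already are.
    """
    for _, row in df.iterrows():
        n = int(row["backbone_carbons"])
        raw = np.array([row.get(f"m{i}", 0.0) for i in range(n + 1)], dtype=float)
        if normalized:
            mid = IsotopologueVector(
                metabolite_id=str(row["metabolite"]),
                n_carbons=n,
                fractions=tuple(raw),
                corrected=corrected,
            )
        else:
            mid = normalize_mid(raw, metabolite_id=str(row["metabolite"]), corrected=corrected)
        yield row, mid


def mids_to_frame(rows: list[dict]) -> pd.DataFrame:
    """Assemble MID-table rows (dicts with meta + intensity list) into a frame."""
    n_max = max(len(r["intensities"]) for r in rows) - 1
    records = []
    for r in rows:
        rec = {k: r[k] for k in _META_COLS}
        for i in range(n_max + 1):
            vals = r["intensities"]
            rec[f"m{i}"] = float(vals[i]) if i < len(vals) else 0.0
        records.append(rec)
    return pd.DataFrame.from_records(records, columns=_META_COLS + [f"m{i}" for i in range(n_max + 1)])


def correct_mid_table(
    df: pd.DataFrame,
    *,
    tracer_purity: float = 0.99,
    abundances=None,
) -> pd.DataFrame:
    """Natural-abundance correct every row of a raw MID table.

    Builds one correction matrix per distinct (fragment formula, backbone
    carbons) pair; the output table holds corrected fractional MIDs.
    """
    matrices: dict[tuple[str, int], object] = {}
    out_rows = []
    for row, mid in iter_mids(df):
        key = (str(row["fragment_formula"]), mid.n_carbons)
        if key not in matrices:
            formula = FragmentFormula.from_string(key[0], key[1])
            matrices[key] = build_correction_matrix(
                formula, abundances=abundances, tracer_purity=tracer_purity
            )
        corrected = correct_natural_abundance(mid, matrices[key])
        out_rows.append(
            {
                "sample_id": row["sample_id"],
                "condition": row["condition"],
                "metabolite": row["metabolite"],
                "fragment_formula": key[0],
                "backbone_carbons": key[1],
                "intensities": list(corrected.fractions),
            }
        )
    return mids_to_frame(out_rows)


def read_flux_series(path) -> list[FluxTimeSeries]:
    """Read a long-format Seahorse-style CSV into one series per well."""
    df = pd.read_csv(path)
    needed = {"well", "condition", "time_min", "ocr", "ecar", "protein_ug"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"flux series CSV missing columns: {sorted(missing)}")
    series = []
    for (well, condition), grp in df.groupby(["well", "condition"], sort=False):
        grp = grp.sort_values("time_min")
        series.append(
            FluxTimeSeries(
                well_id=str(well),
                condition=str(condition),
                timepoints_min=tuple(grp["time_min"]),
                ocr=tuple(grp["ocr"]),
                ecar=tuple(grp["ecar"]),
                protein_mass_ug=float(grp["protein_ug"].iloc[0]),
            )
        )
    return series


def read_injection_schedule(path) -> InjectionSchedule:
    """Read an injection schedule YAML: list of {time_min, compound, concentration}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    events = tuple(
        (float(e["time_min"]), str(e["compound"]), float(e.get("concentration", 0.0)))
        for e in raw
    )
    return InjectionSchedule(events=events)
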