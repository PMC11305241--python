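"""Tabular input schema and per-animal index computation.

Input CSV (schema version 1) requires ``cat_id, sex, age_years, bcs`` plus
either raw kinetic columns
(``tkt_rate_{0|03|3}_rep{1..3}, gr_rate_rep{1..3}, protein_mg_ml, dilution``)
or precomputed specific activities
(``stkt_u_mg, tkt_tdp03_u_mg, tkt_tdp3_u_mg, gr_u_mg``).
Missing values are empty cells.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import assay
from .errors import InvalidInputError

SCHEMA_VERSION = 1
ID_COLUMNS = ("cat_id", "sex", "age_years", "bcs")
PRECOMPUTED_COLUMNS = ("stkt_u_mg", "tkt_tdp03_u_mg", "tkt_tdp3_u_mg", "gr_u_mg")
RAW_RATE_PREFIXES = ("tkt_rate_0", "tkt_rate_03", "tkt_rate_3", "gr_rate")
RAW_EXTRA_COLUMNS = ("protein_mg_ml", "dilution")


def detect_mode(df: pd.DataFrame) -> str:
    """'precomputed' or 'raw', based on which column set is present."""
    if all(c in df.columns for c in PRECOMPUTED_COLUMNS):
        return "precomputed"
    raw_cols = [f"{p}_rep{r}" for p in RAW_RATE_PREFIXES for r in (1, 2, 3)]
    have_any_raw = any(c in df.columns for c in raw_cols)
    if have_any_raw:
        missing = [c for c in list(RAW_EXTRA_COLUMNS) if c not in df.columns]
        missing += [p + "_rep1" for p in RAW_RATE_PREFIXES if p + "_rep1" not in df.columns]
        if missing:
            raise InvalidInputError(f"raw-mode input missing columns: {missing}")
        return "raw"
    raise InvalidInputError(
        "input matches neither the precomputed activity schema "
        f"{PRECOMPUTED_COLUMNS} nor the raw kinetic schema"
    )


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in ID_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidInputError(f"input missing required columns: {missing}")
    detect_mode(df)  # raises with a named-column message if neither schema fits
    if df["cat_id"].duplicated().any():
        dupes = df.loc[df["cat_id"].duplicated(), "cat_id"].tolist()
        raise InvalidInputError(f"duplicate cat_id values: {dupes}")
    return df


def _replicates(row: pd.Series, prefix: str) -> list[float]:
    vals = []
    for rep in (1, 2, 3):
        col = f"{prefix}_rep{rep}"
        if col in row.index and not pd.isna(row[col]):
            vals.append(float(row[col]))
    return vals


def indices_table(
    df: pd.DataFrame,
    latency_formula: str = "baseline",
    cv_threshold: float = assay.CV_QC_THRESHOLD,
) -> pd.DataFrame:
    """Per-animal activities, B1 indices and QC flags from either schema."""
    mode = detect_mode(df)
    rows = []
    for _, row in df.iterrows():
        qc: list[str] = []
        rec = {c: row[c] for c in ID_COLUMNS}
        if mode == "precomputed":
            acts = {c: float(row[c]) if not pd.isna(row[c]) else math.nan
                    for c in PRECOMPUTED_COLUMNS}
            a0, a03, a3, gr = (acts[c] for c in PRECOMPUTED_COLUMNS)
        else:
            protein = float(row["protein_mg_ml"])
            dilution = float(row["dilution"])
            vals = {}
            for prefix, label in zip(RAW_RATE_PREFIXES, ("a0", "a03", "a3", "gr")):
                reps = _replicates(row, prefix)
                if not reps:
                    vals[label] = math.nan
                    qc.append(f"{label}: no replicates")
                    continue
                summ = assay.aggregate_replicates(reps)
                if summ.exceeds(cv_threshold):
                    qc.append(f"{label}: replicate CV {summ.cv_percent:.1f}% > {cv_threshold}%")
                if summ.mean < 0:
                    qc.append(f"{label}: negative mean rate retained")
                vals[label] = assay.specific_activity(summ.mean, protein, dilution)
            a0, a03, a3, gr = vals["a0"], vals["a03"], vals["a3"], vals["gr"]

        if all(math.isfinite(v) for v in (a0, a03, a3)):
            idx = assay.compute_b1_indices(
                assay.ActivityProfile(a0=a0, a03=a03, a3=a3, gr=gr if math.isfinite(gr) else 0.0),
                latency_formula=latency_formula,
            )
            if idx.diagnostic:
                qc.append(idx.diagnostic)
        else:
            idx = assay.B1Indices(*(math.nan,) * 5, diagnostic="missing activities")
            qc.append("missing activities; indices not computed")
        rec.update(
            stkt_u_mg=a0, tkt_tdp03_u_mg=a03, tkt_tdp3_u_mg=a3, gr_u_mg=gr,
            par=idx.par, far=idx.far, sar=idx.sar, sad=idx.sad, latency=idx.latency,
            qc_flags=";".join(qc),
        )
        rows.append(rec)
    out = pd.DataFrame(rows)
    out["age_years"] = out["age_years"].astype(float)
    return out


def write_csv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, lineterminator="\n")


def read_indices_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "qc_flags" in df.columns:
        df["qc_flags"] = df["qc_flags"].fillna("")
    return df
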