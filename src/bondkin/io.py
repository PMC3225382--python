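"""Delimited-table and configuration I/O.

Three table layouts, all plain delimited text (comma by default, tab for
``.tsv``/``.tab`` paths), one header row:

* lifetime tables — ``force_pN, lifetime_s, censored, condition``;
* apparent-parameter tables — ``condition, force_pN, k1, k2, k3, w1, w2,
  w3`` (one row per condition x force, the layout of per-force fitted
  parameter summaries);
* intrinsic-parameter tables — ``condition, force_pN, k12, k23, kr1, kr2,
  kr3`` (rate-vs-force series).

Condition models (one force law per rate) are serialized as YAML.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dwell import LifetimeDataset
from .force import RATE_NAMES, ConditionModel
from .params import ApparentParams, InfeasibleParametersError

__all__ = [
    "read_lifetimes",
    "write_lifetimes",
    "read_apparent_table",
    "write_apparent_table",
    "apparent_records",
    "read_intrinsic_table",
    "write_intrinsic_table",
    "load_condition_model",
    "save_condition_model",
]

logger = logging.getLogger("bondkin")

_APPARENT_COLS = ["condition", "force_pN", "k1", "k2", "k3", "w1", "w2", "w3"]
_INTRINSIC_COLS = ["condition", "force_pN", *RATE_NAMES]


def _sep_for(path) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab")) else ","


def _read_table(path, required, numeric) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    bad_lines = []
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()].tolist()
        bad += df.index[df[col].isna()].tolist()
        bad_lines += [i + 2 for i in bad]  # +2: header + 1-based
        df[col] = coerced.astype(float)
    if bad_lines:
        raise ValueError(
            f"{path}: malformed numeric values at line(s) "
            f"{sorted(set(bad_lines))}")
    return df


def read_lifetimes(path) -> LifetimeDataset:
    """Read a lifetime table; a missing ``censored`` column defaults to
    all-uncensored with a logged warning.  Malformed rows are rejected
    with their line numbers."""
    df = _read_table(path, ["force_pN", "lifetime_s", "condition"],
                     ["force_pN", "lifetime_s"])
    if "censored" not in df.columns:
        logger.warning("%s: no 'censored' column; assuming all uncensored",
                       path)
        df["censored"] = False
    bad = df.index[~(df["lifetime_s"] > 0)].tolist()
    if bad:
        raise ValueError(
            f"{path}: non-positive lifetime at line(s) "
            f"{[i + 2 for i in bad]}")
    return LifetimeDataset(df[["force_pN", "lifetime_s", "censored",
                               "condition"]])


def write_lifetimes(d: LifetimeDataset, path) -> None:
    d.table.to_csv(path, sep=_sep_for(path), index=False,
                   float_format="%.17g")


def read_apparent_table(path, *, wsum_tol: float = 1e-3,
                        column_map: dict | None = None) -> pd.DataFrame:
    """Read an apparent-parameter table, validating and repairing the
    mixture invariants row by row.

    Weight sums off by more than machine-level but within reason are
    renormalized with a warning (tolerance for the warning: ``wsum_tol``);
    rows whose rates are not sorted fastest-first are re-sorted with a
    permutation warning; rows that remain infeasible (negative weights,
    non-positive rates) raise with their line numbers.  ``column_map``
    renames nonstandard input columns to the canonical layout.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in _APPARENT_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    for col in _APPARENT_COLS[1:]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    infeasible = []
    out_rows = []
    for i, row in df.iterrows():
        line = i + 2
        k = row[["k1", "k2", "k3"]].to_numpy(dtype=float)
        w = row[["w1", "w2", "w3"]].to_numpy(dtype=float)
        if np.any(~np.isfinite(k)) or np.any(~np.isfinite(w)):
            infeasible.append((line, "non-numeric entry"))
            continue
        s = w.sum()
        if s <= 0 or np.any(w < -1e-9) or np.any(k <= 0):
            infeasible.append((line, f"weights {w} / rates {k} infeasible"))
            continue
        if abs(s - 1.0) > wsum_tol:
            logger.warning("%s line %d: weight sum %.4f renormalized to 1",
                           path, line, s)
        w = w / s
        if not (k[0] >= k[1] >= k[2]):
            logger.warning("%s line %d: rates not sorted fastest-first; "
                           "re-sorting with matching weight permutation",
                           path, line)
        p = ApparentParams.from_unsorted(k, np.clip(w, 0.0, 1.0),
                                         renormalize=True)
        out_rows.append({"condition": row["condition"],
                         "force_pN": float(row["force_pN"]),
                         "k1": p.k1, "k2": p.k2, "k3": p.k3,
                         "w1": p.w1, "w2": p.w2, "w3": p.w3})
    if infeasible:
        raise InfeasibleParametersError(
            f"{path}: infeasible row(s): " +
            "; ".join(f"line {ln}: {msg}" for ln, msg in infeasible))
    return pd.DataFrame(out_rows, columns=_APPARENT_COLS)


def write_apparent_table(df: pd.DataFrame, path) -> None:
    df[_APPARENT_COLS].to_csv(path, sep=_sep_for(path), index=False,
                              float_format="%.17g")


def apparent_records(df: pd.DataFrame) -> list[tuple[str, float, ApparentParams]]:
    """Rows of a canonical apparent table as (condition, force, params)."""
    out = []
    for _, row in df.iterrows():
        p = ApparentParams(row.k1, row.k2, row.k3, row.w1, row.w2, row.w3)
        out.append((str(row.condition), float(row.force_pN), p))
    return out


def read_intrinsic_table(path) -> pd.DataFrame:
    df = _read_table(path, _INTRINSIC_COLS, ["force_pN", *RATE_NAMES])
    neg = df.index[(df[list(RATE_NAMES)] < 0).any(axis=1)].tolist()
    if neg:
        raise ValueError(
            f"{path}: negative rate(s) at line(s) {[i + 2 for i in neg]}")
    return df[_INTRINSIC_COLS]


def write_intrinsic_table(df: pd.DataFrame, path) -> None:
    df[_INTRINSIC_COLS].to_csv(path, sep=_sep_for(path), index=False,
                               float_format="%.17g")


def load_condition_model(path) -> ConditionModel:
    """Load a condition model from YAML (see
    :meth:`~bondkin.force.ConditionModel.to_dict` for the schema)."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return ConditionModel.from_dict(d)


def save_condition_model(model: ConditionModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model.to_dict(), fh, sort_keys=False)
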