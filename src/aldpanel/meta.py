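"""Sample metadata, histology endpoints and protein annotations.

Sample metadata is a pandas DataFrame with one row per sample (index =
sample id).  Ordinal histology scores use pandas nullable integers so that
a missing biopsy score can never leak into arithmetic as a sentinel.
Comparator test values live in columns prefixed ``cmp_`` (e.g. ``cmp_te``
for transient elastography).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ORDINAL_RANGES",
    "Endpoint",
    "ENDPOINTS",
    "read_sample_meta",
    "write_sample_meta",
    "validate_meta",
    "derive_activity_score",
    "label_endpoint",
    "comparator_columns",
    "read_annotation_table",
]

#: Valid ranges of the histology scores (inclusive).
ORDINAL_RANGES = {
    "kleiner_f": (0, 4),
    "lobular": (0, 3),
    "ballooning": (0, 2),
    "steatosis_s": (0, 3),
    "activity_i": (0, 5),
}

_ORDINAL_COLS = list(ORDINAL_RANGES)
_COMPARATOR_PREFIX = "cmp_"


@dataclass(frozen=True)
class Endpoint:
    """A binary classification target defined by a histology threshold.

    ``F2`` = significant fibrosis (Kleiner ≥ 2), ``F3`` = advanced fibrosis,
    ``I2`` = mild inflammatory activity (lobular + ballooning ≥ 2),
    ``S1`` = any steatosis.
    """

    name: str
    score_field: str
    threshold: int


ENDPOINTS: dict[str, Endpoint] = {
    "F2": Endpoint("F2", "kleiner_f", 2),
    "F3": Endpoint("F3", "kleiner_f", 3),
    "I2": Endpoint("I2", "activity_i", 2),
    "S1": Endpoint("S1", "steatosis_s", 1),
}


def validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Coerce ordinal columns to nullable ints and check invariants."""
    meta = meta.copy()
    if meta.index.has_duplicates:
        dup = meta.index[meta.index.duplicated()][0]
        raise ValueError(f"duplicate sample id {dup!r}")
    for col, (lo, hi) in ORDINAL_RANGES.items():
        if col not in meta.columns:
            continue
        vals = pd.to_numeric(meta[col], errors="raise").astype("Int64")
        bad = vals.dropna()
        if ((bad < lo) | (bad > hi)).any():
            raise ValueError(f"{col} outside its ordinal range {lo}..{hi}")
        meta[col] = vals
    if {"lre_time_months", "followup_months"} <= set(meta.columns):
        t, f = meta["lre_time_months"], meta["followup_months"]
        both = t.notna() & f.notna()
        if (t[both] > f[both] + 1e-9).any():
            raise ValueError("lre_time_months exceeds followup_months")
    return meta


def derive_activity_score(meta: pd.DataFrame) -> pd.DataFrame:
    """Inflammatory activity = lobular inflammation + ballooning (0–5).

    Missing wherever either component is missing; other columns untouched.
    """
    meta = validate_meta(meta)
    lob = meta["lobular"]
    bal = meta["ballooning"]
    meta["activity_i"] = (lob + bal).astype("Int64")
    return meta


def label_endpoint(meta: pd.DataFrame, endpoint: Endpoint | str) -> pd.Series:
    """Per-sample label: 1 = case, 0 = control, <NA> = unlabeled.

    A sample is a case iff its relevant score is ≥ the endpoint threshold;
    samples with the score missing are unlabeled.
    """
    if isinstance(endpoint, str):
        try:
            endpoint = ENDPOINTS[endpoint]
        except KeyError:
            raise ValueError(f"unknown endpoint {endpoint!r}") from None
    score = meta[endpoint.score_field]
    labels = pd.Series(pd.NA, index=meta.index, dtype="Int64", name=endpoint.name)
    present = score.notna()
    labels[present] = (score[present] >= endpoint.threshold).astype(int)
    return labels


def comparator_columns(meta: pd.DataFrame) -> list[str]:
    """Names of the clinical-comparator value columns (``cmp_*``)."""
    return [c for c in meta.columns if c.startswith(_COMPARATOR_PREFIX)]


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    sep = "," if str(path).endswith(".csv") else "\t"
    meta = pd.read_csv(path, sep=sep, index_col=0)
    meta.index = meta.index.astype(str)
    return validate_meta(meta)


def write_sample_meta(meta: pd.DataFrame, path: str | Path) -> None:
    sep = "," if str(path).endswith(".csv") else "\t"
    meta.to_csv(path, sep=sep, index_label="sample_id")


def read_annotation_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV (protein_id, category) → mapping.

    Categories outside {liver_specific, secreted} are folded into "other";
    a protein listed twice is an error.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    ids = df.iloc[:, 0]
    if ids.duplicated().any():
        dup = ids[ids.duplicated()].iloc[0]
        raise ValueError(f"protein {dup!r} annotated more than once")
    cats = df.iloc[:, 1].where(
        df.iloc[:, 1].isin(["liver_specific", "secreted"]), "other"
    )
    return dict(zip(ids, cats))
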