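"""Prognostic evaluation of diagnostic risk scores.

The diagnostic panel models are evaluated, without refitting, for their
ability to predict right-censored clinical outcomes: a composite
liver-related event (LRE) endpoint and all-cause mortality, via Harrell's
concordance index over the whole follow-up and fixed-horizon ROC-AUCs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .panel import mann_whitney_auc

__all__ = [
    "LRE_EVENT_TYPES",
    "compose_lre",
    "harrells_c",
    "horizon_auc",
]

#: Default composite: the named liver-related outcomes.
LRE_EVENT_TYPES = (
    "alcoholic_hepatitis",
    "varices_needing_treatment",
    "variceal_bleeding",
    "ascites",
    "spontaneous_bacterial_peritonitis",
    "hepatic_encephalopathy",
    "hcc",
    "hepatorenal_syndrome",
    "upper_gastrointestinal_bleeding",
    "jaundice_liver_failure",
)


def compose_lre(
    meta: pd.DataFrame,
    event_table: pd.DataFrame,
    event_types: tuple[str, ...] = LRE_EVENT_TYPES,
) -> pd.DataFrame:
    """Build (time, event) survival records from a per-patient event table.

    ``event_table`` has columns (sample_id, event_name, time_months).  Per
    patient, time is the earliest qualifying event time with event=True;
    patients without a qualifying event are censored at follow-up end.
    """
    if not {"sample_id", "event_name", "time_months"} <= set(event_table.columns):
        raise ValueError("event table needs sample_id, event_name, time_months")
    qualifying = event_table[event_table["event_name"].isin(event_types)]
    followup = pd.to_numeric(meta["followup_months"], errors="coerce")
    merged = qualifying.join(followup, on="sample_id")
    late = merged["time_months"] > merged["followup_months"] + 1e-9
    if late.any():
        sid = merged.loc[late, "sample_id"].iloc[0]
        raise ValueError(f"event time exceeds follow-up for sample {sid!r}")
    first = qualifying.groupby("sample_id")["time_months"].min()
    out = pd.DataFrame(index=meta.index)
    out["time"] = followup
    out["event"] = False
    hit = first.index.intersection(meta.index)
    out.loc[hit, "time"] = first[hit]
    out.loc[hit, "event"] = True
    return out


def harrells_c(records: pd.DataFrame) -> float:
    """Harrell's concordance index of ``risk`` against (time, event).

    Comparable pairs: the smaller observed time belongs to an event; pairs
    tied in time are non-comparable unless exactly one is an event.
    Concordant = the earlier-event patient has the higher risk; risk ties
    get half credit.  Returns NaN (with a warning) if no pair is comparable.
    """
    t = records["time"].to_numpy(float)
    e = records["event"].to_numpy(bool)
    r = records["risk"].to_numpy(float)
    n = t.size
    concordant = ties = comparable = 0
    for i in range(n):
        if not e[i]:
            continue
        for j in range(n):
            if i == j:
                continue
            # i is an event; comparable if j's observed time is later,
            # or equal with j censored
            if t[j] > t[i] or (t[j] == t[i] and not e[j]):
                comparable += 1
                if r[i] > r[j]:
                    concordant += 1
                elif r[i] == r[j]:
                    ties += 1
    if comparable == 0:
        warnings.warn("no comparable pairs; C-index undefined")
        return float("nan")
    return (concordant + 0.5 * ties) / comparable


def horizon_auc(records: pd.DataFrame, horizon: float) -> float:
    """Fixed-horizon ROC-AUC of ``risk``.

    Cases: event at or before the horizon.  Controls: observed event-free
    through the horizon (follow-up reaching the horizon counts).  Censored
    before the horizon without an event: excluded.  Returns NaN (with a
    warning) if either group is empty.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    t = records["time"].to_numpy(float)
    e = records["event"].to_numpy(bool)
    r = records["risk"].to_numpy(float)
    case = e & (t <= horizon)
    control = (t >= horizon) & ~case
    use = case | control
    if case.sum() == 0 or control.sum() == 0:
        warnings.warn("no cases or no controls at this horizon")
        return float("nan")
    return mann_whitney_auc(case[use].astype(int), r[use])
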