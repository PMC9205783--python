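"""Benchmarking panel models against clinical comparator tests.

Comparators (elastography, ELF, FIB-4, APRI, ...) are evaluated at fixed
clinically recommended cutoffs; paired ROC-AUCs are compared with DeLong's
placement-value test, and class-based net reclassification improvement
(NRI) quantifies the net fraction of events reclassified upward plus
nonevents reclassified downward when moving from a baseline test to the
panel model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .panel import PanelModel, classification_metrics, mann_whitney_auc, predict_risk

__all__ = [
    "ComparatorSpec",
    "NRIResult",
    "comparator_calls",
    "comparator_metrics",
    "delong_test",
    "nri",
    "rule_out_accuracy",
]


@dataclass(frozen=True)
class ComparatorSpec:
    """A clinical test with its fixed decision cutoff.

    ``direction`` says which side of the cutoff is called diseased; the
    boundary value itself is called a case (≥ / ≤ semantics).
    """

    name: str
    cutoff: float
    direction: str = "higher_is_case"

    def __post_init__(self) -> None:
        if not np.isfinite(self.cutoff):
            raise ValueError("cutoff must be finite")
        if self.direction not in ("higher_is_case", "lower_is_case"):
            raise ValueError(f"unknown direction {self.direction!r}")


@dataclass
class NRIResult:
    """Class-based net reclassification improvement counts and components."""

    events_up: int
    events_down: int
    events_total: int
    nonevents_up: int
    nonevents_down: int
    nonevents_total: int
    nri_event: float
    nri_nonevent: float
    nri_total: float


def comparator_calls(values: np.ndarray, spec: ComparatorSpec) -> np.ndarray:
    """Binary calls at the fixed cutoff (NaN-preserving)."""
    v = np.asarray(values, dtype=float)
    if spec.direction == "higher_is_case":
        calls = (v >= spec.cutoff).astype(float)
    else:
        calls = (v <= spec.cutoff).astype(float)
    calls[np.isnan(v)] = np.nan
    return calls


def comparator_metrics(
    values: np.ndarray | pd.Series, spec: ComparatorSpec, y: np.ndarray | pd.Series
) -> dict[str, float]:
    """Classification metrics of a comparator on its complete subset.

    The ROC-AUC uses the raw values oriented so higher = more diseased;
    other metrics use the fixed-cutoff calls.  ``n_used`` reports the
    complete-case count.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~np.isnan(v) & ~np.isnan(y)
    if not ok.any():
        raise ValueError(f"comparator {spec.name}: all values missing")
    v, y = v[ok], y[ok].astype(int)
    calls = comparator_calls(v, spec).astype(int)
    score = v if spec.direction == "higher_is_case" else -v
    out = classification_metrics(y, calls, score)
    out["n_used"] = int(ok.sum())
    return out


# --------------------------------------------------------------------------
# DeLong


def _placements(y: np.ndarray, score: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and per-sample placement values (midrank / structural components)."""
    cases = score[y == 1]
    controls = score[y == 0]
    m, n = cases.size, controls.size
    tz = stats.rankdata(np.concatenate([cases, controls]), method="average")
    tx = stats.rankdata(cases, method="average")
    ty = stats.rankdata(controls, method="average")
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    return auc, v10, v01


def delong_test(
    p1: np.ndarray, p2: np.ndarray, y: np.ndarray
) -> tuple[float, float, float, float]:
    """DeLong's paired test for two correlated ROC-AUCs.

    Returns (auc1, auc2, z, two-sided p).  Identical predictors yield
    z = 0, p = 1 rather than an error.
    """
    y = np.asarray(y).astype(int)
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.unique(y).size < 2:
        raise ValueError("both classes required for DeLong's test")
    auc1, v10_1, v01_1 = _placements(y, p1)
    auc2, v10_2, v01_2 = _placements(y, p2)
    m, n = v10_1.size, v01_1.size
    s10 = np.cov(np.vstack([v10_1, v10_2]), ddof=1)
    s01 = np.cov(np.vstack([v01_1, v01_2]), ddof=1)
    var_diff = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    if var_diff <= 1e-16:
        return float(auc1), float(auc2), 0.0, 1.0
    z = (auc1 - auc2) / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(auc1), float(auc2), float(z), float(p)


def delong_variance(y: np.ndarray, score: np.ndarray) -> float:
    """DeLong variance of a single AUC (for cross-checks)."""
    y = np.asarray(y).astype(int)
    _, v10, v01 = _placements(y, np.asarray(score, dtype=float))
    return float(np.var(v10, ddof=1) / v10.size + np.var(v01, ddof=1) / v01.size)


# --------------------------------------------------------------------------
# NRI


def nri(
    new_calls: np.ndarray, base_calls: np.ndarray, y: np.ndarray
) -> NRIResult:
    """Class-based NRI of a new model versus a baseline model.

    up = baseline negative reclassified positive; down = the reverse.
    NRI_e = P(up|event) − P(down|event); NRI_ne = P(down|nonevent) −
    P(up|nonevent); NRI = NRI_e + NRI_ne.  With no events (or nonevents)
    the corresponding component and the total are reported missing.
    """
    new = np.asarray(new_calls).astype(int)
    base = np.asarray(base_calls).astype(int)
    y = np.asarray(y).astype(int)
    if not (new.size == base.size == y.size):
        raise ValueError("call vectors and outcomes must align")
    up = (base == 0) & (new == 1)
    down = (base == 1) & (new == 0)
    ev, ne = y == 1, y == 0
    n_ev, n_ne = int(ev.sum()), int(ne.sum())
    nri_e = (up[ev].sum() - down[ev].sum()) / n_ev if n_ev else np.nan
    nri_ne = (down[ne].sum() - up[ne].sum()) / n_ne if n_ne else np.nan
    total = nri_e + nri_ne if n_ev and n_ne else np.nan
    return NRIResult(
        events_up=int(up[ev].sum()),
        events_down=int(down[ev].sum()),
        events_total=n_ev,
        nonevents_up=int(up[ne].sum()),
        nonevents_down=int(down[ne].sum()),
        nonevents_total=n_ne,
        nri_event=float(nri_e),
        nri_nonevent=float(nri_ne),
        nri_total=float(total),
    )


# --------------------------------------------------------------------------
# rule-out


def rule_out_accuracy(
    model: PanelModel, X_population: pd.DataFrame
) -> dict[str, float]:
    """Fraction of a presumed disease-free population classified negative.

    Returns the rule-out fraction with a Clopper–Pearson 95% CI.
    """
    if len(X_population) == 0:
        raise ValueError("empty population")
    probs = predict_risk(model, X_population)
    neg = int((probs < model.cutoff).sum())
    n = len(probs)
    lo, hi = proportion_confint(neg, n, alpha=0.05, method="beta")
    return {
        "fraction_ruled_out": neg / n,
        "ci_lo": float(lo),
        "ci_hi": float(hi),
        "n": n,
    }
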