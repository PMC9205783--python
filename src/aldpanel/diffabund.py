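"""Covariate-adjusted differential abundance and histology correlation.

Two screens per histology factor (fibrosis, inflammation, steatosis):

* ANCOVA — per protein, an OLS model of log2 intensity on the factor as a
  categorical variable plus covariates, tested against the covariates-only
  model with a partial F-test; Benjamini–Hochberg FDR across proteins.
* Spearman partial correlation — rank-based correlation between intensity
  and the ordinal score after residualizing both on the covariates; a
  protein passes the screen at q < 0.05 and |r| ≥ 0.3.

Both share a single design matrix across proteins, so the fits are
vectorized over the whole matrix.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ProteinMatrix

__all__ = [
    "FACTOR_COLUMNS",
    "default_covariates",
    "bh_adjust",
    "ancova_stagewise",
    "spearman_partial_scores",
]

log = logging.getLogger(__name__)

FACTOR_COLUMNS = {
    "fibrosis": "kleiner_f",
    "inflammation": "activity_i",
    "steatosis": "steatosis_s",
}

_COMMON_COVARIATES = ("age", "bmi", "sex", "abstinent")


def default_covariates(factor: str) -> list[str]:
    """Age, BMI, sex and abstinence for every factor; fibrosis and
    inflammation screens additionally adjust for steatosis, and the
    steatosis screen for fibrosis."""
    cov = list(_COMMON_COVARIATES)
    if factor in ("fibrosis", "inflammation"):
        cov.append("steatosis_s")
    elif factor == "steatosis":
        cov.append("kleiner_f")
    else:
        raise ValueError(f"unknown factor {factor!r}")
    return cov


def bh_adjust(p: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _covariate_design(meta: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    """Numeric covariate block: binary fields as 0/1 indicators."""
    cols = {}
    for c in covariates:
        v = meta[c]
        if c == "sex":
            cols[c] = (v == "male").astype(float)
        elif v.dtype == bool or c == "abstinent":
            cols[c] = v.astype(float)
        else:
            cols[c] = pd.to_numeric(v).astype(float)
    return pd.DataFrame(cols, index=meta.index)


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        bad = []
        r = 0
        for j in range(X.shape[1]):
            rj = np.linalg.matrix_rank(X[:, : j + 1])
            if rj == r:
                bad.append(names[j])
            r = rj
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


def _rss(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return np.einsum("ij,ij->j", resid, resid)


def _merge_sparse_levels(factor_vals: np.ndarray) -> np.ndarray:
    """Merge factor levels with < 2 samples into their nearest neighbor."""
    vals = factor_vals.copy()
    while True:
        levels, counts = np.unique(vals, return_counts=True)
        sparse = levels[counts < 2]
        if sparse.size == 0 or levels.size <= 1:
            return vals
        s = sparse[0]
        others = levels[levels != s]
        target = others[np.argmin(np.abs(others - s))]
        warnings.warn(
            f"factor level {s} has < 2 samples; merged into level {target}",
            stacklevel=3,
        )
        vals[vals == s] = target


def ancova_stagewise(
    matrix: ProteinMatrix,
    meta: pd.DataFrame,
    factor: str,
    covariates: list[str] | None = None,
) -> pd.DataFrame:
    """Per-protein partial F-test of the histology factor given covariates.

    Returns a DataFrame indexed by protein with columns ``f_stat``, ``p``,
    ``q``, ``direction`` (sign of top-vs-bottom stage median difference),
    ``significant`` (q < 0.05) and per-stage medians ``median_s<level>``.
    """
    if matrix.scale != "log2":
        raise ValueError("ANCOVA expects a log2 matrix")
    score_col = FACTOR_COLUMNS[factor]
    if covariates is None:
        covariates = default_covariates(factor)

    meta = meta.loc[[s for s in matrix.sample_ids if s in meta.index]]
    cov_df = _covariate_design(meta, covariates)
    score = pd.to_numeric(meta[score_col], errors="coerce")
    ok = score.notna() & cov_df.notna().all(axis=1)
    if not ok.all():
        log.info("ANCOVA %s: dropping %d samples with missing factor or "
                 "covariates", factor, int((~ok).sum()))
    meta, cov_df, score = meta[ok], cov_df[ok], score[ok]
    Y = matrix.data[meta.index].to_numpy().T  # samples × proteins
    if np.isnan(Y).any():
        raise ValueError("ANCOVA requires an imputed (complete) matrix")

    stages = _merge_sparse_levels(score.to_numpy(float))
    levels = np.unique(stages)
    n = len(meta)
    intercept = np.ones((n, 1))
    # one indicator per stage above the baseline level
    dummies = np.column_stack(
        [(stages == lv).astype(float) for lv in levels[1:]]
    ) if levels.size > 1 else np.empty((n, 0))
    X_red = np.column_stack([intercept, cov_df.to_numpy(float)])
    X_full = np.column_stack([X_red, dummies])
    names = ["intercept", *covariates] + [f"stage_{lv:g}" for lv in levels[1:]]
    _check_full_rank(X_full, names)

    rss_f = _rss(X_full, Y)
    rss_r = _rss(X_red, Y)
    df_num = X_full.shape[1] - X_red.shape[1]
    df_den = n - X_full.shape[1]
    if df_num == 0 or df_den <= 0:
        raise ValueError("degenerate design for the partial F-test")
    # floor the denominator at round-off scale so an exactly-fit protein
    # (residuals ~ machine epsilon) yields F = 0, not noise/noise
    centered = Y - Y.mean(axis=0)
    tiny = 1e-12 * np.einsum("ij,ij->j", centered, centered) + 1e-300
    f_stat = (np.maximum(rss_r - rss_f, 0.0) / df_num) / (
        (rss_f + tiny) / df_den
    )
    p = stats.f.sf(f_stat, df_num, df_den)
    q = bh_adjust(p)

    out = pd.DataFrame(
        {"factor": factor, "f_stat": f_stat, "p": p, "q": q},
        index=pd.Index(matrix.protein_ids, name="protein_id"),
    )
    medians = {}
    for lv in levels:
        med = np.median(Y[stages == lv], axis=0)
        medians[lv] = med
        out[f"median_s{lv:g}"] = med
    diff = medians[levels[-1]] - medians[levels[0]]
    out["direction"] = np.sign(diff).astype(int)
    out["significant"] = out["q"] < 0.05
    return out


def spearman_partial_scores(
    matrix: ProteinMatrix,
    meta: pd.DataFrame,
    score_name: str,
    covariates: list[str] | None = None,
    r_threshold: float = 0.3,
) -> pd.DataFrame:
    """Spearman partial correlation of each protein with a histology score.

    Intensity, score and covariates are rank-transformed (average ranks);
    intensity and score ranks are each residualized on the covariate ranks
    and the Pearson correlation of the residuals is reported, with a
    t-distributed p-value on n − 2 − k degrees of freedom.  A protein is
    flagged significant at q < 0.05 and |r| ≥ ``r_threshold``.
    """
    factor = score_name if score_name in FACTOR_COLUMNS else None
    score_col = FACTOR_COLUMNS.get(score_name, score_name)
    if covariates is None:
        covariates = default_covariates(factor) if factor else list(
            _COMMON_COVARIATES
        )

    meta = meta.loc[[s for s in matrix.sample_ids if s in meta.index]]
    cov_df = _covariate_design(meta, covariates)
    score = pd.to_numeric(meta[score_col], errors="coerce")
    ok = score.notna() & cov_df.notna().all(axis=1)
    meta, cov_df, score = meta[ok], cov_df[ok], score[ok]
    Y = matrix.data[meta.index].to_numpy().T
    n, k = len(meta), len(covariates)

    rows = []
    rank = lambda a: stats.rankdata(a, method="average")  # noqa: E731
    score_r = rank(score.to_numpy(float))
    cov_r = (
        np.column_stack([rank(cov_df[c].to_numpy()) for c in covariates])
        if k else np.empty((n, 0))
    )
    Z = np.column_stack([np.ones(n), cov_r])
    # residual-maker applied once to the score ranks
    score_resid = score_r - Z @ np.linalg.lstsq(Z, score_r, rcond=None)[0]
    for i, pid in enumerate(matrix.protein_ids):
        y = Y[:, i]
        use = ~np.isnan(y)
        n_used = int(use.sum())
        if n_used < k + 3:
            warnings.warn(f"protein {pid}: only {n_used} usable samples; skipped")
            continue
        if n_used == n:
            yr = rank(y)
            y_resid = yr - Z @ np.linalg.lstsq(Z, yr, rcond=None)[0]
            s_resid = score_resid
        else:
            yr = rank(y[use])
            sr = rank(score.to_numpy(float)[use])
            Zi = np.column_stack([np.ones(n_used), *(
                [rank(cov_df[c].to_numpy()[use]) for c in covariates]
            )]) if k else np.ones((n_used, 1))
            y_resid = yr - Zi @ np.linalg.lstsq(Zi, yr, rcond=None)[0]
            s_resid = sr - Zi @ np.linalg.lstsq(Zi, sr, rcond=None)[0]
        denom = np.linalg.norm(y_resid) * np.linalg.norm(s_resid)
        r = float(y_resid @ s_resid / denom) if denom > 0 else 0.0
        r = float(np.clip(r, -1.0, 1.0))
        dof = n_used - 2 - k
        if abs(r) < 1.0 and dof > 0:
            t = r * np.sqrt(dof / (1.0 - r**2))
            p = 2.0 * stats.t.sf(abs(t), dof)
        else:
            p = 0.0 if dof > 0 else np.nan
        rows.append({"protein_id": pid, "target": score_name, "r": r,
                     "p": p, "n_used": n_used})
    out = pd.DataFrame(rows).set_index("protein_id")
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = (out["q"] < 0.05) & (out["r"].abs() >= r_threshold)
    return out
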