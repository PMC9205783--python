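"""Marker-panel selection and evaluation.

The modeling protocol: rank features by minimum-redundancy–maximum-
relevance (mRMR), evaluate panel sizes 1..k_max with fivefold cross-
validation repeated ten times (stratified jointly on class label and the
pattern of comparator-data missingness), pick the smallest panel size
attaining the maximal mean F1, and freeze a final L2-logistic model from a
single stratified 80/20 train–test split.

To keep cross-validation honest, the mRMR ranking is recomputed inside each
training fold by default; ranking once on the full data before CV (a
leakage-prone but common shortcut) is available as ``legacy_global_ranking``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "PanelModel",
    "CVReport",
    "missingness_strata",
    "repeated_cv_splits",
    "mrmr_rank",
    "fit_logistic",
    "predict_risk",
    "classify",
    "classification_metrics",
    "mann_whitney_auc",
    "evaluate_panel_sizes",
    "select_panel_size",
    "cv_evaluate",
    "final_fit",
]


# --------------------------------------------------------------------------
# model container


@dataclass
class PanelModel:
    """A frozen logistic marker-panel classifier.

    ``coefficients`` are log-odds per standardized log2-intensity unit; the
    training standardizer (per-protein mean/SD) travels with the model.
    """

    endpoint: str
    panel: list[str]
    intercept: float
    coefficients: np.ndarray
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    cutoff: float = 0.5
    training_fingerprint: str = ""

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        if len(self.panel) != self.coefficients.size:
            raise ValueError("panel and coefficients disagree in length")
        if not 0.0 < self.cutoff < 1.0:
            raise ValueError("cutoff must lie strictly inside (0, 1)")

    def to_json(self, path: str | Path) -> None:
        doc = {
            "endpoint": self.endpoint,
            "panel": self.panel,
            "intercept": self.intercept,
            "coefficients": self.coefficients.tolist(),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "cutoff": self.cutoff,
            "training_fingerprint": self.training_fingerprint,
        }
        Path(path).write_text(json.dumps(doc, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PanelModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            endpoint=doc["endpoint"],
            panel=doc["panel"],
            intercept=doc["intercept"],
            coefficients=np.array(doc["coefficients"]),
            scaler_mean=np.array(doc["scaler_mean"]),
            scaler_scale=np.array(doc["scaler_scale"]),
            cutoff=doc["cutoff"],
            training_fingerprint=doc["training_fingerprint"],
        )


@dataclass
class CVReport:
    """Per-split metrics of a repeated stratified CV plus aggregates."""

    records: pd.DataFrame      # columns repeat, fold, roc_auc, f1, ...
    aggregate: pd.DataFrame    # index metric; columns mean, sd, ci_lo, ci_hi

    @staticmethod
    def from_records(records: pd.DataFrame) -> "CVReport":
        metrics = [c for c in records.columns if c not in ("repeat", "fold", "k")]
        n = len(records)
        rows = {}
        for m in metrics:
            v = records[m].astype(float)
            mean, sd = v.mean(), v.std(ddof=1)
            half = 1.96 * sd / np.sqrt(n)
            rows[m] = {"mean": mean, "sd": sd,
                       "ci_lo": mean - half, "ci_hi": mean + half}
        return CVReport(records, pd.DataFrame(rows).T)


# --------------------------------------------------------------------------
# stratification and splits


def missingness_strata(
    meta: pd.DataFrame,
    considered_vars: list[str],
    min_stratum_size: int = 5,
) -> pd.Series:
    """Pattern-of-missingness key per sample over the considered variables.

    The key is the bit-vector of availability; patterns with fewer members
    than ``min_stratum_size`` (the fold count) are pooled into ``"rare"``.
    """
    if not considered_vars:
        warnings.warn("empty considered_vars: every sample in one stratum")
        return pd.Series("all", index=meta.index, name="stratum")
    missing = [v for v in considered_vars if v not in meta.columns]
    if missing:
        raise KeyError(f"variables not in metadata: {missing}")
    bits = meta[considered_vars].notna().astype(int)
    key = bits.astype(str).agg("".join, axis=1)
    counts = key.value_counts()
    rare = counts.index[counts < min_stratum_size]
    key = key.where(~key.isin(rare), "rare")
    key.name = "stratum"
    return key


def _composite_key(y: np.ndarray, strata: np.ndarray, folds: int) -> np.ndarray:
    """Joint (class × stratum) stratification key, with rare combinations
    pooled within their class so every key holds at least ``folds`` samples."""
    key = np.array([f"{a}|{b}" for a, b in zip(y, strata)], dtype=object)
    while True:
        uniq, counts = np.unique(key, return_counts=True)
        small = uniq[counts < folds]
        if small.size == 0:
            return key
        k = small[0]
        cls = k.split("|", 1)[0]
        same_class = [u for u in uniq if u != k and u.startswith(cls + "|")]
        if not same_class:
            raise ValueError(f"class {cls} has fewer than {folds} members")
        sizes = {u: c for u, c in zip(uniq, counts)}
        target = max(same_class, key=lambda u: sizes[u])
        key[key == k] = target


def repeated_cv_splits(
    labels: np.ndarray | pd.Series,
    strata: np.ndarray | pd.Series | None = None,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """``folds × repeats`` stratified train/test index pairs (positional).

    Each repeat partitions all samples into ``folds`` test folds stratified
    on (class label × missingness stratum); repeats reshuffle independently
    but deterministically from ``seed``.
    """
    y = np.asarray(labels)
    n = y.size
    for cls, cnt in zip(*np.unique(y, return_counts=True)):
        if cnt < folds:
            raise ValueError(f"class {cls!r} has {cnt} < {folds} members")
    s = np.asarray(strata) if strata is not None else np.full(n, "all")
    key = _composite_key(y, s, folds)
    rep_seeds = np.random.default_rng(seed).integers(2**31, size=repeats)
    splits: list[tuple[np.ndarray, np.ndarray]] = []
    for r in range(repeats):
        skf = StratifiedKFold(
            n_splits=folds, shuffle=True, random_state=int(rep_seeds[r])
        )
        for train, test in skf.split(np.zeros(n), key):
            splits.append((train, test))
    return splits


# --------------------------------------------------------------------------
# mRMR


def _anova_f(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """One-way ANOVA F statistic of each column against binary y."""
    f = np.zeros(X.shape[1])
    groups = [X[y == g] for g in np.unique(y)]
    n = X.shape[0]
    grand = X.mean(axis=0)
    ss_between = sum(g.shape[0] * (g.mean(axis=0) - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean(axis=0)) ** 2).sum(axis=0) for g in groups)
    df_b = len(groups) - 1
    df_w = n - len(groups)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_between / df_b) / (ss_within / df_w)
    return np.where(np.isfinite(f), f, 0.0)


def mrmr_rank(
    X: pd.DataFrame, y: np.ndarray | pd.Series, k_max: int = 50
) -> list[str]:
    """Greedy mRMR feature ranking (F-statistic / mean-|Pearson| quotient).

    Relevance of a feature is its one-way ANOVA F against the class;
    redundancy is the mean absolute Pearson correlation with the already
    selected features (floored at 0.001).  The first pick maximizes
    relevance; later picks maximize relevance/redundancy.  Ties break on
    lexicographic feature id; constant features have zero relevance.
    """
    y = np.asarray(y)
    if np.unique(y).size < 2:
        raise ValueError("mRMR needs both classes present")
    if X.isna().any().any():
        raise ValueError("mRMR requires a complete feature matrix")
    feats = list(X.columns)
    Xv = X.to_numpy(float)
    relevance = _anova_f(Xv, y)
    k = min(k_max, len(feats))

    sd = Xv.std(axis=0, ddof=0)
    centered = Xv - Xv.mean(axis=0)

    def pick(scores: np.ndarray, available: np.ndarray) -> int:
        best = None
        for j in np.flatnonzero(available):
            cand = (scores[j], feats[j])
            if best is None or cand[0] > best[0] or (
                cand[0] == best[0] and cand[1] < best[1]
            ):
                best = cand
                best_j = j
        return best_j

    available = np.ones(len(feats), dtype=bool)
    selected: list[int] = []
    redundancy_sum = np.zeros(len(feats))
    order: list[str] = []
    for step in range(k):
        if step == 0:
            scores = relevance.copy()
        else:
            mean_red = redundancy_sum / len(selected)
            scores = relevance / np.maximum(mean_red, 0.001)
        j = pick(scores, available)
        order.append(feats[j])
        selected.append(j)
        available[j] = False
        # update running |corr| sums against the newly selected feature
        with np.errstate(divide="ignore", invalid="ignore"):
            cors = centered.T @ centered[:, j] / (
                len(y) * sd * sd[j]
            )
        cors = np.where(np.isfinite(cors), np.abs(cors), 0.0)
        redundancy_sum += cors
    return order


# --------------------------------------------------------------------------
# logistic panel models


def fit_logistic(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    l2_strength: float = 1.0,
    endpoint: str = "",
    cutoff: float = 0.5,
    fingerprint: str = "",
) -> PanelModel:
    """L2-penalized logistic regression on internally standardized features.

    Maximizes the log-likelihood minus ‖β‖²/(2·l2_strength) with an
    unpenalized intercept, to tight tolerance; features are standardized on
    the training data and the scaler is stored with the model.
    """
    y = np.asarray(y).astype(int)
    Xv = X.to_numpy(float)
    if np.isnan(Xv).any():
        raise ValueError("missing values in the feature matrix")
    mean = Xv.mean(axis=0)
    scale = Xv.std(axis=0, ddof=0)
    scale = np.where(scale == 0, 1.0, scale)
    Z = (Xv - mean) / scale
    clf = LogisticRegression(
        penalty="l2", C=l2_strength, solver="lbfgs",
        max_iter=10_000, tol=1e-10,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(Z, y)
    if clf.n_iter_[0] >= 10_000:
        raise RuntimeError(
            "logistic fit failed to converge in 10000 iterations "
            f"(n={len(y)}, p={Z.shape[1]})"
        )
    return PanelModel(
        endpoint=endpoint,
        panel=list(X.columns),
        intercept=float(clf.intercept_[0]),
        coefficients=clf.coef_[0],
        scaler_mean=mean,
        scaler_scale=scale,
        cutoff=cutoff,
        training_fingerprint=fingerprint,
    )


def predict_risk(model: PanelModel, X: pd.DataFrame) -> pd.Series:
    """Case probability per sample from the frozen model."""
    missing = [p for p in model.panel if p not in X.columns]
    if missing:
        raise KeyError(f"panel proteins absent from input: {missing}")
    Z = (X[model.panel].to_numpy(float) - model.scaler_mean) / model.scaler_scale
    p = expit(model.intercept + Z @ model.coefficients)
    return pd.Series(p, index=X.index, name="risk")


def classify(model: PanelModel, X: pd.DataFrame) -> pd.Series:
    """Binary call: case (1) iff probability ≥ cutoff."""
    return (predict_risk(model, X) >= model.cutoff).astype(int).rename("call")


# --------------------------------------------------------------------------
# metrics


def mann_whitney_auc(y: np.ndarray, score: np.ndarray) -> float:
    """ROC-AUC via the rank-sum relation, half credit for score ties."""
    y = np.asarray(y).astype(int)
    score = np.asarray(score, dtype=float)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = stats.rankdata(score, method="average")
    u = ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def classification_metrics(
    y: np.ndarray, y_hat: np.ndarray, p: np.ndarray | None = None
) -> dict[str, float]:
    """Precision, recall, F1, balanced accuracy, and (if probabilities are
    given) Mann–Whitney ROC-AUC.  With a single-class truth vector the AUC
    is reported missing; empty-denominator rates are 0."""
    y = np.asarray(y).astype(int)
    y_hat = np.asarray(y_hat).astype(int)
    tp = int(((y == 1) & (y_hat == 1)).sum())
    fp = int(((y == 0) & (y_hat == 1)).sum())
    fn = int(((y == 1) & (y_hat == 0)).sum())
    tn = int(((y == 0) & (y_hat == 0)).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if precision + recall
        else 0.0
    )
    sens = recall
    spec = tn / (tn + fp) if tn + fp else 0.0
    out = {
        "precision": precision,
        "recall": recall,
        "f1": f1,
        "balanced_accuracy": (sens + spec) / 2.0,
    }
    if p is not None:
        out["roc_auc"] = mann_whitney_auc(y, p)
    return out


# --------------------------------------------------------------------------
# panel-size evaluation and the final model


def _fit_eval_split(
    X: pd.DataFrame,
    y: np.ndarray,
    train: np.ndarray,
    test: np.ndarray,
    ranking: list[str],
    k: int,
) -> dict[str, float]:
    cols = ranking[:k]
    model = fit_logistic(X.iloc[train][cols], y[train])
    probs = predict_risk(model, X.iloc[test][cols]).to_numpy()
    calls = (probs >= model.cutoff).astype(int)
    return classification_metrics(y[test], calls, probs)


def evaluate_panel_sizes(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    strata: pd.Series | np.ndarray | None = None,
    k_max: int = 50,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    legacy_global_ranking: bool = False,
) -> pd.DataFrame:
    """Mean/SD of F1 and ROC-AUC per panel size k = 1..k_max across the
    repeated CV; mRMR re-ranked inside each training fold unless
    ``legacy_global_ranking`` reproduces the rank-once protocol."""
    y = np.asarray(y).astype(int)
    if k_max > X.shape[1]:
        warnings.warn(
            f"k_max={k_max} exceeds {X.shape[1]} features; truncated"
        )
        k_max = X.shape[1]
    splits = repeated_cv_splits(y, strata, folds, repeats, seed)
    global_ranking = (
        mrmr_rank(X, y, k_max) if legacy_global_ranking else None
    )
    records = []
    for si, (train, test) in enumerate(splits):
        ranking = (
            global_ranking
            if global_ranking is not None
            else mrmr_rank(X.iloc[train], y[train], k_max)
        )
        for k in range(1, k_max + 1):
            m = _fit_eval_split(X, y, train, test, ranking, k)
            records.append(
                {"split": si, "repeat": si // folds, "fold": si % folds,
                 "k": k, **m}
            )
    rec = pd.DataFrame(records)
    agg = rec.groupby("k").agg(
        mean_f1=("f1", "mean"), sd_f1=("f1", "std"),
        mean_roc_auc=("roc_auc", "mean"), sd_roc_auc=("roc_auc", "std"),
    )
    agg.attrs["records"] = rec
    return agg


def select_panel_size(curve: pd.Series | pd.DataFrame) -> int:
    """Smallest k attaining the maximal mean F1 (ties → smallest k)."""
    if isinstance(curve, pd.DataFrame):
        curve = curve["mean_f1"]
    if curve.empty:
        raise ValueError("empty panel-size curve")
    return int(curve.index[np.argmax(curve.to_numpy())])


def cv_evaluate(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    k: int,
    strata: pd.Series | np.ndarray | None = None,
    folds: int = 5,
    repeats: int = 10,
    seed: int = 0,
    legacy_global_ranking: bool = False,
) -> CVReport:
    """Repeated-CV metrics at a fixed panel size ``k``."""
    y = np.asarray(y).astype(int)
    splits = repeated_cv_splits(y, strata, folds, repeats, seed)
    global_ranking = mrmr_rank(X, y, k) if legacy_global_ranking else None
    records = []
    for si, (train, test) in enumerate(splits):
        ranking = (
            global_ranking
            if global_ranking is not None
            else mrmr_rank(X.iloc[train], y[train], k)
        )
        m = _fit_eval_split(X, y, train, test, ranking, k)
        records.append({"repeat": si // folds, "fold": si % folds, **m})
    return CVReport.from_records(pd.DataFrame(records))


def final_fit(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    k_star: int,
    strata: pd.Series | np.ndarray | None = None,
    seed: int = 0,
    endpoint: str = "",
    test_fraction: float = 0.2,
) -> tuple[PanelModel, dict[str, float]]:
    """One stratified 80/20 split; mRMR + logistic fit on the training 80%,
    metrics on the held-out 20%; the returned model is frozen for
    benchmarking, rule-out validation and prognosis."""
    y = np.asarray(y).astype(int)
    folds = max(2, int(round(1.0 / test_fraction)))
    train, test = repeated_cv_splits(y, strata, folds=folds, repeats=1,
                                     seed=seed)[0]
    ranking = mrmr_rank(X.iloc[train], y[train], k_star)
    cols = ranking[:k_star]
    model = fit_logistic(
        X.iloc[train][cols], y[train], endpoint=endpoint,
        fingerprint=f"seed={seed};split=final80/20",
    )
    probs = predict_risk(model, X.iloc[test]).to_numpy()
    calls = (probs >= model.cutoff).astype(int)
    metrics = classification_metrics(y[test], calls, probs)
    metrics["n_train"], metrics["n_test"] = len(train), len(test)
    return model, metrics
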