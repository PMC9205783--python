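"""ANCOVA screen, BH-FDR and Spearman partial correlation, each against an
independent oracle (explicit normal equations, statsmodels, pingouin)."""

import numpy as np
import pandas as pd
import pytest

from aldpanel.diffabund import (
    ancova_stagewise,
    bh_adjust,
    default_covariates,
    spearman_partial_scores,
)
from aldpanel.matrix import ProteinMatrix
from conftest import toy_meta


def _matrix_from(values: np.ndarray, meta: pd.DataFrame, n_prot=None):
    arr = np.atleast_2d(np.asarray(values, dtype=float))
    return ProteinMatrix(
        pd.DataFrame(
            arr,
            index=[f"P{i}" for i in range(arr.shape[0])],
            columns=list(meta.index),
        ),
        scale="log2",
    )


# -- BH ---------------------------------------------------------------------


def test_bh_single_p():
    assert bh_adjust([0.03]) == pytest.approx([0.03])


def test_bh_hand_step_up():
    q = bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])


def test_bh_permutation_equivariance(rng):
    p = rng.random(40)
    q = bh_adjust(p)
    perm = rng.permutation(40)
    assert bh_adjust(p[perm]) == pytest.approx(q[perm])


def test_bh_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    p = rng.random(100) ** 2
    q_ref = multipletests(p, method="fdr_bh")[1]
    assert bh_adjust(p) == pytest.approx(q_ref)


def test_bh_rejects_bad_p():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


# -- ANCOVA -----------------------------------------------------------------


def test_ancova_signal_explained_by_covariate():
    """Intensity = 0.5·age with stage independent of age → F ≈ 0 after
    adjustment."""
    rng = np.random.default_rng(0)
    n = 120
    meta = toy_meta(n, seed=1)
    meta["kleiner_f"] = rng.integers(0, 5, n)
    y = 0.5 * meta["age"].to_numpy(float)
    res = ancova_stagewise(
        _matrix_from(y, meta), meta, "fibrosis", covariates=["age"]
    )
    assert res["f_stat"].iloc[0] < 1e-10
    assert res["p"].iloc[0] > 0.999


def test_ancova_perfect_stage_separation():
    rng = np.random.default_rng(1)
    meta = toy_meta(100, seed=2)
    y = meta["kleiner_f"].astype(float).to_numpy() + rng.normal(0, 0.01, 100)
    res = ancova_stagewise(
        _matrix_from(y, meta), meta, "fibrosis", covariates=["age", "bmi"]
    )
    assert res["p"].iloc[0] < 1e-6
    assert res["direction"].iloc[0] == 1


def test_ancova_matches_normal_equations_oracle():
    """Partial F on a fixed 15-row, 2-covariate toy set, computed through
    explicit normal equations."""
    rng = np.random.default_rng(7)
    n = 15
    meta = toy_meta(n, seed=3)
    meta["kleiner_f"] = np.repeat([0, 1, 2], 5)
    y = rng.normal(20, 1, n) + 0.4 * meta["kleiner_f"].astype(float).to_numpy()
    covs = ["age", "bmi"]
    res = ancova_stagewise(_matrix_from(y, meta), meta, "fibrosis", covs)

    # oracle: beta = (X'X)^{-1} X'y, partial F from the two RSS values
    stage = meta["kleiner_f"].to_numpy(int)
    C = meta[covs].to_numpy(float)
    X_red = np.column_stack([np.ones(n), C])
    X_full = np.column_stack(
        [X_red, (stage == 1).astype(float), (stage == 2).astype(float)]
    )

    def rss(X):
        beta = np.linalg.inv(X.T @ X) @ X.T @ y
        r = y - X @ beta
        return r @ r

    df_num, df_den = 2, n - X_full.shape[1]
    f_oracle = ((rss(X_red) - rss(X_full)) / df_num) / (rss(X_full) / df_den)
    from scipy.stats import f as fdist

    assert res["f_stat"].iloc[0] == pytest.approx(f_oracle, rel=1e-10)
    assert res["p"].iloc[0] == pytest.approx(
        fdist.sf(f_oracle, df_num, df_den), rel=1e-10
    )


def test_ancova_matches_pingouin():
    """Cross-check against the general-purpose ANCOVA implementation."""
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(11)
    n = 60
    meta = toy_meta(n, seed=4)
    meta["kleiner_f"] = rng.integers(0, 3, n)
    y = rng.normal(20, 1, n) + 0.3 * meta["kleiner_f"].astype(float).to_numpy()
    res = ancova_stagewise(
        _matrix_from(y, meta), meta, "fibrosis", covariates=["age", "bmi"]
    )
    df = pd.DataFrame({
        "y": y,
        "stage": meta["kleiner_f"].astype(int).to_numpy(),
        "age": meta["age"].to_numpy(float),
        "bmi": meta["bmi"].to_numpy(float),
    })
    ref = pingouin.ancova(data=df, dv="y", between="stage",
                          covar=["age", "bmi"])
    row = ref[ref["Source"] == "stage"].iloc[0]
    assert res["f_stat"].iloc[0] == pytest.approx(row["F"], rel=1e-6)
    assert res["p"].iloc[0] == pytest.approx(row["p_unc"], rel=1e-6)


def test_ancova_merges_sparse_stage_levels():
    meta = toy_meta(30, seed=5)
    stages = np.zeros(30, dtype=int)
    stages[:14] = 0
    stages[14:29] = 2
    stages[29] = 4  # single sample at stage 4 → merged into stage 2
    meta["kleiner_f"] = stages
    with pytest.warns(UserWarning, match="merged"):
        res = ancova_stagewise(
            _matrix_from(np.random.default_rng(0).normal(20, 1, 30), meta),
            meta, "fibrosis", covariates=["age"],
        )
    assert 0 <= res["p"].iloc[0] <= 1


def test_ancova_rank_deficient_design_rejected():
    meta = toy_meta(20, seed=6)
    meta["bmi2"] = meta["bmi"] * 2.0
    with pytest.raises(ValueError, match="collinear.*bmi2"):
        ancova_stagewise(
            _matrix_from(np.ones(20) * 20, meta), meta, "fibrosis",
            covariates=["bmi", "bmi2"],
        )


def test_default_covariate_sets():
    assert default_covariates("fibrosis") == [
        "age", "bmi", "sex", "abstinent", "steatosis_s"
    ]
    assert default_covariates("steatosis")[-1] == "kleiner_f"


# -- Spearman partial -------------------------------------------------------


def test_partial_reduces_to_plain_spearman():
    from scipy.stats import spearmanr

    rng = np.random.default_rng(3)
    meta = toy_meta(40, seed=7)
    y = rng.normal(20, 1, 40)
    res = spearman_partial_scores(
        _matrix_from(y, meta), meta, "fibrosis", covariates=[]
    )
    r_ref, p_ref = spearmanr(y, meta["kleiner_f"].astype(float))
    assert res["r"].iloc[0] == pytest.approx(r_ref, abs=1e-10)
    assert res["p"].iloc[0] == pytest.approx(p_ref, rel=1e-6)


def test_monotone_transform_gives_r_one():
    meta = toy_meta(30, seed=8)
    y = np.exp(meta["steatosis_s"].astype(float).to_numpy())
    y += np.linspace(0, 1e-6, 30)  # break rank ties deterministically
    res = spearman_partial_scores(
        _matrix_from(y, meta), meta, "steatosis", covariates=[]
    )
    assert res["r"].iloc[0] > 0.9


def test_rank_invariance_under_monotone_intensity_transform():
    meta = toy_meta(50, seed=9)
    rng = np.random.default_rng(4)
    y = rng.normal(20, 2, 50)
    covs = ["age", "bmi"]
    r1 = spearman_partial_scores(_matrix_from(y, meta), meta, "fibrosis",
                                 covs)["r"].iloc[0]
    r2 = spearman_partial_scores(_matrix_from(np.exp(y / 5), meta), meta,
                                 "fibrosis", covs)["r"].iloc[0]
    assert r1 == pytest.approx(r2, abs=1e-12)


def test_partial_matches_pingouin_residualization():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(5)
    meta = toy_meta(12, seed=10)
    y = rng.normal(20, 1, 12)
    res = spearman_partial_scores(
        _matrix_from(y, meta), meta, "fibrosis", covariates=["age", "bmi"]
    )
    df = pd.DataFrame({
        "y": y,
        "score": meta["kleiner_f"].astype(float).to_numpy(),
        "age": meta["age"].to_numpy(float),
        "bmi": meta["bmi"].to_numpy(float),
    })
    ref = pingouin.partial_corr(data=df, x="y", y="score",
                                covar=["age", "bmi"], method="spearman")
    assert res["r"].iloc[0] == pytest.approx(ref["r"].iloc[0], abs=1e-8)
    assert res["p"].iloc[0] == pytest.approx(ref["p_val"].iloc[0], rel=1e-4)
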