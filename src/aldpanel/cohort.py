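"""Synthetic ALD-like cohorts with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: a biopsied subset with the derivation cohort's fibrosis-stage
distribution, inflammation/steatosis scores coupled to fibrosis through a
Gaussian copula, stage-responsive "planted" plasma proteins on a log2 scale,
abundance-dependent (MNAR) dropout, a paired liver matrix for a subset of
patients, noisy clinical comparator tests with realistic availability
patterns, and right-censored time-to-event outcomes.

Everything is deterministic given ``CohortConfig.seed``; each component
(histology, proteome, dropout, outcomes, ...) draws from a named substream
so modules can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import expit, ndtri
from scipy.stats import norm

from ._rng import substream
from .matrix import ProteinMatrix
from .meta import derive_activity_score, validate_meta

__all__ = [
    "CohortConfig",
    "GroundTruth",
    "generate_cohort",
    "apply_mnar_dropout",
    "generate_outcomes",
    "generate_qc_replicates",
    "two_class_gaussian_cohort",
]

# Derivation-cohort histology score distributions (counts).
STAGE_DISTRIBUTION = (36, 124, 106, 27, 67)          # fibrosis F0..F4
ACTIVITY_DISTRIBUTION = (72, 91, 82, 53, 31, 23)     # I0..I5
STEATOSIS_DISTRIBUTION = (156, 85, 72, 39)           # S0..S3
BALLOONING_DISTRIBUTION = (178, 108, 66)             # 0..2


@dataclass(frozen=True)
class CohortConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the derivation cohort: 459 patients of whom 360 are
    biopsied with fibrosis stages 36/124/106/27/67, 76% male, 42% abstinent,
    ~22% with a paired liver proteome, 13 analytical QC replicates, and a
    follow-up horizon of 60 months.
    """

    n_patients: int = 459
    stage_distribution: tuple[int, ...] = STAGE_DISTRIBUTION
    n_proteins: int = 500
    n_markers: int = 9                 # planted fibrosis-responsive proteins
    n_markers_inflammation: int | None = None   # default: n_markers
    n_markers_steatosis: int | None = None      # default: n_markers
    effect_slope: float = 0.5          # log2 units per stage step
    noise_sd: float = 0.5              # log2 units
    mnar_midpoint: float = 19.0        # log2 intensity of 50% dropout
    mnar_steepness: float = 1.0        # 1/log2 units
    liver_pair_fraction: float = 0.22
    qc_replicates: int = 13
    qc_cv: float = 0.19
    hazard_base: float = 4e-4          # LRE events per month at stage 0
    hazard_log_hr_per_stage: float = 0.6
    death_hr_attenuation: float = 0.5
    censor_months: float = 60.0
    copula_r_inflammation: float = 0.6
    copula_r_steatosis: float = 0.3
    baseline_range: tuple[float, float] = (18.0, 30.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_patients, self.n_proteins, self.qc_replicates) < 0:
            raise ValueError("counts must be nonnegative")
        if any(c < 0 for c in self.stage_distribution):
            raise ValueError("stage counts must be nonnegative")
        if sum(self.stage_distribution) == 0:
            raise ValueError("stage_distribution sums to zero")
        if sum(self.stage_distribution) > self.n_patients:
            raise ValueError("biopsied subset exceeds n_patients")
        if not 0.0 <= self.liver_pair_fraction <= 1.0:
            raise ValueError("liver_pair_fraction outside [0, 1]")

    @property
    def markers_per_axis(self) -> dict[str, int]:
        return {
            "fibrosis": self.n_markers,
            "inflammation": (
                self.n_markers
                if self.n_markers_inflammation is None
                else self.n_markers_inflammation
            ),
            "steatosis": (
                self.n_markers
                if self.n_markers_steatosis is None
                else self.n_markers_steatosis
            ),
        }


@dataclass
class GroundTruth:
    """What the generator planted, for recovery tests."""

    markers: dict[str, list[str]]            # axis -> planted protein ids
    slopes: dict[str, pd.Series]             # axis -> per-protein true slope
    latent_stage: pd.Series                  # incl. unbiopsied patients
    event_hazard: pd.Series                  # per-patient LRE rate (/month)


# --------------------------------------------------------------------------
# histology and covariates


def _scores_from_copula(
    z_f: np.ndarray, rho: float, counts: tuple[int, ...], rng: np.random.Generator
) -> np.ndarray:
    """Ordinal scores rank-coupled to the fibrosis latent via a copula."""
    z = rho * z_f + np.sqrt(1.0 - rho**2) * rng.standard_normal(z_f.size)
    u = norm.cdf(z)
    probs = np.asarray(counts, dtype=float)
    cuts = np.cumsum(probs / probs.sum())[:-1]
    return np.searchsorted(cuts, u).astype(int)


def _latent_from_stage(stage: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Latent normal scores consistent with the stage distribution."""
    order = np.argsort(stage, kind="stable")
    n = stage.size
    # uniform positions within each stage's cumulative band, jittered
    u = (np.arange(n) + rng.uniform(0.2, 0.8, n)) / (n + 1)
    z = np.empty(n)
    z[order] = ndtri(u)
    return z


def _split_activity(
    activity: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Decompose activity I into (lobular 0–3, ballooning 0–2) uniformly."""
    lob = np.empty_like(activity)
    bal = np.empty_like(activity)
    for i, a in enumerate(activity):
        b_lo, b_hi = max(0, a - 3), min(2, a)
        bal[i] = rng.integers(b_lo, b_hi + 1)
        lob[i] = a - bal[i]
    return lob, bal


def _comparators(
    stage: np.ndarray,
    activity: np.ndarray,
    steatosis: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Noisy monotone transforms of the histology scores.

    Scales are test-specific (kPa-like for elastography, index-like for
    serum scores); per-patient availability follows a small set of
    missingness patterns, as in routine clinical data.
    """
    n = stage.size
    e = lambda sd: rng.normal(0.0, sd, n)  # noqa: E731
    vals = pd.DataFrame(
        {
            "cmp_te": np.exp(1.45 + 0.33 * stage + e(0.30)),
            "cmp_swe": np.exp(1.65 + 0.28 * stage + e(0.30)),
            "cmp_elf": 8.2 + 0.75 * stage + e(0.70),
            "cmp_fib4": np.exp(-0.25 + 0.35 * stage + e(0.40)),
            "cmp_apri": np.exp(-1.25 + 0.40 * stage + e(0.50)),
            "cmp_aar": 0.80 + 0.15 * activity + e(0.25),
            "cmp_alt": np.exp(3.20 + 0.18 * activity + e(0.40)),
            "cmp_cap": 245.0 + 25.0 * steatosis + e(30.0),
        }
    )
    # availability patterns: all tests; no SWE; no CAP; serum-only; sparse
    patterns = [
        {},
        {"cmp_swe"},
        {"cmp_cap"},
        {"cmp_te", "cmp_swe", "cmp_cap"},
        {"cmp_swe", "cmp_elf", "cmp_cap"},
    ]
    which = rng.choice(len(patterns), size=n, p=[0.45, 0.15, 0.15, 0.1, 0.15])
    for i, k in enumerate(which):
        for col in patterns[k]:
            vals.iloc[i, vals.columns.get_loc(col)] = np.nan
    return vals


# --------------------------------------------------------------------------
# proteome


def _plant_markers(
    cfg: CohortConfig, protein_ids: list[str], rng: np.random.Generator
) -> tuple[dict[str, list[str]], dict[str, np.ndarray]]:
    """Disjoint random marker sets per lesion axis with signed slopes."""
    per_axis = cfg.markers_per_axis
    total = sum(per_axis.values())
    if total > cfg.n_proteins:
        raise ValueError("more planted markers than proteins")
    chosen = rng.choice(cfg.n_proteins, size=total, replace=False)
    markers: dict[str, list[str]] = {}
    slopes: dict[str, np.ndarray] = {}
    offset = 0
    for axis, m in per_axis.items():
        idx = chosen[offset : offset + m]
        offset += m
        markers[axis] = [protein_ids[i] for i in idx]
        s = np.zeros(cfg.n_proteins)
        signs = rng.choice([-1.0, 1.0], size=m)
        s[idx] = signs * cfg.effect_slope
        slopes[axis] = s
    return markers, slopes


def _complete_log2(
    cfg: CohortConfig,
    baselines: np.ndarray,
    slopes: dict[str, np.ndarray],
    scores: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> np.ndarray:
    """Pre-dropout log2 intensities: baseline + Σ_axis slope·score + noise."""
    n = next(iter(scores.values())).size
    x = np.tile(baselines[:, None], (1, n))
    for axis, s in slopes.items():
        x += s[:, None] * scores[axis][None, :]
    x += rng.normal(0.0, cfg.noise_sd, size=x.shape)
    return x


def generate_cohort(
    cfg: CohortConfig,
) -> tuple[ProteinMatrix, ProteinMatrix, pd.DataFrame, GroundTruth]:
    """Generate (plasma, liver, metadata, ground truth).

    The biopsied subset receives fibrosis stages exactly matching
    ``cfg.stage_distribution``; remaining patients model the low-stiffness
    unbiopsied subset (histology missing, latent stage drawn from {0, 1}).
    Plasma and liver matrices are returned on the linear scale with MNAR
    dropout already applied to the plasma matrix.
    """
    n_biopsied = sum(cfg.stage_distribution)
    n = cfg.n_patients
    patient_ids = [f"P{i:04d}" for i in range(n)]
    protein_ids = [f"PROT{i:04d}" for i in range(cfg.n_proteins)]

    rng_h = substream(cfg.seed, "histology")
    # exact stage counts, shuffled over the biopsied subset
    stage_b = np.repeat(np.arange(5), cfg.stage_distribution)
    rng_h.shuffle(stage_b)
    biopsied = np.zeros(n, dtype=bool)
    biopsied[rng_h.choice(n, size=n_biopsied, replace=False)] = True
    latent = np.empty(n, dtype=int)
    latent[biopsied] = stage_b
    latent[~biopsied] = rng_h.choice([0, 1], size=n - n_biopsied, p=[0.55, 0.45])

    z_f = _latent_from_stage(latent.astype(float), rng_h)
    activity = _scores_from_copula(
        z_f, cfg.copula_r_inflammation, ACTIVITY_DISTRIBUTION, rng_h
    )
    steatosis = _scores_from_copula(
        z_f, cfg.copula_r_steatosis, STEATOSIS_DISTRIBUTION, rng_h
    )
    lobular, ballooning = _split_activity(activity, rng_h)

    rng_c = substream(cfg.seed, "covariates")
    age = np.clip(np.round(rng_c.normal(57.0, 9.6, n)), 18, 75).astype(int)
    bmi = np.round(27.4 * np.exp(rng_c.normal(0.0, 0.18, n)), 1)
    sex = np.where(rng_c.random(n) < 0.76, "male", "female")
    abstinent = rng_c.random(n) < 0.42

    meta = pd.DataFrame(
        {
            "cohort": "derivation",
            "age": age,
            "bmi": bmi,
            "sex": sex,
            "abstinent": abstinent,
            "kleiner_f": pd.array(
                np.where(biopsied, latent, -1), dtype="Int64"
            ),
            "lobular": pd.array(np.where(biopsied, lobular, -1), dtype="Int64"),
            "ballooning": pd.array(
                np.where(biopsied, ballooning, -1), dtype="Int64"
            ),
            "steatosis_s": pd.array(
                np.where(biopsied, steatosis, -1), dtype="Int64"
            ),
        },
        index=pd.Index(patient_ids, name="sample_id"),
    )
    for col in ("kleiner_f", "lobular", "ballooning", "steatosis_s"):
        meta[col] = meta[col].mask(meta[col] < 0)
    meta = derive_activity_score(meta)

    rng_cmp = substream(cfg.seed, "comparators")
    cmp_df = _comparators(
        latent.astype(float),
        activity.astype(float),
        steatosis.astype(float),
        rng_cmp,
    )
    cmp_df.index = meta.index
    meta = pd.concat([meta, cmp_df.round(2)], axis=1)

    # proteome --------------------------------------------------------------
    rng_p = substream(cfg.seed, "proteome")
    lo, hi = cfg.baseline_range
    baselines = rng_p.uniform(lo, hi, cfg.n_proteins)
    markers, slopes = _plant_markers(cfg, protein_ids, rng_p)
    # planted markers sit in the reliably quantified abundance range
    for axis in markers:
        idx = [protein_ids.index(p) for p in markers[axis]]
        baselines[idx] = rng_p.uniform(cfg.mnar_midpoint + 2.0, hi, len(idx))

    scores = {
        "fibrosis": latent.astype(float),
        "inflammation": activity.astype(float),
        "steatosis": steatosis.astype(float),
    }
    plasma_log2 = _complete_log2(cfg, baselines, slopes, scores, rng_p)
    plasma_complete = ProteinMatrix(
        pd.DataFrame(plasma_log2, index=protein_ids, columns=patient_ids),
        scale="log2",
    )
    plasma = apply_mnar_dropout(
        plasma_complete, cfg.mnar_midpoint, cfg.mnar_steepness,
        seed=int(substream(cfg.seed, "dropout").integers(2**31)),
    ).to_linear()

    # liver matrix for a paired subset of biopsied patients -----------------
    rng_l = substream(cfg.seed, "liver")
    biopsied_ids = [pid for pid, b in zip(patient_ids, biopsied) if b]
    n_pairs = int(round(cfg.liver_pair_fraction * len(biopsied_ids)))
    pair_ids = sorted(
        rng_l.choice(biopsied_ids, size=n_pairs, replace=False).tolist()
    )
    pair_pos = [patient_ids.index(p) for p in pair_ids]
    liver_base = rng_l.uniform(lo, hi, cfg.n_proteins)
    liver_log2 = np.tile(liver_base[:, None], (1, len(pair_ids)))
    for axis, s in slopes.items():
        liver_log2 += s[:, None] * scores[axis][pair_pos][None, :]
    liver_log2 += rng_l.normal(0.0, cfg.noise_sd, size=liver_log2.shape)
    liver = ProteinMatrix(
        pd.DataFrame(liver_log2, index=protein_ids, columns=pair_ids),
        scale="log2",
    ).to_linear()

    # outcomes --------------------------------------------------------------
    meta["latent_stage"] = latent
    meta = generate_outcomes(
        meta,
        cfg.hazard_base,
        cfg.hazard_log_hr_per_stage,
        cfg.censor_months,
        seed=int(substream(cfg.seed, "outcomes").integers(2**31)),
        death_attenuation=cfg.death_hr_attenuation,
        stage_col="latent_stage",
    )
    hazard = cfg.hazard_base * np.exp(cfg.hazard_log_hr_per_stage * latent)
    meta = meta.drop(columns=["latent_stage"])

    truth = GroundTruth(
        markers=markers,
        slopes={
            axis: pd.Series(s, index=protein_ids) for axis, s in slopes.items()
        },
        latent_stage=pd.Series(latent, index=meta.index),
        event_hazard=pd.Series(hazard, index=meta.index),
    )
    return plasma, liver, validate_meta(meta), truth


# --------------------------------------------------------------------------
# dropout, outcomes, QC


def apply_mnar_dropout(
    matrix: ProteinMatrix, midpoint: float, steepness: float, seed: int
) -> ProteinMatrix:
    """Remove cells with probability logistic(−steepness·(x − midpoint)).

    Low-abundance (log2) cells drop out preferentially, the missingness
    mechanism that motivates downshifted-normal imputation.
    """
    if matrix.scale != "log2":
        raise ValueError("MNAR dropout operates on a log2-scale matrix")
    rng = np.random.default_rng(seed)
    x = matrix.data.to_numpy().copy()
    p_drop = expit(-steepness * (x - midpoint))
    drop = rng.random(x.shape) < p_drop
    x[drop] = np.nan
    return ProteinMatrix(
        pd.DataFrame(x, index=matrix.data.index, columns=matrix.data.columns),
        scale="log2",
    )


def generate_outcomes(
    meta: pd.DataFrame,
    hazard_base: float,
    hazard_log_hr_per_stage: float,
    censor_months: float,
    seed: int,
    death_attenuation: float = 0.5,
    stage_col: str = "kleiner_f",
) -> pd.DataFrame:
    """Exponential event times with stage-dependent hazard, censored.

    LRE rate for a patient at stage s is
    ``hazard_base · exp(hazard_log_hr_per_stage · s)``; all-cause death uses
    the same base rate with the stage coefficient attenuated.  Follow-up
    ends at death or administrative censoring, whichever is first, and LREs
    are only observed within follow-up.
    """
    if hazard_base < 0 or censor_months < 0:
        raise ValueError("rates and horizons must be nonnegative")
    stage = pd.to_numeric(meta[stage_col], errors="coerce").to_numpy(float)
    if np.isnan(stage).any():
        raise ValueError("fibrosis stage required for every patient")
    rng = np.random.default_rng(seed)
    n = len(meta)
    rate_lre = hazard_base * np.exp(hazard_log_hr_per_stage * stage)
    rate_death = hazard_base * np.exp(
        death_attenuation * hazard_log_hr_per_stage * stage
    )
    t_lre = rng.exponential(1.0, n) / np.maximum(rate_lre, 1e-300)
    t_death = rng.exponential(1.0, n) / np.maximum(rate_death, 1e-300)
    followup = np.minimum(t_death, censor_months)
    meta = meta.copy()
    meta["followup_months"] = np.round(followup, 2)
    meta["death"] = t_death <= censor_months
    lre_time = np.minimum(t_lre, followup)
    meta["lre_time_months"] = np.round(lre_time, 2)
    meta["lre_event"] = t_lre <= followup
    return meta


def generate_qc_replicates(cfg: CohortConfig, seed: int | None = None) -> ProteinMatrix:
    """Analytical QC replicates: one profile + multiplicative lognormal noise.

    The lognormal sigma is chosen so the per-protein coefficient of
    variation of the linear intensities targets ``cfg.qc_cv``.
    """
    rng = substream(cfg.seed if seed is None else seed, "qc")
    lo, hi = cfg.baseline_range
    profile = np.exp2(rng.uniform(lo, hi, cfg.n_proteins))
    sigma = np.sqrt(np.log1p(cfg.qc_cv**2))
    cols = [f"QC{i + 1:02d}" for i in range(cfg.qc_replicates)]
    noise = (
        rng.lognormal(0.0, sigma, size=(cfg.n_proteins, cfg.qc_replicates))
        if sigma > 0
        else np.ones((cfg.n_proteins, cfg.qc_replicates))
    )
    data = pd.DataFrame(
        profile[:, None] * noise,
        index=[f"PROT{i:04d}" for i in range(cfg.n_proteins)],
        columns=cols,
    )
    return ProteinMatrix(data, scale="linear")


# --------------------------------------------------------------------------
# closed-form two-class benchmark


def two_class_gaussian_cohort(
    n: int,
    n_features: int,
    n_informative: int,
    delta: float,
    sigma: float,
    seed: int,
    case_fraction: float = 0.5,
) -> tuple[pd.DataFrame, pd.Series, float]:
    """Two-class Gaussian features with a closed-form Bayes ROC-AUC.

    Informative features differ in mean by ``delta`` between classes with
    common within-class SD ``sigma``; the optimal linear score then has
    AUC = Φ(√(Σ(δ/σ)²) / √2), returned as the third element.
    """
    rng = np.random.default_rng(seed)
    y = (rng.random(n) < case_fraction).astype(int)
    X = rng.normal(0.0, sigma, size=(n, n_features))
    X[:, :n_informative] += delta * y[:, None]
    d = np.sqrt(n_informative) * delta / sigma
    bayes_auc = float(norm.cdf(d / np.sqrt(2.0)))
    cols = [f"F{i:03d}" for i in range(n_features)]
    idx = pd.Index([f"S{i:04d}" for i in range(n)], name="sample_id")
    return (
        pd.DataFrame(X, index=idx, columns=cols),
        pd.Series(y, index=idx, name="label"),
        bayes_auc,
    )
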