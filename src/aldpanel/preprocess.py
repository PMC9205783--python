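"""Matrix QC and imputation.

The fixed order of the preprocessing pipeline is: minimum-proteins sample
filter → 60%-valid-values protein filter → log2 transform → QC-CV protein
filter → downshifted-normal imputation.  Imputation replaces each missing
cell of a sample with a draw from a normal distribution whose mean is
downshifted by 1.8 sample SDs and whose SD is scaled to 0.3 of the sample
SD, the standard treatment of MNAR dropout in DIA proteomics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ProteinMatrix

__all__ = [
    "ImputeParams",
    "log2_transform",
    "filter_min_proteins",
    "filter_valid_values",
    "impute_downshifted",
    "qc_cv_filter",
    "run_preprocess",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ImputeParams:
    """Downshifted-normal imputation parameters.

    ``shift`` — downshift of the imputation mean, in multiples of the
    per-sample SD of observed log2 intensities (default 1.8).
    ``width`` — SD of the imputation distribution as a fraction of the
    per-sample SD (default 0.3).
    """

    shift: float = 1.8
    width: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shift < 0:
            raise ValueError("shift must be nonnegative")
        if not 0 < self.width <= 1:
            raise ValueError("width must be in (0, 1]")


def log2_transform(matrix: ProteinMatrix) -> ProteinMatrix:
    """Log2-transform a linear matrix; the missingness mask is unchanged."""
    if matrix.scale == "log2":
        raise ValueError("matrix already log2 transformed")
    return matrix.to_log2()


def filter_min_proteins(matrix: ProteinMatrix, min_count: int = 200) -> ProteinMatrix:
    """Drop samples quantifying fewer than ``min_count`` proteins (≥ keeps)."""
    counts = matrix.mask().sum(axis=0)
    keep = counts >= min_count
    if not keep.any():
        raise ValueError(f"no sample has ≥ {min_count} quantified proteins")
    out = ProteinMatrix(matrix.data.loc[:, keep], matrix.scale)
    log.info(
        "min-proteins filter: %d → %d samples", matrix.shape[1], out.shape[1]
    )
    return out


def filter_valid_values(matrix: ProteinMatrix, min_frac: float = 0.6) -> ProteinMatrix:
    """Drop proteins observed in less than ``min_frac`` of samples (≥ keeps)."""
    frac = matrix.mask().mean(axis=1)
    keep = frac >= min_frac - 1e-12
    if not keep.any():
        raise ValueError("valid-values filter removed every protein")
    out = ProteinMatrix(matrix.data.loc[keep], matrix.scale)
    log.info(
        "valid-values filter (≥%.0f%%): %d → %d proteins",
        100 * min_frac, matrix.shape[0], out.shape[0],
    )
    return out


def impute_downshifted(matrix: ProteinMatrix, params: ImputeParams) -> ProteinMatrix:
    """Replace missing cells with per-sample downshifted normal draws.

    For sample *s* with observed mean m_s and SD d_s, missing cells are
    drawn i.i.d. from Normal(m_s − shift·d_s, (width·d_s)²).  Observed
    cells are untouched; parameters come from observed values only.
    """
    if matrix.scale != "log2":
        raise ValueError("imputation operates on a log2-scale matrix")
    x = matrix.data.to_numpy().copy()
    rng = np.random.default_rng(params.seed)
    for j, sid in enumerate(matrix.sample_ids):
        col = x[:, j]
        obs = ~np.isnan(col)
        if obs.sum() < 2:
            raise ValueError(
                f"sample {sid!r} has fewer than 2 observed values; "
                "SD undefined"
            )
        miss = ~obs
        if not miss.any():
            continue
        m = col[obs].mean()
        d = col[obs].std(ddof=1)
        col[miss] = rng.normal(
            m - params.shift * d, params.width * d, size=int(miss.sum())
        )
    return ProteinMatrix(
        pd.DataFrame(x, index=matrix.data.index, columns=matrix.data.columns),
        scale="log2",
    )


def qc_cv_filter(
    matrix: ProteinMatrix,
    qc: ProteinMatrix,
    max_cv: float = 0.30,
) -> tuple[ProteinMatrix, pd.DataFrame]:
    """Drop proteins whose CV across QC replicates exceeds ``max_cv``.

    CV = SD/mean of linear-scale QC intensities (missing QC cells ignored).
    Returns the filtered matrix and a per-protein report with the CV and
    the reason a protein was removed; proteins with fewer than 2 observed
    QC values cannot be assessed and are removed and reported.
    """
    if qc.shape[1] < 2:
        raise ValueError("need at least 2 QC replicate columns")
    qc_lin = qc.to_linear().data.reindex(matrix.protein_ids)
    n_obs = qc_lin.notna().sum(axis=1)
    mean = qc_lin.mean(axis=1)
    sd = qc_lin.std(axis=1, ddof=1)
    cv = sd / mean
    report = pd.DataFrame({"cv": cv, "n_qc": n_obs})
    report["status"] = "kept"
    report.loc[cv > max_cv, "status"] = "high_cv"
    report.loc[n_obs < 2, "status"] = "unassessable"
    keep = report["status"] == "kept"
    if not keep.any():
        raise ValueError("QC-CV filter removed every protein")
    out = ProteinMatrix(matrix.data.loc[keep], matrix.scale)
    log.info("QC-CV filter (≤%.0f%%): %d → %d proteins",
             100 * max_cv, matrix.shape[0], out.shape[0])
    return out, report


def run_preprocess(
    matrix: ProteinMatrix,
    qc: ProteinMatrix | None = None,
    min_proteins: int = 200,
    min_valid_frac: float = 0.6,
    max_qc_cv: float = 0.30,
    impute: ImputeParams = ImputeParams(),
) -> ProteinMatrix:
    """Full preprocessing pipeline in the fixed order; returns a complete
    (no missing cells) log2 matrix ready for statistics and modeling."""
    m = matrix if matrix.scale == "linear" else matrix.to_linear()
    m = filter_min_proteins(m, min_proteins)
    m = filter_valid_values(m, min_valid_frac)
    m = log2_transform(m)
    if qc is not None:
        m, _ = qc_cv_filter(m, qc, max_qc_cv)
    return impute_downshifted(m, impute)
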