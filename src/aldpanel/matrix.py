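"""Protein quantification matrices.

A :class:`ProteinMatrix` is a proteins × samples grid of MS intensities with
explicit missingness (NaN) and a scale flag.  On the linear scale every
present intensity is strictly positive; ``log2`` marks a matrix that has
already been log-transformed, guarding against double transforms.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ProteinMatrix", "read_protein_matrix", "write_protein_matrix"]

#: Cell tokens treated as missing on read (Spectronaut/MaxQuant dialects).
MISSING_TOKENS = ("", "NA", "NaN", "nan", "Filtered")

#: Header metadata flag marking an already log2-transformed export.
_LOG2_FLAG = "#scale=log2"


@dataclass
class ProteinMatrix:
    """Proteins × samples intensity matrix with explicit missing cells.

    Parameters
    ----------
    data
        DataFrame indexed by protein id, columns sample ids, NaN = missing.
    scale
        ``"linear"`` (raw MS intensities, all present values > 0) or
        ``"log2"``.
    """

    data: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        if self.scale not in ("linear", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        self.data = self.data.astype(float)
        _check_unique(self.data.index, "protein")
        _check_unique(self.data.columns, "sample")
        if self.scale == "linear":
            vals = self.data.to_numpy()
            bad = np.asarray((vals <= 0) & ~np.isnan(vals)).nonzero()
            if bad[0].size:
                i, j = bad[0][0], bad[1][0]
                raise ValueError(
                    "nonpositive linear intensity at protein "
                    f"{self.data.index[i]!r}, sample {self.data.columns[j]!r}"
                )

    # -- convenience -------------------------------------------------------
    @property
    def protein_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def mask(self) -> pd.DataFrame:
        """Boolean DataFrame, True where a value is present."""
        return self.data.notna()

    def copy(self) -> "ProteinMatrix":
        return ProteinMatrix(self.data.copy(), self.scale)

    def to_log2(self) -> "ProteinMatrix":
        if self.scale == "log2":
            raise ValueError("matrix is already on the log2 scale")
        return ProteinMatrix(np.log2(self.data), "log2")

    def to_linear(self) -> "ProteinMatrix":
        if self.scale == "linear":
            return self.copy()
        return ProteinMatrix(np.exp2(self.data), "linear")


def _check_unique(idx: pd.Index, what: str) -> None:
    if idx.has_duplicates:
        dup = idx[idx.duplicated()][0]
        raise ValueError(f"duplicate {what} identifier {dup!r}")


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_protein_matrix(
    path: str | Path, orientation: str = "proteins_in_rows"
) -> ProteinMatrix:
    """Read a delimited intensity matrix (TSV or CSV by extension).

    Empty cells, ``NA``, ``NaN`` and ``Filtered`` are treated as missing.
    A first line ``#scale=log2`` marks a log2 export; otherwise intensities
    are taken as linear.  Duplicate identifiers, non-numeric cells and
    nonpositive linear values raise ``ValueError`` naming the offender.
    """
    path = Path(path)
    if orientation not in ("proteins_in_rows", "samples_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    text = path.read_text()
    scale = "linear"
    if text.startswith(_LOG2_FLAG):
        scale = "log2"
        text = text.split("\n", 1)[1]
    sep = _sep_for(path)
    df = pd.read_csv(
        io.StringIO(text),
        sep=sep,
        index_col=0,
        na_values=list(MISSING_TOKENS),
        keep_default_na=False,
        dtype=str,
    )
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    num = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().nonzero()[0][0]]
            raise ValueError(
                f"non-numeric cell at row {row!r}, column {col!r}: "
                f"{df.loc[row, col]!r}"
            )
        num[col] = converted
    if orientation == "samples_in_rows":
        num = num.T
    return ProteinMatrix(num, scale=scale)


def write_protein_matrix(matrix: ProteinMatrix, path: str | Path) -> None:
    """Write proteins-in-rows TSV/CSV; missing cells are empty fields.

    Values use ``repr`` precision so a read→write→read round trip is exact.
    A log2 matrix gets a ``#scale=log2`` header line.
    """
    path = Path(path)
    sep = _sep_for(path)
    with open(path, "w") as fh:
        if matrix.scale == "log2":
            fh.write(_LOG2_FLAG + "\n")
        fh.write("protein_id" + sep + sep.join(matrix.sample_ids) + "\n")
        vals = matrix.data.to_numpy()
        for i, pid in enumerate(matrix.protein_ids):
            cells = [
                "" if np.isnan(v) else repr(float(v)) for v in vals[i]
            ]
            fh.write(str(pid) + sep + sep.join(cells) + "\n")
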