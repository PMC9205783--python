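"""Liver–plasma integration.

Per-protein Pearson correlation between paired liver and plasma log2
intensities across patients, identification of proteins co-dysregulated in
both compartments, and annotation-category (liver-specific / secreted)
direction fractions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .diffabund import bh_adjust
from .matrix import ProteinMatrix

__all__ = ["pair_correlation", "codysregulated", "annotation_fractions",
           "abundance_map"]


def pair_correlation(
    liver: ProteinMatrix,
    plasma: ProteinMatrix,
    pairing: dict[str, str] | None = None,
    r_threshold: float = 0.3,
) -> pd.DataFrame:
    """Pearson r per common protein across paired patients.

    ``pairing`` maps liver sample ids to plasma sample ids (default: shared
    identifiers).  Pairs with either value missing are dropped; proteins
    with fewer than 3 complete pairs get a missing r.  Significance:
    q < 0.05 and |r| > ``r_threshold``.
    """
    if pairing is None:
        shared = [s for s in liver.sample_ids if s in set(plasma.sample_ids)]
        pairing = {s: s for s in shared}
    if len(set(pairing.values())) != len(pairing):
        raise ValueError("pairing is not one-to-one")
    liv = liver if liver.scale == "log2" else liver.to_log2()
    pla = plasma if plasma.scale == "log2" else plasma.to_log2()
    common = [p for p in liv.protein_ids if p in set(pla.protein_ids)]
    L = liv.data.loc[common, list(pairing.keys())].to_numpy()
    P = pla.data.loc[common, list(pairing.values())].to_numpy()

    rows = []
    for i, pid in enumerate(common):
        ok = ~np.isnan(L[i]) & ~np.isnan(P[i])
        n_pairs = int(ok.sum())
        if n_pairs < 3:
            rows.append({"protein_id": pid, "r": np.nan, "p": np.nan,
                         "n_pairs": n_pairs})
            continue
        r, p = stats.pearsonr(L[i, ok], P[i, ok])
        rows.append({"protein_id": pid, "r": float(r), "p": float(p),
                     "n_pairs": n_pairs})
    out = pd.DataFrame(rows).set_index("protein_id")
    tested = out["p"].notna()
    q = np.full(len(out), np.nan)
    q[tested.to_numpy()] = bh_adjust(out.loc[tested, "p"].to_numpy())
    out["q"] = q
    out["significant"] = (out["q"] < 0.05) & (out["r"].abs() > r_threshold)
    return out


def codysregulated(
    diff_liver: pd.DataFrame, diff_plasma: pd.DataFrame, factor: str
) -> pd.DataFrame:
    """Proteins significant in both compartments for the same factor.

    Each member is annotated ``concordant`` (same direction in liver and
    plasma) or ``discordant`` (opposite), the pattern seen for e.g. tetra-
    nectin (CLEC3B) versus vitronectin in diseased liver versus blood.
    """
    for df in (diff_liver, diff_plasma):
        if not (df["factor"] == factor).all():
            raise ValueError(f"differential results are not all for {factor!r}")
    sig_l = diff_liver.index[diff_liver["significant"]]
    sig_p = diff_plasma.index[diff_plasma["significant"]]
    both = sig_l.intersection(sig_p)
    out = pd.DataFrame(
        {
            "direction_liver": diff_liver.loc[both, "direction"],
            "direction_plasma": diff_plasma.loc[both, "direction"],
        }
    )
    out["concordance"] = np.where(
        out["direction_liver"] * out["direction_plasma"] >= 0,
        "concordant",
        "discordant",
    )
    out.index.name = "protein_id"
    return out.sort_index()


def annotation_fractions(
    diff: pd.DataFrame, annotations: dict[str, str]
) -> pd.DataFrame:
    """Up/down fractions of significant proteins per annotation category.

    Proteins absent from the annotation table count as ``other``.  With an
    empty significant set the fractions are reported missing.
    """
    sig = diff[diff["significant"]]
    cats = pd.Series(
        [annotations.get(p, "other") for p in sig.index], index=sig.index
    )
    cats = cats.where(cats.isin(["liver_specific", "secreted"]), "other")
    rows = []
    for cat in ("liver_specific", "secreted", "other"):
        sub = sig[cats == cat]
        n = len(sub)
        if n == 0:
            rows.append({"category": cat, "n": 0,
                         "frac_up": np.nan, "frac_down": np.nan})
        else:
            up = float((sub["direction"] > 0).mean())
            down = float((sub["direction"] < 0).mean())
            rows.append({"category": cat, "n": n,
                         "frac_up": up, "frac_down": down})
    return pd.DataFrame(rows).set_index("category")


def abundance_map(liver: ProteinMatrix, plasma: ProteinMatrix) -> pd.DataFrame:
    """Median log2 intensity per protein in liver vs plasma (common set)."""
    liv = liver if liver.scale == "log2" else liver.to_log2()
    pla = plasma if plasma.scale == "log2" else plasma.to_log2()
    common = [p for p in liv.protein_ids if p in set(pla.protein_ids)]
    return pd.DataFrame(
        {
            "median_liver_log2": liv.data.loc[common].median(axis=1),
            "median_plasma_log2": pla.data.loc[common].median(axis=1),
        }
    )
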