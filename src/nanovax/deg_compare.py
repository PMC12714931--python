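"""Comparison statistics between two differentially-expressed-gene sets.

Given two DE result tables sharing (part of) a gene universe, the module
selects DEG sets by strict fold-change and FDR thresholds (|log2FC| > 0.5,
padj < 0.1 by default), then quantifies their agreement on the shared
universe: overlap size, one-sided Fisher's exact test for overlap
enrichment, percentage of shared DEGs with concordant regulation
direction, and Pearson correlation of log2 fold changes over the overlap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["DEGSet", "ComparisonMetrics", "select_degs", "compare"]

_REQUIRED = ("log2FoldChange", "padj")


@dataclass
class DEGSet:
    """A DE table plus the DEG subset selected from it."""

    table: pd.DataFrame  # indexed by gene id; log2FoldChange, padj
    degs: frozenset[str]
    lfc_thr: float
    fdr_thr: float

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(self.table.index)


@dataclass(frozen=True)
class ComparisonMetrics:
    universe_size: int
    n_deg_a: int
    n_deg_b: int
    overlap: int
    fisher_p: float
    concordance_pct: float | None  # None when the overlap is empty
    pearson_r: float | None  # None when the overlap has < 2 genes

    def as_dict(self) -> dict:
        return {
            "universe_size": self.universe_size,
            "n_deg_a": self.n_deg_a,
            "n_deg_b": self.n_deg_b,
            "overlap": self.overlap,
            "fisher_p": self.fisher_p,
            "concordance_pct": self.concordance_pct,
            "pearson_r": self.pearson_r,
        }


def select_degs(
    de_table: pd.DataFrame, lfc_thr: float = 0.5, fdr_thr: float = 0.1
) -> DEGSet:
    """DEGs by strict thresholds: |log2FC| > lfc_thr and padj < fdr_thr."""
    missing = [c for c in _REQUIRED if c not in de_table.columns]
    if missing:
        raise ValueError(f"DE table missing columns: {missing}")
    mask = (de_table["log2FoldChange"].abs() > lfc_thr) & (de_table["padj"] < fdr_thr)
    return DEGSet(
        table=de_table,
        degs=frozenset(de_table.index[mask]),
        lfc_thr=lfc_thr,
        fdr_thr=fdr_thr,
    )


def compare(a: DEGSet, b: DEGSet) -> ComparisonMetrics:
    """Agreement metrics over the shared gene universe.

    The universes are intersected first and both DEG sets restricted to
    the intersection. Fisher's exact test is one-sided for enrichment on
    the 2x2 in-A x in-B table.
    """
    universe = a.universe & b.universe
    n = len(universe)
    if n == 0:
        raise ValueError("the two tables share no genes")
    deg_a = a.degs & universe
    deg_b = b.degs & universe
    shared = deg_a & deg_b
    k, na, nb = len(shared), len(deg_a), len(deg_b)
    table = np.array([[k, na - k], [nb - k, n - na - nb + k]])
    _, fisher_p = stats.fisher_exact(table, alternative="greater")

    if k == 0:
        concordance = None
    else:
        genes = sorted(shared)
        sign_a = np.sign(a.table.loc[genes, "log2FoldChange"].to_numpy())
        sign_b = np.sign(b.table.loc[genes, "log2FoldChange"].to_numpy())
        concordance = 100.0 * float(np.mean(sign_a == sign_b))

    if k < 2:
        pearson = None
    else:
        genes = sorted(shared)
        lfc_a = a.table.loc[genes, "log2FoldChange"].to_numpy(dtype=float)
        lfc_b = b.table.loc[genes, "log2FoldChange"].to_numpy(dtype=float)
        if np.ptp(lfc_a) == 0 or np.ptp(lfc_b) == 0:
            pearson = None
        else:
            pearson = float(stats.pearsonr(lfc_a, lfc_b).statistic)

    return ComparisonMetrics(
        universe_size=n,
        n_deg_a=na,
        n_deg_b=nb,
        overlap=k,
        fisher_p=float(fisher_p),
        concordance_pct=concordance,
        pearson_r=pearson,
    )
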