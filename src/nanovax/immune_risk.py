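"""Compartment-specific immune activation risk index with bootstrap CIs.

The risk index is a semi-quantitative off-target activation score per
immune compartment (B cells, T cells, plasma cells/Ig, memory T, cytotoxic
T, epithelium):

    risk_index = delta_auc * n_upregulated_markers

where ``delta_auc`` is the compartment's targeted-minus-untargeted
cumulative immune activation (an upstream mechanistic-simulation output,
supplied via configuration) and ``n_upregulated_markers`` counts the
compartment's marker genes called significantly upregulated by the
differential-expression stage.

Uncertainty is quantified by a nonparametric bootstrap over the
compartment's marker genes (resampled with replacement, B = 1000 by
default) with a percentile interval.

The shipped ``DEFAULT_DELTA_AUC`` values are synthetic fixture numbers, not
simulator outputs: they are chosen to preserve the qualitative compartment
ordering (Ig highest, EP lowest) of the reference mechanistic simulations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._seeds import stage_rng
from .transcriptome_sim import DEFAULT_MARKERS

__all__ = [
    "DEFAULT_DELTA_AUC",
    "CompartmentSpec",
    "RiskIndexResult",
    "default_compartments",
    "count_upregulated_markers",
    "risk_index",
    "bootstrap_ci",
    "risk_table",
]

#: Synthetic per-compartment delta-AUC fixture values (simulation units).
#: They preserve the reference ordering Ig > T > Tmem > TC > B > EP.
DEFAULT_DELTA_AUC: Mapping[str, float] = {
    "Ig": 1.4,
    "T": 1.2,
    "Tmem": 1.1,
    "TC": 0.9,
    "B": 0.8,
    "EP": 0.6,
}


@dataclass(frozen=True)
class CompartmentSpec:
    """One immune compartment: its marker genes and delta-AUC coefficient."""

    name: str
    marker_gene_ids: tuple[str, ...]
    delta_auc: float

    def __post_init__(self) -> None:
        if not self.marker_gene_ids:
            raise ValueError(f"compartment {self.name}: empty marker list")
        if len(set(self.marker_gene_ids)) != len(self.marker_gene_ids):
            raise ValueError(f"compartment {self.name}: duplicate marker ids")
        if self.delta_auc < 0:
            raise ValueError(f"compartment {self.name}: delta_auc must be >= 0")


@dataclass(frozen=True)
class RiskIndexResult:
    compartment: str
    n_upregulated: int
    delta_auc: float
    risk_index: float
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int | None = None


def default_compartments() -> list[CompartmentSpec]:
    """The default six-compartment configuration (synthetic delta-AUC fixture)."""
    return [
        CompartmentSpec(name, tuple(DEFAULT_MARKERS[name]), DEFAULT_DELTA_AUC[name])
        for name in DEFAULT_DELTA_AUC
    ]


def _upregulation_indicators(
    de_table: pd.DataFrame, compartment: CompartmentSpec, fdr: float
) -> np.ndarray:
    """0/1 per marker gene: significantly upregulated at the FDR threshold.

    Markers absent from the DE table count as 0 (with a warning).
    """
    missing = [g for g in compartment.marker_gene_ids if g not in de_table.index]
    if missing:
        warnings.warn(
            f"compartment {compartment.name}: markers absent from DE table "
            f"count as not upregulated: {missing}",
            UserWarning,
            stacklevel=3,
        )
    indicators = np.zeros(len(compartment.marker_gene_ids), dtype=int)
    for i, gene in enumerate(compartment.marker_gene_ids):
        if gene in de_table.index:
            row = de_table.loc[gene]
            indicators[i] = int(row["padj"] < fdr and row["log2FoldChange"] > 0)
    return indicators


def count_upregulated_markers(
    de_table: pd.DataFrame, compartment: CompartmentSpec, fdr: float = 0.05
) -> int:
    """Number of the compartment's markers with padj < fdr and log2FC > 0."""
    return int(_upregulation_indicators(de_table, compartment, fdr).sum())


def risk_index(
    compartment: CompartmentSpec, de_table: pd.DataFrame, fdr: float = 0.05
) -> RiskIndexResult:
    """Point estimate: delta_auc times the upregulated-marker count."""
    n_up = count_upregulated_markers(de_table, compartment, fdr)
    return RiskIndexResult(
        compartment=compartment.name,
        n_upregulated=n_up,
        delta_auc=compartment.delta_auc,
        risk_index=compartment.delta_auc * n_up,
    )


def bootstrap_ci(
    compartment: CompartmentSpec,
    de_table: pd.DataFrame,
    fdr: float = 0.05,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
    return_samples: bool = False,
):
    """Percentile bootstrap CI for the risk index.

    Marker genes are resampled with replacement (same size as the marker
    set) and the risk index recomputed per resample. Deterministic given
    the seed. With ``return_samples=True`` the tuple also carries the B
    bootstrap risk-index values.
    """
    if B < 100:
        raise ValueError("use at least B=100 bootstrap resamples")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    indicators = _upregulation_indicators(de_table, compartment, fdr)
    m = indicators.size
    if m == 1:
        warnings.warn(
            f"compartment {compartment.name}: single marker — bootstrap CI is "
            "degenerate (supported on {0, delta_auc})",
            UserWarning,
            stacklevel=2,
        )
    rng = stage_rng(seed, f"immune_risk/{compartment.name}")
    resamples = rng.integers(0, m, size=(B, m))
    boot = compartment.delta_auc * indicators[resamples].sum(axis=1)
    lo, hi = np.percentile(boot, [100 * (1 - level) / 2, 100 * (1 + level) / 2])
    if return_samples:
        return float(lo), float(hi), boot
    return float(lo), float(hi)


def risk_table(
    compartments: Sequence[CompartmentSpec],
    de_table: pd.DataFrame,
    fdr: float = 0.05,
    B: int = 1000,
    level: float = 0.95,
    seed: int = 0,
) -> pd.DataFrame:
    """Risk index with bootstrap CI for every compartment, as a table."""
    rows = []
    for comp in compartments:
        point = risk_index(comp, de_table, fdr)
        lo, hi = bootstrap_ci(comp, de_table, fdr=fdr, B=B, level=level, seed=seed)
        rows.append(
            {
                "compartment": comp.name,
                "n_upregulated": point.n_upregulated,
                "delta_auc": comp.delta_auc,
                "risk_index": point.risk_index,
                "ci_low": lo,
                "ci_high": hi,
            }
        )
    return pd.DataFrame(rows).set_index("compartment")
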