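"""Truth-labelled synthetic bulk RNA-seq counts for a two-arm vaccination study.

The generator emulates a post-vaccination transcriptional response in a
small bulk RNA-seq experiment: 300 genes by default, measured in 5 Control
and 5 Post-Vaccination samples. Three kinds of signal genes are planted on
top of a flat background:

* ``designed_up`` / ``designed_down`` — genes whose post-vaccination mean is
  shifted up or down relative to control (30 each by default);
* ``marker`` — named immune marker genes (CD19, MS4A1 for B cells; CD3D,
  CD8A, CD4 for T cells; IGHG1, IGHM, PRDM1 for plasma cells; plus
  configurable memory-T, cytotoxic-T and epithelial markers), all
  upregulated post-vaccination to mimic canonical immune activation.

Expression values are drawn from normal distributions with group-specific
means, truncated at zero (transcript abundance cannot be negative) and then
rounded to the nearest integer so that downstream count-based tests apply.
The truth table carries every gene's class and generating parameters, which
makes the matrix usable as a benchmarking ground truth for differential
expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._seeds import stage_rng

__all__ = [
    "GENE_CLASSES",
    "DEFAULT_MARKERS",
    "GeneSpec",
    "SimConfig",
    "ExpressionMatrix",
    "build_gene_catalog",
    "simulate_expression",
]

GENE_CLASSES = ("background", "designed_up", "designed_down", "marker")

#: Compartment -> marker gene ids. B/T/plasma-cell (Ig) markers are the
#: canonical ones; memory-T (Tmem), cytotoxic (TC) and epithelial (EP)
#: markers are package defaults, configurable via ``SimConfig.markers``.
DEFAULT_MARKERS: Mapping[str, tuple[str, ...]] = {
    "B": ("CD19", "MS4A1"),
    "T": ("CD3D", "CD8A", "CD4"),
    "Ig": ("IGHG1", "IGHM", "PRDM1"),
    "Tmem": ("IL7R", "CCR7"),
    "TC": ("GZMB", "PRF1"),
    "EP": ("EPCAM", "KRT18"),
}

CONTROL = "Control"
POST = "PostVaccination"


@dataclass(frozen=True)
class GeneSpec:
    """Generating parameters and ground-truth class for one gene."""

    gene_id: str
    gene_class: str
    mu_control: float
    mu_post: float
    sigma: float
    compartment: Optional[str] = None

    def __post_init__(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"unknown gene class {self.gene_class!r}")
        if self.mu_control < 0 or self.mu_post < 0:
            raise ValueError(f"{self.gene_id}: negative mean expression")
        if self.sigma <= 0:
            raise ValueError(f"{self.gene_id}: sigma must be positive")
        if self.gene_class == "background" and self.mu_post != self.mu_control:
            raise ValueError(f"{self.gene_id}: background genes must be unshifted")
        if self.gene_class in ("designed_up", "marker") and not self.mu_post > self.mu_control:
            raise ValueError(f"{self.gene_id}: {self.gene_class} requires mu_post > mu_control")
        if self.gene_class == "designed_down" and not self.mu_post < self.mu_control:
            raise ValueError(f"{self.gene_id}: designed_down requires mu_post < mu_control")


@dataclass
class SimConfig:
    """Study design and effect sizes for the synthetic RNA-seq draw.

    Defaults reproduce the reference design: 300 genes, 5 + 5 samples,
    30 designed-up (100 -> 300) and 30 designed-down (100 -> 30) genes,
    markers 50 -> 200, all with normal SD 15 — effect sizes large enough
    that every designed gene is detectable at FDR < 0.05 with n = 5/group.
    """

    n_genes: int = 300
    n_up: int = 30
    n_down: int = 30
    n_control: int = 5
    n_post: int = 5
    baseline_mean: float = 100.0
    sigma: float = 15.0
    up_mean_control: float = 100.0
    up_mean_post: float = 300.0
    down_mean_control: float = 100.0
    down_mean_post: float = 30.0
    marker_mean_control: float = 50.0
    marker_mean_post: float = 200.0
    markers: Mapping[str, Sequence[str]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in DEFAULT_MARKERS.items()}
    )
    seed: int = 0

    @property
    def n_markers(self) -> int:
        return sum(len(v) for v in self.markers.values())

    def validate(self) -> None:
        if min(self.n_genes, self.n_up, self.n_down) < 0:
            raise ValueError("gene counts must be non-negative")
        if self.n_control < 1 or self.n_post < 1:
            raise ValueError("each group needs at least one sample")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_up + self.n_down + self.n_markers > self.n_genes:
            raise ValueError(
                "n_up + n_down + markers exceeds n_genes "
                f"({self.n_up}+{self.n_down}+{self.n_markers} > {self.n_genes})"
            )
        marker_ids = [g for genes in self.markers.values() for g in genes]
        if len(marker_ids) != len(set(marker_ids)):
            raise ValueError("duplicate marker gene ids across compartments")


@dataclass
class ExpressionMatrix:
    """Gene-by-sample integer counts with sample groups and per-gene truth."""

    counts: pd.DataFrame  # index gene_id, columns sample_id, int
    groups: pd.Series  # index sample_id -> {Control, PostVaccination}
    truth: pd.DataFrame  # index gene_id; gene_class, compartment, mu_control, mu_post, sigma

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if not self.counts.index.is_unique:
            raise ValueError("gene ids must be unique")
        if list(self.counts.columns) != list(self.groups.index):
            raise ValueError("sample sheet does not match count columns")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def write_dir(self, out_dir: str | Path) -> dict[str, Path]:
        """Write counts.tsv, samples.tsv and truth.tsv; return the paths."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "counts": out / "counts.tsv",
            "samples": out / "samples.tsv",
            "truth": out / "truth.tsv",
        }
        self.counts.rename_axis("gene_id").to_csv(paths["counts"], sep="\t")
        self.groups.rename("group").rename_axis("sample_id").to_csv(paths["samples"], sep="\t")
        self.truth.rename_axis("gene_id").to_csv(paths["truth"], sep="\t")
        return paths

    @classmethod
    def read_dir(cls, in_dir: str | Path) -> "ExpressionMatrix":
        indir = Path(in_dir)
        counts = pd.read_csv(indir / "counts.tsv", sep="\t", index_col="gene_id")
        samples = pd.read_csv(indir / "samples.tsv", sep="\t", index_col="sample_id")
        truth = pd.read_csv(indir / "truth.tsv", sep="\t", index_col="gene_id")
        return cls(counts=counts, groups=samples["group"], truth=truth)


def build_gene_catalog(config: SimConfig) -> list[GeneSpec]:
    """Lay out the full gene catalog for one simulated experiment.

    Deterministic given the config: markers come first (in compartment
    order), then designed-up, designed-down, and background filler genes.
    """
    config.validate()
    specs: list[GeneSpec] = []
    for compartment, genes in config.markers.items():
        for gene_id in genes:
            specs.append(
                GeneSpec(
                    gene_id=gene_id,
                    gene_class="marker",
                    compartment=compartment,
                    mu_control=config.marker_mean_control,
                    mu_post=config.marker_mean_post,
                    sigma=config.sigma,
                )
            )
    for i in range(config.n_up):
        specs.append(
            GeneSpec(
                gene_id=f"UP_{i + 1:03d}",
                gene_class="designed_up",
                mu_control=config.up_mean_control,
                mu_post=config.up_mean_post,
                sigma=config.sigma,
            )
        )
    for i in range(config.n_down):
        specs.append(
            GeneSpec(
                gene_id=f"DOWN_{i + 1:03d}",
                gene_class="designed_down",
                mu_control=config.down_mean_control,
                mu_post=config.down_mean_post,
                sigma=config.sigma,
            )
        )
    n_background = config.n_genes - len(specs)
    for i in range(n_background):
        specs.append(
            GeneSpec(
                gene_id=f"BG_{i + 1:03d}",
                gene_class="background",
                mu_control=config.baseline_mean,
                mu_post=config.baseline_mean,
                sigma=config.sigma,
            )
        )
    ids = [s.gene_id for s in specs]
    if len(ids) != len(set(ids)):
        raise ValueError("overlapping gene ids in catalog")
    return specs


def simulate_expression(catalog: Sequence[GeneSpec], config: SimConfig) -> ExpressionMatrix:
    """Draw the count matrix: Normal(mu_group, sigma), truncated at 0, rounded.

    Truncation happens before rounding so the result is guaranteed
    non-negative. The draw is fully determined by ``config.seed``.
    """
    config.validate()
    rng = stage_rng(config.seed, "transcriptome_sim")
    sample_ids = [f"Ctrl_{i + 1}" for i in range(config.n_control)] + [
        f"Post_{i + 1}" for i in range(config.n_post)
    ]
    groups = pd.Series(
        [CONTROL] * config.n_control + [POST] * config.n_post,
        index=pd.Index(sample_ids, name="sample_id"),
        name="group",
    )
    mu = np.empty((len(catalog), len(sample_ids)))
    sigma = np.empty((len(catalog), 1))
    for i, spec in enumerate(catalog):
        mu[i, : config.n_control] = spec.mu_control
        mu[i, config.n_control :] = spec.mu_post
        sigma[i, 0] = spec.sigma
    draws = rng.normal(loc=mu, scale=sigma)
    counts = np.rint(np.clip(draws, 0.0, None)).astype(np.int64)
    counts_df = pd.DataFrame(
        counts,
        index=pd.Index([s.gene_id for s in catalog], name="gene_id"),
        columns=sample_ids,
    )
    truth = pd.DataFrame(
        {
            "gene_class": [s.gene_class for s in catalog],
            "compartment": [s.compartment for s in catalog],
            "mu_control": [s.mu_control for s in catalog],
            "mu_post": [s.mu_post for s in catalog],
            "sigma": [s.sigma for s in catalog],
        },
        index=counts_df.index,
    )
    return ExpressionMatrix(counts=counts_df, groups=groups, truth=truth)
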