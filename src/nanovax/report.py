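"""End-to-end orchestration, summary figures and a machine-readable report.

``run_all`` executes both arms of the framework from one config —
transcriptomics (simulate -> differential expression -> risk indexing) and
formulation design (sample -> surrogate -> genetic algorithm) — writes
every table to the output directory and returns a ``RunReport`` whose
manifest (file checksums) makes reruns verifiable.

The plotting helpers render the three summary views: the ranked top-k bar
plot, a z-scored parameter heatmap with hierarchical row clustering
(average linkage, Euclidean distance), and a Spearman correlation matrix
of the continuous parameters.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from . import diffexpr, ga_opt, immune_risk, lnp_space, surrogate, transcriptome_sim
from .config import PipelineConfig

__all__ = [
    "RunReport",
    "run_all",
    "plot_topk_ranking",
    "plot_topk_heatmap",
    "plot_spearman_matrix",
]


@dataclass
class RunReport:
    config_echo: dict
    de_summary: dict
    risk_table: pd.DataFrame
    surrogate_metrics: dict
    importances: pd.Series
    topk: pd.DataFrame
    manifest: dict[str, str] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "config": self.config_echo,
            "de_summary": self.de_summary,
            "risk_index": self.risk_table.reset_index().to_dict(orient="records"),
            "surrogate": self.surrogate_metrics,
            "feature_importance": self.importances.to_dict(),
            "ga_top_k": self.topk.to_dict(orient="records"),
            "manifest": self.manifest,
        }
        Path(path).write_text(json.dumps(doc, indent=2, default=_jsonable))


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(config: PipelineConfig | None = None, out_dir: str | Path = "nanovax_run") -> RunReport:
    """Run the full pipeline from one config; write artifacts; return the report."""
    if config is None:
        config = PipelineConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    # --- transcriptomics arm -------------------------------------------------
    catalog = transcriptome_sim.build_gene_catalog(config.rnaseq)
    matrix = transcriptome_sim.simulate_expression(catalog, config.rnaseq)
    written.extend(matrix.write_dir(out).values())

    de = diffexpr.wald_test(matrix)
    de_path = out / "de_results.tsv"
    de.rename_axis("gene_id").to_csv(de_path, sep="\t")
    written.append(de_path)

    truth = matrix.truth
    up_called = diffexpr.significant_up(de, config.diffexpr.fdr)
    down_called = diffexpr.significant_down(de, config.diffexpr.fdr)
    designed_up = truth.index[truth["gene_class"] == "designed_up"]
    designed_down = truth.index[truth["gene_class"] == "designed_down"]
    de_summary = {
        "fdr": config.diffexpr.fdr,
        "n_designed_up": int(len(designed_up)),
        "n_designed_down": int(len(designed_down)),
        "n_designed_up_recovered": int(designed_up.isin(up_called).sum()),
        "n_designed_down_recovered": int(designed_down.isin(down_called).sum()),
        "n_significant_total": int((de["padj"] < config.diffexpr.fdr).sum()),
    }

    risk = immune_risk.risk_table(
        config.compartments,
        de,
        fdr=config.diffexpr.fdr,
        B=config.risk.bootstrap_B,
        level=config.risk.ci_level,
        seed=config.seed,
    )
    risk_path = out / "risk_index.tsv"
    risk.to_csv(risk_path, sep="\t")
    written.append(risk_path)

    # --- formulation arm -----------------------------------------------------
    dataset = lnp_space.sample_formulations(
        n=config.lnp.n, seed=config.seed, noise_sd=config.lnp.noise_sd, scheme=config.lnp.scheme
    )
    lnp_path = out / "lnp_dataset.csv"
    dataset.to_csv(lnp_path)
    written.append(lnp_path)

    train, valid = surrogate.split_dataset(dataset, config.surrogate.train_frac, seed=config.seed)
    model = surrogate.train_rf(
        train,
        n_trees=config.surrogate.n_trees,
        min_leaf=config.surrogate.min_leaf,
        max_depth=config.surrogate.max_depth,
        seed=config.seed,
    )
    metrics = surrogate.evaluate(model, valid)
    importances = surrogate.feature_importance(model)

    ga_result = ga_opt.run_ga(model, config.ga)
    topk_path = out / "ga_top_k.csv"
    ga_result.top_k.to_csv(topk_path, index=False)
    written.append(topk_path)
    trace_path = out / "ga_trace.csv"
    ga_result.trace.to_csv(trace_path, index=False)
    written.append(trace_path)

    # --- figures -------------------------------------------------------------
    written.append(plot_topk_ranking(ga_result.top_k, out / "fig_topk_ranking.png"))
    written.append(plot_topk_heatmap(ga_result.top_k, out / "fig_topk_heatmap.png"))
    fig_path, spearman = plot_spearman_matrix(ga_result.top_k, out / "fig_spearman.png")
    written.append(fig_path)
    spearman_path = out / "spearman_matrix.tsv"
    spearman.to_csv(spearman_path, sep="\t")
    written.append(spearman_path)

    report = RunReport(
        config_echo={
            "seed": config.seed,
            "n_genes": config.rnaseq.n_genes,
            "n_lnp": config.lnp.n,
            "ga": {
                "pop_size": config.ga.pop_size,
                "generations": config.ga.generations,
                "p_crossover": config.ga.p_crossover,
                "p_mutation": config.ga.p_mutation,
            },
        },
        de_summary=de_summary,
        risk_table=risk,
        surrogate_metrics={
            "rmse": metrics.rmse,
            "r2": metrics.r2,
            "n_train": metrics.n_train,
            "n_valid": metrics.n_valid,
        },
        importances=importances,
        topk=ga_result.top_k,
        manifest={str(p.relative_to(out)): _sha256(p) for p in written},
    )
    report.to_json(out / "run_report.json")
    return report


# --- figures ------------------------------------------------------------------

_CONTINUOUS = ["size_nm", "charge_mV", "peg_molpct", "predicted_delta_auc"]


def plot_topk_ranking(topk: pd.DataFrame, path: str | Path) -> Path:
    """Bar plot of predicted delta-AUC by candidate rank (non-increasing)."""
    if len(topk) == 0:
        raise ValueError("empty top-k table")
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(topk["rank"].astype(str), topk["predicted_delta_auc"], color="#4878A8")
    ax.set_xlabel("GA rank")
    ax.set_ylabel("predicted ΔAUC")
    ax.set_title("Top formulations ranked by predicted ΔAUC")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def zscore_columns(frame: pd.DataFrame) -> pd.DataFrame:
    """Column z-scores; zero-variance columns become 0 with a warning."""
    out = {}
    for col in frame.columns:
        x = frame[col].to_numpy(dtype=float)
        sd = x.std(ddof=0)
        if sd == 0:
            warnings.warn(f"zero-variance column {col!r}; z-scores set to 0", UserWarning)
            out[col] = np.zeros_like(x)
        else:
            out[col] = (x - x.mean()) / sd
    return pd.DataFrame(out, index=frame.index)


def plot_topk_heatmap(topk: pd.DataFrame, path: str | Path) -> Path:
    """Z-scored parameter heatmap with average-linkage row clustering."""
    if len(topk) == 0:
        raise ValueError("empty top-k table")
    cols = [c for c in _CONTINUOUS if c in topk.columns]
    z = zscore_columns(topk[cols])
    if len(z) > 1:
        order = hierarchy.leaves_list(
            hierarchy.linkage(z.to_numpy(), method="average", metric="euclidean")
        )
        z = z.iloc[order]
        labels = topk["rank"].iloc[order] if "rank" in topk.columns else z.index
    else:
        labels = topk["rank"] if "rank" in topk.columns else z.index
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(z.to_numpy(), aspect="auto", cmap="coolwarm")
    ax.set_xticks(range(len(cols)), cols, rotation=30, ha="right")
    ax.set_yticks(range(len(z)), [f"LNP-{r}" for r in labels])
    fig.colorbar(im, ax=ax, label="z-score")
    ax.set_title("Top formulations (z-scored parameters)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def spearman_matrix(topk: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman rho over continuous parameters and predicted delta-AUC."""
    if len(topk) < 3:
        raise ValueError("need at least 3 rows for a correlation matrix")
    cols = [c for c in _CONTINUOUS if c in topk.columns]
    data = topk[cols].to_numpy(dtype=float)
    k = len(cols)
    rho = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            if np.ptp(data[:, i]) == 0 or np.ptp(data[:, j]) == 0:
                warnings.warn(
                    f"constant column in pair ({cols[i]}, {cols[j]}); rho undefined",
                    UserWarning,
                )
                rho[i, j] = rho[j, i] = np.nan
            else:
                rho[i, j] = rho[j, i] = stats.spearmanr(data[:, i], data[:, j]).statistic
    return pd.DataFrame(rho, index=cols, columns=cols)


def plot_spearman_matrix(topk: pd.DataFrame, path: str | Path) -> tuple[Path, pd.DataFrame]:
    """Render the Spearman matrix heatmap; returns (figure path, matrix)."""
    rho = spearman_matrix(topk)
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    im = ax.imshow(rho.to_numpy(), vmin=-1, vmax=1, cmap="coolwarm")
    ax.set_xticks(range(len(rho)), rho.columns, rotation=30, ha="right")
    ax.set_yticks(range(len(rho)), rho.index)
    for i in range(len(rho)):
        for j in range(len(rho)):
            val = rho.iloc[i, j]
            ax.text(j, i, "na" if np.isnan(val) else f"{val:.2f}", ha="center", va="center")
    fig.colorbar(im, ax=ax, label="Spearman ρ")
    ax.set_title("Parameter correlations (top candidates)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path), rho
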