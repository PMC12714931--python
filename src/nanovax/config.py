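"""One-file configuration for the whole pipeline (YAML in, dataclasses out).

The file has blocks ``rnaseq``, ``diffexpr``, ``compartments``, ``lnp``,
``surrogate``, ``ga`` and ``report`` plus a master ``seed``. Every stage
derives its own child seed deterministically from the master, so a config
fully determines a run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .ga_opt import GAConfig
from .immune_risk import CompartmentSpec, default_compartments
from .transcriptome_sim import SimConfig

__all__ = ["PipelineConfig", "load_config", "dump_config"]


@dataclass
class LNPBlock:
    n: int = 100
    noise_sd: float = 0.1
    scheme: str = "lhs"


@dataclass
class SurrogateBlock:
    train_frac: float = 0.8
    n_trees: int = 500
    min_leaf: int = 2
    max_depth: int | None = None
    bootstrap_B: int = 500


@dataclass
class DiffexprBlock:
    fdr: float = 0.05


@dataclass
class RiskBlock:
    bootstrap_B: int = 1000
    ci_level: float = 0.95


@dataclass
class PipelineConfig:
    seed: int = 0
    rnaseq: SimConfig = field(default_factory=SimConfig)
    diffexpr: DiffexprBlock = field(default_factory=DiffexprBlock)
    compartments: list[CompartmentSpec] = field(default_factory=default_compartments)
    risk: RiskBlock = field(default_factory=RiskBlock)
    lnp: LNPBlock = field(default_factory=LNPBlock)
    surrogate: SurrogateBlock = field(default_factory=SurrogateBlock)
    ga: GAConfig = field(default_factory=GAConfig)

    def __post_init__(self) -> None:
        # the master seed propagates to stage configs unless set explicitly
        self.rnaseq.seed = self.seed if self.rnaseq.seed == 0 else self.rnaseq.seed
        self.ga.seed = self.seed if self.ga.seed == 0 else self.ga.seed


def _compartments_from(items: list[dict]) -> list[CompartmentSpec]:
    return [
        CompartmentSpec(
            name=item["name"],
            marker_gene_ids=tuple(item["markers"]),
            delta_auc=float(item["delta_auc"]),
        )
        for item in items
    ]


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Read a YAML pipeline config; ``None`` returns the defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = PipelineConfig(seed=int(raw.get("seed", 0)))
    if "rnaseq" in raw:
        block = dict(raw["rnaseq"])
        markers = block.pop("markers", None)
        cfg.rnaseq = SimConfig(seed=cfg.seed, **block)
        if markers is not None:
            cfg.rnaseq.markers = {k: tuple(v) for k, v in markers.items()}
    if "diffexpr" in raw:
        cfg.diffexpr = DiffexprBlock(**raw["diffexpr"])
    if "compartments" in raw:
        cfg.compartments = _compartments_from(raw["compartments"])
    if "risk" in raw:
        cfg.risk = RiskBlock(**raw["risk"])
    if "lnp" in raw:
        cfg.lnp = LNPBlock(**raw["lnp"])
    if "surrogate" in raw:
        cfg.surrogate = SurrogateBlock(**raw["surrogate"])
    if "ga" in raw:
        cfg.ga = GAConfig(seed=cfg.seed, **raw["ga"])
    cfg.rnaseq.validate()
    cfg.ga.validate()
    return cfg


def dump_config(cfg: PipelineConfig, path: str | Path) -> None:
    """Write a config back to YAML (round-trippable with load_config)."""
    doc = {
        "seed": cfg.seed,
        "rnaseq": {
            k: v for k, v in asdict(cfg.rnaseq).items() if k not in ("markers", "seed")
        },
        "diffexpr": asdict(cfg.diffexpr),
        "compartments": [
            {"name": c.name, "markers": list(c.marker_gene_ids), "delta_auc": c.delta_auc}
            for c in cfg.compartments
        ],
        "risk": asdict(cfg.risk),
        "lnp": asdict(cfg.lnp),
        "surrogate": asdict(cfg.surrogate),
        "ga": {k: v for k, v in asdict(cfg.ga).items() if k != "seed"},
    }
    doc["rnaseq"]["markers"] = {k: list(v) for k, v in cfg.rnaseq.markers.items()}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
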