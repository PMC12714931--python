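"""LNP formulation space and the delta-AUC scoring function.

A lipid nanoparticle (LNP) formulation is described by four physicochemical
parameters known to drive biodistribution and immunogenicity:

* particle size, 50–150 nm (optimum near 90 nm for circulation),
* surface charge, −10 to +10 mV (near-neutral is favourable),
* PEGylation, 0.1–0.5 mol% (stealth against opsonization),
* targeting-ligand presence, binary (receptor-mediated uptake).

Delivery performance is scored by the biologically informed function

    delta_auc = -0.01 (size - 90)^2 - 0.02 charge^2 + 0.5 peg + 1.5 targeting

optionally plus Gaussian noise (SD 0.1) mimicking assay variability. The
quadratic terms penalize deviation from the size/charge optima; PEG and
targeting enter linearly. The global optimum over the box is
(90 nm, 0 mV, 0.5 mol%, targeted) with score 1.75.

``sample_formulations`` builds the training dataset: Latin-hypercube
samples over the three continuous dimensions (one point per quantile bin
in each marginal) with a balanced, shuffled targeting assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc

from ._seeds import stage_seed, stage_rng

__all__ = [
    "BOUNDS",
    "FEATURES",
    "LNPFormulation",
    "LNPDataset",
    "score_noiseless",
    "score_frame",
    "score_delta_auc",
    "sample_formulations",
]

#: Box bounds for the continuous formulation parameters.
BOUNDS: dict[str, tuple[float, float]] = {
    "size_nm": (50.0, 150.0),
    "charge_mV": (-10.0, 10.0),
    "peg_molpct": (0.1, 0.5),
}

#: Fixed feature order used throughout (surrogate contract).
FEATURES = ("size_nm", "charge_mV", "peg_molpct", "targeting")


@dataclass(frozen=True)
class LNPFormulation:
    size_nm: float
    charge_mV: float
    peg_molpct: float
    targeting: int

    def __post_init__(self) -> None:
        for name in BOUNDS:
            lo, hi = BOUNDS[name]
            value = getattr(self, name)
            if not lo <= value <= hi:
                raise ValueError(f"{name}={value} outside bounds [{lo}, {hi}]")
        if self.targeting not in (0, 1):
            raise ValueError("targeting must be 0 or 1")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.size_nm, self.charge_mV, self.peg_molpct, self.targeting], dtype=float
        )


@dataclass
class LNPDataset:
    """Scored formulations plus the provenance of the draw."""

    frame: pd.DataFrame  # columns: FEATURES + delta_auc
    noise_sd: float
    seed: int
    scheme: str

    def __len__(self) -> int:
        return len(self.frame)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, noise_sd=float("nan"), seed=-1, scheme="unknown") -> "LNPDataset":
        return cls(pd.read_csv(path), noise_sd=noise_sd, seed=seed, scheme=scheme)


def _score_arrays(size, charge, peg, targeting):
    return -0.01 * (size - 90.0) ** 2 - 0.02 * charge**2 + 0.5 * peg + 1.5 * targeting


def score_noiseless(f: LNPFormulation) -> float:
    """Deterministic delta-AUC score of one in-bounds formulation."""
    return float(_score_arrays(f.size_nm, f.charge_mV, f.peg_molpct, f.targeting))


def score_frame(frame: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Vectorized noiseless score over rows in the fixed feature order."""
    if isinstance(frame, pd.DataFrame):
        arr = frame.loc[:, list(FEATURES)].to_numpy(dtype=float)
    else:
        arr = np.asarray(frame, dtype=float)
    return _score_arrays(arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3])


def score_delta_auc(
    f: LNPFormulation, noise_sd: float = 0.1, rng: np.random.Generator | None = None
) -> float:
    """Noisy delta-AUC: the noiseless score plus Normal(0, noise_sd^2)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    base = score_noiseless(f)
    if noise_sd == 0:
        return base
    if rng is None:
        rng = np.random.default_rng()
    return base + float(rng.normal(0.0, noise_sd))


def sample_formulations(
    n: int = 100,
    seed: int = 0,
    noise_sd: float = 0.1,
    scheme: str = "lhs",
) -> LNPDataset:
    """Draw and score the formulation training set.

    The three continuous parameters come from a Latin hypercube (one point
    per n-quantile bin in every marginal); the targeting flag is assigned
    balanced (ceil(n/2) targeted for odd n) and shuffled. ``scheme="uniform"``
    replaces the hypercube with plain uniform sampling. Deterministic given
    the seed.
    """
    if n < 2:
        raise ValueError("need at least 2 formulations")
    rng = stage_rng(seed, "lnp_space")
    lo = np.array([BOUNDS[k][0] for k in BOUNDS])
    hi = np.array([BOUNDS[k][1] for k in BOUNDS])
    if scheme == "lhs":
        sampler = qmc.LatinHypercube(d=3, seed=stage_seed(seed, "lnp_space/lhs"))
        unit = sampler.random(n)
    elif scheme == "uniform":
        unit = rng.random((n, 3))
    else:
        raise ValueError(f"unknown sampling scheme {scheme!r}")
    cont = qmc.scale(unit, lo, hi)
    targeting = np.concatenate(
        [np.ones(n - n // 2, dtype=int), np.zeros(n // 2, dtype=int)]
    )
    rng.shuffle(targeting)
    noise = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    delta_auc = _score_arrays(cont[:, 0], cont[:, 1], cont[:, 2], targeting) + noise
    frame = pd.DataFrame(
        {
            "size_nm": cont[:, 0],
            "charge_mV": cont[:, 1],
            "peg_molpct": cont[:, 2],
            "targeting": targeting,
            "delta_auc": delta_auc,
        }
    )
    return LNPDataset(frame=frame, noise_sd=noise_sd, seed=seed, scheme=scheme)
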