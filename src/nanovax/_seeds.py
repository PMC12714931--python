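"""Deterministic per-stage seed derivation from one master seed.

Every stochastic stage of the pipeline draws from its own child stream so
that stages stay reproducible independently of each other: re-running the
LNP stage does not perturb the RNA-seq draw and vice versa.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_seed", "stage_rng"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a stable 31-bit child seed for a named pipeline stage."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode("utf-8"))])
    return int(ss.generate_state(1)[0] % (2**31))


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """A numpy Generator seeded for one named stage of the pipeline."""
    return np.random.default_rng(stage_seed(master_seed, stage))
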