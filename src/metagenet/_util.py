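"""Shared helpers: seeded RNG derivation and TSV conventions."""

from __future__ import annotations

import numpy as np

# Stage names used to derive per-stage seeds from one run seed.
_STAGES = (
    "simulate",
    "abundance",
    "metadata",
    "env",
    "rmt",
    "cluster",
    "null",
)


def stage_seed(seed: int, stage: str) -> int:
    """Derive a deterministic per-stage integer seed (< 2**31) from a run seed.

    One top-level seed drives the whole pipeline; every stochastic stage
    consumes its own child seed so stages can be replayed in isolation.
    """
    if stage not in _STAGES:
        raise ValueError(f"unknown stage {stage!r}; known: {_STAGES}")
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(_STAGES.index(stage),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    return np.random.default_rng(stage_seed(seed, stage))


def check_symmetric(m: np.ndarray, name: str = "matrix", tol: float = 1e-10) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{name} must be square, got shape {m.shape}")
    if not np.allclose(m, m.T, atol=tol):
        raise ValueError(f"{name} must be symmetric")
    return m
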