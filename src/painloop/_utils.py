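"""Seeding and validation helpers shared across modules."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stage_rng", "as_rng", "check_probability"]


def stage_rng(seed: int, stage: str, replicate: int = 0) -> np.random.Generator:
    """Derive an independent Generator from (seed, stage name, replicate index).

    Stages get distinct, reproducible streams so any stage can be re-run in
    isolation without replaying the whole pipeline's RNG history.
    """
    tag = zlib.crc32(stage.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag, int(replicate)]))


def as_rng(seed_or_rng) -> np.random.Generator:
    """Accept an int seed, a Generator, or None (fresh entropy)."""
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def check_probability(p, name: str = "p") -> float:
    p = float(p)
    if not np.isfinite(p) or p < 0.0 or p > 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {p!r}")
    return p
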