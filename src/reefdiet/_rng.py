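"""Seed-stream management.

A single integer seed governs every stochastic stage. Each stage derives an
independent generator from ``(seed, crc32(label))`` so stages can be re-run
in isolation and still reproduce the full-pipeline draws bit for bit.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, label: str) -> np.random.Generator:
    """Return the named random substream of a global seed.

    Parameters
    ----------
    seed : int
        Global seed (any non-negative integer below 2**63).
    label : str
        Stage name, e.g. ``"fish"`` or ``"diet"``. Distinct labels give
        statistically independent streams; the same (seed, label) pair always
        returns a generator in the same state.
    """
    key = zlib.crc32(label.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
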