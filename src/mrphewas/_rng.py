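"""Seeded random-number streams, one per pipeline stage.

Every stochastic stage draws from its own generator keyed by
``(run_seed, stage_name)``, so a stage can be re-run in isolation and
reproduce exactly the draws it made inside a full run.
"""

from __future__ import annotations

import zlib

import numpy as np


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Return the deterministic generator for a named stage of a run."""
    if not isinstance(seed, (int, np.integer)):
        raise TypeError(f"seed must be an integer, got {type(seed).__name__}")
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(stage.encode("utf-8"))])
    )
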