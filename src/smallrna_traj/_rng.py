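"""Deterministic sub-stream derivation for the single global seed."""
from __future__ import annotations

import zlib

import numpy as np


def spawn_rng(seed: int, label: str) -> np.random.Generator:
    """A Generator keyed by (seed, crc32(label)).

    Every stochastic stage derives its own stream this way, so changing one
    stage's draws never perturbs another's, and runs are reproducible from
    the single config seed.
    """
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(label.encode())])
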