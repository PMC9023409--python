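"""Seed-substream plumbing.

One master seed drives the whole experiment; every stage (cohort draw,
amputation, each bootstrap, ...) gets its own deterministic substream so
stages can be rerun independently without perturbing each other.
"""

from __future__ import annotations

import numpy as np

# stage codes used in spawn keys
COHORT = 0
AMPUTE = 1
MI_SCORE = 2
MI_ITEM = 3


def substream(seed: int, *key: int) -> np.random.Generator:
    """Generator for the substream identified by ``key`` under ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def subseed(seed: int, *key: int) -> int:
    """Derive a plain integer seed (< 2**31) for APIs that take one."""
    ss = np.random.SeedSequence(seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))
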