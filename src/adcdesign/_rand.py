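"""Seeding helpers.

One root seed per experiment; substreams are derived deterministically from
(seed, key) via numpy's SeedSequence spawn keys, so results never depend on
execution order.
"""

from __future__ import annotations

import numpy as np

Seedlike = int | np.random.SeedSequence


def seed_sequence(seed: Seedlike, *key: int) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        base = seed
        if key:
            return np.random.SeedSequence(
                entropy=base.entropy, spawn_key=tuple(base.spawn_key) + key
            )
        return base
    return np.random.SeedSequence(entropy=int(seed), spawn_key=key)


def rng(seed: Seedlike, *key: int) -> np.random.Generator:
    return np.random.default_rng(seed_sequence(seed, *key))


def child_seed(seed: Seedlike, *key: int) -> int:
    """A derived integer seed < 2**31, stable in (seed, key)."""
    return int(seed_sequence(seed, *key).generate_state(1)[0] >> 1)
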