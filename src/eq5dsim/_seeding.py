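"""Hierarchical, named random substreams.

All randomness in the pipeline flows from one master seed. Each stage draws
from a substream identified by a tuple of keys (stage name, condition,
severity, ...), so changing the amount of randomness consumed by one stage
(e.g. the number of bootstrap replications) never perturbs another.
"""

from __future__ import annotations

import hashlib

import numpy as np


def _key_int(key) -> int:
    """Stable 32-bit integer for a seeding key (int passes through)."""
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    digest = hashlib.sha256(str(key).encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big")


def seed_sequence(master_seed: int, *keys) -> np.random.SeedSequence:
    return np.random.SeedSequence(
        entropy=int(master_seed), spawn_key=tuple(_key_int(k) for k in keys)
    )


def substream(master_seed: int, *keys) -> np.random.Generator:
    """Named, independent random generator derived from the master seed."""
    return np.random.default_rng(seed_sequence(master_seed, *keys))


def derived_seed(master_seed: int, *keys) -> int:
    """A plain integer seed (< 2**31) derived from the master seed."""
    return int(seed_sequence(master_seed, *keys).generate_state(1)[0] % (2**31))
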