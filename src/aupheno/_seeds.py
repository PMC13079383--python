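"""Named seed-stream registry.

Every stochastic element derives its generator from a master seed plus a
tuple of names, so components draw from independent, reproducible streams
and adding participants/permutations never perturbs existing ones.
"""

from __future__ import annotations

import hashlib

import numpy as np


def _name_key(name: object) -> int:
    if isinstance(name, (int, np.integer)):
        return int(name) & 0xFFFFFFFF
    digest = hashlib.sha256(str(name).encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little")


def seed_sequence(master: int, *names: object) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master) & 0x7FFFFFFF, *(_name_key(n) for n in names)])


def stream(master: int, *names: object) -> np.random.Generator:
    """A PCG64 generator for the named stream."""
    return np.random.default_rng(seed_sequence(master, *names))


def child_int(master: int, *names: object) -> int:
    """A derived integer seed below 2**31 (for scikit-learn random_state)."""
    return int(seed_sequence(master, *names).generate_state(1, np.uint32)[0] & 0x7FFFFFFF)
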