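"""Deterministic stream derivation from a single master seed.

Every stochastic component receives its own child generator derived from the
master seed plus a tuple of string/int labels (population id, scenario key,
replicate index, ...). Identical master seed and labels always yield the
same stream, independent of execution order, so full runs are reproducible
bit-for-bit and scenarios can be computed in any order.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed_sequence", "child_rng"]


def _label_word(label: object) -> int:
    # crc32 gives a stable 32-bit word per label across sessions (unlike hash()).
    return zlib.crc32(repr(label).encode("utf-8"))


def child_seed_sequence(master_seed: int, *labels: object) -> np.random.SeedSequence:
    """SeedSequence for the stream identified by ``labels`` under ``master_seed``."""
    entropy = [int(master_seed) & 0x7FFFFFFF] + [_label_word(l) for l in labels]
    return np.random.SeedSequence(entropy)


def child_rng(master_seed: int, *labels: object) -> np.random.Generator:
    """Independent Generator for the stream identified by ``labels``."""
    return np.random.default_rng(child_seed_sequence(master_seed, *labels))
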