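"""Deterministic child-stream seeding.

Every stochastic operation in the package draws from a Generator obtained via
:func:`spawn_rng` so that (a) identical root seeds give bit-identical output and
(b) streams for different plots / stages / sensors are statistically independent
and do not depend on iteration order.
"""

from __future__ import annotations

import zlib

import numpy as np


def _key_to_int(key) -> int:
    if isinstance(key, (int, np.integer)):
        return int(key) & 0xFFFFFFFF
    return zlib.crc32(str(key).encode("utf-8"))


def spawn_rng(seed: int, *keys) -> np.random.Generator:
    """Return a Generator keyed by ``seed`` and an arbitrary tuple of labels.

    Labels may be strings (hashed with CRC32) or integers; the resulting
    entropy list feeds a :class:`numpy.random.SeedSequence`.
    """
    entropy = [int(seed) & 0x7FFFFFFF] + [_key_to_int(k) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(entropy))
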