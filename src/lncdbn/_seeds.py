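"""Deterministic derivation of stage seeds from one experiment seed.

Every stochastic stage (negative sampling, fold shuffling, weight
initialisation) draws its seed from the experiment seed plus a stable tag
path, so any sub-result is reproducible in isolation.
"""

from __future__ import annotations

import zlib

import numpy as np


def derive_seed(root: int, *tags: int | str) -> int:
    """Derive a 31-bit child seed from ``root`` and a path of tags.

    Tags may be ints (fold index, layer index) or strings (stage name,
    cancer name); strings are hashed with CRC-32, which is stable across
    platforms and sessions.
    """
    entropy = [int(root) & 0x7FFFFFFF]
    for tag in tags:
        if isinstance(tag, (int, np.integer)):
            entropy.append(int(tag) & 0xFFFFFFFF)
        else:
            entropy.append(zlib.crc32(str(tag).encode("utf-8")))
    ss = np.random.SeedSequence(entropy)
    return int(ss.generate_state(1, np.uint32)[0]) % (2**31)
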