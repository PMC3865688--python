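"""Named random substreams.

All randomness in the package flows from a single integer seed.  Each stage
derives an independent generator from the seed plus a tuple of string/int
keys, so re-running one stage in isolation reproduces exactly the stream it
saw inside the full pipeline.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *keys) -> np.random.Generator:
    """Return a Generator for the named substream ``(seed, *keys)``.

    Keys may be strings or integers; they are hashed (crc32) into the
    SeedSequence entropy so distinct names give independent streams.
    """
    entropy = [int(seed) & 0x7FFFFFFF]
    for k in keys:
        if isinstance(k, (int, np.integer)):
            entropy.append(int(k) & 0xFFFFFFFF)
        else:
            entropy.append(zlib.crc32(str(k).encode()))
    return np.random.default_rng(np.random.SeedSequence(entropy))


def as_rng(rng_or_seed) -> np.random.Generator:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)
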