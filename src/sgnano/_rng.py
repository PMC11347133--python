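"""Named random substreams derived from one root seed.

Every stochastic stage draws from its own substream so that adding or
re-ordering stages never perturbs the randomness of the others.
"""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the substream ``name`` of root ``seed``.

    The stream key is the CRC32 of the name, so the mapping is stable
    across sessions and platforms.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=(key,)))
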