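"""Named random substreams.

Every stochastic stage draws from a generator derived from the single
pipeline seed plus a stage name, so no stage reads or mutates global
random state and stages can be re-run independently and reproducibly.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator keyed by ``(seed, name)``.

    The name is hashed with CRC32, which is stable across platforms and
    Python versions (unlike ``hash``).
    """
    if seed < 0:
        raise ValueError("seed must be non-negative")
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))
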