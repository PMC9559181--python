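"""Deterministic seed derivation for every stochastic stage.

Each stage derives its seed from the master seed and a stable sequence of
tags (stage name, period index, replicate index ...) through NumPy's
SeedSequence machinery, so that runs are exactly reproducible and stages
never share a random stream by accident.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["derive_seed", "derive_rng"]


def _tag_code(tag: object) -> int:
    if isinstance(tag, (int, np.integer)):
        return int(tag)
    return zlib.crc32(str(tag).encode())


def derive_seed(master: int, *tags: object) -> int:
    """A 31-bit seed determined by the master seed and the tag sequence."""
    ss = np.random.SeedSequence([int(master)] + [_tag_code(t) for t in tags])
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**31))


def derive_rng(master: int, *tags: object) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master, *tags))
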