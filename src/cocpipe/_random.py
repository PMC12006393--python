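"""Named, seed-derived random streams.

Every stochastic component of the package draws from a generator obtained via
:func:`stream`, so one top-level seed reproduces the whole analysis while
sub-generators stay independent of each other and of call order.
"""

from __future__ import annotations

import zlib

import numpy as np

_MOD = 2**31 - 1


def stream(seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the sub-stream `name` derived from `seed`.

    The stream key is a CRC32 hash of the name, so adding a new named stream
    never perturbs existing ones.
    """
    key = zlib.crc32(name.encode("utf-8")) % _MOD
    return np.random.default_rng(np.random.SeedSequence([int(seed) % _MOD, key]))


def substream_seed(seed: int, name: str) -> int:
    """A plain integer seed (< 2**31) for APIs that take one."""
    return int(stream(seed, name).integers(0, _MOD))
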