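"""Named random substreams derived from one top-level seed."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "subseed"]


def subseed(seed: int, name: str) -> np.random.SeedSequence:
    """Deterministic child seed for a named stage.

    The CRC32 of the stage name is mixed into the entropy pool so that
    every generator in a run draws from an independent stream while the
    whole run remains a function of the single top-level seed.
    """
    return np.random.SeedSequence([int(seed), zlib.crc32(name.encode())])


def substream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(subseed(seed, name))
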