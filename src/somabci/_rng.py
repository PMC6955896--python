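"""Deterministic random substreams.

A single global seed fans out to named per-stage streams.  Each stage (and,
within a stage, each trial) addresses its own ``SeedSequence`` spawn key, so
adding a new stage never perturbs the draws of existing ones and train/test
splits never share a substream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream"]


def _key(part: object) -> int:
    if isinstance(part, (int, np.integer)):
        if part < 0:
            raise ValueError("substream path integers must be non-negative")
        return int(part)
    # stable 31-bit hash of the stage name (builtin hash() is salted per process)
    return zlib.crc32(str(part).encode("utf-8")) & 0x7FFFFFFF


def substream(seed: int, *path: object) -> np.random.Generator:
    """Return a Generator for the stream addressed by ``(seed, *path)``.

    ``path`` elements may be stage names (strings) or indices (ints); the
    same address always yields the same stream, and distinct addresses are
    statistically independent.
    """
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=tuple(_key(p) for p in path))
    return np.random.default_rng(ss)
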