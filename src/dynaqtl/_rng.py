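"""Seed handling.

All stochastic stages draw from named substreams of a single master seed, so
a pipeline run is reproducible stage-by-stage and adding a stage never
perturbs the draws of another.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "spawn_seed"]


def substream(master_seed: int, name: str) -> np.random.Generator:
    """Return a Generator for the named substream of ``master_seed``.

    The stream key is derived from a CRC32 of the stage name, so the mapping
    is stable across sessions and platforms.
    """
    key = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, key]))


def spawn_seed(master_seed: int, name: str) -> int:
    """Derive a deterministic 31-bit integer seed for the named substream."""
    key = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    ss = np.random.SeedSequence([int(master_seed) & 0x7FFFFFFF, key])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)
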