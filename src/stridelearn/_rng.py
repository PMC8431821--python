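"""Deterministic seed derivation.

All randomness in the package flows from a single master seed through named
substreams so that runs are bit-reproducible and independent stages
(schedules, motor noise, optimizer restarts, permutations) never share a
stream.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def _key_ints(keys: tuple) -> tuple[int, ...]:
    out = []
    for k in keys:
        if isinstance(k, (int, np.integer)):
            out.append(int(k) & 0x7FFFFFFF)
        else:
            out.append(zlib.crc32(str(k).encode("utf-8")))
    return tuple(out)


def substream(master_seed: int, *keys) -> np.random.Generator:
    """Return a Generator for the substream named by ``keys``."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=_key_ints(keys))
    return np.random.default_rng(ss)


def child_seed(master_seed: int, *keys) -> int:
    """Derive a small (< 2**31) integer seed for the substream named by ``keys``."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=_key_ints(keys))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)
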