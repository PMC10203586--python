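"""Deterministic seed derivation.

A single master seed drives every stochastic component of the pipeline.
Components derive their own independent streams from (seed, *string tags),
so e.g. the trial-design randomisation can be regenerated without replaying
founder simulation. Tag hashing is stable across processes and platforms
(CRC32, not Python's salted ``hash``).
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed_sequence"]


def _tag_words(tags: tuple) -> list[int]:
    words = []
    for t in tags:
        if isinstance(t, (int, np.integer)):
            words.append(int(t) & 0xFFFFFFFF)
        else:
            words.append(zlib.crc32(str(t).encode("utf-8")))
    return words


def child_seed_sequence(seed: int, *tags) -> np.random.SeedSequence:
    """SeedSequence for the stream identified by ``tags`` under ``seed``."""
    return np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *_tag_words(tuple(tags))])


def child_rng(seed: int, *tags) -> np.random.Generator:
    """Independent Generator for the stream identified by ``tags``."""
    return np.random.default_rng(child_seed_sequence(seed, *tags))
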