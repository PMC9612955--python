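"""Seed fan-out: one top-level seed, one named child stream per stage.

Stage streams are derived from ``SeedSequence([seed, crc32(name)])`` so that
changing how many draws one stage consumes (e.g. the bootstrap replicate
count) never perturbs another stage's output.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def child_seed(seed: int, name: str) -> int:
    """Deterministic 31-bit child seed for a named stage."""
    h = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    # mix with the parent seed through SeedSequence, then fold to 31 bits
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, h])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent Generator for stage ``name`` under the top-level ``seed``."""
    h = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, h]))
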