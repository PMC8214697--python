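"""Labeled child random streams.

Every stochastic routine in the package derives its generator from a root
seed plus a tuple of string/int labels.  Streams are independent and stable:
adding a cell (a new label) never perturbs the draws of existing labels.
"""
from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_rng", "child_seed"]


def _label_to_int(label) -> int:
    if isinstance(label, (int, np.integer)):
        return int(label) & 0xFFFFFFFF
    return zlib.crc32(str(label).encode("utf-8"))


def child_seed(seed: int, *labels) -> np.random.SeedSequence:
    """SeedSequence for the stream identified by ``labels`` under ``seed``."""
    return np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *map(_label_to_int, labels)])


def child_rng(seed: int, *labels) -> np.random.Generator:
    """Generator for the labeled stream. Same seed+labels => same draws."""
    return np.random.default_rng(child_seed(seed, *labels))
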