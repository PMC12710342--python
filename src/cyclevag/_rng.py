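"""Seed-substream derivation.

All randomness in the package flows from one master seed.  Named substreams
are derived with ``numpy.random.SeedSequence`` keyed on a stable CRC32 hash
of the stream label, so adding one more taxon/model never perturbs the
random numbers drawn for any other.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed"]


def child_seed(seed: int, *labels: str | int) -> np.random.SeedSequence:
    """SeedSequence for the substream identified by ``labels`` under ``seed``."""
    entropy = [int(seed) & 0x7FFFFFFF]
    for lab in labels:
        if isinstance(lab, int):
            entropy.append(lab & 0xFFFFFFFF)
        else:
            entropy.append(zlib.crc32(str(lab).encode("utf-8")))
    return np.random.SeedSequence(entropy)


def substream(seed: int, *labels: str | int) -> np.random.Generator:
    """Generator for a named, reproducible substream of the master seed."""
    return np.random.default_rng(child_seed(seed, *labels))
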