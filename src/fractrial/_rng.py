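"""Named, independent random streams derived from one master seed.

Every stochastic stage of the pipeline (population sampling, tibia residual
noise, cohort draws, ...) pulls its generator from here so that any stage can
be reproduced in isolation from the master seed alone.
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["stream", "stream_seed"]


def stream_seed(master_seed: int, name: str, *extra: int) -> np.random.SeedSequence:
    """Derive a named child SeedSequence from the master seed.

    The stream name enters via its CRC-32, so streams are stable across runs
    and independent of the order in which stages execute.
    """
    tag = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.SeedSequence(entropy=(int(master_seed), tag, *map(int, extra)))


def stream(master_seed: int, name: str, *extra: int) -> np.random.Generator:
    """A fresh PCG64 generator for the named stream."""
    return np.random.default_rng(stream_seed(master_seed, name, *extra))
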