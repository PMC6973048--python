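"""Shared helpers: reproducible RNG substreams and small numeric guards."""

from __future__ import annotations

import zlib

import numpy as np


def substream(seed: int, *keys) -> np.random.Generator:
    """Derive an independent, reproducible RNG stream from a master seed.

    Extra keys (species name, variable name, replicate index, ...) are hashed
    with CRC32 so the stream depends only on stable string/int identity, not
    on Python's per-process hash randomization.
    """
    ints = [int(seed) & 0x7FFFFFFF]
    ints += [zlib.crc32(str(k).encode("utf-8")) for k in keys]
    return np.random.default_rng(np.random.SeedSequence(ints))


def sample_var(x, ddof: int = 1) -> float:
    """Sample variance (n-1 denominator); NaN when fewer than ddof+1 points."""
    x = np.asarray(x, dtype=float)
    if x.size <= ddof:
        return float("nan")
    return float(np.var(x, ddof=ddof))
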