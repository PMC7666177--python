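"""Shared helpers: named random streams, BH adjustment, input checks."""

from __future__ import annotations

import zlib

import numpy as np
from statsmodels.stats.multitest import multipletests


def named_rng(seed: int, stream: str) -> np.random.Generator:
    """Return a generator for a named stream derived from one master seed.

    Each (seed, stream-name) pair yields an independent, reproducible
    stream, so pipeline stages can be regenerated without replaying the
    stages before them.
    """
    key = zlib.crc32(stream.encode("utf8"))
    return np.random.default_rng(np.random.SeedSequence([int(seed), key]))


def sub_seed(seed: int, stream: str) -> int:
    """A 31-bit integer seed derived from (seed, stream), for libraries
    that take plain integer seeds (e.g. scikit-learn)."""
    return int(named_rng(seed, stream).integers(0, 2**31 - 1))


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaNs propagate)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def check_finite(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
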