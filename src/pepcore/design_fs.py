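"""Frequency-only design: independent per-position sampling (FS strategy)."""

from __future__ import annotations

import numpy as np

from .evostats import FrequencyProfile
from .peptide_io import ALPHABET, PeptideAlignment, decode_alignment


def sample_encoded_fs(
    fp: FrequencyProfile, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Encoded (n, L) sample with each position drawn from ``fp.f[i]``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    cdf = np.cumsum(fp.f, axis=1)
    u = rng.random((n, fp.L))
    return (u[:, :, None] > cdf[None, :, :]).sum(axis=2).astype(np.int64)


def sample_fs(
    fp: FrequencyProfile,
    n: int,
    seed: int,
    allotype: str = "",
) -> PeptideAlignment:
    """Draw ``n`` sequences position-independently from the site frequencies.

    Uses the profile exactly as given (typically pseudocount-regularized, so
    every residue has nonzero support). Reproducible from ``seed``.
    """
    if fp.A != len(ALPHABET):
        raise ValueError("sample_fs requires the 20-letter alphabet")
    rng = np.random.default_rng(seed)
    enc = sample_encoded_fs(fp, n, rng)
    return decode_alignment(enc, allotype=allotype)
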