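"""Synthetic peptide alignments with known first- and second-order statistics.

Sequences are drawn from a mixture of K product ("profile") distributions:
a component k is chosen with probability w_k, then each position i is drawn
independently from that component's profile p_k[i]. The mixture induces
pairwise covariation with closed-form joint frequencies, giving an exact
oracle for every downstream estimator:

    f_ia      = sum_k w_k p_k[i, a]
    f_ij^ab   = sum_k w_k p_k[i, a] p_k[j, b]      (i != j)
    f_ii^ab   = delta_ab f_ia
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evostats import FrequencyProfile, JointFrequencyTensor
from .peptide_io import ALPHABET, AllotypeDataset, PeptideAlignment, decode_alignment


@dataclass
class SyntheticSpec:
    """Mixture-of-profiles specification.

    ``profiles`` has shape (K, L, A); ``weights`` is a K-simplex vector.
    ``anchor_positions`` records which (0-based) positions were given
    low-entropy profiles — metadata for conservation-peak checks.
    """

    weights: np.ndarray
    profiles: np.ndarray
    anchor_positions: tuple[int, ...] = ()
    label: str = "synthetic"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.profiles = np.asarray(self.profiles, dtype=float)
        if self.profiles.ndim != 3:
            raise ValueError("profiles must have shape (K, L, A)")
        if self.weights.shape != (self.profiles.shape[0],):
            raise ValueError("one weight per component required")
        if not np.isclose(self.weights.sum(), 1.0, atol=1e-9) or (self.weights < 0).any():
            raise ValueError("weights must form a probability simplex")
        if not np.allclose(self.profiles.sum(axis=2), 1.0, atol=1e-9):
            raise ValueError("each profile row must sum to 1")

    @property
    def K(self) -> int:
        return self.profiles.shape[0]

    @property
    def L(self) -> int:
        return self.profiles.shape[1]

    @property
    def A(self) -> int:
        return self.profiles.shape[2]


def exact_statistics(spec: SyntheticSpec) -> tuple[FrequencyProfile, JointFrequencyTensor]:
    """Closed-form site and joint frequencies of the mixture (no sampling)."""
    w, p = spec.weights, spec.profiles
    f = np.einsum("k,kia->ia", w, p)
    fj = np.einsum("k,kia,kjb->iajb", w, p, p)
    idx = np.arange(spec.L)
    ar = np.arange(spec.A)
    fj[idx[:, None], :, idx[:, None], :] = 0.0
    fj[idx[:, None], ar[None, :], idx[:, None], ar[None, :]] = f
    return (
        FrequencyProfile(f, pseudocount=0.0, M_source=0),
        JointFrequencyTensor(fj, pseudocount=0.0),
    )


def sample_msa(spec: SyntheticSpec, M: int, seed: int) -> PeptideAlignment:
    """Draw M sequences from the mixture; reproducible from ``seed``.

    Requires the 20-letter alphabet for decoding (small-alphabet specs are
    for in-memory oracle tests; use :func:`sample_encoded` there).
    """
    if spec.A != len(ALPHABET):
        raise ValueError("sample_msa requires the 20-letter alphabet")
    enc = sample_encoded(spec, M, seed)
    return decode_alignment(enc, allotype=spec.label)


def sample_encoded(spec: SyntheticSpec, M: int, seed: int) -> np.ndarray:
    """Encoded (M, L) integer sample from the mixture."""
    if M < 1:
        raise ValueError("M must be >= 1")
    rng = np.random.default_rng(seed)
    comps = rng.choice(spec.K, size=M, p=spec.weights)
    out = np.empty((M, spec.L), dtype=np.int64)
    for k in range(spec.K):
        rows = np.nonzero(comps == k)[0]
        if rows.size == 0:
            continue
        u = rng.random((rows.size, spec.L))
        cdf = np.cumsum(spec.profiles[k], axis=1)
        out[rows] = (u[:, :, None] > cdf[None, :, :]).sum(axis=2)
    return out


def _peaked_row(rng: np.random.Generator, A: int, top: int, weight: float) -> np.ndarray:
    """Random profile row concentrating ``weight`` mass on one residue."""
    row = rng.dirichlet(np.ones(A))
    row *= (1.0 - weight) / row.sum()
    row[top] += weight
    return row


def make_anchored_spec(
    L: int = 9,
    A: int = 20,
    K: int = 3,
    anchor_positions: tuple[int, ...] = (0, 3, 5, 8),
    anchor_weight: float = 0.85,
    contrast: float = 0.6,
    seed: int = 0,
    label: str = "synthetic",
) -> SyntheticSpec:
    """Build a mixture spec with conserved anchor positions and component
    contrast (hence pairwise coupling) at the non-anchor positions.

    Anchors share one dominant residue across components (high first-order
    conservation, little coupling); non-anchor positions get a different
    dominant residue per component with mass ``contrast``, which induces
    covariation between position pairs.
    """
    rng = np.random.default_rng(seed)
    weights = rng.dirichlet(np.full(K, 5.0))
    profiles = np.empty((K, L, A))
    anchor_res = rng.choice(A, size=L, replace=A < L)
    comp_res = np.array([rng.permutation(A)[:K] for _ in range(L)])  # (L, K)
    for i in range(L):
        if i in anchor_positions:
            for k in range(K):
                profiles[k, i] = _peaked_row(rng, A, anchor_res[i], anchor_weight)
        else:
            for k in range(K):
                profiles[k, i] = _peaked_row(rng, A, comp_res[i, k], contrast)
    return SyntheticSpec(weights, profiles, tuple(anchor_positions), label=label)


def make_benchmark_suite(
    seed: int = 0,
    n_allotypes: int = 3,
    M: int = 500,
    L: int = 9,
) -> tuple[AllotypeDataset, dict[str, SyntheticSpec]]:
    """A reproducible multi-allotype benchmark with distinct anchors and
    coupling strengths, each alignment large enough to pass the default
    minimum-sequence filter."""
    anchor_sets = [(0, 3, 5, 8), (0, 2, 5, 8), (1, 3, 6, 8), (0, 4, 6, 8)]
    contrasts = [0.6, 0.45, 0.75, 0.55]
    entries: dict[str, PeptideAlignment] = {}
    registry: dict[str, SyntheticSpec] = {}
    for n in range(n_allotypes):
        label = f"SYN-{n + 1:02d}"
        spec = make_anchored_spec(
            L=L,
            anchor_positions=anchor_sets[n % len(anchor_sets)],
            contrast=contrasts[n % len(contrasts)],
            seed=seed * 1000 + n,
            label=label,
        )
        registry[label] = spec
        entries[label] = sample_msa(spec, M, seed=seed * 1000 + 500 + n)
    return AllotypeDataset(entries), registry
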