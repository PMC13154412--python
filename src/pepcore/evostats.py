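"""First- and second-order evolutionary statistics of peptide alignments.

Conventions
-----------
* Frequencies are regularized by mixing with the uniform distribution:
  ``f = (1 - pc) * counts / M + pc / A`` where ``A`` is the alphabet size.
  The same scheme applies to site, background and joint frequencies so the
  marginalization identity survives regularization exactly.
* Joint-frequency diagonal blocks (i == j) carry the site frequencies on
  the residue diagonal (``f_ii^ab = delta_ab * f_ia``) — a single position
  cannot hold two residues at once.
* Natural logarithms throughout (units: nats).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .peptide_io import ALPHABET, AllotypeDataset, PeptideAlignment, encode_alignment

DEFAULT_PSEUDOCOUNT = 1e-3


@dataclass
class FrequencyProfile:
    """Per-position residue frequencies ``f[i, a]`` of shape (L, A)."""

    f: np.ndarray
    pseudocount: float = 0.0
    M_source: int = 0

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=float)
        if self.f.ndim != 2:
            raise ValueError("frequency profile must be 2-D (L, A)")
        if not np.allclose(self.f.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("frequency profile rows must sum to 1")
        if (self.f < 0).any() or (self.f > 1).any():
            raise ValueError("frequencies must lie in [0, 1]")

    @property
    def L(self) -> int:
        return self.f.shape[0]

    @property
    def A(self) -> int:
        return self.f.shape[1]


@dataclass
class BackgroundFrequencies:
    """Background residue distribution ``q[a]`` of shape (A,)."""

    q: np.ndarray
    source: str = "pooled"

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 1:
            raise ValueError("background must be 1-D")
        if not np.isclose(self.q.sum(), 1.0, atol=1e-9):
            raise ValueError("background must sum to 1")
        if (self.q <= 0).any() or (self.q >= 1).any():
            raise ValueError("background entries must lie strictly in (0, 1)")


@dataclass
class ConservationVector:
    """Per-position KL conservation ``C[i]`` (non-negative, nats)."""

    C: np.ndarray

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)


@dataclass
class PositionalWeights:
    """Log-odds coefficients ``k[i, a] = ln[f(1-q) / (q(1-f))]``."""

    k: np.ndarray

    def __post_init__(self) -> None:
        self.k = np.asarray(self.k, dtype=float)
        if not np.isfinite(self.k).all():
            raise ValueError("positional weights must be finite")


@dataclass
class JointFrequencyTensor:
    """Pairwise joint frequencies ``fj[i, a, j, b]`` of shape (L, A, L, A)."""

    fj: np.ndarray
    pseudocount: float = 0.0

    def __post_init__(self) -> None:
        self.fj = np.asarray(self.fj, dtype=float)
        if self.fj.ndim != 4 or self.fj.shape[0] != self.fj.shape[2] \
                or self.fj.shape[1] != self.fj.shape[3]:
            raise ValueError("joint tensor must have shape (L, A, L, A)")

    @property
    def L(self) -> int:
        return self.fj.shape[0]

    @property
    def A(self) -> int:
        return self.fj.shape[1]


@dataclass
class CouplingMatrix:
    """Symmetric non-negative coupling strengths ``C2[i, j]`` of shape (L, L)."""

    C2: np.ndarray

    def __post_init__(self) -> None:
        self.C2 = np.asarray(self.C2, dtype=float)
        if self.C2.ndim != 2 or self.C2.shape[0] != self.C2.shape[1]:
            raise ValueError("coupling matrix must be square")

    @property
    def L(self) -> int:
        return self.C2.shape[0]


# ---------------------------------------------------------------------------
# counting helpers (shared with the annealer's incremental tallies)
# ---------------------------------------------------------------------------

def site_counts(encoded: np.ndarray, A: int) -> np.ndarray:
    """Residue counts per position, shape (L, A)."""
    M, L = encoded.shape
    counts = np.zeros((L, A), dtype=np.int64)
    for i in range(L):
        counts[i] = np.bincount(encoded[:, i], minlength=A)
    return counts


def pair_counts(encoded: np.ndarray, A: int) -> np.ndarray:
    """Ordered-pair residue counts, shape (L, A, L, A); diagonal blocks are
    the site counts on the residue diagonal."""
    M, L = encoded.shape
    counts = np.zeros((L, A, L, A), dtype=np.int64)
    for i in range(L):
        ci = np.bincount(encoded[:, i], minlength=A)
        counts[i, np.arange(A), i, np.arange(A)] = ci
        for j in range(i + 1, L):
            flat = np.bincount(encoded[:, i] * A + encoded[:, j], minlength=A * A)
            block = flat.reshape(A, A)
            counts[i, :, j, :] = block
            counts[j, :, i, :] = block.T
    return counts


def regularize_site(counts: np.ndarray, M: int, pseudocount: float) -> np.ndarray:
    A = counts.shape[-1]
    return (1.0 - pseudocount) * counts / M + pseudocount / A


def regularize_joint(counts: np.ndarray, M: int, pseudocount: float) -> np.ndarray:
    """Regularize pair counts; diagonal blocks mix on their A-entry diagonal
    only, preserving the one-residue-per-position constraint."""
    L, A = counts.shape[0], counts.shape[1]
    fj = (1.0 - pseudocount) * counts / M
    off = np.full((L, L), pseudocount / (A * A))
    idx = np.arange(L)
    off[idx, idx] = 0.0
    fj += off[:, None, :, None]
    ar = np.arange(A)
    fj[idx[:, None], ar[None, :], idx[:, None], ar[None, :]] += pseudocount / A
    return fj


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def site_frequencies(
    aln: PeptideAlignment, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> FrequencyProfile:
    """Per-position residue frequencies with uniform-mixture regularization."""
    if pseudocount < 0 or pseudocount >= 1:
        raise ValueError("pseudocount must lie in [0, 1)")
    enc = encode_alignment(aln)
    counts = site_counts(enc, len(ALPHABET))
    f = regularize_site(counts, aln.M, pseudocount)
    return FrequencyProfile(f, pseudocount=pseudocount, M_source=aln.M)


def background_frequencies(
    data: AllotypeDataset | PeptideAlignment,
    mode: str = "pooled",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> BackgroundFrequencies:
    """Background distribution: ``uniform`` (1/A) or ``pooled`` over all
    sequences and positions of the input."""
    A = len(ALPHABET)
    if mode == "uniform":
        return BackgroundFrequencies(np.full(A, 1.0 / A), source="uniform")
    if mode != "pooled":
        raise ValueError(f"unknown background mode {mode!r}")
    alns = (
        list(data.entries.values())
        if isinstance(data, AllotypeDataset)
        else [data]
    )
    if not alns:
        raise ValueError("cannot pool background from an empty dataset")
    counts = np.zeros(A, dtype=np.int64)
    total = 0
    for aln in alns:
        enc = encode_alignment(aln)
        counts += np.bincount(enc.ravel(), minlength=A)
        total += enc.size
    q = (1.0 - pseudocount) * counts / total + pseudocount / A
    return BackgroundFrequencies(q, source="pooled")


def conservation(
    fp: FrequencyProfile, bg: BackgroundFrequencies
) -> ConservationVector:
    """Per-position KL divergence of site frequencies from background,
    ``C_i = sum_a f_ia ln(f_ia / q_a)`` with the 0 ln 0 = 0 convention."""
    f, q = fp.f, bg.q
    if f.shape[1] != q.shape[0]:
        raise ValueError("profile and background alphabet sizes differ")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(f > 0, f * np.log(f / q), 0.0)
    return ConservationVector(terms.sum(axis=1))


def positional_weights(
    fp: FrequencyProfile, bg: BackgroundFrequencies
) -> PositionalWeights:
    """Elementwise log-odds ``k_ia = ln[(f_ia (1-q_a)) / (q_a (1-f_ia))]``."""
    f, q = fp.f, bg.q
    if f.shape[1] != q.shape[0]:
        raise ValueError("profile and background alphabet sizes differ")
    bad = (f <= 0) | (f >= 1)
    if bad.any():
        i, a = np.argwhere(bad)[0]
        raise ValueError(
            f"positional weight undefined at position {i + 1}, residue "
            f"{ALPHABET[a] if a < len(ALPHABET) else a}: f={f[i, a]} not in (0,1); "
            "use a nonzero pseudocount"
        )
    return PositionalWeights(np.log(f * (1.0 - q) / (q * (1.0 - f))))


def joint_frequencies(
    aln: PeptideAlignment, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> JointFrequencyTensor:
    """Pairwise joint residue frequencies with the diagonal-block convention."""
    if pseudocount < 0 or pseudocount >= 1:
        raise ValueError("pseudocount must lie in [0, 1)")
    enc = encode_alignment(aln)
    counts = pair_counts(enc, len(ALPHABET))
    fj = regularize_joint(counts, aln.M, pseudocount)
    return JointFrequencyTensor(fj, pseudocount=pseudocount)


def coupling_from_arrays(
    fj: np.ndarray, f: np.ndarray, k: np.ndarray
) -> np.ndarray:
    """Coupling strengths from raw arrays:
    ``C_ij = sum_ab (k_ia k_jb)^2 (f_ij^ab - f_ia f_jb)^2``."""
    d = fj - f[:, :, None, None] * f[None, None, :, :]
    k2 = k * k
    return np.einsum("ia,jb,iajb->ij", k2, k2, d * d, optimize=True)


def coupling_matrix(
    jf: JointFrequencyTensor, fp: FrequencyProfile, kw: PositionalWeights
) -> CouplingMatrix:
    """Second-order coupling matrix from joint frequencies, site frequencies
    and positional weights."""
    if jf.fj.shape != (fp.L, fp.A, fp.L, fp.A) or kw.k.shape != fp.f.shape:
        raise ValueError("shape mismatch between joint, profile and weights")
    return CouplingMatrix(coupling_from_arrays(jf.fj, fp.f, kw.k))


def alignment_statistics(
    aln: PeptideAlignment,
    bg: BackgroundFrequencies | None = None,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
):
    """Convenience bundle: (profile, background, conservation, weights,
    joint tensor, coupling matrix) computed with one shared pseudocount."""
    fp = site_frequencies(aln, pseudocount)
    if bg is None:
        bg = background_frequencies(aln, "pooled", pseudocount)
    cons = conservation(fp, bg)
    kw = positional_weights(fp, bg)
    jf = joint_frequencies(aln, pseudocount)
    cm = coupling_matrix(jf, fp, kw)
    return fp, bg, cons, kw, jf, cm


def coupling_pcc(
    A: CouplingMatrix | np.ndarray,
    B: CouplingMatrix | np.ndarray,
    include_diagonal: bool = True,
) -> float:
    """Pearson correlation over the upper triangle of two coupling matrices.

    The diagonal is included by default; pass ``include_diagonal=False`` to
    correlate off-diagonal couplings only.
    """
    a = A.C2 if isinstance(A, CouplingMatrix) else np.asarray(A, dtype=float)
    b = B.C2 if isinstance(B, CouplingMatrix) else np.asarray(B, dtype=float)
    if a.shape != b.shape:
        raise ValueError("coupling matrices must share a shape")
    iu = np.triu_indices(a.shape[0], k=0 if include_diagonal else 1)
    x, y = a[iu], b[iu]
    if x.size < 3:
        raise ValueError("need at least 3 elements for a correlation")
    if np.isclose(x.std(), 0) or np.isclose(y.std(), 0):
        raise ValueError("correlation undefined: zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def flat_pcc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two arrays flattened."""
    x, y = np.asarray(x, float).ravel(), np.asarray(y, float).ravel()
    if np.isclose(x.std(), 0) or np.isclose(y.std(), 0):
        raise ValueError("correlation undefined: zero variance")
    return float(np.corrcoef(x, y)[0, 1])
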