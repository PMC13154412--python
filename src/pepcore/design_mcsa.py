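"""Monte Carlo simulated annealing design of peptide sets (MC1 / MC2).

The annealer evolves a whole M-sequence set so that its coupling matrix
matches a native target. The outer loop lowers the temperature geometrically
(``T_k = T0 * decay**k``); the inner loop proposes mutations judged by the
Metropolis criterion on the coupling objective. By default each inner
iteration mutates one randomly chosen sequence (8% per cell) and accepts or
rejects that sequence's move; ``move_mode="set"`` instead mutates all M
sequences and decides the whole sweep as a unit (coarser moves, which stall
well short of convergence at realistic scales).

MC1: random initialization, uniform mutation proposals (coupling-only).
MC2: FS initialization, frequency-guided proposals (frequency + coupling).

Pairwise residue counts are maintained incrementally per accepted sweep;
``debug_full_check_every`` cross-checks the tallies against a from-scratch
recount (used by the test suite to prove the incremental path).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design_fs import sample_encoded_fs
from .evostats import (
    BackgroundFrequencies,
    CouplingMatrix,
    FrequencyProfile,
    PositionalWeights,
    coupling_from_arrays,
    pair_counts,
    regularize_joint,
    regularize_site,
    site_counts,
)
from .peptide_io import ALPHABET, PeptideAlignment, decode_alignment


@dataclass
class TargetStatistics:
    """Native statistics the annealer optimizes against (shared pseudocount
    and background with the design-set statistics)."""

    fp: FrequencyProfile
    bg: BackgroundFrequencies
    coupling: CouplingMatrix

    @classmethod
    def from_alignment(cls, aln: PeptideAlignment, pseudocount: float = 1e-3,
                       bg_mode: str = "pooled") -> "TargetStatistics":
        from .evostats import alignment_statistics, background_frequencies

        bg = background_frequencies(aln, bg_mode, pseudocount)
        fp, _, _, _, _, cm = alignment_statistics(aln, bg, pseudocount)
        return cls(fp=fp, bg=bg, coupling=cm)


@dataclass
class AnnealConfig:
    n_outer: int = 2000
    n_inner: int = 2000
    T0: float = 15.0
    decay: float = 0.99
    mutation_prob: float = 0.08
    diag_weight: float = 0.1
    init_mode: str = "random"            # {random, fs}
    proposal_mode: str = "uniform"       # {uniform, frequency_guided}
    move_mode: str = "sequence"          # {sequence, set}
    M: int = 200
    seed: int = 0
    pseudocount: float = 1e-3
    early_stop_rejections: int | None = None
    record_trajectory: bool = True
    debug_full_check_every: int = 0      # 0 disables the from-scratch check

    def __post_init__(self) -> None:
        if not (0 < self.decay < 1):
            raise ValueError("decay must lie in (0, 1)")
        if self.T0 <= 0:
            raise ValueError("T0 must be positive")
        if not (0 < self.mutation_prob <= 1):
            raise ValueError("mutation_prob must lie in (0, 1]")
        if self.diag_weight < 0:
            raise ValueError("diag_weight must be non-negative")
        if self.init_mode not in ("random", "fs"):
            raise ValueError(f"unknown init_mode {self.init_mode!r}")
        if self.proposal_mode not in ("uniform", "frequency_guided"):
            raise ValueError(f"unknown proposal_mode {self.proposal_mode!r}")
        if self.move_mode not in ("sequence", "set"):
            raise ValueError(f"unknown move_mode {self.move_mode!r}")
        if self.M < 1 or self.n_outer < 1 or self.n_inner < 1:
            raise ValueError("M, n_outer and n_inner must be >= 1")
        if not (0 < self.pseudocount < 1):
            raise ValueError("anneal requires a pseudocount in (0, 1)")

    @classmethod
    def mc1(cls, **kw) -> "AnnealConfig":
        kw.setdefault("init_mode", "random")
        kw.setdefault("proposal_mode", "uniform")
        return cls(**kw)

    @classmethod
    def mc2(cls, **kw) -> "AnnealConfig":
        kw.setdefault("init_mode", "fs")
        kw.setdefault("proposal_mode", "frequency_guided")
        return cls(**kw)


@dataclass
class AnnealResult:
    design: PeptideAlignment
    trajectory: dict[str, np.ndarray]
    initial_E: float
    final_E: float


def objective(
    design_C: CouplingMatrix | np.ndarray,
    native_C: CouplingMatrix | np.ndarray,
    diag_weight: float = 0.1,
) -> float:
    """Weighted sum of squared coupling differences; diagonal terms are
    down-weighted because they dominate the raw objective."""
    a = design_C.C2 if isinstance(design_C, CouplingMatrix) else np.asarray(design_C, float)
    b = native_C.C2 if isinstance(native_C, CouplingMatrix) else np.asarray(native_C, float)
    if a.shape != b.shape:
        raise ValueError("coupling matrices must share a shape")
    d2 = (a - b) ** 2
    diag = np.trace(d2)
    return float(d2.sum() - diag + diag_weight * diag)


def metropolis_accept(delta_E: float, T: float, rng: np.random.Generator) -> bool:
    """Accept non-uphill moves always; uphill with probability exp(-dE/T)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    if delta_E <= 0:
        return True
    return bool(rng.random() < np.exp(-delta_E / T))


def propose(
    design: np.ndarray,
    mutation_prob: float,
    proposal_mode: str,
    fp: FrequencyProfile | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One whole-set mutation sweep.

    Each (sequence, position) cell mutates independently with probability
    ``mutation_prob``. Uniform mode replaces with one of the other A-1
    residues; frequency-guided mode resamples from ``fp.f[i]`` (possibly
    returning the same residue). Returns the mutated copy and the integer
    index array of rows that actually changed.
    """
    if proposal_mode == "frequency_guided" and fp is None:
        raise ValueError("frequency_guided proposals require a frequency profile")
    A = len(ALPHABET) if fp is None else fp.A
    new = design.copy()
    mask = rng.random(design.shape) < mutation_prob
    rows, cols = np.nonzero(mask)
    if rows.size:
        if proposal_mode == "uniform":
            offsets = rng.integers(1, A, size=rows.size)
            new[rows, cols] = (design[rows, cols] + offsets) % A
        else:
            cdf = np.cumsum(fp.f, axis=1)
            u = rng.random(rows.size)
            new[rows, cols] = (u[:, None] > cdf[cols]).sum(axis=1)
    changed_rows = np.nonzero((new != design).any(axis=1))[0]
    return new, changed_rows


def _propose_one_sequence(
    design: np.ndarray,
    mutation_prob: float,
    proposal_mode: str,
    fp: FrequencyProfile | None,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Mutate one randomly chosen sequence (per-cell rule as in
    :func:`propose`); over an inner loop all M sequences get visited.
    Accepting or rejecting per mutated sequence keeps moves fine-grained
    enough for the annealer to converge."""
    if proposal_mode == "frequency_guided" and fp is None:
        raise ValueError("frequency_guided proposals require a frequency profile")
    A = len(ALPHABET) if fp is None else fp.A
    M, L = design.shape
    row = int(rng.integers(M))
    mask = rng.random(L) < mutation_prob
    cols = np.nonzero(mask)[0]
    new = design.copy()
    if cols.size:
        if proposal_mode == "uniform":
            offsets = rng.integers(1, A, size=cols.size)
            new[row, cols] = (design[row, cols] + offsets) % A
        else:
            cdf = np.cumsum(fp.f, axis=1)
            u = rng.random(cols.size)
            new[row, cols] = (u[:, None] > cdf[cols]).sum(axis=1)
    changed = (np.array([row]) if (new[row] != design[row]).any()
               else np.empty(0, dtype=int))
    return new, changed


class _PairTally:
    """Incrementally maintained site and ordered-pair residue counts."""

    def __init__(self, encoded: np.ndarray, A: int) -> None:
        self.A = A
        self.M, self.L = encoded.shape
        self.site = site_counts(encoded, A)
        self.pair = pair_counts(encoded, A)
        self._flat = self.pair.reshape(-1)
        ii, jj = np.nonzero(~np.eye(self.L, dtype=bool))
        self._I, self._J = ii, jj                       # ordered off-diag pairs
        self._diag = np.arange(self.L)

    def _lin(self, rows_mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        A, L = self.A, self.L
        a = rows_mat[:, self._I]
        b = rows_mat[:, self._J]
        off = ((self._I * A + a) * L + self._J) * A + b
        d = rows_mat[:, self._diag]
        diag = ((self._diag * A + d) * L + self._diag) * A + d
        return off.ravel(), diag.ravel()

    def swap_rows(self, old_rows: np.ndarray, new_rows: np.ndarray) -> None:
        """Replace the contribution of ``old_rows`` with ``new_rows``."""
        off_o, diag_o = self._lin(old_rows)
        off_n, diag_n = self._lin(new_rows)
        np.subtract.at(self._flat, off_o, 1)
        np.subtract.at(self._flat, diag_o, 1)
        np.add.at(self._flat, off_n, 1)
        np.add.at(self._flat, diag_n, 1)
        for i in range(self.L):
            self.site[i] -= np.bincount(old_rows[:, i], minlength=self.A)
            self.site[i] += np.bincount(new_rows[:, i], minlength=self.A)

    def verify(self, encoded: np.ndarray, atol: float = 1e-9) -> None:
        """Assert tallies match a from-scratch recount of ``encoded``."""
        ref_site = site_counts(encoded, self.A)
        ref_pair = pair_counts(encoded, self.A)
        if not (np.abs(self.site - ref_site).max() <= atol
                and np.abs(self.pair - ref_pair).max() <= atol):
            raise AssertionError("incremental tallies diverged from full recount")


def _design_energy(
    tally: _PairTally, q: np.ndarray, native_C: np.ndarray,
    pseudocount: float, diag_weight: float,
) -> tuple[float, np.ndarray]:
    f = regularize_site(tally.site, tally.M, pseudocount)
    k = np.log(f * (1.0 - q) / (q * (1.0 - f)))
    fj = regularize_joint(tally.pair, tally.M, pseudocount)
    C = coupling_from_arrays(fj, f, k)
    return objective(C, native_C, diag_weight), C


def anneal(native_stats: TargetStatistics, cfg: AnnealConfig) -> AnnealResult:
    """Run the two-level annealing loop; fully reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    fp, q = native_stats.fp, native_stats.bg.q
    native_C = native_stats.coupling.C2
    L, A = fp.L, fp.A

    if cfg.init_mode == "random":
        design = rng.integers(0, A, size=(cfg.M, L), dtype=np.int64)
    else:
        design = sample_encoded_fs(fp, cfg.M, rng)

    tally = _PairTally(design, A)
    E, _ = _design_energy(tally, q, native_C, cfg.pseudocount, cfg.diag_weight)
    initial_E = E
    best_E = E
    best_design = design.copy()

    traj: dict[str, list] = {k: [] for k in
                             ("outer", "inner", "T", "E", "best_E", "accepted")}
    rejection_streak = 0
    step = 0
    stop = False
    guided_fp = fp if cfg.proposal_mode == "frequency_guided" else None

    for outer in range(cfg.n_outer):
        T = cfg.T0 * cfg.decay ** outer
        for inner in range(cfg.n_inner):
            step += 1
            if cfg.move_mode == "sequence":
                new, changed = _propose_one_sequence(
                    design, cfg.mutation_prob, cfg.proposal_mode, guided_fp, rng
                )
            else:
                new, changed = propose(
                    design, cfg.mutation_prob, cfg.proposal_mode, guided_fp, rng
                )
            if changed.size:
                tally.swap_rows(design[changed], new[changed])
                E_new, _ = _design_energy(
                    tally, q, native_C, cfg.pseudocount, cfg.diag_weight
                )
            else:
                E_new = E
            accepted = metropolis_accept(E_new - E, T, rng)
            if accepted:
                design = new
                E = E_new
                rejection_streak = 0
                if E < best_E:
                    best_E = E
                    best_design = design.copy()
            else:
                if changed.size:  # revert tallies
                    tally.swap_rows(new[changed], design[changed])
                rejection_streak += 1
            if cfg.debug_full_check_every and step % cfg.debug_full_check_every == 0:
                tally.verify(design)
            if cfg.record_trajectory:
                traj["outer"].append(outer)
                traj["inner"].append(inner)
                traj["T"].append(T)
                traj["E"].append(E)
                traj["best_E"].append(best_E)
                traj["accepted"].append(accepted)
            if (cfg.early_stop_rejections is not None
                    and rejection_streak >= cfg.early_stop_rejections):
                stop = True
                break
        if stop:
            break

    trajectory = {k: np.asarray(v) for k, v in traj.items()}
    return AnnealResult(
        design=decode_alignment(best_design),
        trajectory=trajectory,
        initial_E=float(initial_E),
        final_E=float(best_E),
    )


def temperature_schedule(T0: float, decay: float, n_outer: int) -> np.ndarray:
    """Geometric cooling schedule ``T_k = T0 * decay**k`` for k = 0..n-1."""
    return T0 * decay ** np.arange(n_outer)
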