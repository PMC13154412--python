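"""Evaluation of designed peptide sets against their native targets.

Produces the comparison artifacts used throughout: conservation profiles,
coupling matrices, Pearson correlations of first- and second-order
statistics, and an export bundle (FASTA + CSV matrices + key/value summary)
for downstream affinity / structure tools.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import evostats
from .evostats import (
    BackgroundFrequencies,
    background_frequencies,
    coupling_pcc,
    flat_pcc,
)
from .peptide_io import ALPHABET, PeptideAlignment, decode_alignment, write_designed

STRATEGIES = ("FS", "L1", "L2", "MC1", "MC2", "random", "native")


def random_baseline(L: int, n: int, seed: int, allotype: str = "") -> PeptideAlignment:
    """Uniform i.i.d. sequences over the 20-letter alphabet."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    enc = rng.integers(0, len(ALPHABET), size=(n, L))
    return decode_alignment(enc, allotype=allotype)


@dataclass
class DesignReport:
    strategy: str
    first_order_pcc: float
    coupling_pcc: float
    coupling_pcc_offdiag: float
    per_position_kl: np.ndarray          # designed vs native frequencies
    native_conservation: np.ndarray
    designed_conservation: np.ndarray
    native_coupling: np.ndarray
    designed_coupling: np.ndarray
    native_frequencies: np.ndarray
    designed_frequencies: np.ndarray

    def summary(self) -> dict[str, float]:
        return {
            "strategy": self.strategy,
            "first_order_pcc": self.first_order_pcc,
            "coupling_pcc": self.coupling_pcc,
            "coupling_pcc_offdiag": self.coupling_pcc_offdiag,
            "mean_position_kl": float(self.per_position_kl.mean()),
        }


def compare(
    native: PeptideAlignment,
    designed: PeptideAlignment,
    bg_mode: str = "pooled",
    pseudocount: float = 1e-3,
    strategy: str = "design",
    include_diagonal: bool = True,
) -> DesignReport:
    """Compute both statistics stacks under one shared background and
    pseudocount, then correlate them."""
    if native.L != designed.L:
        raise ValueError("native and designed alignments differ in length")
    # background pooled over both sets keeps the comparison symmetric in roles
    pooled = PeptideAlignment(native.sequences + designed.sequences)
    bg = background_frequencies(pooled, bg_mode, pseudocount)
    n_fp, _, n_cons, _, _, n_cm = evostats.alignment_statistics(
        native, bg, pseudocount
    )
    d_fp, _, d_cons, _, _, d_cm = evostats.alignment_statistics(
        designed, bg, pseudocount
    )
    kl = np.where(
        d_fp.f > 0, d_fp.f * np.log(d_fp.f / n_fp.f), 0.0
    ).sum(axis=1)
    return DesignReport(
        strategy=strategy,
        first_order_pcc=flat_pcc(d_fp.f, n_fp.f),
        coupling_pcc=coupling_pcc(d_cm, n_cm, include_diagonal=include_diagonal),
        coupling_pcc_offdiag=coupling_pcc(d_cm, n_cm, include_diagonal=False),
        per_position_kl=kl,
        native_conservation=n_cons.C,
        designed_conservation=d_cons.C,
        native_coupling=n_cm.C2,
        designed_coupling=d_cm.C2,
        native_frequencies=n_fp.f,
        designed_frequencies=d_fp.f,
    )


def _logo_frame(f: np.ndarray) -> pd.DataFrame:
    """Long-format logo data: position (1-based), residue, frequency."""
    L, A = f.shape
    rows = [
        {"position": i + 1, "residue": ALPHABET[a], "frequency": f[i, a]}
        for i in range(L)
        for a in range(A)
    ]
    return pd.DataFrame(rows)


BUNDLE_FILES = (
    "designed.fasta",
    "logo_native.csv",
    "logo_designed.csv",
    "coupling_native.csv",
    "coupling_designed.csv",
    "conservation.csv",
    "report.txt",
)


def export_bundle(
    report: DesignReport, designed: PeptideAlignment, outdir: str | Path
) -> list[Path]:
    """Write the full evaluation bundle into ``outdir``; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []

    p = outdir / "designed.fasta"
    write_designed(designed, p, "fasta", strategy=report.strategy)
    paths.append(p)

    for name, f in (
        ("logo_native.csv", report.native_frequencies),
        ("logo_designed.csv", report.designed_frequencies),
    ):
        p = outdir / name
        _logo_frame(f).to_csv(p, index=False)
        paths.append(p)

    for name, m in (
        ("coupling_native.csv", report.native_coupling),
        ("coupling_designed.csv", report.designed_coupling),
    ):
        p = outdir / name
        pd.DataFrame(m).to_csv(p, index=False, header=False)
        paths.append(p)

    p = outdir / "conservation.csv"
    pd.DataFrame(
        {
            "position": np.arange(1, len(report.native_conservation) + 1),
            "native_C": report.native_conservation,
            "designed_C": report.designed_conservation,
            "designed_vs_native_KL": report.per_position_kl,
        }
    ).to_csv(p, index=False)
    paths.append(p)

    p = outdir / "report.txt"
    with open(p, "w") as fh:
        for key, val in report.summary().items():
            fh.write(f"{key}\t{val}\n")
    paths.append(p)
    return paths


def read_coupling_csv(path: str | Path) -> np.ndarray:
    return pd.read_csv(path, header=None).to_numpy(dtype=float)
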