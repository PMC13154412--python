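"""Reading, validation, encoding and writing of fixed-length peptide alignments.

All downstream statistics assume the fixed alphabet ordering defined by
:data:`ALPHABET` (alphabetical one-letter amino-acid codes).  Positions are
reported 1-based in user-facing output; arrays are 0-based internally.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Canonical 20-letter amino-acid alphabet, alphabetical one-letter codes.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
ALPHABET_INDEX = {c: i for i, c in enumerate(ALPHABET)}

FORMATS = ("fasta", "lines", "table")


class AlignmentError(ValueError):
    """Raised when an alignment or a sequence fails validation."""


def _validate_sequence(seq: str, length: int) -> None:
    if len(seq) != length:
        raise AlignmentError(
            f"sequence {seq!r} has length {len(seq)}, expected {length}"
        )
    for ch in seq:
        if ch not in ALPHABET_INDEX:
            raise AlignmentError(
                f"sequence {seq!r} contains non-canonical character {ch!r}"
            )


@dataclass
class PeptideAlignment:
    """A gap-free alignment of M peptides of identical length L.

    Parameters
    ----------
    sequences:
        Upper-case peptide strings over the canonical 20-letter alphabet.
    allotype:
        Free-text HLA allotype label, e.g. ``"HLA-DRB5*01:01"``.
    """

    sequences: list[str]
    allotype: str = ""

    def __post_init__(self) -> None:
        if not self.sequences:
            raise AlignmentError("alignment must contain at least one sequence")
        self.sequences = [s.upper() for s in self.sequences]
        length = len(self.sequences[0])
        for seq in self.sequences:
            _validate_sequence(seq, length)

    @property
    def M(self) -> int:
        return len(self.sequences)

    @property
    def L(self) -> int:
        return len(self.sequences[0])

    def __len__(self) -> int:
        return self.M

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequences)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PeptideAlignment):
            return NotImplemented
        return self.sequences == other.sequences and self.allotype == other.allotype


@dataclass
class AllotypeDataset:
    """Ordered map from allotype label to its :class:`PeptideAlignment`."""

    entries: dict[str, PeptideAlignment] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {aln.L for aln in self.entries.values()}
        if len(lengths) > 1:
            raise AlignmentError(f"alignments have inconsistent lengths: {lengths}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[str]:
        return iter(self.entries)

    def __getitem__(self, allotype: str) -> PeptideAlignment:
        return self.entries[allotype]

    def items(self):
        return self.entries.items()

    @property
    def L(self) -> int:
        if not self.entries:
            raise AlignmentError("empty dataset has no length")
        return next(iter(self.entries.values())).L


def encode_alignment(aln: PeptideAlignment) -> np.ndarray:
    """Encode an alignment as an ``(M, L)`` integer matrix over 0..19."""
    out = np.empty((aln.M, aln.L), dtype=np.int64)
    for m, seq in enumerate(aln.sequences):
        for i, ch in enumerate(seq):
            try:
                out[m, i] = ALPHABET_INDEX[ch]
            except KeyError:
                raise AlignmentError(f"unknown character {ch!r}") from None
    return out


def decode_alignment(matrix: np.ndarray, allotype: str = "") -> PeptideAlignment:
    """Inverse of :func:`encode_alignment`."""
    matrix = np.asarray(matrix)
    if matrix.ndim != 2:
        raise AlignmentError("encoded alignment must be 2-D")
    if matrix.min() < 0 or matrix.max() >= len(ALPHABET):
        raise AlignmentError("encoded values out of alphabet range")
    seqs = ["".join(ALPHABET[v] for v in row) for row in matrix]
    return PeptideAlignment(seqs, allotype=allotype)


def _read_fasta(path: Path) -> list[tuple[str, str]]:
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def _read_lines(path: Path) -> list[tuple[str, str]]:
    out = []
    with open(path) as fh:
        for n, line in enumerate(fh):
            line = line.strip()
            if line and not line.startswith("#"):
                out.append((f"seq{n + 1}", line))
    return out


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_alignment(
    path: str | Path,
    format: str = "fasta",
    length: int | None = None,
    allotype: str = "",
    strict: bool = True,
) -> PeptideAlignment | AllotypeDataset:
    """Read peptides from ``path`` in one of the supported dialects.

    ``fasta`` and ``lines`` yield a single :class:`PeptideAlignment`;
    ``table`` (two columns ``allotype``, ``peptide`` with a header row)
    yields an :class:`AllotypeDataset`.

    In strict mode any invalid sequence raises; in lenient mode invalid
    sequences are dropped and the count is logged.
    """
    path = Path(path)
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    if not path.exists():
        raise FileNotFoundError(path)

    if format == "table":
        delim = _sniff_delimiter(path)
        groups: dict[str, list[str]] = {}
        with open(path, newline="") as fh:
            reader = csv.reader(fh, delimiter=delim)
            header = next(reader, None)
            if header is None:
                raise AlignmentError(f"{path}: empty table")
            for row in reader:
                if not row or not "".join(row).strip():
                    continue
                if len(row) < 2:
                    raise AlignmentError(f"{path}: malformed row {row!r}")
                groups.setdefault(row[0].strip(), []).append(row[1].strip())
        entries = {}
        for label, seqs in groups.items():
            entries[label] = _build_alignment(seqs, length, label, strict, str(path))
        if not entries:
            raise AlignmentError(f"{path}: no valid sequences")
        return AllotypeDataset(entries)

    pairs = _read_fasta(path) if format == "fasta" else _read_lines(path)
    seqs = [s for _, s in pairs]
    return _build_alignment(seqs, length, allotype, strict, str(path))


def _build_alignment(
    seqs: list[str], length: int | None, allotype: str, strict: bool, origin: str
) -> PeptideAlignment:
    if length is None and seqs:
        length = len(seqs[0])
    valid, dropped = [], 0
    for seq in seqs:
        seq = seq.upper()
        try:
            _validate_sequence(seq, length)
        except AlignmentError:
            if strict:
                raise
            dropped += 1
            continue
        valid.append(seq)
    if dropped:
        logger.warning("%s: dropped %d invalid sequence(s)", origin, dropped)
    if not valid:
        raise AlignmentError(f"{origin}: no valid sequences")
    return PeptideAlignment(valid, allotype=allotype)


def filter_allotypes(ds: AllotypeDataset, min_sequences: int = 200) -> AllotypeDataset:
    """Keep allotypes with at least ``min_sequences`` peptides (inclusive)."""
    kept, dropped = {}, []
    for label, aln in ds.items():
        if aln.M >= min_sequences:
            kept[label] = aln
        else:
            dropped.append(label)
    if dropped:
        logger.info(
            "filter_allotypes(min=%d): dropped %d allotype(s): %s",
            min_sequences,
            len(dropped),
            ", ".join(dropped),
        )
    return AllotypeDataset(kept)


def write_designed(
    aln: PeptideAlignment | AllotypeDataset,
    path: str | Path,
    format: str = "fasta",
    strategy: str = "design",
) -> None:
    """Write an alignment (or dataset, table dialect only) to ``path``.

    FASTA headers carry ``allotype|strategy|index`` so exports remain
    traceable when fed to external affinity / structure predictors.
    """
    path = Path(path)
    if format not in FORMATS:
        raise ValueError(f"unknown format {format!r}; expected one of {FORMATS}")
    if isinstance(aln, AllotypeDataset):
        if format != "table":
            raise ValueError("datasets can only be written in table format")
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["allotype", "peptide"])
            for label, sub in aln.items():
                for seq in sub:
                    writer.writerow([label, seq])
        return

    if format == "fasta":
        records = [
            SeqRecord(
                Seq(seq),
                id=f"{aln.allotype or 'unknown'}|{strategy}|{idx + 1}",
                description="",
            )
            for idx, seq in enumerate(aln)
        ]
        SeqIO.write(records, str(path), "fasta")
    elif format == "lines":
        path.write_text("".join(seq + "\n" for seq in aln))
    else:  # table
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t")
            writer.writerow(["allotype", "peptide"])
            for seq in aln:
                writer.writerow([aln.allotype, seq])
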