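"""Numeric encodings of RNA sequences.

The classifier consumes fixed-length windows of RNA sequence (101 nt by
default, the standard CLIP-peak window width).  Each window is one-hot
encoded over the alphabet A, C, G, U (alphabetical column order); ``N``
positions and padding become all-zero rows so they are inert under both
convolution and graph filtering.  The module also provides the classical
k-gram frequency features (all base permutations of length 1..k, 84
dimensions for k=3) and plain overlapping k-mer tokenisation, which are
alternative sequence representations used for comparison rather than by
the model itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
from Bio import SeqIO

#: Fixed column order of the one-hot encoding.
ALPHABET = "ACGU"

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

#: Default window width (nt) for encoded sequences.
DEFAULT_WINDOW = 101


@dataclass(frozen=True)
class NucleotideSequence:
    """An identified RNA sequence over {A, C, G, U, N}.

    DNA-style ``T`` (and lowercase input) is accepted and normalised to
    ``U`` on construction; any other character is rejected with its
    position.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: empty residue string")
        normalised = self.residues.upper().replace("T", "U")
        for pos, ch in enumerate(normalised):
            if ch not in "ACGUN":
                raise ValueError(
                    f"sequence {self.id!r}: invalid residue {ch!r} at position {pos}"
                )
        object.__setattr__(self, "residues", normalised)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def n_informative(self) -> int:
        """Number of non-N positions."""
        return len(self.residues) - self.residues.count("N")


@dataclass(frozen=True)
class OneHotMatrix:
    """L x 4 one-hot encoding of a sequence window.

    Rows sum to 1 for an informative position and to 0 for N or padding.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != 4:
            raise ValueError(f"one-hot matrix must be L x 4, got {v.shape}")
        object.__setattr__(self, "values", v)

    @property
    def length(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class KGramVector:
    """Per-order frequency tables of all base permutations of length 1..k.

    ``counts_by_order[i]`` holds the 4**i frequencies of order ``i``
    (lexicographic over A,C,G,U); the concatenated dimension is
    sum(4**i for i in 1..k) — 84 for k=3.
    """

    k: int
    counts_by_order: dict[int, np.ndarray] = field(repr=False)

    @property
    def vector(self) -> np.ndarray:
        return np.concatenate([self.counts_by_order[i] for i in range(1, self.k + 1)])

    @property
    def dimension(self) -> int:
        return sum(4**i for i in range(1, self.k + 1))


def one_hot_encode(seq: NucleotideSequence, window_length: int = DEFAULT_WINDOW) -> OneHotMatrix:
    """Encode a sequence as a fixed-size ``window_length`` x 4 matrix.

    Shorter sequences are right-padded with all-zero rows; longer ones are
    centre-truncated (CLIP peaks place the binding evidence centrally).
    """
    if window_length < 1:
        raise ValueError("window_length must be >= 1")
    residues = seq.residues
    if len(residues) > window_length:
        start = (len(residues) - window_length) // 2
        residues = residues[start : start + window_length]
    out = np.zeros((window_length, 4), dtype=float)
    for row, ch in enumerate(residues):
        if ch != "N":
            out[row, _BASE_INDEX[ch]] = 1.0
    return OneHotMatrix(out)


def kgram_features(seq: NucleotideSequence, k: int = 3) -> KGramVector:
    """Count all base permutations of lengths 1..k as per-order frequencies.

    Windows containing ``N`` are skipped.  Within each order the counts are
    normalised to sum to 1 (when at least one valid window exists).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if seq.n_informative < k:
        raise ValueError(
            f"sequence {seq.id!r}: needs at least {k} informative positions, "
            f"has {seq.n_informative}"
        )
    residues = seq.residues
    counts_by_order: dict[int, np.ndarray] = {}
    for order in range(1, k + 1):
        counts = np.zeros(4**order, dtype=float)
        for start in range(len(residues) - order + 1):
            window = residues[start : start + order]
            if "N" in window:
                continue
            idx = 0
            for ch in window:
                idx = idx * 4 + _BASE_INDEX[ch]
            counts[idx] += 1.0
        total = counts.sum()
        if total > 0:
            counts /= total
        counts_by_order[order] = counts
    return KGramVector(k=k, counts_by_order=counts_by_order)


def kmer_tokens(seq: NucleotideSequence, k: int, stride: int = 1) -> list[str]:
    """Overlapping k-length substrings of the sequence, in order."""
    if k < 1 or stride < 1:
        raise ValueError("k and stride must be >= 1")
    if seq.n_informative < k:
        raise ValueError(
            f"sequence {seq.id!r}: k={k} exceeds informative length {seq.n_informative}"
        )
    residues = seq.residues
    return [residues[i : i + k] for i in range(0, len(residues) - k + 1, stride)]


def read_fasta(path: str | Path) -> list[NucleotideSequence]:
    """Read a multi-record FASTA file into :class:`NucleotideSequence` records.

    The description line after ``>`` becomes the id.  Malformed input is
    rejected with a line number; records without sequence are rejected by
    name.
    """
    path = Path(path)
    _precheck_fasta(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise ValueError(f"{path}: record {rec.description!r} has no sequence")
        records.append(NucleotideSequence(id=rec.description, residues=str(rec.seq)))
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def _precheck_fasta(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if not stripped.startswith(">"):
                raise ValueError(
                    f"{path}: line {lineno}: expected a FASTA header line starting with '>'"
                )
            return
    raise ValueError(f"{path}: empty file")


def write_fasta(path: str | Path, sequences: Iterator[NucleotideSequence] | list[NucleotideSequence]) -> None:
    """Write sequences as plain uncompressed FASTA."""
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n{seq.residues}\n")


def onehot_to_tsv(matrix: OneHotMatrix, path: str | Path) -> None:
    """Debug export: one row per position, 4 tab-separated columns (A,C,G,U)."""
    header = "\t".join(ALPHABET)
    np.savetxt(path, matrix.values, fmt="%.0f", delimiter="\t", header=header, comments="")
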