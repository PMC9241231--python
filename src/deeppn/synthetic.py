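"""Planted-motif synthetic benchmark emulating CLIP-style datasets.

Real training data for this problem are paired positive/negative FASTA
sets derived from CLIP-seq peaks.  The generator reproduces their
structure with known ground truth: positives are i.i.d. background
sequence with one motif instance sampled from a position-probability
matrix planted at a uniformly random offset; negatives are background
draws, mononucleotide shuffles, or dinucleotide (Euler-path) shuffles of
motif-bearing sequences — the dinucleotide shuffle being the standard
CLIP negative control that preserves local composition.

The ``default-bench`` preset (1000+1000 sequences of length 101, a deterministic
6-nt consensus UGCAUG motif, dinucleotide-shuffle negatives) is the fixed benchmark the end-to-end tests train on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import LabeledDataset
from .seq_encoding import ALPHABET, NucleotideSequence, write_fasta

_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}

NEGATIVE_MODES = ("background", "shuffle", "dinucleotide_shuffle")


@dataclass(frozen=True)
class MotifModel:
    """Position-probability matrix over A,C,G,U (rows), width m (columns)."""

    pwm: np.ndarray
    name: str = "motif"

    def __post_init__(self) -> None:
        pwm = np.asarray(self.pwm, dtype=float)
        if pwm.ndim != 2 or pwm.shape[0] != 4:
            raise ValueError(f"pwm must be 4 x width, got {pwm.shape}")
        if np.any(pwm < 0):
            raise ValueError("pwm entries must be non-negative")
        if not np.allclose(pwm.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("pwm columns must each sum to 1")
        object.__setattr__(self, "pwm", pwm)

    @property
    def width(self) -> int:
        return self.pwm.shape[1]

    @classmethod
    def from_consensus(cls, consensus: str, strength: float = 1.0, name: str | None = None) -> "MotifModel":
        """PWM placing ``strength`` on the consensus base per column and
        spreading the rest uniformly over the other three bases."""
        consensus = consensus.upper().replace("T", "U")
        if not 0.25 <= strength <= 1.0:
            raise ValueError("strength must be in [0.25, 1]")
        pwm = np.full((4, len(consensus)), (1.0 - strength) / 3.0)
        for col, ch in enumerate(consensus):
            if ch not in _BASE_INDEX:
                raise ValueError(f"invalid consensus base {ch!r}")
            pwm[_BASE_INDEX[ch], col] = strength
        return cls(pwm=pwm, name=name or consensus)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset."""

    n_pos: int = 1000
    n_neg: int = 1000
    seq_length: int = 101
    motif: MotifModel = field(default_factory=lambda: MotifModel.from_consensus("UGCAUG", 1.0))
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    negative_mode: str = "dinucleotide_shuffle"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("counts must be >= 1")
        if abs(sum(self.background) - 1.0) > 1e-9 or any(b < 0 for b in self.background):
            raise ValueError("background composition must be a probability vector")
        if self.motif.width >= self.seq_length:
            raise ValueError("motif width must be smaller than seq_length")
        if self.negative_mode not in NEGATIVE_MODES:
            raise ValueError(f"negative_mode must be one of {NEGATIVE_MODES}")


def default_bench_config(seed: int = 1) -> SimulationConfig:
    """The fixed end-to-end benchmark preset ("default-bench")."""
    return SimulationConfig(seed=seed)


def sample_background(
    length: int, composition: tuple[float, ...], rng: np.random.Generator, seq_id: str = "bg"
) -> NucleotideSequence:
    """Draw i.i.d. positions from the base composition."""
    codes = rng.choice(4, size=length, p=np.asarray(composition, dtype=float))
    return NucleotideSequence(id=seq_id, residues="".join(ALPHABET[c] for c in codes))


def plant_motif(
    seq: NucleotideSequence, motif: MotifModel, rng: np.random.Generator
) -> tuple[NucleotideSequence, int]:
    """Replace a uniformly chosen window with a PWM-sampled motif instance.

    Returns the modified sequence and the 0-based planted offset for
    ground-truth audits.
    """
    m = motif.width
    if m > len(seq):
        raise ValueError("motif wider than the sequence")
    pos = int(rng.integers(0, len(seq) - m + 1))
    instance = "".join(
        ALPHABET[int(rng.choice(4, p=motif.pwm[:, col]))] for col in range(m)
    )
    residues = seq.residues[:pos] + instance + seq.residues[pos + m :]
    return NucleotideSequence(id=seq.id, residues=residues), pos


def shuffle_negative(
    seq: NucleotideSequence, mode: str, rng: np.random.Generator
) -> NucleotideSequence:
    """Composition-preserving shuffle used to build negative controls.

    "shuffle" permutes residues (mononucleotide counts preserved);
    "dinucleotide_shuffle" preserves all adjacent-pair counts via a random
    Euler path through the dinucleotide multigraph.
    """
    if mode == "shuffle":
        chars = list(seq.residues)
        perm = rng.permutation(len(chars))
        return NucleotideSequence(id=seq.id, residues="".join(chars[i] for i in perm))
    if mode == "dinucleotide_shuffle":
        return NucleotideSequence(id=seq.id, residues=_dinucleotide_shuffle(seq.residues, rng))
    raise ValueError(f"unknown shuffle mode {mode!r}")


def _dinucleotide_shuffle(s: str, rng: np.random.Generator) -> str:
    """Altschul–Erickson shuffle: a uniform random Eulerian walk over the
    dinucleotide multigraph, preserving every adjacent-pair count and the
    first and last residue."""
    if len(s) < 3 or len(set(s)) == 1:
        return s
    vertices = sorted(set(s))
    edges: dict[str, list[str]] = {v: [] for v in vertices}
    for a, b in zip(s, s[1:]):
        edges[a].append(b)
    last = s[-1]

    # Choose a random "last edge" for every vertex except the terminal one,
    # retrying until those last edges form a tree oriented toward the terminal
    # vertex (the connectivity condition for an Eulerian walk).
    non_terminal = [v for v in vertices if v != last and edges[v]]
    while True:
        last_edge = {v: edges[v][int(rng.integers(len(edges[v])))] for v in non_terminal}
        ok = True
        for v in non_terminal:
            seen = {v}
            cur = v
            while cur != last:
                cur = last_edge.get(cur)
                if cur is None or cur in seen:
                    ok = False
                    break
                seen.add(cur)
            if not ok:
                break
        if ok:
            break

    shuffled_edges: dict[str, list[str]] = {}
    for v in vertices:
        rest = list(edges[v])
        if v in last_edge:
            rest.remove(last_edge[v])
        perm = rng.permutation(len(rest))
        ordered = [rest[i] for i in perm]
        if v in last_edge:
            ordered.append(last_edge[v])
        shuffled_edges[v] = ordered

    out = [s[0]]
    counters = {v: 0 for v in vertices}
    cur = s[0]
    for _ in range(len(s) - 1):
        nxt = shuffled_edges[cur][counters[cur]]
        counters[cur] += 1
        out.append(nxt)
        cur = nxt
    return "".join(out)


def generate_dataset(config: SimulationConfig) -> tuple[LabeledDataset, pd.DataFrame]:
    """Build a class-balanced labeled dataset plus its ground-truth table.

    The truth table has one row per record: id, label, and the planted
    motif offset (-1 for negatives).  Fully reproducible from the seed.
    """
    rng = np.random.default_rng(config.seed)
    records = []
    truth_rows = []
    for i in range(config.n_pos):
        bg = sample_background(config.seq_length, config.background, rng, seq_id=f"pos_{i:05d}")
        seq, pos = plant_motif(bg, config.motif, rng)
        records.append((seq, 1))
        truth_rows.append({"id": seq.id, "label": 1, "planted_position": pos})
    for i in range(config.n_neg):
        if config.negative_mode == "background":
            seq = sample_background(
                config.seq_length, config.background, rng, seq_id=f"neg_{i:05d}"
            )
        else:
            bg = sample_background(
                config.seq_length, config.background, rng, seq_id=f"neg_{i:05d}"
            )
            planted, _ = plant_motif(bg, config.motif, rng)
            seq = shuffle_negative(planted, config.negative_mode, rng)
        records.append((seq, 0))
        truth_rows.append({"id": seq.id, "label": 0, "planted_position": -1})
    return LabeledDataset(tuple(records)), pd.DataFrame(truth_rows)


def write_dataset(
    dataset: LabeledDataset, truth: pd.DataFrame, out_prefix: str | Path
) -> tuple[Path, Path, Path]:
    """Emit <prefix>.positives.fa, <prefix>.negatives.fa and <prefix>.truth.tsv."""
    out_prefix = Path(out_prefix)
    pos_path = out_prefix.with_name(out_prefix.name + ".positives.fa")
    neg_path = out_prefix.with_name(out_prefix.name + ".negatives.fa")
    truth_path = out_prefix.with_name(out_prefix.name + ".truth.tsv")
    write_fasta(pos_path, [s for s, y in dataset.records if y == 1])
    write_fasta(neg_path, [s for s, y in dataset.records if y == 0])
    truth.to_csv(truth_path, sep="\t", index=False)
    return pos_path, neg_path, truth_path
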