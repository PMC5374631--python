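"""Position-specific log-odds profiles of mono- and di-nucleotides.

A mono-nucleotide profile (mPWM) contrasts, position by position, the
nucleotide frequencies of binding sequences against non-binding sequences:

    mPWM(i, j) = ln( f+(i, j) / f-(i, j) )

where f+/f- are the per-position relative frequencies of nucleotide i at
position j in the positive/negative training sets. The di-nucleotide profile
(dPWM) applies the same construction to overlapping di-nucleotides, giving
n - 1 columns for sequences of length n. Frequencies are additively smoothed
with a pseudocount so the log-odds stay finite; the same pseudocount on both
classes keeps the profile antisymmetric under class exchange.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .seq_io import SequenceRecord

RNA_BASES = "ACGU"


def kmer_alphabet(k: int) -> list[str]:
    """All 4^k RNA k-mers in lexicographic order A < C < G < U."""
    return ["".join(p) for p in product(RNA_BASES, repeat=k)]


def _sequences(seqs: Iterable[SequenceRecord | str]) -> list[str]:
    return [s.sequence if isinstance(s, SequenceRecord) else s for s in seqs]


@dataclass(frozen=True)
class FrequencyMatrix:
    """Per-position k-mer relative frequencies over a set of equal-length
    sequences, with additive smoothing.

    ``freq`` has shape (4^k, L) with rows in lexicographic k-mer order and
    L = n - k + 1 columns; every column sums to 1.
    """

    k: int
    n: int
    freq: np.ndarray
    alpha: float
    n_sequences: int

    @property
    def positions(self) -> int:
        return self.n - self.k + 1

    def __post_init__(self) -> None:
        expected = (4**self.k, self.positions)
        if self.freq.shape != expected:
            raise ValueError(f"freq shape {self.freq.shape} != {expected}")
        sums = self.freq.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise ValueError("frequency columns must sum to 1")


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Log-odds scores (natural log) per (k-mer, position).

    ``score`` has shape (4^k, L): 4 x n for mono-nucleotides, 16 x (n-1)
    for di-nucleotides.
    """

    k: int
    score: np.ndarray
    alpha: float

    @property
    def positions(self) -> int:
        return self.score.shape[1]

    @property
    def sequence_length(self) -> int:
        """Length of the sequences the matrix was built from."""
        return self.positions + self.k - 1

    def __post_init__(self) -> None:
        if self.k not in (1, 2):
            raise ValueError(f"order k={self.k} unsupported (use 1 or 2)")
        if self.score.shape[0] != 4**self.k:
            raise ValueError(
                f"score has {self.score.shape[0]} rows, expected {4 ** self.k}"
            )
        if self.positions < 1:
            raise ValueError("matrix must have at least one position")


_KMER_INDEX = {k: {s: i for i, s in enumerate(kmer_alphabet(k))} for k in (1, 2, 3)}


def count_kmer_frequencies(
    seqs: Sequence[SequenceRecord | str],
    k: int,
    n: int | None = None,
    alpha: float = 1.0,
) -> FrequencyMatrix:
    """Count k-mer occurrences per start position across equal-length
    sequences and normalize to smoothed relative frequencies:

        freq(s, j) = (count(s, j) + alpha) / (N + 4^k * alpha)
    """
    if k not in (1, 2):
        raise ValueError(f"order k={k} unsupported (use 1 or 2)")
    if alpha < 0:
        raise ValueError("pseudocount alpha must be nonnegative")
    strings = _sequences(seqs)
    if not strings:
        raise ValueError("cannot build a frequency matrix from zero sequences")
    if n is None:
        n = len(strings[0])
    for idx, s in enumerate(strings):
        if len(s) != n:
            name = seqs[idx].id if isinstance(seqs[idx], SequenceRecord) else f"#{idx}"
            raise ValueError(
                f"sequence {name} has length {len(s)}, expected {n}"
            )
    L = n - k + 1
    if L < 1:
        raise ValueError(f"sequence length {n} too short for order k={k}")
    index = _KMER_INDEX[k]
    counts = np.zeros((4**k, L), dtype=float)
    for s in strings:
        for j in range(L):
            counts[index[s[j : j + k]], j] += 1
    denom = len(strings) + (4**k) * alpha
    if denom == 0:
        raise ValueError("empty input with alpha=0")
    freq = (counts + alpha) / denom
    return FrequencyMatrix(k=k, n=n, freq=freq, alpha=alpha, n_sequences=len(strings))


def build_pwm(
    pos: Sequence[SequenceRecord | str],
    neg: Sequence[SequenceRecord | str],
    k: int = 1,
    alpha: float = 1.0,
) -> PositionWeightMatrix:
    """Build a log-odds profile contrasting positive against negative
    training sequences: score(s, j) = ln(f+(s, j) / f-(s, j)).

    Both frequency matrices use the same pseudocount; with alpha = 0 a zero
    frequency in either class raises instead of producing infinities.
    """
    n = len(pos[0].sequence if isinstance(pos[0], SequenceRecord) else pos[0])
    fpos = count_kmer_frequencies(pos, k, n, alpha)
    fneg = count_kmer_frequencies(neg, k, n, alpha)
    if alpha == 0 and ((fpos.freq == 0).any() or (fneg.freq == 0).any()):
        raise ValueError(
            "zero frequency encountered with alpha=0; "
            "set a positive pseudocount to keep log-odds finite"
        )
    score = np.log(fpos.freq / fneg.freq)
    return PositionWeightMatrix(k=k, score=score, alpha=alpha)


def profile_terms(seq: str | SequenceRecord, pwm: PositionWeightMatrix) -> np.ndarray:
    """Per-position log-odds terms of a sequence against a profile.

    Element j is the score of the k-mer starting at position j; this vector
    is exactly the profile block of the feature vector. The sequence must
    match the training length of the matrix.
    """
    s = seq.sequence if isinstance(seq, SequenceRecord) else seq
    if len(s) != pwm.sequence_length:
        raise ValueError(
            f"sequence length {len(s)} != matrix training length "
            f"{pwm.sequence_length}"
        )
    index = _KMER_INDEX[pwm.k]
    return np.array(
        [pwm.score[index[s[j : j + pwm.k]], j] for j in range(pwm.positions)]
    )


def best_offset(seq: str | SequenceRecord, pwm_mono: PositionWeightMatrix) -> int:
    """Ungapped alignment offset of a sequence against a mono-nucleotide
    profile of width w, maximizing the summed log-odds; ties go to the
    smallest offset.

    For sequences longer than w the offset indexes the best w-mer window of
    the sequence (0 .. m - w). For shorter sequences it indexes the matrix
    column where the sequence starts (0 .. w - m), summing only covered
    columns; overhangs past the matrix ends are not allowed.
    """
    if pwm_mono.k != 1:
        raise ValueError("best_offset requires a mono-nucleotide matrix")
    s = seq.sequence if isinstance(seq, SequenceRecord) else seq
    m, w = len(s), pwm_mono.positions
    index = _KMER_INDEX[1]
    rows = np.fromiter((index[ch] for ch in s), dtype=int, count=m)
    if m >= w:
        cols = np.arange(w)
        best_o, best_score = 0, -np.inf
        for o in range(m - w + 1):
            total = pwm_mono.score[rows[o : o + w], cols].sum()
            if total > best_score:
                best_o, best_score = o, total
        return best_o
    best_o, best_score = 0, -np.inf
    for o in range(w - m + 1):
        total = pwm_mono.score[rows, np.arange(o, o + m)].sum()
        if total > best_score:
            best_o, best_score = o, total
    return best_o


# -- serialization ------------------------------------------------------------

_HEADER_PREFIX = "#pwm"


def write_pwm(pwm: PositionWeightMatrix, path: str | Path) -> None:
    """Write a profile as a tab-separated symbols x positions table.

    The one-line header carries k, n and alpha; scores are printed at 17
    significant digits so a round trip is bit-stable.
    """
    symbols = kmer_alphabet(pwm.k)
    with open(path, "w") as fh:
        fh.write(
            f"{_HEADER_PREFIX}\tk={pwm.k}\tn={pwm.sequence_length}"
            f"\talpha={pwm.alpha!r}\n"
        )
        for sym, row in zip(symbols, pwm.score):
            fh.write(sym + "\t" + "\t".join(f"{v:.17g}" for v in row) + "\n")


def read_pwm(path: str | Path) -> PositionWeightMatrix:
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith(_HEADER_PREFIX):
            raise ValueError(f"{path}: not a PWM file (missing header)")
        fields = dict(item.split("=", 1) for item in header.split("\t")[1:])
        k = int(fields["k"])
        alpha = float(fields["alpha"])
        symbols = []
        rows = []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            symbols.append(parts[0])
            rows.append([float(v) for v in parts[1:]])
    if symbols != kmer_alphabet(k):
        raise ValueError(f"{path}: symbol rows out of order or incomplete")
    return PositionWeightMatrix(k=k, score=np.array(rows), alpha=alpha)
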