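"""Fixed-layout feature encoding of RNA (and optionally protein) sequences.

An RNA sequence of n nucleotides is encoded as 2n + 83 features: its n
per-position mono-nucleotide log-odds terms, its n - 1 di-nucleotide
log-odds terms, and 84 composition features (4 mono-, 16 di-, 64
tri-nucleotide frequencies). For the default 25-nt window this gives a
133-element vector; appending the 63-element
composition/transition/distribution (CTD) descriptor of the binding
protein gives 196.

Sequences shorter or longer than the profile window are aligned to the
mono-nucleotide profile without gaps at the maximum-scoring offset: longer
sequences contribute their best window to the profile blocks, shorter ones
are zero-filled where no nucleotide covers a matrix column. Compositions are
always taken over the entire sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .profiles import (
    _KMER_INDEX,
    PositionWeightMatrix,
    best_offset,
    kmer_alphabet,
    profile_terms,
)
from .seq_io import NEGATIVE, POSITIVE, SequenceRecord

COMPOSITION_LENGTH = 84  # 4 + 16 + 64
CTD_LENGTH = 63  # 7 + 21 + 35

#: The 7 physicochemical amino-acid groups (by dipole and side-chain volume)
#: used by the CTD descriptor, in fixed order.
AMINO_GROUPS: tuple[frozenset[str], ...] = (
    frozenset("AGV"),
    frozenset("C"),
    frozenset("MSTY"),
    frozenset("FILP"),
    frozenset("HNQW"),
    frozenset("KR"),
    frozenset("DE"),
)

_AA_TO_GROUP: dict[str, int] = {
    aa: gi for gi, group in enumerate(AMINO_GROUPS) for aa in group
}

#: Unordered group pairs for the transition block, fixed order
#: (1,2), (1,3), ..., (6,7).
GROUP_PAIRS: tuple[tuple[int, int], ...] = tuple(combinations(range(7), 2))


class LayoutError(ValueError):
    """Feature-vector layout mismatch."""


@dataclass(frozen=True)
class FeatureVector:
    """Numeric feature values plus the ordered block layout that produced
    them, e.g. (("mPWM", 25), ("dPWM", 24), ("composition", 84))."""

    values: np.ndarray
    layout: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        total = sum(length for _, length in self.layout)
        if total != self.values.size:
            raise LayoutError(
                f"layout covers {total} features but vector has "
                f"{self.values.size}"
            )

    def __len__(self) -> int:
        return self.values.size

    def block(self, name: str) -> np.ndarray:
        """The slice of values belonging to the named block."""
        offset = 0
        for block_name, length in self.layout:
            if block_name == name:
                return self.values[offset : offset + length]
            offset += length
        raise KeyError(f"no block named {name!r} in layout {self.layout}")


def kmer_composition(seq: str | SequenceRecord, k: int) -> np.ndarray:
    """Normalized k-mer frequencies of a sequence, lexicographic order
    A < C < G < U; denominator is the window count |seq| - k + 1."""
    s = seq.sequence if isinstance(seq, SequenceRecord) else seq
    if k not in (1, 2, 3):
        raise ValueError(f"composition order k={k} unsupported")
    if len(s) < k:
        raise ValueError(f"sequence of length {len(s)} too short for k={k}")
    index = _KMER_INDEX[k]
    counts = np.zeros(4**k)
    for j in range(len(s) - k + 1):
        counts[index[s[j : j + k]]] += 1
    return counts / (len(s) - k + 1)


def composition_block(seq: str | SequenceRecord) -> np.ndarray:
    """The 84 composition features: mono, di and tri k-mer frequencies."""
    return np.concatenate([kmer_composition(seq, k) for k in (1, 2, 3)])


def _aligned_profile_blocks(
    s: str, mpwm: PositionWeightMatrix, dpwm: PositionWeightMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Profile blocks for a sequence of any length, via ungapped alignment.

    Longer sequences: both blocks come from the maximum-scoring w-mer window
    (located with the mono profile). Shorter sequences: the sequence is
    placed at its best offset against the matrix columns; mono columns with
    no covering nucleotide, and di columns either of whose two positions is
    uncovered, are zero-filled.
    """
    w = mpwm.positions
    m = len(s)
    if m == w:
        return profile_terms(s, mpwm), profile_terms(s, dpwm)
    offset = best_offset(s, mpwm)
    if m > w:
        window = s[offset : offset + w]
        return profile_terms(window, mpwm), profile_terms(window, dpwm)
    # short sequence: covers matrix columns [offset, offset + m)
    mono = np.zeros(w)
    idx1 = _KMER_INDEX[1]
    for i, ch in enumerate(s):
        mono[offset + i] = mpwm.score[idx1[ch], offset + i]
    di = np.zeros(w - 1)
    idx2 = _KMER_INDEX[2]
    for i in range(m - 1):
        j = offset + i  # di column j needs nucleotides at j and j+1
        di[j] = dpwm.score[idx2[s[i : i + 2]], j]
    return mono, di


def encode_rna(
    seq: SequenceRecord | str,
    mpwm: PositionWeightMatrix,
    dpwm: PositionWeightMatrix,
) -> FeatureVector:
    """Encode an RNA sequence against training-derived profiles.

    Returns a vector of 2w + 83 features for a width-w profile regardless of
    the sequence length; compositions are always computed over the entire
    sequence, which must be at least 3 nt for the tri-nucleotide block.
    """
    s = seq.sequence if isinstance(seq, SequenceRecord) else seq
    if len(s) < 3:
        raise ValueError(
            f"sequence of length {len(s)} too short to encode "
            "(tri-nucleotide composition needs >= 3 nt)"
        )
    w = mpwm.positions
    if dpwm.positions != w - 1:
        raise LayoutError(
            f"inconsistent profiles: mono width {w}, di width "
            f"{dpwm.positions} (expected {w - 1})"
        )
    mono, di = _aligned_profile_blocks(s, mpwm, dpwm)
    comp = composition_block(s)
    return FeatureVector(
        values=np.concatenate([mono, di, comp]),
        layout=(("mPWM", w), ("dPWM", w - 1), ("composition", COMPOSITION_LENGTH)),
    )


def encode_protein_ctd(protein: str) -> np.ndarray:
    """Composition/transition/distribution descriptor of a protein sequence.

    63 features: 7 group compositions; 21 normalized adjacent-pair transition
    frequencies over unordered distinct group pairs; and for each group the
    normalized residue positions of its first, 25%, 50%, 75% and 100%-th
    occurrence (five zeros for absent groups).
    """
    protein = protein.strip().upper()
    if len(protein) < 2:
        raise ValueError("protein sequence must have at least 2 residues")
    try:
        groups = [_AA_TO_GROUP[aa] for aa in protein]
    except KeyError as exc:
        raise ValueError(f"non-standard amino acid {exc.args[0]!r}") from None
    L = len(groups)

    composition = np.bincount(groups, minlength=7) / L

    pair_counts = np.zeros(len(GROUP_PAIRS))
    pair_index = {p: i for i, p in enumerate(GROUP_PAIRS)}
    for a, b in zip(groups, groups[1:]):
        if a != b:
            pair_counts[pair_index[(min(a, b), max(a, b))]] += 1
    transitions = pair_counts / (L - 1)

    distribution = np.zeros((7, 5))
    quantiles = (0.25, 0.5, 0.75, 1.0)
    for g in range(7):
        positions = [i + 1 for i, gi in enumerate(groups) if gi == g]
        if not positions:
            continue
        c = len(positions)
        distribution[g, 0] = positions[0] / L
        for qi, q in enumerate(quantiles, start=1):
            rank = max(1, int(np.ceil(q * c)))
            distribution[g, qi] = positions[rank - 1] / L

    return np.concatenate([composition, transitions, distribution.ravel()])


def assemble(
    rna_fv: FeatureVector, protein_fv: Optional[np.ndarray] = None
) -> FeatureVector:
    """Concatenate the RNA feature vector with an optional protein CTD
    block; RNA blocks always come first."""
    if protein_fv is None:
        return rna_fv
    protein_fv = np.asarray(protein_fv, dtype=float)
    if protein_fv.size != CTD_LENGTH:
        raise LayoutError(
            f"protein block has {protein_fv.size} features, expected {CTD_LENGTH}"
        )
    return FeatureVector(
        values=np.concatenate([rna_fv.values, protein_fv]),
        layout=rna_fv.layout + (("protein", CTD_LENGTH),),
    )


RNA_BLOCKS = ("mPWM", "dPWM", "composition")


def build_design_matrix(
    records: Sequence[SequenceRecord],
    mpwm: Optional[PositionWeightMatrix],
    dpwm: Optional[PositionWeightMatrix],
    *,
    blocks: Sequence[str] = RNA_BLOCKS,
    protein_sequences: Optional[Mapping[str, str]] = None,
) -> tuple[np.ndarray, np.ndarray, tuple[tuple[str, int], ...]]:
    """Encode labeled records into (X, y, layout) for classifier training.

    ``blocks`` selects feature blocks for ablation studies (any nonempty
    subset of mPWM / dPWM / composition, in canonical order). When
    ``protein_sequences`` maps RBP names to amino-acid sequences, each
    record's protein CTD block is appended; records whose RBP has no protein
    entry raise. Labels map positive -> +1, negative -> -1.
    """
    blocks = tuple(b for b in RNA_BLOCKS if b in blocks)
    if not blocks:
        raise ValueError("at least one RNA feature block is required")
    needs_pwm = "mPWM" in blocks or "dPWM" in blocks
    if needs_pwm and (mpwm is None or dpwm is None):
        raise ValueError("profile blocks requested but no profiles supplied")

    ctd_cache: dict[str, np.ndarray] = {}
    rows: list[np.ndarray] = []
    labels: list[int] = []
    layout: Optional[tuple[tuple[str, int], ...]] = None
    for rec in records:
        if needs_pwm:
            full = encode_rna(rec, mpwm, dpwm)
            parts = [full.block(b) for b in blocks]
            sub_layout = tuple(
                (name, length) for name, length in full.layout if name in blocks
            )
        else:
            parts = [composition_block(rec)]
            sub_layout = (("composition", COMPOSITION_LENGTH),)
        if protein_sequences is not None:
            if rec.rbp is None or rec.rbp not in protein_sequences:
                raise KeyError(
                    f"record {rec.id!r}: no protein sequence for RBP {rec.rbp!r}"
                )
            if rec.rbp not in ctd_cache:
                ctd_cache[rec.rbp] = encode_protein_ctd(protein_sequences[rec.rbp])
            parts.append(ctd_cache[rec.rbp])
            sub_layout = sub_layout + (("protein", CTD_LENGTH),)
        rows.append(np.concatenate(parts))
        if layout is None:
            layout = sub_layout
        if rec.label == POSITIVE:
            labels.append(1)
        elif rec.label == NEGATIVE:
            labels.append(-1)
        else:
            labels.append(0)
    assert layout is not None
    return np.vstack(rows), np.asarray(labels), layout


def write_svmlight(
    X: np.ndarray,
    y: np.ndarray,
    path: str,
    layout: Optional[Iterable[tuple[str, int]]] = None,
) -> None:
    """Write an encoded dataset in the sparse label index:value format used
    by SVM tooling (1-based feature indices); a ``.layout`` sidecar records
    the block structure."""
    with open(path, "w") as fh:
        for row, label in zip(X, y):
            pairs = " ".join(
                f"{j + 1}:{v:.17g}" for j, v in enumerate(row) if v != 0.0
            )
            fh.write(f"{int(label)} {pairs}\n")
    if layout is not None:
        with open(str(path) + ".layout", "w") as fh:
            for name, length in layout:
                fh.write(f"{name}\t{length}\n")
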