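"""Sequence and region I/O.

Reads labeled RNA sequences from FASTA, region tables describing candidate
binding sites on a genome, and slices genome sequences into RNA regions.
DNA input is transcribed on the fly (T -> U); coordinates are 0-based
half-open internally, BED-style.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")
DNA_ALPHABET = frozenset("ACGTN")

POSITIVE = "positive"
NEGATIVE = "negative"
UNKNOWN = "unknown"
LABELS = (POSITIVE, NEGATIVE, UNKNOWN)


class FastaFormatError(ValueError):
    """Raised when a FASTA entry cannot be turned into a valid RNA record."""


@dataclass(frozen=True)
class RegionRecord:
    """A genomic interval hosting a (non-)binding site.

    ``start``/``end`` are 0-based half-open. ``affinity`` is the binding
    affinity score in [0, 1] assigned by the peak caller, or None.
    """

    chrom: str
    start: int
    end: int
    strand: str = "+"
    rbp: Optional[str] = None
    affinity: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid region {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SequenceRecord:
    """An RNA sequence with a binding label and optional RBP group tag."""

    id: str
    sequence: str
    label: str = UNKNOWN
    rbp: Optional[str] = None
    origin: Optional[RegionRecord] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"record {self.id!r}: invalid character(s) "
                f"{', '.join(sorted(bad))!s} (alphabet is A/C/G/U)"
            )
        if self.label not in LABELS:
            raise ValueError(f"record {self.id!r}: unknown label {self.label!r}")

    def __len__(self) -> int:
        return len(self.sequence)

    def with_label(self, label: str) -> "SequenceRecord":
        return replace(self, label=label)

    def with_rbp(self, rbp: Optional[str]) -> "SequenceRecord":
        return replace(self, rbp=rbp)


def normalize_rna(raw: str, *, record_id: str = "?") -> str:
    """Upper-case a nucleotide string and transcribe T -> U.

    Raises ValueError naming the first offending character if the result is
    not pure A/C/G/U.
    """
    seq = raw.strip().upper().replace("T", "U")
    for ch in seq:
        if ch not in RNA_ALPHABET:
            raise FastaFormatError(
                f"record {record_id!r}: invalid character {ch!r} "
                "(expected A/C/G/U, T accepted as U)"
            )
    return seq


class GenomeSource:
    """In-memory genome: a mapping chrom -> DNA string over A/C/G/T/N.

    Lookups for unknown chromosomes raise KeyError explicitly.
    """

    def __init__(self, chroms: Mapping[str, str]):
        self._chroms = {name: seq.upper() for name, seq in chroms.items()}
        for name, seq in self._chroms.items():
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise ValueError(
                    f"chromosome {name!r}: invalid character(s) {sorted(bad)}"
                )

    @classmethod
    def from_fasta(cls, path: str | Path) -> "GenomeSource":
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        if not records:
            raise FastaFormatError(f"no FASTA records in {path}")
        return cls(records)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._chroms

    def __getitem__(self, chrom: str) -> str:
        try:
            return self._chroms[chrom]
        except KeyError:
            raise KeyError(
                f"unknown chromosome {chrom!r}; known: {sorted(self._chroms)}"
            ) from None

    def length(self, chrom: str) -> int:
        return len(self[chrom])

    def chrom_names(self) -> list[str]:
        return sorted(self._chroms)


def read_fasta(
    path: str | Path,
    label: str = UNKNOWN,
    rbp: Optional[str] = None,
) -> list[SequenceRecord]:
    """Read a FASTA file into normalized SequenceRecords.

    All records receive ``label`` and ``rbp``. Sequences are upper-cased and
    transcribed (T -> U); anything outside A/C/G/U raises FastaFormatError.
    """
    out: list[SequenceRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = normalize_rna(str(rec.seq), record_id=rec.id)
        if not seq:
            raise FastaFormatError(f"record {rec.id!r}: empty sequence")
        out.append(SequenceRecord(id=rec.id, sequence=seq, label=label, rbp=rbp))
    return out


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n{rec.sequence}\n")


def extract_region_sequence(
    genome: GenomeSource,
    region: RegionRecord,
    *,
    skip_n: bool = True,
) -> Optional[SequenceRecord]:
    """Slice a region out of the genome and transcribe it to RNA.

    For '-' strand the slice is reverse-complemented before transcription.
    Returns None (with a logged warning) if the slice contains 'N' and
    ``skip_n`` is set; raises ValueError on out-of-bounds regions.
    """
    chrom_seq = genome[region.chrom]
    if region.end > len(chrom_seq):
        raise ValueError(
            f"region {region.chrom}:{region.start}-{region.end} exceeds "
            f"chromosome length {len(chrom_seq)}"
        )
    dna = chrom_seq[region.start : region.end]
    if "N" in dna:
        if skip_n:
            logger.warning(
                "skipping region %s:%d-%d: contains 'N'",
                region.chrom,
                region.start,
                region.end,
            )
            return None
        raise ValueError(
            f"region {region.chrom}:{region.start}-{region.end} contains 'N'"
        )
    if region.strand == "-":
        dna = str(Seq(dna).reverse_complement())
    rna = dna.replace("T", "U")
    rec_id = f"{region.chrom}:{region.start}-{region.end}({region.strand})"
    return SequenceRecord(
        id=rec_id, sequence=rna, rbp=region.rbp, origin=region
    )


def filter_regions(
    regions: Iterable[RegionRecord],
    length: int = 25,
    min_affinity: float = 0.9,
    strand: str = "+",
) -> list[RegionRecord]:
    """Keep regions of exactly ``length`` nt on ``strand`` with affinity
    strictly greater than ``min_affinity``. Order is preserved.

    Regions without an affinity score are dropped (the score is required to
    exceed the threshold).
    """
    kept = []
    for r in regions:
        if r.length != length:
            continue
        if r.strand != strand:
            continue
        if r.affinity is None or not (r.affinity > min_affinity):
            continue
        kept.append(r)
    return kept


REGION_COLUMNS = ("rbp", "chrom", "start", "end", "affinity", "strand")


def read_region_table(
    path: str | Path,
    *,
    one_based: bool = False,
) -> list[RegionRecord]:
    """Read a tab-separated region table (rbp, chrom, start, end, affinity,
    strand), with or without a header row.

    ``one_based=True`` converts 1-based inclusive coordinates to the internal
    0-based half-open convention (start - 1, end unchanged).
    """
    import pandas as pd

    df = pd.read_csv(str(path), sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] != len(REGION_COLUMNS):
        raise ValueError(
            f"region table {path} has {df.shape[1]} columns, "
            f"expected {len(REGION_COLUMNS)}: {REGION_COLUMNS}"
        )
    first = df.iloc[0].tolist()
    if first[0].strip().lower() == "rbp":  # header row
        df = df.iloc[1:]
    df.columns = REGION_COLUMNS
    out = []
    for row in df.itertuples(index=False):
        start = int(row.start)
        end = int(row.end)
        if one_based:
            start -= 1
        affinity = None
        if not pd.isna(row.affinity) and row.affinity not in ("", ".", "NA"):
            affinity = float(row.affinity)
        out.append(
            RegionRecord(
                chrom=row.chrom,
                start=start,
                end=end,
                strand=row.strand,
                rbp=row.rbp,
                affinity=affinity,
            )
        )
    return out


def write_region_table(regions: Iterable[RegionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(REGION_COLUMNS) + "\n")
        for r in regions:
            aff = "" if r.affinity is None else repr(r.affinity)
            fh.write(
                f"{r.rbp or ''}\t{r.chrom}\t{r.start}\t{r.end}\t{aff}\t{r.strand}\n"
            )
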