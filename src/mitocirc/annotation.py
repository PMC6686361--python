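"""Annotated circular mitogenomes and positional bookkeeping.

The central objects are :class:`GeneFeature` (one annotated interval with a
strand and a feature type) and :class:`MitogenomeRecord` (the circular
heavy-strand sequence plus its ordered annotation).  All coordinates are
1-based and inclusive, the convention of GenBank flat files and of printed
mitogenome tables.  A feature whose ``end`` is smaller than its ``start``
wraps across the origin of the circle.

`build_gene_table` reproduces the classic per-gene summary of a mitogenome
paper: length, signed distance to the next feature (positive = intergenic
spacer, negative = overlap), start/stop codon classification for the
protein-coding genes, and A+T content.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

# Vertebrate mitochondrial stop codons (translation table 2): AGA/AGG act as
# stops in addition to the standard TAA/TAG.
MITO_STOP_CODONS = frozenset({"TAA", "TAG", "AGA", "AGG"})

FEATURE_TYPES = ("PCG", "tRNA", "rRNA", "CR", "CCR")

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse complement of an IUPAC nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


class CoordinateError(ValueError):
    """A feature coordinate lies outside [1, genome_length]."""


class EmptyAnnotationError(ValueError):
    """An operation that needs features was given none."""


class MalformedPCGError(ValueError):
    """A protein-coding feature too short to carry start and stop codons."""


class SequenceRequiredError(ValueError):
    """An operation that needs nucleotide sequence was given annotation only."""


@dataclass(frozen=True)
class GeneFeature:
    """One annotated interval on a circular genome.

    ``start``/``end`` are 1-based inclusive heavy-strand coordinates;
    ``end < start`` denotes wrap across the origin.  ``strand`` is ``H``
    (heavy) or ``L`` (light); light-strand features keep heavy-strand
    coordinates and their sense sequence is obtained by reverse complement.
    """

    name: str
    ftype: str
    start: int
    end: int
    strand: str = "H"

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise ValueError(f"unknown feature type {self.ftype!r}")
        if self.strand not in ("H", "L"):
            raise ValueError(f"strand must be 'H' or 'L', got {self.strand!r}")

    @property
    def wraps(self) -> bool:
        return self.end < self.start

    def validate(self, genome_length: int) -> None:
        for pos in (self.start, self.end):
            if not 1 <= pos <= genome_length:
                raise CoordinateError(
                    f"{self.name}: position {pos} outside [1, {genome_length}]"
                )


def feature_length(f: GeneFeature, genome_length: int) -> int:
    """Length in bp of a feature on a circle of ``genome_length``."""
    f.validate(genome_length)
    if f.end >= f.start:
        return f.end - f.start + 1
    return genome_length - f.start + 1 + f.end


def neighbor_gap(f1: GeneFeature, f2: GeneFeature, genome_length: int) -> int:
    """Signed distance between adjacent features on the circle.

    ``f2`` must be the next feature after ``f1`` in start order (the last
    feature pairs with the first, across the origin).  Positive values are
    intergenic spacers, negative values overlaps, zero means abutting.
    """
    f1.validate(genome_length)
    f2.validate(genome_length)
    end1 = f1.end + genome_length if f1.wraps else f1.end
    start2 = f2.start
    if start2 <= f1.start:  # pair wraps across the origin
        start2 += genome_length
    return start2 - end1 - 1


@dataclass
class MitogenomeRecord:
    """A circular mitogenome: heavy-strand sequence plus ordered annotation."""

    features: list[GeneFeature]
    sequence: str | None = None
    genome_length: int = 0
    circular: bool = True
    name: str = ""

    @classmethod
    def from_features(
        cls,
        features: Iterable[GeneFeature],
        sequence: str | None = None,
        genome_length: int | None = None,
        name: str = "",
    ) -> "MitogenomeRecord":
        """Build a record, inferring genome length and disambiguating names.

        Without an explicit ``genome_length`` (or sequence) the length is the
        maximum ``end`` over non-wrapping features.  Duplicate feature names
        (the two tRNA-Ser / tRNA-Leu genes) receive suffixes 1/2 in order of
        appearance.
        """
        feats = sorted(features, key=lambda f: f.start)
        if not feats:
            raise EmptyAnnotationError("no features supplied")
        if sequence is not None:
            sequence = sequence.upper().replace("U", "T")
            genome_length = len(sequence)
        if genome_length is None:
            genome_length = max(f.end for f in feats if not f.wraps)
        feats = _disambiguate_names(feats)
        for f in feats:
            f.validate(genome_length)
        return cls(
            features=feats,
            sequence=sequence,
            genome_length=genome_length,
            name=name,
        )

    def __post_init__(self) -> None:
        if self.sequence is not None:
            if self.genome_length and self.genome_length != len(self.sequence):
                raise ValueError(
                    "genome_length disagrees with sequence length"
                )
            self.genome_length = len(self.sequence)
        self.features = sorted(self.features, key=lambda f: f.start)

    def get(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def features_of_type(self, ftype: str) -> list[GeneFeature]:
        return [f for f in self.features if f.ftype == ftype]

    def h_strand_sequence(self, f: GeneFeature) -> str:
        """Heavy-strand subsequence under a feature (wrap-aware)."""
        if self.sequence is None:
            raise SequenceRequiredError("record carries no sequence")
        if f.wraps:
            return self.sequence[f.start - 1 :] + self.sequence[: f.end]
        return self.sequence[f.start - 1 : f.end]

    def sense_sequence(self, f: GeneFeature) -> str:
        """Sense-strand (coding) sequence: reverse complement for strand L."""
        seq = self.h_strand_sequence(f)
        return revcomp(seq) if f.strand == "L" else seq


def _disambiguate_names(feats: Sequence[GeneFeature]) -> list[GeneFeature]:
    from collections import Counter

    tally = Counter(f.name for f in feats)
    seen: dict[str, int] = {}
    out: list[GeneFeature] = []
    for f in feats:
        if tally[f.name] > 1:
            seen[f.name] = seen.get(f.name, 0) + 1
            f = GeneFeature(
                name=f"{f.name}{seen[f.name]}",
                ftype=f.ftype,
                start=f.start,
                end=f.end,
                strand=f.strand,
            )
        out.append(f)
    return out


def classify_codons(
    f: GeneFeature, genome: MitogenomeRecord
) -> tuple[str | None, str | None]:
    """Start and stop codon of a protein-coding gene.

    The stop is classified on the sense strand: a complete vertebrate
    mitochondrial stop (TAA/TAG/AGA/AGG) when the length is a multiple of
    three, the incomplete stops ``T--`` (length ≡ 1 mod 3, terminal T) and
    ``TA-`` (length ≡ 2 mod 3, terminal TA) otherwise.  Codons containing
    ambiguous bases classify as ``None`` with a warning.
    """
    if f.ftype != "PCG":
        raise ValueError(f"{f.name}: codon classification only for PCGs")
    seq = genome.sense_sequence(f)
    if len(seq) < 6:
        raise MalformedPCGError(f"{f.name}: PCG shorter than 6 nt")
    start_codon: str | None = seq[:3]
    if set(start_codon) - set("ACGT"):
        warnings.warn(f"{f.name}: ambiguous start codon {start_codon}")
        start_codon = None
    rem = len(seq) % 3
    stop_codon: str | None
    if rem == 0:
        last = seq[-3:]
        if last in MITO_STOP_CODONS:
            stop_codon = last
        else:
            warnings.warn(f"{f.name}: terminal codon {last} is not a stop")
            stop_codon = None
    elif rem == 1:
        if seq[-1] == "T":
            stop_codon = "T--"
        else:
            warnings.warn(f"{f.name}: dangling nucleotide {seq[-1]} is not T")
            stop_codon = None
    else:
        if seq[-2:] == "TA":
            stop_codon = "TA-"
        else:
            warnings.warn(f"{f.name}: dangling dinucleotide {seq[-2:]} is not TA")
            stop_codon = None
    return start_codon, stop_codon


@dataclass
class GeneTableRow:
    """One row of the per-gene summary table."""

    feature: GeneFeature
    length_bp: int
    gap_to_next: int
    start_codon: str | None = None
    stop_codon: str | None = None
    at_percent: float | None = None


def build_gene_table(genome: MitogenomeRecord) -> list[GeneTableRow]:
    """Per-feature summary in start order.

    Every feature gets a ``gap_to_next`` (the last pairs with the first,
    across the origin).  Codon and A+T columns require sequence and are left
    ``None`` without it.
    """
    feats = genome.features
    if not feats:
        raise EmptyAnnotationError("record has no features")
    L = genome.genome_length
    rows: list[GeneTableRow] = []
    n = len(feats)
    for i, f in enumerate(feats):
        nxt = feats[(i + 1) % n]
        gap = neighbor_gap(f, nxt, L)
        row = GeneTableRow(
            feature=f, length_bp=feature_length(f, L), gap_to_next=gap
        )
        if genome.sequence is not None:
            seq = genome.h_strand_sequence(f)
            acgt = sum(seq.count(b) for b in "ACGT")
            if acgt:
                row.at_percent = 100.0 * (seq.count("A") + seq.count("T")) / acgt
            if f.ftype == "PCG":
                row.start_codon, row.stop_codon = classify_codons(f, genome)
        rows.append(row)
    return rows


@dataclass
class SpacerOverlapSummary:
    n_spacers: int
    total_spacer_bp: int
    longest_spacer: int
    longest_spacer_between: tuple[str, str] | None
    n_overlaps: int
    total_overlap_bp: int
    longest_overlap: int
    longest_overlap_between: tuple[str, str] | None


def spacer_overlap_summary(rows: Sequence[GeneTableRow]) -> SpacerOverlapSummary:
    """Count and size intergenic spacers (gap > 0) and overlaps (gap < 0)."""
    n = len(rows)
    spacers: list[tuple[int, tuple[str, str]]] = []
    overlaps: list[tuple[int, tuple[str, str]]] = []
    for i, row in enumerate(rows):
        pair = (row.feature.name, rows[(i + 1) % n].feature.name)
        if row.gap_to_next > 0:
            spacers.append((row.gap_to_next, pair))
        elif row.gap_to_next < 0:
            overlaps.append((-row.gap_to_next, pair))
    return SpacerOverlapSummary(
        n_spacers=len(spacers),
        total_spacer_bp=sum(s for s, _ in spacers),
        longest_spacer=max((s for s, _ in spacers), default=0),
        longest_spacer_between=max(spacers, default=(0, None))[1],
        n_overlaps=len(overlaps),
        total_overlap_bp=sum(s for s, _ in overlaps),
        longest_overlap=max((s for s, _ in overlaps), default=0),
        longest_overlap_between=max(overlaps, default=(0, None))[1],
    )
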