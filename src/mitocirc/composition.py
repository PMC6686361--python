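"""Base composition, A+T content and strand skew statistics.

AT-skew = (A − T)/(A + T) and GC-skew = (G − C)/(G + C), computed over the
unambiguous bases of a sequence.  Because complementation swaps A with T and
G with C, both skews change sign under reverse complement; measuring every
gene on the same physical strand (the heavy strand) therefore makes
light-strand genes such as ND6 stand out with inverted skew signs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .annotation import (
    EmptyAnnotationError,
    MitogenomeRecord,
    SequenceRequiredError,
)


class EmptyInputError(ValueError):
    """Composition of an empty (or all-ambiguous) sequence is undefined."""


@dataclass
class CompositionProfile:
    """Counts, percentages and skews of one nucleotide sequence.

    ``at_skew``/``gc_skew`` are ``None`` when the respective denominator
    (A+T or G+C) is zero.  Ambiguous bases are excluded from denominators.
    """

    counts: dict[str, int]
    freqs: dict[str, float]
    at_percent: float
    at_skew: float | None
    gc_skew: float | None

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def composition(seq: str) -> CompositionProfile:
    """Composition profile of a nucleotide string (N excluded)."""
    if not seq:
        raise EmptyInputError("empty sequence")
    seq = seq.upper().replace("U", "T")
    counts = {b: seq.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise EmptyInputError("sequence contains no unambiguous bases")
    n_other = len(seq) - total
    if n_other / len(seq) > 0.01:
        warnings.warn(
            f"{n_other}/{len(seq)} ambiguous bases excluded from composition"
        )
    freqs = {b: 100.0 * c / total for b, c in counts.items()}
    a, c, g, t = counts["A"], counts["C"], counts["G"], counts["T"]
    return CompositionProfile(
        counts=counts,
        freqs=freqs,
        at_percent=freqs["A"] + freqs["T"],
        at_skew=(a - t) / (a + t) if a + t else None,
        gc_skew=(g - c) / (g + c) if g + c else None,
    )


def merge_counts(profiles: list[CompositionProfile]) -> CompositionProfile:
    """Length-weighted merge: the profile of the concatenated sequences."""
    counts = {b: sum(p.counts[b] for p in profiles) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise EmptyInputError("no unambiguous bases in any profile")
    freqs = {b: 100.0 * c / total for b, c in counts.items()}
    a, c, g, t = counts["A"], counts["C"], counts["G"], counts["T"]
    return CompositionProfile(
        counts=counts,
        freqs=freqs,
        at_percent=freqs["A"] + freqs["T"],
        at_skew=(a - t) / (a + t) if a + t else None,
        gc_skew=(g - c) / (g + c) if g + c else None,
    )


#: feature types that get their own row in the skew table
_SKEW_ROW_TYPES = ("PCG", "rRNA", "CR", "CCR")


def skew_table(
    genome: MitogenomeRecord, strand_mode: str = "h_strand"
) -> pd.DataFrame:
    """Per-gene composition/skew table plus 13PCG and overall rows.

    ``strand_mode='h_strand'`` (default) measures every feature on the
    heavy-strand subsequence regardless of coding strand, which is what makes
    the light-strand ND6 row show inverted skew signs.  ``'sense'`` measures
    each feature on its own coding strand.
    """
    if genome.sequence is None:
        raise SequenceRequiredError("skew table requires sequence")
    if strand_mode not in ("h_strand", "sense"):
        raise ValueError(f"unknown strand_mode {strand_mode!r}")
    rows: dict[str, CompositionProfile] = {}
    pcg_profiles: list[CompositionProfile] = []
    for f in genome.features:
        if f.ftype not in _SKEW_ROW_TYPES:
            continue
        seq = (
            genome.sense_sequence(f)
            if strand_mode == "sense"
            else genome.h_strand_sequence(f)
        )
        prof = composition(seq)
        rows[f.name] = prof
        if f.ftype == "PCG":
            pcg_profiles.append(prof)
    if pcg_profiles:
        rows["13PCG"] = merge_counts(pcg_profiles)
    rows["overall"] = composition(genome.sequence)
    return _profiles_to_frame(rows)


def _profiles_to_frame(rows: dict[str, CompositionProfile]) -> pd.DataFrame:
    records = []
    for name, p in rows.items():
        records.append(
            {
                "Gene": name,
                "A%": p.freqs["A"],
                "C%": p.freqs["C"],
                "G%": p.freqs["G"],
                "T%": p.freqs["T"],
                "A+T%": p.at_percent,
                "AT-skew": p.at_skew,
                "GC-skew": p.gc_skew,
            }
        )
    return pd.DataFrame.from_records(records).set_index("Gene")


def codon_position_composition(
    genome: MitogenomeRecord,
) -> dict[int, CompositionProfile]:
    """Composition at codon positions 1/2/3 over all PCG sense-strand codons.

    Trailing incomplete codons (the 1–2 nt of incomplete stops) are excluded.
    """
    if genome.sequence is None:
        raise SequenceRequiredError("codon positions require sequence")
    pcgs = genome.features_of_type("PCG")
    if not pcgs:
        raise EmptyAnnotationError("no protein-coding genes annotated")
    parts = {1: [], 2: [], 3: []}
    for f in pcgs:
        seq = genome.sense_sequence(f)
        n_codons = len(seq) // 3
        for i in range(n_codons):
            codon = seq[3 * i : 3 * i + 3]
            parts[1].append(codon[0])
            parts[2].append(codon[1])
            parts[3].append(codon[2])
    return {pos: composition("".join(chars)) for pos, chars in parts.items()}
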