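"""Codon counting and relative synonymous codon usage (RSCU).

Codons are counted over the sense strands of all annotated protein-coding
genes under the vertebrate mitochondrial genetic code (translation table 2:
AUA is Met, UGA is Trp, and AGA/AGG join UAA/UAG as stops, so the stop
family has four members).  RSCU of a codon is its count divided by the mean
count of its synonymous family; a value of 1 means no usage bias.

Codons are held in the RNA alphabet (UUU) for display, matching the usual
presentation of mitogenome codon-usage tables; parsers accept T or U.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
from Bio.Data import CodonTable

from .annotation import MitogenomeRecord
from .composition import EmptyInputError

#: The vertebrate mitochondrial code, keyed by RNA codons.
_TABLE2 = CodonTable.unambiguous_rna_by_id[2]

STOP = "*"


def codon_families(table_id: int = 2) -> dict[str, tuple[str, ...]]:
    """Synonymous families: amino acid (one letter, ``*`` for stop) → codons."""
    table = CodonTable.unambiguous_rna_by_id[table_id]
    fams: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        fams.setdefault(aa, []).append(codon)
    fams[STOP] = list(table.stop_codons)
    return {aa: tuple(sorted(cods)) for aa, cods in fams.items()}


FAMILIES = codon_families()
CODON_TO_AA = {c: aa for aa, cods in FAMILIES.items() for c in cods}
ALL_CODONS = tuple(sorted(CODON_TO_AA))


def _normalize(codon: str) -> str:
    codon = codon.upper().replace("T", "U")
    if codon not in CODON_TO_AA:
        raise ValueError(f"not an unambiguous codon: {codon!r}")
    return codon


def extract_codons(genome: MitogenomeRecord) -> dict[str, int]:
    """Pool sense-strand codon counts over all annotated PCGs.

    Each gene is read in consecutive triplets from its start codon; a
    trailing incomplete codon (1–2 nt, the incomplete stop) is dropped.
    Codons containing ambiguous bases are skipped with a warning.
    """
    counts = {c: 0 for c in ALL_CODONS}
    for f in genome.features_of_type("PCG"):
        seq = genome.sense_sequence(f)
        n_codons = len(seq) // 3
        for i in range(n_codons):
            codon = seq[3 * i : 3 * i + 3].replace("T", "U")
            if codon in counts:
                counts[codon] += 1
            else:
                warnings.warn(f"{f.name}: skipping ambiguous codon {codon}")
    return counts


def rscu(counts: dict[str, int]) -> dict[str, float]:
    """RSCU per codon: count / (family total / family size).

    A family with zero total yields RSCU 0 for all of its members.
    """
    counts = {_normalize(c): n for c, n in counts.items()}
    out: dict[str, float] = {}
    for aa, fam in FAMILIES.items():
        fam_total = sum(counts.get(c, 0) for c in fam)
        for c in fam:
            out[c] = (
                counts.get(c, 0) * len(fam) / fam_total if fam_total else 0.0
            )
    return out


def codon_percentages(counts: dict[str, int]) -> dict[str, float]:
    """Each codon's share (in percent) of all counted codons."""
    counts = {_normalize(c): n for c, n in counts.items()}
    total = sum(counts.values())
    if total == 0:
        raise EmptyInputError("no codons counted")
    return {c: 100.0 * counts.get(c, 0) / total for c in ALL_CODONS}


def aa_usage(
    counts: dict[str, int],
) -> tuple[list[tuple[str, int]], str]:
    """Amino-acid families ranked by summed count, and the top single codon.

    Ties in family totals break alphabetically; the top codon is the argmax
    of the raw counts (alphabetical on ties).
    """
    counts = {_normalize(c): n for c, n in counts.items()}
    fam_totals = {
        aa: sum(counts.get(c, 0) for c in fam) for aa, fam in FAMILIES.items()
    }
    ranking = sorted(fam_totals.items(), key=lambda kv: (-kv[1], kv[0]))
    top_codon = min(ALL_CODONS, key=lambda c: (-counts.get(c, 0), c))
    return ranking, top_codon


@dataclass
class CodonUsageTable:
    """64-codon counts with RSCU and percentage columns."""

    counts: dict[str, int]
    families: dict[str, tuple[str, ...]] = field(default_factory=lambda: FAMILIES)
    rscu: dict[str, float] = field(init=False)
    percent: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.counts = {_normalize(c): n for c, n in self.counts.items()}
        for c in ALL_CODONS:
            self.counts.setdefault(c, 0)
        self.rscu = rscu(self.counts)
        self.percent = codon_percentages(self.counts)

    @classmethod
    def from_genome(cls, genome: MitogenomeRecord) -> "CodonUsageTable":
        return cls(counts=extract_codons(genome))

    @classmethod
    def from_tsv(cls, path) -> "CodonUsageTable":
        """Read a codon/count table (TSV with ``codon`` and ``count`` columns)."""
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(counts=dict(zip(df["codon"], df["count"])))

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "Codon": c,
                "AA": CODON_TO_AA[c],
                "Count": self.counts[c],
                "RSCU": self.rscu[c],
                "Percent": self.percent[c],
            }
            for c in ALL_CODONS
        ]
        return pd.DataFrame(rows)


def reference_codon_counts() -> dict[str, int]:
    """Codon counts of the Gyps himalayensis mitogenome PCGs (shipped data)."""
    ref = resources.files("mitocirc.data") / "gyps_himalayensis_codon_counts.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#")
    return dict(zip(df["codon"], df["count"]))
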