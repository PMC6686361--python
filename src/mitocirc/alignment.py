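"""Alignment site classification and concatenated-PCG export.

`classify_sites` tallies alignment columns into constant, variable,
parsimony-informative and singleton sites.  A column is parsimony-
informative when at least two character states are each present in at least
two taxa; a variable column that is not informative is a singleton site.
Only unambiguous A/C/G/T cells enter the classification; columns with fewer
than two such cells are excluded from all counts.

`concat_pcgs` extracts the sense-strand protein-coding genes of several
mitogenomes in a fixed order and concatenates them per taxon — the standard
supermatrix input for external alignment and tree inference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .annotation import MitogenomeRecord


class AlignmentError(ValueError):
    """Rows of unequal length or duplicated taxon labels."""


class MissingGeneError(KeyError):
    """A requested gene is not annotated in one of the genomes."""


@dataclass
class AlignmentBlock:
    """A multiple alignment: ordered taxa and equal-length gapped rows."""

    taxa: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.rows):
            raise AlignmentError("one row per taxon required")
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("taxon labels must be unique")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise AlignmentError(f"ragged rows: lengths {sorted(lengths)}")
        self.rows = [r.upper() for r in self.rows]

    @property
    def site_count(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass
class SiteClassCounts:
    constant: int
    variable: int
    parsimony_informative: int
    singleton: int
    excluded: int = 0


_UNAMBIG = frozenset("ACGT")


def classify_sites(aln: AlignmentBlock) -> SiteClassCounts:
    """Column-class tally of an alignment (needs at least two rows)."""
    if len(aln.rows) < 2:
        raise AlignmentError("at least two rows required")
    constant = variable = informative = singleton = excluded = 0
    for col in zip(*aln.rows):
        states: dict[str, int] = {}
        for base in col:
            if base in _UNAMBIG:
                states[base] = states.get(base, 0) + 1
        if sum(states.values()) < 2:
            excluded += 1
            continue
        if len(states) == 1:
            constant += 1
        else:
            variable += 1
            if sum(1 for n in states.values() if n >= 2) >= 2:
                informative += 1
            else:
                singleton += 1
    return SiteClassCounts(
        constant=constant,
        variable=variable,
        parsimony_informative=informative,
        singleton=singleton,
        excluded=excluded,
    )


def concat_pcgs(
    genomes: Mapping[str, MitogenomeRecord],
    gene_order: Sequence[str],
) -> dict[str, str]:
    """Per-taxon concatenation of sense-strand PCGs in a fixed gene order.

    The output is unaligned: external tools handle alignment and inference.
    """
    out: dict[str, str] = {}
    for taxon, genome in genomes.items():
        parts: list[str] = []
        names = {f.name for f in genome.features}
        for gene in gene_order:
            if gene not in names:
                raise MissingGeneError(f"{taxon}: gene {gene!r} not annotated")
            parts.append(genome.sense_sequence(genome.get(gene)))
        out[taxon] = "".join(parts)
    return out


#: The 13 protein-coding genes in the annotation order of the raptor
#: remnant-CCR gene arrangement.
PCG_ORDER = (
    "ND1", "ND2", "COXI", "COXII", "ATP8", "ATP6", "COXIII",
    "ND3", "ND4L", "ND4", "ND5", "Cytb", "ND6",
)
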