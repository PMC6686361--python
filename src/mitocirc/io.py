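"""File formats and report writers.

FASTA and GenBank parsing go through Biopython; feature tables and all
reports are tab-separated text with headers.  Coordinates in feature tables
are 1-based inclusive (the GenBank convention); readers reject malformed
input with a named error instead of silently coercing it.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from importlib import resources

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .annotation import (
    GeneFeature,
    GeneTableRow,
    MitogenomeRecord,
    spacer_overlap_summary,
)

IUPAC_NUCLEOTIDES = frozenset("ACGTRYSWKMBDHVN-")


class FormatError(ValueError):
    """Malformed or empty input file."""


class UnsupportedFeatureError(ValueError):
    """A GenBank feature with a multi-interval (join) location."""


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into (label, sequence) pairs.

    Sequences are uppercased with U mapped to T; symbols outside the IUPAC
    nucleotide alphabet raise :class:`FormatError`.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    out = []
    for rec in records:
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - IUPAC_NUCLEOTIDES
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} has non-IUPAC symbols {sorted(bad)}"
            )
        out.append((rec.id, seq))
    return out


def write_fasta(
    path: str | Path, records: Iterable[tuple[str, str]], width: int = 70
) -> None:
    with open(path, "w") as fh:
        for label, seq in records:
            fh.write(f">{label}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_feature_table(path: str | Path) -> list[GeneFeature]:
    """Read a TSV feature table: ``name  type  start  end  strand``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"name", "type", "start", "end", "strand"}
    if not required <= set(df.columns):
        raise FormatError(
            f"{path}: feature table must have columns {sorted(required)}"
        )
    return [
        GeneFeature(
            name=str(r["name"]),
            ftype=str(r["type"]),
            start=int(r["start"]),
            end=int(r["end"]),
            strand=str(r["strand"]),
        )
        for _, r in df.iterrows()
    ]


def write_feature_table(path: str | Path, features: Sequence[GeneFeature]) -> None:
    df = pd.DataFrame(
        [
            {
                "name": f.name,
                "type": f.ftype,
                "start": f.start,
                "end": f.end,
                "strand": f.strand,
            }
            for f in features
        ]
    )
    df.to_csv(path, sep="\t", index=False)


def reference_annotation() -> MitogenomeRecord:
    """The shipped Gyps himalayensis annotation (coordinates only)."""
    ref = resources.files("mitocirc.data") / "gyps_himalayensis_features.tsv"
    with resources.as_file(ref) as path:
        features = read_feature_table(path)
    return MitogenomeRecord.from_features(features, name="Gyps himalayensis")


_GENBANK_TYPE_MAP = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA"}


def read_genbank(path: str | Path) -> MitogenomeRecord:
    """Read a GenBank flat file into a :class:`MitogenomeRecord`.

    CDS features map to PCG, tRNA/rRNA keep their type, and D-loop or
    misc_feature entries become CR (or CCR when the name mentions "pseudo").
    ``complement(...)`` locations map to strand L.
    """
    try:
        rec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    try:
        seq = str(rec.seq).upper()
    except Exception as exc:  # undefined sequence: no ORIGIN block
        raise FormatError(f"{path}: record has no ORIGIN sequence") from exc
    if not seq or set(seq) == {"N"}:
        raise FormatError(f"{path}: record has no ORIGIN sequence")
    features: list[GeneFeature] = []
    for feat in rec.features:
        if feat.type not in ("CDS", "tRNA", "rRNA", "D-loop", "misc_feature"):
            continue
        if len(feat.location.parts) > 1:
            raise UnsupportedFeatureError(
                f"{path}: multi-interval feature at {feat.location}"
            )
        name = _genbank_feature_name(feat)
        if feat.type in _GENBANK_TYPE_MAP:
            ftype = _GENBANK_TYPE_MAP[feat.type]
        else:
            ftype = "CCR" if "pseudo" in name.lower() else "CR"
        features.append(
            GeneFeature(
                name=name,
                ftype=ftype,
                start=int(feat.location.start) + 1,
                end=int(feat.location.end),
                strand="L" if feat.location.strand == -1 else "H",
            )
        )
    return MitogenomeRecord.from_features(features, sequence=seq, name=rec.id)


def _genbank_feature_name(feat: SeqFeature) -> str:
    for key in ("gene", "product", "note"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return feat.type


def write_genbank(genome: MitogenomeRecord, path: str | Path) -> None:
    """Export a record (sequence required) as a GenBank flat file."""
    if genome.sequence is None:
        raise FormatError("GenBank export requires sequence")
    rec = SeqRecord(
        Seq(genome.sequence),
        id=genome.name or "mitogenome",
        name=(genome.name or "mitogenome").replace(" ", "_")[:16],
        description="circular mitochondrial genome",
        annotations={"molecule_type": "DNA", "topology": "circular"},
    )
    type_map = {"PCG": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}
    for f in genome.features:
        gb_type = type_map.get(f.ftype, "D-loop" if f.ftype == "CR" else "misc_feature")
        loc = FeatureLocation(
            f.start - 1, f.end, strand=-1 if f.strand == "L" else 1
        )
        qualifiers = {"gene": [f.name]}
        if f.ftype == "CCR":
            qualifiers["note"] = ["pseudo-control region"]
        rec.features.append(SeqFeature(loc, type=gb_type, qualifiers=qualifiers))
    SeqIO.write(rec, str(path), "genbank")


def gene_table_frame(rows: Sequence[GeneTableRow]) -> pd.DataFrame:
    """Gene table as a DataFrame, mirroring the printed column order."""
    return pd.DataFrame(
        [
            {
                "Gene": r.feature.name,
                "From": r.feature.start,
                "To": r.feature.end,
                "Nucleotide_bp": r.length_bp,
                "Start_codon": r.start_codon or "",
                "Stop_codon": r.stop_codon or "",
                "Intergenic_bp": r.gap_to_next,
                "Strand": r.feature.strand,
                "A+T%": "" if r.at_percent is None else round(r.at_percent, 1),
            }
            for r in rows
        ]
    )


def write_reports(results: dict, outdir: str | Path) -> list[Path]:
    """Write the standard TSV reports plus a run log.

    ``results`` maps report names (``gene_table``, ``skew_table``,
    ``codon_usage``, ``cr_motifs``, ``ccr_repeats``) to DataFrames; the
    optional key ``run_log`` maps to a list of lines.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, df in results.items():
        if name == "run_log":
            continue
        path = outdir / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=isinstance(df.index, pd.MultiIndex) or df.index.name is not None)
        written.append(path)
    log_path = outdir / "run_log.txt"
    with open(log_path, "w") as fh:
        for line in results.get("run_log", []):
            fh.write(line.rstrip("\n") + "\n")
    written.append(log_path)
    return written
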