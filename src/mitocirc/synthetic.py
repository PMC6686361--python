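"""Seeded synthetic mitogenomes with planted ground truth.

The generator emits circular mitogenomes in the raptor "remnant-CCR" gene
arrangement (13 PCGs, 22 tRNAs, 2 rRNAs, a control region and a
pseudo-control region, with ND6 and eight tRNAs on the light strand) or the
standard avian arrangement (single control region).  Default gene lengths
and inter-gene gaps follow the shipped Gyps himalayensis reference
annotation, so the default coordinates reproduce that layout exactly.

Every generated artifact carries a :class:`SyntheticTruth` describing what
was planted — feature coordinates, per-gene codon streams, control-region
motif positions and domain edges, CCR tandem-repeat cassettes — and is
re-checked against that truth before being returned.  All randomness flows
from one explicitly seeded NumPy generator; identical (config, seed) give
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .alignment import AlignmentBlock
from .annotation import (
    GeneFeature,
    MitogenomeRecord,
    build_gene_table,
    classify_codons,
    feature_length,
    revcomp,
)
from .codons import reference_codon_counts
from .control_region import (
    CENTRAL_BOXES,
    CRPartition,
    MotifHit,
    MotifLibraryEntry,
    TandemRepeat,
    default_motif_library,
    find_poly_c,
    find_tandem_repeats,
    scan_motifs,
    verify_tandem_repeat,
    IUPAC,
)
from .io import reference_annotation


class ConfigError(ValueError):
    """An infeasible or inconsistent generator configuration."""


_MAX_RETRIES = 1000

#: Default heavy-strand base frequencies (whole-mitogenome composition of the
#: reference vulture genome: A 24.55%, C 31.59%, G 14.37%, T 29.49%).
DEFAULT_BASE_FREQS = {"A": 0.2455, "C": 0.3159, "G": 0.1437, "T": 0.2949}

#: AT-rich control-region background (T 33.1, C 25.9, A 23.5, G 17.5).
CR_BASE_FREQS = {"A": 0.235, "C": 0.259, "G": 0.175, "T": 0.331}

#: Start codon and stop classification planted per protein-coding gene.
#: Incomplete stops are written as their dangling nucleotides (T-- / TA-).
DEFAULT_PCG_CODONS = {
    "ND1": ("ATG", "AGG"),
    "ND2": ("ATG", "T--"),
    "COXI": ("GTG", "AGG"),
    "COXII": ("ATG", "TAA"),
    "ATP8": ("ATG", "TAA"),
    "ATP6": ("ATG", "TAA"),
    "COXIII": ("ATG", "TAA"),
    "ND3": ("ATT", "TAA"),
    "ND4L": ("ATG", "TAA"),
    "ND4": ("ATG", "TAA"),
    "ND5": ("ATG", "TAA"),
    "Cytb": ("ATG", "TAA"),
    "ND6": ("ATT", "TAG"),
}

#: Tandem-repeat units of the reference pseudo-control region.
CCR_UNIT_11 = "TCTTTTTTCAT"
CCR_UNIT_44 = "CCCTAAACAAGTAATAATATAAGTAGATGAGCTATCTACAAAGC"


@dataclass
class CRSpec:
    """Layout of a synthetic control region (0-based offsets)."""

    length: int = 1202
    background_freqs: dict = field(default_factory=lambda: dict(CR_BASE_FREQS))
    poly_c: tuple[int, int] = (20, 12)  # (offset, run length)
    poly_c_min_run: int = 4
    #: (motif name, offset) placements; names resolve in ``library``.
    motifs: tuple = (
        ("TACAT", 60),
        ("ATGTA", 80),
        ("F-box", 440),
        ("E-box", 540),
        ("D-box", 640),
        ("C-box", 740),
        ("CSB-a", 900),
        ("CSB-b", 980),
        ("CSB-1", 1060),
    )
    library: list[MotifLibraryEntry] = field(default_factory=default_motif_library)


@dataclass
class CCRSpec:
    """Segment plan of a synthetic pseudo-control region.

    ``segments`` is an ordered list of ``("nr", length)`` and
    ``("repeat", unit, full_copies, partial_len)`` cassettes.
    """

    segments: tuple = (
        ("nr", 125),
        ("repeat", CCR_UNIT_11, 12, 8),
        ("nr", 120),
        ("repeat", CCR_UNIT_44, 5, 14),
    )
    background_freqs: dict = field(default_factory=lambda: dict(CR_BASE_FREQS))
    min_unit: int = 5
    max_unit: int = 250
    min_copies: float = 2.0

    @property
    def length(self) -> int:
        total = 0
        for seg in self.segments:
            if seg[0] == "nr":
                total += seg[1]
            else:
                _, unit, copies, partial = seg
                total += len(unit) * copies + partial
        return total


@dataclass
class GeneratorConfig:
    """Everything the genome generator needs, including the seed."""

    gene_order_template: str = "remnant_ccr_raptor"
    base_freqs_h_strand: dict = field(
        default_factory=lambda: dict(DEFAULT_BASE_FREQS)
    )
    gene_lengths: dict = field(default_factory=dict)  # overrides
    planted_spacers: tuple = ()  # ((name1, name2), bp), gap = +bp
    planted_overlaps: tuple = ()  # ((name1, name2), bp), gap = -bp
    cr_spec: CRSpec = field(default_factory=CRSpec)
    ccr_spec: CCRSpec = field(default_factory=CCRSpec)
    codon_freqs: dict | None = None  # codon -> probability (T or U alphabet)
    pcg_codons: dict = field(default_factory=lambda: dict(DEFAULT_PCG_CODONS))
    seed: int = 0


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator."""

    features: list[GeneFeature] = field(default_factory=list)
    genome_length: int = 0
    codon_stream: dict = field(default_factory=dict)  # gene -> [RNA codons]
    cr_motifs: list[MotifHit] = field(default_factory=list)  # CR-relative
    cr_poly_c: tuple[int, int, int] | None = None
    cr_domains: CRPartition | None = None
    ccr_repeats: list[TandemRepeat] = field(default_factory=list)  # CCR-relative
    site_classes: list[str] | None = None


# ---------------------------------------------------------------------------
# gene-order templates


def _template_layout(cfg: GeneratorConfig) -> list[tuple[GeneFeature, int]]:
    """Ordered (feature-prototype, gap_after) pairs for the chosen template.

    Prototype coordinates are placeholders; only name/type/strand, length and
    gap are used.  Lengths come from the reference annotation unless
    overridden, gaps likewise with spacer/overlap plants applied on top.
    """
    ref = reference_annotation()
    rows = build_gene_table(ref)
    order = [
        (r.feature, feature_length(r.feature, ref.genome_length), r.gap_to_next)
        for r in rows
    ]
    if cfg.gene_order_template == "remnant_ccr_raptor":
        pass
    elif cfg.gene_order_template == "standard_avian":
        order = _standard_avian_order(order)
    else:
        raise ConfigError(
            f"unknown gene_order_template {cfg.gene_order_template!r}"
        )
    by_pair = {}
    for (pair, bp) in cfg.planted_spacers:
        by_pair[tuple(pair)] = int(bp)
    for (pair, bp) in cfg.planted_overlaps:
        by_pair[tuple(pair)] = -int(bp)
    layout: list[tuple[GeneFeature, int]] = []
    n = len(order)
    for i, (feat, length, gap) in enumerate(order):
        length = int(cfg.gene_lengths.get(feat.name, length))
        if length < 1:
            raise ConfigError(f"{feat.name}: nonpositive length")
        nxt = order[(i + 1) % n][0].name
        gap = by_pair.get((feat.name, nxt), gap)
        proto = GeneFeature(feat.name, feat.ftype, 1, length, feat.strand)
        layout.append((proto, gap))
    return layout


def _standard_avian_order(order):
    """Rearrange the raptor layout into Thr-Pro-ND6-Glu-CR with no CCR."""
    by_name = {feat.name: (feat, length) for feat, length, _ in order}
    names = [feat.name for feat, _, _ in order]
    head = [n for n in names if n not in
            ("Control region", "tRNA-Pro", "ND6", "tRNA-Glu",
             "Pseudo-control region")]
    tail = ["tRNA-Pro", "ND6", "tRNA-Glu", "Control region"]
    out = []
    new_names = head + tail
    for i, name in enumerate(new_names):
        feat, length = by_name[name]
        nxt = new_names[(i + 1) % len(new_names)]
        # reuse the reference gap when the adjacency exists there, else abut
        ref_gap = 0
        for (f, _, g), (f2, _, _) in zip(order, order[1:] + order[:1]):
            if f.name == name and f2.name == nxt:
                ref_gap = g
        out.append((feat, length, ref_gap))
    return out


# ---------------------------------------------------------------------------
# sequence assembly helpers


def _draw_bases(rng: np.random.Generator, freqs: dict, k: int) -> str:
    bases = np.array(list("ACGT"))
    p = np.array([freqs[b] for b in "ACGT"], dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ConfigError(f"base frequencies sum to {p.sum()}, not 1")
    p = p / p.sum()
    return "".join(rng.choice(bases, size=k, p=p))


def _realize_pattern(rng: np.random.Generator, pattern: str) -> str:
    """Pick one concrete sequence matching an IUPAC pattern."""
    return "".join(
        rng.choice(list(IUPAC[ch])) for ch in pattern.upper()
    )


def _default_codon_freqs() -> dict[str, float]:
    counts = reference_codon_counts()
    from .codons import CODON_TO_AA

    usable = {
        c.replace("U", "T"): n
        for c, n in counts.items()
        if CODON_TO_AA[c] != "*"
    }
    total = sum(usable.values())
    return {c: n / total for c, n in usable.items()}


def _draw_codons(rng: np.random.Generator, freqs: dict, k: int) -> list[str]:
    codons = np.array([c.upper().replace("U", "T") for c in freqs])
    p = np.array(list(freqs.values()), dtype=float)
    if not np.isclose(p.sum(), 1.0, atol=1e-6):
        raise ConfigError("codon frequencies must sum to 1")
    p = p / p.sum()
    return list(rng.choice(codons, size=k, p=p))


def _pcg_sense_sequence(
    rng: np.random.Generator,
    length: int,
    start_codon: str,
    stop_spec: str,
    codon_freqs: dict,
) -> str:
    """Sense-strand PCG sequence: start codon, drawn interior, stop tail."""
    rem = length % 3
    n_full = length // 3
    if stop_spec == "T--" and rem != 1:
        raise ConfigError("T-- stop requires length = 1 mod 3")
    if stop_spec == "TA-" and rem != 2:
        raise ConfigError("TA- stop requires length = 2 mod 3")
    if stop_spec in ("TAA", "TAG", "AGA", "AGG"):
        if rem != 0:
            raise ConfigError("complete stop requires length = 0 mod 3")
        tail = stop_spec
        n_interior = n_full - 2
    else:
        tail = {1: "T", 2: "TA"}[rem]
        n_interior = n_full - 1
    if n_interior < 0:
        raise ConfigError("PCG too short for start and stop codons")
    seq = start_codon + "".join(_draw_codons(rng, codon_freqs, n_interior)) + tail
    assert len(seq) == length
    return seq


# ---------------------------------------------------------------------------
# control region


def generate_cr(
    cr_spec: CRSpec, seed_or_rng
) -> tuple[str, dict]:
    """A control region with planted poly-C, palindromes, boxes and CSBs.

    Background positions are rejection-resampled until the planted motifs
    are the only matches of their own patterns (at each pattern's mismatch
    budget) and the planted poly-C is the only C-run at or above
    ``poly_c_min_run``.  Returns the sequence and a truth dict with keys
    ``motifs`` (list of :class:`MotifHit`), ``poly_c`` and ``domains``.
    """
    rng = _as_rng(seed_or_rng)
    L = cr_spec.length
    lib = {e.name: e for e in cr_spec.library}
    seq = np.array(list(_draw_bases(rng, cr_spec.background_freqs, L)))
    planted = np.zeros(L, dtype=bool)

    pc_off, pc_len = cr_spec.poly_c
    plants: list[MotifHit] = []
    spans = []
    if pc_len:
        if pc_off + pc_len > L:
            raise ConfigError("poly-C outside the region")
        seq[pc_off : pc_off + pc_len] = "C"
        planted[pc_off : pc_off + pc_len] = True
        spans.append((pc_off, pc_off + pc_len))
        # keep the run maximal: neighbours must not be C
        for j in (pc_off - 1, pc_off + pc_len):
            if 0 <= j < L:
                seq[j] = rng.choice(list("AGT"))
                planted[j] = True
    for name, off in cr_spec.motifs:
        if name not in lib:
            raise ConfigError(f"motif {name!r} not in library")
        pat = lib[name].pattern
        if off + len(pat) > L:
            raise ConfigError(f"{name}: placement outside the region")
        realization = _realize_pattern(rng, pat)
        if planted[off : off + len(pat)].any():
            raise ConfigError(f"{name}: overlaps another planted element")
        seq[off : off + len(pat)] = list(realization)
        planted[off : off + len(pat)] = True
        spans.append((off, off + len(pat)))
        plants.append(
            MotifHit(
                motif_name=name,
                pattern=pat,
                start=off + 1,
                end=off + len(pat),
                strand="forward",
            )
        )

    used_entries = [lib[name] for name, _ in cr_spec.motifs]
    expected = {(h.motif_name, h.start, h.end) for h in plants}
    for _ in range(_MAX_RETRIES):
        text = "".join(seq)
        extra_windows: list[tuple[int, int]] = []
        for h in scan_motifs(text, used_entries):
            if (h.motif_name, h.start, h.end) not in expected:
                extra_windows.append((h.start - 1, h.end))
        for s, e, _ in find_poly_c(text, cr_spec.poly_c_min_run):
            if pc_len and (s - 1, e) == (pc_off, pc_off + pc_len):
                continue
            extra_windows.append((s - 1, e))
        if not extra_windows:
            break
        for a, b in extra_windows:
            idx = [i for i in range(a, b) if not planted[i]]
            if not idx:
                raise ConfigError(
                    "planted elements collide: accidental match inside plants"
                )
            fresh = _draw_bases(rng, cr_spec.background_freqs, len(idx))
            for i, ch in zip(idx, fresh):
                seq[i] = ch
    else:
        raise ConfigError("rejection sampling exceeded retry cap")

    domains = None
    central = [h for h in plants if h.motif_name in CENTRAL_BOXES]
    if central:
        d2s = min(h.start for h in central)
        d2e = max(h.end for h in central)
        domains = CRPartition((1, d2s - 1), (d2s, d2e), (d2e + 1, L))
    truth = {
        "motifs": plants,
        "poly_c": (pc_off + 1, pc_off + pc_len, pc_len) if pc_len else None,
        "domains": domains,
    }
    return "".join(seq), truth


def generate_ccr(
    ccr_spec: CCRSpec, seed_or_rng
) -> tuple[str, list[TandemRepeat]]:
    """A pseudo-control region tiled from nr segments and repeat cassettes.

    Nonrepetitive background is rejection-resampled until the repeat finder
    recovers exactly the planted arrays — no accidental arrays, and no
    boundary characters extending a planted one.
    """
    rng = _as_rng(seed_or_rng)
    parts: list[tuple[str, object]] = []
    planted: list[TandemRepeat] = []
    pos = 0
    nr_slots: list[tuple[int, int]] = []
    for seg in ccr_spec.segments:
        if seg[0] == "nr":
            nr_len = int(seg[1])
            nr_slots.append((pos, pos + nr_len))
            parts.append(("nr", nr_len))
            pos += nr_len
        elif seg[0] == "repeat":
            _, unit, copies, partial = seg
            unit = unit.upper()
            if copies < 2:
                raise ConfigError("repeat cassettes need at least 2 copies")
            if not (2 <= len(unit)):
                raise ConfigError("repeat unit too short")
            if partial >= len(unit):
                raise ConfigError("partial must be shorter than the unit")
            span = len(unit) * copies + partial
            planted.append(
                TandemRepeat(
                    unit=unit,
                    unit_len=len(unit),
                    start=pos + 1,
                    end=pos + span,
                    copy_number=round(span / len(unit), 1),
                    partial_len=partial,
                )
            )
            parts.append(("repeat", unit * copies + unit[:partial]))
            pos += span
        else:
            raise ConfigError(f"unknown CCR segment kind {seg[0]!r}")
    L = pos
    planted = [
        replace(
            t,
            end_anchor="5prime" if (t.start + t.end) / 2 <= L / 2 else "3prime",
        )
        for t in planted
    ]

    def assemble(nr_texts: list[str]) -> str:
        out = []
        it = iter(nr_texts)
        for kind, payload in parts:
            out.append(next(it) if kind == "nr" else payload)
        return "".join(out)

    nr_texts = [
        _draw_bases(rng, ccr_spec.background_freqs, b - a) for a, b in nr_slots
    ]
    expected = {(t.start, t.end, t.unit_len) for t in planted}
    for _ in range(_MAX_RETRIES):
        text = assemble(nr_texts)
        found = find_tandem_repeats(
            text,
            min_unit=ccr_spec.min_unit,
            max_unit=ccr_spec.max_unit,
            min_copies=ccr_spec.min_copies,
        )
        if {(t.start, t.end, t.unit_len) for t in found} == expected:
            return text, planted
        # resample every nr segment that intersects an unexpected or
        # mis-bounded array
        bad: set[int] = set()
        for t in found:
            if (t.start, t.end, t.unit_len) in expected:
                continue
            for k, (a, b) in enumerate(nr_slots):
                if t.start - 1 < b and a < t.end:
                    bad.add(k)
        if not bad:  # a planted array went missing: plants collide
            raise ConfigError("planted repeat cassettes interfere")
        for k in bad:
            a, b = nr_slots[k]
            nr_texts[k] = _draw_bases(rng, ccr_spec.background_freqs, b - a)
    raise ConfigError("rejection sampling exceeded retry cap")


# ---------------------------------------------------------------------------
# whole genome


def generate_genome(
    cfg: GeneratorConfig,
) -> tuple[MitogenomeRecord, SyntheticTruth]:
    """A complete synthetic mitogenome plus its planted truth."""
    rng = np.random.default_rng(cfg.seed)
    layout = _template_layout(cfg)

    # assign coordinates
    coords: list[GeneFeature] = []
    start = 1
    prev_end = 0
    for proto, gap in layout:
        length = proto.end
        feat = GeneFeature(proto.name, proto.ftype, start, start + length - 1,
                           proto.strand)
        if coords and feat.start <= coords[-1].start:
            raise ConfigError(
                f"{feat.name}: overlap plan pushes start before previous gene"
            )
        coords.append(feat)
        prev_end = feat.end
        start = feat.end + gap + 1
    L = prev_end
    for f in coords:
        if f.start < 1 or f.end > L:
            raise ConfigError(f"{f.name}: coordinates outside [1, {L}]")

    codon_freqs = cfg.codon_freqs or _default_codon_freqs()
    seq = np.full(L, "", dtype="<U1")

    def write_segment(start_pos: int, text: str, overwrite: bool = False):
        idx = np.arange(start_pos - 1, start_pos - 1 + len(text))
        chars = np.array(list(text))
        if overwrite:
            seq[idx] = chars
        else:
            mask = seq[idx] == ""
            seq[idx[mask]] = chars[mask]

    cr_truth: dict = {}
    ccr_repeats: list[TandemRepeat] = []
    for feat in coords:
        length = feature_length(feat, L)
        if feat.ftype == "PCG":
            start_codon, stop_spec = cfg.pcg_codons.get(feat.name, ("ATG", None))
            if stop_spec is None:
                stop_spec = {0: "TAA", 1: "T--", 2: "TA-"}[length % 3]
            sense = _pcg_sense_sequence(
                rng, length, start_codon, stop_spec, codon_freqs
            )
            write_segment(
                feat.start, revcomp(sense) if feat.strand == "L" else sense
            )
        elif feat.ftype == "CR":
            if cfg.cr_spec.length != length:
                raise ConfigError(
                    f"CR spec length {cfg.cr_spec.length} != allotted {length}"
                )
            cr_seq, cr_truth = generate_cr(cfg.cr_spec, rng)
            write_segment(feat.start, cr_seq)
        elif feat.ftype == "CCR":
            if cfg.ccr_spec.length != length:
                raise ConfigError(
                    f"CCR spec length {cfg.ccr_spec.length} != allotted {length}"
                )
            ccr_seq, ccr_repeats = generate_ccr(cfg.ccr_spec, rng)
            write_segment(feat.start, ccr_seq)
        else:  # tRNA / rRNA placeholders: background composition
            write_segment(feat.start, _draw_bases(rng, cfg.base_freqs_h_strand,
                                                  length))
    unfilled = np.flatnonzero(seq == "")
    if len(unfilled):
        filler = _draw_bases(rng, cfg.base_freqs_h_strand, len(unfilled))
        seq[unfilled] = list(filler)

    # plant PCG start/stop constraints last so they survive overlaps
    for feat in coords:
        if feat.ftype != "PCG":
            continue
        length = feature_length(feat, L)
        start_codon, stop_spec = cfg.pcg_codons.get(feat.name, ("ATG", None))
        if stop_spec is None:
            stop_spec = {0: "TAA", 1: "T--", 2: "TA-"}[length % 3]
        tail = stop_spec if stop_spec in ("TAA", "TAG", "AGA", "AGG") else \
            {"T--": "T", "TA-": "TA"}[stop_spec]
        if feat.strand == "H":
            write_segment(feat.start, start_codon, overwrite=True)
            write_segment(feat.end - len(tail) + 1, tail, overwrite=True)
        else:
            write_segment(feat.end - 2, revcomp(start_codon), overwrite=True)
            write_segment(feat.start, revcomp(tail), overwrite=True)

    genome = MitogenomeRecord(
        features=coords,
        sequence="".join(seq),
        name=f"synthetic:{cfg.gene_order_template}:seed{cfg.seed}",
    )
    codon_stream: dict[str, list[str]] = {}
    for f in coords:
        if f.ftype != "PCG":
            continue
        sense = genome.sense_sequence(f).replace("T", "U")
        codon_stream[f.name] = [
            sense[3 * i : 3 * i + 3] for i in range(len(sense) // 3)
        ]
    truth = SyntheticTruth(
        features=coords,
        genome_length=L,
        codon_stream=codon_stream,
        cr_motifs=cr_truth.get("motifs", []),
        cr_poly_c=cr_truth.get("poly_c"),
        cr_domains=cr_truth.get("domains"),
        ccr_repeats=ccr_repeats,
    )
    _validate_genome(genome, truth, cfg)
    return genome, truth


def _validate_genome(
    genome: MitogenomeRecord, truth: SyntheticTruth, cfg: GeneratorConfig
) -> None:
    """Self-check the emitted genome against its planted truth."""
    rows = build_gene_table(genome)
    closure = sum(r.length_bp for r in rows) + sum(r.gap_to_next for r in rows)
    if closure != genome.genome_length:
        raise ConfigError("circular closure violated")
    for f in genome.features_of_type("PCG"):
        start, stop = classify_codons(f, genome)
        want = cfg.pcg_codons.get(f.name)
        if want is not None:
            want_start, want_stop = want
            if start != want_start or (want_stop and stop != want_stop):
                raise ConfigError(
                    f"{f.name}: planted codons corrupted by overlap plan "
                    f"(got {start}/{stop}, wanted {want_start}/{want_stop})"
                )
        elif stop is None:
            raise ConfigError(f"{f.name}: no valid stop classification")
    if truth.ccr_repeats:
        ccr = [f for f in genome.features if f.ftype == "CCR"][0]
        ccr_seq = genome.h_strand_sequence(ccr)
        for rep in truth.ccr_repeats:
            if not verify_tandem_repeat(ccr_seq, rep):
                raise ConfigError("planted repeat failed re-verification")
    if truth.cr_motifs:
        cr = [f for f in genome.features if f.ftype == "CR"][0]
        cr_seq = genome.h_strand_sequence(cr)
        for h in truth.cr_motifs:
            window = cr_seq[h.start - 1 : h.end]
            if any(b not in IUPAC[p] for b, p in zip(window, h.pattern)):
                raise ConfigError(f"planted motif {h.motif_name} corrupted")


# ---------------------------------------------------------------------------
# alignments


def generate_alignment(
    n_taxa: int,
    n_sites: int,
    class_mix: dict | Sequence[float],
    seed: int = 0,
) -> tuple[AlignmentBlock, SyntheticTruth]:
    """An alignment with an exact planted mix of site classes.

    ``class_mix`` gives proportions for ``constant``, ``informative`` and
    ``singleton`` columns (dict or 3-sequence, summing to 1).  Column counts
    are the proportions times ``n_sites`` apportioned by largest remainder,
    so the planted counts are exact; column order is shuffled.
    """
    if isinstance(class_mix, dict):
        mix = [
            float(class_mix.get(k, 0.0))
            for k in ("constant", "informative", "singleton")
        ]
    else:
        mix = [float(x) for x in class_mix]
    if len(mix) != 3 or not np.isclose(sum(mix), 1.0, atol=1e-9):
        raise ConfigError("class_mix must give 3 proportions summing to 1")
    if n_taxa < 2:
        raise ConfigError("need at least 2 taxa")
    if mix[1] > 0 and n_taxa < 4:
        raise ConfigError("informative columns require at least 4 taxa")
    rng = np.random.default_rng(seed)
    raw = [p * n_sites for p in mix]
    counts = [int(x) for x in raw]
    rem = n_sites - sum(counts)
    order = np.argsort([-(x - int(x)) for x in raw])
    for i in range(rem):
        counts[order[i]] += 1

    bases = list("ACGT")
    labels: list[str] = []
    columns: list[list[str]] = []
    for _ in range(counts[0]):
        b = rng.choice(bases)
        columns.append([b] * n_taxa)
        labels.append("constant")
    for _ in range(counts[1]):
        b1, b2 = rng.choice(bases, size=2, replace=False)
        k = int(rng.integers(2, n_taxa - 1))  # both states in >= 2 taxa
        members = rng.permutation(n_taxa)
        col = [b1] * n_taxa
        for t in members[:k]:
            col[t] = b2
        columns.append(col)
        labels.append("informative")
    for _ in range(counts[2]):
        b1, b2 = rng.choice(bases, size=2, replace=False)
        col = [b1] * n_taxa
        col[int(rng.integers(0, n_taxa))] = b2
        columns.append(col)
        labels.append("singleton")

    perm = rng.permutation(n_sites)
    columns = [columns[i] for i in perm]
    labels = [labels[i] for i in perm]
    rows = ["".join(col[t] for col in columns) for t in range(n_taxa)]
    taxa = [f"taxon_{i + 1:02d}" for i in range(n_taxa)]
    aln = AlignmentBlock(taxa=taxa, rows=rows)
    truth = SyntheticTruth(site_classes=labels)
    return aln, truth


def _as_rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)
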