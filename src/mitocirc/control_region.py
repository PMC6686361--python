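"""Control-region structure: motifs, domain partition, tandem repeats.

The avian control region is classically divided into a hypervariable domain
I, a conserved central domain II anchored by the F/E/D/C boxes, and a domain
III carrying the conserved sequence blocks (CSBs).  Raptor mitogenomes often
carry a second noncoding region, the pseudo-control region (CCR), composed
of a nonrepetitive 5' segment (nr-CCR) followed by clusters of tandem
repeats (r-CCR).

The tandem-repeat model here is perfect-match: an array is a maximal,
non-extendable run of an exactly repeated primitive unit, optionally ending
in a partial copy, reported in the ``copies x (unit_len)`` notation
(copy number = span / unit length, one decimal).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}


class PatternError(ValueError):
    """A motif pattern contains a non-IUPAC symbol."""


class PartitionUndefinedError(ValueError):
    """Domain partition anchors (central boxes / CSBs) are missing."""


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence; 1-based inclusive positions within the region."""

    motif_name: str
    pattern: str
    start: int
    end: int
    strand: str = "forward"
    mismatches: int = 0


@dataclass(frozen=True)
class MotifLibraryEntry:
    name: str
    pattern: str
    max_mismatch: int = 0
    strand: str = "forward"  # forward, reverse or both


def load_motif_library(path: str | Path) -> list[MotifLibraryEntry]:
    """Read a motif library TSV: ``name  iupac_pattern  max_mismatch  strand``."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        MotifLibraryEntry(
            name=str(r["name"]),
            pattern=str(r["iupac_pattern"]).upper(),
            max_mismatch=int(r["max_mismatch"]),
            strand=str(r["strand"]),
        )
        for _, r in df.iterrows()
    ]


def default_motif_library() -> list[MotifLibraryEntry]:
    """The shipped (provisional) control-region motif library."""
    ref = resources.files("mitocirc.data") / "cr_motif_library.tsv"
    with resources.as_file(ref) as path:
        return load_motif_library(path)


def _check_pattern(pattern: str) -> None:
    bad = set(pattern.upper()) - set(IUPAC)
    if bad or not pattern:
        raise PatternError(f"invalid IUPAC pattern {pattern!r}")


def _mismatches(window: str, pattern: str) -> int:
    return sum(b not in IUPAC[p] for b, p in zip(window, pattern.upper()))


def find_poly_c(region: str, min_run: int = 4) -> list[tuple[int, int, int]]:
    """Maximal runs of C of length >= min_run, as (start, end, length), 1-based."""
    if min_run < 2:
        raise ValueError("min_run must be >= 2")
    region = region.upper()
    runs: list[tuple[int, int, int]] = []
    i = 0
    n = len(region)
    while i < n:
        if region[i] == "C":
            j = i
            while j < n and region[j] == "C":
                j += 1
            if j - i >= min_run:
                runs.append((i + 1, j, j - i))
            i = j
        else:
            i += 1
    return runs


def scan_motifs(
    region: str, library: list[MotifLibraryEntry]
) -> list[MotifHit]:
    """All matches of each library entry with at most its mismatch budget.

    Overlapping hits are all reported; reverse-strand scanning matches the
    reverse complement of the pattern against the region.
    """
    region = region.upper()
    arr = np.frombuffer(region.encode("ascii"), dtype="S1")
    n = len(region)
    hits: list[MotifHit] = []
    for entry in library:
        _check_pattern(entry.pattern)
        strands = (
            ("forward", "reverse") if entry.strand == "both" else (entry.strand,)
        )
        for strand in strands:
            pat = entry.pattern if strand == "forward" else revcomp(entry.pattern)
            m = len(pat)
            if m > n:
                continue
            mm = np.zeros(n - m + 1, dtype=np.int32)
            for j, p in enumerate(pat.upper()):
                allowed = np.frombuffer(IUPAC[p].encode("ascii"), dtype="S1")
                mm += ~np.isin(arr[j : j + n - m + 1], allowed)
            for i in np.flatnonzero(mm <= entry.max_mismatch):
                hits.append(
                    MotifHit(
                        motif_name=entry.name,
                        pattern=entry.pattern,
                        start=int(i) + 1,
                        end=int(i) + m,
                        strand=strand,
                        mismatches=int(mm[i]),
                    )
                )
    hits.sort(key=lambda h: (h.start, h.end, h.motif_name))
    return hits


@dataclass
class PalindromePairs:
    """TACAT / ATGTA occurrences and their nearest-downstream pairings."""

    tacat: list[MotifHit]
    atgta: list[MotifHit]
    pairs: list[tuple[MotifHit, MotifHit | None]]


def find_palindrome_pairs(region: str) -> PalindromePairs:
    """Locate the complementary TACAT/ATGTA palindromic motifs.

    Every TACAT is paired with the nearest ATGTA starting downstream of it
    (or ``None`` when no downstream ATGTA exists).
    """
    lib = [
        MotifLibraryEntry("TACAT", "TACAT", 0, "forward"),
        MotifLibraryEntry("ATGTA", "ATGTA", 0, "forward"),
    ]
    hits = scan_motifs(region, lib)
    tacat = [h for h in hits if h.motif_name == "TACAT"]
    atgta = [h for h in hits if h.motif_name == "ATGTA"]
    pairs: list[tuple[MotifHit, MotifHit | None]] = []
    for t in tacat:
        downstream = [a for a in atgta if a.start > t.end]
        pairs.append((t, downstream[0] if downstream else None))
    return PalindromePairs(tacat=tacat, atgta=atgta, pairs=pairs)


@dataclass
class CRPartition:
    """The three control-region domains, 1-based inclusive subintervals.

    Domain II spans from the first to the last central-box hit; domain I is
    everything 5' of it, domain III everything 3'.  Flanking domains may be
    empty, encoded as (start, start-1) intervals.
    """

    domain_1: tuple[int, int]
    domain_2: tuple[int, int]
    domain_3: tuple[int, int]


CENTRAL_BOXES = ("F-box", "E-box", "D-box", "C-box")
CSB_NAMES = ("CSB-a", "CSB-b", "CSB-1", "CSB-2", "CSB-3")


def partition_cr(
    cr: str,
    hits: list[MotifHit],
    central_boxes: tuple[str, ...] = CENTRAL_BOXES,
    csb_names: tuple[str, ...] = CSB_NAMES,
) -> CRPartition:
    """Partition a control region into domains I/II/III from motif anchors."""
    central = [h for h in hits if h.motif_name in central_boxes]
    csbs = [h for h in hits if h.motif_name in csb_names]
    missing = []
    if not central:
        missing.append(f"central box ({'/'.join(central_boxes)})")
    if not csbs:
        missing.append(f"CSB ({'/'.join(csb_names)})")
    if missing:
        raise PartitionUndefinedError(
            "cannot partition control region; missing anchors: "
            + "; ".join(missing)
        )
    d2_start = min(h.start for h in central)
    d2_end = max(h.end for h in central)
    return CRPartition(
        domain_1=(1, d2_start - 1),
        domain_2=(d2_start, d2_end),
        domain_3=(d2_end + 1, len(cr)),
    )


@dataclass(frozen=True)
class TandemRepeat:
    """A perfect tandem array: ``copy_number x (unit_len)`` with a partial tail.

    ``copy_number`` is span/unit_len to one decimal; ``partial_len`` the
    length of the trailing incomplete unit; ``end_anchor`` records which half
    of the scanned region the array's midpoint falls in.
    """

    unit: str
    unit_len: int
    start: int
    end: int
    copy_number: float
    partial_len: int
    end_anchor: str = "5prime"

    @property
    def span(self) -> int:
        return self.end - self.start + 1

    def notation(self) -> str:
        return f"{self.copy_number} x ({self.unit_len})"


def _is_primitive(unit: str) -> bool:
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit == unit[:d] * (n // d):
            return False
    return True


def find_tandem_repeats(
    region: str,
    min_unit: int = 5,
    max_unit: int = 250,
    min_copies: float = 2.0,
) -> list[TandemRepeat]:
    """Maximal perfect tandem arrays in ``region``.

    For every candidate period the region is scanned for maximal runs where
    each base equals the base one period earlier; a run of length ``r``
    yields an array of span ``r + u`` (``u`` full-copy period plus fractional
    tail).  Arrays are reported once, with their smallest primitive unit;
    arrays whose primitive period is below ``min_unit``, and arrays wholly
    contained in a longer reported array, are dropped.
    """
    n = len(region)
    if min_unit < 2:
        raise ValueError("min_unit must be >= 2")
    region = region.upper()
    arr = np.frombuffer(region.encode("ascii"), dtype="S1")
    found: list[TandemRepeat] = []
    for u in range(min_unit, min(max_unit, n // 2) + 1):
        eq = arr[u:] == arr[:-u]
        if not eq.any():
            continue
        # maximal runs of True in eq
        padded = np.concatenate(([False], eq, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1) - 1  # inclusive, in eq coords
        for a, b in zip(starts, ends):
            a, b = int(a), int(b)
            span = (b - a + 1) + u  # region[a : b + u + 1]
            if span < min_copies * u:
                continue
            unit = region[a : a + u]
            if not _is_primitive(unit):
                continue  # reported at its primitive period instead
            found.append(
                TandemRepeat(
                    unit=unit,
                    unit_len=u,
                    start=a + 1,
                    end=b + u + 1,
                    copy_number=round(span / u, 1),
                    partial_len=span % u,
                    end_anchor=(
                        "5prime" if (a + 1 + b + u + 1) / 2 <= n / 2 else "3prime"
                    ),
                )
            )
    # containment filter: keep only maximal arrays; on identical intervals
    # keep the smallest unit.
    found.sort(key=lambda t: (t.start, -(t.end), t.unit_len))
    kept: list[TandemRepeat] = []
    for t in found:
        contained = any(
            k.start <= t.start and t.end <= k.end and (k.start, k.end) != (t.start, t.end)
            or ((k.start, k.end) == (t.start, t.end) and k.unit_len < t.unit_len)
            for k in kept
        )
        if not contained:
            kept.append(t)
    kept.sort(key=lambda t: (t.start, t.end))
    return kept


@dataclass
class CCRDecomposition:
    """Ordered tiling of a pseudo-control region into nr-CCR and repeat spans.

    ``segments`` is a list of ``("nr-CCR", start, end)`` tuples interleaved
    with :class:`TandemRepeat` objects; together they tile the region.
    """

    segments: list

    def total_length(self) -> int:
        total = 0
        for seg in self.segments:
            if isinstance(seg, TandemRepeat):
                total += seg.span
            else:
                _, s, e = seg
                total += e - s + 1
        return total


def decompose_ccr(
    ccr: str,
    min_unit: int = 5,
    max_unit: int = 250,
    min_copies: float = 2.0,
) -> CCRDecomposition:
    """Tile a CCR into repeat arrays (r-CCR) and nonrepetitive gaps (nr-CCR)."""
    repeats = find_tandem_repeats(
        ccr, min_unit=min_unit, max_unit=max_unit, min_copies=min_copies
    )
    segments: list = []
    pos = 1
    for rep in repeats:
        if rep.start < pos:  # overlaps a previously placed array
            continue
        if rep.start > pos:
            segments.append(("nr-CCR", pos, rep.start - 1))
        segments.append(rep)
        pos = rep.end + 1
    if pos <= len(ccr):
        segments.append(("nr-CCR", pos, len(ccr)))
    return CCRDecomposition(segments=segments)


def verify_tandem_repeat(region: str, t: TandemRepeat) -> bool:
    """Check that a reported array really is unit^k + unit-prefix."""
    span_seq = region.upper()[t.start - 1 : t.end]
    k = len(span_seq) // t.unit_len
    expected = t.unit * k + t.unit[: t.partial_len]
    return span_seq == expected and len(span_seq) % t.unit_len == t.partial_len
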