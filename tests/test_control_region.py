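"""Motif scanning, domain partition and tandem-repeat decomposition."""

import numpy as np
import pytest

from mitocirc import (
    CRSpec,
    CCRSpec,
    TandemRepeat,
    decompose_ccr,
    default_motif_library,
    find_palindrome_pairs,
    find_poly_c,
    find_tandem_repeats,
    generate_ccr,
    generate_cr,
    partition_cr,
    revcomp,
    scan_motifs,
)
from mitocirc.control_region import (
    IUPAC,
    MotifHit,
    MotifLibraryEntry,
    PartitionUndefinedError,
    PatternError,
    verify_tandem_repeat,
)

# ---------------------------------------------------------------------------
# independent oracles


def brute_poly_c(region, min_run):
    runs, i = [], 0
    while i < len(region):
        j = i
        while j < len(region) and region[j] == "C":
            j += 1
        if j > i and j - i >= min_run:
            runs.append((i + 1, j, j - i))
        i = max(j, i + 1)
    return runs


def brute_scan(region, entries):
    hits = []
    for e in entries:
        for strand in (("forward", "reverse") if e.strand == "both"
                       else (e.strand,)):
            pat = e.pattern if strand == "forward" else revcomp(e.pattern)
            for i in range(len(region) - len(pat) + 1):
                mm = sum(
                    region[i + j] not in IUPAC[p]
                    for j, p in enumerate(pat)
                )
                if mm <= e.max_mismatch:
                    hits.append((e.name, i + 1, i + len(pat), strand, mm))
    return sorted(hits)


def brute_tandem(region, min_unit=5, max_unit=250, min_copies=2.0):
    """Exhaustive search over all (start, unit_len) pairs."""
    n = len(region)
    cands = []
    for u in range(min_unit, min(max_unit, n // 2) + 1):
        for a in range(0, n - 2 * u + 1):
            if a > 0 and region[a - 1] == region[a + u - 1]:
                continue  # not left-maximal
            e = a + u
            while e < n and region[e] == region[e - u]:
                e += 1
            span = e - a
            if span < min_copies * u:
                continue
            unit = region[a : a + u]
            if any(u % d == 0 and unit == unit[:d] * (u // d)
                   for d in range(1, u)):
                continue  # unit not primitive
            cands.append((a + 1, e, u))
    kept = []
    for a, e, u in set(cands):
        if any(
            (a2 <= a and e <= e2 and (a2, e2) != (a, e))
            or ((a2, e2) == (a, e) and u2 < u)
            for a2, e2, u2 in cands
        ):
            continue
        kept.append((a, e, u))
    return sorted(kept)


# ---------------------------------------------------------------------------
# poly-C


def test_poly_c_examples():
    assert find_poly_c("AACCCCCCAA", 4) == [(3, 8, 6)]
    assert find_poly_c("ACACAC", 3) == []
    assert find_poly_c("CCCCACCC", 3) == [(1, 4, 4), (6, 8, 3)]


def test_poly_c_min_run_validation():
    with pytest.raises(ValueError):
        find_poly_c("CCCC", 1)


def test_poly_c_matches_linear_scan_oracle():
    rng = np.random.default_rng(5)
    for _ in range(200):
        seq = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 80),
                                 p=[0.2, 0.4, 0.2, 0.2]))
        for min_run in (2, 3, 4):
            assert find_poly_c(seq, min_run) == brute_poly_c(seq, min_run)


# ---------------------------------------------------------------------------
# palindromes


def test_palindrome_pair_example():
    res = find_palindrome_pairs("GTACATTTATGTAG")
    assert [(h.start, h.end) for h in res.tacat] == [(2, 6)]
    assert [(h.start, h.end) for h in res.atgta] == [(9, 13)]
    assert len(res.pairs) == 1
    t, a = res.pairs[0]
    assert (t.start, a.start) == (2, 9)


def test_unpaired_tacat_reported():
    res = find_palindrome_pairs("GGTACATGG")
    assert len(res.tacat) == 1
    assert res.pairs[0][1] is None


def test_palindromes_are_reverse_complements():
    assert revcomp("TACAT") == "ATGTA"


def test_planted_pairs_recovered():
    rng = np.random.default_rng(9)
    for _ in range(30):
        gap = int(rng.integers(1, 30))
        pad = "".join(rng.choice(list("CG"), size=20))
        mid = "".join(rng.choice(list("CG"), size=gap))
        seq = pad + "TACAT" + mid + "ATGTA" + pad
        res = find_palindrome_pairs(seq)
        assert len(res.pairs) == 1
        t, a = res.pairs[0]
        assert (t.start, a.start) == (21, 26 + gap)


# ---------------------------------------------------------------------------
# motif scanning


def test_iupac_degenerate_match():
    hits = scan_motifs("GGTACATGG", [MotifLibraryEntry("m", "TAYAT", 0)])
    assert [(h.start, h.mismatches) for h in hits] == [(3, 0)]


def test_mismatch_budget():
    hits = scan_motifs("GGTACGTGG", [MotifLibraryEntry("m", "TACAT", 1)])
    assert [(h.start, h.mismatches) for h in hits] == [(3, 1)]
    assert scan_motifs("GGTACGTGG", [MotifLibraryEntry("m", "TACAT", 0)]) == []


def test_reverse_strand_scanning():
    region = "GG" + revcomp("TACAT") + "GG"
    hits = scan_motifs(region, [MotifLibraryEntry("m", "TACAT", 0, "both")])
    assert [(h.strand, h.start) for h in hits] == [("reverse", 3)]


def test_invalid_pattern_rejected():
    with pytest.raises(PatternError):
        scan_motifs("ACGT", [MotifLibraryEntry("m", "AXGT", 0)])


def test_scan_matches_sliding_window_oracle():
    rng = np.random.default_rng(17)
    alphabet = list("ACGT")
    pat_alphabet = list(IUPAC)
    for _ in range(60):
        region = "".join(rng.choice(alphabet, size=rng.integers(10, 120)))
        entries = [
            MotifLibraryEntry(
                f"m{k}",
                "".join(rng.choice(pat_alphabet, size=rng.integers(3, 8))),
                int(rng.integers(0, 2)),
                rng.choice(["forward", "reverse", "both"]),
            )
            for k in range(3)
        ]
        got = [
            (h.motif_name, h.start, h.end, h.strand, h.mismatches)
            for h in scan_motifs(region, entries)
        ]
        assert sorted(got) == brute_scan(region, entries)


# ---------------------------------------------------------------------------
# partition


def test_partition_recovers_planted_domains():
    for seed in range(5):
        cr, truth = generate_cr(CRSpec(), seed)
        hits = scan_motifs(cr, default_motif_library())
        part = partition_cr(cr, hits)
        assert part == truth["domains"]
        d1, d2, d3 = part.domain_1, part.domain_2, part.domain_3
        assert d1[1] + 1 == d2[0] and d2[1] + 1 == d3[0]
        assert d1[0] == 1 and d3[1] == len(cr)


def test_partition_requires_anchors():
    with pytest.raises(PartitionUndefinedError):
        partition_cr("ACGT" * 50, [])
    only_di = [MotifHit("TACAT", "TACAT", 5, 9)]
    with pytest.raises(PartitionUndefinedError) as err:
        partition_cr("ACGT" * 50, only_di)
    assert "central box" in str(err.value)


# ---------------------------------------------------------------------------
# tandem repeats


def test_dinucleotide_array():
    reps = find_tandem_repeats("ATATATATAT", min_unit=2, max_unit=5)
    assert len(reps) == 1
    r = reps[0]
    assert (r.unit, r.unit_len, r.copy_number, r.partial_len) == ("AT", 2, 5.0, 0)
    assert (r.start, r.end) == (1, 10)


def test_planted_array_with_partial_tail():
    unit = "TCTTTTTTCAT"
    region = "GAGGAGGAGGAGCGACGCAGGAG" + unit * 12 + unit[:8] + "GAGGACGAGAGG"
    reps = find_tandem_repeats(region)
    assert len(reps) == 1
    r = reps[0]
    assert (r.unit, r.unit_len) == (unit, 11)
    assert (r.copy_number, r.partial_len) == (12.7, 8)
    assert r.start == 24 and r.span == 140


def test_repeat_free_region_is_empty():
    ccr, _ = generate_ccr(CCRSpec(segments=(("nr", 200),)), 3)
    assert find_tandem_repeats(ccr) == []


def test_reported_repeats_verify_and_are_primitive():
    rng = np.random.default_rng(29)
    for _ in range(150):
        seq = "".join(rng.choice(list("AT"), size=rng.integers(20, 120)))
        for r in find_tandem_repeats(seq, min_unit=2, max_unit=20):
            assert verify_tandem_repeat(seq, r)
            assert r.copy_number == round(r.span / r.unit_len, 1)
            assert r.partial_len == r.span % r.unit_len
            u = r.unit
            assert not any(
                len(u) % d == 0 and u == u[: d] * (len(u) // d)
                for d in range(1, len(u))
            )


def test_finder_matches_exhaustive_search_small_regions():
    rng = np.random.default_rng(31)
    for trial in range(120):
        # two-letter alphabets make accidental repeats plentiful
        alphabet = list("AT") if trial % 3 else list("ACGT")
        n = int(rng.integers(10, 150))
        seq = "".join(rng.choice(alphabet, size=n))
        got = [(r.start, r.end, r.unit_len)
               for r in find_tandem_repeats(seq, min_unit=2, max_unit=75)]
        assert sorted(got) == brute_tandem(seq, min_unit=2, max_unit=75)


def test_planted_unit_recovery():
    """Planted cassettes (unit 5-50 bp, 2-30 copies) are recovered exactly."""
    rng = np.random.default_rng(37)
    ok = 0
    trials = 60
    for _ in range(trials):
        ulen = int(rng.integers(5, 51))
        copies = int(rng.integers(2, 31))
        partial = int(rng.integers(0, ulen))
        spec = CCRSpec(
            segments=(
                ("nr", int(rng.integers(30, 80))),
                ("repeat", _random_primitive_unit(rng, ulen), copies, partial),
                ("nr", int(rng.integers(30, 80))),
            ),
            max_unit=60,
        )
        ccr, planted = generate_ccr(spec, int(rng.integers(0, 2**31)))
        found = find_tandem_repeats(ccr, max_unit=60)
        want = planted[0]
        match = [
            r for r in found
            if r.unit_len == want.unit_len
            and abs(r.copy_number - want.copy_number) <= 0.1
        ]
        ok += bool(match)
    assert ok == trials


def _random_primitive_unit(rng, ulen):
    while True:
        unit = "".join(rng.choice(list("ACGT"), size=ulen))
        if not any(
            ulen % d == 0 and unit == unit[:d] * (ulen // d)
            for d in range(1, ulen)
        ):
            return unit


# ---------------------------------------------------------------------------
# CCR decomposition


def test_decompose_generator_ccr(default_genome):
    genome, truth = default_genome
    ccr_feat = next(f for f in genome.features if f.ftype == "CCR")
    ccr = genome.h_strand_sequence(ccr_feat)
    decomp = decompose_ccr(ccr)
    reps = [s for s in decomp.segments if isinstance(s, TandemRepeat)]
    nrs = [s for s in decomp.segments if not isinstance(s, TandemRepeat)]
    assert [(r.start, r.end, r.unit_len) for r in reps] == [
        (t.start, t.end, t.unit_len) for t in truth.ccr_repeats
    ]
    assert len(decomp.segments) == 4
    assert nrs[0] == ("nr-CCR", 1, 125)
    assert decomp.total_length() == len(ccr)


def test_decompose_repeat_free_region():
    ccr, _ = generate_ccr(CCRSpec(segments=(("nr", 150),)), 4)
    decomp = decompose_ccr(ccr)
    assert decomp.segments == [("nr-CCR", 1, 150)]


def test_decomposition_tiles_arbitrary_input():
    rng = np.random.default_rng(41)
    for _ in range(40):
        seq = "".join(rng.choice(list("ACGT"), size=rng.integers(20, 400),
                                 p=[0.4, 0.1, 0.1, 0.4]))
        decomp = decompose_ccr(seq, min_unit=3)
        assert decomp.total_length() == len(seq)
        pos = 1
        for seg in decomp.segments:
            s = seg.start if isinstance(seg, TandemRepeat) else seg[1]
            e = seg.end if isinstance(seg, TandemRepeat) else seg[2]
            assert s == pos
            pos = e + 1
        assert pos == len(seq) + 1


def test_end_anchor_reflects_region_half():
    region = "ATATATATATAT" + "G" * 100
    r5 = find_tandem_repeats(region, min_unit=2, max_unit=6)[0]
    assert r5.end_anchor == "5prime"
    region = "G" * 100 + "ATATATATATAT"
    r3 = find_tandem_repeats(region, min_unit=2, max_unit=6)[0]
    assert r3.end_anchor == "3prime"
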