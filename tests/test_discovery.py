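"""Pileup-based locus discovery: k-mer matching, placement, pileups, calls."""

import numpy as np
import pytest

from drivefam.discovery import (CopyNumberCalibration, CoverageTrack, Pileup,
                                ReferenceIndex, call_loci, call_pileups,
                                detect_duplicated_regions,
                                estimate_copy_number, map_partner_reads,
                                match_reads_to_family, read_sam_coverage)
from drivefam.io import Interval, SeqRecord, revcomp

RNG = np.random.default_rng(0)
BASES = np.array(list("ACGT"))


def rand_seq(n, rng=RNG):
    return "".join(BASES[rng.integers(0, 4, n)])


# --- panel matching ----------------------------------------------------------

def test_exact_substring_read_matches_panel():
    gene = rand_seq(1200)
    panel = [SeqRecord("g", gene)]
    read = SeqRecord("r/1", gene[300:450])
    mate = SeqRecord("r/2", rand_seq(150))
    (cls,) = match_reads_to_family([(read, mate)], panel)
    assert cls.r1_is_family and not cls.r2_is_family
    assert [p.id for p in cls.partner_reads] == ["r/2"]
    # reverse-complement reads match too (strand-agnostic)
    (cls,) = match_reads_to_family(
        [(SeqRecord("q/1", revcomp(gene[300:450])), mate)], panel)
    assert cls.r1_is_family


def test_random_read_does_not_match_unrelated_panel():
    panel = [SeqRecord("g", rand_seq(1200))]
    pairs = [(SeqRecord(f"r{i}/1", rand_seq(150)),
              SeqRecord(f"r{i}/2", rand_seq(150))) for i in range(50)]
    assert match_reads_to_family(pairs, panel, k=21) == []


def _mutated_read_pairs(gene, n, n_mismatch, rng):
    pairs = []
    for i in range(n):
        start = rng.integers(0, 1050)
        read = list(gene[start:start + 150])
        for p in rng.choice(150, n_mismatch, replace=False):
            read[p] = "ACGT"[(("ACGT".index(read[p])) + 1 +
                              rng.integers(3)) % 4]
        pairs.append((SeqRecord(f"m{i}/1", "".join(read)),
                      SeqRecord(f"m{i}/2", rand_seq(150, rng))))
    return pairs


def test_divergent_reads_still_match():
    """Shared-k-mer matching tolerates the divergence seen between family
    paralogs: reads with 8% iid mismatches (twice the per-branch simulator
    rate) match their source gene >=99% of the time, and the 20%-mismatch
    match rate follows the binomial clean-k-mer model (Monte Carlo vs
    analytic expectation)."""
    from scipy import stats

    rng = np.random.default_rng(5)
    gene = rand_seq(1200, rng)
    panel = [SeqRecord("g", gene)]
    n = 1000
    hits8 = match_reads_to_family(
        _mutated_read_pairs(gene, n, 12, rng), panel, k=15,
        min_kmer_frac=0.05)
    assert sum(c.r1_is_family for c in hits8) >= 0.99 * n

    hits20 = match_reads_to_family(
        _mutated_read_pairs(gene, n, 30, rng), panel, k=15,
        min_kmer_frac=0.05)
    rate20 = sum(c.r1_is_family for c in hits20) / n
    # expected clean k-mers ~ Binomial(136, (1-0.2)^15); match needs >= 7
    p_clean = (1 - 30 / 150) ** 15
    analytic = 1 - stats.binom(136, p_clean).cdf(6)
    assert abs(rate20 - analytic) < 0.1


def test_empty_panel_rejected():
    with pytest.raises(ValueError, match="empty"):
        match_reads_to_family([], [])


# --- placement ---------------------------------------------------------------

def test_partner_reads_place_at_true_origins(six_locus_run):
    run = six_locus_run
    origins = run["origins"]
    n_checked = n_correct = 0
    for rid, (pos, strand) in run["placements"].items():
        iv, true_strand = origins[rid]
        n_checked += 1
        n_correct += (pos == iv.start and strand == true_strand)
    assert n_checked > 1000
    assert n_correct / n_checked >= 0.99


def test_repeat_reads_discarded_as_ambiguous():
    ltr = rand_seq(400)
    genome = "".join(rand_seq(500) + ltr for _ in range(10)) + rand_seq(500)
    idx = ReferenceIndex(genome)
    # a read wholly inside an exact LTR copy cannot be placed
    assert idx.place(ltr[100:250]) is None
    # a unique-flank read places exactly
    assert idx.place(genome[200:350]) == (200, "+")


def test_sam_coverage_matches_independent_parse(tmp_path):
    sam = tmp_path / "x.sam"
    sam.write_text(
        "@HD\tVN:1.6\tSO:unsorted\n"
        "@SQ\tSN:chr1\tLN:1000\n"
        "r1\t0\tchr1\t11\t60\t100M\t*\t0\t0\t" + "A" * 100 + "\t*\n"
        "r2\t16\tchr1\t51\t60\t50M\t*\t0\t0\t" + "C" * 50 + "\t*\n"
        "r3\t4\t*\t0\t0\t*\t*\t0\t0\t" + "G" * 50 + "\t*\n")
    track = read_sam_coverage(str(sam))
    # hand-computed: r1 covers [10,110), r2 covers [50,100)
    expected = np.zeros(1000)
    expected[10:110] += 1
    expected[50:100] += 1
    assert np.array_equal(track.cov["chr1"], expected)


# --- pileups -----------------------------------------------------------------

def brute_force_pileups(arr, min_depth, merge_gap):
    runs = []
    cur = None
    for i, v in enumerate(arr):
        if v >= min_depth:
            if cur is None:
                cur = [i, i + 1]
            else:
                cur[1] = i + 1
        elif cur is not None:
            runs.append(cur)
            cur = None
    if cur is not None:
        runs.append(cur)
    merged = []
    for s, e in runs:
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    return [tuple(r) for r in merged]


@pytest.mark.parametrize("seed", range(5))
def test_pileup_calling_equals_brute_force(seed):
    rng = np.random.default_rng(seed)
    arr = rng.integers(0, 6, 3000).astype(np.int32)
    arr[rng.random(3000) < 0.5] = 0
    track = CoverageTrack({"c": arr})
    got = call_pileups(track, min_depth=3, merge_gap=50,
                       extend_to_support=False)
    assert [(p.interval.start, p.interval.end) for p in got] == \
        brute_force_pileups(arr, 3, 50)


def test_pileup_simple_cases():
    track = CoverageTrack({"c": np.zeros(5000, np.int32)})
    assert call_pileups(track) == []
    arr = np.zeros(5000, np.int32)
    arr[1000:3200] = 10
    got = call_pileups(CoverageTrack({"c": arr}), min_depth=3)
    assert len(got) == 1 and got[0].width == 2200
    assert got[0].max_depth == 10
    # two blocks 150 bp apart merge at merge_gap=200
    arr = np.zeros(5000, np.int32)
    arr[1000:1500] = 5
    arr[1650:2000] = 5
    got = call_pileups(CoverageTrack({"c": arr}), min_depth=3, merge_gap=200)
    assert len(got) == 1 and (got[0].interval.start, got[0].interval.end) == \
        (1000, 2000)


def test_support_extension_recovers_mound_width():
    """A triangular mound is reported at its full support, not the
    depth>=3 core."""
    arr = np.zeros(3000, np.int32)
    for i in range(300):  # ramp 0..30 over [1000,1300), plateau, ramp down
        arr[1000 + i] = i // 10
        arr[1700 + i] = 30 - i // 10
    arr[1300:1700] = 30
    got = call_pileups(CoverageTrack({"c": arr}), min_depth=3)
    assert (got[0].interval.start, got[0].interval.end) == (1010, 2000)
    core = call_pileups(CoverageTrack({"c": arr}), min_depth=3,
                        extend_to_support=False)
    assert core[0].width < got[0].width


# --- locus calling -----------------------------------------------------------

def P(chrom, s, e, depth=10):
    return Pileup(Interval(chrom, s, e, "pileup"), depth, float(depth))


def test_pairing_rule_by_hand():
    calls = call_loci([P("c", 0, 2200), P("c", 3400, 5600)],
                      max_pair_span=4000)
    (c,) = calls
    assert (c.interval.start, c.interval.end) == (2200, 3400)
    assert c.widest_width == 2200
    assert "symmetric" in c.flags


def test_lone_pileup_single_flank():
    (c,) = call_loci([P("c", 0, 2200)], max_pair_span=4000)
    assert "single_flank" in c.flags and c.right_pileup is None


def test_three_evenly_spaced_greedy_pairing():
    calls = call_loci([P("c", 0, 1000), P("c", 2000, 3000),
                       P("c", 4000, 5000)], max_pair_span=2000)
    assert len(calls) == 2
    assert (calls[0].interval.start, calls[0].interval.end) == (1000, 2000)
    assert "single_flank" in calls[1].flags
    # a genuinely crowded pattern: two right-flank candidates in range of
    # the same left pileup
    crowded = call_loci([P("c", 0, 1000), P("c", 1500, 2500),
                         P("c", 2800, 3800)], max_pair_span=3000)
    assert "complicated" in crowded[0].flags


def test_asymmetric_flags():
    (c,) = call_loci([P("c", 0, 2000), P("c", 3000, 7000)],
                     max_pair_span=4000)
    assert "asymmetric" in c.flags and "complicated" in c.flags
    assert c.widest_width == 4000


# --- copy-number calibration -------------------------------------------------

def test_paper_anchor_widths():
    calib = CopyNumberCalibration.paper_default()
    assert calib.boundaries == (1100.0, 3300.0, 5950.0)
    assert estimate_copy_number(2200, calib) == 1
    assert estimate_copy_number(4400, calib) == 2
    assert estimate_copy_number(7500, calib) == 3
    assert estimate_copy_number(0, calib) == 0
    with pytest.raises(ValueError):
        estimate_copy_number(-1, calib)


def test_analytic_calibration_and_recalibration():
    calib = CopyNumberCalibration.from_mate_pair_params(5000, 8000, 150)
    w1, w2, w3 = calib.anchors
    assert w1 == 1200 + 3000 + 300
    assert w2 == 2 * 1200 + 350 + 3300
    assert w1 < w2 < w3
    rec = calib.recalibrated([w1 * 0.9, w1 * 0.9])
    assert rec.anchors[0] == pytest.approx(w1 * 0.9)
    n, flagged = calib.estimate(20000)
    assert n == 3 and flagged


# --- duplication detection ---------------------------------------------------

def test_duplicated_region_detected_from_simulation():
    """A segment present twice in the sample shows ~2x coverage when all
    reads are aligned to a reference that carries it once."""
    from drivefam.simulate import (FamilyParams, MatePairParams, build_genome,
                                   simulate_mate_pairs)

    fam = FamilyParams(n_loci=2, locus_gene_counts=[1, 1], seed=13,
                       flank_unique_len=8000, duplicate_locus=0,
                       duplication_pad=3000)
    genome, truth = build_genome(fam)
    mp = MatePairParams(coverage=40, error_rate=0.0)
    r1, r2, _ = simulate_mate_pairs(genome, mp, 14)
    reference = SeqRecord(genome.id, genome.sequence[:truth.reference_length])
    track, _ = map_partner_reads(r1 + r2, reference)
    fam_dups, all_dups = detect_duplicated_regions(
        track, family_loci=[l.interval for l in truth.loci])
    (dup,) = truth.duplications
    assert any(r.overlaps(dup) for r in fam_dups)


def test_duplication_reports_and_edge_cases():
    arr = np.full(30000, 20, np.int32)
    track = CoverageTrack({"c": arr})
    fam_dups, all_dups = detect_duplicated_regions(track, family_loci=[])
    assert fam_dups == [] and all_dups == []  # uniform coverage
    arr2 = arr.copy()
    arr2[10000:14000] = 45
    track2 = CoverageTrack({"c": arr2})
    loci = [Interval("c", 20000, 21000)]  # family locus elsewhere
    fam_dups, all_dups = detect_duplicated_regions(track2, family_loci=loci)
    assert fam_dups == [] and len(all_dups) == 1  # kept in full report only
    with pytest.raises(ValueError, match="zero-coverage"):
        detect_duplicated_regions(CoverageTrack({"c": np.zeros(5000,
                                                               np.int32)}))
    with pytest.raises(ValueError):
        detect_duplicated_regions(track, window=100)
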