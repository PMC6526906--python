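"""Bait regions, read recruitment, greedy OLC assembly, contig stitching."""

import numpy as np
import pytest

from drivefam.assembly import (AmbiguousStitchError, assemble_greedy,
                               define_regions, percent_identity,
                               recruit_and_filter, stitch_contigs,
                               subtract_intervals)
from drivefam.discovery import LocusCall, Pileup
from drivefam.io import Interval, SeqRecord, revcomp

RNG = np.random.default_rng(7)
BASES = np.array(list("ACGT"))


def rand_seq(n, rng=RNG):
    return "".join(BASES[rng.integers(0, 4, n)])


def make_call(chrom="c", left=(10000, 14000), gap=(14000, 22000),
              right=(22000, 26000)):
    lp = Pileup(Interval(chrom, *left, "pileup"), 10, 10.0)
    rp = Pileup(Interval(chrom, *right, "pileup"), 10, 10.0)
    return LocusCall(Interval(chrom, *gap, "locus"), lp, rp)


# --- regions -----------------------------------------------------------------

def test_orange_is_padded_pileups_clipped_at_locus():
    call = make_call()
    regions = define_regions(call, flank=2000, chrom_length=40000)
    # left: [10000-2000, 14000] clipped at locus start; right symmetric
    assert [(iv.start, iv.end) for iv in regions.orange] == \
        [(8000, 14000), (22000, 28000)]
    assert not regions.one_sided


def test_orange_excludes_masked_repeat():
    call = make_call()
    mask = [Interval("c", 9000, 9400)]
    regions = define_regions(call, repeat_mask=mask, chrom_length=40000)
    left = [(iv.start, iv.end) for iv in regions.orange
            if iv.end <= 14000]
    # interval-subtraction oracle
    assert left == [(8000, 9000), (9400, 14000)]


def test_subtract_intervals_oracle():
    iv = Interval("c", 0, 100)
    mask = [Interval("c", 10, 20), Interval("c", 15, 30),
            Interval("c", 90, 200)]
    got = [(p.start, p.end) for p in subtract_intervals(iv, mask)]
    covered = set()
    for m in mask:
        covered.update(range(max(0, m.start), min(100, m.end)))
    expected_bases = set(range(100)) - covered
    got_bases = {b for s, e in got for b in range(s, e)}
    assert got_bases == expected_bases


def test_one_sided_locus_flagged():
    lp = Pileup(Interval("c", 0, 2000, "pileup"), 10, 10.0)
    call = LocusCall(Interval("c", 2000, 8000, "locus"), lp, None,
                     {"single_flank"})
    regions = define_regions(call, chrom_length=30000)
    assert regions.one_sided
    call_none = LocusCall(Interval("c", 2000, 8000, "locus"), None, None)
    with pytest.raises(ValueError):
        define_regions(call_none)


# --- recruitment -------------------------------------------------------------

def test_recruitment_rules():
    """Pairs need an orange read; kept reads must not match green."""
    rng = np.random.default_rng(1)
    ref = rand_seq(30000, rng)
    call = make_call()
    regions = define_regions(call, chrom_length=30000)

    orange_read = SeqRecord("a/1", ref[9000:9150])
    locus_read = SeqRecord("a/2", ref[17000:17150])   # inside the locus
    green_read = SeqRecord("b/1", ref[5000:5150])     # green, not orange...
    green_read2 = SeqRecord("b/2", ref[6000:6150])
    far_read = SeqRecord("c/1", rand_seq(150, rng))
    locus_read2 = SeqRecord("c/2", ref[18000:18150])

    pairs = [(orange_read, locus_read),   # mate kept
             (green_read, green_read2),   # both in green: nothing
             (far_read, locus_read2)]     # neither read in orange: excluded
    got = recruit_and_filter(pairs, regions, ref)
    assert [r.id for r in got] == ["a/2"]
    with pytest.raises(ValueError, match="no reads recruited"):
        recruit_and_filter([(far_read, far_read)], regions, ref)


# --- greedy OLC --------------------------------------------------------------

def tile_reads(seq, step, length=150, prefix="t"):
    out = []
    for i, s in enumerate(range(0, len(seq) - length + 1, step)):
        out.append(SeqRecord(f"{prefix}{i}", seq[s:s + length]))
    return out


def test_min_overlap_threshold_edge():
    a = rand_seq(150)
    b = a[111:] + rand_seq(111)  # 39-bp overlap
    got = assemble_greedy([SeqRecord("x", a), SeqRecord("y", b)],
                          min_overlap=40)
    assert len(got) == 2
    c = a[110:] + rand_seq(110)  # 40-bp overlap merges
    got = assemble_greedy([SeqRecord("x", a), SeqRecord("y", c)],
                          min_overlap=40)
    assert len(got) == 1
    assert got[0].sequence == a + c[40:]


def test_error_free_tiling_recovers_truth():
    truth = rand_seq(2000)
    reads = tile_reads(truth, 40)
    got = assemble_greedy(reads)
    assert len(got) == 1
    assert got[0].sequence == truth[:len(got[0].sequence)] or \
        got[0].sequence == truth
    assert got[0].mismatch_rate == 0.0
    assert got[0].support.min() >= 1


def test_both_strands_considered():
    truth = rand_seq(1500)
    reads = tile_reads(truth, 50)
    flipped = [SeqRecord(r.id, revcomp(r.sequence)) if i % 2 else r
               for i, r in enumerate(reads)]
    got = assemble_greedy(flipped)
    assert len(got) == 1
    assert got[0].sequence in (truth, revcomp(truth))


def test_consensus_majority_fixes_errors():
    truth = rand_seq(600)
    reads = tile_reads(truth, 30)  # tiles cover the full 600 bp exactly
    seq = list(reads[5].sequence)
    seq[75] = "ACGT"[("ACGT".index(seq[75]) + 1) % 4]
    reads[5] = SeqRecord(reads[5].id, "".join(seq))
    got = assemble_greedy(reads)
    assert len(got) == 1
    assert got[0].sequence == truth
    assert got[0].mismatch_rate > 0


def test_paralogs_do_not_collapse():
    """Two ~95%-identical paralogs yield contigs that each map wholly
    within one paralog (no chimeras)."""
    rng = np.random.default_rng(3)
    a = rand_seq(800, rng)
    b = list(a)
    for p in rng.choice(800, 40, replace=False):  # 5% divergence
        b[p] = "ACGT"[("ACGT".index(b[p]) + 1 + rng.integers(3)) % 4]
    b = "".join(b)
    reads = tile_reads(a, 35, prefix="a") + tile_reads(b, 35, prefix="b")
    got = assemble_greedy(reads)
    assert len(got) >= 2
    for c in got:
        sources = {m[0][0] for m in c.members}
        assert len(sources) == 1, "chimeric contig mixing paralogs"
        assert c.mismatch_rate <= 0.02


def test_singleton_reads_emitted():
    got = assemble_greedy([SeqRecord("solo", rand_seq(150))])
    assert len(got) == 1 and len(got[0].sequence) == 150


# --- stitching ---------------------------------------------------------------

def test_stitch_two_overlapping_contigs():
    region = rand_seq(3000)
    left_flank, right_flank = region[:400], region[-400:]
    c1 = region[200:1800]
    c2 = region[1650:2800]  # 150-bp overlap with c1
    seq, rep = stitch_contigs([c1, c2], left_flank, right_flank)
    assert seq == region[200:2800]
    assert len(seq) == len(c1) + len(c2) - 150
    assert rep["joins"] == [150]


def test_stitch_orients_reversed_contig():
    region = rand_seq(2500)
    c1 = region[100:1500]
    c2 = revcomp(region[1300:2400])
    seq, rep = stitch_contigs([c1, c2], region[:400], region[-400:])
    assert seq == region[100:2400]


def test_stitch_gap_estimated_from_expected_span():
    region = rand_seq(4000)
    c1 = region[100:1500]
    c2 = region[2500:3900]
    seq, rep = stitch_contigs([c1, c2], region[:400], region[-400:],
                              expected_span=3800)
    assert rep["n_gap"] == 3800 - len(c1) - len(c2)
    assert seq.count("N") == rep["n_gap"]
    # truth gap is 1000; estimate within +/-500
    assert abs(rep["n_gap"] - 1000) <= 500


def test_stitch_errors_on_missing_anchor_and_ambiguity():
    region = rand_seq(3000)
    with pytest.raises(ValueError, match="anchors"):
        stitch_contigs([rand_seq(500)], region[:400], region[-400:])
    # ambiguous: two equally valid middle contigs that differ
    c_left = region[100:1200]
    mid1 = region[1000:2200]
    mid2 = list(mid1)
    mid2[600] = "A" if mid1[600] != "A" else "C"
    mid2 = "".join(mid2)
    c_right = region[2000:2900]
    with pytest.raises(AmbiguousStitchError):
        stitch_contigs([c_left, mid1, mid2, c_right], region[:400],
                       region[-400:])


def test_single_contig_spanning_locus_returned_unchanged():
    region = rand_seq(2000)
    c = region[100:1900]
    seq, rep = stitch_contigs([c], region[:400], region[-400:])
    assert seq == c and rep["contigs_used"] == 1


# --- end-to-end on simulated locus (session fixtures) ------------------------

def test_assembled_locus_matches_truth_exactly(assembled_locus_errorfree):
    run = assembled_locus_errorfree
    call, genome = run["call"], run["genome"]
    target = genome.sequence[call.interval.start - 1200:
                             call.interval.end + 1200]
    import edlib
    res = edlib.align(run["locus_seq"], target, mode="HW", task="distance")
    assert res["editDistance"] == 0
    assert run["stitch_report"]["n_gap"] == 0


def test_consensus_mismatch_rate_similar_inside_and_out(
        assembled_locus_err002):
    """Assemblies are not collapsing non-identical repeats: the consensus
    disagreement rate over the genes stays within 2x the rate in the
    flanking unique sequence (plus a small absolute allowance for the
    Poisson noise of sequencing errors)."""
    import edlib

    run = assembled_locus_err002
    contig = max(run["contigs"], key=len)
    truth, genome = run["truth"], run["genome"]
    res = edlib.align(contig.sequence, genome.sequence, mode="HW",
                      task="locations")
    start = res["locations"][0][0]
    gene_cols = np.zeros(len(contig.sequence), bool)
    for meta in truth.gene_meta.values():
        iv = meta["genome_interval"]
        s, e = max(0, iv.start - start), max(0, iv.end - start)
        gene_cols[s:min(e, len(gene_cols))] = True
    mm, sup = contig.column_mismatches, contig.support
    rate_in = mm[gene_cols].sum() / sup[gene_cols].sum()
    rate_out = mm[~gene_cols].sum() / sup[~gene_cols].sum()
    assert rate_in <= 2 * rate_out + 5e-4
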