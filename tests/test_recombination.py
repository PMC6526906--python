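"""Segmenting, clade assignment, and the four-gamete machinery."""

import itertools

import numpy as np
import pytest

from drivefam.io import parse_newick
from drivefam.recombination import (SEGMENT_NAMES, assign_major_clades,
                                    fgt_matrix, four_gamete_test,
                                    p_distance_matrix, segment_genes)
from drivefam.simulate import FamilyParams, build_genome

RNG = np.random.default_rng(17)
BASES = np.array(list("ACGT"))


def rand_seq(n, rng=RNG):
    return "".join(BASES[rng.integers(0, 4, n)])


def mutate(seq, n_mut, rng):
    s = list(seq)
    for p in rng.choice(len(s), n_mut, replace=False):
        s[p] = "ACGT"[("ACGT".index(s[p]) + 1 + rng.integers(3)) % 4]
    return "".join(s)


# --- segmentation ------------------------------------------------------------

@pytest.fixture(scope="module")
def segmented():
    fam = FamilyParams(n_loci=4, locus_gene_counts=[2, 2, 2, 2], seed=31,
                       pseudogene_frac=0.0, conversion_rate=0.0,
                       five_exon_frac=0.4)
    genome, truth = build_genome(fam)
    genes = {g: (truth.gene_models[g], truth.gene_sequences[g])
             for g in truth.gene_sequences}
    upstream = {}
    for g in genes:
        iv = truth.gene_meta[g]["genome_interval"]
        upstream[g] = genome.sequence[max(0, iv.start - 289):iv.start]
    return truth, segment_genes(genes, upstream)


def test_six_exon_gene_has_eight_segments(segmented):
    truth, segs = segmented
    six = [g for g, m in truth.gene_meta.items() if m["n_exons"] == 6]
    assert six
    for g in six:
        present = [s for s in segs.names() if g in segs[s]]
        assert len(present) == 8


def test_five_exon_gene_misses_exon4_segment(segmented):
    truth, segs = segmented
    five = [g for g, m in truth.gene_meta.items() if m["n_exons"] == 5]
    assert five, "simulation should include five-exon genes at this seed"
    for g in five:
        assert g not in segs.segments.get("exon4", {})
        assert g in segs["exon5"]


def test_repeat_regions_excised_from_exon_segments(segmented):
    truth, segs = segmented
    for g, seq in truth.gene_sequences.items():
        model = truth.gene_models[g]
        e3s, e3e = model.exons[2]
        rs, re_ = model.exon3_repeat_region
        assert len(segs["exon3"][g]) == (e3e - e3s) - (re_ - rs)


def test_upstream_segment_respects_bounds(segmented):
    truth, segs = segmented
    for g, s in segs["upstream"].items():
        assert 133 <= len(s) <= 289


# --- clade assignment --------------------------------------------------------

def test_planted_partition_recovered():
    rng = np.random.default_rng(4)
    anc_a, anc_b = rand_seq(300, rng), rand_seq(300, rng)
    seqs = {}
    for i in range(3):
        seqs[f"a{i}"] = mutate(anc_a, 3, rng)   # ~1% within-group
        seqs[f"b{i}"] = mutate(anc_b, 3, rng)
    labels = assign_major_clades(seqs)
    groups = {labels[f"a{i}"] for i in range(3)}
    assert len(groups) == 1
    assert {labels[f"b{i}"] for i in range(3)} != groups
    assert labels["a0"] == "A"  # alphabetically first gene anchors label A


def test_identical_sequences_unassignable():
    seqs = {f"g{i}": "ACGT" * 50 for i in range(4)}
    assert assign_major_clades(seqs) is None


def test_supplied_tree_bipartition():
    tree = parse_newick("((a:0.1,b:0.1):2.0,(c:0.1,d:0.1):2.0);")
    labels = assign_major_clades(tree)
    assert labels == {"a": "A", "b": "A", "c": "B", "d": "B"}


def test_too_few_sequences_rejected():
    with pytest.raises(ValueError):
        assign_major_clades({"a": "ACGT", "b": "ACGT", "c": "ACGT"})


def test_p_distance_pairwise_deletion():
    d, ids = p_distance_matrix({"a": "AAAA", "b": "AA-A", "c": "TTTT"})
    ia, ib, ic = ids.index("a"), ids.index("b"), ids.index("c")
    assert d[ia, ib] == 0.0  # gap column dropped pairwise
    assert d[ia, ic] == 1.0


# --- four-gamete test --------------------------------------------------------

def test_four_gamete_examples():
    x = {"g1": "A", "g2": "A", "g3": "B", "g4": "B"}
    y = {"g1": "A", "g2": "B", "g3": "A", "g4": "B"}
    combos, pos = four_gamete_test(x, y)
    assert combos == {"AA", "AB", "BA", "BB"} and pos is True
    combos, pos = four_gamete_test(x, x)
    assert combos == {"AA", "BB"} and pos is False
    # fewer than 4 shared genes: not evaluable
    combos, pos = four_gamete_test({"g1": "A", "g2": "B"},
                                   {"g1": "A", "g2": "B"})
    assert pos is None


def test_exhaustive_agreement_with_enumeration_oracle():
    """All 2-segment label matrices over 4..6 genes agree with brute-force
    combination enumeration, and the test is symmetric."""
    for n in (4, 5, 6):
        genes = [f"g{i}" for i in range(n)]
        for xa in itertools.product("AB", repeat=n):
            for ya in itertools.product("AB", repeat=n):
                x = dict(zip(genes, xa))
                y = dict(zip(genes, ya))
                combos, pos = four_gamete_test(x, y)
                oracle = {a + b for a, b in zip(xa, ya)}
                assert combos == oracle
                assert pos == (len(oracle) == 4)
                assert four_gamete_test(y, x)[1] == pos
        if n > 4:
            break  # 4^6 pairs for n=4 is exhaustive; larger n spot-checked


def test_label_swap_invariance():
    rng = np.random.default_rng(9)
    genes = [f"g{i}" for i in range(6)]
    x = {g: "AB"[rng.integers(2)] for g in genes}
    y = {g: "AB"[rng.integers(2)] for g in genes}
    _, pos = four_gamete_test(x, y)
    swapped = {g: ("A" if v == "B" else "B") for g, v in x.items()}
    assert four_gamete_test(swapped, y)[1] == pos


# --- matrix ------------------------------------------------------------------

def test_eight_segments_give_28_pairs():
    labels = {}
    rng = np.random.default_rng(2)
    for i, seg in enumerate(SEGMENT_NAMES):
        labels[seg] = {f"g{j}": "AB"[(j + i) % 2] for j in range(6)}
    mat = fgt_matrix(labels)
    assert len(mat.positive) == 28


def test_identical_labels_no_positives():
    labels = {seg: {f"g{j}": "AB"[j % 2] for j in range(6)}
              for seg in SEGMENT_NAMES}
    mat = fgt_matrix(labels)
    assert mat.n_positive == 0 and mat.n_testable == 28


def test_single_label_flip_is_not_positive():
    """One discordant gene gives only three combinations: accumulation of
    individual changes can explain it, so the test stays negative.  Two
    opposite-direction flips produce the fourth combination."""
    base = {"g1": "A", "g2": "A", "g3": "B", "g4": "B"}
    one_flip = dict(base, g2="B")
    combos, pos = four_gamete_test(base, one_flip)
    assert combos == {"AA", "AB", "BB"} and pos is False
    two_flips = dict(base, g2="B", g3="A")
    combos, pos = four_gamete_test(base, two_flips)
    assert pos is True


@pytest.mark.parametrize("converted", ["g1", "g2", "g3", "g4"])
@pytest.mark.parametrize("seed", [0, 1])
def test_four_gene_design_conversion_always_detected(converted, seed):
    """In the 4-gene, 2-segment design, a whole-segment conversion is
    always four-gamete positive: the two-clades-of-two constraint forces
    the converted segment's split to regroup an unconverted gene, which
    supplies the fourth combination."""
    rng = np.random.default_rng(seed)
    anc_a, anc_b = rand_seq(400, rng), rand_seq(400, rng)
    seg1, seg2 = {}, {}
    for g, anc in (("g1", anc_a), ("g2", anc_a), ("g3", anc_b),
                   ("g4", anc_b)):
        seg1[g] = mutate(anc, 4, rng)
        seg2[g] = mutate(anc, 4, rng)
    # conversion copies a clade-crossing donor gene's segment verbatim,
    # which pins the recipient to its donor in the converted segment's tree
    donor = "g3" if converted in ("g1", "g2") else "g1"
    seg2[converted] = seg2[donor]
    labels = {"seg1": assign_major_clades(seg1),
              "seg2": assign_major_clades(seg2)}
    combos, pos = four_gamete_test(labels["seg1"], labels["seg2"])
    assert pos is True


def test_congruent_histories_yield_zero_positive_rate():
    """Sequence segments evolved on one tree without conversion give no
    positive tests (clade structure identical across segments)."""
    rng = np.random.default_rng(12)
    anc_a, anc_b = rand_seq(900, rng), rand_seq(900, rng)
    seqs = {}
    for i in range(3):
        seqs[f"a{i}"] = mutate(anc_a, 9, rng)
        seqs[f"b{i}"] = mutate(anc_b, 9, rng)
    # cut the same genes into 3 "segments" of 300 bp
    labels = {}
    for k in range(3):
        seg = {g: s[300 * k:300 * (k + 1)] for g, s in seqs.items()}
        labels[f"seg{k}"] = assign_major_clades(seg)
    mat = fgt_matrix(labels)
    assert mat.n_positive == 0


def test_opposite_direction_conversions_positive_with_many_genes():
    """With three genes per clade, reciprocal clade-crossing conversions
    in one segment produce all four combinations directly."""
    rng = np.random.default_rng(23)
    anc_a, anc_b = rand_seq(600, rng), rand_seq(600, rng)
    seqs = {}
    for i in range(3):
        seqs[f"a{i}"] = mutate(anc_a, 6, rng)
        seqs[f"b{i}"] = mutate(anc_b, 6, rng)
    # reciprocal nonallelic conversions of the second half
    seqs["a0"] = seqs["a0"][:300] + mutate(anc_b, 6, rng)[300:]
    seqs["b0"] = seqs["b0"][:300] + mutate(anc_a, 6, rng)[300:]
    labels = {
        "exon1": assign_major_clades(
            {g: s[:300] for g, s in seqs.items()}),
        "exon2": assign_major_clades(
            {g: s[300:] for g, s in seqs.items()}),
    }
    mat = fgt_matrix(labels)
    assert mat.positive[("exon1", "exon2")] is True
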