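"""Nei-Gojobori site/difference counting and pairwise diversity."""

import itertools

import numpy as np
import pytest
from Bio.Seq import Seq

from drivefam.diversity import (SENSE_CODONS, DiversityResult, STOPS,
                                haplotype_count, ng86_pair_diffs,
                                ng86_site_counts, nucleotide_diversity,
                                segregating_sites, translate_codon)
from drivefam.simulate import simulate_population_alignment


def bio_translate(codon):
    return str(Seq(codon).translate())


def test_site_counts_match_enumeration_for_all_sense_codons():
    """Oracle: enumerate all 9 single-base changes per codon with the
    Biopython translation table; stop-codon changes are excluded from the
    opportunity."""
    assert len(SENSE_CODONS) == 61
    for codon in SENSE_CODONS:
        syn = nonsyn = 0.0
        aa = bio_translate(codon)
        for pos, alt in itertools.product(range(3), "ACGT"):
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1:]
            if bio_translate(mut) == "*":
                continue
            if bio_translate(mut) == aa:
                syn += 1 / 3
            else:
                nonsyn += 1 / 3
        s, n = ng86_site_counts(codon)
        assert s == pytest.approx(syn)
        assert n == pytest.approx(nonsyn)
        assert s + n <= 3 + 1e-12


def test_site_count_examples():
    assert ng86_site_counts("ATG") == (0.0, 3.0)  # every change alters Met
    s, n = ng86_site_counts("TTT")
    assert s == pytest.approx(1 / 3)  # only TTT->TTC synonymous
    s, n = ng86_site_counts("GGG")
    assert s == pytest.approx(1.0)  # all third-position changes synonymous
    with pytest.raises(ValueError):
        ng86_site_counts("TAA")
    with pytest.raises(ValueError):
        ng86_site_counts("AXG")


def test_pair_diff_examples():
    assert ng86_pair_diffs("TTT", "TTC") == (1.0, 0.0)
    assert ng86_pair_diffs("TTT", "TTA") == (0.0, 1.0)
    assert ng86_pair_diffs("AAA", "AAA") == (0.0, 0.0)


def test_pair_diffs_sum_to_hamming():
    rng = np.random.default_rng(0)
    codons = [c for c in SENSE_CODONS]
    for _ in range(200):
        c1, c2 = rng.choice(codons, 2)
        sd, nd = ng86_pair_diffs(c1, c2)
        ham = sum(a != b for a, b in zip(c1, c2))
        assert sd + nd == pytest.approx(ham)


def test_pathway_averaging_by_hand():
    """TTT (Phe) vs GTA (Val): enumerate both orders of the two changes by
    hand and average."""
    # path 1: TTT -> GTT (F->V, nonsyn) -> GTA (V->V, syn)
    # path 2: TTT -> TTA (F->L, nonsyn) -> GTA (L->V, nonsyn)
    # average: syn = (1 + 0)/2, nonsyn = (1 + 2)/2
    assert ng86_pair_diffs("TTT", "GTA") == (0.5, 1.5)


def test_stop_avoiding_pathways():
    """TGT (Cys) vs TAC (Tyr): the pathway through TAT is fine but the one
    through TGC->? includes TGC (Cys, fine): both orders checked by hand.
    A case with a stop intermediate: TAT vs TGA is not valid (TGA stop
    endpoint), use ACA (Thr) vs AGG (Arg) whose pathway via AGA stays
    sense but via ACG stays sense too -- then force a stop case: TCA (Ser)
    vs TAT (Tyr) passes through TAA (stop) on one order, which must be
    excluded from the average."""
    # TCA -> TAA (stop, excluded) -> TAT  |  TCA -> TCT (syn) -> TAT (nonsyn)
    assert ng86_pair_diffs("TCA", "TAT") == (1.0, 1.0)


def brute_force_pi(aln, correction="none"):
    """Independent double loop using Biopython translation."""
    ids = sorted(aln)
    import math
    pn, ps = [], []
    for g1, g2 in itertools.combinations(ids, 2):
        Sd = Nd = S = N = 0.0
        for i in range(0, len(aln[g1]), 3):
            c1, c2 = aln[g1][i:i + 3], aln[g2][i:i + 3]
            if "-" in c1 + c2 or len(c1) < 3:
                continue
            if bio_translate(c1) == "*" or bio_translate(c2) == "*":
                continue
            s1, n1 = ng86_site_counts(c1)
            s2, n2 = ng86_site_counts(c2)
            S += (s1 + s2) / 2
            N += (n1 + n2) / 2
            sd, nd = ng86_pair_diffs(c1, c2)
            Sd += sd
            Nd += nd
        p_s = Sd / S if S else 0.0
        p_n = Nd / N if N else 0.0
        if correction == "JC":
            p_s = -0.75 * math.log(1 - 4 * p_s / 3)
            p_n = -0.75 * math.log(1 - 4 * p_n / 3)
        ps.append(p_s)
        pn.append(p_n)
    return sum(pn) / len(pn), sum(ps) / len(ps)


@pytest.mark.parametrize("correction", ["none", "JC"])
def test_pi_matches_brute_force_double_loop(correction):
    rng = np.random.default_rng(3)
    anc = "".join(rng.choice(SENSE_CODONS, 40))
    aln = {}
    for i in range(6):
        s = list(anc)
        for _ in range(6):
            p = rng.integers(len(s))
            alt = "ACGT"[rng.integers(4)]
            c0 = p - p % 3
            cand = "".join(s[c0:c0 + 3])
            cand = cand[:p - c0] + alt + cand[p - c0 + 1:]
            if cand not in STOPS:
                s[p] = alt
        aln[f"s{i}"] = "".join(s)
    got = nucleotide_diversity(aln, correction=correction)
    pn, ps = brute_force_pi(aln, correction)
    assert got.pi_n == pytest.approx(pn)
    assert got.pi_s == pytest.approx(ps)


def test_identical_sequences_zero_diversity():
    aln = {"a": "ATGGCTAAA", "b": "ATGGCTAAA"}
    r = nucleotide_diversity(aln)
    assert r.pi_n == r.pi_s == 0.0 and r.ratio is None


def test_single_synonymous_change_closed_form():
    """Two sequences differing by one synonymous change: piS equals
    1/total synonymous sites, piN = 0."""
    rng = np.random.default_rng(8)
    anc = "".join(rng.choice([c for c in SENSE_CODONS
                              if c not in ("ATG", "TGG")], 100))
    # find a codon with a synonymous third-position change
    for i in range(0, 300, 3):
        codon = anc[i:i + 3]
        for alt in "ACGT":
            mut = codon[:2] + alt
            if alt != codon[2] and mut not in STOPS and \
                    translate_codon(mut) == translate_codon(codon):
                other = anc[:i] + mut + anc[i + 3:]
                r = nucleotide_diversity({"a": anc, "b": other})
                assert r.pi_n == 0.0
                assert r.pi_s == pytest.approx(1 / r.syn_sites)
                return
    pytest.fail("no synonymous change found")


def test_haplotypes_and_segregating_sites():
    assert haplotype_count({"a": "AAA", "b": "AAA", "c": "AAA"}) == 1
    assert segregating_sites({"a": "AAA", "b": "AAA"}) == 0
    aln = {"a": "AAA", "b": "AAC", "c": "AAC"}
    assert haplotype_count(aln) == 2
    assert segregating_sites(aln) == 1
    # a column with {A, -, A} is not segregating
    aln = {"a": "ATA", "b": "A-A", "c": "ATA"}
    assert segregating_sites(aln) == 0


def test_neutral_simulation_ratio_near_one():
    aln = simulate_population_alignment(40, 300, 15, 1.0, seed=12)
    r = nucleotide_diversity(aln)
    assert r.ratio == pytest.approx(1.0, rel=0.15)


def test_validation_errors():
    with pytest.raises(ValueError):
        nucleotide_diversity({"a": "ATG"})
    with pytest.raises(ValueError):
        nucleotide_diversity({"a": "ATGC", "b": "ATGC"})
    with pytest.raises(ValueError, match="correction"):
        nucleotide_diversity({"a": "ATG", "b": "ATG"}, correction="K2P")
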