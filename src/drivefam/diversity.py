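"""Nei-Gojobori nucleotide diversity (piN/piS) on population codon alignments.

Implements the NG86 counting method: each codon position contributes
fractional synonymous/nonsynonymous *sites* according to the proportion of
possible single-base changes that preserve the amino acid (changes to stop
codons are excluded from the opportunity), and each codon pair contributes
synonymous/nonsynonymous *differences* averaged over all minimal
substitution pathways that avoid stop-codon intermediates.  Per-pair
proportions pN = Nd/N and pS = Sd/S (optionally Jukes-Cantor corrected) are
averaged over all sequence pairs to give piN and piS.  piN/piS well below 1
indicates purifying selection on the protein; values near or above 1 are
consistent with relaxed constraint or balancing selection.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOPS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")
SENSE_CODONS = sorted(c for c in GENETIC_CODE if c not in STOPS)


def translate_codon(codon: str) -> str:
    return GENETIC_CODE[codon]


def _is_valid(codon: str) -> bool:
    return len(codon) == 3 and all(b in "ACGT" for b in codon)


@lru_cache(maxsize=None)
def ng86_site_counts(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one sense codon.

    Each of the 9 possible single-base changes contributes 1/3 of a site
    to the synonymous or nonsynonymous tally; changes producing stop
    codons contribute to neither (they are excluded from the opportunity).
    """
    if not _is_valid(codon):
        raise ValueError(f"invalid codon {codon!r}")
    if codon in STOPS:
        raise ValueError(f"stop codon {codon} has no NG86 site counts")
    aa = GENETIC_CODE[codon]
    syn = nonsyn = 0.0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1:]
            if mut in STOPS:
                continue
            if GENETIC_CODE[mut] == aa:
                syn += 1 / 3
            else:
                nonsyn += 1 / 3
    return syn, nonsyn


@lru_cache(maxsize=None)
def ng86_pair_diffs(codon1: str, codon2: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous differences between two sense codons.

    Averaged with equal weight over all minimal substitution pathways whose
    intermediate codons are not stops; if every pathway passes through a
    stop (a corner case), all pathways are counted.  The two counts sum to
    the Hamming distance of the codons.
    """
    for c in (codon1, codon2):
        if not _is_valid(c) or c in STOPS:
            raise ValueError(f"invalid or stop codon {c!r}")
    diff_pos = [i for i in range(3) if codon1[i] != codon2[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order):
        syn = nonsyn = 0
        cur = codon1
        for pos in order:
            nxt = cur[:pos] + codon2[pos] + cur[pos + 1:]
            if nxt in STOPS and nxt != codon2:
                return None
            if GENETIC_CODE[cur] == GENETIC_CODE[nxt]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        return syn, nonsyn

    results = [walk(o) for o in itertools.permutations(diff_pos)]
    valid = [r for r in results if r is not None]
    if not valid:  # all pathways cross stops: count them anyway

        def walk_any(order):
            syn = nonsyn = 0
            cur = codon1
            for pos in order:
                nxt = cur[:pos] + codon2[pos] + cur[pos + 1:]
                a1 = GENETIC_CODE[cur]
                a2 = GENETIC_CODE[nxt]
                if a1 == a2:
                    syn += 1
                else:
                    nonsyn += 1
                cur = nxt
            return syn, nonsyn

        valid = [walk_any(o) for o in itertools.permutations(diff_pos)]
    syn = sum(r[0] for r in valid) / len(valid)
    nonsyn = sum(r[1] for r in valid) / len(valid)
    return syn, nonsyn


@dataclass
class DiversityResult:
    pi_n: float
    pi_s: float
    ratio: Optional[float]
    S: int
    n_haplotypes: int
    n_sequences: int
    syn_sites: float
    nonsyn_sites: float


def haplotype_count(alignment: dict[str, str]) -> int:
    """Distinct full-length sequences (gaps significant)."""
    return len(set(alignment.values()))


def segregating_sites(alignment: dict[str, str]) -> int:
    """Columns with at least two distinct non-gap states."""
    seqs = list(alignment.values())
    if not seqs:
        return 0
    S = 0
    for col in zip(*seqs):
        states = {b for b in col if b not in "-N"}
        if len(states) >= 2:
            S += 1
    return S


def _jc(p: float) -> float:
    if p >= 0.75:
        raise ValueError(f"proportion {p} too large for Jukes-Cantor")
    return -0.75 * math.log(1 - 4 * p / 3)


def nucleotide_diversity(alignment: dict[str, str],
                         correction: str = "none") -> DiversityResult:
    """piN and piS over all sequence pairs of a codon alignment.

    Codons with a gap or ambiguity in either member of a pair are dropped
    for that pair only (pairwise deletion); stop codons are likewise
    skipped.  ``correction`` is "none" (raw proportions) or "JC"
    (Jukes-Cantor).  The reported site counts are means over pairs.
    """
    if len(alignment) < 2:
        raise ValueError("need at least 2 sequences")
    if correction not in ("none", "JC"):
        raise ValueError("correction must be 'none' or 'JC'")
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) != 1:
        raise ValueError("sequences must be aligned (equal length)")
    L = lengths.pop()
    if L % 3:
        raise ValueError("alignment length not divisible by 3")
    ids = sorted(alignment)
    codons = {g: [alignment[g][i:i + 3] for i in range(0, L, 3)] for g in ids}

    pn_vals, ps_vals, n_sites, s_sites = [], [], [], []
    for g1, g2 in itertools.combinations(ids, 2):
        Sd = Nd = Ssite = Nsite = 0.0
        compared = 0
        for c1, c2 in zip(codons[g1], codons[g2]):
            if not (_is_valid(c1) and _is_valid(c2)):
                continue
            if c1 in STOPS or c2 in STOPS:
                continue
            s1, n1 = ng86_site_counts(c1)
            s2, n2 = ng86_site_counts(c2)
            Ssite += (s1 + s2) / 2
            Nsite += (n1 + n2) / 2
            sd, nd = ng86_pair_diffs(c1, c2) if c1 != c2 else (0.0, 0.0)
            Sd += sd
            Nd += nd
            compared += 1
        if compared == 0:
            raise ValueError("no comparable codons between "
                             f"{g1} and {g2}")
        ps = Sd / Ssite if Ssite else 0.0
        pn = Nd / Nsite if Nsite else 0.0
        if correction == "JC":
            ps, pn = _jc(ps), _jc(pn)
        ps_vals.append(ps)
        pn_vals.append(pn)
        s_sites.append(Ssite)
        n_sites.append(Nsite)

    pi_n = sum(pn_vals) / len(pn_vals)
    pi_s = sum(ps_vals) / len(ps_vals)
    return DiversityResult(
        pi_n=pi_n, pi_s=pi_s,
        ratio=(pi_n / pi_s) if pi_s > 0 else None,
        S=segregating_sites(alignment),
        n_haplotypes=haplotype_count(alignment),
        n_sequences=len(alignment),
        syn_sites=sum(s_sites) / len(s_sites),
        nonsyn_sites=sum(n_sites) / len(n_sites),
    )
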