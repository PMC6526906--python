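"""Segment-wise four-gamete tests for nonallelic gene conversion.

Paralog phylogenies built from different gene segments disagree when
conversion has shuffled sequence between family members.  Each gene is cut
into up to eight segments (a conserved upstream region, intron 1, and each
exon with the exon-3/exon-6 repeat regions excised); per segment, genes are
assigned to one of the two major clades of a tree (supplied, or built
internally by neighbour joining on p-distances); and every pair of segments
is subjected to a four-gamete test: observing all four clade combinations
(AA, AB, BA, BB) across genes implies recombination between the segments,
since stepwise mutation alone can produce at most three.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import dendropy
import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from .simulate import GeneModel

log = logging.getLogger("drivefam")

SEGMENT_NAMES = ["upstream", "intron1", "exon1", "exon2", "exon3", "exon4",
                 "exon5", "exon6"]

#: bounds (bp) of the conserved region taken upstream of the start codon
UPSTREAM_BOUNDS = (133, 289)


@dataclass
class SegmentSet:
    """Per-segment gene sequences: segment name -> {gene id -> sequence}."""

    segments: dict[str, dict[str, str]] = field(default_factory=dict)

    def __getitem__(self, name: str) -> dict[str, str]:
        return self.segments[name]

    def names(self) -> list[str]:
        return [s for s in SEGMENT_NAMES if s in self.segments]


def segment_genes(genes: dict[str, tuple[GeneModel, str]],
                  upstream: Optional[dict[str, str]] = None,
                  upstream_bounds: tuple[int, int] = UPSTREAM_BOUNDS
                  ) -> SegmentSet:
    """Cut genes into analysis segments.

    ``genes`` maps gene id -> (GeneModel, gene sequence); ``upstream`` maps
    gene id -> sequence immediately 5' of the gene.  Exon-3 and exon-6
    repeat regions are excised so repeat copy-number variation cannot
    masquerade as divergence.  Five-exon genes simply lack the exon-4
    segment; genes without adequate upstream sequence are excluded from the
    upstream segment with a warning.
    """
    lo, hi = upstream_bounds
    out: dict[str, dict[str, str]] = {}

    def put(seg: str, gid: str, seq: str) -> None:
        if seq:
            out.setdefault(seg, {})[gid] = seq

    for gid, (model, seq) in genes.items():
        if upstream and gid in upstream and upstream[gid] is not None:
            up = upstream[gid]
            if len(up) >= lo:
                put("upstream", gid, up[-min(len(up), hi):])
            else:
                log.warning("gene %s: upstream sequence shorter than %d bp; "
                            "excluded from upstream segment", gid, lo)
        exons = model.exons
        if len(exons) >= 2:
            put("intron1", gid, seq[exons[0][1]:exons[1][0]])
        # name exons 1..6 by homology: five-exon genes miss "exon 4"
        labels = ["exon1", "exon2", "exon3", "exon4", "exon5", "exon6"]
        if len(exons) == 5:
            labels = ["exon1", "exon2", "exon3", "exon5", "exon6"]
        for (s, e), label in zip(exons, labels):
            eseq = seq[s:e]
            region = None
            if label == "exon3":
                region = model.exon3_repeat_region
            elif label == "exon6":
                region = model.exon6_repeat_region
            if region is not None:
                rs, re_ = max(region[0], s), min(region[1], e)
                if rs < re_:
                    eseq = seq[s:rs] + seq[re_:e]
            put(label, gid, eseq)
    return SegmentSet(out)


# --- clade assignment --------------------------------------------------------

def p_distance_matrix(seqs: dict[str, str]) -> tuple[np.ndarray, list[str]]:
    """Pairwise p-distances with pairwise deletion of gapped columns."""
    ids = sorted(seqs)
    lengths = {len(seqs[g]) for g in ids}
    if len(lengths) != 1:
        raise ValueError("segment sequences must be aligned (equal length)")
    arr = np.array([list(seqs[g]) for g in ids])
    n = len(ids)
    d = np.zeros((n, n))
    gap = (arr == "-") | (arr == "N")
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            tot = int(ok.sum())
            d[i, j] = d[j, i] = \
                float((arr[i, ok] != arr[j, ok]).sum()) / tot if tot else 0.0
    return d, ids


def _bipartitions_from_skbio(tree, all_leaves: frozenset
                             ) -> list[tuple[float, frozenset]]:
    out = []
    for node in tree.non_tips(include_self=False):
        leaves = frozenset(t.name for t in node.tips())
        if node.length and 2 <= len(leaves) <= len(all_leaves) - 2:
            out.append((float(node.length), leaves))
    return out


def _bipartitions_from_dendropy(tree: dendropy.Tree, all_leaves: frozenset
                                ) -> list[tuple[float, frozenset]]:
    out = []
    for edge in tree.preorder_edge_iter():
        node = edge.head_node
        if node is tree.seed_node or node.is_leaf():
            continue
        leaves = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if edge.length and 2 <= len(leaves) <= len(all_leaves) - 2:
            out.append((float(edge.length), leaves))
    return out


def assign_major_clades(segment: Union[dict[str, str], dendropy.Tree]
                        ) -> Optional[dict[str, str]]:
    """Split genes into the two major clades of a segment tree.

    Accepts either an aligned sequence dict (an NJ tree is built from
    p-distances) or a pre-built dendropy tree.  The split is made at the
    internal edge of maximal length whose bipartition leaves at least two
    genes on each side; label A goes to the clade containing the
    alphabetically first gene.  Returns None when no such edge exists
    (e.g. identical sequences): the segment is unassignable.
    """
    if isinstance(segment, dendropy.Tree):
        all_leaves = frozenset(
            lf.taxon.label for lf in segment.leaf_node_iter())
        bips = _bipartitions_from_dendropy(segment, all_leaves)
    else:
        if len(segment) < 4:
            raise ValueError("need at least 4 sequences to split clades")
        d, ids = p_distance_matrix(segment)
        if d.max() == 0:
            return None
        tree = nj(DistanceMatrix(d, ids))
        all_leaves = frozenset(ids)
        bips = _bipartitions_from_skbio(tree, all_leaves)
    if not bips:
        return None
    # max edge length; ties broken by the lexicographically first clade
    best = max(bips, key=lambda b: (b[0], tuple(sorted(b[1]))))
    clade = best[1]
    first = min(all_leaves)
    a_side = clade if first in clade else all_leaves - clade
    return {g: ("A" if g in a_side else "B") for g in sorted(all_leaves)}


# --- four-gamete machinery ---------------------------------------------------

def four_gamete_test(labels_x: dict[str, str], labels_y: dict[str, str]
                     ) -> tuple[set[str], Optional[bool]]:
    """Four-gamete test between two segments' clade labels.

    Genes labelled in both segments contribute a combination (e.g. "AB");
    the test is positive iff all four combinations occur.  With fewer than
    4 shared genes the test is not evaluable (returns None).
    """
    shared = [g for g in labels_x
              if labels_x.get(g) in ("A", "B") and labels_y.get(g) in ("A", "B")]
    if len(shared) < 4:
        return set(), None
    combos = {labels_x[g] + labels_y[g] for g in shared}
    return combos, len(combos) == 4


@dataclass
class FGTMatrix:
    """Pairwise four-gamete results over segments."""

    segments: list[str]
    combos: dict[tuple[str, str], set[str]] = field(default_factory=dict)
    positive: dict[tuple[str, str], Optional[bool]] = field(default_factory=dict)

    @property
    def n_positive(self) -> int:
        return sum(1 for v in self.positive.values() if v)

    @property
    def n_testable(self) -> int:
        return sum(1 for v in self.positive.values() if v is not None)

    def summary(self) -> str:
        return f"{self.n_positive}/{self.n_testable} positive four-gamete tests"


def fgt_matrix(clade_labels: dict[str, dict[str, str]]) -> FGTMatrix:
    """All unordered segment-pair four-gamete tests (8 segments -> 28 pairs).

    Segments where either clade has fewer than two members are excluded
    upfront; genes unassigned in one segment are dropped pairwise.
    """
    usable = {}
    for seg, labels in clade_labels.items():
        if labels is None:
            continue
        counts = {"A": 0, "B": 0}
        for v in labels.values():
            if v in counts:
                counts[v] += 1
        if counts["A"] >= 2 and counts["B"] >= 2:
            usable[seg] = labels
    segs = [s for s in SEGMENT_NAMES if s in usable] + \
        sorted(set(usable) - set(SEGMENT_NAMES))
    if len(segs) < 2:
        raise ValueError("need at least 2 assigned segments")
    mat = FGTMatrix(segments=segs)
    for s1, s2 in itertools.combinations(segs, 2):
        combos, pos = four_gamete_test(usable[s1], usable[s2])
        mat.combos[(s1, s2)] = combos
        mat.positive[(s1, s2)] = pos
    return mat
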