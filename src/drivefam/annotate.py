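"""Homology-based annotation and classification of assembled family genes.

Each assembled gene is aligned globally against a panel of exemplar gene
models; exon boundaries are projected through the best alignment, and the
projected coding sequence is screened for inactivating changes (in-frame
stops, frameshifting indels).  Intact genes are then classified by the
poison-isoform criterion: genes with an in-frame ATG near the start of
exon 2 (and transcript evidence for an exon-1-skipping isoform, when known)
are putative drivers (Class 1); genes lacking that ATG are putative
antidote-only suppressors (Class 2); and genes too diverged from every
characterized exemplar are set apart as Class 3.  Finally, genes are named
by genomic synteny against a reference isolate.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional

from Bio import Align
from Bio.Seq import Seq

from .simulate import GeneModel

log = logging.getLogger("drivefam")

#: whole-CDS identity below which a gene matches no characterized exemplar
CLASS3_IDENTITY = 0.55
#: identity floor under which annotation refuses to call the gene family
FLOOR_IDENTITY = 0.40
#: nt window around the exon-2 start (antidote frame) for the poison ATG
POISON_WINDOW = 30


class UnclassifiableGeneError(ValueError):
    """No exemplar aligns above the identity floor."""


@dataclass
class AnnotatedGene:
    """Annotation of one assembled family gene."""

    id: str
    model: GeneModel
    cds: str
    pseudogene: bool
    pseudogene_reason: Optional[str]
    identity_to_exemplar: float
    exemplar_id: str
    locus_id: str = ""
    class_label: Optional[object] = None
    poison_atg_pos: Optional[int] = None

    @property
    def n_exons(self) -> int:
        return self.model.n_exons


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -0.5
    # free end gaps: exemplar and query may differ in flanking extent
    try:
        aligner.end_insertion_score = 0
        aligner.end_deletion_score = 0
    except AttributeError:  # older Biopython naming
        aligner.target_end_gap_score = 0
        aligner.query_end_gap_score = 0
    return aligner


def _alignment_identity(alignment, len_target: int, len_query: int) -> float:
    """Whole-sequence identity: matching columns over the shorter length.

    Normalising by sequence length (not aligned columns) keeps unrelated
    sequences near zero even under free-end-gap alignment.
    """
    c = alignment.counts()
    return c.identities / min(len_target, len_query)


def _projector(alignment):
    """Map exemplar (target) coordinates onto the query through an alignment."""
    tblocks, qblocks = alignment.aligned

    def project(pos: int) -> int:
        prev_q = 0
        for (ts, te), (qs, qe) in zip(tblocks, qblocks):
            if pos < ts:
                return prev_q  # inside a deletion: clamp to block edge
            if pos < te:
                return qs + (pos - ts)
            prev_q = qe
        return prev_q

    return project


def annotate_by_homology(gene_id: str, sequence: str,
                         exemplars: dict[str, tuple[str, GeneModel]]
                         ) -> AnnotatedGene:
    """Annotate a sequence by projection from its closest exemplar.

    ``exemplars`` maps exemplar id -> (sequence, GeneModel).  The best
    exemplar is chosen by global alignment score; exon boundaries, repeat
    regions and the antidote start are projected through the alignment.  A
    pseudogene is flagged when the projected CDS contains an internal stop
    or an exon carries a net indel that is not a multiple of 3.
    """
    if len(sequence) < 300:
        raise ValueError("sequence too short to annotate (< 300 bp)")
    if not exemplars:
        raise ValueError("no exemplar gene models supplied")
    aligner = _make_aligner()
    best = None
    for ex_id, (ex_seq, ex_model) in exemplars.items():
        aln = aligner.align(ex_seq, sequence)[0]
        score = aln.score
        if best is None or score > best[0]:
            best = (score, ex_id, ex_seq, ex_model, aln)
    _, ex_id, ex_seq, ex_model, aln = best
    identity = _alignment_identity(aln, len(ex_seq), len(sequence))
    if identity < FLOOR_IDENTITY:
        raise UnclassifiableGeneError(
            f"{gene_id}: best exemplar {ex_id} at {identity:.0%} identity "
            f"(< {FLOOR_IDENTITY:.0%} floor)")

    project = _projector(aln)
    exons = []
    pseudo = False
    reason = None
    for i, (es, ee) in enumerate(ex_model.exons):
        qs, qe = project(es), project(ee)
        if qe - qs < 10:
            # exon absent in the query; tolerated for the optional exon 4
            continue
        exons.append((qs, qe))
        if (qe - qs - (ee - es)) % 3 != 0 and not pseudo:
            pseudo, reason = True, "frameshift"

    def proj_region(region):
        if region is None:
            return None
        s, e = project(region[0]), project(region[1])
        return (s, e) if e > s else None

    model = GeneModel(
        exons=exons,
        exon3_repeat_region=proj_region(ex_model.exon3_repeat_region),
        exon6_repeat_region=proj_region(ex_model.exon6_repeat_region),
        antidote_start=project(ex_model.antidote_start),
    )
    model.validate()
    cds = model.cds(sequence)
    if not pseudo:
        prot = str(Seq(cds[:len(cds) // 3 * 3]).translate())
        if "*" in prot[:-1]:
            pseudo, reason = True, "premature_stop"
    gene = AnnotatedGene(
        id=gene_id, model=model, cds=cds, pseudogene=pseudo,
        pseudogene_reason=reason, identity_to_exemplar=identity,
        exemplar_id=ex_id)
    gene.poison_atg_pos = find_poison_atg(gene)
    return gene


def find_poison_atg(gene: AnnotatedGene, window: int = POISON_WINDOW
                    ) -> Optional[int]:
    """Codon-aligned ATG within +/-window nt of the exon-2 start (CDS coords)."""
    if len(gene.model.exons) < 2:
        return None
    e2 = gene.model.exon2_cds_start()
    cds = gene.cds
    for pos in range(0, len(cds) - 2, 3):
        if abs(pos - e2) <= window and cds[pos:pos + 3] == "ATG":
            return pos
    return None


def classify_gene(gene: AnnotatedGene,
                  has_intron1_transcript: Optional[bool] = None,
                  class3_identity: float = CLASS3_IDENTITY):
    """Assign the functional class label.

    Pseudogenes keep the label "pseudo".  Genes below ``class3_identity``
    to every characterized exemplar are Class 3 regardless of their ATG.
    Otherwise Class 1 requires the in-frame poison ATG near exon-2 start
    and transcript evidence that is true or unknown; everything else is
    Class 2 (predicted antidote-only suppressors).
    """
    if gene.pseudogene:
        gene.class_label = "pseudo"
    elif gene.identity_to_exemplar < class3_identity:
        gene.class_label = 3
    elif gene.poison_atg_pos is not None and has_intron1_transcript in (True, None):
        gene.class_label = 1
    else:
        gene.class_label = 2
    return gene.class_label


# --- synteny naming ----------------------------------------------------------

@dataclass
class SyntenyMap:
    """Ordered loci of one isolate: (locus id, gene ids in genome order)."""

    isolate: str
    loci: list[tuple[str, list[str]]] = field(default_factory=list)


def _name_number(name: str) -> Optional[int]:
    m = re.search(r"(\d+)$", name)
    return int(m.group(1)) if m else None


def name_by_synteny(query: SyntenyMap, reference: SyntenyMap,
                    similarity: dict[tuple[str, str], float]
                    ) -> dict[str, str]:
    """Name query genes after their syntenic reference genes.

    At loci matched between the maps (by locus id), the query gene most
    similar to each reference gene inherits its name; remaining query genes
    receive fresh increasing numbers in genome order, starting after the
    reference's maximum.  Ties in similarity are broken by genome order
    with a warning.
    """
    ref_by_locus = dict(reference.loci)
    ref_names = [g for _, genes in reference.loci for g in genes]
    prefix = re.sub(r"\d+$", "", ref_names[0]) if ref_names else "gene"
    numbers = [n for n in (_name_number(g) for g in ref_names) if n is not None]
    next_num = (max(numbers) + 1) if numbers else 1

    names: dict[str, str] = {}
    extras: list[str] = []
    for locus_id, qgenes in query.loci:
        rgenes = ref_by_locus.get(locus_id)
        if rgenes is None:
            log.warning("locus %s absent from reference map; new numbers "
                        "assigned", locus_id)
            extras.extend(qgenes)
            continue
        unassigned = list(qgenes)
        for rg in rgenes:
            if not unassigned:
                break
            scored = [(similarity.get((qg, rg), 0.0), qg) for qg in unassigned]
            top = max(s for s, _ in scored)
            tied = [qg for s, qg in scored if s == top]
            if len(tied) > 1:
                log.warning("similarity tie for %s among %s; genome order "
                            "breaks the tie", rg, tied)
            winner = tied[0]
            names[winner] = rg
            unassigned.remove(winner)
        extras.extend(unassigned)
    for qg in extras:
        names[qg] = f"{prefix}{next_num}"
        next_num += 1
    return names
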