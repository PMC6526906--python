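"""Synthetic genomes for a tandem poison-antidote drive gene family.

The generator emulates the structure of the real data the pipeline was built
for: a compact genome carrying ~20-24 family loci, each holding 0-3 tandem
~1.2-kb genes flanked by LTR retrotransposon remnants and embedded in long
stretches of unique sequence; nonallelic gene-conversion tracts copied
between paralogs; intragenic tandem repeats (33-bp units in exon 3, 21-bp
units in exon 6) with per-gene copy-number variation; and mate-pair
sequencing libraries of 150-bp read pairs spanning 5-8 kb inserts.  Every
planted element is recorded in a :class:`TruthSet` so that downstream
recovery can be scored exactly.

Genes are built from an explicit exon/intron part list so that coordinates
of exons, repeat regions and start codons remain exact under repeat
expansion/contraction, exon-4 loss, frameshifts and conversion events.
"""

from __future__ import annotations


from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .io import Interval, SeqRecord, revcomp, write_bed, write_fasta, write_fastq, write_gff3

BASES = np.array(list("ACGT"))

# Synthetic consensus repeat units (frame-aligned: lengths divisible by 3,
# no stop codons in frame).  The real units are degenerate; per-gene
# substitution noise supplies that degeneracy here.
EXON3_UNIT = "GCTACAGGTTCAACTGGTGCTTTCCTTGGAACA"  # 33 bp, 11 codons
EXON6_UNIT = "GGAGTTCCAACTGCTGGTTCA"  # 21 bp, 7 codons

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

#: CDS length of each exon in the six-exon base gene (bp, all divisible by 3
#: so every exon starts on a codon boundary).  Exon 3 includes a 3-unit
#: 33-bp repeat region at offset 6; exon 6 a 3-unit 21-bp region at offset 3.
_EXON_LENGTHS = {"exon1": 120, "exon2": 132, "exon3": 189, "exon4": 63,
                 "exon5": 141, "exon6": 303}
_INTRON_LEN = 50
_EXON3_REPEAT_OFFSET = 6
_EXON6_REPEAT_OFFSET = 3
_BASE_REPEAT_UNITS = 3


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, n)])


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random sense codons (no stops)."""
    out = []
    while len(out) < n_codons:
        codon = "".join(BASES[rng.integers(0, 4, 3)])
        if codon not in STOP_CODONS:
            out.append(codon)
    return "".join(out)


@dataclass
class GeneModel:
    """Exon structure of one family gene in gene-local coordinates.

    ``antidote_start`` is the position of the first ATG (the full-length
    antidote reading frame); ``poison_start`` the position of an in-frame
    ATG near the start of exon 2 when present (the poison isoform start).
    """

    exons: list[tuple[int, int]]
    exon3_repeat_region: Optional[tuple[int, int]] = None
    exon6_repeat_region: Optional[tuple[int, int]] = None
    antidote_start: int = 0
    poison_start: Optional[int] = None

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def validate(self) -> None:
        if self.n_exons not in (5, 6):
            raise ValueError(f"gene must have 5 or 6 exons, got {self.n_exons}")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if not (s1 < e1 <= s2 < e2):
                raise ValueError("exons must be ordered and non-overlapping")

    def cds(self, gene_seq: str) -> str:
        """Spliced coding sequence from the antidote start codon."""
        parts = []
        for s, e in self.exons:
            s = max(s, self.antidote_start)
            if s < e:
                parts.append(gene_seq[s:e])
        return "".join(parts)

    def genomic_to_cds(self, pos: int) -> Optional[int]:
        """Map a gene-local position into spliced CDS coordinates."""
        acc = 0
        for s, e in self.exons:
            s = max(s, self.antidote_start)
            if s <= pos < e:
                return acc + (pos - s)
            if s < e:
                acc += e - s
        return None

    def exon2_cds_start(self) -> int:
        pos = self.genomic_to_cds(self.exons[1][0])
        assert pos is not None
        return pos


@dataclass
class FamilyParams:
    """Parameters of the simulated gene family and genome."""

    n_loci: int = 24
    copy_number_weights: tuple[float, ...] = (0.1, 0.5, 0.3, 0.1)
    locus_gene_counts: Optional[Sequence[int]] = None  # explicit override
    subs_rate: float = 0.04  # per-branch substitutions/site, star phylogeny
    n_subfamilies: int = 1  # >1 plants deep clade structure above the star
    subfamily_rate: float = 0.06  # ancestor-to-subfamily substitutions/site
    conversion_rate: float = 0.5  # expected events per gene
    tract_length_dist: tuple[int, int] = (100, 2000)
    repeat_unit_exon3: str = EXON3_UNIT
    repeat_unit_exon6: str = EXON6_UNIT
    repeat_count_range_exon3: tuple[int, int] = (1, 5)
    repeat_count_range_exon6: tuple[int, int] = (1, 4)
    ltr_seq: Optional[str] = None  # generated from seed when None
    ltr_len: int = 350
    ltr_divergence: float = 0.05  # substitutions/site per planted LTR copy
    n_dispersed_ltrs: int = 10
    flank_unique_len: int = 20000
    pseudogene_frac: float = 0.15
    five_exon_frac: float = 0.25
    class1_frac: float = 0.5  # fraction of intact genes given a poison ATG
    duplicate_locus: Optional[int] = None  # index of a locus to duplicate
    duplication_pad: int = 3000  # flanking bp included in the duplication
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.copy_number_weights) - 1.0) > 1e-9:
            raise ValueError("copy_number_weights must sum to 1")
        if len(self.copy_number_weights) != 4:
            raise ValueError("copy_number_weights must cover counts 0..3")
        for r in (self.subs_rate, self.conversion_rate, self.ltr_divergence):
            if r < 0:
                raise ValueError("rates must be >= 0")
        if self.tract_length_dist[0] > self.tract_length_dist[1]:
            raise ValueError("tract length min > max")
        if self.flank_unique_len < 1000:
            raise ValueError(
                "flank_unique_len < 1 kb cannot guarantee unique flanks at "
                "this genome size"
            )
        if len(self.repeat_unit_exon3) % 3 or len(self.repeat_unit_exon6) % 3:
            raise ValueError("repeat units must be frame-preserving "
                             "(length divisible by 3)")


@dataclass
class MatePairParams:
    """Mate-pair library model: read pairs at the two ends of long fragments."""

    read_len: int = 150
    insert_min: int = 5000
    insert_max: int = 8000
    coverage: float = 80.0
    error_rate: float = 0.001  # iid per-base substitution probability

    def validate(self) -> None:
        if self.read_len >= self.insert_min:
            raise ValueError("read_len must be < insert_min")
        if not (0 <= self.error_rate < 0.1):
            raise ValueError("error_rate must be in [0, 0.1)")
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")


@dataclass
class LocusTruth:
    interval: Interval
    gene_count: int
    gene_ids: list[str]


@dataclass
class TruthSet:
    """Ground truth for one simulated genome."""

    loci: list[LocusTruth] = field(default_factory=list)
    gene_sequences: dict[str, str] = field(default_factory=dict)
    gene_models: dict[str, GeneModel] = field(default_factory=dict)
    gene_meta: dict[str, dict] = field(default_factory=dict)
    conversion_events: list[tuple[str, str, Interval]] = field(default_factory=list)
    duplications: list[Interval] = field(default_factory=list)
    read_origins: dict[str, tuple[Interval, str]] = field(default_factory=dict)
    repeat_intervals: list[Interval] = field(default_factory=list)  # planted LTR copies
    #: genome length before any segmental duplication was appended; mapping
    #: sample reads onto genome[:reference_length] emulates aligning to a
    #: reference that lacks the duplication (duplicated source shows ~2x)
    reference_length: Optional[int] = None

    def validate(self) -> None:
        for loc in self.loci:
            if not 0 <= loc.gene_count <= 3:
                raise ValueError("locus gene count outside 0..3")
        for donor, recipient, tract in self.conversion_events:
            if tract.end > len(self.gene_sequences[recipient]):
                raise ValueError("conversion tract outside recipient bounds")

    def gene_counts_by_locus(self) -> dict[str, int]:
        return {loc.interval.name: loc.gene_count for loc in self.loci}

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_bed([loc.interval for loc in self.loci], out / "truth_loci.bed")
        gff = []
        for gid, meta in self.gene_meta.items():
            gff.append((meta["genome_interval"], "gene", {
                "ID": gid,
                "locus": meta["locus_id"],
                "class": str(meta["class_label"]),
                "pseudogene": str(meta["pseudogene"]).lower(),
            }))
        write_gff3(gff, out / "truth_genes.gff3")
        with open(out / "truth_events.tsv", "w") as fh:
            fh.write("donor\trecipient\ttract_start\ttract_end\n")
            for d, r, t in self.conversion_events:
                fh.write(f"{d}\t{r}\t{t.start}\t{t.end}\n")
        if self.gene_sequences:
            write_fasta(
                [SeqRecord(gid, seq) for gid, seq in self.gene_sequences.items()],
                out / "truth_genes.fa",
            )


# --- sequence-level operations ---------------------------------------------

def apply_conversion(recipient: str, donor: str, tract) -> tuple[str, dict]:
    """Copy a gene-conversion tract from donor into recipient.

    Both sequences must be the same length (aligned coordinates); the tract
    is a half-open (start, end) pair or Interval.  Outside the tract the
    output equals the recipient; inside, the donor.
    """
    if len(recipient) != len(donor):
        raise ValueError("recipient and donor must be equal length")
    start, end = (tract.start, tract.end) if isinstance(tract, Interval) else tract
    if not (0 <= start <= end <= len(recipient)):
        raise ValueError(f"tract [{start},{end}) outside sequence bounds")
    out = recipient[:start] + donor[start:end] + recipient[end:]
    return out, {"tract": (start, end), "changed": sum(
        1 for a, b in zip(recipient[start:end], donor[start:end]) if a != b)}


def mutate_repeats(gene_seq: str, region: tuple[int, int], unit: str,
                   delta_units: int) -> str:
    """Expand (+) or contract (-) a tandem repeat region by whole units.

    Units are inserted at (or removed from) the start of the region, which
    must contain at least ``-delta_units`` whole units for a contraction.
    The region end coordinate moves by ``delta_units * len(unit)``; flanking
    sequence is untouched.
    """
    start, end = region
    if not (0 <= start <= end <= len(gene_seq)):
        raise ValueError("repeat region outside gene bounds")
    if delta_units < 0:
        avail = (end - start) // len(unit)
        if avail < -delta_units:
            raise ValueError(
                f"cannot delete {-delta_units} units: region holds {avail}")
        cut = -delta_units * len(unit)
        return gene_seq[:start] + gene_seq[start + cut:]
    return gene_seq[:start] + unit * delta_units + gene_seq[start:]


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    """iid substitutions at the given per-base rate."""
    if rate <= 0 or not seq:
        return seq
    n = rng.binomial(len(seq), rate)
    if n == 0:
        return seq
    pos = rng.choice(len(seq), size=min(n, len(seq)), replace=False)
    s = list(seq)
    for p in pos:
        alts = [b for b in "ACGT" if b != s[p]]
        s[p] = alts[rng.integers(0, 3)]
    return "".join(s)


# --- gene construction ------------------------------------------------------

_PART_ORDER_6 = ["exon1", "intron1", "exon2", "intron2", "exon3", "intron3",
                 "exon4", "intron4", "exon5", "intron5", "exon6"]


def _build_ancestor_parts(rng: np.random.Generator, params: FamilyParams
                          ) -> dict[str, str]:
    """Ancestral gene as named exon/intron parts with 3 repeat units planted."""
    parts: dict[str, str] = {}
    for name, ln in _EXON_LENGTHS.items():
        parts[name] = _random_cds(rng, ln // 3)
    for i in range(1, 6):
        parts[f"intron{i}"] = _random_seq(rng, _INTRON_LEN)
    # antidote start codon
    parts["exon1"] = "ATG" + parts["exon1"][3:]
    # plant base repeat regions (3 units each)
    u3, u6 = params.repeat_unit_exon3, params.repeat_unit_exon6
    o3, o6 = _EXON3_REPEAT_OFFSET, _EXON6_REPEAT_OFFSET
    e3 = parts["exon3"]
    parts["exon3"] = e3[:o3] + u3 * _BASE_REPEAT_UNITS + \
        e3[o3 + len(u3) * _BASE_REPEAT_UNITS:]
    e6 = parts["exon6"]
    parts["exon6"] = e6[:o6] + u6 * _BASE_REPEAT_UNITS + \
        e6[o6 + len(u6) * _BASE_REPEAT_UNITS:]
    return parts


def _assemble_parts(parts: dict[str, str], part_order: list[str],
                    repeat3: Optional[tuple[int, int]],
                    repeat6: Optional[tuple[int, int]]
                    ) -> tuple[str, GeneModel]:
    """Concatenate parts into the gene sequence and derive the GeneModel.

    ``repeat3``/``repeat6`` are repeat-region intervals local to the exon3
    and exon6 parts.
    """
    seq = ""
    exons = []
    r3 = r6 = None
    for name in part_order:
        start = len(seq)
        seq += parts[name]
        end = len(seq)
        if name.startswith("exon"):
            exons.append((start, end))
        if name == "exon3" and repeat3 is not None:
            r3 = (start + repeat3[0], start + repeat3[1])
        if name == "exon6" and repeat6 is not None:
            r6 = (start + repeat6[0], start + repeat6[1])
    model = GeneModel(exons=exons, exon3_repeat_region=r3,
                      exon6_repeat_region=r6, antidote_start=0)
    model.validate()
    return seq, model


def _scan_poison_atg(seq: str, model: GeneModel, window: int = 30
                     ) -> Optional[int]:
    """Find a codon-aligned ATG within +/-window nt of the exon-2 CDS start."""
    cds = model.cds(seq)
    e2 = model.exon2_cds_start()
    for pos in range(0, len(cds) - 2, 3):
        if abs(pos - e2) <= window and cds[pos:pos + 3] == "ATG":
            return pos
    return None


def _fix_internal_stops(parts: dict[str, str], part_order: list[str],
                        rng: np.random.Generator) -> None:
    """Resample mutated codons that introduced in-frame stops (intact genes)."""
    exon_names = [n for n in part_order if n.startswith("exon")]
    while True:
        cds = "".join(parts[n] for n in exon_names)
        bad = [i for i in range(0, len(cds) - 3, 3)
               if cds[i:i + 3] in STOP_CODONS]
        if not bad:
            return
        for pos in bad:
            # locate owning exon and rewrite the codon to a random sense codon
            acc = 0
            for name in exon_names:
                if acc <= pos < acc + len(parts[name]):
                    off = pos - acc
                    parts[name] = (parts[name][:off] +
                                   _random_cds(rng, 1) +
                                   parts[name][off + 3:])
                    break
                acc += len(parts[name])


def _enforce_class(parts: dict[str, str], part_order: list[str],
                   class_label: int, window: int = 30) -> None:
    """Plant (class 1) or scrub (class 2) the in-frame poison ATG near exon 2."""
    exon_names = [n for n in part_order if n.startswith("exon")]
    e1_len = len(parts["exon1"])
    if class_label == 1:
        parts["exon2"] = "ATG" + parts["exon2"][3:]
        return
    # class 2: remove codon-aligned ATGs within the window around exon-2 start
    cds = "".join(parts[n] for n in exon_names)
    for pos in range(0, len(cds) - 2, 3):
        if abs(pos - e1_len) <= window and cds[pos:pos + 3] == "ATG":
            acc = 0
            for name in exon_names:
                if acc <= pos < acc + len(parts[name]):
                    off = pos - acc
                    parts[name] = (parts[name][:off] + "CTG" +
                                   parts[name][off + 3:])
                    break
                acc += len(parts[name])


def _realize_gene(ancestor: dict[str, str], rng: np.random.Generator,
                  params: FamilyParams) -> tuple[str, GeneModel, dict]:
    """Derive one paralog from the ancestor: structure, repeats, divergence."""
    parts = dict(ancestor)
    five_exon = rng.random() < params.five_exon_frac
    order = [n for n in _PART_ORDER_6
             if not (five_exon and n in ("exon4", "intron4"))]

    # per-gene repeat copy numbers
    n3 = int(rng.integers(params.repeat_count_range_exon3[0],
                          params.repeat_count_range_exon3[1] + 1))
    n6 = int(rng.integers(params.repeat_count_range_exon6[0],
                          params.repeat_count_range_exon6[1] + 1))
    u3, u6 = params.repeat_unit_exon3, params.repeat_unit_exon6
    o3, o6 = _EXON3_REPEAT_OFFSET, _EXON6_REPEAT_OFFSET
    parts["exon3"] = mutate_repeats(
        parts["exon3"], (o3, o3 + len(u3) * _BASE_REPEAT_UNITS), u3,
        n3 - _BASE_REPEAT_UNITS)
    parts["exon6"] = mutate_repeats(
        parts["exon6"], (o6, o6 + len(u6) * _BASE_REPEAT_UNITS), u6,
        n6 - _BASE_REPEAT_UNITS)
    repeat3 = (o3, o3 + n3 * len(u3))
    repeat6 = (o6, o6 + n6 * len(u6))

    # star-phylogeny divergence
    for name in order:
        parts[name] = _mutate(parts[name], rng, params.subs_rate)
    parts["exon1"] = "ATG" + parts["exon1"][3:]
    _fix_internal_stops(parts, order, rng)

    pseudo = rng.random() < params.pseudogene_frac
    class_label: int | str
    if pseudo:
        class_label = "pseudo"
        reason = "premature_stop" if rng.random() < 0.5 else "frameshift"
        if reason == "premature_stop":
            parts["exon5"] = parts["exon5"][:60] + "TAA" + parts["exon5"][63:]
        else:
            parts["exon2"] = parts["exon2"][:30] + parts["exon2"][31:]
    else:
        reason = None
        class_label = 1 if rng.random() < params.class1_frac else 2
        _enforce_class(parts, order, class_label)

    seq, model = _assemble_parts(parts, order, repeat3, repeat6)
    model.poison_start = None
    if not pseudo:
        p = _scan_poison_atg(seq, model)
        model.poison_start = p
    meta = {
        "class_label": class_label,
        "pseudogene": pseudo,
        "pseudogene_reason": reason,
        "n_exons": model.n_exons,
        "exon3_units": n3,
        "exon6_units": n6,
        "has_intron1_transcript": (class_label == 1) if not pseudo else None,
    }
    return seq, model, meta


# --- genome assembly --------------------------------------------------------

def _draw_gene_counts(params: FamilyParams, rng: np.random.Generator
                      ) -> list[int]:
    if params.locus_gene_counts is not None:
        counts = list(params.locus_gene_counts)
        if len(counts) != params.n_loci:
            raise ValueError("locus_gene_counts length != n_loci")
        return counts
    return list(rng.choice(4, size=params.n_loci,
                           p=list(params.copy_number_weights)))


def build_genome(params: FamilyParams) -> tuple[SeqRecord, TruthSet]:
    """Simulate a genome carrying the gene family, with full ground truth.

    Layout per locus: LTR [gene LTR] * gene_count, embedded between unique
    flanks of ``flank_unique_len``; dispersed LTR copies are inserted into
    flanks.  Every planted LTR copy is independently diverged from the LTR
    consensus at ``ltr_divergence``.  Deterministic given ``params.seed``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    chrom = "sim_1"
    truth = TruthSet()

    ltr = params.ltr_seq or _random_seq(rng, params.ltr_len)
    root = _build_ancestor_parts(rng, params)
    ancestors = [root]
    if params.n_subfamilies > 1:
        ancestors = []
        for _ in range(params.n_subfamilies):
            sub = dict(root)
            for name in _PART_ORDER_6:
                sub[name] = _mutate(sub[name], rng, params.subfamily_rate)
            sub["exon1"] = "ATG" + sub["exon1"][3:]
            _fix_internal_stops(sub, _PART_ORDER_6, rng)
            ancestors.append(sub)
    counts = _draw_gene_counts(params, rng)

    # realize genes and apply nonallelic conversion before genome placement
    genes: list[tuple[str, int]] = []  # (gene id, locus index)
    seqs: dict[str, str] = {}
    models: dict[str, GeneModel] = {}
    metas: dict[str, dict] = {}
    gnum = 0
    for li, cnt in enumerate(counts):
        for _ in range(cnt):
            gnum += 1
            gid = f"g{gnum:02d}"
            sub = int(rng.integers(len(ancestors)))
            seq, model, meta = _realize_gene(ancestors[sub], rng, params)
            meta["locus_id"] = f"L{li:02d}"
            meta["subfamily"] = sub
            seqs[gid], models[gid], metas[gid] = seq, model, meta
            genes.append((gid, li))

    _apply_family_conversion(seqs, models, metas, params, rng, truth)

    # dispersed LTR placement: which inter-locus flanks carry one
    n_flanks = params.n_loci + 1
    disp_flanks = set(
        rng.choice(n_flanks, size=min(params.n_dispersed_ltrs, n_flanks),
                   replace=False)) if params.n_dispersed_ltrs else set()

    def flank_seq(idx: int) -> tuple[str, Optional[tuple[int, int]]]:
        s = _random_seq(rng, params.flank_unique_len)
        if idx in disp_flanks:
            off = int(rng.integers(len(s) // 4, 3 * len(s) // 4))
            copy_ = _mutate(ltr, rng, params.ltr_divergence)
            return s[:off] + copy_ + s[off:], (off, off + len(copy_))
        return s, None

    pieces: list[str] = []
    pos = 0

    def emit(s: str) -> int:
        nonlocal pos
        pieces.append(s)
        start = pos
        pos += len(s)
        return start

    def emit_ltr() -> None:
        copy_ = _mutate(ltr, rng, params.ltr_divergence)
        start = emit(copy_)
        truth.repeat_intervals.append(
            Interval(chrom, start, start + len(copy_), "LTR"))

    def emit_flank(idx: int) -> None:
        s, local = flank_seq(idx)
        start = emit(s)
        if local is not None:
            truth.repeat_intervals.append(
                Interval(chrom, start + local[0], start + local[1], "LTR"))

    emit_flank(0)
    gene_iter = iter(genes)
    placed: dict[str, Interval] = {}
    for li, cnt in enumerate(counts):
        locus_start = pos
        emit_ltr()
        gids = []
        for _ in range(cnt):
            gid, _li = next(gene_iter)
            gstart = emit(seqs[gid])
            placed[gid] = Interval(chrom, gstart, gstart + len(seqs[gid]), gid, "+")
            emit_ltr()
            gids.append(gid)
        truth.loci.append(LocusTruth(
            Interval(chrom, locus_start, pos, f"L{li:02d}"), cnt, gids))
        emit_flank(li + 1)

    genome = "".join(pieces)

    if params.duplicate_locus is not None:
        truth.reference_length = len(genome)
        loc = truth.loci[params.duplicate_locus].interval
        s = max(0, loc.start - params.duplication_pad)
        e = min(len(genome), loc.end + params.duplication_pad)
        truth.duplications.append(Interval(chrom, s, e, "dup0"))
        # pad beyond the insert size so the duplicate copy is fully interior
        # to the fragment-sampling process (coverage halves near genome ends)
        genome = genome + _random_seq(rng, 2000) + genome[s:e] \
            + _random_seq(rng, 10000)

    truth.gene_sequences = seqs
    truth.gene_models = models
    for gid, meta in metas.items():
        meta["genome_interval"] = placed[gid]
        truth.gene_meta[gid] = meta
    truth.validate()
    return SeqRecord(chrom, genome, description="simulated family genome"), truth


def _apply_family_conversion(seqs: dict[str, str], models: dict[str, GeneModel],
                             metas: dict[str, dict], params: FamilyParams,
                             rng: np.random.Generator, truth: TruthSet) -> None:
    """Plant nonallelic gene-conversion events between equal-length paralogs.

    Class and pseudogene truth labels are re-derived from the converted
    sequences, since a tract can move a poison ATG or a stop codon.
    """
    if not seqs or params.conversion_rate <= 0:
        return
    by_len: dict[int, list[str]] = {}
    for gid, s in seqs.items():
        by_len.setdefault(len(s), []).append(gid)
    eligible = [g for grp in by_len.values() if len(grp) >= 2 for g in grp]
    if not eligible:
        return
    n_events = rng.poisson(params.conversion_rate * len(seqs))
    lo, hi = params.tract_length_dist
    for _ in range(n_events):
        recipient = eligible[rng.integers(len(eligible))]
        group = [g for g in by_len[len(seqs[recipient])] if g != recipient]
        donor = group[rng.integers(len(group))]
        glen = len(seqs[recipient])
        tlen = min(int(rng.integers(lo, hi + 1)), glen)
        tstart = int(rng.integers(0, glen - tlen + 1))
        tract = Interval(recipient, tstart, tstart + tlen, "conv")
        seqs[recipient], _ = apply_conversion(seqs[recipient], seqs[donor],
                                              (tstart, tstart + tlen))
        truth.conversion_events.append((donor, recipient, tract))
        _rederive_meta(recipient, seqs, models, metas)


def _rederive_meta(gid: str, seqs: dict[str, str], models: dict[str, GeneModel],
                   metas: dict[str, dict]) -> None:
    model, seq, meta = models[gid], seqs[gid], metas[gid]
    if meta["pseudogene"] and meta["pseudogene_reason"] == "frameshift":
        return  # frameshift coordinates are ambiguous; keep label
    cds = model.cds(seq)
    stops = [i for i in range(0, len(cds) - 3, 3) if cds[i:i + 3] in STOP_CODONS]
    if stops:
        meta.update(pseudogene=True, pseudogene_reason="premature_stop",
                    class_label="pseudo", has_intron1_transcript=None)
        return
    # a conversion tract can also repair a planted premature stop
    meta.update(pseudogene=False, pseudogene_reason=None)
    p = _scan_poison_atg(seq, model)
    model.poison_start = p
    meta["class_label"] = 1 if p is not None else 2
    meta["has_intron1_transcript"] = meta["class_label"] == 1


# --- mate-pair simulation ---------------------------------------------------

def simulate_mate_pairs(genome: SeqRecord | str, params: MatePairParams,
                        seed: int) -> tuple[list[SeqRecord], list[SeqRecord],
                                            dict[str, tuple[Interval, str]]]:
    """Simulate a mate-pair library from a genome.

    Fragments of uniform length in [insert_min, insert_max] are drawn with
    uniform start and strand; the two reads are the fragment's terminal
    ``read_len`` bases, both reported on the fragment's forward strand (the
    true genomic strand is recorded in read_origins, and downstream matching
    is orientation-agnostic).  The number of pairs is Poisson with mean
    coverage * genome_len / (2 * read_len).  Substitution errors are iid.
    """
    params.validate()
    if isinstance(genome, SeqRecord):
        chrom, seq = genome.id, genome.sequence
    else:
        chrom, seq = "genome", genome
    G = len(seq)
    if G <= params.insert_max:
        raise ValueError("genome shorter than insert_max")
    rng = np.random.default_rng(seed)
    L = params.read_len
    n = rng.poisson(params.coverage * G / (2 * L))
    frag_len = rng.integers(params.insert_min, params.insert_max + 1, size=n)
    starts = (rng.random(n) * (G - frag_len + 1)).astype(np.int64)
    strands = rng.random(n) < 0.5  # True => minus strand fragment
    n_err = rng.binomial(L, params.error_rate, size=(n, 2)) \
        if params.error_rate > 0 else np.zeros((n, 2), np.int64)

    r1_list: list[SeqRecord] = []
    r2_list: list[SeqRecord] = []
    origins: dict[str, tuple[Interval, str]] = {}

    def add_errors(read: str, k: int, rng: np.random.Generator) -> str:
        if k == 0:
            return read
        pos = rng.choice(L, size=k, replace=False)
        s = list(read)
        for p in pos:
            alts = [b for b in "ACGT" if b != s[p]]
            s[p] = alts[rng.integers(0, 3)]
        return "".join(s)

    for i in range(n):
        s, F = int(starts[i]), int(frag_len[i])
        left = seq[s:s + L]
        right = seq[s + F - L:s + F]
        if strands[i]:
            r1, r2 = revcomp(right), revcomp(left)
            o1 = (Interval(chrom, s + F - L, s + F), "-")
            o2 = (Interval(chrom, s, s + L), "-")
        else:
            r1, r2 = left, right
            o1 = (Interval(chrom, s, s + L), "+")
            o2 = (Interval(chrom, s + F - L, s + F), "+")
        rid = f"frag{i:07d}"
        r1 = add_errors(r1, int(n_err[i, 0]), rng)
        r2 = add_errors(r2, int(n_err[i, 1]), rng)
        r1_list.append(SeqRecord(f"{rid}/1", r1))
        r2_list.append(SeqRecord(f"{rid}/2", r2))
        origins[f"{rid}/1"] = o1
        origins[f"{rid}/2"] = o2
    return r1_list, r2_list, origins


def write_simulation(out_dir: str | Path, genome: SeqRecord, truth: TruthSet,
                     r1: list[SeqRecord], r2: list[SeqRecord]) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta([genome], out / "genome.fa")
    write_fastq(r1, out / "reads_R1.fastq")
    write_fastq(r2, out / "reads_R2.fastq")
    truth.write(out)


# --- population alignments for diversity analyses ---------------------------

def simulate_population_alignment(n_seqs: int, n_codons: int,
                                  mutations_per_seq: float,
                                  nonsyn_syn_ratio: float,
                                  seed: int) -> dict[str, str]:
    """Simulate a population codon alignment with a planted piN/piS ratio.

    Starting from a random ancestral coding sequence, each sampled sequence
    receives Poisson-many single-base changes proposed uniformly over all
    non-stop-creating substitutions; synonymous proposals are always
    accepted and nonsynonymous ones with probability ``nonsyn_syn_ratio``
    (<=1).  Because Nei-Gojobori site counts normalise by the same mutational
    opportunity, the expected piN/piS of the sample equals the planted ratio.
    """
    from .diversity import translate_codon  # local import to avoid a cycle

    if not 0 < nonsyn_syn_ratio <= 1:
        raise ValueError("nonsyn_syn_ratio must be in (0, 1]")
    rng = np.random.default_rng(seed)
    anc = _random_cds(rng, n_codons)
    out = {}
    for i in range(n_seqs):
        s = list(anc)
        n_mut = rng.poisson(mutations_per_seq)
        applied = 0
        while applied < n_mut:
            p = int(rng.integers(len(s)))
            old = s[p]
            new = "ACGT"[rng.integers(4)]
            if new == old:
                continue
            c0 = p - p % 3
            codon = "".join(s[c0:c0 + 3])
            mutant = codon[:p - c0] + new + codon[p - c0 + 1:]
            if mutant in STOP_CODONS:
                continue
            syn = translate_codon(mutant) == translate_codon(codon)
            if syn or rng.random() < nonsyn_syn_ratio:
                s[p] = new
                applied += 1
        out[f"iso{i:03d}"] = "".join(s)
    return out
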