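"""End-to-end orchestration: simulate -> discover -> assemble -> annotate ->
analyze, with a reproducibility manifest and truth-based scoring.

Each stage reads and writes plain files under the run directory so any
stage can be rerun in isolation; the manifest records the config hash,
seed, per-stage output checksums and timings.  Deterministic stages
reproduce identical checksums for identical config+seed.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .annotate import annotate_by_homology, classify_gene
from .assembly import (assemble_greedy, define_regions, recruit_and_filter,
                       stitch_contigs)
from .discovery import (CopyNumberCalibration, ReferenceIndex, call_loci,
                        call_pileups, map_partner_reads,
                        match_reads_to_family)
from .io import Interval, SeqRecord, load_config, read_fastq_pairs, write_bed
from .recombination import assign_major_clades, fgt_matrix, segment_genes
from .simulate import (FamilyParams, MatePairParams, TruthSet, build_genome,
                       simulate_mate_pairs, write_simulation)

DEFAULT_STAGES = ["simulate", "discover", "assemble", "annotate",
                  "recombination", "score"]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str = __version__
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, outputs: dict[str, str], elapsed: float
               ) -> None:
        self.stages[stage] = {"outputs": outputs,
                              "elapsed_s": round(elapsed, 3)}

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump({"config_hash": self.config_hash, "seed": self.seed,
                       "version": self.version, "stages": self.stages},
                      fh, indent=2)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _checksums(out_dir: Path, names: list[str]) -> dict[str, str]:
    return {n: _sha256(out_dir / n) for n in names if (out_dir / n).exists()}


def run_pipeline(config: dict | str | Path,
                 out_dir: Optional[str | Path] = None
                 ) -> tuple[RunManifest, dict]:
    """Run the configured stages in dependency order.

    Returns the manifest and an in-memory dict of stage products (genome,
    truth, locus calls, assemblies, annotations, FGT matrix, score report).
    A stage failure raises StageError naming the stage; later stages are
    not run.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    cfg_bytes = json.dumps(config, sort_keys=True, default=str).encode()
    seed = int(config.get("seed", 0))
    out = Path(out_dir or config.get("out_dir", "drivefam_run"))
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(hashlib.sha256(cfg_bytes).hexdigest(), seed)
    stages = config.get("stages", DEFAULT_STAGES)
    products: dict = {}

    for stage in stages:
        t0 = time.time()
        try:
            files = _STAGE_FUNCS[stage](config, seed, out, products)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(stage, exc) from exc
        manifest.record(stage, _checksums(out, files), time.time() - t0)
    manifest.write(out / "manifest.json")
    return manifest, products


# --- stages ------------------------------------------------------------------

def _stage_simulate(config, seed, out, products) -> list[str]:
    fam = FamilyParams(**config.get("family", {}), seed=seed)
    mp = MatePairParams(**config.get("mate_pairs", {}))
    genome, truth = build_genome(fam)
    r1, r2, origins = simulate_mate_pairs(genome, mp, seed + 1)
    truth.read_origins = origins
    write_simulation(out, genome, truth, r1, r2)
    products.update(genome=genome, truth=truth, pairs=list(zip(r1, r2)),
                    family_params=fam, mate_pair_params=mp)
    return ["genome.fa", "reads_R1.fastq", "reads_R2.fastq",
            "truth_loci.bed", "truth_genes.gff3", "truth_events.tsv"]


def _stage_discover(config, seed, out, products) -> list[str]:
    from .io import read_fasta

    dcfg = config.get("discovery", {})
    if "pairs" not in products:
        r1p, r2p = dcfg["reads"]
        products["pairs"] = read_fastq_pairs(r1p, r2p)
    if "genome" not in products and "genome" in dcfg:
        products["genome"] = read_fasta(dcfg["genome"])[0]
    if "panel" not in products and "panel" in dcfg:
        products["panel"] = read_fasta(dcfg["panel"])
    products.setdefault("mate_pair_params", MatePairParams(
        **config.get("mate_pairs", {})))
    products.setdefault("family_params", FamilyParams(
        **config.get("family", {})))
    pairs = products["pairs"]
    truth: Optional[TruthSet] = products.get("truth")
    genome: SeqRecord = products["genome"]
    mp: MatePairParams = products["mate_pair_params"]
    fam: FamilyParams = products["family_params"]

    panel = [SeqRecord(gid, s) for gid, s in truth.gene_sequences.items()] \
        if truth else [SeqRecord(r.id, r.sequence)
                       for r in products["panel"]]
    classes = match_reads_to_family(pairs, panel,
                                    k=dcfg.get("k", 15),
                                    min_kmer_frac=dcfg.get("min_kmer_frac",
                                                           0.05))
    partners = [r for c in classes for r in c.partner_reads]
    ref_index = ReferenceIndex(genome)
    products["ref_index"] = ref_index
    track, placements = map_partner_reads(partners, ref_index)

    covered = track.cov[genome.id]
    nonzero = covered[covered > 0]
    min_depth = max(3, int(0.1 * np.median(nonzero))) if nonzero.size else 3
    pileups = call_pileups(track, min_depth=min_depth,
                           merge_gap=dcfg.get("merge_gap", 200))
    calib = CopyNumberCalibration.from_mate_pair_params(
        mp.insert_min, mp.insert_max, mp.read_len,
        spacer_len=fam.ltr_len)
    calls = call_loci(pileups,
                      max_pair_span=dcfg.get("max_pair_span",
                                             2 * mp.insert_max),
                      calibration=calib)
    products.update(pileups=pileups, locus_calls=calls, calibration=calib,
                    partner_track=track)
    write_bed(
        [Interval(c.interval.chrom, c.interval.start, c.interval.end,
                  f"cn={c.copy_number};{'|'.join(sorted(c.flags))}")
         for c in calls], out / "loci.bed")
    return ["loci.bed"]


def _stage_assemble(config, seed, out, products) -> list[str]:
    acfg = config.get("assembly", {})
    calls = [c for c in products["locus_calls"]
             if (c.copy_number or 0) >= 1 and "single_flank" not in c.flags]
    n_loci = acfg.get("n_loci", 1)
    genome: SeqRecord = products["genome"]
    assemblies = {}
    truth: Optional[TruthSet] = products.get("truth")
    repeat_mask = list(truth.repeat_intervals) if truth \
        else list(products.get("repeat_mask", ()))
    all_calls = products["locus_calls"]
    for call in calls[:n_loci]:
        # mask annotated repeats plus every *other* called locus: a family
        # gene inside green would subtract this locus's own gene reads
        mask = repeat_mask + [c.interval for c in all_calls
                              if c.interval != call.interval]
        regions = define_regions(call, repeat_mask=mask,
                                 chrom_length=len(genome.sequence))
        reads = recruit_and_filter(products["pairs"], regions, genome,
                                   max_reads=acfg.get("max_reads", 2600),
                                   seed=seed + 7)
        contigs = assemble_greedy(reads)
        left = genome.sequence[max(0, call.interval.start - 600):
                               call.interval.start]
        right = genome.sequence[call.interval.end:call.interval.end + 600]
        locus_seq, report = stitch_contigs(
            contigs, left, right,
            expected_span=len(call.interval) + 1200)
        assemblies[call.interval.name] = {
            "sequence": locus_seq, "contigs": contigs, "report": report,
            "call": call}
        with open(out / f"locus_{call.interval.name}.fa", "w") as fh:
            fh.write(f">{call.interval.name}\n{locus_seq}\n")
    products["assemblies"] = assemblies
    return [f"locus_{k}.fa" for k in assemblies]


def _stage_annotate(config, seed, out, products) -> list[str]:
    """Annotate the simulated family against itself as the exemplar panel."""
    truth: TruthSet = products["truth"]
    exemplars = {gid: (truth.gene_sequences[gid], truth.gene_models[gid])
                 for gid in truth.gene_sequences}
    annotations = {}
    for gid, seq in truth.gene_sequences.items():
        gene = annotate_by_homology(gid, seq, exemplars)
        gene.locus_id = truth.gene_meta[gid]["locus_id"]
        classify_gene(gene, truth.gene_meta[gid]["has_intron1_transcript"])
        annotations[gid] = gene
    products["annotations"] = annotations
    with open(out / "annotations.tsv", "w") as fh:
        fh.write("gene\tlocus\tn_exons\tclass\tpseudogene\treason\n")
        for gid, g in sorted(annotations.items()):
            fh.write(f"{gid}\t{g.locus_id}\t{g.n_exons}\t{g.class_label}\t"
                     f"{g.pseudogene}\t{g.pseudogene_reason or '.'}\n")
    return ["annotations.tsv"]


def _stage_recombination(config, seed, out, products) -> list[str]:
    truth: TruthSet = products["truth"]
    genome: SeqRecord = products["genome"]
    intact = {gid: (truth.gene_models[gid], truth.gene_sequences[gid])
              for gid, meta in truth.gene_meta.items()
              if not meta["pseudogene"]}
    upstream = {}
    for gid in intact:
        iv = truth.gene_meta[gid]["genome_interval"]
        upstream[gid] = genome.sequence[max(0, iv.start - 289):iv.start]
    segs = segment_genes(intact, upstream)
    labels = {}
    for name in segs.names():
        seqs = segs[name]
        by_len: dict[int, dict[str, str]] = {}
        for gid, s in seqs.items():
            by_len.setdefault(len(s), {})[gid] = s
        major = max(by_len.values(), key=len)
        if len(major) >= 4:
            labels[name] = assign_major_clades(major)
    usable = {k: v for k, v in labels.items() if v is not None}
    mat = fgt_matrix(usable) if len(usable) >= 2 else None
    products["fgt"] = mat
    with open(out / "fgt_summary.txt", "w") as fh:
        fh.write((mat.summary() if mat else "not evaluable") + "\n")
    return ["fgt_summary.txt"]


def _stage_score(config, seed, out, products) -> list[str]:
    report = score_against_truth(products)
    products["score"] = report
    with open(out / "score.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    return ["score.json"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "discover": _stage_discover,
    "assemble": _stage_assemble,
    "annotate": _stage_annotate,
    "recombination": _stage_recombination,
    "score": _stage_score,
}


# --- truth-based scoring -----------------------------------------------------

def score_copy_numbers(truth: TruthSet, calls) -> dict:
    """Per-locus copy-number recovery: a truth locus with no overlapping
    call is scored as called 0 (an absent locus produces no pileups)."""
    per_locus = []
    used = set()
    for loc in truth.loci:
        called = 0
        for i, c in enumerate(calls):
            if c.interval.overlaps(loc.interval) and c.copy_number is not None:
                called = c.copy_number
                used.add(i)
                break
        per_locus.append({"locus": loc.interval.name, "true": loc.gene_count,
                          "called": called,
                          "correct": called == loc.gene_count})
    n_correct = sum(p["correct"] for p in per_locus)
    false_pos = [c.interval.name for i, c in enumerate(calls)
                 if i not in used and (c.copy_number or 0) > 0]
    adjacent = all(abs(p["true"] - p["called"]) <= 1 for p in per_locus)
    return {"per_locus": per_locus,
            "n_loci": len(per_locus),
            "n_correct": n_correct,
            "accuracy": n_correct / len(per_locus) if per_locus else 1.0,
            "errors_adjacent_only": adjacent,
            "false_positive_calls": false_pos}


def score_assemblies(truth: TruthSet, genome: SeqRecord, assemblies) -> dict:
    out = {}
    for name, asm in assemblies.items():
        call = asm["call"]
        target = genome.sequence[max(0, call.interval.start - 1200):
                                 call.interval.end + 1200]
        out[name] = {
            "identity_pct": _infix_identity(asm["sequence"], target),
            "length": len(asm["sequence"]),
            "n_contigs": len(asm["contigs"])}
    return out


def _infix_identity(query: str, target: str) -> float:
    import edlib

    if not query:
        return 0.0
    res = edlib.align(query, target, mode="HW", task="distance")
    return 100.0 * (1 - res["editDistance"] / len(query))


def score_against_truth(products: dict) -> dict:
    """Aggregate recovery report for a pipeline run."""
    truth: TruthSet = products["truth"]
    report: dict = {}
    if "locus_calls" in products:
        report["copy_number"] = score_copy_numbers(truth,
                                                   products["locus_calls"])
    if products.get("assemblies"):
        report["assembly"] = score_assemblies(truth, products["genome"],
                                              products["assemblies"])
    if products.get("annotations"):
        ann = products["annotations"]
        agree = sum(
            1 for gid, g in ann.items()
            if g.class_label == truth.gene_meta[gid]["class_label"])
        report["annotation"] = {"n_genes": len(ann),
                                "class_agreement": agree / len(ann)}
    if products.get("fgt") is not None:
        mat = products["fgt"]
        report["four_gamete"] = {"positive": mat.n_positive,
                                 "testable": mat.n_testable,
                                 "conversion_events_planted":
                                     len(truth.conversion_events)}
    return report
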