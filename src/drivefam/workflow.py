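"""In-memory convenience drivers chaining the pipeline's core steps.

These run the same computations as the file-based pipeline stages but
return intermediate products directly; the analysis scripts, tests and the
acceptance harness all drive the package through them.
"""

from __future__ import annotations

import numpy as np

from .assembly import (assemble_greedy, define_regions, recruit_and_filter,
                       stitch_contigs)
from .discovery import (CopyNumberCalibration, ReferenceIndex, call_loci,
                        call_pileups, map_partner_reads,
                        match_reads_to_family)
from .io import SeqRecord
from .simulate import FamilyParams, MatePairParams, build_genome, \
    simulate_mate_pairs


def discovery_chain(fam: FamilyParams, mp: MatePairParams, read_seed: int
                    ) -> dict:
    """simulate -> classify pairs -> map partners -> pileups -> locus calls.

    Returns every intermediate product keyed by name (genome, truth, pairs,
    origins, classes, partners, index, track, placements, pileups, calls,
    calib, fam, mp).
    """
    genome, truth = build_genome(fam)
    r1, r2, origins = simulate_mate_pairs(genome, mp, read_seed)
    pairs = list(zip(r1, r2))
    panel = [SeqRecord(g, s) for g, s in truth.gene_sequences.items()]
    classes = match_reads_to_family(pairs, panel)
    partners = [r for c in classes for r in c.partner_reads]
    index = ReferenceIndex(genome)
    track, placements = map_partner_reads(partners, index)
    cov = track.cov[genome.id]
    nz = cov[cov > 0]
    min_depth = max(3, int(0.1 * np.median(nz))) if nz.size else 3
    pileups = call_pileups(track, min_depth=min_depth)
    calib = CopyNumberCalibration.from_mate_pair_params(
        mp.insert_min, mp.insert_max, mp.read_len, spacer_len=fam.ltr_len)
    calls = call_loci(pileups, max_pair_span=2 * mp.insert_max,
                      calibration=calib)
    return dict(genome=genome, truth=truth, pairs=pairs, origins=origins,
                classes=classes, partners=partners, index=index, track=track,
                placements=placements, pileups=pileups, calls=calls,
                calib=calib, fam=fam, mp=mp)


def assemble_one_locus(error_rate: float, seed: int = 5,
                       max_reads: int = 2600) -> dict:
    """Simulate a single two-gene locus and run the targeted assembly."""
    fam = FamilyParams(n_loci=1, locus_gene_counts=[2], seed=seed)
    prod = discovery_chain(fam, MatePairParams(coverage=80,
                                               error_rate=error_rate),
                           seed + 1)
    call = prod["calls"][0]
    genome = prod["genome"]
    regions = define_regions(call, repeat_mask=prod["truth"].repeat_intervals,
                             chrom_length=len(genome.sequence))
    reads = recruit_and_filter(prod["pairs"], regions, genome,
                               max_reads=max_reads, seed=0)
    contigs = assemble_greedy(reads)
    left = genome.sequence[call.interval.start - 600:call.interval.start]
    right = genome.sequence[call.interval.end:call.interval.end + 600]
    locus_seq, report = stitch_contigs(
        contigs, left, right, expected_span=len(call.interval) + 1200)
    prod.update(call=call, regions=regions, candidate_reads=reads,
                contigs=contigs, locus_seq=locus_seq, stitch_report=report)
    return prod
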