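#!/usr/bin/env python
"""Targeted bait-and-assemble reconstruction of one two-gene locus.

Defines orange (bait) and green (subtraction) regions from the locus
call, recruits candidate reads, assembles them with the greedy OLC
assembler, stitches contigs between the flanks, and measures identity to
the planted truth at 0% and 0.2% sequencing error.
"""

from pathlib import Path

import edlib
import pandas as pd

from drivefam.workflow import assemble_one_locus

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    rows = []
    for err in (0.0, 0.002):
        run = assemble_one_locus(err, seed=5)
        call, genome = run["call"], run["genome"]
        target = genome.sequence[call.interval.start - 1200:
                                 call.interval.end + 1200]
        res = edlib.align(run["locus_seq"], target, mode="HW",
                          task="distance")
        ident = 100 * (1 - res["editDistance"] / len(run["locus_seq"]))
        rows.append({
            "error_rate": err,
            "candidate_reads": len(run["candidate_reads"]),
            "n_contigs": len(run["contigs"]),
            "contigs_used": run["stitch_report"]["contigs_used"],
            "n_gap": run["stitch_report"]["n_gap"],
            "stitched_bp": len(run["locus_seq"]),
            "identity_pct": round(ident, 3),
        })
        print(f"error {err:.1%}: {len(run['candidate_reads'])} candidates "
              f"-> {len(run['contigs'])} contigs -> "
              f"{len(run['locus_seq'])} bp locus at {ident:.3f}% identity")
    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(RESULTS / "assembly_report.tsv", sep="\t",
                              index=False)


if __name__ == "__main__":
    main()
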