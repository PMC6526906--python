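#!/usr/bin/env python
"""Simulate the study-scale genome and call family-locus copy numbers.

Builds a 24-locus genome covering tandem gene counts 0-3, sequences it to
80x with 5-8 kb mate pairs, classifies read pairs against the gene panel,
maps the partner reads, and reads copy number off the widest flanking
pileup.  Writes the per-locus call table and prints recovery against the
planted truth.
"""

from pathlib import Path

import pandas as pd

from drivefam.pipeline import score_copy_numbers
from drivefam.simulate import FamilyParams, MatePairParams
from drivefam.workflow import discovery_chain

RESULTS = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    fam = FamilyParams(n_loci=24, locus_gene_counts=[0, 1, 2, 3] * 6,
                       seed=SEED)
    run = discovery_chain(fam, MatePairParams(coverage=80), SEED + 1)
    rep = score_copy_numbers(run["truth"], run["calls"])

    rows = []
    for c in run["calls"]:
        rows.append({
            "locus": c.interval.name,
            "start": c.interval.start, "end": c.interval.end,
            "left_width": c.left_pileup.width if c.left_pileup else 0,
            "right_width": c.right_pileup.width if c.right_pileup else 0,
            "widest_width": c.widest_width,
            "copy_number": c.copy_number,
            "flags": "|".join(sorted(c.flags)),
        })
    RESULTS.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(RESULTS / "locus_calls.tsv", sep="\t",
                              index=False)
    pd.DataFrame(rep["per_locus"]).to_csv(
        RESULTS / "copy_number_recovery.tsv", sep="\t", index=False)

    print(f"genome: {len(run['genome'].sequence):,} bp, "
          f"{len(run['pairs']):,} read pairs, "
          f"{len(run['partners']):,} partner reads mapped")
    print(f"loci called: {len(run['calls'])}; copy-number accuracy "
          f"{rep['n_correct']}/{rep['n_loci']} = {rep['accuracy']:.1%}")
    print(f"false-positive calls: {rep['false_positive_calls'] or 'none'}")


if __name__ == "__main__":
    main()
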