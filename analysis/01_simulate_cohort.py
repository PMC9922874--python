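#!/usr/bin/env python
"""Generate the study-like synthetic cohort.

Five genotypes (control + four DGC loss-of-function mutants) x three
conditions (unstressed, temperature stress, metabolic stress) x 4
replicates, 5,000 genes with planted stress-response classes. Writes
counts, design, annotation and the planted truth under results/sim/.
"""

import argparse
from pathlib import Path

from dgcstress import counts_io
from dgcstress.synthetic_data import (SimConfig, simulate_annotation,
                                      simulate_counts, write_truth)

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=2023)
parser.add_argument("--outdir", type=Path,
                    default=Path(__file__).resolve().parent.parent
                    / "results" / "sim")
args = parser.parse_args()

config = SimConfig(seed=args.seed)
matrix, design, truth = simulate_counts(config)
annotation = simulate_annotation(matrix.gene_ids, config.seed)

args.outdir.mkdir(parents=True, exist_ok=True)
counts_io.write_counts(matrix, args.outdir / "counts.tsv")
counts_io.write_design(design, args.outdir / "design.tsv")
counts_io.write_annotation(annotation, args.outdir / "annotation.tsv")
write_truth(truth, args.outdir / "truth.tsv")

n_planted = (truth.classes != "null").sum()
print(f"simulated {matrix.n_genes} genes x {matrix.n_samples} samples "
      f"({len(config.genotypes)} genotypes x {len(config.conditions)} "
      f"conditions x {config.n_replicates} replicates)")
print(f"planted non-null genes: {n_planted} across "
      f"{truth.classes.nunique() - 1} classes; outputs in {args.outdir}")
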