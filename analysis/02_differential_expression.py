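#!/usr/bin/env python
"""Normalization, dispersion estimation and composite-null Wald tests.

Reads the simulated cohort from results/sim/, estimates median-of-ratios
size factors and trend-shrunk NB dispersions, then tests every
stress-vs-unstressed and mutant-vs-control contrast for a greater-than-
twofold change (H0: |log2FC| <= 1). Writes per-contrast DE tables under
results/de/.
"""

import argparse
from pathlib import Path

import pandas as pd

import dgcstress as d
from dgcstress import counts_io

root = Path(__file__).resolve().parent.parent / "results"
parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--simdir", type=Path, default=root / "sim")
parser.add_argument("--outdir", type=Path, default=root / "de")
args = parser.parse_args()

matrix = counts_io.filter_detected(
    counts_io.read_counts(args.simdir / "counts.tsv"))
design = counts_io.read_design(args.simdir / "design.tsv")
design.validate_against(matrix)
print(f"detected genes (>=1 count): {matrix.n_genes}")

size_factors = d.estimate_size_factors(matrix)
print(f"size factors span {size_factors.min():.3f}..{size_factors.max():.3f}")

dispersions = d.estimate_dispersions(matrix, design, size_factors)
a0, a1 = dispersions.coefficients
print(f"dispersion trend alpha(mu) = {a1:.3g}/mu + {a0:.3g}; "
      f"median final dispersion {dispersions.final.median():.4f}")

args.outdir.mkdir(parents=True, exist_ok=True)
size_factors.to_csv(args.outdir / "size_factors.tsv", sep="\t",
                    index_label="sample_id", float_format="%.6g")
pd.DataFrame({"genewise": dispersions.genewise, "trend": dispersions.trend,
              "final": dispersions.final}).to_csv(
    args.outdir / "dispersions.tsv", sep="\t",
    index_label=counts_io.GENE_ID, float_format="%.6g")

for contrast in d.auto_contrasts(design):
    res = d.wald_test(matrix, design, size_factors, dispersions, contrast)
    res.write(args.outdir / f"{contrast.label}.tsv")
    n_sig = int((res.table.padj < 0.1).sum())
    print(f"  {contrast.label}: {n_sig} genes with padj < 0.1")
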