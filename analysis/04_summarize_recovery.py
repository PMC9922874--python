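#!/usr/bin/env python
"""Score the pipeline against the planted truth and export summaries.

Compares recovered gene sets with the simulation's planted classes
(recall/precision per class), tallies functional categories of the
stress-changed genes, and writes a class-ordered log2FC heatmap matrix.
Outputs under results/summary/.
"""

import argparse
from pathlib import Path

import pandas as pd

from dgcstress import classify as cl
from dgcstress import counts_io, dge, report
from dgcstress.evaluate import recovery_metrics
from dgcstress.synthetic_data import SimConfig, read_truth

root = Path(__file__).resolve().parent.parent / "results"
parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=2023,
                    help="seed of the simulated cohort (for its config)")
parser.add_argument("--simdir", type=Path, default=root / "sim")
parser.add_argument("--dedir", type=Path, default=root / "de")
parser.add_argument("--outdir", type=Path, default=root / "summary")
args = parser.parse_args()

config = SimConfig(seed=args.seed)
truth = read_truth(args.simdir / "truth.tsv")
annotation = counts_io.read_annotation(args.simdir / "annotation.tsv")

policy = cl.ThresholdPolicy()
de_results = {}
calls = {}
for path in sorted(args.dedir.glob("*_vs_*.tsv")):
    de = dge.read_de_result(path, lfc_threshold=policy.changed_log2fc)
    de_results[de.contrast.label] = de
    calls[de.contrast.label] = cl.call_tristate(de, policy)

args.outdir.mkdir(parents=True, exist_ok=True)

metrics = recovery_metrics(config, truth, calls)
rows = []
for key, score in metrics.items():
    if hasattr(score, "recall"):
        rows.append({"class": key, "n_truth": score.n_truth,
                     "n_predicted": score.n_predicted, "n_hit": score.n_hit,
                     "recall": round(score.recall, 3),
                     "precision": round(score.precision, 3)})
recovery = pd.DataFrame(rows)
recovery.to_csv(args.outdir / "recovery.tsv", sep="\t", index=False)
print(recovery.to_string(index=False))
print(f"band genes: {metrics['band_called_changed']} called changed, "
      f"{metrics['band_called_unchanged']} called unchanged, of "
      f"{metrics['band_total']} planted in the 0.7..1 band")

# functional categories of the temperature-changed genes in controls
temp_changed = cl.changed_set(calls["control:temperature_vs_unstressed"])
if temp_changed:
    breakdown = report.category_breakdown(temp_changed, annotation)
    breakdown.to_csv(args.outdir / "categories_temperature.tsv", sep="\t",
                     index=False)
    top = breakdown.iloc[0]
    print(f"top category among {len(temp_changed)} temperature-changed "
          f"genes: {top.category} ({top['count']} genes, {top.percent})")

# heatmap matrix of the temperature stress-response classes
classes = pd.read_csv(root / "classify" / "classes_temperature.tsv",
                      sep="\t", index_col=counts_io.GENE_ID)["class"]
interesting = classes[classes != cl.UNCLASSIFIED]
if len(interesting):
    stress_labels = [lbl for lbl in de_results
                     if lbl.endswith("temperature_vs_unstressed")]
    matrix = report.heatmap_matrix(
        interesting, {lbl: de_results[lbl] for lbl in stress_labels},
        sort_contrast="control:temperature_vs_unstressed")
    report.write_heatmap_csv(matrix, args.outdir / "heatmap_temperature.csv")
    print(f"heatmap matrix: {matrix.shape[0]} classified genes x "
          f"{matrix.shape[1] - 1} contrasts -> heatmap_temperature.csv")
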