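#!/usr/bin/env python
"""Tri-state calls, mutant set intersections and stress-response classes.

Reads the DE tables from results/de/, applies the decision policy
(changed >= twofold with adjusted p < 0.1; unchanged < 1.62-fold), builds
the per-mutant dysregulated sets and their all-mutant intersection, the
DGC-dependent / -prevented / -independent classes per stress, and the
cross-stress direction partition. Writes under results/classify/.
"""

import argparse
from pathlib import Path

import pandas as pd

from dgcstress import classify as cl
from dgcstress import counts_io, dge, report

root = Path(__file__).resolve().parent.parent / "results"
parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--dedir", type=Path, default=root / "de")
parser.add_argument("--outdir", type=Path, default=root / "classify")
args = parser.parse_args()

policy = cl.ThresholdPolicy()
print(f"policy: changed >= {report.threshold_fc(policy.changed_log2fc)}-fold "
      f"({policy.p_mode} p < {policy.alpha}), unchanged < "
      f"{report.threshold_fc(policy.unchanged_log2fc)}-fold")

calls = {}
for path in sorted(args.dedir.glob("*_vs_*.tsv")):
    de = dge.read_de_result(path, lfc_threshold=policy.changed_log2fc)
    calls[de.contrast.label] = cl.call_tristate(de, policy)

args.outdir.mkdir(parents=True, exist_ok=True)
for label, table in calls.items():
    table.to_csv(args.outdir / f"calls_{label}.tsv", sep="\t",
                 index_label=counts_io.GENE_ID, float_format="%.6g")

mutants = ("Dg", "Dys", "Syn1", "Nos")
conditions = ("unstressed", "temperature", "metabolic")
baseline = {m: {c: calls[f"{c}:{m}_vs_control"] for c in conditions}
            for m in mutants}
dys = cl.mutant_dysregulated_sets(baseline, require_k=4)
dys.membership.to_csv(args.outdir / "dysregulated_membership.tsv", sep="\t")
for m in mutants:
    print(f"dysregulated in {m} (any condition): {len(dys.per_mutant[m])}")
print(f"dysregulated in all {len(mutants)} mutants: {len(dys.selected)}")
core = cl.mutant_dysregulated_sets(
    {m: baseline[m] for m in ("Dg", "Dys", "Syn1")}, require_k=3)
extra = len(core.selected - dys.selected)
print(f"core Dg/Dys/Syn1 intersection adds {extra} genes")
if dys.selected:
    conc = cl.direction_concordance(dys.selected, dys.directions)
    print(f"direction concordance: {conc.n_same} of {conc.n_total} "
          f"({conc.percent}%)")

for stress in ("temperature", "metabolic"):
    ctrl = calls[f"control:{stress}_vs_unstressed"]
    mut = {m: calls[f"{m}:{stress}_vs_unstressed"] for m in mutants}
    classes = cl.stress_response_classes(ctrl, mut)
    classes.to_csv(args.outdir / f"classes_{stress}.tsv", sep="\t",
                   index_label=counts_io.GENE_ID)
    counts = classes.value_counts()
    print(f"{stress}: dependent {counts.get(cl.DGC_DEPENDENT, 0)}, "
          f"prevented {counts.get(cl.DGC_PREVENTED, 0)}, "
          f"independent {counts.get(cl.DGC_INDEPENDENT, 0)}")

overlap = cl.cross_stress_overlap(calls["control:temperature_vs_unstressed"],
                                  calls["control:metabolic_vs_unstressed"])
pd.Series({k: len(v) for k, v in overlap.bins.items()}, name="n_genes") \
    .to_csv(args.outdir / "cross_stress_bins.tsv", sep="\t",
            index_label="bin")
print(f"control: {overlap.n_temp} temperature-changed, {overlap.n_metab} "
      f"metabolic-changed; combined total {overlap.combined_total}, shared "
      f"{overlap.n_both} ({overlap.overlap_percent}%)")
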