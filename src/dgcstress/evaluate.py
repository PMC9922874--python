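"""Recovery scoring of pipeline calls against planted simulation truth.

Predicted gene sets come from the classifier exactly as a user would obtain
them; truth sets are derived from the planted log2 fold changes via the same
class definitions (a gene whose planted effects satisfy a class definition
belongs to that class's truth set regardless of which generator label
planted it — planted classes overlap in observable signature).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from . import classify as cl
from .synthetic_data import (
    SimConfig,
    SimTruth,
    truth_cross_stress_opposite,
    truth_dysregulated_intersection,
    truth_stress_response_sets,
)


@dataclass(frozen=True)
class RecoveryScore:
    n_truth: int
    n_predicted: int
    n_hit: int

    @property
    def recall(self) -> float:
        return self.n_hit / self.n_truth if self.n_truth else float("nan")

    @property
    def precision(self) -> float:
        return self.n_hit / self.n_predicted if self.n_predicted \
            else float("nan")


def _score(predicted: set, truth: set) -> RecoveryScore:
    return RecoveryScore(n_truth=len(truth), n_predicted=len(predicted),
                         n_hit=len(predicted & truth))


def recovery_metrics(config: SimConfig, truth: SimTruth,
                     calls: Mapping[str, pd.DataFrame]) -> dict:
    """Recall/precision of every evaluable planted class, plus band-gene
    call accounting, from per-contrast tri-state calls."""
    control = config.control
    unstressed = config.unstressed
    mutants = config.mutants
    out: dict = {}

    # stress-response classes per stress
    for stress in config.stresses:
        ctrl_calls = calls[f"{control}:{stress}_vs_{unstressed}"]
        mut_calls = {m: calls[f"{m}:{stress}_vs_{unstressed}"]
                     for m in mutants}
        predicted = cl.stress_response_classes(ctrl_calls, mut_calls)
        truth_sets = truth_stress_response_sets(
            truth, stress, control=control, mutants=mutants,
            unstressed=unstressed)
        for name, truth_set in truth_sets.items():
            pred = set(predicted.index[predicted == name])
            out[f"{name}_{stress}"] = _score(pred, truth_set)

    # baseline dysregulation intersection across all mutants
    baseline_calls = {
        m: {c: calls[f"{c}:{m}_vs_{control}"] for c in config.conditions}
        for m in mutants}
    dys = cl.mutant_dysregulated_sets(baseline_calls, len(mutants))
    truth_all = truth_dysregulated_intersection(
        truth, mutants=mutants, conditions=config.conditions, control=control)
    out["baseline_all_mutants"] = _score(set(dys.selected), truth_all)

    # opposite regulation under the two stresses (control genotype)
    if len(config.stresses) >= 2:
        s1, s2 = config.stresses[0], config.stresses[1]
        overlap = cl.cross_stress_overlap(
            calls[f"{control}:{s1}_vs_{unstressed}"],
            calls[f"{control}:{s2}_vs_{unstressed}"])
        pred_opp = set(overlap.bins["temp_down_metab_up"]) | \
            set(overlap.bins["temp_up_metab_down"])
        truth_opp = truth_cross_stress_opposite(
            truth, control=control, stresses=(s1, s2), unstressed=unstressed)
        out["cross_stress_opposite"] = _score(pred_opp, truth_opp)

    # band genes: planted inside the indeterminacy band on the control
    # response to the first stress; count CHANGED/UNCHANGED miscalls there
    band_genes = truth.genes_of_class("band")
    if band_genes and config.stresses:
        band_calls = calls[
            f"{control}:{config.stresses[0]}_vs_{unstressed}"
        ].loc[band_genes, "call"]
        out["band_total"] = len(band_genes)
        out["band_called_changed"] = int(
            band_calls.isin(cl.CHANGED_CALLS).sum())
        out["band_called_unchanged"] = int((band_calls == cl.UNCHANGED).sum())
    return out
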