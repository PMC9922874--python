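"""Tri-state gene calls, multi-genotype set intersections and the
DGC-dependent / DGC-prevented / DGC-independent stress-response classes.

A gene's behaviour in one contrast is summarized as one of four calls:

* ``changed_up`` / ``changed_down`` — |log2FC| >= the changed threshold
  (default 1.0, i.e. twofold) **and** the p-gate passes (adjusted or raw
  p < alpha, default 0.1);
* ``unchanged`` — |log2FC| < the no-change threshold (default 0.7, i.e.
  1.62-fold). This is a pure effect-size statement; no p-value is consulted;
* ``indeterminate`` — everything else: estimates inside the band
  0.7 <= |log2FC| < 1, and large effects that fail the p-gate (a noisy
  large effect is not evidence of "no change").

Genes excluded from testing keep the call ``not_tested`` and are dropped
from set denominators explicitly (callers can log them), never silently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .dge import DEResult, FLAG_NOT_TESTED
from .errors import DesignError, UndefinedPercentageError
from .report import round_half_away

CHANGED_UP = "changed_up"
CHANGED_DOWN = "changed_down"
UNCHANGED = "unchanged"
INDETERMINATE = "indeterminate"
NOT_TESTED = "not_tested"

CHANGED_CALLS = (CHANGED_UP, CHANGED_DOWN)


@dataclass(frozen=True)
class ThresholdPolicy:
    """The decision constants: twofold change, 1.62-fold no-change band,
    significance 0.1 on adjusted (default) or raw p."""

    changed_log2fc: float = 1.0
    unchanged_log2fc: float = 0.7
    alpha: float = 0.1
    p_mode: str = "adjusted"

    def __post_init__(self) -> None:
        if not 0 <= self.unchanged_log2fc < self.changed_log2fc:
            raise ValueError(
                "need 0 <= unchanged_log2fc < changed_log2fc "
                f"(got {self.unchanged_log2fc} vs {self.changed_log2fc})")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.p_mode not in ("adjusted", "raw"):
            raise ValueError(f"p_mode must be 'adjusted' or 'raw', got "
                             f"{self.p_mode!r}")


def call_tristate(de: DEResult, policy: ThresholdPolicy) -> pd.DataFrame:
    """Per-gene tri-state calls for one contrast.

    Returns a DataFrame indexed like the DE table with columns ``call``,
    ``log2fc`` (copied through for direction/ranking decisions downstream)
    and ``p_used`` (the gated p-value).
    """
    t = de.table
    p_used = t["padj"] if policy.p_mode == "adjusted" else t["p"]
    lfc = t["log2fc"]
    gate = p_used < policy.alpha

    call = np.full(len(t), INDETERMINATE, dtype=object)
    call[(lfc >= policy.changed_log2fc) & gate] = CHANGED_UP
    call[(lfc <= -policy.changed_log2fc) & gate] = CHANGED_DOWN
    unchanged = lfc.abs() < policy.unchanged_log2fc
    call[unchanged & ~np.isin(call, CHANGED_CALLS)] = UNCHANGED
    call[(t["flag"] == FLAG_NOT_TESTED).to_numpy()] = NOT_TESTED

    return pd.DataFrame({"call": call, "log2fc": lfc, "p_used": p_used},
                        index=t.index)


def changed_set(calls: pd.DataFrame) -> set[str]:
    return set(calls.index[calls["call"].isin(CHANGED_CALLS)])


def _direction(calls: pd.DataFrame) -> pd.Series:
    """+1 for changed_up, -1 for changed_down, 0 otherwise."""
    return calls["call"].map({CHANGED_UP: 1, CHANGED_DOWN: -1}).fillna(0) \
        .astype(int)


# ---------------------------------------------------------------------------
# baseline dysregulation across mutants
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DysregulationResult:
    """Per-mutant dysregulated sets and their k-of-n intersection."""

    per_mutant: dict[str, frozenset]
    selected: frozenset            # genes dysregulated in >= require_k mutants
    membership: pd.DataFrame       # union genes x mutants, 0/1
    directions: pd.DataFrame       # union genes x mutants, -1/0/+1
    require_k: int
    scope: str


def mutant_dysregulated_sets(
        calls: Mapping[str, Mapping[str, pd.DataFrame]],
        require_k: int, *,
        scope: str = "union",
        unstressed: str = "unstressed") -> DysregulationResult:
    """Which genes are dysregulated in which mutants, irrespective of stress.

    ``calls[mutant][condition]`` holds the tri-state calls of the
    mutant-vs-control contrast within that condition. Under the default
    ``scope="union"`` a gene counts as dysregulated in a mutant if it is
    CHANGED in at least one condition; ``scope="unstressed_only"`` restricts
    to the unstressed comparison. ``require_k = n`` reproduces the all-n
    intersection; passing only the core mutants reproduces the relaxed
    variant.

    The per-gene sign for multi-condition hits is taken from the unstressed
    contrast when CHANGED there, otherwise from the condition with the
    largest |log2FC| (a deterministic tie-break).
    """
    if scope not in ("union", "unstressed_only"):
        raise ValueError(f"unknown scope {scope!r}")
    mutants = list(calls)
    if not 1 <= require_k <= len(mutants):
        raise ValueError(
            f"require_k must be in [1, {len(mutants)}], got {require_k}")

    per_mutant: dict[str, frozenset] = {}
    signs: dict[str, pd.Series] = {}
    for mutant, by_condition in calls.items():
        conditions = ([unstressed] if scope == "unstressed_only"
                      else list(by_condition))
        dysregulated: set[str] = set()
        for condition in conditions:
            dysregulated |= changed_set(by_condition[condition])
        per_mutant[mutant] = frozenset(dysregulated)

        # direction per gene for this mutant
        any_table = next(iter(by_condition.values()))
        sign = pd.Series(0, index=any_table.index, dtype=int)
        if unstressed in by_condition:
            base = by_condition[unstressed]
            base_dir = _direction(base)
            sign[base_dir != 0] = base_dir[base_dir != 0]
        undecided = sign == 0
        if undecided.any():
            lfc_cols = pd.DataFrame(
                {c: by_condition[c]["log2fc"] for c in by_condition})
            best = lfc_cols.abs().idxmax(axis=1)
            picked = lfc_cols.to_numpy()[
                np.arange(len(lfc_cols)),
                lfc_cols.columns.get_indexer(best)]
            sign[undecided] = np.sign(picked)[undecided.to_numpy()].astype(int)
        signs[mutant] = sign

    union = sorted(set().union(*per_mutant.values())) if per_mutant else []
    membership = pd.DataFrame(
        {m: [int(g in per_mutant[m]) for g in union] for m in mutants},
        index=pd.Index(union, name="gene_id"))
    selected = frozenset(
        g for g in union if membership.loc[g].sum() >= require_k)
    directions = pd.DataFrame(
        {m: signs[m].reindex(union) for m in mutants},
        index=membership.index)
    return DysregulationResult(per_mutant=per_mutant, selected=selected,
                               membership=membership, directions=directions,
                               require_k=require_k, scope=scope)


@dataclass(frozen=True)
class Concordance:
    n_same: int
    n_total: int
    percent: int  # rounded half-away-from-zero to the nearest integer


def direction_concordance(genes, directions: pd.DataFrame) -> Concordance:
    """Fraction of genes whose up/down sign agrees across all genotypes."""
    genes = sorted(genes)
    if not genes:
        raise UndefinedPercentageError(
            "direction concordance is undefined for an empty gene set")
    sub = directions.reindex(genes)
    if sub.isna().any().any() or (sub == 0).any().any():
        bad = sub.index[(sub.isna() | (sub == 0)).any(axis=1)][0]
        raise ValueError(
            f"gene {bad!r} lacks a direction in at least one genotype")
    n_same = int((sub.nunique(axis=1) == 1).sum())
    n_total = len(genes)
    percent = int(round_half_away(100.0 * n_same / n_total, 0))
    return Concordance(n_same=n_same, n_total=n_total, percent=percent)


# ---------------------------------------------------------------------------
# stress-response classes
# ---------------------------------------------------------------------------

DGC_DEPENDENT = "dgc_dependent_response"
DGC_PREVENTED = "dgc_prevented_response"
DGC_INDEPENDENT = "dgc_independent_response"
UNCLASSIFIED = "unclassified"


def stress_response_classes(control_calls: pd.DataFrame,
                            mutant_calls: Mapping[str, pd.DataFrame]
                            ) -> pd.Series:
    """Classify each gene's stress response relative to the DGC.

    * dgc_dependent_response — CHANGED in control and UNCHANGED in all
      mutants (the response needs an intact DGC);
    * dgc_prevented_response — UNCHANGED in control and CHANGED in all
      mutants (the DGC normally suppresses the response);
    * dgc_independent_response — CHANGED in control and in all mutants;
    * unclassified — anything else (including any indeterminate call).
    """
    if not mutant_calls:
        raise DesignError("stress_response_classes needs at least one mutant")
    idx = control_calls.index
    for mutant, table in mutant_calls.items():
        if not table.index.equals(idx):
            raise DesignError(
                f"calls for mutant {mutant!r} cover a different gene universe")

    ctrl = control_calls["call"]
    ctrl_changed = ctrl.isin(CHANGED_CALLS).to_numpy()
    ctrl_unchanged = (ctrl == UNCHANGED).to_numpy()
    mut_changed = np.ones(len(idx), dtype=bool)
    mut_unchanged = np.ones(len(idx), dtype=bool)
    for table in mutant_calls.values():
        call = table["call"]
        mut_changed &= call.isin(CHANGED_CALLS).to_numpy()
        mut_unchanged &= (call == UNCHANGED).to_numpy()

    out = np.full(len(idx), UNCLASSIFIED, dtype=object)
    out[ctrl_changed & mut_unchanged] = DGC_DEPENDENT
    out[ctrl_unchanged & mut_changed] = DGC_PREVENTED
    out[ctrl_changed & mut_changed] = DGC_INDEPENDENT
    # the three classes are disjoint by construction; assert anyway
    assert not (ctrl_changed & ctrl_unchanged).any()
    assert not (mut_changed & mut_unchanged).any()
    return pd.Series(out, index=idx, name="class")


# ---------------------------------------------------------------------------
# cross-stress overlap
# ---------------------------------------------------------------------------

BIN_NAMES = ("both_up", "both_down", "temp_up_metab_down",
             "temp_down_metab_up", "temp_only", "metab_only")


@dataclass(frozen=True)
class OverlapResult:
    """Partition of the two CHANGED sets by direction.

    ``combined_total`` follows the convention of summing the two per-stress
    set sizes (so genes changed under both stresses are counted twice);
    ``union_total`` is the plain union size, reported alongside.
    """

    bins: dict[str, frozenset] = field(repr=False)
    n_temp: int = 0
    n_metab: int = 0
    n_both: int = 0
    combined_total: int = 0
    union_total: int = 0
    overlap_percent: int = 0


def cross_stress_overlap(temp_calls: pd.DataFrame,
                         metab_calls: pd.DataFrame) -> OverlapResult:
    """Direction partition of the genes changed under either stress
    (both call tables must cover the same gene universe)."""
    if set(temp_calls.index) != set(metab_calls.index):
        raise DesignError("cross-stress overlap needs one common gene universe")
    t_up = set(temp_calls.index[temp_calls["call"] == CHANGED_UP])
    t_down = set(temp_calls.index[temp_calls["call"] == CHANGED_DOWN])
    m_up = set(metab_calls.index[metab_calls["call"] == CHANGED_UP])
    m_down = set(metab_calls.index[metab_calls["call"] == CHANGED_DOWN])
    t_set = t_up | t_down
    m_set = m_up | m_down
    both = t_set & m_set
    bins = {
        "both_up": frozenset(t_up & m_up),
        "both_down": frozenset(t_down & m_down),
        "temp_up_metab_down": frozenset(t_up & m_down),
        "temp_down_metab_up": frozenset(t_down & m_up),
        "temp_only": frozenset(t_set - m_set),
        "metab_only": frozenset(m_set - t_set),
    }
    combined = len(t_set) + len(m_set)
    if combined == 0:
        overlap_percent = 0
    else:
        overlap_percent = int(round_half_away(100.0 * len(both) / combined, 0))
    return OverlapResult(bins=bins, n_temp=len(t_set), n_metab=len(m_set),
                         n_both=len(both), combined_total=combined,
                         union_total=len(t_set | m_set),
                         overlap_percent=overlap_percent)
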