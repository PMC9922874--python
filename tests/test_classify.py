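import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dgcstress import classify as cl
from dgcstress import dge
from dgcstress.errors import DesignError, UndefinedPercentageError


def fake_de(log2fc, padj=None, p=None, flags=None, label="x:temperature_vs_unstressed"):
    """Assemble a DEResult directly from estimate vectors."""
    n = len(log2fc)
    idx = pd.Index([f"g{i}" for i in range(n)], name="gene_id")
    padj = padj if padj is not None else [0.01] * n
    p = p if p is not None else padj
    table = pd.DataFrame({
        "base_mean": 100.0, "log2fc": list(log2fc), "se": 0.2,
        "p": list(p), "padj": list(padj),
        "flag": flags if flags is not None else [dge.FLAG_OK] * n,
    }, index=idx)
    con = dge.Contrast("stress", "x", "temperature", "unstressed")
    return dge.DEResult(table=table, contrast=con, lfc_threshold=1.0)


def calls_from(log2fc, padj=None, **kwargs):
    return cl.call_tristate(fake_de(log2fc, padj, **kwargs),
                            cl.ThresholdPolicy())


class TestThresholdPolicy:
    def test_rejects_inverted_band(self):
        with pytest.raises(ValueError):
            cl.ThresholdPolicy(changed_log2fc=0.5, unchanged_log2fc=0.7)

    def test_rejects_bad_alpha(self):
        with pytest.raises(ValueError):
            cl.ThresholdPolicy(alpha=1.5)


class TestTriState:
    @pytest.mark.parametrize("lfc,padj,expected", [
        (1.2, 0.05, cl.CHANGED_UP),            # clears both gates
        (-1.2, 0.05, cl.CHANGED_DOWN),
        (0.69, 0.9, cl.UNCHANGED),             # below the band, any p
        (0.69, 0.0001, cl.UNCHANGED),
        (0.85, 0.0001, cl.INDETERMINATE),      # inside the 0.7..1 band
        (-1.5, 0.3, cl.INDETERMINATE),         # large effect, fails p-gate
    ])
    def test_call_definitions(self, lfc, padj, expected):
        calls = calls_from([lfc], [padj])
        assert calls["call"].iloc[0] == expected

    def test_not_tested_genes_keep_na_call(self):
        de = fake_de([np.nan, 1.5], [np.nan, 0.01],
                     flags=[dge.FLAG_NOT_TESTED, dge.FLAG_OK])
        calls = cl.call_tristate(de, cl.ThresholdPolicy())
        assert calls["call"].iloc[0] == cl.NOT_TESTED
        assert calls["call"].iloc[1] == cl.CHANGED_UP

    def test_raw_p_mode_uses_raw_column(self):
        de = fake_de([1.5], padj=[0.5], p=[0.05])
        adjusted = cl.call_tristate(de, cl.ThresholdPolicy())
        raw = cl.call_tristate(de, cl.ThresholdPolicy(p_mode="raw"))
        assert adjusted["call"].iloc[0] == cl.INDETERMINATE
        assert raw["call"].iloc[0] == cl.CHANGED_UP

    @settings(max_examples=80, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.floats(-4, 4), st.floats(0, 1)),
                    min_size=1, max_size=30))
    def test_partition_exhaustive_disjoint_and_consistent(self, rows):
        lfc = [r[0] for r in rows]
        padj = [r[1] for r in rows]
        policy = cl.ThresholdPolicy()
        calls = cl.call_tristate(fake_de(lfc, padj), policy)
        assert set(calls["call"]) <= {cl.CHANGED_UP, cl.CHANGED_DOWN,
                                      cl.UNCHANGED, cl.INDETERMINATE}
        for call, f, q in zip(calls["call"], lfc, padj):
            if call in cl.CHANGED_CALLS:
                assert abs(f) >= policy.changed_log2fc and q < policy.alpha
            elif call == cl.UNCHANGED:
                assert abs(f) < policy.unchanged_log2fc

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.floats(-4, 4), st.floats(0, 1)),
                    min_size=1, max_size=30),
           st.floats(1.0, 2.0), st.floats(0.1, 0.6))
    def test_threshold_monotonicity(self, rows, stricter_changed,
                                    smaller_unchanged):
        lfc = [r[0] for r in rows]
        padj = [r[1] for r in rows]
        de = fake_de(lfc, padj)
        base = cl.call_tristate(de, cl.ThresholdPolicy())
        harder = cl.call_tristate(de, cl.ThresholdPolicy(
            changed_log2fc=1.0 + stricter_changed))
        narrower = cl.call_tristate(de, cl.ThresholdPolicy(
            unchanged_log2fc=smaller_unchanged))
        assert cl.changed_set(harder) <= cl.changed_set(base)
        assert set(narrower.index[narrower["call"] == cl.UNCHANGED]) <= \
            set(base.index[base["call"] == cl.UNCHANGED])


def toy_mutant_calls():
    """Six genes with hand-set calls across 4 mutants (unstressed only):
    g0 CHANGED in all four; g1 in Dg/Dys/Syn1; g2 in Nos only; rest quiet."""
    mutants = ("Dg", "Dys", "Syn1", "Nos")
    changed = {
        "Dg": {"g0", "g1"}, "Dys": {"g0", "g1"},
        "Syn1": {"g0", "g1"}, "Nos": {"g0", "g2"},
    }
    out = {}
    for m in mutants:
        lfc = [2.0 if f"g{i}" in changed[m] else 0.1 for i in range(6)]
        out[m] = {"unstressed": calls_from(lfc)}
    return out


class TestDysregulatedSets:
    def test_all_unchanged_gives_empty_sets(self):
        calls = {m: {"unstressed": calls_from([0.1, 0.2])}
                 for m in ("Dg", "Dys")}
        res = cl.mutant_dysregulated_sets(calls, 2)
        assert all(len(s) == 0 for s in res.per_mutant.values())
        assert res.selected == frozenset()

    def test_toy_intersections_match_enumeration(self):
        calls = toy_mutant_calls()
        res4 = cl.mutant_dysregulated_sets(calls, 4)
        assert res4.selected == {"g0"}
        core = {m: calls[m] for m in ("Dg", "Dys", "Syn1")}
        res3 = cl.mutant_dysregulated_sets(core, 3)
        assert res3.selected == {"g0", "g1"}
        # brute-force enumeration over all genes and k
        sets = {m: cl.changed_set(calls[m]["unstressed"]) for m in calls}
        for k in range(1, 5):
            expected = {g for g in (f"g{i}" for i in range(6))
                        if sum(g in s for s in sets.values()) >= k}
            got = cl.mutant_dysregulated_sets(calls, k).selected
            assert got == expected

    def test_require_k_is_monotone(self):
        calls = toy_mutant_calls()
        prev = None
        for k in range(1, 5):
            cur = cl.mutant_dysregulated_sets(calls, k).selected
            if prev is not None:
                assert cur <= prev
            prev = cur

    def test_require_k_out_of_range(self):
        calls = toy_mutant_calls()
        with pytest.raises(ValueError):
            cl.mutant_dysregulated_sets(calls, 5)
        with pytest.raises(ValueError):
            cl.mutant_dysregulated_sets(calls, 0)

    def test_union_scope_catches_stress_only_dysregulation(self):
        quiet = calls_from([0.1])
        loud = calls_from([2.0])
        calls = {"Dg": {"unstressed": quiet, "temperature": loud}}
        union = cl.mutant_dysregulated_sets(calls, 1)
        only_base = cl.mutant_dysregulated_sets(calls, 1,
                                                scope="unstressed_only")
        assert union.per_mutant["Dg"] == {"g0"}
        assert only_base.per_mutant["Dg"] == frozenset()

    def test_direction_from_unstressed_then_largest_effect(self):
        # g0: CHANGED down at baseline -> sign -1 even though temperature
        # has a bigger positive effect; g1: only temperature -> +1
        base = calls_from([-1.5, 0.1])
        temp = calls_from([3.0, 2.0])
        res = cl.mutant_dysregulated_sets({"Dg": {"unstressed": base,
                                                  "temperature": temp}}, 1)
        assert res.directions.at["g0", "Dg"] == -1
        assert res.directions.at["g1", "Dg"] == 1


class TestDirectionConcordance:
    def make_directions(self, n_same, n_total, n_mutants=4):
        rows = []
        for i in range(n_total):
            if i < n_same:
                rows.append([1] * n_mutants)
            else:
                rows.append([1] + [-1] * (n_mutants - 1))
        return pd.DataFrame(rows, index=[f"g{i}" for i in range(n_total)],
                            columns=["Dg", "Dys", "Syn1", "Nos"][:n_mutants])

    @pytest.mark.parametrize("n_same,n_total,expected", [
        (44, 46, 96),   # the all-mutant intersection concordance
        (19, 21, 90),   # temperature DGC-independent genes
        (37, 42, 88),   # metabolic DGC-independent genes
    ])
    def test_published_style_ratios(self, n_same, n_total, expected):
        directions = self.make_directions(n_same, n_total)
        res = cl.direction_concordance(directions.index, directions)
        assert (res.n_same, res.n_total, res.percent) == \
            (n_same, n_total, expected)

    def test_all_same_sign_gives_100(self):
        directions = self.make_directions(5, 5)
        assert cl.direction_concordance(directions.index,
                                        directions).percent == 100

    def test_empty_set_raises_rather_than_silent_zero(self):
        directions = self.make_directions(2, 2)
        with pytest.raises(UndefinedPercentageError):
            cl.direction_concordance([], directions)

    def test_missing_sign_raises(self):
        directions = self.make_directions(2, 2)
        directions.iloc[0, 1] = 0
        with pytest.raises(ValueError, match="g0"):
            cl.direction_concordance(directions.index, directions)


class TestStressResponseClasses:
    def classes_for(self, ctrl_lfc, mutant_lfcs, ctrl_padj=0.01):
        ctrl = calls_from([ctrl_lfc], [ctrl_padj])
        mutants = {f"m{i}": calls_from([v]) for i, v in enumerate(mutant_lfcs)}
        return cl.stress_response_classes(ctrl, mutants).iloc[0]

    def test_dependent_prevented_independent_definitions(self):
        assert self.classes_for(2.0, [0.1] * 4) == cl.DGC_DEPENDENT
        assert self.classes_for(0.2, [-2.0] * 4) == cl.DGC_PREVENTED
        assert self.classes_for(2.0, [2.0] * 4) == cl.DGC_INDEPENDENT

    def test_one_indeterminate_mutant_blocks_classification(self):
        # 0.85 sits in the band: neither CHANGED nor UNCHANGED
        assert self.classes_for(2.0, [2.0, 2.0, 2.0, 0.85]) == cl.UNCLASSIFIED

    def test_mismatched_universe_raises(self):
        ctrl = calls_from([2.0, 0.1])
        bad = {"m0": calls_from([2.0])}
        with pytest.raises(DesignError):
            cl.stress_response_classes(ctrl, bad)

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-3, 3), min_size=4, max_size=4),
           st.floats(-3, 3))
    def test_classes_pairwise_disjoint(self, mutant_lfcs, ctrl_lfc):
        got = self.classes_for(ctrl_lfc, mutant_lfcs)
        assert got in {cl.DGC_DEPENDENT, cl.DGC_PREVENTED,
                       cl.DGC_INDEPENDENT, cl.UNCLASSIFIED}


class TestCrossStressOverlap:
    def test_disjoint_sets_share_nothing(self):
        temp = calls_from([2.0, 0.1, 0.1])
        metab = calls_from([0.1, -2.0, 0.1])
        res = cl.cross_stress_overlap(temp, metab)
        assert res.n_both == 0 and res.overlap_percent == 0
        assert res.bins["temp_only"] == {"g0"}
        assert res.bins["metab_only"] == {"g1"}

    def test_published_style_set_sizes(self):
        """Set sizes 357 and 483 with 59 shared give a combined total of 840
        and a 7% overlap under the summed-sizes convention."""
        n = 800
        temp_lfc = np.full(n, 0.1)
        metab_lfc = np.full(n, 0.1)
        temp_lfc[:357] = -2.0                  # temperature-changed
        metab_lfc[298:298 + 483] = 2.0         # metabolic-changed, 59 shared
        res = cl.cross_stress_overlap(calls_from(temp_lfc),
                                      calls_from(metab_lfc))
        assert (res.n_temp, res.n_metab, res.n_both) == (357, 483, 59)
        assert res.combined_total == 840
        assert res.union_total == 781
        assert res.overlap_percent == 7

    def test_partition_matches_bruteforce_enumeration(self):
        temp_lfc = [2.0, 2.0, -2.0, -2.0, 2.0, 0.1, 0.1, -2.0]
        metab_lfc = [2.0, -2.0, 2.0, -2.0, 0.1, 2.0, 0.1, 0.2]
        temp, metab = calls_from(temp_lfc), calls_from(metab_lfc)
        res = cl.cross_stress_overlap(temp, metab)
        genes = [f"g{i}" for i in range(8)]
        expected = {b: set() for b in cl.BIN_NAMES}
        for g, t, m in zip(genes, temp_lfc, metab_lfc):
            t_dir = 0 if abs(t) < 1 else (1 if t > 0 else -1)
            m_dir = 0 if abs(m) < 1 else (1 if m > 0 else -1)
            if t_dir and m_dir:
                key = {(1, 1): "both_up", (-1, -1): "both_down",
                       (1, -1): "temp_up_metab_down",
                       (-1, 1): "temp_down_metab_up"}[(t_dir, m_dir)]
            elif t_dir:
                key = "temp_only"
            elif m_dir:
                key = "metab_only"
            else:
                continue
            expected[key].add(g)
        assert {k: set(v) for k, v in res.bins.items()} == expected
        # bins partition the union disjointly
        union = set().union(*res.bins.values())
        assert sum(len(v) for v in res.bins.values()) == len(union)

    def test_mismatched_universe_raises(self):
        with pytest.raises(DesignError):
            cl.cross_stress_overlap(calls_from([1.0]), calls_from([1.0, 2.0]))
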