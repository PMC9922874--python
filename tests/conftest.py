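import numpy as np
import pandas as pd
import pytest

import dgcstress as d
from dgcstress import classify as cl
from dgcstress.counts_io import CountMatrix, StudyDesign
from dgcstress.synthetic_data import SimConfig, simulate_counts


@pytest.fixture(scope="session")
def two_group_sim():
    """Small control-vs-Dg simulation with planted twofold genes."""
    cfg = SimConfig(
        n_genes=400, genotypes=("control", "Dg"), conditions=("unstressed",),
        n_replicates=6,
        class_counts={"baseline_dgc_dependent_up": 40,
                      "baseline_dgc_dependent_down": 40},
        seed=101)
    matrix, design, truth = simulate_counts(cfg)
    return cfg, matrix, design, truth


@pytest.fixture(scope="session")
def default_run():
    """The full factorial default simulation, fitted end to end."""
    cfg = SimConfig()
    matrix, design, truth = simulate_counts(cfg)
    matrix = d.filter_detected(matrix)
    sf = d.estimate_size_factors(matrix)
    disp = d.estimate_dispersions(matrix, design, sf)
    de = {c.label: d.wald_test(matrix, design, sf, disp, c)
          for c in d.auto_contrasts(design)}
    policy = cl.ThresholdPolicy()
    calls = {lbl: cl.call_tristate(res, policy) for lbl, res in de.items()}
    return {"config": cfg, "matrix": matrix, "design": design, "truth": truth,
            "size_factors": sf, "dispersions": disp, "de": de,
            "calls": calls, "policy": policy}


def toy_matrix(values, gene_ids=None, sample_ids=None) -> CountMatrix:
    values = np.asarray(values, dtype=np.int64)
    gene_ids = gene_ids or [f"g{i}" for i in range(values.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(values.shape[1])]
    return CountMatrix(pd.DataFrame(
        values, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids))


def flat_design(sample_ids, genotype="control", condition="unstressed"):
    return StudyDesign(pd.DataFrame({
        "sample_id": list(sample_ids),
        "genotype": genotype,
        "condition": condition,
        "replicate": range(1, len(sample_ids) + 1),
    }))
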