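"""Count-matrix simulator with the study's factorial design and planted truth.

The generator emulates a whole-organism bulk RNA-seq experiment: five
genotypes (a control and four DGC loss-of-function mutants) crossed with
three conditions (unstressed, temperature stress, metabolic stress), a few
replicates per cell, ~thousands of detected transcripts, per-sample library
size factors, and gene-wise NB dispersions following a mean-dispersion
trend ``alpha(mu) = a1/mu + a0``.

Planted gene classes mirror the biology the downstream classifier looks
for; effects are additive on the log2 scale across a genotype main effect
and a genotype x condition response effect, so the mean of gene *g* in
sample *j* is ``s_j * q_g * 2**(main[genotype_j] + response[genotype_j,
condition_j])``. Class labels:

* ``null`` — no planted effect.
* ``baseline_dgc_dependent_up`` / ``_down`` — genotype main effect of
  +/- ``effect_log2fc`` in every mutant (DGC-dependent baseline genes).
* ``dgc_dependent_response:<stress>`` — response effect in the control
  genotype only (stress-responsive in controls, flat in mutants).
* ``dgc_prevented_response:<stress>`` — response effect in every mutant but
  not in the control.
* ``dgc_independent_response:<stress>`` — same response effect in every
  genotype (random sign per gene).
* ``stress_specific:<stress>:<up|down>`` — same as independent but with a
  fixed direction; used to shape the per-stress up/down asymmetry.
* ``cross_stress_opposite`` — down under temperature, up under metabolic
  stress, in every genotype.
* ``band`` — control-genotype response of magnitude ``band_log2fc``
  (inside the indeterminacy band 0.7 <= |log2FC| < 1) under the first
  stress condition.

Random-number discipline: one root seed; each gene draws from its own
deterministic substream keyed by (seed, gene index), so adding genes never
perturbs earlier genes. Size factors come from a separate substream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .counts_io import GENE_ID, CountMatrix, StudyDesign
from .dge import Contrast, auto_contrasts
from .errors import ConfigError, FormatError

DEFAULT_GENOTYPES = ("control", "Dg", "Dys", "Syn1", "Nos")
DEFAULT_CONDITIONS = ("unstressed", "temperature", "metabolic")

#: Default planted classes for the full-design simulation: 30-50 genes per
#: measured class, with the stress-specific split shaped like the asymmetry
#: seen in real stress transcriptomes (temperature mostly down, metabolic
#: mostly up).
DEFAULT_CLASS_COUNTS: dict[str, int] = {
    "baseline_dgc_dependent_up": 20,
    "baseline_dgc_dependent_down": 20,
    "dgc_dependent_response:temperature": 40,
    "dgc_dependent_response:metabolic": 40,
    "dgc_prevented_response:temperature": 40,
    "dgc_prevented_response:metabolic": 40,
    "dgc_independent_response:temperature": 40,
    "dgc_independent_response:metabolic": 40,
    "stress_specific:temperature:down": 30,
    "stress_specific:temperature:up": 10,
    "stress_specific:metabolic:up": 30,
    "stress_specific:metabolic:down": 10,
    "cross_stress_opposite": 30,
    "band": 40,
}


def default_class_counts(n_genes: int) -> dict[str, int]:
    """The default planted classes scaled proportionally to ``n_genes``
    (the stated counts assume the 5,000-gene design)."""
    factor = n_genes / 5000.0
    return {label: int(round(count * factor))
            for label, count in DEFAULT_CLASS_COUNTS.items()
            if int(round(count * factor)) > 0}


@dataclass
class SimConfig:
    """Simulation parameters; defaults reproduce the study-like design."""

    n_genes: int = 5000
    genotypes: tuple[str, ...] = DEFAULT_GENOTYPES
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    n_replicates: int = 4
    class_counts: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_COUNTS))
    effect_log2fc: float = 2.0
    band_log2fc: float = 0.85
    baseline_mean_log_range: tuple[float, float] = (2.0, 9.0)
    dispersion_params: tuple[float, float] = (0.01, 1.5)  # (a0, a1)
    size_factor_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 2023

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ConfigError("n_genes must be non-negative")
        if self.n_replicates < 1:
            raise ConfigError("n_replicates must be a positive integer")
        if len(self.genotypes) < 1 or len(self.conditions) < 1:
            raise ConfigError("need at least one genotype and one condition")
        total = sum(self.class_counts.values())
        if any(v < 0 for v in self.class_counts.values()):
            raise ConfigError("class counts must be non-negative")
        if total > self.n_genes:
            raise ConfigError(
                f"class_counts sum to {total} > n_genes={self.n_genes}")
        if self.effect_log2fc < 1.0:
            raise ConfigError(
                "effect_log2fc must be >= 1 (changed classes must clear the "
                "twofold threshold)")
        if not 0.7 <= self.band_log2fc < 1.0:
            raise ConfigError("band_log2fc must lie in [0.7, 1.0)")
        a0, a1 = self.dispersion_params
        if a0 <= 0 or a1 < 0:
            raise ConfigError("dispersion trend needs a0 > 0 and a1 >= 0")
        lo, hi = self.baseline_mean_log_range
        if not lo < hi:
            raise ConfigError("baseline_mean_log_range must be increasing")
        lo, hi = self.size_factor_range
        if not 0 < lo <= hi:
            raise ConfigError("size_factor_range must be positive")
        for label in self.class_counts:
            _parse_class(label, self)  # raises ConfigError on bad labels

    @property
    def mutants(self) -> tuple[str, ...]:
        return tuple(g for g in self.genotypes if g != self.control)

    @property
    def control(self) -> str:
        return self.genotypes[0]

    @property
    def unstressed(self) -> str:
        return self.conditions[0]

    @property
    def stresses(self) -> tuple[str, ...]:
        return tuple(c for c in self.conditions if c != self.unstressed)


def _parse_class(label: str, config: SimConfig) -> tuple[str, tuple[str, ...]]:
    parts = label.split(":")
    head, args = parts[0], tuple(parts[1:])
    known = {
        "null": 0,
        "baseline_dgc_dependent_up": 0,
        "baseline_dgc_dependent_down": 0,
        "dgc_dependent_response": 1,
        "dgc_prevented_response": 1,
        "dgc_independent_response": 1,
        "stress_specific": 2,
        "cross_stress_opposite": 0,
        "band": 0,
    }
    if head not in known or len(args) != known[head]:
        raise ConfigError(f"unknown planted class label {label!r}")
    if known[head] >= 1 and args[0] not in config.stresses:
        raise ConfigError(f"class {label!r} names unknown stress {args[0]!r}")
    if head == "stress_specific" and args[1] not in ("up", "down"):
        raise ConfigError(f"class {label!r} direction must be up or down")
    if head == "cross_stress_opposite" and len(config.stresses) < 2:
        raise ConfigError("cross_stress_opposite needs two stress conditions")
    return head, args


def _planted_effects(label: str, config: SimConfig, rng: np.random.Generator):
    """(genotype main effects, (genotype, condition) response effects)."""
    head, args = _parse_class(label, config)
    e = config.effect_log2fc
    main: dict[str, float] = {}
    resp: dict[tuple[str, str], float] = {}
    if head in ("baseline_dgc_dependent_up", "baseline_dgc_dependent_down"):
        sign = 1.0 if head.endswith("up") else -1.0
        for m in config.mutants:
            main[m] = sign * e
    elif head == "dgc_dependent_response":
        sign = rng.choice((-1.0, 1.0))
        resp[(config.control, args[0])] = sign * e
    elif head == "dgc_prevented_response":
        sign = rng.choice((-1.0, 1.0))
        for m in config.mutants:
            resp[(m, args[0])] = sign * e
    elif head == "dgc_independent_response":
        sign = rng.choice((-1.0, 1.0))
        for g in config.genotypes:
            resp[(g, args[0])] = sign * e
    elif head == "stress_specific":
        sign = 1.0 if args[1] == "up" else -1.0
        for g in config.genotypes:
            resp[(g, args[0])] = sign * e
    elif head == "cross_stress_opposite":
        temp, metab = config.stresses[0], config.stresses[1]
        for g in config.genotypes:
            resp[(g, temp)] = -e
            resp[(g, metab)] = e
    elif head == "band":
        sign = rng.choice((-1.0, 1.0))
        resp[(config.control, config.stresses[0] if config.stresses
              else config.unstressed)] = sign * config.band_log2fc
    return main, resp


@dataclass(frozen=True)
class SimTruth:
    """Planted class label per gene and true log2FC per gene x contrast."""

    classes: pd.Series           # gene -> class label
    true_log2fc: pd.DataFrame    # genes x contrast labels

    def genes_of_class(self, label: str) -> list[str]:
        return list(self.classes.index[self.classes == label])

    def truth_changed(self, contrast_label: str,
                      threshold: float = 1.0) -> set[str]:
        lfc = self.true_log2fc[contrast_label]
        return set(lfc.index[lfc.abs() >= threshold])

    def truth_unchanged(self, contrast_label: str,
                        threshold: float = 0.7) -> set[str]:
        lfc = self.true_log2fc[contrast_label]
        return set(lfc.index[lfc.abs() < threshold])


def _gene_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(1, index)))


def simulate_counts(config: SimConfig) -> tuple[CountMatrix, StudyDesign,
                                                SimTruth]:
    """Draw NB counts for the configured design; deterministic given seed."""
    # samples and size factors
    rows = []
    for genotype in config.genotypes:
        for condition in config.conditions:
            for r in range(1, config.n_replicates + 1):
                rows.append((f"{genotype}_{condition}_r{r}", genotype,
                             condition, r))
    design = StudyDesign(pd.DataFrame(
        rows, columns=["sample_id", "genotype", "condition", "replicate"]))
    n_samples = len(rows)

    sf_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(0,)))
    lo, hi = config.size_factor_range
    log_s = sf_rng.uniform(np.log(lo), np.log(hi), size=n_samples)
    log_s -= log_s.mean()  # geometric mean 1, identifiable vs median-of-ratios
    size_factors = np.exp(log_s)

    # class label per gene: planted classes first (config order), rest null
    labels: list[str] = []
    for label, count in config.class_counts.items():
        labels.extend([label] * count)
    labels.extend(["null"] * (config.n_genes - len(labels)))
    gene_ids = [f"g{i:05d}" for i in range(config.n_genes)]

    sample_genotype = np.array([r[1] for r in rows])
    sample_condition = np.array([r[2] for r in rows])
    contrasts = auto_contrasts(design, control=config.control,
                               unstressed=config.unstressed)
    contrast_labels = [c.label for c in contrasts]

    a0, a1 = config.dispersion_params
    mlo, mhi = config.baseline_mean_log_range
    counts = np.zeros((config.n_genes, n_samples), dtype=np.int64)
    truth_lfc = np.zeros((config.n_genes, len(contrasts)))

    for i, label in enumerate(labels):
        rng = _gene_rng(config.seed, i)
        q = np.exp(rng.uniform(mlo, mhi))
        main, resp = _planted_effects(label, config, rng)
        exponent = np.array([
            main.get(g, 0.0) + resp.get((g, c), 0.0)
            for g, c in zip(sample_genotype, sample_condition)
        ])
        mu = size_factors * q * np.exp2(exponent)
        alpha = a0 + a1 / q
        counts[i] = rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu))
        for k, con in enumerate(contrasts):
            truth_lfc[i, k] = _true_lfc(con, main, resp)

    matrix = CountMatrix(pd.DataFrame(
        counts, index=pd.Index(gene_ids, name=GENE_ID),
        columns=[r[0] for r in rows]))
    truth = SimTruth(
        classes=pd.Series(labels, index=matrix.counts.index, name="class"),
        true_log2fc=pd.DataFrame(truth_lfc, index=matrix.counts.index,
                                 columns=contrast_labels),
    )
    return matrix, design, truth


def _true_lfc(contrast: Contrast, main: dict[str, float],
              resp: dict[tuple[str, str], float]) -> float:
    if contrast.kind == "stress":
        return resp.get((contrast.genotype, contrast.condition), 0.0) \
            - resp.get((contrast.genotype, contrast.reference), 0.0)
    # mutant vs control within a condition
    return (main.get(contrast.genotype, 0.0)
            + resp.get((contrast.genotype, contrast.condition), 0.0)
            - main.get(contrast.reference, 0.0)
            - resp.get((contrast.reference, contrast.condition), 0.0))


# ---------------------------------------------------------------------------
# truth-derived evaluation sets
# ---------------------------------------------------------------------------
# Recovery is scored against genes whose *planted effects* satisfy a class
# definition (under the truth thresholds changed >= 1.0, unchanged < 0.7),
# not against raw labels: planted classes overlap in observable signature
# (e.g. a stress_specific gene satisfies the dgc_independent definition).

def truth_stress_response_sets(truth: SimTruth, stress: str, *,
                               control: str = "control",
                               mutants: tuple[str, ...] = DEFAULT_GENOTYPES[1:],
                               unstressed: str = "unstressed",
                               changed: float = 1.0,
                               unchanged: float = 0.7) -> dict[str, set[str]]:
    """True DGC-dependent / -prevented / -independent sets for one stress."""
    ctrl = f"{control}:{stress}_vs_{unstressed}"
    ctrl_changed = truth.truth_changed(ctrl, changed)
    ctrl_unchanged = truth.truth_unchanged(ctrl, unchanged)
    mut_changed = [truth.truth_changed(f"{m}:{stress}_vs_{unstressed}", changed)
                   for m in mutants]
    mut_unchanged = [
        truth.truth_unchanged(f"{m}:{stress}_vs_{unstressed}", unchanged)
        for m in mutants]
    all_changed = set.intersection(*mut_changed)
    all_unchanged = set.intersection(*mut_unchanged)
    return {
        "dgc_dependent_response": ctrl_changed & all_unchanged,
        "dgc_prevented_response": ctrl_unchanged & all_changed,
        "dgc_independent_response": ctrl_changed & all_changed,
    }


def truth_dysregulated_intersection(truth: SimTruth, *,
                                    mutants: tuple[str, ...],
                                    conditions: tuple[str, ...],
                                    control: str = "control",
                                    require_k: int | None = None,
                                    changed: float = 1.0) -> set[str]:
    """Genes truly dysregulated (union over conditions) in >= k mutants."""
    if require_k is None:
        require_k = len(mutants)
    per_mutant = []
    for m in mutants:
        union: set[str] = set()
        for c in conditions:
            union |= truth.truth_changed(f"{c}:{m}_vs_{control}", changed)
        per_mutant.append(union)
    genes = set().union(*per_mutant) if per_mutant else set()
    return {g for g in genes
            if sum(g in s for s in per_mutant) >= require_k}


def truth_cross_stress_opposite(truth: SimTruth, *,
                                control: str = "control",
                                stresses: tuple[str, str] = ("temperature",
                                                             "metabolic"),
                                unstressed: str = "unstressed",
                                changed: float = 1.0) -> set[str]:
    """Genes truly changed in opposite directions under the two stresses
    (control genotype)."""
    a = truth.true_log2fc[f"{control}:{stresses[0]}_vs_{unstressed}"]
    b = truth.true_log2fc[f"{control}:{stresses[1]}_vs_{unstressed}"]
    mask = (a.abs() >= changed) & (b.abs() >= changed) & (a * b < 0)
    return set(a.index[mask])


# ---------------------------------------------------------------------------
# synthetic annotation & truth I/O
# ---------------------------------------------------------------------------

#: Functional categories (with rough frequencies) used by the synthetic
#: annotation; loosely shaped like a whole-fly functional census.
ANNOTATION_CATEGORIES: tuple[tuple[str, float], ...] = (
    ("Metabolic processes", 0.25),
    ("Proteolysis", 0.12),
    ("Mitochondria-associated", 0.07),
    ("Transcription regulation", 0.05),
    ("Reproduction", 0.05),
    ("Immune response", 0.05),
    ("Transport", 0.08),
    ("Signaling", 0.08),
    ("Cytoskeleton", 0.05),
    ("Chaperones", 0.04),
    ("Other", 0.16),
)


def simulate_annotation(gene_ids, seed: int, *,
                        frac_annotated: float = 0.7) -> pd.Series:
    """Synthetic gene -> category table; a fraction of genes stay unannotated."""
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(2,)))
    names = [c for c, _ in ANNOTATION_CATEGORIES]
    probs = np.array([p for _, p in ANNOTATION_CATEGORIES])
    probs = probs / probs.sum()
    annotated = [g for g in gene_ids if rng.random() < frac_annotated]
    cats = rng.choice(names, size=len(annotated), p=probs)
    return pd.Series(cats, index=pd.Index(annotated, name=GENE_ID),
                     name="category")


def write_truth(truth: SimTruth, path: str | Path) -> None:
    """One row per gene x contrast, plus the class column."""
    long = truth.true_log2fc.stack().rename("true_log2fc").reset_index()
    long.columns = [GENE_ID, "contrast", "true_log2fc"]
    long["class"] = truth.classes.reindex(long[GENE_ID]).to_numpy()
    long.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_truth(path: str | Path) -> SimTruth:
    # keep_default_na=False: the class label "null" must stay a string
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[],
                     dtype={"true_log2fc": float})
    for col in (GENE_ID, "contrast", "true_log2fc", "class"):
        if col not in df.columns:
            raise FormatError(f"{path}: truth table needs column {col!r}")
    wide = df.pivot(index=GENE_ID, columns="contrast", values="true_log2fc")
    classes = df.drop_duplicates(GENE_ID).set_index(GENE_ID)["class"]
    # restore original gene order
    order = df[GENE_ID].drop_duplicates()
    return SimTruth(classes=classes.reindex(order),
                    true_log2fc=wide.reindex(order))
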