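"""End-to-end orchestration: counts -> normalization -> dispersions ->
composite-null Wald tests -> tri-state calls -> set intersections and
stress-response classes -> summary report.

The pipeline is deterministic given its inputs; artifacts are written with
fixed float formatting and no timestamps, so re-running a config reproduces
every file byte-identically. A machine-readable ``manifest.json`` lists the
artifacts with SHA-256 digests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import classify, counts_io, dge, report
from .classify import ThresholdPolicy
from .errors import ConfigError, DGCStressError

log = logging.getLogger("dgcstress")


@dataclass
class RunConfig:
    """Paths, thresholds and options for one pipeline run."""

    counts: Path
    design: Path
    outdir: Path
    annotation: Path | None = None
    changed_log2fc: float = 1.0
    unchanged_log2fc: float = 0.7
    alpha: float = 0.1
    p_mode: str = "adjusted"
    contrasts: str | list[str] = "auto"
    require_k: int | None = None          # default: all mutants
    baseline_scope: str = "union"
    control: str = "control"
    unstressed: str = "unstressed"
    shrinkage_weight: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.counts = Path(self.counts)
        self.design = Path(self.design)
        self.outdir = Path(self.outdir)
        if self.annotation is not None:
            self.annotation = Path(self.annotation)
        try:
            self.policy  # validates thresholds/alpha/p_mode
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc
        if self.baseline_scope not in ("union", "unstressed_only"):
            raise ConfigError(
                f"baseline_scope must be 'union' or 'unstressed_only', "
                f"got {self.baseline_scope!r}")
        if not 0.0 <= self.shrinkage_weight <= 1.0:
            raise ConfigError("shrinkage_weight must be in [0, 1]")

    @property
    def policy(self) -> ThresholdPolicy:
        return ThresholdPolicy(
            changed_log2fc=self.changed_log2fc,
            unchanged_log2fc=self.unchanged_log2fc,
            alpha=self.alpha, p_mode=self.p_mode)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: run config must be a mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config key(s) {sorted(unknown)}")
        for required in ("counts", "design", "outdir"):
            if required not in raw:
                raise ConfigError(f"{path}: missing required key {required!r}")
        return cls(**raw)


@dataclass
class RunResult:
    """In-memory view of the artifacts, for tests and the CLI alike."""

    size_factors: pd.Series
    dispersions: dge.DispersionFit
    de_results: dict[str, dge.DEResult]
    calls: dict[str, pd.DataFrame]
    dysregulation: classify.DysregulationResult | None
    concordance: classify.Concordance | None
    classes: dict[str, pd.Series] = field(default_factory=dict)
    overlap: classify.OverlapResult | None = None
    summary_lines: list[str] = field(default_factory=list)
    n_dropped_undetected: int = 0


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute every stage and write artifacts under ``config.outdir``."""
    out = config.outdir
    out.mkdir(parents=True, exist_ok=True)
    policy = config.policy
    summary: list[str] = []

    def stage(name: str):
        log.info("stage: %s", name)

    # --- load & filter -----------------------------------------------------
    stage("load")
    try:
        matrix = counts_io.read_counts(config.counts)
        design = counts_io.read_design(config.design)
        design.validate_against(matrix)
    except DGCStressError as exc:
        raise DGCStressError(f"[load] {exc}") from exc
    annotation = None
    if config.annotation is not None:
        annotation = counts_io.read_annotation(config.annotation)

    n_before = matrix.n_genes
    matrix = counts_io.filter_detected(matrix)
    n_dropped = n_before - matrix.n_genes
    summary.append(f"detected genes (>=1 count): {matrix.n_genes} "
                   f"({n_dropped} all-zero genes dropped)")

    # --- normalization -----------------------------------------------------
    stage("size_factors")
    try:
        size_factors = dge.estimate_size_factors(matrix)
    except DGCStressError as exc:
        raise DGCStressError(f"[size_factors] {exc}") from exc
    size_factors.to_csv(out / "size_factors.tsv", sep="\t",
                        index_label="sample_id", float_format="%.6g")

    # --- dispersions -------------------------------------------------------
    stage("dispersions")
    try:
        dispersions = dge.estimate_dispersions(
            matrix, design, size_factors,
            shrinkage_weight=config.shrinkage_weight)
    except DGCStressError as exc:
        raise DGCStressError(f"[dispersions] {exc}") from exc
    disp_table = pd.DataFrame({
        "genewise": dispersions.genewise,
        "trend": dispersions.trend,
        "final": dispersions.final,
    })
    disp_table.to_csv(out / "dispersions.tsv", sep="\t",
                      index_label=counts_io.GENE_ID, float_format="%.6g")
    a0, a1 = dispersions.coefficients
    summary.append(f"dispersion trend: alpha(mu) = {a1:.4g}/mu + {a0:.4g}")

    # --- contrasts & tests -------------------------------------------------
    stage("wald_tests")
    if config.contrasts == "auto":
        contrasts = dge.auto_contrasts(design, control=config.control,
                                       unstressed=config.unstressed)
    else:
        contrasts = [dge.parse_contrast(lbl, design)
                     for lbl in config.contrasts]
    de_dir = out / "de"
    de_dir.mkdir(exist_ok=True)
    de_results: dict[str, dge.DEResult] = {}
    n_fallback = 0
    for contrast in contrasts:
        try:
            res = dge.wald_test(matrix, design, size_factors, dispersions,
                                contrast,
                                lfc_threshold=policy.changed_log2fc)
        except DGCStressError as exc:
            raise DGCStressError(f"[wald_tests] {contrast.label}: {exc}") \
                from exc
        de_results[contrast.label] = res
        res.write(de_dir / f"{contrast.label}.tsv")
        n_fallback += int((res.table["flag"] == dge.FLAG_FALLBACK).sum()
                          + (res.table["flag"] == dge.FLAG_ZERO_GROUP).sum())
    summary.append(f"contrasts tested: {len(contrasts)}")
    summary.append(f"fallback-estimated gene x contrast entries: {n_fallback}")

    # --- tri-state calls ---------------------------------------------------
    stage("calls")
    calls_dir = out / "calls"
    calls_dir.mkdir(exist_ok=True)
    calls: dict[str, pd.DataFrame] = {}
    for label, res in de_results.items():
        c = classify.call_tristate(res, policy)
        calls[label] = c
        c.to_csv(calls_dir / f"{label}.tsv", sep="\t",
                 index_label=counts_io.GENE_ID, float_format="%.6g")
    summary.append(f"policy: changed >= {report.threshold_fc(policy.changed_log2fc):.2f}-fold "
                   f"(log2 {policy.changed_log2fc:g}), unchanged < "
                   f"{report.threshold_fc(policy.unchanged_log2fc):.2f}-fold "
                   f"(log2 {policy.unchanged_log2fc:g}), "
                   f"{policy.p_mode} p < {policy.alpha:g}")

    # --- baseline dysregulation across mutants -----------------------------
    stage("dysregulated_sets")
    mutants = [g for g in design.genotypes if g != config.control]
    dys = None
    concordance = None
    if mutants:
        mutant_baseline = {
            m: {c: calls[dge.genotype_contrast(m, c, config.control).label]
                for c in design.conditions}
            for m in mutants
        }
        require_k = config.require_k or len(mutants)
        dys = classify.mutant_dysregulated_sets(
            mutant_baseline, require_k, scope=config.baseline_scope,
            unstressed=config.unstressed)
        dys.membership.to_csv(out / "dysregulated_membership.tsv", sep="\t")
        for m in mutants:
            summary.append(
                f"dysregulated in {m} ({config.baseline_scope} scope): "
                f"{len(dys.per_mutant[m])}")
        summary.append(
            f"dysregulated in >= {require_k} of {len(mutants)} mutants: "
            f"{len(dys.selected)}")
        if dys.selected:
            concordance = classify.direction_concordance(
                dys.selected, dys.directions)
            summary.append(
                f"direction concordance in the intersection: "
                f"{concordance.n_same} of {concordance.n_total} "
                f"({concordance.percent}%)")

    # --- stress-response classes -------------------------------------------
    stage("stress_response_classes")
    classes: dict[str, pd.Series] = {}
    stresses = [c for c in design.conditions if c != config.unstressed]
    for stress in stresses:
        ctrl_label = dge.stress_contrast(config.control, stress,
                                         config.unstressed).label
        mut = {m: calls[dge.stress_contrast(m, stress, config.unstressed).label]
               for m in mutants}
        if not mut:
            continue
        cls = classify.stress_response_classes(calls[ctrl_label], mut)
        classes[stress] = cls
        cls.to_csv(out / f"classes_{stress}.tsv", sep="\t",
                   index_label=counts_io.GENE_ID)
        for name in (classify.DGC_DEPENDENT, classify.DGC_PREVENTED,
                     classify.DGC_INDEPENDENT):
            summary.append(f"{stress}: {name} genes: {(cls == name).sum()}")

    # --- cross-stress overlap (control genotype) ---------------------------
    overlap = None
    if len(stresses) >= 2:
        stage("cross_stress_overlap")
        t_label = dge.stress_contrast(config.control, stresses[0],
                                      config.unstressed).label
        m_label = dge.stress_contrast(config.control, stresses[1],
                                      config.unstressed).label
        overlap = classify.cross_stress_overlap(calls[t_label], calls[m_label])
        summary.append(
            f"control {stresses[0]}-changed: {overlap.n_temp}; "
            f"{stresses[1]}-changed: {overlap.n_metab}; combined total "
            f"{overlap.combined_total} (union {overlap.union_total}); shared "
            f"{overlap.n_both} ({overlap.overlap_percent}%)")
        pd.Series({k: len(v) for k, v in overlap.bins.items()}) \
            .rename("n_genes").to_csv(out / "cross_stress_bins.tsv", sep="\t",
                                      index_label="bin")

    # --- annotation breakdown ----------------------------------------------
    if annotation is not None and overlap is not None:
        stage("category_breakdown")
        for stress, label in ((stresses[0], t_label), (stresses[1], m_label)):
            genes = classify.changed_set(calls[label])
            annotated = [g for g in genes if g in annotation.index]
            if annotated:
                bd = report.category_breakdown(genes, annotation)
                bd.to_csv(out / f"categories_{stress}.tsv", sep="\t",
                          index=False)

    # --- summary & manifest ------------------------------------------------
    stage("summary")
    (out / "summary.txt").write_text("\n".join(summary) + "\n")
    artifacts = sorted(p for p in out.rglob("*")
                       if p.is_file() and p.name != "manifest.json")
    manifest = {
        # outdir is omitted: the manifest describes the directory it sits in
        "config": {k: str(v) if isinstance(v, Path) else v
                   for k, v in vars(config).items() if k != "outdir"},
        "artifacts": {str(p.relative_to(out)): _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return RunResult(size_factors=size_factors, dispersions=dispersions,
                     de_results=de_results, calls=calls, dysregulation=dys,
                     concordance=concordance, classes=classes,
                     overlap=overlap, summary_lines=summary,
                     n_dropped_undetected=n_dropped)
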