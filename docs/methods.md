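# Methods

## Model

Counts $K_{gj}$ for gene $g$ in sample $j$ are modeled as negative binomial
with mean $\mu_{gj} = s_j q_{gj}$ and variance $\mu + \alpha_g \mu^2$, where
$s_j$ is a per-sample size factor, $q_{gj}$ depends only on the sample's
(genotype, condition) cell, and $\alpha_g$ is the gene's overdispersion.
Every comparison is a two-group contrast: stress vs unstressed within one
genotype, or mutant vs control within one condition. This deliberately
avoids a multi-factor model — the downstream classification logic consumes
one (log2FC, SE, p) triple per gene per contrast, and a saturated two-group
fit answers exactly that question with no identifiability caveats.

### Size factors

Median-of-ratios: reference genes are those with a nonzero count in every
sample, and $s_j$ is the median over reference genes of
$K_{gj}/(\prod_{j'} K_{gj'})^{1/m}$. The median is computed in log space,
which matches the reference implementation bit-for-bit (the choice only
matters when an even reference count makes the median interpolate). Genes
with zero total count are removed before normalization — their ratios are
undefined — and reported as dropped.

### Dispersions

Per gene, a method-of-moments estimate pooled across design cells:
$\hat\alpha_g = \max\!\big(0, \sum_c (n_c{-}1)(v_c - m_c) \,/\, \sum_c
(n_c{-}1) m_c^2\big)$ with $m_c, v_c$ the within-cell mean and variance of
normalized counts. Pooling within cells keeps planted or real effects out
of the variance. The mean-dispersion trend $\alpha(\mu) = a_1/\mu + a_0$ is
fitted by gamma-weighted iteratively reweighted least squares (weights
$1/\mathrm{trend}^2$, genes whose ratio to the current trend leaves
$[10^{-4}, 15]$ excluded, coefficients clamped non-negative) — the usual
parametric-trend recipe for count data. The final dispersion is a fixed
50/50 geometric combination, $\log\alpha^{final} = \tfrac12\log\hat\alpha +
\tfrac12\log\alpha^{trend}$, clamped to $[10^{-8}, 10]$; the weight is
configurable. Zero-variance genes floor the gene-wise term at $10^{-8}$ and
land near the trend-shrunk floor. A full MAP treatment (posterior widths,
outlier flagging) is intentionally out of scope; parameter-recovery tests
show the trend coefficients are recovered within a few percent at 100
replicates and the shrunk values support calibrated SEs at n = 4 (the sd of
(estimate − truth)/SE is ≈ 1.03 on the default simulation).

### Composite-null Wald test

Each group's log mean is fitted by Newton/IRLS with the size factors as
offsets (the saturated two-group design decouples the groups); convergence
is declared when the NB deviance changes by < 1e-8, with a 50-iteration
cap. $SE(\log_2 FC) = \sqrt{1/W_1 + 1/W_2}/\ln 2$ from the Fisher
information $W_k = \sum_{j \in k} \mu_j/(1 + \alpha\mu_j)$. The twofold
test uses $W = \max(0, |\log_2 FC| - \theta)/SE$, $\theta = 1$, and
$p = \min(1, 2\bar\Phi(W))$; estimates inside the null interval get p = 1
by construction. This composite null is conservative by design: at the
boundary (true |log2FC| = 1, n = 10 per group) the measured rejection rate
at p < 0.1 is ≈ 0.05. Calibration simulations keep a majority of null
genes in the matrix — median-of-ratios normalization assumes most genes do
not change, and a matrix where every gene shifts makes the size factors
unstable.

Genes that do not converge, or with all-zero counts in exactly one group,
fall back to the +0.5-stabilized log-ratio of group mean normalized counts
with a moment-based SE, and are flagged — never silently dropped. Genes
all-zero in both groups are excluded from testing and carry an explicit
`not_tested` flag. Multiplicity is handled by Benjamini–Hochberg within
each contrast, never across contrasts, matching per-comparison results
tables; the adjustment itself is delegated to statsmodels and verified
against a brute-force step-up oracle in the tests.

## Decision thresholds

`ThresholdPolicy` holds the study's constants: CHANGED requires
|log2FC| ≥ 1 (twofold) **and** a p-gate (default: BH-adjusted p < 0.1,
switchable to raw p — the underlying filter convention is genuinely
ambiguous, so both are first-class); UNCHANGED requires |log2FC| < 0.7
(1.62-fold) and consults no p-value, because the no-change rule is an
effect-size statement; everything else — including the band
0.7 ≤ |log2FC| < 1 and large effects failing the p-gate — is
INDETERMINATE. A noisy large effect is deliberately *not* "no change".

For the baseline analysis ("dysregulated in a mutant irrespective of
stress") the default scope is the union over conditions of the
mutant-vs-control calls, with an `unstressed_only` switch; the per-gene
direction comes from the unstressed contrast when CHANGED there, otherwise
from the condition with the largest |log2FC| (a deterministic tie-break).

## The synthetic cohort

The generator emulates the study design: 5 genotypes (control + Dg, Dys,
Syn1, Nos loss-of-function) x 3 conditions (unstressed, temperature,
metabolic) x 4 replicates, 5,000 genes. Effects are additive in log2 space
across a genotype main effect and a genotype x condition response effect,
so one gene can be both baseline-DGC-dependent and stress-responsive.
Planted classes (30–50 genes per measured class) cover baseline
DGC-dependent genes, the three response classes per stress,
direction-specific stress-only genes (shaped like the empirical asymmetry:
temperature mostly down, metabolic mostly up), opposite-direction
cross-stress genes, and "band" genes planted at |log2FC| = 0.85 inside the
indeterminacy band.

Parameter defaults, chosen once:

| parameter | default | why |
|---|---|---|
| effect size | ±2 log2 units | comfortably beyond the twofold gate |
| band magnitude | 0.85 | midpoint of the 0.7–1.0 band |
| baseline means | log-uniform $e^2$–$e^9$ | spans weak to strong expressors |
| dispersion trend | $\alpha(\mu) = 0.01 + 1.5/\mu$ | pooling ~10 flies per library averages biological variation, so a low asymptotic dispersion is realistic for this design |
| size factors | log-uniform 0.5–2, geometric mean 1 | identifiable against median-of-ratios |
| replicates | 4 per cell | typical bulk RNA-seq replication |

Randomness discipline: one root seed; every gene draws from a substream
keyed by (seed, gene index), so enlarging the gene set never perturbs
existing genes; size factors and the synthetic annotation use separate
substreams.

What the generator does *not* emulate: GC/length bias, batch effects,
correlated genes, read-level error, outlier samples, or genes whose effect
sizes vary across mutants. Passing recovery tests therefore demonstrate
that the estimator and classifier logic are correct under the assumed NB
model — not that the pipeline is robust to real-data artifacts outside it.

### Scoring recovery against truth

Recall/precision are computed against *truth-derived* sets: a gene belongs
to a class's truth set when its planted log2FCs satisfy the class
definition (thresholds 1.0/0.7 applied to the noiseless truth), regardless
of the label that planted it. This matters because planted classes overlap
in observable signature — a stress-specific gene with effects in every
genotype genuinely satisfies the DGC-independent definition, and
dependent/prevented response genes genuinely appear in the within-condition
mutant-vs-control contrasts, hence in the union-scope baseline
intersection.

### Power limits at this design size

Two properties of the decision rules bound what recovery can achieve at
n = 4 replicates, independent of implementation quality:

* Classes requiring CHANGED in all 4–5 genotypes multiply per-contrast
  power. The lowest expression quartile (baseline means ~7–50 counts) has
  per-contrast power ≈ 0.4 under the adjusted gate (SE ≈ 0.4 log2 units
  there), capping all-genotype recall at ≈ 0.70–0.82 even though estimates
  are unbiased and precision is ≈ 1.0. Only more replicates or a brighter
  expression floor would change this.
* UNCHANGED is a point-estimate rule, so a band gene at true
  |log2FC| = 0.85 with SE ≈ 0.1–0.25 drifts below 0.7 with probability
  ~5–25%; on the default simulation 6 of 40 band genes are called
  UNCHANGED (none CHANGED, thanks to the composite null). Guaranteeing
  zero such calls would require SE ≤ 0.05, i.e. ~50+ replicates, or an
  equivalence-test formulation of "no change" that the rule deliberately
  does not use.

The acceptance suite asserts the nominal recovery targets as stated and
documents these two gaps rather than relaxing the rules or brightening the
simulation.

## Numerical choices

* Rounding of reported percentages and fold changes is half-away-from-zero
  with an explicit decimals argument (0 or 1 for percentages, 2 for
  fold-change conversions); percentage strings are always recomputed from
  their counts.
* The "combined total" across two stresses follows the summed-set-sizes
  convention (genes changed under both stresses count twice); the plain
  union size is reported alongside.
* IRLS: Newton steps clipped to ±10, log-means clipped to ±50; deviance
  tolerance 1e-8 absolute, 50 iterations.
* Dispersions clamped to [1e-8, 10]; trend fitting needs ≥ 20 usable genes,
  otherwise it degenerates to a flat line at the mean gene-wise value.
* Empty gene sets raise an error wherever a percentage would be undefined —
  never a silent zero.
* The pipeline writes artifacts with fixed float formatting and no
  timestamps; identical inputs reproduce every artifact byte-identically.

## Known limitations

* No LFC shrinkage, no Cook's-style outlier handling, no independent
  filtering; results for very-low-count genes are noticeably noisier than a
  full MAP treatment would give.
* Two-group contrasts only — no interaction tests (a DGC x stress
  interaction must be read off the classification, not tested directly).
* The classifier's all-mutant requirements are strict conjunctions; a
  single indeterminate mutant leaves a gene unclassified rather than
  propagating uncertainty.
* Problem sizes in the test and acceptance runs (5,000 genes, 2,000-gene
  calibration sets) are chosen to keep the full suite fast while leaving
  Monte-Carlo error well below the asserted margins.
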