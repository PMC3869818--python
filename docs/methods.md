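# Methods

`netconverge` implements a four-stage analysis for asking whether two
complex diseases converge on a shared molecular network, and whether that
convergence can be cashed out as a blood biomarker. This note documents
the models, the parameter choices, what the synthetic data does and does
not emulate, and the numerical decisions.

## Network propagation model

The substrate is a weighted, undirected functional linkage network (FLN):
nodes are genes, edge weights are positive functional-association
likelihoods. Disease proximity is scored by a random walk with restart
(RWR). With `W` the column-stochastic step kernel (column *j* holds gene
*j*'s incident edge weights divided by its weighted degree) and `p0` the
uniform distribution over the seed genes, the walk iterates

    p  <-  (1 - alpha) * W p + alpha * p0

to its fixed point. `alpha` is the restart probability; the default is
0.5, i.e. each step is an even coin flip between diffusing along the
network and returning to the seed set. The fixed point is a probability
distribution over all genes, so scores are comparable across runs on the
same network.

Choices that the propagation model leaves open, and how they are resolved
here:

- **Normalization.** The step kernel is column-stochastic by weighted
  degree: a walker picks an incident edge with probability proportional to
  its weight. Symmetric (degree-half) normalizations exist in the
  propagation literature; the weight-proportional form is the one that
  matches "step to a random immediate neighbor" kinetics with weights as
  propensities.
- **Dangling genes.** Isolated genes have a zero column in `W`; their step
  mass is redirected to `p0` (teleport). This keeps the iterate a
  probability vector at every step, which the tests exploit (conservation
  is asserted to `10 x tolerance`).
- **Iteration.** Starts at `p = p0`; converges when the L1 change drops
  below `tolerance` (default 1e-10, maximum 10,000 iterations).
  Non-convergence raises an error carrying the last iterate.
- **Oracle.** `rwr_closed_form` solves `(I - (1-alpha) W_eff) p = alpha p0`
  densely (with the same teleport rule folded into `W_eff`). For
  `alpha > 0` the system is nonsingular. The iterative and direct routes
  agree to < 1e-8 on randomized graphs; they are kept as two genuinely
  independent code paths.
- **Candidate universe.** The ranked output is restricted to non-seed
  genes at topological distance 1 from the seed set. Seeds themselves are
  excluded from the candidate ranking — prioritizing an already-confirmed
  gene is uninformative — but retained in the full audit table.
- **Ties.** Ranks are descending by score with lexicographic tie-break on
  the gene identifier, so rankings are bit-for-bit reproducible.

## Cross-disease convergence

Each disease contributes a candidate set (its seeds' first neighborhood);
the shared neighborhood is their exact set intersection, reported as a
three-part Venn decomposition over candidates only (training genes are
excluded from all three parts). The shared genes are ranked by a walk
seeded with the union of both training sets (default), because a single
combined ranking is the natural presentation when one list serves both
diseases; a symmetric "mean of per-disease scores" mode is retained for
sensitivity analysis and is invariant under swapping the diseases. No
score threshold is applied before intersecting.

## Expression signature

Per study, each gene is tested by a two-sample *t*-test between a case
group and the control group. The pooled-variance (Student) form is the
default, with `n1 + n2 - 2` degrees of freedom and two-tailed p-values;
Welch is available behind a flag. The log2 fold change is the difference
of group means, matrices being assumed log2-transformed and normalized
already (preprocessing of raw intensity files is out of scope). Genes
that are constant and equal across both groups get `t = 0, p = 1`;
zero-variance genes with distinct means get `p = 0`.

Multiple testing is controlled per comparison by Benjamini–Hochberg at
FDR 0.05: `q_(i) = min_{j>=i} m p_(j) / j` capped at 1, rejecting at
`q <= 0.05`. BH is applied within each comparison table, not globally —
each study stands on its own, as when re-analyzing independent public
series. The cross-study signature is the intersection of the per-study
significant sets, each gene annotated up/down per study by the sign of its
fold change; `concordant_up` is the subset up-regulated everywhere, the
pattern expected of a blood biomarker shared across diseases.

A deliberate consequence of FDR-based membership: with 10 samples per
group and a log2 effect of 2 against unit noise, a single comparison
detects a planted gene with raw-p power ~0.98, but BH membership power
depends on the composition of the study (roughly 0.85–0.9 when ~6% of
genes are truly shifted), so membership in *all* of four comparisons
holds only ~2/3 of the time per gene. Multi-study intersections are
therefore small and seed-sensitive — which mirrors how fragile such
intersections are on real cohorts, and is why the end-to-end checks run at
the preset's documented seed.

## Biomarker evaluation

Relative quantification follows the ddCt workflow: per sample,
`dCt = Ct(target) - Ct(reference)`; `ddCt = dCt - mean(dCt | calibrator)`
with healthy controls as calibrator; `fold change = 2^(-ddCt)`. Two group
estimates are reported:

- the arithmetic mean ± SEM of per-sample fold changes (the conventional
  presentation); and
- `2^(-mean ddCt)`, the group-level estimator, which is unbiased on the
  log scale. Per-sample fold changes are log-normal, so their arithmetic
  mean overshoots the true ratio by `exp((sigma ln 2)^2 / 2)` — about 27%
  at `sigma = 1`. Parameter-recovery checks therefore use the group-level
  estimator; the per-sample mean is reported alongside it.

Hypothesis testing is done on dCt values (the log scale), not on fold
changes, keeping errors symmetric on the tested scale. Covariate
screening uses Pearson correlation (binary covariates coded 0/1, i.e.
point-biserial), with missing pairs dropped per covariate and constants
reported as undefined. Covariate adjustment is OLS of dCt on a 0/1 group
indicator plus covariates; the group coefficient is the adjusted
case–control dCt difference. Rank-deficient designs are rejected naming
the collinear columns.

ROC analysis scores each sample by `-dCt` (higher = more transcript). The
AUC is the Mann–Whitney probability with ties worth 0.5 (verified against
brute-force pair counting); if cases score below controls the score is
negated and the flip recorded, so reported AUCs are ≥ 0.5. The 95% CI
uses the Hanley–McNeil standard error with normal quantiles, truncated to
[0, 1] — the CI construction is a choice; a stratified bootstrap
(`roc_bootstrap_ci`, 2000 seeded resamples) is available as an
alternative. The p-value is the two-sided normal test of AUC against 0.5.

## Synthetic data: what it emulates, and what it does not

All generators are deterministic under an integer seed, with child seeds
derived via `numpy` seed sequences.

**Network** (`simulate_fln`): a planted-partition graph, default 500 genes
with two 40-gene disease modules overlapping by 20. Within-module pairs
connect with probability 0.3 and weights Uniform(0.5, 1.0); all other
pairs with probability 0.01 and weights Uniform(0.05, 0.2). The defaults
give each module gene ~12 strong intra-module edges against ~5 weak
background edges, enough scale heterogeneity to exercise weight-sensitive
propagation while keeping a full run in seconds. Training sets are 10
genes sampled per module; a designated biomarker gene in the overlap is
reserved from seed duty (a biomarker should be a *candidate*, not part of
the training signal).

**Expression** (`simulate_expression_study`): background values
Normal(0, 1) on the log2 scale; planted genes shifted by ±2 in their case
group. The preset builds one three-group study (HC/IFG/T2D, 10 per group)
and two case–control studies (HC/PD, 10 per group) over the network's
genes, planting 30 genes per study of which 5 are shared across all
studies: the reserved overlap gene up-regulated everywhere, and four
background genes with mixed or all-down directions, so the planted
concordant-up set is exactly the reserved gene.

**qPCR** (`simulate_qpcr_cohort`): control dCt ~ Normal(5, 1); cases
shifted by −log2(5) ≈ −2.32 (a true five-fold up-regulation); reference
Ct ~ Normal(20, 0.25²) independent of group, target Ct = reference + dCt.
Cohort sizes are 50/46 and 51/45 cases/controls, a realistic scale for
single-center biomarker cohorts. With these parameters the analytic AUC
is Φ(2.32/√2) ≈ 0.95. Covariates (age, sex, BMI, disease stage) are drawn
independently of group by default; a planted confounder — a covariate
both associated with the group and feeding into dCt — can be requested to
exercise the adjustment path.

Not emulated: microarray probe-level artifacts, normalization and batch
effects, heavy-tailed expression noise, PCR amplification-efficiency
variation, multi-reference-gene normalization, linkage disequilibrium or
any genetic architecture behind the seed lists, and scale-free global
topology (modules are planted in an Erdős–Rényi background). Passing
tests therefore demonstrate correctness of the statistics and the
pipeline's recovery behavior under idealized noise — not robustness to
real-data artifacts.

## Problem sizes

The test and acceptance workloads are sized to run comfortably on one
CPU: oracle comparisons use 100 random graphs of up to 50 nodes; FDR
calibration uses 200 fully-null studies of 1000 genes; the end-to-end
bundle is one 500-gene network plus three 500-gene expression studies and
two ~96-sample qPCR cohorts; parameter recovery averages 20 replicate
cohorts.

## Known limitations

- The candidate universe is hard-limited to distance ≤ 1 from the seeds;
  genes two steps away never enter the ranking regardless of score.
- BH-based signature membership is composition-dependent (see above);
  intersection sizes should be read as conservative.
- The Hanley–McNeil CI is asymptotic and can under-cover for AUCs near 1
  with small samples; use the bootstrap alternative there.
- Pearson screening captures linear covariate relationships only, and the
  OLS adjustment assumes homoscedastic additive effects on the dCt scale.
- Gene identifiers are opaque strings: no symbol/probe/ID mapping layer is
  provided, so inputs must share a namespace.
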