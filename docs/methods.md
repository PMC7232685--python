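# Methods

## The problem

In cancer genetics the phenotype of interest is often a right-censored
survival time rather than a case/control label, and single-SNP association
scans miss purely epistatic effects — pairs (or higher-order sets) of loci
whose joint genotype predicts survival while every marginal genotype
distribution is uninformative. `kmmdr` implements a
multifactor-dimensionality-reduction (MDR) search for such gene-gene
interactions on survival phenotypes, with the Kaplan-Meier median survival
time as the cell classifier (KM-MDR), alongside three established
comparators.

## Classifiers

For q biallelic SNPs coded by minor-allele count, subjects fall into 3^q
multilocus genotype cells. Each classifier reduces the cells to a binary
high/low-risk attribute on a training sample:

* **KM-MDR.** Compute the overall KM median t_m (smallest t with
  Ŝ(t) ≤ 0.5). Cell j is high-risk iff its own KM median t_mj satisfies
  t_mj < t_m. If t_mj is not estimable (few events in the cell), the
  *complement rule* applies: pool all training subjects outside cell j; if
  that complement median is estimable and exceeds t_m, cell j — which must
  then be dragging the overall median down — is high-risk, otherwise
  low-risk. Empty cells are low-risk. If t_m itself is not estimable the
  method is not applicable and the caller receives
  `MethodNotApplicableError`.
* **Surv-MDR.** Cell j is high-risk iff the two-sample log-rank statistic
  comparing cell members against all other subjects is positive.
* **Cox-MDR.** Each subject gets the martingale residual
  status − Λ̂(t)·exp(zγ̂) from the genotype-free null Cox model (Breslow
  baseline; Nelson-Aalen when there are no covariates). Cell j is
  high-risk iff the sum of its members' residuals is positive.
* **AFT-MDR.** As Cox-MDR with scores −(log t − μ̂ − zγ̂)/σ̂ from a null
  log-normal accelerated-failure-time fit (censoring handled by maximum
  likelihood in the fit; the censored time itself enters the residual, as
  no imputation scheme is defined for this comparator).

Boundary conventions, chosen once: t_mj = t_m ties are low-risk (the
high-risk rule is strict); score sums exactly zero are low-risk; the median
rule uses "≤ 0.5" so a curve touching one half exactly defines the median
there; at tied times events precede censoring; log-rank event times with a
single subject at risk contribute zero variance.

## Scores and the search

The pooled high vs low groups are scored with the squared two-sample
log-rank statistic Z², with

    Z = Σ_i (d_1i − E_1i) / sqrt(Σ_i V_i),
    E_1i = d_i n_1i / n_i,
    V_i = (n_i − d_i) d_i n_1i n_2i / ((n_i − 1) n_i²).

(The standardized form is used throughout: only with the square root in the
denominator is Z² chi-square(1) under the null.) The residual-based
comparators are scored by balanced accuracy of the cell label against the
subject's score sign, the construction used in the generalized-MDR family;
when one pseudo-label class is absent, balanced accuracy degenerates to the
recall of the present class.

The engine enumerates all C(p, q) SNP subsets under k-fold cross-validation
(default k = 10, folds stratified by event status so every fold keeps the
sample's censoring fraction). Per fold, every subset is trained and scored
on the training split; the fold winner accrues cross-validation
consistency (CVC). Score ties are *not* broken lexicographically: with
sparse genotypes two subsets can induce the identical (or identically
degenerate) H/L partition and hence exactly equal scores, and a fixed
tie order would systematically favour the alphabetically first SNP pair —
empirically inflating its null selection rate above the uniform 1/C(p,2)
reference. Ties are instead broken in a random order seeded by the fold
assignment: reruns are bit-for-bit reproducible, but no SNP tuple is
favoured on average. Each subset's testing score is
a *single* statistic computed on the union of all held-out folds, each
labelled by its own training rule, so every subject contributes exactly
once. The reported training score is the across-fold mean. Best-model
selection ranks by testing score, then CVC, then parsimony (smaller q),
then lexicographic order; a configuration switch (`selection_order =
"cvc_first"`) swaps the first two criteria, since both orderings appear in
the MDR literature. A fold where the classifier is not applicable is marked
failed; a subset with more than half its folds failed is reported but
flagged `skipped` and never selected.

Degenerate statistics (empty high group, zero log-rank variance) score 0 in
the engine: a split carrying no evidence should not win a fold or a model
comparison.

Permutation p-values rerun the whole cross-validated search under B joint
permutations of the survival rows against the genotype rows (implemented by
permuting the genotype matrix, which realizes the same null while keeping
the status-stratified folds valid). The null statistic is the permutation's
*maximum* testing score over all subsets, so the p-value of the selected
model is family-wise calibrated; p = (1 + #{null ≥ observed})/(1 + B).

## Synthetic data

The generator reproduces the simulation design the method was characterized
under:

* **Genotypes.** n subjects × p SNPs, entries Binomial(2, MAF) — HWE at
  each locus, linkage equilibrium across loci. Defaults n = 400, p = 10
  (power) or p = 8 (null/type-I datasets).
* **Penetrance.** A 3×3 table f_ij = P(high risk | g1 = i, g2 = j) with
  *no marginal effects*: all HWE-weighted row and column means equal the
  prevalence K. Such tables form a 4-dimensional linear space; the
  generator draws a random direction there, scales it exactly to the target
  heritability h² = Σ p_i p_j (f_ij − K)² / (K(1−K)), and rejects draws
  leaving [0, 1]. The heritability grid {0.01, 0.025, 0.05, 0.1, 0.2,
  0.3, 0.4} × MAF {0.2, 0.4} with five seeds per cell yields the 70-model
  power design. The prevalence is not pinned down by the published design;
  the generator prefers K = 0.5 and falls back to the nearest feasible K
  when the box constraint binds (unavoidable at low MAF / high h², where
  rare cells must absorb multi-unit deviations).
* **Risk and survival.** x ~ Bernoulli(f) at the causal pair, then either
  a Cox model λ(t|x,z) = λ₀(t)exp(xβ + zγ) with Weibull baseline of shape
  a = 5 and scale b = 2 (survival exp(−(t/b)^a); latent time
  b·(−log U/exp(η))^{1/a}) and β = 1.2, or a log-normal AFT model
  log T = μ + xβ + zγ + σε with μ = 0, β = −1, σ = 1. The covariate z is
  N(0,1) with γ ∈ {0, 1}.
* **Censoring.** Uniform(0, c) censoring with c calibrated by bisection on
  one 10⁵-draw Monte-Carlo batch of latent times so the expected censored
  fraction hits the target in {0, 0.1, 0.3, 0.5} (a single fixed uniform
  law cannot produce all four fractions across scenarios; the calibrated
  bound is recorded with each dataset). Realized per-dataset fractions
  vary binomially around the target.

What the generator does **not** emulate: linkage disequilibrium, genotype
missingness, marginal main effects, competing risks, covariate-genotype
correlation, or non-lognormal AFT errors. Passing tests therefore
demonstrate correctness of the machinery under idealized HWE/LE sampling,
not robustness on real cohort data.

## Operating characteristics

Type-I error is the rate at which a designated pair (SNP1, SNP2) is chosen
as the best two-way model over null datasets (8 SNPs, no effect). Under
SNP exchangeability, any deterministic selection rule that is symmetric in
the pairs and always selects one — ours is — yields exactly 1/C(8,2) =
1/28 ≈ 0.0357 in expectation; empirical estimates below that reference
indicate conservatism from non-selection (search failures), which with the
KM classifier occurs only under censoring heavy enough to hide the overall
median. Power is the rate at which the causal pair is selected. All
methods are evaluated on identical datasets and identical folds (paired
design), so method contrasts are free of between-dataset noise. Per-cell
and per-dataset seeds derive from one master `SeedSequence`, making every
estimate bit-for-bit reproducible.

Monte-Carlo sizes used by the shipped checks — chosen as a compromise
between standard error and a single-workstation run: 300–1000 null
datasets per type-I cell on a 2×2 (MAF × censoring) subgrid (the
acceptance script uses 2000), 50 datasets per power scenario at three
heritabilities, 200 replicates at B = 99 for permutation calibration
(standard error of the rejection rate ≈ 0.015).

## Known limitations

* KM-MDR cannot adjust for covariates; with a real covariate effect the
  regression-based comparators are the appropriate tools.
* Under censoring heavy enough that the overall training median is not
  estimable, KM-MDR is undefined (the engine reports the failure rather
  than guessing).
* The exact 70 published penetrance tables are not public; the constrained
  generator reproduces their defining properties (zero marginals, target
  h², HWE weights), not their specific entries, so power levels are
  comparable in structure but not numerically identical to the published
  curves.
* The search is exhaustive; C(p, q) growth makes q ≥ 3 on large p
  expensive (the engine supports it; no shortcut search is provided).
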