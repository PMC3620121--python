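# Methods

This note documents the statistical procedures implemented in `stonegene`,
the defaults chosen where the underlying study left the design open, what
the synthetic-data generators do and do not emulate, and the package's
known limitations.

## Data model

Genotypes are coded 0/1/2 as the count of the manifest-designated
**variant** allele — never the observed minor allele, which can flip
between samples. Missing calls are excluded per SNP (pairwise deletion);
nothing is imputed. Case/control status is binary; optional covariates are
age (years) and sex.

Two text dialects are supported: PLINK-style PED/MAP (six leading columns,
two allele tokens per SNP, `0 0` missing, affection 2 = case) and a
tab-delimited 0/1/2/NA matrix with a separate manifest. Both round-trip
losslessly.

### Reconstruction from printed tables

`expand_counts` rebuilds an individual-level pseudo-cohort from per-SNP
2×3 genotype count tables. Each column is filled independently with a
fixed per-column permutation, so per-SNP marginals equal the input tables
exactly while the columns carry no systematic joint structure. This means
every statistic that depends only on per-SNP margins (allele counts,
crude ORs, trend tests, score *means*) is reproduced exactly, whereas any
joint quantity (score SD, MDR, CART, haplotypes) is only structurally
exercised, not reproduced.

Several published tables pool variant carriers into one row. For every
such SNP in the built-in panel the printed allele counts equal the pooled
carrier counts, which is only consistent with zero variant homozygotes;
the pooled count is therefore expanded as all heterozygotes by default
(`collapsed_mode="het"`), preserving the printed allele counts. The
alternative all-homozygote expansion is available for sensitivity checks.

## Single-locus statistics

* **HWE**: 1-df Pearson χ² against expectations from the sample allele
  frequency, and the exact conditional test (probabilities of heterozygote
  counts given the minor-allele count; two-sided by summing outcomes at
  most as probable as the observed one). Monomorphic SNPs return
  statistic 0, p = 1, flagged. Both tests are offered because the study's
  HWE method is not identifiable from the report, and the two disagree
  near the significance boundary for a couple of the reconstructed
  control tables.
* **Crude OR**: cross-product with Woolf log-normal 95% CI; the
  Haldane–Anscombe +0.5 correction is applied only when a cell is zero
  (flagged). A zero row/column raises instead of fabricating a value.
* **Adjusted OR**: maximum-likelihood logistic regression (statsmodels
  `Logit`) of status on the coded genotype term plus covariates, Wald CIs
  and p-values (the convention of the original analysis software).
  Non-convergence or separation is flagged; with complete separation a
  flagged infinite-OR result is returned rather than an arbitrary number.
* **Trend**: Cochran–Armitage 1-df χ² with scores 0,1,2 (configurable).
  On 2×2 tables it reduces exactly to the Pearson χ², which is how the
  published carrier-row "Ptrend" values arise.
* **Monte-Carlo trend p**: status labels are permuted over the pooled
  genotype vector (10,000 replicates by default; the study does not state
  its count) and `p = (1 + #{T* ≥ T}) / (reps + 1)`.

Report rounding follows the published style: two decimals for ORs/CIs,
three for p-values.

## Haplotypes and LD

EM over unphased 2–3 SNP genotypes: the E-step distributes each
individual's genotype over compatible diplotypes proportionally to
products of current haplotype frequencies, the M-step re-estimates
frequencies from expected gamete counts. Initialisation is the
deterministic product of observed allele frequencies; seeded Dirichlet
restarts are used only if that run fails to converge (tolerance 1e-8 on
the max frequency change, 500 iterations). The observed-data
log-likelihood is checked to be non-decreasing at every step.

LD is summarised from a pair's 4-vector of haplotype frequencies
(ordered ww, wv, vw, vv): `D = f(vv) − p1·p2` on the variant alleles,
`D′ = |D|/D_max` with the sign-dependent maximum, `r² = D²/(p1q1p2q2)`.

Haplotype association uses expected counts (2N × frequency) per group —
the convention of standard web tools for unphased data — with Woolf CIs
against the all-wild reference haplotype and a global χ² over the full
count table. Haplotypes below 1% frequency in both groups are pooled as
"rare"; the study does not state its threshold, and 1% mirrors common
practice.

## Genotype score

Score = Σ per-SNP genotype code counting the risk allele. The default
preset counts the **variant** allele at all SNPs, exactly as the study
defines it, even where the variant is marginally protective (the PGR
insertion); a direction-aware preset (`direction="manifest"`) flips such
markers but is not the default. Individuals missing any scored genotype
are excluded and counted, not rescaled.

Group comparison is a Welch two-sample test. Per-level ORs come from a
logistic regression on score-level indicators with the control-median
level as reference (configurable); levels empty in either group are pooled
toward the reference and flagged. The per-allele OR is the exponentiated
coefficient of the score as an ordinal term.

`score_pmf_convolution` gives the exact score distribution under inter-SNP
independence by sequential convolution of the M three-point genotype
distributions; its mean equals the sum of per-SNP means analytically, and
the group mean score equals that sum for *any* cohort (LD-invariant), a
property the tests assert exactly.

## MDR

Cells of the k-locus genotype table are labelled on each training split:
high risk when the cell's case:control ratio is at least the split's
overall ratio (ties high — the standard convention), low below, unknown
when empty. Held-out individuals are classified by their cell label;
accuracy is **balanced** accuracy (the convention of MDR ≥ 2.0; the study
groups are near-balanced so the distinction is small), and individuals in
unknown-labelled cells are excluded from both numerator and denominator.
The alternative assign-low policy for empty cells is deliberately not the
default because it penalises sparse high-order models asymmetrically.

Cross-validation is stratified 10-fold with seeded shuffling (matching the
"x/10" consistency convention). For each order the search is exhaustive;
CVC of a combination is the number of folds in which it attains the best
training accuracy among all same-order combinations, and the reported
winner maximises fold-averaged testing accuracy (ties: higher CVC, then
lexicographic order). Permutation p-values re-run the same-order search on
label-shuffled data, 1,000 permutations by default.

The engine is vectorised across combinations (one `bincount` per fold and
group over offset cell indices), which keeps a 1,000-permutation search
over all 78 pairs of a 13-SNP panel in the seconds range.

## CART

Binary recursive partitioning on genotype *levels* (a 3-level SNP offers
the three splits isolating one level), maximising Gini impurity decrease.
Ties break by manifest order of the SNP, then by the partition isolating
the rarer level set, making growth deterministic. Defaults:
`min_parent = 20`, `min_child = 7`, `max_depth = 5`,
`min_gini_gain = 1e-4` — the original analysis software's settings are
unreported; these values are sized for a ~450-individual candidate-gene
cohort and are fully configurable. No pruning is applied by default (the
study reports a single grown tree). Individuals with a missing call at a
split SNP follow the right branch.

Terminal nodes are reported by ascending case rate; the size-weighted mean
of terminal case rates equals the root case rate exactly (asserted).
Node ORs come from one logistic regression on terminal-node indicators
with the lowest-case-rate node as reference, optionally adjusted for age
and sex; pure nodes (zero cases or controls) fall back to a
Haldane-corrected crude OR, flagged.

## Synthetic cohorts

`simulate_cohort` is **retrospective** (genotype | status), matching the
case-control sampling of the study design: each group's genotypes are
drawn per SNP from that group's frequency triple; SNPs are independent
except within declared LD blocks, where each individual's two haplotypes
are drawn from the block's four haplotype frequencies. Covariates are
drawn independently of genotype (no confounding) unless a confounded spec
is constructed explicitly. The built-in study spec uses the published
group sizes (230/220), the genotype frequencies implied by the printed
tables, haplotype frequencies derived from the published D′ values
(0.575 for the ESR1 pair, 0.8916 for the SLCO1B1 pair) with
positive variant-variant coupling, a 64% female fraction and group age
distributions of 48.6 ± 11.9 (cases) and 49.0 ± 9.8 (controls) years.

`simulate_epistasis` is **prospective**: population genotypes under HWE
and linkage equilibrium, disease status drawn from a full 3^k penetrance
table, sampling until the case/control quotas fill (bounded; an
unattainable quota raises). The balanced two-locus "XOR" constructor
(elevated risk exactly when one locus carries a variant) embeds a pure
interaction with bounded marginal effects and is the reference benchmark
for MDR/CART recovery. Recovery experiments use 400 + 400 individuals,
variant frequencies 0.3/0.3, penetrance 0.5 vs 0.05, and eight null
markers, with 20 seeded replicates.

What the generators do **not** emulate: population structure, genotyping
error, missingness patterns, covariate-genotype confounding, and any
joint structure of the real cohort beyond the declared LD pairs. Passing
recovery tests therefore demonstrate correctness of the machinery under
the stated sampling models, not field performance on real data.

## Numerical conventions and degenerate inputs

A single integer seed drives every stochastic operation through
`numpy.random.default_rng`; fixed seed ⇒ bit-identical cohorts and
permutation p-values. Trend statistics on tables concentrated in one
column return (0, 1, flagged). CI exponents are clipped at ±700 to avoid
overflow on quasi-separated nodes. Empirical p-values always use the
add-one form `(1 + k)/(n + 1)`, so they are never exactly zero.

## Limitations

* The study's individual-level data are not public. Joint-structure
  results (the specific MDR winners, the published tree, haplotype
  numerics, the observed score range/medians) are therefore *not*
  reproduction targets; the package validates that machinery on synthetic
  cohorts with known truth instead. Marginal statistics of the printed
  tables are reproduced exactly.
* Printed ORs are age/sex-adjusted; without the raw data only the
  genuinely crude ones (e.g. the SLCO1B1 Ex6+40 carrier OR, the ADRA2A
  GG-vs-CC OR) are exact targets. The crude ESR1 IVS1-397 TT-vs-CC OR is
  2.84 against the printed adjusted 2.98 — documented, not asserted equal.
* The published per-allele estimate for the score (2.7 with CI 1.12–1.16)
  is internally inconsistent (the estimate lies outside its own CI) and is
  not used as a target.
* Haplotype systems are limited to 2–3 SNPs; no per-individual phase
  output, no haplotype-covariate interactions, no >2-locus LD summaries.
* MDR implements the canonical algorithm only — no model-based or
  covariate-adjusted variants. CART has no surrogate splits or
  cost-complexity pruning.
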