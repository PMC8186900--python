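# Methods

## Cohort model

The unit of analysis is a targeted-panel case–control cohort: a samples ×
sites dosage matrix (0/1/2 alternate-allele counts, −1 missing) read from a
joint-genotyped multi-sample VCF, a per-variant functional annotation table
(gene, region, exonic consequence, ExAC frequency, PolyPhen2/SIFT scores,
MutationTaster prediction), and a phenotype table with a two-level
case/control factor plus case-only subgroup labels (e.g. atrial septal
defect). Conventions chosen where the upstream tools leave room:

- Half-called genotypes (`0/.`) are missing — conservative, affects only
  call-rate accounting. Phased separators are treated like unphased.
- Multi-allelic records are read as one site keyed by the first ALT; site QC
  removes records with > 2 alternate alleles anyway.
- An annotation row without a genotyped counterpart is kept but flagged
  orphan and never enters the burden analysis.

## Site QC

Four exclusion rules with defaults `max_alt_alleles=2`, `min_call_rate=0.90`,
`hwe_p=1e-7`, `diff_missing_p=1e-6`. Choices:

- **HWE** is the exact conditional (Levene–Haldane) test, not chi-square:
  at the sparse genotype counts a panel produces the exact test is the field
  standard and matches the 10⁻⁷ threshold's usage. It conditions on the
  minor-allele count regardless of ref/alt orientation; the p-value is the
  two-sided "sum of ≤-likely outcomes". Computed on controls only, where
  equilibrium is expected; cases may legitimately deviate.
- **Differential missingness** is a two-sided Fisher exact test on the
  missing/called × case/control table.
- **Call rate** is computed over all samples jointly, matching the single
  published threshold.
- The `>2 alternate alleles` rule is applied literally (triallelic records
  pass); a stricter `biallelic_only` flag is available because whether
  triallelic sites should be tested is genuinely ambiguous.

The exact tests are validated against independent brute-force enumeration
oracles (rational arithmetic, in `tests/oracles.py`): exhaustively for all
2×2 tables with N ≤ 30 and all genotype configurations with n ≤ 10, plus a
null-simulation check that the HWE test is conservative, never
anticonservative.

## Rare-damaging adjudication

Criteria are conjunctive: exonic (splicing included), non-synonymous,
ExAC MAF < 1 %, and damaging. "Damaging" means ≥ 2 votes among
PolyPhen2 ≥ 0.95, SIFT ≤ 0.05, MutationTaster = D; unknown scores are
non-votes. Two deliberate interpretations:

- **Unknown ExAC frequency ⇒ rare.** Absence from the reference database is
  the standard signature of a novel, hence rare, variant.
- **Protein-truncating classes (stopgain/stoploss/frameshift/splicing) are
  damaging without predictor votes** (`lof_auto_damaging`, default on): the
  predictors only score missense changes, so requiring votes would silently
  exclude the most severe class.
- Rarity uses the annotation's overall ExAC frequency column; the
  population-subset column is configurable but not the default.

## Collapsing burden test

A sample carries a gene iff dosage ≥ 1 at ≥ 1 QC-passing rare damaging site
of that gene; missing dosages contribute nothing. Genes with ≥ 2 qualifying
variant sites across the combined cohort form the tested universe; the
Benjamini–Hochberg step-up runs over exactly that family, and significance
is declared at q < 0.20. The Fisher test is one-tailed in the
case-enrichment direction — the stated alternative of a case–control rare
variant study. Odds ratios apply the Haldane–Anscombe +0.5 to all cells when
any cell is zero (flagged in the output). The subgroup carrier test defaults
to two-sided, since no direction is pre-specified for phenotype subgroups;
sidedness is configurable.

BH is implemented directly from the step-up definition
q₍ᵢ₎ = min over j ≥ i of p₍ⱼ₎·m/j (capped at 1) and cross-checked against
statsmodels in the tests.

## Ancestry PCA

Sites with call rate ≥ 0.9, MAF ≥ 0.05 and nonzero dosage variance enter;
missing dosages are mean-imputed; normalisation is Patterson-style
(centre 2p̂, scale √(2p̂(1−p̂))), followed by SVD. Case/control matching is
summarised by the (PC1, PC2) centroid distance with a label-permutation
p-value (default 999 permutations, seeded). No LD pruning is implemented:
targeted panels carry too few sites for LD structure to dominate, a noted
divergence from genome-wide practice.

## PERMANOVA

One-way pseudo-F on squared pairwise distances (Euclidean default,
Bray–Curtis available): SS_total = Σ_{i<j} d²ᵢⱼ/N, SS_within from the
within-group pairs, F = (SS_among/(a−1))/(SS_within/(N−a)). The null is the
label permutation distribution with the small-sample correction
p = (1 + exceedances)/(1 + permutations); when the number of distinct label
assignments is at most the permutation budget (two-group case), the null is
enumerated exactly and p is the exact tail fraction. Constant data
(SS_within = 0) is ranked on SS_among instead of the undefined F. The
motivating study's own PERMANOVA input (a qPCR ΔCt panel) is not tabulated
anywhere, so the module is validated by simulation: a worked 1-D example
with a hand-enumerable null (F = 200, p = 1/3) and replicated null
calibration. The null-calibration design uses 8+8 samples with 199
Monte-Carlo permutations: the p grid (1/200) then resolves α = 0.05 exactly,
whereas tiny exhaustive designs sit visibly below α through discreteness
alone.

## Co-expression network and MCL

Edges connect genes with Pearson r ≥ 0.8, signed by default — the target is
positive co-regulation; an absolute-value mode exists. Zero-variance genes
are dropped with a log note. MCL runs on the column-stochastic flow matrix
(edge weights as capacities, +1 self-loops) alternating expansion (matrix
power 2) and inflation (elementwise power 2.0, the canonical default, then
column renormalisation) until the flow change falls below 10⁻⁶ or 100
iterations (non-convergence is reported, with the current clustering).
Clusters are read from attractor rows of the limit matrix; overlapping
attractor systems merge. No independent MCL implementation is installed in
the test environment, so MCL is validated structurally: disconnected
components can never merge (checked exhaustively on random graphs),
permutation invariance, inflation monotonicity on a planted two-module
family, and exact recovery of planted modules. The heart-specific gene
selection stand-in keeps genes whose heart expression exceeds a configurable
fold (default 2×) of the maximum across other tissues.

## Synthetic cohort generator

The generator emits exactly the formats the readers consume (VCF v4.2 with
`0/1`-style genotypes and `./.` missing codes, annotation/phenotype TSVs)
plus a truth table of every planted feature. The default world is the
motivating cohort's scale: 298 cases, 220 controls, 104 genes with
Poisson(15) variants each (~1560 sites), genotypes Binomial(2, MAF) under
HWE with MAF ~ 0.5·Beta(0.2, 2) (a rare-skewed panel spectrum), 2% baseline
missingness, and an ASD-like subgroup covering 183/298 cases. Annotation
fractions (95% exonic, 45% synonymous, 3% truncating, half of the remaining
missense drawn from a damaging-predictor profile) reproduce the order of
magnitude of the published funnel (≈800 nonsynonymous, a few hundred rare
damaging) without attempting to match its exact percentages, which depend on
the protected data.

Planted features and their parameterisations:

- **Enrichment** is planted at the carrier level (per-sample Bernoulli at
  the stated group rates, realised as a heterozygote at one of the gene's
  rare sites) because the burden statistic collapses to carriers — effect
  sizes are then directly the tested quantity.
- **HWE violations** use an inbreeding-style distortion
  P(het) = 2p(1−p)(1−F) with F = −1 by default (all-heterozygote excess at
  p = 0.5), guaranteed past the 10⁻⁷ threshold at control-group sizes.
- **Differential missingness** adds +0.40 missingness to cases at planted
  sites — far past the 10⁻⁶ threshold; such sites typically also fail call
  rate, as they would in real data, so planted-truth checks assert the
  planted reason is among the exclusion reasons.
- **Population structure** is a two-population Balding–Nichols model:
  per-population frequencies Beta(p(1−F)/F, (1−p)(1−F)/F) at fixation index
  F = Fst, optionally aligned with case/control status to emulate a failed
  ancestry match.

What a green test does not establish: the generator draws sites
independently (no LD), plants no relatedness, batch covariates or
sequencing-error model, and its annotation classes are cleanly separated —
real predictor scores disagree more than the simulated profiles do. Power
and FDR results transfer to real panels only insofar as carriers are as
cleanly ascertainable as simulated.

## Calibration experiments

`validation.py` fixes the replicated experiments: 200 null cohorts
(298/220, 57 genes × 3 rare damaging sites, every gene testable — the
stated testable-universe size) for FDR/type-I calibration, and 200
replicates with one gene planted at 10% vs 1% carrier rates for power and
ranking. Replicate seeds derive from one master seed below 2³¹. Observed
behaviour (printed by `analysis/06_calibration.py`): any-q discovery in ~5%
of null replicates (bound 20%), per-gene rejection ~1.3% at α = 5%
(discreteness makes Fisher conservative), power ≈ 98% with rank-first ≈ 99%.

## Known limitations

- No covariate adjustment (the motivating design used none); stratified
  cohorts must be caught by the PCA stage, not corrected.
- No variance-component or weighted rare-variant tests (SKAT-style); the
  carrier-collapsing test is the implemented statistic.
- The exact tests' p-values are discrete; calibration bounds are one-sided
  (conservative) by construction.
- `read_genotypes` loads the full dosage matrix into memory — appropriate
  for panels (thousands of sites), not exomes.
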