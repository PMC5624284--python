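# Methods

`gutmeta` implements a case/control stool-metagenome analysis chain:
metacommunity typing with a Dirichlet-multinomial mixture (DMM), adapted
LDA-effect-size (LEfSe) biomarker discovery, the microbial dysbiosis index
(MD-index), reporter-score pathway enrichment, lipopolysaccharide (LPS)
acylation and short-chain fatty acid (SCFA) capacity profiling, SparCC
compositional correlation networks, and coverage-based growth rates. This
note records the models, the defaults that matter, and the numerical choices
made where the published descriptions leave the design open.

## Dirichlet-multinomial metacommunity typing

Sample *i* with depth *n_i* is modelled as
*x_i ~ Multinomial(n_i, p)* with *p ~ Dirichlet(α_z)* and component
*z ~ π*. The EM fit computes responsibilities from the
Dirichlet-multinomial log-pmf (E-step) and updates each *α_k* with a
responsibility-weighted Minka fixed point (M-step). Implementation notes:

- **Initialization**: seeded k-means on row-normalized proportions, one-hot
  responsibilities, then a moment-matched concentration estimate per
  component. `n_restarts` (default 5) keeps the best fit by likelihood.
- **Partial M-steps**: during EM each fixed-point update runs at most 25
  inner iterations (a generalized EM; every fixed-point step is monotone),
  with a full 200-iteration polish at the end. Inner tolerance 1e-8
  (relative, per entry).
- **Convergence and monotonicity**: EM stops when |Δnll| < tol·max(1, |nll|)
  (tol default 1e-6) and asserts monotone nll at a *relative* 1e-8 — on
  realistic depths the nll is ~1e8 and float64 accumulation noise makes an
  absolute criterion meaningless.
- **Empty components** (weight < 1/(10 n)) are re-seeded once from the
  worst-fit decile, then dropped with a warning if they empty again.
- **Model selection**: the number of components minimizes the
  Laplace-approximated negative log posterior under a weak Normal(0, 10²)
  prior on θ = log α:
  `nlp = −log p(X|θ̂) − log p(θ̂) + ½ log|H(θ̂)| − (P/2) log 2π`,
  with H the central-finite-difference Hessian of the negative log posterior
  in θ (step 1e-4·max(1, |θ|), symmetrized; diagonal fallback when H is not
  positive definite). Mixture weights are held at their EM optimum rather
  than included in θ. Candidate range K = 1..7 by default.

## Adapted LEfSe

The "less stringent" variant screens every feature with a two-sided
rank-sum test at an *unadjusted* α = 0.05 and keeps features that differ in
at least one declared comparison (all metacommunity pairs plus the CT/CD
subgroups of mixed communities). For each comparison, 30 bootstrap rounds
subsample 2/3 of each group without replacement, fit a two-class LDA on the
feature matrix scaled to parts-per-million (×1e6), and score each feature

    e_b = ½ (|Δ_raw| + |w_unit| · |Δ_proj|),   lda_score = log10(1 + mean_b e_b)

where Δ_raw is the per-feature class-mean difference, w_unit the unit first
LDA axis and Δ_proj the class-mean difference of the projected data. A
feature's final score is the maximum over comparisons; biomarkers need
score ≥ 2. Singular within-class scatter falls back to an eigen solver with
shrinkage 0.1, then to a standardized mean difference. Enriched group =
higher median (mean, then first group, on ties).

**Known limitation.** The score is an *absolute* abundance-difference scale.
When group labels are randomly permuted on a cohort that genuinely contains
metacommunity structure, every high-variance signature taxon that happens to
pass the screen (~15–25% per taxon with five comparisons) lands above the
threshold, because its selected mean difference is large in absolute ppm
regardless of labels. A "median ≤ 2 biomarkers under label permutation"
property therefore cannot hold for a cohort with ≥ ~13 strongly spiked taxa
under this scoring; the specificity guarantees we do test are (a) fully null
cohorts yield zero biomarkers in ≥ 80% of seeds and (b) the per-feature null
score stays below 2 with probability ≥ 0.95. This mirrors the behaviour of
the original tool, whose statistical gate is the screening test, not the LDA
threshold.

## MD-index

`md = log10((up_mass + ε)/(down_mass + ε))` with ε = 1e-6; up/down sets
default to the biomarkers enriched in case- vs control-polarized groups
(polarity = metacommunities with ≥ 75% of one disease label, plus the CT/CD
subgroups), and user-supplied lists are accepted. Antisymmetry and
per-sample scale invariance hold exactly at ε = 0.

## Reporter scores

Per KO: two-sided rank-sum p between the groups, direction = sign of the
median difference, z = direction · Φ⁻¹(1 − p/2) (p clipped to
[1e-15, 1−1e-15]); the signed two-tailed construction puts enrichment and
depletion on one axis. Per pathway with k scored members:
raw_z = Σz/√k, standardized against the mean/SD of 1000 random size-k sets
drawn without replacement from the scored KOs (not the full KO universe —
unscored KOs have no z). |score| > 1.9 is the display/report threshold.

## LPS and SCFA capacity

Lipid-A pathway gene set (configurable):
LpxA, LpxC, LpxD, LpxH, LpxB, LpxK, WaaA, LpxL, LpxM. All nine present →
hexa-acylated producer; all but the terminal acyltransferase LpxM →
penta-acylated producer; none → Gram-positive; any other pattern →
unclassified (counted, logged, and by default included in the Gram-negative
mass, with a flag to exclude). The hexa:penta ratio is
log10((hexa+ε)/(penta+ε)), ε = 1e-6; samples with no Gram-negative mass
report 0 with a `no_mass` flag. Homology hits survive at identity > 35,
score > 60, E < 1e-3 (strict, as printed); the best-scoring surviving hit
assigns each gene to one terminal enzyme, and SCFA capacity is the summed
abundance of assigned genes per acid (CO dehydrogenase and acetyl-CoA
synthase → acetate; propionyl-CoA and propionyl-CoA/succinyl-CoA
transferases → propionate; butyryl-CoA transferase → butyrate).

## SparCC networks

Per inference iteration: fractions are Dirichlet-resampled from counts with
a unit pseudocount; t_ij = Var(log x_i/x_j); basis variances solve
[(D−2)I + J]ω = row-sums(t) (the sparse-correlation approximation); and
ρ_ij = (ω_i + ω_j − t_ij)/(2√(ω_iω_j)), clipped to [−1, 1]. The strongest
pair above the 0.25 exclusion threshold is iteratively removed from the
system (≤ 10 rounds), and the reported matrix averages 20 iterations.
Negative basis variances clip to 1e-8 with a warning. Empirical p-values
permute each taxon's counts independently across samples (the standard
pseudo-p choice; whole-sample permutation would preserve composition and
destroy no signal), re-running with 5 iterations per null;
p = (1 + #{|ρ_null| ≥ |ρ_obs|})/(1 + n_null). Networks keep edges with
p < 0.01 and |ρ| ≥ 0.3; the differential census counts lost/gained/shared
edges and strong (|ρ| > 0.5) losses/gains on the shared node universe.

## Growth rates (peak-to-trough ratio)

Profiles are circular binned depths (≥ 16 bins). A circular moving average
(window = 10% of bins) locates the origin (argmax of smoothed log coverage)
and terminus (argmin); estimates are discarded when mean coverage < 5 per
bin or the ori–ter separation falls outside 30–70% of the genome. The raw
smoothed ratio systematically underestimates the PTR because averaging a
window across the exponential peak (trough) shrinks (inflates) the
extremum; the reported value corrects this analytically with the per-bin
slope implied by the estimate itself (5 fixed-point rounds), which makes
noiseless profiles round-trip exactly and removes the bias under Poisson
noise. A perfectly flat profile is reported as PTR = 1 (detected).

## Ecology statistics

Natural log throughout (Shannon, Jensen-Shannon); the Jensen-Shannon
*distance* is the square root of the divergence (metric form, max
√ln 2). Bray-Curtis and Jensen-Shannon distances are computed with scipy;
Gower handles mixed types with range normalization and missing-pair
exclusion, and `bioenv` standardizes numeric covariates before the Gower
step, searching subsets exhaustively (first-in-order wins ties; a guard
refuses > 20 covariates without a size bound). PCoA is classical scaling
with a deterministic sign convention (largest-magnitude loading positive);
negative eigenvalues are reported, axes come from positive ones. PERMANOVA
uses the pseudo-F on squared distances with seeded label permutations and
the add-one p-value. Rank-sum p-values are exact for combined n ≤ 25
without ties, else normal-approximated with tie/continuity correction.
Fisher's exact tests (one per membership group, 2×2 against disease) and
all per-feature comparisons are BH-adjusted; q-tiers: * < 0.2, ** < 0.1,
*** < 0.05, **** < 0.001.

## Synthetic cohort generator

The default cohort emulates the assumed study structure: 54 controls (CT)
and 49 cases (CD) in three metacommunities — A (40 CT + 3 CD),
B (14 CT + 21 CD), C (25 CD, case-exclusive) — over 150 taxa, with six
signature taxa per component enriched 6-fold in α, a 200-KO functional
layer in which four 10-KO pathways shift 2-fold between disease groups,
annotations that make the case-exclusive signatures hexa-acylated LPS
producers and the control signatures Gram-positive SCFA carriers, coverage
profiles whose true PTRs favour the beneficial taxa in community A and the
opportunists in community C, and clinical covariates (inflammation markers
strongly, age/BMI weakly) loaded on the community axis. All randomness
derives from a single seed through named substreams, so identical configs
reproduce identical cohorts.

Two constructions keep the generator's null properties exact rather than
approximate:

- **Equalized signature base mass.** Every signature taxon gets the same
  baseline share (0.008) before its component-specific fold is applied, so
  the per-component concentration totals are identical and *non-signature*
  taxa are exactly exchangeable across components — enrichment does not
  leak into bystander taxa through compositional closure.
- **Tight within-component dispersion.** Per-component concentration and
  mean depth are both 5×10⁶, i.e. within-metacommunity composition varies
  only a few per mill between hosts. Real gut metagenomes are far more
  overdispersed; the choice makes the spiked/null contrast unambiguous so
  that threshold-based stages (LDA ≥ 2, reporter > 1.9, |ρ| ≥ 0.3) separate
  cleanly. Passing tests therefore demonstrate correctness of the machinery
  under clearly identified signal, not performance under realistic
  inter-individual variability.

The generator does **not** emulate: realistic overdispersion (above),
taxon-taxon correlation beyond the optional injected pairs (the baseline is
a pure DMM, so the fitted K has a well-defined truth), sequencing error or
read-level artifacts, strain-level variation, or longitudinal structure.
The `correlations` config field injects positive co-variation into chosen
taxon pairs of one component via a shared log-normal factor on α (default
strength 0.05, strong enough for ρ ≈ 0.8 at the default dispersion); it is
empty by default and is used by the differential-network tests.

## Problem sizes used in the test-suite and acceptance script

Model selection scans K = 1..7 with 5 restarts on the 103-sample default
cohort; parameter recovery uses 500 samples from a 2-component mixture
(α totals ≈ 48, depth 2000); biomarker specificity uses 20 null cohorts;
SparCC calibration uses 50 taxa × 200 samples (null), a planted ρ = 0.8
pair among 30 bystanders over 20 seeds, and 500 permutation nulls for
p-value uniformity; PTR recovery uses 50 seeds × 3 growth rates at 200×
per bin; PERMANOVA type-I error uses 500 runs of 20 samples at 199
permutations (9999 permutations in the acceptance script's single cohort
test). Selection-consistency spot checks run at 10 replicates.
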