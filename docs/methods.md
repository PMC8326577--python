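# Methods

`gutsig` implements a compositional analysis framework for shotgun
gut-metagenome cohorts in which one case group (e.g. IBD) is compared
against an internal control and one or more external healthy controls.
This note records the models, the parameters that matter, and the design
choices made where more than one reasonable reading existed.

## Abundance estimation (EM mixture model)

Reads mapped against a reference-genome collection are often compatible
with several genomes.  The sample is modelled as a mixture: a read comes
from genome *g* with probability π_g, and an ambiguous read contributes
the summed likelihood of its compatible set (flat compatibility weights
by default; per-alignment weights may be supplied).  EM performs the
soft assignment: the E-step computes responsibilities ∝ π_g, the M-step
averages them.  The log-likelihood is concave in π, so the uniform
initialisation is only a determinism choice; convergence is declared
when max |Δπ| < 1e-8 (at most 1000 iterations).  Reads with identical
compatibility sets are interchangeable, so tables are stored as unique
patterns with multiplicities — EM cost scales with the number of
patterns, not reads.

Post-processing order is fixed: **QC → EM → noise floor → strain
aggregation → closure**.  Samples with fewer than 250,000 mapped reads
are dropped (profiles below that depth are unreliable); estimated
proportions strictly below 1e-5 are zeroed as statistical noise (values
exactly at the floor are kept); strains of one species are summed.  The
source material does not state whether noise-floored vectors were
renormalised; rows are re-closed here so that every downstream statistic
operates on a proper composition.

## Compositional processing

Relative abundances carry no information about totals, so inference
operates on the centered log-ratio transform clr(x)_j = ln(x_j/G(x)).
Zeros are imputed multiplicatively before the log: each zero becomes
δ = 5e-6 (half the noise floor, hence below anything treated as signal)
and nonzero entries are shrunk to preserve the unit sum.  The policy is
recorded on every `ClrMatrix` for provenance.  Natural log is used for
CLR; Shannon entropy is reported in bits (log2) on the untransformed
relative abundances.

Dimensionality is reduced by the prevalence rule: a species is kept if
it is nonzero in at least 90% of the samples of *some* diagnosis group
(union across groups).  At most five randomly chosen replicate samples
are retained per subject (seeded, deterministic).

Bray–Curtis dissimilarity BCD = 1 − 2·Σ_k min(v1_k, v2_k)/(S1+S2) is
computed for within-subject (intrapersonal) and within-group,
between-subject (interpersonal) pairs; groups are compared with
two-sided Mann–Whitney U tests.

## Signature selection (noise-calibrated random forest)

Features are the CLR species values plus label-encoded metadata (age,
sex, unique subject id — the latter lets the forest absorb replicate
structure).  For each of R = 100 runs a fresh noise column is appended,
drawn from N(μ̂, σ̂²) with μ̂, σ̂ the pooled mean/SD of all CLR entries,
and a random forest (500 trees by default, impurity importances, which
sum to 1 per run) is fit on all samples.  Features whose mean importance
exceeds the noise feature's are tested (two-sided Mann–Whitney U of
their R importances against the noise feature's R importances), BH
corrected across candidates only — mirroring the screening-then-testing
order — and selected at q < 0.05.  Classifier accuracy is reported from
a stratified 70/30 split as per-class F1 and support-weighted F1, with
the confusion table kept for misclassification analysis.

**Known limitation.**  The R runs are refits on one fixed dataset, so a
feature's importances across runs are not independent draws under a
global null: any feature that by chance correlates with the labels
(|r| ≈ 2/√n) is consistently rewarded in every run, and the
Mann–Whitney test against the fresh noise column then becomes
arbitrarily significant as R or the tree count grows.  The procedure
therefore ranks features reliably and has excellent power for real
effects (a 2-CLR-unit shift is selected essentially always), but its
false-selection rate under a complete null is well above the nominal q
threshold.  This is a property of the procedure itself, not of this
implementation; the test suite measures and reports it honestly rather
than hiding it.

## Consensus differential abundance

Per control group, each species is tested case-vs-control with a
two-sided Mann–Whitney U on CLR values; BH correction is applied across
species *within* each comparison (the comparisons are reported
"individually").  Fold changes are computed on the relative-abundance
scale as the ratio of zero-replaced geometric means (the compositional
analogue of a mean; a CLR difference is not a fold change of a single
taxon) — an arithmetic-mean variant is available.  A species reaches
consensus only if, against **every** control, q < 0.05, fold ≥ 2, and
the direction (elevated/depleted in the case group) agrees.  Adding a
control can therefore only shrink the consensus set.

## Association networks (GGM)

CLR profiles of a group are modelled as a single multivariate Gaussian;
replicates enter as independent samples under that assumption.  The
sparse precision matrix is estimated by graphical lasso along a path of
30 log-spaced penalties from λ_max (largest absolute off-diagonal
covariance — the smallest penalty giving an empty graph) down to
0.01·λ_max.  The penalty is selected by StARS: 20 subsamples without
replacement of size min(⌊10√n⌋, 0.8n), per-edge selection frequencies
θ̂, instability = mean of 2θ̂(1−θ̂) over pairs, monotonized by a running
supremum toward denser graphs; the selected λ* is the smallest penalty
whose monotonized instability stays ≤ β = 0.1.  The selected fit is
then stabilized by r = 50 bootstrap refits (resampling n samples with
replacement): an off-diagonal entry survives only if nonzero in the
full fit and in ≥ f·r = 40 bootstrap fits.  Entries with |ω̂_ij| ≤ 1e-8
are treated as numerical dust, not edges.  The solver runs at a 5e-4
duality-gap tolerance — far below the edge threshold — which keeps the
many subsample/bootstrap refits cheap.

The network is unweighted and signed: edge sign is the sign of the
implied partial correlation −ω̂_ij/√(ω̂_ii ω̂_jj) (the sign convention
for "negative associations" was otherwise unspecified).  Eigenvector
centrality solves x_i = Σ_j A_ij x_j by power iteration on the
unsigned adjacency (a unit diagonal shift guarantees convergence on
bipartite components without changing the eigenvector); disconnected
graphs are scored on the largest component, other nodes at zero, unit
Euclidean norm overall.  Cross-network comparison reports unique/shared
edge sets, top-10 EVC overlap, the fraction of connected nodes per
differential-abundance category, negative-edge fractions, and the
fraction of case-unique edges touching case-elevated species.

## Functional capacity

Each genome carries protein-family counts (e.g. TIGRFAM hits), each
family belongs to one role.  A sample's family profile is the
abundance-weighted sum of counts over the ≥90%-prevalent species,
closed to sum 1 and CLR-transformed across families.  The literal
"weighted by CLR-transformed abundance" reading is ill-posed (CLR
weights are negative for below-geometric-mean taxa, producing negative
"abundances"), so plain relative-abundance weights are the default and
the CLR-weight variant (clipped at zero) is available behind a flag for
comparison.  Family-level testing reuses the consensus machinery —
per-sample profiles are required for a Mann–Whitney test across
samples, so the per-sample reading of cohort profiles is adopted —
and consensus families are aggregated by role with direction.

## Synthetic cohorts and what they do (not) show

The generator emulates the structure the analysis assumes: latent log
absolute abundances are multivariate Gaussian with a known sparse
precision matrix (support Bernoulli(sparsity) on the upper triangle,
magnitudes uniform on ±[0.1, 0.4], diagonal inflated until the minimum
eigenvalue is ≥ 0.05), per-species baseline means N(0, 1), group
effects planted as log2-unit mean shifts (an effect of 2 ≈ fourfold),
a shared N(0, 0.5²) per-subject intercept across 1–5 replicates, then
exponentiation, closure, noise-flooring at 1e-5 and re-closure.  Ages
are uniform per group, sex Bernoulli(0.5).  Read tables draw each
read's source genome multinomially, with probability `ambiguity` adding
one extra compatible genome.  Family counts are presence-gated Poisson
draws with planted copy-number boosts.

The generator matches the GGM's own assumptions, so network-recovery
results are a best case: real data exhibit zero inflation beyond the
noise floor, heavier tails, and compositional closure of *counts*
rather than of latent abundances.  Passing tests demonstrate that each
procedure recovers what it is designed to recover under its stated
model, not that the model is correct for any particular cohort.

## Problem sizes and numerical choices in the test suite

Test and benchmark sizes are chosen to exercise the asymptotics without
waste: consensus-DA recovery uses D = 30 species at 100 subjects/group
over 20 seeds; network recovery uses D = 30, n = 500, 5 seeds (edge-F1
vs truth ≥ 0.7); selection calibration/power uses n = 200, D = 50, 20
seeds with 30 forest runs of 100 trees.  EM recovery uses 5 genomes,
300k reads, 30% ambiguity (mean L1 error < 0.02).  Ties in the
Mann–Whitney tests use scipy's tie-corrected normal approximation for
large samples and the exact distribution for small ones; the exhaustive
enumeration oracle in the tests covers group sizes ≤ 8.
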