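# Methods

This note documents the models and procedures implemented in `neoresponse`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic-data tests do and do not demonstrate.

## Clonal reconstruction

The cancer cell fraction of a mutation is estimated as

    CCF = VAF / p * ((1 - p) * CN_normal + p * CN_tumour)

with p the tumour purity, CN_normal the germline copy number at the locus
(2 on autosomes; all tables here are autosome-only) and CN_tumour the total
tumour copy number. Mutation multiplicity is deliberately not modelled: the
estimator treats every mutation as present on one copy, so amplified
clonal mutations can yield CCF > 1. Such values are reported unclipped.

The confidence interval is a Wilson score interval on alt/total at 95%,
mapped through the same multiplier as the point estimate. The binomial CI
family was not pinned down further by the source analyses; Wilson is the
common default of the reference implementations and is well behaved at the
read depths involved (~160x). A mutation is *clonal* iff the CI contains 1.
Read literally, this rule classifies intervals lying entirely **above** 1 as
subclonal; the call object carries an `above_one` flag so such calls can be
audited, but the rule is applied verbatim. Patients with no classifiable
mutation get a missing (not zero) subclonal percentage.

Tumour mutation burden divides the somatic mutation count by the 45.54 Mb
exome footprint, making TMB additive over disjoint mutation sets.

## Mutational signatures

Catalogues over the 96 trinucleotide channels are decomposed against a
column-normalized reference matrix by non-negative least squares on the
normalized catalogue; weights below 0.06 are zeroed and the remainder
renormalized to the simplex (the discard threshold of the commonly used
decomposition tool). Decomposition is only attempted for tumours with more
than 10 mutations; below that a no-result marker is returned. Exposures are
reported as log2((w_s + c)/(w_1 + c)) against the age/clock signature with
pseudo-count c = 0.01 — small relative to the 0.06 discard threshold, and
keeping the ratio finite when the clock weight is zero. The non-clock
fraction is 1 minus the summed weights of signatures {1, 5}.

The shipped reference matrix (`synth.synthetic_reference_signatures`) is a
synthetic stand-in: sparse Dirichlet columns with a fixed internal seed.
Any 96xS column-normalized matrix in the same layout can be supplied
instead.

## HRD scar score

The score is TAI + LOH + LST computed from allele-specific segments, with
the component definitions fixed explicitly (the published scar definitions):

* **LOH** — minor CN 0, major CN > 0, length > 15 Mb, not the whole
  chromosome.
* **TAI** — allelic imbalance (major != minor) touching a telomere, not
  crossing the centromere, not whole-chromosome.
* **LST** — per chromosome arm, after removing segments < 3 Mb and merging
  adjacent equal-CN segments closer than 3 Mb: breakpoints whose flanking
  segments are both >= 10 Mb and separated by < 3 Mb.

Segments are validated as sorted and non-overlapping per chromosome; the
result is invariant to input row order. The genome model (autosome lengths
and centromere bounds, GRCh37 coordinates) ships as a small TSV.

The genome-altered fraction is the length-weighted fraction of covered
genome whose total CN differs from round(ploidy). "Altered" could also be
read as CN != 2 regardless of ploidy; the ploidy-relative reading was chosen
as the more standard one, and ploidy defaults to 2.

## HLA LOH and neoantigens

An HLA class I allele is called lost iff its estimated copy number is below
0.5 **and** the loss is statistically significant; the significance level is
0.05 (the source rule says only "statistically significant"). Neoepitope
candidates (8–11-mers) are retained iff mutant affinity < 500 nM (strict),
mutant binds more strongly than the wild-type peptide, and the source gene
exceeds 1 TPM (strict). Presentation impact is summarized as the percentage
of neoepitopes presentable only by lost alleles, and the fraction of loss
events where the lost allele presented at least as many neoepitopes as the
best retained allele.

## Expression normalization

The chain is TMM → FPKM → TPM, as used by the upstream analyses (TPM
directly from counts is the more common route; the printed chain is
implemented as stated). TMM uses 30% trimming on M, 5% on A, inverse
asymptotic-variance weights, and picks as reference the sample whose upper
quartile of positive proportions is closest to the cohort mean; factors are
normalized to unit geometric mean. The implementation agrees with edgeR's
`calcNormFactors` to ~1e-5 on random matrices (cross-checked in the test
suite via Rscript when available). FPKM divides by TMM-scaled library size
and gene length; TPM rescales each sample to 1e6. Matrix layers use
log2(TPM + 1); the 0.01 offset is used only where a score specifies it.

## Single-sample enrichment and metagenes

The single-sample method is the ssGSEA statistic: per sample, genes are
ranked (rank weights |r|^0.25), and the score integrates the difference
between the weighted in-set ECDF and the unweighted out-of-set ECDF, with
optional normalization by the score range across samples. It is invariant
under strictly increasing per-sample transforms and matches the gseapy
implementation (rank normalization) to numerical precision. A z-score-based
alternative is available behind `method="zscore"`, since the upstream
package family offers several variants without a per-signature record.

Metagenes: cytolytic = geomean of GZMA/PRF1 TPM at offset 0.01; taxane
response = geomean(BUB1B, CDK1, AURKB, TTK) − geomean(UGCG, CERT1);
Danaher-style cell scores = log2 geometric means of marker TPM.
Immunophenotype classes average per-gene z-scores (across samples) within
gene groups; zero-variance genes contribute z = 0 with a warning.
Dysfunction/exclusion scoring is an external model; this package computes
its input contract — log2(TPM+1) centred by each sample's mean over all
genes (per-sample centering; per-gene or global centering were the other
readings) — and otherwise accepts the scores as input columns.
"High" score flags are strictly above the cohort mean.

## Digital pathology

Per-cell density is Σ_N = N/(π d_N²) with d_N the distance to the Nth
nearest neighbour within the same cell class; N defaults to 50 and a
stability sweep over N in {40,45,50,55,60} reports the maximum relative
deviation of the slide summary. The slide-level feature is the **median**
per-cell density (robust to clustering; the mean is also emitted — the
upstream summary statistic was not named). No edge correction is applied,
matching the upstream procedure; densities near slide boundaries are
therefore biased upward slightly. Units are px⁻²; a microns-per-pixel
conversion is available. In cohort assembly, slides with more than 2,000
lymphocytes compute the median over a fixed-seed subsample of 2,000 cells
(neighbour distances still use all cells); the Monte-Carlo error of a median
at that size is far below the 10% recovery tolerance.

## Association statistics

Univariable logistic regression reports the OR per unit with Wald 95% CIs
(profile-likelihood CIs were the alternative reading). Complete or
quasi-complete separation — detected on the standardized coefficient scale —
yields a flagged infinite-OR result excluded from FDR. FDR is
Benjamini–Hochberg. Ordinal trends use a proportional-odds (ordered logit)
model over pCR > RCB-I > RCB-II > RCB-III fitted by maximum likelihood
(BFGS, gradient tolerance 1e-8), with a likelihood-ratio test against the
intercept-only model; with two classes the coefficient reproduces the
logistic fit to ~1e-6, which the suite asserts. Rank-sum comparisons against
the pCR group use exact enumeration for combined n <= 20 and the normal
approximation with continuity correction otherwise. An analysis-inclusion
filter (>= 1 chemotherapy cycle; >= 1 anti-HER2 cycle if HER2+) is provided
for association analyses.

## The predictor

Pipeline order is fixed: collinearity filter → k-best → z-scale → three
classifiers. The collinearity filter visits features by decreasing |r| with
the outcome (ties by name) and keeps a feature iff its |pairwise r| with all
kept features is <= 0.8 — strictly above 0.8 is removed, so r = 0.8 exactly
keeps both. k-best ranks by one-way ANOVA F with deterministic name
tie-breaks; k is treated as a tunable hyperparameter (it could equally have
been fixed; tuning it is the more general reading). The classifiers are
elastic-net logistic regression (saga), an SVM whose margin scores become
probabilities via a sigmoid (Platt) fit on the training data — the upstream
work does not say how margins were made averagable — and a random forest.
The predictor score is the unweighted mean of the three probabilities.

Tuning draws hyperparameters log-uniformly for C and gamma within the search
bounds (elastic-net C in [1e-3, 1e3], l1 ratio [0.1, 1]; SVM kernel in
{rbf, sigmoid, linear}, gamma [1e-9, 1e-2], C [1e-3, 1e3]; forest trees
[5, 100], max-feature fraction [0.05, 0.70], min samples per split [2, 15])
and scores each draw by mean AUC over stratified five-fold CV (folds fixed
by the CV seed; stratification guarantees both classes per fold at ~26%
prevalence). All preprocessing is refitted inside each training fold, so no
information leaks from validation folds; the collinearity keep-list, which
does not depend on the draw, is computed once per fold. The default search
length is 100 iterations (desk scale; configurable upward). A *model*
averages five predictors tuned with distinct CV seeds, each refitted on the
full training cohort at its optimum. Six nested models add modalities
cumulatively; run-to-run determinism under a fixed master seed is asserted
in the suite.

Importance drops each feature, refits the full chain per algorithm, and
expresses the training-cohort AUC change as z = Δ/σ(Δ); the signed variant
uses −Δ/σ so features that add value are negative. The AUC for importance is
measured on the full training cohort after refit (where it was measured was
not stated upstream; a CV-based variant would be slower and noisier at this
cohort size). The clinical-impact projection finds the highest score
threshold leaving at most fn_budget true responders below it, then rescales
the confusion matrix to 100 patients by largest-remainder rounding; ties in
the sweep resolve toward the lower threshold (fewer false negatives).

The canonical fully-integrated feature set has exactly 34 features across
five modalities (6 clinical, 10 DNA, 12 RNA, 2 digital pathology, 4
treatment one-hots: anthracycline, anti-HER2, taxane-first,
anthracycline-first), listed with modality tags and source operations in
`src/neoresponse/data/feature_definitions.tsv`; matrix assembly validates
against this file.

## The synthetic cohort generator

Each patient carries independent standard-normal latent traits (tmb,
subclonality, hrd, cna, proliferation, immune, dysfunction, exclusion,
nodal). The latent response is the effect-size-weighted sum of traits plus
unit Gaussian noise — a proportional-odds generative model, matching the
ordinal analyses downstream — and three ascending cutpoints bin it into
RCB-III/II/I/pCR. Default cutpoints sit at the latent quantiles of a
plausible neoadjuvant class mix (26% pCR, 16% RCB-I, 40% RCB-II, 18%
RCB-III); default effect sizes are signed as reported for the real features
(tmb +1.1, subclonality −0.8, hrd +1.0, cna +0.7, proliferation +1.3,
immune +1.1, dysfunction −0.8, exclusion −0.5, nodal −0.5 log-odds per SD).
The magnitudes are calibrated, once, so that the planted multi-omic signal
jointly dominates the latent response (signal:noise variance ~7:1) — the
regime of a strongly profiled cohort that the package's discrimination
checks presuppose; with all effect sizes zeroed the generator is verified to
carry no residual signal (held-out AUC at chance).

Observables are tied to traits: mutation counts are Poisson with log-mean
shifted by the tmb trait around 90 mutations (~2/Mb); subclonal fractions
follow a logistic function of the subclonality trait, subclonal CCFs are
scaled Beta(2,3); read counts follow the exact VAF inversion of the CCF
formula at Poisson depth 160 with purity uniform on [0.3, 0.9] and tumour CN
drawn from {1,2,3,4} (CN 0 loci are rejected); trinucleotide contexts are
drawn from per-patient signature mixtures whose HRD-like weight rises with
the hrd trait; segments start diploid and receive planted whole-arm gains
(cna trait) and LOH/TAI/LST-style scars (hrd trait); expression is
log-normal-Poisson with proliferation/immune/stem/suppressor gene blocks
shifted by the corresponding traits and hormone-receptor genes tied to
ER/HER2 status; lymphocyte point patterns are homogeneous spatial Poisson
with intensity log-linear in the immune trait (base 0.003 cells/px² in a
1000x1000 px window); neoepitope candidates are planted to pass or fail the
three filters with a controlled rate; HLA loss probability falls with the
latent response; dysfunction/exclusion input columns are the traits plus
noise. One master seed; each table draws from `default_rng([seed, offset])`
with fixed offsets, so bundles are bit-reproducible and adding a table never
perturbs the others.

Default cohort sizes are 200 (training) and 75 (validation), mirroring the
proportions of a realistic discovery/validation design at desk scale.

**What the generator does not emulate:** read-level data, purity/ploidy
estimation error, gene–gene correlation beyond block structure, spatially
clustered (non-Poisson) immune infiltrates, batch effects, histology
artefacts, or linkage between DNA and RNA beyond the shared latent traits.
Passing tests therefore demonstrate that each extractor recovers what it is
defined to measure and that the ensemble integrates planted multi-modal
signal — not that the particular AUC levels would transfer to real cohorts.

## Problem sizes and numerical choices

The acceptance script and heavy tests use: the default 200/75 cohorts with
100-iteration search and five CV seeds for the tuned models, with held-out
AUC reported as the mean over five independent 75-patient validation
cohorts (one draw estimates AUC with SE ~0.05); 50 replicate
cohorts with default-hyperparameter predictors for the integrated-vs-
clinical win rate; 10 replicate null cohorts (all effect sizes zero) for
chance-level calibration; depth 1e4 with 500 mutations for CCF recovery;
n = 500 for the proportional-odds slope recovery. Degenerate inputs raise
explicit errors (empty genome, non-ascending cutpoints, zero-area windows,
all-zero libraries, single-class outcomes); duplicate pathology coordinates
are jittered by machine epsilon with a warning; zero-variance features are
dropped (filtering) or scored zero (z-scores) with warnings.

## Known limitations

Mutation multiplicity and subclonal copy number are not modelled in CCF;
the clonality rule's behaviour for CIs entirely above 1 is applied verbatim
(flagged); kNN density has no edge correction; the proportional-odds model
assumes parallel cutpoint slopes; the importance z-scores are measured on
training data and will overstate absolute (not relative) importance; the
synthetic reference signature matrix is a stand-in, not a biological
catalogue.
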