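# Methods

This note documents the statistical model, the estimation machinery, the
simulator that backs the validation suite, and the design choices made
where the problem left them open.

## Kinetic model

RNA abundance under constant synthesis (ksyn) and first-order decay (kdeg)
relaxes to a steady state ksyn/kdeg. During a metabolic-label window of
length t_label, the fraction of molecules synthesized within the window —
the fraction new θ — satisfies θ = 1 − exp(−kdeg·t_label). Inverting,

    kdeg = −ln(1 − θ) / t_label,   ksyn = TPM · kdeg,

with TPM standing in for steady-state abundance. Uncertainty on log kdeg is
propagated from the logit-scale uncertainty of θ by the delta method,
d log kdeg / d logit θ = θ / (−ln(1−θ)). The model assumes steady state
during labeling; pulse-chase and dynamic designs are out of scope.

## Fraction-new estimation (per TEC)

Read-level mutation data arrive as cB rows (sample, gene, TEC, nT, TC, n).
Conditional on being "new"/"old", TC | nT is Binomial(nT, p_new) /
Binomial(nT, p_old):

- **p_old** is the pooled conversion rate in no-label control samples,
  Σ n·TC / Σ n·nT — a closed-form MLE.
- **p_new** is estimated per labeled sample by EM on the two-component
  marginal mixture with a sample-global mixing weight as nuisance. The EM
  stops on log-likelihood stabilization or on parameter stabilization
  (|Δp_new| < 1e-7 and |Δθ| < 1e-5): when θ's MLE sits at a boundary (for
  example, nearly all reads labeled) EM converges sublinearly in θ while
  p_new has long stabilized. p_new > p_old is enforced at every step.
- **θ_TEC** is then a 1-D MLE per (sample, gene, TEC) with rates fixed,
  found by bounded search; its SE comes from the observed Fisher
  information on the logit scale (central differences, step 1e-4).

θ̂ is clamped to [1/(n+2), 1 − 1/(n+2)] — an add-a-pseudocount convention
that keeps the Beta likelihood below proper when a TEC shows no (or only)
converted reads. TECs whose reads carry no Ts are excluded and counted.

## Isoform deconvolution

Each TEC's expected fraction new is the TPM-weighted convex combination of
its member isoforms' fraction news, and the observed TEC estimate is
modeled as Beta with that mean and concentration equal to the TEC read
count (see README for the formulas). Choices made here:

- The Beta shape parameters follow the mean/concentration form literally:
  α = θ̄n, β = n − θ̄n.
- Mixing weights use raw TPM ratios with no effective-length correction; a
  length correction would change weights for TECs covering partial
  transcripts but the TPM form is kept as the model's definition, noted as
  a modeling approximation.
- Optimization is on logit(θ) with L-BFGS-B from three starts (the
  read-weighted average of each isoform's TEC estimates, 0.25, 0.75); ties
  break by best objective. SEs come from the pseudo-inverse of a
  central-difference Hessian. Two isoforms occupying exactly the same TECs,
  or a Hessian condition number above 1e8, set `identifiable = False` and
  the SEs are then lower bounds.
- Fitted θs are clamped like TEC estimates (ε = 1/(Σn+2)); clamp hits are
  flagged `at_boundary` so the implied kdeg is recognizably censored.
- Fits run per sample; replicates are combined downstream. An alternative
  is pooling replicate reads before fitting; per-sample fits preserve
  replicate variability for the regularized averaging step.
- Isoform inclusion defaults: TPM > 1 and expected reads ≥ 10 in all
  samples (both configurable). TECs whose members are all excluded are
  dropped and the weights renormalized over survivors — an approximation
  that slightly misattributes reads shared with excluded isoforms.

## Replicate averaging and differential statistics

Replicate log kdeg values are combined by inverse-variance weighting. The
replicate-to-replicate variance is shrunk toward a genome-wide trend (log
variance regressed on log mean read depth) with precision weights of
n_reps − 1 observed d.f. against 5 prior d.f.; a single replicate takes the
trend wholesale and is flagged. The exact trend model was an open choice;
only the shrinkage behavior (lower RMSE than raw variances under a common
true variance) is asserted by the tests.

Differential stability is a two-sided z-test on L2FC(kdeg) with quadrature
SEs; the default significance gate is padj < 0.01 and |L2FC| > 1 (both
configurable), with Benjamini–Hochberg adjustment across transcripts.

The Isoform Decay Range of a gene is max − min of its isoforms'
replicate-average log kdeg (≥ 2 modeled isoforms). Its uncertainty is the
quadrature sum of the two extreme isoforms' SEs — correlation between
extremes is ignored, and SEs of non-extreme isoforms do not enter; this is
the conservative reading of "total uncertainty in the range". For k > 2
isoforms the range of null-identical estimates is biased upward, so the
z-test is calibrated exactly only at k = 2 and conservative-to-liberal
behavior at larger k follows the range statistic itself; the null
calibration suite uses 2-isoform genes. The between-condition IDR change
uses the same quadrature rule; `fraction_attributable` = ΔIDR/IDR_A,
clipped above at 1, NA when IDR_A = 0, with a 10%-decrease reporting
threshold by default.

## Annotation support filtering

Genes are tiled into exonic bins (union of all isoforms' exons, ≤ 200 nt)
and intronic bins (gene span minus that union, ≤ 600 nt); terminal partial
bins keep true lengths. The per-gene pre-mRNA background is the intronic
RPKM shrunk toward a genome-wide log-log trend of intronic on exonic RPKM;
the precision weight of the observation is its intronic read count against
a prior weight of 10 reads (intronless genes take the trend value; a
degenerate trend falls back to the global mean with a warning).

Each exonic bin is tested one-sided against the background with a negative
binomial whose mean is background RPKM × bin kb × library size in millions
(floored at 0.1 reads) and whose dispersion is a method-of-moments estimate
pooled across intronic bins (configurable constant override; dispersion → 0
recovers the Poisson tail). p-values are BH-adjusted within sample; a bin
is *supported* if significant in at least one sample — the complement of
the "unsupported in all samples" call used for isoform flags.

Transcript ends are trimmed by removing contiguous runs of unsupported
terminal bins while the removal only shortens (never eliminates) a terminal
exon, so the junction chain is invariant; any remaining unsupported bin
makes the transcript `problematic` and it is left untrimmed. An isoform is
`unsupported` when some exon has no supported overlapping bin; reporting is
restricted to isoforms with TPM > 1 in all samples. Trimming operates on
support pooled across samples.

The junction-coverage-compatibility (JCC) score per gene compares observed
junction read counts with counts predicted proportional to the summed TPM
of junction-carrying isoforms, rescaled to match the observed per-gene
total (the scaling variant is recorded in the output metadata);
JCC = Σ|obs − pred| / Σobs, NA without junction reads. Counting consumes
fragment-interval or precomputed bin-count tables rather than alignments,
which keeps the module testable end to end; alignment-derived counts can be
fed in through the same tables.

## Simulator

The simulator emulates a two-condition, replicated TimeLapse-seq design at
the count level (no sequences or FASTQs — downstream estimators consume
counts, so the statistical structure is what matters; read-order shuffling
is therefore moot). Gene models are synthetic: each gene has 5–8 exons;
minor isoforms skip a distinct cassette exon and carry a distinct 3'
extension, guaranteeing mutually distinguishing exonic regions so TECs are
informative. Defaults define the emulated conditions: 2 h label,
p_new = 0.05, p_old = 0.002, 3 replicates plus a no-label control, read
length 100, T fraction 0.25 per read (configurable; sequence-realistic U
content is not modeled). Major-isoform log kdeg is Normal(log 0.3 h⁻¹,
0.8); each minor isoform has a 50% chance of differential turnover
(independent kdeg draw) versus copying the major's kdeg, recorded in the
truth table; expression is log-normal per gene with a dominant major share,
normalized to 10⁶ TPM; ksyn = TPM·kdeg by construction. The exact kinetic
sampling distributions were an open choice; they are keyword arguments
recorded in the truth output.

Reads are allocated to isoforms ∝ TPM × length, placed uniformly, and
their TEC computed by exact compatibility. Implementation note: for a
fixed fragment length the TEC is piecewise constant in the start
coordinate, changing only where an endpoint crosses some isoform's exon
boundary, so each transcript is segmented once and half a million reads
are placed with array operations; the segmentation is verified against a
brute-force per-fragment compatibility oracle in the tests. New/old status
is Bernoulli(θ) (0 in no-label samples); conversions are Binomial per T.
Everything derives from one seed via spawned child seeds.

What passing tests show — and do not show: the simulator matches the
generative assumptions of the estimators (binomial conversions, exact
TECs, correct TPMs up to optional log-normal noise). Recovery results
therefore validate the inference machinery, not robustness to alignment
error, positional coverage bias, SNPs masquerading as conversions, or
quantifier misestimation, none of which are modeled.

## Decay-covariate harness

Numeric features are standardized; positive features whose range spans
more than two decades are log10-transformed first (threshold
configurable). Categorical features are ordered by mean outcome, pooled to
at most 10 groups by iteratively merging the adjacent pair with the
closest group means (the pooling tolerance was unspecified; adjacent-rank
merging to ≤ 10 is the declared rule), then the per-row group ranks are
z-scored. Unseen levels at prediction time take the mean rank with a
warning.

The regression harness fits 100 bootstrap LASSO models; the classification
harness downsamples the majority class to the minority size 100 times and
fits L1 logistic models; in both, the penalty is chosen per resample by
10-fold cross-validation under the minimum-CV-error rule (the 1-SE rule is
the main alternative; minimum-error is the default of the underlying
solvers and keeps coefficients less aggressively shrunk). Sensitivity
labels: *sensitive* = L2FC(kdeg) < −0.7 and post-inhibition kdeg below 65%
of baseline; *insensitive* = L2FC ≈ 0 or positive (≥ −0.1 by default);
everything else excluded. A high-confidence variant (L2FC < −1,
FDR < 0.01, gene JCC < 0.4, not unsupported) is provided separately.

The 10-nt translation-initiation (Kozak) window scorer sums one matrix
entry per position; the matrix is user-supplied configuration. The shipped
`example_pssm()` is synthetic (random) and exists only so examples and
tests run; it carries no biological meaning.

## Numerical details and degenerate inputs

- All mixture likelihoods work in log space with max-shift stabilization.
- The mixing objective clips θ to [1e-12, 1 − 1e-12] inside the optimizer;
  public entry points validate open-interval membership strictly.
- Grid-search oracles in the tests use steps of 1e-3–1e-4 and tolerances
  twice the step.
- Variance floors: 1e-10 for replicate variances before logs; μ floor of
  0.1 reads in the bin test.
- Duplicate cB keys aggregate with a warning; reads compatible with
  transcripts of multiple genes are discarded and counted (the upstream
  convention for such reads is not standardized; discarding is explicit
  and reported). Empty compatibility lists are likewise tallied.

## Problem sizes used in validation

The end-to-end recovery suite runs 300 genes at 5×10⁵ reads per replicate
(3 replicates + control); null calibration uses 2500 two-isoform genes;
bin-test calibration 10⁴ bins; LASSO recovery 2000×11 (regression) and
1200×5 (classification) with the full 100 resamples. These sizes give
Monte-Carlo error small enough for the 3-SD acceptance bands while keeping
a full validation run around a minute.

## Known limitations

- Steady-state assumption; no dynamic or pulse-chase designs.
- No joint estimation of abundance and fraction new; TPMs are plug-in.
- Uncertainty in p_new/p_old is not propagated into θ SEs (second-order
  at realistic depths).
- The Beta observation model treats TEC θ̂s as exchangeable given n; heavy
  clamping at very low read counts slightly biases extreme fraction news
  toward the center.
- The IDR z-test is exactly calibrated for 2-isoform genes only (see
  above).
- Multi-label (dual-nucleoside) designs and hierarchical Bayesian
  fraction-new models are out of scope.
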