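# Methods

## Statistical model and procedure

The pipeline treats the assay readout as a genes × arrays matrix of
log-scale normalized intensities with a binary array label (respiratory
sensitizer vs non-respiratory; solvent-only vehicle controls belong to the
negative class). All stages assume arrays are complete (no missing values)
and that replicate stimulations of one compound are exchangeable up to a
shared compound-level effect.

**Filter tier.** For each gene a one-way ANOVA F-test compares the two
class groups. With two groups F equals the square of the pooled-variance
t statistic, which the test suite checks as an algebraic identity. Genes
with zero between- and within-group variance are assigned p = 1 so a flat
probe can never outrank an informative one; zero within-group variance with
a real group difference gives p = 0. Benjamini–Hochberg q-values are
reported for interpretation, but selection keeps the K smallest raw
p-values (the published procedure reports a p-threshold implied by a fixed
candidate count, not a q cutoff). Ties on p break by descending F, then
gene identifier, making the selection a deterministic, permutation-invariant
function of the data.

**Wrapper tier.** Backward elimination ranks candidates by the magnitude of
their linear-SVM weight on standardized features (the standard RFE
criterion) and removes the `step` smallest per round. After every
`eval_every` removals the surviving set is scored by leave-one-out
cross-validation: each array's decision value comes from an SVM trained on
all other arrays, with per-gene standardization statistics recomputed
inside the fold so the held-out array never leaks into the scaling. The
Kullback–Leibler error of the LOOCV predictions is

    KLD = mean_i  KL( one-hot(y_i) || [σ(d_i), 1−σ(d_i)] )
        = mean_i  −ln σ(y_i d_i),

the mean negative natural-log predicted probability of the true class under
a fixed-slope logistic mapping of the decision value, with probabilities
clipped at 1e-12. ROC AUC is recorded alongside at every evaluation.

**Stopping rule.** The signature is the candidate set at the *first local
minimum* of the KLD trace — the first evaluation below both neighbours and
no worse than the full candidate set. A pure global minimum is exposed as
an option but is not the default for a structural reason we verified
empirically: whenever LOOCV classifies every array correctly, −ln σ(y·d) is
monotone in the magnitude of the decision values, and removing features
concentrates weight and inflates |d|, so the global minimum slides to one-
or two-gene signatures on cleanly separable data. The cross-validated error
surface on realistic (imperfectly separable) data instead rises again once
informative transcripts start being removed, which is exactly the interior
minimum the first-local-minimum rule stops at. Default block sizes are
step = eval_every = 1 up to 200 candidates and 5 above, keeping the trace
dense where signatures are small and the wall-clock bounded where they are
not.

**Classification.** The final model is a linear soft-margin SVM
(cost C, default 1.0, the library default in common use; solver tolerance
1e-7 so the hyperplane is stable to sample order at the precision the
elimination trace relies on) on features standardized by training mean and
population sd; those statistics are frozen into the model and reused
verbatim on new arrays. The classification threshold is the unmodified
decision value at 0 — no post-hoc bias shift or class weighting. A compound
is called a sensitizer when any replicate has d strictly greater than 0;
a maximum of exactly 0 is a non-sensitizer call. Cooper statistics
(sensitivity, specificity, accuracy) are computed at compound level and
reported both as fractions and nearest-integer percent; rates with a zero
denominator are reported as undefined rather than 0. ROC AUC uses the
Mann–Whitney formulation (ties credited 1/2) at replicate level.

**Robustness (VCF).** The derivation is rerun on `iterations` (default 20)
stratified splits assigning round-half-up 70% of each class to training.
Per iteration the signature is re-derived by the filter tier at the same K
(running the full wrapper inside every iteration is available behind a
flag), an SVM is trained on it and the 30% part is scored. A gene's
Validation Call Frequency is the percentage of iterations selecting it; on
a 20-iteration run VCFs lie on the 5% grid. Per-iteration seeds derive
deterministically from the master seed. Note that resampled training sets
share most of their arrays, so even null data yields some genes with high
VCF; the informative null signature of instability is churn (many more
distinct genes ever selected than K), which the tests assert instead of an
independence-based bound that the null simulation itself disproves.

**Frozen PCA.** Components are fitted by SVD of the training arrays
restricted to the signature, per-gene centred and (by default)
unit-variance scaled with training statistics; near-zero-variance genes
(sd ≤ 1e-10 relative) are dropped with a warning. Each component's sign is
fixed so its largest-magnitude loading is positive, making plots and
regression tests stable. The fitted model is immutable: projection applies
the stored centring, scaling and rotation, so test arrays can never move
training coordinates.

## Preprocessing

**Batch adjustment** is a location-only stand-in for empirical-Bayes batch
correction: per gene, each batch is mean-centred and shifted to the pooled
grand mean, which removes additive batch offsets exactly, preserves the
per-gene grand mean to 1e-10, and does not moderate variances. Batches with
a single array are left unadjusted with a warning. Full empirical-Bayes
adjustment is expected from external tooling upstream.

**Outlier arrays** are flagged in the space of the top three principal
components of the gene-centred matrix: an array whose Euclidean distance to
its compound-group centre exceeds median + k·MAD (raw MAD, default k = 4)
of all within-group distances is flagged. The group centre is the
coordinate-wise *median*: with triplicate groups a gross outlier drags a
mean centroid toward itself far enough that its clean siblings get flagged
too, a masking effect we observed directly; the median centre is immune to
it. A manual exclusion list in the CLI config reproduces any ad-hoc
exclusion exactly. With fewer than three replicate groups the detector
warns and flags nothing.

**Marker QC** applies a two-sided Welch (unequal-variance) t-test of a
per-array scalar marker — CD86 surface expression in the reference assay —
per compound against its vehicle control group; Welch is the safer default
when the variance assumption behind a plain t-test is unstated. Two
zero-variance groups with equal means give p = 1.

## Synthetic cohorts

The generator draws x_gj = μ_g + δ_g·1[class=resp] + c_{g,compound}
+ b_batch + ε_gj with ε ~ N(0, noise_sd²), per-(gene, compound) random
effects c ~ N(0, compound_sd²) shared across a compound's replicates, a
scalar per-batch shift b, and signed effects δ_g ~ ±N(effect_size_mean,
effect_size_sd²) on a designated signal-gene subset, half up- and half
down-regulated; vehicles are background-only arrays of the negative class.
Baselines are μ_g ~ N(7, 1), a typical log2 microarray intensity scale.
An optional outlier array receives extra isotropic noise of sd
outlier_magnitude·noise_sd, which moves it away from its replicate group in
every PC direction rather than along a single axis.

Defaults mirror the reference study design at reduced gene count: 2000
genes with 50 signal genes (effect mean 1.5, sd 0.2 log-units), replicate
noise sd 0.3, compound effect sd 0.15, 10 respiratory + 20 non-respiratory
compounds in biological triplicate, two vehicle groups of 6, a single
batch. The effect and noise magnitudes are realistic for moderately strong
transcriptional responses on log2 microarray data; the compound effect is
set below the replicate noise so class separation, not compound identity,
dominates. These sizes keep a full test-suite run to a couple of minutes
while preserving the ~1:3 gene-to-sample regime of the assay.

The generator deliberately omits gene–gene correlation structure,
probe-level effects, and intensity-dependent variance. Recovery results on
it therefore show that the selection and classification machinery works
when its distributional assumptions hold — not that the assay's biological
signal behaves this way; correlated transcripts in particular would lower
effective signature diversity and VCF contrast relative to the simulation.

## Numerical choices and degenerate inputs

- Probabilities in the KLD error are clipped at 1e-12; d = ±50 is already
  error < 1e-12.
- Standardization uses population (ddof 0) sd; genes with sd ≤ 1e-10
  relative to their mean are treated as constant (scale 1 in the SVM,
  dropped in PCA).
- Elimination ties on |w| break by gene identifier; the whole trace is
  bit-reproducible across runs.
- Split sizes round half up on the training side; a class that cannot
  appear in both parts is a hard error.
- Readers reject duplicate identifiers, non-numeric cells and missing
  values with messages naming the offending gene/sample.

## Known limitations

- The KLD stopping criterion is evaluated on LOOCV at array level;
  replicates of a compound remain in the training fold, so LOOCV is
  optimistic about between-compound generalization. Compound-level
  cross-validation is the natural extension and the VCF stage's
  stratified splits partly compensate.
- The batch adjuster corrects locations only; multiplicative batch effects
  pass through.
- The outlier detector assumes at least three replicate groups and top-3 PC
  space; subtler single-gene artifacts are invisible to it.
- VCF is computed with filter-only re-derivation by default; running the
  full wrapper per iteration is exposed but slow.
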