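# Methods

## Signature scores

The AR signaling score treats a fixed panel of AR-regulated genes plus a
reference vector (their expression profile in the androgen-stimulated
state) as a template: a sample's score is the Pearson correlation
between its log2(FPKM) values over the panel, taken in signature order,
and the reference entries. The score is therefore invariant to any
positive affine rescaling of the sample's signature-gene vector and
flips sign under negation — it measures profile shape, not level. Genes
absent from the matrix are dropped pairwise and recorded per sample; a
hard floor (`min_genes_present`, default 80% of the panel, never below
3) guards against scoring from too small an intersection. A sample with
no variance across the panel has no defined correlation and is emitted
as NaN with a `zero_variance` flag rather than silently imputed.

The mTOR activation score contrasts, within each sample, the expression
of genes up-regulated on mTOR activation against genes down-regulated on
activation, using a two-sample t statistic with genes as observations.
The pooled (Student) variant is the default since the source procedure
names only "a t test"; Welch is available, and when one gene group is
constant the pooled statistic is undefined, so the implementation falls
back to Welch with a flag. The absolute value |t| is the default score;
because |t| cannot distinguish activation from suppression, the signed
statistic is always recorded in the per-sample flags (and is the
quantity used for latent-recovery checks).

No cross-sample standardization is applied before either score: both
are strictly single-sample statistics.

## Association layer

Correlations report Pearson r, r², Spearman rho (average ranks), and a
two-sided p from t = r√((n−2)/(1−r²)) on n−2 degrees of freedom, after
pairwise deletion of missing values; constant input is an error, not a
zero. At n ≤ 7 the t approximation deviates from the exact permutation
null by up to ~0.2 in p (measured against exhaustive enumeration of all
n! orderings), so accept/reject decisions near α can differ from the
exact test; the test suite asserts agreement within that documented
tolerance and exact decision agreement whenever the permutation p is
more than 0.12 from α = 0.05. Group comparisons default to Welch's
t test (pooled available) and report group means, fold change of means
(second group over first, in order of appearance), t, df and two-sided
p. Fold changes are ratios of group means, not means of per-pair folds.

ΔΔCt: ΔCt = mean(Ct_target) − mean(Ct_housekeeper) per condition,
ΔΔCt = ΔCt_treatment − ΔCt_control, fold = 2^(−ΔΔCt), assuming ideal
doubling efficiency. Replicate SDs are propagated as the variance of a
mean summed across the four replicate groups and reported as an SD of
ΔΔCt plus the fold at ±1 SD. Densitometry folds are
(band/housekeeper)/(control band/control housekeeper); the construction
makes the control lane exactly 1.0 and the statistic scale-invariant.

## Lipidomics QC

The chain runs in a fixed order: drift correction → CV filter →
dilution-linearity report → protein normalization → aggregation and
differential abundance. QC-based correction must precede noise
filtering (a drifting feature's raw QC CV conflates drift with
irreproducibility); the remaining order is a package decision recorded
in each run manifest. All stages are multiplicative per row, so they
commute to floating-point precision, and drift correction applies one
factor per (feature, injection index), so it can never reorder samples
within an injection.

Drift models are fitted per feature to pooled-QC peak area versus
injection index with LOWESS (default span 0.5 over QC points) or a
cubic smoothing spline. The LOWESS window is floored at four QC points
per local regression so that sparse QC series are smoothed rather than
interpolated — interpolation would absorb irreproducibility into the
correction and defeat the CV filter. The correction divisor at index i
is fitted(i)/median(QC areas), linearly interpolated between QCs, held
constant beyond the first/last QC (no extrapolation), and floored at a
configurable epsilon. Features with fewer than four QCs are flagged
`uncorrectable` and passed through unchanged; original areas are kept
in a `peak_area_raw` audit column.

The CV filter computes per-feature pooled-QC CV as sample (n−1) SD over
mean of raw-scale areas × 100 and removes features strictly above 30%
(a feature at exactly 30.0% is retained). Dilution linearity
operationalizes visual inspection of the 100/50/25/12.5/6.25% series as
Pearson r ≥ 0.9 with positive slope over ≥ 4 points. Protein
normalization divides biological-sample areas by per-sample total
protein (µg); pooled and dilution QCs, which are not tied to one
biological sample, are exempt.

Lipid shorthand names are parsed as `CLASS total_carbons:double_bonds`
(with or without parentheses) or as chain-level `CLASS(c1:d1/c2:d2)`
forms that are summed to the total composition, against a declared
class vocabulary. Differential abundance compares groups per species or
per class total with a two-sided t test (Welch default), reports fold
of means and percent change, and applies Benjamini–Hochberg FDR across
the keys of a comparison; raw p is always kept alongside q. Class
summaries additionally report the mean over member species of the
per-species percent change and the count of species with fold > 1 —
two different conventions (class-total fold versus average per-species
change) that can disagree, so both are emitted and neither is treated
as canonical.

## Synthetic data

The expression generator draws standard-normal latent AR and mTOR
activities per sample and per-gene baselines μ_g ~ N(5, 1) in log2
units. Signature genes load on the AR latent proportionally to their
reference entries (scaled to unit loading SD), so the reference vector
is the noiseless fully-activated profile; mTOR up/down genes load
±1 on the mTOR latent; the focal gene (PIP4K2A) loads −γ (default
γ = 0.8) on the AR latent; background genes (default 200) are baseline
plus noise. Gaussian noise with SD 0.5 log2 units is the default —
comparable to biological scatter of strongly regulated transcripts in
bulk cohorts. Presets mirror the cohort sizes the scores are typically
applied to (333 and 149 samples). The generator emulates latent-factor
structure only: no count noise, no gene-gene correlation beyond the
latents, no batch effects, and no missing genes — passing recovery
tests therefore demonstrates correctness of the estimators under the
assumed model, not robustness to everything real cohorts contain.

The lipidomics generator builds an injection schedule with a pooled QC
at the run start, after every 5 (or 6) samples and at the run end,
followed by the five-point dilution series. Feature base abundances are
lognormal (median 1e5 area units, σ = 1); the second group's
concentrations are multiplied by planted per-species or per-class
folds. The default assessed panel is seven PI species with folds
(2.8, 2.6, 2.9, 3.1, 2.5, 2.2, 0.77): six of seven increased and a
mean per-species change of exactly +141%, among 273 species total.
Sample areas scale with a per-sample protein aliquot (uniform 80–120
µg), pooled-QC truth is the mean of the pooled samples' amounts, and
dilution QCs scale it by their fraction. Per-feature drift is a ramp
plus one low-frequency sinusoid bounded by the drift amplitude
(default 1.5×), covering both monotone and oscillatory drift shapes;
observation noise is multiplicative lognormal (default CV 5%). A
configurable fraction (default 10%) of features outside the assessed
panel is constructed irreproducible by alternating areas ±50% within
each sample type, which pins their pooled-QC CV near 50% regardless of
how QCs interleave with samples. Both generators are pure functions of
parameters and seed and return a truth object; recovery tests read the
truth, never re-derive it.

## Verification problem sizes

The test suite and acceptance script use: 1,000 random instances for
definition-level oracle equivalence of both scores (naive sum-formula
oracles, ≤ 1e-12 relative error); 20 cohorts of 333 samples for
latent-activity recovery and 200 replicates for planted-sign recovery;
a 30-per-group lipidomics run (13 pooled QCs) for drift-correction
improvement and CV-filter exactness, and a 6-per-group run for PI
class-fold recovery within 10% of planted truth; and 50 instances at
n = 5–7 for the permutation-null comparison. These sizes give stable
pass/fail behaviour across seeds at desk scale.

## Known limitations

Dilution-linearity uses a fixed r threshold rather than lack-of-fit
testing; the drift model assumes smooth drift (step changes between
batches are not modeled); |t| scores conflate activation with
suppression direction; class aggregation trusts the shorthand name
grammar and does not resolve regioisomers; and the ΔΔCt fold assumes
100% amplification efficiency.
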