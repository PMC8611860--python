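# Methods

## Differential-expression screening

Expression is handled throughout on the log2 scale, the microarray
convention, so the fold change is the geometric-mean ratio
FC = 2^(mean log2 tumor − mean log2 normal).  The screen uses a paired
two-tailed t-test on per-pair log2 differences with n_pairs − 1 degrees
of freedom.  Two degenerate cases are defined rather than propagated as
NaN: all per-pair differences zero gives p = 1 (no signal), and zero
variance with a nonzero mean is reported as the limiting p = 0 with a
`degenerate` flag.

Up/down calls use the raw p-value (p < 0.05, strict) together with
FC ≥ 2 or ≤ 0.5; BH q-values are computed (via statsmodels) and reported
but do not enter the call, since the screening thresholds are defined on
raw p.  Two named presets exist: `microarray` (FC boundary inclusive) and
`validation` (|log2FC| > 1, boundary strict).  The two rules differ only
at FC exactly 2 or 0.5; both are kept because each matches one common way
of printing the same threshold.

Quantile normalization is implemented directly (sorted-column row means,
values re-assigned by within-column rank, ties receiving the mean of
their tied reference positions).  It assumes most features are unchanged
between samples; when a large fraction of features carries signal the
procedure compresses true fold changes.  The synthetic screening study
therefore plants 80 DE features among 4 000 (2 %), the regime a
genome-scale array operates in.

The five-rule candidate filter ranks DE lncRNAs by |log2FC| (ties broken
by ascending p, then accession, for determinism) and applies: a
signal-intensity floor read as "the higher-expressing condition must
exceed 7 on the log2 scale" (normal for downregulated features, tumor for
upregulated ones); removal of chrX/chrY features; removal of transcripts
≥ 2 000 nt; removal of exonic-sense lncRNAs.  Each casualty is logged
with the first rule that removed it.

## Enrichment

The hypergeometric upper tail P(X ≥ m) is summed in log space
(log-gamma terms per pmf value, combined with logsumexp), which stays
accurate for backgrounds up to ~1e5; the verification suite checks it
against exact integer combinatorics over every configuration with
N ≤ 60 (max |error| < 1e-13).  The enrichment factor is fold enrichment
(m/n)/(M/N) — the conventional quantity for descending-order ranking.
BH adjustment runs within each gene-set category (BP/CC/MF/KEGG/custom),
mirroring per-ontology reporting.  Terms need at least `min_hits = 2`
query hits by default.  The background is an explicit required input:
whether it is a whole array or an expressed subset materially changes N,
so no default is guessed.

## ceRNA inference

Correlation is Pearson on log2 expression.  The percentile cut uses the
nearest-rank definition (the ⌈q/100·n⌉-th order statistic of all defined
pair correlations in one condition) with *strict* exceedance, which gives
defined behavior on ties (a degenerate all-equal distribution selects
nothing).  Selection demands exceedance in both normal and tumor
conditions; an `either` rule is available for exploration.

The partial correlation ρ_XY|Z is evaluated in closed form from the three
sample correlations.  Its algebraic identity with the residual
correlation (regress X on Z, Y on Z, correlate the residuals) is used as
an independent test oracle, holding to ~1e-15 on sample statistics.  The
denominator collapses when |ρ_XZ| or |ρ_ZY| → 1; since sample
correlations of exactly collinear data round to within ~1e-15 of ±1, a
triplet is declared degenerate when 1 − ρ² < 1e-12 rather than only at
exact unity.  Values outside [−1, 1] by floating error are clamped.

Seed matching uses the 6-mer seed, mature miRNA positions 2–7 (0-based
slice [1, 7)), and searches the target sense strand for its reverse
complement in RNA space (A↔U, G↔C) after T→U normalization, so DNA FASTA
inputs work unchanged.  Watson–Crick only — no G:U wobble, no 7-mer/8-mer
classes, no context or conservation scores.  All overlapping occurrences
are reported with 0-based start coordinates.

Retention uses the sensitivity correlation ρ_XY − ρ_XY|Z ≥ δ with
δ = 0.2 by default: a fully mediated pair has sensitivity ≈ ρ_XY (large),
while a pair whose shared miRNA is incidental has ρ_XY|Z ≈ ρ_XY
(sensitivity ≈ 0).  δ is the main specificity dial; raising it can only
remove triplets (a tested monotonicity).  Sensitivity is computed in the
tumor condition by default (the cancer network being the object of
interest) and is configurable.

## Synthetic data

The generator emulates a paired tumor/normal design (default 4 pairs,
as in small microarray screens).  Expression is
baseline + pair effect + condition effect + N(0, noise_sd), all in log2
units, with the pair effect shared within a pair so per-pair differences
recover planted log2 fold changes exactly at zero noise.

The ceRNA system drives both planted transcripts with the same latent
per-sample miRNA activity z ~ N(0,1): x = baseline − βz + ε,
y = baseline − βz + ε′, and the measured miRNA column is baseline + z + ε″.
Both targets are *repressed* (negative coefficients), producing the
positive lncRNA–mRNA correlation the selection step assumes.  Because the
miRNA is measured with noise, conditioning on it leaves a small residual
partial correlation (≈ ρ_XY·σ²/(1+σ²) in population terms) — the
sensitivity filter tolerates this by design.  Decoy features are
independent noise with marginal variance matched to planted features, and
decoy transcripts carry no planted seed site (chance 6-mer occurrences
are allowed, as in real sequence).  Seed sites are inserted at uniformly
drawn, recorded 0-based positions; mature miRNA sequences are drawn with
mutually distinct seeds.

Default recovery-study conditions: 50 sample pairs, 20 planted triplets
with β = 0.8 and noise_sd = 0.5, among 200 decoy lncRNA/mRNA feature
pairs and 20 decoy miRNAs (so 220×220 candidate pairs in total).
Four pairs — the realistic screening design — cannot support correlation
inference, so the recovery experiments use the larger n; this is a
deliberate, documented property of the study design, not of the method.

Survival times are exponential with group-dependent hazard (base 0.2/year;
the elevated group's hazard is multiplied by the configured hazard
ratio).  Censoring is an independent exponential whose rate is chosen so
the expected censored fraction equals `censor_rate` exactly.

What the generator does *not* emulate: probe-level artifacts, background
correction, dye effects, batch structure, heteroscedastic
intensity-dependent noise, miRNA–target many-to-many regulation beyond
the planted triplets, or non-proportional hazards.  Passing the planted
recovery tests therefore demonstrates correctness of the inference
machinery under the assumed model, not performance on real arrays.

## Survival and cohort statistics

Kaplan–Meier estimation and the log-rank test are delegated to lifelines;
the suite checks the estimator against the empirical survival function
(no censoring) and the log-rank statistic against a direct
observed-minus-expected hand computation.  Median split assigns values
strictly above the median to `high`, ties to `low`; a constant vector is
an error.  Survival time is in years; day-scaled inputs are converted by
/365.25 behind a config switch.

Cohort percentages are rounded half-away-from-zero to one decimal, the
convention that reproduces hand-tabulated clinical tables.  Dunnett's
many-to-one comparison uses the multivariate-t distribution of the
maximal |t| under the pooled error variance (scipy's implementation, with
a seeded generator for its stochastic integration); simulation confirms
the family-wise error rate stays at 0.05 within a 3σ binomial band over
1 000 null replicates.

## Pipeline

All stages run from one YAML config with unknown keys rejected.  Each
stage's RNG seed is derived from the global seed and the stage name via
SHA-256, giving stage-level independence with full reproducibility; the
run manifest records per-artifact SHA-256 checksums, and the determinism
test asserts byte-identical artifacts across repeated runs.  The DE stage
screens under both threshold presets and the intersect stage intersects
their up/down calls — the same set-intersection operation a two-cohort
design (e.g. discovery array ∩ external validation) would use, exercised
here within one simulated cohort since external databases are out of
scope.

## Validation problem sizes

The verification suite uses: the full hypergeometric grid N ≤ 60 (~1.2 M
configurations); 200 seeded trivariate Gaussian draws of n = 80 for the
partial-correlation oracle; 1 000 random miRNA/target pairs for seed
matching; the default recovery studies above; 1 000 replicates each for
log-rank type-I error (n = 100) and Dunnett FWER (6 groups × 10); and a
reduced pipeline configuration for the byte-determinism check.
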