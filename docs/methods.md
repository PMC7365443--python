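# Methods

## Differential-abundance model

The quantitation model treats each replicate experiment's peptide log2
reporter ratios as draws from a common Gaussian null N(µ, σ²) contaminated by
a minority of truly shifted proteins. µ and σ are estimated by nonlinear
least squares on the ratio histogram rather than by sample moments: the
histogram fit down-weights the heavy tails that the differential proteins
themselves create, which moment estimators absorb. The histogram spans
median ± 5·1.4826·MAD with 100 equal bins; the fit is initialised at
(max bin count, median, 1.4826·MAD) and run with tolerance 1e-8, max 500
function evaluations. Failure (non-convergence, σ ≤ 0, < 50 ratios, < 10
nonempty bins) is always an error naming the experiment, never a silent
fall-back to moments. A residual sum of squares above amplitude² flags the
model `low_quality` (a bimodal ratio distribution triggers this); the flag is
advisory, the fit still returns.

The null is fitted on **peptide** ratios by default (larger n, stabler fit);
protein-level median ratios are scored against it with z =
(r − µ)/(σ/√n_peptides). Fitting the null on protein-level ratios instead is
available via `null_level="protein"` — with only two replicate experiments
the text-book choice is genuinely open, and peptide-level was chosen as the
default because the protein-level histogram can be too sparse for a stable
100-bin fit below ~500 proteins. Protein aggregation uses the median, robust
to a single outlier peptide. FDR is Benjamini–Hochberg on the Gaussian
p-values.

The differential call is two-tier: *differential* means q < 0.05 in at least
one experiment; *differential_concordant* additionally requires q < 0.05 in
the other experiment and an identical, nonzero ratio sign. Concordance uses
the raw ratio sign (not the sign relative to µ): with a centred null these
coincide, and the raw sign is what a reader of the protein table sees. A
protein with fewer than two quantitated peptides in either experiment is
`unquantified` and never tested. Note the consequence checked by the
null-shift test: adding a constant to the treatment channels moves µ by that
constant and leaves the q-based differential set unchanged, but can relabel
which concordant proteins are "up" vs "down" since signs are absolute.

## Enrichment

Proteins quantified in both experiments are ranked by the mean of the two
log2 ratios, descending, ties broken lexicographically by accession so the
ranking is deterministic. The set statistic is the weighted KS running sum:
hits increment by |score|^p (p = 1 by default; p = 0 supported) normalised
over hits, misses decrement by 1/(N − n_hits), ES = the signed extremum,
clipped to [−1, 1] against floating-point overshoot. With two paired samples
a phenotype permutation null is impossible, so the null resamples random
member sets of equal size from the ranked universe. p = (1 + #{|ES_null| ≥
|ES|})/(1 + n_perm) — the +1 keeps p > 0 and makes the null distribution of p
uniform on {k/(n_perm+1)}; NES divides ES by the mean |null ES| of matching
sign. Gene-set permutation tests a different null than phenotype permutation
(coordinate extremeness of the members relative to random sets of proteins,
ignoring inter-protein correlation), which is the standard caveat for small
designs. A set covering the whole universe never decrements and is returned
with a `degenerate` flag.

## Assay calculators

**Kinetics.** The linear phase is found by sliding-window least squares
(default width 10 points). `initial_rate` picks the earliest window with
r² ≥ 0.98 whose slope sign matches the expected direction — correct for
assays that begin at maximal velocity (LDH, PK; NADH consumption).
`max_rate` picks the steepest such window — correct for coupled assays that
accelerate into a log phase (HK via G6PDH). Selecting the maximum over many
noisy windows biases the estimate upward, so for noisy traces a wide window
should be used: with 2 s sampling and noise 0.002 A, a 90-point (3 min)
window keeps the bias well under 2 % — the width used in the recovery tests.
A flat window has r² defined as 1 (a constant is a perfect line); slopes
below 1e-4 A/min are flagged `below_min_rate`. Unit conversion assumes the
NAD(P)H extinction coefficient 6.22 mM⁻¹cm⁻¹ and a 1 cm path by default;
both are config fields and every output records the values used, since the
cuvette geometry is rarely reported in papers.

**Flux.** Rates are (Δconcentration × volume)/(Δt × protein). The
lactate/glucose ratio is bounded by 2 under pure glycolysis; a ratio outside
(0, 2] warns (non-glycolytic lactate, e.g. glutaminolysis, or assay error)
but never errors. Non-positive consumption makes the ratio undefined (NaN
with a warning).

**Respirometry.** Each event opens a segment; the plateau mean is taken from
`settle_s` (default 30 s) after the event to the next event, requiring at
least `plateau_s` (default 30 s) of data. CrU is the maximum over FCCP bolus
plateaus, matching titration-to-maximum practice. ROX comes from an explicit
inhibitor event; without one, a user constant is required or zero is assumed
with a logged warning — never silently. Corrected values subtract ROX;
CrO′ ≤ Cr′ ≤ CrU′ violations set a quality flag rather than raising, since
real leak rates occasionally exceed routine in stressed cells.

**Statistics.** The t-test is the pooled-variance two-tail Student test,
df = n_a + n_b − 2, with stars at 0.05/0.01/0.001. Two identical constant
groups return p = 1; distinct constants with zero variance are an error
(infinite t). The implementation is hand-rolled (three lines of algebra) and
cross-checked against `scipy.stats.ttest_ind` to 1e-9 in the tests, keeping
implementation and oracle independent.

## Synthetic data

The proteomics generator emulates a paired two-replicate 4-plex design:
log-normal base intensities (median 1e4, log-sd 1) per peptide per replicate,
treatment channels shifted multiplicatively by 2^(null_center + effect +
N(0, peptide_noise_sd)), so peptide log2 ratios have exactly the configured
noise sd (0.3 by default, a typical reporter-ratio spread). Differential
proteins are a configured fraction (round(frac_diff·n)), effect magnitudes
|N(1.0, 0.2)| log2 units with random sign. Peptides per protein are
1 + Poisson(λ−1), λ = 4, so the ≥2-peptide filter excludes a realistic
minority. One seed fans out to per-purpose substreams via
`numpy.random.SeedSequence`, making outputs byte-identical per seed.

What the generator does **not** emulate: isotope-impurity cross-talk between
reporter channels, intensity-dependent ratio variance, missing channels,
shared/razor peptides, or protein-correlated peptide noise. Passing recovery
tests therefore demonstrate correctness of the statistics under the model's
own assumptions, not robustness to those real-data artefacts.

The kinetic generator produces lag (flat) → linear → exponential-approach
plateau, the simplest smooth saturation consistent with substrate depletion;
the respirometry generator produces piecewise-constant plateaus with
Gaussian noise; metabolite endpoints get multiplicative log-normal noise of
configured CV; sphere counts are Binomial(n_seeded, SFE). Instrument noise
magnitudes are set for testability (they exercise the estimators at
realistic signal-to-noise), not calibrated to any particular instrument.

`generate_differential_roster` is a synthetic stand-in for a study-scale
protein differential table: it builds row-level per-experiment ratios and
q-values whose filter funnel (2,759 quantified → 101 differential → 19
concordant: 15 down, 4 up by default) matches what a two-replicate design of
this kind yields, so the classifier's funnel logic can be exercised at scale.
The counts are properties of the generated rows; the classifier recomputes
them from scratch.

## Problem sizes

Simulation-based checks use 20 null experiments of 1,000 proteins for FDR
calibration, one 1,000-protein spike-in experiment for recovery, 10,000
draws for the null-fit check, 1,000 permutations for set significance and
200 repeats × 199 permutations for p-value calibration — sizes at which the
Monte-Carlo error bands quoted in the tests are meaningful while the whole
suite runs in seconds.

## Known limitations

- The Gaussian null assumes unimodal, symmetric ratio noise; strongly skewed
  or bimodal ratio distributions are only flagged, not modelled.
- √n peptide scaling treats peptides as independent; shared peptide noise
  within a protein would make the p-values anticonservative.
- Gene-set permutation p-values ignore inter-protein correlation.
- `max_rate` window selection has a positive noise bias shrinking with
  window width; no analytical bias correction is applied.
- Enzyme activities are relative to the configured cuvette parameters;
  absolute U/mg comparisons across labs require matching ε, path, volume and
  protein inputs.
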