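# Methods

## The measurement model

Each hybridization carries two samples (mutant and wild-type cRNA) labelled
with different dyes on one array; expression is read per probe as a channel
pair (A, B). Which physical channel holds the mutant is a per-array flag: in
the default orientation the mutant is on channel B, and dye-reversed
replicates put it on channel A. All downstream quantities are functions of
the per-gene log-ratio mutant − wild-type in log₂ space, so the dye-swap
flag is resolved before any genotype-level computation and every result is
invariant under simultaneously swapping the channel columns and the flag
(covered by a dedicated symmetry test).

## Normalization chain

Stages run in a fixed order: (1) optional loess dye correction at probe
level, (2) geometric-mean summarization of replicate probes per gene,
(3) floor at 1, log₂ transform, percentile shift.

**Loess dye correction.** Intensity-dependent dye bias appears as curvature
of M = log₂(B/A) against A = ½(log₂A + log₂B). We fit a degree-1 weighted
local regression of M on A (span 0.4 of the probes per local fit, two
robustness iterations, via statsmodels' lowess) and subtract the fit,
reconstituting channels so A is preserved per probe. The stage is skipped
when the array metadata says the scanner already applied it ("auto" mode).
Span 0.4 removes ≥ 95% of a planted sinusoidal bias of amplitude 0.5 in our
simulations. Two caveats are documented rather than hidden: (a) local-linear
smoothing leaves a curvature-proportional residual, so on a strongly curved
bias a second pass still changes M at the ~1e-2 level and repeated passes
converge geometrically — near-idempotence (< 1e-3) holds once no smooth
structure remains; (b) like every M-vs-A regression, the fit absorbs the
local mean of true biology, a ~0.005 log₂ effect at our default mixture.

**Summarization.** Replicate probes of a gene are collapsed by geometric
mean per channel, i.e. exp(mean(log intensities)); a single probe passes
through unchanged. Zero intensities are rejected upstream.

**Floor / log₂ / shift.** Intensities below 1 are raised to 1 (so pre-shift
log₂ values are ≥ 0), then each channel of each array is shifted so its 75th
percentile (linear-interpolation quantile rule) is 0. The shift absorbs any
per-array, per-channel scale factor; downstream ratios are therefore scale
invariant. The shift is per channel per array by default; a pooled variant
(one shift over both channels) is available because the two conventions
differ by a per-array constant in the log-ratio. Per-channel is the default
because the channels are the biological contrast; note that per-channel
shifting recenters each channel on its own distribution, which (i) makes
noiseless ratio recovery exact only under the pooled variant — the
per-channel quantiles of the two channels differ slightly whenever some
genes truly change — and (ii) absorbs any genome-wide expression shift
entirely. Percentile normalization is only meaningful when most genes are
unchanged; a design in which every gene moves the same way is
unidentifiable from these data.

## Baseline differential expression

At the baseline timepoint the three mutant and three wild-type normalized
log₂ values per gene enter an unpaired two-sample t-test (pooled variance;
Welch by flag; scipy's `ttest_ind`). p-values are two-sided and raw — no
multiple-testing correction, by design. Calls combine significance with a
two-sided linear fold rule on the replicate-mean ratio: over iff
fold ≥ 1.5 and p < 0.05, under iff fold ≤ 1/1.5 and p < 0.05. Conventions
for degenerate inputs: zero variance in both groups with equal means gives
p = 1 (call none); zero variance with unequal means gives p = 0, leaving the
call to the fold rule — this is the noiseless limit and makes noise-free
recovery tests exact. Genes floored in every array of both genotypes carry
no signal and are forced to "none" and flagged. The t-test operates on
normalized log₂ intensities (the standard choice for this workflow), not on
linear ratios.

## Change filter and trajectory patterns

Both rules act on the linear ratio trajectory r(0..3), baseline first.

* Filter: keep gene iff max over post-baseline t of |r(t) − r(0)|/r(0)
  ≥ 0.40. Each timepoint is compared to baseline, not to its predecessor.
* Transition labels: for consecutive timepoints, relative change
  (r_next − r_prev)/r_prev; `Up` iff ≥ +0.20, `Dn` iff ≤ −0.20, else `Nc`.
  Labels concatenate to one of 3^(T−1) codes (27 for T = 4).

Boundary convention is ≥ at the threshold ("at least 20%/40%"), with an
absolute guard of 1e-12 on the relative change so decimal inputs like
1.0 → 1.2 classify as intended despite binary floating point. Threshold 0 is
accepted with strict-inequality semantics (only exactly equal ratios give
`Nc`). The signed relative change is measured against the earlier value,
making Up/Dn asymmetric in ratio space (1.0 → 1.2 is Up; 1.2 → 1.0 is a
16.7% drop, hence Nc at the 20% threshold); a log-symmetric variant
(|log₂(r_next/r_prev)| ≥ log₂ 1.2) is available behind `log_scale=True`.
Structural properties asserted by the test suite: filtered genes are
partitioned by pattern; filter and patterns are invariant to scaling a
gene's trajectory; raising the transition threshold can only convert Up/Dn
to Nc (the sensitivity scan reports this monotonicity explicitly); raising
the filter threshold can only shrink the filtered set.

## Enrichment

One-sided hypergeometric upper tail P(X ≥ k) (scipy), exact against full
pmf enumeration for all N ≤ 30 in the tests. The universe defaults to the
genes present on the array after summarization; an explicit universe list
overrides. List genes outside the universe are dropped (logged) and n is the
list size after exclusion. The Bonferroni multiplier counts the terms with
k ≥ 1 in the current list (switchable to all terms in the table); corrected
p-values never fall below raw and cap at 1. Percentages are kept at full
precision internally; display rounding is half-even to 2 decimals with at
most one trailing zero stripped (so 10.00 prints as "10.0" while 7.45 keeps
both decimals).

## Synthetic data generator

The generator emulates the study design so every stage is testable offline:
6253 genes, 2 probes per gene, four timepoints (pre, 10 min and 60 min of
oxidative stress, 60 min post-washout), 3 replicate arrays per timepoint
with the middle replicate dye-reversed, co-hybridized genotypes.

Per gene it plants: a pattern code drawn from configurable weights (default
mixture: ~92% non-responders `NcNcNc`, and a 511/6253 responding fraction
dominated by `NcNcUp` (241/6253) and `NcNcDn` (50/6253), the remainder
uniform over the other 24 codes — the late-divergence structure typical of
recovery-defective mutants); a baseline ratio r₀ (for the 5% baseline-DE
fraction, a fold drawn log-uniformly from [2, 4] in a random direction; for
the rest, a log-normal wobble of SD 0.1 log₂, clipped at ±0.4 so it can
never cross the 1.5-fold call boundary); and a wild-type abundance drawn
log-uniformly over [50, 50000] arbitrary units.

Trajectories realize their code with a safety margin (default 1.5×): Up/Dn
steps are ±margin·20% relative changes, the first non-Nc step is pinned at
r₀·(1 ± margin·40%) so the gene clears the filter regardless of preceding
Nc jitter, and Nc steps jitter uniformly within a half-width chosen so that
(i) each stays inside the 20% threshold with margin and (ii) a run of all-Nc
steps drifts less than the 40% filter from baseline. Every planted
trajectory is re-checked against the actual classifier at generation time;
margins small enough to be ambiguous (< 1.05) are rejected up front.

Arrays get independent per-probe, per-channel log-normal noise (default SD
0.05 log₂ — at that level, with 1.5× margins, pattern misassignment requires
a ≳2.8σ noise excursion on a transition, so recovery stays above 99%, well
clear of the 90% acceptance bar). Optional dye bias adds
amplitude·sin(π·u) to the log-ratio, u being the min-max-scaled mean log₂
intensity — a smooth, intensity-dependent, loess-removable shape. All
randomness flows from the design seed through named `default_rng` streams
(`seed` for truth — the pattern draw is documented as the first consumption,
so tests can regenerate it independently — `[seed, 1]` for hybridization
noise, `[seed, 2]` for the synthetic annotation table), making every output
file bitwise reproducible.

What the generator does **not** emulate — and hence what passing recovery
tests do not show about real arrays: spatial artifacts and background,
probe-sequence effects, correlated (non-independent) noise across probes or
channels, outlier-heavy noise tails, and annotation structure with a true
GO graph. Real-data performance near the 20%/40% boundaries will be worse
than the planted-margin setting by construction.

## Problem sizes and numerical choices

Unit tests run at 200–2000 genes; end-to-end recovery and calibration checks
run at the full study scale (6253 genes, and 10,000 genes for the null
calibration of the t-test), which completes in seconds per run. Quantiles
use linear interpolation; trajectory boundaries use the 1e-12 absolute
guard described above; the fold-change boundary uses a 1e-12 relative
guard; file I/O parses floats with exact round-trip semantics and writes
shortest-repr decimals so writer ∘ reader is byte-identical.

## Known limitations

* Per-channel percentile shifting leaves a small per-array offset in the
  log-ratio whenever the responding fraction is asymmetric (~2% at the
  default mixture); it cancels nowhere but is far inside the 1.5× planting
  margins. Use the pooled variant if exact ratio recovery matters more than
  per-channel comparability.
* The rule-based classifier has no uncertainty: a gene a hair from a
  threshold flips clusters under infinitesimal noise. The sensitivity scan
  (default 20% vs 30%) is the provided robustness check.
* Bonferroni over observed terms is conservative and ignores term overlap;
  no FDR alternative is implemented, by design.
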