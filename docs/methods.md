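# Methods

## Model and assumptions

The quantification model treats each sample (or isobaric channel) as
applying one multiplicative loss/loading factor `k_s` to every peptide that
passes through the immunoprecipitation–elution–filtration workflow. Internal
hipMHC standards are spiked into the lysate *before* enrichment, so they
experience the same `k_s` as endogenous peptides; this shared-loss premise
is the entire basis of the correction and is a built-in property of the
synthetic-data generator. Observed intensity is modelled as

    I(p, s) = base_p · k_s · effect(p, s)^(1/γ) · 2^ε,   ε ~ N(0, σ_log2)

with `γ ≥ 1` a power-law compression of the fold scale (dynamic-range
suppression: a true fold F is observed as F^(1/γ)) and multiplicative
lognormal measurement noise drawn independently per PSM per channel.

## Correction factors

* **TMT (median of ratios).** All retained correction-standard PSMs are
  pooled across standards, charge states and fractions. For each PSM the
  per-channel ratio to the reference channel is taken; the factor for
  channel c is the reciprocal of the median ratio, and the reference factor
  is exactly 1. PSMs with zero/missing reference intensity are excluded
  with a warning.
* **Abundance window.** Standard PSMs whose mean reporter intensity falls
  outside `[Q1/10, Q3·10]` of the endogenous per-PSM mean-intensity
  interquartile range are dropped before the median (quantiles by linear
  interpolation, bounds inclusive). The window is the widest literal
  reading of "within 10-fold of the interquartile range" and the fold is
  configurable. Removing *all* standard PSMs is a hard error: it means the
  spike level is outside the regime the correction is valid in.
* **Label-free (mean of ratios).** Per standard, the per-sample summed AUC
  is ratioed against the reference sample; the factor is the reciprocal of
  the mean over standards. Summed-AUC-per-standard (rather than per-PSM)
  ratios are used because LF replicates quantify each standard once per
  analysis.
* **Per-condition factors.** When the global mean fold change between
  conditions exceeds 2× (|mean log₂ FC| > 1), a single factor set would
  absorb biology into normalization (reporter co-isolation makes standard
  ratios track the bulk shift), so factors are computed independently
  within each condition group, each with its own reference channel. The
  trigger is automatic by default and can be forced on/off.

Estimator variance: a channel ratio carries √2·σ_log2 of log₂ noise, so the
median of n pooled ratios recovers log₂ k with SE ≈ 1.253·√2·σ_log2/√n.
At σ_log2 = 0.2 this is ≈ 0.079 with 20 pooled standard PSMs and ≈ 0.040
with 80 — the tests assert the noise-free case exactly and the noisy case
at this statistical scale, and the acceptance report states the measured
rate at which all channel factors land within 0.1 log₂ of truth at n = 20,
which this arithmetic places near 35–45%, not near certainty.

## Suppression

A titrated standard with spikes spanning a_min…a_max estimates suppression
as the expected fold divided by the observed adjusted-intensity fold at the
extreme points, matching the single-fold-per-peptide convention; an OLS fit
of intensity on fmol (r² for raw and adjusted values) is reported
alongside, and a slope-based estimate is available from the same fit.
Under the generator's power-law model the extreme-point estimate returns
(a_max/a_min)^(1−1/γ) exactly — e.g. √10 ≈ 3.16 for a 30–300 fmol titration
at γ = 2 — which the test suite uses as a round-trip oracle.

## Absolute quantification

Targeted runs are modelled channel-per-replicate: the heavy calibrant is
spiked at a different known amount into each replicate, the light
endogenous peptide is present in all of them, and normalization standards
are spiked equally. Per channel, the scan-level reporter trace is fitted
with a no-baseline Gaussian (nonlinear least squares; initialised at the
tallest scan with σ from the half-max width); the **apex is the fitted
amplitude**, not the tallest raw scan, making it robust to scan cadence. A
fit that fails to converge falls back to the tallest observed scan and is
flagged. Correction factors come from the normalization standards' apex
ratios (same median-of-ratios estimator as multiplexed runs). The adjusted
calibrant apexes versus fmol form an OLS standard curve (intercept
included); endogenous apexes invert through it, negative back-calculations
clamp to zero with a flag, and copies per cell uses
N_A = 6.02214076 × 10²³ with replicates quantified independently
(mean ± sample SD reported).

## Differential statistics

Fold change is the ratio of arithmetic group means (complete cases only; no
imputation — peptides missing in any compared sample are excluded, and a
zero control mean excludes the peptide). Significance of an increase is an
unpaired two-sided Student's t test (equal-variance by default, Welch by
flag); a zero-variance tie returns p = 1. Mean-adjusted significance
divides treated intensities by the arithmetic mean of per-peptide fold
changes (geometric mean by option) before re-testing; centering is skipped
inside the ±0.07 log₂ exemption band, where it would only add noise. No
multiple-testing correction is applied at the peptide level by default;
a Benjamini–Hochberg layer is available. The replicate-spread summary
reports per-peptide CV (sample SD / mean, ddof = 1) with its median, and a
Gaussian fitted to the Freedman–Diaconis-binned histogram of pooled
log₂(x/μ) ratios (μ = the peptide's mean across the replicates), whose σ
converts to the 3σ fold-change bound 2^(3σ); the direct SD of the pooled
ratios is reported alongside the histogram fit. Fewer than 30 pooled
ratios fall back to the direct SD.

## Enrichment

Peptide scores collapse to one score per protein — the maximum log₂ FC for
positive-direction analyses, the minimum for negative — sorted descending
with lexicographic tie-break for determinism. The enrichment score is the
standard weighted running sum (w = 1): hits add |score|^w normalised by the
summed hit weights, misses subtract 1/(N − N_hits); the ES is the signed
extreme of the running sum, with a near-tie (|max| = |min| within 1e−9)
resolving to the positive side so that floating-point jitter cannot flip
the sign. The null is gene-label permutation (≥100, default 1000, fully
seeded): nominal p is the same-sign tail fraction floored at
1/n_permutations, NES divides ES by the mean same-sign null magnitude (a
documented stand-in for external tools' internal normalization), and FDR q
is Benjamini–Hochberg across tested sets. Sets overlapping the list below
the minimum size (8 for peptide-derived lists, 15 for expression lists) are
flagged not-testable. The conventional reporting filter is p ≤ 0.05 and
q ≤ 0.25.

## Synthetic data

The generator emulates the study designs: a 6-plex (or label-free) replicate
experiment of ~10⁷ cells with two correction standards at 30 fmol and one
standard titrated 30–300 fmol across channels, and targeted runs with a
0.3/1/3-fmol embedded calibrant series. Base abundances are lognormal
(log₂ ~ N(17, 2)); endogenous peptides yield Poisson-many PSMs (mean 2;
zero means unobserved, reproducing real missingness) while standards get a
fixed PSM count (default 10 per standard) so normalization is always
estimable; each PSM is an independent full-scale measurement whose
per-channel intensities carry independent lognormal noise (default
σ_log2 = 0.2, consistent with raw TMT replicate CVs near 15%). Standards
pass through the same loss factors as endogenous peptides. Everything is
driven by a single integer seed and byte-reproducible.

What the generator does **not** emulate: co-isolation interference
structure, correlated (shared) reporter noise within a spectrum,
intensity-dependent noise, charge-state/retention-time chemistry, or
peptide-specific suppression (γ is global). Passing tests therefore
demonstrate the estimators' correctness under the stated model, not
instrument-level fidelity; in particular, correlated within-spectrum noise
would make factor recovery *easier* than the independent-noise setting
tested here.

## Problem sizes and numerical choices

The test suite and acceptance script use 150–2000 synthetic peptides per
run, 200 seeded repeats for factor-recovery rates (repeats use 150
endogenous peptides, since the endogenous set only enters through the
abundance-window quantiles), 100 seeds for noisy absolute-quant recovery
and 1000 permutations for enrichment — sizes chosen so each property is
measured at well-resolved statistical precision while a full run stays in
the tens of seconds. Gaussian and histogram fits use `scipy.optimize`
defaults with analytic initial values; fit failures fall back to documented
closed-form surrogates rather than erroring mid-pipeline. All thresholds
(ion score 20 LF / 15 TMT, percolator q ≤ 0.05, isolation interference
≤ 30%, length 8–15) are inclusive and overridable.

## Known limitations

Cross-plex bridge normalization, match-between-runs-specific score
handling, spectrum-level simulation, and binding-affinity prediction are
out of scope. The NES normalization is a sign-matched mean, not parity
with any external desktop tool. Absolute quantification assumes the
calibrant series brackets the endogenous level (extrapolation warns) and
that suppression is locally linear across the bracket.
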