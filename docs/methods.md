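# Methods

This note records the models, parameter choices and numerical conventions
behind `phosquant`, and what the synthetic-data tests do and do not
demonstrate about real data.

## Experimental model

The package models a two-channel SILAC time course: a light channel
(reconstituted cell line) and a heavy channel (deficient line, R +10.00827
Da, K +8.01420 Da), mixed 1:1 per timepoint, with eight stimulation
timepoints and three replicate experiments.  Seven of the timepoints
correspond to stated stimulation times of 0, 1, 1.5, 2, 3, 5 and 10 min;
the experimental description counts eight total timepoints without naming
the eighth time, so timepoints are handled internally as ordered labels
(t0…t7) and no eighth time is invented.  Downstream rules (the
4-of-8-timepoints observation requirement, per-timepoint testing) depend
only on the ordering.

Two quantitation tracks coexist:

* **Label-free** (within the light channel, across timepoints): peak areas
  are divided by the area of the co-purified 10-pmol spike peptide
  LIEDAEpYTAK in the same timepoint/replicate, cancelling injection-scale
  differences.  The trajectory value is log10(normalized area / geometric
  mean over the peptide's defined timepoints), so defined values sum to zero
  per peptide; display is capped at ±log10(100).
* **SILAC** (heavy/light, within a run): ratios are formed on *raw* areas —
  the channels are co-injected, so run-scale factors cancel by construction
  and spike normalization would only add noise.  Display is capped at
  ±log10(50).

## Identification and FDR

Score gates follow the original search criteria (strict inequalities):
engine A (Xcorr-like) > 1.5/2.0/2.5 at charge +1/+2/+3, engine B
(Mowse-like) > 10, |precursor error| < 20 ppm, charges outside +1…+3
rejected.  FDR uses the concatenated target-decoy estimator
FDR = 2·D/(T+D), clamped to [0, 1].  The per-engine operating threshold is
the smallest unique observed score whose acceptance set (ties accepted)
has estimated FDR ≤ the 0.005 target; because the estimate is not monotone
in the cutoff, the scan covers every unique score rather than stopping at
the first infeasible one.  A published logistic-regression spectral score
used in the original filtering chain is external to this package; decoy FDR
on the engine scores is used instead, which changes the ranking statistic
but not the error-control contract.  The FDR is computed on the assembled
(post-union) list; computing it per engine before union is the documented
alternative and gives the same thresholds here because thresholding is
per-engine either way.

Non-redundancy is keyed on (sequence, set of localized phosphosites), so
positional isomers remain separate entries; the best score per engine and
all (timepoint, replicate) observations are retained.

## Site localization

The localizer is a simplified member of the Ascore family, not a
re-implementation of any published parameterization: singly charged b/y
ions only, fragment tolerance 0.5 Da, peak depths k = 1…10 per 100-m/z
window (ties in intensity break by m/z so results are independent of peak
order).  For the top two candidate isoforms, site-determining ions are
those b/y ions whose m/z differ between them; each candidate's matched
count k among n site-determining ions is scored as −10·log10 P(X ≥ k) with
X ~ Binomial(n, p), p = k_depth·(2·tol)/100.  The reported score is the
top-two difference maximized over depths; equal matched counts give score 0,
the lowest-index site and an ambiguity flag.  Numeric scores are therefore
not comparable with vendor Ascore values; only the top-site call and the
relative confidence are meaningful, which is all the pipeline consumes.

## Peak integration

The vendor ICIS algorithm is proprietary; the integrator here is a
documented approximation driven by the four conventional parameters:

* *multiple resolution* (8) — width in scans of the moving-average smoother
  used for apex and boundary detection;
* *noise window* (40 scans) — window around the apex within which the
  baseline is estimated;
* *scans in baseline* (5) — number of lowest-intensity scans in that window
  whose mean defines the baseline;
* *noise tolerance* (0.1) — boundaries are where the smoothed trace falls to
  baseline + 0.1·(apex − baseline), then extended down any monotone descent
  toward baseline so slow tails are not clipped.

The area is the trapezoidal integral of the raw, baseline-subtracted trace
between the boundaries.  A minimum area of 500 counts (the typical spectral
noise level) is required, inclusive at the boundary; cells failing the floor
are blanks, and a blank on either channel blanks the SILAC ratio.  The SIC
extraction m/z tolerance defaults to 10 ppm (not stated in the source
protocol; chosen as typical for the instrument class).  Window parameters
are in scans, so callers sampling much faster than ~1 scan/s should scale
them accordingly.

## Statistics

Both t-tests run on log10 areas: multiplicative replicate noise makes log
areas approximately normal, and the paired test's differences are then log
ratios.  The label-free track uses an unpaired two-sided Student t-test per
timepoint against the timepoint with minimal mean (ties: earliest wins;
reference gets p = 1; Welch available by configuration).  The SILAC track
uses a paired two-sided t-test across replicates.  Zero-variance inputs are
not perturbed: identical groups give p = 1, distinct means with zero spread
return a blank p with a degenerate flag (silent p = 0 at n = 3 would be
worse than a blank).

q-values are computed from scratch: π0 is estimated on the λ grid
0.05…0.95 (step 0.05) via π0(λ) = #{p > λ}/(m(1−λ)) with a cubic polynomial
smoother evaluated at λ = 0.95, falling back to π0 = 1 when fewer than 100
p-values are available or the estimate leaves (0, 1]; then
q_i = min_{p_j ≥ p_i} π0·m·p_j/rank(p_j), clipped to 1.  The multiple-testing
family is one heatmap (all peptides × timepoints of one comparison type).
Significance is strict: q < 0.02.  Numeric agreement with any particular
QVALUE release is not claimed — the λ grid and smoother are stated above
and the π0 = 1 mode reproduces the classic step-up values exactly.

Heatmap cells aggregate replicates as ratio-per-replicate, then mean of
logs (the alternative — mean of areas, then one ratio — is a documented
switch away but not the default).

Reproducibility of SILAC ratios across replicates is summarized by log2
ratio-of-ratios (R2/R1, R3/R1, R3/R2) per peptide at a fixed timepoint:
mean, SD, and the fraction within ±0.6 (≈1.5-fold agreement).  For
log-normal channel noise the log2 ratio-of-ratios is normal, so the
in-range fraction has the closed form Φ(0.6/σ′) − Φ(−0.6/σ′) with σ′ its
SD — the calibration used in the tests.

## Synthetic data

The generator emulates the statistical structure the analysis assumes, per
peptide and (timepoint, replicate):

* base abundance log-uniform over 10⁴–10⁵·⁵ area counts; trajectory classes
  `null` (flat, ratio 1), `induced` (light rises to an ~18-fold maximum),
  `early_up_late_down` (ratio ~2 early decaying to 0.3 — the
  kinase-activation-loop pattern), `constitutively_reduced` (ratio 0.25
  throughout); default mixture 40/25/20/15%;
* injection scale factor per (timepoint, replicate) uniform on [0.5, 2.0],
  applied to every area including the spike, whose own area is otherwise
  noise-free so that normalization tests have an exact target;
* multiplicative log-normal replicate noise, σ = 0.2 (natural log), chosen
  to give replicate CVs in the tens of percent;
* Gaussian elution peaks (σ = 3 s on a 60-s window, 1-s scans) over a
  half-normal baseline (SD 10 counts) whose integrated magnitude is of the
  order of the 500-count floor;
* 10% of (peptide, timepoint) cells missing entirely;
* engine scores as two correlated Gaussians (ρ = 0.7) with separated
  target/decoy distributions; each spectrum is spurious with probability
  2%, landing on a decoy or a target sequence with equal probability —
  exactly the assumption under which the decoy count estimates the false
  target count.

Everything is driven by one `numpy` generator seeded by the caller, so runs
are bit-reproducible.

What the generator does *not* emulate: chromatographic co-elution and
retention-time drift, isotope envelopes and deisotoping errors, intensity-
dependent (heteroscedastic) noise, correlated missingness (censoring of
low-abundance peptides), real fragmentation intensity patterns, and
engine-specific score pathologies.  Passing tests therefore demonstrate the
correctness and calibration of the analysis chain under its own model
assumptions — not performance on raw instrument data, for which the
original study's deposited quantitation tables would be required.

## Problem sizes and defaults

Test and acceptance runs use 15–120 peptides (up to ~5,000 PSMs), three
seeds for recovery checks, and ≥2,000 tests for p-value calibration —
sizes at which Monte-Carlo error is small relative to the tolerances while
a full run stays in the seconds range.  All printed thresholds (score
gates, 20 ppm, 0.5% FDR, 500-count floor, 4-of-8 rule, caps, q < 0.02) are
configuration defaults, never hard-coded in stage logic.

## Known limitations

* The FDR bracket between the decoy estimate and realized false matches is
  a small-count comparison (both ~Poisson with means of 10–20 at these
  sizes); checks account for both errors rather than treating the estimate
  as exact.
* Paired t-tests at n = 3 replicates have 2 degrees of freedom; q < 0.02
  discoveries on the SILAC track require strong, consistent effects, and
  small runs may report none.
* The localizer handles at most the candidate set it is given and two
  phospho groups; neutral-loss and c/z ions are out of scope.
* Figures are rendered views; only the TSV exports are asserted
  byte-reproducible.
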