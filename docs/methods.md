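# Methods

## What is simulated, and why

The package benchmarks *processing* workflows, not spectrometers. Spectra are
therefore generated directly in the absorption-mode frequency domain — no
FID, Fourier transform or phasing — because every workflow under test starts
from processed spectra anyway. A study consists, per pulse sequence (zgpr
and NOESYpr), of three urine replicates and five calibration-solution
spectra: one tube measured three times (replicates share a single chemistry
draw but have independent noise and shift jitter) versus five separately
prepared solutions (independent chemistry draws).

Each metabolite is a set of multiplets: a centre shift, line offsets and
weights (weights sum to 1), and a proton count. A line of metabolite *x* at
shift δ is rendered as a pseudo-Voigt of height

    h = C_x · N_x · weight · response_factor · A(δ)

where `A(δ) = 1 − α·exp(−(δ−δw)²/(2σw²))` is the presaturation attenuation
notch around the water position δw = 4.70 ppm. The absolute
`response_factor` (10⁻³ intensity per µM·proton) is arbitrary: internal
referencing is a ratio and external calibration is scale-free, so no
conclusion depends on it.

## Default study conditions

| parameter | default | rationale |
|---|---|---|
| spectral window | 11.3 → −0.7 ppm, 2¹⁶ points | 12-ppm width typical of urine work; digital resolution is not critical and is configurable |
| spectrometer frequency | 600 MHz | standard high-field metabolomics instrument |
| linewidth (FWHM) | 1.2 Hz = 0.002 ppm | typical for buffered small molecules |
| Lorentzian fraction η | 0.8 | mostly Lorentzian lines with mild Gaussian character |
| urine concentrations | 64–7959 µM over 32 metabolites | physiological span; creatinine is the most concentrated |
| calibration solutions | five per metabolite, geometric ladder 0.4×–5× the urine level, clipped to 0.1–12 mM globally | brackets the expected value inside the stated global range |
| TSP | 9-proton singlet at 0.000 ppm, 500 µM in every sample | the reference concentration is a convention; results are invariant to it |
| noise | σ set so the weakest urine multiplet has SNR ≈ 15 | exercises the SNR > 10 quantifiability rule without mass dropouts |
| baseline | random polynomial, degree ≤ 3, amplitude 20 σ | what a degree-3 automatic correction is expected to remove |
| residual water | Gaussian hump at 4.70 ppm, σ = 0.01 ppm, height ≈ tallest metabolite peak | a presaturation tuned so residual water matches the strongest metabolite signal |
| attenuation notch | α = 0.6, σw = 0.15 ppm | assumed values — the attenuation profile of a real presaturation is instrument- and setup-dependent and is not calibrated against measurements |
| shift jitter | global 0.003 ppm + per-peak 0.0005 ppm | small sample-to-sample drifts; undone (globally) by TSP referencing |
| zgpr/NOESYpr ratio | per-peak, uniform in [1.1, 1.3], drawn once per study | the sequences see the same samples, so the ratio is a property of the peak, shared by all spectra |
| creatine fraction range | f ~ U(0.1, 0.9) per solution | wide interconversion scatter; the sum is conserved exactly |
| operators | 6; region boundaries jittered with σ = 0.003 ppm, alternative-multiplet probability 0.15 | operator-dependent integration limits; deconvolution and realignment run as single operators |

One deliberate design choice in the calibration design: each metabolite's
five ladder levels are assigned to the five solutions in a metabolite-specific
(deterministic) permutation, so co-resonant species are decorrelated across
solutions. With strictly proportional ladders, a contaminated region would
still produce a beautifully linear — but wrong — calibration curve; with the
permuted design, contamination shows up as a low R², which is what lets the
curve-usability rule (below) mimic an operator discarding a visibly
non-proportional curve.

Sample chemistry is applied to nominal concentrations before rendering:
cysteine is fully dimerized (cysteine → 0, cystine = cysteine/2, 2:1 molar
stoichiometry; the library's nominal cystine entry already records this
outcome), and a per-solution fraction f redistributes the conserved
creatine+creatinine total.

## The quantification strategies

* **int_tsp** — trapezoidal integral over the (operator-perturbed) region,
  converted by `Cx = (Ix/Is)·Cs·Ns/Nx`. No self-diagnostic exists: any
  contamination or attenuation lands directly in the result.
* **int_extcal** — same integrals; OLS line `Ix = a·Cx + b` (intercept
  retained, matching the printed model form) over the five solutions,
  inverted. A curve is **unusable** when a ≤ 0 or R² < 0.95; negative
  concentrations clamp to 0 with a flag (difference composites keep sign).
* **int_realign_extcal** — per-region integer-grid cross-correlation
  realignment against the first urine replicate before integration; integer
  shifts preserve areas exactly.
* **deconv_extcal** — per-region segment (±0.010 ppm margin): local linear
  baseline through the end medians, Savitzky–Golay (window 9, order 3)
  second-derivative seeding at 5× the derivative-noise MAD, plus the library
  line positions of co-resonant multiplets as fallback seeds (targeted
  deconvolution: the operator tells the tool where to look), then
  Levenberg–Marquardt refinement of (centre, height, width, shared η) with a
  jointly fitted residual linear baseline. Bounds: centre ±2 widths of the
  seed, width 0.2–5× default, η ∈ [0, 1]. Metabolite areas sum the
  closed-form areas of fitted peaks matched to library lines within 0.003
  ppm (each peak used once; ties by |Δδ|, then larger area); a missing line
  means ND. Calibration spectra are deconvolved with the same engine and
  feed the same curve machinery.

Quantifiability is SNR > 10, strictly, with SNR = peak height over the
standard deviation of the detrended 10.5–11.2 ppm noise region (a simple,
reproducible convention; not the vendor peak-to-peak one).

Composites: creatine+creatinine and lactate+threonine are quantified from
one combined region each (not by adding two separate results);
cysteine_est = 2×cystine; fructose_est = (glucose+fructose region) − glucose
per replicate, sign preserved.

## What the generator does and does not emulate

It emulates the study's documented failure mechanisms — the
acetic-acid/lysine overlap (1.92 ppm singlet inside the 1.87–1.97 ppm
multiplet), the shared lactate/threonine methyl region, the shared
creatine/creatinine 3.03–3.06 ppm region with interconversion, the
glucose-near-water attenuation bias, cysteine loss to cystine — with
plausible literature-style chemical shifts. It does **not** emulate spin
physics (J-coupling patterns are fixed line tables, no second-order
effects), pH-dependent shifts, shimming distortions, T1/mixing-time effects
(the NOESYpr difference is a per-peak intensity rescale only), or the
peptide/protein background of real urine. Passing tests therefore shows that
the *processing logic* behaves as the mechanisms predict, not that any
particular real-urine number would be reproduced.

## Numerical choices

* ppm axes are strictly decreasing; region boundaries are inclusive at both
  ends; lines are rendered within ±300 FWHM of their centre.
* Baseline correction: degree-3 polynomial by 20 iterations of asymmetric
  reweighting (points above the fit weighted 0.01) — deterministic and
  parameter-light; removes any polynomial of degree ≤ 3 exactly.
* TSP referencing translates the axis so the parabolically interpolated TSP
  apex sits at exactly 0 ppm; it errors when no maximum exceeds 5× noise.
* Internal referencing evaluates `(Ix/Is)` first so self-referencing returns
  Cs exactly in floating point.
* Realignment shifts are integer grid steps with edge-value fill, searched
  over ±(2·max_shift + 5 steps) and clamped (with a flag) to ±max_shift.
* The exact rank-sum test enumerates all C(n+m, n) assignments of pooled
  mid-ranks when n+m ≤ 14 (ties handled exactly; the symmetric-tail
  definition gives p = 1 for identical samples) and otherwise uses the
  tie-corrected normal approximation. Kruskal–Wallis uses the tie-corrected
  rank formula with a χ² reference; all-equal data returns H = 0, p = 1.
  No multiple-testing correction is applied; reported p-values are raw.
* PCA autoscales with training statistics only and projects the held-out
  theoretical sample with the training loadings; constant columns are
  dropped with a warning entry.

## Problem sizes

The default acceptance computation uses ten independently generated studies
(per study: 8 zgpr spectra of 2¹⁶ points, 35 quantities) — enough for the
headline fraction to be stable to ~1 percentage point across seeds while the
whole script finishes in well under a minute. The test suite uses one shared
default study plus small constructed fixtures.

## Known limitations

* Chemical shifts, multiplicities and the urine composition are curated
  defaults, editable as a table, not measured values; only the overlap
  structure is load-bearing.
* The attenuation notch parameters (α, σw) are assumptions; the glucose bias
  they produce is qualitative (direction and mechanism), not calibrated.
* Deconvolution is segment-wise with a shared η per segment; heavily
  crowded segments (e.g. the 3.4–3.6 ppm sugar region) can still fail
  assignment and return ND, as the region-overlap design intends.
* The operator model perturbs region boundaries and multiplet choice only;
  real operators also differ in phasing, baseline and annotation judgement.
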