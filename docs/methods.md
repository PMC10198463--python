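# Methods

This note documents the models, defaults, and numerical choices behind
`ramancode`, and what the synthetic tests do and do not establish about
real measurements.

## The code book

A code scheme is three reference/coding compound pairs (regions X, Y, Z),
a level map, an alphabet, and a sequence template.

* **Default pairs** (region: reference / coding, cm⁻¹): X: II-2160 / II-2110,
  Y: I-2245 / I-2220, Z: III-1140 / III-1105.  All marker bands are modeled
  as Lorentzians with FWHM 10 cm⁻¹ (narrow alkyne and fingerprint bands);
  Gaussian lineshapes are available via configuration.  The first-listed
  compound of each pair acts as the reference; published accounts do not
  state which member is which, and decoding depends only on the choice
  being fixed scheme-wide.  The pair figure names I-2220 while the
  survivability narrative lists I-2225; the code book defaults to 2220 and
  the survivability fixture carries I-2225 — both transcriptions are kept
  and the discrepancy is noted rather than resolved.
* **Level map**: `r_ℓ = (ℓ/9) · r_max` with `r_max = 1.5`, `r_0 = 0`
  exactly (no coding compound at level 0).  The true dosage-to-level table
  used on the bench is not public; a linear ladder is the simplest
  10-level scheme and is fully configurable.
* **Code numbering**: `#XYZ = 100x + 10y + z`.  This digit order is the
  only one consistent with `#575 ↔ cGRGDdvc` under the printed alphabet
  (x=5→G, y=7→R, z=5→G) and with the screen outcome "X=#5, Y=#7,
  Z=#0–9".
* **Template**: `c{Z}{Y}{X}Ddvc` read N→C — the Z-residue is the 2nd
  position of the written string, X the 4th, matching the 7th/6th/5th
  amino-acid convention of the cyclic peptide.

## Amino-group allocation

Sequential partial Dde deprotection allocates fractions (0.6, 0.3, 0.1) of
the bead's amino groups to regions X, Y, Z.  The stepwise schedule operates
on *remaining* groups: `s_k = f_k / (1 − Σ_{j<k} f_j)` = (0.60, 0.75, 1.0).
`design_allocation` computes the schedule and a forward simulation of
sequential deprotection reproduces the targets to machine precision (this
is a unit-tested identity, not an approximation).

## The synthetic bead model

A bead spectrum on the 600–3200 cm⁻¹ grid (2 cm⁻¹ step, the instrument
resolution) is a sum of seven height-normalized profiles:

* reference amplitude of region k:
  `A_k = base_amplitude · native_scale · allocation · decay^k`, with
  `base_amplitude` 100 a.u., native scales 1/5/50 (Groups II/I/III), and a
  per-synthesis-round signal decay `decay = 0.4`.  This yields reference
  heights 60/60/80 a.u. for X/Y/Z.  The decay default was derived by
  requiring the allocation design to do what it was designed for —
  equalize the three regions' signal levels given cross-sections that span
  a factor of 50: `1·0.6 ≈ 5·0.3·d ≈ 50·0.1·d²` has the consistent
  solution `d ≈ 0.4`.  It is an *effective* per-round decay folding in
  coupling efficiency and sampling-volume effects, not a measured coupling
  yield.
* coding amplitude `A_k · r_ℓ` for the bead's digit ℓ;
* the polystyrene matrix band at 1001 cm⁻¹ (FWHM 12, amplitude 400 a.u.) —
  the conventional strong polystyrene ring-breathing band; the position is
  configurable.

**Noise model** (the published data show only replicate-dispersion shading,
no quantitative noise figures; these defaults were fixed once from a
signal-to-noise design calculation targeting ≈4 σ separation between
adjacent level centroids, so that decoding is reliable at default
conditions while a noise sweep still degrades it):

* additive Gaussian, per-point sd 2.0 a.u. per frame, shrunk by
  `1/sqrt(n_frames)` with 5 frames averaged by default;
* a lognormal bead-to-bead brightness factor, CV 8%, applied to all
  chemical peaks jointly (bead size/focus) — it cancels in every ratio by
  construction;
* a random quadratic baseline with 10 a.u. scale (substrate fluorescence,
  stray light).

The generator emulates: level structure, region equalization, replicate
variance, brightness variation, baseline drift, frame averaging.  It does
**not** emulate wavenumber miscalibration, cosmic-ray spikes, detector
nonlinearity, cell-derived background bands, or compound-specific
linewidth variation — so passing tests demonstrate the pipeline's logic
and statistical behavior, not robustness to every instrumental artifact.

**Binding model.** The default screen gives `p = 0` to any code without
x=5, y=7 (the -RG- of the RGD motif is obligatory), `p = 1.0` to #575 and
`p = 0.1` to the other z values.  With a 12,000-bead library (~12 beads
per code) this makes the modal decoded sequence `cGRGDdvc` with ≈99.6%
probability over the split-and-pool randomness; the observed positive
count (~20–50) is below the ~63 of a real screen because a uniform OBOC
library cannot give one code more beads than its expectation, so matching
both the total hit count and a 35% modal share is impossible — the model
preserves the qualitative structure instead.

## Preprocessing

Crop to 900–2400 cm⁻¹ (covers the three regions plus the internal
standard), Savitzky–Golay smoothing (window 7 points, cubic), then
asymmetric-least-squares baseline estimation (λ = 1e5, p = 0.01, 10
iterations) solved via banded Cholesky (O(n) per iteration, verified in
tests against an independent sparse-matrix formulation).  The vendor
software's algorithm is unspecified ("automatic smoothing and baseline
correction"); ALS is the standard parameter-exposed choice for Raman.
Correction is applied always, not "when needed" — the criterion for *need*
is unstated, and applying it to flat baselines is harmless (tested).
Every step logs itself into the spectrum's metadata; `preprocess` skips
steps already recorded, making the pipeline idempotent by provenance
(repeated smoothing would otherwise progressively broaden narrow bands).

## Quantification and decoding

* `quantify_peak`: baseline-corrected maximum height in a 20 cm⁻¹ window,
  clipped at zero.  Height, not area: robust to linewidth misestimation.
  Used for isolated peaks (polystyrene, survivability, full-loading
  levels).
* `region_ratio`: pair peaks sit only 25–50 cm⁻¹ apart, so each is sampled
  at the grid point nearest its nominal center (a windowed maximum would
  ride up the partner's tail), rescaled by the known lineshape attenuation
  at that grid offset, and the two heights unmixed through the analytic
  2×2 tail-overlap matrix of the pair.  Noise-free, the recovered ratio
  matches `r_ℓ` to ≲1% of the ratio scale; the residual is inter-region
  tail overlap (the Group I/II pairs are 60 cm⁻¹ apart), which is a shared
  systematic absorbed by calibration, since standards are processed
  identically.
* `calibrate_levels`: centroid = replicate mean ratio per (region, level),
  dispersion = replicate sd floored at 1e-3 (so single-replicate
  calibrations still define a margin scale).  Missing levels and
  non-monotone centroids are hard errors, the latter prompting more
  replicates rather than silently reordering.
* `classify_level`: 1-D nearest centroid; margin = (second-nearest −
  nearest distance)/dispersion of the assigned level; exact midpoint ties
  resolve to the lower level; out-of-range ratios clamp to the extreme
  level with a flag.  Equivalence with brute-force distance minimization
  is property-tested on 10⁴ random ratios.
* `decode_bead`: preprocess → three ratios → three levels → code →
  sequence.  Confidence = `1 − exp(−min margin)` — a monotone map of the
  worst region margin to [0, 1]; beads whose reference peak falls below
  5 a.u. are reported undecodable, never guessed.  Whole-spectrum matching
  was deliberately not used: the ratio is the stated decoded quantity, and
  a 1-D classifier per region keeps the error model interpretable.

Zero-noise decoding of all 1000 codes is exact (exhaustive test).  At the
default noise the worst per-bead centroid margins are ≈4 σ, giving batch
accuracy ≥ 99.9%; accuracy is monotone non-increasing in noise sd, and
high-confidence beads are empirically at least as accurate as
low-confidence ones (both property-tested with fixed seeds).

## Survivability

Pass iff `|R_after − R_before| / R_before ≤ δ` with `R` the
compound/polystyrene height ratio and `δ = 0.15` by default — the
published account is qualitative ("unchanged spectrum"), so the threshold
is exposed in configuration.  Conditions run in decreasing severity
(piperidine, TFA, imidazole/NH₂OH, activation, DMSO buffer — the two
harshest first, as on the bench) with early exit; a condition missing
before any failure is an error, conditions after a failure are untested by
design.  The packaged fixture transcribes the 20 named compounds'
outcomes; the source's count of 21 does not resolve to a 21st name and no
row is invented.  The code-set stability analog treats every encoding peak
of simulated beads with degradation 0 (fully survivable chemistry) and
verifies no code assignment moves.

## Screening statistics

Positional counts are a 3×10 occurrence matrix over decoded positives;
a region with exactly one occupied level is conserved.  The modal sequence
is the most frequent code, ties broken deterministically toward the lower
code number (and flagged).  Undecodable beads are excluded from counts but
reported in the summary.  Per-code spectral averaging is a pointwise mean
on a common grid.

## Problem sizes

Defaults used by the test-suite and the acceptance script: 10 diagonal
standards × 5 replicates for calibration; 12,000-bead libraries for the
end-to-end screen; 50 full-loading spectra per group for intensity-scale
recovery; 100-code samples for treatment stability.  These sizes give
sub-percent standard errors on every reported ratio while keeping a full
run in seconds on one CPU.

## Known limitations

* The linear level ladder and `r_max = 1.5` stand in for the bench's
  proprietary dosage table; absolute ratio values are therefore
  scheme-relative, only their separability is meaningful.
* The cross-talk correction assumes the scheme's nominal lineshapes; a
  mismatch (real bands are Voigt-like) would leave a small systematic that
  calibration absorbs but that degrades the "ratio equals r_ℓ" reading.
* Cell-type information is carried only as a categorical label on
  positives; no fluorescence image analysis is performed.
* JCAMP-DX support covers plain AFFN `(X++(Y..Y))` tables only.
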