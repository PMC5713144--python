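# Methods

## The correction model

`saxsred` treats SAXS data reduction as an ordered chain of elementary
transforms on a `DetectorFrame` (2D signal + uncertainty + mask +
metadata + provenance). The chain for one measurement is:

DS read-in → MK masking → PU Poisson uncertainty → DT deadtime →
DC dark current → TI time → FL flux → TR transmission →
(SA self-absorption) → FA frame averaging.

Three such chains combine into the processes:

* **Process A** reduces the instrumental background (empty container)
  through the per-measurement steps above and keeps the result in
  memory.
* **Process B** reduces the sample (solid, or pure dispersant),
  subtracts the Process-A output at the first merging point (BG), then
  applies the once-per-process steps FF flatfield → AE angular
  efficiency → SP solid angle → PO polarization → TH thickness →
  AU absolute units. Output B is dΣ/dΩ in (m·sr)⁻¹.
* **Process C** runs the identical chain on the dispersion, scales the
  stored dispersant signal by (1 − φ) (DV, the volume displaced by the
  analyte) — remapping it from 1D to 2D first if it was stored as a
  curve (RM) — and subtracts it at the second merging point, leaving
  the analyte's cross section alone.

The same container must be used for the background and the sample
measurements so that its scattering cancels in the subtraction; the
pipeline warns when container identifiers disagree, and when a library
entry's beam energy differs from the run energy by more than a relative
10⁻³.

### Uncertainty propagation

Every step propagates uncertainty under the pragmatic assumption that
steps are statistically independent of one another: a multiplicative
step with factor c ± σ_c maps I ± σ_I to
cI ± √((c·σ_I)² + (I·σ_c)²); subtractions add uncertainties in
quadrature; inverse-variance frame averaging yields σ = (Σ 1/σ_k²)^(-1/2).
The independence assumption is not exactly true for corrections that
appear in more than one process with the same correction values (FF,
AE, SP, PO appear in both branches feeding the second merging point),
so the propagated uncertainty of Output C is a mild overestimate — by
construction it is never below Output B's, which the tests check
pixelwise. Steps that can be deferred past a merging point (FF, AE,
SP, PO, TH, AU) run exactly once per process to keep this duplication
minimal while still producing Output B in reusable form.

Because the propagated estimator inherits these approximations, the
1D averaging step computes a second, scatter-based estimator (standard
error of the in-bin mean) alongside the propagated one; exports report
the larger of the two per bin and preserve both. The in-bin mean is
deliberately unweighted so the scatter estimator remains honest.

Background subtraction is performed in 2D before any averaging: an
anisotropic background feature (for example a slit-scatter flare)
inflates the in-bin scatter of both curves if averaging comes first,
while in 2D it cancels pixel by pixel. The test suite demonstrates
this on replicated simulated flares.

### Commutation and ordering

The scalar steps {TI, FL, TR, TH, AU} and the per-pixel map steps
{FF, AE, SP, PO} are plain multiplications and commute mathematically.
Floating-point multiplication chains are not associative, so literal
reordering would change results at the last bit; the pipeline therefore
*canonicalizes*: a step list may present the members of a commuting
group in any order, but each step executes at its canonical site.
Permuted configurations are thus bit-identical by construction.
Orderings that break a genuine constraint (for example PU after DT —
the counting uncertainty must be computed on raw counts) are an error
in strict mode and a warning otherwise.

The units state of a frame advances monotonically along
raw_counts → rate (TI) → normalized (FL) → absolute (AU), and frames
can only be subtracted in matching states.

## Correction formulas

* **PU**: σ = √max(N, 1). The one-count floor keeps empty pixels from
  acquiring infinite weight in inverse-variance averaging.
* **DT**: non-paralyzable model, N̂ = N/(1 − rτ) with r the measured
  rate; the standard choice for the recommended photon-counting
  detectors. Correction refused (SaturationError) at rτ ≥ 0.9.
* **DC**: the dark map is stored as a rate (counts/s) so one dark
  acquisition serves any exposure; since DC precedes TI, the
  subtraction is dark_rate·t in counts.
* **TR**: divide by T = Φ_e/Φ_i; a warning fires when σ_T/T > 1%,
  since the absolute level depends one-for-one on T (the simulator's
  bias-injection test shows a +1% T bias shifting Output B by −1%).
  FL and TR may be fused into a single division by the emergent flux
  Φ_e, which equals the sequential corrections to better than 10⁻¹²
  whenever the metadata are consistent.
* **SA** (plate-like samples normal to the beam only, off by default):
  with s = sec 2θ and u = (s − 1)·ln T, the relative factor is
  F = expm1(u)/u (→ 1 as 2θ → 0), the average Beer–Lambert attenuation
  over scattering depth normalized by the straight-through
  transmission. Verified against numerical path-length integration to
  10⁻⁸.
* **FF**: multiplication matrix normalized to mean 1 over unmasked
  pixels (renormalized with a warning if off by > 10⁻⁶).
* **AE**: the sensor layer of optical depth μ_s·d_s absorbs
  ε(ψ) = 1 − exp(−μ_s·d_s/cos ψ) of photons incident at angle ψ;
  oblique pixels see a longer sensor path and are more efficient. The
  correction multiplies by ε(0)/ε(ψ), referenced to the on-axis pixel;
  the absolute quantum efficiency is folded into the AU calibration.
  This Beer–Lambert path-length model is the package's own adopted
  form; it reproduces the expected qualitative behavior (effect
  largest for thin/transparent sensors, vanishing as μ_s·d_s → ∞).
* **SP**: Ω = (p_x·p_y/L²)·cos³2θ for a flat detector normal to the
  beam (so the incidence angle ψ equals 2θ; detector tilt is out of
  scope). Dividing by Ω puts the signal on an absolute per-steradian
  footing rather than normalizing to the on-axis pixel, so the AU
  factor carries only the remaining scale. Verified against 64×64
  sub-pixel numerical integration to 10⁻⁶ at the default geometry.
* **PO**: P = ν[1 − (cos χ sin 2θ)²] + (1 − ν)[1 − (sin χ sin 2θ)²],
  with ν the horizontally polarized fraction; ν = ½ gives the
  azimuthally uniform unpolarized limit 1 − sin²(2θ)/2. Pixels with
  P < 10⁻⁶ are auto-masked instead of producing enormous corrected
  values.
* **TH**: divide by the sample thickness — for dispersions, the
  thickness of the liquid phase only.
* **AU**: the calibration factor (e.g. from a glassy-carbon or water
  calibrant) is an input, not an operation; calibrant reduction is out
  of scope.
* **DV**: multiply the *dispersant* signal by (1 − φ); applying it to
  the dispersion (role C) measurement is rejected as a sequence error.
* **RM**: linear interpolation of a stored isotropic I(Q) curve onto
  the per-pixel q map; pixels outside the stored Q range are masked.
  Exact on linear curves and at curve nodes.

Conventions: pixel (0, 0) center at coordinate (0.0, 0.0), beam center
in fractional pixel units (column, row); azimuth χ = 0 along
+horizontal, counterclockwise as seen from the sample, range (−π, π];
q = (4π/λ)·sin θ in nm⁻¹.

Masked pixels keep their numeric values through all arithmetic — only
averages and binned statistics honor the mask — so every step remains
a pure, invertible elementwise transform. No operation ever unmasks a
pixel. Provenance enforcement (step-order preconditions, required
prior steps at subtraction) is strict-mode opt-in; the default warns,
since instruments legitimately run bespoke subsequences.

## The synthetic instrument

The forward simulator inverts the correction chain. Expected detected
rate per pixel:

    rate = Φ_i · T · [Σ_sample(q)·d + c] · Ω · P · (ε/ε₀) · S + dark

with Σ_sample the role-dependent cross section (A: none; B: flat
dispersant level; C: dilute-sphere analyte + (1 − φ)·dispersant), c the
container's equivalent scattering, S the per-pixel sensitivity (the
reciprocal of the flatfield correction matrix), and dark the dark-count
rate. Counts are drawn Poisson per frame, then distorted by the same
non-paralyzable deadtime model the DT step inverts (the pair is exact
at the counts level; a paralyzable option exists to measure
model-mismatch error). The analyte is a dilute homogeneous sphere:

    dΣ/dΩ(q) = φ·V·Δρ²·[3(sin qR − qR cos qR)/(qR)³]²,  V = (4/3)πR³.

Default study conditions (chosen once, as a realistic small
beamline setup): 256×256 detector, 172 µm pixels, L = 1 m, λ = 0.1 nm
(12.4 keV), sensor optical depth 1.0, beam 95% horizontally polarized;
R = 5 nm spheres at φ = 1% with Δρ = 3×10¹⁴ m⁻² in a 40 (m·sr)⁻¹
flat-scattering solvent, 1 mm path, container equivalent 0.02 sr⁻¹;
Φ_i = 2×10¹² ph/s, transmissions 0.92 (empty container) and 0.34
(filled), τ = 1 µs, dark 0.05 cps, 1% rms flatfield; 10 frames × 1 s.
These give ~10⁴ solvent counts per pixel, i.e. ~1% per-pixel counting
statistics, and a peak analyte signal ~12× the solvent level —
representative of a well-exposed dispersion measurement. Unit and
module tests use the same instrument scaled to 64×64 / 2–3 frames for
speed.

What the simulator does *not* model — and what passing tests therefore
do not certify — are resolution smearing (beam size/divergence),
multiple scattering, energy-dependent contrast, detector point spread,
charge-integrating artefacts, and temporally varying backgrounds.
Those belong to pattern analysis or are out of scope; the closed loop
validates the correction arithmetic and its uncertainty bookkeeping,
not those physical effects.

In the closed-loop acceptance check, Output C is compared to the
analytic sphere curve only in q-bins where the analyte itself
delivered, on average, more than 10³ accumulated counts per pixel over
all frames. Near the sphere form-factor minimum the analyte
contributes essentially nothing, so a relative comparison there would
measure only background shot noise against a near-zero reference;
outside those bins the recovered curve must (and does) match to a few
tenths of a percent, well inside the 3% gate.

## Numerical choices

* Self-absorption evaluated as expm1(u)/u for stability near u = 0.
* Deadtime distortion applied after the Poisson draw; corrected counts
  then invert it exactly.
* The CLI writes simulated counts rounded to integers (as a real
  detector would); the ≤ 0.5-count rounding is negligible against
  Poisson noise.
* Azimuthal bins assign pixels by center q, top edge inclusive;
  default binning is 100 linear bins over the unmasked q range, with a
  log-spaced option. σ_sem is NaN for single-pixel bins.
* All HDF5 objects are written with timestamp tracking disabled so
  identical runs produce byte-identical files.
* Dark and flatfield calibrations in the synthetic fixture carry zero
  uncertainty (they are "perfectly known"); real calibrations can be
  supplied with per-pixel σ and propagate through the same machinery.
* Library entries may be stored 1D only for isotropic dispersants
  (`check_isotropy` runs a χ-bin dispersion test); 2D storage is the
  default.
* Process A applies TR with the container's own measured transmission.

## Known limitations

* Flat detector normal to the beam; no tilt, curvature or multi-panel
  geometry.
* First-order (linearized) uncertainty propagation; correlations
  between steps are ignored except where the merging-point design
  bounds them.
* The angular-efficiency model is a single-layer Beer–Lambert sensor;
  layered sensors or fluorescence escape are not modeled.
* The displaced-volume correction assumes strict proportionality to
  (1 − φ); structured solvent exclusion around particles is not
  modeled.
* Azimuthal averaging assigns whole pixels to bins (no pixel
  splitting), which adds a discretization error of order the ratio of
  pixel q-width to bin width near the beam center.
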