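# Methods

## Generalized polarization

GP = (I440 − I490)/(I440 + I490), with both intensities read at the exact
grid wavelength of the 400–540 nm, 1 nm emission scan. No bandwidth
integration is applied: integration windows are an instrument-specific
choice, and the single-wavelength read keeps the statistic exactly
antisymmetric under channel swap and invariant under intensity rescaling.
Scan averaging (pointwise mean of the repeat scans of one spectrum) happens
*before* GP; replicate aggregation (mean and n−1 standard deviation across
independent preparations) happens *on* GP values. No background or blank
subtraction is applied, and no wavelength interpolation is performed
anywhere — mismatched grids are a hard error, because silent resampling
hides acquisition faults.

## Melting analysis

The transition is read from the negative derivative of GP with respect to
temperature, computed by the central finite difference over flanking
neighbors, −(GP[i+1] − GP[i−1])/(T[i+1] − T[i−1]). This form is exact for
affine GP on any grid and second-order accurate on uniform grids; on
non-uniform ramps it degrades gracefully to first order. Endpoints are
dropped rather than estimated one-sided, since one-sided stencils bias
exactly the edge region where truncated transitions already cause trouble.

From the derivative peak:

- **T_M** — grid argmax, ties broken toward the lower temperature.
  Optional three-point parabolic refinement (vertex of the parabola through
  the peak and its neighbors, clamped to the neighbor interval) is off by
  default so that reported values land on the acquisition grid and are
  reproducible at grid resolution. At 1 °C steps this means T_M carries a
  ±1 °C quantization, which for broad noisy transitions is the dominant
  uncertainty.
- **Cooperativity (FWHM)** — width between the two half-maximum crossings
  nearest the peak, each located by linear interpolation between bracketing
  grid points. Crossings-nearest-the-peak is robust to secondary bumps; a
  peak that never falls below half maximum inside the range yields NA
  rather than an extrapolated width. For a logistic transition of width k
  the true FWHM is 2k·ln(3 + 2√2) ≈ 3.53 k; the discrete estimate converges
  to it as the grid refines (checked at 1, 0.1, 0.01 °C steps).
- **Enthalpy proxy (AUC)** — trapezoidal area under the −dGP/dT peak, in GP
  units. By the fundamental theorem of calculus it approximates the total
  GP drop across the measured range (within 2% at ≤1 °C sampling of smooth
  curves); it is *not* a calorimetric enthalpy.
- **Detection** — a transition is reported only when the derivative maximum
  is strictly positive, at least 3× the median absolute derivative
  (configurable prominence factor), not constant, and interior to the
  derivative grid. The interior-argmax rule rejects transitions truncated
  by the measured range (e.g. a lipid melting below the instrument's
  reachable temperatures); the prominence rule rejects flat or gently
  sloped curves. The 3× threshold is a design choice, not a measured
  constant, and is exposed as a parameter. Note that on a window only
  ~±4 k wide a very broad transition occupies most of the range and can
  fail the prominence test; windows of ±(6–8) k or wider are recommended
  for broad nanodisc transitions.
- **ΔT_M** — sample T_M minus reference T_M (positive = right-shifted);
  NA with a warning when either transition is undetected.

## Synthetic generator

The generator emulates the statistical structure the analysis assumes, not
any particular instrument. A two-state gel/fluid equilibrium gives the
ordered fraction f(T) = 1/(1 + exp((T − tm)/k)); emission is the f-weighted
mixture of two peak-normalized Gaussian bands at 440 and 490 nm (σ = 18 nm,
common amplitude), plus i.i.d. Gaussian noise with SD a fraction of the
peak amplitude (default 1%), clipped at zero. Each simulated experiment has
3 scans × 3 replicates with sub-seeds derived deterministically from the
master seed, so outputs are byte-reproducible.

With equal-width, equal-amplitude bands the GP of a noise-free rendered
spectrum is *exactly linear* in f: GP = (2f − 1)(1 − b)/(1 + b), where
b = exp(−(50/18)²/2) ≈ 0.021 is the 440/490 cross-talk. The derivative peak
of rendered data therefore sits exactly on the generating midpoint whenever
tm lies on the grid, which is what makes grid-exact parameter recovery a
meaningful end-to-end check. The idealized plateau curve
gp_fluid + (gp_gel − gp_fluid)·f (plateaus 0.55/−0.15) parameterizes the
model object but does not constrain rendered spectra; the rendered GP range
(±0.96) is set by band overlap alone. Consequences: synthetic GP curves are
symmetric about the midpoint and share one amplitude — real curves have
asymmetric, lipid-specific plateaus, temperature-dependent quantum yield,
photobleaching and correlated drift, none of which are modeled. Passing
recovery tests shows the *analysis* is faithful, not that the generator
reproduces real spectra.

Preset midpoints encode literature vesicle transition temperatures (DMPC
24, DPPC 41, DSPC 54, POPC −2 °C) and the reported 11 nm-disc shifts
(+5/+2/0 °C for DMPC/DPPC/DSPC). The 15 nm disc duplicates the 11 nm disc
(reported as indistinguishable), the 50 nm disc matches the vesicle, and
the 25 nm disc takes the on-grid midpoint between them. Transition widths
k = 0.4 (LUV), 2.5 (11/15 nm), 1.5 (25 nm), 0.8 (50 nm) °C encode only the
qualitative ordering "larger discs melt more cooperatively"; neither the
widths nor the GP plateaus are measured values. POPC has only a vesicle
preset: its transition in discs has no published numbers to encode.

## Boundary-lipid geometry

For a disc of diameter d with a perturbed rim annulus of width w (measured
inward from the rim), the unperturbed area fraction is
f = ((d/2 − w)/(d/2))², zero once w ≥ d/2, with the closed-form inverse
w = (d/2)(1 − √f). The reported unperturbed fractions for the four
scaffolds (77/83/90/95% at 11/15/25/50 nm) calibrate to w = 0.63–0.67 nm —
near-constant across a 4.5× diameter range (spread ~6% of the mean), which
is the geometric content of the "fixed perturbed boundary" picture under
this area reading. A fixed w = 1.5 nm would instead give 53/62/77/88%;
because the literature's exact computation behind the larger width is not
reproducible from the area formula, the module parameterizes w and exposes
calibration rather than hard-coding a width. Diameters are nominal scaffold
diameters with no belt-thickness correction.

The continuum model replaces the step annulus with a monotone perturbation
profile in distance x from the rim, default p(x) = exp(−x/λ), giving the
disc-averaged GP (2/R²)∫₀ᴿ r·[GP_bulk + (GP_rim − GP_bulk)p(R − r)] dr by
adaptive quadrature (relative tolerance 1e-8). The profile is pluggable; a
step profile reproduces the two-population mixture exactly, which is the
degenerate-limit check.

## Numerical and design choices

- Temperatures are grouped at 0.01 °C resolution (Peltier precision);
  wavelength matching is exact to 1e-9 nm.
- GP tables are written at 6 significant digits and round-trip to 1e-6
  relative tolerance; melting summaries are JSON with sorted keys and fixed
  rounding, so identical inputs give byte-identical outputs.
- A degenerate spectrum (both channels zero) and a missing channel are
  errors, not NaNs, so a corrupt temperature point cannot silently distort
  a melting curve.
- A tie at the derivative maximum resolves to the lower temperature; a
  two-point derivative with equal values is treated as a tie, while three
  or more equal values are treated as "no peak".

## Problem sizes

The packaged analyses use per-lipid 1 °C ramps of roughly 21–36
temperatures, 141-wavelength spectra, 3 scans × 3 replicates (≈ 2–4 × 10⁴
spectra rows per sample), chosen to match a realistic overnight
fluorometer session; every stage runs in seconds on one CPU. The headline
reproduction script simulates noise-free data under the same protocol, so
its recovered transition temperatures are exact grid values.

## Known limitations

- The AUC proxy is in GP units and cannot be compared across dyes or
  instruments, only within an experiment.
- FWHM at 1 °C sampling overestimates very sharp transitions (a k = 0.4 °C
  logistic reads ≈ 2.3 °C instead of 1.4 °C); comparisons are meaningful at
  a fixed grid step.
- The detection rule is heuristic; soy-like multi-component, broad,
  structureless melts are reported as "no transition" rather than fit with
  multiple peaks (multi-peak deconvolution is out of scope).
- No excitation-spectrum (GP_ex) support, no inner-filter or scatter
  corrections, no vendor binary formats.
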