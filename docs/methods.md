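# Methods

## Signal model

A pulsed laser with repetition period `T = 12.5 ns` (80 MHz) excites a dye
whose fluorescence decays as a sum of one or two exponentials.  Lifetimes
comparable to `T` leave residual signal at the next pulse, so the
steady-state histogram is the geometric superposition of all preceding
pulses ("incomplete decay"):

    f(t) = Σᵢ aᵢ · e^(−t/τᵢ) / (1 − e^(−T/τᵢ)),   0 ≤ t < T.

This closed form is verified in the tests against an explicit 50-pulse sum
to 1e-10 relative error.  The detected curve is `f` circularly convolved
with the normalized instrument response function (IRF) on the 256-bin ADC
grid, optionally displaced by a sub-bin shift (linear interpolation between
integer rolls), plus a constant offset.  Circular convolution is
self-consistent here because the incomplete-decay model makes the whole
signal `T`-periodic.  The shift convention displaces the **IRF** toward
later times by `+shift` bins; the sign is arbitrary but fixed and
documented.

The headline statistic is the amplitude-weighted mean lifetime
`τ_m = Σaᵢτᵢ / Σaᵢ`, which for a voltage dye responds linearly to membrane
potential: `τ = m·V + b` with `m ≈ 3.5 ps/mV` and `b ≈ 1.77 ns` for the
HEK293T-like default calibration.

## Fitting

Per-pixel or per-ROI decays are fit by iterative reconvolution.  The
nonlinear search runs over log-lifetimes (plus the shift when free); at each
step the component amplitudes are solved by non-negative weighted linear
least squares (variable projection).  Defaults follow the acquisition
conventions for this kind of data: fit window bins 23–240 of 256, IRF shift
fixed at 0.5 bins, offset fixed at 0, peak-count threshold 300 (2-component)
or 150 (1-component), up to 20 optimizer iterations, relative tolerance
1e-6.  Optimizers: Levenberg–Marquardt (default) and Nelder–Mead simplex
(the ROI-summed variant used for dim indicators, offset fixed 0, shift
free).

**Weighting.**  The first pass uses Neyman weights `1/max(counts, 1)`.
These are biased at low counts: bins that fluctuate low receive more weight,
pulling lifetimes short (≈ −54 ps on τ_m at a 300-count decay peak, which
translates to −15 mV through a 3.5 ps/mV calibration).  A second pass
therefore recomputes the weights from the *fitted model* (iteratively
reweighted least squares) and refits; the residual bias is below 10 ps at
the same budget.  The number of reweighting passes is configurable
(`reweight_passes`, default 1; 0 restores plain Neyman weighting).

**Initialization** is deterministic: a log-linear regression over the decay
tail gives τ₀; the biexponential starts at (0.7·τ₀, 1.5·τ₀).  **Degeneracy
guard:** a biexponential fit whose lifetime ratio exceeds 0.8 is collapsed
to a single-exponential refit and flagged, since the two-component model is
unidentifiable there at realistic counts.

**Spatial binning**: "bin n" sums each pixel's decay over its
(2n+1)×(2n+1) neighborhood, clipped at image edges; the threshold is
evaluated on the binned peak, so the fitted mask is exactly
`{binned peak ≥ threshold}`.

## Synthetic data

The generator emulates membrane-stained cultured cells imaged by TCSPC
FLIM.  Defaults are the study conditions: 256 bins / 12.5 ns axis; Gaussian
IRF (center 1.0 ns, fwhm 0.2 ns — hybrid-PMT responses are approximately
Gaussian and only the convolution contract matters); component lifetimes
0.9 and 2.6 ns with the amplitude fraction chosen per group to hit the
calibration-demanded mean lifetime `f = (τ₂ − τ_m)/(τ₂ − τ₁)` (the data
constrain τ_m, not the individual amplitudes; fixing the component
lifetimes and varying the fraction is one admissible rule and is flagged as
such); calibration slope 3.50 ps/mV and 0 mV lifetime 1770 ps; per-group
resting potentials drawn from N(−40, 10²) mV, inside the −53…−29 mV range
reported for common cell lines; dark counts uniform at 0.01 counts/bin/pixel
(of the order implied by a sub-1000 cps detector over a 30 s, 64×64-pixel
exposure); a 0.5-bin IRF–decay displacement matching the fixed fit-side
shift convention.

Scenes are annuli with 2-pixel membranes; touching cells merge into one
8-connected "cell group" sharing a potential, mirroring the reporting
convention for electrically coupled neighbours.  Debris puncta are 1–2 px
bright mono-exponential (3.5 ns) objects placed clear of membranes.  Time
series follow a step-and-recover voltage profile (default −15 mV step,
80% responder fraction); ratio pairs give membrane pixels an expected
background-subtracted blue/green ratio `R = 1.8 + 0.0039·V` with Poisson
shot noise per channel.

A single integer seed expands into independent substreams per stage
(`numpy.random.SeedSequence.spawn`), so identical seed + config is
byte-identical output.

What the generator does **not** emulate: optics (PSF blur, pinhole),
detector pile-up and afterpulsing, concentration-dependent self-quenching,
space-clamp error in cell groups, spatial lifetime gradients within a
group.  Passing tests therefore demonstrate correctness of the estimators
under ideal counting statistics, not robustness to those instrument and
biology effects.

## Calibration, conversion, error propagation

Per-cell lines are ordinary least squares of τ on V (voltage is the
controlled variable); population calibrations are arithmetic means ± SEM of
slopes and intercepts.  Conversion: `V = (τ − b)/m`, `ΔV = Δτ/m`.
First-order error propagation:

    δV  = |V| · √[(δτ² + δb²)/(τ − b)² + (δm/m)²]
    δΔV = |ΔV| · √[(δΔτ/Δτ)² + (δm/m)²]

As printed, δV vanishes at V = 0 (the |V| prefactor); the implementation
keeps that behaviour and flags the τ = b point, with an optional
`floor=True` variant bounding δV below by δτ/|m| for users who want a
non-degenerate uncertainty there.  Both formulas are validated against
Monte-Carlo sampling to within 10% at small relative errors.

## Resolution metrics

Intra-cell resolution: each cell's lifetimes converted through its own
line; one RMSD versus the clamped voltages per cell; summarized as
mean ± SEM.  Note the self-calibration shrinkage: residuals of an OLS line
underestimate the noise by √((n−2)/n), material when a cell contributes few
voltage steps.  Inter-cell resolution: each cell's 0 mV intercept converted
through the population calibration, RMSD against the 0 mV truth.

Two RMSD conventions are computed.  The decomposition `√(σ² + Bias²)` is
sometimes written with σ² already equal to the mean *squared deviation*
(which contains the bias), in which case the combination double-counts the
bias; both the literal combination (`as_printed`) and the standard
root-mean-square deviation are reported, the standard one as the headline.

## GHK estimation

`V = (RT/F)·ln[(P_K[K]ₒ + P_Na[Na]ₒ + P_Cl[Cl]ᵢ)/(P_K[K]ᵢ + P_Na[Na]ᵢ + P_Cl[Cl]ₒ)]`,
with chloride's in/out reversed (anion).  Extracellular totals come from
salt stoichiometry of the buffer recipes (normal buffer: K 5.74, Na 142.78,
Cl 146.78 mM; high-K⁺: K 120.44, Na 28.18, Cl 146.88 mM) — e.g. K from
KCl + KH₂PO₄, chloride counting CaCl₂ and MgCl₂ twice.  The range procedure
evaluates the full Cartesian product of the standard parameter grid
(3 values each for P_Na, P_Cl, [K]ᵢ, [Na]ᵢ, [Cl]ᵢ; 243 combinations) at
293 K and reports the extrema: −91.2…−27.0 mV in normal buffer and
−25.2…+2.5 mV in high K⁺.  The high-K⁺ *maximum* recomputes to +2.5 mV
under these stoichiometric totals rather than a rounded +2; the minimum and
the normal-buffer endpoints match their commonly quoted values to the mV.

## Other numerics

- **Freedman–Diaconis histograms**: width `2·IQR·n^(−1/3)` with
  linear-interpolation quantiles (the width depends on the quantile
  convention, so it is fixed and documented); edges anchored at the data
  minimum, last edge extended to keep Σcounts = n; degenerate IQR falls
  back to a single bin.
- **Four-parameter logistic**: `y = bottom + (top − bottom)/(1 + (EC50/x)^hill)`
  by least squares.  The model is invariant under
  (bottom, top, hill) → (top, bottom, −hill); results are canonicalized to
  bottom ≤ top with the Hill sign encoding direction (negative =
  decreasing response).  Near-flat responses are flagged degenerate.
- **Segmentation**: unsharp mask (σ = 2 px, amount 1.0), Otsu threshold by
  default (fixed-value override), morphological closing, 8-connected
  components, 30 px minimum size.  These stand in for unpublished
  acquisition-side parameters and are validated only against synthetic
  truth.
- **Ratio imaging**: per-channel background is the median of a user-supplied
  empty region (robust to stray debris; the estimator choice is otherwise
  unconstrained); pixels below 100 background-subtracted counts in either
  channel are masked.

## Problem sizes

The test suite and acceptance script run everything at desk scale, chosen
to exercise the estimators well inside their operating regime: 50-replicate
lifetime recoveries at 10⁵ photons; end-to-end recovery on 128×128 scenes
with 20 cells at three peak-photon budgets (300 / 1000 / 3000); resolution
simulations with ≈100 cells × 20 voltage steps; Monte-Carlo error checks at
2×10⁵ draws.

## Known limitations

- The biexponential amplitude rule is one admissible choice; real dyes may
  move amplitudes and lifetimes with voltage simultaneously.
- Weighted least squares (even reweighted) is an approximation to the
  Poisson likelihood; at peaks well below ~100 counts a deviance objective
  would behave better.
- The segmentation defaults are tuned to annular synthetic morphology.
- Space-clamp error, pile-up and afterpulsing are out of scope; on real
  hardware they bias calibrations in ways the generator cannot reveal.
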