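# Methods

This note documents the models, default parameters and numerical choices
behind `photokin`, and what the synthetic datasets do and do not emulate.

## Two-step assembly model

Holo-protein formation is modelled as two consecutive irreversible steps:
second-order uptake of the free bilin into the binding pocket (`k1`,
M⁻¹ s⁻¹), then first-order covalent thioether-bond formation (`k2`, s⁻¹):

    d[apo]/dt  = −k1 [apo][bilin]
    d[bilin]/dt = −k1 [apo][bilin]
    d[nc]/dt   =  k1 [apo][bilin] − k2 [nc]
    d[cov]/dt  =  k2 [nc]

No reverse steps are included: thioether formation is treated as
irreversible, and non-covalent binding is not allowed to dissociate. Both
conservation ledgers (total bilin, total protein) hold to integrator
tolerance (LSODA, rtol 1e−10). Two informative limits are used as oracles:
with `k1·A0 ≫ k2` the covalent rise collapses to a single exponential in
`k2`; with `A0 ≫ B0` the uptake is pseudo-first-order with rate `k1·A0`.

**Dead time.** The simulation starts at mixing (t = 0) but emitted data
start at the 1 s dead time, so fits see partially formed product in the
first spectrum — as real stopped-manual-mixing data do.

**Fitting.** `fit_two_step` searches (log k1, log k2) with the three species
extinction spectra profiled out per wavelength by non-negative least squares
(extinctions are physical, so the amplitudes are sign-constrained; the
global exponential fits use plain least squares because difference
amplitudes are signed). When `k1·A0·t_first > 3` the uptake is >95 %
complete before the first data point and only a lower bound on `k1` is
identifiable; the fit flags this instead of pretending precision.

## Default assembly scenarios

Concentrations follow the mixing protocol: 500 µL of 23 µM apo-protein into
2 mL of 3 µM bilin → 4.6 µM protein, 2.40 µM bilin, 1.9× molar excess of
protein, 1 cm pathlength.

* **PCB (attachment-limited).** `k1 = 1e6 M⁻¹s⁻¹` (uptake complete within
  the dead time), `k2 = 1/18 s⁻¹`. Band centres: free PCB Soret 385 nm and
  Q 605 nm (Q amplitude = 37.9 mM⁻¹cm⁻¹, the literature extinction);
  non-covalent intermediate Q 690 nm; covalent adduct Q 649 nm. Spectra are
  recorded every 0.2 s to 150 s.
* **BV (two observed phases).** The default BV dataset is a
  sum-of-exponentials surrogate with τ = 14 s and 385 s: the covalent
  product rises as `B0(1 − a·e^(−t/τ₁) − (1−a)·e^(−t/τ₂))` with a = 0.62,
  and a burst-formed non-covalent population `n0·e^(−t/τ₁)` (n0 = 1.45 µM ≤
  a·B0, which keeps free bilin non-increasing) decays with the fast phase.
  This reproduces the transient red-shifted intermediate: early spectra peak
  near 705 nm and relax to the covalent band at 697 nm. Band centres: free
  BV Q 690 nm (broad, amplitude = 30.8 mM⁻¹cm⁻¹), intermediate 705 nm,
  covalent 697 nm. A separate mechanistic scenario
  (`default_bv_assembly_two_step`, `k2 ≫ k1·A0`) exercises rate-limiting
  second-order uptake, whose late-time kinetics are visibly non-exponential.
* Band widths (Q 32–120 nm, Soret ~50 nm) and the relative amplitudes of
  the protein-bound species are package defaults chosen to give realistic
  band overlap; no instrument reports them directly. Noise is additive
  homoscedastic Gaussian, σ = 1 mOD per (t, λ) point.

The tracked early-minus-late Q-band peak shift on the default BV dataset is
~7.5 nm rather than the nominal 8 nm separation of the band centres: the
broad free-bilin band and the growing covalent band pull the early composite
maximum slightly below 705 nm. This is a property of overlapping bands, not
of the tracker, which is exact to <0.1 nm on isolated bands.

**Binning.** Wavelength binning averages consecutive groups of N pixels
(default 7, ~1 nm resolution from a 0.5 nm grid); a short trailing group is
averaged rather than dropped. Logarithmic time binning groups rows into
log-spaced bins (default 10 per decade); the bin representative is the
geometric mean of member times — the natural centre on a log axis. Peak
tracking and fitting run on the binned matrices, where the 3-point parabolic
sub-pixel refinement is noise-limited rather than grid-limited.

## Global exponential fitting

Variable projection: amplitudes are exact linear least-squares solutions for
each trial of the time constants, so the nonlinear search (trust-region
least squares on log τ, relative tolerance 1e−8 level, ≤500 iterations per
start) runs in 1–2 dimensions. Multi-start uses 5 log-spaced initial values
per τ (ordered pairs for 2 exponentials) spanning the τ bounds, which
default to [5e−4, 10]× the observed time span. Fitted τ are reported sorted
ascending with the amplitude spectra permuted accordingly; a τ ratio < 1.5
triggers a degeneracy warning. Standard errors come from the Gauss–Newton
approximation at the optimum via the delta method on log τ.

The exponential basis is referenced to a configurable time origin `t_ref`
(default 0). Pump–probe fits set `t_ref` to the first observed delay, so the
fitted amplitudes describe the earliest spectrum directly — this is what
makes the GSB-ratio estimator exact when no overlap bands are present.

Assembly fits include a non-decaying offset spectrum (the final-state
spectrum); the full 450–800 nm visible window is fitted.

## Photostationary decomposition

"Determined iteratively" is operationalised as a descending scan: starting
from the marker ratio `s0 = S_equil(marker)/S_dark(marker)` the factor is
lowered in steps of 0.005 until the extracted spectrum satisfies

* no negative feature below −3× the noise floor, and
* second differences near the marker within 5× the median absolute second
  difference of `S_equil`, and no more than 2× the curvature already present
  there (a subtraction artifact must stand out against the local band
  curvature, not against noise).

Both criteria are evaluated on a 9-point moving-average copy so single-pixel
noise excursions do not masquerade as over-subtraction. With a photoproduct
transparent at the marker the scan accepts `s0` immediately and `s` equals
the generating dark fraction to the noise-propagated precision
(±σ/S_dark(marker) ≈ ±0.005 at the defaults). `s0 > 1` is rejected as an
inconsistent mixture. For pump–probe subtraction the factor is rescaled by
`S_dark/S_equil` at the 385 nm pump wavelength (the dark-state share of
absorbed pump photons); the spectra pair forming that ratio is genuinely
ambiguous, so `reference='phot'` selects the dark/photoproduct convention
instead. Dataset subtraction requires identical grids — mismatched
calibrations are an error, never silently interpolated.

Default mixtures: PCB dark state Q 649 nm with a 545 nm photoproduct, dark
fraction 0.22; BV dark state Q 697 nm with a 615 nm photoproduct, dark
fraction 0.35. The photoproducts are transparent (≤ noise) at the markers,
which is what makes the factor identifiable from the marker alone.

## Pump–probe model and quantum yields

Matrices are built on a log-spaced 10 ps – 20 ns grid (60 delays, no
instrument-response convolution — the grid starts well past the 8 ps pump):

    ΔA(t, λ) = D₁(λ)e^(−(t−t₀)/τ₁) + D₂(λ)e^(−(t−t₀)/τ₂) + ΔA_∞(λ) + noise

with the early spectrum `gsb + esa + se` (bleach ≤ 0, excited-state
absorption ≥ 0, stimulated emission ≤ 0), the Lumi spectrum
`ΔA_∞ = Φ_true·gsb + pa`, and the decaying amplitude split 0.4/0.6 between
the exponentials. Noise is 0.1 mOD.

Four state analogs share Φ_true = 0.06: Pr (GSB 649 nm, τ = 50/1200 ps),
Pg (545 nm, 40/800 ps, with a strong product band at 565 nm adjacent to the
bleach), Pfr (697 nm, 30/280 ps — slow phase >4× faster than Pr), Po
(615 nm, 25/320 ps — ~2.5× faster than Pg). In every default the early
amplitude exceeds the Lumi amplitude by >10×, the signature of a low
photochemical yield.

`estimate_qy` locates the Lumi GSB minimum by 3-point parabolic refinement
and forms the ratio of the fitted model between t → ∞ and the early
reference t₀ (first delay), evaluating both with the same local parabola so
the ratio is exact for an unobstructed bleach. Product absorption
overlapping the bleach can only fill it in, so the estimate is a lower
bound; it also displaces the Lumi minimum, and a displacement >10 nm against
the steady-state absorption maximum raises the `gsb_shift_large` flag
(Pg-like case). Stimulated-emission interference is flagged conceptually but
not corrected — no principled correction exists without a target model, and
target/compartmental analysis of the excited-state decay is out of scope
(the inversion is underdetermined). Excitation-wavelength dependence of Φ is
ignored. Estimates are clipped to [0, 1] with a flag if clipping occurred.

## What the generator does not emulate

Homoscedastic Gaussian noise (no shot-noise scaling, no baseline drift or
cosmic spikes), perfect wavelength calibration between datasets, no
instrument response in time, Gaussian bands in wavelength rather than
physical vibronic lineshapes, and no photoswitching kinetics under
continuous illumination (only the resulting stationary mixtures). Passing
recovery tests therefore demonstrates correctness of the estimators under
the stated statistical model, not robustness to instrument systematics.

## Problem sizes

Default datasets are 746×701 (PCB assembly, pre-binning), 750×701 (BV),
60×151 (pump–probe) and 701-point spectra; the full pipeline runs in a few
seconds on one core, and the test suite (including 20-replicate recovery
studies) in well under a minute.
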