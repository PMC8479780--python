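# photokin

Spectro-kinetic analysis of bilin photoreceptor assembly and primary
photochemistry, built around the in-vitro characterisation of a red/green
cyanobacteriochrome (CBCR) GAF domain that binds either phycocyanobilin
(PCB) or biliverdin (BV).

The package implements the complete analysis chain for three kinds of
optical measurement, together with a synthetic-data generator that produces
each of them with known ground truth, so every stage can be validated
end to end without instrument data:

1. **Chromophore assembly kinetics.** Time-resolved absorbance matrices of
   the holo-protein formation reaction are modelled by a two-step scheme

       apo + bilin  --k1-->  non-covalent complex  --k2-->  covalent adduct

   with second-order uptake `k1` (M⁻¹ s⁻¹) and first-order thioether
   formation `k2` (s⁻¹). The module simulates the scheme as ODEs, fits it to
   data with the species extinction spectra profiled out by non-negative
   least squares, and produces the standard diagnostics (difference spectra,
   Q-band peak tracking of the red-shifted non-covalent intermediate).

2. **Global multiexponential fitting.** A shared variable-projection engine
   fits matrices with 1–2 exponentials plus an optional non-decaying
   component: for each trial of the time constants τᵢ the per-wavelength
   amplitude spectra Dᵢ(λ) (DAS/DADS) and offset D∞(λ) are solved exactly by
   linear least squares, and a multi-start nonlinear search runs over τ only,

       A(t, λ) = Σᵢ Dᵢ(λ) e^(−(t−t₀)/τᵢ) + D∞(λ).

3. **Photostationary decomposition and quantum yields.** Equilibrium spectra
   under background illumination are decomposed as
   `S_phot = S_equil − s·S_dark`, with the subtraction factor `s` determined
   iteratively: complete removal of the dark state at its marker band
   (649 nm for the PCB adduct, 697 nm for BV) under negativity and sharpness
   constraints that guard against over-subtraction. Pump–probe matrices
   (10 ps – 20 ns) are fitted globally; the offset spectrum is the primary
   photoproduct (Lumi) spectrum, and the photochemical quantum yield is
   approximated by the ground-state-bleach ratio

       Φ_L = ΔA_∞(λ*) / ΔA_model(t₀, λ*)

   at the Lumi GSB minimum λ*, with a GSB-shift diagnostic flagging cases
   where overlapping product absorption makes Φ_L an underestimate.

See `docs/methods.md` for the model assumptions, default parameters and
numerical choices.

## Worked example

```python
import numpy as np
from photokin import synthetic_data as syn
from photokin import (bin_wavelength, bin_time_log,
                      GlobalExpModel, global_exp_fit,
                      determine_subtraction_factor, fit_ta, estimate_qy)

# 1) assembly: generate the default PCB experiment (4.6 uM apo-protein,
#    2.40 uM PCB, 1 s dead time), apply the acquisition binning, fit
scenario = syn.default_pcb_assembly(seed=1)
matrix = syn.simulate_assembly(scenario)
binned = bin_time_log(bin_wavelength(matrix, 7), 10)
fit = global_exp_fit(binned, GlobalExpModel(n_exp=1, with_offset=True))
print(f"assembly tau = {fit.taus[0]:.1f} s")

# 2) photostationary mixture: recover the subtraction factor
eq = syn.default_pcb_equilibrium(seed=1)
dark, equil = syn.simulate_equilibrium(eq)
dec = determine_subtraction_factor(equil, dark, 649.0, eq.noise_sigma)
print(f"subtraction factor s = {dec.s:.3f}")

# 3) pump-probe: fit and estimate the quantum yield
ta = syn.default_ta_scenarios(seed=1)["Pr"]
result = fit_ta(syn.simulate_ta(ta))
est = estimate_qy(result)
print(f"TA taus = {result.taus[0]:.0f}, {result.taus[1]:.0f} ps; "
      f"Phi = {est.phi:.3f}")
```

Output:

```
assembly tau = 18.2 s
subtraction factor s = 0.220
TA taus = 50, 1200 ps; Phi = 0.046
```

The assembly fit recovers the 18 s thioether-formation time constant of the
attachment-limited PCB reaction; the decomposition recovers the generating
dark fraction (0.22); the pump–probe fit recovers both excited-state decay
constants, and the GSB ratio slightly underestimates the generating yield
(0.06) because product absorption partially fills the bleach — the expected
direction of this estimator's bias.

The same stages are available from the shell (`photokin --help`):

```sh
photokin run config.yaml          # full pipeline from a YAML config
photokin bin in.tsv out.tsv --wl-bin 7 --time-log 10
photokin fit out.tsv --n-exp 1 --out fit.yaml
photokin decompose equil.tsv dark.tsv --marker 649 --pump 385
photokin ta qy pumpprobe.tsv
```

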