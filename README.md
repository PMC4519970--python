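# lumifret

Analysis toolkit for **lanthanide time-gated FRET biosensors** — sensors
in which a Tb³⁺–peptide complex (ms-lifetime donor) transfers energy
across a flexible, protease-cleavable linker to a red fluorescent
protein (ns-lifetime acceptor).  Because the donor decays a million
times more slowly than anything else in the cuvette, opening the
detector ~100 µs after a flash isolates the sensitized acceptor
emission from direct excitation and autofluorescence.

The package is for spectroscopists and modellers working with such
constructs.  It provides:

* **Förster theory over distance ensembles** — per-frame transfer rate,
  efficiency and quenched lifetime from a donor–acceptor distance
  series (e.g. extracted from an MD trajectory), with
  k_T(r) = (1/τ_D)(R0/r)⁶,  E = k_T/(τ_D⁻¹+k_T),  τ_DA = τ_D(1−E),
  R0⁶ = [9000 ln10/(128π⁵N_A)] κ² n⁻⁴ Q_D J;
* **spectral processing** — overlap integral J = ∫F_D(λ)ε_A(λ)λ⁴dλ,
  inner-filter (reabsorption) correction I_corr = I·10^(D/2), and
  photobleach-control subtraction to isolate the sensitized band;
* **time gating** — closed-form gate integrals of multi-exponential
  decays, and a forward model + reconstruction of a full gated
  titration series;
* **binding analysis** — constrained least-squares fit of the one-site
  isotherm I = I_max[Tb]/(K_d+[Tb]) with bootstrap intervals and a
  tangent-intersection saturation estimate;
* **synthetic generators** for every input (chain-model linker
  distances, Gaussian-band spectra, noisy titrations, decays), so the
  entire pipeline runs and is tested without instrument data.

## Worked example

```python
import numpy as np
from lumifret import (FretParameters, ChainModel, sample_linker_distances,
                      ensemble_fret, TitrationDesign, synth_titration,
                      fit_binding, saturation_by_tangents,
                      DecayComponent, GateWindow, gated_intensity)

# photophysics of the Tb3+ -> red-FP pair
params = FretParameters(J=3.22591e15, tau_D=0.33, tau_DR=3.5)
print(f"Q_D = {params.Q_D:.4f},  R0 = {params.R0:.2f} nm")

# why gating works: survival of each species through a 100 us delay / 1 ms gate
gate = GateWindow(delay=100.0, width=1000.0)
prompt = DecayComponent(amplitude=1.0, lifetime=0.003)   # 3 ns, direct acceptor
slow = DecayComponent(amplitude=1.0, lifetime=190.0)     # 0.19 ms, sensitized
print(f"gated fraction, 3 ns prompt: {gated_intensity(prompt, gate)/0.003:.3g}")
print(f"gated fraction, 0.19 ms sensitized: {gated_intensity(slow, gate)/190.0:.3f}")

# FRET over an ideal-chain model of the 19-residue linker
ens = sample_linker_distances(ChainModel(), n_samples=100_000, seed=1)
res = ensemble_fret(ens, params)
print(f"linker ensemble: mean E = {res.mean_E:.3f}, mean tau_DA = {res.mean_tauDA*1000:.2f} us")

# fit a noisy synthetic titration (5%-of-plateau noise, 1-50 uM grid)
design = TitrationDesign(np.array([1,2,5,10,15,20,25,30,40,50.]),
                         true_Kd=17.0, true_Imax=95.0, noise_sd=4.75, seed=11)
fit = fit_binding(synth_titration(design), n_boot=1000, seed=11)
sat = saturation_by_tangents(fit, synth_titration(design))
print(fit.summary())
print(f"saturation (tangent intersection) = {sat:.1f} uM")
```

prints

```
Q_D = 0.0943,  R0 = 4.08 nm
gated fraction, 3 ns prompt: 0
gated fraction, 0.19 ms sensitized: 0.588
linker ensemble: mean E = 0.986, mean tau_DA = 4.69 us
Kd   = 12.4 ± 2.8 µM  (95% CI 7.65–18.4)
Imax = 83.8 ± 6.6 a.u.  (95% CI 72.4–98.7)
residual sd = 4.31 a.u.
saturation (tangent intersection) = 11.4 uM
```

Reading the numbers: the lifetime ratio 0.33/3.5 ms gives a donor
quantum yield of 0.094, which with the experimental overlap integral
puts the Förster radius at 4.08 nm.  The gate passes 59% of a
sensitized (0.19 ms) photon yield but essentially zero of a 3 ns prompt
component — the reason gated detection sees only FRET-derived signal.
The bare ideal-chain linker holds donor and acceptor well inside R0, so
transfer is nearly complete (E ≈ 0.99); real-sensor ensembles with
donor/acceptor offsets give smaller E (see `docs/methods.md`).  The fit
of one noisy replicate recovers K_d = 12.4 µM with the generating value
(17 µM) inside its 95% interval — single noisy titrations on this grid
carry exactly this kind of spread, which is why recovery is judged by
medians over many replicates.

A one-command pipeline demo (quantum yield → Förster radius → linker
sampling → ensemble FRET → gated-titration simulation → spectral
reconstruction → binding fit) with a JSON report juxtaposing computed
and reference values:

```sh
lumifret --outdir demo_out demo --seed 5
```

Other subcommands: `simulate {distances|spectra|titration|decay}`,
`overlap`, `correct`, `ensemble`, `gate`, `reconstruct`, `titrate`;
see `lumifret --help`.  Stochastic subcommands require an explicit
`--seed` (or `--seed auto`, which draws and logs one).

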