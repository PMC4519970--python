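# Methods

`lumifret` models the photophysics and data processing of a lanthanide
time-gated FRET biosensor: a Tb³⁺-binding peptide (donor, sensitized via
a tryptophan antenna) joined by a flexible 19-residue cleavable linker
to a red fluorescent protein (acceptor).  This note records the models,
the defaults and why, the numerical choices, and what the synthetic
generators do and do not emulate.

## Förster theory

For a donor–acceptor pair at separation *r* (nm) the transfer rate is

    k_T(r) = (1/τ_D) (R0/r)^6
    R0^6   = [9000 ln10 / (128 π⁵ N_A)] κ² n⁻⁴ Q_D J

with the overlap integral J = ∫ F_D(λ) ε_A(λ) λ⁴ dλ (donor emission
area-normalised, ε in M⁻¹cm⁻¹, λ in nm, so J carries M⁻¹·cm⁻¹·nm⁴).
Efficiency and quenched lifetime follow as E = k_T/(τ_D⁻¹ + k_T) and
τ_DA = τ_D(1 − E).  The bracketed constant is evaluated exactly from
N_A rather than via the rounded textbook coefficient 8.79×10⁻⁵ Å⁶; a
fully CGS evaluation of k_T (`rate_constant_explicit`) agrees with the
R0 route to machine precision and is tested to ≤10⁻⁶ relative over
r ∈ [0.5, 20] nm.

Defaults, with units and provenance:

| parameter | default | unit | why |
|---|---|---|---|
| τ_D   | 0.33 | ms | measured unquenched Tb³⁺ lifetime of this sensor |
| τ_D,R | 3.5  | ms | Tb³⁺ radiative lifetime; gives Q_D = τ_D/τ_D,R ≈ 0.094 |
| J     | 3.22591×10¹⁵ | M⁻¹cm⁻¹nm⁴ | experimental overlap integral of this pair |
| κ²    | 2/3  | – | isotropic-rotation limit; per-frame κ² is out of scope |
| n     | 1.4  | – | common protein-FRET convention; not reported for this system. R0 shifts ≈3.6% between n = 1.33 and 1.4 (R0 ∝ n⁻²ᐟ³), well under other uncertainties; overridable in `FretParameters` |

With these values R0 ≈ 4.08 nm.  Lifetimes are ms and rates ms⁻¹
throughout the Förster module because the donor decays on the ms scale;
decay and gate times in the gating module are µs, the scale on which
gating operates.  The two meet only through the lifetime arguments of
`DecayComponent`, documented at the call sites.

Ensemble statistics (`ensemble_fret`) apply the three per-distance maps
frame-by-frame and report weighted means (uniform weights unless given),
Freedman–Diaconis histograms, and cumulative curves computed from the
weighted empirical distribution rather than the histogram.  Because
τ_DA is affine in E, mean τ_DA = τ_D(1 − mean E) holds to machine
precision and is asserted as an identity, not a tolerance.

A note on a published rounding inconsistency: the experimental lifetime
pair 0.33 → 0.18 ms implies E = 1 − 0.18/0.33 = 0.4545, while the
quoted experimental efficiency is 44% — presumably computed from
unrounded lifetimes.  The package documents both and forces no
agreement; the test asserts only that they differ by < 2 percentage
points.

## Spectral processing

Spectra are sampled on strictly increasing nm grids and interpolated
linearly; nothing is ever extrapolated beyond a spectrum's support.
Overlap integrals use trapezoidal quadrature on a shared grid (default
step 1 nm, typical fluorimeter sampling); convergence is tested by step
halving (<0.1% change for bands resolved by ≥10 points).

Reabsorption (inner-filter) correction multiplies measured emission by
10^(D(λ)/2) per wavelength — the half-power corresponds to a mean
emission path from the centre of the cuvette — so correction is exact
when D is the sample's optical density at the emission wavelength.
Photobleach subtraction (full − bleached, isolating the sensitized
acceptor band) clamps negative residuals at zero but counts them, so
noise artifacts remain visible without propagating unphysical
intensities.

## Time gating

A gate of width g opened t_d after a δ-pulse collects
A·τ·(e^(−t_d/τ) − e^(−(t_d+g)/τ)) from each exponential species; the
closed form is tested against adaptive quadrature to 10⁻⁸ relative and
is additive over abutting gates to 10⁻¹².  With the experimental gate
(t_d = 100 µs, g = 1 ms) a 3 ns prompt component retains < 10⁻¹⁰ of its
photon yield — the quantitative basis for treating directly excited
acceptor fluorescence as absent — while a 0.19 ms sensitized component
retains 58.8% of its yield.  The sensitized acceptor is modelled with
the quenched-donor lifetime, since acceptor emission fed by a slow
donor inherits the donor's decay; the acceptor's intrinsic ns decay is
the prompt component that the gate removes.

The gated-titration forward model emits, per concentration, the
"measured" full spectrum (Tb³⁺ lines + sensitized acceptor band, both
scaled by binding occupancy and by their gated decay fractions, then
attenuated by 10^(−D/2)), the photobleached control (donor lines only;
bleaching is assumed to affect only the acceptor chromophore, so donor
amplitudes are shared), and the absorbance spectrum (acceptor band at
fixed protein concentration).  Reconstruction applies the experimental
order of operations — correct the full spectrum, then subtract the
bleached one — and reads out at 606 nm by linear interpolation.  In the
noiseless case reconstruction inverts the forward model exactly, so the
end-to-end round trip recovers the generating (K_d, I_max) to optimizer
tolerance; this is a consistency check of the pipeline's algebra, not
evidence about real spectra.

## Binding isotherm

`fit_binding` fits I = I_max[Tb]/(K_d+[Tb]) by positivity-constrained
nonlinear least squares (scipy `curve_fit`, trust-region reflective;
initial I_max = max I, initial K_d = concentration nearest
half-maximum; xtol 10⁻¹⁰).  Free ligand is approximated by total
ligand, as the isotherm assumes — with 23.4 µM protein titrated to
50 µM Tb³⁺ this depletion is a known simplification.  Standard errors
come from the Jacobian at the optimum; 95% intervals from a seeded
residual bootstrap (default 1000 refits) in which fitted residuals are
rescaled by √(n/(n−2)) to undo the variance deflation of a
two-parameter fit — without this, intervals undercover on 10-point
designs.  Degenerate inputs (all-zero intensities, <3 points) raise;
designs not spanning both the rising and flattening regions warn.

The saturating concentration is estimated as the intersection of two
OLS secant lines through the first and last k points (default 3) of the
fitted curve evaluated at the measured concentrations.  The analytic
construction (true tangent at origin vs plateau I = I_max) intersects
exactly at K_d; the secant variant is grid-dependent and, on the
default grid, approaches K_d from below as k grows.  The historically
reported 24.2 µM for this sensor is therefore juxtaposed in reports,
never asserted.

## Synthetic data: what it emulates, what it does not

* **Linker distances.** A freely jointed chain of 19 virtual Cα–Cα
  bonds of 0.38 nm (standard polypeptide geometry), or a discretised
  Kratky–Porod worm-like chain (von Mises–Fisher bond-angle sampling
  with ⟨cos θ⟩ = e^(−b/ℓp)).  Optional fixed end offsets stand in for
  the Tb³⁺-site and chromophore displacements, added along the
  end-to-end direction.  The FJC satisfies ⟨r²⟩ = Nb² exactly and is
  tested to 3 standard errors at 10⁵ samples; samples never exceed the
  contour length.  This is an ideal-chain stand-in for the solvated MD
  ensemble of the real sensor: it ignores excluded volume, sequence
  chemistry, and the unknown donor/acceptor reference points, so with
  zero offsets its distances (≈1.6 nm mean) sit well inside R0 and give
  mean E ≈ 0.99 — the MD-derived mean E = 43% is *not* expected from it
  and is not an acceptance quantity.  What any ensemble must satisfy is
  the linearity identity: a mean E of 0.43 with τ_D = 0.33 ms forces
  mean τ_DA = 0.1881 ms ≈ the published 0.19 ms.
* **Spectra.** Tb³⁺ emission as four Gaussians (490/545/585/620 nm,
  σ = 4 nm, 545 dominant) and TagRFP-like bands (extinction 555 nm,
  σ = 18 nm, peak 10⁵ M⁻¹cm⁻¹; emission 584 nm, σ = 16 nm).  Gaussians
  were chosen so every overlap integral has a closed form
  (testability over spectroscopic realism); real Tb³⁺ lines have
  crystal-field structure and the real protein band is asymmetric.
* **Titrations.** Isotherm plus seeded Gaussian noise (analog
  fluorimeter), clamped at zero; default noise 5% of the plateau.
  Defaults K_d = 17 µM, I_max = 95 a.u. on a 10-point 1–50 µM grid
  (1, 2, 5, 10, 15, 20, 25, 30, 40, 50): the published range with a
  practitioner's spacing, as the individual points were not printed.
* **Decays.** Sums of exponentials with optional seeded Poisson noise
  (photon counting).  No instrument response, lamp afterglow or pile-up.

All generators are bit-reproducible under a fixed seed.  Passing tests
on these inputs demonstrates the correctness of the pipeline's algebra
and statistics; it does not validate the spectroscopic realism of any
generator.

## Problem sizes

Distance-ensemble checks use 10⁵ samples (standard error of ⟨r²⟩ ≈
0.4%); parameter-recovery experiments use 200 replicates of 10-point
titrations for medians, and 100 replicates × 200 bootstrap refits for
coverage.  These sizes put Monte-Carlo error well inside the asserted
tolerances while keeping the full suite around a minute.

## Known limitations

* κ² is fixed; orientational dynamics of the dipoles are out of scope.
* No MD engine or binary trajectory reader; distance series enter as
  plain text (one or two columns).
* The inner-filter correction uses the fixed D/2 path; cuvette-geometry
  effects beyond that are not modelled.
* Single-site binding only; no Hill coefficient, no ligand depletion.
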