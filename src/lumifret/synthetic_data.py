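"""Synthetic generators for every input the analysis pipeline consumes.

The generators emulate, at desk scale, the raw material of a lanthanide
time-gated FRET experiment on a Tb³⁺–peptide / red-fluorescent-protein
sensor:

* a flexible polypeptide linker's end-to-end distance distribution
  (freely jointed or worm-like chain, 19 virtual Cα–Cα bonds of 0.38 nm
  by default),
* Tb³⁺ line emission and TagRFP-like absorption/extinction/emission
  band spectra built from Gaussians so that every overlap integral has
  a closed form,
* noisy saturation-binding titrations I = I_max[Tb]/(K_d+[Tb]) over the
  experimental 1–50 µM range,
* multi-exponential luminescence decays spanning ns (prompt acceptor
  fluorescence) to ms (lanthanide-sensitized emission).

Everything stochastic takes an explicit seed and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spectra import Spectrum
from .titration import TitrationSeries
from .forster import DistanceEnsemble

__all__ = [
    "ChainModel",
    "TitrationDesign",
    "DecayComponent",
    "GaussianBand",
    "TB_EMISSION_LINES",
    "RFP_EXTINCTION_BAND",
    "RFP_EMISSION_BAND",
    "sample_linker_distances",
    "synth_spectra",
    "synth_titration",
    "synth_decay",
]


@dataclass(frozen=True)
class ChainModel:
    """Coarse polymer model of the donor–acceptor linker.

    The 19-residue cleavable linker is represented as ``n_segments``
    virtual bonds of ``bond_length`` nm (0.38 nm Cα–Cα).  ``end_offsets``
    are fixed distances (nm) added along the end-to-end direction at each
    terminus, standing in for the Tb³⁺ site and chromophore offsets.
    """

    n_segments: int = 19
    bond_length: float = 0.38
    model: str = "freely_jointed"
    persistence_length: float | None = None  # nm, worm_like only
    end_offsets: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if self.bond_length <= 0:
            raise ValueError("bond_length must be positive")
        if self.model not in ("freely_jointed", "worm_like"):
            raise ValueError("model must be 'freely_jointed' or 'worm_like'")
        if self.model == "worm_like":
            if self.persistence_length is None or self.persistence_length <= 0:
                raise ValueError("worm_like model requires persistence_length > 0")
        if any(o < 0 for o in self.end_offsets):
            raise ValueError("end_offsets must be nonnegative")

    @property
    def contour_length(self) -> float:
        """Maximum end-to-end distance including the terminal offsets."""
        return self.n_segments * self.bond_length + sum(self.end_offsets)


@dataclass(frozen=True)
class TitrationDesign:
    """Forward-model design of a Tb³⁺ saturation-binding titration."""

    concentrations: np.ndarray  # µM, strictly increasing
    true_Kd: float  # µM
    true_Imax: float  # a.u.
    noise_sd: float = 0.0  # a.u.
    seed: int = 0

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        if c.ndim != 1 or c.size == 0:
            raise ValueError("concentrations must be a nonempty 1-D array")
        if np.any(c <= 0) or np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be positive and strictly increasing")
        if self.true_Kd <= 0 or self.true_Imax <= 0:
            raise ValueError("true_Kd and true_Imax must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        object.__setattr__(self, "concentrations", c)


@dataclass(frozen=True)
class DecayComponent:
    """One exponential decay species: amplitude at t=0 and lifetime in µs."""

    amplitude: float  # a.u.
    lifetime: float  # µs

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be nonnegative")
        if self.lifetime <= 0:
            raise ValueError("lifetime must be positive")


@dataclass(frozen=True)
class GaussianBand:
    """Analytic Gaussian band: peak * exp(-(λ-center)²/(2 width²))."""

    center: float  # nm
    width: float  # nm (standard deviation)
    peak: float  # peak value in the spectrum's units


# Tb³⁺ emission lines ( ⁵D₄→⁷F_J transitions): narrow Gaussians, relative
# peak heights with the 545 nm line dominant.  Peaks are arbitrary units.
TB_EMISSION_LINES: tuple[GaussianBand, ...] = (
    GaussianBand(center=490.0, width=4.0, peak=0.55),
    GaussianBand(center=545.0, width=4.0, peak=1.00),
    GaussianBand(center=585.0, width=4.0, peak=0.25),
    GaussianBand(center=620.0, width=4.0, peak=0.12),
)

# TagRFP-like chromophore bands: absorption/extinction centred 555 nm
# (peak extinction 1e5 M⁻¹cm⁻¹, typical of red fluorescent proteins),
# emission centred 584 nm.
RFP_EXTINCTION_BAND = GaussianBand(center=555.0, width=18.0, peak=1.0e5)
RFP_EMISSION_BAND = GaussianBand(center=584.0, width=16.0, peak=1.0)


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _fjc_end_to_end(rng, n_samples: int, n_seg: int, b: float) -> np.ndarray:
    r = np.zeros((n_samples, 3))
    for _ in range(n_seg):
        r += _random_unit_vectors(rng, n_samples)
    return b * np.linalg.norm(r, axis=1)


def _wlc_end_to_end(
    rng, n_samples: int, n_seg: int, b: float, lp: float
) -> np.ndarray:
    # Discrete Kratky-Porod chain: successive bond directions tilted by a
    # polar angle with <cos θ> = exp(-b/lp), azimuth uniform.
    mean_cos = np.exp(-b / lp)
    end = np.zeros((n_samples, 3))
    direction = _random_unit_vectors(rng, n_samples)
    end += direction
    for _ in range(n_seg - 1):
        # sample cos θ from p(c) ∝ exp(κ c) (von Mises-Fisher polar angle)
        # with κ chosen so the mean matches the Kratky-Porod correlation
        kappa = _vmf_kappa(mean_cos)
        if kappa < 1e-8:
            cos_t = rng.uniform(-1.0, 1.0, size=n_samples)
        else:
            u = rng.uniform(size=n_samples)
            cos_t = 1.0 + np.log(u + (1 - u) * np.exp(-2 * kappa)) / kappa
        sin_t = np.sqrt(np.maximum(0.0, 1.0 - cos_t**2))
        phi = rng.uniform(0.0, 2 * np.pi, size=n_samples)
        # local orthonormal frame around the current direction
        ref = np.where(
            np.abs(direction[:, [0]]) < 0.9, [[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]]
        )
        e1 = np.cross(direction, ref)
        e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
        e2 = np.cross(direction, e1)
        direction = (
            cos_t[:, None] * direction
            + sin_t[:, None] * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
        )
        direction /= np.linalg.norm(direction, axis=1, keepdims=True)
        end += direction
    return b * np.linalg.norm(end, axis=1)


def _vmf_kappa(mean_cos: float) -> float:
    """Invert <cos θ> = coth κ − 1/κ (Langevin function) by bisection."""
    if mean_cos <= 0:
        return 0.0
    lo, hi = 1e-9, 1e6
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        val = 1.0 / np.tanh(mid) - 1.0 / mid
        if val < mean_cos:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def sample_linker_distances(
    chain: ChainModel, n_samples: int, seed: int
) -> DistanceEnsemble:
    """Sample end-to-end distances (nm) from the chain model.

    Freely jointed: sum of ``n_segments`` isotropic unit vectors scaled by
    the bond length (⟨r²⟩ = N b² exactly).  Worm-like: discretised
    Kratky–Porod chain with the given persistence length.  The fixed
    ``end_offsets`` are added along the end-to-end direction, so the
    result never exceeds the contour length.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    if chain.n_segments == 1:
        r = np.full(n_samples, chain.bond_length)
    elif chain.model == "freely_jointed":
        r = _fjc_end_to_end(rng, n_samples, chain.n_segments, chain.bond_length)
    else:
        r = _wlc_end_to_end(
            rng,
            n_samples,
            chain.n_segments,
            chain.bond_length,
            chain.persistence_length,
        )
    r = r + sum(chain.end_offsets)
    return DistanceEnsemble(distances=r)


def _gaussian(wl: np.ndarray, band: GaussianBand) -> np.ndarray:
    return band.peak * np.exp(-((wl - band.center) ** 2) / (2.0 * band.width**2))


def synth_spectra(
    kind: str,
    step: float = 1.0,
    wl_range: tuple[float, float] = (400.0, 750.0),
    peak_scale: float = 1.0,
) -> Spectrum:
    """Analytic synthetic spectra of the sensor's components.

    ``kind`` is one of ``tb_emission`` (four narrow Tb³⁺ lines at
    490/545/585/620 nm), ``rfp_extinction`` / ``rfp_absorbance``
    (Gaussian band at 555 nm) or ``rfp_emission`` (Gaussian band at
    584 nm).  ``peak_scale`` multiplies the catalogue peak values;
    for ``rfp_absorbance`` it IS the peak optical density.
    """
    wl = np.arange(wl_range[0], wl_range[1] + step / 2, step)
    if kind == "tb_emission":
        vals = sum(_gaussian(wl, band) for band in TB_EMISSION_LINES) * peak_scale
        return Spectrum(wl, vals, "emission")
    if kind == "rfp_extinction":
        return Spectrum(wl, _gaussian(wl, RFP_EXTINCTION_BAND) * peak_scale, "extinction")
    if kind == "rfp_absorbance":
        band = GaussianBand(
            RFP_EXTINCTION_BAND.center, RFP_EXTINCTION_BAND.width, peak_scale
        )
        return Spectrum(wl, _gaussian(wl, band), "absorbance")
    if kind == "rfp_emission":
        return Spectrum(wl, _gaussian(wl, RFP_EMISSION_BAND) * peak_scale, "emission")
    raise ValueError(f"unknown spectrum kind {kind!r}")


def synth_titration(design: TitrationDesign) -> TitrationSeries:
    """Noisy saturation-binding titration from the one-site isotherm.

    I_i = I_max c_i / (K_d + c_i) + N(0, noise_sd), seeded; negative
    draws are clamped to zero as a fluorimeter would report.
    """
    c = design.concentrations
    ideal = design.true_Imax * c / (design.true_Kd + c)
    if design.noise_sd > 0:
        rng = np.random.default_rng(design.seed)
        ideal = ideal + rng.normal(0.0, design.noise_sd, size=c.size)
    return TitrationSeries(concentrations=c, intensities=np.maximum(ideal, 0.0))


def synth_decay(
    components: list[DecayComponent] | tuple[DecayComponent, ...],
    t_grid: np.ndarray,
    poisson_noise: bool = False,
    seed: int | None = None,
) -> np.ndarray:
    """Multi-exponential decay S(t) = Σ A_k exp(−t/τ_k) on a µs time grid.

    With ``poisson_noise`` the curve is replaced by seeded Poisson draws
    (photon-counting statistics); amplitudes are then expected counts.
    """
    if not components:
        raise ValueError("need at least one decay component")
    t = np.asarray(t_grid, dtype=float)
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be nonnegative and strictly increasing")
    s = np.zeros_like(t)
    for comp in components:
        s += comp.amplitude * np.exp(-t / comp.lifetime)
    if poisson_noise:
        if seed is None:
            raise ValueError("poisson_noise requires a seed")
        s = np.random.default_rng(seed).poisson(s).astype(float)
    return s
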