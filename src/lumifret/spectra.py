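"""Spectrum container, text I/O, overlap integral and spectral corrections.

A :class:`Spectrum` is a wavelength grid (nm, strictly increasing) with one
value per wavelength and a declared ``kind``:

* ``absorbance`` — dimensionless optical density D,
* ``extinction`` — molar extinction coefficient in M^-1 cm^-1,
* ``emission``   — fluorescence intensity in arbitrary units.

The module implements the three spectral operations of a time-gated
sensitized-emission experiment: the donor/acceptor overlap integral J,
the inner-filter (reabsorption) correction I_corr = I * 10^(D/2) for a
path taken from the centre of the cuvette, and the subtraction of a
photobleached-sample spectrum from a corrected full spectrum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np

__all__ = [
    "Spectrum",
    "OverlapIntegralResult",
    "SubtractionResult",
    "SpectrumParseError",
    "read_spectrum",
    "write_spectrum",
    "resample_common_grid",
    "overlap_integral",
    "inner_filter_correct",
    "subtract_spectra",
]

KINDS = ("absorbance", "extinction", "emission")


class SpectrumParseError(ValueError):
    """Raised when a spectrum file cannot be parsed; names the offending line."""


@dataclass(frozen=True)
class Spectrum:
    """An immutable sampled spectrum on a strictly increasing nm grid."""

    wavelengths: np.ndarray
    values: np.ndarray
    kind: str

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        vals = np.asarray(self.values, dtype=float)
        if wl.ndim != 1 or vals.ndim != 1:
            raise ValueError("wavelengths and values must be 1-D")
        if wl.size != vals.size:
            raise ValueError(
                f"length mismatch: {wl.size} wavelengths vs {vals.size} values"
            )
        if wl.size == 0:
            raise ValueError("empty spectrum")
        if np.any(wl <= 0):
            raise ValueError("wavelengths must be positive (nm)")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}, got {self.kind!r}")
        if self.kind in ("absorbance", "extinction") and np.any(vals < 0):
            raise ValueError(f"{self.kind} values must be nonnegative")
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return self.wavelengths.size

    @property
    def wl_min(self) -> float:
        return float(self.wavelengths[0])

    @property
    def wl_max(self) -> float:
        return float(self.wavelengths[-1])

    def interp(self, wavelengths: np.ndarray) -> np.ndarray:
        """Linear interpolation; raises outside the original support."""
        wl = np.asarray(wavelengths, dtype=float)
        if np.any(wl < self.wl_min) or np.any(wl > self.wl_max):
            raise ValueError(
                "requested wavelengths outside spectrum support "
                f"[{self.wl_min}, {self.wl_max}] nm; extrapolation refused"
            )
        return np.interp(wl, self.wavelengths, self.values)

    def scaled(self, factor: float) -> "Spectrum":
        return Spectrum(self.wavelengths, self.values * factor, self.kind)


class OverlapIntegralResult(NamedTuple):
    """Overlap integral J (M^-1 cm^-1 nm^4) and the nm range integrated."""

    J: float
    wavelength_range: tuple[float, float]


class SubtractionResult(NamedTuple):
    """Difference spectrum with the count of negatives clamped to zero."""

    spectrum: Spectrum
    n_clamped: int


def read_spectrum(path: str | Path, kind: str) -> Spectrum:
    """Read a two-column (nm, value) text spectrum.

    Comma or whitespace delimited; lines starting with ``#`` are comments.
    Rows are sorted by wavelength; duplicate wavelengths are rejected.
    """
    path = Path(path)
    wl, vals = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise SpectrumParseError(
                    f"{path}:{lineno}: expected two columns, got {len(parts)}"
                )
            try:
                wl.append(float(parts[0]))
                vals.append(float(parts[1]))
            except ValueError as exc:
                raise SpectrumParseError(
                    f"{path}:{lineno}: non-numeric row {line!r}"
                ) from exc
    if not wl:
        raise SpectrumParseError(f"{path}: no data rows")
    wl_arr = np.array(wl)
    vals_arr = np.array(vals)
    order = np.argsort(wl_arr, kind="stable")
    wl_arr, vals_arr = wl_arr[order], vals_arr[order]
    if np.any(np.diff(wl_arr) == 0):
        dup = wl_arr[:-1][np.diff(wl_arr) == 0][0]
        raise SpectrumParseError(f"{path}: duplicate wavelength {dup} nm")
    return Spectrum(wl_arr, vals_arr, kind)


def write_spectrum(spectrum: Spectrum, path: str | Path) -> None:
    """Write the two-column text dialect that :func:`read_spectrum` consumes."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# kind: {spectrum.kind}\n# wavelength_nm value\n")
        for w, v in zip(spectrum.wavelengths, spectrum.values):
            fh.write(f"{w:.6g} {v:.10g}\n")


def _shared_grid(a: Spectrum, b: Spectrum, step: float) -> np.ndarray:
    lo = max(a.wl_min, b.wl_min)
    hi = min(a.wl_max, b.wl_max)
    if hi <= lo:
        raise ValueError(
            f"no spectral overlap: [{a.wl_min}, {a.wl_max}] vs "
            f"[{b.wl_min}, {b.wl_max}] nm"
        )
    n = int(np.floor((hi - lo) / step + 1e-9)) + 1
    return lo + step * np.arange(n)


def resample_common_grid(
    a: Spectrum, b: Spectrum, step: float = 1.0
) -> tuple[Spectrum, Spectrum]:
    """Linearly interpolate both spectra onto their shared wavelength grid.

    The grid spans [max(min_a, min_b), min(max_a, max_b)] at the given
    step, so no value is ever extrapolated beyond its original support.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    grid = _shared_grid(a, b, step)
    return (
        Spectrum(grid, a.interp(grid), a.kind),
        Spectrum(grid, b.interp(grid), b.kind),
    )


def overlap_integral(
    donor_emission: Spectrum,
    acceptor_extinction: Spectrum,
    step: float = 1.0,
) -> OverlapIntegralResult:
    """Overlap integral J = ∫ F_D(λ) ε_A(λ) λ⁴ dλ.

    F_D is the donor emission area-normalised to unit integral over the
    shared grid, ε_A the acceptor molar extinction (M^-1 cm^-1), λ in nm,
    giving J in M^-1 cm^-1 nm^4.  Trapezoidal quadrature throughout.
    """
    if donor_emission.kind != "emission":
        raise ValueError("donor spectrum must have kind='emission'")
    if acceptor_extinction.kind != "extinction":
        raise ValueError("acceptor spectrum must have kind='extinction'")
    if np.any(donor_emission.values < 0):
        raise ValueError("donor emission must be nonnegative")
    donor, acceptor = resample_common_grid(donor_emission, acceptor_extinction, step)
    wl = donor.wavelengths
    area = np.trapezoid(donor.values, wl)
    if area <= 0:
        raise ValueError("donor emission has zero area on the shared grid")
    f_norm = donor.values / area
    j = float(np.trapezoid(f_norm * acceptor.values * wl**4, wl))
    return OverlapIntegralResult(J=j, wavelength_range=(float(wl[0]), float(wl[-1])))


def inner_filter_correct(measured: Spectrum, absorbance: Spectrum) -> Spectrum:
    """Correct an emission spectrum for reabsorption: I_corr = I * 10^(D/2).

    D is the optical density of the sample at each emission wavelength; the
    half-power reflects a mean emission path from the centre of the cuvette.
    The output is restricted to wavelengths where D is known (no
    extrapolation of the absorbance spectrum).
    """
    if measured.kind != "emission":
        raise ValueError("measured spectrum must have kind='emission'")
    if absorbance.kind != "absorbance":
        raise ValueError("absorbance spectrum must have kind='absorbance'")
    mask = (measured.wavelengths >= absorbance.wl_min) & (
        measured.wavelengths <= absorbance.wl_max
    )
    if not mask.any():
        raise ValueError("no spectral overlap between emission and absorbance")
    wl = measured.wavelengths[mask]
    d = absorbance.interp(wl)
    corrected = measured.values[mask] * 10.0 ** (d / 2.0)
    return Spectrum(wl, corrected, "emission")


def subtract_spectra(full: Spectrum, bleached: Spectrum) -> SubtractionResult:
    """Pointwise ``full - bleached`` on the common grid, clamped at zero.

    Used to isolate the sensitized acceptor band: the photobleached sample
    carries only donor emission, so the difference is acceptor-only.
    Negative residuals (noise artifacts) are clamped to 0 and counted.
    """
    if full.kind != "emission" or bleached.kind != "emission":
        raise ValueError("both spectra must have kind='emission'")
    mask = (full.wavelengths >= bleached.wl_min) & (
        full.wavelengths <= bleached.wl_max
    )
    if not mask.any():
        raise ValueError("no spectral overlap between the two emission spectra")
    wl = full.wavelengths[mask]
    diff = full.values[mask] - bleached.interp(wl)
    n_clamped = int(np.sum(diff < 0))
    return SubtractionResult(Spectrum(wl, np.maximum(diff, 0.0), "emission"), n_clamped)
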