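"""Hyperbolic (one-site) binding-isotherm fitting for Tb³⁺ titrations.

The gated sensitized-emission intensity follows the standard saturation
isotherm

    I = I_max [Tb] / (K_d + [Tb]),

fit by positivity-constrained nonlinear least squares.  Free Tb³⁺ is
approximated by total Tb³⁺ (no depletion term), as the model equation
assumes.  The module also provides the empirical tangent-intersection
estimate of the saturating concentration: secant lines through the first
and last few points of the fitted curve, intersected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import curve_fit
from scipy import stats

__all__ = [
    "TitrationSeries",
    "BindingFit",
    "read_titration",
    "write_titration",
    "fit_binding",
    "saturation_by_tangents",
]


@dataclass(frozen=True)
class TitrationSeries:
    """Paired Tb³⁺ concentrations (µM, strictly increasing) and gated
    fluorescence intensities (a.u.)."""

    concentrations: np.ndarray
    intensities: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.concentrations, dtype=float)
        i = np.asarray(self.intensities, dtype=float)
        if c.ndim != 1 or i.ndim != 1 or c.size != i.size:
            raise ValueError("concentrations and intensities must be equal-length 1-D")
        if c.size == 0:
            raise ValueError("empty titration series")
        if np.any(c <= 0) or np.any(np.diff(c) <= 0):
            raise ValueError("concentrations must be positive and strictly increasing")
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "intensities", i)

    def __len__(self) -> int:
        return self.concentrations.size


def _hyperbola(c, imax, kd):
    return imax * c / (kd + c)


@dataclass(frozen=True)
class BindingFit:
    """Fitted one-site isotherm with uncertainties.

    ``se_*`` are asymptotic standard errors from the local linearisation;
    ``ci_*`` are 95% intervals (percentile bootstrap when ``n_boot`` > 0,
    otherwise normal-theory).  ``saturation_conc`` is filled by
    :func:`saturation_by_tangents`.
    """

    Kd: float  # µM
    Imax: float  # a.u.
    se_Kd: float
    se_Imax: float
    ci_Kd: tuple[float, float]
    ci_Imax: tuple[float, float]
    residual_sd: float
    n_boot: int
    seed: int | None
    saturation_conc: float | None = None

    def predict(self, concentrations) -> np.ndarray:
        c = np.asarray(concentrations, dtype=float)
        return _hyperbola(c, self.Imax, self.Kd)

    def summary(self) -> str:
        lines = [
            f"Kd   = {self.Kd:.3g} ± {self.se_Kd:.2g} µM  "
            f"(95% CI {self.ci_Kd[0]:.3g}–{self.ci_Kd[1]:.3g})",
            f"Imax = {self.Imax:.3g} ± {self.se_Imax:.2g} a.u.  "
            f"(95% CI {self.ci_Imax[0]:.3g}–{self.ci_Imax[1]:.3g})",
            f"residual sd = {self.residual_sd:.3g} a.u.",
        ]
        if self.saturation_conc is not None:
            lines.append(f"saturation (tangent intersection) = {self.saturation_conc:.3g} µM")
        return "\n".join(lines)


def read_titration(path: str | Path) -> TitrationSeries:
    """Two-column text (µM, intensity); '#' comments allowed."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric row {line!r}") from exc
    if not rows:
        raise ValueError(f"{path}: no data rows")
    rows.sort(key=lambda t: t[0])
    c, i = zip(*rows)
    return TitrationSeries(np.array(c), np.array(i))


def write_titration(series: TitrationSeries, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# concentration_uM intensity_au\n")
        for c, i in zip(series.concentrations, series.intensities):
            fh.write(f"{c:.6g} {i:.10g}\n")


def _initial_guess(c: np.ndarray, i: np.ndarray) -> tuple[float, float]:
    imax0 = float(i.max())
    kd0 = float(c[np.argmin(np.abs(i - imax0 / 2.0))])
    return imax0, max(kd0, 1e-12)


def fit_binding(
    series: TitrationSeries,
    n_boot: int = 1000,
    seed: int | None = None,
    ci_level: float = 0.95,
) -> BindingFit:
    """Least-squares fit of I = I_max[Tb]/(K_d+[Tb]) with K_d, I_max > 0.

    Initialisation: I_max ← max(I), K_d ← the concentration whose
    intensity is nearest half-maximum.  Standard errors come from the
    Jacobian at the optimum; intervals from a seeded residual bootstrap
    (``n_boot`` refits) or, with ``n_boot=0``, from normal theory.
    """
    c, i = series.concentrations, series.intensities
    if len(series) < 3:
        raise ValueError("need at least 3 titration points to fit two parameters")
    if np.all(i == 0):
        raise ValueError("all intensities are zero; binding parameters unidentifiable")
    top = float(i.max())
    rising_sampled = bool(np.any(i < 0.6 * top))
    flattening_sampled = top > 0 and abs(i[-1] - i[-2]) <= 0.2 * top
    if not (rising_sampled and flattening_sampled):
        warnings.warn(
            "titration points may not span both the rising and flattening "
            "regions; fit may be poorly constrained",
            stacklevel=2,
        )

    def _fit(y):
        popt, pcov = curve_fit(
            _hyperbola,
            c,
            y,
            p0=_initial_guess(c, y),
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            xtol=1e-10,
            ftol=1e-12,
            maxfev=500 * (len(c) + 2),
        )
        return popt, pcov

    try:
        (imax, kd), pcov = _fit(i)
    except RuntimeError as exc:
        raise RuntimeError(f"binding fit did not converge: {exc}") from exc

    residuals = i - _hyperbola(c, imax, kd)
    dof = max(len(c) - 2, 1)
    residual_sd = float(np.sqrt(np.sum(residuals**2) / dof))
    perr = np.sqrt(np.diag(pcov))
    se_imax, se_kd = float(perr[0]), float(perr[1])

    alpha = 1.0 - ci_level
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        fitted = _hyperbola(c, imax, kd)
        # fitted residuals are variance-deflated by the 2 estimated
        # parameters; rescale so resampled noise has the right spread
        scaled = residuals * np.sqrt(len(c) / dof)
        boot_kd, boot_imax = [], []
        for _ in range(n_boot):
            y_star = fitted + rng.choice(scaled, size=len(c), replace=True)
            try:
                (bi, bk), _ = _fit(np.maximum(y_star, 0.0))
            except RuntimeError:  # pragma: no cover - pathological resample
                continue
            boot_imax.append(bi)
            boot_kd.append(bk)
        qs = (100 * alpha / 2, 100 * (1 - alpha / 2))
        ci_kd = tuple(np.percentile(boot_kd, qs))
        ci_imax = tuple(np.percentile(boot_imax, qs))
    else:
        z = stats.norm.ppf(1 - alpha / 2)
        ci_kd = (kd - z * se_kd, kd + z * se_kd)
        ci_imax = (imax - z * se_imax, imax + z * se_imax)

    return BindingFit(
        Kd=float(kd),
        Imax=float(imax),
        se_Kd=se_kd,
        se_Imax=se_imax,
        ci_Kd=(float(min(ci_kd[0], kd)), float(max(ci_kd[1], kd))),
        ci_Imax=(float(min(ci_imax[0], imax)), float(max(ci_imax[1], imax))),
        residual_sd=residual_sd,
        n_boot=n_boot,
        seed=seed,
    )


def saturation_by_tangents(
    fit: BindingFit, series: TitrationSeries, k_points: int = 3
) -> float:
    """Saturating concentration as the intersection of two secant lines.

    One ordinary-least-squares line through the first ``k_points`` of the
    fitted curve (the rising limb) and one through the last ``k_points``
    (the plateau), both evaluated at the measured concentrations; returns
    the abscissa of their intersection in µM.
    """
    c = series.concentrations
    if k_points < 2:
        raise ValueError("k_points must be >= 2")
    if 2 * k_points > len(c):
        raise ValueError("k_points too large for the series length")
    y = fit.predict(c)
    rise = np.polyfit(c[:k_points], y[:k_points], 1)
    plateau = np.polyfit(c[-k_points:], y[-k_points:], 1)
    d_slope = rise[0] - plateau[0]
    if abs(d_slope) < 1e-12 * max(abs(rise[0]), abs(plateau[0]), 1.0):
        raise ValueError("tangent lines are parallel; no intersection")
    return float((plateau[1] - rise[1]) / d_slope)
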