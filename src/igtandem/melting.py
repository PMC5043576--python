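"""Two-state thermal-melt (DSF) curve fitting.

The model is a Boltzmann sigmoid between two linear baselines,

    F(T) = (a1 + b1 T) + [(a2 + b2 T) - (a1 + b1 T)] / (1 + exp((Tm - T)/k)),

fitted by nonlinear least squares. Tm is the transition midpoint in deg C
and k > 0 the transition width. The maximum of the smoothed first
derivative dF/dT initializes Tm and is reported alongside the fit for
comparison (some instruments report the derivative peak as "Tm"; on an
asymmetric-baseline curve the two can differ slightly).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

from .errors import FitConvergenceError, NoTransitionError


@dataclass
class MeltingCurve:
    """A fluorescence-vs-temperature melt profile (temperatures in deg C,
    strictly ascending; fluorescence in arbitrary units)."""

    temperature: np.ndarray
    fluorescence: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, float)
        self.fluorescence = np.asarray(self.fluorescence, float)
        if self.temperature.shape != self.fluorescence.shape:
            raise ValueError("temperature/fluorescence length mismatch")
        if len(self.temperature) < 10:
            raise ValueError("melting curve needs >= 10 points")
        if not np.all(np.diff(self.temperature) > 0):
            raise ValueError("temperatures must be strictly increasing")

    @classmethod
    def from_tsv(cls, path, label: str = "") -> "MeltingCurve":
        import pandas as pd

        df = pd.read_csv(path, sep=None, engine="python")
        cols = list(df.columns)
        return cls(df[cols[0]].to_numpy(float), df[cols[1]].to_numpy(float),
                   label or str(path))


def boltzmann(t, tm, k, a1, b1, a2, b2):
    """Two-state sigmoid with linear pre/post baselines."""
    t = np.asarray(t, float)
    pre = a1 + b1 * t
    post = a2 + b2 * t
    return pre + (post - pre) / (1.0 + np.exp((tm - t) / k))


@dataclass
class MeltFit:
    tm: float          # deg C
    k: float           # deg C, > 0
    baseline_pre: tuple[float, float]   # intercept, slope
    baseline_post: tuple[float, float]
    rms: float         # residual RMS, fluorescence units
    tm_stderr: float   # deg C
    tm_derivative_peak: float  # Tm initializer from smoothed dF/dT
    label: str = ""


def _smoothed(y: np.ndarray, window: int) -> np.ndarray:
    window = min(window if window % 2 else window + 1, len(y) - (len(y) + 1) % 2)
    if window < 5:
        return y.copy()
    return savgol_filter(y, window, polyorder=2)


def fit_melting(curve: MeltingCurve, smooth_window: int = 9,
                noise_factor: float = 5.0) -> MeltFit:
    """Fit a two-state melt and return Tm with its standard error.

    Raw points are fitted (no interpolation); smoothing is used only to
    initialize Tm at the derivative peak and to test for a visible
    transition (smoothed amplitude must exceed ``noise_factor`` times the
    residual noise estimate). Raises :class:`NoTransitionError` for flat
    curves and :class:`FitConvergenceError` with diagnostics when the
    optimizer fails.
    """
    t, f = curve.temperature, curve.fluorescence
    smooth = _smoothed(f, smooth_window)
    noise = float(np.std(f - smooth))
    amplitude = float(smooth.max() - smooth.min())
    if amplitude <= max(noise_factor * noise, 1e-12):
        raise NoTransitionError(
            f"{curve.label or 'curve'}: no detectable transition "
            f"(amplitude {amplitude:.3g} vs noise {noise:.3g})")
    dfdt = np.gradient(smooth, t)
    ipk = int(np.argmax(np.abs(dfdt)))
    tm0 = float(t[ipk])

    n_edge = max(3, len(t) // 7)
    b1, a1 = np.polyfit(t[:n_edge], f[:n_edge], 1)
    b2, a2 = np.polyfit(t[-n_edge:], f[-n_edge:], 1)
    p0 = [tm0, 1.0, a1, b1, a2, b2]
    span = t[-1] - t[0]
    bounds = ([t[0], 1e-3, -np.inf, -np.inf, -np.inf, -np.inf],
              [t[-1], span, np.inf, np.inf, np.inf, np.inf])
    try:
        popt, pcov = curve_fit(boltzmann, t, f, p0=p0, bounds=bounds,
                               maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        raise FitConvergenceError(
            f"{curve.label or 'curve'}: melt fit failed (init Tm={tm0:.1f}, "
            f"amplitude={amplitude:.3g}): {exc}") from exc
    tm_err = float(np.sqrt(pcov[0, 0])) if np.all(np.isfinite(pcov)) else np.inf
    if not np.isfinite(tm_err):
        raise FitConvergenceError(
            f"{curve.label or 'curve'}: non-finite Tm covariance "
            f"(popt={np.round(popt, 3).tolist()})")
    resid = f - boltzmann(t, *popt)
    return MeltFit(
        tm=float(popt[0]), k=float(popt[1]),
        baseline_pre=(float(popt[2]), float(popt[3])),
        baseline_post=(float(popt[4]), float(popt[5])),
        rms=float(np.sqrt(np.mean(resid ** 2))),
        tm_stderr=tm_err,
        tm_derivative_peak=tm0,
        label=curve.label,
    )


def delta_tm(fit_a: MeltFit, fit_b: MeltFit) -> tuple[float, float]:
    """Tm(b) - Tm(a) in deg C with the propagated standard error
    sqrt(se_a^2 + se_b^2)."""
    return (fit_b.tm - fit_a.tm,
            float(np.hypot(fit_a.tm_stderr, fit_b.tm_stderr)))
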