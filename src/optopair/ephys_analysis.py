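"""Photocurrent characterization: peaks, exponential time constants,
normalization, spectral ratios, action spectra and reversal potentials.

The decay after light offset is fitted with a single exponential back to a
zero baseline, A * exp(-(t - t_off)/tau); the rise at light onset with a
saturating exponential I_ss * (1 - exp(-(t - t_on)/tau)).  Both use
Levenberg-Marquardt least squares with the initial tau taken from the 1/e
crossing of the segment.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from scipy import optimize

from .opsin_models import Trace

__all__ = [
    "FitResult",
    "IVRamp",
    "peak_photocurrent",
    "fit_off_tau",
    "fit_on_tau",
    "normalize_photocurrent",
    "wavelength_ratio",
    "percent_reduction",
    "action_spectrum",
    "reversal_potential",
    "desensitization_ratio",
]


class DegenerateInputError(ValueError):
    """Raised when a segment contains no usable signal."""


class NoCrossingError(ValueError):
    """Raised when a ramp current never changes sign."""


@dataclass
class FitResult:
    """Outcome of a nonlinear exponential fit."""

    tau: float  # ms
    amplitude: float  # pA
    baseline: float  # pA
    rmse: float  # pA
    r_squared: float
    converged: bool
    window: Tuple[float, float]  # (s, s)


def _baseline(trace: Trace, light_on: float, pre_window: float = 0.05) -> float:
    """Mean of the pre-light baseline (default 50 ms before light onset)."""
    seg = trace.slice(max(trace.t0, light_on - pre_window), light_on)
    if seg.size == 0:
        return 0.0
    return float(np.mean(seg))


def peak_photocurrent(
    trace: Trace,
    window: Tuple[float, float],
    baseline_window: float = 0.05,
) -> float:
    """Signed extremum of the largest deflection from the pre-light baseline.

    The baseline is the mean over ``baseline_window`` seconds preceding the
    window start; the returned value is the deflection extremum plus
    nothing, i.e. the signed peak relative to that baseline.
    """
    t0, t1 = window
    seg = trace.slice(t0, t1)
    if seg.size == 0:
        raise ValueError("empty peak window")
    base = _baseline(trace, t0, baseline_window)
    dev = seg - base
    i = int(np.argmax(np.abs(dev)))
    return float(dev[i])


def _tau_init_decay(t_ms: np.ndarray, y: np.ndarray) -> float:
    """Initial tau (ms) from the 1/e crossing of |y| relative to its first sample."""
    y0 = abs(y[0])
    target = y0 / np.e
    below = np.nonzero(np.abs(y) <= target)[0]
    if below.size:
        return max(float(t_ms[below[0]]), t_ms[1] if t_ms.size > 1 else 1.0)
    return float(t_ms[-1]) if t_ms[-1] > 0 else 1.0


def _fit_metrics(y: np.ndarray, yhat: np.ndarray) -> Tuple[float, float]:
    resid = y - yhat
    rmse = float(np.sqrt(np.mean(resid**2)))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return rmse, r2


def fit_off_tau(
    trace: Trace,
    light_off: float,
    fit_len: Optional[float] = None,
    free_baseline: bool = False,
) -> FitResult:
    """Fit the post-offset decay with A * exp(-(t - t_off)/tau) to zero baseline.

    ``fit_len`` defaults to 5x the initial tau estimate (capped at the trace
    end).  With ``free_baseline`` an additive offset is also fitted
    (non-default variant).
    """
    i0 = trace.index_of(light_off)
    if i0 < 0 or i0 >= trace.n:
        raise ValueError("light_off outside trace")
    t_ms_full = (trace.times[i0:] - light_off) * 1e3
    y_full = trace.values[i0:]
    if not np.any(np.abs(y_full) > 0):
        raise DegenerateInputError("all-zero decay segment")
    tau0 = _tau_init_decay(t_ms_full, y_full)
    if fit_len is None:
        fit_len = min(5.0 * tau0 * 1e-3, t_ms_full[-1] * 1e-3)
    n_fit = max(int(round(fit_len * 1e3 / (trace.dt * 1e3))), 5)
    t_ms = t_ms_full[:n_fit]
    y = y_full[:n_fit]
    if t_ms.size < 5:
        raise DegenerateInputError("decay segment must contain >= 5 samples")
    a0 = float(y[0])

    if free_baseline:

        def model(t, a, tau, c):
            return a * np.exp(-t / tau) + c

        p0 = [a0, tau0, 0.0]
    else:

        def model(t, a, tau):
            return a * np.exp(-t / tau)

        p0 = [a0, tau0]

    converged = True
    try:
        popt, _ = optimize.curve_fit(
            model, t_ms, y, p0=p0, maxfev=2000, xtol=1e-10, ftol=1e-10
        )
    except RuntimeError:
        converged = False
        popt = np.asarray(p0, dtype=float)
    tau = float(abs(popt[1]))
    yhat = model(t_ms, *popt)
    rmse, r2 = _fit_metrics(y, yhat)
    if converged and (tau <= 0 or not np.isfinite(tau)):
        converged = False
    base = float(popt[2]) if free_baseline else 0.0
    return FitResult(
        tau=tau,
        amplitude=float(popt[0]),
        baseline=base,
        rmse=rmse,
        r_squared=r2,
        converged=converged,
        window=(light_off, light_off + t_ms[-1] * 1e-3),
    )


def fit_on_tau(trace: Trace, light_on: float, light_off: float) -> FitResult:
    """Fit the light-on rise with I_ss * (1 - exp(-(t - t_on)/tau))."""
    i0 = trace.index_of(light_on)
    i1 = trace.index_of(light_off)
    if i1 - i0 < 5:
        raise DegenerateInputError("light-on segment must contain >= 5 samples")
    t_ms = (trace.times[i0:i1] - light_on) * 1e3
    y = trace.values[i0:i1]
    if not np.any(np.abs(y) > 0):
        raise DegenerateInputError("all-zero light-on segment")
    i_ss0 = float(y[-1])
    # 1/e rise: first time |y| exceeds (1 - 1/e) of the plateau
    target = abs(i_ss0) * (1 - 1 / np.e)
    above = np.nonzero(np.abs(y) >= target)[0]
    tau0 = float(t_ms[above[0]]) if above.size and t_ms[above[0]] > 0 else max(
        float(t_ms[-1]) / 3.0, 1e-3
    )

    def model(t, i_ss, tau):
        return i_ss * (1.0 - np.exp(-t / tau))

    converged = True
    try:
        popt, _ = optimize.curve_fit(
            model, t_ms, y, p0=[i_ss0, tau0], maxfev=2000, xtol=1e-10, ftol=1e-10
        )
    except RuntimeError:
        converged = False
        popt = np.array([i_ss0, tau0])
    tau = float(abs(popt[1]))
    yhat = model(t_ms, *popt)
    rmse, r2 = _fit_metrics(y, yhat)
    if converged and (tau <= 0 or not np.isfinite(tau)):
        converged = False
    return FitResult(
        tau=tau,
        amplitude=float(popt[0]),
        baseline=0.0,
        rmse=rmse,
        r_squared=r2,
        converged=converged,
        window=(light_on, light_off),
    )


def normalize_photocurrent(peak: float, capacitance: float, fluorescence: float) -> float:
    """Peak photocurrent normalized to cell size and expression (pA/pF/A.U.)."""
    if capacitance <= 0 or fluorescence <= 0:
        raise ValueError("capacitance and fluorescence must be positive")
    return peak / (capacitance * fluorescence)


def wavelength_ratio(peak_a: float, peak_b: float) -> float:
    """|peak_a| / |peak_b|, e.g. the 590/470 response ratio."""
    if peak_b == 0:
        raise ZeroDivisionError("reference peak is zero")
    return abs(peak_a) / abs(peak_b)


def percent_reduction(value: float, reference: float) -> float:
    """Percent reduction of |value| relative to |reference|."""
    if reference == 0:
        raise ZeroDivisionError("reference is zero")
    return 100.0 * (abs(reference) - abs(value)) / abs(reference)


def action_spectrum(
    per_cell_responses: Mapping[str, Mapping[float, float]]
) -> Dict[float, Tuple[float, float]]:
    """Per-cell normalized action spectrum, averaged across cells.

    Each cell's peaks are divided by that cell's maximum |peak| across the
    spectrum, then wavelengths are averaged across cells.  Returns
    {wavelength: (mean, sem)} with sem 0 for a single cell.
    """
    norm: Dict[float, list] = {}
    for cell, responses in per_cell_responses.items():
        if len(responses) < 2:
            raise ValueError(f"cell {cell!r} must be measured at >= 2 wavelengths")
        m = max(abs(v) for v in responses.values())
        if m == 0:
            raise DegenerateInputError(f"cell {cell!r} has all-zero responses")
        for lam, v in responses.items():
            norm.setdefault(lam, []).append(abs(v) / m)
    out: Dict[float, Tuple[float, float]] = {}
    for lam in sorted(norm):
        vals = np.asarray(norm[lam])
        sem = float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else 0.0
        out[lam] = (float(np.mean(vals)), sem)
    return out


@dataclass
class IVRamp:
    """Time-aligned voltage and current traces from a ramp protocol."""

    voltage: Trace
    current: Trace

    def __post_init__(self) -> None:
        if self.voltage.n != self.current.n or self.voltage.dt != self.current.dt:
            raise ValueError("voltage and current must share length and dt")


def reversal_potential(ramp: IVRamp, leak: Optional[IVRamp] = None) -> float:
    """Reversal potential (mV): zero crossing of the leak-subtracted I-V relation.

    If a light-off ``leak`` ramp is provided it is subtracted sample-wise,
    removing the leak and any light-independent offset current; otherwise
    the crossing of the raw light-on current is interpolated directly.
    """
    v = ramp.voltage.values
    i = ramp.current.values.copy()
    if leak is not None:
        i = i - leak.current.values
    return _zero_crossing(v, i)


def _zero_crossing(v: np.ndarray, i: np.ndarray) -> float:
    """Zero of the I-V relation by a local linear fit around the crossing.

    Noise-robust: instead of the first sign flip, the samples nearest the
    crossing (smallest |I|, 5% of the ramp or >= 10 points) are fitted
    with a straight line whose root is returned.
    """
    sign = np.sign(i)
    if np.all(sign >= 0) or np.all(sign <= 0):
        raise NoCrossingError("current does not change sign within the ramp")
    n_local = max(int(0.05 * i.size), 10)
    idx = np.argsort(np.abs(i))[:n_local]
    slope, intercept = np.polyfit(v[idx], i[idx], 1)
    if slope == 0:
        return float(np.mean(v[idx]))
    return float(-intercept / slope)


def desensitization_ratio(trace: Trace, light_on: float, light_off: float) -> float:
    """|plateau| / |peak| over the light-on segment; plateau is the mean of
    the last 10% of the illumination."""
    seg = trace.slice(light_on, light_off)
    if seg.size == 0:
        raise DegenerateInputError("empty light-on segment")
    base = _baseline(trace, light_on)
    dev = seg - base
    peak = np.max(np.abs(dev))
    if peak == 0:
        raise DegenerateInputError("zero peak")
    n_tail = max(int(round(0.1 * seg.size)), 1)
    plateau = np.mean(np.abs(dev[-n_tail:]))
    return float(plateau / peak)
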