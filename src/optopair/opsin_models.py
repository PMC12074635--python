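"""Opsin parameter sets and photocycle simulation.

Photocurrents are generated from a three-state photocycle

    closed (C)  --k_a-->  open (O)  --k_d-->  desensitized (D)
    closed (C)  <--1/tau_off--  open (O)
    closed (C)  <--k_recov--  desensitized (D)

where the opening rate ``k_a`` is proportional to the photon flux weighted
by a Gaussian spectral sensitivity (in wavenumber), and the light-driven
desensitization rate ``k_d`` scales with the same normalized flux.  The
desensitized state may retain a partial conductance (``g_desens_frac``),
which captures the long-lived conducting photointermediate of
Chrimson-family cation channels responsible for their slow residual
current after blue illumination; for the anion channels it is 0 and the
model reduces to the classical three-state scheme.

Membrane current follows the ohmic form

    I(t) = g_scale * g_unit * (O(t) + f_D * D(t)) * (V_hold - E_rev)

in pA for conductances in nS and potentials in mV.  Occupancies are
propagated exactly (eigen-decomposition of the rate matrix) over each
piecewise-constant light segment.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq

__all__ = [
    "PLANCK_H",
    "SPEED_OF_LIGHT",
    "OpsinParams",
    "LightEpoch",
    "LightProtocol",
    "Trace",
    "spectral_sensitivity",
    "photon_flux",
    "equal_flux_irradiance",
    "activation_rate",
    "simulate_photocurrent",
    "simulate_occupancy",
    "builtin_opsin_table",
    "REFERENCE_IRRADIANCE",
]

PLANCK_H = 6.62607015e-34  # J s
SPEED_OF_LIGHT = 2.99792458e8  # m/s

#: irradiance (mW/mm^2) at the opsin's peak wavelength defining the
#: reference photon flux for the desensitization rate scale k_desens.
REFERENCE_IRRADIANCE = 10.0


@dataclass
class OpsinParams:
    """Kinetic and spectral parameter set for one opsin.

    Parameters
    ----------
    name : str
        Label for the opsin.
    e_rev : float
        Reversal potential in mV.
    lambda_peak : float
        Peak wavelength of the action spectrum in nm.
    spectral_width : float
        Gaussian sigma of the action spectrum, in wavenumber (cm^-1).
    sigma_eff : float
        Activation cross-section scaling photon flux (photons s^-1 mm^-2)
        to an opening rate in ms^-1.
    tau_off : float
        Channel closing time constant in ms.
    k_desens : float
        Open->desensitized rate in ms^-1 at the reference photon flux
        (the flux of ``REFERENCE_IRRADIANCE`` mW/mm^2 at ``lambda_peak``).
    k_recov : float
        Desensitized->closed recovery rate in ms^-1.
    g_unit : float
        Conductance at open fraction 1, in nS.
    charge_sign : str
        "anion" or "cation"; interpretive label for e_rev, the current sign
        always follows I = g*O*(V - e_rev).
    g_desens_frac : float
        Conductance of the desensitized state relative to the open state,
        in [0, 1].  Nonzero for Chrimson-family channels (long-lived
        conducting photointermediate), 0 otherwise.
    """

    name: str
    e_rev: float
    lambda_peak: float
    spectral_width: float
    sigma_eff: float
    tau_off: float
    k_desens: float = 0.0
    k_recov: float = 0.02
    g_unit: float = 10.0
    charge_sign: str = "cation"
    g_desens_frac: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_off <= 0:
            raise ValueError("tau_off must be positive")
        for attr in ("sigma_eff", "k_desens", "k_recov", "g_unit"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be non-negative")
        if not (350.0 <= self.lambda_peak <= 700.0):
            raise ValueError("lambda_peak must lie in [350, 700] nm")
        if self.spectral_width <= 0:
            raise ValueError("spectral_width must be positive")
        if self.charge_sign not in ("anion", "cation"):
            raise ValueError("charge_sign must be 'anion' or 'cation'")
        if not (0.0 <= self.g_desens_frac <= 1.0):
            raise ValueError("g_desens_frac must lie in [0, 1]")

    @property
    def reference_rate(self) -> float:
        """Opening rate (ms^-1) at the reference irradiance and peak wavelength."""
        return activation_rate(self, self.lambda_peak, REFERENCE_IRRADIANCE)

    def with_(self, **kwargs) -> "OpsinParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)


@dataclass
class LightEpoch:
    """A rectangular light pulse: onset/duration in s, wavelength nm, irradiance mW/mm^2.

    Epochs of different wavelengths may overlap in time (co-illumination);
    their activation rates add.
    """

    t_on: float
    duration: float
    wavelength: float
    irradiance: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.irradiance < 0:
            raise ValueError("irradiance must be non-negative")
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")

    @property
    def t_off(self) -> float:
        return self.t_on + self.duration


@dataclass
class LightProtocol:
    """Collection of light epochs within [0, t_end]."""

    epochs: List[LightEpoch] = field(default_factory=list)
    t_end: float = 1.0

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        for ep in self.epochs:
            if ep.t_on < 0 or ep.t_off > self.t_end + 1e-12:
                raise ValueError("all epochs must fit within [0, t_end]")

    def boundaries(self) -> np.ndarray:
        """Sorted unique time points where the light pattern changes."""
        pts = {0.0, self.t_end}
        for ep in self.epochs:
            pts.add(ep.t_on)
            pts.add(ep.t_off)
        return np.array(sorted(p for p in pts if 0.0 <= p <= self.t_end))

    def active_epochs(self, t: float) -> List[LightEpoch]:
        return [ep for ep in self.epochs if ep.t_on - 1e-12 <= t < ep.t_off - 1e-12]


@dataclass
class Trace:
    """Uniformly sampled time series with units and sampling metadata."""

    t0: float
    dt: float
    values: np.ndarray
    units: str = "pA"
    kind: str = "current"

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("trace values must be finite")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    def index_of(self, t: float) -> int:
        """Index of the sample at or immediately after time t."""
        return int(np.ceil((t - self.t0) / self.dt - 1e-9))

    def slice(self, t_start: float, t_stop: float) -> np.ndarray:
        i0 = max(self.index_of(t_start), 0)
        i1 = min(self.index_of(t_stop), self.n)
        return self.values[i0:i1]


def spectral_sensitivity(params: OpsinParams, wavelength: float) -> float:
    """Relative sensitivity in (0, 1]: Gaussian in wavenumber around the peak.

    The Gaussian is centered at nu_peak = 1e7 / lambda_peak (cm^-1) with
    sigma ``spectral_width``; equals 1 exactly at the peak wavelength.
    """
    wl = np.asarray(wavelength, dtype=float)
    if np.any(wl <= 0):
        raise ValueError("wavelength must be positive")
    nu = 1e7 / wl
    nu_peak = 1e7 / params.lambda_peak
    s = np.exp(-0.5 * ((nu - nu_peak) / params.spectral_width) ** 2)
    return float(s) if np.isscalar(wavelength) else s


def photon_flux(irradiance: float, wavelength: float) -> float:
    """Photon flux (photons s^-1 mm^-2) from irradiance (mW/mm^2) and wavelength (nm)."""
    if irradiance < 0:
        raise ValueError("irradiance must be non-negative")
    if wavelength <= 0:
        raise ValueError("wavelength must be positive")
    power_w = irradiance * 1e-3  # W/mm^2
    lam_m = wavelength * 1e-9
    return power_w * lam_m / (PLANCK_H * SPEED_OF_LIGHT)


def equal_flux_irradiance(
    ref_irradiance: float, ref_wavelength: float, target_wavelength: float
) -> float:
    """Irradiance at ``target_wavelength`` matching the reference photon flux.

    Since flux is proportional to P * lambda, P_target = P_ref * lam_ref / lam_target.
    """
    if ref_irradiance < 0:
        raise ValueError("irradiance must be non-negative")
    if ref_wavelength <= 0 or target_wavelength <= 0:
        raise ValueError("wavelengths must be positive")
    return ref_irradiance * ref_wavelength / target_wavelength


def activation_rate(params: OpsinParams, wavelength: float, irradiance: float) -> float:
    """Opening rate k_a in ms^-1 for one light source; rates of simultaneous sources add."""
    return params.sigma_eff * spectral_sensitivity(params, wavelength) * photon_flux(
        irradiance, wavelength
    )


def _rate_matrix(params: OpsinParams, k_a: float) -> np.ndarray:
    """Photocycle rate matrix (per ms) for state order [C, O, D]."""
    k_off = 1.0 / params.tau_off
    ref = params.reference_rate
    u = k_a / ref if ref > 0 else 0.0
    k_d = params.k_desens * u
    k_r = params.k_recov
    return np.array(
        [
            [-k_a, k_off, k_r],
            [k_a, -(k_off + k_d), 0.0],
            [0.0, k_d, -k_r],
        ]
    )


def _propagate(A_ms: np.ndarray, s0: np.ndarray, t_offsets_s: np.ndarray) -> np.ndarray:
    """States at the given offsets (s) for a constant rate matrix (per ms).

    Uses eigen-decomposition; falls back to per-point matrix exponentials
    if the eigenvector basis is ill-conditioned.
    """
    A = A_ms * 1e3  # per second
    t = np.asarray(t_offsets_s, dtype=float)
    try:
        w, V = np.linalg.eig(A)
        cond = np.linalg.cond(V)
        if not np.isfinite(cond) or cond > 1e8:
            raise np.linalg.LinAlgError
        c = np.linalg.solve(V, s0)
        states = (V @ (c[:, None] * np.exp(np.outer(w, t)))).real
    except np.linalg.LinAlgError:
        states = np.column_stack([expm(A * ti) @ s0 for ti in t])
    # guard tiny negative round-off; renormalize conservation exactly
    states = np.clip(states, 0.0, 1.0)
    states /= states.sum(axis=0, keepdims=True)
    return states


def _total_activation(params: OpsinParams, epochs: Sequence[LightEpoch]) -> float:
    return float(sum(activation_rate(params, ep.wavelength, ep.irradiance) for ep in epochs))


def simulate_occupancy(
    params: OpsinParams, protocol: LightProtocol, dt: float
) -> Dict[str, Trace]:
    """Integrate the photocycle; returns occupancy traces for C, O and D.

    Occupancies are in [0, 1] and sum to 1 at every sample.  Integration is
    exact per piecewise-constant light segment.
    """
    if dt > 1e-4:
        raise ValueError("dt must be <= 0.1 ms for photocycle integration")
    n = int(round(protocol.t_end / dt)) + 1
    times = dt * np.arange(n)
    bounds = protocol.boundaries()
    out = np.empty((3, n))
    s = np.array([1.0, 0.0, 0.0])
    for a, b in zip(bounds[:-1], bounds[1:]):
        mid = 0.5 * (a + b)
        k_a = _total_activation(params, protocol.active_epochs(mid))
        A = _rate_matrix(params, k_a)
        mask = (times >= a - 1e-12) & (times < b - 1e-12)
        if a == bounds[0]:
            mask |= times <= a + 1e-12
        if mask.any():
            out[:, mask] = _propagate(A, s, times[mask] - a)
        s = _propagate(A, s, np.array([b - a]))[:, 0]
    # final sample at exactly t_end
    last = times >= bounds[-1] - 1e-12
    if last.any():
        out[:, last] = s[:, None]
    names = ("closed", "open", "desensitized")
    return {
        nm: Trace(t0=0.0, dt=dt, values=out[i], units="dimensionless", kind="occupancy")
        for i, nm in enumerate(names)
    }


def simulate_photocurrent(
    params: OpsinParams,
    protocol: LightProtocol,
    holding: float = -60.0,
    dt: float = 1e-5,
    g_scale: float = 1.0,
) -> Trace:
    """Simulated whole-cell photocurrent (pA) at a fixed holding potential.

    I(t) = g_scale * g_unit * (O(t) + g_desens_frac * D(t)) * (holding - e_rev).
    The current is exactly 0 before the first light epoch.
    """
    occ = simulate_occupancy(params, protocol, dt)
    conducting = occ["open"].values + params.g_desens_frac * occ["desensitized"].values
    current = g_scale * params.g_unit * conducting * (holding - params.e_rev)
    return Trace(t0=0.0, dt=dt, values=current, units="pA", kind="current")


# ---------------------------------------------------------------------------
# builtin opsin table


def _sigma_for_rate(k10: float, lambda_peak: float) -> float:
    """Cross-section giving opening rate k10 (ms^-1) at the reference irradiance."""
    return k10 / photon_flux(REFERENCE_IRRADIANCE, lambda_peak)


def _width_for_ratio(
    lambda_peak: float,
    tau_off: float,
    k10: float,
    lam_measured: float,
    target_ratio: float,
    irradiance: float = REFERENCE_IRRADIANCE,
) -> float:
    """Spectral sigma (cm^-1) such that the steady-state photocurrent at
    ``lam_measured`` is ``target_ratio`` of the peak-wavelength response.

    Uses the two-state closed form O_ss = k_a / (k_a + 1/tau_off): the
    long-pulse peak ratio, not the raw sensitivity ratio, is matched.
    """
    q = 1.0 / tau_off
    k_peak = k10 * photon_flux(irradiance, lam_measured) / photon_flux(
        irradiance, lambda_peak
    )  # rate at lam_measured if sensitivity were 1

    def f(width: float) -> float:
        nu = 1e7 / lam_measured
        nu_peak = 1e7 / lambda_peak
        s = np.exp(-0.5 * ((nu - nu_peak) / width) ** 2)
        k_m = k_peak * s
        o_m = k_m / (k_m + q)
        o_p = k10 / (k10 + q)
        return o_m / o_p - target_ratio

    return brentq(f, 50.0, 20000.0, xtol=1e-6)


def builtin_opsin_table() -> Dict[str, OpsinParams]:
    """Parameter sets for the characterized opsins.

    Off-time constants and reversal potentials are the measured values;
    spectral widths of the potassium channels are calibrated so the model
    reproduces the measured 590-nm response ratios (HcKCR1: 73% of 530 nm;
    HcKCR2: 9% of 470 nm; WiChR: 27.6% of 470 nm).  The cation-channel
    reversal potential is set to 0 mV (assumption; not measured here), and
    Chrimson-family channels carry a partially conducting desensitized
    state (see module docstring).
    """
    table: Dict[str, OpsinParams] = {}

    def add(p: OpsinParams) -> None:
        table[p.name] = p

    # --- Chrimson-family cation channels -------------------------------
    chrimson_common = dict(
        e_rev=0.0,
        lambda_peak=585.0,
        spectral_width=2200.0,
        charge_sign="cation",
        k_desens=0.3,
        k_recov=0.01,
        g_desens_frac=0.35,
        g_unit=10.0,
    )
    add(
        OpsinParams(
            name="IvfChr",
            tau_off=5.6,
            sigma_eff=_sigma_for_rate(0.4, 585.0),
            **chrimson_common,
        )
    )
    add(
        OpsinParams(
            name="C-ChrimsonR-ts",
            tau_off=21.5,
            sigma_eff=_sigma_for_rate(0.4, 585.0),
            **chrimson_common,
        )
    )

    # --- ZipACR family (anion channels) --------------------------------
    zip_common = dict(e_rev=-39.0, lambda_peak=515.0, charge_sign="anion", g_unit=10.0)
    add(
        OpsinParams(
            name="ZipACR",
            tau_off=9.5,
            spectral_width=1250.0,
            sigma_eff=_sigma_for_rate(3.0, 515.0),
            k_desens=0.06,
            k_recov=0.005,
            **zip_common,
        )
    )
    add(
        OpsinParams(
            name="Zip151V",
            tau_off=15.5,
            spectral_width=1200.0,
            sigma_eff=_sigma_for_rate(3.0, 515.0),
            k_desens=0.0,
            **zip_common,
        )
    )
    add(
        OpsinParams(
            name="Zip151T",
            tau_off=20.2,
            spectral_width=1300.0,
            sigma_eff=_sigma_for_rate(3.0, 515.0),
            k_desens=0.0,
            **zip_common,
        )
    )

    # --- slow anion channels -------------------------------------------
    for name, tau in (("GtACR2", 161.0), ("RsACR_995", 122.7), ("RlACR_477", 95.8)):
        add(
            OpsinParams(
                name=name,
                e_rev=-39.0,
                lambda_peak=470.0,
                spectral_width=1300.0,
                sigma_eff=_sigma_for_rate(1.0, 470.0),
                tau_off=tau,
                k_desens=0.0,
                charge_sign="anion",
                g_unit=10.0,
            )
        )

    # --- potassium-selective channels, widths calibrated to printed ratios
    kchr = [
        # name, tau_off, e_rev, lambda_peak, measured wavelength, ratio
        ("HcKCR1", 49.7, -58.0, 530.0, 590.0, 0.730),
        ("HcKCR2", 58.6, -50.7, 470.0, 590.0, 0.090),
        ("WiChR", 229.3, -65.2, 470.0, 590.0, 0.276),
    ]
    for name, tau, e_rev, lam_peak, lam_meas, ratio in kchr:
        k10 = 0.3
        width = _width_for_ratio(lam_peak, tau, k10, lam_meas, ratio)
        add(
            OpsinParams(
                name=name,
                e_rev=e_rev,
                lambda_peak=lam_peak,
                spectral_width=width,
                sigma_eff=_sigma_for_rate(k10, lam_peak),
                tau_off=tau,
                k_desens=0.0,
                charge_sign="anion",  # hyperpolarizing; grouped with inhibitors
                g_unit=10.0,
            )
        )

    return table
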