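"""Leaky integrate-and-fire simulation of neurons co-expressing opsin pairs.

The neuron is a single-compartment LIF cell held at a bias potential by
constant current injection.  Each expressed opsin contributes an ohmic
conductance g_scale * g_unit * (O + f_D * D) toward its reversal
potential; opsin state occupancies are integrated exactly (piecewise
matrix exponentials) on the voltage grid before the membrane equation is
stepped with forward Euler:

    c_m dV/dt = -g_l (V - e_l) - sum_i g_i(t) (V - E_i) + I_inj + I_bias + xi

Threshold crossing emits a spike, clips the sample at threshold, resets V
and enforces an absolute refractory period.

Pairing cells built by :func:`standard_pairing` use a somatic chloride
reversal of -70 mV for the anion channel (K-gluconate-like conditions)
rather than the high-chloride HEK value stored in the opsin table: with a
reversal above the spike threshold a chloride conductance is net
excitatory at every magnitude and shunting block is impossible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .opsin_models import (
    LightEpoch,
    LightProtocol,
    OpsinParams,
    Trace,
    builtin_opsin_table,
    simulate_occupancy,
)
from .spike_analysis import PulseSet, SpikeTrain

__all__ = [
    "NeuronParams",
    "CoExpressionCell",
    "CurrentEpoch",
    "SimResult",
    "simulate_cell",
    "rheobase",
    "calibrate_block_conductance",
    "make_protocols",
    "recovery_curve",
    "standard_pairing",
    "E_CL_SOMATIC",
]

#: somatic chloride reversal potential (mV) used for anion channels in neurons
E_CL_SOMATIC = -70.0


class CalibrationError(RuntimeError):
    """Raised when a bisection search cannot bracket its target."""


@dataclass
class NeuronParams:
    """Passive LIF parameters (granule-cell-like defaults)."""

    c_m: float = 30.0  # pF
    g_l: float = 3.0  # nS
    e_l: float = -70.0  # mV
    v_th: float = -50.0  # mV
    v_reset: float = -65.0  # mV
    t_ref: float = 2.0  # ms

    def __post_init__(self) -> None:
        if self.c_m <= 0 or self.g_l <= 0:
            raise ValueError("c_m and g_l must be positive")
        if self.v_reset >= self.v_th:
            raise ValueError("v_reset must be below v_th")

    @property
    def tau_m(self) -> float:
        """Membrane time constant in ms."""
        return self.c_m / self.g_l


@dataclass
class CoExpressionCell:
    """A LIF neuron expressing one or more opsins.

    ``opsins`` is a list of (OpsinParams, g_scale) pairs; the bias current
    is solved so the resting potential equals ``bias_target`` with no light
    or injection.  ``block_calibrated`` marks that the anion-channel
    g_scale has been set by :func:`calibrate_block_conductance`.
    """

    neuron: NeuronParams
    opsins: List[Tuple[OpsinParams, float]] = field(default_factory=list)
    bias_target: float = -60.0
    block_calibrated: bool = False

    def __post_init__(self) -> None:
        for _, g in self.opsins:
            if g < 0:
                raise ValueError("g_scale must be non-negative")

    @property
    def bias_current(self) -> float:
        """Constant injection (pA) holding the dark resting V at bias_target."""
        return self.neuron.g_l * (self.bias_target - self.neuron.e_l)

    def anion_index(self) -> int:
        for i, (p, _) in enumerate(self.opsins):
            if p.charge_sign == "anion":
                return i
        raise ValueError("cell expresses no anion channel")

    def with_g(self, index: int, g_scale: float) -> "CoExpressionCell":
        opsins = list(self.opsins)
        p, _ = opsins[index]
        opsins[index] = (p, g_scale)
        return CoExpressionCell(
            neuron=self.neuron,
            opsins=opsins,
            bias_target=self.bias_target,
            block_calibrated=self.block_calibrated,
        )


@dataclass
class CurrentEpoch:
    """A rectangular somatic current injection (s, s, pA)."""

    t_on: float
    duration: float
    amplitude: float

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")

    @property
    def t_off(self) -> float:
        return self.t_on + self.duration


@dataclass
class SimResult:
    """Voltage trace, emitted spikes and per-opsin open-state traces."""

    voltage: Trace
    spikes: SpikeTrain
    opsin_open: Dict[str, Trace]


def _injection_array(current: Sequence[CurrentEpoch], times: np.ndarray) -> np.ndarray:
    inj = np.zeros_like(times)
    for ep in current:
        inj[(times >= ep.t_on - 1e-12) & (times < ep.t_off - 1e-12)] += ep.amplitude
    return inj


def simulate_cell(
    cell: CoExpressionCell,
    light: Optional[LightProtocol] = None,
    current: Sequence[CurrentEpoch] = (),
    dt: float = 2.5e-5,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    t_end: Optional[float] = None,
) -> SimResult:
    """Integrate the co-expressing LIF cell under a light/current protocol.

    ``noise_sd`` is the standard deviation (pA) of additive white current
    noise per time step; 0 gives a fully deterministic run.
    """
    if dt > 5e-5:
        raise ValueError("dt must be <= 0.05 ms for the membrane integration")
    if light is None:
        duration = t_end if t_end is not None else max(
            [ep.t_off for ep in current], default=0.1
        ) + 0.05
        light = LightProtocol(epochs=[], t_end=duration)
    n = int(round(light.t_end / dt)) + 1
    times = dt * np.arange(n)

    # conductance time courses per opsin (independent of V)
    conds: List[np.ndarray] = []
    e_revs: List[float] = []
    opsin_open: Dict[str, Trace] = {}
    for params, g_scale in cell.opsins:
        occ = simulate_occupancy(params, light, dt)
        g_t = (
            g_scale
            * params.g_unit
            * (occ["open"].values + params.g_desens_frac * occ["desensitized"].values)
        )
        conds.append(g_t)
        e_revs.append(params.e_rev)
        opsin_open[params.name] = occ["open"]

    inj = _injection_array(current, times) + cell.bias_current
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        inj = inj + rng.normal(0.0, noise_sd, size=n)

    nrn = cell.neuron
    dt_ms = dt * 1e3
    g_l, e_l, c_m = nrn.g_l, nrn.e_l, nrn.c_m
    v_th, v_reset, t_ref_ms = nrn.v_th, nrn.v_reset, nrn.t_ref

    g_sum = np.zeros(n)
    ge_sum = np.zeros(n)
    for g_t, e in zip(conds, e_revs):
        g_sum += g_t
        ge_sum += g_t * e

    v = np.empty(n)
    v[0] = cell.bias_target
    spike_times: List[float] = []
    ref_until = -np.inf
    vi = cell.bias_target
    for k in range(1, n):
        t = times[k]
        if t < ref_until:
            vi = v_reset
            v[k] = vi
            continue
        g_tot = g_l + g_sum[k - 1]
        drive = g_l * e_l + ge_sum[k - 1] + inj[k - 1]
        dv = dt_ms * (drive - g_tot * vi) / c_m
        vi = vi + dv
        if vi >= v_th:
            spike_times.append(t)
            v[k] = v_th  # clip the spike sample at threshold
            vi = v_reset
            ref_until = t + t_ref_ms * 1e-3
        else:
            v[k] = vi

    return SimResult(
        voltage=Trace(t0=0.0, dt=dt, values=v, units="mV", kind="voltage"),
        spikes=SpikeTrain(np.asarray(spike_times)),
        opsin_open=opsin_open,
    )


def rheobase(
    cell: CoExpressionCell,
    pulse_width: float = 5.0,
    upper: float = 3000.0,
    dt: float = 2.5e-5,
) -> float:
    """Minimal current amplitude (pA) eliciting >= 1 spike for a pulse of
    ``pulse_width`` ms, by bisection to 1 pA resolution (noise 0)."""
    if pulse_width <= 0:
        raise ValueError("pulse_width must be positive")
    width_s = pulse_width * 1e-3
    t_end = 0.005 + width_s + 0.05

    def spikes_at(amp: float) -> bool:
        res = simulate_cell(
            cell,
            light=LightProtocol(epochs=[], t_end=t_end),
            current=[CurrentEpoch(0.005, width_s, amp)],
            dt=dt,
        )
        return res.spikes.n > 0

    if not spikes_at(upper):
        raise CalibrationError("no spike at the upper search bound")
    lo, hi = 0.0, upper
    while hi - lo > 1.0:
        mid = 0.5 * (lo + hi)
        if spikes_at(mid):
            hi = mid
        else:
            lo = mid
    return hi


def make_protocols(kind: str, **params) -> Tuple[LightProtocol, List[CurrentEpoch]]:
    """Builders for the standard stimulation protocols.

    Kinds
    -----
    block_40hz
        Current pulses (default 5 ms at 40 Hz for 1 s) with 470-nm light
        pulses (4 mW/mm^2) fully overlapping every other current pulse.
    recovery
        One 5-ms 470-nm pulse (4 mW/mm^2) followed by a 5-ms current pulse
        whose onset trails the light OFFSET by ``delta_ms``.
    drive_train
        5-ms light pulses at ``rate_hz`` (10/20 Hz) for ``duration``.
    long_pulse
        A single 500-ms illumination epoch.
    in_vivo_pulse
        100-ms pulses at 0.33 Hz, 20 mW/mm^2 (450 or 638 nm).
    """
    if kind == "block_40hz":
        rate = params.get("rate_hz", 40.0)
        duration = params.get("duration", 1.0)
        pulse_s = params.get("pulse_ms", 5.0) * 1e-3
        amp = params.get("amplitude", 100.0)
        wavelength = params.get("wavelength", 470.0)
        irradiance = params.get("irradiance", 4.0)
        t0 = params.get("t_start", 0.05)
        period = 1.0 / rate
        n_pulses = int(round(duration * rate))
        t_end = t0 + duration + 0.05
        current = [CurrentEpoch(t0 + i * period, pulse_s, amp) for i in range(n_pulses)]
        light = [
            LightEpoch(t0 + i * period, pulse_s, wavelength, irradiance)
            for i in range(n_pulses)
            if i % 2 == 1
        ]
        return LightProtocol(light, t_end), current
    if kind == "recovery":
        delta_s = params.get("delta_ms", 5.0) * 1e-3
        amp = params.get("amplitude", 100.0)
        pulse_s = params.get("pulse_ms", 5.0) * 1e-3
        t_light = params.get("t_light", 0.05)
        light_off = t_light + pulse_s
        t_cur = light_off + delta_s
        t_end = t_cur + pulse_s + 0.06
        light = [LightEpoch(t_light, pulse_s, 470.0, params.get("irradiance", 4.0))]
        return LightProtocol(light, t_end), [CurrentEpoch(t_cur, pulse_s, amp)]
    if kind == "drive_train":
        rate = params.get("rate_hz", 10.0)
        duration = params.get("duration", 1.0)
        pulse_s = params.get("pulse_ms", 5.0) * 1e-3
        wavelength = params.get("wavelength", 635.0)
        irradiance = params.get("irradiance", 7.0)
        t0 = params.get("t_start", 0.05)
        period = 1.0 / rate
        n_pulses = int(round(duration * rate))
        light = [
            LightEpoch(t0 + i * period, pulse_s, wavelength, irradiance)
            for i in range(n_pulses)
        ]
        return LightProtocol(light, t0 + duration + 0.05), []
    if kind == "long_pulse":
        wavelength = params.get("wavelength", 470.0)
        irradiance = params.get("irradiance", 10.0)
        duration = params.get("duration", 0.5)
        t0 = params.get("t_start", 0.1)
        light = [LightEpoch(t0, duration, wavelength, irradiance)]
        return LightProtocol(light, t0 + duration + params.get("tail", 0.15)), []
    if kind == "in_vivo_pulse":
        wavelength = params.get("wavelength", 638.0)
        irradiance = params.get("irradiance", 20.0)
        n_pulses = params.get("n_pulses", 3)
        period = 1.0 / params.get("rate_hz", 0.33)
        t0 = params.get("t_start", 0.5)
        light = [
            LightEpoch(t0 + i * period, 0.1, wavelength, irradiance)
            for i in range(n_pulses)
        ]
        return LightProtocol(light, t0 + (n_pulses - 1) * period + 0.1 + 0.4), []
    raise ValueError(f"unknown protocol kind: {kind!r}")


def calibrate_block_conductance(
    cell: CoExpressionCell,
    drive_current: float,
    protocol_kind: str = "block_40hz",
    upper: float = 64.0,
    rel_resolution: float = 0.01,
    dt: float = 2.5e-5,
) -> float:
    """Minimal anion-channel g_scale blocking all targeted spikes.

    Runs the 40-Hz blocking protocol (overlapping 5-ms 470-nm pulses on
    alternate current pulses) and bisects the ACR g_scale to the requested
    relative resolution.  The drive current must be suprathreshold.
    """
    idx = cell.anion_index()
    light, current = make_protocols(protocol_kind, amplitude=drive_current)
    targeted = PulseSet(
        np.array([ep.t_on for ep in light.epochs]), light.epochs[0].duration, "light-470"
    )
    pulses = PulseSet(
        np.array([ep.t_on for ep in current]), current[0].duration, "current"
    )
    control = simulate_cell(cell.with_g(idx, 0.0), light=None, current=current, dt=dt,
                            t_end=light.t_end)
    mask_targeted = np.isin(
        np.round(pulses.onsets, 9), np.round(targeted.onsets, 9)
    )
    from .spike_analysis import per_pulse_spike_probability

    _, ctrl_success = per_pulse_spike_probability(control.spikes, pulses)
    if not np.all(ctrl_success[mask_targeted]):
        raise CalibrationError("drive current is not suprathreshold on targeted pulses")

    def blocks_all(g: float) -> bool:
        res = simulate_cell(cell.with_g(idx, g), light=light, current=current, dt=dt)
        _, success = per_pulse_spike_probability(res.spikes, pulses)
        return not np.any(success[mask_targeted])

    if not blocks_all(upper):
        raise CalibrationError("cannot block all targeted spikes at the upper bound")
    lo, hi = 0.0, upper
    while hi - lo > rel_resolution * hi:
        mid = 0.5 * (lo + hi)
        if blocks_all(mid):
            hi = mid
        else:
            lo = mid
    return hi


def recovery_curve(
    cell: CoExpressionCell,
    deltas: Sequence[float] = (0.0, 5.0, 10.0, 15.0, 20.0),
    n_trials: int = 1,
    noise_sd: float = 0.0,
    seed: Optional[int] = None,
    amplitude: float = 120.0,
    dt: float = 2.5e-5,
) -> Dict[float, float]:
    """Spike probability of a 5-ms current pulse vs interval after light offset.

    For each offset-to-onset interval (ms) the fraction of trials whose
    current pulse elicits a spike within the pulse + 10 ms is returned.
    Requires a block-calibrated cell.
    """
    if not cell.block_calibrated:
        raise RuntimeError("cell must be block-calibrated before recovery analysis")
    from .spike_analysis import per_pulse_spike_probability

    rng = np.random.default_rng(seed)
    out: Dict[float, float] = {}
    for delta in deltas:
        light, current = make_protocols("recovery", delta_ms=delta, amplitude=amplitude)
        pulses = PulseSet(np.array([current[0].t_on]), current[0].duration, "current")
        hits = 0
        for _ in range(n_trials):
            trial_seed = int(rng.integers(0, 2**31 - 1)) if noise_sd > 0 else None
            res = simulate_cell(
                cell, light=light, current=current, dt=dt,
                noise_sd=noise_sd, seed=trial_seed,
            )
            frac, _ = per_pulse_spike_probability(res.spikes, pulses)
            hits += int(frac > 0)
        out[float(delta)] = hits / n_trials
    return out


def standard_pairing(
    acr_name: str = "Zip151T",
    chr_name: str = "IvfChr",
    g_chr: float = 0.8,
    g_acr: float = 2.0,
    e_cl: float = E_CL_SOMATIC,
    neuron: Optional[NeuronParams] = None,
    acr_tau_off: Optional[float] = None,
) -> CoExpressionCell:
    """Build a bicistronic-style pairing cell (ACR + red ChR).

    The anion channel's reversal potential is set to the somatic chloride
    value ``e_cl``; ``acr_tau_off`` substitutes the closing time constant
    (used for kinetic-surrogate comparisons).
    """
    table = builtin_opsin_table()
    acr = table[acr_name].with_(e_rev=e_cl)
    if acr_tau_off is not None:
        acr = acr.with_(tau_off=acr_tau_off)
    chr_ = table[chr_name]
    return CoExpressionCell(
        neuron=neuron or NeuronParams(),
        opsins=[(acr, g_acr), (chr_, g_chr)],
        bias_target=-60.0,
    )
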