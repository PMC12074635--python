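"""Spike-train metrics: detection, per-pulse probability, blocking
efficiency, offset-locked spikes and two-sample t statistics."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import stats

from .opsin_models import Trace

__all__ = [
    "SpikeTrain",
    "PulseSet",
    "detect_spikes",
    "per_pulse_spike_probability",
    "fidelity_curve",
    "blocking_efficiency",
    "offset_spike_fraction",
    "two_sample_t",
]


@dataclass
class SpikeTrain:
    """Ordered action-potential times in seconds."""

    times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def n(self) -> int:
        return self.times.size


@dataclass
class PulseSet:
    """Ordered stimulus pulse onsets sharing one width, in seconds."""

    onsets: np.ndarray
    width: float
    kind: str = "current"

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.width <= 0:
            raise ValueError("width must be positive")
        if self.onsets.size > 1:
            if not np.all(np.diff(self.onsets) >= self.width):
                raise ValueError("pulses within a set must not overlap")

    @property
    def offsets(self) -> np.ndarray:
        return self.onsets + self.width

    @property
    def n(self) -> int:
        return self.onsets.size


def detect_spikes(voltage: Trace, threshold: float = -20.0, min_isi: float = 2.0) -> SpikeTrain:
    """Upward threshold crossings, suppressing refractory-period doublets.

    ``min_isi`` is in ms; crossings closer than this to the previous
    accepted spike are discarded.
    """
    if min_isi <= 0:
        raise ValueError("min_isi must be positive")
    v = voltage.values
    above = v >= threshold
    crossings = np.nonzero(above[1:] & ~above[:-1])[0] + 1
    times: List[float] = []
    min_isi_s = min_isi * 1e-3
    for idx in crossings:
        t = voltage.t0 + idx * voltage.dt
        if not times or t - times[-1] >= min_isi_s:
            times.append(t)
    return SpikeTrain(np.asarray(times))


def per_pulse_spike_probability(
    spikes: SpikeTrain, pulses: PulseSet, latency_window: float = 10.0
) -> Tuple[float, np.ndarray]:
    """Fraction of pulses followed by >= 1 spike within pulse + latency window.

    A pulse succeeds if a spike falls in [onset, onset + width + latency_window];
    each spike is credited to at most one pulse (the earliest eligible one).
    Returns (fraction, per-pulse booleans).
    """
    if latency_window <= 0:
        raise ValueError("latency_window must be positive")
    if pulses.n == 0:
        raise ValueError("empty pulse set")
    win = pulses.width + latency_window * 1e-3
    success = np.zeros(pulses.n, dtype=bool)
    used = np.zeros(spikes.n, dtype=bool)
    for i, onset in enumerate(pulses.onsets):
        eligible = np.nonzero(
            (spikes.times >= onset) & (spikes.times <= onset + win) & ~used
        )[0]
        if eligible.size:
            used[eligible[0]] = True
            success[i] = True
    return float(success.mean()), success


def fidelity_curve(results: Dict[float, float]) -> List[Tuple[float, float]]:
    """Spike probability vs irradiance, sorted by irradiance."""
    return sorted((float(k), float(v)) for k, v in results.items())


def blocking_efficiency(
    spikes_light: SpikeTrain,
    spikes_control: SpikeTrain,
    targeted_pulses: PulseSet,
    current_pulses: PulseSet,
    latency_window: float = 10.0,
) -> float:
    """Percent of targeted current-evoked spikes abolished by overlapping light.

    Targeted pulses are the current pulses overlapped by a light pulse; only
    those that spiked in the control (no-light) trial enter the denominator.
    """
    _, control_success = per_pulse_spike_probability(
        spikes_control, current_pulses, latency_window
    )
    _, light_success = per_pulse_spike_probability(
        spikes_light, current_pulses, latency_window
    )
    targeted = np.zeros(current_pulses.n, dtype=bool)
    for i, onset in enumerate(current_pulses.onsets):
        end = onset + current_pulses.width
        overlap = (targeted_pulses.onsets < end) & (targeted_pulses.offsets > onset)
        targeted[i] = bool(np.any(overlap))
    denom = targeted & control_success
    if not np.any(denom):
        raise ValueError("no targeted pulse spiked in the control trial")
    blocked = denom & ~light_success
    return 100.0 * float(blocked.sum()) / float(denom.sum())


def offset_spike_fraction(
    spikes: SpikeTrain,
    light_offsets: Sequence[float],
    window: float = 10.0,
    pulse_onsets: Sequence[float] | None = None,
) -> float:
    """Fraction of light offsets followed by a time-locked spike.

    An offset counts if >= 1 spike falls within ``window`` ms after it and
    no spike occurred during the pulse itself.  Pulse onsets come from
    ``pulse_onsets`` when given; otherwise a window of the same length
    preceding the offset stands in for the late pulse phase.
    """
    offsets = np.asarray(list(light_offsets), dtype=float)
    if offsets.size == 0:
        raise ValueError("empty offsets")
    win_s = window * 1e-3
    hits = 0
    for j, off in enumerate(offsets):
        on = float(pulse_onsets[j]) if pulse_onsets is not None else off - win_s
        during = np.any((spikes.times >= on) & (spikes.times < off))
        after = np.any((spikes.times >= off) & (spikes.times <= off + win_s))
        if after and not during:
            hits += 1
    return hits / offsets.size


def two_sample_t(
    a: Sequence[float], b: Sequence[float], paired: bool = False
) -> Tuple[float, float, float, bool]:
    """Two-sample t statistic: Welch by default, paired on request.

    Returns (t, df, p, paired).  Identical groups give t = 0, p = 1.
    """
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal n")
        d = a - b
        if np.allclose(d, 0):
            return 0.0, float(a.size - 1), 1.0, True
        res = stats.ttest_rel(a, b)
        return float(res.statistic), float(a.size - 1), float(res.pvalue), True
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    na, nb = a.size, b.size
    if va == 0 and vb == 0 and np.mean(a) == np.mean(b):
        return 0.0, float(na + nb - 2), 1.0, False
    res = stats.ttest_ind(a, b, equal_var=False)
    # Welch-Satterthwaite degrees of freedom
    num = (va / na + vb / nb) ** 2
    den = (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
    df = num / den if den > 0 else float(na + nb - 2)
    return float(res.statistic), float(df), float(res.pvalue), False
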