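"""End-to-end experiment recipes tying the simulation and analysis stages
together, with seeded, reproducible outputs.

Each registered experiment generates its synthetic data, runs the analysis
stage and writes a JSON summary (plus CSV tables) into the output
directory.  All randomness flows from the single config seed through
named substreams.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import ephys_analysis as ea
from . import neuron_sim as ns
from . import spike_analysis as sa
from . import whisker_kinematics as wk
from .opsin_models import LightProtocol, builtin_opsin_table, simulate_photocurrent

__all__ = [
    "RunConfig",
    "run_experiment",
    "EXPERIMENTS",
    "whisker_group_experiment",
    "fidelity_scan",
    "blocking_assay",
    "offset_spike_assay",
    "recovery_threshold",
]

log = logging.getLogger("optopair")


@dataclass
class RunConfig:
    """Seed, output location and overrides for one experiment run."""

    seed: int = 0
    out_dir: Optional[Path] = None
    overrides: Dict = field(default_factory=dict)
    verbosity: int = 0

    def substream(self, name: str) -> np.random.Generator:
        """Named child RNG derived from the config seed (no global state)."""
        tag = zlib.crc32(name.encode("utf-8"))
        ss = np.random.SeedSequence([self.seed, tag])
        return np.random.default_rng(ss)


def _write_summary(config: RunConfig, name: str, summary: Dict) -> Optional[Path]:
    if config.out_dir is None:
        return None
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(
        json.dumps({"seed": config.seed, "experiment": name,
                    "overrides": config.overrides}, indent=2, sort_keys=True)
    )
    path = out / f"{name}_summary.json"
    path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    return path


# ---------------------------------------------------------------------------
# reusable assay building blocks


def fidelity_scan(
    cell: ns.CoExpressionCell,
    wavelength: float,
    irradiances: Sequence[float],
    rate_hz: float = 10.0,
    duration: float = 0.5,
    pulse_ms: float = 10.0,
    dt: float = 5e-5,
) -> Dict[float, float]:
    """Per-pulse spike probability of a light drive train vs irradiance."""
    out: Dict[float, float] = {}
    for irr in irradiances:
        light, _ = ns.make_protocols(
            "drive_train", rate_hz=rate_hz, duration=duration,
            wavelength=wavelength, irradiance=irr, pulse_ms=pulse_ms,
        )
        res = ns.simulate_cell(cell, light=light, dt=dt)
        pulses = sa.PulseSet(
            np.array([ep.t_on for ep in light.epochs]), pulse_ms * 1e-3, "light"
        )
        frac, _ = sa.per_pulse_spike_probability(res.spikes, pulses)
        out[float(irr)] = frac
    return out


def blocking_assay(
    cell: ns.CoExpressionCell,
    drive_current: float,
    wavelength: float = 470.0,
    irradiance: float = 4.0,
    dt: float = 2.5e-5,
) -> float:
    """Blocking efficiency (%) of light pulses overlapping alternate current
    pulses in the 40-Hz protocol."""
    light, current = ns.make_protocols(
        "block_40hz", amplitude=drive_current,
        wavelength=wavelength, irradiance=irradiance,
    )
    pulses = sa.PulseSet(
        np.array([ep.t_on for ep in current]), current[0].duration, "current"
    )
    targeted = sa.PulseSet(
        np.array([ep.t_on for ep in light.epochs]), light.epochs[0].duration, "light"
    )
    control = ns.simulate_cell(cell, light=LightProtocol([], light.t_end),
                               current=current, dt=dt)
    lit = ns.simulate_cell(cell, light=light, current=current, dt=dt)
    return sa.blocking_efficiency(lit.spikes, control.spikes, targeted, pulses)


def offset_spike_assay(
    cell: ns.CoExpressionCell,
    irradiance: float = 10.0,
    window_ms: float = 15.0,
    dt: float = 2.5e-5,
) -> float:
    """Offset-spike fraction for a single 500-ms 470-nm illumination."""
    light, _ = ns.make_protocols("long_pulse", wavelength=470.0, irradiance=irradiance)
    res = ns.simulate_cell(cell, light=light, dt=dt)
    ep = light.epochs[0]
    return sa.offset_spike_fraction(
        res.spikes, [ep.t_off], window=window_ms, pulse_onsets=[ep.t_on]
    )


def recovery_threshold(curve: Mapping[float, float]) -> float:
    """Smallest interval (ms) with full recovery; inf if none recovers."""
    for delta in sorted(curve):
        if curve[delta] >= 1.0:
            return float(delta)
    return float("inf")


# ---------------------------------------------------------------------------
# whisker end-to-end experiment


def whisker_group_experiment(
    rng: np.random.Generator,
    n_animals: int = 4,
    n_trials: int = 3,
    red_amplitude: float = 15.0,
    blue_amplitude: float = 10.0,
    n_whiskers: int = 3,
    baseline_s: float = 0.3,
    post_s: float = 0.3,
    fps: float = 750.0,
    noise_sd: float = 8.0,
) -> Dict[str, Dict[float, List[float]]]:
    """Simulate one group (videos -> tracking -> Z -> AUC) and return the
    per-animal AUC table {animal: {450: [...], 638: [...]}}.

    ``blue_amplitude`` encodes the condition: a control construct responds
    to blue light with a deflection somewhat smaller than red, a paired
    (suppressed) construct barely responds.
    """
    onset = baseline_s
    duration = baseline_s + post_s
    out: Dict[str, Dict[float, List[float]]] = {}
    for a in range(n_animals):
        per_wl: Dict[float, List[float]] = {450.0: [], 638.0: []}
        for wavelength, amp in ((450.0, blue_amplitude), (638.0, red_amplitude)):
            for trial in range(n_trials):
                fns = [
                    wk.make_response_angle_fn(
                        base_angle=55.0 + 3.0 * w, amplitude=amp, onsets=(onset,)
                    )
                    for w in range(n_whiskers)
                ]
                stack, truth = wk.generate_whisker_video(
                    n_whiskers=n_whiskers,
                    angle_fns=fns,
                    duration=duration,
                    fps=fps,
                    noise_sd=noise_sd,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                rois = wk.default_rois(truth, stack.frames.shape[1:])
                tracked = wk.track_angles(stack, rois)
                z = wk.zscore_trace(tracked, (0.0, onset))
                auc = wk.response_auc(
                    z, onset, wavelength=wavelength, trial_id=f"a{a}t{trial}"
                )
                per_wl[wavelength].append(auc.auc)
        out[f"animal{a}"] = per_wl
    return out


# ---------------------------------------------------------------------------
# registered experiments


def _exp_pairing_offset(config: RunConfig) -> Dict:
    """Offset-spike contrast between the fast-ACR and slowed-ACR pairings
    under 500-ms blue illumination."""
    fractions = {}
    for acr in ("ZipACR", "Zip151T"):
        cell = ns.standard_pairing(acr_name=acr)
        fractions[acr] = offset_spike_assay(cell)
    return {"offset_spike_fraction": fractions}


def _exp_variant_kinetics(config: RunConfig) -> Dict:
    """Photocurrent characterization of the anion-channel variants:
    off-tau recovery, on-tau vs intensity and the action spectrum."""
    table = builtin_opsin_table()
    rows = []
    for name in ("ZipACR", "Zip151V", "Zip151T", "GtACR2"):
        p = table[name]
        light, _ = ns.make_protocols(
            "long_pulse", wavelength=470.0, irradiance=10.0, duration=1.0,
            t_start=0.2, tail=max(1.0, 6 * p.tau_off * 1e-3),
        )
        trace = simulate_photocurrent(p, light, holding=-60.0, dt=5e-5)
        fit = ea.fit_off_tau(trace, light.epochs[0].t_off)
        peak = ea.peak_photocurrent(trace, (0.2, light.epochs[0].t_off))
        rows.append({"opsin": name, "tau_off_fit_ms": fit.tau,
                     "tau_off_true_ms": p.tau_off, "peak_pA": peak})
    df = pd.DataFrame(rows)
    if config.out_dir:
        Path(config.out_dir).mkdir(parents=True, exist_ok=True)
        df.to_csv(Path(config.out_dir) / "variant_kinetics.csv", index=False)
    return {"variants": rows}


def _exp_spike_fidelity(config: RunConfig) -> Dict:
    """Per-pulse spike probability vs irradiance for the plain red ChR and
    the paired construct (blue drive suppressed)."""
    irr = [0.5, 1, 2, 4, 7, 10]
    chr_cell = ns.standard_pairing(g_acr=0.0)
    paired = ns.standard_pairing()
    return {
        "chr_red": fidelity_scan(chr_cell, 635.0, irr),
        "paired_red": fidelity_scan(paired, 635.0, irr),
        "paired_blue": fidelity_scan(paired, 470.0, irr),
    }


def _exp_block_recovery(config: RunConfig) -> Dict:
    """Calibrated shunting block at 40 Hz plus the recovery-interval curve."""
    cell = ns.standard_pairing()
    drive = 1.5 * ns.rheobase(cell.with_g(cell.anion_index(), 0.0))
    g_block = ns.calibrate_block_conductance(cell, drive)
    cell = cell.with_g(cell.anion_index(), g_block)
    cell.block_calibrated = True
    eff_blue = blocking_assay(cell, drive, 470.0, 4.0)
    eff_red = blocking_assay(cell, drive, 635.0, 7.0)
    curve = ns.recovery_curve(cell, amplitude=drive)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"delta_ms": list(curve), "spike_probability": list(curve.values())}
        ).to_csv(out / "recovery_curve.csv", index=False)
    return {
        "drive_pA": drive,
        "g_block": g_block,
        "blocking_efficiency_470": eff_blue,
        "blocking_efficiency_635": eff_red,
        "recovery_curve": {str(k): v for k, v in curve.items()},
    }


def _exp_whisker_scoring(config: RunConfig) -> Dict:
    """Two-group synthetic whisker experiment: control vs suppressed blue
    responses, scored as blue/red AUC ratios."""
    o = config.overrides
    common = dict(
        n_animals=o.get("n_animals", 4),
        n_trials=o.get("n_trials", 3),
        n_whiskers=o.get("n_whiskers", 3),
        baseline_s=o.get("baseline_s", 0.3),
        post_s=o.get("post_s", 0.3),
        noise_sd=o.get("noise_sd", 8.0),
    )
    control = whisker_group_experiment(
        config.substream("whisker-control"), blue_amplitude=10.0, **common
    )
    null = whisker_group_experiment(
        config.substream("whisker-null"), blue_amplitude=0.5, **common
    )
    res_ctrl = wk.auc_ratio_analysis(control, comparison=null)
    res_null = wk.auc_ratio_analysis(null)
    return {
        "control_ratio_mean": res_ctrl.mean,
        "control_ratio_sem": res_ctrl.sem,
        "null_ratio_mean": res_null.mean,
        "null_ratio_sem": res_null.sem,
        "t": res_ctrl.ttest[0],
        "p": res_ctrl.ttest[2],
    }


EXPERIMENTS: Dict[str, Callable[[RunConfig], Dict]] = {
    "pairing_offset": _exp_pairing_offset,
    "variant_kinetics": _exp_variant_kinetics,
    "spike_fidelity": _exp_spike_fidelity,
    "block_recovery": _exp_block_recovery,
    "whisker_scoring": _exp_whisker_scoring,
}


def run_experiment(name: str, config: Optional[RunConfig] = None) -> Dict:
    """Run a registered experiment; returns (and optionally writes) its summary."""
    if name not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}; known: {sorted(EXPERIMENTS)}")
    config = config or RunConfig()
    log.info("running experiment %s (seed %d)", name, config.seed)
    summary = EXPERIMENTS[name](config)
    _write_summary(config, name, summary)
    return summary
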