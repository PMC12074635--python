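import numpy as np
import pytest

from optopair import neuron_sim as ns
from optopair.opsin_models import (
    LightEpoch,
    LightProtocol,
    builtin_opsin_table,
    simulate_photocurrent,
)


@pytest.fixture(scope="session")
def opsin_table():
    return builtin_opsin_table()


@pytest.fixture(scope="session")
def zipacr(opsin_table):
    return opsin_table["ZipACR"]


@pytest.fixture(scope="session")
def ivfchr(opsin_table):
    return opsin_table["IvfChr"]


def one_pulse_trace(params, wavelength=470.0, irradiance=10.0, t_on=0.1,
                    duration=1.0, tail=None, holding=-60.0, dt=5e-5):
    """Photocurrent for a single rectangular light pulse."""
    tail = tail if tail is not None else max(0.3, 6 * params.tau_off * 1e-3)
    proto = LightProtocol(
        [LightEpoch(t_on, duration, wavelength, irradiance)], t_on + duration + tail
    )
    return simulate_photocurrent(params, proto, holding=holding, dt=dt), proto


@pytest.fixture(scope="session")
def calibrated_zipt_cell():
    """Zip151T + IvfChr pairing with block-calibrated shunt conductance.

    Session-scoped: the bisection calibration is reused by every test that
    needs the blocking-configured cell.
    """
    cell = ns.standard_pairing()
    drive = 1.5 * ns.rheobase(cell.with_g(cell.anion_index(), 0.0))
    g_block = ns.calibrate_block_conductance(cell, drive)
    cell = cell.with_g(cell.anion_index(), g_block)
    cell.block_calibrated = True
    return cell, drive, g_block
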