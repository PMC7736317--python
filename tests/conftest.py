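"""Shared fixtures: seeded synthetic acquisitions and oracle helpers."""

import numpy as np
import pytest

from qmpm.curves import TimeCurve
from qmpm.synthetic import (
    InputFunctionParams,
    KineticParams,
    NetworkConfig,
    NoiseDriftParams,
    SimulationConfig,
    make_vessel_network,
    render_timelapse,
    simulate_input_function,
    simulate_stack,
    simulate_tissue_curve,
)


@pytest.fixture(scope="session")
def kinetic_grid():
    """Default acquisition time base: one frame every second for 10 min."""
    return 1.0 * np.arange(601)


@pytest.fixture(scope="session")
def default_input(kinetic_grid):
    """Bolus with the peak on the acquisition grid (arrival 7 s, rise 3 s)."""
    return InputFunctionParams(t_arrival_s=7.0)


@pytest.fixture(scope="session")
def curve_pair(kinetic_grid, default_input):
    """Noise-free blood/tissue pair at the default kinetic parameters."""
    blood = simulate_input_function(default_input, kinetic_grid)
    tissue = simulate_tissue_curve(KineticParams(0.05, 0.30), blood)
    return blood, tissue


@pytest.fixture(scope="session")
def noiseless_stack():
    """Rendered stack with noise, drift and cells all off."""
    cfg = SimulationConfig(apply_noise=False, duration_s=300.0)
    return simulate_stack(cfg, seed=21)


@pytest.fixture(scope="session")
def snr20_stack():
    """Default-condition acquisition: SNR ~20, drift, blood-pool channel."""
    cfg = SimulationConfig(drift_total_px=(3.5, -2.5), include_blood_pool=True)
    return simulate_stack(cfg, seed=42)


@pytest.fixture(scope="session")
def fast_stack():
    """Velocimetry acquisition: 2 ms frames, three cells at 1/2/4 mm/s.

    At 4 mm/s the per-frame displacement is 8 um, at most half the
    default 20 um linking gate.
    """
    times = 0.002 * np.arange(40)
    geom = make_vessel_network(
        NetworkConfig(n_vessels=3, radius_range_um=(8.0, 12.0), seed=2)
    )
    const = TimeCurve(times, np.full(times.size, 1.0))
    zero = TimeCurve(times, np.zeros(times.size))
    stack, truth = render_timelapse(
        geom,
        const,
        zero,
        NoiseDriftParams(seed=4),
        cells=[1.0, 2.0, 4.0],
        include_blood_pool=True,
    )
    return stack, truth


def brute_force_otsu(hist):
    """Exhaustive between-class-variance maximiser (smallest-threshold tie-break)."""
    h = np.asarray(hist, dtype=float)
    bins = np.arange(h.size)
    best_t, best_v = None, -np.inf
    for t in range(1, h.size):
        w0, w1 = h[:t].sum(), h[t:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (h[:t] * bins[:t]).sum() / w0
        mu1 = (h[t:] * bins[t:]).sum() / w1
        v = w0 * w1 * (mu0 - mu1) ** 2
        if v > best_v:
            best_t, best_v = t, v
    return best_t
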