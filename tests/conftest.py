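import math

import numpy as np
import pytest

from glomcluster.io_formats import (
    GlomerularContext,
    NeuronMorphology,
    Sweep,
    SweepSet,
    SwcNode,
)


def make_nodes(points, radii=None, structures=None):
    """Chain/tree helper: points is a list of (x, y, z, parent_index or None)."""
    nodes = []
    for i, (x, y, z, parent) in enumerate(points):
        r = radii[i] if radii else 1.0
        s = structures[i] if structures else ("soma" if parent is None else "dendrite")
        nodes.append(SwcNode(i + 1, s, x, y, z, r,
                             None if parent is None else parent + 1))
    return nodes


@pytest.fixture
def straight_dendrite():
    """Soma at origin, 100 μm straight dendrite along +x in two 50 μm steps."""
    nodes = make_nodes([(0, 0, 0, None), (50, 0, 0, 0), (100, 0, 0, 1)])
    return NeuronMorphology(nodes=nodes, soma_area=50.0)


@pytest.fixture
def flat_context():
    return GlomerularContext(plane_point=np.zeros(3), plane_normal=np.array([0.0, 0.0, 1.0]))


def make_step_sweep(rate=33000.0, duration=0.7, onset=0.1, offset=0.6,
                    amplitude=-20.0, v_of_t=None):
    n = int(duration * rate)
    t = np.arange(n) / rate
    v = np.full(n, -60.0) if v_of_t is None else v_of_t(t)
    cmd = np.zeros(n)
    cmd[(t >= onset) & (t < offset)] = amplitude
    return Sweep(voltage=v, current_command=cmd, step_amplitude=amplitude,
                 step_onset=onset, step_offset=offset)


def passive_sweep(r_gohm, tau_ms, amplitude, rate=33000.0, noise_sd=0.0, seed=0,
                  onset=0.1, offset=0.6, duration=0.7, v_rest=-60.0):
    """Noiseless (or noisy) RC step response."""
    rng = np.random.default_rng(seed)

    def v_of_t(t):
        v = np.full(len(t), v_rest)
        during = (t >= onset) & (t < offset)
        tau = tau_ms / 1000.0
        v[during] += r_gohm * amplitude * (1 - np.exp(-(t[during] - onset) / tau))
        after = t >= offset
        v_end = r_gohm * amplitude * (1 - math.exp(-(offset - onset) / tau))
        v[after] += v_end * np.exp(-(t[after] - offset) / tau)
        if noise_sd > 0:
            v += rng.normal(0, noise_sd, size=len(t))
        return v

    return make_step_sweep(rate=rate, duration=duration, onset=onset,
                           offset=offset, amplitude=amplitude, v_of_t=v_of_t)


def sweepset(sweeps, rate=33000.0, cell_id="c1"):
    return SweepSet(sampling_rate=rate, sweeps=sweeps, cell_id=cell_id)
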