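import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sncdev.cable import SimulationConfig
from sncdev.morphology import (
    AIS,
    AXON,
    AXON_START,
    DENDRITE,
    SOMA,
    NeuronMorphology,
    SectionNode,
)
from sncdev.synthetic import default_stage_params, sample_neuron

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_soma(diam=15.0):
    return SectionNode("soma", SOMA, None, diam, diam, diam)


@pytest.fixture
def toy_neuron():
    """Two 100 µm primary dendrites; axon on D1 at 30 µm; axon start 10 µm,
    AIS 25 µm."""
    secs = {
        "soma": make_soma(),
        "d1": SectionNode("d1", DENDRITE, "soma", 100.0, 2.0, 2.0),
        "d2": SectionNode("d2", DENDRITE, "soma", 100.0, 2.0, 2.0),
        "axst": SectionNode("axst", AXON_START, "d1", 10.0, 0.7, 0.7,
                            parent_arc=30.0),
        "ais": SectionNode("ais", AIS, "axst", 25.0, 0.7, 0.7),
        "axd": SectionNode("axd", AXON, "ais", 50.0, 0.7, 0.7),
    }
    return NeuronMorphology(secs, soma_volume=math.pi / 4 * 15.0**3,
                            name="toy")


@pytest.fixture
def somatic_axon_neuron():
    secs = {
        "soma": make_soma(),
        "d1": SectionNode("d1", DENDRITE, "soma", 120.0, 2.0, 2.0),
        "axst": SectionNode("axst", AXON_START, "soma", 12.0, 0.7, 0.7),
        "ais": SectionNode("ais", AIS, "axst", 20.0, 0.7, 0.7),
    }
    return NeuronMorphology(secs, soma_volume=2000.0, name="somatic")


@pytest.fixture(scope="session")
def p21_neuron():
    """Representative synthetic P21 neuron (dendritic axon, typical sizes);
    shared across simulation tests."""
    rng = np.random.default_rng(101)
    return sample_neuron(default_stage_params("P21"), rng, name="p21rep")


@pytest.fixture(scope="session")
def short_config():
    """Scaled-down pacemaking protocol: 3 s at dt 0.02 ms, ~15 µm
    compartments, 1.5 s discard."""
    return SimulationConfig(dt=0.02, duration=3000.0,
                            steady_state_discard=1500.0,
                            max_compartment_length=15.0,
                            record_sites=[("soma", 0.5), ("ais", 0.5)])


@pytest.fixture(scope="session")
def recovery(p21_neuron, short_config):
    """Shared gNa-recovery experiment: a target half-width generated at a
    known off-grid gNa plus the sweep used to recover it."""
    from sncdev.channels import MODEL2, build_scheme
    from sncdev.screen import _halfwidth_at, sweep

    base = build_scheme(MODEL2)
    g_true = 95.0
    target = _halfwidth_at(
        p21_neuron, base.with_density({"abd": {"Na": g_true}}), short_config)
    sw = sweep(p21_neuron, MODEL2, grid=(70, 80, 90, 100, 110, 120),
               config=short_config, base_scheme=base)
    return g_true, target, sw


@pytest.fixture(scope="session")
def p21_run(p21_neuron, short_config):
    """One shared default Model-2 pacemaking run on the P21 neuron."""
    from sncdev.cable import run_protocol
    from sncdev.channels import build_scheme

    return run_protocol(p21_neuron, build_scheme(), short_config)
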