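"""Solver verification against closed-form and independent numerical
oracles: passive fixed point, RC charging, steady-state cable attenuation,
charge balance, and a full single-compartment model integrated by an
adaptive-step reference solver."""

import math

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from sncdev.cable import (
    CompartmentGrid,
    SimulationConfig,
    Stimulus,
    discretize,
    integrate,
)
from sncdev.channels import (
    CalciumPool,
    assign,
    build_scheme,
    default_channels,
    pack_kinetics,
)
from sncdev.morphology import DENDRITE, SOMA, NeuronMorphology, SectionNode

from conftest import make_soma

RM = 100_000.0  # Ohm·cm²; leak density 0.1 pS/µm²


def passive_cylinder(length=20.0, diam=20.0):
    soma = SectionNode("soma", SOMA, None, length, diam, diam)
    return NeuronMorphology({"soma": soma}, math.pi / 4 * diam**2 * length)


def passive_densities(grid, leak=0.1):
    dens = np.zeros((grid.n, 7))
    dens[:, 6] = leak
    return dens


# ---------------------------------------------------------------------------
# discretization
# ---------------------------------------------------------------------------

def test_discretize_compartment_count():
    secs = {"soma": make_soma(),
            "d": SectionNode("d", DENDRITE, "soma", 100.0, 2.0, 2.0)}
    m = NeuronMorphology(secs, 1000.0)
    grid = discretize(m, rule=10.0)
    assert sum(1 for s in grid.section_id if s == "d") == 10


def test_area_conserved_under_rule_halving(p21_neuron):
    a1 = discretize(p21_neuron, rule=20.0).area.sum()
    a2 = discretize(p21_neuron, rule=10.0).area.sum()
    assert abs(a1 / a2 - 1) < 1e-3
    # and matches the morphology's own membrane area
    memb = sum(s.area for s in p21_neuron.sections.values())
    assert a2 == pytest.approx(memb, rel=1e-9)


def test_axial_conductance_closed_form():
    """Uniform cylinder: g = pi d² / (4 Ra l) per internal step."""
    d, l, ra = 2.0, 100.0, 150.0
    secs = {"soma": make_soma(),
            "c": SectionNode("c", DENDRITE, "soma", l, d, d)}
    grid = discretize(NeuronMorphology(secs, 1000.0), rule=10.0, ra=ra)
    step = l / 10
    r_step = 4 * ra * step / (math.pi * d * d) * 1e-2  # MOhm
    internal = [grid.gax[i] for i in range(grid.n)
                if grid.section_id[i] == "c" and
                grid.section_id[grid.parent[i]] == "c"]
    assert internal == pytest.approx([1.0 / r_step] * len(internal), rel=1e-9)


def test_discretize_rejects_bad_rule(p21_neuron):
    with pytest.raises(ValueError):
        discretize(p21_neuron, rule=0.0)


# ---------------------------------------------------------------------------
# passive oracles
# ---------------------------------------------------------------------------

def test_passive_fixed_point_is_leak_reversal():
    grid = discretize(passive_cylinder(), rule=50.0)
    cfg = SimulationConfig(dt=0.05, duration=800.0, steady_state_discard=0.0,
                           record_sites=[("soma", 0.5)])
    tr = integrate(grid, passive_densities(grid), cfg)
    assert tr.v[-1, 0] == pytest.approx(-50.0, abs=0.05)


def test_rc_charging_time_constant():
    """Membrane time constant Rm·Cm = 100 kOhm·cm² × 0.75 µF/cm² = 75 ms."""
    grid = discretize(passive_cylinder(), rule=50.0)
    cfg = SimulationConfig(dt=0.05, duration=400.0, steady_state_discard=0.0,
                           record_sites=[("soma", 0.5)])
    tr = integrate(grid, passive_densities(grid), cfg)
    t, v = tr.t, tr.v[:, 0]
    mask = (t > 1) & (t < 300)
    tau = -1.0 / np.polyfit(t[mask], np.log(-(v[mask]) - 50.0), 1)[0]
    assert tau == pytest.approx(75.0, rel=0.01)


def test_steady_state_cable_attenuation():
    """V(x) ~ exp(-x/lambda), lambda = sqrt(Rm d / (4 Ra))."""
    d, ra = 2.0, 150.0
    lam = math.sqrt(RM * d * 1e-4 / (4 * ra)) * 1e4  # µm
    L = 8 * lam
    secs = {"soma": SectionNode("soma", SOMA, None, 1.0, d, d),
            "cab": SectionNode("cab", DENDRITE, "soma", L, d, d)}
    m = NeuronMorphology(secs, 1.0)
    grid = discretize(m, rule=lam / 150)
    cfg = SimulationConfig(dt=0.2, duration=1200.0, steady_state_discard=0.0,
                           record_sites=[("cab", x) for x in
                                         (0.02, 0.1, 0.2, 0.3)])
    tr = integrate(grid, passive_densities(grid), cfg,
                   stimuli=[Stimulus("cab", 0.0, 0.01, 0.0, 1200.0)])
    v = tr.v[-1, :] + 50.0
    xs = np.array([grid.arc_mid[grid.locate("cab", f)] for f in
                   (0.02, 0.1, 0.2, 0.3)])
    pred = v[0] * np.exp(-(xs - xs[0]) / lam)
    assert np.all(np.abs(v / pred - 1.0) < 0.01)


def test_charge_balance_passive():
    """Injected charge = capacitive + leak charge (active conductances
    zeroed)."""
    grid = discretize(passive_cylinder(), rule=50.0)
    amp, t_on = 0.05, 200.0
    cfg = SimulationConfig(dt=0.01, duration=t_on, steady_state_discard=0.0,
                           record_sites=[("soma", 0.5)])
    tr = integrate(grid, passive_densities(grid), cfg,
                   stimuli=[Stimulus("soma", 0.5, amp, 0.0, t_on)])
    v = tr.v[:, 0]
    area_cm2 = grid.area.sum() * 1e-8
    c_nf = 0.75 * area_cm2 * 1e3
    g_leak_us = 1e6 * area_cm2 / RM
    q_in = amp * t_on
    q_cap = c_nf * (v[-1] - v[0])
    q_leak = g_leak_us * np.trapezoid(v - (-50.0), tr.t)
    assert abs((q_cap + q_leak) / q_in - 1.0) < 0.005


# ---------------------------------------------------------------------------
# full model vs adaptive-step reference
# ---------------------------------------------------------------------------

def _reference_rhs(kp, gdens_us, cm_nf, cafac, pool):
    """RHS of the single-compartment model for solve_ivp (independent of the
    stepping kernel; gate curves from the channel specs)."""
    chans = {c.name: c for c in default_channels(soma_variant=True)}
    na_m, na_h = chans["Na"].gates
    kdr_n = chans["KDR"].gates[0]
    a_a, a_b = chans["A"].gates
    cal_d = chans["CaL"].gates[0]
    h_q = chans["H"].gates[0]
    sk = chans["KCa"].gates[0]
    e = {"Na": chans["Na"].reversal, "K": -90.0, "Ca": chans["CaL"].reversal,
         "H": chans["H"].reversal, "lk": chans["leak"].reversal}

    def rhs(t, y):
        v, m, h, n, a, b, dg, q, z, ca = y
        gna = gdens_us[0] * m**3 * h
        gkdr = gdens_us[1] * n**3
        ga = gdens_us[2] * a**2 * b
        gca = gdens_us[3] * dg
        gsk = gdens_us[4] * z
        gh = gdens_us[5] * q
        glk = gdens_us[6]
        i_total = (gna * (v - e["Na"]) + (gkdr + ga + gsk) * (v - e["K"])
                   + gca * (v - e["Ca"]) + gh * (v - e["H"])
                   + glk * (v - e["lk"]))
        dv = -i_total / cm_nf
        out = [dv]
        for gate, x in ((na_m, m), (na_h, h), (kdr_n, n), (a_a, a),
                        (a_b, b), (cal_d, dg), (h_q, q)):
            out.append((gate.steady_state(v) - x) / gate.time_constant(v))
        zinf = sk.steady_state(ca)
        out.append((zinf - z) / sk.tau)
        ica = gca * (v - e["Ca"])
        influx = max(-ica * cafac, 0.0)
        out.append(influx - (ca - pool.resting_concentration)
                   / pool.decay_time_constant)
        return out

    return rhs


def test_single_compartment_matches_adaptive_reference():
    """Backward-Euler kernel vs an adaptive-step (LSODA-class) solution of
    the same ODEs: RMS voltage error < 0.5 mV over 1 s."""
    m = passive_cylinder(15.0, 15.0)
    grid = discretize(m, rule=50.0)
    scheme = build_scheme()
    dens = assign(grid, scheme)
    pool = CalciumPool()
    cfg = SimulationConfig(dt=0.0005, duration=1000.0,
                           steady_state_discard=0.0,
                           record_sites=[("soma", 0.5)], record_stride=10)
    tr = integrate(grid, dens, cfg, calcium=pool)

    kp = pack_kinetics()
    gdens_us = dens[0] * grid.area[0] * 1e-6
    cm_nf = 0.75 * grid.area[0] * 1e-5
    cafac = pool.influx_scaling(grid.volume)[0]
    rhs = _reference_rhs(kp, gdens_us, cm_nf, cafac, pool)

    chans = {c.name: c for c in default_channels(soma_variant=True)}
    v0 = -70.0
    y0 = [v0]
    for gate in (chans["Na"].gates[0], chans["Na"].gates[1],
                 chans["KDR"].gates[0], chans["A"].gates[0],
                 chans["A"].gates[1], chans["CaL"].gates[0],
                 chans["H"].gates[0]):
        y0.append(float(gate.steady_state(v0)))
    y0.append(float(chans["KCa"].gates[0].steady_state(
        pool.resting_concentration)))
    y0.append(pool.resting_concentration)

    sol = solve_ivp(rhs, (0.0, 1000.0), y0, method="LSODA",
                    t_eval=tr.t, rtol=1e-8, atol=1e-9, max_step=0.5)
    assert sol.success
    rms = math.sqrt(np.mean((tr.v[:, 0] - sol.y[0]) ** 2))
    assert rms < 0.5


# ---------------------------------------------------------------------------
# convergence & protocol
# ---------------------------------------------------------------------------

def test_temporal_convergence_of_spike_times(p21_neuron):
    """Halving dt from the default 0.01 ms moves the steady-state spike
    pattern (times relative to the first analysed spike) by < 0.1 ms."""
    from sncdev.waveform import detect_spikes

    grid = discretize(p21_neuron, rule=15.0)
    dens = assign(grid, build_scheme())
    spikes = {}
    for dt in (0.01, 0.005):
        cfg = SimulationConfig(dt=dt, duration=2500.0,
                               steady_state_discard=1500.0,
                               max_compartment_length=15.0,
                               record_sites=[("soma", 0.5)])
        tr = integrate(grid, dens, cfg)
        k = tr.t >= 1500.0
        spikes[dt] = detect_spikes(tr.v[k, 0], tr.dt)
    s1, s2 = spikes[0.01], spikes[0.005]
    n = min(len(s1), len(s2))
    assert n >= 3
    rel = (s1[:n] - s1[0]) - (s2[:n] - s2[0])
    assert np.max(np.abs(rel)) < 0.1


def test_spatial_convergence_of_half_width(p21_neuron, short_config):
    """Halving the compartment rule changes somatic AP half-width by < 2%."""
    from sncdev.screen import _halfwidth_at

    scheme = build_scheme()
    hw_coarse = _halfwidth_at(p21_neuron, scheme, short_config)
    fine = SimulationConfig(dt=0.02, duration=3000.0,
                            steady_state_discard=1500.0,
                            max_compartment_length=7.5,
                            record_sites=[("soma", 0.5)])
    hw_fine = _halfwidth_at(p21_neuron, scheme, fine)
    assert abs(hw_coarse / hw_fine - 1.0) < 0.02


def test_run_protocol_reports_silence_not_error(p21_neuron):
    """A model silenced by removing all sodium is reported silent."""
    from sncdev.cable import run_protocol

    scheme = build_scheme(overrides={r: {"Na": 0.01} for r in
                                     ("soma", "abd", "nabd", "axon_start")})
    cfg = SimulationConfig(dt=0.05, duration=1200.0,
                           steady_state_discard=600.0,
                           max_compartment_length=20.0)
    traces, summary = run_protocol(p21_neuron, scheme, cfg)
    assert summary is None
    assert traces.meta["n_spikes_steady"] == 0
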