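"""Compartmentalisation and integration of the branched cable equation.

Each membrane compartment obeys

    Cm dV/dt = -sum_i [ g_i (V - E_i) ] - I_axial

with Hodgkin-Huxley conductances g_i and axial current flowing between
adjacent compartments of the tree.  Passive constants default to the model's
published values: Ra = 150 Ohm·cm, Cm = 0.75 µF/cm², Rm = 100,000 Ohm·cm²
(leak reversal −50 mV); runs start from −70 mV and last 6,000 ms at
dt = 0.01 ms, with analysis restricted to the post-transient steady state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import _kernel
from .channels import CalciumPool, ConductanceScheme, assign, pack_kinetics
from .morphology import DENDRITE, SOMA, NeuronMorphology, identify_abd

__all__ = [
    "SimulationConfig",
    "CompartmentGrid",
    "TraceSet",
    "Stimulus",
    "NumericalError",
    "discretize",
    "integrate",
    "run_protocol",
]


class NumericalError(RuntimeError):
    """The integrator state became non-finite."""

    def __init__(self, time_ms: float, compartment: int):
        super().__init__(f"non-finite state at t = {time_ms:.2f} ms "
                         f"(compartment {compartment})")
        self.time_ms = time_ms
        self.compartment = compartment


@dataclass
class SimulationConfig:
    dt: float = 0.01                     # ms
    duration: float = 6000.0             # ms
    v_init: float = -70.0                # mV
    axial_resistivity: float = 150.0     # Ohm·cm
    specific_capacitance: float = 0.75   # µF/cm²
    specific_membrane_resistance: float = 100_000.0  # Ohm·cm²
    leak_reversal: float = -50.0         # mV
    steady_state_discard: float = 2000.0  # ms
    # implicitness of the voltage step: 1 = backward Euler, 0.5 =
    # Crank-Nicolson; the default trades a little damping of the stiff AIS
    # modes for near-second-order phase accuracy
    theta: float = 0.6
    record_stride: int = 1               # store every k-th step
    max_compartment_length: float = 10.0  # µm
    record_sites: list = field(default_factory=lambda: [("soma", 0.5), ("ais", 0.5)])

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not self.duration > self.steady_state_discard >= 0:
            raise ValueError("need duration > steady_state_discard >= 0")


@dataclass
class Stimulus:
    """Current step injected into the compartment at (section, arc)."""

    section: str
    arc: float       # µm from the section's proximal end
    amplitude: float  # nA
    t_start: float
    t_stop: float


@dataclass
class CompartmentGrid:
    """Flat compartment arrays in Hines (parent-before-child) order."""

    parent: np.ndarray        # int64, -1 for the root
    gax: np.ndarray           # µS to parent
    length: np.ndarray        # µm
    area: np.ndarray          # µm²
    volume: np.ndarray        # µm³
    regions: list[str]        # soma/abd/nabd/axon_start/ais/axon
    section_id: list[str]
    arc_mid: np.ndarray       # µm, compartment centre within its section
    morphology: NeuronMorphology

    @property
    def n(self) -> int:
        return len(self.regions)

    def locate(self, section: str, arc: float) -> int:
        """Index of the compartment of ``section`` containing arc position
        ``arc`` (fractions in [0, 1] are interpreted relative to length)."""
        sec = self.morphology.sections[section]
        if 0.0 <= arc <= 1.0 and sec.length > 1.0:
            arc = arc * sec.length
        best, bestd = -1, math.inf
        for i in range(self.n):
            if self.section_id[i] == section:
                d = abs(self.arc_mid[i] - arc)
                if d < bestd:
                    best, bestd = i, d
        if best < 0:
            raise KeyError(f"no compartments for section {section!r}")
        return best

    def region_indices(self, *names: str) -> np.ndarray:
        return np.array([i for i, r in enumerate(self.regions) if r in names],
                        dtype=np.int64)


@dataclass
class TraceSet:
    """Recorded voltage (and calcium) traces at named sites."""

    t: np.ndarray                  # ms
    sites: list[tuple[str, float]]
    v: np.ndarray                  # (nt, nsites) mV
    ca: np.ndarray | None = None   # (nt, nsites) mM
    meta: dict = field(default_factory=dict)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0])

    def site(self, name: str) -> np.ndarray:
        for j, (sec, _) in enumerate(self.sites):
            if sec == name:
                return self.v[:, j]
        raise KeyError(name)

    def to_csv(self, path) -> None:
        import pandas as pd
        cols = {"t_ms": self.t}
        for j, (sec, arc) in enumerate(self.sites):
            cols[f"v_{sec}_{arc:g}"] = self.v[:, j]
        pd.DataFrame(cols).to_csv(path, index=False)


def _frustum_half_resistances(ra, l, dp, dm, dd):
    """(proximal-half, distal-half) axial resistance of a frustum in MOhm.

    Ra in Ohm·cm, geometry in µm: R = 4 Ra l / (pi d1 d2), the µm/cm unit
    factors collapsing to 1e-2 MOhm.
    """
    r1 = 4.0 * ra * (l / 2.0) / (math.pi * dp * dm) * 1e-2
    r2 = 4.0 * ra * (l / 2.0) / (math.pi * dm * dd) * 1e-2
    return r1, r2


def discretize(m: NeuronMorphology, rule: float = 10.0,
               ra: float = 150.0) -> CompartmentGrid:
    """Split every section into compartments no longer than ``rule`` µm.

    Compartments are frusta with linearly interpolated diameters; the soma
    is its equivalent cylinder (the morphology already stores it as such).
    """
    if rule <= 0:
        raise ValueError("compartment rule must be positive")
    m.validate()
    abd = identify_abd(m)
    abd_set = set(m.subtree(abd)) if abd is not None else set()

    parent_list: list[int] = []
    gax_list: list[float] = []
    rows: list[tuple[float, float, float, str, str, float]] = []
    # per-compartment proximal/distal half resistances for connections
    half_r: list[tuple[float, float]] = []
    # section -> list of compartment indices (in order)
    sec_comps: dict[str, list[int]] = {}

    def region_of(sec) -> str:
        if sec.label == DENDRITE:
            return "abd" if sec.id in abd_set else "nabd"
        return sec.label

    # root-first traversal
    order = []
    stack = [m.soma]
    while stack:
        s = stack.pop()
        order.append(s)
        stack.extend(m.children(s.id))

    for sec in order:
        ncomp = max(1, int(math.ceil(sec.length / rule)))
        lc = sec.length / ncomp
        comps = []
        for j in range(ncomp):
            f0, f1 = j / ncomp, (j + 1) / ncomp
            dp = sec.diam_proximal + f0 * (sec.diam_distal - sec.diam_proximal)
            dd = sec.diam_proximal + f1 * (sec.diam_distal - sec.diam_proximal)
            dm = 0.5 * (dp + dd)
            area = math.pi * dm * lc
            vol = math.pi / 4.0 * dm * dm * lc
            idx = len(rows)
            rows.append((lc, area, vol, region_of(sec), sec.id,
                         (j + 0.5) * lc))
            half_r.append(_frustum_half_resistances(ra, lc, dp, dm, dd))
            if j == 0:
                if sec.parent is None:
                    parent_list.append(-1)
                    gax_list.append(0.0)
                else:
                    pcomps = sec_comps[sec.parent]
                    plen = m.sections[sec.parent].length
                    arc = sec.parent_arc if sec.parent_arc is not None else plen
                    pj = min(int(arc / (plen / len(pcomps))), len(pcomps) - 1)
                    pidx = pcomps[pj]
                    # connect through the child's proximal half and the
                    # parent compartment's distal half
                    r = half_r[idx][0] + half_r[pidx][1]
                    parent_list.append(pidx)
                    gax_list.append(1.0 / r)  # 1/MOhm = µS
            else:
                r = half_r[idx][0] + half_r[idx - 1][1]
                parent_list.append(idx - 1)
                gax_list.append(1.0 / r)
            comps.append(idx)
        sec_comps[sec.id] = comps

    lc_a, area_a, vol_a, reg_a, sid_a, mid_a = zip(*rows)
    return CompartmentGrid(
        parent=np.asarray(parent_list, dtype=np.int64),
        gax=np.asarray(gax_list),
        length=np.asarray(lc_a),
        area=np.asarray(area_a),
        volume=np.asarray(vol_a),
        regions=list(reg_a),
        section_id=list(sid_a),
        arc_mid=np.asarray(mid_a),
        morphology=m,
    )


def integrate(
    grid: CompartmentGrid,
    densities: np.ndarray,
    config: SimulationConfig,
    stimuli: list[Stimulus] | None = None,
    calcium: CalciumPool | None = None,
    kinetics: np.ndarray | None = None,
) -> TraceSet:
    """Integrate the full model; ``densities`` is the (n, 7) pS/µm² table
    from :func:`sncdev.channels.assign`."""
    n = grid.n
    if densities.shape != (n, len(_CH)):
        raise ValueError("density table does not match the grid")
    calcium = calcium or CalciumPool()
    kp = kinetics if kinetics is not None else pack_kinetics()

    area = grid.area
    gdens = densities * area[:, None] * 1e-6           # pS/µm²·µm² -> µS
    cm = config.specific_capacitance * area * 1e-5     # nF
    soma_flag = np.array([1.0 if r == "soma" else 0.0 for r in grid.regions])

    v = np.full(n, config.v_init)
    ca = np.full(n, calcium.resting_concentration)
    cafac = calcium.influx_scaling(grid.volume)
    gates, z = _kernel.init_gates(v, ca, soma_flag, kp)

    stimuli = stimuli or []
    scomp = np.array([grid.locate(s.section, s.arc) for s in stimuli],
                     dtype=np.int64)
    samp = np.array([s.amplitude for s in stimuli])
    st0 = np.array([s.t_start for s in stimuli])
    st1 = np.array([s.t_stop for s in stimuli])

    sites = list(config.record_sites)
    rec_idx = np.array([grid.locate(sec, arc) for sec, arc in sites],
                       dtype=np.int64)
    nsteps = int(round(config.duration / config.dt))
    stride = int(config.record_stride)
    nrows = nsteps // stride + 1
    vout = np.empty((nrows, len(sites)))
    caout = np.empty((nrows, len(sites)))

    bad = _kernel.run(v, gates, z, ca, grid.parent, grid.gax, cm, gdens,
                      soma_flag, kp,
                      calcium.resting_concentration,
                      calcium.decay_time_constant, cafac,
                      scomp, samp, st0, st1,
                      config.dt, nsteps, rec_idx, stride, vout, caout,
                      config.theta)
    if bad >= 0:
        i_bad = int(np.argmax(~np.isfinite(v))) if not np.all(np.isfinite(v)) else 0
        raise NumericalError(bad * config.dt, i_bad)

    t = np.arange(nrows) * stride * config.dt
    return TraceSet(t=t, sites=sites, v=vout, ca=caout,
                    meta={"dt": config.dt, "duration": config.duration,
                          "v_init": config.v_init})


_CH = ("Na", "KDR", "A", "CaL", "KCa", "H", "leak")


def run_protocol(
    m: NeuronMorphology,
    scheme: ConductanceScheme,
    config: SimulationConfig | None = None,
    stimuli: list[Stimulus] | None = None,
):
    """Default unstimulated pacemaking protocol.

    Discretizes, assigns the scheme, integrates, discards the
    pre-steady-state window and summarises firing from the somatic trace.
    Returns (TraceSet, FiringSummary or None if silent).
    """
    from .waveform import detect_spikes, firing_summary

    config = config or SimulationConfig()
    grid = discretize(m, rule=config.max_compartment_length,
                      ra=config.axial_resistivity)
    dens = assign(grid, scheme)
    traces = integrate(grid, dens, config, stimuli=stimuli)
    soma_v = traces.site("soma")
    keep = traces.t >= config.steady_state_discard
    spikes = detect_spikes(soma_v[keep], traces.dt)
    summary = None
    if len(spikes) >= 3:
        summary = firing_summary(spikes)
    traces.meta["n_spikes_steady"] = int(len(spikes))
    return traces, summary
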