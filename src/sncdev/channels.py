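"""Channel complement, gating kinetics and conductance-density schemes.

The model carries seven membrane conductances — fast sodium (Na), delayed
rectifier potassium (KDR), A-type potassium (A), L-type calcium (CaL),
calcium-activated SK potassium (KCa), hyperpolarisation-activated cation
current (H) and leak — with activation/inactivation Hodgkin-Huxley gating.
Gate kinetics are encoded as *data*: Boltzmann steady states and bell-shaped
voltage-dependent time constants.  The shipped default set is a
reconstruction in the spirit of the published SNc DA neuron model lineage
(Migliore-type Na, Schild-type delayed rectifier, published A/CaL/SK/H
forms); the exact rate equations of the original models are not
transcribed here, and downstream validation is property-based (pacemaking,
AIS initiation, AP shape) rather than curve reproduction.

Densities are expressed in pS/µm² (1 pS/µm² = 1e-4 S/cm²).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "GateSpec",
    "ChannelSpec",
    "CalciumPool",
    "ConductanceScheme",
    "default_channels",
    "build_scheme",
    "assign",
    "density_to_si",
    "MODEL1",
    "MODEL2",
    "REGIONS",
    "CHANNELS",
    "pack_kinetics",
]

REGIONS = ("soma", "abd", "nabd", "axon_start", "ais", "axon")
CHANNELS = ("Na", "KDR", "A", "CaL", "KCa", "H", "leak")
MODEL1 = "Model1_homogeneous"
MODEL2 = "Model2_heterogeneous"

# regions that carry the full channel complement; AIS and distal axon carry
# only fast Na, KDR (and leak — specific membrane resistance is global)
FULL_REGIONS = ("soma", "abd", "nabd", "axon_start")
AXONAL_CHANNELS = ("Na", "KDR", "leak")


def density_to_si(pS_per_um2: float) -> float:
    """pS/µm² -> S/cm²."""
    return pS_per_um2 * 1e-4


@dataclass(frozen=True)
class GateSpec:
    """One HH gate: Boltzmann steady state and a bell-shaped time constant.

    x_inf(V) = 1 / (1 + exp(-(V - vhalf)/k))        (k < 0: inactivation)
    tau(V)   = tau_min + tau_amp / (exp((V - vtau)/s1) + exp(-(V - vtau)/s2))
    """

    exponent: int
    vhalf: float
    k: float
    tau_min: float  # ms
    tau_amp: float  # ms
    vtau: float
    s1: float
    s2: float

    def steady_state(self, v):
        return 1.0 / (1.0 + np.exp(-(np.asarray(v, float) - self.vhalf) / self.k))

    def time_constant(self, v):
        v = np.asarray(v, float)
        return self.tau_min + self.tau_amp / (
            np.exp((v - self.vtau) / self.s1) + np.exp(-(v - self.vtau) / self.s2)
        )

    def params(self) -> tuple[float, ...]:
        return (self.vhalf, self.k, self.tau_min, self.tau_amp,
                self.vtau, self.s1, self.s2)


@dataclass(frozen=True)
class CalciumGate:
    """SK activation: a Hill function of intracellular calcium only."""

    exponent: int
    kd: float  # mM, half-activation
    hill: float
    tau: float  # ms, fixed

    def steady_state(self, ca):
        ca = np.maximum(np.asarray(ca, float), 0.0)
        cn = ca ** self.hill
        return cn / (cn + self.kd ** self.hill)

    def time_constant(self, ca):
        return np.full_like(np.asarray(ca, float), self.tau)


@dataclass(frozen=True)
class ChannelSpec:
    name: str
    gates: tuple
    reversal: float  # mV ('CaL' uses a fixed calcium reversal approximation)
    calcium_coupled: bool = False

    def __post_init__(self):
        if self.name == "leak" and self.gates:
            raise ValueError("leak carries no gates")
        if self.name == "KCa":
            if not all(isinstance(g, CalciumGate) for g in self.gates):
                raise ValueError("KCa gating must depend on calcium only")


# reversal potentials (not printed in the source study; standard values)
E_NA = 60.0
E_K = -90.0
E_CA = 60.0  # fixed-reversal approximation for the L-type current
E_H = -35.0
E_LEAK = -50.0


def default_channels(soma_variant: bool = False) -> list[ChannelSpec]:
    """The seven-channel default complement.

    ``soma_variant`` selects the somatic A-current kinetics (depolarised,
    slower inactivation; the somatic density difference is carried by the
    conductance scheme, not here).
    """
    na = ChannelSpec("Na", (
        GateSpec(3, -37.0, 6.0, 0.03, 0.30, -38.0, 14.0, 14.0),   # m
        GateSpec(1, -52.0, -6.5, 0.35, 8.0, -55.0, 12.0, 12.0),   # h
    ), E_NA)
    kdr = ChannelSpec("KDR", (
        GateSpec(3, -28.0, 9.0, 0.8, 10.0, -40.0, 20.0, 20.0),    # n
    ), E_K)
    a_b = (GateSpec(1, -70.0, -8.0, 20.0, 100.0, -70.0, 18.0, 18.0)
           if soma_variant else
           GateSpec(1, -80.0, -8.0, 10.0, 50.0, -80.0, 18.0, 18.0))
    ia = ChannelSpec("A", (
        GateSpec(2, -30.0, 8.0, 0.5, 2.0, -50.0, 18.0, 18.0),     # a
        a_b,                                                      # b
    ), E_K)
    cal = ChannelSpec("CaL", (
        GateSpec(1, -30.0, 5.0, 1.0, 3.0, -45.0, 15.0, 15.0),     # d
    ), E_CA)
    kca = ChannelSpec("KCa", (
        CalciumGate(1, 1.0e-3, 4.0, 5.0),                          # z
    ), E_K, calcium_coupled=True)
    ih = ChannelSpec("H", (
        GateSpec(1, -80.0, -8.0, 50.0, 600.0, -85.0, 16.0, 16.0), # q
    ), E_H)
    leak = ChannelSpec("leak", (), E_LEAK)
    return [na, kdr, ia, cal, kca, ih, leak]


@dataclass
class CalciumPool:
    """Single-exponential intracellular calcium pool.

    Influx is proportional to the inward CaL current over the compartment
    volume; decay is first order back to the resting concentration.
    Defaults (rest 50 nM, tau 5 ms) are model configuration, not published
    values.
    """

    resting_concentration: float = 5.0e-5  # mM
    decay_time_constant: float = 5.0       # ms
    # fraction of the compartment volume acting as the effective pool
    # (whole compartment by default; the fast decay keeps the signal local
    # in time rather than space)
    shell_fraction: float = 1.0

    def influx_scaling(self, volume_um3: np.ndarray) -> np.ndarray:
        """mM per (nA·ms) for each compartment volume in µm³."""
        faraday = 96485.332  # C/mol
        vol = np.maximum(volume_um3 * self.shell_fraction, 1e-9)
        return 1.0e6 / (2.0 * faraday * vol)


# ---------------------------------------------------------------------------
# conductance schemes
# ---------------------------------------------------------------------------

# default density tables in pS/µm².  The heterogeneous scheme implements the
# ABD-enriched sodium/calcium distribution (gNa 120 vs 50, gCa 2.2 vs 1);
# the homogeneous scheme sets ABD = nABD.  Somatic/axon-start values and the
# non-Na/Ca channel densities are model configuration.
_BASE_DENSITIES = {
    "soma":       {"Na": 120.0, "KDR": 40.0, "A": 40.0, "CaL": 2.2,
                   "KCa": 4.0, "H": 0.1, "leak": 0.1},
    "abd":        {"Na": 120.0, "KDR": 40.0, "A": 20.0, "CaL": 2.2,
                   "KCa": 4.0, "H": 0.1, "leak": 0.1},
    "nabd":       {"Na": 50.0, "KDR": 40.0, "A": 20.0, "CaL": 1.0,
                   "KCa": 4.0, "H": 0.1, "leak": 0.1},
    "axon_start": {"Na": 120.0, "KDR": 40.0, "A": 20.0, "CaL": 2.2,
                   "KCa": 4.0, "H": 0.1, "leak": 0.1},
    "axon":       {"Na": 120.0, "KDR": 40.0, "leak": 0.1},
}


@dataclass
class ConductanceScheme:
    """Region × channel density map (pS/µm²) with AIS multipliers."""

    variant: str
    densities: dict[str, dict[str, float]]
    ais_na_multiplier: float = 15.0
    ais_kdr_multiplier: float = 8.0

    def __post_init__(self):
        if self.variant not in (MODEL1, MODEL2):
            raise ValueError(f"unknown variant {self.variant!r}")
        for region, row in self.densities.items():
            for ch, dens in row.items():
                if dens < 0:
                    raise ValueError(f"negative density {region}/{ch}")
        if not (self.ais_na_multiplier > 1 and self.ais_kdr_multiplier > 1):
            raise ValueError("AIS multipliers must exceed 1")
        if self.variant == MODEL2 and \
                self.densities["abd"]["Na"] < self.densities["nabd"]["Na"]:
            warnings.warn("heterogeneous scheme with ABD gNa below nABD gNa "
                          "inverts the ABD-enrichment premise")
        # AIS densities derive from the somatodendritic maximum
        sd_na = max(self.densities[r]["Na"] for r in FULL_REGIONS)
        sd_kdr = max(self.densities[r]["KDR"] for r in FULL_REGIONS)
        ais = {"Na": self.ais_na_multiplier * sd_na,
               "KDR": self.ais_kdr_multiplier * sd_kdr,
               "leak": self.densities["soma"]["leak"]}
        self.densities = {**self.densities, "ais": ais}
        if ais["Na"] <= sd_na:
            raise ValueError("AIS gNa must exceed somatodendritic gNa")

    def density(self, region: str, channel: str) -> float:
        return self.densities.get(region, {}).get(channel, 0.0)

    def with_density(self, updates: dict[str, dict[str, float]]) -> "ConductanceScheme":
        """Copy of the scheme with region/channel densities replaced, the
        AIS row kept *fixed* (a parameter sweep of dendritic densities must
        not drag the AIS boost along with it)."""
        new = ConductanceScheme(
            self.variant,
            {r: dict(row) for r, row in self.densities.items() if r != "ais"},
            self.ais_na_multiplier, self.ais_kdr_multiplier,
        )
        for region, row in updates.items():
            if region == "ais":
                raise ValueError("AIS densities are derived, not swept")
            for ch, v in row.items():
                if v < 0:
                    raise ValueError(f"negative density {region}/{ch}")
                new.densities[region][ch] = float(v)
        new.densities["ais"] = dict(self.densities["ais"])
        return new

    def to_json(self) -> str:
        return json.dumps({
            "variant": self.variant,
            "densities": self.densities,
            "ais_na_multiplier": self.ais_na_multiplier,
            "ais_kdr_multiplier": self.ais_kdr_multiplier,
        }, sort_keys=True, indent=1)

    @staticmethod
    def from_json(text: str) -> "ConductanceScheme":
        d = json.loads(text)
        dens = {r: row for r, row in d["densities"].items() if r != "ais"}
        return ConductanceScheme(d["variant"], dens,
                                 d["ais_na_multiplier"], d["ais_kdr_multiplier"])


def build_scheme(variant: str = MODEL2, overrides: dict | None = None,
                 ais_na_multiplier: float = 15.0,
                 ais_kdr_multiplier: float = 8.0) -> ConductanceScheme:
    """Construct a Model 1 (homogeneous) or Model 2 (heterogeneous) scheme.

    ``overrides`` maps region -> channel -> density (pS/µm²), applied on top
    of the defaults; in Model 1 the ABD row is first made equal to the nABD
    row.
    """
    dens = {r: dict(row) for r, row in _BASE_DENSITIES.items()}
    if variant == MODEL1:
        dens["abd"] = dict(dens["nabd"])
    elif variant != MODEL2:
        raise ValueError(f"unknown variant {variant!r}")
    for region, row in (overrides or {}).items():
        if region not in dens:
            raise ValueError(f"unknown region {region!r}")
        for ch, v in row.items():
            if ch not in CHANNELS:
                raise ValueError(f"unknown channel {ch!r}")
            dens[region][ch] = float(v)
    return ConductanceScheme(variant, dens, ais_na_multiplier, ais_kdr_multiplier)


def assign(grid, scheme: ConductanceScheme) -> np.ndarray:
    """Per-compartment density table.

    ``grid`` is a CompartmentGrid (regions per compartment); returns an
    (n_compartments, 7) array of densities in pS/µm² in CHANNELS order.
    Soma compartments use the somatic A-current kinetic variant (flagged on
    the grid, consumed by the integrator).
    """
    regions = grid.regions
    out = np.zeros((len(regions), len(CHANNELS)))
    for i, region in enumerate(regions):
        if region not in REGIONS:
            raise ValueError(f"compartment {i}: unlabelled region {region!r}")
        allowed = CHANNELS if region in FULL_REGIONS else AXONAL_CHANNELS
        for j, ch in enumerate(CHANNELS):
            if ch in allowed:
                out[i, j] = scheme.density(region, ch)
    return out


def pack_kinetics(channels: list[ChannelSpec] | None = None) -> np.ndarray:
    """Flatten gate kinetics into the parameter vector consumed by the
    integration kernel.

    Layout: 8 voltage gates × 7 params (Na-m, Na-h, KDR-n, A-a, A-b dend,
    A-b soma, CaL-d, H-q), then SK (kd, hill, tau), then the five reversal
    potentials (Na, K, Ca, H, leak).
    """
    dend = {c.name: c for c in (channels or default_channels(False))}
    soma = {c.name: c for c in default_channels(True)} if channels is None \
        else dend
    order = [
        dend["Na"].gates[0], dend["Na"].gates[1],
        dend["KDR"].gates[0],
        dend["A"].gates[0], dend["A"].gates[1], soma["A"].gates[1],
        dend["CaL"].gates[0],
        dend["H"].gates[0],
    ]
    kp = []
    for g in order:
        kp.extend(g.params())
    sk = dend["KCa"].gates[0]
    kp.extend((sk.kd, sk.hill, sk.tau))
    kp.extend((dend["Na"].reversal, dend["KDR"].reversal, dend["CaL"].reversal,
               dend["H"].reversal, dend["leak"].reversal))
    return np.asarray(kp, dtype=np.float64)
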