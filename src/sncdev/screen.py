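"""Sodium-conductance screening.

For each model neuron, somatodendritic gNa is swept over a grid, the
somatic AP half-width measured at every grid point, and the gNa best
matching a target (biological) half-width recovered by piecewise-linear
interpolation (linear extrapolation outside the achieved range).
Sensitivity of the AP to gNa is quantified as the coefficient of variation
of half-width over a fixed gNa range.

Two screening modes mirror the two model variants: the heterogeneous
(mature-stage) screen varies gNa in the ABD only, calcium densities held
fixed; the homogeneous (early-stage) screen varies gNa in ABD and nABDs
together.  Default grids: 50-150 pS/µm² in steps of 10 (heterogeneous) and
25-165 pS/µm² in steps of 10 (homogeneous).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .cable import SimulationConfig, discretize, integrate
from .channels import MODEL1, MODEL2, ConductanceScheme, assign, build_scheme
from .morphology import NeuronMorphology
from .waveform import ap_shape, average_ap, detect_spikes

__all__ = [
    "SweepResult",
    "ScreenOutcome",
    "default_grid",
    "sweep",
    "optimal_gna",
    "halfwidth_cv",
    "P21_GRID",
    "P7_GRID",
    "P21_CV_RANGE",
    "P7_CV_RANGE",
]

# published sweep grids and threefold CV ranges
P21_GRID = tuple(range(50, 151, 10))    # ABD gNa, heterogeneous model
P7_GRID = tuple(range(25, 166, 10))     # ABD+nABD gNa, homogeneous model
P21_CV_RANGE = (50.0, 150.0)
P7_CV_RANGE = (55.0, 165.0)


def default_grid(variant: str) -> tuple[int, ...]:
    return P21_GRID if variant == MODEL2 else P7_GRID


@dataclass
class SweepResult:
    neuron: str
    variant: str
    grid: tuple[float, ...]
    half_widths: tuple[float, ...]  # NaN where the model was silent

    def __post_init__(self):
        if any(b <= a for a, b in zip(self.grid, self.grid[1:])):
            raise ValueError("gNa grid must be strictly increasing")
        if len(self.half_widths) != len(self.grid):
            raise ValueError("one half-width per grid point")

    def valid_points(self) -> tuple[np.ndarray, np.ndarray]:
        g = np.asarray(self.grid, float)
        h = np.asarray(self.half_widths, float)
        ok = np.isfinite(h)
        return g[ok], h[ok]


@dataclass
class ScreenOutcome:
    neuron: str
    optimal_gna: float        # pS/µm²
    target_half_width: float  # ms
    achieved_half_width: float
    cv_percent: float = math.nan
    extrapolated: bool = False


def _halfwidth_at(m: NeuronMorphology, scheme: ConductanceScheme,
                  config: SimulationConfig) -> float:
    """Somatic AP half-width under the scheme, NaN when silent."""
    grid = discretize(m, rule=config.max_compartment_length,
                      ra=config.axial_resistivity)
    dens = assign(grid, scheme)
    traces = integrate(grid, dens, config)
    v = traces.site("soma")
    keep = traces.t >= config.steady_state_discard
    spikes = detect_spikes(v[keep], traces.dt)
    if len(spikes) < 3:
        return math.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        w = average_ap(v[keep], spikes, traces.dt)
    return ap_shape(w, traces.dt).half_width


def sweep(
    m: NeuronMorphology,
    variant: str = MODEL2,
    grid: tuple[float, ...] | None = None,
    config: SimulationConfig | None = None,
    base_scheme: ConductanceScheme | None = None,
) -> SweepResult:
    """One simulation + AP-shape measurement per gNa grid point.

    Heterogeneous mode varies ABD gNa only; homogeneous mode varies ABD and
    nABD gNa together.  The AIS densities stay at the base scheme's values
    throughout.  Silent grid points yield NaN half-widths.
    """
    grid = tuple(grid) if grid is not None else default_grid(variant)
    if not grid:
        raise ValueError("empty gNa grid")
    config = config or SimulationConfig()
    base = base_scheme or build_scheme(variant)
    regions = ("abd",) if variant == MODEL2 else ("abd", "nabd")
    hws = []
    for g in grid:
        sch = base.with_density({r: {"Na": float(g)} for r in regions})
        hws.append(_halfwidth_at(m, sch, config))
    return SweepResult(m.name, variant, grid, tuple(hws))


def optimal_gna(sw: SweepResult, target_half_width: float,
                cv_range: tuple[float, float] | None = None) -> ScreenOutcome:
    """Invert the half-width/gNa relation at the target half-width.

    Piecewise-linear interpolation between grid points; linear extrapolation
    from the two nearest points when the target lies outside the achieved
    half-width range.  Under non-monotonicity, the bracketing interval whose
    half-widths are closest to the target wins (with a warning).
    """
    g, h = sw.valid_points()
    if len(g) < 2:
        raise ValueError("need at least two non-silent grid points")
    target = float(target_half_width)

    # exact grid hit (also the shared endpoint of two bracketing intervals)
    hit = int(np.argmin(np.abs(h - target)))
    if abs(h[hit] - target) <= 1e-12 * max(1.0, abs(target)):
        cv = halfwidth_cv(sw, cv_range) if cv_range is not None else math.nan
        return ScreenOutcome(sw.neuron, float(g[hit]), target, float(h[hit]),
                             cv_percent=cv)

    # bracketing intervals
    brackets = []
    for i in range(len(g) - 1):
        lo, hi = sorted((h[i], h[i + 1]))
        if lo <= target <= hi:
            brackets.append(i)
    extrapolated = False
    if brackets:
        if len(brackets) > 1:
            warnings.warn("half-width/gNa relation is non-monotone around "
                          "the target; using the closest bracket")
        i = min(brackets,
                key=lambda i: min(abs(h[i] - target), abs(h[i + 1] - target)))
    else:
        extrapolated = True
        # two grid points whose half-widths are nearest the target
        i = int(np.argmin(np.minimum(np.abs(h[:-1] - target),
                                     np.abs(h[1:] - target))))
    if h[i + 1] == h[i]:
        gopt = 0.5 * (g[i] + g[i + 1])
    else:
        gopt = g[i] + (target - h[i]) * (g[i + 1] - g[i]) / (h[i + 1] - h[i])
    achieved = float(np.interp(np.clip(gopt, g[0], g[-1]), g, h))
    cv = halfwidth_cv(sw, cv_range) if cv_range is not None else math.nan
    return ScreenOutcome(sw.neuron, float(gopt), target, achieved,
                         cv_percent=cv, extrapolated=extrapolated)


def halfwidth_cv(sw: SweepResult, cv_range: tuple[float, float] | None = None
                 ) -> float:
    """100 × SD/mean of half-widths over grid points inside ``cv_range``
    (sample SD, n−1)."""
    if cv_range is None:
        cv_range = (P21_CV_RANGE if sw.variant == MODEL2 else P7_CV_RANGE)
    g, h = sw.valid_points()
    sel = (g >= cv_range[0]) & (g <= cv_range[1])
    if sel.sum() < 3:
        raise ValueError("need at least three grid points inside the CV range")
    hh = h[sel]
    return float(100.0 * np.std(hh, ddof=1) / np.mean(hh))
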