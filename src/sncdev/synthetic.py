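"""Stage-typed synthetic SNc dopaminergic neuron morphologies.

Real reconstructions of developing SNc DA neurons are summarised in the
study population by per-stage (P3/P7/P14/P21) means, SDs and ranges of
morphometric quantities plus the fraction of neurons whose axon arises
directly from the soma.  This module turns those summary statistics into a
generative model: each field is drawn from a truncated normal whose
location/scale are moment-matched so that the *truncated* distribution hits
the published mean exactly (and the published SD as closely as the bounds
permit), and a random binary dendritic tree realises the drawn segment
counts and lengths.

The generator defines the study conditions for every downstream simulation
and statistical test; its defaults are the published population values and
are not tuning knobs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

from .morphology import (
    AIS,
    AXON,
    AXON_START,
    DENDRITE,
    SOMA,
    NeuronMorphology,
    SectionNode,
    apply_taper,
    equivalent_cylinder,
)

__all__ = [
    "STAGES",
    "FieldDist",
    "StageParams",
    "default_stage_params",
    "sample_neuron",
    "sample_population",
    "sample_feature_table",
    "FEATURE_COLUMNS",
    "AHC_FEATURES",
    "LDA_FEATURES",
]

STAGES = ("P3", "P7", "P14", "P21")

# published per-stage somatic-axon counts (neurons with a somatic axon,
# neurons assessed): 2/10, 4/23, 1/13, 4/38
SOMATIC_AXON_COUNTS = {"P3": (2, 10), "P7": (4, 23), "P14": (1, 13),
                       "P21": (4, 38)}
P_SOMATIC_AXON = {k: a / b for k, (a, b) in SOMATIC_AXON_COUNTS.items()}


def pooled_somatic_axon_fraction() -> float:
    """Fraction of somatic-axon neurons pooled over the four stages."""
    num = sum(a for a, _ in SOMATIC_AXON_COUNTS.values())
    den = sum(b for _, b in SOMATIC_AXON_COUNTS.values())
    return num / den

# primary-dendrite stem diameters are never tabulated for the population;
# these are configuration defaults, not published values
PRIMARY_DIAM = {"P3": 1.2, "P7": 1.5, "P14": 2.0, "P21": 2.0}


@dataclass(frozen=True)
class FieldDist:
    """Target moments and support for one morphometric/electrophysiological
    field: published mean and SD, with truncation bounds derived from the
    published range width (centred on the mean, floored at zero for
    nonnegative quantities)."""

    mean: float
    sd: float
    lo: float
    hi: float
    n: int  # published group size (used for SE-scale checks)

    # A finite sample's range understates the population support (the
    # expected range of ~10-50 normal draws is about 3 SD); the truncation
    # window is therefore the printed range inflated by 30%, centred on the
    # mean and floored at zero for nonnegative quantities.
    RANGE_INFLATION = 1.3

    @staticmethod
    def from_row(mean: float, sd: float, rng_width: float, n: int,
                 nonneg: bool = True) -> "FieldDist":
        half = FieldDist.RANGE_INFLATION * rng_width / 2.0
        lo = mean - half
        if nonneg and lo < 0:
            lo = 0.0
        hi = lo + 2 * half
        return FieldDist(mean, sd, lo, hi, n)


# Per-stage population table: field -> (mean, sd, range width, n).
# Morphological units µm / µm³; electrophysiological units mV, ms, mV·ms⁻².
_TABLE: dict[str, dict[str, tuple[float, float, float, int]]] = {
    "P3": {
        "ap_threshold": (-44.57, 3.60, 12.22, 14),
        "ap_amplitude": (51.47, 4.71, 16.44, 14),
        "ap_halfwidth": (2.69, 0.47, 1.75, 14),
        "ap_is_peak": (122.47, 42.52, 136.64, 14),
        "ap_sd_peak": (47.86, 33.73, 128.63, 14),
        "sd_is_ratio": (0.44, 0.32, 1.04, 14),
        "n_segments_total": (33.40, 17.02, 59.0, 10),
        "n_segments_abd": (6.88, 5.06, 16.0, 8),
        "n_segments_nabd": (27.90, 18.49, 63.0, 10),
        "n_primary_nabd": (3.70, 1.34, 4.0, 10),
        "avg_segments_per_nabd": (8.26, 5.66, 15.17, 10),
        "len_total": (1297.0, 450.0, 1342.0, 10),
        "len_abd": (259.0, 175.0, 506.0, 8),
        "len_nabd_total": (1090.0, 505.0, 1419.0, 10),
        "len_nabd_avg": (335.0, 213.0, 629.0, 10),
        "axon_soma_distance": (15.38, 17.33, 62.51, 14),
        "axon_start_length": (3.20, 2.73, 8.06, 14),
        "ais_soma_distance": (18.58, 15.79, 58.90, 14),
        "ais_length": (25.85, 7.98, 29.14, 13),
        "soma_volume": (1103.0, 480.0, 1399.0, 10),
    },
    "P7": {
        "ap_threshold": (-44.59, 3.92, 14.61, 34),
        "ap_amplitude": (53.69, 7.22, 31.34, 34),
        "ap_halfwidth": (2.34, 0.51, 1.99, 34),
        "ap_is_peak": (123.06, 33.54, 170.07, 34),
        "ap_sd_peak": (78.27, 68.73, 274.33, 34),
        "sd_is_ratio": (0.62, 0.47, 1.72, 34),
        "n_segments_total": (22.87, 9.46, 34.0, 23),
        "n_segments_abd": (7.32, 4.45, 16.0, 19),
        "n_segments_nabd": (16.83, 9.35, 37.0, 23),
        "n_primary_nabd": (3.61, 1.23, 4.0, 23),
        "avg_segments_per_nabd": (4.56, 1.71, 6.40, 23),
        "len_total": (1225.0, 430.0, 1748.0, 23),
        "len_abd": (345.0, 214.0, 711.0, 19),
        "len_nabd_total": (940.0, 456.0, 1867.0, 23),
        "len_nabd_avg": (263.0, 99.0, 376.0, 23),
        "axon_soma_distance": (19.73, 18.47, 74.58, 31),
        "axon_start_length": (9.68, 4.87, 21.44, 31),
        "ais_soma_distance": (29.41, 17.97, 76.56, 31),
        "ais_length": (28.74, 7.60, 39.13, 30),
        "soma_volume": (1328.0, 448.0, 1800.0, 23),
    },
    "P14": {
        "ap_threshold": (-43.97, 5.24, 19.17, 13),
        "ap_amplitude": (58.70, 7.33, 25.25, 13),
        "ap_halfwidth": (1.59, 0.30, 0.91, 13),
        "ap_is_peak": (311.96, 109.61, 373.65, 13),
        "ap_sd_peak": (221.71, 155.65, 546.47, 13),
        "sd_is_ratio": (0.73, 0.48, 1.73, 13),
        "n_segments_total": (24.46, 11.34, 35.0, 13),
        "n_segments_abd": (13.33, 7.24, 22.0, 12),
        "n_segments_nabd": (12.15, 5.38, 19.0, 13),
        "n_primary_nabd": (3.15, 0.99, 3.0, 13),
        "avg_segments_per_nabd": (4.13, 2.29, 6.67, 13),
        "len_total": (2392.0, 854.0, 2711.0, 12),
        "len_abd": (1106.0, 656.0, 2043.0, 12),
        "len_nabd_total": (1306.0, 327.0, 1110.0, 13),
        "len_nabd_avg": (433.0, 123.0, 416.0, 13),
        "axon_soma_distance": (33.59, 27.64, 103.35, 13),
        "axon_start_length": (14.72, 6.54, 21.25, 13),
        "ais_soma_distance": (48.31, 29.60, 116.91, 13),
        "ais_length": (28.31, 8.58, 26.68, 13),
        "soma_volume": (2845.0, 789.0, 2408.0, 13),
    },
    "P21": {
        "ap_threshold": (-44.68, 3.53, 18.20, 54),
        "ap_amplitude": (62.43, 7.18, 29.79, 54),
        "ap_halfwidth": (1.30, 0.19, 0.92, 54),
        "ap_is_peak": (178.28, 54.72, 241.06, 51),
        "ap_sd_peak": (204.94, 105.09, 582.73, 53),
        "sd_is_ratio": (1.26, 0.83, 4.66, 50),
        "n_segments_total": (27.03, 8.22, 33.0, 38),
        "n_segments_abd": (12.06, 6.09, 23.0, 34),
        "n_segments_nabd": (16.24, 6.76, 27.0, 38),
        "n_primary_nabd": (3.34, 1.28, 6.0, 38),
        "avg_segments_per_nabd": (5.37, 3.15, 17.0, 38),
        "len_total": (2614.0, 957.0, 3853.0, 38),
        "len_abd": (1008.0, 495.0, 2014.0, 34),
        "len_nabd_total": (1712.0, 881.0, 4314.0, 38),
        "len_nabd_avg": (547.0, 274.0, 1138.0, 38),
        "axon_soma_distance": (33.25, 27.54, 105.91, 40),
        "axon_start_length": (21.61, 6.70, 31.48, 40),
        "ais_soma_distance": (54.85, 27.14, 104.64, 40),
        "ais_length": (32.14, 7.14, 34.22, 40),
        "soma_volume": (2489.0, 846.0, 3569.0, 38),
    },
}

# fields that the generator draws directly (the rest are additive/ratio
# derivatives computed per neuron)
DRAWN_MORPH_FIELDS = (
    "n_segments_abd",
    "n_segments_nabd",
    "n_primary_nabd",
    "len_abd",
    "len_nabd_total",
    "axon_soma_distance",
    "axon_start_length",
    "ais_length",
    "soma_volume",
)

EPHYS_FIELDS = (
    "ap_threshold",
    "ap_amplitude",
    "ap_halfwidth",
    "ap_is_peak",
    "ap_sd_peak",
    "sd_is_ratio",
)

# feature vocabulary used by the developmental statistics layer; the 12-
# and 9-parameter subsets are the defaults for clustering / discriminant
# analysis
FEATURE_COLUMNS = EPHYS_FIELDS + (
    "soma_volume",
    "axon_start_length",
    "ais_soma_distance",
    "len_nabd_avg",
    "len_nabd_total",
    "len_total",
    "len_abd",
    "ais_length",
    "axon_soma_distance",
    "n_segments_total",
    "n_segments_abd",
    "n_segments_nabd",
    "n_primary_nabd",
    "avg_segments_per_nabd",
)

AHC_FEATURES = (
    "ap_halfwidth",
    "ap_is_peak",
    "ap_sd_peak",
    "sd_is_ratio",
    "ap_amplitude",
    "soma_volume",
    "axon_start_length",
    "ais_soma_distance",
    "len_nabd_avg",
    "len_nabd_total",
    "len_total",
    "len_abd",
)

# nine-parameter discriminant set: the clustering set minus the three
# arithmetically derived columns (ratio, grand total, per-dendrite average)
LDA_FEATURES = (
    "ap_halfwidth",
    "ap_is_peak",
    "ap_sd_peak",
    "ap_amplitude",
    "soma_volume",
    "axon_start_length",
    "ais_soma_distance",
    "len_nabd_total",
    "len_abd",
)


@dataclass(frozen=True)
class StageParams:
    """Per-stage generator parameters."""

    stage: str
    fields: dict[str, FieldDist]
    p_somatic_axon: float
    primary_dendrite_diam: float
    axon_diam: float = 0.7
    terminal_diam: float = 0.5
    ais_diam: float = 0.7
    distal_axon_length: float = 50.0

    def __post_init__(self):
        if not 0.0 <= self.p_somatic_axon <= 1.0:
            raise ValueError("p_somatic_axon must lie in [0, 1]")
        for name, f in self.fields.items():
            if f.sd < 0 or not (f.lo <= f.mean <= f.hi):
                raise ValueError(f"inconsistent field distribution for {name}")


@lru_cache(maxsize=None)
def default_stage_params(stage: str) -> StageParams:
    if stage not in STAGES:
        raise ValueError(f"unknown developmental stage {stage!r}")
    nonneg = lambda k: k != "ap_threshold"
    fields = {
        k: FieldDist.from_row(*row, nonneg=nonneg(k))
        for k, row in _TABLE[stage].items()
    }
    return StageParams(
        stage=stage,
        fields=fields,
        p_somatic_axon=P_SOMATIC_AXON[stage],
        primary_dendrite_diam=PRIMARY_DIAM[stage],
    )


# ---------------------------------------------------------------------------
# moment-matched truncated normal
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4096)
def _match_truncnorm(mean: float, sd: float, lo: float, hi: float):
    """(loc, scale, a, b) of a truncated normal on [lo, hi] whose truncated
    mean equals ``mean`` exactly and whose truncated SD is as close to ``sd``
    as the support allows."""
    if sd == 0:
        return mean, 0.0, 0.0, 0.0

    def _loc_for(scale: float) -> float:
        def f(loc):
            a, b = (lo - loc) / scale, (hi - loc) / scale
            return stats.truncnorm.mean(a, b, loc=loc, scale=scale) - mean
        lo_loc, hi_loc = lo - 2 * scale, hi + 2 * scale
        for _ in range(30):  # expand until the target mean is bracketed
            if f(lo_loc) < 0:
                break
            lo_loc -= 4 * scale
        for _ in range(30):
            if f(hi_loc) > 0:
                break
            hi_loc += 4 * scale
        return optimize.brentq(f, lo_loc, hi_loc, xtol=1e-10 * max(1.0, abs(mean)))

    def sd_err(log_scale: float) -> float:
        scale = float(np.exp(log_scale))
        loc = _loc_for(scale)
        a, b = (lo - loc) / scale, (hi - loc) / scale
        return (stats.truncnorm.std(a, b, loc=loc, scale=scale) - sd) ** 2

    res = optimize.minimize_scalar(
        sd_err, bounds=(np.log(sd / 5), np.log(sd * 40)), method="bounded",
        options={"xatol": 1e-4},
    )
    scale = float(np.exp(res.x))
    loc = _loc_for(scale)
    a, b = (lo - loc) / scale, (hi - loc) / scale
    return loc, scale, a, b


def draw_field(dist: FieldDist, rng: np.random.Generator, size=None, u=None):
    """Sample from the moment-matched truncated normal for one field.

    ``u`` optionally supplies the uniform variate(s), enabling stratified
    population sampling."""
    if dist.sd == 0:
        return np.full(size, dist.mean) if size else dist.mean
    loc, scale, a, b = _match_truncnorm(dist.mean, dist.sd, dist.lo, dist.hi)
    if u is None:
        u = rng.random(size)
    return stats.truncnorm.ppf(u, a, b, loc=loc, scale=scale)


def matched_moments(dist: FieldDist) -> tuple[float, float]:
    """Analytic (mean, sd) actually realised by the matched sampler."""
    if dist.sd == 0:
        return dist.mean, 0.0
    loc, scale, a, b = _match_truncnorm(dist.mean, dist.sd, dist.lo, dist.hi)
    m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
    return float(m), float(np.sqrt(v))


# ---------------------------------------------------------------------------
# neuron construction
# ---------------------------------------------------------------------------

def _round_odd(x: float, rng: np.random.Generator) -> int:
    """Nearest odd integer >= 1 with randomised tie direction (binary trees
    on a single stem have odd segment counts)."""
    k = int(np.floor(x))
    lo_odd = k if k % 2 == 1 else k - 1
    hi_odd = lo_odd + 2
    # choose proportionally to proximity (stochastic rounding keeps the mean)
    p_hi = (x - lo_odd) / 2.0
    n = hi_odd if rng.random() < p_hi else lo_odd
    return max(1, n)


def _partition(total: float, n: int, rng: np.random.Generator,
               floor_frac: float = 0.05) -> np.ndarray:
    """Split a length over n segments with Dirichlet weights, each segment
    getting at least floor_frac of an even share."""
    w = rng.dirichlet(np.ones(n))
    w = floor_frac / n + (1 - floor_frac) * w
    return total * w


def _build_binary_tree(
    prefix: str,
    parent: str,
    n_segments: int,
    lengths: np.ndarray,
    diam: float,
    rng: np.random.Generator,
) -> dict[str, SectionNode]:
    """Random binary tree with n_segments sections rooted at ``parent``.

    Topology: start from the stem and repeatedly bifurcate a uniformly
    chosen terminal segment until the count is met (n_segments odd).
    """
    assert n_segments % 2 == 1
    sections: dict[str, SectionNode] = {}
    stem_id = f"{prefix}s0"
    sections[stem_id] = SectionNode(stem_id, DENDRITE, parent, float(lengths[0]),
                                    diam, diam)
    tips = [stem_id]
    idx = 1
    while idx < n_segments:
        t = tips.pop(int(rng.integers(len(tips))))
        for _ in range(2):
            sid = f"{prefix}s{idx}"
            sections[sid] = SectionNode(sid, DENDRITE, t, float(lengths[idx]),
                                        diam, diam)
            tips.append(sid)
            idx += 1
    return sections


def _longest_path(sections: dict[str, SectionNode], stem_id: str) -> list[str]:
    """Section ids along the longest root-to-tip path of one dendritic tree."""
    children: dict[str, list[str]] = {}
    for s in sections.values():
        children.setdefault(s.parent, []).append(s.id)

    def best(sid: str) -> tuple[float, list[str]]:
        kids = children.get(sid, [])
        if not kids:
            return sections[sid].length, [sid]
        ln, path = max((best(k) for k in kids), key=lambda t: t[0])
        return sections[sid].length + ln, [sid] + path

    return best(stem_id)[1]


def sample_neuron(params: StageParams, rng: np.random.Generator,
                  name: str | None = None,
                  presampled: dict | None = None) -> NeuronMorphology:
    """Draw one synthetic neuron satisfying all morphometric identities.

    ``presampled`` optionally fixes drawn field values (and the
    ``somatic_axon`` flag) — used by :func:`sample_population` for
    stratified sampling."""
    f = params.fields
    pre = presampled or {}

    def draw(fld: str) -> float:
        if fld in pre:
            return float(pre[fld])
        return float(draw_field(f[fld], rng))

    somatic = bool(pre["somatic_axon"]) if "somatic_axon" in pre \
        else bool(rng.random() < params.p_somatic_axon)

    soma_volume = draw("soma_volume")
    d_soma, l_soma = equivalent_cylinder(soma_volume)
    sections: dict[str, SectionNode] = {
        "soma": SectionNode("soma", SOMA, None, l_soma, d_soma, d_soma)
    }

    # nABDs: total segment count partitioned over primaries, each odd
    k = max(1, int(round(draw("n_primary_nabd"))))
    seg_nabd = max(k, int(round(draw("n_segments_nabd"))))
    if (seg_nabd - k) % 2 == 1:  # need sum of k odd numbers
        seg_nabd += int(rng.choice([-1, 1])) if seg_nabd > k else 1
    n_bif = (seg_nabd - k) // 2
    bif_alloc = rng.multinomial(n_bif, np.ones(k) / k)
    per_primary = 1 + 2 * bif_alloc

    len_nabd_total = draw("len_nabd_total")
    len_alloc = _partition(len_nabd_total, k, rng)
    diam = params.primary_dendrite_diam
    for j in range(k):
        seg_lengths = _partition(float(len_alloc[j]), int(per_primary[j]), rng)
        sections.update(
            _build_binary_tree(f"n{j}", "soma", int(per_primary[j]),
                               seg_lengths, diam, rng)
        )

    # axon geometry
    axon_start_len = max(0.1, draw("axon_start_length"))
    ais_len = max(0.5, draw("ais_length"))

    if somatic:
        axon_parent, axon_arc = "soma", None
    else:
        seg_abd = _round_odd(draw("n_segments_abd"), rng)
        len_abd = draw("len_abd")
        seg_lengths = _partition(len_abd, seg_abd, rng)
        abd_secs = _build_binary_tree("a", "soma", seg_abd, seg_lengths, diam, rng)
        sections.update(abd_secs)
        # the axon origin lies somewhere along the longest root-to-tip path
        # of the ABD; when the drawn distance overshoots that path, length
        # is shifted from off-path segments onto the path (total preserved),
        # and only distances exceeding the whole ABD are redrawn
        path = _longest_path(abd_secs, "as0")
        path_len = sum(abd_secs[s].length for s in path)
        axon_d = min(draw("axon_soma_distance"), 0.95 * len_abd)
        if axon_d > 0.95 * path_len:
            need = min(axon_d / 0.95, len_abd)
            fp = need / path_len
            off = len_abd - path_len
            fo = (len_abd - need) / off if off > 0 else 1.0
            path_set = set(path)
            from dataclasses import replace as _rep
            for sid, sec in list(abd_secs.items()):
                fct = fp if sid in path_set else fo
                abd_secs[sid] = _rep(sec, length=max(sec.length * fct, 1e-3))
                sections[sid] = abd_secs[sid]
            path_len = sum(abd_secs[s].length for s in path)
        cum = 0.0
        for sid in path:
            if cum + abd_secs[sid].length >= axon_d:
                axon_parent, axon_arc = sid, float(axon_d - cum)
                break
            cum += abd_secs[sid].length

    sections["axst"] = SectionNode("axst", AXON_START, axon_parent, axon_start_len,
                                   params.axon_diam, params.axon_diam, axon_arc)
    sections["ais"] = SectionNode("ais", AIS, "axst", ais_len,
                                  params.ais_diam, params.ais_diam)
    sections["axd"] = SectionNode("axd", AXON, "ais", params.distal_axon_length,
                                  params.axon_diam, params.axon_diam)

    m = NeuronMorphology(sections, soma_volume,
                         name=name or f"{params.stage}-synthetic")
    m = apply_taper(m, params.terminal_diam, params.axon_diam)
    m.meta["stage"] = params.stage
    m.validate()
    return m


def sample_population(params: StageParams, n: int, seed: int | np.random.Generator,
                      stratified: bool = True) -> list[NeuronMorphology]:
    """Draw a population of n synthetic neurons.

    With ``stratified`` (default) each drawn field uses Latin-hypercube-style
    stratified uniforms (one independent random permutation per field) and
    the somatic-axon flag is quota-sampled, so population-level sample
    moments concentrate tightly on the stage parameters — the generator's
    purpose is to emulate published population statistics.  Marginal
    per-neuron distributions are unchanged; set ``stratified=False`` for
    fully independent neurons.
    """
    if n < 1:
        raise ValueError("population size must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if not stratified:
        return [sample_neuron(params, rng, name=f"{params.stage}-{i:04d}")
                for i in range(n)]

    pre_rows: list[dict] = [{} for _ in range(n)]
    for fld in DRAWN_MORPH_FIELDS:
        u = (rng.permutation(n) + rng.random(n)) / n
        vals = draw_field(params.fields[fld], rng, u=u)
        for i in range(n):
            pre_rows[i][fld] = float(vals[i])
    n_somatic = int(round(params.p_somatic_axon * n))
    flags = np.zeros(n, dtype=bool)
    flags[rng.choice(n, size=n_somatic, replace=False)] = True
    for i in range(n):
        pre_rows[i]["somatic_axon"] = bool(flags[i])
    return [sample_neuron(params, rng, name=f"{params.stage}-{i:04d}",
                          presampled=pre_rows[i]) for i in range(n)]


def sample_feature_table(stages: dict[str, int], seed: int, params=None):
    """Feature table of morphological + electrophysiological parameters for a
    mixed developmental population.

    Morphological columns come from sampled synthetic morphologies;
    electrophysiological columns are drawn from the per-stage population
    distributions (the generator does not simulate every neuron).  Returns a
    pandas DataFrame with a ``stage`` column; ABD columns are NaN for
    somatic-axon neurons.
    """
    import pandas as pd

    from .morphology import summarize

    rng = np.random.default_rng(seed)
    rows = []
    for stage, n in stages.items():
        p = params[stage] if params else default_stage_params(stage)
        for i, m in enumerate(sample_population(p, n, rng)):
            s = summarize(m).as_dict()
            row = {c: s[c] for c in FEATURE_COLUMNS if c in s}
            for c in EPHYS_FIELDS:
                row[c] = float(draw_field(p.fields[c], rng))
            row["stage"] = stage
            row["neuron"] = f"{stage}-{i:04d}"
            rows.append(row)
    return pd.DataFrame(rows).set_index("neuron")
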