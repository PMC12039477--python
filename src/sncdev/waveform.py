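"""Action-potential waveform analysis.

Implements the spike-shape measurements used for somatic recordings of SNc
DA neurons: spike detection, spike-triggered averaging, threshold at the
20 mV/ms point of the first voltage derivative, threshold-to-peak amplitude,
half-width at 50% of that amplitude, and the decomposition of the rising
phase into initial-segment (IS) and somatodendritic (SD) components as the
first and second local maxima of the second time derivative.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "APMetrics",
    "FiringSummary",
    "detect_spikes",
    "average_ap",
    "ap_threshold",
    "ap_shape",
    "firing_summary",
    "initiation_site",
]

SLOPE_CRITERION = 20.0  # mV/ms, threshold definition


@dataclass
class APMetrics:
    threshold: float       # mV
    amplitude: float       # mV (threshold to peak)
    half_width: float      # ms
    is_peak: float         # mV·ms⁻²
    sd_peak: float         # mV·ms⁻²
    sd_is_ratio: float     # dimensionless

    def as_dict(self):
        return dict(self.__dict__)


@dataclass
class FiringSummary:
    mean_rate: float  # Hz
    isi_cv: float
    n_spikes: int


def detect_spikes(v: np.ndarray, dt: float, level: float = -20.0,
                  refractory: float = 2.0) -> np.ndarray:
    """Times (ms) of upward crossings of ``level`` separated by at least the
    refractory period."""
    v = np.asarray(v, float)
    if not np.all(np.isfinite(v)):
        raise ValueError("trace contains non-finite values")
    up = np.nonzero((v[:-1] < level) & (v[1:] >= level))[0]
    times = []
    last = -math.inf
    for i in up:
        # linear interpolation of the crossing instant
        t = (i + (level - v[i]) / (v[i + 1] - v[i])) * dt
        if t - last >= refractory:
            times.append(t)
            last = t
    return np.asarray(times)


def average_ap(v: np.ndarray, spike_times: np.ndarray, dt: float,
               window: tuple[float, float] = (-5.0, 10.0)) -> np.ndarray:
    """Spike-triggered average waveform aligned on the AP peak.

    ``window`` is (ms before, ms after) the peak; spikes whose windows
    overrun the trace are trimmed from the average with a warning.
    """
    v = np.asarray(v, float)
    if len(spike_times) < 1:
        raise ValueError("need at least one spike")
    wpre = int(round(-window[0] / dt))
    wpost = int(round(window[1] / dt))
    segs = []
    skipped = 0
    for t in spike_times:
        i = int(round(t / dt))
        # align on the local peak within ±2 ms of the crossing
        j0, j1 = max(i - int(2 / dt), 0), min(i + int(2 / dt) + 1, len(v))
        ipk = j0 + int(np.argmax(v[j0:j1]))
        if ipk - wpre < 0 or ipk + wpost + 1 > len(v):
            skipped += 1
            continue
        segs.append(v[ipk - wpre: ipk + wpost + 1])
    if skipped:
        warnings.warn(f"{skipped} spike(s) at the trace edge excluded from "
                      "the average")
    if not segs:
        raise ValueError("no spike fits the averaging window")
    return np.mean(segs, axis=0)


def _first_derivative(w: np.ndarray, dt: float) -> np.ndarray:
    return np.gradient(w, dt)


def ap_threshold(w: np.ndarray, dt: float,
                 slope: float = SLOPE_CRITERION) -> float:
    """Voltage at the first crossing of ``slope`` mV/ms before the peak.

    Returns NaN when the slope criterion is never reached.
    """
    w = np.asarray(w, float)
    dv = _first_derivative(w, dt)
    ipk = int(np.argmax(w))
    idx = np.nonzero((dv[:ipk] < slope) & (dv[1:ipk + 1] >= slope))[0]
    if len(idx) == 0:
        return math.nan
    i = idx[0]
    f = (slope - dv[i]) / (dv[i + 1] - dv[i])
    return float(w[i] + f * (w[i + 1] - w[i]))


def _local_maxima(x: np.ndarray) -> np.ndarray:
    return np.nonzero((x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:]))[0] + 1


def ap_shape(w: np.ndarray, dt: float, smooth_window: int = 0) -> APMetrics:
    """Shape metrics of a single averaged AP waveform.

    Amplitude is threshold-to-peak; half-width is measured at 50% of that
    amplitude.  IS and SD components are the first and second local maxima
    of d²V/dt² between threshold time and the AP peak (optionally
    Savitzky-Golay smoothed to suppress sampling noise); with fewer than two
    maxima the SD fields are NaN.
    """
    w = np.asarray(w, float)
    thr = ap_threshold(w, dt)
    if math.isnan(thr):
        raise ValueError("threshold undefined: slope criterion never reached")
    ipk = int(np.argmax(w))
    vpk = float(w[ipk])
    amplitude = vpk - thr

    half = thr + 0.5 * amplitude
    above = w >= half
    # crossing points around the peak, with sub-sample interpolation
    i_up = ipk
    while i_up > 0 and above[i_up - 1]:
        i_up -= 1
    i_dn = ipk
    while i_dn < len(w) - 1 and above[i_dn + 1]:
        i_dn += 1
    if i_up == 0 or i_dn == len(w) - 1:
        half_width = math.nan
    else:
        f_up = (half - w[i_up - 1]) / (w[i_up] - w[i_up - 1])
        t_up = (i_up - 1 + f_up) * dt
        f_dn = (half - w[i_dn]) / (w[i_dn + 1] - w[i_dn])
        t_dn = (i_dn + f_dn) * dt
        half_width = t_dn - t_up

    d2 = np.gradient(_first_derivative(w, dt), dt)
    if smooth_window and smooth_window >= 5:
        d2 = savgol_filter(d2, smooth_window | 1, 3)
    dv = _first_derivative(w, dt)
    idx_thr = np.nonzero(dv[:ipk] >= SLOPE_CRITERION)[0]
    # the IS acceleration peak can sit right at AP onset; open the search
    # window half a millisecond before the threshold crossing
    i0 = max(int(idx_thr[0]) - int(round(0.5 / dt)), 0) if len(idx_thr) else 0
    seg = d2[i0:ipk + 1]
    maxima = _local_maxima(seg)
    if len(maxima) >= 2:
        # the two largest maxima, in temporal order: first = IS, second = SD
        top2 = sorted(sorted(maxima, key=lambda i: seg[i])[-2:])
        is_peak, sd_peak = float(seg[top2[0]]), float(seg[top2[1]])
        ratio = sd_peak / is_peak
    elif len(maxima) == 1:
        is_peak, sd_peak, ratio = float(seg[maxima[0]]), math.nan, math.nan
    else:
        is_peak = sd_peak = ratio = math.nan
    return APMetrics(thr, amplitude, half_width, is_peak, sd_peak, ratio)


def firing_summary(spike_times: np.ndarray) -> FiringSummary:
    """Mean rate and ISI coefficient of variation (needs >= 3 spikes)."""
    st = np.asarray(spike_times, float)
    if len(st) < 3:
        raise ValueError("firing summary needs at least three spikes")
    isi = np.diff(st)
    rate = 1000.0 * (len(st) - 1) / (st[-1] - st[0])
    return FiringSummary(mean_rate=float(rate),
                         isi_cv=float(np.std(isi, ddof=1) / np.mean(isi)),
                         n_spikes=int(len(st)))


def _threshold_times(v: np.ndarray, dt: float, level: float) -> np.ndarray:
    up = np.nonzero((v[:-1] < level) & (v[1:] >= level))[0]
    return (up + (level - v[up]) / (v[up + 1] - v[up])) * dt


def initiation_site(v_ais: np.ndarray, v_soma: np.ndarray, dt: float,
                    level: float = -20.0) -> np.ndarray:
    """Per-spike lead time of the AIS relative to the soma (ms, positive =
    AIS crosses the detection level first)."""
    ta = _threshold_times(np.asarray(v_ais, float), dt, level)
    ts = _threshold_times(np.asarray(v_soma, float), dt, level)
    if len(ta) != len(ts):
        raise ValueError(f"mismatched spike counts: AIS {len(ta)} vs soma {len(ts)}")
    return ts - ta
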