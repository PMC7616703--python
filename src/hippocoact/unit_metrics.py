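"""Single-unit quality, cell-class, event-triggered and spatial metrics.

* waveform score: RMS of the mean waveform over its spike-to-spike s.d.,
  ``sqrt(sum_i (w_i / sigma_i)^2 / n)``; units are included when the
  score exceeds 0.75 and the fraction of inter-spike intervals < 2 ms
  stays below 2%.
* cell class: a 1-D, 2-component Gaussian mixture on trough-to-peak
  waveform widths; the intersection of the two component densities is
  the principal-cell / interneuron threshold (wide = principal).
* PETH: firing rate in 400 bins of 1 ms spanning +-200 ms around event
  peaks, z-scored over the window and smoothed with a 3-point moving
  average; a unit is activated when the smoothed z within +-20 ms of the
  peak exceeds 3 (suppressed analogously below -3).
* place maps on 1.4 x 1.4 cm bins, smoothed with a 2-D Gaussian of
  s.d. 1.2 bin widths, and Skaggs spatial information in bits/spike.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import EventSet, PositionTrack, SpikeTable

WAVEFORM_SCORE_MIN = 0.75
ISI_VIOLATION_MS = 2.0
ISI_VIOLATION_MAX_FRACTION = 0.02
PETH_WINDOW_MS = 200.0
PETH_BIN_MS = 1.0
PETH_N_BINS = 400
ACTIVATION_Z = 3.0
ACTIVATION_PEAK_WINDOW_MS = 20.0
PLACE_BIN_CM = 1.4
PLACE_SMOOTH_SD_BINS = 1.2
FIXED_WIDTH_THRESHOLD_MS = 0.425


# ----------------------------------------------------------------------
# waveform quality and cell class
# ----------------------------------------------------------------------

@dataclass
class WaveformTemplate:
    """Mean spike waveform (uV) with per-sample s.d. across spikes."""

    w: np.ndarray
    sigma: np.ndarray
    trough_to_peak_ms: float = float("nan")

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, float)
        self.sigma = np.asarray(self.sigma, float)
        if self.w.shape != self.sigma.shape:
            raise ValueError("w and sigma must share length")

    @property
    def n(self) -> int:
        return len(self.w)


def waveform_score(tpl: WaveformTemplate) -> float:
    """RMS of the per-sample mean-to-s.d. ratio, sqrt(sum (w/sigma)^2 / n)."""
    if np.any(tpl.sigma <= 0):
        raise ValueError("sigma must be strictly positive everywhere")
    return float(np.sqrt(np.mean((tpl.w / tpl.sigma) ** 2)))


def isi_violation_fraction(spike_times: np.ndarray, threshold_ms: float = ISI_VIOLATION_MS) -> float:
    """Fraction of inter-spike intervals strictly below ``threshold_ms``."""
    t = np.sort(np.asarray(spike_times, float))
    if len(t) < 2:
        return 0.0
    isi_ms = np.diff(t) * 1000.0
    return float(np.mean(isi_ms < threshold_ms))


def unit_passes_inclusion(tpl: WaveformTemplate, spike_times: np.ndarray) -> bool:
    return (
        waveform_score(tpl) > WAVEFORM_SCORE_MIN
        and isi_violation_fraction(spike_times) < ISI_VIOLATION_MAX_FRACTION
    )


def gmm_intersection(means: np.ndarray, sds: np.ndarray, weights: np.ndarray,
                     grid_step_ms: float = 1e-3) -> float:
    """Crossing point of two weighted Gaussian densities, by grid scan.

    The scan covers the interval between the two means at ``grid_step_ms``
    resolution and returns the grid point where the dominant component
    flips.
    """
    lo, hi = np.sort(means)
    if hi - lo < grid_step_ms:
        return float((lo + hi) / 2)
    grid = np.arange(lo, hi, grid_step_ms)
    from scipy.stats import norm

    d0 = weights[0] * norm.pdf(grid, means[0], sds[0])
    d1 = weights[1] * norm.pdf(grid, means[1], sds[1])
    lower = int(np.argmin(means))
    dominant_lower = (d0 > d1) if lower == 0 else (d1 > d0)
    flips = np.flatnonzero(dominant_lower[:-1] & ~dominant_lower[1:])
    if len(flips) == 0:
        return float((lo + hi) / 2)
    return float(grid[flips[0]])


def classify_cell_types(
    trough_to_peak_ms: np.ndarray,
    seed: int = 0,
    fallback_fixed_threshold: bool = False,
) -> tuple[np.ndarray, float]:
    """Split units into principal cells (wide) and interneurons (narrow).

    Fits a 1-D 2-component Gaussian mixture to the trough-to-peak widths
    and thresholds where the two component densities intersect; widths
    above the threshold are principal cells.  On unimodal input the
    mixture is degenerate: a warning is raised and, with
    ``fallback_fixed_threshold``, the fixed 0.425 ms threshold is used.
    """
    from sklearn.mixture import GaussianMixture

    x = np.asarray(trough_to_peak_ms, float).reshape(-1, 1)
    if len(x) < 2 or np.ptp(x) == 0:
        warnings.warn("degenerate width distribution; all units one class")
        thr = FIXED_WIDTH_THRESHOLD_MS
        labels = np.where(x[:, 0] > thr, "principal", "interneuron")
        return labels, thr
    gmm = GaussianMixture(n_components=2, n_init=10, random_state=seed).fit(x)
    means = gmm.means_[:, 0]
    sds = np.sqrt(gmm.covariances_.reshape(2))
    sep = abs(means[0] - means[1]) / max(sds.mean(), 1e-12)
    if sep < 1.0:
        warnings.warn("width distribution looks unimodal; mixture components overlap")
        if fallback_fixed_threshold:
            thr = FIXED_WIDTH_THRESHOLD_MS
            return np.where(x[:, 0] > thr, "principal", "interneuron"), thr
    thr = gmm_intersection(means, sds, gmm.weights_)
    labels = np.where(x[:, 0] > thr, "principal", "interneuron")
    return labels, thr


# ----------------------------------------------------------------------
# peri-event time histograms
# ----------------------------------------------------------------------

@dataclass
class Peth:
    """Event-aligned firing rate: 400 bins of 1 ms spanning +-200 ms."""

    rates: np.ndarray  # Hz per bin, averaged over events
    z: np.ndarray  # z-scored then 3-point smoothed
    n_events: int
    zero_variance: bool = False
    bin_ms: float = PETH_BIN_MS

    @property
    def bin_centers_ms(self) -> np.ndarray:
        n = len(self.rates)
        return (np.arange(n) - n / 2 + 0.5) * self.bin_ms


def _smooth3(z: np.ndarray) -> np.ndarray:
    """3-point moving average with reflective edge padding."""
    padded = np.concatenate(([z[0]], z, [z[-1]]))
    return np.convolve(padded, np.ones(3) / 3, mode="valid")


def compute_peth(
    spike_times: np.ndarray,
    event_peaks: np.ndarray,
    window_ms: float = PETH_WINDOW_MS,
    bin_ms: float = PETH_BIN_MS,
) -> Peth:
    """PETH of one unit around event peaks (co-occurring events excluded upstream)."""
    event_peaks = np.asarray(event_peaks, float)
    if len(event_peaks) == 0:
        raise ValueError("need at least one event")
    spikes = np.sort(np.asarray(spike_times, float))
    n_bins = int(round(2 * window_ms / bin_ms))
    edges_s = (np.arange(n_bins + 1) * bin_ms - window_ms) / 1000.0
    counts = np.zeros(n_bins)
    for t in event_peaks:
        rel = spikes[np.searchsorted(spikes, t + edges_s[0]): np.searchsorted(spikes, t + edges_s[-1])] - t
        counts += np.histogram(rel, bins=edges_s)[0]
    rates = counts / len(event_peaks) / (bin_ms / 1000.0)
    s = rates.std()
    if s == 0:
        z = np.zeros(n_bins)
        return Peth(rates, z, len(event_peaks), zero_variance=True, bin_ms=bin_ms)
    z = _smooth3((rates - rates.mean()) / s)
    return Peth(rates, z, len(event_peaks), bin_ms=bin_ms)


def classify_activation(
    peth: Peth,
    threshold_z: float = ACTIVATION_Z,
    peak_window_ms: float = ACTIVATION_PEAK_WINDOW_MS,
    sweep: np.ndarray | None = None,
) -> tuple[str, dict[float, str]]:
    """Activated / suppressed / none, with a threshold sweep.

    A unit is activated when the maximum smoothed z within +-20 ms of the
    event peak exceeds the threshold (baseline is the mean rate over the
    400 ms window, absorbed by the z-scoring); suppressed when the
    minimum falls below the negated threshold.  The sweep reports the
    call at each threshold in (2, 4).
    """
    centers = peth.bin_centers_ms
    near = np.abs(centers) <= peak_window_ms
    zmax = float(peth.z[near].max())
    zmin = float(peth.z[near].min())

    def call(th: float) -> str:
        if zmax > th:
            return "activated"
        if zmin < -th:
            return "suppressed"
        return "none"

    if sweep is None:
        sweep = np.arange(2.0, 4.01, 0.25)
    return call(threshold_z), {float(th): call(th) for th in sweep}


# ----------------------------------------------------------------------
# place maps and spatial information
# ----------------------------------------------------------------------

@dataclass
class PlaceMap:
    """Smoothed 2-D rate map on 1.4 cm bins with occupancy probabilities."""

    rate: np.ndarray  # Hz, masked (nan) where unvisited
    occupancy_p: np.ndarray  # probability over visited bins, sums to 1
    spike_counts: np.ndarray
    visited: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.visited is None:
            self.visited = ~np.isnan(self.rate)


def _gaussian_smooth_masked(img: np.ndarray, mask: np.ndarray, sd_bins: float) -> np.ndarray:
    """Gaussian smoothing with truncated-kernel renormalization at edges
    and unvisited bins (convolve data and mask, then divide)."""
    from scipy.ndimage import gaussian_filter

    data = np.where(mask, img, 0.0)
    num = gaussian_filter(data, sd_bins, mode="constant")
    den = gaussian_filter(mask.astype(float), sd_bins, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def compute_place_map(
    spike_times: np.ndarray,
    track: PositionTrack,
    bin_cm: float = PLACE_BIN_CM,
    smooth_sd_bins: float = PLACE_SMOOTH_SD_BINS,
) -> PlaceMap:
    """Spike-count and occupancy maps -> smoothed rate map.

    Both maps are smoothed with the same 2-D Gaussian (s.d. 1.2 bin
    widths) before division; unvisited bins stay masked (nan), never
    infinite.  Spike positions are linearly interpolated on the track.
    """
    nx = int(np.ceil(track.arena_cm[0] / bin_cm))
    ny = int(np.ceil(track.arena_cm[1] / bin_cm))
    dt = np.median(np.diff(track.t)) if len(track.t) > 1 else 0.0
    occ, _, _ = np.histogram2d(
        track.x, track.y, bins=[nx, ny], range=[[0, nx * bin_cm], [0, ny * bin_cm]]
    )
    occ *= dt
    spike_times = np.asarray(spike_times, float)
    inside = (spike_times >= track.t[0]) & (spike_times <= track.t[-1])
    sx = np.interp(spike_times[inside], track.t, track.x)
    sy = np.interp(spike_times[inside], track.t, track.y)
    cnt, _, _ = np.histogram2d(sx, sy, bins=[nx, ny], range=[[0, nx * bin_cm], [0, ny * bin_cm]])
    visited = occ > 0
    s_occ = _gaussian_smooth_masked(occ, visited, smooth_sd_bins)
    s_cnt = _gaussian_smooth_masked(cnt, visited, smooth_sd_bins)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = s_cnt / s_occ
    rate[~visited] = np.nan
    p = np.where(visited, occ, 0.0)
    p = p / p.sum() if p.sum() > 0 else p
    return PlaceMap(rate, p, cnt, visited)


def spatial_information(pmap: PlaceMap) -> float:
    """Skaggs information per spike: sum_i p_i (li/l) log2(li/l) over visited bins."""
    p = pmap.occupancy_p[pmap.visited]
    lam_i = pmap.rate[pmap.visited]
    lam = float(np.sum(p * lam_i))
    if lam <= 0:
        warnings.warn("mean rate is zero; spatial information undefined, returning 0")
        return 0.0
    ratio = lam_i / lam
    pos = ratio > 0
    return float(np.sum(p[pos] * ratio[pos] * np.log2(ratio[pos])))


def unit_metrics_table(
    table: SpikeTable,
    templates: dict[int, WaveformTemplate],
    events: EventSet | None = None,
):
    """Per-unit summary: score, ISI violations, inclusion, activation call."""
    import pandas as pd

    rows = []
    for u in table.unit_ids:
        tpl = templates.get(u)
        spikes = table.times(u)
        score = waveform_score(tpl) if tpl is not None else np.nan
        viol = isi_violation_fraction(spikes)
        included = tpl is not None and unit_passes_inclusion(tpl, spikes)
        call = ""
        if events is not None and len(events) and len(spikes):
            call = classify_activation(compute_peth(spikes, events.peak_times))[0]
        rows.append((u, score, viol, included, call))
    return pd.DataFrame(
        rows, columns=["unit_id", "waveform_score", "isi_violation", "included", "activation"]
    ).set_index("unit_id")
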