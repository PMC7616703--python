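"""LFP preprocessing and offline event detection.

Implements the three offline detectors used throughout the pipeline:

* dentate spikes (DS): 1-200 Hz band-passed granule-cell-layer LFP,
  peaks above 6x the median absolute value of the filtered trace, one
  event per 50 ms frame (largest peak kept);
* sharp-wave ripples (SWR): common-average-referenced pyramidal-layer
  LFP band-passed 80-250 Hz, Hilbert envelope peaks above 5x the median
  envelope, with three acceptance criteria (ripple power >= 2x the
  reference, >= 4 ripple cycles, ripple power >= 2x the 200-500 Hz band);
* theta cycles: peak-trough-peak triplets on an oscillatory theta
  component (masked empirical-mode sifting, band-pass fallback) with
  half-cycle intervals in [31, 100] ms and peak-to-peak in [71, 200] ms.

All thresholds are median-relative, so detection is invariant to global
gain rescaling.  Filtering is zero-phase (forward-backward) throughout:
offline latency is not at issue and phase distortion would bias peak
times.  Equal-amplitude peaks inside a merge window tie-break to the
earlier peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import interpolate, signal

from .core import EVENT_COLUMNS, EventSet, LaminarLfp

DS_BAND_HZ = (1.0, 200.0)
DS_THRESHOLD_MAD = 6.0
DS_MERGE_WINDOW_S = 0.050
RIPPLE_BAND_HZ = (80.0, 250.0)
SUPRA_RIPPLE_BAND_HZ = (200.0, 500.0)
SWR_THRESHOLD_MED_ENV = 5.0
SWR_MIN_CYCLES = 4
THETA_HALF_CYCLE_MS = (31.0, 100.0)
THETA_PEAK_TO_PEAK_MS = (71.0, 200.0)


# ----------------------------------------------------------------------
# preprocessing
# ----------------------------------------------------------------------

def decimate_lfp(raw: LaminarLfp, target_fs_hz: float = 1250.0) -> LaminarLfp:
    """Anti-alias filter (8th-order Chebyshev type I) and resample.

    The decimation factor is split into stages of at most 8 (large
    single-stage IIR decimation is numerically fragile); each stage uses
    ``scipy.signal.decimate`` with its Chebyshev-I anti-aliasing filter,
    zero-phase.  20 kHz input lands exactly on 1250 Hz (factor 16).
    """
    if target_fs_hz > raw.fs_hz / 2:
        raise ValueError("target rate above Nyquist of input")
    q_total = raw.fs_hz / target_fs_hz
    q = int(round(q_total))
    if abs(q_total - q) > 1e-9:
        raise ValueError("sampling-rate ratio must be an integer")
    x = raw.samples
    remaining = q
    while remaining > 1:
        stage = 0
        for cand in (8, 7, 6, 5, 4, 3, 2):
            if remaining % cand == 0:
                stage = cand
                break
        if stage == 0:
            stage = remaining
        # scipy's 'iir' decimator is the 8th-order Chebyshev type I filter
        x = signal.decimate(x, stage, ftype="iir", zero_phase=True, axis=-1)
        remaining //= stage
    return LaminarLfp(x, target_fs_hz, list(raw.layer_map), raw.t0)


def bandpass(x: np.ndarray, fs_hz: float, lo: float, hi: float, order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    hi = min(hi, 0.99 * fs_hz / 2)
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs_hz, output="sos")
    return signal.sosfiltfilt(sos, x, axis=-1)


def _merge_peaks(peak_idx: np.ndarray, amplitudes: np.ndarray, merge_samples: int) -> np.ndarray:
    """Within any merge frame keep only the largest peak (ties: earlier).

    Greedy by descending amplitude with stable (earlier-first) ordering,
    suppressing peaks within ``merge_samples`` of an already kept peak.
    """
    order = np.lexsort((peak_idx, -amplitudes))  # amp desc, then index asc
    kept: list[int] = []
    for k in order:
        i = peak_idx[k]
        if all(abs(i - peak_idx[j]) > merge_samples for j in kept):
            kept.append(k)
    return np.sort(peak_idx[kept]).astype(int)


def _edges_at_level(x: np.ndarray, peak: int, level: float) -> tuple[int, int]:
    """First crossings below ``level`` on each side of ``peak``."""
    i = peak
    while i > 0 and x[i] > level:
        i -= 1
    j = peak
    while j < len(x) - 1 and x[j] > level:
        j += 1
    return i, j


# ----------------------------------------------------------------------
# dentate spikes
# ----------------------------------------------------------------------

def detect_dentate_spikes(
    lfp: LaminarLfp,
    channel: int | list[int] | None = None,
    reference_channel: int | None = None,
) -> EventSet:
    """Detect DS events on the granule-cell-layer LFP.

    ``channel`` defaults to all channels labeled ``gcl``.  With several
    candidate channels, detection runs on each and the channel with the
    largest mean DS amplitude supplies the event timestamps.  If
    ``reference_channel`` is given (typically an oriens channel on
    laminar probes) it is subtracted before filtering.
    """
    if channel is None:
        channels = list(lfp.channels_in_layer("gcl"))
        if not channels:
            raise ValueError("no channel labeled gcl; pass channel explicitly")
    else:
        channels = [channel] if np.isscalar(channel) else list(channel)
    for c in channels:
        if not 0 <= c < lfp.n_channels:
            raise ValueError(f"channel index {c} out of range")

    fs = lfp.fs_hz
    merge = int(round(DS_MERGE_WINDOW_S * fs))
    best: pd.DataFrame | None = None
    best_mean_amp = -np.inf
    best_channel = channels[0]
    for c in channels:
        x = lfp.samples[c].astype(float)
        if reference_channel is not None:
            x = x - lfp.samples[reference_channel]
        filt = bandpass(x, fs, *DS_BAND_HZ)
        mad = np.median(np.abs(filt))
        thr = DS_THRESHOLD_MAD * mad
        peaks, _ = signal.find_peaks(filt, height=thr)
        if len(peaks) == 0:
            df = pd.DataFrame(columns=EVENT_COLUMNS)
            mean_amp = -np.inf
        else:
            peaks = _merge_peaks(peaks, filt[peaks], merge)
            rows = []
            for p in peaks:
                i0, i1 = _edges_at_level(filt, p, thr / 2)
                rows.append(("DS", lfp.t0 + p / fs, lfp.t0 + i0 / fs, lfp.t0 + i1 / fs, c, filt[p]))
            df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
            mean_amp = float(df["peak_amplitude"].mean())
        if mean_amp > best_mean_amp or best is None:
            best, best_mean_amp, best_channel = df, mean_amp, c

    prov = {
        "detector": "detect_dentate_spikes",
        "band_hz": DS_BAND_HZ,
        "threshold": f"{DS_THRESHOLD_MAD} x median absolute value",
        "merge_window_s": DS_MERGE_WINDOW_S,
        "channel": int(best_channel),
    }
    return EventSet(best, prov)


# ----------------------------------------------------------------------
# sharp-wave ripples
# ----------------------------------------------------------------------

def _band_power(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    return float(np.mean(bandpass(x, fs, *band) ** 2)) if len(x) > 30 else 0.0


def count_ripple_cycles(ripple_filtered: np.ndarray) -> int:
    """Ripple cycles = positive-going zero crossings of the band-passed trace."""
    s = np.signbit(ripple_filtered)
    return int(np.sum(s[:-1] & ~s[1:]))


def detect_swr(lfp: LaminarLfp, pyr_channels: list[int] | None = None) -> EventSet:
    """Detect SWR events on common-average-referenced pyramidal channels.

    Candidates are ripple-band envelope peaks above 5x the channel's
    median envelope; onset/offset where the envelope decays below half
    the detection threshold.  A candidate becomes an SWR only if
    (i) its ripple-band power is >= 2x that of the common average over
    the same window, (ii) it spans >= 4 ripple cycles, and (iii) its
    ripple-band power is >= 2x its 200-500 Hz power.  Events are taken
    from the channel with the largest mean ripple envelope amplitude.
    """
    if lfp.n_channels < 2:
        raise ValueError("need at least 2 channels for a common average reference")
    if pyr_channels is None:
        pyr_channels = list(lfp.channels_in_layer("pyr"))
        if not pyr_channels:
            raise ValueError("no channel labeled pyr; pass pyr_channels explicitly")

    fs = lfp.fs_hz
    car = lfp.samples.mean(axis=0)
    best: pd.DataFrame | None = None
    best_mean_env = -np.inf
    best_channel = pyr_channels[0]
    for c in pyr_channels:
        x = lfp.samples[c] - car
        rip = bandpass(x, fs, *RIPPLE_BAND_HZ)
        env = np.abs(signal.hilbert(rip))
        thr = SWR_THRESHOLD_MED_ENV * np.median(env)
        peaks, _ = signal.find_peaks(env, height=thr)
        rows = []
        last_offset = -np.inf
        for p in peaks:
            i0, i1 = _edges_at_level(env, p, thr / 2)
            if i0 < last_offset:  # same envelope excursion as previous event
                continue
            seg = rip[i0:i1]
            raw_seg = x[i0:i1]
            car_seg = car[i0:i1]
            if len(seg) < 8:
                continue
            p_rip = float(np.mean(seg**2))
            p_ref = _band_power(car_seg, fs, RIPPLE_BAND_HZ)
            p_supra = _band_power(raw_seg, fs, SUPRA_RIPPLE_BAND_HZ)
            if p_rip < 2.0 * p_ref:
                continue
            if count_ripple_cycles(seg) < SWR_MIN_CYCLES:
                continue
            if p_supra > 0 and p_rip < 2.0 * p_supra:
                continue
            pk = i0 + int(np.argmax(env[i0:i1]))
            rows.append(("SWR", lfp.t0 + pk / fs, lfp.t0 + i0 / fs, lfp.t0 + i1 / fs, c, env[pk]))
            last_offset = i1
        df = pd.DataFrame(rows, columns=EVENT_COLUMNS)
        mean_env = float(df["peak_amplitude"].mean()) if len(df) else -np.inf
        if mean_env > best_mean_env or best is None:
            best, best_mean_env, best_channel = df, mean_env, c

    prov = {
        "detector": "detect_swr",
        "band_hz": RIPPLE_BAND_HZ,
        "threshold": f"{SWR_THRESHOLD_MED_ENV} x median envelope",
        "min_cycles": SWR_MIN_CYCLES,
        "channel": int(best_channel),
    }
    return EventSet(best, prov)


# ----------------------------------------------------------------------
# DS / SWR co-occurrence exclusion
# ----------------------------------------------------------------------

def exclude_cooccurring(
    ds: EventSet, swr: EventSet, window_ms: float = 50.0
) -> tuple[EventSet, EventSet, float]:
    """Remove DS and SWR events whose peaks fall within +-window of each other.

    Returns the filtered sets and the co-occurrence rate (pairs per second
    of the spanned recording) before removal.
    """
    w = window_ms / 1000.0
    ds_t = ds.peak_times
    swr_t = swr.peak_times
    if len(ds_t) == 0 or len(swr_t) == 0:
        return ds, swr, 0.0
    idx = np.searchsorted(swr_t, ds_t)
    near_ds = np.zeros(len(ds_t), bool)
    for k, (t, i) in enumerate(zip(ds_t, idx)):
        for j in (i - 1, i):
            if 0 <= j < len(swr_t) and abs(t - swr_t[j]) <= w:
                near_ds[k] = True
    idx = np.searchsorted(ds_t, swr_t)
    near_swr = np.zeros(len(swr_t), bool)
    for k, (t, i) in enumerate(zip(swr_t, idx)):
        for j in (i - 1, i):
            if 0 <= j < len(ds_t) and abs(t - ds_t[j]) <= w:
                near_swr[k] = True
    span = max(ds_t.max(), swr_t.max()) - min(ds_t.min(), swr_t.min())
    co_rate = float(near_ds.sum()) / span if span > 0 else 0.0
    ds_out = EventSet(ds.events[~near_ds].reset_index(drop=True), dict(ds.provenance))
    swr_out = EventSet(swr.events[~near_swr].reset_index(drop=True), dict(swr.provenance))
    return ds_out, swr_out, co_rate


# ----------------------------------------------------------------------
# theta cycles
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ThetaCycle:
    """One peak-trough-peak theta cycle (times in seconds)."""

    peak1_t: float
    trough_t: float
    peak2_t: float

    def __post_init__(self) -> None:
        if not self.peak1_t < self.trough_t < self.peak2_t:
            raise ValueError("cycle must be ordered peak1 < trough < peak2")


def _spline_envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through extrema, with edge padding."""
    n = len(x)
    pts_i = np.concatenate(([0], idx, [n - 1]))
    pts_v = np.concatenate(([x[idx[0]]], x[idx], [x[idx[-1]]]))
    uniq = np.unique(pts_i, return_index=True)[1]
    spline = interpolate.CubicSpline(pts_i[uniq], pts_v[uniq])
    return spline(np.arange(n))


def _sift(x: np.ndarray, max_iter: int = 12) -> np.ndarray:
    """One empirical-mode sift: iteratively remove the mean envelope."""
    h = x.copy()
    for _ in range(max_iter):
        maxima, _ = signal.find_peaks(h)
        minima, _ = signal.find_peaks(-h)
        if len(maxima) < 2 or len(minima) < 2:
            break
        mean_env = 0.5 * (_spline_envelope(h, maxima) + _spline_envelope(h, minima))
        if np.max(np.abs(mean_env)) < 1e-10 * max(np.max(np.abs(h)), 1e-30):
            break
        h = h - mean_env
    return h


def masked_sift(x: np.ndarray, fs_hz: float, mask_freq_hz: float, n_phases: int = 4) -> np.ndarray:
    """One intrinsic mode function via masked sifting.

    A cosine mask at ``mask_freq_hz`` (amplitude 2x the residual s.d.)
    is added before sifting and subtracted after, averaged over
    ``n_phases`` mask phases; the mask prevents mode mixing by forcing
    components slower than the mask frequency out of the extracted IMF.
    """
    n = len(x)
    t = np.arange(n) / fs_hz
    amp = 2.0 * np.std(x)
    if amp == 0:
        return np.zeros(n)
    imfs = []
    for k in range(n_phases):
        mask = amp * np.cos(2 * np.pi * mask_freq_hz * t + 2 * np.pi * k / n_phases)
        imfs.append(_sift(x + mask) - mask)
    return np.mean(imfs, axis=0)


def _zero_crossing_freq(x: np.ndarray, fs_hz: float) -> float:
    """Dominant frequency as positive-going zero crossings per second."""
    s = np.signbit(x)
    return float(np.sum(s[:-1] & ~s[1:])) * fs_hz / max(len(x), 1)


def theta_component(
    x: np.ndarray,
    fs_hz: float,
    theta_band_hz: tuple[float, float] = (5.0, 12.0),
    n_phases: int = 4,
) -> np.ndarray:
    """Oscillatory theta component by masked empirical-mode decomposition.

    IMFs are extracted with a dyadic ladder of mask frequencies
    (fs/4, fs/8, ... down past the theta band); the theta component is
    the sum of IMFs whose zero-crossing frequency falls inside
    ``theta_band_hz``.  Returns zeros when no IMF is theta-rhythmic
    (aperiodic input).
    """
    residual = np.asarray(x, dtype=float).copy()
    theta = np.zeros_like(residual)
    mask_f = fs_hz / 4.0
    while mask_f > theta_band_hz[0] / 2.0:
        imf = masked_sift(residual, fs_hz, mask_f, n_phases)
        residual = residual - imf
        f = _zero_crossing_freq(imf, fs_hz)
        if theta_band_hz[0] <= f <= theta_band_hz[1]:
            theta += imf
        mask_f /= 2.0
    return theta


def detect_theta_cycles(
    x: np.ndarray,
    fs_hz: float,
    method: str = "masked_sift",
    t0: float = 0.0,
) -> list[ThetaCycle]:
    """Delineate individual theta cycles as peak-trough-peak triplets.

    The oscillatory theta component is extracted either by masked
    empirical-mode sifting (default) or a 5-12 Hz zero-phase band-pass
    (``method='bandpass'``); the cycle-acceptance rules are identical.
    A triplet is accepted iff both half-cycle intervals lie in
    [31, 100] ms and the peak-to-peak distance in [71, 200] ms.
    """
    x = np.asarray(x, dtype=float)
    if method == "masked_sift":
        theta = theta_component(x, fs_hz)
    elif method == "bandpass":
        theta = bandpass(x, fs_hz, 5.0, 12.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    # a component carrying < 0.25% of the signal power is filter/sift
    # residue, not a theta rhythm: aperiodic input gives the empty list
    if np.sqrt(np.mean(theta**2)) < 0.05 * max(np.sqrt(np.mean(x**2)), 1e-30):
        return []
    peaks, _ = signal.find_peaks(theta)
    troughs, _ = signal.find_peaks(-theta)
    if len(peaks) < 2 or len(troughs) < 1:
        return []
    half_lo, half_hi = (v / 1000.0 for v in THETA_HALF_CYCLE_MS)
    p2p_lo, p2p_hi = (v / 1000.0 for v in THETA_PEAK_TO_PEAK_MS)
    cycles = []
    for p1, p2 in zip(peaks, peaks[1:]):
        inner = troughs[(troughs > p1) & (troughs < p2)]
        if len(inner) != 1:
            continue
        tr = inner[0]
        t_p1, t_tr, t_p2 = (t0 + i / fs_hz for i in (p1, tr, p2))
        if not (half_lo <= t_tr - t_p1 <= half_hi):
            continue
        if not (half_lo <= t_p2 - t_tr <= half_hi):
            continue
        if not (p2p_lo <= t_p2 - t_p1 <= p2p_hi):
            continue
        cycles.append(ThetaCycle(t_p1, t_tr, t_p2))
    return cycles


def theta_cycles_to_windows(cycles: list[ThetaCycle]) -> list[tuple[float, float]]:
    """Half-open [peak1, peak2) windows, the coactivity time base in waking."""
    return [(c.peak1_t, c.peak2_t) for c in cycles]
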