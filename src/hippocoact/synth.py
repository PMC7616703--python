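"""Synthetic laminar recording sessions with a full ground-truth ledger.

A session is a pre-sleep / exploration / post-sleep triplet of segments.
Sleep segments carry dentate spikes (DS) and sharp-wave ripples (SWR)
planted on a 1/f background; the exploration segment carries ~8 Hz theta.
Spike trains are inhomogeneous Poisson with event-locked multiplicative
gains per (region x event type), optional Gaussian place fields, and
pairwise couplings planted through a shared Bernoulli latent per event
window.  Every planted parameter is recorded in a :class:`GroundTruthLedger`
so downstream detection, typing and coactivity stages can be scored
against truth.

Amplitudes are expressed in the detector's own units: the background is
scaled so the median absolute value (MAD) of each channel is ~1, and
``event_amp`` is the planted granule-layer DS peak (or pyramidal-layer
ripple envelope peak) in multiples of that MAD.

The DS laminar profile is planted in current-source-density (CSD) space -
a Gaussian sink at the per-type molecular-layer depth with two flanking
sources - and converted to an LFP depth profile by solving the discrete
Poisson equation, so the second spatial difference recovers the planted
sink exactly.  A linear depth ramp (zero second difference, hence
invisible to CSD) carries the granule-layer detection amplitude.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import EVENT_COLUMNS, EventSet, LaminarLfp, PositionTrack, SpikeTable, default_layer_map

MAX_EVENT_DURATION_S = 0.050
#: minimum spacing imposed between planted event peaks (any type)
MIN_EVENT_SPACING_S = 0.150


# ----------------------------------------------------------------------
# configuration
# ----------------------------------------------------------------------

def _default_gains() -> dict:
    # Multiplicative firing-rate gains per (region, event type).  DG is
    # driven hardest by DS (DS2 > DS1); CA regions are driven hardest by
    # SWR; all regions respond to both event families.
    return {
        "DG": {"DS1": 3.0, "DS2": 6.0, "SWR": 2.0, "THETA": 1.5},
        "CA3": {"DS1": 1.5, "DS2": 2.5, "SWR": 5.0, "THETA": 1.5},
        "CA1": {"DS1": 1.5, "DS2": 2.5, "SWR": 6.0, "THETA": 1.5},
    }


@dataclass
class SynthConfig:
    """All knobs of the synthetic session generator.

    Durations are seconds; rates Hz.  ``event_amp`` is the planted event
    amplitude in multiples of the background median absolute value (the
    detectors threshold at 6x MAD for DS and 5x the median envelope for
    SWR, so ``event_amp=8`` sits comfortably above threshold).
    """

    pre_sleep_s: float = 600.0
    exploration_s: float = 0.0
    post_sleep_s: float = 0.0
    fs_hz: float = 1250.0
    n_channels: int = 64
    layer_map: list[str] | None = None
    ds_rate_hz: float = 0.40
    swr_rate_hz: float = 0.75
    ds1_fraction: float = 0.35
    event_amp: float = 8.0
    ripple_freq_hz: float = 150.0
    theta_freq_hz: float = 8.0
    theta_amp: float = 3.0
    n_units: dict = field(default_factory=lambda: {"DG": 12, "CA3": 6, "CA1": 10})
    interneuron_fraction: float = 0.15
    base_rate_hz: dict = field(default_factory=lambda: {"principal": 1.2, "interneuron": 8.0})
    gains: dict = field(default_factory=_default_gains)
    coupling_spec: list = field(default_factory=list)  # (unit_i, unit_j, condition, weight)
    coupling_burst_rate: float = 3.0  # extra synchronous spikes per coupled window
    reactivation_gain: float = 0.0  # carries theta couplings into post-sleep events
    place_field_fraction: float = 0.5
    place_field_sd_cm: float = 5.0
    place_field_peak_hz: float = 15.0
    arena_cm: tuple = (41.0, 41.0)
    tracking_hz: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.pre_sleep_s + self.post_sleep_s, 1.0) <= 0 and self.exploration_s <= 0:
            raise ValueError("session must have positive duration")
        for name in ("ds_rate_hz", "swr_rate_hz", "fs_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.ds1_fraction <= 1.0:
            raise ValueError("ds1_fraction must lie in [0, 1]")
        max_rate = 1.0 / (2.0 * MAX_EVENT_DURATION_S)
        if self.ds_rate_hz + self.swr_rate_hz >= max_rate:
            raise ValueError(
                "event rates too high: mean inter-event interval shorter than "
                "twice the maximum event duration"
            )
        if self.layer_map is None:
            self.layer_map = default_layer_map(self.n_channels)
        if len(self.layer_map) != self.n_channels:
            raise ValueError("layer_map length must equal n_channels")

    @property
    def segments(self) -> list[tuple[str, float, float]]:
        """Non-overlapping (name, start, end) triplet in session order."""
        segs, t = [], 0.0
        for name, dur in (
            ("pre_sleep", self.pre_sleep_s),
            ("exploration", self.exploration_s),
            ("post_sleep", self.post_sleep_s),
        ):
            if dur > 0:
                segs.append((name, t, t + dur))
                t += dur
        for (_, a0, a1), (_, b0, b1) in zip(segs, segs[1:]):
            if b0 < a1:
                raise ValueError("overlapping segment definitions")
        return segs

    @property
    def duration_s(self) -> float:
        return self.segments[-1][2]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SynthConfig":
        data = yaml.safe_load(Path(path).read_text())
        if "arena_cm" in data:
            data["arena_cm"] = tuple(data["arena_cm"])
        if "coupling_spec" in data:
            data["coupling_spec"] = [tuple(c) for c in data["coupling_spec"]]
        return cls(**data)


@dataclass
class GroundTruthLedger:
    """Every planted parameter of one synthetic session."""

    events: pd.DataFrame  # t, type, duration_s, sink_channel, amp, segment
    units: pd.DataFrame  # unit_id, region, cell_class, base_rate_hz, pf_x, pf_y
    gains: dict
    couplings: list  # (unit_i, unit_j, condition, weight)
    segments: list
    seed: int

    def __post_init__(self) -> None:
        dur = max(end for _, _, end in self.segments) if self.segments else 0.0
        if len(self.events) and not (
            (self.events["t"] >= 0).all() and (self.events["t"] <= dur).all()
        ):
            raise ValueError("planted events must lie inside the session")

    def events_of_type(self, *types: str) -> pd.DataFrame:
        return self.events[self.events["type"].isin(types)]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "events": self.events.to_dict(orient="list"),
            "units": self.units.to_dict(orient="list"),
            "gains": self.gains,
            "couplings": [list(c) for c in self.couplings],
            "segments": [list(s) for s in self.segments],
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "GroundTruthLedger":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(
            events=pd.DataFrame(payload["events"]),
            units=pd.DataFrame(payload["units"]),
            gains=payload["gains"],
            couplings=[tuple(c) for c in payload["couplings"]],
            segments=[tuple(s) for s in payload["segments"]],
            seed=payload["seed"],
        )


# ----------------------------------------------------------------------
# signal primitives
# ----------------------------------------------------------------------

def pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise, scaled to unit median absolute value."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0)
    freqs[0] = freqs[1]
    spec /= np.sqrt(freqs)
    x = np.fft.irfft(spec, n)
    return x / np.median(np.abs(x))


def _background(cfg: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    n = int(round(cfg.duration_s * cfg.fs_hz))
    bg = np.empty((cfg.n_channels, n))
    t = np.arange(n) / cfg.fs_hz
    # low-amplitude delta common across the probe (volume conduction)
    delta = 0.4 * np.sin(2 * np.pi * 2.0 * t + rng.uniform(0, 2 * np.pi))
    for c in range(cfg.n_channels):
        bg[c] = pink_noise(n, rng) + delta
    # real laminar LFP is spatially correlated across neighboring sites;
    # smooth along the depth axis then restore unit MAD per channel so
    # event_amp keeps its threshold-relative meaning
    if cfg.n_channels >= 8:
        from scipy.ndimage import gaussian_filter1d

        bg = gaussian_filter1d(bg, sigma=1.5, axis=0, mode="nearest")
        bg /= np.median(np.abs(bg), axis=1, keepdims=True)
    return bg


def ds_depth_profile(
    cfg: SynthConfig, sink_channel: int, gcl_amp: float
) -> tuple[np.ndarray, np.ndarray]:
    """(LFP depth profile, planted interior CSD profile) for one DS.

    The sink is planted as a compact negative Gaussian LFP dip at
    ``sink_channel``: its discrete second difference is, exactly, a
    central sink with two flanking sources (the classic dipole-free
    triplet), so CSD analysis recovers the planted depth with no
    approximation.  A linear depth ramp - whose second difference is
    identically zero, hence invisible to CSD - pins the deepest
    granule-layer channel at ``gcl_amp`` for the amplitude detector.
    """
    ch = np.arange(cfg.n_channels)
    sigma = max(1.5, cfg.n_channels / 32)
    lfp = -2.0 * gcl_amp * np.exp(-0.5 * ((ch - sink_channel) / sigma) ** 2)
    ramp = np.linspace(0.15, 1.0, cfg.n_channels) * gcl_amp
    profile = lfp + ramp
    # CSD-silent linear correction pinning the deepest granule-layer
    # channel at exactly gcl_amp (the sink's LFP footprint would
    # otherwise erode the detection amplitude for deep sinks)
    profile += np.linspace(0.0, gcl_amp - profile[-1], cfg.n_channels)
    planted_csd = -(profile[:-2] - 2 * profile[1:-1] + profile[2:])
    return profile, planted_csd


def _event_times(
    rate_hz: float, windows: list[tuple[float, float]], rng: np.random.Generator
) -> np.ndarray:
    """Poisson event times inside the union of windows."""
    times = []
    for a, b in windows:
        n = rng.poisson(rate_hz * (b - a))
        times.append(rng.uniform(a + MAX_EVENT_DURATION_S, b - MAX_EVENT_DURATION_S, n))
    return np.sort(np.concatenate(times)) if times else np.empty(0)


def _thin(times: np.ndarray, min_gap: float) -> np.ndarray:
    """Drop events closer than ``min_gap`` to the previously kept one."""
    kept: list[float] = []
    for t in times:
        if not kept or t - kept[-1] >= min_gap:
            kept.append(t)
    return np.asarray(kept)


# ----------------------------------------------------------------------
# session generation
# ----------------------------------------------------------------------

def generate_session(cfg: SynthConfig) -> tuple[LaminarLfp, SpikeTable, GroundTruthLedger]:
    """Generate one complete synthetic session.

    Returns the laminar LFP, per-unit spike table, and the ground-truth
    ledger.  Identical config + seed gives bit-identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    segments = cfg.segments
    n = int(round(cfg.duration_s * cfg.fs_hz))
    fs = cfg.fs_hz
    lfp = _background(cfg, rng)

    sleep_windows = [(a, b) for name, a, b in segments if name != "exploration"]
    expl_windows = [(a, b) for name, a, b in segments if name == "exploration"]

    # ---- planted events ------------------------------------------------
    ds_t = _event_times(cfg.ds_rate_hz, sleep_windows, rng)
    swr_t = _event_times(cfg.swr_rate_hz, sleep_windows, rng)
    merged = np.sort(np.concatenate([ds_t, swr_t]))
    keep = set(_thin(merged, MIN_EVENT_SPACING_S))
    ds_t = np.array([t for t in ds_t if t in keep])
    swr_t = np.array([t for t in swr_t if t in keep])

    layer_arr = np.asarray(cfg.layer_map)
    gcl_ch = np.flatnonzero(layer_arr == "gcl")
    pyr_ch = np.flatnonzero(layer_arr == "pyr")
    rad_ch = np.flatnonzero(layer_arr == "rad")
    om_ch = np.flatnonzero(layer_arr == "om")
    im_ch = np.flatnonzero(layer_arr == "im")

    def _seg_of(t: float) -> str:
        for name, a, b in segments:
            if a <= t < b:
                return name
        return segments[-1][0]

    rows = []
    # dentate spikes: per-type molecular-layer sink depth
    for t in ds_t:
        is_ds1 = rng.uniform() < cfg.ds1_fraction
        ds_type = "DS1" if is_ds1 else "DS2"
        pool = om_ch if is_ds1 else im_ch
        sink = int(pool[len(pool) // 2]) if len(pool) else cfg.n_channels // 2
        dur = rng.uniform(0.040, 0.050)
        amp = cfg.event_amp * rng.uniform(1.0, 1.3)
        profile, _ = ds_depth_profile(cfg, sink, amp)
        i0 = int(round(t * fs))
        half = int(round(dur * fs / 2))
        idx = np.arange(max(0, i0 - 2 * half), min(n, i0 + 2 * half))
        envelope = np.exp(-0.5 * ((idx - i0) / (half / 1.6)) ** 2)
        lfp[:, idx] += profile[:, None] * envelope[None, :]
        rows.append((t, ds_type, dur, sink, amp, _seg_of(t)))

    # sharp-wave ripples: pyramidal-layer ripple over a radiatum sharp wave
    for t in swr_t:
        dur = rng.uniform(0.040, 0.050)
        amp = cfg.event_amp * rng.uniform(1.0, 1.3)
        i0 = int(round(t * fs))
        half = int(round(dur * fs / 2))
        idx = np.arange(max(0, i0 - 2 * half), min(n, i0 + 2 * half))
        envelope = np.exp(-0.5 * ((idx - i0) / (half / 1.4)) ** 2)
        ripple = np.sin(2 * np.pi * cfg.ripple_freq_hz * (idx - i0) / fs) * envelope
        for c in pyr_ch:
            lfp[c, idx] += amp * ripple
        for c in rad_ch:
            lfp[c, idx] -= 2.5 * envelope  # negative sharp wave
        rows.append((t, "SWR", dur, -1, amp, _seg_of(t)))

    # theta during exploration: strongest near lacunosum-moleculare
    lm_center = np.flatnonzero(layer_arr == "lm")
    lm_center = lm_center[len(lm_center) // 2] if len(lm_center) else cfg.n_channels // 2
    depth_gain = 0.5 + 0.5 * np.exp(-0.5 * ((np.arange(cfg.n_channels) - lm_center) / (cfg.n_channels / 6)) ** 2)
    for a, b in expl_windows:
        i0, i1 = int(a * fs), int(b * fs)
        tt = np.arange(i0, i1) / fs
        phase = 2 * np.pi * cfg.theta_freq_hz * tt + 0.3 * np.cumsum(rng.standard_normal(i1 - i0)) / np.sqrt(fs)
        wave = cfg.theta_amp * np.sin(phase)
        lfp[:, i0:i1] += depth_gain[:, None] * wave[None, :]

    events = pd.DataFrame(rows, columns=["t", "type", "duration_s", "sink_channel", "amp", "segment"])
    events = events.sort_values("t").reset_index(drop=True)

    # ---- units and spikes ----------------------------------------------
    unit_rows = []
    uid = 0
    for region, count in cfg.n_units.items():
        for _ in range(count):
            cls = "interneuron" if rng.uniform() < cfg.interneuron_fraction else "principal"
            base = cfg.base_rate_hz[cls] * rng.lognormal(0.0, 0.3)
            has_pf = cls == "principal" and rng.uniform() < cfg.place_field_fraction
            pf_x = rng.uniform(0, cfg.arena_cm[0]) if has_pf else np.nan
            pf_y = rng.uniform(0, cfg.arena_cm[1]) if has_pf else np.nan
            unit_rows.append((uid, region, cls, base, pf_x, pf_y))
            uid += 1
    units = pd.DataFrame(
        unit_rows, columns=["unit_id", "region", "cell_class", "base_rate_hz", "pf_x", "pf_y"]
    ).set_index("unit_id")

    # carry selected theta couplings into post-sleep event windows
    couplings = [tuple(c) for c in cfg.coupling_spec]
    if cfg.reactivation_gain > 0:
        for (i, j, cond, w) in list(couplings):
            if cond == "theta":
                couplings.append((i, j, "ds_post", cfg.reactivation_gain * w))
                couplings.append((i, j, "swr_post", cfg.reactivation_gain * w))

    spikes = {u: [rng.uniform(0, cfg.duration_s, rng.poisson(r * cfg.duration_s))]
              for u, r in zip(units.index, units["base_rate_hz"])}

    # extra event-locked spikes: inhomogeneous Poisson by superposition,
    # concentrated around the event peak (as real event-nested firing is)
    for _, ev in events.iterrows():
        w0, w1 = ev["t"] - 0.025, ev["t"] + 0.025
        etype = ev["type"]
        for u in units.index:
            region = units.loc[u, "region"]
            gain = cfg.gains.get(region, {}).get(etype, 1.0)
            extra = units.loc[u, "base_rate_hz"] * max(gain - 1.0, 0.0) * (w1 - w0)
            k = rng.poisson(extra)
            if k:
                spikes[u].append(np.clip(rng.normal(ev["t"], ev["duration_s"] / 6, k), w0, w1))

    # planted pairwise couplings: shared Bernoulli latent per window
    def _windows_for(cond: str) -> list[tuple[float, float]]:
        cond = cond.lower()
        if cond == "theta":
            period = 1.0 / cfg.theta_freq_hz
            out = []
            for a, b in expl_windows:
                starts = np.arange(a, b - period, period)
                out.extend((s, s + 0.05) for s in starts)
            return out
        fam = "DS" if cond.startswith("ds") else "SWR"
        seg = "pre_sleep" if cond.endswith("pre") else ("post_sleep" if cond.endswith("post") else None)
        sel = events[events["type"].str.startswith(fam[:2]) if fam == "DS" else events["type"] == "SWR"]
        if seg is not None:
            sel = sel[sel["segment"] == seg]
        return [(t - 0.025, t + 0.025) for t in sel["t"]]

    for (i, j, cond, w) in couplings:
        p = min(max(float(w), 0.0), 1.0)
        for (w0, w1) in _windows_for(cond):
            if rng.uniform() < p:
                for u in (i, j):
                    k = rng.poisson(cfg.coupling_burst_rate)
                    if k:
                        spikes[u].append(rng.uniform(w0, w1, k))

    # place-field spiking during exploration is added by attach_trajectory
    spike_dict = {int(u): np.sort(np.concatenate(v)) for u, v in spikes.items()}
    table = SpikeTable(units[["region", "cell_class"]].copy(), spike_dict)

    ledger = GroundTruthLedger(
        events=events,
        units=units.reset_index(),
        gains=cfg.gains,
        couplings=couplings,
        segments=segments,
        seed=cfg.seed,
    )
    return LaminarLfp(lfp, fs, list(cfg.layer_map)), table, ledger


def planted_event_set(ledger: GroundTruthLedger, types: tuple[str, ...] | None = None) -> EventSet:
    """View the ledger's planted events as an :class:`EventSet` (truth)."""
    ev = ledger.events if types is None else ledger.events_of_type(*types)
    df = pd.DataFrame(
        {
            "type": ev["type"],
            "peak_t": ev["t"],
            "onset_t": ev["t"] - ev["duration_s"] / 2,
            "offset_t": ev["t"] + ev["duration_s"] / 2,
            "channel": ev["sink_channel"],
            "peak_amplitude": ev["amp"],
        }
    )
    return EventSet(df.reset_index(drop=True), {"detector": "ground_truth"})


# ----------------------------------------------------------------------
# trajectory and place fields
# ----------------------------------------------------------------------

def generate_trajectory(cfg: SynthConfig, rng: np.random.Generator | None = None) -> PositionTrack:
    """Smooth random-walk trajectory confined to the arena, at 25 Hz.

    Velocity follows an Ornstein-Uhlenbeck process (mean speed ~10 cm/s)
    with reflection at the walls, which covers the arena well within a
    10-minute exploration.
    """
    expl = [(a, b) for name, a, b in cfg.segments if name == "exploration"]
    if not expl:
        raise ValueError("no exploration segment defined")
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    a, b = expl[0]
    dt = 1.0 / cfg.tracking_hz
    n = int(round((b - a) * cfg.tracking_hz))
    pos = np.empty((n, 2))
    pos[0] = (cfg.arena_cm[0] / 2, cfg.arena_cm[1] / 2)
    vel = rng.standard_normal(2) * 5.0
    tau, sigma_v = 1.0, 12.0
    for k in range(1, n):
        vel += (-vel / tau) * dt + sigma_v * np.sqrt(2 * dt / tau) * rng.standard_normal(2)
        pos[k] = pos[k - 1] + vel * dt
        for d, lim in enumerate(cfg.arena_cm):
            if pos[k, d] < 0:
                pos[k, d] = -pos[k, d]
                vel[d] = -vel[d]
            if pos[k, d] > lim:
                pos[k, d] = 2 * lim - pos[k, d]
                vel[d] = -vel[d]
    t = a + np.arange(n) * dt
    return PositionTrack(t, pos[:, 0], pos[:, 1], cfg.arena_cm)


def place_field_spikes(
    track: PositionTrack,
    center: tuple[float, float],
    sd_cm: float,
    peak_hz: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Inhomogeneous-Poisson spikes from a Gaussian place field along a track."""
    dt = np.median(np.diff(track.t))
    d2 = (track.x - center[0]) ** 2 + (track.y - center[1]) ** 2
    rate = peak_hz * np.exp(-0.5 * d2 / sd_cm**2)
    counts = rng.poisson(rate * dt)
    spikes = []
    for k in np.flatnonzero(counts):
        spikes.append(track.t[k] + rng.uniform(0, dt, counts[k]))
    return np.sort(np.concatenate(spikes)) if spikes else np.empty(0)


def attach_trajectory(
    table: SpikeTable, ledger: GroundTruthLedger, cfg: SynthConfig
) -> tuple[SpikeTable, PositionTrack]:
    """Add place-field spiking during exploration for ledger-designated units."""
    rng = np.random.default_rng(cfg.seed + 1)
    track = generate_trajectory(cfg, rng)
    spikes = dict(table.spikes)
    for _, row in ledger.units.iterrows():
        if np.isnan(row["pf_x"]):
            continue
        extra = place_field_spikes(
            track, (row["pf_x"], row["pf_y"]), cfg.place_field_sd_cm, cfg.place_field_peak_hz, rng
        )
        u = int(row["unit_id"])
        spikes[u] = np.sort(np.concatenate([spikes.get(u, np.empty(0)), extra]))
    return SpikeTable(table.units.copy(), spikes), track


# ----------------------------------------------------------------------
# waveform templates
# ----------------------------------------------------------------------

def generate_unit_waveforms(table: SpikeTable, cfg: SynthConfig, fs_hz: float = 20000.0):
    """Mean biphasic spike templates (4 channels) per unit with per-sample s.d.

    Trough-to-peak widths are drawn from a two-component mixture matching
    the unit's planted class: narrow ~0.2 ms for interneurons, wide
    ~0.6 ms for principal cells (the field's classic bimodal split).
    Per-sample s.d. is strictly positive (a zero-noise template would make
    the downstream waveform score diverge).
    """
    from .unit_metrics import WaveformTemplate

    rng = np.random.default_rng(cfg.seed + 2)
    n = 64  # 3.2 ms at 20 kHz
    t = np.arange(n) / fs_hz * 1000.0  # ms
    out: dict[int, WaveformTemplate] = {}
    for u in table.unit_ids:
        cls = table.units.loc[u, "cell_class"]
        ttp = (
            max(0.08, rng.normal(0.2, 0.03))
            if cls == "interneuron"
            else max(0.3, rng.normal(0.6, 0.08))
        )
        trough_ms = 1.0
        amp = rng.uniform(60.0, 180.0)  # uV
        w = -amp * np.exp(-0.5 * ((t - trough_ms) / 0.12) ** 2)
        w += 0.45 * amp * np.exp(-0.5 * ((t - trough_ms - ttp) / (0.35 * max(ttp, 0.15))) ** 2)
        sigma = np.maximum(0.15 * np.abs(w) + 0.05 * amp, 1e-3)
        out[u] = WaveformTemplate(w=w, sigma=sigma, trough_to_peak_ms=ttp)
    return out


# ----------------------------------------------------------------------
# direct planted-structure generators (count / coefficient level)
# ----------------------------------------------------------------------

def ds_waveform_epochs(
    n_events: int = 600,
    ds1_fraction: float = 0.35,
    separation: float = 2.8,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic granule-layer DS waveform epochs for the typing discriminant.

    Two fixed 400 ms templates (500 bins of 0.8 ms) stand for the DS1 and
    DS2 granule-layer LFP shapes - DS1 narrower and deeper, DS2 broader
    with a later rebound.  Noise is 50 Hz low-passed (matching the
    classifier's preprocessing, hence spectrally realistic) and scaled so
    the class separation *along the template-difference direction* equals
    ``separation`` Mahalanobis units; at the default 2.8 the Bayes
    accuracy is ~0.92, bracketing the accuracy regime of real granule-
    layer waveform typing.  Returns (epochs, labels).
    """
    from scipy.signal import butter, sosfiltfilt

    rng = np.random.default_rng(seed)
    tt = (np.arange(500) - 250) * 0.0008
    tpl1 = -np.exp(-0.5 * (tt / 0.012) ** 2) + 0.3 * np.exp(-0.5 * ((tt - 0.03) / 0.02) ** 2)
    tpl2 = -0.8 * np.exp(-0.5 * (tt / 0.02) ** 2) + 0.15 * np.exp(-0.5 * ((tt - 0.05) / 0.03) ** 2)
    sos = butter(4, 50.0, fs=1250.0, output="sos")
    diff = tpl1 - tpl2
    u = diff / np.linalg.norm(diff)
    probe = np.array([sosfiltfilt(sos, rng.standard_normal(500)) for _ in range(300)])
    probe /= probe.std(axis=1, keepdims=True)
    sd_u = (probe @ u).std()
    scale = (np.linalg.norm(diff) / separation) / sd_u
    epochs, labels = [], []
    for _ in range(n_events):
        is_ds1 = rng.uniform() < ds1_fraction
        base = tpl1 if is_ds1 else tpl2
        labels.append("DS1" if is_ds1 else "DS2")
        noise = sosfiltfilt(sos, rng.standard_normal(500))
        noise *= scale / max(noise.std(), 1e-12)
        epochs.append(base + noise)
    return np.asarray(epochs), np.asarray(labels)


def coupled_count_matrix(
    n_units: int,
    n_events: int,
    couplings: list[tuple[int, int, float]],
    noise_sd: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """units x events series with planted linear pairwise couplings.

    For each (i, j, w): ``x_j = w * x_i + sqrt(1 - w^2) * noise`` on
    standardized series, peers independent - the direct construction used
    to verify peer-controlled regression recovers planted weights.
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_units, n_events))
    for (i, j, w) in couplings:
        x[j] = w * x[i] + np.sqrt(max(1.0 - w**2, 0.0)) * noise_sd * rng.standard_normal(n_events)
    return x


def reactivation_pair_table(
    n_mice: int = 4,
    n_pairs_per_mouse: int = 150,
    transfer: float = 0.3,
    pre_weight: float = 0.2,
    mouse_sd: float = 0.25,
    noise_sd: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Planted reactivation structure at the coactivity-coefficient level.

    ``post = transfer * theta + pre_weight * pre + mouse offset + noise``
    for every cell pair; ``theta`` and ``pre`` are independent standard
    normals.  Columns match :func:`hippocoact.reactivation.assemble_pair_table`.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for m in range(n_mice):
        offset = rng.normal(0.0, mouse_sd)
        theta = rng.standard_normal(n_pairs_per_mouse)
        pre = rng.standard_normal(n_pairs_per_mouse)
        post = transfer * theta + pre_weight * pre + offset + noise_sd * rng.standard_normal(n_pairs_per_mouse)
        for k in range(n_pairs_per_mouse):
            rows.append((f"mouse{m}", k, k + 1, theta[k], pre[k], post[k]))
    return pd.DataFrame(rows, columns=["mouse_id", "unit_i", "unit_j", "theta", "pre", "post"])
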