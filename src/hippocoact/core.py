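"""Shared containers and on-disk formats.

The pipeline passes around four kinds of object: laminar LFP arrays,
per-unit spike tables, detected event sets, and animal position tracks.
All time stamps are seconds (float64) on a common session clock; sample
indices are 0-based; event windows are half-open ``[start, end)``.

On disk, LFP is stored as little-endian float32 raw binary (channel-major)
with a JSON sidecar carrying the sampling rate and the channel->layer map;
spikes, events and positions are plain CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: fixed vocabulary of laminar labels, CA1 oriens down to the DG granule
#: cell layer.  ``unknown`` is allowed for channels outside the axis.
LAYER_LABELS = ("ori", "pyr", "rad", "lm", "om", "mm", "im", "gcl", "unknown")

EVENT_TYPES = ("DS", "DS1", "DS2", "SWR", "THETA_CYCLE")

EVENT_COLUMNS = ["type", "peak_t", "onset_t", "offset_t", "channel", "peak_amplitude"]


@dataclass
class LaminarLfp:
    """Multichannel LFP: ``samples`` is channels x time (volts, arbitrary gain)."""

    samples: np.ndarray
    fs_hz: float
    layer_map: list[str]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim == 1:
            self.samples = self.samples[None, :]
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        if len(self.layer_map) != self.samples.shape[0]:
            raise ValueError("layer_map length must equal channel count")
        bad = set(self.layer_map) - set(LAYER_LABELS)
        if bad:
            raise ValueError(f"unknown layer labels: {sorted(bad)}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.fs_hz

    def channels_in_layer(self, layer: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.layer_map) == layer)

    # ---- persistence -------------------------------------------------
    def save(self, path: str | Path) -> None:
        """Write ``<path>.dat`` (float32 raw, channel-major) + ``<path>.json``."""
        path = Path(path)
        self.samples.astype("<f4").tofile(path.with_suffix(".dat"))
        sidecar = {
            "fs_hz": self.fs_hz,
            "n_channels": self.n_channels,
            "n_samples": self.n_samples,
            "channel_order": list(range(self.n_channels)),
            "layer_map": list(self.layer_map),
            "t0": self.t0,
            "dtype": "<f4",
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "LaminarLfp":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        raw = np.fromfile(path.with_suffix(".dat"), dtype=meta.get("dtype", "<f4"))
        samples = raw.reshape(meta["n_channels"], meta["n_samples"])
        return cls(samples, meta["fs_hz"], meta["layer_map"], meta.get("t0", 0.0))


@dataclass
class SpikeTable:
    """Spike times per unit with region (DG/CA3/CA1) and cell-class labels.

    ``units`` is a DataFrame indexed by unit id with columns ``region`` and
    ``cell_class`` (``principal`` / ``interneuron`` / ``unknown``);
    ``spikes`` maps unit id -> sorted float64 spike times in seconds.
    """

    units: pd.DataFrame
    spikes: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for uid, t in self.spikes.items():
            t = np.asarray(t, dtype=np.float64)
            self.spikes[uid] = np.sort(t)
        missing = set(self.spikes) - set(self.units.index)
        if missing:
            raise ValueError(f"spike trains for unknown units: {sorted(missing)}")

    @property
    def unit_ids(self) -> list[int]:
        return list(self.units.index)

    def times(self, unit_id: int) -> np.ndarray:
        return self.spikes.get(unit_id, np.empty(0))

    def select(self, region: str | None = None, cell_class: str | None = None) -> "SpikeTable":
        mask = pd.Series(True, index=self.units.index)
        if region is not None:
            mask &= self.units["region"] == region
        if cell_class is not None:
            mask &= self.units["cell_class"] == cell_class
        units = self.units[mask]
        return SpikeTable(units, {u: self.spikes[u] for u in units.index if u in self.spikes})

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for uid in self.unit_ids:
            for t in self.times(uid):
                rows.append((uid, self.units.loc[uid, "region"], self.units.loc[uid, "cell_class"], t))
        return pd.DataFrame(rows, columns=["unit_id", "region", "cell_class", "spike_t"])

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SpikeTable":
        units = (
            frame.groupby("unit_id")[["region", "cell_class"]].first()
            if len(frame)
            else pd.DataFrame(columns=["region", "cell_class"])
        )
        spikes = {int(u): g["spike_t"].to_numpy() for u, g in frame.groupby("unit_id")}
        return cls(units, spikes)

    @classmethod
    def load(cls, path: str | Path) -> "SpikeTable":
        return cls.from_frame(pd.read_csv(path))


@dataclass
class EventSet:
    """Detected network events, sorted by peak time, with detector provenance."""

    events: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ev = self.events
        if len(ev) == 0:
            self.events = pd.DataFrame(columns=EVENT_COLUMNS)
            return
        for col in EVENT_COLUMNS:
            if col not in ev.columns:
                raise ValueError(f"EventSet missing column {col!r}")
        if not ((ev["onset_t"] <= ev["peak_t"]) & (ev["peak_t"] <= ev["offset_t"])).all():
            raise ValueError("event times must satisfy onset <= peak <= offset")
        self.events = ev.sort_values("peak_t").reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.events)

    @property
    def peak_times(self) -> np.ndarray:
        return self.events["peak_t"].to_numpy()

    def of_type(self, *types: str) -> "EventSet":
        return EventSet(self.events[self.events["type"].isin(types)].copy(), dict(self.provenance))

    def relabel(self, labels) -> "EventSet":
        ev = self.events.copy()
        ev["type"] = list(labels)
        return EventSet(ev, dict(self.provenance))

    def save(self, path: str | Path) -> None:
        path = Path(path)
        self.events.to_csv(path, index=False)
        path.with_suffix(".provenance.json").write_text(json.dumps(self.provenance, indent=1, default=str))

    @classmethod
    def load(cls, path: str | Path) -> "EventSet":
        path = Path(path)
        prov_path = path.with_suffix(".provenance.json")
        prov = json.loads(prov_path.read_text()) if prov_path.exists() else {}
        return cls(pd.read_csv(path), prov)


@dataclass
class PositionTrack:
    """Animal position at the tracking frame rate (25 Hz by default)."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    arena_cm: tuple[float, float] = (41.0, 41.0)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=np.float64)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if not (len(self.t) == len(self.x) == len(self.y)):
            raise ValueError("t, x, y must share length")

    @property
    def frame_rate_hz(self) -> float:
        if len(self.t) < 2:
            return float("nan")
        return 1.0 / np.median(np.diff(self.t))

    def save(self, path: str | Path) -> None:
        pd.DataFrame({"t": self.t, "x": self.x, "y": self.y}).to_csv(path, index=False)

    @classmethod
    def load(cls, path: str | Path, arena_cm: tuple[float, float] = (41.0, 41.0)) -> "PositionTrack":
        df = pd.read_csv(path)
        return cls(df["t"].to_numpy(), df["x"].to_numpy(), df["y"].to_numpy(), arena_cm)


def default_layer_map(n_channels: int = 64) -> list[str]:
    """Laminar label layout for a linear probe spanning CA1 oriens -> DG gcl.

    Proportions follow the anatomy of a dorsal-hippocampus penetration:
    oriens / pyramidale / radiatum / lacunosum-moleculare above the fissure,
    then outer / middle / inner molecular layers and the granule cell layer.
    """
    fractions = [
        ("ori", 0.14),
        ("pyr", 0.08),
        ("rad", 0.24),
        ("lm", 0.12),
        ("om", 0.12),
        ("mm", 0.12),
        ("im", 0.10),
        ("gcl", 0.08),
    ]
    counts = [max(1, int(round(f * n_channels))) for _, f in fractions]
    while sum(counts) > n_channels:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) < n_channels:
        counts[int(np.argmax([f for _, f in fractions]))] += 1
    layers: list[str] = []
    for (name, _), c in zip(fractions, counts):
        layers.extend([name] * c)
    return layers[:n_channels]
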