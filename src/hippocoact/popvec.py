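"""Event-nested population vectors and their statistics.

One population vector per event: spike counts of every simultaneously
recorded principal cell in the half-open 50 ms window ``[peak-25ms,
peak+25ms)``.  Baseline ("no event") vectors come from 50 ms windows of
the same session that avoid +-250 ms around any DS or SWR peak.
Vector-level statistics: Gini sparsity, proportion of coactive cells,
DS-vs-SWR logistic discriminability, pairwise similarity (Pearson and
Jaccard on binarized vectors), and PCA dimensionality (components to
reach 90% variance, scaled by the unit count).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import EventSet, SpikeTable

WINDOW_S = 0.050
BASELINE_EXCLUSION_S = 0.250
MIN_EVENTS_PER_TYPE = 100
MIN_UNITS = 20
PRE_POST_OFFSET_S = (0.200, 0.250)  # control windows 200-250 ms from the peak


@dataclass
class PopulationVectorMatrix:
    """units x events spike counts with per-column event labels."""

    counts: np.ndarray
    event_labels: np.ndarray  # per column: DS1/DS2/SWR/baseline/...
    unit_ids: list[int]
    window_s: float = WINDOW_S

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.event_labels = np.asarray(self.event_labels)
        if self.counts.shape != (len(self.unit_ids), len(self.event_labels)):
            raise ValueError("counts must be units x events")
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be non-negative")

    @property
    def binary(self) -> np.ndarray:
        return (self.counts > 0).astype(np.int8)

    def columns_of(self, *labels: str) -> np.ndarray:
        return np.flatnonzero(np.isin(self.event_labels, labels))

    def subset(self, *labels: str) -> "PopulationVectorMatrix":
        cols = self.columns_of(*labels)
        return PopulationVectorMatrix(
            self.counts[:, cols], self.event_labels[cols], list(self.unit_ids), self.window_s
        )


def count_spikes_in_windows(table: SpikeTable, windows: list[tuple[float, float]]) -> np.ndarray:
    """units x windows spike counts, each window half-open [start, end)."""
    units = table.unit_ids
    out = np.zeros((len(units), len(windows)), dtype=np.int64)
    for r, u in enumerate(units):
        t = table.times(u)
        for c, (a, b) in enumerate(windows):
            out[r, c] = np.searchsorted(t, b, "left") - np.searchsorted(t, a, "left")
    return out


def sample_baseline_windows(
    event_peaks: np.ndarray,
    session_span: tuple[float, float],
    n_windows: int,
    seed: int = 0,
    window_s: float = WINDOW_S,
    exclusion_s: float = BASELINE_EXCLUSION_S,
) -> list[tuple[float, float]]:
    """Count-matched 50 ms baseline windows avoiding +-250 ms of any event peak.

    Candidate starts are laid on a window-spaced grid over the admissible
    complement and sampled uniformly without replacement.
    """
    rng = np.random.default_rng(seed)
    peaks = np.sort(np.asarray(event_peaks, float))
    starts = np.arange(session_span[0], session_span[1] - window_s, window_s)
    centers = starts + window_s / 2
    idx = np.searchsorted(peaks, centers)
    ok = np.ones(len(starts), bool)
    for j in (0, 1):
        k = np.clip(idx - 1 + j, 0, max(len(peaks) - 1, 0))
        if len(peaks):
            ok &= np.abs(centers - peaks[k]) > exclusion_s + window_s / 2
    admissible = starts[ok]
    if len(admissible) < n_windows:
        warnings.warn("fewer admissible baseline windows than requested")
        n_windows = len(admissible)
    chosen = rng.choice(admissible, size=n_windows, replace=False)
    return [(s, s + window_s) for s in np.sort(chosen)]


def extract_population_vectors(
    table: SpikeTable,
    events: EventSet,
    baselines: list[tuple[float, float]] | None = None,
    window_kind: str = "event",
    enforce_inclusion: bool = True,
    min_events: int = MIN_EVENTS_PER_TYPE,
    min_units: int = MIN_UNITS,
) -> PopulationVectorMatrix:
    """Population vector matrix over events (+ optional baseline windows).

    ``window_kind`` selects the 50 ms window per event: ``event`` is
    centered on the peak; ``pre`` / ``post`` use the 200-250 ms control
    epochs before / after the peak.  Inclusion requires ``min_events``
    per compared event type and ``min_units`` simultaneously recorded
    cells (override with ``enforce_inclusion=False``, which warns).
    """
    units = table.unit_ids
    labels = list(events.events["type"])
    if window_kind == "event":
        windows = [(t - WINDOW_S / 2, t + WINDOW_S / 2) for t in events.peak_times]
    elif window_kind == "pre":
        windows = [(t - PRE_POST_OFFSET_S[1], t - PRE_POST_OFFSET_S[0]) for t in events.peak_times]
    elif window_kind == "post":
        windows = [(t + PRE_POST_OFFSET_S[0], t + PRE_POST_OFFSET_S[1]) for t in events.peak_times]
    else:
        raise ValueError(f"unknown window_kind {window_kind!r}")
    if baselines:
        windows = windows + list(baselines)
        labels = labels + ["baseline"] * len(baselines)
    labels = np.asarray(labels)

    if len(units) < min_units or any(
        np.sum(labels == ty) < min_events for ty in set(labels) - {"baseline"}
    ):
        msg = (
            f"inclusion thresholds unmet (need >= {min_events} events/type "
            f"and >= {min_units} units; got {len(units)} units)"
        )
        if enforce_inclusion:
            raise ValueError(msg)
        warnings.warn(msg)

    counts = count_spikes_in_windows(table, windows)
    return PopulationVectorMatrix(counts, labels, units)


# ----------------------------------------------------------------------
# sparsity and coactivity fractions
# ----------------------------------------------------------------------

def gini_sparsity(vec: np.ndarray) -> float:
    """Gini index of one population vector, S = sum (2i-N-1) x_i / (N sum x).

    ``x`` sorted ascending, ranks ``i`` 1-based.  0 for perfectly even
    vectors, (N-1)/N for a point mass; undefined (ValueError) for
    all-zero vectors.
    """
    x = np.sort(np.asarray(vec, dtype=float))
    n = len(x)
    total = x.sum()
    if total <= 0:
        raise ValueError("Gini sparsity undefined for all-zero vectors")
    i = np.arange(1, n + 1)
    return float(np.sum((2 * i - n - 1) * x) / (n * total))


def mean_gini_sparsity(mat: PopulationVectorMatrix, label: str) -> tuple[float, int]:
    """Session statistic: mean Gini over a type's vectors; all-zero vectors
    are excluded and their count reported."""
    cols = mat.columns_of(label)
    vals, n_excluded = [], 0
    for c in cols:
        v = mat.counts[:, c]
        if v.sum() == 0:
            n_excluded += 1
            continue
        vals.append(gini_sparsity(v))
    return (float(np.mean(vals)) if vals else float("nan")), n_excluded


def proportion_coactive(mat: PopulationVectorMatrix) -> dict[str, float]:
    """Per event type: mean over events of (#active units / #units)."""
    frac = mat.binary.mean(axis=0)
    return {str(ty): float(frac[mat.columns_of(ty)].mean()) for ty in np.unique(mat.event_labels)}


# ----------------------------------------------------------------------
# DS-vs-SWR logistic discriminability
# ----------------------------------------------------------------------

def train_event_classifier(
    mat: PopulationVectorMatrix,
    types: tuple[str, str] = ("DS", "SWR"),
    train_fraction: float = 0.75,
    n_runs: int = 20,
    seed: int = 0,
) -> np.ndarray:
    """Held-out accuracy of a logistic DS-vs-SWR population-vector classifier.

    Vectors are binarized (controls for rate differences); the larger
    class is subsampled to balance; 75% train / 25% held out.  Repeated
    over ``n_runs`` subsample/split seeds; the accuracy distribution is
    returned.  Run it on ``pre`` / ``post`` control matrices to probe the
    absence of structure outside the events themselves.
    """
    from sklearn.linear_model import LogisticRegression

    a_cols = mat.columns_of(types[0])
    b_cols = mat.columns_of(types[1])
    if len(a_cols) == 0 or len(b_cols) == 0:
        raise ValueError("both event types must be present")
    xbin = mat.binary.T  # events x units
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(n_runs):
        n = min(len(a_cols), len(b_cols))
        a = rng.choice(a_cols, n, replace=False)
        b = rng.choice(b_cols, n, replace=False)
        cut = int(round(train_fraction * n))
        pa, pb = rng.permutation(n), rng.permutation(n)
        tr = np.concatenate([a[pa[:cut]], b[pb[:cut]]])
        te = np.concatenate([a[pa[cut:]], b[pb[cut:]]])
        y = np.concatenate([np.zeros(cut), np.ones(cut)])
        yt = np.concatenate([np.zeros(n - cut), np.ones(n - cut)])
        clf = LogisticRegression(C=1000.0, max_iter=2000)  # tiny ridge for separable data
        clf.fit(xbin[tr], y)
        accs.append(float(np.mean(clf.predict(xbin[te]) == yt)))
    return np.asarray(accs)


# ----------------------------------------------------------------------
# similarity and dimensionality
# ----------------------------------------------------------------------

def vector_similarity(
    mat: PopulationVectorMatrix,
    types: tuple[str, ...],
    seed: int = 0,
    use_counts: bool = False,
) -> dict[str, dict[str, float]]:
    """Mean within-type pairwise Pearson and Jaccard similarity.

    Event counts are matched by subsampling every type to the smallest;
    vectors are binarized for both metrics (``use_counts`` switches the
    Pearson metric to raw counts).  Zero-variance pairs are skipped and
    counted.
    """
    rng = np.random.default_rng(seed)
    n_min = min(len(mat.columns_of(ty)) for ty in types)
    out: dict[str, dict[str, float]] = {}
    for ty in types:
        cols = rng.choice(mat.columns_of(ty), n_min, replace=False)
        vb = mat.binary[:, cols]
        vc = mat.counts[:, cols] if use_counts else vb
        pearson, jaccard, skipped = [], [], 0
        for a in range(n_min):
            for b in range(a + 1, n_min):
                u, v = vc[:, a].astype(float), vc[:, b].astype(float)
                if u.std() == 0 or v.std() == 0:
                    skipped += 1
                else:
                    pearson.append(float(np.corrcoef(u, v)[0, 1]))
                bu, bv = vb[:, a] > 0, vb[:, b] > 0
                union = np.sum(bu | bv)
                if union > 0:
                    jaccard.append(float(np.sum(bu & bv) / union))
        out[str(ty)] = {
            "pearson_mean": float(np.mean(pearson)) if pearson else float("nan"),
            "jaccard_mean": float(np.mean(jaccard)) if jaccard else float("nan"),
            "n_skipped_zero_variance": skipped,
        }
    return out


def n_components_for_variance(x: np.ndarray, variance_target: float) -> int:
    """Smallest number of principal components reaching the variance target.

    ``x`` is observations x features; exact full-rank PCA on the centered
    matrix.
    """
    from sklearn.decomposition import PCA

    p = PCA().fit(x)
    cum = np.cumsum(p.explained_variance_ratio_)
    return int(np.searchsorted(cum, variance_target - 1e-12) + 1)


def population_dimensionality(
    mat: PopulationVectorMatrix,
    types: tuple[str, ...],
    variance_target: float = 0.90,
    targets_sweep: np.ndarray | None = None,
    seed: int = 0,
    min_units: int = MIN_UNITS,
) -> dict[str, dict]:
    """Scaled PCA dimensionality per event type.

    Event counts are matched by subsampling to the smallest type; per
    type, PCA on the (events x units) count matrix; the statistic is
    (#components to reach ``variance_target``) / (#units), with a sweep
    over targets also reported.
    """
    if len(mat.unit_ids) < min_units:
        raise ValueError(f"need >= {min_units} units for dimensionality")
    rng = np.random.default_rng(seed)
    if targets_sweep is None:
        targets_sweep = np.arange(0.5, 0.96, 0.05)
    n_min = min(len(mat.columns_of(ty)) for ty in types)
    n_units = len(mat.unit_ids)
    out: dict[str, dict] = {}
    for ty in types:
        cols = rng.choice(mat.columns_of(ty), n_min, replace=False)
        x = mat.counts[:, cols].T.astype(float)
        k = n_components_for_variance(x, variance_target)
        out[str(ty)] = {
            "scaled_dimensionality": k / n_units,
            "n_components": k,
            "sweep": {
                float(t): n_components_for_variance(x, float(t)) / n_units for t in targets_sweep
            },
        }
    return out
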