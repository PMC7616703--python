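"""Population vectors: extraction, sparsity, discriminability, similarity,
dimensionality."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hippocoact import (
    EventSet,
    PopulationVectorMatrix,
    SpikeTable,
    extract_population_vectors,
    gini_sparsity,
    population_dimensionality,
    proportion_coactive,
    sample_baseline_windows,
    train_event_classifier,
    vector_similarity,
)
from hippocoact.popvec import count_spikes_in_windows, mean_gini_sparsity


def _event_set(times, ty="DS"):
    return EventSet(
        pd.DataFrame(
            {
                "type": ty,
                "peak_t": times,
                "onset_t": np.asarray(times) - 0.02,
                "offset_t": np.asarray(times) + 0.02,
                "channel": 0,
                "peak_amplitude": 1.0,
            }
        )
    )


def _matrix(counts, labels):
    counts = np.asarray(counts)
    return PopulationVectorMatrix(counts, np.asarray(labels), list(range(counts.shape[0])))


# ----------------------------------------------------------------------
# extraction
# ----------------------------------------------------------------------

class TestExtraction:
    def _table(self, spike_map):
        units = pd.DataFrame(
            {"region": "DG", "cell_class": "principal"}, index=list(spike_map)
        )
        return SpikeTable(units, spike_map)

    def test_unit_firing_at_every_peak_gives_all_ones(self):
        peaks = np.arange(10.0, 20.0, 1.0)
        table = self._table({0: peaks.copy(), 1: np.array([500.0])})
        mat = extract_population_vectors(
            table, _event_set(peaks), enforce_inclusion=False
        )
        assert (mat.binary[0] == 1).all()
        assert (mat.binary[1] == 0).all()  # silent unit keeps its all-zero row

    def test_window_counts_match_bruteforce(self):
        rng = np.random.default_rng(0)
        spikes = {u: np.sort(rng.uniform(0, 100, 400)) for u in range(5)}
        table = self._table(spikes)
        windows = [(s, s + 0.05) for s in rng.uniform(1, 99, 30)]
        counts = count_spikes_in_windows(table, windows)
        for r, u in enumerate(table.unit_ids):
            for c, (a, b) in enumerate(windows):
                assert counts[r, c] == np.sum((spikes[u] >= a) & (spikes[u] < b))

    def test_half_open_window_boundary(self):
        # spike exactly at the window start counts; at the end it does not
        table = self._table({0: np.array([9.975, 10.025]), 1: np.array([50.0]), 2: np.array([60.0])})
        mat = extract_population_vectors(
            table, _event_set([10.0]), enforce_inclusion=False
        )
        assert mat.counts[0, 0] == 1

    def test_inclusion_thresholds_enforced(self):
        table = self._table({0: np.arange(10.0), 1: np.arange(10.0)})
        with pytest.raises(ValueError, match="inclusion"):
            extract_population_vectors(table, _event_set([5.0]))

    def test_baseline_windows_avoid_events(self):
        peaks = np.sort(np.random.default_rng(0).uniform(10, 590, 200))
        wins = sample_baseline_windows(peaks, (0, 600), 150, seed=1)
        assert len(wins) == 150
        for a, b in wins:
            center = (a + b) / 2
            assert np.min(np.abs(peaks - center)) > 0.25

    def test_pre_post_control_windows(self):
        peaks = np.array([100.0])
        table = self._table({0: np.array([99.78]), 1: np.array([100.22]), 2: np.array([2.0])})
        pre = extract_population_vectors(table, _event_set(peaks), window_kind="pre",
                                         enforce_inclusion=False)
        post = extract_population_vectors(table, _event_set(peaks), window_kind="post",
                                          enforce_inclusion=False)
        assert pre.counts[0, 0] == 1 and pre.counts[1, 0] == 0
        assert post.counts[1, 0] == 1 and post.counts[0, 0] == 0


# ----------------------------------------------------------------------
# Gini sparsity
# ----------------------------------------------------------------------

class TestGini:
    def test_even_vector_zero(self):
        assert gini_sparsity([3, 3, 3, 3]) == pytest.approx(0.0)

    def test_point_mass(self):
        assert gini_sparsity([0, 0, 0, 8]) == pytest.approx(0.75)  # (N-1)/N

    def test_small_example_matches_pairwise_identity(self):
        x = [1, 2, 3]
        assert gini_sparsity(x) == pytest.approx(2 / 9)
        n = len(x)
        mad = sum(abs(a - b) for a in x for b in x) / (2 * n * sum(x))
        assert gini_sparsity(x) == pytest.approx(mad)

    def test_all_zero_undefined(self):
        with pytest.raises(ValueError):
            gini_sparsity([0, 0, 0])

    @settings(max_examples=50, deadline=None)
    @given(
        x=st.lists(st.integers(0, 20), min_size=2, max_size=30).filter(lambda v: sum(v) > 0),
        scale=st.integers(1, 7),
    )
    def test_scale_invariance_and_bound(self, x, scale):
        g = gini_sparsity(x)
        assert g == pytest.approx(gini_sparsity([scale * v for v in x]))
        assert -1e-12 <= g <= (len(x) - 1) / len(x) + 1e-12

    def test_session_mean_excludes_empty_vectors(self):
        counts = np.array([[1, 0, 2], [1, 0, 0]])
        mat = _matrix(counts, ["DS", "DS", "DS"])
        mean, n_excluded = mean_gini_sparsity(mat, "DS")
        assert n_excluded == 1
        assert mean == pytest.approx((gini_sparsity([1, 1]) + gini_sparsity([2, 0])) / 2)


# ----------------------------------------------------------------------
# coactive fraction
# ----------------------------------------------------------------------

class TestCoactive:
    def test_silent_and_full(self):
        mat = _matrix(np.array([[0, 3], [0, 1], [0, 2]]), ["DS", "DS"])
        frac = proportion_coactive(mat)["DS"]
        assert frac == pytest.approx((0.0 + 1.0) / 2)

    def test_matches_binary_column_mean(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(0.5, (25, 40))
        mat = _matrix(counts, ["SWR"] * 40)
        assert proportion_coactive(mat)["SWR"] == pytest.approx(
            float((counts > 0).mean(axis=0).mean())
        )


# ----------------------------------------------------------------------
# logistic discriminability
# ----------------------------------------------------------------------

class TestEventClassifier:
    def _support_separated(self, n_units=30, n_events=150, seed=0):
        rng = np.random.default_rng(seed)
        counts = np.zeros((n_units, 2 * n_events), int)
        counts[: n_units // 2, :n_events] = rng.poisson(2.0, (n_units // 2, n_events))
        counts[n_units // 2 :, n_events:] = rng.poisson(2.0, (n_units // 2, n_events))
        labels = ["DS"] * n_events + ["SWR"] * n_events
        return _matrix(counts, labels)

    def test_disjoint_supports_near_perfect(self):
        accs = train_event_classifier(self._support_separated(), seed=0)
        assert np.mean(accs) > 0.95

    def test_same_distribution_at_chance(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(1.0, (30, 300))
        mat = _matrix(counts, ["DS"] * 150 + ["SWR"] * 150)
        accs = train_event_classifier(mat, seed=0, n_runs=20)
        assert abs(np.mean(accs) - 0.5) < 0.06

    def test_label_permutation_null_centered_at_half(self):
        mat = self._support_separated(seed=2)
        rng = np.random.default_rng(3)
        perm_labels = rng.permutation(mat.event_labels)
        null_mat = PopulationVectorMatrix(mat.counts, perm_labels, mat.unit_ids)
        accs = train_event_classifier(null_mat, seed=0, n_runs=20)
        assert abs(np.mean(accs) - 0.5) < 0.07

    def test_single_class_errors(self):
        mat = _matrix(np.ones((5, 10), int), ["DS"] * 10)
        with pytest.raises(ValueError):
            train_event_classifier(mat)


# ----------------------------------------------------------------------
# similarity
# ----------------------------------------------------------------------

class TestSimilarity:
    def test_identical_vectors_similarity_one(self):
        counts = np.tile(np.array([[1], [0], [1], [1]]), (1, 6))
        mat = _matrix(counts, ["DS"] * 6)
        out = vector_similarity(mat, ("DS",))["DS"]
        assert out["pearson_mean"] == pytest.approx(1.0)
        assert out["jaccard_mean"] == pytest.approx(1.0)

    def test_disjoint_supports_jaccard_zero(self):
        counts = np.array([[1, 0], [1, 0], [0, 1], [0, 1]])
        mat = _matrix(counts, ["DS", "DS"])
        assert vector_similarity(mat, ("DS",))["DS"]["jaccard_mean"] == pytest.approx(0.0)

    def test_jaccard_matches_set_arithmetic(self):
        rng = np.random.default_rng(0)
        counts = (rng.uniform(size=(20, 12)) < 0.4).astype(int)
        mat = _matrix(counts, ["DS"] * 12)
        out = vector_similarity(mat, ("DS",), seed=0)["DS"]["jaccard_mean"]
        vals = []
        for a in range(12):
            for b in range(a + 1, 12):
                sa = set(np.flatnonzero(counts[:, a]))
                sb = set(np.flatnonzero(counts[:, b]))
                if sa | sb:
                    vals.append(len(sa & sb) / len(sa | sb))
        assert out == pytest.approx(np.mean(vals))

    def test_zero_variance_pairs_skipped(self):
        counts = np.array([[1, 1, 0], [1, 1, 1], [1, 1, 0]])  # col 1 all ones
        full = np.concatenate([counts, counts], axis=1)
        mat = _matrix(np.vstack([full, np.zeros((1, 6), int)]), ["DS"] * 6)
        out = vector_similarity(mat, ("DS",))["DS"]
        assert np.isfinite(out["jaccard_mean"])


# ----------------------------------------------------------------------
# dimensionality
# ----------------------------------------------------------------------

class TestDimensionality:
    def test_rank_one_matrix(self):
        base = np.arange(1, 26)
        counts = np.outer(base, np.ones(120, int))
        mat = _matrix(counts, ["DS"] * 120)
        out = population_dimensionality(mat, ("DS",))["DS"]
        assert out["n_components"] == 1
        assert out["scaled_dimensionality"] == pytest.approx(1 / 25)

    def test_white_noise_matches_direct_simulation(self):
        rng = np.random.default_rng(0)
        n_units, n_events = 25, 400
        counts = rng.poisson(3.0, (n_units, n_events))
        mat = _matrix(counts, ["DS"] * n_events)
        out = population_dimensionality(mat, ("DS",), seed=0)["DS"]
        # independent oracle: same-shape iid simulation, PCA by hand
        sims = []
        for s in range(5):
            x = np.random.default_rng(100 + s).poisson(3.0, (n_events, n_units)).astype(float)
            x -= x.mean(axis=0)
            sv = np.linalg.svd(x, compute_uv=False) ** 2
            cum = np.cumsum(sv) / sv.sum()
            sims.append((np.searchsorted(cum, 0.9 - 1e-12) + 1) / n_units)
        assert abs(out["scaled_dimensionality"] - np.mean(sims)) < 0.1

    def test_planted_low_rank_recovered(self):
        # non-negative rank-k structure + weak rounding noise: the 90%
        # variance target is reached by ~k components, far fewer than an
        # unstructured matrix of the same shape needs
        rng = np.random.default_rng(1)
        k, n_units, n_events = 3, 30, 300
        factors = rng.uniform(0, 1, (n_units, k))
        latents = rng.uniform(0, 3, (k, n_events))
        counts = np.round(5 * factors @ latents).astype(int)
        mat = _matrix(counts, ["DS"] * n_events)
        out = population_dimensionality(mat, ("DS",))["DS"]
        assert out["n_components"] <= k + 1
        white = _matrix(rng.poisson(3.0, (n_units, n_events)), ["DS"] * n_events)
        out_white = population_dimensionality(white, ("DS",))["DS"]
        assert out_white["n_components"] > 2 * out["n_components"]

    def test_minimum_units_enforced(self):
        mat = _matrix(np.ones((5, 50), int), ["DS"] * 50)
        with pytest.raises(ValueError):
            population_dimensionality(mat, ("DS",))
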