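"""Duration-independent feature computation and the classifier matrix."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from aupheno import catalog, features, ingest
from conftest import cohort_to_matrix, make_sequence


def brute_mean_sd(values):
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n
    return mean, var**0.5


class TestPresenceIntensityStats:
    def test_constant_presence(self):
        seq = make_sequence(n=6, presence=np.ones(6, int))
        assert features.compute_presence_stats(seq, 7) == (1.0, 0.0)

    def test_fair_binary_vector(self):
        seq = make_sequence(n=4, presence=[0, 1, 1, 0])
        assert features.compute_presence_stats(seq, 7) == (0.5, 0.5)

    def test_constant_intensity(self):
        seq = make_sequence(n=5, intensity=np.full(5, 2.5))
        assert features.compute_intensity_stats(seq, 12) == (2.5, 0.0)

    def test_au28_intensity_unavailable(self):
        seq = make_sequence(n=5)
        with pytest.raises(features.UnavailableChannelError):
            features.compute_intensity_stats(seq, 28)
        with pytest.raises(features.UnavailableChannelError):
            features.compute_presence_metric(seq, 28)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pres = rng.integers(0, 2, 1000)
        inten = rng.uniform(0, 5, 1000)
        seq = make_sequence(n=1000, presence=pres, intensity=inten)
        np.testing.assert_allclose(
            features.compute_presence_stats(seq, 7), brute_mean_sd(list(pres)), atol=1e-12
        )
        np.testing.assert_allclose(
            features.compute_intensity_stats(seq, 7), brute_mean_sd(list(inten)), atol=1e-12
        )


class TestPresenceMetric:
    def test_strict_inequality_at_threshold(self):
        seq = make_sequence(n=5, intensity=[0, 0.5, 1.0, 1.5, 5.0])
        assert features.compute_presence_metric(seq, 12) == pytest.approx(0.4)

    def test_all_zero(self):
        seq = make_sequence(n=5, intensity=np.zeros(5))
        assert features.compute_presence_metric(seq, 12) == 0.0

    def test_matches_linear_scan(self):
        rng = np.random.default_rng(7)
        inten = rng.uniform(0, 5, 1000)
        seq = make_sequence(n=1000, intensity=inten)
        expected = sum(1 for v in inten if v > 1.0) / 1000
        assert features.compute_presence_metric(seq, 12) == pytest.approx(expected)


class TestVariationMetric:
    def test_small_example(self):
        seq = make_sequence(n=5, presence=[0, 1, 1, 0, 1])
        assert features.compute_variation_metric(seq, 45) == pytest.approx(0.6)

    def test_constant_vector_no_flips(self):
        seq = make_sequence(n=50, presence=np.ones(50, int))
        assert features.compute_variation_metric(seq, 45) == 0.0

    def test_matches_adjacent_pair_scan(self):
        rng = np.random.default_rng(8)
        pres = rng.integers(0, 2, 1000)
        seq = make_sequence(n=1000, presence=pres)
        expected = sum(1 for a, b in zip(pres, pres[1:]) if a != b) / 1000
        assert features.compute_variation_metric(seq, 45) == pytest.approx(expected)

    def test_needs_two_frames(self):
        seq = make_sequence(n=1)
        with pytest.raises(ValueError):
            features.compute_variation_metric(seq, 45)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 1), min_size=2, max_size=200))
    def test_bounded_below_one(self, bits):
        seq = make_sequence(n=len(bits), presence=bits)
        v = features.compute_variation_metric(seq, 45)
        assert 0.0 <= v < 1.0


def test_duration_independence_under_frame_duplication():
    """Doubling every frame leaves the proportions/means unchanged and
    exactly halves the variation metric (flip count is preserved while
    the denominator doubles)."""
    rng = np.random.default_rng(9)
    pres = rng.integers(0, 2, 100)
    inten = rng.uniform(0, 5, 100)
    seq = make_sequence(n=100, presence=pres, intensity=inten)
    doubled = make_sequence(n=200, presence=np.repeat(pres, 2), intensity=np.repeat(inten, 2))
    assert features.compute_presence_stats(doubled, 7)[0] == pytest.approx(
        features.compute_presence_stats(seq, 7)[0]
    )
    assert features.compute_intensity_stats(doubled, 7)[0] == pytest.approx(
        features.compute_intensity_stats(seq, 7)[0]
    )
    assert features.compute_presence_metric(doubled, 7) == pytest.approx(
        features.compute_presence_metric(seq, 7)
    )
    assert features.compute_variation_metric(doubled, 45) == pytest.approx(
        features.compute_variation_metric(seq, 45) / 2
    )


class TestFeatureMatrix:
    def test_column_count_and_order(self, small_matrix):
        cols = small_matrix.feature_names
        assert len(cols) == 106  # 17 dual-channel AUs x 6 + AU28 x 4
        assert cols == catalog.feature_columns()
        dual = [c for c in cols if c.startswith("AU07_")]
        assert len(dual) == 6
        au28 = [c for c in cols if c.startswith("AU28_")]
        assert au28 == ["AU28_presence_mean", "AU28_presence_sd", "AU28_activity", "AU28_variation"]

    def test_qc_exclusion_removes_exactly_one_row(self, small_cohort):
        filtered, entries = [], []
        for p in small_cohort:
            f, e = ingest.filter_low_confidence(p.sequence)
            filtered.append(f)
            entries.append(e)
        qc = ingest.assess_validity(entries)
        full = features.build_feature_matrix(filtered, qc, {p.id: p.group for p in small_cohort})
        victim = full.X.index[0]
        for e in qc.entries:
            if e.participant_id == victim:
                e.included = False
        qc.excluded = sorted(qc.excluded + [victim])
        sub = features.build_feature_matrix(filtered, qc, {p.id: p.group for p in small_cohort})
        assert len(sub) == len(full) - 1
        assert victim not in sub.X.index

    def test_row_order_invariant_to_cohort_order(self, small_cohort):
        m1, _ = cohort_to_matrix(small_cohort)
        m2, _ = cohort_to_matrix(list(reversed(small_cohort)))
        pd.testing.assert_frame_equal(m1.X.sort_index(), m2.X.sort_index())

    def test_undefined_feature_names_participant(self):
        good = make_sequence(pid="ok", n=10)
        bad = make_sequence(pid="broken", n=10)
        bad.frames = bad.frames.iloc[:1]  # too short for variation
        qc = ingest.assess_validity(
            [ingest.QCEntry("ok", 10, 0, 1.0), ingest.QCEntry("broken", 1, 0, 1.0)]
        )
        with pytest.raises(ValueError, match="broken"):
            features.build_feature_matrix([good, bad], qc, {"ok": "case", "broken": "control"})

    def test_csv_roundtrip(self, small_matrix, tmp_path):
        path = tmp_path / "fm.csv"
        small_matrix.to_csv(path)
        back = features.FeatureMatrix.from_csv(path)
        pd.testing.assert_frame_equal(back.X, small_matrix.X)
        assert (back.labels == small_matrix.labels).all()


def test_realized_features_converge_to_latents():
    """With long sequences the realized metrics approach the generator's
    latent bookkeeping."""
    from aupheno import simulate

    cfg = simulate.CohortConfig(
        n_case=4, n_control=0, seed=21, fps=30, duration_mean_s=400,
        duration_jitter_s=0.0, contamination=0.0, rating_couplings={},
    )
    for p in simulate.generate_cohort(cfg):
        for au in (7, 12, 45):
            pres_t, inten_t, var_t = p.true_metrics[au]
            assert features.compute_presence_metric(p.sequence, au) == pytest.approx(pres_t, abs=0.05)
            assert features.compute_intensity_stats(p.sequence, au)[0] == pytest.approx(inten_t, abs=0.1)
            assert features.compute_variation_metric(p.sequence, au) == pytest.approx(var_t, abs=0.02)
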