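import numpy as np
import pytest

from crownprof import features, pipeline
from crownprof.features import (
    FEATURE_NAMES, FeatureSequence, build_sequences, fit_normalizer,
    split_dataset, to_dataset,
)


@pytest.fixture(scope="module")
def condition_args(prepared_module):
    prep = prepared_module
    plot = prep.plots[0]
    return (plot, prep.mean_profiles, prep.directional_profiles,
            prep.tables, prep.derived)


@pytest.fixture(scope="module")
def prepared_module():
    from crownprof import synthetic
    params = synthetic.StandParams(n_trees=40, seed=5)
    plots, _ = synthetic.generate_stands(params, 1, seed=5)
    return pipeline.prepare_stand(plots)


class TestBuildSequences:
    def test_feature_dimension_with_and_without_cpci(self, condition_args):
        with_cpci = build_sequences(*condition_args, use_cpci=True)
        without = build_sequences(*condition_args, use_cpci=False)
        assert with_cpci[0].x.shape == (10, 14)
        assert without[0].x.shape == (10, 13)
        assert with_cpci[0].feature_names == FEATURE_NAMES
        assert "CPCI" not in without[0].feature_names

    def test_ch_feature_steps_through_layers(self, condition_args):
        seqs = build_sequences(*condition_args)
        prep_derived = condition_args[4]
        ch_idx = FEATURE_NAMES.index("CH")
        for s in seqs[:5]:
            lcl = prep_derived[s.tree_id].lcl
            np.testing.assert_allclose(
                s.x[:, ch_idx], 0.1 * np.arange(1, 11) * lcl
            )

    def test_lag_feature_is_previous_target(self, condition_args):
        seqs = build_sequences(*condition_args)
        lag = FEATURE_NAMES.index("CR_lag")
        for s in seqs[:5]:
            assert s.x[0, lag] == 0.0          # treetop anchor
            np.testing.assert_allclose(s.x[1:, lag], s.y[:-1])

    def test_static_features_constant_across_steps(self, condition_args):
        seqs = build_sequences(*condition_args)
        for s in seqs[:5]:
            for name in ("AGE", "DBH", "TH", "CW", "HCB", "LCL", "BA", "SDI"):
                col = s.x[:, FEATURE_NAMES.index(name)]
                assert np.ptp(col) == 0.0

    def test_directional_mode_uses_directional_profiles(self, condition_args):
        plot, mean_p, dir_p, tables, derived = condition_args
        seqs_s = build_sequences(plot, mean_p, dir_p, tables, derived,
                                 direction_mode="S")
        for s in seqs_s[:5]:
            np.testing.assert_allclose(s.y, dir_p[s.tree_id]["S"].radii[1:])
            cp = s.x[:, FEATURE_NAMES.index("CPCI")]
            np.testing.assert_allclose(cp, tables[s.tree_id].directional["S"])

    def test_bottom_up_order_reverses_and_reseeds_lag(self, condition_args):
        td = build_sequences(*condition_args, step_order="top_down")
        bu = build_sequences(*condition_args, step_order="bottom_up")
        lag = FEATURE_NAMES.index("CR_lag")
        for a, b in zip(td[:3], bu[:3]):
            np.testing.assert_allclose(b.y, a.y[::-1])
            assert b.x[0, lag] == 0.0
            np.testing.assert_allclose(b.x[1:, lag], b.y[:-1])


class TestNormalizer:
    def test_min_max_maps_training_range_to_unit(self):
        x = np.zeros((3, 10, 2))
        x[:, :, 0] = np.array([2.0, 4.0, 6.0])[:, None]
        x[:, :, 1] = 1.0                        # constant variable
        seqs = [FeatureSequence(f"t{i}", "MEAN", x[i], x[i, :, 0], ("a", "b"))
                for i in range(3)]
        norm = fit_normalizer(seqs)
        xn = norm.transform_x(x)
        np.testing.assert_allclose(np.unique(xn[:, :, 0]), [0.0, 0.5, 1.0])
        np.testing.assert_allclose(xn[:, :, 1], 0.0)   # constant -> 0

    def test_inverse_transform_roundtrip(self, condition_args):
        seqs = build_sequences(*condition_args)
        norm = fit_normalizer(seqs)
        x = np.stack([s.x for s in seqs])
        np.testing.assert_allclose(norm.inverse_x(norm.transform_x(x)), x,
                                   atol=1e-9)
        y = np.stack([s.y for s in seqs])
        np.testing.assert_allclose(norm.inverse_y(norm.transform_y(y)), y,
                                   atol=1e-12)

    def test_out_of_range_values_not_clipped(self, condition_args):
        seqs = build_sequences(*condition_args)
        norm = fit_normalizer(seqs[:10])
        dbh = FEATURE_NAMES.index("DBH")
        probe = np.full((1, 10, len(FEATURE_NAMES)), norm.x_min)
        probe[0, :, dbh] = norm.x_max[dbh] * 2.0
        assert np.all(norm.transform_x(probe)[0, :, dbh] > 1.0)

    def test_targets_roundtrip_to_profile_radii(self, condition_args):
        seqs = build_sequences(*condition_args)
        norm = fit_normalizer(seqs)
        ds = to_dataset(seqs, norm)
        mean_profiles = condition_args[1]
        for i, s in enumerate(seqs):
            np.testing.assert_allclose(
                norm.inverse_y(ds.y[i]), mean_profiles[s.tree_id].radii[1:],
                atol=1e-12,
            )

    def test_empty_training_partition_rejected(self):
        with pytest.raises(ValueError):
            fit_normalizer([])


class TestSplitDataset:
    def _seqs(self, n_trees=100):
        rng = np.random.default_rng(0)
        return [
            FeatureSequence(f"t{i}", "MEAN", rng.uniform(size=(10, 3)),
                            rng.uniform(size=10), ("a", "b", "c"))
            for i in range(n_trees)
        ]

    def test_sizes_follow_ratios(self):
        train, val, test = split_dataset(self._seqs(100), seed=1)
        assert (len(train), len(val), len(test)) == (80, 10, 10)

    def test_deterministic_under_seed(self):
        a = split_dataset(self._seqs(), seed=7)
        b = split_dataset(self._seqs(), seed=7)
        for pa, pb in zip(a, b):
            assert [s.tree_id for s in pa] == [s.tree_id for s in pb]

    def test_partitions_disjoint_and_cover(self):
        seqs = self._seqs(53)
        train, val, test = split_dataset(seqs, seed=3)
        ids = [set(s.tree_id for s in p) for p in (train, val, test)]
        assert not (ids[0] & ids[1]) and not (ids[0] & ids[2]) \
            and not (ids[1] & ids[2])
        assert ids[0] | ids[1] | ids[2] == {s.tree_id for s in seqs}

    def test_tree_level_grouping(self):
        # two sequences (directions) per tree must co-locate
        seqs = self._seqs(30) + self._seqs(30)
        train, val, test = split_dataset(seqs, seed=5)
        for part in (train, val, test):
            counts = {}
            for s in part:
                counts[s.tree_id] = counts.get(s.tree_id, 0) + 1
            assert all(c == 2 for c in counts.values())

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(self._seqs(), ratios=(0.7, 0.2, 0.2), seed=0)
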