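import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crownprof.competition import (
    cpci_layers, directional_cpci, layer_gate, pair_overlap_area,
    total_overlap, voronoi_neighbors,
)

#: lens area of two unit circles 1 m apart: 2*pi/3 - sqrt(3)/2
UNIT_LENS = 2 * math.pi / 3 - math.sqrt(3) / 2


class TestLayerGate:
    @pytest.mark.parametrize("a,b,expected", [
        (3.0, 4.9, True),      # inside the 2 m threshold
        (3.0, 5.0, True),      # boundary counts as competing
        (3.0, 5.1, False),     # just outside
        (0.0, 0.0, True),
        (7.3, 7.3, True),
    ])
    def test_threshold(self, a, b, expected):
        assert layer_gate(a, b) is expected

    def test_negative_height_rejected(self):
        with pytest.raises(ValueError):
            layer_gate(-1.0, 0.5)


class TestPairOverlapArea:
    @pytest.mark.parametrize("r1,r2,d,expected", [
        (1.0, 1.0, 2.0, 0.0),                 # tangent -> disjoint boundary
        (1.0, 1.0, 5.0, 0.0),                 # far apart
        (1.0, 0.5, 0.1, math.pi * 0.25),      # small circle contained
        (0.5, 1.0, 0.1, math.pi * 0.25),      # containment is symmetric
        (1.0, 1.0, 1.0, UNIT_LENS),           # classic two-unit-circle lens
        (1.0, 1.0, 0.0, math.pi),             # coincident circles
        (0.0, 1.0, 0.5, 0.0),                 # zero-radius disc
    ])
    def test_reference_values(self, r1, r2, d, expected):
        assert pair_overlap_area(r1, r2, d) == pytest.approx(expected, abs=1e-9)

    def test_symmetric_in_radii(self, rng):
        for _ in range(200):
            r1, r2 = rng.uniform(0.1, 3.0, 2)
            d = rng.uniform(0.0, 6.0)
            assert pair_overlap_area(r1, r2, d) == pytest.approx(
                pair_overlap_area(r2, r1, d), rel=1e-12)

    def test_bounded_by_smaller_disc(self, rng):
        for _ in range(200):
            r1, r2 = rng.uniform(0.05, 3.0, 2)
            d = rng.uniform(0.0, 6.0)
            assert pair_overlap_area(r1, r2, d) <= math.pi * min(r1, r2) ** 2 + 1e-12

    def test_regime_continuity_at_boundaries(self, rng):
        # lens formula meets the disjoint and containment limits
        for _ in range(1000):
            r1, r2 = rng.uniform(0.1, 3.0, 2)
            outer = pair_overlap_area(r1, r2, r1 + r2)
            assert abs(outer) < 1e-6
            inner = pair_overlap_area(r1, r2, abs(r1 - r2))
            assert abs(inner - math.pi * min(r1, r2) ** 2) < 1e-6

    def test_monotone_decreasing_in_distance(self, rng):
        r1, r2 = 1.5, 1.0
        dists = np.linspace(0, 3.0, 50)
        areas = [pair_overlap_area(r1, r2, d) for d in dists]
        assert all(b <= a + 1e-12 for a, b in zip(areas, areas[1:]))

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            pair_overlap_area(-1.0, 1.0, 1.0)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        r1=st.floats(0.0, 5.0, allow_nan=False),
        r2=st.floats(0.0, 5.0, allow_nan=False),
        d=st.floats(0.0, 12.0, allow_nan=False),
    )
    def test_overlap_invariants_hold_everywhere(self, r1, r2, d):
        a = pair_overlap_area(r1, r2, d)
        assert 0.0 <= a <= math.pi * min(r1, r2) ** 2 + 1e-9
        assert a == pytest.approx(pair_overlap_area(r2, r1, d), abs=1e-12)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        radii=st.tuples(*[st.floats(0.0, 4.0, allow_nan=False)] * 4),
        cpci=st.floats(0.0, 10.0, allow_nan=False),
    )
    def test_directional_share_identity_everywhere(self, radii, cpci):
        shares = directional_cpci(cpci, dict(zip("EWSN", radii)))
        if sum(radii) == 0:
            assert all(v == 0.0 for v in shares.values())
        else:
            assert sum(shares.values()) == pytest.approx(3 * cpci, abs=1e-9)


class TestVoronoiNeighbors:
    def test_center_of_square_touches_all_corners(self):
        positions = {
            "c": (0.0, 0.0), "a": (5.0, 5.0), "b": (-5.0, 5.0),
            "d": (5.0, -5.0), "e": (-5.0, -5.0),
        }
        nb = voronoi_neighbors(positions, plot_radius=10.0)
        assert nb["c"].competitor_ids == {"a", "b", "d", "e"}

    def test_neighbor_relation_symmetric(self, rng):
        for _ in range(5):
            pts = rng.uniform(-12, 12, (30, 2))
            keep = np.hypot(pts[:, 0], pts[:, 1]) < 14
            positions = {f"t{i}": tuple(p) for i, p in enumerate(pts[keep])}
            nb = voronoi_neighbors(positions, plot_radius=15.0)
            for i, cs in nb.items():
                assert i not in cs.competitor_ids
                for j in cs.competitor_ids:
                    assert i in nb[j].competitor_ids

    def test_degenerate_collinear_falls_back_to_all_pairs(self):
        positions = {f"t{i}": (float(i), 0.0) for i in range(4)}
        nb = voronoi_neighbors(positions, plot_radius=10.0)
        assert nb["t0"].competitor_ids == {"t1", "t2", "t3"}

    def test_two_trees_fall_back_to_all_pairs(self):
        nb = voronoi_neighbors({"a": (0, 0), "b": (3, 0)}, plot_radius=10.0)
        assert nb["a"].competitor_ids == {"b"}

    def test_cell_polygons_cover_stems(self, rng):
        pts = rng.uniform(-8, 8, (15, 2))
        positions = {f"t{i}": tuple(p) for i, p in enumerate(pts)}
        nb = voronoi_neighbors(positions, plot_radius=12.0)
        from shapely.geometry import Point, Polygon
        for i, cs in nb.items():
            assert Polygon(cs.cell_polygon).buffer(1e-9).contains(
                Point(positions[i]))


def flat_profile(cr, lcl=5.0):
    """11-layer profile with constant radius below the top anchor."""
    radii = np.full(11, float(cr))
    radii[0] = 0.0
    heights = np.linspace(0, 1, 11) * lcl
    return radii, heights


class TestTotalOverlapAndCPCI:
    def test_no_competitors_zero(self):
        radii, heights = flat_profile(1.0)
        assert total_overlap(radii, heights, [], 5) == 0.0
        _, _, cpci = cpci_layers(radii, heights, [])
        np.testing.assert_array_equal(cpci, np.zeros(10))

    def test_single_gated_pair_equals_lens_area(self):
        # competitor crown lives only at layer 5 of an equal-LCL tree
        radii_i, heights_i = flat_profile(1.0)
        radii_j = np.zeros(11)
        radii_j[5] = 1.0
        _, heights_j = flat_profile(1.0)
        ao = total_overlap(radii_i, heights_i, [(radii_j, heights_j, 1.0)], 5)
        assert ao == pytest.approx(UNIT_LENS, abs=1e-9)

    def test_gate_excludes_distant_layers(self):
        # with LCL 5 each layer is 0.5 m; layer 1 vs layer 10 differ by 4.5 m
        radii_i, heights_i = flat_profile(1.0)
        radii_j = np.zeros(11)
        radii_j[10] = 1.0
        _, heights_j = flat_profile(1.0)
        assert total_overlap(radii_i, heights_i,
                             [(radii_j, heights_j, 1.0)], 1) == 0.0

    def test_area_scales_quadratically(self):
        radii_i, heights_i = flat_profile(1.0)
        radii_j, heights_j = flat_profile(1.0)
        base = total_overlap(radii_i, heights_i, [(radii_j, heights_j, 1.0)], 5)
        doubled = total_overlap(2 * radii_i, heights_i,
                                [(2 * radii_j, heights_j, 2.0)], 5)
        assert doubled == pytest.approx(4 * base, rel=1e-12)

    def test_two_identical_trees_single_pair_value(self):
        # one gated layer pair, CR 1 m, equal CH, stems 1 m apart:
        # CPCI = lens / (pi * 1^2) since the size ratio is 1
        radii_i = np.zeros(11)
        radii_i[5] = 1.0
        _, heights = flat_profile(1.0, lcl=20.0)  # layers 2 m apart -> only t=5 gated
        radii_j = radii_i.copy()
        _, _, cpci = cpci_layers(radii_i, heights, [(radii_j, heights, 1.0)])
        assert cpci[4] == pytest.approx(UNIT_LENS / math.pi, abs=1e-9)
        assert cpci[4] == pytest.approx(0.3910, abs=5e-4)

    def test_cpci_nondecreasing_in_competitor_radius(self):
        radii_i, heights = flat_profile(1.0)
        values = []
        for cr_j in np.linspace(0.5, 2.0, 12):
            radii_j, _ = flat_profile(cr_j)
            _, _, cpci = cpci_layers(radii_i, heights, [(radii_j, heights, 1.0)])
            values.append(cpci[5])
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_zero_subject_radius_gives_zero_cpci(self):
        radii_i = np.zeros(11)
        _, heights = flat_profile(1.0)
        radii_j, _ = flat_profile(1.0)
        _, _, cpci = cpci_layers(radii_i, heights, [(radii_j, heights, 0.5)])
        np.testing.assert_array_equal(cpci, np.zeros(10))


class TestDirectionalCPCI:
    def test_equal_radii_share_three_quarters(self):
        shares = directional_cpci(2.0, {d: 1.3 for d in "EWSN"})
        for d in "EWSN":
            assert shares[d] == pytest.approx(0.75 * 2.0)

    def test_direct_substitution(self):
        shares = directional_cpci(1.0, {"E": 2.0, "W": 1.0, "S": 1.0, "N": 0.0})
        assert shares == pytest.approx(
            {"E": 0.5, "W": 0.75, "S": 0.75, "N": 1.0})

    def test_shares_sum_to_three_cpci(self, rng):
        for _ in range(100):
            radii = dict(zip("EWSN", rng.uniform(0, 3, 4)))
            cpci = rng.uniform(0, 5)
            shares = directional_cpci(cpci, radii)
            assert sum(shares.values()) == pytest.approx(3 * cpci, abs=1e-12)

    def test_larger_radius_smaller_share(self, rng):
        shares = directional_cpci(1.0, {"E": 3.0, "W": 2.0, "S": 1.0, "N": 0.5})
        assert shares["E"] < shares["W"] < shares["S"] < shares["N"]

    def test_all_zero_radii_all_zero_shares(self):
        shares = directional_cpci(1.0, {d: 0.0 for d in "EWSN"})
        assert all(v == 0.0 for v in shares.values())

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            directional_cpci(1.0, {"E": -1.0, "W": 1.0, "S": 1.0, "N": 1.0})


class TestPlotLevel:
    def test_directional_identity_on_stand(self, prepared):
        for tid, tab in prepared.tables.items():
            total = sum(tab.directional[d] for d in "EWSN")
            np.testing.assert_allclose(total, 3 * tab.cpci, atol=1e-12)

    def test_crowded_trees_have_higher_cpci(self):
        # CPCI should rank-correlate with the crowding the generator injected.
        # Tested with gamma=0 so that crown size is independent of crowding:
        # with gamma>0 crowded crowns shrink, which suppresses their overlap
        # and confounds the purely geometric association.
        from scipy.stats import spearmanr
        from crownprof import pipeline, synthetic
        params = synthetic.StandParams(n_trees=150, gamma=0.0, seed=3)
        plots, truths = synthetic.generate_stands(params, 2, seed=3)
        prep = pipeline.prepare_stand(plots)
        mean_crowd, mean_cpci = [], []
        for truth in truths:
            for tid, t in truth.trees.items():
                if tid not in prep.tables:
                    continue
                mean_crowd.append(np.mean(list(t.crowding.values())))
                mean_cpci.append(prep.tables[tid].cpci.mean())
        rho, p = spearmanr(mean_crowd, mean_cpci)
        assert rho > 0
        assert p < 0.01
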