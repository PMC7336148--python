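"""Map rescaling, the Ave combination, thresholding and spatial metrics.

Every metric is checked against a brute-force recomputation of its defining
formula on random map/focus pairs, plus the hand-checkable special cases.
"""

import numpy as np
import pytest

from dmsi.anatomy import FocusRegion, distance_to_region, grow_patch
from dmsi.inverse_linear import SourceMap
from dmsi.maps_metrics import (
    THRESHOLD_GRID,
    ThresholdCurve,
    average_maps,
    dmin,
    dmin_reproducibility,
    inter_dmsi_distance,
    map_dmin,
    map_size,
    metrics_for_study,
    rescale_map,
    spatial_dispersion,
    threshold_curves,
    threshold_map,
)


def smap(values, label="MNE"):
    return SourceMap(np.asarray(values, dtype=float), label)


def random_map_focus(mesh, rng, label="MNE"):
    m = smap(rng.random(mesh.n_vertices) + 1e-6, label)
    seed = int(rng.integers(mesh.n_vertices))
    focus = grow_patch(mesh, seed, 12.0)
    return m, focus


class TestRescale:
    def test_affine_example(self):
        out = rescale_map(smap([2, 4, 6, 8, 10]))
        np.testing.assert_allclose(out.amplitudes, [0, 0.25, 0.5, 0.75, 1.0])

    def test_identity_on_unit_range(self):
        v = np.array([0.0, 0.3, 1.0])
        np.testing.assert_allclose(rescale_map(smap(v)).amplitudes, v)

    def test_constant_maps_to_zeros(self):
        assert np.all(rescale_map(smap([3.3, 3.3, 3.3])).amplitudes == 0)


class TestAverage:
    def test_four_identical_maps(self):
        m = rescale_map(smap([0.1, 0.9, 0.5]))
        out = average_maps([m, m, m, m])
        np.testing.assert_allclose(out.amplitudes, m.amplitudes)
        assert out.method_label == "Ave"

    def test_one_hot_arithmetic(self):
        e1 = smap([1.0, 0.0, 0.0])
        e2 = smap([0.0, 1.0, 0.0])
        out = average_maps([e1, e1, e2, e2])
        np.testing.assert_allclose(out.amplitudes, [0.5, 0.5, 0.0])

    def test_matches_elementwise_mean(self, rng):
        maps = [smap(rng.random(20)) for _ in range(4)]
        out = average_maps(maps)
        oracle = np.mean([m.amplitudes for m in maps], axis=0)
        np.testing.assert_allclose(out.amplitudes, oracle)

    def test_vertex_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="vertex counts"):
            average_maps([smap(rng.random(5)), smap(rng.random(6))])

    def test_shared_argmax_is_preserved(self, rng):
        idx = 7
        maps = []
        for _ in range(4):
            v = rng.random(20) * 0.5
            v[idx] = 1.0
            maps.append(smap(v))
        assert average_maps(maps).argmax() == idx


class TestThreshold:
    def test_zero_threshold_keeps_strictly_positive_map(self):
        v = np.arange(1, 101, dtype=float)
        assert map_size(threshold_map(smap(v), 0)) == 100

    def test_full_threshold_keeps_only_maximum(self):
        v = np.arange(1, 101, dtype=float)
        assert map_size(threshold_map(smap(v), 100)) == 1

    def test_half_threshold_example(self):
        out = threshold_map(smap([0.1, 0.4, 0.5, 1.0]), 50)
        np.testing.assert_allclose(out.amplitudes, [0, 0, 0.5, 1.0])

    def test_monotone_in_threshold(self, rng):
        m = smap(rng.random(50))
        sizes = [map_size(threshold_map(m, t)) for t in THRESHOLD_GRID]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))


class TestDmin:
    def test_argmax_inside_focus_is_zero(self, mesh500, rng):
        m, focus = random_map_focus(mesh500, rng)
        m.amplitudes[focus.vertex_ids[0]] = 10.0
        assert dmin(m, focus, mesh500) == 0.0

    def test_matches_brute_force(self, mesh500, rng):
        for _ in range(20):
            m, focus = random_map_focus(mesh500, rng)
            got = dmin(m, focus, mesh500)
            am = int(np.argmax(m.amplitudes))
            brute = min(
                np.linalg.norm(mesh500.vertices[am] - mesh500.vertices[j])
                for j in focus.vertex_ids
            )
            assert got == pytest.approx(brute, abs=1e-12)

    def test_all_zero_map_rejected(self, mesh500):
        with pytest.raises(ValueError, match="all-zero"):
            dmin(smap(np.zeros(mesh500.n_vertices)), FocusRegion([0]), mesh500)


class TestReproducibility:
    def test_identical_dmins_give_zero(self):
        out = dmin_reproducibility({("P1", "MNE"): [4.0, 4.0, 4.0]})
        assert out[("P1", "MNE")] == 0.0

    def test_linear_interpolation_quantiles(self):
        out = dmin_reproducibility({("P1", "MNE"): [1.0, 2.0, 3.0, 4.0]})
        assert out[("P1", "MNE")] == pytest.approx(1.5)

    def test_order_invariance(self, rng):
        vals = list(rng.random(9))
        a = dmin_reproducibility({("P", "m"): vals})
        b = dmin_reproducibility({("P", "m"): vals[::-1]})
        assert a == b

    def test_singletons_excluded(self):
        out = dmin_reproducibility({("P1", "MNE"): [2.0], ("P2", "MNE"): [1.0, 3.0]})
        assert ("P1", "MNE") not in out
        assert out["excluded"] == [("P1", "MNE")]


class TestInterDMSI:
    def test_coincident_maxima_give_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        out = inter_dmsi_distance({m: x for m in ("MNE", "dSPM", "sLORETA")})
        assert all(v == 0.0 for v in out.values())

    def test_collinear_example(self):
        pts = {"A": [0.0, 0, 0], "B": [3.0, 0, 0], "C": [6.0, 0, 0]}
        out = inter_dmsi_distance(pts)
        assert out == {"A": pytest.approx(4.5), "B": pytest.approx(3.0), "C": pytest.approx(4.5)}

    def test_matches_brute_force(self, rng):
        pts = {f"M{i}": rng.random(3) * 50 for i in range(5)}
        out = inter_dmsi_distance(pts)
        for k, x in pts.items():
            brute = np.mean(
                [np.linalg.norm(np.asarray(x) - np.asarray(y)) for kk, y in pts.items() if kk != k]
            )
            assert out[k] == pytest.approx(brute)

    def test_missing_method_adjusts_divisor(self):
        pts = {"A": [0.0, 0, 0], "B": [4.0, 0, 0], "C": None}
        out = inter_dmsi_distance(pts)
        assert out["A"] == pytest.approx(4.0)
        assert "C" not in out


class TestSpatialDispersion:
    def test_all_energy_in_focus_is_zero(self, mesh500):
        focus = grow_patch(mesh500, 10, 12.0)
        v = np.zeros(mesh500.n_vertices)
        v[focus.vertex_ids[0]] = 5.0
        assert spatial_dispersion(smap(v), focus, mesh500) == 0.0

    def test_hand_case_sqrt_fifty(self, mesh500):
        """Two equal amplitudes, one at distance 0 and one at 10 mm:
        SD = sqrt((0 + 100)/2) ~= 7.0711 mm."""
        focus = FocusRegion([0])
        d = distance_to_region(mesh500, focus)
        far = int(np.argmin(np.abs(d - 10.0)))
        # move that vertex to exactly 10 mm? instead weight exact distances
        v = np.zeros(mesh500.n_vertices)
        v[0] = 1.0
        v[far] = 1.0
        expect = np.sqrt(d[far] ** 2 / 2.0)
        assert spatial_dispersion(smap(v), focus, mesh500) == pytest.approx(expect)
        # and the printed hand value on an exact-geometry toy
        verts = np.array([[0, 0, 0], [10, 0, 0], [0, 10, 0], [0, 0, 10]], float)
        faces = np.array([[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]])
        from dmsi.anatomy import CorticalMesh

        toy = CorticalMesh.from_geometry(verts, faces)
        sd = spatial_dispersion(smap([1.0, 1.0, 0, 0]), FocusRegion([0]), toy)
        assert sd == pytest.approx(7.0711, abs=1e-4)

    def test_matches_brute_force_formula(self, mesh500, rng):
        for _ in range(20):
            m, focus = random_map_focus(mesh500, rng)
            got = spatial_dispersion(m, focus, mesh500)
            num = den = 0.0
            for i in range(mesh500.n_vertices):
                di = min(
                    np.linalg.norm(mesh500.vertices[i] - mesh500.vertices[j])
                    for j in focus.vertex_ids
                )
                num += di**2 * m.amplitudes[i] ** 2
                den += m.amplitudes[i] ** 2
            assert got == pytest.approx(np.sqrt(num / den), abs=1e-9)

    def test_sd_squared_variant(self, mesh500, rng):
        m, focus = random_map_focus(mesh500, rng)
        sd = spatial_dispersion(m, focus, mesh500)
        sd2 = spatial_dispersion(m, focus, mesh500, sd_squared=True)
        assert sd2 == pytest.approx(sd**2)

    def test_invariant_to_positive_rescaling(self, mesh500, rng):
        m, focus = random_map_focus(mesh500, rng)
        a = spatial_dispersion(m, focus, mesh500)
        b = spatial_dispersion(smap(7.7 * m.amplitudes), focus, mesh500)
        assert a == pytest.approx(b)


class TestMapDmin:
    def test_active_vertex_in_focus_gives_zero(self, mesh500, rng):
        m, focus = random_map_focus(mesh500, rng)
        assert map_dmin(m, focus, mesh500) == 0.0  # unthresholded: all active

    def test_single_active_vertex_reduces_to_dmin(self, mesh500):
        focus = grow_patch(mesh500, 3, 10.0)
        v = np.zeros(mesh500.n_vertices)
        v[200] = 1.0
        m = smap(v)
        assert map_dmin(m, focus, mesh500) == pytest.approx(dmin(m, focus, mesh500))

    def test_matches_brute_force(self, mesh500, rng):
        for _ in range(10):
            m, focus = random_map_focus(mesh500, rng)
            tm = threshold_map(m, 80)
            got = map_dmin(tm, focus, mesh500)
            active = np.flatnonzero(tm.amplitudes)
            brute = min(
                np.linalg.norm(mesh500.vertices[i] - mesh500.vertices[j])
                for i in active
                for j in focus.vertex_ids
            )
            assert got == pytest.approx(brute, abs=1e-12)


class TestCurves:
    def test_eleven_points_and_monotonicity(self, mesh500, rng):
        m, focus = random_map_focus(mesh500, rng)
        curves = threshold_curves(m, focus, mesh500)
        for c in curves.values():
            assert len(c.values) == 11
        assert np.all(np.diff(curves["MapSize"].values) <= 0)
        assert np.all(np.diff(curves["MapDmin"].values) >= -1e-12)

    def test_pointwise_recomputation(self, mesh500, rng):
        m, focus = random_map_focus(mesh500, rng)
        curves = threshold_curves(m, focus, mesh500)
        for i, t in enumerate(THRESHOLD_GRID):
            tm = threshold_map(m, t)
            assert curves["SD"].values[i] == pytest.approx(
                spatial_dispersion(tm, focus, mesh500)
            )
            assert curves["MapSize"].values[i] == map_size(tm)
            assert curves["MapDmin"].values[i] == pytest.approx(
                map_dmin(tm, focus, mesh500)
            )

    def test_sd_at_full_threshold_equals_dmin(self, mesh500, rng):
        """At 100% only the argmax survives, so SD collapses to Dmin."""
        m, focus = random_map_focus(mesh500, rng)
        curves = threshold_curves(m, focus, mesh500)
        assert curves["SD"].values[-1] == pytest.approx(dmin(m, focus, mesh500))

    def test_curve_validation_rejects_wrong_grid(self):
        with pytest.raises(ValueError):
            ThresholdCurve((0, 50, 100), "SD", np.zeros(3))

    def test_mapsize_monotonicity_enforced(self):
        vals = np.arange(11, dtype=float)  # increasing: invalid for MapSize
        with pytest.raises(ValueError, match="nonincreasing"):
            ThresholdCurve(THRESHOLD_GRID, "MapSize", vals)


def test_metrics_table_shape(mesh500, rng):
    maps = {
        lab: smap(rng.random(mesh500.n_vertices) + 1e-6, lab)
        for lab in ("MNE", "sLORETA", "dSPM", "cMEM", "Ave")
    }
    focus = grow_patch(mesh500, 50, 12.0)
    table = metrics_for_study(maps, focus, mesh500, patient_id="P1", study_id="S1")
    assert len(table) == 5 * 11
    assert set(table["method"]) == set(maps)
    assert (table["dmin_mm"] >= 0).all()
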