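"""Apical-basal position, orientation, neighbor networks and tubule indices."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import cdist

from conftest import make_nucleus
from semiq import morphometrics as morph
from semiq.types import CELL_TYPES, CellType


def _circular_mask(shape, center, radius):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return np.hypot(yy - center[0], xx - center[1]) <= radius


class TestApicalBasalPosition:
    def test_centroid_is_fully_apical(self):
        mask = _circular_mask((401, 401), (200, 200), 180)
        assert morph.apical_basal_position((200, 200), (200, 200), mask) == pytest.approx(1.0)

    def test_boundary_is_basal(self):
        mask = _circular_mask((401, 401), (200, 200), 180)
        abp = morph.apical_basal_position((200, 380), (200, 200), mask)
        assert abp == pytest.approx(0.0, abs=0.02)

    def test_half_radius_is_midpoint(self):
        mask = _circular_mask((401, 401), (200, 200), 180)
        abp = morph.apical_basal_position((200, 290), (200, 200), mask)
        assert abp == pytest.approx(0.5, abs=0.02)

    def test_monotone_along_ray(self):
        mask = _circular_mask((401, 401), (200, 200), 180)
        cols = np.arange(205, 376, 10)
        abps = [morph.apical_basal_position((200, c), (200, 200), mask) for c in cols]
        assert all(a > b for a, b in zip(abps, abps[1:]))
        assert all(0 <= a <= 1 for a in abps)

    def test_outside_mask_rejected(self):
        mask = _circular_mask((100, 100), (50, 50), 20)
        with pytest.raises(ValueError):
            morph.apical_basal_position((5, 5), (50, 50), mask)


class TestRelativeOrientation:
    def test_radial_axis_is_zero(self):
        # nucleus straight right of the centroid, axis pointing at it
        assert morph.relative_orientation(0.0, (100, 200), (100, 100)) == pytest.approx(0.0)

    def test_perpendicular_axis_is_ninety(self):
        assert morph.relative_orientation(90.0, (100, 200), (100, 100)) == pytest.approx(90.0)

    def test_oblique_axis_folds_to_acute(self):
        # axis at 135° to the radial direction folds to 45°
        assert morph.relative_orientation(-45.0, (100, 200), (100, 100)) == pytest.approx(45.0)

    @given(
        axis=st.floats(-90, 89.999),
        angle=st.floats(0, 2 * math.pi),
        rot=st.floats(0, 2 * math.pi),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_invariant_under_axis_flip_and_frame_rotation(self, axis, angle, rot):
        nucleus = (100 + 50 * math.sin(angle), 100 + 50 * math.cos(angle))
        base = morph.relative_orientation(axis, nucleus, (100, 100))
        flipped_axis = ((axis + 180) + 90) % 180 - 90
        assert morph.relative_orientation(flipped_axis, nucleus, (100, 100)) == pytest.approx(
            base, abs=1e-6
        )
        # rotate nucleus position and axis together around the centroid
        dr, dc = nucleus[0] - 100, nucleus[1] - 100
        cr, sr = math.cos(rot), math.sin(rot)
        rotated = (100 + dr * cr - dc * sr, 100 + dr * sr + dc * cr)
        rot_axis = ((axis + math.degrees(rot)) + 90) % 180 - 90
        assert morph.relative_orientation(rot_axis, rotated, (100, 100)) == pytest.approx(
            base, abs=1e-6
        )

    def test_coincident_centroids_rejected(self):
        with pytest.raises(ValueError):
            morph.relative_orientation(0.0, (5, 5), (5, 5))


def _tubule_records(rng, n, types=None):
    types = types or list(CELL_TYPES)
    recs = []
    for i in range(n):
        recs.append(
            make_nucleus(
                id=i + 1,
                centroid=(float(rng.uniform(0, 300)), float(rng.uniform(0, 300))),
                call=types[rng.integers(0, len(types))],
                abp=float(rng.uniform(0, 1)),
            )
        )
    return recs


class TestNeighborNetwork:
    def test_two_cells_mutual_edges(self):
        a = make_nucleus(id=1, call=CellType.SPG, centroid=(0, 0), abp=0.1)
        b = make_nucleus(id=2, call=CellType.SPC, centroid=(3, 4), abp=0.4)
        edges = morph.nearest_neighbor_network([a, b])
        assert len(edges) == 2
        assert {(e.reference_id, e.target_id) for e in edges} == {(1, 2), (2, 1)}
        assert all(e.euclidean_px == pytest.approx(5.0) for e in edges)

    def test_three_cell_worked_example(self):
        spg = make_nucleus(id=1, call=CellType.SPG, centroid=(0, 0), abp=0.1)
        spc_near = make_nucleus(id=2, call=CellType.SPC, centroid=(3, 0), abp=0.3)
        spc_far = make_nucleus(id=3, call=CellType.SPC, centroid=(0, 4), abp=0.3)
        edges = morph.nearest_neighbor_network([spg, spc_near, spc_far])
        spg_edge = next(e for e in edges if e.reference_id == 1)
        assert spg_edge.target_id == 2 and spg_edge.euclidean_px == pytest.approx(3.0)

    def test_single_type_tubule_has_no_edges(self):
        recs = [
            make_nucleus(id=i + 1, call=CellType.ESPD, centroid=(i * 10.0, 0), abp=0.7)
            for i in range(5)
        ]
        assert morph.nearest_neighbor_network(recs) == []

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        recs = _tubule_records(rng, 50)
        edges = morph.nearest_neighbor_network(recs)
        # oracle: all-pairs distances, independent scan
        by_id = {r.id: r for r in recs}
        coords = np.array([r.centroid for r in recs])
        dmat = cdist(coords, coords)
        expected = {}
        for i, ref in enumerate(recs):
            for t in set(r.call for r in recs) - {ref.call}:
                cand = [(dmat[i, j], recs[j].id) for j in range(len(recs)) if recs[j].call == t]
                expected[(ref.id, t)] = min(cand)
        assert len(edges) == len(expected)
        for e in edges:
            d, tid = expected[(e.reference_id, e.target_type)]
            assert e.euclidean_px == pytest.approx(d)
            assert e.target_id == tid
            assert e.radial_signed == pytest.approx(by_id[tid].abp - by_id[e.reference_id].abp)


class TestNeighborSummary:
    def test_mutual_pair_counts(self):
        a = make_nucleus(id=1, call=CellType.SPG, centroid=(0, 0), abp=0.1)
        b = make_nucleus(id=2, call=CellType.SPC, centroid=(3, 4), abp=0.3)
        edges = morph.nearest_neighbor_network([a, b])
        s = morph.neighbor_summary(edges, n_tubules=1)
        assert s.pair_counts.loc["SPG", "SPC"] == 1
        assert s.pair_counts.loc["SPC", "SPG"] == 1

    def test_signed_radial_displacement(self):
        spg = make_nucleus(id=1, call=CellType.SPG, centroid=(0, 0), abp=0.3)
        spc = make_nucleus(id=2, call=CellType.SPC, centroid=(0, 10), abp=0.5)
        edges = morph.nearest_neighbor_network([spg, spc])
        s = morph.neighbor_summary(edges, n_tubules=1)
        assert s.mean_radial_signed.loc["SPG", "SPC"] == pytest.approx(0.2)
        assert s.mean_radial_signed.loc["SPC", "SPG"] == pytest.approx(-0.2)

    def test_no_edges_all_missing(self):
        s = morph.neighbor_summary([], n_tubules=3)
        assert s.mean_euclidean_px.isna().all().all()
        assert (s.pair_counts.to_numpy() == 0).all()

    def test_pair_count_row_sum_counts_references_with_neighbors(self):
        rng = np.random.default_rng(9)
        recs = _tubule_records(rng, 30)
        edges = morph.nearest_neighbor_network(recs)
        s = morph.neighbor_summary(edges, n_tubules=1)
        types_present = {r.call for r in recs}
        for t in CELL_TYPES:
            n_ref = sum(1 for r in recs if r.call == t and len(types_present - {t}) > 0)
            assert s.pair_counts.loc[t.label].sum() == pytest.approx(n_ref)

    def test_zero_tubules_rejected(self):
        with pytest.raises(ValueError):
            morph.neighbor_summary([], 0)


class TestSpermatogenicIndex:
    def test_ideal_meiosis_ratio(self):
        assert morph.spermatogenic_index(
            {CellType.ESPD: 40, CellType.SPG: 10}
        ) == pytest.approx(4.0)

    def test_zero_spermatids(self):
        assert morph.spermatogenic_index({CellType.ESPD: 0, CellType.SPG: 10}) == 0.0

    def test_no_spermatogonia_is_missing(self):
        assert math.isnan(morph.spermatogenic_index({CellType.ESPD: 5, CellType.SPG: 0}))


class TestLumenRadii:
    def _annular_nuclei(self, shape, center, r_free, r_out):
        nuc = np.zeros(shape, np.int32)
        k = 1
        for r in np.arange(r_free + 5, r_out, 24.0):
            for t in np.linspace(0, 2 * np.pi, max(8, int(2 * np.pi * r / 30)), endpoint=False):
                rr = int(center[0] + r * np.sin(t))
                cc = int(center[1] + r * np.cos(t))
                nuc[max(rr - 5, 0) : rr + 5, max(cc - 5, 0) : cc + 5] = k
                k += 1
        return nuc

    def test_free_central_disk_recovered(self):
        tub = _circular_mask((900, 900), (450, 450), 420)
        nuc = self._annular_nuclei((900, 900), (450, 450), 120, 400)
        t_r, l_r, ratio = morph.tubule_lumen_radii(tub, nuc, um_per_px=1.0)
        assert abs(l_r - 120) / 120 < 0.15
        assert t_r == pytest.approx(420, rel=0.01)
        assert 0 < ratio < 1

    def test_uniformly_filled_tubule_has_smaller_ratio(self):
        tub = _circular_mask((900, 900), (450, 450), 420)
        annular = self._annular_nuclei((900, 900), (450, 450), 120, 400)
        filled = self._annular_nuclei((900, 900), (450, 450), 20, 400)
        _, _, ratio_annular = morph.tubule_lumen_radii(tub, annular, 1.0)
        _, _, ratio_filled = morph.tubule_lumen_radii(tub, filled, 1.0)
        assert ratio_filled < ratio_annular

    def test_empty_tubule_degenerates_to_unit_ratio(self):
        tub = _circular_mask((300, 300), (150, 150), 100)
        t_r, l_r, ratio = morph.tubule_lumen_radii(tub, np.zeros((300, 300), np.int32), 1.0)
        assert ratio == pytest.approx(1.0)
        assert l_r == pytest.approx(t_r)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            morph.tubule_lumen_radii(np.zeros((10, 10), bool), np.zeros((10, 10), np.int32), 1.0)


class TestSummaries:
    def test_counts_conservation(self):
        recs = [make_nucleus(id=i + 1, call=CellType.SPC, centroid=(i * 30.0, 40)) for i in range(10)]
        tub = _circular_mask((400, 400), (200, 200), 150)
        out = morph.summarize_tubule(recs, tub, None, um_per_px=0.17)
        assert out["counts"][CellType.SPC] == 10
        assert sum(out["counts"].values()) == out["n_nuclei"] == 10
        assert math.isnan(out["spermatogenic_index"])  # no SPG present


class TestImprobableClassFilter:
    def test_disallowed_call_dropped(self):
        rec = make_nucleus(call=CellType.ESPD)
        out = morph.filter_improbable_classes(
            [rec], {CellType.SERTOLI, CellType.SPG, CellType.SPC}
        )
        assert out == []

    def test_renormalization_arithmetic(self):
        rec = make_nucleus(probs=[0, 0.2, 0.5, 0, 0.3, 0, 0])  # SPC call, rSPD mass
        (out,) = morph.filter_improbable_classes(
            [rec], {CellType.SERTOLI, CellType.SPG, CellType.SPC}
        )
        assert out.probs[int(CellType.SPC)] == pytest.approx(0.5 / 0.7)
        assert out.probs[int(CellType.SPG)] == pytest.approx(0.2 / 0.7)
        assert out.call is CellType.SPC
        assert out.probs.sum() == pytest.approx(1.0)

    def test_pure_allowed_record_unchanged(self):
        rec = make_nucleus(probs=[1, 0, 0, 0, 0, 0, 0])
        (out,) = morph.filter_improbable_classes([rec], {CellType.SERTOLI})
        np.testing.assert_allclose(out.probs, rec.probs)

    def test_empty_allowed_set_rejected(self):
        with pytest.raises(ValueError):
            morph.filter_improbable_classes([make_nucleus()], set())
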