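import numpy as np
import pytest

import impelo
from impelo.beam_model import CTCalibrationCurve
from impelo.dose_engine import BeamGeometry, assemble_influence, place_spots
from oracles import wepl_fine_integration


class TestWEPL:
    def test_uniform_water(self, water_small, calibration):
        p0 = np.array([51.0, 100.0, 51.0])
        p1 = np.array([51.0, 0.0, 51.0])
        w = impelo.wepl_along_ray(water_small, calibration, p0, p1)
        assert w == pytest.approx(100.0, abs=1e-9)

    def test_half_density_scales_linearly(self, water_small):
        curve = CTCalibrationCurve(hu=[-1000.0, 0.0], density=[0.0, 1.0])
        ph = impelo.Phantom(
            hu=np.full(water_small.shape, -500.0),
            spacing=water_small.spacing,
            origin=water_small.origin,
        )
        w = impelo.wepl_along_ray(ph, curve, [51, 100, 51], [51, 0, 51])
        assert w == pytest.approx(50.0, abs=1e-9)

    def test_heterogeneous_slab_matches_fine_integration(self, calibration):
        rng = np.random.default_rng(0)
        hu = rng.choice([-700.0, 0.0, 300.0, 900.0], size=(30, 30, 30))
        ph = impelo.Phantom(hu=hu, spacing=[2.0] * 3, origin=[1.0] * 3)
        for _ in range(5):
            p0 = rng.uniform(0, 60, size=3)
            p1 = rng.uniform(0, 60, size=3)
            if np.linalg.norm(p1 - p0) < 5:
                continue
            w = impelo.wepl_along_ray(ph, calibration, p0, p1)
            w_ref = wepl_fine_integration(ph, calibration, p0, p1, step=0.01)
            assert abs(w - w_ref) < 0.1

    def test_zero_length_ray_rejected(self, water_small, calibration):
        with pytest.raises(ValueError, match="zero-length"):
            impelo.wepl_along_ray(water_small, calibration, [5, 5, 5], [5, 5, 5])


def _single_beam(phantom, angle=0.0):
    mid = phantom.origin + 0.5 * phantom.spacing * (np.array(phantom.shape) - 1)
    return BeamGeometry(gantry_angle_deg=angle, iso=mid)


@pytest.fixture(scope="module")
def water_case(model, calibration):
    ph = impelo.make_water_phantom(120.0, 2.0)
    ctv = np.zeros(ph.shape, dtype=bool)
    ctv[25:35, 25:35, 25:35] = True  # 2 cm cube
    geom = _single_beam(ph)
    ss = place_spots(ph, calibration, ctv, [geom], model, margin=5.0)
    return ph, ctv, geom, ss


@pytest.fixture(scope="module")
def tiny(calibration, model):
    ph = impelo.make_water_phantom(80.0, 4.0)
    ctv = np.zeros(ph.shape, dtype=bool)
    ctv[8:13, 8:13, 8:13] = True
    geom = _single_beam(ph)
    ss = place_spots(ph, calibration, ctv, [geom], model, lateral_spacing=8.0)
    infl = assemble_influence(ph, calibration, ss, model, cutoff=0.0)
    return ph, geom, ss, infl


class TestPlaceSpots:
    def test_selected_ranges_cover_target_wepl(self, water_case, model,
                                               calibration):
        """Selected layers are exactly those whose r80 falls in the target
        WEPL window [min - margin, max + margin], recomputed independently
        per target voxel by straight-ray WEPL in water."""
        ph, ctv, geom, ss = water_case
        # water: WEPL to a voxel = distance from the beam entry plane (y max)
        ys = ph.axis_coords(1)[np.unique(np.argwhere(ctv)[:, 1])]
        depth_min = ph.upper_corner[1] - ys.max()
        depth_max = ph.upper_corner[1] - ys.min() + ph.spacing[1]
        selected = sorted({model.layers[b.energy_index].r80 for b in ss.blocks})
        lo, hi = depth_min - 5.0 - 1.0, depth_max + 5.0 + 1.0
        assert all(lo <= r <= hi for r in selected)
        # completeness: every model layer strictly inside the window is used
        inside = [l.r80 for l in model.layers
                  if depth_min - 5.0 + 1.0 < l.r80 < depth_max + 5.0 - 1.0]
        assert set(np.round(inside, 6)) <= set(np.round(selected, 6))

    def test_lateral_coverage_of_target(self, water_case):
        ph, ctv, geom, ss = water_case
        pts = ph.origin[None, :] + np.argwhere(ctv) * ph.spacing[None, :]
        rel = pts - geom.iso[None, :]
        px, py = rel @ geom.ex, rel @ geom.ey
        spot_xy = np.unique(
            [(s.x, s.y) for s in ss.spots], axis=0
        )
        d2 = (px[:, None] - spot_xy[None, :, 0]) ** 2 + \
             (py[:, None] - spot_xy[None, :, 1]) ** 2
        spacing = np.diff(np.unique(spot_xy[:, 0]))[0]
        assert np.sqrt(d2.min(axis=1)).max() <= spacing * np.sqrt(2) / 2 + 1e-6

    def test_block_partition_and_ordering(self, water_case, model):
        _, _, _, ss = water_case
        ss.validate_partition()
        r80s = [model.layers[b.energy_index].r80 for b in ss.blocks]
        assert all(a > b for a, b in zip(r80s, r80s[1:]))  # distal first

    def test_doubling_spacing_never_adds_spots(self, water_case, model,
                                               calibration):
        ph, ctv, geom, _ = water_case
        s1 = place_spots(ph, calibration, ctv, [geom], model, lateral_spacing=4.0)
        s2 = place_spots(ph, calibration, ctv, [geom], model, lateral_spacing=8.0)
        assert len(s2) <= len(s1)

    def test_empty_target_rejected(self, water_small, calibration, model):
        with pytest.raises(ValueError, match="empty"):
            place_spots(water_small, calibration,
                        np.zeros(water_small.shape, bool),
                        [_single_beam(water_small)], model)

    def test_target_beyond_max_range_names_limit(self, calibration):
        shallow = impelo.BeamModel(
            layers=[impelo.synthesize_bragg_idd(e) for e in (70.0, 75.0)]
        )
        ph = impelo.make_water_phantom(300.0, 4.0)
        ctv = np.zeros(ph.shape, dtype=bool)
        ctv[35:40, 35:40, 35:40] = True  # ~ 150 mm deep from any face
        with pytest.raises(ValueError, match="r80"):
            place_spots(ph, calibration, ctv, [_single_beam(ph)], shallow)


class TestSpotDose:
    def test_central_axis_value_at_peak(self, water_single_spot):
        """On the axis the dose is IDD(depth) / (2 pi sx sy) with the
        divergence-scaled air sigma in quadrature with the scattering term."""
        ph, geom, layer, spot, dose = water_single_spot
        i = ph.shape[0] // 2
        k = ph.shape[2] // 2
        depths = ph.upper_corner[1] - ph.axis_coords(1)
        j = int(np.argmin(np.abs(depths - layer.peak_depth)))
        w = depths[j]
        zeta = (ph.axis_coords(1)[j] - geom.iso[1]) * geom.u0[1]
        from impelo.beam_model import sigma_mcs
        sx = np.sqrt((layer.sigma_air * (geom.sad_x + zeta) / geom.sad_x) ** 2
                     + sigma_mcs(layer, w) ** 2)
        sy = np.sqrt((layer.sigma_air * (geom.sad_y + zeta) / geom.sad_y) ** 2
                     + sigma_mcs(layer, w) ** 2)
        expected = layer.idd_at(w) / (2 * np.pi * sx * sy)
        assert dose[i, j, k] == pytest.approx(expected, rel=1e-6)

    def test_lateral_sum_recovers_idd(self, water_single_spot):
        ph, geom, layer, spot, dose = water_single_spot
        area = ph.spacing[0] * ph.spacing[2]
        depths = ph.upper_corner[1] - ph.axis_coords(1)
        sums = dose.sum(axis=(0, 2)) * area
        check = (depths > 5.0) & (depths < layer.r80)
        idd = layer.idd_at(depths[check])
        assert np.all(np.abs(sums[check] - idd) <= 0.02 * idd)

    def test_nonnegative(self, water_single_spot):
        *_, dose = water_single_spot
        assert np.all(dose >= 0)

    def test_peak_depth_on_axis_within_one_step(self, water_single_spot):
        ph, geom, layer, spot, dose = water_single_spot
        i, k = ph.shape[0] // 2, ph.shape[2] // 2
        depths = ph.upper_corner[1] - ph.axis_coords(1)
        j = int(np.argmax(dose[i, :, k]))
        assert abs(depths[j] - layer.peak_depth) <= ph.spacing[1] + 1e-9


class TestInfluenceAssembly:
    def test_columns_match_individual_spot_dose(self, tiny, calibration, model):
        ph, geom, ss, infl = tiny
        j = len(ss.spots) // 2
        idx, vals = impelo.spot_dose(ph, calibration, ss.spots[j], geom, model,
                                     cutoff=0.0)
        col = infl.D[:, j].toarray().ravel()
        expected = np.zeros(ph.n_voxels)
        expected[idx] = vals
        np.testing.assert_allclose(col, expected, rtol=1e-12)

    def test_sum_of_columns_equals_unit_dose(self, tiny, calibration, model):
        ph, geom, ss, infl = tiny
        d = impelo.dose_from_weights(infl, np.ones(len(ss.spots)))
        total = np.zeros(ph.n_voxels)
        for s in ss.spots:
            idx, vals = impelo.spot_dose(ph, calibration, s, geom, model,
                                         cutoff=0.0)
            total[idx] += vals
        np.testing.assert_allclose(d.values, total, rtol=1e-9, atol=1e-12)

    def test_dose_linearity_and_basis_vectors(self, tiny):
        *_, infl = tiny
        n = infl.D.shape[1]
        rng = np.random.default_rng(0)
        x1, x2 = rng.random(n), rng.random(n)
        d1 = impelo.dose_from_weights(infl, x1).values
        d2 = impelo.dose_from_weights(infl, x2).values
        d12 = impelo.dose_from_weights(infl, x1 + x2).values
        np.testing.assert_allclose(d12, d1 + d2, rtol=1e-12, atol=1e-12)
        e3 = np.zeros(n)
        e3[3] = 1.0
        np.testing.assert_allclose(
            impelo.dose_from_weights(infl, e3).values,
            infl.D[:, 3].toarray().ravel(),
        )
        assert np.all(impelo.dose_from_weights(infl, np.zeros(n)).values == 0)

    def test_block_restriction_reproduces_full_product(self, tiny):
        """Dx equals the sum over blocks of D_i x_i (block decomposition)."""
        *_, infl = tiny
        rng = np.random.default_rng(1)
        x = rng.random(infl.D.shape[1])
        total = np.zeros(infl.D.shape[0])
        for blk in infl.blocks:
            total += infl.D[:, blk.cols] @ x[blk.cols]
        np.testing.assert_allclose(total, infl.D @ x, rtol=1e-12)

    def test_dimension_mismatch_rejected(self, tiny):
        *_, infl = tiny
        with pytest.raises(ValueError, match="length"):
            impelo.dose_from_weights(infl, np.ones(infl.D.shape[1] + 1))

    def test_memory_guard(self, tiny, calibration, model):
        ph, geom, ss, _ = tiny
        with pytest.raises(MemoryError, match="budget"):
            assemble_influence(ph, calibration, ss, model, nnz_budget=10)
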