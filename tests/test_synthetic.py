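"""Phantom geometry, emitter sampling, and the acquisition/rendering model."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from npquant import synthetic as syn
from npquant.psfmetrics import extract_profile, fit_gaussian

from conftest import emitter_row, single_emitter


class TestPhantom:
    def test_voxelized_volume_matches_analytic(self):
        ph = syn.build_phantom(cell_semiaxes_um=(20.0, 15.0, 8.0),
                               nucleus_semiaxes_um=(6.0, 5.0, 3.0))
        vox = ph.voxelize((200.0, 200.0, 200.0))
        voxel_um3 = 0.2**3
        assert vox.sum() * voxel_um3 == pytest.approx(ph.volume_um3, rel=0.01)
        # analytic value: half-ellipsoid (2/3) pi a b c
        assert ph.volume_um3 == pytest.approx(2 / 3 * np.pi * 20 * 15 * 8, rel=1e-12)

    def test_default_cell_size_is_realistic(self):
        assert syn.build_phantom().volume_um3 == pytest.approx(1600.0, rel=0.01)

    def test_oversized_nucleus_rejected(self):
        with pytest.raises(ValueError):
            syn.build_phantom(cell_semiaxes_um=(8.0, 6.0, 4.0),
                              nucleus_semiaxes_um=(9.0, 2.0, 2.0))

    def test_protruding_nucleus_rejected(self):
        with pytest.raises(ValueError, match="contained"):
            syn.build_phantom(cell_semiaxes_um=(8.0, 6.0, 4.0),
                              nucleus_semiaxes_um=(3.0, 2.5, 1.8),
                              nucleus_height_um=3.5)

    def test_deterministic(self):
        a = syn.build_phantom(seed=3)
        b = syn.build_phantom(seed=3)
        assert a == b


class TestSampleParticles:
    def test_empty_request(self, small_phantom):
        em = syn.sample_particles(small_phantom, 0, 0, seed=0)
        assert len(em) == 0

    def test_inside_count_and_flags(self, small_phantom):
        em = syn.sample_particles(small_phantom, 100, 0, particle_diameter_nm=85.0,
                                  seed=0)
        assert len(em) == 100
        assert em.inside.all()
        assert small_phantom.contains(em.positions_nm, margin_nm=85.0).all()

    def test_outside_emitters_flagged_and_outside(self, small_phantom):
        em = syn.sample_particles(small_phantom, 0, 30, seed=0)
        assert len(em) == 30 and not em.inside.any()
        assert not small_phantom.contains(em.positions_nm).any()

    @pytest.mark.parametrize("size", [2, 3, 4])
    def test_cluster_members_in_contact(self, small_phantom, size):
        em = syn.sample_particles(small_phantom, 4 * size, 0, particle_diameter_nm=85.0,
                                  cluster_sizes=[size], seed=2)
        for cid in np.unique(em.cluster_id):
            pts = em.positions_nm[em.cluster_id == cid]
            assert len(pts) == size
            assert np.allclose(pdist(pts), 85.0, atol=1e-6)

    def test_same_seed_is_identical(self, small_phantom):
        a = syn.sample_particles(small_phantom, 20, 5, seed=9)
        b = syn.sample_particles(small_phantom, 20, 5, seed=9)
        np.testing.assert_array_equal(a.positions_nm, b.positions_nm)

    def test_infeasible_margin_rejected(self, small_phantom):
        with pytest.raises((ValueError, RuntimeError)):
            syn.sample_particles(small_phantom, 10, 0, margin_nm=5.0e6, seed=0)


class TestRenderChannel:
    FOV = (3000.0, 4000.0, 4000.0)

    def test_background_only_statistics(self):
        grid = syn.render_channel(syn.EmitterSet.empty(), syn.STED, self.FOV, seed=0)
        n = grid.data.size
        se = np.sqrt(syn.STED.background / n)
        assert grid.data.mean() == pytest.approx(syn.STED.background, abs=3 * se)

    def test_photon_conservation(self):
        em = single_emitter((1500.0, 2000.0, 2000.0), brightness=2.0e4)
        grid = syn.render_channel(em, syn.STED, self.FOV, noise=False)
        flux = (grid.data - syn.STED.background).sum()
        assert flux == pytest.approx(2.0e4, rel=0.01)

    def test_point_source_fwhm(self):
        em = single_emitter((1495.0, 2000.0, 2000.0))
        grid = syn.render_channel(em, syn.STED, self.FOV, noise=False)
        profile = extract_profile(grid, (1495.0, 2000.0, 500.0),
                                  (1495.0, 2000.0, 3500.0))
        fit = fit_gaussian(profile)
        assert fit.fwhm_nm == pytest.approx(syn.STED.lateral_fwhm_nm, rel=0.10)

    def test_linearity_below_saturation(self):
        em1 = single_emitter((1500.0, 2000.0, 2000.0), brightness=1.0e4)
        em2 = single_emitter((1500.0, 2000.0, 2000.0), brightness=2.0e4)
        g1 = syn.render_channel(em1, syn.STED, self.FOV, noise=False)
        g2 = syn.render_channel(em2, syn.STED, self.FOV, noise=False)
        s1 = (g1.data - syn.STED.background).sum()
        s2 = (g2.data - syn.STED.background).sum()
        assert s2 == pytest.approx(2.0 * s1, rel=1e-9)

    def test_saturation_clips_at_detector_max(self):
        em = single_emitter((1500.0, 2000.0, 2000.0), brightness=1.0e10)
        grid = syn.render_channel(em, syn.STED, self.FOV, seed=1)
        assert grid.data.max() == syn.STED.detector_max

    def test_deterministic_rendering(self):
        em = emitter_row([(1500.0, 1000.0, 1000.0), (1500.0, 3000.0, 3000.0)])
        a = syn.render_channel(em, syn.STED, self.FOV, seed=5)
        b = syn.render_channel(em, syn.STED, self.FOV, seed=5)
        np.testing.assert_array_equal(a.data, b.data)

    def test_emitter_outside_fov_rejected(self):
        em = single_emitter((1500.0, 2000.0, 9000.0))
        with pytest.raises(ValueError, match="field of view"):
            syn.render_channel(em, syn.STED, self.FOV)


class TestGroundTruth:
    def test_counts_partition(self, tiny_scene):
        gt = tiny_scene["ground_truth"]
        assert gt.n_inside + gt.n_outside == len(gt.table)
        assert gt.n_inside == int(tiny_scene["emitters"].inside.sum())

    def test_inside_flags_consistent_with_geometry(self, tiny_scene):
        em = tiny_scene["emitters"]
        ph = tiny_scene["phantom"]
        np.testing.assert_array_equal(em.inside, ph.contains(em.positions_nm))

    def test_merged_membership_at_separation(self):
        em = emitter_row([(0.0, 0.0, 0.0), (0.0, 0.0, 50.0), (0.0, 0.0, 500.0)])
        gt = syn.ground_truth_table(em, separation_nm=76.0)
        ids = gt.table["merged_object_id"].to_numpy()
        assert ids[0] == ids[1] != ids[2]

    def test_scene_is_deterministic(self, small_phantom):
        em = syn.sample_particles(small_phantom, 5, 2, seed=4)
        a = syn.simulate_scene(small_phantom, em, seed=4)
        b = syn.simulate_scene(small_phantom, em, seed=4)
        for key in ("nanoparticle", "membrane", "lamina"):
            np.testing.assert_array_equal(a[key].data, b[key].data)


class TestAcquisitionConfig:
    def test_printed_modes(self):
        assert syn.STED.pixel_nm == 30.0 and syn.STED.lateral_fwhm_nm == 76.0
        assert syn.CONFOCAL.pixel_nm == 60.0 and syn.CONFOCAL.lateral_fwhm_nm == 277.0
        assert syn.STED.z_step_nm == syn.CONFOCAL.z_step_nm == 130.0

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            syn.AcquisitionConfig("x", pixel_nm=-1, z_step_nm=130, lateral_fwhm_nm=76)
        with pytest.raises(ValueError):
            syn.AcquisitionConfig("x", pixel_nm=30, z_step_nm=130, lateral_fwhm_nm=76,
                                  background=10, detector_max=5)
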