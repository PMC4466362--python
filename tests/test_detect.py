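"""Particle-object detection, the 5% discard rule, widths, inside counting."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from npquant import synthetic as syn
from npquant.cellmask import CellMask, segment_cell
from npquant.detect import (
    classify_inside,
    detect_particles,
    measure_lateral_width,
    objects_to_dataframe,
    summarize,
)
from npquant.grids import VoxelGrid

from conftest import emitter_row, noisy_background

FOV = (3000.0, 4000.0, 4000.0)


class TestDetection:
    def test_blank_channel_yields_nothing(self):
        assert detect_particles(noisy_background()) == []

    def test_constant_channel_yields_nothing(self):
        grid = VoxelGrid(np.full((8, 8, 8), 5.0), (130.0, 30.0, 30.0))
        assert detect_particles(grid) == []

    @pytest.mark.parametrize("separation_fwhm,expected", [(4.0, 2), (0.5, 1)])
    def test_pair_separation(self, separation_fwhm, expected):
        sep = separation_fwhm * syn.STED.lateral_fwhm_nm
        em = emitter_row([(1500.0, 2000.0, 2000.0 - sep / 2),
                          (1500.0, 2000.0, 2000.0 + sep / 2)])
        grid = syn.render_channel(em, syn.STED, FOV, seed=3)
        assert len(detect_particles(grid)) == expected

    def test_discard_rule_five_percent_band(self):
        # with an explicit threshold T: a dim object peaking just above T is
        # discarded, one peaking at 10% of the (T, I_max) range is kept
        rng = np.random.default_rng(0)
        data = rng.poisson(5.0, (20, 60, 60)).astype(float)
        data[5:8, 10:13, 10:13] = 1000.0
        T = 100.0
        for frac, expected in [(0.01, 1), (0.10, 2)]:
            img = data.copy()
            img[12:15, 40:43, 40:43] = T + frac * (1000.0 - T)
            grid = VoxelGrid(img, (130.0, 30.0, 30.0), "nanoparticle")
            objs = detect_particles(grid, watershed_sigma_um=0.2, threshold=T)
            assert len(objs) == expected

    def test_brightest_object_never_discarded(self):
        rng = np.random.default_rng(1)
        data = rng.poisson(5.0, (20, 60, 60)).astype(float)
        data[10:12, 30:32, 30:32] = 812.0
        objs = detect_particles(VoxelGrid(data, (130.0, 30.0, 30.0)),
                                watershed_sigma_um=0.2)
        assert max(o.peak_intensity for o in objs) == 812.0

    def test_counting_invariant_to_intensity_rescaling(self, tiny_scene):
        grid = tiny_scene["nanoparticle"]
        scaled = VoxelGrid(grid.data * 3.7, grid.spacing_nm, grid.channel)
        assert len(detect_particles(grid)) == len(detect_particles(scaled))

    def test_detection_recall_and_precision_on_separated_emitters(self, tiny_scene):
        # every well-separated emitter becomes exactly one object
        objs = detect_particles(tiny_scene["nanoparticle"])
        em = tiny_scene["emitters"]
        cent = np.array([o.centroid_nm for o in objs])
        d_obj, _ = cKDTree(em.positions_nm).query(cent)
        d_em, _ = cKDTree(cent).query(em.positions_nm)
        precision = (d_obj < 300.0).mean()
        recall = (d_em < 300.0).mean()
        assert precision >= 0.95 and recall >= 0.95


class TestLateralWidth:
    def test_single_voxel_width_is_pixel_size(self):
        data = np.zeros((9, 9, 9))
        data[4, 4, 4] = 100.0
        grid = VoxelGrid(data, (130.0, 30.0, 30.0))
        objs = detect_particles(grid, watershed_sigma_um=0.2, threshold=10.0,
                                snr_guard=0.0)
        assert len(objs) == 1
        assert objs[0].lateral_width_nm == pytest.approx(30.0)

    def test_single_particle_width_band(self):
        em = emitter_row([(1500.0, 2000.0, 2000.0)], diameter_nm=85.0)
        grid = syn.render_channel(em, syn.STED, FOV, seed=2)
        objs = detect_particles(grid)
        assert len(objs) == 1
        assert 76.0 <= objs[0].lateral_width_nm <= 150.0

    def test_linear_cluster_width_exceeds_single_cutoff(self):
        em = emitter_row([(1500.0, 2000.0, 1915.0), (1500.0, 2000.0, 2000.0),
                          (1500.0, 2000.0, 2085.0)], diameter_nm=85.0)
        grid = syn.render_channel(em, syn.STED, FOV, seed=2)
        objs = detect_particles(grid)
        assert len(objs) == 1
        assert objs[0].lateral_width_nm > 150.0

    def test_measure_matches_stored_width(self, tiny_scene):
        grid = tiny_scene["nanoparticle"]
        objs = detect_particles(grid)
        for o in objs[:5]:
            assert measure_lateral_width(o, grid) == o.lateral_width_nm


class TestClassifyInside:
    def _mask(self, shape, spacing, box):
        m = np.zeros(shape, dtype=bool)
        m[box] = True
        return CellMask(m, spacing)

    def test_strict_containment(self):
        data = np.zeros((12, 12, 12))
        data[5:7, 5:7, 5:7] = 500.0
        grid = VoxelGrid(data, (130.0, 30.0, 30.0))
        objs = detect_particles(grid, watershed_sigma_um=0.2, threshold=50.0,
                                snr_guard=0.0)
        inside_mask = self._mask(data.shape, grid.spacing_nm,
                                 (slice(0, 12), slice(0, 12), slice(0, 12)))
        partial_mask = self._mask(data.shape, grid.spacing_nm,
                                  (slice(0, 12), slice(0, 6), slice(0, 12)))
        assert classify_inside(objs, inside_mask, grid)[0].inside
        assert not classify_inside(objs, partial_mask, grid)[0].inside

    def test_geometry_mismatch_rejected(self):
        data = np.zeros((6, 6, 6))
        data[2, 2, 2] = 100.0
        grid = VoxelGrid(data, (130.0, 30.0, 30.0))
        objs = detect_particles(grid, watershed_sigma_um=0.2, threshold=10.0,
                                snr_guard=0.0)
        bad = CellMask(np.ones((5, 6, 6), dtype=bool), (130.0, 30.0, 30.0))
        with pytest.raises(ValueError, match="geometry"):
            classify_inside(objs, bad, grid)

    def test_straddling_objects_excluded_on_phantom(self):
        # half the emitters rest on the membrane; flagged-inside objects must
        # essentially all correspond to true interior emitters
        ph = syn.build_phantom()
        em = syn.sample_particles(ph, 50, 50, 85.0, brightness=2.0e4,
                                  margin_nm=600.0, min_separation_nm=350.0, seed=7)
        scene = syn.simulate_scene(ph, em, seed=7)
        grid = scene["nanoparticle"]
        mask = segment_cell(scene["membrane"])
        objs = classify_inside(detect_particles(grid), mask.on_grid(grid), grid)
        flagged = np.array([o.centroid_nm for o in objs if o.inside])
        d, _ = cKDTree(em.positions_nm[em.inside]).query(flagged)
        precision = (d < 300.0).mean()
        assert precision >= 0.95


class TestSummaries:
    def test_zero_objects(self):
        mask = CellMask(np.ones((4, 10, 10), dtype=bool), (130.0, 100.0, 100.0))
        s = summarize([], mask)
        assert s.n_objects_inside == 0 and s.mean_intensity_inside == 0.0

    def test_objects_per_area(self, tiny_scene):
        grid = tiny_scene["nanoparticle"]
        mask = segment_cell(tiny_scene["membrane"]).on_grid(grid)
        objs = classify_inside(detect_particles(grid), mask, grid)
        s = summarize(objs, mask)
        assert s.objects_per_um2 * s.projected_area_um2 == pytest.approx(
            s.n_objects_inside, rel=1e-9
        )

    def test_dataframe_round_numbers(self, tiny_scene):
        objs = detect_particles(tiny_scene["nanoparticle"])
        df = objects_to_dataframe(objs)
        assert len(df) == len(objs)
        assert (df["peak_intensity"] >= df["mean_intensity"] - 1e-9).all()
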