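"""Generator: calibration, packing, effect model, optics, and fixtures."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.spatial import cKDTree

import spherotox as st
from spherotox.synthgen import GenerationError, apply_noise, get_record

from conftest import cell_row, synthetic_truth_from_cells


class TestCalibration:
    def test_1000_cells_give_220_um_spheroid(self, control_truth):
        """The size law is anchored at 1,000 cells -> 220 um diameter."""
        assert 2 * control_truth.spheroid_radius_um == pytest.approx(220, rel=0.05)
        # and the packed cells actually fill that sphere
        pts = control_truth.cells[["x_um", "y_um", "z_um"]].to_numpy()
        center = np.array(control_truth.spheroid_center_um)
        r = np.linalg.norm(pts - center, axis=1)
        assert r.max() <= control_truth.spheroid_radius_um + 1e-9
        assert r.max() > 0.9 * control_truth.spheroid_radius_um

    def test_diameter_scales_with_cube_root_of_cell_number(self):
        """8x the cells double the diameter (cube-root law)."""
        d = {}
        for n in (1000, 8000):
            cfg = st.SyntheticConfig(n_cells=n, seed=3)
            truth = st.generate_spheroid_truth(cfg)
            d[n] = 2 * truth.spheroid_radius_um
        assert d[8000] / d[1000] == pytest.approx(2.0, rel=0.05)

    def test_cells_do_not_overlap(self, control_truth):
        pts = control_truth.cells[["x_um", "y_um", "z_um"]].to_numpy()
        dist, _ = cKDTree(pts).query(pts, k=2)
        assert dist[:, 1].min() >= control_truth.config.center_spacing_um - 1e-9

    def test_bottom_half_holds_half_the_cells(self, control_truth):
        """Uniform packing: the bottom hemisphere holds 50% +- 3 sigma of
        cells — the geometric basis of the half-spheroid count."""
        z = control_truth.cells["z_um"].to_numpy()
        frac = (z < control_truth.spheroid_center_um[2]).mean()
        sigma = math.sqrt(0.25 / len(z))
        assert abs(frac - 0.5) < 3 * sigma

    def test_impossible_packing_raises(self):
        cfg = st.SyntheticConfig(n_cells=2000, cell_diameter_um=6.0,
                                 nucleus_diameter_um=10.0, seed=0)
        with pytest.raises(GenerationError):
            st.generate_spheroid_truth(cfg)

    def test_zero_cells_rejected(self):
        with pytest.raises(GenerationError):
            st.SyntheticConfig(n_cells=0)


class TestEffectModel:
    def test_no_dose_no_death(self, control_truth):
        assert control_truth.n_dead == 0

    def test_dead_fraction_half_at_true_ic50(self):
        """Hill midpoint: dose = IC50 kills 50% +- binomial error."""
        cfg = st.SyntheticConfig(n_cells=1000, seed=7)
        eff = st.EffectParams(ic50_true_uM=2.5, hill=1.0)
        truth = st.generate_spheroid_truth(cfg, eff, dose_uM=2.5)
        assert eff.dead_fraction(2.5) == 0.5
        sigma = math.sqrt(0.25 / 1000)
        assert abs(truth.n_dead / 1000 - 0.5) < 3 * sigma

    def test_dead_fraction_monotone_and_zero_at_zero(self):
        eff = st.EffectParams(ic50_true_uM=1.0, hill=2.0)
        doses = [0.0, 0.1, 0.3, 1.0, 3.0, 10.0]
        fr = [eff.dead_fraction(d) for d in doses]
        assert fr[0] == 0.0
        assert all(b >= a for a, b in zip(fr, fr[1:]))

    def test_zero_dose_identical_to_untreated_draw(self, control_truth):
        """Any effect parameters at dose 0 reproduce the untreated
        ground truth bit-for-bit under the same seed."""
        cfg = control_truth.config
        eff = st.EffectParams(ic50_true_uM=0.01, hill=3.0,
                              swelling_per_dead_fraction=2.0,
                              detach_fraction=0.9)
        other = st.generate_spheroid_truth(cfg, eff, dose_uM=0.0)
        pd.testing.assert_frame_equal(other.cells, control_truth.cells)

    def test_swelling_dilates_centroids(self):
        cfg = st.SyntheticConfig(n_cells=300, seed=5)
        eff = st.EffectParams(ic50_true_uM=1.0, swelling_per_dead_fraction=0.5,
                              detach_fraction=0.0)
        t0 = st.generate_spheroid_truth(cfg, eff, dose_uM=0.0)
        t1 = st.generate_spheroid_truth(cfg, eff, dose_uM=1.0)  # dead frac 0.5
        assert t1.spheroid_radius_um == pytest.approx(
            1.25 * t0.spheroid_radius_um)

    def test_dye_intensities_follow_state(self):
        cfg = st.SyntheticConfig(n_cells=500, seed=11)
        truth = st.generate_spheroid_truth(
            cfg, st.EffectParams(ic50_true_uM=1.0), dose_uM=1.0)
        cells = truth.cells
        dead = cells["state"] == "dead"
        assert (cells.loc[dead, "I_FITC"] == 0).all()
        assert (cells.loc[dead, "I_TexasRed"] > 0).all()
        assert (cells.loc[~dead, "I_TexasRed"] == 0).all()
        assert (cells.loc[~dead, "I_FITC"] > 0).all()
        # Hoechst condensation brightens dead nuclei on average
        assert cells.loc[dead, "I_DAPI"].mean() > cells.loc[~dead, "I_DAPI"].mean()


class TestRendering:
    def _ideal_config(self, **kw):
        defaults = dict(
            n_cells=1, seed=0, psf_sigma_um=0.0, noise_model="none",
            background_level=0.0, attenuation_length_um=math.inf,
            imaging_depth_cutoff_um=math.inf, plane_thickness_um=0.0,
            intensity_cv=0.0,
        )
        defaults.update(kw)
        return st.SyntheticConfig(**defaults)

    def test_optics_disabled_gives_geometric_cross_sections(self):
        """With PSF, noise, attenuation, and slab integration all off,
        plane pixels equal the geometric sphere cross-section."""
        cfg = self._ideal_config(n_planes=11)
        cells = pd.DataFrame([cell_row(150.0, 150.0, 52.0, I_DAPI=100.0)])
        truth = synthetic_truth_from_cells(cells, cfg)
        stack = st.render_stack(truth, cfg)
        dapi = stack.channel("DAPI").astype(float)
        # oracle: direct evaluation of the section indicator per pixel
        for k in range(11):
            dz = k * 10.0 - 52.0
            rad2 = 25.0 - dz * dz
            grid = (np.arange(300) + 0.5)
            rho2 = ((grid - 150.0) ** 2)[:, None] + ((grid - 150.0) ** 2)[None, :]
            expected = 100.0 * (rho2 < rad2) if rad2 > 0 else np.zeros((300, 300))
            np.testing.assert_array_equal(dapi[k], expected)

    def test_cells_below_depth_cutoff_are_invisible(self):
        """Centroid deeper than the cutoff -> zero signal on all planes."""
        cfg = self._ideal_config(n_planes=23, imaging_depth_cutoff_um=110.0)
        cells = pd.DataFrame([
            cell_row(100.0, 100.0, 115.0, I_DAPI=100.0),
            cell_row(200.0, 200.0, 112.0, I_DAPI=100.0),
        ])
        truth = synthetic_truth_from_cells(cells, cfg)
        with pytest.warns(UserWarning, match="no signal"):
            stack = st.render_stack(truth, cfg)
        assert stack.channel("DAPI").sum() == 0

    def test_attenuation_dims_signal_exponentially(self):
        cfg = self._ideal_config(n_planes=11, attenuation_length_um=100.0)
        cells = pd.DataFrame([cell_row(150.0, 150.0, 50.0, I_DAPI=1000.0)])
        truth = synthetic_truth_from_cells(cells, cfg)
        stack = st.render_stack(truth, cfg)
        peak = stack.channel("DAPI")[5].max()
        assert peak == pytest.approx(1000.0 * math.exp(-50.0 / 100.0), abs=1)

    def test_poisson_noise_preserves_the_mean(self):
        """Monte-Carlo: Poisson noise on a uniform mean-100 plane keeps
        the empirical mean within 1% over >= 1e5 pixels."""
        rng = np.random.default_rng(42)
        plane = np.full((400, 400), 100.0)
        noisy = apply_noise(plane, "poisson", rng)
        assert noisy.mean() == pytest.approx(100.0, rel=0.01)
        assert noisy.std() == pytest.approx(10.0, rel=0.05)

    def test_empty_plane_range_warns_not_fails(self):
        cfg = self._ideal_config(n_planes=3)
        cells = pd.DataFrame([cell_row(150.0, 150.0, 200.0)])
        truth = synthetic_truth_from_cells(cells, cfg)
        with pytest.warns(UserWarning, match="no signal"):
            stack = st.render_stack(truth, cfg)
        assert stack.data.sum() == 0

    def test_same_seed_renders_identical_stacks(self, default_config,
                                                control_truth):
        again = st.render_stack(control_truth, default_config)
        base = st.render_stack(control_truth, default_config)
        np.testing.assert_array_equal(again.data, base.data)


class TestTableFixtures:
    def test_staurosporine_ipsc_3d_ic50(self, table1):
        rec = get_record(table1, "Staurosporine", "iPSC-3D")
        assert rec.outcome.kind == "ic50"
        assert rec.outcome.value_uM == 0.91
        assert rec.outcome.se_uM == 0.12

    def test_table1_has_48_compounds_42_toxic_6_negative(self, table1):
        rows = [r for r in table1 if r.assay == "iPSC-3D"]
        assert len(rows) == 48
        toxic = [r for r in rows if not r.is_negative_control]
        assert len(toxic) == 42
        negatives = [r for r in rows if r.is_negative_control]
        assert len(negatives) == 6
        assert all(r.outcome.kind == "no_tox" for r in negatives)

    def test_haloperidol_2d_no_tox_at_100(self, table1):
        rec = get_record(table1, "Haloperidol·HCl", "iPSC-2D")
        assert rec.outcome.kind == "no_tox"
        assert rec.outcome.max_uM == 100

    def test_censored_notations_parse_to_outcome_kinds(self, table1):
        kinds = {(r.name, r.assay): r.outcome.kind for r in table1}
        assert kinds[("Colchicine", "iPSC-3D")] == "gt_max"      # ">100"
        assert kinds[("Retinoic acid", "iPSC-3D")] == "approx"   # "~500"
        assert kinds[("Rotenone", "iPSC-2D")] == "nd"            # "n.d."
        assert kinds[("Carboplatin", "iPSC-3D")] == "no_tox"     # "No tox (500)"

    def test_table2_hepg2_staurosporine(self, table2):
        rec = get_record(table2, "Staurosporine", "HepG2-3D")
        assert rec.outcome.value_uM == 0.00582
        assert rec.outcome.se_uM == 0.00098
        assert len({r.name for r in table2}) == 23

    def test_unknown_table_and_compound_raise(self, table1):
        with pytest.raises(KeyError):
            st.load_table_fixtures("T9")
        with pytest.raises(KeyError):
            get_record(table1, "Nonexistine", "iPSC-3D")
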