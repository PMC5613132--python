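import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst
from hypothesis.extra import numpy as hnp

from latmap import restconn as rc
from latmap import synthetic as syn


def default_run(seed=7, n_volumes=120, **kw):
    spec = syn.RestingSpec(n_volumes=n_volumes, **kw)
    run, truth = syn.simulate_resting(spec, "typical", seed=seed)
    return spec, run, truth


class TestBandpass:
    def test_constant_series_zeroed(self):
        out = rc.bandpass(np.full(60, 5.0), tr_s=2.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_passband_sinusoid_retained(self):
        # DFT-bin oracle: 0.05 Hz at T=180, TR=2 is bin 18, inside (3.6, 36)
        t = np.arange(180) * 2.0
        sig = np.sin(2 * np.pi * 0.05 * t)
        out = rc.bandpass(sig, tr_s=2.0)
        assert out.var() / sig.var() >= 0.99

    def test_stopband_sinusoid_removed(self):
        t = np.arange(180) * 2.0
        sig = np.sin(2 * np.pi * 0.2 * t)
        out = rc.bandpass(sig, tr_s=2.0)
        assert out.var() / sig.var() <= 0.01

    def test_matches_explicit_dft_arithmetic(self):
        rng = np.random.default_rng(0)
        sig = rng.normal(size=100)
        out = rc.bandpass(sig, tr_s=2.0, f_lo=0.01, f_hi=0.1)
        freqs = np.fft.rfftfreq(100, d=2.0)
        spec = np.fft.rfft(sig)
        spec[~((freqs > 0.01) & (freqs < 0.1))] = 0.0
        np.testing.assert_allclose(out, np.fft.irfft(spec, n=100), atol=1e-12)

    def test_output_zero_mean(self):
        rng = np.random.default_rng(1)
        out = rc.bandpass(rng.normal(10, 2, 80), tr_s=2.0)
        assert abs(out.mean()) < 1e-12

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            rc.bandpass(np.zeros(60), tr_s=2.0, f_hi=0.3)
        with pytest.raises(ValueError):
            rc.bandpass(np.zeros(10), tr_s=2.0)


class TestMotionExpansion:
    def test_zero_motion_gives_zero_columns(self):
        out = rc.expand_motion_regressors(np.zeros((30, 6)))
        assert out.shape == (30, 24)
        assert not out.any()

    def test_exactly_24_columns(self):
        rng = np.random.default_rng(2)
        out = rc.expand_motion_regressors(rng.normal(size=(50, 6)))
        assert out.shape == (50, 24)
        assert len(rc.motion_column_names()) == 24

    def test_hand_computed_expansion(self):
        motion = np.zeros((2, 6))
        motion[:, 0] = [1.0, 2.0]
        out = rc.expand_motion_regressors(motion)
        np.testing.assert_allclose(out[:, 0], [1.0, 2.0])     # m
        np.testing.assert_allclose(out[:, 1], [1.0, 4.0])     # m^2
        np.testing.assert_allclose(out[:, 2], [0.0, 1.0])     # lag-1, zero-padded
        np.testing.assert_allclose(out[:, 3], [0.0, 1.0])     # lagged m^2

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            rc.expand_motion_regressors(np.zeros((30, 5)))


class TestBackwardDifference:
    def test_constant_gives_zeros(self):
        np.testing.assert_allclose(rc.backward_difference(np.full(10, 3.0)), 0.0)

    def test_hand_case(self):
        np.testing.assert_allclose(rc.backward_difference(np.array([1.0, 3.0, 6.0])),
                                   [0.0, 2.0, 3.0])

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(hnp.arrays(np.float64, 12, elements=hst.floats(-1e6, 1e6)))
    def test_cumsum_recovers_input(self, series):
        d = rc.backward_difference(series)
        np.testing.assert_allclose(np.cumsum(d) + series[0], series, atol=1e-6)


class TestNuisanceRegression:
    def test_perfect_fit_residual_zero(self):
        _, run, _ = default_run(n_volumes=60)
        design = rc.build_nuisance_design(run)
        col = design.matrix[:, 24]  # the CSF column
        run.data[3, 3, 3, :] = 2.5 * col + 1.0
        resid = rc.nuisance_regress(run, design)
        np.testing.assert_allclose(resid.data[3, 3, 3], 0.0, atol=1e-9)

    def test_zero_design_returns_demeaned(self):
        _, run, _ = default_run(n_volumes=40)
        design = rc.NuisanceDesign(matrix=np.zeros((40, 2)), names=["a", "b"])
        resid = rc.nuisance_regress(run, design)
        np.testing.assert_allclose(resid.data,
                                   run.data - run.data.mean(-1, keepdims=True),
                                   atol=1e-9)

    def test_residuals_orthogonal_to_design(self):
        _, run, _ = default_run(seed=13, n_volumes=80)
        design = rc.build_nuisance_design(run)
        resid = rc.nuisance_regress(run, design)
        flat = resid.data.reshape(-1, 80)
        rng = np.random.default_rng(0)
        cols = design.matrix / np.linalg.norm(design.matrix, axis=0)
        for v in rng.choice(flat.shape[0], 200, replace=False):
            series = flat[v]
            norm = np.linalg.norm(series)
            if norm == 0:
                continue
            corr = np.abs(cols.T @ (series / norm))
            assert corr.max() < 1e-8

    def test_rank_deficiency_names_columns(self):
        _, run, _ = default_run(n_volumes=40)
        col = np.arange(40.0)
        design = rc.NuisanceDesign(matrix=np.column_stack([col, col]),
                                   names=["dup1", "dup2"])
        with pytest.raises(ValueError, match="dup1"):
            rc.nuisance_regress(run, design)

    def test_design_has_28_named_columns(self):
        _, run, _ = default_run(n_volumes=40)
        design = rc.build_nuisance_design(run)
        assert design.matrix.shape == (40, 28)
        assert design.names[-4:] == ["csf", "csf_backdiff", "wm", "wm_backdiff"]

    def test_preprocess_keeps_residuals_orthogonal_to_filtered_design(self):
        """Band-pass then regress with identically filtered regressors: no
        out-of-band reintroduction, residuals stay orthogonal."""
        _, run, _ = default_run(seed=21, n_volumes=120)
        clean = rc.preprocess_run(run)
        filtered = rc.bandpass_run(run)
        design = rc.build_nuisance_design(filtered)
        mat = rc.bandpass(design.matrix.T, run.tr_s).T
        keep = np.ptp(mat, axis=0) > 0
        cols = mat[:, keep] / np.linalg.norm(mat[:, keep], axis=0)
        flat = clean.data.reshape(-1, 120)
        rng = np.random.default_rng(1)
        for v in rng.choice(flat.shape[0], 100, replace=False):
            norm = np.linalg.norm(flat[v])
            if norm == 0:
                continue
            assert np.abs(cols.T @ (flat[v] / norm)).max() < 1e-8


class TestSeedExtraction:
    def test_5mm_sphere_on_2mm_grid_is_81_voxels(self):
        """Brute-force lattice oracle: voxel offsets with squared distance
        (2i)^2 + (2j)^2 + (2k)^2 <= 25 mm^2."""
        expected = sum(1 for i in range(-3, 4) for j in range(-3, 4)
                       for k in range(-3, 4)
                       if 4 * (i * i + j * j + k * k) <= 25)
        assert expected == 81
        affine = syn.default_affine((16, 16, 16), 2.0)
        center = rc.voxel_to_mm((8, 8, 8), affine)
        mask = rc.sphere_mask(center, 5.0, (16, 16, 16), affine)
        assert mask.n_voxels == 81

    def test_constant_volume_mean(self):
        _, run, _ = default_run(n_volumes=40)
        run.data[:] = 4.2
        series = rc.extract_seed(run, rc.SeedSpec(center_mm=(0.0, 0.0, 0.0)))
        np.testing.assert_allclose(series, 4.2)

    def test_tiny_radius_is_center_voxel(self):
        affine = syn.default_affine((16, 16, 16), 2.0)
        center = rc.voxel_to_mm((8, 8, 8), affine)
        mask = rc.sphere_mask(center, 0.9, (16, 16, 16), affine)
        assert mask.n_voxels == 1

    def test_empty_sphere_rejected(self):
        affine = syn.default_affine((16, 16, 16), 2.0)
        with pytest.raises(ValueError, match="empty"):
            rc.sphere_mask((500.0, 0.0, 0.0), 5.0, (16, 16, 16), affine)


class TestHemisphericGlobalSignal:
    def test_constant_volume(self):
        _, run, _ = default_run(n_volumes=40)
        run.data[:] = 1.5
        gl, gr = rc.hemispheric_global_signal(run)
        np.testing.assert_allclose(gl, 1.5)
        np.testing.assert_allclose(gr, 1.5)

    def test_scaling_linearity(self):
        _, run, _ = default_run(n_volumes=40)
        left = run.hemispheres.left.data
        run.data[left] = 2.0
        run.data[~left] = 1.0
        gl, gr = rc.hemispheric_global_signal(run)
        np.testing.assert_allclose(gl, 2.0 * gr)

    def test_planted_component_recovered(self):
        spec, run, truth = default_run(seed=30, n_volumes=120)
        gl, gr = rc.hemispheric_global_signal(run)
        assert np.corrcoef(gl, truth["global_left_series"])[0, 1] > 0.95
        assert np.corrcoef(gr, truth["global_right_series"])[0, 1] > 0.95

    def test_swapping_hemispheres_swaps_series_and_negates_contrast(self):
        spec, run, _ = default_run(seed=31, n_volumes=60)
        gl, gr = rc.hemispheric_global_signal(run)
        swapped = rc.RestingRun(
            data=run.data, affine=run.affine, tr_s=run.tr_s, motion=run.motion,
            gray=run.gray, white=run.white, csf=run.csf,
            hemispheres=rc.RoiPair(
                left=rc.RoiMask(data=run.hemispheres.right.data, side="left",
                                label="swapped_l"),
                right=rc.RoiMask(data=run.hemispheres.left.data, side="right",
                                 label="swapped_r")),
            subject_id=run.subject_id)
        gl2, gr2 = rc.hemispheric_global_signal(swapped)
        np.testing.assert_array_equal(gl2, gr)
        np.testing.assert_array_equal(gr2, gl)
        res = rc.seed_connectivity(run, [])
        res_sw = rc.seed_connectivity(swapped, [])
        np.testing.assert_allclose(res_sw.contrast_left_gt_right.data,
                                   res.contrast_right_gt_left.data, atol=1e-10)


class TestSeedConnectivity:
    def test_contrast_antisymmetry(self):
        spec, run, _ = default_run(seed=8)
        clean = rc.preprocess_run(run)
        seeds = [rc.SeedSpec(center_mm=p.center_mm, name=p.name)
                 for p in spec.seeds]
        res = rc.seed_connectivity(clean, seeds)
        np.testing.assert_array_equal(res.contrast_left_gt_right.data,
                                      -res.contrast_right_gt_left.data)

    def test_beta_recovery_rmse(self):
        """Planted target beta recovered with RMSE <= 0.1 at T = 180 and
        unit noise."""
        spec, run, _ = default_run(seed=9, n_volumes=180)
        clean = rc.preprocess_run(run)
        seeds = [rc.SeedSpec(center_mm=p.center_mm, name=p.name)
                 for p in spec.seeds]
        res = rc.seed_connectivity(clean, seeds)
        target = rc.sphere_mask(spec.seeds[0].target_mm, 4.0, spec.shape,
                                spec.affine)
        b = res.betas["seed_lh"].data[target.data]
        rmse = float(np.sqrt(np.mean((b - 0.8) ** 2)))
        assert rmse <= 0.1

    def test_mean_beta_across_subjects(self):
        """Across seeded synthetic subjects the mean recovered seed beta sits
        within +/-0.05 of the planted value."""
        spec = syn.RestingSpec(n_volumes=180)
        seeds = [rc.SeedSpec(center_mm=p.center_mm, name=p.name)
                 for p in spec.seeds]
        target = rc.sphere_mask(spec.seeds[0].target_mm, 3.0, spec.shape,
                                spec.affine)
        betas = []
        for s in range(10):
            run, _ = syn.simulate_resting(spec, "typical", seed=500 + s)
            res = rc.seed_connectivity(rc.preprocess_run(run), seeds)
            betas.append(res.betas["seed_lh"].data[target.data].mean())
        assert abs(np.mean(betas) - 0.8) <= 0.05

    def test_collinear_predictors_named(self):
        spec = syn.RestingSpec(noise_sd=0.0, global_amp_dominant=0.0,
                               global_amp_other=0.0, motion_amp=0.0,
                               csf_amp=0.0, wm_amp=0.0)
        run, _ = syn.simulate_resting(spec, "typical", seed=1)
        seeds = [rc.SeedSpec(center_mm=p.center_mm, name=p.name)
                 for p in spec.seeds]
        with pytest.raises(ValueError, match="collinear"):
            rc.seed_connectivity(run, seeds)  # globals duplicate the seed


def _connectivity_group(flag, n, rng, spec, seeds):
    out = []
    for _ in range(n):
        run, _ = syn.simulate_resting(spec, flag, seed=int(rng.integers(2 ** 31)))
        out.append(rc.seed_connectivity(rc.preprocess_run(run), seeds))
    return out


@pytest.fixture(scope="module")
def contrast_setup():
    spec = syn.RestingSpec(n_volumes=120)
    seeds = [rc.SeedSpec(center_mm=p.center_mm, name=p.name) for p in spec.seeds]
    rng = np.random.default_rng(77)
    typ = _connectivity_group("typical", 4, rng, spec, seeds)
    atyp = _connectivity_group("atypical", 4, rng, spec, seeds)
    return spec, typ, atyp


class TestGroupContrast:
    def test_identical_groups_zero_map(self, contrast_setup):
        _, typ, _ = contrast_setup
        out = rc.group_connectivity_contrast(typ, typ, "left_gt_right")
        np.testing.assert_allclose(out.data, 0.0)

    def test_group_swap_negates(self, contrast_setup):
        _, typ, atyp = contrast_setup
        ab = rc.group_connectivity_contrast(typ, atyp, "left_gt_right")
        ba = rc.group_connectivity_contrast(atyp, typ, "left_gt_right")
        np.testing.assert_allclose(ab.data, -ba.data, atol=1e-12)

    def test_contrast_localizes_to_planted_regions(self, contrast_setup):
        """Opposite hemisphere-dominant global coupling: the group t map is
        elevated in the planted asymmetric regions and flat elsewhere."""
        spec, typ, atyp = contrast_setup
        out = rc.group_connectivity_contrast(typ, atyp, "left_gt_right")
        gray = syn.make_tissue_masks(spec.shape)["gray"]
        cl = spec.asym_center_left_mm
        region_l = rc.sphere_mask(cl, spec.asym_radius_mm, spec.shape, spec.affine)
        region_r = rc.sphere_mask((-cl[0], cl[1], cl[2]), spec.asym_radius_mm,
                                  spec.shape, spec.affine)
        planted = (region_l.data | region_r.data) & gray.data
        rest = gray.data & ~planted
        assert out.data[planted].mean() > 1.0
        assert abs(out.data[rest].mean()) < 0.3
        assert out.data[planted].mean() > out.data[rest].mean() + 1.0
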