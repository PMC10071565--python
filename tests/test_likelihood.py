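import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from emdock.fourier_core import OversamplingInfo, gaussian_atom_density
from emdock.likelihood import (AtomModel, Pose, llg_term, model_to_efc,
                               orientation_grid, refine_pose, rice_llg_term,
                               rotation_score, shift_model_fourier, sigma_a,
                               total_llg, translation_search_fft)


class TestSigmaA:
    def test_perfect_complete_model(self):
        s = np.linspace(0, 0.5, 20)
        assert np.allclose(sigma_a(1.0, 0.0, s), 1.0)

    def test_sqrt_completeness(self):
        assert sigma_a(0.25, 0.0, 0.3) == pytest.approx(0.5)

    def test_log_linear_in_s_squared(self):
        s = np.linspace(0.05, 0.5, 40)
        for delta in (0.5, 1.0, 2.0):
            log_sa = np.log(sigma_a(0.8, delta, s))
            slope = np.polyfit(s ** 2, log_sa, 1)[0]
            # slope proportional to -Delta^2
            assert slope == pytest.approx(
                -2.0 * np.pi ** 2 / 3.0 * delta ** 2, rel=1e-8)

    def test_validation(self):
        with pytest.raises(ValueError):
            sigma_a(0.0, 1.0, 0.1)
        with pytest.raises(ValueError):
            sigma_a(0.5, -1.0, 0.1)


class TestModelFourier:
    def test_identity_pose_deterministic(self, small_experiment,
                                         small_docking):
        terms = small_experiment["analysis"].terms_mean
        model = small_docking["model"]
        a = model_to_efc(model, terms, Pose())
        b = model_to_efc(model, terms, Pose())
        assert np.array_equal(a.e_c, b.e_c)

    def test_fourier_shift_theorem(self, small_experiment, small_docking):
        terms = small_experiment["analysis"].terms_mean
        model = small_docking["model"]
        t = np.array([2.4, -1.2, 3.6])
        via_pose = model_to_efc(model, terms, Pose(translation=t))
        via_phase = shift_model_fourier(model_to_efc(model, terms, Pose()),
                                        t)
        assert np.abs(np.abs(via_pose.e_c)
                      - np.abs(via_phase.e_c)).max() < 1e-8
        assert np.abs(via_pose.e_c - via_phase.e_c).max() < 1e-8

    def test_quarter_turn_permutes_amplitudes(self):
        # 90 deg rotation about z maps |F|(h,k,l) -> |F|(k,-h,l) exactly
        rng = np.random.default_rng(0)
        n, vox = 32, 1.0
        coords = n * vox / 2 + rng.normal(scale=4.0, size=(40, 3))
        rho = gaussian_atom_density(coords, 1.0, 1.2, (n, n, n), vox)
        centre = np.full(3, n * vox / 2)
        rot = Rotation.from_euler("z", 90, degrees=True)
        rho_r = gaussian_atom_density(rot.apply(coords - centre) + centre,
                                      1.0, 1.2, (n, n, n), vox)
        a = np.abs(np.fft.fftn(rho))
        b = np.abs(np.fft.fftn(rho_r))
        i = np.arange(n)
        permuted = a[np.ix_(i, (-i) % n, i)].transpose(1, 0, 2)
        assert np.abs(b - permuted).max() < 1e-8 * a.max()

    def test_atoms_outside_box_rejected(self, small_experiment,
                                        small_docking):
        terms = small_experiment["analysis"].terms_mean
        model = small_docking["model"]
        with pytest.raises(ValueError):
            model_to_efc(model, terms, Pose(translation=[500.0, 0, 0]))


class TestLLGTerm:
    def test_uninformative_model_scores_zero(self):
        assert llg_term(1.3, 0.7, 0.4, 0.8, 0.0) == 0.0
        vals = llg_term(np.ones(5), np.ones(5), np.zeros(5), np.ones(5) * .5,
                        np.zeros(5))
        assert np.all(vals == 0)

    def test_density_ratio_oracle(self):
        # LLG = log p(E_mean; E_C) - log p(E_mean; sigma_a = 0), with the
        # conditional a complex normal centred on x E_C with variance 1-x^2
        rng = np.random.default_rng(1)
        for _ in range(20):
            em_amp, ec_amp = rng.uniform(0.2, 2.0, 2)
            dphi = rng.uniform(-np.pi, np.pi)
            d, sa = rng.uniform(0.1, 0.95, 2)
            x = d * sa
            e_mean = em_amp * np.exp(1j * dphi)
            e_c = ec_amp + 0j

            def cn_logpdf(z, mu, var):
                return -np.log(np.pi * var) - np.abs(z - mu) ** 2 / var

            expected = (cn_logpdf(e_mean, x * e_c, 1 - x ** 2)
                        - cn_logpdf(e_mean, 0.0, 1.0))
            assert llg_term(em_amp, ec_amp, dphi, d, sa) == pytest.approx(
                expected, abs=1e-10)

    def test_monotone_in_phase_difference(self):
        phis = np.linspace(0, np.pi, 50)
        vals = llg_term(1.0, 1.0, phis, 0.7, 0.8)
        assert np.all(np.diff(vals) < 0)
        assert vals[0] == max(vals)

    def test_argument_bound(self):
        with pytest.raises(ValueError):
            llg_term(1.0, 1.0, 0.0, 1.0, 1.0)


class TestTotalLLG:
    def test_misaligned_sets_rejected(self, small_experiment,
                                      small_docking):
        norm = small_docking["norm"]
        mf = model_to_efc(small_docking["model"], norm.terms, Pose())
        bad = norm.select(np.arange(len(norm)) > 0)
        with pytest.raises(ValueError):
            total_llg(bad, mf, small_docking["over"])

    def test_correlation_decomposition_agrees(self, small_docking):
        norm = small_docking["norm"]
        mf = model_to_efc(small_docking["model"], norm.terms,
                          Pose(rot_deg=[5, 0, 0]))
        rep = total_llg(norm, mf, small_docking["over"])
        assert rep.total == pytest.approx(rep.decomposition_total,
                                          abs=1e-8 * max(abs(rep.total), 1))

    def test_oversampling_scales_total(self, small_docking):
        norm = small_docking["norm"]
        mf = model_to_efc(small_docking["model"], norm.terms, Pose())
        full = total_llg(norm, mf, OversamplingInfo(1.0, 1.0))
        half = total_llg(norm, mf, OversamplingInfo(0.5, 1.0))
        assert half.total == pytest.approx(0.5 * full.total, rel=1e-12)

    def test_quality_monotonicity(self):
        # lower injected noise => higher LLG at the true pose
        from emdock import analyze_half_maps
        from emdock.synthetic import (SyntheticSpec, generate_true_map,
                                      simulate_half_maps)
        totals = []
        for level in (40.0, 10.0):
            spec = SyntheticSpec(n_grid=32, n_atoms=60, cluster_radius=10.0,
                                 seed=5, noise_level=level)
            tm, gt = generate_true_map(spec)
            m1, m2, gt = simulate_half_maps(tm, gt)
            an = analyze_half_maps(m1, m2, d_min=spec.d_min)
            model = AtomModel(gt.coords, width=spec.atom_width)
            mf = model_to_efc(model, an.normalized.terms, Pose(), delta=0.5)
            totals.append(total_llg(an.normalized, mf,
                                    OversamplingInfo(1, 1)).total)
        assert totals[1] > totals[0] > 0


class TestRotationScore:
    def test_true_orientation_ranks_first(self, small_docking):
        grid = Rotation.concatenate([Rotation.identity(),
                                     Rotation.random(40, random_state=2)])
        df = rotation_score(small_docking["norm"], small_docking["model"],
                            grid, small_docking["over"], delta=0.5,
                            rescore_top=5)
        assert int(df.iloc[0].orientation_index) == 0

    def test_translation_invariance(self, small_docking):
        grid = Rotation.random(5, random_state=3)
        model = small_docking["model"]
        voxel = float(small_docking["norm"].terms.cell[0]
                      / small_docking["norm"].terms.grid_shape[0])
        shifted = AtomModel(model.coords
                            + voxel * np.array([3.0, -2.0, 1.0]),
                            model.weights, model.width)
        a = rotation_score(small_docking["norm"], model, grid,
                           small_docking["over"], method="exact")
        b = rotation_score(small_docking["norm"], shifted, grid,
                           small_docking["over"], method="exact")
        assert np.allclose(a.llg_rot.values, b.llg_rot.values, rtol=1e-6)

    def test_phase_scrambled_map_same_scores(self, small_docking):
        norm = small_docking["norm"]
        rng = np.random.default_rng(4)
        scrambled = norm.__class__(
            norm.terms, np.abs(norm.e_mean)
            * np.exp(1j * rng.uniform(0, 2 * np.pi, len(norm))),
            norm.d_obs, norm.sigma_s, norm.sigma_e)
        grid = Rotation.random(4, random_state=5)
        a = rotation_score(norm, small_docking["model"], grid,
                           small_docking["over"], method="exact")
        b = rotation_score(scrambled, small_docking["model"], grid,
                           small_docking["over"], method="exact")
        assert np.allclose(a.llg_rot.values, b.llg_rot.values, rtol=1e-10)

    def test_empty_grid_rejected(self, small_docking):
        with pytest.raises(ValueError):
            rotation_score(small_docking["norm"], small_docking["model"],
                           Rotation.random(5, random_state=1)[:0],
                           small_docking["over"])


class TestOrientationGrid:
    def test_requested_count(self):
        assert len(orientation_grid(n=100)) == 100

    def test_step_from_resolution_and_radius(self):
        g = orientation_grid(d_min=4.0, model_radius=20.0)
        assert len(g) > 100

    def test_quasi_uniform_coverage(self):
        grid = orientation_grid(n=800)
        probes = Rotation.random(50, random_state=6)
        worst = max((probes[i] * grid.inv()).magnitude().min()
                    for i in range(len(probes)))
        # covering radius well under the 48pi/n^ (1/3) spacing estimate x2
        assert np.rad2deg(worst) < 40.0


class TestTranslationSearch:
    def test_zero_model_coefficients_flat_zero(self, small_docking):
        # an empty model carries no scattering: E_C = 0 and sigma_A = 0
        norm = small_docking["norm"]
        mf = model_to_efc(small_docking["model"], norm.terms, Pose())
        mf.e_c = np.zeros_like(mf.e_c)
        mf.sigma_a = np.zeros_like(mf.sigma_a)
        grid = translation_search_fft(norm, mf, small_docking["over"])
        assert np.ptp(grid) < 1e-9
        assert grid.max() == pytest.approx(0.0, abs=1e-9)

    def test_matches_direct_evaluation(self, small_docking):
        norm = small_docking["norm"]
        over = small_docking["over"]
        mf = model_to_efc(small_docking["model"], norm.terms, Pose(),
                          delta=0.5)
        grid = translation_search_fft(norm, mf, over)
        rng = np.random.default_rng(7)
        voxel = norm.terms.cell[0] / norm.terms.grid_shape[0]
        n = norm.terms.grid_shape[0]
        for _ in range(10):
            ijk = tuple(rng.integers(0, n, 3))
            shift = np.array([np.fft.fftfreq(n, 1.0 / n)[i]
                              for i in ijk]) * voxel
            direct = total_llg(norm, shift_model_fourier(mf, shift),
                               over).total
            assert grid[ijk] == pytest.approx(direct,
                                              rel=1e-6, abs=1e-6)

    def test_peak_at_true_translation(self, small_experiment,
                                      small_docking):
        norm = small_docking["norm"]
        over = small_docking["over"]
        model = small_docking["model"]
        voxel = small_experiment["spec"].voxel_size
        t0 = np.array([3, -2, 5]) * voxel     # on-grid shift
        moved = AtomModel(model.coords - t0, model.weights, model.width)
        mf = model_to_efc(moved, norm.terms, Pose(), delta=0.5)
        grid = translation_search_fft(norm, mf, over)
        idx = np.unravel_index(np.argmax(grid), grid.shape)
        n = grid.shape[0]
        found = np.array([np.fft.fftfreq(n, 1.0 / n)[i]
                          for i in idx]) * voxel
        assert np.allclose(found, t0, atol=voxel / 2)


class TestRefinePose:
    def test_stationary_at_truth(self, small_docking):
        pose, _, path, llg = refine_pose(Pose(), small_docking["norm"],
                                         small_docking["model"],
                                         small_docking["over"], delta0=0.5)
        assert np.linalg.norm(pose.translation) < 0.2
        assert np.rad2deg(np.linalg.norm(pose.rotation.as_rotvec())) < 0.5
        assert np.all(np.diff(path) >= -1e-9)

    def test_recovers_from_perturbed_start(self, small_docking):
        start = Pose(rot_deg=[4.0, -3.0, 2.0], translation=[1.5, 1.0, -1.2])
        pose, _, _, llg = refine_pose(start, small_docking["norm"],
                                      small_docking["model"],
                                      small_docking["over"], delta0=0.5)
        assert np.linalg.norm(pose.translation) < 0.3
        assert np.rad2deg(np.linalg.norm(pose.rotation.as_rotvec())) < 1.0

    def test_com_rotation_decouples_from_translation(self, small_docking):
        # numeric Hessian at the optimum: rotation-translation cross terms
        # stay small relative to the diagonal when rotating about the COM
        norm, model, over = (small_docking["norm"], small_docking["model"],
                             small_docking["over"])

        def neg_llg(p):
            pose = Pose(p[:3], p[3:6])
            mf = model_to_efc(model, norm.terms, pose, delta=0.5)
            return -total_llg(norm, mf, over).total

        eps = np.array([0.25, 0.25, 0.25, 0.1, 0.1, 0.1])
        h = np.zeros((6, 6))
        f0 = neg_llg(np.zeros(6))
        fp = np.zeros(6)
        fm = np.zeros(6)
        for i in range(6):
            e = np.zeros(6)
            e[i] = eps[i]
            fp[i] = neg_llg(e)
            fm[i] = neg_llg(-e)
            h[i, i] = (fp[i] - 2 * f0 + fm[i]) / eps[i] ** 2
        for i in range(3):
            for j in range(3, 6):
                e = np.zeros(6)
                e[i], e[j] = eps[i], eps[j]
                fpp = neg_llg(e)
                h[i, j] = (fpp - fp[i] - fp[j] + f0) / (eps[i] * eps[j])
        for i in range(3):
            for j in range(3, 6):
                corr = abs(h[i, j]) / np.sqrt(abs(h[i, i] * h[j, j]))
                assert corr < 0.5
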