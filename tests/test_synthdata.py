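import numpy as np
import pytest

from tmstarget import connectivity as cn
from tmstarget import headgeom as hg
from tmstarget import nta
from tmstarget import synth
from tmstarget import targeting as tg
from tmstarget.synth import SyntheticCohortConfig


class TestSphericalHead:
    def test_concentric_depth_is_14mm(self, head):
        for cpc in [(0.3, 0.4), (0.6, 0.3), (0.5, 0.5)]:
            site = hg.cpc_to_scalp(head, hg.CPCCoordinate(*cpc))
            depth = np.linalg.norm(site.position - hg.scalp_to_cortex(head, site))
            assert depth == pytest.approx(14.0, abs=0.2)

    def test_fiducials_on_scalp(self, head):
        head.validate(tol_mm=0.1)

    def test_mask_reproducible_and_nonempty(self, mask):
        _, mask2 = synth.make_spherical_head()
        assert mask.n_voxels > 0
        assert np.array_equal(mask.indices, mask2.indices)
        # shell: every voxel center within shell_mm of the cortex sphere
        radii = np.linalg.norm(mask.world_coords(), axis=1)
        assert np.all(np.abs(radii - 78.0) <= 2.0 + 1e-9)

    def test_invalid_subdiv_rejected(self):
        with pytest.raises(ValueError):
            synth.make_spherical_head(subdiv=0)


class TestSubjectModel:
    def test_zero_jitter_makes_subjects_identical(self, head, mask, smoother):
        cfg = SyntheticCohortConfig(jitter_deg=0.0)
        m0 = synth.sample_subject_model(cfg, 0, head, mask, smoother)
        m1 = synth.sample_subject_model(cfg, 1, head, mask, smoother)
        assert np.allclose(m0.loadings, m1.loadings)

    def test_same_subject_is_deterministic(self, head, mask, smoother):
        cfg = SyntheticCohortConfig()
        m0 = synth.sample_subject_model(cfg, 4, head, mask, smoother)
        m1 = synth.sample_subject_model(cfg, 4, head, mask, smoother)
        assert np.array_equal(m0.loadings, m1.loadings)
        assert np.array_equal(m0.centers, m1.centers)

    def test_implied_correlation_has_unit_diagonal(self, head, mask, smoother):
        cfg = SyntheticCohortConfig()
        model = synth.sample_subject_model(cfg, 2, head, mask, smoother)
        sub = model.subset(np.arange(0, mask.n_voxels, 23))
        R = sub.implied_correlation()
        assert np.allclose(np.diag(R), 1.0, atol=1e-10)
        assert np.all(np.linalg.eigvalsh(R) > -1e-9)

    def test_network_cov_carries_negative_pathology_coupling(self):
        cfg = SyntheticCohortConfig()
        C = synth._network_cov(cfg)
        assert C[0, -1] == cfg.neg_coupling
        assert np.all(np.linalg.eigvalsh(C) > 0)


class TestPathoMap:
    def test_unit_self_correlation_at_peak(self, head, mask, smoother):
        cfg = SyntheticCohortConfig()
        model = synth.sample_subject_model(cfg, 0, head, mask, smoother)
        P = synth.patho_map(model)
        v_star = int(np.argmax(model.loadings[:, model.pathology_index]))
        assert P.values[v_star] == pytest.approx(1.0, abs=1e-9)

    def test_strong_anticorrelation_at_target_network_peak(self, head, mask, smoother):
        cfg = SyntheticCohortConfig()
        model = synth.sample_subject_model(cfg, 0, head, mask, smoother)
        P = synth.patho_map(model)
        v_target = int(np.argmax(model.loadings[:, 0]))
        assert P.values[v_target] < -0.3

    def test_model_level_quantity_is_deterministic(self, head, mask, smoother):
        cfg = SyntheticCohortConfig()
        model = synth.sample_subject_model(cfg, 1, head, mask, smoother)
        p1 = synth.patho_map(model).values
        synth.simulate_bold(model, 50, run_seed=0)  # no effect on the model
        p2 = synth.patho_map(model).values
        assert np.array_equal(p1, p2)


class TestSimulateBold:
    def test_single_network_noiseless_is_rank_one(self, head, mask):
        cfg = SyntheticCohortConfig(n_networks=1, local_sd=0.0, noise_sd=0.0)
        model = synth.sample_subject_model(cfg, 0, head, mask, smoother=None)
        keep = np.flatnonzero(model.loadings[:, 0] > 1e-6)[:30]
        ts = synth.simulate_bold(model.subset(keep), 300, noise_sd=0.0, run_seed=3)
        corr = np.corrcoef(ts.data)
        assert np.allclose(corr, 1.0, atol=1e-10)

    def test_same_seed_bitwise_identical(self, head, mask, smoother):
        cfg = SyntheticCohortConfig()
        model = synth.sample_subject_model(cfg, 0, head, mask, smoother)
        sub = model.subset(np.arange(40))
        a = synth.simulate_bold(sub, 100, run_seed=[9, 9])
        b = synth.simulate_bold(sub, 100, run_seed=[9, 9])
        assert np.array_equal(a.data, b.data)

    def test_sample_fc_converges_to_implied(self, head, mask, smoother, rng):
        """Law of large numbers: sample FC approaches the closed-form implied
        correlation on a random 50-voxel subset at T=10000."""
        cfg = SyntheticCohortConfig()
        model = synth.sample_subject_model(cfg, 0, head, mask, smoother)
        sub_idx = rng.choice(mask.n_voxels, size=50, replace=False)
        sub = model.subset(sub_idx)
        ts = synth.simulate_bold(sub, 10000, run_seed=[4, 2])
        z, _ = cn.standardize(ts)
        sample = z.data @ z.data.T / ts.n_volumes
        err = np.abs(sample - sub.implied_correlation())
        # T_eff = 2 * bandwidth * duration ~ 1300, so per-pair sd(r) ~ 0.028;
        # the max over ~1275 pairs stays below 3.6 sigma, the bulk far lower
        assert np.max(err) < 0.10
        assert np.median(err[np.triu_indices(50, 1)]) < 0.03

    def test_fc_error_scales_as_inverse_sqrt_T(self, head, mask, smoother):
        cfg = SyntheticCohortConfig()
        model = synth.sample_subject_model(cfg, 0, head, mask, smoother)
        sub = model.subset(np.arange(0, mask.n_voxels, 29))
        Rimp = sub.implied_correlation()
        iu = np.triu_indices(sub.n_voxels, 1)
        ratios = []
        for rep in range(4):
            errs = {}
            for T in (600, 2400):
                ts = synth.simulate_bold(sub, T, run_seed=[8, rep, T])
                z, _ = cn.standardize(ts)
                R = z.data @ z.data.T / T
                errs[T] = np.sqrt(np.mean((R - Rimp)[iu] ** 2))
            ratios.append(errs[2400] / errs[600])
        assert 0.35 <= np.mean(ratios) <= 0.65


class TestGroundTruth:
    def test_matches_explicit_correlation_matrix_oracle(self, small_head_mask):
        """Implied seed maps equal weighted row averages of the explicit
        implied correlation matrix on a small mask."""
        head, mask = small_head_mask
        cfg = SyntheticCohortConfig(subdiv=3, grid_mm=10.0, shell_mm=4.0)
        smoother = synth.build_smoother(mask, cfg.local_smooth_mm)
        model = synth.sample_subject_model(cfg, 1, head, mask, smoother)
        rng = np.random.default_rng(6)
        W = rng.random((mask.n_voxels, 3))
        S = synth.implied_seed_maps(model, W)
        R = model.implied_correlation()
        for col in range(3):
            w = W[:, col] / W[:, col].sum()
            assert np.allclose(S[:, col], R.T @ w, atol=1e-10)

    def test_noiseless_self_consistency_and_shared_truth_at_zero_jitter(
            self, small_head_mask):
        head, mask = small_head_mask
        cfg = SyntheticCohortConfig(subdiv=3, grid_mm=10.0, shell_mm=4.0,
                                    jitter_deg=0.0)
        smoother = synth.build_smoother(mask, cfg.local_smooth_mm)
        space = hg.build_search_space((0.25, 0.35), (0.3, 0.4), 0.05)
        from tmstarget.efield import search_space_fields
        fields = search_space_fields(head, mask, space)
        targets = []
        for sid in range(2):
            model = synth.sample_subject_model(cfg, sid, head, mask, smoother)
            P = synth.patho_map(model)
            t1 = synth.ground_truth_target(model, head, space, fields, P)
            t2 = synth.ground_truth_target(model, head, space, fields, P)
            assert (t1.cpc.p_nz, t1.cpc.p_al) == (t2.cpc.p_nz, t2.cpc.p_al)
            targets.append(t1)
        assert targets[0].cpc.p_nz == targets[1].cpc.p_nz
        assert targets[0].cpc.p_al == targets[1].cpc.p_al

    def test_jitter_increases_ground_truth_spread(self, head, mask, smoother,
                                                  mdd_space, mdd_fields):
        from tmstarget.stability import inter_distance
        spreads = []
        for jitter in (1.0, 4.0, 8.0):
            cfg = SyntheticCohortConfig(jitter_deg=jitter)
            targets = []
            for sid in range(8):
                model = synth.sample_subject_model(cfg, sid, head, mask, smoother)
                P = synth.patho_map(model)
                targets.append(synth.ground_truth_target(
                    model, head, mdd_space, mdd_fields, P))
            spreads.append(inter_distance(targets))
        assert spreads[0] < spreads[1] < spreads[2]


@pytest.fixture(scope="module")
def tiny_config():
    return SyntheticCohortConfig(n_subjects=3, subdiv=2, grid_mm=14.0,
                                 shell_mm=6.0, run_volumes=40,
                                 local_smooth_mm=16.0)


class TestCohortFixtures:
    def test_generate_cohort_layout(self, tiny_config, tmp_path_factory):
        out = synth.generate_cohort(tiny_config, tmp_path_factory.mktemp("cohort"))
        subdirs = sorted(p.name for p in out.iterdir() if p.is_dir())
        assert subdirs == ["sub-00", "sub-01", "sub-02"]
        runs = list(out.glob("sub-*/ses-*_run-*_bold.nii"))
        assert len(runs) == 3 * 2 * 2
        assert (out / "manifest.yaml").exists()

    def test_regeneration_is_byte_identical(self, tiny_config, tmp_path_factory):
        import yaml
        a = synth.generate_cohort(tiny_config, tmp_path_factory.mktemp("a"))
        b = synth.generate_cohort(tiny_config, tmp_path_factory.mktemp("b"))
        ma = yaml.safe_load((a / "manifest.yaml").read_text())
        mb = yaml.safe_load((b / "manifest.yaml").read_text())
        assert ma == mb  # includes per-run sha256 checksums

    def test_loaded_cohort_supports_full_nta_round_trip(self, tiny_config,
                                                        tmp_path_factory):
        out = synth.generate_cohort(tiny_config, tmp_path_factory.mktemp("c"))
        space = hg.build_search_space((0.27, 0.31), (0.33, 0.37), 0.02)
        for rec in synth.load_cohort(out):
            ts = cn.concatenate_runs(rec.sessions[0])
            ts_std, _ = cn.standardize(ts)
            nm = nta.compute_nta_map(rec.head, rec.mask, ts_std, space, rec.patho)
            assert nm.n_valid >= 1
            tg.classic_target(nm, rec.head)
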