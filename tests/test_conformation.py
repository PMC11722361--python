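import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from pamscope import conformation as conf
from pamscope import structure as st
from pamscope import synthetic as syn
from pamscope.units import KB, HBAR, R_GAS

from conftest import make_structure, make_trajectory


def rotation_search_rmsd(mobile, reference, n_starts=64, seed=0):
    """Independent RMSD oracle: direct minimization over rotation vectors
    from many random starts (no SVD)."""
    mob = mobile - mobile.mean(axis=0)
    ref = reference - reference.mean(axis=0)

    def cost(rv):
        m = Rotation.from_rotvec(rv).as_matrix()
        return np.sqrt((((mob @ m.T) - ref) ** 2).sum(axis=1).mean())

    best = np.inf
    rng = np.random.default_rng(seed)
    for _ in range(n_starts):
        rv0 = rng.uniform(-np.pi, np.pi, 3)
        res = minimize(cost, rv0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        best = min(best, res.fun)
    return best


class TestKabsch:
    def test_identical_sets(self):
        pts = np.random.default_rng(0).standard_normal((6, 3))
        t, rmsd = conf.kabsch_superpose(pts, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(t.rotation, np.eye(3), atol=1e-10)

    def test_pure_rotation_removed(self):
        pts = np.random.default_rng(1).standard_normal((5, 3))
        rot90 = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        _, rmsd = conf.kabsch_superpose(pts @ rot90.T, pts)
        assert rmsd == pytest.approx(0.0, abs=1e-10)

    def test_matches_rotation_search_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(4):
            n = int(rng.integers(4, 11))
            ref = rng.standard_normal((n, 3))
            mob = ref + 0.1 * rng.standard_normal((n, 3))
            mob[0] += 0.3
            _, rmsd = conf.kabsch_superpose(mob, ref)
            oracle = rotation_search_rmsd(mob, ref)
            assert rmsd == pytest.approx(oracle, abs=1e-3)

    def test_symmetry_and_rigid_invariance(self):
        rng = np.random.default_rng(3)
        a = rng.standard_normal((7, 3))
        b = a + 0.05 * rng.standard_normal((7, 3))
        _, rab = conf.kabsch_superpose(a, b)
        _, rba = conf.kabsch_superpose(b, a)
        assert rab == pytest.approx(rba, rel=1e-10)
        rot = Rotation.from_rotvec([0.3, -0.2, 1.1]).as_matrix()
        _, r2 = conf.kabsch_superpose(a @ rot.T + 5.0, b)
        assert r2 == pytest.approx(rab, rel=1e-8)

    def test_degenerate_and_mismatched_inputs(self):
        line = np.array([[0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]])
        with pytest.raises(ValueError, match="degenerate"):
            conf.kabsch_superpose(line, line + 0.1)
        with pytest.raises(ValueError):
            conf.kabsch_superpose(np.zeros((4, 3)), np.zeros((5, 3)))


class TestBackboneRmsd:
    def make_backbone(self, offset=0.0, rng=None):
        rng = rng or np.random.default_rng(5)
        coords = rng.uniform(0, 3, (8, 3)) + offset
        return make_structure(
            coords,
            names=["N", "CA", "C", "O"] * 2,
            elements=["N", "C", "C", "O"] * 2,
            res_ids=[10, 10, 10, 10, 11, 11, 11, 11],
            res_names=["ALA"] * 8,
        )

    def test_translated_copy_is_zero(self):
        a = self.make_backbone()
        b = make_structure(
            a.coordinates + np.array([1.0, -0.5, 2.0]),
            names=list(a.atom_name), elements=list(a.element),
            res_ids=list(a.residue_number), res_names=list(a.residue_name),
        )
        rmsd, n_matched, n_dropped = conf.backbone_rmsd(a, b)
        assert rmsd == pytest.approx(0.0, abs=1e-6)
        assert n_matched == 8 and n_dropped == 0

    def test_unmatched_atoms_dropped_and_counted(self):
        a = self.make_backbone()
        b = a.subset(np.arange(4))  # second residue missing
        rmsd, n_matched, n_dropped = conf.backbone_rmsd(a, b)
        assert n_matched == 4 and n_dropped == 4
        assert rmsd == pytest.approx(0.0, abs=1e-6)

    def test_too_few_matches_raises(self):
        a = self.make_backbone()
        b = make_structure(np.zeros((2, 3)), names=["N", "CA"],
                           elements=["N", "C"], res_ids=[99, 99],
                           res_names=["GLY", "GLY"])
        with pytest.raises(ValueError, match="matched"):
            conf.backbone_rmsd(a, b)


class TestRmsf:
    def test_frozen_trajectory_is_zero(self):
        model = make_structure(np.random.default_rng(0).uniform(0, 2, (6, 3)))
        traj = make_trajectory(model, np.tile(model.coordinates, (10, 1, 1)))
        sel = st.selection_from_indices(model, range(6))
        per_atom, per_res = conf.sidechain_rmsf(traj, sel, sel)
        assert per_res == pytest.approx(0.0, abs=1e-10)

    def test_isotropic_jitter_gives_sigma_sqrt3(self):
        rng = np.random.default_rng(7)
        base = rng.uniform(0, 3, (14, 3))
        model = make_structure(base)
        sigma = 0.02  # nm
        frames = np.tile(base, (4000, 1, 1))
        # atoms 10..13 jitter; atoms 0..9 anchor the fit
        frames[:, 10:, :] += sigma * rng.standard_normal((4000, 4, 3))
        traj = make_trajectory(model, frames)
        fit = st.selection_from_indices(model, range(10))
        target = st.selection_from_indices(model, range(10, 14))
        _, per_res = conf.sidechain_rmsf(traj, fit, target)
        expected = sigma * np.sqrt(3) * 10.0  # Angstrom
        assert per_res == pytest.approx(expected, rel=0.05)

    def test_rigid_rotation_removed_by_fitting(self):
        rng = np.random.default_rng(8)
        base = rng.uniform(0, 2, (6, 3))
        model = make_structure(base)
        frames = []
        for theta in np.linspace(0, np.pi / 2, 30):
            rot = Rotation.from_euler("z", theta).as_matrix()
            frames.append(base @ rot.T)
        traj = make_trajectory(model, np.array(frames))
        sel = st.selection_from_indices(model, range(6))
        _, per_res = conf.sidechain_rmsf(traj, sel, sel)
        assert per_res == pytest.approx(0.0, abs=1e-6)


class TestComDistanceSeries:
    def two_domain_traj(self, separations_nm):
        coords = np.zeros((4, 3))
        coords[2:, 0] = 1.0
        model = make_structure(coords)
        frames = []
        for s in separations_nm:
            f = coords.copy()
            f[2:, 0] = s
            frames.append(f)
        return make_trajectory(model, np.array(frames)), model

    def test_static_structure_degenerate(self):
        traj, model = self.two_domain_traj([3.16])
        a = st.selection_from_indices(model, [0, 1])
        b = st.selection_from_indices(model, [2, 3])
        dist = conf.com_distance_series(traj, a, b)
        assert dist.mean == pytest.approx(31.6)
        assert len(dist.bin_edges) == 2  # single degenerate bin

    def test_bimodal_series_modes_at_planted_centers(self):
        rng = np.random.default_rng(9)
        seps = np.concatenate([
            rng.normal(3.0, 0.02, 2000), rng.normal(4.0, 0.02, 2000)
        ])
        traj, model = self.two_domain_traj(seps)
        a = st.selection_from_indices(model, [0, 1])
        b = st.selection_from_indices(model, [2, 3])
        dist = conf.com_distance_series(traj, a, b)
        centers = 0.5 * (dist.bin_edges[:-1] + dist.bin_edges[1:])
        in_left = (centers > 29) & (centers < 31)
        in_right = (centers > 39) & (centers < 41)
        mid = (centers > 33) & (centers < 37)
        assert dist.density[in_left].max() > 10 * max(dist.density[mid].max(), 1e-12)
        assert dist.density[in_right].max() > 10 * max(dist.density[mid].max(), 1e-12)
        # density integrates to 1
        widths = np.diff(dist.bin_edges)
        assert (dist.density * widths).sum() == pytest.approx(1.0)


class TestCompareDistributionsZ:
    def test_identical_series(self):
        x = np.random.default_rng(0).standard_normal(50)
        z, p = conf.compare_distributions_z(x, x)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_closed_form_on_standardized_gaussians(self):
        rng = np.random.default_rng(1)

        def standardized(mu, n):
            x = rng.standard_normal(n)
            x = (x - x.mean()) / x.std(ddof=1)
            return x + mu

        a = standardized(0.0, 100)
        b = standardized(1.0, 100)
        z, p = conf.compare_distributions_z(a, b)
        assert z == pytest.approx(-1.0 / np.sqrt(0.02), rel=1e-6)  # -7.071
        assert p < 1e-11

    def test_planted_ten_angstrom_shift_is_significant(self):
        rng = np.random.default_rng(2)
        a = rng.normal(31.6, 1.0, 500)
        b = rng.normal(41.6, 1.0, 500)
        _, p = conf.compare_distributions_z(a, b, tau_a=5.0, tau_b=5.0)
        assert p < 1e-4

    def test_antisymmetry(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(0, 1, 200), rng.normal(0.5, 1, 200)
        za, pa = conf.compare_distributions_z(a, b)
        zb, pb = conf.compare_distributions_z(b, a)
        assert za == pytest.approx(-zb) and pa == pytest.approx(pb)


class TestQuasiharmonicEntropy:
    def test_single_mode_x_equals_one(self):
        t = 300.0
        kbt = KB * t
        lam = (HBAR / kbt) ** 2 * kbt  # makes x = hbar*omega/kBT = 1
        s = conf.entropy_from_eigenvalues(np.array([lam]), t)
        expected = R_GAS * (1.0 / (np.e - 1.0) - np.log(1.0 - np.exp(-1.0)))
        assert s == pytest.approx(expected, rel=1e-10)
        assert s == pytest.approx(8.65, abs=0.01)

    def test_stiff_mode_contributes_nothing(self):
        t = 300.0
        s = conf.entropy_from_eigenvalues(np.array([1e-7]), t)
        assert 0.0 <= s < 1e-3

    def test_monotone_under_covariance_scaling(self):
        rng = np.random.default_rng(4)
        lam = rng.uniform(1e-5, 1e-3, 12)
        s1 = conf.entropy_from_eigenvalues(lam, 300.0)
        s2 = conf.entropy_from_eigenvalues(2.0 * lam, 300.0)
        assert s2 > s1

    def test_block_additivity(self):
        rng = np.random.default_rng(5)
        lam_a = rng.uniform(1e-5, 1e-3, 6)
        lam_b = rng.uniform(1e-5, 1e-3, 9)
        s_sum = conf.entropy_from_eigenvalues(np.concatenate([lam_a, lam_b]), 300.0)
        s_parts = (conf.entropy_from_eigenvalues(lam_a, 300.0)
                   + conf.entropy_from_eigenvalues(lam_b, 300.0))
        assert s_sum == pytest.approx(s_parts, rel=1e-12)

    def test_planted_gaussian_ensemble_recovery(self):
        rng = np.random.default_rng(6)
        masses = rng.uniform(10, 20, 5)
        diag = rng.uniform(1e-4, 3e-3, 15)
        traj, truth = syn.gen_gaussian_ensemble(diag, masses, 20000, seed=21)
        sel = st.selection_from_indices(traj.reference, range(5))
        res = conf.quasiharmonic_entropy(traj, sel, 300.0, remove_rigid_body=False)
        s_true = conf.entropy_from_eigenvalues(
            truth["mass_weighted_eigenvalues"], 300.0
        )
        assert res.entropy == pytest.approx(s_true, rel=0.02)

    def test_rigid_body_removal_drops_six_modes(self):
        rng = np.random.default_rng(7)
        masses = rng.uniform(10, 20, 6)
        diag = rng.uniform(1e-4, 1e-3, 18)
        traj, _ = syn.gen_gaussian_ensemble(diag, masses, 5000, seed=22)
        sel = st.selection_from_indices(traj.reference, range(6))
        res = conf.quasiharmonic_entropy(traj, sel, 300.0, remove_rigid_body=True)
        assert res.n_modes_dropped == 6
        assert res.entropy >= 0.0

    def test_temperature_required_positive(self):
        traj, _ = syn.gen_gaussian_ensemble(np.full(9, 1e-4), [12.0] * 3, 100, seed=1)
        sel = st.selection_from_indices(traj.reference, range(3))
        with pytest.raises(ValueError):
            conf.quasiharmonic_entropy(traj, sel, -10.0)

    def test_schlitter_is_upper_bound(self):
        rng = np.random.default_rng(8)
        masses = rng.uniform(10, 20, 4)
        diag = rng.uniform(1e-4, 1e-3, 12)
        traj, _ = syn.gen_gaussian_ensemble(diag, masses, 8000, seed=23)
        sel = st.selection_from_indices(traj.reference, range(4))
        s_qh = conf.quasiharmonic_entropy(traj, sel, 300.0, remove_rigid_body=False)
        s_sch = conf.quasiharmonic_entropy(traj, sel, 300.0,
                                           remove_rigid_body=False, schlitter=True)
        assert s_sch.entropy >= s_qh.entropy
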