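import numpy as np
import pandas as pd
import pytest

from pamscope import contacts as ct
from pamscope import structure as st
from pamscope import synthetic as syn

from conftest import make_structure, make_trajectory


def single_frame_traj(coords_nm, masses=None, charges=None):
    model = make_structure(coords_nm, masses=masses, charges=charges)
    return make_trajectory(model, np.asarray(coords_nm)[None, :, :])


class TestComDistance:
    def test_two_single_atoms(self):
        traj = single_frame_traj([[0, 0, 0], [0, 0, 0.4]])
        a = st.selection_from_indices(traj.reference, [0])
        b = st.selection_from_indices(traj.reference, [1])
        assert ct.com_distance(traj, a, b)[0] == pytest.approx(0.4)

    def test_equal_mass_midpoint(self):
        traj = single_frame_traj([[0, 0, 0], [0, 0, 0.2], [0, 0, 0.5]])
        pair = st.selection_from_indices(traj.reference, [0, 1])
        probe = st.selection_from_indices(traj.reference, [2])
        assert ct.com_distance(traj, pair, probe)[0] == pytest.approx(0.4)

    def test_unequal_mass_hand_computed(self):
        coords = np.array([[0, 0, 0], [0, 0, 0.3], [0, 0, 0.6], [0, 0, 1.0]])
        masses = [12.0, 16.0, 31.0, 14.0]
        traj = single_frame_traj(coords, masses=masses)
        group = st.selection_from_indices(traj.reference, [0, 1, 2])
        probe = st.selection_from_indices(traj.reference, [3])
        com_z = (12 * 0 + 16 * 0.3 + 31 * 0.6) / (12 + 16 + 31)
        assert ct.com_distance(traj, group, probe)[0] == pytest.approx(1.0 - com_z)

    def test_empty_selection_rejected(self):
        traj = single_frame_traj([[0, 0, 0], [0, 0, 1]])
        with pytest.warns(UserWarning):
            empty = st.selection_from_indices(traj.reference, [])
        full = st.selection_from_indices(traj.reference, [0])
        with pytest.raises(ValueError):
            ct.com_distance(traj, empty, full)


class TestPairInteractionEnergy:
    def test_unit_point_charges_coulomb(self):
        traj = single_frame_traj([[0, 0, 0], [0, 0, 0.5]], charges=[1.0, -1.0])
        a = st.selection_from_indices(traj.reference, [0])
        b = st.selection_from_indices(traj.reference, [1])
        series = ct.pair_interaction_energy(traj, a, b)
        assert series.energies[0] == pytest.approx(-277.87, abs=0.05)

    def test_repeated_frame_constant_series(self):
        coords = np.array([[0, 0, 0], [0, 0, 0.5]])
        model = make_structure(coords, charges=[0.5, -0.5])
        traj = make_trajectory(model, np.tile(coords, (7, 1, 1)))
        a = st.selection_from_indices(model, [0])
        b = st.selection_from_indices(model, [1])
        series = ct.pair_interaction_energy(traj, a, b)
        assert np.ptp(series.energies) == 0.0

    def test_external_table_pass_through(self):
        traj = single_frame_traj([[0, 0, 0], [0, 0, 0.5]])
        table = pd.Series([-123.4])
        a = st.selection_from_indices(traj.reference, [0])
        b = st.selection_from_indices(traj.reference, [1])
        series = ct.pair_interaction_energy(
            traj, a, b, pair_id="R1335-G3", energy_table=table
        )
        assert series.energies[0] == -123.4
        assert series.pair_id == "R1335-G3"

    def test_missing_charges_rejected(self):
        traj = single_frame_traj([[0, 0, 0], [0, 0, 0.5]])
        a = st.selection_from_indices(traj.reference, [0])
        b = st.selection_from_indices(traj.reference, [1])
        with pytest.raises(ValueError, match="charge"):
            ct.pair_interaction_energy(traj, a, b)


class TestPrefilter:
    def test_category_specific_cutoffs(self):
        crit = ct.ContactCriteria()
        # 10% of frames at 0.55 nm: below the base cutoff, not the phosphate one
        d = np.full(1000, 2.0)
        d[:100] = 0.55
        kept = ct.prefilter_pairs(
            {"b": ("base", [d]), "p": ("phosphate", [d])}, crit
        )
        assert kept == ["b"]

    def test_never_close_gives_empty(self):
        crit = ct.ContactCriteria()
        d = np.full(100, 3.0)
        assert ct.prefilter_pairs({"b": ("base", [d])}, crit) == []

    def test_boundary_occupancy_inclusive(self):
        crit = ct.ContactCriteria()
        d = np.full(100, 2.0)
        d[:5] = 0.4  # exactly 5%
        assert ct.prefilter_pairs({"b": ("base", [d])}, crit) == ["b"]

    def test_pooled_occupancy_equals_weighted_mean_of_replicates(self):
        crit = ct.ContactCriteria(min_occupancy_prefilter=0.3)
        rng = np.random.default_rng(0)
        reps = [rng.uniform(0.2, 1.2, n) for n in (50, 150, 300)]
        pooled = np.concatenate(reps)
        occ_pooled = np.mean(pooled < 0.6)
        occ_weighted = sum((r < 0.6).sum() for r in reps) / sum(len(r) for r in reps)
        assert occ_pooled == pytest.approx(occ_weighted)
        kept = ct.prefilter_pairs({"b": ("base", reps)}, crit)
        assert kept == (["b"] if occ_pooled >= 0.3 else [])


class TestClassifyContacts:
    crit = ct.ContactCriteria()

    @pytest.mark.parametrize(
        "category,distance,energy,expected",
        [
            ("base", 0.4, -150.0, 1),   # both criteria met
            ("base", 0.4, -50.0, 0),    # energy too weak
            ("base", 0.4, 150.0, 0),    # repulsive
            ("phosphate", 0.55, -400.0, 0),  # 0.55 >= 0.5 cutoff
            ("phosphate", 0.45, -400.0, 1),
            ("base", 0.6, -150.0, 0),   # distance criterion is strict
        ],
    )
    def test_dual_criterion(self, category, distance, energy, expected):
        series = ct.classify_contacts(
            np.array([distance]), np.array([energy]), self.crit, category
        )
        assert series.occupancy[0] == expected

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ct.classify_contacts(np.zeros(3), np.zeros(4), self.crit, "base")

    def test_tightening_criteria_is_monotone(self):
        rng = np.random.default_rng(2)
        d = rng.uniform(0.2, 1.0, 500)
        e = rng.uniform(-500.0, 50.0, 500)
        loose = ct.classify_contacts(d, e, ct.ContactCriteria(), "base").occupancy
        tight = ct.classify_contacts(
            d, e,
            ct.ContactCriteria(base_distance_cutoff=0.5, base_energy_threshold=200.0),
            "base",
        ).occupancy
        assert np.all(tight <= loose)


class TestAutocorrelationTime:
    def test_white_noise_tends_to_half_interval(self):
        rng = np.random.default_rng(10)
        taus = [
            ct.integrated_autocorrelation_time(rng.standard_normal(20000), 1.0)
            for _ in range(20)
        ]
        assert np.mean(taus) == pytest.approx(0.5, abs=0.05)

    @pytest.mark.parametrize("phi", [0.5, 0.8])
    def test_ar1_closed_form(self, phi):
        rng = np.random.default_rng(11)
        n = 200_000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.standard_normal(n)
        for t in range(1, n):
            x[t] = phi * x[t - 1] + eps[t]
        expected = 0.5 + phi / (1.0 - phi)
        tau = ct.integrated_autocorrelation_time(x, 1.0)
        assert tau == pytest.approx(expected, rel=0.15)

    def test_constant_series_is_zero(self):
        assert ct.integrated_autocorrelation_time(np.full(100, 3.3), 1.0) == 0.0

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            ct.integrated_autocorrelation_time(np.arange(5.0), 1.0)


class TestFrequencyWithError:
    def test_all_ones_degenerate(self):
        series = ct.ContactSeries("p", np.ones(100, dtype=int), 1.0)
        est = ct.frequency_with_error(series, tau=5.0)
        assert est.mean == 1.0
        assert est.std_error == 0.0

    def test_iid_effective_samples_near_n(self):
        series = ct.ContactSeries("p", np.random.default_rng(0).integers(0, 2, 1000), 1.0)
        est = ct.frequency_with_error(series, tau=0.4)
        assert est.n_eff == pytest.approx(1000, rel=0.3)

    def test_neff_capped_at_n(self):
        series = ct.ContactSeries("p", np.ones(50, dtype=int), 1.0)
        est = ct.frequency_with_error(series, tau=0.01)
        assert est.n_eff <= 50

    def test_negative_tau_rejected(self):
        series = ct.ContactSeries("p", np.ones(10, dtype=int), 1.0)
        with pytest.raises(ValueError):
            ct.frequency_with_error(series, tau=-1.0)


class TestAggregateReplicates:
    def make(self, means):
        return [ct.FrequencyEstimate(m, 0.0, 1.0, 10.0, 0.0, i)
                for i, m in enumerate(means)]

    def test_identical_replicates(self):
        mean, err = ct.aggregate_replicates(self.make([0.5, 0.5, 0.5, 0.5]))
        assert (mean, err) == (0.5, 0.0)

    def test_two_replicates_hand_arithmetic(self):
        mean, err = ct.aggregate_replicates(self.make([0.2, 0.4]))
        assert mean == pytest.approx(0.3)
        assert err == pytest.approx(0.1)

    def test_permutation_symmetry(self):
        a = ct.aggregate_replicates(self.make([0.1, 0.5, 0.3]))
        b = ct.aggregate_replicates(self.make([0.3, 0.1, 0.5]))
        assert a == pytest.approx(b)

    def test_single_replicate_flagged(self):
        with pytest.warns(UserWarning, match="fewer than 2"):
            mean, err = ct.aggregate_replicates(self.make([0.7]))
        assert mean == 0.7 and np.isnan(err)


class TestPlantedRecovery:
    def test_probe_trajectory_recall_and_precision_exact(self):
        episodes = [
            syn.Episode("base", 0, 2000),
            syn.Episode("base", 3000, 3500, strong_energy=False),  # near-miss
            syn.Episode("phosphate", 4000, 5500),
        ]
        traj, pairs, truth = syn.gen_probe_trajectory(episodes, 10000, seed=3)
        idx = truth["site_atom_indices"]
        probe = st.selection_from_indices(traj.reference, idx["probe"])
        crit = ct.ContactCriteria()
        for cat, sel_key in (("base", "base"), ("phosphate", "phosphate")):
            site = st.selection_from_indices(traj.reference, idx[sel_key])
            d = ct.com_distance(traj, probe, site)
            series = ct.classify_contacts(d, pairs[cat].energies, crit, cat)
            np.testing.assert_array_equal(
                series.occupancy, truth["occupancy_series"][cat]
            )
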