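"""Surrogate interaction scorer, state fingerprints, efficiency, pose scores."""

import numpy as np
import pytest

import holdscan.energy as en
import holdscan.thermo as th
from holdscan.traj import Trajectory
from conftest import make_topology


def _pair_system(r, elements=("C", "C"), charges=(0.0, 0.0)):
    top = make_topology(
        2,
        element=np.array(elements, dtype="U2"),
        is_ligand=np.array([True, False]),
    )
    coords = np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])
    params = en.EnergyParams(charges=np.array(charges))
    return coords, top, params


class TestInteractionEnergy:
    def test_lj_zero_crossing_at_sigma(self):
        sigma = en.DEFAULT_LJ_TABLE["C"][1]
        coords, top, params = _pair_system(sigma)
        assert en.interaction_energy(coords, top, [0], [1], params) \
            == pytest.approx(0.0, abs=1e-12)

    def test_lj_minimum_at_r_min(self):
        eps, sigma = en.DEFAULT_LJ_TABLE["C"]
        coords, top, params = _pair_system(2 ** (1 / 6) * sigma)
        assert en.interaction_energy(coords, top, [0], [1], params) \
            == pytest.approx(-eps, rel=1e-12)

    def test_coulomb_distance_dependent_dielectric(self):
        # +1/-1 at 4.0 A under eps(r)=4r: 332.0637 / (4 * 4 * 4) = 5.19
        coords, top, params = _pair_system(4.0, charges=(1.0, -1.0))
        e_total = en.interaction_energy(coords, top, [0], [1], params)
        e_lj = en.interaction_energy(
            coords, top, [0], [1], en.EnergyParams(charges=np.zeros(2))
        )
        assert e_total - e_lj == pytest.approx(-5.19, abs=5e-3)

    def test_symmetric_under_selection_swap(self):
        rng = np.random.default_rng(0)
        n = 8
        top = make_topology(n, is_ligand=np.arange(n) < 3)
        coords = rng.normal(scale=3.0, size=(n, 3)) + 4.0
        params = en.EnergyParams(charges=rng.normal(scale=0.3, size=n))
        a = en.interaction_energy(coords, top, np.arange(3), np.arange(3, n), params)
        b = en.interaction_energy(coords, top, np.arange(3, n), np.arange(3), params)
        assert a == pytest.approx(b, rel=1e-12)

    def test_doubling_charges_quadruples_coulomb(self):
        coords, top, params = _pair_system(6.0, charges=(0.5, -0.5))
        params2 = en.EnergyParams(charges=np.array([1.0, -1.0]))
        lj = en.interaction_energy(
            coords, top, [0], [1], en.EnergyParams(charges=np.zeros(2))
        )
        e1 = en.interaction_energy(coords, top, [0], [1], params) - lj
        e2 = en.interaction_energy(coords, top, [0], [1], params2) - lj
        assert e2 == pytest.approx(4.0 * e1, rel=1e-12)

    def test_cutoff_matches_brute_force_within_tail_bound(self):
        # brute-force double loop with no cutoff vs the 12 A implementation;
        # neutral atoms so the discrepancy is the analytic LJ tail
        rng = np.random.default_rng(1)
        n = 14
        top = make_topology(n, is_ligand=np.arange(n) < 4)
        coords = rng.uniform(-8.0, 8.0, size=(n, 3))
        params = en.EnergyParams(charges=np.zeros(n), cutoff=12.0)
        impl = en.interaction_energy(coords, top, np.arange(4), np.arange(4, n), params)
        eps, sigma = en.DEFAULT_LJ_TABLE["C"]
        brute = 0.0
        for i in range(4):
            for j in range(4, n):
                r = np.linalg.norm(coords[i] - coords[j])
                sr6 = (sigma / r) ** 6
                brute += 4 * eps * (sr6**2 - sr6)
        # tail bound: pairs beyond the cutoff each contribute at most
        # 4*eps*(sigma/cutoff)^6 in magnitude
        tail = 4 * 10 * 4 * eps * (sigma / 12.0) ** 6
        assert abs(impl - brute) <= tail

    def test_missing_parameters_named(self):
        coords, top, params = _pair_system(4.0, elements=("C", "Zn"))
        with pytest.raises(ValueError, match="Zn"):
            en.interaction_energy(coords, top, [0], [1], params)


class TestStateEnergy:
    def test_constant_series_zero_sem(self):
        se = en.state_energy("m1", np.full(20, -25.0))
        assert se.dH == pytest.approx(-25.0)
        assert se.sem == 0.0
        assert se.dG == se.dH

    def test_planted_gaussian_mean_recovered(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(-30.0, 3.0, size=100)
        se = en.state_energy("m3", vals)
        assert se.dH == pytest.approx(-30.0, abs=3 * 3.0 / 10)
        assert se.sem == pytest.approx(3.0 / 10, rel=0.3)

    def test_accepted_frames_only(self):
        energies = np.concatenate([np.full(50, -20.0), np.full(50, -30.0)])
        se = en.state_energy("m1", energies, frames=np.arange(50))
        assert se.dH == pytest.approx(-20.0)
        assert se.n_frames == 50

    def test_entropy_term_enters_dg(self):
        se = en.state_energy("m1", np.full(5, -30.0), TdS=-10.0)
        assert se.dG == pytest.approx(-20.0)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            en.state_energy("m1", np.array([]))


class TestBindingDG:
    @pytest.mark.parametrize(
        "c, p, l, expected",
        [(-100.0, -60.0, -30.0, -10.0), (-90.0, -60.0, -30.0, 0.0), (0.0, 0.0, 0.0, 0.0)],
    )
    def test_decomposition(self, c, p, l, expected):
        assert en.binding_dg(c, p, l) == pytest.approx(expected)


class TestEfficiencyFromStates:
    def test_half_ratio(self):
        assert en.efficiency_from_states(-5.2, -10.4) == pytest.approx(0.50)

    def test_equal_energies_zero(self):
        assert en.efficiency_from_states(-7.0, -7.0) == 0.0

    def test_uniform_overestimation_cancels(self):
        # a systematic 1.45x scale error in both state energies leaves the
        # efficiency untouched — the central ratio argument
        eta = en.efficiency_from_states(-5.1, -10.2)
        eta_scaled = en.efficiency_from_states(-5.1 * 1.45, -10.2 * 1.45)
        assert eta_scaled == pytest.approx(eta, rel=1e-12)

    def test_zero_m3_rejected(self):
        with pytest.raises(ValueError):
            en.efficiency_from_states(-5.0, 0.0)


class TestCompareToExperiment:
    EXPERIMENTAL = [
        th.AgonistEnergetics("ACh", -5.1, -10.2),
        th.AgonistEnergetics("Ebt", -6.96, -12.0),
    ]

    def test_exact_match_zero_discrepancy(self):
        report = en.compare_to_experiment({"ACh": (-5.1, -10.2)}, self.EXPERIMENTAL)
        row = report.iloc[0]
        assert row.pct_over_m1 == pytest.approx(0.0, abs=1e-10)
        assert row.pct_over_m3 == pytest.approx(0.0, abs=1e-10)
        assert row.eta_diff == pytest.approx(0.0, abs=1e-12)

    def test_uniform_scale_shows_in_dg_not_eta(self):
        report = en.compare_to_experiment(
            {"Ebt": (-6.96 * 1.45, -12.0 * 1.45)}, self.EXPERIMENTAL
        )
        row = report.iloc[0]
        assert row.pct_over_m1 == pytest.approx(45.0, abs=1e-9)
        assert row.pct_over_m3 == pytest.approx(45.0, abs=1e-9)
        assert row.eta_diff == pytest.approx(0.0, abs=1e-12)

    def test_missing_agonist_rejected(self):
        with pytest.raises(KeyError, match="CCh"):
            en.compare_to_experiment({"CCh": (-5.0, -10.0)}, self.EXPERIMENTAL)


def _drift_traj(drift_per_frame, n_frames=10, seed=3):
    """Rigid site; ligand translates linearly away from its start."""
    rng = np.random.default_rng(seed)
    site = rng.normal(scale=6.0, size=(10, 3))
    lig0 = np.array([[0.0, 0, 0], [1.4, 0, 0], [2.8, 0, 0]])
    frames = [
        np.vstack([site, lig0 + np.array([0.0, 0.0, drift_per_frame * f])])
        for f in range(n_frames)
    ]
    top = make_topology(13, is_ligand=np.array([False] * 10 + [True] * 3))
    return Trajectory(top, np.asarray(frames))


class TestPoseScores:
    SITE = np.arange(10)
    LIG = np.arange(10, 13)

    def _contacts(self, traj):
        # ligand-site pairs in contact in the first frame
        c = traj.coords[0]
        return [
            (i, j)
            for i in self.LIG for j in self.SITE
            if np.linalg.norm(c[i] - c[j]) <= 4.0
        ]

    def test_frozen_trajectory(self):
        traj = _drift_traj(0.0)
        contacts = self._contacts(traj)
        assert contacts, "fixture must start with at least one contact"
        ps = en.pose_scores(traj, np.arange(10), self.LIG, self.SITE, contacts)
        assert ps.pose_score == pytest.approx(0.0, abs=1e-6)
        assert ps.pers_score == 1.0
        assert ps.comp_score == pytest.approx(-5.0, abs=1e-6)

    def test_drifting_ligand_loses_contacts(self):
        # linear drift 0 -> 4 A in 9 steps: mean RMSD ~ 2, contacts all lost
        traj = _drift_traj(4.0 / 9.0)
        contacts = self._contacts(traj)
        ps = en.pose_scores(traj, np.arange(10), self.LIG, self.SITE, contacts)
        assert ps.pose_score == pytest.approx(2.0, abs=0.3)
        assert ps.pers_score == 0.0
        assert ps.comp_score == pytest.approx(ps.pose_score)

    def test_stable_pose_scores_below_unstable(self):
        stable = _drift_traj(0.02)
        unstable = _drift_traj(0.5)
        c_s = self._contacts(stable)
        c_u = self._contacts(unstable)
        comp_s = en.pose_scores(stable, np.arange(10), self.LIG, self.SITE, c_s).comp_score
        comp_u = en.pose_scores(unstable, np.arange(10), self.LIG, self.SITE, c_u).comp_score
        assert comp_s < comp_u

    def test_short_segment_rejected(self):
        traj = _drift_traj(0.0, n_frames=2)
        with pytest.raises(ValueError):
            en.pose_scores(traj, [0], self.LIG, self.SITE, [])


class TestEnergyCSV:
    def test_round_trip(self, tmp_path):
        import pandas as pd
        df = pd.DataFrame({"frame": [0, 1], "energy_kcal": [-20.5, -21.5]})
        path = tmp_path / "e.csv"
        df.to_csv(path, index=False)
        back = en.read_energy_csv(path)
        assert list(back.frame) == [0, 1]

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("frame,value\n0,-20\n")
        with pytest.raises(ValueError, match="energy_kcal"):
            en.read_energy_csv(path)
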