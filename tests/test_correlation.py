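import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mdcc
from mdcc.modes import GaussianMode, ModeModel

from conftest import make_trajectory
from oracles import mdcc_direct


def single_mode(atom_id, center, cov_scale=1.0):
    return ModeModel(atom_id, [GaussianMode(1.0, np.asarray(center, float),
                                            np.eye(3) * cov_scale)])


@pytest.fixture()
def hand_case():
    """6-frame two-atom fixture with prescribed mixtures.

    Atom 0 oscillates in x around two y-separated sites; atom 1 oscillates
    around the origin only.  Sites are 5 A apart with 0.25 A^2 isotropic
    covariances, so responsibilities are essentially hard.
    """
    pi = np.array([[1, 0, 0], [-1, 0, 0], [1, 5, 0],
                   [-1, 5, 0], [1, 0, 0], [-1, 5, 0]], dtype=float)
    pj = np.array([[1, 0, 0], [-1, 0, 0], [1, 0, 0],
                   [-1, 0, 0], [1, 0, 0], [1, 0, 0]], dtype=float)
    traj = make_trajectory(np.stack([pi, pj], axis=1))
    cov = np.eye(3) * 0.25
    model_i = ModeModel(0, [GaussianMode(0.5, np.zeros(3), cov),
                            GaussianMode(0.5, np.array([0., 5, 0]), cov)])
    model_j = ModeModel(1, [GaussianMode(1.0, np.zeros(3), cov)])
    return traj, model_i, model_j


class TestDCC:
    def test_self_correlation_is_one(self, toy_traj):
        assert mdcc.dcc_atom_pair(toy_traj, 0, 0) == 1.0

    def test_mirror_motion_is_minus_one(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(20, 3))
        a -= a.mean(axis=0)
        traj = make_trajectory(np.stack([a, -a], axis=1))
        assert mdcc.dcc_atom_pair(traj, 0, 1) == pytest.approx(-1.0)

    def test_hand_evaluated_four_frame_case(self):
        """x_i = (1,-1,2,-2), x_j = (1,-1,-2,2): numerator -6, both
        denominators sqrt(10) -> -0.6."""
        xi = np.array([1, -1, 2, -2.0])
        xj = np.array([1, -1, -2, 2.0])
        coords = np.zeros((4, 2, 3))
        coords[:, 0, 0] = xi
        coords[:, 1, 0] = xj
        traj = make_trajectory(coords)
        assert mdcc.dcc_atom_pair(traj, 0, 1) == pytest.approx(-0.6, abs=1e-12)

    def test_zero_variance_atom_reports_missing(self):
        coords = np.zeros((5, 2, 3))
        coords[:, 0, 0] = np.arange(5)
        traj = make_trajectory(coords)
        assert np.isnan(mdcc.dcc_atom_pair(traj, 0, 1))

    def test_symmetric(self, flip_traj):
        assert mdcc.dcc_atom_pair(flip_traj, 0, 2) == pytest.approx(
            mdcc.dcc_atom_pair(flip_traj, 2, 0), abs=1e-15)

    def test_translation_invariant(self, flip_traj):
        shifted = make_trajectory(flip_traj.coords + np.array([5., -3, 1]))
        for i, j in [(0, 1), (1, 2)]:
            assert mdcc.dcc_atom_pair(shifted, i, j) == pytest.approx(
                mdcc.dcc_atom_pair(flip_traj, i, j), abs=1e-12)


class TestMDCCModePair:
    def test_hand_case_matches_direct_summation_oracle(self, hand_case):
        traj, mi, mj = hand_case
        mix_i = ([m.weight for m in mi.modes],
                 [m.center.tolist() for m in mi.modes],
                 [m.covariance.tolist() for m in mi.modes])
        mix_j = ([m.weight for m in mj.modes],
                 [m.center.tolist() for m in mj.modes],
                 [m.covariance.tolist() for m in mj.modes])
        for k, expect in [(0, 1.0), (1, 1.0 / 3.0)]:
            got = mdcc.mdcc_mode_pair(traj, mi, mj, k, 0, min_mass=1.0)
            oracle, mass = mdcc_direct(traj.atom_coords(0).tolist(),
                                       traj.atom_coords(1).tolist(),
                                       mix_i, mix_j, k, 0)
            assert got.mdcc == pytest.approx(oracle, abs=1e-10)
            assert got.cooccurrence_mass == pytest.approx(mass, abs=1e-10)
            # the prescribed responsibilities are essentially hard
            assert got.mdcc == pytest.approx(expect, abs=1e-6)
            assert got.cooccurrence_mass == pytest.approx(3.0, abs=1e-6)

    def test_single_mode_at_sample_mean_reduces_to_dcc(self, flip_traj):
        models = mdcc.single_mode_models(flip_traj)
        for i, j in [(0, 1), (0, 2), (1, 2)]:
            mp = mdcc.mdcc_mode_pair(flip_traj, models[i], models[j], 0, 0)
            assert mp.cooccurrence_mass == pytest.approx(
                flip_traj.n_frames, abs=1e-9)
            assert mp.mdcc == pytest.approx(
                mdcc.dcc_atom_pair(flip_traj, i, j), abs=1e-10)

    def test_symmetry_under_atom_swap(self, flip_traj, flip_models):
        a = mdcc.mdcc_mode_pair(flip_traj, flip_models[0], flip_models[1], 1, 0)
        b = mdcc.mdcc_mode_pair(flip_traj, flip_models[1], flip_models[0], 0, 1)
        assert a.mdcc == pytest.approx(b.mdcc, abs=1e-12)
        assert a.cooccurrence_mass == pytest.approx(b.cooccurrence_mass,
                                                    abs=1e-12)

    def test_center_shift_invariance(self, flip_traj, flip_models):
        """Shifting both trajectories and all mode centers by the same
        constant vector leaves the statistic unchanged."""
        shift = np.array([3.0, -2.0, 7.0])
        shifted = make_trajectory(flip_traj.coords + shift)
        shifted_models = [
            ModeModel(m.atom_id,
                      [GaussianMode(g.weight, g.center + shift, g.covariance)
                       for g in m.modes]) for m in flip_models]
        a = mdcc.mdcc_mode_pair(flip_traj, flip_models[0], flip_models[1], 0, 0)
        b = mdcc.mdcc_mode_pair(shifted, shifted_models[0],
                                shifted_models[1], 0, 0)
        assert b.mdcc == pytest.approx(a.mdcc, abs=1e-9)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_bounded_by_one_on_random_fixtures(self, seed):
        rng = np.random.default_rng(seed)
        T = int(rng.integers(20, 60))
        coords = rng.normal(0, 2, (T, 2, 3))
        traj = make_trajectory(coords)
        models = []
        for atom in range(2):
            K = int(rng.integers(1, 4))
            w = rng.dirichlet(np.ones(K))
            models.append(ModeModel(atom, [
                GaussianMode(w[k], rng.normal(0, 2, 3),
                             np.eye(3) * rng.uniform(0.2, 3))
                for k in range(K)]))
        for k in range(models[0].n_modes):
            for l in range(models[1].n_modes):
                mp = mdcc.mdcc_mode_pair(traj, models[0], models[1], k, l,
                                         min_mass=0.0)
                if not mp.omitted:
                    assert abs(mp.mdcc) <= 1.0 + 1e-12

    def test_zero_cooccurrence_is_omitted(self):
        """Atom 0's second mode is occupied exactly when atom 1 is far from
        its only region of support, so the joint weight vanishes."""
        pi = np.array([[0, 0, 0], [0, 0, 0], [50., 0, 0], [50., 0, 0]])
        pj = np.array([[0, 0, 0], [0, 0, 0], [0, 0, 0], [0., 0, 0]])
        traj = make_trajectory(np.stack([pi + np.array([0, 0.1, 0]) *
                                         np.arange(4)[:, None], pj +
                                         np.array([0, 0.1, 0]) *
                                         np.arange(4)[:, None]], axis=1))
        tiny = np.eye(3) * 1e-4
        mi = ModeModel(0, [GaussianMode(0.5, np.zeros(3), tiny),
                           GaussianMode(0.5, np.array([50., 0, 0]), tiny)])
        mj = ModeModel(1, [GaussianMode(1.0, np.zeros(3), tiny)])
        # mode 1 of atom 0 never co-occurs with frames where atom 1 exists
        # at weight 1... joint mass is ~2 frames, below the 10-frame floor
        mp = mdcc.mdcc_mode_pair(traj, mi, mj, 1, 0)
        assert mp.omitted
        assert np.isnan(mp.mdcc)


class TestCooccurrence:
    def test_single_mode_pair_mass_equals_frames(self, flip_traj):
        models = mdcc.single_mode_models(flip_traj)
        assert mdcc.cooccurrence_mass(flip_traj, models[0], models[1],
                                      0, 0) == pytest.approx(
            flip_traj.n_frames, abs=1e-9)

    def test_threshold_rule(self):
        assert mdcc.mass_threshold(1000) == 50.0
        assert mdcc.mass_threshold(100) == 10.0
        assert mdcc.mass_threshold(1000, min_fraction=0.01) == 10.0


class TestAllPairs:
    def test_toy_pair_and_mode_counts(self, toy_traj, toy_models):
        table = mdcc.all_pairs(toy_traj, toy_models)
        assert set(zip(table["atom_i"], table["atom_j"])) == {(0, 1)}
        assert len(table) == toy_models[0].n_modes * toy_models[1].n_modes

    def test_stationary_atoms_all_missing(self):
        coords = np.tile(np.array([[0., 0, 0], [5., 0, 0], [0., 5, 0]]),
                         (4, 1, 1))
        traj = make_trajectory(coords)
        models = mdcc.single_mode_models(traj)
        table = mdcc.all_pairs(traj, models)
        assert table["dcc"].isna().all()
        assert table["omitted"].all()

    def test_combinatorial_row_count(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(0, 1, (30, 4, 3)) + np.arange(4)[None, :, None] * 8
        traj = make_trajectory(coords)
        models = mdcc.fit_all_atoms(traj, mdcc.FitConfig(seed=2))
        table = mdcc.all_pairs(traj, models)
        pairs = table.drop_duplicates(["atom_i", "atom_j"])
        assert len(pairs) == 6
        for (i, j), grp in table.groupby(["atom_i", "atom_j"]):
            assert len(grp) == models[i].n_modes * models[j].n_modes

    def test_max_and_surviving_helpers(self, flip_traj, flip_models,
                                       flip_pairs):
        assert mdcc.max_mdcc(flip_pairs, 1, 0) == mdcc.max_mdcc(flip_pairs, 0, 1)
        live = flip_pairs[~flip_pairs["omitted"]]
        assert mdcc.max_mdcc(flip_pairs, 0, 1) == pytest.approx(
            live[(live.atom_i == 0) & (live.atom_j == 1)]["mdcc"].max())
        surv = mdcc.surviving_modes(flip_pairs, 0)
        assert surv <= set(range(flip_models[0].n_modes))
        assert len(surv) >= 2

    def test_table_roundtrip(self, flip_pairs, tmp_path):
        path = tmp_path / "pairs.tsv"
        mdcc.write_pair_table(flip_pairs, path)
        back = mdcc.read_pair_table(path)
        assert len(back) == len(flip_pairs)
        assert np.allclose(back["mdcc"].fillna(0), flip_pairs["mdcc"].fillna(0),
                           atol=1e-9)
        assert (back["omitted"] == flip_pairs["omitted"]).all()
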