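"""Pairwise bond forces, windowed profiles and maxima location."""

import numpy as np
import pandas as pd
import pytest

import colmech as cm
from colmech.errors import StructuralError, ValidationError
from colmech.fibril_topology import linear_chain_coords
from colmech.force_distribution import sliding_window_mean


def static_trajectory(topology, coords, rest_lengths, k=10.0):
    """Single-frame trajectory with prescribed rest lengths (no dynamics)."""
    return cm.Trajectory(
        topology=topology,
        frames=np.asarray(coords, dtype=float)[None, :, :],
        params=cm.SimulationParams(n_steps=1, record_every=1),
        bond_rest_lengths=np.asarray(rest_lengths, dtype=float),
        bond_spring_constants=np.full(len(topology.bonds), k),
        equilibration_frames=0,
    )


class TestComputePairwiseForces:
    def test_static_frame_hooke_law_exact(self):
        chain = cm.linear_chain_topology(3, spacing=1.0)
        coords = linear_chain_coords(chain)
        coords[2, 2] += 0.25  # stretch the second bond by 0.25 nm
        traj = static_trajectory(chain, coords, rest_lengths=[1.0, 1.0], k=8.0)
        tab = cm.compute_pairwise_forces(traj)
        assert tab.force(0, 1) == pytest.approx(0.0, abs=1e-12)
        assert tab.force(1, 2) == pytest.approx(8.0 * 0.25, abs=1e-12)

    def test_matches_independent_direct_evaluation_on_static_frame(
        self, mini_fibril
    ):
        rng = np.random.default_rng(0)
        coords = cm.generate_coordinates(mini_fibril) + rng.normal(
            0, 0.05, (mini_fibril.n_sites, 3)
        )
        r0 = np.full(len(mini_fibril.bonds), 0.3)
        traj = static_trajectory(mini_fibril, coords, r0, k=7.0)
        tab = cm.compute_pairwise_forces(traj)
        # brute-force oracle: k (|ri - rj| - r0) for every bond
        for row in tab.entries.sample(50, random_state=1).itertuples():
            d = np.linalg.norm(coords[row.i] - coords[row.j])
            assert row.F == pytest.approx(7.0 * (d - 0.3), abs=1e-10)

    def test_newton_pair_symmetry(self, mini_force_table):
        e = mini_force_table.entries
        for row in e.head(20).itertuples():
            assert mini_force_table.force(row.i, row.j) == \
                mini_force_table.force(row.j, row.i)

    def test_loaded_single_chain_recovers_applied_force(self, chain20_trajectory):
        """Steady-state backbone tension equals the 1 nN per-chain load."""
        tab = cm.compute_pairwise_forces(chain20_trajectory)
        mean = tab.entries.F.mean()
        se = tab.entries.se.mean()  # conservative: bonds are correlated
        assert abs(mean - 1.0) <= 3 * se
        assert se < 0.02  # documented sampling-quality contract

    def test_unloaded_forces_negligible_relative_to_load(self, chain20_unloaded):
        """Zero external load: mean bond force is only the thermal
        radial offset ~2kT/r0, negligible against the 1 nN load."""
        tab = cm.compute_pairwise_forces(chain20_unloaded)
        mean = tab.entries.F.mean()
        p = chain20_unloaded.params
        offset = 2 * p.kT / chain20_unloaded.topology.config.axial_rise
        assert abs(mean) < 0.05          # < 5% of the 1 nN load
        assert mean == pytest.approx(offset, rel=0.5)

    def test_no_retained_frames_is_an_error(self):
        chain = cm.linear_chain_topology(4)
        traj = cm.simulate_pulling(
            chain,
            cm.SimulationParams(seed=1, n_steps=200, record_every=100),
            coords=linear_chain_coords(chain),
        )
        traj.equilibration_frames = traj.n_frames
        with pytest.raises(StructuralError, match="retained"):
            cm.compute_pairwise_forces(traj)


class TestDiffForceTables:
    def _toy_table(self, forces, topology):
        entries = pd.DataFrame(
            {
                "i": topology.bonds.i,
                "j": topology.bonds.j,
                "kind": topology.bonds.kind,
                "F": forces,
                "sd": np.full(len(forces), 0.1),
                "se": np.full(len(forces), 0.01),
                "n_frames": 10,
            }
        )
        return cm.PairwiseForceTable(entries=entries, topology=topology)

    def test_table_minus_itself_is_zero(self):
        chain = cm.linear_chain_topology(4)
        t = self._toy_table([1.0, 2.0, 3.0], chain)
        d = cm.diff_force_tables(t, t)
        assert np.allclose(d.entries.F, 0.0)

    def test_zero_control_leaves_loaded_unchanged(self):
        chain = cm.linear_chain_topology(4)
        loaded = self._toy_table([1.0, 2.0, 3.0], chain)
        control = self._toy_table([0.0, 0.0, 0.0], chain)
        d = cm.diff_force_tables(loaded, control)
        assert np.allclose(d.entries.F, [1.0, 2.0, 3.0])

    def test_hand_computed_differences_and_sd_propagation(self):
        chain = cm.linear_chain_topology(4)
        a = self._toy_table([1.5, -0.5, 2.0], chain)
        b = self._toy_table([0.5, 0.25, -1.0], chain)
        d = cm.diff_force_tables(a, b)
        assert np.allclose(d.entries.F, [1.0, -0.75, 3.0])
        assert np.allclose(d.entries.sd, np.sqrt(0.1**2 + 0.1**2))

    def test_mismatched_bond_sets_rejected(self):
        a = self._toy_table([1.0, 1.0, 1.0], cm.linear_chain_topology(4))
        b = self._toy_table([1.0, 1.0], cm.linear_chain_topology(3))
        with pytest.raises(StructuralError, match="mismatched"):
            cm.diff_force_tables(a, b)


class TestWindowedProfile:
    def test_window_means_brute_force_oracle(self):
        """11 bond forces 1..11 at positions 1..11, w=10 -> (5.5, 6.5)."""
        positions = np.arange(1, 12)
        values = np.arange(1, 12, dtype=float)
        centers, means = sliding_window_mean(positions, values, 10)
        assert np.allclose(means, [5.5, 6.5])
        assert np.allclose(centers, [1 + 4.5, 2 + 4.5])

    def test_unit_window_is_identity(self):
        positions = np.arange(5)
        values = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        centers, means = sliding_window_mean(positions, values, 1)
        assert np.allclose(means, values)

    def test_constant_series_gives_constant_profile(self):
        centers, means = sliding_window_mean(np.arange(30), np.full(30, 2.5), 10)
        assert np.allclose(means, 2.5)

    def test_window_longer_than_chain_rejected(self):
        with pytest.raises(ValidationError):
            sliding_window_mean(np.arange(5), np.ones(5), 10)

    def test_profile_has_one_series_per_crosslinked_pair(self, mini_force_table):
        prof = cm.windowed_profile(mini_force_table, w=10)
        n_pairs = len(mini_force_table.topology.crosslinked_pairs())
        for terminal in ("N", "C"):
            assert prof.terminals[terminal].per_pair.shape[0] == n_pairs

    def test_sem_computed_across_pairs(self, mini_force_table):
        prof = cm.windowed_profile(mini_force_table, w=10)
        tp = prof.terminals["N"]
        manual = tp.per_pair.std(axis=0, ddof=1) / np.sqrt(tp.per_pair.shape[0])
        assert np.allclose(tp.sem, manual)


class TestLocateMaxima:
    def test_single_peak_at_crosslink_ranked_first_distance_zero(self):
        from colmech.force_distribution import ForceProfile, TerminalProfile

        tp = TerminalProfile(
            centers=np.array([10.0, 20.0, 30.0]),
            per_pair=np.array([[0.1, 5.0, 0.1]]),
            pair_labels=[(0, 4)],
            crosslink_positions=np.array([20.0]),
        )
        ranked = cm.locate_maxima(
            ForceProfile(window_length=1, terminals={"N": tp}), "N"
        )
        assert ranked.center.iloc[0] == 20.0
        assert ranked.distance_to_crosslink.iloc[0] == 0.0

    def test_flat_profile_ties_broken_by_ascending_position(self):
        from colmech.force_distribution import ForceProfile, TerminalProfile

        tp = TerminalProfile(
            centers=np.array([3.0, 1.0, 2.0]),
            per_pair=np.array([[1.0, 1.0, 1.0]]),
            pair_labels=[(0, 4)],
            crosslink_positions=np.array([1.0]),
        )
        ranked = cm.locate_maxima(
            ForceProfile(window_length=1, terminals={"N": tp}), "N"
        )
        assert list(ranked.center) == [1.0, 2.0, 3.0]

    def test_fibril_top_n_window_adjacent_to_crosslink(self, mini_force_table):
        """Exhaustive-scan check that the strongest N-terminal window sits
        within one window length of the crosslink."""
        prof = cm.windowed_profile(mini_force_table, w=10)
        ranked = cm.locate_maxima(prof, "N")
        tp = prof.terminals["N"]
        brute = tp.centers[np.argmax(tp.mean)]
        assert ranked.center.iloc[0] == brute
        assert ranked.distance_to_crosslink.iloc[0] <= prof.window_length


class TestFibrilForcePattern:
    def test_telopeptide_off_path_forces_lower_than_on_path(
        self, mini_fibril, mini_force_table
    ):
        """Telopeptides outside the force-propagation pathways carry
        minimal backbone force compared with crosslink-path backbone."""
        s = mini_fibril.sites
        e = mini_force_table.entries
        xl_chains = {
            (s.helix_id.values[x.donor], s.chain_id.values[x.donor])
            for x in mini_fibril.crosslinks
        } | {
            (s.helix_id.values[x.acceptor], s.chain_id.values[x.acceptor])
            for x in mini_fibril.crosslinks
        }
        bond_chain = list(
            zip(s.helix_id.values[e.i.values], s.chain_id.values[e.i.values])
        )
        telo = (
            (np.array([s.region.values[i] for i in e.i]) == "telopeptide")
            & (np.array([s.region.values[j] for j in e.j]) == "telopeptide")
        )
        off_path = np.array([bc not in xl_chains for bc in bond_chain])
        backbone = (e.kind == "backbone").values
        telo_off = e.F.values[telo & off_path & backbone]
        on_path = e.F.values[~off_path & backbone]
        assert len(telo_off) > 0
        assert telo_off.mean() < 0.2 * on_path.mean()

    def test_n_crosslink_stress_concentration_signs(
        self, mini_fibril, mini_force_table
    ):
        """Near-crosslink windows exceed far windows on the same chain, and
        the N-terminal crosslink concentrates more than the C-terminal."""
        prof = cm.windowed_profile(mini_force_table, w=10)
        tp = prof.terminals["N"]
        dist = np.min(
            np.abs(tp.centers[:, None] - tp.crosslink_positions[None, :]), axis=1
        )
        near = tp.mean[dist <= prof.window_length / 2]
        far = tp.mean[dist > prof.window_length]
        assert len(near) > 0 and len(far) > 0
        assert near.mean() > far.mean()
        e = mini_force_table.entries
        xl = e[e.kind == "crosslink"]
        term = {
            (min(x.donor, x.acceptor), max(x.donor, x.acceptor)): x.terminal
            for x in mini_fibril.crosslinks
        }
        labels = [term[(i, j)] for i, j in zip(xl.i, xl.j)]
        f_n = xl.F.values[np.array(labels) == "N"]
        f_c = xl.F.values[np.array(labels) == "C"]
        assert f_n.mean() > f_c.mean() > 0  # both in tension, N dominant
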