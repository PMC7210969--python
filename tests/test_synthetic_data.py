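"""Generators: Langevin pulling, MSAs, EPR sweeps, FOX plates."""

import numpy as np
import pytest

import colmech as cm
from colmech.errors import ValidationError
from colmech.fibril_topology import linear_chain_coords
from colmech.synthetic_data import (
    default_msa_spec,
    read_trajectory,
    write_trajectory,
)


class TestSimulatePulling:
    def test_same_seed_reproduces_frames_bit_identically(self):
        chain = cm.linear_chain_topology(8)
        p = cm.SimulationParams(seed=3, n_steps=2000, record_every=50)
        a = cm.simulate_pulling(chain, p)
        b = cm.simulate_pulling(chain, p)
        assert np.array_equal(a.frames, b.frames)

    def test_zero_force_equipartition(self):
        """Unloaded chain: bond-length variance ~ kT/k; mean extension is
        the small positive radial-Jacobian offset ~2kT/(k r0), well under
        2% of the rest length."""
        chain = cm.linear_chain_topology(20)
        p = cm.SimulationParams(
            seed=4, per_chain_force=0.0, timestep=0.001,
            n_steps=100_000, record_every=100,
        )
        traj = cm.simulate_pulling(chain, p, coords=linear_chain_coords(chain))
        d = traj.retained_frames[:, chain.bonds.i, :] - \
            traj.retained_frames[:, chain.bonds.j, :]
        lengths = np.linalg.norm(d, axis=-1)
        r0 = chain.config.axial_rise
        n_eff = lengths.size
        var = lengths.var()
        rel_se = np.sqrt(2.0 / n_eff)
        expect = p.kT / p.spring_constant
        assert abs(var - expect) < max(3 * rel_se, 0.03) * expect
        assert abs(lengths.mean() - r0) < 0.02 * r0

    def test_harmonic_chain_extension_under_constant_tension(self):
        """10-bead chain at force F: end-to-end ~ 9 (r0 + F/k)."""
        chain = cm.linear_chain_topology(10)
        p = cm.SimulationParams(seed=5)
        traj = cm.simulate_pulling(chain, p, coords=linear_chain_coords(chain))
        z = traj.retained_frames[:, :, 2]
        ee = (z[:, -1] - z[:, 0]).mean()
        expect = 9 * (chain.config.axial_rise + p.per_chain_force / p.spring_constant)
        assert ee == pytest.approx(expect, rel=0.03)

    def test_displacement_monotone_in_force(self, mini_fibril):
        """Mean axial bead displacement grows with per-chain force."""
        disp = []
        for f in (0.5, 1.0, 2.0):
            p = cm.SimulationParams(
                seed=9, per_chain_force=f, n_steps=15_000, record_every=100,
                equilibration_fraction=0.4,
            )
            traj = cm.simulate_pulling(mini_fibril, p)
            z0 = mini_fibril.sites.axial_coord.values
            dz = np.abs(traj.retained_frames[:, :, 2] - z0[None, :]).mean()
            disp.append(dz)
        assert disp[0] < disp[1] < disp[2]

    def test_connectivity_conserved_no_rupture_flag(self, mini_trajectory):
        assert mini_trajectory.rupture_flag is False

    def test_rupture_flag_raised_when_a_bond_overstretches(self):
        chain = cm.linear_chain_topology(5)
        p = cm.SimulationParams(
            seed=6, per_chain_force=30.0, n_steps=2000, record_every=50,
            rupture_check_factor=2.0,
        )
        traj = cm.simulate_pulling(chain, p, coords=linear_chain_coords(chain))
        assert traj.rupture_flag is True

    def test_divergent_timestep_raises_with_advice(self):
        chain = cm.linear_chain_topology(5)
        p = cm.SimulationParams(seed=6, timestep=1.0, n_steps=500, record_every=50)
        with pytest.raises(RuntimeError, match="smaller timestep"):
            cm.simulate_pulling(chain, p, coords=linear_chain_coords(chain))

    def test_equal_mode_rejects_unequal_weights(self):
        with pytest.raises(ValidationError):
            cm.SimulationParams(loading_mode="equal", shear_weights=(2.0, 0.0))

    def test_shear_weights_must_conserve_total_load(self, mini_fibril):
        p = cm.SimulationParams(
            loading_mode="shear",
            shear_weights=tuple([2.0] * mini_fibril.config.n_helices),
        )
        with pytest.raises(ValidationError, match="sum to n_helices"):
            cm.simulate_pulling(mini_fibril, p)

    def test_trajectory_round_trip(self, tmp_path):
        chain = cm.linear_chain_topology(6)
        p = cm.SimulationParams(seed=8, n_steps=500, record_every=100)
        traj = cm.simulate_pulling(chain, p, coords=linear_chain_coords(chain))
        write_trajectory(traj, tmp_path / "run")
        back = read_trajectory(tmp_path / "run", chain)
        assert back.n_frames == traj.n_frames
        assert np.allclose(back.frames, traj.frames, atol=1e-5)
        assert back.params == traj.params


class TestGenerateMsa:
    def test_enrichment_probability_one_plants_everywhere(self):
        spec = cm.SyntheticMsaSpec(
            reference="AAAAAAAAAA", n_sequences=12,
            planted={"Y": [3, 7]}, enrichment_probability=1.0, seed=1,
        )
        aln = cm.generate_msa(spec)
        assert len(aln) == 12
        for rec in aln:
            assert rec.seq[2] == "Y" and rec.seq[6] == "Y"

    def test_zero_sequences_gives_empty_alignment(self):
        spec = cm.SyntheticMsaSpec(reference="AAAA", n_sequences=0)
        assert len(cm.generate_msa(spec)) == 0

    def test_planted_columns_exceed_background_by_direct_tally(self, mini_fibril):
        spec = default_msa_spec(mini_fibril, n_sequences=40, seed=2)
        aln = cm.generate_msa(spec)
        planted_cols = {p - 1 for ps in spec.planted.values() for p in ps}
        def col_freq(col, members):
            return sum(rec.seq[col] in members for rec in aln) / len(aln)
        planted_freqs = [
            col_freq(p - 1, {c}) for c, ps in spec.planted.items() for p in ps
        ]
        background = [
            col_freq(c, set("YFM"))
            for c in range(0, len(spec.reference), 37)
            if c not in planted_cols
        ]
        assert min(planted_freqs) > max(background)

    def test_out_of_range_planted_position_rejected(self):
        with pytest.raises(ValidationError):
            cm.SyntheticMsaSpec(reference="AAAA", planted={"Y": [9]})

    def test_fasta_round_trip(self, tmp_path, mini_fibril):
        from colmech.synthetic_data import write_msa_fasta

        spec = default_msa_spec(mini_fibril, n_sequences=5, seed=3)
        aln = cm.generate_msa(spec)
        path = write_msa_fasta(aln, tmp_path / "msa.fasta")
        back = cm.read_alignment(path)
        assert len(back) == 5
        assert str(back[0].seq) == str(aln[0].seq)


class TestGenerateEprSweep:
    def test_zero_noise_matches_clean_simulation(self):
        g = cm.GTensor.isotropic(2.005)
        p = cm.AcquisitionParams()
        clean = cm.powder_spectrum(g, p)
        sweep = cm.generate_epr_sweep(g, p, noise_sd=0.0, seed=1)
        assert np.array_equal(sweep.intensity, clean.intensity)

    def test_same_seed_same_noise(self):
        g = cm.GTensor.isotropic(2.005)
        p = cm.AcquisitionParams()
        a = cm.generate_epr_sweep(g, p, noise_sd=0.1, seed=2)
        b = cm.generate_epr_sweep(g, p, noise_sd=0.1, seed=2)
        assert np.array_equal(a.intensity, b.intensity)

    def test_residual_standard_deviation_matches_request(self):
        g = cm.GTensor.isotropic(2.005)
        p = cm.AcquisitionParams(field_min_mT=320.0, field_max_mT=350.0,
                                 field_step_mT=0.005)
        clean = cm.powder_spectrum(g, p)
        assert len(clean.field_mT) >= 4096
        sweep = cm.generate_epr_sweep(g, p, noise_sd=0.07, seed=3)
        resid = sweep.intensity - clean.intensity
        assert resid.std() == pytest.approx(0.07, rel=0.10)

    def test_negative_noise_rejected(self):
        with pytest.raises(ValidationError):
            cm.generate_epr_sweep(cm.GTensor.isotropic(2.0), noise_sd=-1.0)


class TestGenerateFoxPlate:
    def test_zero_delta_zero_noise_gives_identical_conditions(self):
        plate = cm.generate_fox_plate(true_delta_uM=0.0, noise_sd=0.0)
        by = plate.groupby(["time_min", "condition"]).absorbance.mean().unstack()
        assert np.allclose(by["pulled"], by["untreated"])

    def test_noiseless_plate_inverts_exactly(self):
        cal = cm.FoxCalibration()
        plate = cm.generate_fox_plate(true_delta_uM=1.0, calibration=cal,
                                      noise_sd=0.0)
        est = cm.estimate_delta_concentration(plate, cal, time_min=30.0)
        assert est.delta_uM == pytest.approx(1.0, abs=1e-12)

    def test_well_count_from_construction(self):
        plate = cm.generate_fox_plate(replicates=3, times_min=(0, 30, 60))
        assert len(plate) == 18  # 3 wells x 2 conditions x 3 time points

    def test_zero_slope_calibration_rejected(self):
        with pytest.raises(ValidationError):
            cm.FoxCalibration(slope=0.0)

    def test_seeded_reproducibility(self):
        a = cm.generate_fox_plate(seed=5)
        b = cm.generate_fox_plate(seed=5)
        assert a.equals(b)
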