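import math
import warnings

import numpy as np
import pytest

from nucleofit.genome import BeadChain, NucleusGeometry, ParameterPoint
from nucleofit.simulate import (
    ForceField,
    bending_constant_from_P,
    build_system,
    free_chain_system,
    init_configuration,
    langevin_step,
    run_simulation,
)


def _many_chains(n_chains, n_beads, W=30.0):
    """Independent identical chains batched in one (non-interacting) system."""
    bpb = 1500.0
    return [
        BeadChain(
            chromosome=f"c{i}", bead_count=n_beads, bead_diameters=[W] * n_beads,
            bp_per_bead=bpb, centromere_bead_index=n_beads // 2,
            telomere_bead_indices=(0, n_beads - 1),
            bead_bp_edges=[j * bpb for j in range(n_beads + 1)],
        )
        for i in range(n_chains)
    ]


class TestBendingConstant:
    @pytest.mark.parametrize("P,b,expected", [(30, 30, 1.0), (69, 30, 2.3)])
    def test_leading_order(self, P, b, expected):
        assert bending_constant_from_P(P, b) == pytest.approx(expected)

    def test_exact_inverts_langevin_function(self):
        k = bending_constant_from_P(69, 30, exact=True)
        assert 1 / math.tanh(k) - 1 / k == pytest.approx(math.exp(-30 / 69), abs=1e-10)

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            bending_constant_from_P(-1, 30)
        with pytest.raises(ValueError):
            bending_constant_from_P(30, 0)


class TestInitConfiguration:
    def test_deterministic_and_inside_sphere(self):
        from nucleofit.genome import discretize_genome
        from nucleofit.validate import scaled_genome, scaled_geometry

        geom = scaled_geometry()
        pp = ParameterPoint(P=80, C=55, W=30, L=140)
        chains = discretize_genome(scaled_genome(), pp, geom)
        system = build_system(chains, geom, pp)
        s1 = init_configuration(system, seed=4)
        s2 = init_configuration(system, seed=4)
        np.testing.assert_array_equal(s1.positions, s2.positions)
        r = np.linalg.norm(s1.positions, axis=1)
        assert np.all(r <= geom.R_N - system.diameters / 2.0 + 1e-9)

    def test_overcrowded_system_rejected(self):
        geom = NucleusGeometry(R_N=100.0, W_rDNA=30.0, n_rdna_beads=1)
        pp = ParameterPoint(P=30, C=50, W=30, L=50)
        chains = _many_chains(10, 50)
        with pytest.raises(ValueError, match="do not fit"):
            build_system(chains, geom, pp)


class TestLangevinStep:
    def test_zero_temperature_zero_force_is_immobile(self):
        system = free_chain_system(1, P=0, force_field=ForceField(temperature=0.0))
        state = init_configuration(system, seed=1)
        before = state.positions.copy()
        after = langevin_step(state, system, dt=0.02, n_steps=10)
        np.testing.assert_allclose(after.positions, before)

    def test_stretched_bond_relaxes_to_rest_length(self):
        system = free_chain_system(2, P=0, force_field=ForceField(temperature=0.0))
        state = init_configuration(system, seed=1)
        state.positions[1] = state.positions[0] + np.array([41.0, 0.0, 0.0])
        out = langevin_step(state, system, dt=0.02, n_steps=2000)
        bond = np.linalg.norm(out.positions[1] - out.positions[0])
        assert bond == pytest.approx(30.0, abs=0.05)

    def test_free_bead_einstein_relation(self):
        # 300 non-interacting single beads; MSD(t) = 6 (kT/gamma) t
        chains = _many_chains(300, 1)
        system = build_system(chains, None, ParameterPoint(1, 50, 30, 300), ForceField(epsilon=0))
        traj = run_simulation(system, n_steps=20_000, sample_every=200, equilibration_steps=0, seed=2)
        dt = traj.metadata["dt"]
        for lag in (5, 20):
            d = traj.positions[lag:] - traj.positions[:-lag]
            ratio = (d**2).sum(axis=2).mean() / (6.0 * lag * 200 * dt)
            assert ratio == pytest.approx(1.0, rel=0.05)


class TestRunSimulation:
    def test_sample_count_arithmetic(self):
        system = free_chain_system(5, P=0)
        traj = run_simulation(system, n_steps=10_000, sample_every=100,
                              equilibration_steps=2_000, seed=0)
        assert traj.n_samples == 80
        np.testing.assert_array_equal(traj.times[:2], [2_100, 2_200])

    def test_requires_steps_beyond_equilibration(self):
        system = free_chain_system(5, P=0)
        with pytest.raises(ValueError):
            run_simulation(system, n_steps=100, sample_every=10, equilibration_steps=100)

    def test_identical_seeds_identical_trajectories(self):
        system = free_chain_system(20, P=60)
        t1 = run_simulation(system, n_steps=5_000, sample_every=500, equilibration_steps=0, seed=9)
        t2 = run_simulation(system, n_steps=5_000, sample_every=500, equilibration_steps=0, seed=9)
        np.testing.assert_array_equal(t1.positions, t2.positions)

    def test_wlc_end_to_end_matches_closed_form(self):
        # ensemble of independent semiflexible phantom chains started in
        # their exact equilibrium ensemble
        from nucleofit.validate import wlc_mean_square_end_to_end

        n_chains, n_beads, P, W = 40, 50, 100.0, 30.0
        chains = _many_chains(n_chains, n_beads, W)
        system = build_system(chains, None, ParameterPoint(P, 50, W, 300), ForceField(epsilon=0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            traj = run_simulation(system, n_steps=60_000, sample_every=1_000,
                                  equilibration_steps=10_000, seed=3)
        per_chain = []
        for c in range(n_chains):
            sl = system.chain_slice(c)
            p = traj.positions[:, sl, :]
            per_chain.append(((p[:, -1, :] - p[:, 0, :]) ** 2).sum(axis=1).mean())
        per_chain = np.array(per_chain)
        se = per_chain.std(ddof=1) / np.sqrt(n_chains)
        expected = wlc_mean_square_end_to_end(P, (n_beads - 1) * W)
        assert abs(per_chain.mean() - expected) < 3 * se + 0.03 * expected

    def test_tangent_correlation_recovers_persistence_length(self):
        # contour length 10 P, fitted P within 10 % of target; a wide chain
        # ensemble keeps the statistical error on the fit well below that
        n_chains, n_beads, P, W = 120, 60, 180.0, 30.0
        chains = _many_chains(n_chains, n_beads, W)
        system = build_system(chains, None, ParameterPoint(P, 50, W, 300), ForceField(epsilon=0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            traj = run_simulation(system, n_steps=30_000, sample_every=1_000,
                                  equilibration_steps=5_000, seed=8)
        n_s = 8
        corr = np.zeros(n_s)
        for c in range(n_chains):
            sl = system.chain_slice(c)
            p = traj.positions[:, sl, :]
            bonds = p[:, 1:, :] - p[:, :-1, :]
            e = bonds / np.linalg.norm(bonds, axis=2, keepdims=True)
            for s in range(1, n_s + 1):
                corr[s - 1] += np.einsum("fij,fij->fi", e[:, :-s], e[:, s:]).mean()
        corr /= n_chains
        s_nm = np.arange(1, n_s + 1) * W
        fitted = -1.0 / np.polyfit(s_nm, np.log(corr), 1)[0]
        assert fitted == pytest.approx(P, rel=0.10)

    def test_confined_beads_stay_inside_nucleus(self):
        from nucleofit.genome import discretize_genome
        from nucleofit.validate import scaled_genome, scaled_geometry

        geom = scaled_geometry()
        pp = ParameterPoint(P=80, C=85, W=30, L=140)
        chains = discretize_genome(scaled_genome(), pp, geom)
        system = build_system(chains, geom, pp)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            traj = run_simulation(system, n_steps=30_000, sample_every=1_000,
                                  equilibration_steps=0, seed=6)
        r = np.linalg.norm(traj.positions, axis=2)
        assert r.max() <= geom.R_N + pp.W

    def test_excluded_volume_prevents_deep_overlap(self):
        # minimum non-bonded pair distance stays near the contact distance
        chains = _many_chains(4, 20)
        geom = NucleusGeometry(R_N=300.0, W_rDNA=30.0, n_rdna_beads=1)
        pp = ParameterPoint(P=60, C=50, W=30, L=100)
        system = build_system(chains, geom, pp, ForceField(epsilon=1.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            traj = run_simulation(system, n_steps=30_000, sample_every=500,
                                  equilibration_steps=5_000, seed=13)
        from scipy.spatial.distance import pdist

        min_d = min(pdist(frame).min() for frame in traj.positions)
        assert min_d > 0.7 * 30.0

    def test_divergence_reported_with_step(self):
        system = free_chain_system(10, P=0)
        with pytest.raises(FloatingPointError, match="diverged"):
            run_simulation(system, n_steps=20_000, sample_every=100,
                           equilibration_steps=0, seed=1, dt=1e7)
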