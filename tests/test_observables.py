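import numpy as np
import pytest

from nucleofit.genome import BeadChain, NucleusGeometry, ParameterPoint
from nucleofit.observables import (
    HIC_SEP_BINS,
    NUCLEOLUS,
    SPB,
    ObservableSet,
    ObservableSpec,
    angle_to_nucleolar_axis,
    bead_contact_frequencies,
    contact_map,
    fit_time_scale,
    hic_summaries,
    msd,
    pairwise_distance_stats,
)
from nucleofit.simulate import ForceField, System, Trajectory, build_system


def _toy_trajectory(positions, n_rdna=0, W=30.0, R_N=1000.0):
    """Trajectory with hand-set positions: one chain, optional trailing rDNA
    beads."""
    positions = np.asarray(positions, float)
    n = positions.shape[1]
    bpb = 1500.0
    rdna_range = (n - n_rdna, n) if n_rdna else None
    chain = BeadChain(
        chromosome="chrT", bead_count=n, bead_diameters=[W] * n, bp_per_bead=bpb,
        centromere_bead_index=0, telomere_bead_indices=(0, n - 1),
        rdna_bead_range=rdna_range, bead_bp_edges=[i * bpb for i in range(n + 1)],
    )
    geom = NucleusGeometry(R_N=R_N, W_rDNA=W, n_rdna_beads=max(n_rdna, 1))
    system = build_system([chain], geom, ParameterPoint(60, 50, W, 300), ForceField())
    return Trajectory(times=np.arange(positions.shape[0]), positions=positions, system=system,
                      metadata={"dt": 1.0, "sample_every": 1})


class TestDistanceStats:
    def test_constant_distance_all_statistics(self):
        frames = np.zeros((250, 2, 3))
        frames[:, 1, 0] = 70.0
        traj = _toy_trajectory(frames)
        for stat in ("mean", "median", "mode"):
            v = pairwise_distance_stats(traj, ("chrT", 0), ("chrT", 2000), statistic=stat)
            assert v == pytest.approx(70.0, abs=1e-6 if stat != "mode" else 1.0)

    def test_median_of_skewed_frames(self):
        frames = np.zeros((30, 2, 3))
        frames[:10, 1, 0] = 1.0
        frames[10:20, 1, 0] = 2.0
        frames[20:, 1, 0] = 9.0
        traj = _toy_trajectory(frames)
        assert pairwise_distance_stats(traj, ("chrT", 0), ("chrT", 2000)) == 2.0

    def test_pythagorean_displacement(self):
        frames = np.zeros((30, 2, 3))
        frames[:, 1] = [3.0, 4.0, 0.0]
        traj = _toy_trajectory(frames)
        assert pairwise_distance_stats(traj, ("chrT", 0), ("chrT", 2000),
                                       statistic="mean") == pytest.approx(5.0)

    def test_mode_matches_density_argmax(self):
        rng = np.random.default_rng(3)
        d = rng.normal(120.0, 12.0, 10_000)
        frames = np.zeros((10_000, 2, 3))
        frames[:, 1, 0] = d
        traj = _toy_trajectory(frames)
        mode = pairwise_distance_stats(traj, ("chrT", 0), ("chrT", 2000), statistic="mode")
        assert mode == pytest.approx(120.0, abs=4.0)

    def test_mode_needs_enough_frames(self):
        traj = _toy_trajectory(np.zeros((50, 2, 3)))
        with pytest.raises(ValueError, match="mode needs"):
            pairwise_distance_stats(traj, ("chrT", 0), ("chrT", 2000), statistic="mode")

    def test_2d_below_3d_and_rotation_invariance(self):
        rng = np.random.default_rng(8)
        frames = rng.normal(0, 80, (3000, 2, 3))
        traj = _toy_trajectory(frames)
        d3 = pairwise_distance_stats(traj, ("chrT", 0), ("chrT", 2000), "median", "3d")
        d2 = pairwise_distance_stats(traj, ("chrT", 0), ("chrT", 2000), "median", "2d", seed=1)
        assert d2 < d3
        # global rotation leaves both invariant (2d uses its own random axes)
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("zyx", [0.3, 1.1, -0.7]).as_matrix()
        traj_rot = _toy_trajectory(frames @ R.T)
        assert pairwise_distance_stats(traj_rot, ("chrT", 0), ("chrT", 2000), "median", "3d") == pytest.approx(d3)
        assert pairwise_distance_stats(traj_rot, ("chrT", 0), ("chrT", 2000), "median", "2d", seed=1) == pytest.approx(d2, rel=0.05)


class TestAngles:
    def _traj(self, locus_xyz):
        # bead 0 at locus, beads 1-2 rDNA at z = -500
        frames = np.zeros((40, 3, 3))
        frames[:, 0] = locus_xyz
        frames[:, 1] = [0, 0, -480.0]
        frames[:, 2] = [0, 0, -520.0]
        return _toy_trajectory(frames, n_rdna=2)

    def test_collinear_same_side_is_zero(self):
        assert angle_to_nucleolar_axis(self._traj([0, 0, -300.0]), ("chrT", 0)) == pytest.approx(0.0, abs=1e-6)

    def test_orthogonal_is_ninety(self):
        assert angle_to_nucleolar_axis(self._traj([300.0, 0, 0]), ("chrT", 0)) == pytest.approx(90.0)

    def test_antipodal_is_180(self):
        assert angle_to_nucleolar_axis(self._traj([0, 0, 400.0]), ("chrT", 0)) == pytest.approx(180.0)

    def test_degenerate_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            angle_to_nucleolar_axis(self._traj([0.0, 0.0, 0.0]), ("chrT", 0))


class TestContacts:
    def test_three_bead_fixed_geometry_brute_force(self):
        # beads at 0, 50, 120 nm on a line; cutoff 60: only (0,1) in contact
        frames = np.zeros((10, 3, 3))
        frames[:, 1, 0] = 50.0
        frames[:, 2, 0] = 120.0
        traj = _toy_trajectory(frames)
        f = bead_contact_frequencies(traj, cutoff_nm=60.0)
        expected = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]], float)
        np.testing.assert_allclose(f, expected)

    def test_permanent_contact_has_frequency_one(self):
        frames = np.zeros((10, 2, 3))
        frames[:, 1, 0] = 10.0
        traj = _toy_trajectory(frames)
        assert bead_contact_frequencies(traj, 60.0)[0, 1] == 1.0

    def test_frequency_monotone_in_cutoff(self):
        rng = np.random.default_rng(5)
        traj = _toy_trajectory(rng.normal(0, 60, (50, 6, 3)))
        f1 = bead_contact_frequencies(traj, 40.0)
        f2 = bead_contact_frequencies(traj, 80.0)
        assert np.all(f2 >= f1)

    def test_contact_map_symmetric_and_validates_bin_size(self):
        rng = np.random.default_rng(6)
        traj = _toy_trajectory(rng.normal(0, 60, (20, 8, 3)))
        cm = contact_map(traj, bin_size_bp=3000)
        np.testing.assert_allclose(cm.matrix, cm.matrix.T)
        assert np.all(cm.matrix >= 0)
        with pytest.raises(ValueError, match="bin size"):
            contact_map(traj, bin_size_bp=1000)

    def test_frame_order_does_not_matter(self):
        rng = np.random.default_rng(9)
        frames = rng.normal(0, 60, (30, 5, 3))
        t1 = _toy_trajectory(frames)
        t2 = _toy_trajectory(frames[::-1])
        np.testing.assert_allclose(
            bead_contact_frequencies(t1, 60.0), bead_contact_frequencies(t2, 60.0)
        )


class TestHicSummaries:
    def test_yeast_schema_has_56_values(self, yeast):
        from nucleofit.genome import discretize_genome

        pp = ParameterPoint(P=69, C=110, W=60, L=300)
        geom = NucleusGeometry()
        chains = discretize_genome(yeast, pp, geom)
        system = build_system(chains, geom, pp)
        freq = np.full((system.n_beads, system.n_beads), 0.2)
        out = hic_summaries(freq, system)
        assert len(out) == 56
        classes = [s.cls for s in out.specs]
        assert classes.count("contact_summary_intra") == 16
        assert classes.count("contact_summary_inter") == 16
        assert classes.count("contact_vs_s_genomewide") == 12
        assert classes.count("contact_vs_s_centromeric") == 12
        # separation bins span 25-85 kb in 5 kb intervals
        seps = [s.sep_bp for s in out.specs if s.cls == "contact_vs_s_genomewide"]
        assert seps == list(range(25_000, 85_000, 5_000))
        # uniform matrix: all intra values equal, all equal 0.2
        intra = out.values[:16]
        np.testing.assert_allclose(intra, 0.2)


class TestMsd:
    def test_immobile_bead_zero(self):
        traj = _toy_trajectory(np.zeros((50, 2, 3)))
        np.testing.assert_allclose(msd(traj, ("chrT", 0), [1, 5, 10]), 0.0)

    def test_ballistic_drift(self):
        frames = np.zeros((100, 2, 3))
        frames[:, 0, 0] = 3.0 * np.arange(100)
        traj = _toy_trajectory(frames)
        out = msd(traj, ("chrT", 0), [1, 4])
        np.testing.assert_allclose(out, [9.0, 144.0])

    def test_lag_beyond_span_rejected(self):
        traj = _toy_trajectory(np.zeros((20, 2, 3)))
        with pytest.raises(ValueError, match="lag"):
            msd(traj, ("chrT", 0), [25])


class TestTimeScaleFit:
    def _curve(self, t):
        return 200.0 * t**0.5

    def test_identity_and_doubling(self):
        t = np.geomspace(1, 100, 20)
        assert fit_time_scale(t, self._curve(t), t, self._curve(t)) == pytest.approx(1.0, rel=1e-3)
        # experiment = simulation with time axis x2
        assert fit_time_scale(t, self._curve(t), 2 * t, self._curve(t)) == pytest.approx(2.0, rel=0.01)

    def test_noisy_recovery_of_known_scale(self):
        rng = np.random.default_rng(11)
        t_sim = np.geomspace(1, 500, 40)
        scale = 0.37
        t_exp = np.geomspace(1, 100, 25)
        m_exp = self._curve(t_exp / scale) * np.exp(rng.normal(0, 0.05, t_exp.size))
        fitted = fit_time_scale(t_sim, self._curve(t_sim), t_exp, m_exp)
        assert fitted == pytest.approx(scale, rel=0.05)


def test_contact_map_text_round_trip(tmp_path):
    rng = np.random.default_rng(7)
    traj = _toy_trajectory(rng.normal(0, 60, (20, 8, 3)))
    cm = contact_map(traj, bin_size_bp=3000)
    dense = tmp_path / "map.txt"
    cm.write_dense(dense)
    back = type(cm).read_dense(dense)
    np.testing.assert_allclose(back.matrix, cm.matrix, atol=1e-6)
    assert list(back.bins["chrom"]) == list(cm.bins["chrom"])
    trip = tmp_path / "map.tsv"
    cm.write_triplets(trip)
    back2 = type(cm).read_triplets(trip, cm.bins, cm.bin_size_bp)
    np.testing.assert_allclose(back2.matrix, cm.matrix, atol=1e-6)


def test_observable_set_round_trip(tmp_path):
    specs = (
        ObservableSpec(id="a", cls="median_3d_distance", chrom_a="chrI", bp_a=5, chrom_b=SPB),
        ObservableSpec(id="b", cls="contact_vs_s_genomewide", sep_bp=25_000, group="hic_A"),
    )
    obs = ObservableSet(specs, np.array([1.5, 0.25]), np.array([0.1, 0.01]))
    path = tmp_path / "obs.tsv"
    obs.write(path)
    back = ObservableSet.read(path)
    assert back.ids == ["a", "b"]
    np.testing.assert_allclose(back.values, obs.values)
    assert back.specs[0].chrom_b == SPB
    assert back.specs[1].group == "hic_A"
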