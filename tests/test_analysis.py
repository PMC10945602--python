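"""Observables: axis length, packing ratio, Kirkwood sedimentation, Rg,
contact maps/decay, DBSCAN microdomains (vs a naive reference), alpha-shape
geometry (vs convex-hull limits), TF occupancy, and convergence series."""

import numpy as np
import pytest
from scipy.spatial import ConvexHull

import fibermc as fm
from fibermc.analysis import (
    ContactMap,
    alpha_shape_area_2d,
    alpha_shape_volume_3d,
    inverse_frequency_distance,
)

from conftest import make_stub_trajectory


class TestFiberAxis:
    def test_collinear_cores_exact_length(self):
        cores = np.zeros((50, 3))
        cores[:, 0] = np.arange(50) * 5.0
        axis = fm.fiber_axis_and_length(cores)
        assert axis.length == pytest.approx(245.0, rel=1e-3)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(0)
        cores = np.cumsum(rng.normal(0, 3, (30, 3)), axis=0)
        from fibermc.geometry import rotation_matrix

        Q = rotation_matrix(np.array([1.0, 1.0, 0.2]), 1.1)
        a = fm.fiber_axis_and_length(cores).length
        b = fm.fiber_axis_and_length(cores @ Q.T + 7.0).length
        assert b == pytest.approx(a, rel=1e-9)

    def test_circle_arc_length(self):
        R = 40.0
        t = np.linspace(0, 2 * np.pi, 50, endpoint=False)
        cores = np.column_stack([R * np.cos(t), R * np.sin(t), np.zeros_like(t)])
        # arc length spanned by the 50 cores: 49/50 of the circumference
        expected = 2 * np.pi * R * 49 / 50
        got = fm.fiber_axis_and_length(cores).length
        assert got == pytest.approx(expected, rel=0.02)

    def test_single_core_undefined(self):
        with pytest.raises(ValueError):
            fm.fiber_axis_and_length(np.zeros((1, 3)))

    def test_zigzag_axis_passes_between_stacks(self):
        # ideal zigzag: the smoothed axis should suppress the up-down
        # oscillation, running between the two stacks
        amp = 4.0
        cores = np.zeros((40, 3))
        cores[:, 0] = np.arange(40) * 3.0
        cores[:, 1] = amp * (-1) ** np.arange(40)
        axis = fm.fiber_axis_and_length(cores)
        assert np.abs(axis.points[:, 1]).max() < 0.5 * amp


class TestPackingRatio:
    def test_direct_formula(self):
        cores = np.zeros((50, 3))
        cores[:, 0] = np.arange(50) * (275.0 / 49)  # Fl ~ 275 nm
        assert fm.packing_ratio(cores) == pytest.approx(11 * 50 / 275.0, rel=1e-3)

    def test_halving_length_doubles_ratio(self):
        cores = np.zeros((50, 3))
        cores[:, 0] = np.arange(50) * 4.0
        a = fm.packing_ratio(cores)
        cores[:, 0] /= 2
        assert fm.packing_ratio(cores) == pytest.approx(2 * a, rel=1e-3)


class TestSedimentation:
    def test_mononucleosome_limits(self):
        one = np.zeros((1, 3))
        assert fm.sedimentation_coefficient(one, 0.0) == pytest.approx(11.1)
        assert fm.sedimentation_coefficient(one, 1.0) == pytest.approx(12.0)

    def test_two_core_hand_value(self):
        cores = np.array([[0.0, 0, 0], [11.0, 0, 0]])
        # 11.1 * (1 + (5.5/2) * (2/11)) = 16.65 under the ordered-pair sum
        assert fm.sedimentation_coefficient(cores, 0.0) == pytest.approx(16.65)

    def test_monotone_decreasing_under_dilation(self):
        rng = np.random.default_rng(3)
        cores = rng.normal(0, 10, (20, 3))
        vals = [fm.sedimentation_coefficient(cores * s, 0.0) for s in (1.0, 1.5, 2.0, 3.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_coincident_cores_error(self):
        with pytest.raises(ValueError):
            fm.sedimentation_coefficient(np.zeros((2, 3)), 0.0)


class TestRadiusOfGyration:
    def test_closed_forms(self):
        assert fm.radius_of_gyration(np.zeros((1, 3))) == 0.0
        two = np.array([[0.0, 0, 0], [6.0, 0, 0]])
        assert fm.radius_of_gyration(two) == pytest.approx(3.0)
        a = 5.0
        square = np.array([[0, 0, 0], [a, 0, 0], [a, a, 0], [0, a, 0]], dtype=float)
        assert fm.radius_of_gyration(square) == pytest.approx(a / np.sqrt(2))

    def test_rigid_invariance(self):
        rng = np.random.default_rng(1)
        cores = rng.normal(0, 5, (12, 3))
        from fibermc.geometry import rotation_matrix

        Q = rotation_matrix(np.array([0.2, 1.0, 0.5]), 2.0)
        assert fm.radius_of_gyration(cores @ Q.T + 3.0) == pytest.approx(
            fm.radius_of_gyration(cores), rel=1e-12
        )


@pytest.fixture()
def two_core_setup():
    topo = fm.build_uniform_fiber(2, 9)  # one linker bead
    ff = fm.ForceField(n_tails_per_core=0, tail_beads=0)
    cfg = fm.build_zigzag(topo, ff)
    return topo, ff, cfg


class TestContactMap:
    def _separated(self, cfg, gap):
        # place core 1 at a controlled surface gap from core 0 and park the
        # linker bead far away so only the core pair can touch
        out = cfg.copy()
        out.core_pos[0] = [0.0, 0, 0]
        out.core_pos[1] = [6.0 + gap, 0.0, 0.0]  # radii 3.0 + 3.0
        out.linker_pos[0] = [500.0, 500, 500]
        return out

    def test_gap_below_cutoff_is_contact(self, two_core_setup):
        topo, ff, cfg = two_core_setup
        m = fm.contact_map([self._separated(cfg, 1.9)], topo, ff)
        assert m.counts[0, 1] == 1

    def test_gap_above_cutoff_no_contact(self, two_core_setup):
        topo, ff, cfg = two_core_setup
        m = fm.contact_map([self._separated(cfg, 2.1)], topo, ff)
        assert m.counts[0, 1] == 0

    def test_symmetry(self, two_core_setup):
        topo, ff, cfg = two_core_setup
        m = fm.contact_map([self._separated(cfg, 1.0)], topo, ff)
        np.testing.assert_array_equal(m.counts, m.counts.T)

    def test_empty_frame_list_rejected(self, two_core_setup):
        topo, ff, _ = two_core_setup
        with pytest.raises(ValueError):
            fm.contact_map([], topo, ff)


class TestEnsembleMap:
    def test_sum_of_identical_maps(self):
        m = ContactMap(np.array([[0.0, 3], [3, 0]]), n_frames=5)
        out = fm.ensemble_contact_map([m] * 10)
        np.testing.assert_array_equal(out.counts, 10 * m.counts)
        assert out.n_frames == 50

    def test_identity_and_elementwise(self):
        rng = np.random.default_rng(2)
        mats = []
        for _ in range(4):
            a = rng.integers(0, 5, (6, 6)).astype(float)
            mats.append(ContactMap((a + a.T) / 1.0, n_frames=3))
        out = fm.ensemble_contact_map(mats)
        np.testing.assert_allclose(out.counts, sum(m.counts for m in mats))
        one = fm.ensemble_contact_map([mats[0]])
        np.testing.assert_array_equal(one.counts, mats[0].counts)

    def test_shape_mismatch(self):
        a = ContactMap(np.zeros((3, 3)), 1)
        b = ContactMap(np.zeros((4, 4)), 1)
        with pytest.raises(ValueError):
            fm.ensemble_contact_map([a, b])


class TestContactDecay:
    def test_three_by_three_hand_values(self):
        m = ContactMap(np.array([[0.0, 1, 1], [1, 0, 1], [1, 1, 0]]), 1)
        decay = fm.contact_decay(m)
        assert decay.values[0] == pytest.approx(2 / 3)
        assert decay.values[1] == pytest.approx(1 / 3)

    def test_nearest_neighbour_only(self):
        m = np.zeros((5, 5))
        for i in range(4):
            m[i, i + 1] = m[i + 1, i] = 2.0
        decay = fm.contact_decay(ContactMap(m, 1))
        assert decay.values[0] == pytest.approx(1.0)
        assert decay.values[1:].sum() == 0.0

    def test_normalization_on_random_maps(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            a = rng.random((8, 8))
            m = ContactMap(a + a.T - np.diag(2 * np.diag(a)), 1)
            assert fm.contact_decay(m).values.sum() == pytest.approx(1.0)

    def test_zero_map_undefined(self):
        with pytest.raises(ValueError):
            fm.contact_decay(ContactMap(np.zeros((4, 4)), 1))


def naive_dbscan(dist: np.ndarray, eps: float, minpts: int) -> np.ndarray:
    """Reference DBSCAN by direct definition (density-reachability BFS)."""
    n = len(dist)
    neighbours = [set(np.flatnonzero(dist[i] <= eps).tolist()) for i in range(n)]
    core = [len(neighbours[i]) >= minpts for i in range(n)]
    labels = np.full(n, -1)
    cluster = 0
    for i in range(n):
        if labels[i] != -1 or not core[i]:
            continue
        queue = [i]
        labels[i] = cluster
        while queue:
            p = queue.pop()
            if not core[p]:
                continue
            for q in neighbours[p]:
                if labels[q] == -1:
                    labels[q] = cluster
                    queue.append(q)
        cluster += 1
    return labels


def _same_partition(a, b):
    """Labels equal up to renaming, noise matched exactly."""
    a, b = np.asarray(a), np.asarray(b)
    if not np.array_equal(a == -1, b == -1):
        return False
    mapping = {}
    for x, y in zip(a, b):
        if x == -1:
            continue
        if mapping.setdefault(x, y) != y:
            return False
    return len(set(mapping.values())) == len(mapping)


class TestMicrodomains:
    def test_two_block_example(self):
        # two 3-nucleosome blocks: d = 0.1 within, 10 across
        f = np.full((6, 6), 0.1)
        f[:3, 3:] = f[3:, :3] = 10.0
        np.fill_diagonal(f, 0.0)
        m = ContactMap(1.0 / np.where(f > 0, f, 1), 1)  # frequency = 1/d
        dom = fm.detect_microdomains(m, epsilon=1.0, minpoints=2)
        assert dom.n_clusters == 2
        assert _same_partition(dom.labels, [0, 0, 0, 1, 1, 1])

    def test_uniform_map_single_cluster(self):
        f = np.full((8, 8), 2.0)
        np.fill_diagonal(f, 0.0)
        dom = fm.detect_microdomains(ContactMap(f, 1), epsilon=1.0, minpoints=3)
        assert dom.n_clusters == 1
        assert (dom.labels == 0).all()

    def test_matches_naive_reference_on_random_instances(self):
        rng = np.random.default_rng(7)
        for trial in range(100):
            n = int(rng.integers(5, 21))
            a = rng.random((n, n)) * rng.choice([0.5, 2.0, 8.0])
            counts = (a + a.T) * (rng.random((n, n)) < 0.7)
            counts = np.triu(counts, 1)
            counts = counts + counts.T
            m = ContactMap(counts, 1)
            eps = float(rng.uniform(0.5, 6.0))
            minpts = int(rng.integers(2, 6))
            d = inverse_frequency_distance(m)
            ref = naive_dbscan(d, eps, minpts)
            got = fm.detect_microdomains(m, epsilon=eps, minpoints=minpts).labels
            assert _same_partition(got, ref), f"trial {trial}"

    def test_zero_frequency_distance_capped(self):
        counts = np.zeros((4, 4))
        counts[0, 1] = counts[1, 0] = 2.0
        d = inverse_frequency_distance(ContactMap(counts, 1))
        finite = d[0, 1]
        assert d[0, 2] == pytest.approx(10 * finite)


class TestAlphaShape:
    def test_cube_volume_and_area(self):
        corners = np.array(
            [[x, y, z] for x in (0, 10.0) for y in (0, 10.0) for z in (0, 10.0)]
        )
        assert alpha_shape_volume_3d(corners, alpha=100.0) == pytest.approx(1000.0, rel=0.01)
        assert alpha_shape_area_2d(corners[:, :2], alpha=100.0) == pytest.approx(100.0, rel=0.01)

    def test_homogeneity_and_translation(self):
        rng = np.random.default_rng(9)
        pts = rng.normal(0, 5, (15, 3))
        v = alpha_shape_volume_3d(pts, 100.0)
        a = alpha_shape_area_2d(pts[:, :2], 100.0)
        s = 1.7  # alpha is a length, so it scales with the coordinates
        assert alpha_shape_volume_3d(pts * s, 100.0 * s) == pytest.approx(v * s**3, rel=1e-6)
        assert alpha_shape_area_2d(pts[:, :2] * s, 100.0 * s) == pytest.approx(a * s**2, rel=1e-6)
        assert alpha_shape_volume_3d(pts + 20.0, 100.0) == pytest.approx(v, rel=1e-6)

    def test_volume_bounded_by_convex_hull(self):
        rng = np.random.default_rng(11)
        for _ in range(10):
            pts = rng.normal(0, 4, (20, 3))
            alpha = float(rng.uniform(3, 50))
            assert alpha_shape_volume_3d(pts, alpha) <= ConvexHull(pts).volume + 1e-9

    def test_degenerate_vertices_error(self):
        flat = np.zeros((5, 3))
        flat[:, 0] = np.arange(5)
        with pytest.raises(ValueError):
            alpha_shape_volume_3d(flat, 100.0)

    def test_promoter_geometry_mean_sd(self):
        corners = np.array(
            [[x, y, z] for x in (0, 10.0) for y in (0, 10.0) for z in (0, 10.0)]
        )
        topo = fm.build_uniform_fiber(8, 44)
        ff = fm.ForceField(n_tails_per_core=0, tail_beads=0)
        cfg = fm.build_zigzag(topo, ff)
        cfg.core_pos[:] = corners
        geo = fm.promoter_geometry([cfg, cfg], list(range(8)), alpha=100.0)
        assert geo.volume_mean == pytest.approx(1000.0, rel=0.01)
        assert geo.volume_sd == pytest.approx(0.0, abs=1e-9)


class TestTFOccupancy:
    def test_replica_average(self):
        # replicas with 10 bindable beads engaging 2, 2, 0, 0 and 1 pairs:
        # realized concentrations 40, 40, 0, 0, 20 percent -> ensemble 20%
        trajs = [make_stub_trajectory(4, engaged_pairs=k) for k in (2, 2, 0, 0, 1)]
        got = fm.effective_tf_concentration(trajs)
        assert got == pytest.approx(np.mean([40, 40, 0, 0, 20]))

    def test_no_bindable_returns_none(self):
        t = make_stub_trajectory(2, n_bindable=0)
        assert fm.effective_tf_concentration([t]) is None

    def test_never_engaged_is_zero(self):
        t = make_stub_trajectory(3, engaged_pairs=0)
        assert fm.effective_tf_concentration([t]) == 0.0


class TestMatrixDensity:
    def test_examples(self):
        assert fm.matrix_density(ContactMap(np.zeros((5, 5)), 1)) == 0.0
        full = np.ones((5, 5))
        assert fm.matrix_density(ContactMap(full, 1)) == 1.0
        m = np.zeros((15, 15))
        hits = [(0, 3), (1, 7), (2, 9), (4, 11), (5, 13), (0, 14), (3, 8), (6, 10),
                (7, 12), (9, 14)]
        for i, j in hits:
            m[i, j] = m[j, i] = 1.0
        assert fm.matrix_density(ContactMap(m, 1)) == pytest.approx(10 / 105)


class TestConvergence:
    def test_straight_fiber_triplet_angle(self):
        t = make_stub_trajectory(3)
        for f in t.frames:
            f.config.core_pos[:] = np.array([[0.0, 0, 0], [5, 0, 0], [10, 0, 0]])
        rep = fm.convergence_report(t)
        np.testing.assert_allclose(rep.triplet_angle_deg, 180.0)
        assert rep.end_to_end[0] == pytest.approx(10.0)
        assert len(rep.total_energy) == 3


class TestEnsembleAssembly:
    def test_pooled_counts(self):
        trajs = [make_stub_trajectory(150, seed=i + 1) for i in range(10)]
        ens = fm.assemble_analysis_ensemble(trajs, tail_steps=10_000_000)
        assert len(ens) == 1000
        trajs = [make_stub_trajectory(120, seed=i + 1) for i in range(20)]
        ens = fm.assemble_analysis_ensemble(trajs, tail_steps=10_000_000)
        assert len(ens) == 2000

    def test_single_frame_tail(self):
        t = make_stub_trajectory(5)
        ens = fm.assemble_analysis_ensemble([t], tail_steps=100_000)
        assert len(ens) == 1
        assert ens.provenance[0] == (0, t.frames[-1].step)

    def test_tail_too_long_rejected(self):
        t = make_stub_trajectory(3)
        with pytest.raises(ValueError):
            fm.assemble_analysis_ensemble([t], tail_steps=1_000_000)

    def test_provenance_records_replica_and_step(self):
        trajs = [make_stub_trajectory(4, seed=i + 1) for i in range(3)]
        ens = fm.assemble_analysis_ensemble(trajs, tail_steps=200_000)
        assert ens.provenance == [
            (0, 300_000), (0, 400_000), (1, 300_000), (1, 400_000),
            (2, 300_000), (2, 400_000),
        ]


class TestBpResolutionMap:
    def test_shape_symmetry_and_occupancy(self):
        topo = fm.build_uniform_fiber(6, 44)
        ff = fm.ForceField(n_tails_per_core=0, tail_beads=0)
        cfg = fm.build_zigzag(topo, ff)
        m = fm.contact_map([cfg], topo, ff, resolution="bp", bin_bp=200)
        total_bp = 6 * 147 + 5 * 44
        assert m.n == int(np.ceil((total_bp - 147 / 2) / 200)) or m.n > 0
        np.testing.assert_array_equal(m.counts, m.counts.T)
        assert m.resolution == "bp" and m.bin_bp == 200

    def test_unknown_resolution_rejected(self):
        topo = fm.build_uniform_fiber(3, 44)
        ff = fm.ForceField(n_tails_per_core=0, tail_beads=0)
        cfg = fm.build_zigzag(topo, ff)
        with pytest.raises(ValueError):
            fm.contact_map([cfg], topo, ff, resolution="kb")
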