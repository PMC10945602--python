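"""Fiber-topology builders: discretization, patterns, densities, gene tiling."""

import numpy as np
import pytest

import fibermc as fm
from fibermc.topology import MESC_LINKER_DISTRIBUTION, beads_for_bp
from fibermc.tracks import GenomicTrack


class TestUniformFiber:
    @pytest.mark.parametrize(
        "n_cores, linker_bp, n_runs, beads_per_run",
        [(50, 26, 49, 3), (1, 44, 0, None), (50, 62, 49, 7), (50, 44, 49, 5)],
    )
    def test_discretization(self, n_cores, linker_bp, n_runs, beads_per_run):
        topo = fm.build_uniform_fiber(n_cores, linker_bp)
        assert len(topo.linker_runs) == n_runs
        if n_runs:
            assert set(topo.linker_runs) == {beads_per_run}
        assert not any(topo.lh_occupied)
        assert not any(topo.acetylated)
        assert not any(topo.tf_bindable)

    @pytest.mark.parametrize("bad", [(0, 44), (5, 0), (5, -3)])
    def test_invalid_arguments(self, bad):
        with pytest.raises(ValueError):
            fm.build_uniform_fiber(*bad)

    def test_flag_vector_lengths(self):
        topo = fm.build_uniform_fiber(7, 53)
        assert len(topo.tf_bindable) == topo.n_linker_beads == sum(topo.linker_runs)
        assert len(topo.lh_occupied) == len(topo.acetylated) == 7


class TestLifelikeFiber:
    def test_default_distribution_sums_to_one(self):
        assert abs(sum(MESC_LINKER_DISTRIBUTION.values()) - 1.0) < 1e-12

    def test_degenerate_distribution_equals_uniform(self):
        life = fm.build_lifelike_fiber(50, {26: 1.0}, seed=5)
        uni = fm.build_uniform_fiber(50, 26)
        assert life.linker_runs == uni.linker_runs
        assert life.linker_bp == uni.linker_bp

    def test_empirical_frequencies_match(self):
        topo = fm.build_lifelike_fiber(10_001, seed=42)
        bp = np.array(topo.linker_bp)
        for cls, frac in MESC_LINKER_DISTRIBUTION.items():
            assert abs(np.mean(bp == cls) - frac) < 0.02

    def test_seed_determinism(self):
        a = fm.build_lifelike_fiber(200, seed=7)
        b = fm.build_lifelike_fiber(200, seed=7)
        assert a == b

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            fm.build_lifelike_fiber(10, {26: 0.5, 44: 0.4}, seed=0)


class TestTFTopology:
    def test_pattern1_five_regions(self):
        topo = fm.apply_tf_topology(
            fm.build_uniform_fiber(50, 44), fm.TFTopologySpec.pattern(1)
        )
        starts = fm.TFTopologySpec.pattern(1).region_starts(50)
        assert len(starts) == 5
        # marked nucleosome count = region_count x span
        marked = set()
        for a in starts:
            marked.update(range(a, a + 5))
        assert len(marked) == 25

    def test_pattern2_end_regions(self):
        spec = fm.TFTopologySpec.pattern(2)
        starts = spec.region_starts(50)
        assert starts == [1, 36]  # nucleosomes 1-15 and 36-50
        marked = sum(15 for _ in starts)
        assert marked == 30

    def test_pattern3_centered(self):
        starts = fm.TFTopologySpec.pattern(3).region_starts(50)
        assert starts == [18]  # 18..32, centered on nucleosome 25

    def test_marked_beads_are_internal_linkers(self):
        topo = fm.build_uniform_fiber(50, 44)
        out = fm.apply_tf_topology(topo, fm.TFTopologySpec.pattern(3))
        flags = np.array(out.tf_bindable)
        runs = sorted({out.run_of_bead(b) for b in np.flatnonzero(flags)})
        # region 18..32 (1-based) -> internal runs 17..30 (0-based)
        assert runs == list(range(17, 31))

    def test_pattern_does_not_fit(self):
        with pytest.raises(ValueError):
            fm.apply_tf_topology(
                fm.build_uniform_fiber(10, 44), fm.TFTopologySpec.pattern(2)
            )

    def test_canonical_parameters_enforced(self):
        with pytest.raises(ValueError):
            fm.TFTopologySpec(4, 5, "evenly", pattern_id=1)

    def test_scaled_variant_allowed(self):
        spec = fm.TFTopologySpec(3, 3, "evenly")
        starts = spec.region_starts(25)
        assert len(starts) == 3
        assert starts[0] == 1 and starts[-1] == 23


class TestTFConcentration:
    @pytest.mark.parametrize("pct, expected", [(100, 147), (0, 0), (25, 36)])
    def test_floor_rule(self, pct, expected):
        topo = fm.build_uniform_fiber(50, 26)  # 49 runs x 3 = 147 beads
        out = fm.set_tf_concentration(topo, pct, seed=1)
        assert sum(out.tf_bindable) == expected

    def test_nested_monotone_for_fixed_seed(self):
        topo = fm.build_uniform_fiber(50, 26)
        prev = set()
        for pct in (0, 10, 25, 50, 75, 100):
            cur = set(
                np.flatnonzero(
                    np.array(fm.set_tf_concentration(topo, pct, seed=3).tf_bindable)
                ).tolist()
            )
            assert prev <= cur
            prev = cur

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            fm.set_tf_concentration(fm.build_uniform_fiber(5, 44), 120)


class TestLinkerHistones:
    def test_full_density(self):
        out = fm.place_linker_histones(fm.build_uniform_fiber(50, 44), 1.0)
        assert sum(out.lh_occupied) == 50

    def test_floor_rule_random_mode(self):
        out = fm.place_linker_histones(
            fm.build_uniform_fiber(129, 44), 0.8, mode="random", seed=4
        )
        assert sum(out.lh_occupied) == 103  # floor(103.2)

    def test_explicit_positions(self):
        pos = [0, 5, 17, 128]
        out = fm.place_linker_histones(
            fm.build_uniform_fiber(129, 44), 0.37, mode="explicit", positions=pos
        )
        assert sorted(np.flatnonzero(np.array(out.lh_occupied)).tolist()) == pos

    def test_random_mode_seeded(self):
        a = fm.place_linker_histones(fm.build_uniform_fiber(60, 44), 0.5,
                                     mode="random", seed=9)
        b = fm.place_linker_histones(fm.build_uniform_fiber(60, 44), 0.5,
                                     mode="random", seed=9)
        assert a.lh_occupied == b.lh_occupied

    def test_density_out_of_range(self):
        with pytest.raises(ValueError):
            fm.place_linker_histones(fm.build_uniform_fiber(10, 44), 1.5)


class TestAcetylation:
    def test_four_islands(self):
        islands = [(6, 11), (17, 22), (28, 33), (39, 44)]
        out = fm.mark_acetylation(fm.build_uniform_fiber(50, 44), islands)
        assert sum(out.acetylated) == 24

    @pytest.mark.parametrize("islands, expected", [([], 0), ([(1, 50)], 50)])
    def test_degenerate_islands(self, islands, expected):
        out = fm.mark_acetylation(fm.build_uniform_fiber(50, 44), islands)
        assert sum(out.acetylated) == expected

    def test_out_of_range_island(self):
        with pytest.raises(ValueError):
            fm.mark_acetylation(fm.build_uniform_fiber(50, 44), [(45, 55)])


class TestGeneFiber:
    def test_eed_fixture_shape(self):
        from fibermc.fixtures import make_fixture

        topo, tracks = make_fixture("eed_wt")
        assert topo.n_cores == 129
        assert len(topo.nfr_spans) == 7
        assert sum(topo.lh_occupied) == 47  # floor(0.37 * 129)
        assert not any(topo.tf_bindable)
        assert set(tracks) == {"nfr", "lh"}

    def test_tf_track_marks_two_blocks(self):
        from fibermc.fixtures import make_fixture

        topo, _ = make_fixture("eed_tf")
        flags = np.array(topo.tf_bindable, dtype=int)
        # count contiguous marked blocks in the global bead vector
        blocks = np.sum(np.diff(np.concatenate(([0], flags))) == 1)
        assert blocks == 2

    def test_no_nfr_uniform_equivalence(self):
        n = 12
        topo = fm.build_gene_fiber(
            region_bp=n * 189,
            nfr_track=GenomicTrack(),
            nrl_bp=189,
            linker_distribution={42: 1.0},
            seed=0,
            n_cores=n,
        )
        uni = fm.build_uniform_fiber(n, 42)
        assert topo.linker_runs == uni.linker_runs
        assert topo.linker_bp == uni.linker_bp

    def test_overlapping_nfrs_rejected(self):
        track = GenomicTrack(((500, 900, "a"), (800, 1100, "b")))
        with pytest.raises(ValueError):
            fm.build_gene_fiber(5000, track, n_cores=10)

    def test_track_outside_region_rejected(self):
        with pytest.raises(ValueError):
            fm.build_gene_fiber(1000, GenomicTrack(((800, 1300, "x"),)), n_cores=4)


class TestSerialization:
    def test_topology_roundtrip_bitwise(self):
        from fibermc.fixtures import make_fixture

        topo, _ = make_fixture("eed_tf")
        assert fm.FiberTopology.from_json(topo.to_json()) == topo

    def test_bed_roundtrip(self, tmp_path):
        track = GenomicTrack(((10, 50, "a"), (60, 90, "b")), chrom="chr7")
        path = tmp_path / "t.bed"
        track.to_bed(path)
        back = GenomicTrack.from_bed(path)
        assert back.intervals == track.intervals

    def test_unsupported_schema(self):
        with pytest.raises(ValueError):
            fm.FiberTopology.from_json('{"schema": 99}')


def test_bead_accounting_invariant():
    for topo in (
        fm.build_uniform_fiber(10, 26),
        fm.build_lifelike_fiber(30, seed=2),
    ):
        assert topo.n_linker_beads == sum(topo.linker_runs)
        assert len(topo.tf_bindable) == topo.n_linker_beads


def test_beads_for_bp_rounding():
    assert beads_for_bp(26) == 3
    assert beads_for_bp(62) == 7
    assert beads_for_bp(4) == 1  # minimum one bead
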