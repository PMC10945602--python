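"""Energy model: harmonic terms, screened electrostatics, excluded volume,
bookkeeping identities, rigid-body invariance, and brute-force oracle
equivalence on small systems."""

import numpy as np
import pytest

import fibermc as fm
from fibermc.energy import get_system
from fibermc.geometry import rotation_matrix


def neutral(**kw):
    base = dict(
        core_total_charge=0.0,
        linker_bead_charge=0.0,
        tail_bead_charge=0.0,
        lh_bead_charge=0.0,
        excluded_volume_strength=0.0,
    )
    base.update(kw)
    return fm.ForceField(**base)


class TestDnaElastic:
    def test_reference_geometry_is_zero(self):
        topo = fm.build_uniform_fiber(6, 44)
        ff = fm.ForceField()
        cfg = fm.build_zigzag(topo, ff)
        es, eb, et = fm.dna_elastic_energy(cfg, topo, ff)
        assert es == pytest.approx(0.0, abs=1e-18)
        assert eb == pytest.approx(0.0, abs=1e-12)
        assert et == pytest.approx(0.0, abs=1e-18)

    def test_single_bond_stretch_quadratic(self):
        # translate the far core along the exit tangent: only the final bond
        # (last bead -> entry point) stretches, directions are unchanged
        topo = fm.build_uniform_fiber(2, 44)
        ff = fm.ForceField()
        cfg = fm.build_zigzag(topo, ff)
        sys_ = get_system(topo, ff)
        t_out = cfg.core_frames[0] @ sys_.geom.exit_tangent
        delta = 0.37
        cfg.core_pos[1] += delta * t_out
        es, eb, _ = fm.dna_elastic_energy(cfg, topo, ff)
        assert es == pytest.approx(ff.dna_stretch_const * delta**2, rel=1e-9)
        assert eb == pytest.approx(0.0, abs=1e-12)

    def test_bend_quadratic_in_angle(self):
        # rotating the far segment about the last linker bead bends exactly
        # the two joints at that bead's neighbourhood; check leading theta^2
        from fibermc._kernels import chain_elastic

        l0, g, h = 3.0, 9.7, 20.0
        for theta in (0.05, 0.2, 0.5):
            pts = np.array([
                [0.0, 0, 0], [l0, 0, 0],
                [l0 + l0 * np.cos(theta), l0 * np.sin(theta), 0],
            ])
            es, eb = chain_elastic(pts, np.array([1.0, 0, 0]),
                                   np.zeros(3), False, h, l0, g)
            assert es == pytest.approx(0.0, abs=1e-12)
            assert eb == pytest.approx(g * theta**2, rel=1e-9)


class TestTailLh:
    def test_reference_geometry_zero(self):
        topo = fm.place_linker_histones(fm.build_uniform_fiber(4, 44), 1.0)
        ff = fm.ForceField()
        cfg = fm.build_zigzag(topo, ff)
        assert fm.tail_lh_energy(cfg, topo, ff) == pytest.approx((0, 0, 0, 0), abs=1e-12)

    def test_acetylated_distortion_is_100x(self):
        # identical internal distortion: stretch the first bead outward along
        # the chain axis, leaving all angles at their reference
        ff = fm.ForceField()
        wt = fm.build_uniform_fiber(1, 44)
        ac = fm.mark_acetylation(fm.build_uniform_fiber(1, 44), [(1, 1)])
        energies = {}
        for name, topo in (("wt", wt), ("ac", ac)):
            cfg = fm.build_zigzag(topo, ff)
            sys_ = get_system(topo, ff)
            u = cfg.core_frames[0] @ sys_.geom.tail_dir[0]
            cfg.tail_pos[0] += 0.25 * u
            ets, etb, _, _ = fm.tail_lh_energy(cfg, topo, ff)
            energies[name] = ets + etb
        assert energies["ac"] == pytest.approx(100 * energies["wt"], rel=1e-6)

    def test_no_lh_terms_without_lh(self):
        topo = fm.build_uniform_fiber(5, 44)
        ff = fm.ForceField()
        cfg = fm.build_zigzag(topo, ff)
        cfg.linker_pos += 0.1
        _, _, els, elb = fm.tail_lh_energy(cfg, topo, ff)
        assert els == 0.0 and elb == 0.0


class TestElectrostatics:
    def test_screened_pair_closed_form(self):
        # 2 cores, 27 bp linker (3 beads): the only charged pair within a
        # large cutoff is the non-bonded 1-3 bead pair at 6 nm
        topo = fm.build_uniform_fiber(2, 27)
        ff = neutral(linker_bead_charge=-24.0, n_tails_per_core=0, tail_beads=0,
                     nonbond_cutoff=500.0)
        cfg = fm.build_zigzag(topo, ff)
        d = np.linalg.norm(cfg.linker_pos[2] - cfg.linker_pos[0])
        expected = ff.coulomb_prefactor * 576.0 * np.exp(-d / ff.debye_length) / d
        assert fm.electrostatic_energy(cfg, topo, ff) == pytest.approx(expected, rel=1e-6)

    def test_zero_charge_gives_zero(self):
        topo = fm.build_uniform_fiber(3, 44)
        ff = neutral()
        cfg = fm.build_zigzag(topo, ff)
        assert fm.electrostatic_energy(cfg, topo, ff) == 0.0

    def test_bilinearity_in_charge(self):
        topo = fm.build_uniform_fiber(3, 44)
        cfg_args = {}
        vals = {}
        for q in (-12.0, -24.0):
            ff = neutral(linker_bead_charge=q, n_tails_per_core=0, tail_beads=0)
            cfg = cfg_args.setdefault("cfg", fm.build_zigzag(topo, ff))
            vals[q] = fm.electrostatic_energy(cfg, topo, ff)
        assert vals[-24.0] == pytest.approx(4 * vals[-12.0], rel=1e-9)


class TestExcludedVolume:
    def test_fiber_without_overlaps_has_zero_ev(self):
        topo = fm.build_uniform_fiber(2, 27)
        ff = neutral(excluded_volume_strength=0.05, n_tails_per_core=0, tail_beads=0)
        cfg = fm.build_zigzag(topo, ff)
        assert fm.excluded_volume_energy(cfg, topo, ff) == 0.0

    @pytest.mark.parametrize(
        "d, expected",
        [
            (2.5, 0.0),  # beyond contact
            (2.4, 0.0),  # exactly at contact: continuous cutoff
            (1.2, 0.05 * (2.0**12 - 2 * 2.0**6 + 1)),  # half contact
        ],
    )
    def test_pair_form(self, d, expected):
        # isolated pair of linker-sized beads (radius 1.2 nm each)
        from fibermc._kernels import full_nonbond

        pos = np.array([[0.0, 0, 0], [d, 0, 0]])
        ec, ev = full_nonbond(
            pos, np.zeros(2), np.full(2, 1.2), np.array([0, 1], dtype=np.int64),
            np.full((2, 2), -2, dtype=np.int64), 0.415, 0.785, 0.05, 6.0,
        )
        assert ev == pytest.approx(expected, rel=1e-9, abs=1e-12)
        if d < 2.4:
            assert ev > fm.ForceField().kT


class TestTotalEnergy:
    def test_relaxed_neutral_fiber_total_zero(self):
        topo = fm.build_uniform_fiber(5, 44)
        ff = neutral()
        cfg = fm.build_zigzag(topo, ff)
        assert fm.total_energy(cfg, topo, ff).total == pytest.approx(0.0, abs=1e-9)

    def test_total_is_component_sum(self):
        topo = fm.set_tf_concentration(fm.build_uniform_fiber(6, 44), 50, seed=1)
        ff = fm.ForceField()
        cfg = fm.build_zigzag(topo, ff)
        rng = np.random.default_rng(0)
        cfg.linker_pos += rng.normal(0, 0.2, cfg.linker_pos.shape)
        bd = fm.total_energy(cfg, topo, ff)
        assert bd.total == pytest.approx(
            sum(getattr(bd, f) for f in bd.FIELDS), rel=1e-12
        )

    def test_restraint_strictly_increases_total(self):
        topo = fm.set_tf_concentration(fm.build_uniform_fiber(10, 44), 100, seed=1)
        ff = fm.ForceField()
        cfg = fm.build_zigzag(topo, ff)
        base = fm.total_energy(cfg, topo, ff).total
        rs = fm.RestraintSet(fm.RestraintParams(), np.array([[0, 40]]))
        with_r = fm.total_energy(cfg, topo, ff, rs).total
        length = np.linalg.norm(cfg.linker_pos[40] - cfg.linker_pos[0])
        assert length != pytest.approx(13.0)
        assert with_r > base


class TestInvariance:
    def test_breakdown_invariant_under_rigid_transform(self):
        topo = fm.place_linker_histones(
            fm.set_tf_concentration(fm.build_uniform_fiber(6, 44), 50, seed=3), 0.5
        )
        ff = fm.ForceField()
        cfg = fm.build_zigzag(topo, ff)
        rng = np.random.default_rng(1)
        cfg.linker_pos += rng.normal(0, 0.1, cfg.linker_pos.shape)
        rs = fm.update_restraints(cfg, topo, fm.RestraintSet(fm.RestraintParams()))
        bd0 = fm.total_energy(cfg, topo, ff, rs).as_array()
        Q = rotation_matrix(np.array([1.0, 2.0, 3.0]), 0.7)
        moved = cfg.transformed(R=Q, t=np.array([5.0, -3.0, 11.0]))
        bd1 = fm.total_energy(moved, topo, ff, rs).as_array()
        np.testing.assert_allclose(bd1, bd0, rtol=1e-9, atol=1e-9)


def brute_force_nonbond(system, pos):
    """Independent double-loop EC/EV with the same exclusion rules."""
    ff = system.ff
    ec = ev = 0.0
    lam = ff.debye_length
    rc = ff.cutoff
    shift = np.exp(-rc / lam) / rc
    n = len(pos)
    for i in range(n):
        for j in range(i + 1, n):
            gi, gj = system.site_group[i], system.site_group[j]
            if gi == gj:
                continue
            if gj in system.site_excl[i] or gi in system.site_excl[j]:
                continue
            d = np.linalg.norm(pos[i] - pos[j])
            if d > rc or d == 0:
                continue
            qi, qj = system.site_charge[i], system.site_charge[j]
            if qi and qj:
                ec += ff.coulomb_prefactor * qi * qj * (np.exp(-d / lam) / d - shift)
            sig = system.site_radius[i] + system.site_radius[j]
            if sig > 0 and d < sig:
                x = (sig / d) ** 6
                ev += ff.excluded_volume_strength * (x * x - 2 * x + 1)
    return ec, ev


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_nonbonded_matches_double_loop(self, seed):
        # <= 20-bead backbone: 3 cores, short linkers, one LH, a tail pair
        topo = fm.place_linker_histones(fm.build_uniform_fiber(3, 27), 1.0)
        ff = fm.ForceField(n_tails_per_core=2, tail_beads=2)
        cfg = fm.build_zigzag(topo, ff)
        rng = np.random.default_rng(seed)
        cfg.linker_pos += rng.normal(0, 0.5, cfg.linker_pos.shape)
        cfg.tail_pos += rng.normal(0, 0.5, cfg.tail_pos.shape)
        cfg.lh_pos += rng.normal(0, 0.5, cfg.lh_pos.shape)
        sys_ = get_system(topo, ff)
        pos = sys_.site_positions(cfg)
        ec_ref, ev_ref = brute_force_nonbond(sys_, pos)
        ec, ev = sys_.nonbonded(cfg)
        assert ec == pytest.approx(ec_ref, rel=1e-9, abs=1e-12)
        assert ev == pytest.approx(ev_ref, rel=1e-9, abs=1e-12)
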