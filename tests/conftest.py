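"""Shared fixtures.

The session-scoped simulation ensembles are the scaled-down study
conditions used by the slower ensemble-level tests: a 25-nucleosome,
44 bp-linker fiber with three TF-binding regions of three nucleosomes
(30 of 120 linker beads bindable, i.e. an effective 25% concentration),
its 0% counterpart, and a short-linker (26 bp) fiber scanned with and
without full linker-histone occupancy. They are computed once and shared.
"""

from __future__ import annotations

import numpy as np
import pytest

import fibermc as fm

SCALED_N_CORES = 25
SCALED_LINKER_BP = 44
SCALED_STEPS = 500_000
SCALED_SAVE = 50_000
SCALED_REPLICAS = 4
SCALED_TAIL = 250_000


@pytest.fixture(scope="session")
def ff():
    return fm.ForceField()


@pytest.fixture(scope="session")
def neutral_ff():
    """Force field with all nonbonded interactions off (mechanics only)."""
    return fm.ForceField(
        core_total_charge=0.0,
        linker_bead_charge=0.0,
        tail_bead_charge=0.0,
        lh_bead_charge=0.0,
        excluded_volume_strength=0.0,
    )


@pytest.fixture(scope="session")
def marked_regions():
    spec = fm.TFTopologySpec(3, 3, "evenly")
    starts = spec.region_starts(SCALED_N_CORES)
    return [list(range(a - 1, a - 1 + 3)) for a in starts]


@pytest.fixture(scope="session")
def pattern_topology():
    topo = fm.build_uniform_fiber(SCALED_N_CORES, SCALED_LINKER_BP)
    return fm.apply_tf_topology(topo, fm.TFTopologySpec(3, 3, "evenly"))


@pytest.fixture(scope="session")
def pattern_ensemble(pattern_topology, ff):
    """Four replicas of the TF-marked scaled fiber (the 25% arm)."""
    plan = fm.ReplicaPlan.from_base_seed(
        SCALED_REPLICAS, SCALED_STEPS, SCALED_SAVE, base_seed=101
    )
    return fm.run_ensemble(pattern_topology, ff, fm.RestraintParams(), plan)


@pytest.fixture(scope="session")
def zero_tf_ensemble(ff):
    """Four replicas of the same fiber with no TF-bindable beads."""
    topo = fm.build_uniform_fiber(SCALED_N_CORES, SCALED_LINKER_BP)
    topo = fm.set_tf_concentration(topo, 0, seed=11)
    plan = fm.ReplicaPlan.from_base_seed(
        SCALED_REPLICAS, SCALED_STEPS, SCALED_SAVE, base_seed=101
    )
    return fm.run_ensemble(topo, ff, fm.RestraintParams(), plan)


@pytest.fixture(scope="session")
def pattern_maps(pattern_ensemble, pattern_topology, ff):
    k = SCALED_TAIL // SCALED_SAVE
    return [
        fm.contact_map(t.frames[-k:], pattern_topology, ff)
        for t in pattern_ensemble
    ]


@pytest.fixture(scope="session")
def lh_engagement_rates(ff):
    """Realized TF engagement on a 26 bp fiber without and with full LH."""
    rates = {}
    plan = fm.ReplicaPlan.from_base_seed(3, 200_000, 20_000, base_seed=301)
    for rho in (0.0, 1.0):
        topo = fm.build_uniform_fiber(20, 26)
        topo = fm.set_tf_concentration(topo, 50, seed=21)
        if rho > 0:
            topo = fm.place_linker_histones(topo, rho, mode="uniform")
        trajs = fm.run_ensemble(topo, ff, fm.RestraintParams(), plan)
        rates[rho] = fm.effective_tf_concentration(trajs)
    return rates


def make_stub_trajectory(n_frames: int, save_every: int = 100_000,
                         seed: int = 1, n_bindable: int = 10,
                         engaged_pairs: int = 0) -> fm.Trajectory:
    """A lightweight trajectory for bookkeeping-level tests."""
    topo = fm.build_uniform_fiber(3, 45)  # 2 runs x 5 = 10 linker beads
    flags = [True] * min(n_bindable, topo.n_linker_beads) + [False] * max(
        0, topo.n_linker_beads - n_bindable
    )
    import dataclasses

    topo = dataclasses.replace(topo, tf_bindable=tuple(flags))
    ff = fm.ForceField(n_tails_per_core=0, tail_beads=0)
    cfg = fm.build_zigzag(topo, ff)
    pairs = np.array(
        [(2 * i, 2 * i + 1) for i in range(engaged_pairs)], dtype=np.int64
    ).reshape(-1, 2)
    frames = [
        fm.Frame(
            step=(k + 1) * save_every,
            config=cfg,
            restraint_pairs=pairs,
            energy=fm.EnergyBreakdown(),
        )
        for k in range(n_frames)
    ]
    return fm.Trajectory(
        topology=topo,
        ff=ff,
        restraint_params=fm.RestraintParams(min_bead_separation=1),
        frames=frames,
        seed=seed,
        twist_offset=0.0,
        n_steps=n_frames * save_every,
        save_every=save_every,
    )
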