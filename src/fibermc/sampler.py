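"""Metropolis Monte Carlo sampling of chromatin fibers.

One replica runs a fixed number of trial moves over a fiber, maintaining the
dynamically engaged TF restraint set, and saves frames at a fixed stride.
Replicas differ by their random seed and a replica-wide DNA twist offset of
0, +12 or -12 degrees applied to the start structure (mimicking natural
twist variation). Acceptance uses the full energy change for spatial moves
and the Rosenbluth weight ratio for tail regrowth.

Energy changes are evaluated incrementally (affected bonded terms plus a
moved-versus-static nonbonded cross sum); saved frames recompute the full
breakdown from scratch, so no accumulation drift is possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .energy import EnergyBreakdown, System, get_system
from .forcefield import KB_KCAL, ForceField
from .geometry import Configuration, build_zigzag, rotation_matrix
from .moves import (
    MoveSet,
    _node_at,
    _regrow_inplace,
    apply_pivot,
    pivot_ranges,
    pivot_side,
    random_displacement,
)
from .restraints import RestraintParams, RestraintSet, tf_restraint_energy, update_restraints
from .topology import FiberTopology

__all__ = [
    "metropolis_accept",
    "ReplicaPlan",
    "Frame",
    "Trajectory",
    "run_replica",
    "run_ensemble",
]

TWIST_OFFSETS = (0.0, 12.0, -12.0)


def metropolis_accept(delta_E: float, temperature: float, rng_draw: float) -> bool:
    """Accept iff rng_draw < min(1, exp(-dE/kBT))."""
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if delta_E <= 0:
        return True
    return rng_draw < np.exp(-delta_E / (KB_KCAL * temperature))


@dataclass(frozen=True)
class ReplicaPlan:
    """Replica schedule: seeds, twist offsets, step counts and frame stride."""

    n_replicas: int
    n_steps: int
    save_every: int = 100_000
    seeds: tuple[int, ...] = ()
    twist_offsets: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if self.n_steps % self.save_every != 0:
            raise ValueError("n_steps must be a multiple of save_every")
        seeds = self.seeds or tuple(range(1, self.n_replicas + 1))
        offsets = self.twist_offsets or tuple(
            TWIST_OFFSETS[i % 3] for i in range(self.n_replicas)
        )
        if len(seeds) != self.n_replicas or len(offsets) != self.n_replicas:
            raise ValueError("seeds and twist_offsets must match n_replicas")
        if len(set(seeds)) != len(seeds):
            raise ValueError("replica seeds must be distinct")
        object.__setattr__(self, "seeds", tuple(int(s) for s in seeds))
        object.__setattr__(self, "twist_offsets", tuple(float(t) for t in offsets))

    @classmethod
    def from_base_seed(
        cls, n_replicas: int, n_steps: int, save_every: int = 100_000, base_seed: int = 1
    ) -> "ReplicaPlan":
        return cls(
            n_replicas,
            n_steps,
            save_every,
            tuple(base_seed + i for i in range(n_replicas)),
        )


@dataclass
class Frame:
    """One saved state: configuration, engaged restraints, energy breakdown."""

    step: int
    config: Configuration
    restraint_pairs: np.ndarray
    energy: EnergyBreakdown


@dataclass
class Trajectory:
    """Saved frames of one replica plus its metadata."""

    topology: FiberTopology
    ff: ForceField
    restraint_params: RestraintParams
    frames: list[Frame]
    seed: int
    twist_offset: float
    n_steps: int
    save_every: int
    acceptance: dict[str, tuple[int, int]] = field(default_factory=dict)
    initial: Configuration | None = None
    events: list[tuple[int, str, int, int, float]] = field(default_factory=list)

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def acceptance_rates(self) -> dict[str, float]:
        return {
            k: (a / n if n else float("nan")) for k, (a, n) in self.acceptance.items()
        }


class _Engine:
    """Incremental-energy MC engine for one replica."""

    def __init__(
        self,
        system: System,
        config: Configuration,
        restraint_params: RestraintParams,
        moves: MoveSet,
        rng: np.random.Generator,
    ):
        self.sys = system
        self.ff = system.ff
        self.cfg = config
        self.moves = moves
        self.rng = rng
        self.site_pos = system.site_positions(config)
        self.site_new = self.site_pos.copy()
        self.restraints = RestraintSet(restraint_params)
        self.events: list[tuple[int, str, int, int, float]] = []
        self.stats: dict[str, list[int]] = {
            k: [0, 0] for k in ("pivot", "translate", "rotate", "lh", "tail")
        }
        probs = moves.kind_probabilities(system)
        self.kinds = list(probs)
        self.cum = np.cumsum([probs[k] for k in self.kinds])
        self.beta = 1.0 / self.ff.kT
        self._nb_args = (
            system.site_charge,
            system.site_radius,
            system.site_group,
            system.site_excl,
        )
        self._nb_params = (
            self.ff.coulomb_prefactor,
            self.ff.debye_length,
            self.ff.excluded_volume_strength,
            self.ff.cutoff,
        )

    # -- helpers ------------------------------------------------------------

    def _complement(self, ranges: list[tuple[int, int]]) -> np.ndarray:
        out = []
        prev = 0
        for lo, hi in ranges:
            if lo > prev:
                out.append((prev, lo))
            prev = max(prev, hi)
        if prev < self.sys.n_sites:
            out.append((prev, self.sys.n_sites))
        return np.array(out or [(0, 0)], dtype=np.int64)

    def _nb_delta(self, moved: list[tuple[int, int]]) -> float:
        moved_arr = np.array([r for r in moved if r[1] > r[0]] or [(0, 0)], dtype=np.int64)
        static = self._complement(sorted(moved))
        dec, dev = _kernels.cross_nonbond_delta(
            self.site_pos, self.site_new, *self._nb_args, moved_arr, static,
            *self._nb_params,
        )
        return float(dec + dev)

    def _commit(self, moved: list[tuple[int, int]]) -> None:
        for lo, hi in moved:
            self.site_pos[lo:hi] = self.site_new[lo:hi]

    def _revert_sites(self, moved: list[tuple[int, int]]) -> None:
        for lo, hi in moved:
            self.site_new[lo:hi] = self.site_pos[lo:hi]

    def _accept(self, dE: float) -> bool:
        if dE <= 0:
            return True
        return self.rng.random() < np.exp(-self.beta * dE)

    def _update_restraints(self, step: int) -> None:
        old = {tuple(p) for p in self.restraints.pairs}
        self.restraints = update_restraints(
            self.cfg, self.sys.topology, self.restraints, self.restraints.params
        )
        new = {tuple(p) for p in self.restraints.pairs}
        for i, j in new - old:
            d = float(np.linalg.norm(self.cfg.linker_pos[j] - self.cfg.linker_pos[i]))
            self.events.append((step, "engage", int(i), int(j), d))
        for i, j in old - new:
            d = float(np.linalg.norm(self.cfg.linker_pos[j] - self.cfg.linker_pos[i]))
            self.events.append((step, "release", int(i), int(j), d))

    def _bindable_split(self, b0: int, b1: int) -> bool:
        """True if the moved bead range separates bindable beads."""
        bind = self.sys.bindable
        if len(bind) < 2:
            return False
        inside = int(np.searchsorted(bind, b1) - np.searchsorted(bind, b0))
        return 0 < inside < len(bind)

    # -- move attempts ------------------------------------------------------

    def try_pivot(self) -> tuple[bool, bool]:
        sys_, cfg, topo = self.sys, self.cfg, self.sys.topology
        fiber_idx = int(self.rng.integers(topo.n_cores + topo.n_linker_beads))
        node_kind, node_index = _node_at(topo, fiber_idx)
        side = pivot_side(topo, node_kind, node_index)
        (c0, c1), (b0, b1) = pivot_ranges(topo, node_kind, node_index, side)
        if c1 <= c0 and b1 <= b0:
            return False, False  # nothing to rotate (end node)
        if node_kind == "core":
            run = node_index if side == "after" else node_index - 1
        else:
            run = topo.run_of_bead(node_index)
        axis = self.rng.normal(size=3)
        angle = np.deg2rad(self.rng.uniform(-self.moves.pivot_max_deg, self.moves.pivot_max_deg))

        old_es, old_eb = sys_.run_elastic(cfg, run)
        old_tf = tf_restraint_energy(self.restraints, cfg)
        # save state for revert
        saved = (
            cfg.core_pos[c0:c1].copy(),
            cfg.core_frames[c0:c1].copy(),
            cfg.linker_pos[b0:b1].copy(),
        )
        per_t = cfg.tail_pos.shape[0] // topo.n_cores if cfg.tail_pos.size else 0
        t0, t1 = c0 * per_t, c1 * per_t
        saved_t = cfg.tail_pos[t0:t1].copy() if per_t else None
        lh0 = lh1 = 0
        saved_lh = None
        if cfg.lh_pos.size:
            s0 = int(np.searchsorted(sys_.lh_cores, c0))
            s1 = int(np.searchsorted(sys_.lh_cores, c1))
            lh0, lh1 = s0 * self.ff.lh_beads, s1 * self.ff.lh_beads
            saved_lh = cfg.lh_pos[lh0:lh1].copy()

        apply_pivot(cfg, topo, node_kind, node_index, side, axis, angle)

        csp = sys_.core_sites_per
        moved = [
            (c0 * csp, c1 * csp),
            (sys_.linker_site_start + b0, sys_.linker_site_start + b1),
            (sys_.tail_site_start + t0, sys_.tail_site_start + t1),
            (sys_.lh_site_start + lh0, sys_.lh_site_start + lh1),
        ]
        Q = rotation_matrix(axis, angle)
        pivot_pt = (
            cfg.core_pos[node_index] if node_kind == "core" else cfg.linker_pos[node_index]
        )
        for lo, hi in moved:
            if hi > lo:
                self.site_new[lo:hi] = (self.site_pos[lo:hi] - pivot_pt) @ Q.T + pivot_pt

        new_es, new_eb = sys_.run_elastic(cfg, run)
        new_tf = tf_restraint_energy(self.restraints, cfg)
        dE = (new_es + new_eb - old_es - old_eb) + (new_tf - old_tf) + self._nb_delta(moved)

        if self._accept(dE):
            self._commit(moved)
            return True, self._bindable_split(b0, b1)
        cfg.core_pos[c0:c1], cfg.core_frames[c0:c1] = saved[0], saved[1]
        cfg.linker_pos[b0:b1] = saved[2]
        if saved_t is not None:
            cfg.tail_pos[t0:t1] = saved_t
        if saved_lh is not None:
            cfg.lh_pos[lh0:lh1] = saved_lh
        self._revert_sites(moved)
        return False, False

    def try_linker(self, bead: int) -> tuple[bool, bool]:
        sys_, cfg = self.sys, self.cfg
        run = sys_.topology.run_of_bead(bead)
        old_es, old_eb = sys_.run_elastic(cfg, run)
        engaged = bead in self.restraints.pairs
        old_tf = tf_restraint_energy(self.restraints, cfg) if engaged else 0.0
        dv = random_displacement(self.moves.translate_nm, self.rng)
        s = sys_.linker_site(bead)
        saved = cfg.linker_pos[bead].copy()
        cfg.linker_pos[bead] += dv
        self.site_new[s] = cfg.linker_pos[bead]
        moved = [(s, s + 1)]
        new_es, new_eb = sys_.run_elastic(cfg, run)
        new_tf = tf_restraint_energy(self.restraints, cfg) if engaged else 0.0
        dE = (new_es + new_eb - old_es - old_eb) + (new_tf - old_tf) + self._nb_delta(moved)
        if self._accept(dE):
            self._commit(moved)
            bind = self.sys.bindable
            i = int(np.searchsorted(bind, bead))
            return True, bool(len(bind) > 1 and i < len(bind) and bind[i] == bead)
        cfg.linker_pos[bead] = saved
        self._revert_sites(moved)
        return False, False

    def try_core(self, core: int, rotate: bool) -> bool:
        sys_, cfg, topo = self.sys, self.cfg, self.sys.topology
        runs = [r for r in (core - 1, core) if 0 <= r < topo.n_cores - 1]
        old = sum(sum(sys_.run_elastic(cfg, r)) for r in runs)
        old += sum(sys_.tail_elastic(cfg, core)) + sum(sys_.lh_elastic(cfg, core))
        saved_pos = cfg.core_pos[core].copy()
        saved_frame = cfg.core_frames[core].copy()
        if rotate:
            Q = rotation_matrix(
                self.rng.normal(size=3),
                np.deg2rad(self.rng.uniform(-self.moves.rotate_max_deg, self.moves.rotate_max_deg)),
            )
            cfg.core_frames[core] = Q @ cfg.core_frames[core]
        else:
            cfg.core_pos[core] += random_displacement(self.moves.translate_nm, self.rng)
        lo, hi = sys_.core_site_range(core)
        self.site_new[lo] = cfg.core_pos[core]
        if hi > lo + 1:
            self.site_new[lo + 1 : hi] = (
                cfg.core_pos[core] + sys_.geom.charge_sites @ cfg.core_frames[core].T
            )
        moved = [(lo, hi)]
        new = sum(sum(sys_.run_elastic(cfg, r)) for r in runs)
        new += sum(sys_.tail_elastic(cfg, core)) + sum(sys_.lh_elastic(cfg, core))
        dE = (new - old) + self._nb_delta(moved)
        if self._accept(dE):
            self._commit(moved)
            return True
        cfg.core_pos[core] = saved_pos
        cfg.core_frames[core] = saved_frame
        self._revert_sites(moved)
        return False

    def try_lh(self, lh_bead: int) -> bool:
        sys_, cfg = self.sys, self.cfg
        core = int(sys_.lh_cores[lh_bead // self.ff.lh_beads])
        old = sum(sys_.lh_elastic(cfg, core))
        saved = cfg.lh_pos[lh_bead].copy()
        cfg.lh_pos[lh_bead] += random_displacement(self.moves.lh_translate_nm, self.rng)
        s = sys_.lh_site_start + lh_bead
        self.site_new[s] = cfg.lh_pos[lh_bead]
        moved = [(s, s + 1)]
        new = sum(sys_.lh_elastic(cfg, core))
        dE = (new - old) + self._nb_delta(moved)
        if self._accept(dE):
            self._commit(moved)
            return True
        cfg.lh_pos[lh_bead] = saved
        self._revert_sites(moved)
        return False

    def try_tail(self, chain: int) -> bool:
        sys_, cfg = self.sys, self.cfg
        lo, hi = sys_.tail_chain_sites(chain)
        saved = cfg.tail_pos[
            chain * self.ff.tail_beads : (chain + 1) * self.ff.tail_beads
        ].copy()
        ratio = _regrow_inplace(sys_, cfg, self.site_pos, chain, self.moves.trial_count, self.rng)
        if np.isfinite(ratio) and self.rng.random() < ratio:
            beads = cfg.tail_pos[
                chain * self.ff.tail_beads : (chain + 1) * self.ff.tail_beads
            ]
            self.site_pos[lo:hi] = beads
            self.site_new[lo:hi] = beads
            return True
        cfg.tail_pos[
            chain * self.ff.tail_beads : (chain + 1) * self.ff.tail_beads
        ] = saved
        return False

    # -- one MC step --------------------------------------------------------

    def step(self, step_no: int) -> None:
        sys_ = self.sys
        u = self.rng.random()
        kind = self.kinds[int(np.searchsorted(self.cum, u, side="right"))]
        accepted = False
        need_update = False
        if kind == "pivot":
            accepted, need_update = self.try_pivot()
        elif kind == "translate":
            idx = int(self.rng.integers(sys_.n_linker + sys_.n_cores))
            if idx < sys_.n_linker:
                accepted, need_update = self.try_linker(idx)
            else:
                accepted = self.try_core(idx - sys_.n_linker, rotate=False)
        elif kind == "rotate":
            accepted = self.try_core(int(self.rng.integers(sys_.n_cores)), rotate=True)
        elif kind == "lh":
            accepted = self.try_lh(int(self.rng.integers(sys_.n_lh_beads)))
        elif kind == "tail":
            accepted = self.try_tail(int(self.rng.integers(sys_.n_tail_chains)))
        self.stats[kind][1] += 1
        if accepted:
            self.stats[kind][0] += 1
        if (need_update and len(sys_.bindable) >= 2) or (
            step_no % 1000 == 0 and len(sys_.bindable) >= 2
        ):
            self._update_restraints(step_no)


def run_replica(
    topology: FiberTopology,
    ff: ForceField,
    restraint_params: RestraintParams | None = None,
    *,
    n_steps: int,
    save_every: int = 100_000,
    seed: int = 1,
    twist_offset: float = 0.0,
    initial: Configuration | None = None,
    moves: MoveSet | None = None,
) -> Trajectory:
    """Run one MC replica and return its trajectory.

    Bitwise reproducible for a fixed seed. Frames are saved every
    ``save_every`` steps; the start structure is stored as metadata, not
    counted as a frame. Aborts with a diagnostic on non-finite energies.
    """
    if n_steps % save_every != 0:
        raise ValueError("n_steps must be a multiple of save_every")
    restraint_params = restraint_params or RestraintParams()
    moves = moves or MoveSet()
    system = get_system(topology, ff)
    rng = np.random.default_rng(seed)
    config = (initial.copy() if initial is not None else build_zigzag(topology, ff, twist_offset))
    engine = _Engine(system, config, restraint_params, moves, rng)
    if len(system.bindable) >= 2:
        engine._update_restraints(0)

    frames: list[Frame] = []
    initial_copy = config.copy()
    for step in range(1, n_steps + 1):
        engine.step(step)
        if step % save_every == 0:
            bd = system.breakdown(engine.cfg, engine.restraints)
            if not np.isfinite(bd.total):
                raise RuntimeError(
                    f"non-finite energy at step {step}: {bd}"
                )
            frames.append(
                Frame(step, engine.cfg.copy(), engine.restraints.pairs.copy(), bd)
            )
    return Trajectory(
        topology=topology,
        ff=ff,
        restraint_params=restraint_params,
        frames=frames,
        seed=seed,
        twist_offset=twist_offset,
        n_steps=n_steps,
        save_every=save_every,
        acceptance={k: (v[0], v[1]) for k, v in engine.stats.items()},
        initial=initial_copy,
        events=engine.events,
    )


def run_ensemble(
    topology: FiberTopology,
    ff: ForceField,
    restraint_params: RestraintParams | None = None,
    plan: ReplicaPlan | None = None,
    *,
    initial: Configuration | None = None,
    moves: MoveSet | None = None,
) -> list[Trajectory]:
    """Run independent replicas per the plan (seeds + twist-offset cycle)."""
    if plan is None:
        raise ValueError("a ReplicaPlan is required")
    return [
        run_replica(
            topology,
            ff,
            restraint_params,
            n_steps=plan.n_steps,
            save_every=plan.save_every,
            seed=plan.seeds[r],
            twist_offset=plan.twist_offsets[r],
            initial=initial,
            moves=moves,
        )
        for r in range(plan.n_replicas)
    ]
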