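"""Monte Carlo trial moves.

Move set: a global pivot (the shorter fiber end beyond a random backbone
node is rigidly rotated about a random axis through that node), local
translations of DNA and LH beads, local translation/rotation of cores,
configurational-bias (Rosenbluth) regrowth of tail chains, and a tail-state
swap between the extended and folded reference geometries.

The pure functions here return proposed configurations and are also the
geometric helpers the sampler's incremental engine reuses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .energy import System, get_system
from .forcefield import ForceField
from .geometry import Configuration, rotation_matrix
from .topology import FiberTopology

__all__ = [
    "MoveSet",
    "global_pivot",
    "local_move",
    "tail_regrowth",
    "swap_tail_state",
    "pivot_side",
    "apply_pivot",
]


@dataclass(frozen=True)
class MoveSet:
    """Move-kind weights and amplitudes.

    ``pivot_weight`` is the probability of a global pivot; the remainder is
    split among local translation (DNA beads + cores), core rotation, LH
    translation and tail regrowth in proportion to their element counts.
    """

    pivot_weight: float = 0.2
    pivot_max_deg: float = 20.0
    translate_nm: float = 0.5
    rotate_max_deg: float = 10.0
    lh_translate_nm: float = 0.5
    trial_count: int = 8  # Rosenbluth trial directions per regrown bead

    def __post_init__(self) -> None:
        if not (0 <= self.pivot_weight < 1):
            raise ValueError("pivot_weight must be in [0, 1)")
        for name in ("pivot_max_deg", "translate_nm", "rotate_max_deg", "lh_translate_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.trial_count < 1:
            raise ValueError("trial_count must be >= 1")

    def kind_probabilities(self, system: System) -> dict[str, float]:
        """Normalized move-kind probabilities for a concrete system."""
        counts = {
            "translate": system.n_linker + system.n_cores,
            "rotate": system.n_cores,
            "lh": system.n_lh_beads,
            "tail": system.n_tail_chains if system.ff.tail_beads else 0,
        }
        total = sum(counts.values())
        rest = 1.0 - self.pivot_weight if system.n_cores > 1 else 1.0
        probs = {"pivot": self.pivot_weight if system.n_cores > 1 else 0.0}
        for k, c in counts.items():
            probs[k] = rest * c / total if total else 0.0
        return probs


# -- pivot ------------------------------------------------------------------


def pivot_side(topology: FiberTopology, node_kind: str, node_index: int) -> str:
    """Which side of a backbone node is shorter ('before' or 'after').

    Backbone nodes are cores and linker beads in fiber order; ties go to
    'after'.
    """
    offsets = topology.run_offsets
    if node_kind == "core":
        fiber_idx = node_index + int(offsets[node_index])
    else:
        run = topology.run_of_bead(node_index)
        fiber_idx = (run + 1) + node_index
    n_nodes = topology.n_cores + topology.n_linker_beads
    before, after = fiber_idx, n_nodes - fiber_idx - 1
    return "before" if before < after else "after"


def pivot_ranges(
    topology: FiberTopology, node_kind: str, node_index: int, side: str
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Half-open (core, linker-bead) index ranges of the rotated segment."""
    nc, nl = topology.n_cores, topology.n_linker_beads
    offsets = topology.run_offsets
    if node_kind == "core":
        c = node_index
        if side == "after":
            return (c + 1, nc), (int(offsets[c]), nl)
        return (0, c), (0, int(offsets[c]))
    b = node_index
    run = topology.run_of_bead(b)
    if side == "after":
        return (run + 1, nc), (b + 1, nl)
    return (0, run + 1), (0, b)


def apply_pivot(
    config: Configuration,
    topology: FiberTopology,
    node_kind: str,
    node_index: int,
    side: str,
    axis: np.ndarray,
    angle: float,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Rotate the chosen segment in place; returns the rotated index ranges."""
    Q = rotation_matrix(axis, angle)
    pivot = (
        config.core_pos[node_index]
        if node_kind == "core"
        else config.linker_pos[node_index]
    ).copy()
    (c0, c1), (b0, b1) = pivot_ranges(topology, node_kind, node_index, side)
    nc = topology.n_cores
    if c1 > c0:
        config.core_pos[c0:c1] = (config.core_pos[c0:c1] - pivot) @ Q.T + pivot
        config.core_frames[c0:c1] = np.einsum("ab,ibc->iac", Q, config.core_frames[c0:c1])
    if b1 > b0:
        config.linker_pos[b0:b1] = (config.linker_pos[b0:b1] - pivot) @ Q.T + pivot
    if config.tail_pos.size:
        per = config.tail_pos.shape[0] // nc
        t0, t1 = c0 * per, c1 * per
        if t1 > t0:
            config.tail_pos[t0:t1] = (config.tail_pos[t0:t1] - pivot) @ Q.T + pivot
    if config.lh_pos.size:
        lh_cores = [i for i in range(nc) if topology.lh_occupied[i]]
        per = config.lh_pos.shape[0] // len(lh_cores)
        s0 = int(np.searchsorted(lh_cores, c0))
        s1 = int(np.searchsorted(lh_cores, c1))
        if s1 > s0:
            sl = slice(s0 * per, s1 * per)
            config.lh_pos[sl] = (config.lh_pos[sl] - pivot) @ Q.T + pivot
    return (c0, c1), (b0, b1)


def global_pivot(
    config: Configuration,
    topology: FiberTopology,
    amplitude_deg: float,
    rng: np.random.Generator,
) -> Configuration:
    """Propose a pivot of the shorter fiber end about a random axis."""
    if topology.n_cores < 2:
        raise ValueError("pivot requires a fiber with >= 2 cores")
    n_nodes = topology.n_cores + topology.n_linker_beads
    fiber_idx = int(rng.integers(n_nodes))
    node_kind, node_index = _node_at(topology, fiber_idx)
    side = pivot_side(topology, node_kind, node_index)
    axis = rng.normal(size=3)
    angle = np.deg2rad(rng.uniform(-amplitude_deg, amplitude_deg))
    out = config.copy()
    apply_pivot(out, topology, node_kind, node_index, side, axis, angle)
    return out


def _node_at(topology: FiberTopology, fiber_idx: int) -> tuple[str, int]:
    """Backbone node (kind, element index) at a fiber-order position."""
    offsets = topology.run_offsets
    for c in range(topology.n_cores):
        core_pos = c + int(offsets[c])
        if fiber_idx == core_pos:
            return "core", c
        if fiber_idx < core_pos:
            # inside run c-1: beads offsets[c-1] .. offsets[c]-1
            bead = fiber_idx - c  # subtract cores before this position
            return "linker", bead
    return "linker", fiber_idx - topology.n_cores


# -- local moves ------------------------------------------------------------


def random_displacement(amplitude: float, rng: np.random.Generator) -> np.ndarray:
    """Random direction scaled by U(0, amplitude): norm <= amplitude."""
    v = rng.normal(size=3)
    v /= np.linalg.norm(v)
    return v * rng.uniform(0.0, amplitude)


def local_move(
    config: Configuration,
    target: tuple[str, int],
    amplitude: float,
    rng: np.random.Generator,
    rotate: bool = False,
) -> Configuration:
    """Propose a bounded single-element translation (or core rotation).

    ``target`` is ('linker'|'core'|'lh', index). Core rotations spin the
    orientation triad about a random axis through the core center, keeping
    it orthonormal.
    """
    kind, idx = target
    out = config.copy()
    if kind == "core" and rotate:
        Q = rotation_matrix(rng.normal(size=3), np.deg2rad(rng.uniform(-amplitude, amplitude)))
        out.core_frames[idx] = Q @ out.core_frames[idx]
        return out
    dv = random_displacement(amplitude, rng) if amplitude > 0 else np.zeros(3)
    if kind == "linker":
        out.linker_pos[idx] += dv
    elif kind == "core":
        out.core_pos[idx] += dv
    elif kind == "lh":
        out.lh_pos[idx] += dv
    else:
        raise ValueError(f"unknown move target kind {kind!r}")
    return out


# -- tail regrowth (configurational-bias / Rosenbluth) ----------------------


def _chain_geometry(system: System, config: Configuration, chain: int):
    """(anchor, outward dir, bead slice, current bond lengths) of a tail chain."""
    ff, geom = system.ff, system.geom
    core = chain // ff.n_tails_per_core
    t = chain % ff.n_tails_per_core
    R, c = config.core_frames[core], config.core_pos[core]
    a = c + R @ geom.tail_attach[t]
    u = R @ geom.tail_dir[t]
    lo = chain * ff.tail_beads
    beads = config.tail_pos[lo : lo + ff.tail_beads]
    pts = np.vstack([a, beads])
    bonds = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return core, a, u, lo, beads, bonds


def tail_regrowth(
    config: Configuration,
    topology: FiberTopology,
    ff: ForceField,
    tail_id: int,
    trial_count: int,
    rng: np.random.Generator,
) -> tuple[Configuration, float]:
    """Rebuild one tail bead-by-bead with Rosenbluth-weighted trials.

    Returns the proposed configuration and the new/old Rosenbluth weight
    ratio for the acceptance rule. Bead count and bond lengths are
    preserved; trial directions are uniform on the sphere, weighted by the
    Boltzmann factor of the bend + nonbonded energy.
    """
    system = get_system(topology, ff)
    site_pos = system.site_positions(config)
    out = config.copy()
    ratio = _regrow_inplace(system, out, site_pos, tail_id, trial_count, rng)
    return out, ratio


def _regrow_inplace(
    system: System,
    config: Configuration,
    site_pos: np.ndarray,
    chain: int,
    trial_count: int,
    rng: np.random.Generator,
) -> float:
    """Regrow ``chain`` in place; returns W_new / W_old."""
    ff = system.ff
    core, a, u, lo, beads, bonds = _chain_geometry(system, config, chain)
    acet = bool(system.topology.acetylated[core])
    kb_eff = ff.tail_bend_const * (ff.acetyl_stiffness_multiplier if acet else 1.0)
    beta = 1.0 / ff.kT
    chain_sites = system.tail_chain_sites(chain)
    s0 = chain_sites[0]

    def bead_meta(j: int) -> tuple:
        s = s0 + j
        return (
            float(system.site_charge[s]),
            float(system.site_radius[s]),
            int(system.site_group[s]),
            int(system.site_excl[s, 0]),
            int(system.site_excl[s, 1]),
        )

    nb_params = (
        ff.coulomb_prefactor,
        ff.debye_length,
        ff.excluded_volume_strength,
        ff.cutoff,
    )
    site_meta = (
        system.site_charge,
        system.site_radius,
        system.site_group,
        system.site_excl,
    )

    def sphere(n: int) -> np.ndarray:
        v = rng.normal(size=(n, 3))
        return v / np.linalg.norm(v, axis=1, keepdims=True)

    def weights(j, trials, prev_pt, prev_dir, grown, n_grown):
        # n_grown counts already-placed beads of this chain; the kernel skips
        # the bonded predecessor (it is an excluded pair)
        q, r, g, e0, e1 = bead_meta(j)
        out = np.empty(len(trials))
        _kernels.tail_trial_weights(
            site_pos, *site_meta, chain_sites[0], chain_sites[1],
            trials, prev_pt, prev_dir, grown, n_grown,
            q, r, g, e0, e1, kb_eff, *nb_params, beta, out,
        )
        return out

    tb = ff.tail_beads
    grown = np.empty((tb, 3))

    # retrace the old chain: first trial is the existing bead
    w_old = 1.0
    prev_pt, prev_dir = a, u
    for j in range(tb):
        trials = np.empty((trial_count, 3))
        trials[0] = beads[j]
        if trial_count > 1:
            trials[1:] = prev_pt + bonds[j] * sphere(trial_count - 1)
        ws = weights(j, trials, prev_pt, prev_dir, grown, j)
        w_old *= float(ws.sum())
        grown[j] = beads[j]
        prev_dir = beads[j] - prev_pt
        prev_pt = beads[j]

    # grow the new chain
    w_new = 1.0
    prev_pt, prev_dir = a, u
    new_beads = np.empty_like(beads)
    for j in range(tb):
        trials = prev_pt + bonds[j] * sphere(trial_count)
        ws = weights(j, trials, prev_pt, prev_dir, grown, j)
        tot = float(ws.sum())
        w_new *= tot
        if tot <= 0 or not np.isfinite(tot):
            return 0.0
        pick = int(np.searchsorted(np.cumsum(ws), rng.random() * tot, side="right"))
        pick = min(pick, trial_count - 1)
        new_beads[j] = trials[pick]
        grown[j] = trials[pick]
        prev_dir = new_beads[j] - prev_pt
        prev_pt = new_beads[j]

    config.tail_pos[lo : lo + ff.tail_beads] = new_beads
    return w_new / w_old if w_old > 0 else np.inf


# -- tail-state swap --------------------------------------------------------


def swap_tail_state(
    config: Configuration,
    topology: FiberTopology,
    ff: ForceField,
    core_id: int,
) -> Configuration:
    """Propose the alternative (extended <-> folded) tail geometry of a core.

    Returns a configuration with the core's tails placed on the other
    reference template; the caller accepts or rejects it (the protocol uses
    a Metropolis test on the local electrostatic energy change). Applying
    the swap twice restores the original template.
    """
    system = get_system(topology, ff)
    geom = system.geom
    out = config.copy()
    new_state = 1 - int(config.tail_state[core_id])
    out.tail_state[core_id] = new_state
    R, c = config.core_frames[core_id], config.core_pos[core_id]
    tb = ff.tail_beads
    for t in range(ff.n_tails_per_core):
        chain = core_id * ff.n_tails_per_core + t
        tmpl = geom.tail_template(t, folded=bool(new_state))
        out.tail_pos[chain * tb : (chain + 1) * tb] = tmpl @ R.T + c
    return out
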