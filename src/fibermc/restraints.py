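"""Implicit TF (Myc:Max) binding as dynamically engaged harmonic restraints.

A bivalent TF heterotetramer bridging two linker-DNA sites is modelled
implicitly: two TF-bindable linker beads engage in a harmonic restraint
``E = k (l - l0)^2`` when they come within the capture radius while being at
least ``min_bead_separation`` beads apart along the fiber; an engaged pair
whose distance exceeds the capture radius is released. Each bead holds at
most one restraint (one tetramer per site); when several pairings are
possible the nearest pair engages first, ties broken by lower bead index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .geometry import Configuration
from .topology import FiberTopology

__all__ = [
    "RestraintParams",
    "Restraint",
    "RestraintSet",
    "tf_restraint_energy",
    "update_restraints",
]


@dataclass(frozen=True)
class RestraintParams:
    """Harmonic TF-bridge parameters (kcal/mol, nm, beads)."""

    k: float = 20.0  # kcal/mol/nm^2
    l0: float = 13.0  # rest length, nm
    capture_radius: float = 20.0  # engage below / release above, nm
    min_bead_separation: int = 30  # genomic separation in linker beads

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("restraint stiffness k must be > 0")
        if not (0 < self.l0 < self.capture_radius):
            raise ValueError("need 0 < l0 < capture_radius")
        if self.min_bead_separation < 1:
            raise ValueError("min_bead_separation must be >= 1")


@dataclass(frozen=True)
class Restraint:
    """One engaged bead pair (global linker-bead indices, bead_i < bead_j)."""

    bead_i: int
    bead_j: int
    params: RestraintParams

    def length(self, config: Configuration) -> float:
        return float(
            np.linalg.norm(config.linker_pos[self.bead_j] - config.linker_pos[self.bead_i])
        )

    def energy(self, config: Configuration) -> float:
        return self.params.k * (self.length(config) - self.params.l0) ** 2


@dataclass
class RestraintSet:
    """Currently engaged restraints with a per-bead engagement index."""

    params: RestraintParams = field(default_factory=RestraintParams)
    pairs: np.ndarray = field(default_factory=lambda: np.zeros((0, 2), dtype=np.int64))

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        self._check_unique()

    def _check_unique(self) -> None:
        beads = self.pairs.ravel()
        if len(beads) != len(np.unique(beads)):
            raise ValueError("a bead may participate in at most one restraint")
        if np.any(np.abs(self.pairs[:, 1] - self.pairs[:, 0]) < self.params.min_bead_separation):
            raise ValueError("restraint pair violates the minimum bead separation")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def active(self) -> list[Restraint]:
        return [
            Restraint(int(i), int(j), self.params) for i, j in self.pairs
        ]

    @property
    def engaged_beads(self) -> np.ndarray:
        return np.unique(self.pairs.ravel())

    def partner_of(self, bead: int) -> int | None:
        for i, j in self.pairs:
            if i == bead:
                return int(j)
            if j == bead:
                return int(i)
        return None

    def copy(self) -> "RestraintSet":
        return RestraintSet(self.params, self.pairs.copy())


def tf_restraint_energy(restraints: RestraintSet, config: Configuration) -> float:
    """Sum of k(l - l0)^2 over engaged pairs; zero for an empty set."""
    if len(restraints) == 0:
        return 0.0
    d = np.linalg.norm(
        config.linker_pos[restraints.pairs[:, 1]] - config.linker_pos[restraints.pairs[:, 0]],
        axis=1,
    )
    return float(restraints.params.k * np.sum((d - restraints.params.l0) ** 2))


def update_restraints(
    config: Configuration,
    topology: FiberTopology,
    current: RestraintSet,
    params: RestraintParams | None = None,
) -> RestraintSet:
    """Release out-of-range pairs, then engage eligible free pairs.

    Release: engaged pairs farther than the capture radius are eliminated.
    Engagement: unengaged TF-bindable bead pairs closer than the capture
    radius and at least ``min_bead_separation`` beads apart are engaged
    greedily nearest-first (ties by lower bead index), one restraint per
    bead. Deterministic for a given configuration.
    """
    params = params or current.params
    bindable = np.flatnonzero(np.asarray(topology.tf_bindable, dtype=bool))
    kept: list[tuple[int, int]] = []
    engaged: set[int] = set()
    for i, j in current.pairs:
        d = np.linalg.norm(config.linker_pos[j] - config.linker_pos[i])
        if d <= params.capture_radius:
            kept.append((int(i), int(j)))
            engaged.add(int(i))
            engaged.add(int(j))
    if len(bindable) >= 2:
        free_mask = np.array([b not in engaged for b in bindable])
        free = bindable[free_mask]
        if len(free) >= 2:
            pos = np.ascontiguousarray(config.linker_pos[free])
            mmax = len(free) * (len(free) - 1) // 2
            out_i = np.empty(mmax, dtype=np.int64)
            out_j = np.empty(mmax, dtype=np.int64)
            out_d = np.empty(mmax)
            n = _kernels.restraint_candidates(
                pos,
                free.astype(np.int64),
                params.capture_radius,
                params.min_bead_separation,
                out_i,
                out_j,
                out_d,
            )
            if n:
                order = np.lexsort((out_j[:n], out_i[:n], out_d[:n]))
                taken: set[int] = set()
                for idx in order:
                    a, b = int(free[out_i[idx]]), int(free[out_j[idx]])
                    if a in taken or b in taken:
                        continue
                    taken.add(a)
                    taken.add(b)
                    kept.append((a, b))
    pairs = np.array(sorted(kept), dtype=np.int64).reshape(-1, 2)
    return RestraintSet(params, pairs)
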