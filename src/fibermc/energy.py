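"""Potential energy of a fiber configuration.

The total energy is the sum of linker-DNA stretching/bending/twisting (ES,
EB, ET), histone-tail stretching/bending (EtS, EtB), linker-histone
stretching/bending (ElhS, ElhB), excluded-volume (EV) and screened-Coulomb
electrostatic (EC) terms over all beads, plus the TF harmonic-restraint term
(E_TF). All harmonic terms vanish at their reference geometry.

:class:`System` precomputes the flattened interaction-site table (positions,
charges, effective radii, exclusion groups) and the bonded index structures
for a (topology, force field) pair; it is what the sampler and the energy
operations share.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from . import _kernels
from .forcefield import ForceField
from .geometry import Configuration, CoreGeometry
from .topology import FiberTopology

__all__ = [
    "EnergyBreakdown",
    "System",
    "get_system",
    "dna_elastic_energy",
    "tail_lh_energy",
    "electrostatic_energy",
    "excluded_volume_energy",
    "total_energy",
]


@dataclass(frozen=True)
class EnergyBreakdown:
    """Per-term energies in kcal/mol; ``total`` is their exact sum."""

    ES: float = 0.0
    EB: float = 0.0
    ET: float = 0.0
    EtS: float = 0.0
    EtB: float = 0.0
    ElhS: float = 0.0
    ElhB: float = 0.0
    EV: float = 0.0
    EC: float = 0.0
    E_TF: float = 0.0

    FIELDS = ("ES", "EB", "ET", "EtS", "EtB", "ElhS", "ElhB", "EV", "EC", "E_TF")

    @property
    def total(self) -> float:
        return float(sum(getattr(self, f) for f in self.FIELDS))

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in self.FIELDS] + [self.total])

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "EnergyBreakdown":
        return cls(**{f: float(v) for f, v in zip(cls.FIELDS, arr)})


class System:
    """Index structures and site table for one (topology, force field) pair.

    Site layout (contiguous blocks): per-core sites (center then surface
    charges) for all cores, then linker beads, then tail beads grouped by
    core and chain, then LH beads grouped by occupied core.
    """

    def __init__(self, topology: FiberTopology, ff: ForceField):
        self.topology = topology
        self.ff = ff
        self.geom = CoreGeometry(ff)
        nc = topology.n_cores
        nl = topology.n_linker_beads
        self.n_cores = nc
        self.n_linker = nl
        self.core_sites_per = 1 + ff.n_core_charge_sites
        self.n_tail_chains = nc * ff.n_tails_per_core
        self.n_tail_beads = self.n_tail_chains * ff.tail_beads
        self.lh_cores = np.array(
            [i for i in range(nc) if topology.lh_occupied[i]], dtype=np.int64
        )
        self.n_lh_beads = len(self.lh_cores) * ff.lh_beads
        self.lh_slot = {int(c): j for j, c in enumerate(self.lh_cores)}

        self.core_site_start = 0
        self.linker_site_start = nc * self.core_sites_per
        self.tail_site_start = self.linker_site_start + nl
        self.lh_site_start = self.tail_site_start + self.n_tail_beads
        self.n_sites = self.lh_site_start + self.n_lh_beads
        self.run_offsets = topology.run_offsets

        self._build_site_meta()
        self.bindable = np.flatnonzero(np.array(topology.tf_bindable, dtype=bool))

    # -- site metadata ------------------------------------------------------

    def _build_site_meta(self) -> None:
        ff, topo = self.ff, self.topology
        ns = self.n_sites
        charge = np.zeros(ns)
        radius = np.zeros(ns)
        group = np.full(ns, -1, dtype=np.int64)
        excl = np.full((ns, 2), -2, dtype=np.int64)  # -2 matches no group

        nc, nl = self.n_cores, self.n_linker
        csp = self.core_sites_per
        for i in range(nc):
            s = i * csp
            group[s : s + csp] = i
            radius[s] = ff.ev_radius_core
            charge[s + 1 : s + csp] = self.geom.site_charge

        g_link = nc  # first linker-bead group id
        offsets = self.run_offsets
        for b in range(nl):
            s = self.linker_site_start + b
            group[s] = g_link + b
            charge[s] = ff.linker_bead_charge
            radius[s] = ff.ev_radius_linker
            run = int(np.searchsorted(offsets, b, side="right") - 1)
            first, last = offsets[run], offsets[run + 1] - 1
            excl[s, 0] = run if b == first else g_link + b - 1
            excl[s, 1] = run + 1 if b == last else g_link + b + 1

        g_tail = nc + nl
        tb = ff.tail_beads
        for t in range(self.n_tail_chains):
            core = t // ff.n_tails_per_core
            for j in range(tb):
                k = t * tb + j
                s = self.tail_site_start + k
                group[s] = g_tail + k
                charge[s] = ff.tail_bead_charge
                radius[s] = ff.ev_radius_tail
                excl[s, 0] = core if j == 0 else g_tail + k - 1
                excl[s, 1] = g_tail + k + 1 if j < tb - 1 else -2

        g_lh = g_tail + self.n_tail_beads
        lb = ff.lh_beads
        for slot, core in enumerate(self.lh_cores):
            for j in range(lb):
                k = slot * lb + j
                s = self.lh_site_start + k
                group[s] = g_lh + k
                charge[s] = ff.lh_bead_charge
                radius[s] = ff.ev_radius_lh
                excl[s, 0] = int(core) if j == 0 else g_lh + k - 1
                excl[s, 1] = g_lh + k + 1 if j < lb - 1 else -2

        self.site_charge = charge
        self.site_radius = radius
        self.site_group = group
        self.site_excl = excl

    def site_positions(self, config: Configuration) -> np.ndarray:
        """Flattened interaction-site coordinates for a configuration."""
        pos = np.empty((self.n_sites, 3))
        csp = self.core_sites_per
        cs = self.geom.charge_sites
        for i in range(self.n_cores):
            s = i * csp
            pos[s] = config.core_pos[i]
            if csp > 1:
                pos[s + 1 : s + csp] = config.core_pos[i] + cs @ config.core_frames[i].T
        pos[self.linker_site_start : self.tail_site_start] = config.linker_pos
        pos[self.tail_site_start : self.lh_site_start] = config.tail_pos
        pos[self.lh_site_start :] = config.lh_pos
        return pos

    def linker_site(self, bead: int) -> int:
        return self.linker_site_start + bead

    def core_site_range(self, core: int) -> tuple[int, int]:
        s = core * self.core_sites_per
        return s, s + self.core_sites_per

    def tail_chain_sites(self, chain: int) -> tuple[int, int]:
        s = self.tail_site_start + chain * self.ff.tail_beads
        return s, s + self.ff.tail_beads

    # -- bonded terms -------------------------------------------------------

    def run_elastic(self, config: Configuration, run: int) -> tuple[float, float]:
        """(stretch, bend) energy of one linker run including its junctions."""
        ff, geom = self.ff, self.geom
        i, j = run, run + 1
        Ri, Rj = config.core_frames[i], config.core_frames[j]
        e_out = config.core_pos[i] + Ri @ geom.exit_point
        t_out = Ri @ geom.exit_tangent
        e_in = config.core_pos[j] + Rj @ geom.entry_point
        t_in = Rj @ geom.entry_tangent
        lo, hi = self.run_offsets[run], self.run_offsets[run + 1]
        pts = np.empty((hi - lo + 2, 3))
        pts[0] = e_out
        pts[1:-1] = config.linker_pos[lo:hi]
        pts[-1] = e_in
        es, eb = _kernels.chain_elastic(
            pts, t_out, t_in, True, ff.dna_stretch_const, ff.dna_bond_nm,
            ff.dna_bend_const,
        )
        return float(es), float(eb)

    def twist_energy(self, config: Configuration) -> float:
        from .geometry import _natural_twist

        natural = _natural_twist(self.topology, self.ff)
        dev = config.twist_registry - natural - config.twist_offset
        dev = (dev + 180.0) % 360.0 - 180.0
        return self.ff.dna_twist_const * float(np.sum(np.deg2rad(dev) ** 2))

    def tail_elastic(self, config: Configuration, core: int) -> tuple[float, float]:
        """(stretch, bend) energy of all tail chains of one core."""
        ff, geom = self.ff, self.geom
        if ff.n_tails_per_core == 0 or ff.tail_beads == 0:
            return 0.0, 0.0
        acet = bool(self.topology.acetylated[core])
        mult = ff.acetyl_stiffness_multiplier if acet else 1.0
        l0 = ff.acetyl_tail_bond_nm if acet else ff.tail_bond_nm
        ks = ff.tail_stretch_const * mult
        kb = ff.tail_bend_const * mult
        R, c = config.core_frames[core], config.core_pos[core]
        tb = ff.tail_beads
        ets = etb = 0.0
        for t in range(ff.n_tails_per_core):
            chain = core * ff.n_tails_per_core + t
            a = c + R @ geom.tail_attach[t]
            u = R @ geom.tail_dir[t]
            pts = np.empty((tb + 1, 3))
            pts[0] = a
            pts[1:] = config.tail_pos[chain * tb : (chain + 1) * tb]
            s, b = _kernels.chain_elastic(pts, u, u, False, ks, l0, kb)
            ets += float(s)
            etb += float(b)
        return ets, etb

    def lh_elastic(self, config: Configuration, core: int) -> tuple[float, float]:
        """(stretch, bend) energy of the LH chain of one occupied core."""
        ff, geom = self.ff, self.geom
        slot = self.lh_slot.get(int(core))
        if slot is None or ff.lh_beads == 0:
            return 0.0, 0.0
        R, c = config.core_frames[core], config.core_pos[core]
        u = R @ geom.lh_dir
        anchor = c + R @ (geom.lh_dir * (ff.lh_attach_radius - ff.lh_bond_nm))
        pts = np.empty((ff.lh_beads + 1, 3))
        pts[0] = anchor
        pts[1:] = config.lh_pos[slot * ff.lh_beads : (slot + 1) * ff.lh_beads]
        s, b = _kernels.chain_elastic(
            pts, u, u, False, ff.lh_stretch_const, ff.lh_bond_nm, ff.lh_bend_const
        )
        return float(s), float(b)

    # -- aggregate terms ----------------------------------------------------

    def dna_elastic(self, config: Configuration) -> tuple[float, float, float]:
        es = eb = 0.0
        for run in range(self.n_cores - 1):
            s, b = self.run_elastic(config, run)
            es += s
            eb += b
        return es, eb, self.twist_energy(config)

    def tail_lh(self, config: Configuration) -> tuple[float, float, float, float]:
        ets = etb = els = elb = 0.0
        for core in range(self.n_cores):
            s, b = self.tail_elastic(config, core)
            ets += s
            etb += b
        for core in self.lh_cores:
            s, b = self.lh_elastic(config, int(core))
            els += s
            elb += b
        return ets, etb, els, elb

    def nonbonded(self, config: Configuration) -> tuple[float, float]:
        """(EC, EV) over all non-excluded site pairs."""
        pos = self.site_positions(config)
        ec, ev = _kernels.full_nonbond(
            pos,
            self.site_charge,
            self.site_radius,
            self.site_group,
            self.site_excl,
            self.ff.coulomb_prefactor,
            self.ff.debye_length,
            self.ff.excluded_volume_strength,
            self.ff.cutoff,
        )
        return float(ec), float(ev)

    def breakdown(self, config: Configuration, restraints=None) -> EnergyBreakdown:
        es, eb, et = self.dna_elastic(config)
        ets, etb, els, elb = self.tail_lh(config)
        ec, ev = self.nonbonded(config)
        e_tf = 0.0
        if restraints is not None:
            from .restraints import tf_restraint_energy

            e_tf = tf_restraint_energy(restraints, config)
        return EnergyBreakdown(
            ES=es, EB=eb, ET=et, EtS=ets, EtB=etb, ElhS=els, ElhB=elb,
            EV=ev, EC=ec, E_TF=e_tf,
        )


@lru_cache(maxsize=32)
def get_system(topology: FiberTopology, ff: ForceField) -> System:
    """Cached System for a (topology, force field) pair."""
    return System(topology, ff)


# -- spec-level operations --------------------------------------------------


def dna_elastic_energy(
    config: Configuration, topology: FiberTopology, ff: ForceField
) -> tuple[float, float, float]:
    """(ES, EB, ET): linker-DNA stretching, bending and twisting energies."""
    return get_system(topology, ff).dna_elastic(config)


def tail_lh_energy(
    config: Configuration, topology: FiberTopology, ff: ForceField
) -> tuple[float, float, float, float]:
    """(EtS, EtB, ElhS, ElhB): tail and linker-histone chain energies."""
    return get_system(topology, ff).tail_lh(config)


def electrostatic_energy(
    config: Configuration, topology: FiberTopology, ff: ForceField
) -> float:
    """EC: pairwise Debye-Hueckel energy over non-excluded site pairs."""
    return get_system(topology, ff).nonbonded(config)[0]


def excluded_volume_energy(
    config: Configuration, topology: FiberTopology, ff: ForceField
) -> float:
    """EV: purely repulsive shifted-truncated 12-6 over non-excluded pairs."""
    return get_system(topology, ff).nonbonded(config)[1]


def total_energy(
    config: Configuration,
    topology: FiberTopology,
    ff: ForceField,
    restraints=None,
) -> EnergyBreakdown:
    """Full per-term energy breakdown including the TF restraint term."""
    return get_system(topology, ff).breakdown(config, restraints)
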