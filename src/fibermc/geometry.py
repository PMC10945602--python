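"""Configurations, rigid-core geometry, and the ideal-zigzag start structure.

A :class:`Configuration` is one geometric state of a fiber: core centers and
orthonormal orientation triads, linker/tail/LH bead coordinates, and the
per-linker twist registry. :class:`CoreGeometry` holds everything that lives
in the core's body frame: DNA entry/exit points and tangents on the wrapped
superhelix, surface charge sites, tail attachment points, and the LH chain
reference at the dyad.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .forcefield import ForceField
from .topology import FiberTopology

__all__ = ["CoreGeometry", "Configuration", "build_zigzag", "rotation_matrix"]


def rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Rodrigues rotation about a (non-zero) axis by ``angle`` radians."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0:
        raise ValueError("rotation axis must be non-zero")
    x, y, z = axis / n
    c, s = np.cos(angle), np.sin(angle)
    C = 1.0 - c
    return np.array(
        [
            [c + x * x * C, x * y * C - z * s, x * z * C + y * s],
            [y * x * C + z * s, c + y * y * C, y * z * C - x * s],
            [z * x * C - y * s, z * y * C + x * s, c + z * z * C],
        ]
    )


def _align_rotation(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Minimal rotation taking unit vector ``a`` to unit vector ``b``."""
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-12:
        if c > 0:
            return np.eye(3)
        # antiparallel: rotate pi about any perpendicular axis
        perp = np.cross(a, [1.0, 0.0, 0.0])
        if np.linalg.norm(perp) < 1e-9:
            perp = np.cross(a, [0.0, 1.0, 0.0])
        return rotation_matrix(perp, np.pi)
    return rotation_matrix(v, np.arccos(np.clip(c, -1.0, 1.0)))


class CoreGeometry:
    """Body-frame geometry of a nucleosome core, derived from a force field.

    The wrapped DNA is a superhelix of ``wrap_turns`` turns at
    ``attach_radius``; entry and exit sit symmetrically about the dyad
    (local -x direction at azimuth 180 deg), with tangents following the
    helix. All vectors are in the core body frame; world coordinates are
    ``center + R @ local``.
    """

    def __init__(self, ff: ForceField):
        self.ff = ff
        r = ff.attach_radius
        sweep = ff.wrap_turns * 2 * np.pi
        half = (sweep - 2 * np.pi * np.floor(ff.wrap_turns)) / 2  # beyond full turns
        # entry at +phi0 (z>0), exit at -phi0 (z<0); DNA sweeps phi downward
        phi0 = half if half > 0 else np.pi
        z0 = ff.helix_pitch * ff.wrap_turns / 2
        self.entry_point = np.array([r * np.cos(phi0), r * np.sin(phi0), z0])
        self.exit_point = np.array([r * np.cos(phi0), -r * np.sin(phi0), -z0])
        dzdphi = 2 * z0 / sweep
        # tangent of travel (phi decreasing, z decreasing)
        def tangent(phi: float) -> np.ndarray:
            t = np.array([r * np.sin(phi), -r * np.cos(phi), -dzdphi])
            return t / np.linalg.norm(t)

        self.entry_tangent = tangent(phi0)  # direction of DNA arriving at the core
        self.exit_tangent = tangent(-phi0)  # direction of DNA leaving the core

        # charge sites: two rings of n/2 on the cylinder surface
        n = ff.n_core_charge_sites
        sites = []
        n_top = n // 2
        n_bot = n - n_top
        for k in range(n_top):
            a = 2 * np.pi * k / n_top
            sites.append([ff.charge_site_radius * np.cos(a),
                          ff.charge_site_radius * np.sin(a), ff.charge_site_z])
        for k in range(n_bot):
            a = 2 * np.pi * (k + 0.5) / n_bot
            sites.append([ff.charge_site_radius * np.cos(a),
                          ff.charge_site_radius * np.sin(a), -ff.charge_site_z])
        self.charge_sites = np.array(sites) if sites else np.zeros((0, 3))
        self.site_charge = ff.core_total_charge / max(n, 1)

        # tail attachments: evenly spaced azimuths, alternating z
        m = ff.n_tails_per_core
        self.tail_attach = np.zeros((m, 3))
        self.tail_dir = np.zeros((m, 3))
        for t in range(m):
            a = 2 * np.pi * (t + 0.5) / m
            z = ff.charge_site_z * (1 if t % 2 == 0 else -1)
            self.tail_attach[t] = (ff.attach_radius * np.cos(a),
                                   ff.attach_radius * np.sin(a), z)
            self.tail_dir[t] = (np.cos(a), np.sin(a), 0.0)

        # LH chain reference: beads along the dyad direction (azimuth pi)
        u = np.array([-1.0, 0.0, 0.0])
        self.lh_dir = u
        self.lh_sites = np.array(
            [u * (ff.lh_attach_radius + j * ff.lh_bond_nm) for j in range(ff.lh_beads)]
        ) if ff.lh_beads else np.zeros((0, 3))

    def tail_template(self, tail: int, folded: bool) -> np.ndarray:
        """Reference bead coordinates (body frame) of one tail chain."""
        bond = self.ff.acetyl_tail_bond_nm if folded else self.ff.tail_bond_nm
        a, u = self.tail_attach[tail], self.tail_dir[tail]
        return np.array([a + u * bond * (j + 1) for j in range(self.ff.tail_beads)])


@dataclass
class Configuration:
    """One geometric state of a fiber (positions in nm, twist in degrees)."""

    core_pos: np.ndarray  # (NC, 3)
    core_frames: np.ndarray  # (NC, 3, 3), columns = body axes in world coords
    linker_pos: np.ndarray  # (NL, 3)
    tail_pos: np.ndarray  # (NC * n_tails * tail_beads, 3)
    lh_pos: np.ndarray  # (n_lh_cores * lh_beads, 3)
    twist_registry: np.ndarray  # (NC - 1,) degrees, actual twist per linker
    twist_offset: float = 0.0  # replica-wide twist offset, degrees
    tail_state: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int8))

    def copy(self) -> "Configuration":
        return Configuration(
            self.core_pos.copy(),
            self.core_frames.copy(),
            self.linker_pos.copy(),
            self.tail_pos.copy(),
            self.lh_pos.copy(),
            self.twist_registry.copy(),
            self.twist_offset,
            self.tail_state.copy(),
        )

    def check_frames(self, tol: float = 1e-9) -> None:
        for i, R in enumerate(self.core_frames):
            if not np.allclose(R @ R.T, np.eye(3), atol=tol * 1e3):
                raise ValueError(f"core frame {i} is not orthonormal")

    def transformed(self, R: np.ndarray | None = None, t: np.ndarray | None = None
                    ) -> "Configuration":
        """Rigid-body transform of the whole state (for invariance tests)."""
        R = np.eye(3) if R is None else np.asarray(R, float)
        t = np.zeros(3) if t is None else np.asarray(t, float)
        out = self.copy()
        for arr in (out.core_pos, out.linker_pos, out.tail_pos, out.lh_pos):
            if arr.size:
                arr[:] = arr @ R.T + t
        out.core_frames[:] = np.einsum("ab,ibc->iac", R, out.core_frames)
        return out


def _natural_twist(topology: FiberTopology, ff: ForceField) -> np.ndarray:
    bp = np.asarray(topology.linker_bp, dtype=float)
    return np.mod(bp * ff.bp_twist_deg, 360.0)


def build_zigzag(
    topology: FiberTopology,
    ff: ForceField,
    twist_offset: float = 0.0,
    roll_mode: str = "two_start",
) -> Configuration:
    """Ideal two-start zigzag start structure.

    Cores are propagated one by one: the linker leaves core ``i`` along its
    exit tangent as a straight bead run at the equilibrium bond length, and
    core ``i+1`` is oriented so its entry tangent continues that line,
    rolled about it. In the default ``two_start`` mode the roll alternates
    cores between the two stacks (180 degrees) plus the replica twist
    offset, giving an open, extended fiber; ``natural`` mode rolls by the
    linker's full helical twist instead. All DNA elastic terms are exactly
    zero in either construction.
    """
    geom = CoreGeometry(ff)
    nc = topology.n_cores
    core_pos = np.zeros((nc, 3))
    core_frames = np.zeros((nc, 3, 3))
    core_frames[0] = np.eye(3)
    natural = _natural_twist(topology, ff)
    linker_pos = np.zeros((topology.n_linker_beads, 3))

    k = 0
    for i in range(nc - 1):
        R = core_frames[i]
        e_out = core_pos[i] + R @ geom.exit_point
        t_out = R @ geom.exit_tangent
        nb = topology.linker_runs[i]
        for j in range(nb):
            linker_pos[k] = e_out + (j + 1) * ff.dna_bond_nm * t_out
            k += 1
        entry_world = e_out + (nb + 1) * ff.dna_bond_nm * t_out
        if roll_mode == "two_start":
            psi = np.deg2rad((180.0 + twist_offset) % 360.0)
        elif roll_mode == "natural":
            psi = np.deg2rad((natural[i] + twist_offset) % 360.0)
        else:
            raise ValueError(f"unknown roll_mode {roll_mode!r}")
        A = _align_rotation(geom.entry_tangent, t_out)
        R_next = rotation_matrix(t_out, psi) @ A
        core_frames[i + 1] = R_next
        core_pos[i + 1] = entry_world - R_next @ geom.entry_point

    # tails at their reference template (folded for acetylated cores)
    nt, tb = ff.n_tails_per_core, ff.tail_beads
    tail_pos = np.zeros((nc * nt * tb, 3))
    tail_state = np.zeros(nc, dtype=np.int8)
    for i in range(nc):
        folded = bool(topology.acetylated[i])
        tail_state[i] = 1 if folded else 0
        R, c = core_frames[i], core_pos[i]
        for t in range(nt):
            tmpl = geom.tail_template(t, folded)
            tail_pos[(i * nt + t) * tb : (i * nt + t + 1) * tb] = tmpl @ R.T + c

    # LH chains for occupied cores, in core order
    lh_cores = [i for i in range(nc) if topology.lh_occupied[i]]
    lh_pos = np.zeros((len(lh_cores) * ff.lh_beads, 3))
    for j, i in enumerate(lh_cores):
        R, c = core_frames[i], core_pos[i]
        lh_pos[j * ff.lh_beads : (j + 1) * ff.lh_beads] = geom.lh_sites @ R.T + c

    return Configuration(
        core_pos=core_pos,
        core_frames=core_frames,
        linker_pos=linker_pos,
        tail_pos=tail_pos,
        lh_pos=lh_pos,
        twist_registry=(natural + twist_offset) % 360.0,
        twist_offset=twist_offset,
        tail_state=tail_state,
    )
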