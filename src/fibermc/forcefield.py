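"""Force-field parameters for the mesoscale chromatin model.

Units are kcal/mol, nm, degrees and Kelvin throughout. The energy model is a
simplified but term-complete mesoscale potential: worm-like-chain harmonic
stretching/bending/twisting for linker DNA, harmonic stretching/bending for
histone-tail and linker-histone bead chains, a purely repulsive
shifted-truncated 12-6 excluded-volume term, and Debye-Hueckel screened
electrostatics. Nucleosome cores are rigid bodies carrying a configurable
number of surface point charges on a cylinder.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = ["KB_KCAL", "ForceField"]

#: Boltzmann constant in kcal/mol/K.
KB_KCAL = 0.0019872041


@dataclass(frozen=True)
class ForceField:
    """All tunable energy and geometry parameters of the model."""

    # -- thermodynamic state
    temperature: float = 293.0  # K
    monovalent_salt: float = 0.15  # M, sets the Debye length
    dielectric: float = 80.0

    # -- linker DNA (worm-like chain bead model, ~9 bp/bead)
    dna_stretch_const: float = 20.0  # kcal/mol/nm^2
    dna_bond_nm: float = 3.0  # equilibrium bead spacing (~9 bp)
    dna_bend_const: float = 9.7  # kcal/mol/rad^2 (from ~50 nm persistence length)
    dna_twist_const: float = 14.6  # kcal/mol/rad^2 per linker bond
    bp_twist_deg: float = 360.0 / 10.5  # helical twist per bp

    # -- histone tails (coarse bead chains on the core surface)
    tail_stretch_const: float = 10.0
    tail_bend_const: float = 2.0
    acetyl_stiffness_multiplier: float = 100.0
    n_tails_per_core: int = 4
    tail_beads: int = 2  # beads per tail chain
    tail_bond_nm: float = 1.5  # extended (wildtype) reference bond
    acetyl_tail_bond_nm: float = 0.8  # folded (acetylated) reference bond
    tail_bead_charge: float = 1.8  # e

    # -- linker histone (bead chain at the dyad)
    lh_stretch_const: float = 10.0
    lh_bend_const: float = 5.0
    lh_beads: int = 3
    lh_bond_nm: float = 1.7
    lh_attach_radius: float = 6.5  # nm from the core axis
    lh_bead_charge: float = 6.0  # e, per bead (positively charged CTD)

    # -- excluded volume (purely repulsive shifted-truncated 12-6)
    excluded_volume_strength: float = 0.05  # kcal/mol
    ev_radius_core: float = 3.0  # effective sphere radii per species, nm
    ev_radius_linker: float = 1.2
    ev_radius_tail: float = 0.9
    ev_radius_lh: float = 1.0

    # -- electrostatics
    core_total_charge: float = -150.0  # e, spread over the surface sites
    n_core_charge_sites: int = 12
    linker_bead_charge: float = -24.0  # e per ~9 bp bead (salt-screened)
    nonbond_cutoff: float | None = None  # nm; None -> derived from screening

    # -- rigid core geometry (cylinder wrapped by ~1.65 DNA turns)
    core_radius: float = 5.5
    core_half_height: float = 2.75
    attach_radius: float = 4.5  # superhelix radius of the wrapped DNA
    wrap_turns: float = 1.65
    helix_pitch: float = 2.4  # nm per superhelical turn
    charge_site_radius: float = 5.0
    charge_site_z: float = 1.8

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name in ("nonbond_cutoff",) or not isinstance(v, (int, float)):
                continue
            if f.name.endswith("_const") or f.name in (
                "acetyl_stiffness_multiplier",
                "excluded_volume_strength",
            ):
                if v < 0:
                    raise ValueError(f"{f.name} must be >= 0, got {v}")
        if self.monovalent_salt <= 0:
            raise ValueError("monovalent_salt must be > 0 (finite Debye length)")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")

    # -- derived quantities --------------------------------------------------

    @property
    def kT(self) -> float:
        return KB_KCAL * self.temperature

    @property
    def debye_length(self) -> float:
        """Screening length in nm, 0.304/sqrt(c) for monovalent salt."""
        return 0.304 / np.sqrt(self.monovalent_salt)

    @property
    def coulomb_prefactor(self) -> float:
        """kcal*nm/(mol*e^2): 332.06 kcal*A/mol scaled to nm over dielectric."""
        return 33.20636 / self.dielectric

    @property
    def ev_radii(self) -> dict[str, float]:
        return {
            "core": self.ev_radius_core,
            "linker": self.ev_radius_linker,
            "tail": self.ev_radius_tail,
            "lh": self.ev_radius_lh,
        }

    @property
    def excluded_volume_diameters(self) -> dict[str, float]:
        return {k: 2 * v for k, v in self.ev_radii.items()}

    @property
    def cutoff(self) -> float:
        """Nonbonded cutoff: beyond both screening and any EV contact."""
        if self.nonbond_cutoff is not None:
            return self.nonbond_cutoff
        ev_max = 2 * max(self.ev_radii.values())
        return max(7.0 * self.debye_length, ev_max)

    def with_overrides(self, **kwargs) -> "ForceField":
        return replace(self, **kwargs)
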