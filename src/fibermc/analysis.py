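"""Observables computed from trajectories and pooled ensembles.

Covers the full analysis suite of the model: fiber-axis packing ratio,
Kirkwood-approximation sedimentation coefficient, radius of gyration,
nucleosome/bp-resolution contact maps (single-trajectory and ensemble),
contact-decay profiles, DBSCAN microdomain detection on inverse-frequency
distances, alpha-shape promoter area/volume, realized TF concentration, and
convergence diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import make_smoothing_spline
from scipy.spatial import Delaunay, QhullError, cKDTree
from sklearn.cluster import DBSCAN

from .energy import get_system
from .geometry import Configuration
from .sampler import Frame, Trajectory
from .topology import FiberTopology

__all__ = [
    "FiberAxis",
    "ContactMap",
    "ContactDecay",
    "MicrodomainSet",
    "PromoterGeometry",
    "ConvergenceReport",
    "Ensemble",
    "fiber_axis_and_length",
    "packing_ratio",
    "sedimentation_coefficient",
    "radius_of_gyration",
    "contact_map",
    "ensemble_contact_map",
    "contact_decay",
    "detect_microdomains",
    "promoter_geometry",
    "effective_tf_concentration",
    "matrix_density",
    "convergence_report",
    "assemble_analysis_ensemble",
    "region_contact_enrichment",
]

# Mononucleosome sedimentation coefficients (Svedberg) without / with LH,
# and the nucleosome radius of the Kirkwood-form correction.
S0_SVEDBERG = 11.1
S1_SVEDBERG = 12.0
R1_NM = 5.5

#: Default smoothing parameter of the fiber-axis spline: strong enough that
#: the axis of an ideal two-start zigzag passes between the two stacks,
#: gentle enough to track smooth curvature (tuned constant, configurable).
AXIS_SMOOTHING = 4.0


# -- fiber axis and packing ratio -------------------------------------------


@dataclass(frozen=True)
class FiberAxis:
    """Smoothed axis polyline through the core centers; arc length in nm."""

    points: np.ndarray  # (n, 3) dense samples along the axis
    length: float  # Fl, nm


def fiber_axis_and_length(
    config: Configuration | np.ndarray, smoothing: float = AXIS_SMOOTHING
) -> FiberAxis:
    """Cubic smoothing spline through core centers; Fl by dense quadrature."""
    cores = config.core_pos if isinstance(config, Configuration) else np.asarray(config)
    n = len(cores)
    if n < 2:
        raise ValueError("fiber axis undefined for fewer than 2 cores")
    t = np.arange(n, dtype=float)
    dense_t = np.linspace(0.0, n - 1.0, max(40 * n, 200))
    axis = np.empty((len(dense_t), 3))
    for d in range(3):
        spl = make_smoothing_spline(t, cores[:, d], lam=smoothing)
        axis[:, d] = spl(dense_t)
    seg = np.linalg.norm(np.diff(axis, axis=0), axis=1)
    return FiberAxis(points=axis, length=float(seg.sum()))


def packing_ratio(
    config: Configuration | np.ndarray, smoothing: float = AXIS_SMOOTHING
) -> float:
    """Nucleosomes per 11 nm of fiber-axis length: 11 * NC / Fl."""
    cores = config.core_pos if isinstance(config, Configuration) else np.asarray(config)
    axis = fiber_axis_and_length(cores, smoothing)
    return 11.0 * len(cores) / axis.length


# -- compaction measures ----------------------------------------------------


def sedimentation_coefficient(
    config: Configuration | np.ndarray, lh_density: float = 0.0
) -> float:
    """Kirkwood-form sedimentation coefficient S20,w in Svedberg.

    ``((S1 - S0) rho + S0) * (1 + (R1/NC) sum_{i != j} 1/Rij)`` over ordered
    core pairs; a mononucleosome returns the LH-interpolated prefactor alone.
    """
    if not (0 <= lh_density <= 1):
        raise ValueError("lh_density must be in [0, 1]")
    cores = config.core_pos if isinstance(config, Configuration) else np.asarray(config)
    nc = len(cores)
    pref = (S1_SVEDBERG - S0_SVEDBERG) * lh_density + S0_SVEDBERG
    if nc == 1:
        return pref
    diff = cores[:, None, :] - cores[None, :, :]
    r = np.linalg.norm(diff, axis=-1)
    iu = np.triu_indices(nc, k=1)
    if np.any(r[iu] == 0):
        raise ValueError("coincident cores: sedimentation coefficient singular")
    pair_sum = 2.0 * float(np.sum(1.0 / r[iu]))  # ordered pairs i != j
    return pref * (1.0 + (R1_NM / nc) * pair_sum)


def radius_of_gyration(config: Configuration | np.ndarray) -> float:
    """Root-mean-square core distance from the core centroid, nm."""
    cores = config.core_pos if isinstance(config, Configuration) else np.asarray(config)
    center = cores.mean(axis=0)
    return float(np.sqrt(np.mean(np.sum((cores - center) ** 2, axis=1))))


# -- contact maps ------------------------------------------------------------


@dataclass
class ContactMap:
    """Symmetric interaction-count matrix at nucleosome or bp resolution.

    ``counts`` accumulates per-frame contact indicators over ``n_frames``
    frames; ``frequency`` is the frame-normalized map. The stored matrix is
    raw counts; the normalization state is explicit.
    """

    counts: np.ndarray
    n_frames: int
    resolution: str = "nucleosome"  # or "bp"
    cutoff_nm: float = 2.0
    bin_bp: int | None = None  # bp-resolution bin width

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("contact map must be square")
        if not np.allclose(self.counts, self.counts.T):
            raise ValueError("contact map must be symmetric")

    @property
    def n(self) -> int:
        return self.counts.shape[0]

    @property
    def frequency(self) -> np.ndarray:
        return self.counts / max(self.n_frames, 1)

    def to_tsv(self, path: str | Path, normalized: bool = False) -> None:
        m = self.frequency if normalized else self.counts
        header = (
            f"# resolution: {self.resolution}\n"
            f"# frames: {self.n_frames}\n"
            f"# cutoff_nm: {self.cutoff_nm}\n"
            f"# normalized: {normalized}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, m, delimiter="\t", fmt="%.6g")


def _nucleosome_elements(
    topology: FiberTopology, ff
) -> tuple[np.ndarray, np.ndarray]:
    """(owner nucleosome, radius) for every contact element site.

    Elements are the core center, the core's tail beads, and linker beads;
    each linker run is split at its midpoint between the two flanking cores
    (ties upstream). Site order matches ``System.site_positions``.
    """
    system = get_system(topology, ff)
    owner = np.full(system.n_sites, -1, dtype=np.int64)
    for c in range(system.n_cores):
        lo, hi = system.core_site_range(c)
        owner[lo] = c  # center only; charge sites are not physical elements
    offsets = topology.run_offsets
    for run, nb in enumerate(topology.linker_runs):
        up = (nb + 1) // 2  # first half (ties upstream) -> core `run`
        for j in range(nb):
            owner[system.linker_site_start + offsets[run] + j] = (
                run if j < up else run + 1
            )
    tb = ff.tail_beads * ff.n_tails_per_core
    for c in range(system.n_cores):
        lo = system.tail_site_start + c * tb
        owner[lo : lo + tb] = c
    radius = system.site_radius.copy()
    return owner, radius


def contact_map(
    frames: list[Frame] | list[Configuration],
    topology: FiberTopology,
    ff,
    cutoff: float = 2.0,
    resolution: str = "nucleosome",
    bin_bp: int = 200,
) -> ContactMap:
    """Accumulate per-frame contacts between nucleosome elements.

    Two nucleosomes are in contact in a frame if any element of one (core,
    tails, or linker DNA) is within ``cutoff`` nm surface-to-surface of any
    element of the other (center distance minus both excluded-volume radii).
    """
    if not frames:
        raise ValueError("contact_map requires at least one frame")
    configs = [f.config if isinstance(f, Frame) else f for f in frames]
    system = get_system(topology, ff)
    owner, radius = _nucleosome_elements(topology, ff)
    sel = owner >= 0
    sel_idx = np.flatnonzero(sel)
    own = owner[sel_idx]
    rad = radius[sel_idx]
    rmax = rad.max() if len(rad) else 0.0

    if resolution == "nucleosome":
        n = topology.n_cores
        bin_of = own
    elif resolution == "bp":
        spans = topology.bead_bp_spans()
        core_mid = topology.core_bp_positions()
        site_bp = np.empty(system.n_sites)
        site_bp[:] = -1
        for c in range(system.n_cores):
            lo, hi = system.core_site_range(c)
            site_bp[lo] = core_mid[c]
        for b in range(system.n_linker):
            site_bp[system.linker_site_start + b] = spans[b].mean()
        tb = ff.tail_beads * ff.n_tails_per_core
        for c in range(system.n_cores):
            lo = system.tail_site_start + c * tb
            site_bp[lo : lo + tb] = core_mid[c]
        total_bp = core_mid[-1] + 147 / 2
        n = int(np.ceil(total_bp / bin_bp))
        bin_of = np.minimum((site_bp[sel_idx] / bin_bp).astype(int), n - 1)
    else:
        raise ValueError(f"unknown resolution {resolution!r}")

    counts = np.zeros((n, n))
    query_r = cutoff + 2 * rmax
    for config in configs:
        pos = system.site_positions(config)[sel_idx]
        tree = cKDTree(pos)
        pairs = tree.query_pairs(query_r, output_type="ndarray")
        if len(pairs) == 0:
            continue
        a, b = pairs[:, 0], pairs[:, 1]
        gap = np.linalg.norm(pos[a] - pos[b], axis=1) - rad[a] - rad[b]
        hit = (gap < cutoff) & (own[a] != own[b])
        ia, ib = bin_of[a[hit]], bin_of[b[hit]]
        frame_hit = np.zeros((n, n), dtype=bool)
        frame_hit[ia, ib] = True
        frame_hit[ib, ia] = True
        counts += frame_hit
    return ContactMap(
        counts=counts,
        n_frames=len(configs),
        resolution=resolution,
        cutoff_nm=cutoff,
        bin_bp=bin_bp if resolution == "bp" else None,
    )


def ensemble_contact_map(maps: list[ContactMap]) -> ContactMap:
    """Elementwise sum of single-trajectory maps (the population-level map)."""
    if not maps:
        raise ValueError("need at least one map")
    first = maps[0]
    for m in maps[1:]:
        if m.counts.shape != first.counts.shape or m.resolution != first.resolution:
            raise ValueError("contact maps differ in shape or resolution")
    return ContactMap(
        counts=sum(m.counts for m in maps),
        n_frames=sum(m.n_frames for m in maps),
        resolution=first.resolution,
        cutoff_nm=first.cutoff_nm,
        bin_bp=first.bin_bp,
    )


# -- contact decay ----------------------------------------------------------


@dataclass(frozen=True)
class ContactDecay:
    """Normalized contact-pattern profile I(k), k = 1..NC-1; sums to 1."""

    values: np.ndarray
    normalization: float


def contact_decay(cmap: ContactMap) -> ContactDecay:
    """Fraction of off-diagonal interaction mass at each offset |i - j| = k."""
    if cmap.resolution != "nucleosome":
        raise ValueError("contact decay is defined on nucleosome-resolution maps")
    m = cmap.counts
    n = cmap.n
    raw = np.array([np.trace(m, offset=k) for k in range(1, n)])
    total = raw.sum()
    if total == 0:
        raise ValueError("contact decay undefined for an all-zero map")
    return ContactDecay(values=raw / total, normalization=float(total))


# -- microdomains -----------------------------------------------------------


@dataclass(frozen=True)
class MicrodomainSet:
    """DBSCAN cluster label per nucleosome (-1 = noise) and parameters."""

    labels: np.ndarray
    epsilon: float
    minpoints: int

    @property
    def n_clusters(self) -> int:
        return len(set(self.labels[self.labels >= 0].tolist()))


def inverse_frequency_distance(cmap: ContactMap) -> np.ndarray:
    """d = 1/frequency distance matrix; zero frequencies capped at 10x the
    maximum finite distance (DBSCAN needs finite entries), zero diagonal."""
    f = cmap.frequency
    n = cmap.n
    d = np.empty((n, n))
    pos = f > 0
    d[pos] = 1.0 / f[pos]
    np.fill_diagonal(d, 0.0)
    off = ~pos & ~np.eye(n, dtype=bool)
    finite_max = d[pos & ~np.eye(n, dtype=bool)].max() if np.any(pos & ~np.eye(n, dtype=bool)) else 1.0
    d[off] = 10.0 * finite_max
    np.fill_diagonal(d, 0.0)
    return d


def detect_microdomains(
    cmap: ContactMap, epsilon: float, minpoints: int = 5
) -> MicrodomainSet:
    """DBSCAN on the inverse-contact-frequency distance matrix.

    The stated radii for the ensemble maps are eps = 3 (62 bp fibers),
    2 (44 bp and life-like) and 1.4 (26 bp), with minpoints = 5.
    """
    if cmap.resolution != "nucleosome":
        raise ValueError("microdomain detection uses nucleosome-resolution maps")
    d = inverse_frequency_distance(cmap)
    labels = DBSCAN(eps=epsilon, min_samples=minpoints, metric="precomputed").fit(d).labels_
    return MicrodomainSet(labels=labels, epsilon=epsilon, minpoints=minpoints)


# -- promoter geometry (alpha shapes) ---------------------------------------


@dataclass(frozen=True)
class PromoterGeometry:
    """Ensemble mean +- SD of promoter alpha-shape area (nm^2), volume (nm^3)."""

    area_mean: float
    area_sd: float
    volume_mean: float
    volume_sd: float
    alpha: float
    core_indices: tuple[int, ...]


def _cross2(u: np.ndarray, v: np.ndarray) -> float:
    return float(u[0] * v[1] - u[1] * v[0])


def _circumradius_tri(p: np.ndarray) -> float:
    a = np.linalg.norm(p[1] - p[0])
    b = np.linalg.norm(p[2] - p[1])
    c = np.linalg.norm(p[2] - p[0])
    area2 = abs(_cross2(p[1] - p[0], p[2] - p[0]))
    if area2 == 0:
        return np.inf
    return a * b * c / (2 * area2)


def _circumradius_tet(p: np.ndarray) -> float:
    A = 2 * (p[1:] - p[0])
    b = np.sum(p[1:] ** 2 - p[0] ** 2, axis=1)
    try:
        center = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.inf
    return float(np.linalg.norm(center - p[0]))


def alpha_shape_area_2d(points: np.ndarray, alpha: float) -> float:
    """Area of the 2D alpha shape (triangles with circumradius <= alpha)."""
    pts = np.asarray(points, dtype=float)[:, :2]
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise ValueError("degenerate vertex set for alpha-shape area") from exc
    area = 0.0
    for simplex in tri.simplices:
        p = pts[simplex]
        if _circumradius_tri(p) <= alpha:
            area += 0.5 * abs(_cross2(p[1] - p[0], p[2] - p[0]))
    return area


def alpha_shape_volume_3d(points: np.ndarray, alpha: float) -> float:
    """Volume of the 3D alpha shape (tetrahedra with circumradius <= alpha)."""
    pts = np.asarray(points, dtype=float)
    try:
        tri = Delaunay(pts)
    except QhullError as exc:
        raise ValueError("degenerate vertex set for alpha-shape volume") from exc
    vol = 0.0
    for simplex in tri.simplices:
        p = pts[simplex]
        if _circumradius_tet(p) <= alpha:
            vol += abs(np.linalg.det(p[1:] - p[0])) / 6.0
    return vol


def promoter_geometry(
    frames: list[Frame] | list[Configuration],
    core_indices: list[int],
    alpha: float = 100.0,
) -> PromoterGeometry:
    """Alpha-shape area (x,y projection) and volume (x,y,z) of selected cores.

    ``core_indices`` are 0-based; an alpha of 100 gives a loose, nearly
    convex envelope for promoter-sized vertex sets.
    """
    idx = np.asarray(core_indices, dtype=int)
    if len(idx) < 4:
        raise ValueError("promoter geometry needs >= 4 vertex cores")
    areas, vols = [], []
    for f in frames:
        cores = (f.config if isinstance(f, Frame) else f).core_pos[idx]
        areas.append(alpha_shape_area_2d(cores, alpha))
        vols.append(alpha_shape_volume_3d(cores, alpha))
    return PromoterGeometry(
        area_mean=float(np.mean(areas)),
        area_sd=float(np.std(areas)),
        volume_mean=float(np.mean(vols)),
        volume_sd=float(np.std(vols)),
        alpha=alpha,
        core_indices=tuple(int(i) for i in idx),
    )


# -- TF occupancy and map statistics ----------------------------------------


def effective_tf_concentration(trajectories: list[Trajectory]) -> float | None:
    """Mean realized TF concentration (%) across replicas.

    Per replica: the percentage of linker-DNA beads engaged in a restraint,
    averaged over saved frames — the same scale as the nominal
    concentration, so a fully engaged 50%-marked fiber reads 50%. The
    ensemble value is the mean over replicas. Returns None if no bead is
    bindable.
    """
    per_replica = []
    for traj in trajectories:
        n_bind = int(np.sum(np.asarray(traj.topology.tf_bindable, dtype=bool)))
        if n_bind == 0:
            return None
        n_total = traj.topology.n_linker_beads
        vals = [
            len(np.unique(f.restraint_pairs.ravel())) / n_total * 100.0
            for f in traj.frames
        ]
        per_replica.append(float(np.mean(vals)) if vals else 0.0)
    return float(np.mean(per_replica)) if per_replica else None


def matrix_density(cmap: ContactMap) -> float:
    """Fraction of strictly positive entries above the diagonal."""
    iu = np.triu_indices(cmap.n, k=1)
    vals = cmap.counts[iu]
    return float(np.mean(vals > 0)) if len(vals) else 0.0


def region_contact_enrichment(
    cmap: ContactMap, regions: list[list[int]]
) -> tuple[float, float, float]:
    """Contact enrichment between distinct marked regions.

    Returns (marked mean, control mean, ratio) where 'marked' averages the
    map over nucleosome pairs from two different regions and 'control'
    averages unmarked-unmarked pairs at the same genomic separations
    (separation-matched weighting). Ratio is marked/control (inf if the
    control mass is zero but marked is not).
    """
    n = cmap.n
    f = cmap.frequency
    in_region = np.full(n, -1, dtype=int)
    for ri, reg in enumerate(regions):
        in_region[np.asarray(reg, dtype=int)] = ri
    marked_by_sep: dict[int, list[float]] = {}
    control_by_sep: dict[int, list[float]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            k = j - i
            if in_region[i] >= 0 and in_region[j] >= 0 and in_region[i] != in_region[j]:
                marked_by_sep.setdefault(k, []).append(f[i, j])
            elif in_region[i] < 0 and in_region[j] < 0:
                control_by_sep.setdefault(k, []).append(f[i, j])
    seps = [k for k in marked_by_sep if k in control_by_sep]
    if not seps:
        raise ValueError("no separation-matched control pairs available")
    marked = float(np.mean([np.mean(marked_by_sep[k]) for k in seps]))
    control = float(np.mean([np.mean(control_by_sep[k]) for k in seps]))
    if control == 0:
        return marked, control, np.inf if marked > 0 else np.nan
    return marked, control, marked / control


# -- convergence and ensembles ----------------------------------------------


@dataclass(frozen=True)
class ConvergenceReport:
    """Per-frame series used to monitor trajectory convergence."""

    steps: np.ndarray
    total_energy: np.ndarray
    end_to_end: np.ndarray
    sedimentation: np.ndarray
    triplet_angle_deg: np.ndarray


def convergence_report(trajectory: Trajectory) -> ConvergenceReport:
    """Energy, end-to-end distance, S20,w and mean triplet angle per frame."""
    if not trajectory.frames:
        raise ValueError("convergence report needs >= 1 frame")
    rho = trajectory.topology.lh_density
    steps, e, ee, sed, ang = [], [], [], [], []
    for f in trajectory.frames:
        cores = f.config.core_pos
        steps.append(f.step)
        e.append(f.energy.total)
        ee.append(float(np.linalg.norm(cores[-1] - cores[0])))
        sed.append(sedimentation_coefficient(cores, rho))
        if len(cores) >= 3:
            v1 = cores[:-2] - cores[1:-1]
            v2 = cores[2:] - cores[1:-1]
            c = np.einsum("ij,ij->i", v1, v2) / (
                np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
            )
            ang.append(float(np.degrees(np.arccos(np.clip(c, -1, 1))).mean()))
        else:
            ang.append(float("nan"))
    return ConvergenceReport(
        steps=np.array(steps),
        total_energy=np.array(e),
        end_to_end=np.array(ee),
        sedimentation=np.array(sed),
        triplet_angle_deg=np.array(ang),
    )


@dataclass
class Ensemble:
    """Frames pooled across replicas with per-frame provenance."""

    topology: FiberTopology
    frames: list[Frame]
    provenance: list[tuple[int, int]]  # (replica index, MC step)

    def __len__(self) -> int:
        return len(self.frames)


def assemble_analysis_ensemble(
    trajectories: list[Trajectory], tail_steps: int
) -> Ensemble:
    """Pool the final ``tail_steps`` worth of frames from every replica.

    With the standard stride (frames every 100,000 steps), a 10-million-step
    tail over 10 replicas pools 1000 structures; over 20 replicas, 2000.
    """
    if not trajectories:
        raise ValueError("need at least one trajectory")
    save_every = trajectories[0].save_every
    if tail_steps % save_every != 0:
        raise ValueError("tail_steps must be a multiple of save_every")
    k = tail_steps // save_every
    frames: list[Frame] = []
    prov: list[tuple[int, int]] = []
    for r, traj in enumerate(trajectories):
        if k > len(traj.frames):
            raise ValueError(
                f"tail of {k} frames exceeds trajectory length {len(traj.frames)}"
            )
        for f in traj.frames[len(traj.frames) - k :]:
            frames.append(f)
            prov.append((r, f.step))
    return Ensemble(topology=trajectories[0].topology, frames=frames, provenance=prov)
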