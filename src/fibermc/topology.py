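"""Fiber topology construction.

A :class:`FiberTopology` is the static description of a chromatin fiber:
how many nucleosome cores it has, how many linker-DNA beads sit between
consecutive cores (one bead per ~9 bp), where nucleosome-free regions (NFRs)
extend a linker run, which cores carry a linker histone (LH), which cores
have acetylated tails, and which linker beads can bind the transcription
factor (TF).

Builders cover the three system families studied with this model: uniform
fibers (single linker length), "life-like" fibers whose linker lengths are
drawn from the mESC linker-length distribution, and gene-locus fibers tiled
from genomic tracks (NFRs, LH ChIP regions, TF ChIP regions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .tracks import GenomicTrack

__all__ = [
    "BP_PER_BEAD",
    "CORE_BP",
    "MESC_LINKER_DISTRIBUTION",
    "FiberTopology",
    "TFTopologySpec",
    "beads_for_bp",
    "build_uniform_fiber",
    "build_lifelike_fiber",
    "apply_tf_topology",
    "set_tf_concentration",
    "place_linker_histones",
    "mark_acetylation",
    "build_gene_fiber",
]

#: Linker-DNA discretization: one bead per ~9 bp.
BP_PER_BEAD = 9

#: DNA wrapped by one nucleosome core.
CORE_BP = 147

#: mESC linker-length distribution (fraction per bp class).
MESC_LINKER_DISTRIBUTION: dict[int, float] = {
    26: 0.30,
    35: 0.17,
    44: 0.15,
    53: 0.13,
    62: 0.09,
    70: 0.07,
    80: 0.09,
}


def beads_for_bp(bp: float) -> int:
    """Beads representing ``bp`` of linker DNA: round(bp/9), at least 1."""
    if bp <= 0:
        raise ValueError(f"linker length must be positive, got {bp}")
    return max(1, int(np.floor(bp / BP_PER_BEAD + 0.5)))


@dataclass(frozen=True)
class FiberTopology:
    """Static description of a chromatin fiber at bead resolution.

    ``linker_runs[i]`` is the bead count of the linker connecting cores ``i``
    and ``i+1``; ``linker_bp[i]`` its DNA length in bp (NFR extensions
    included). ``nfr_spans`` records ``(linker_index, bp)`` for every NFR
    folded into a linker run. Flag vectors: ``lh_occupied`` and ``acetylated``
    per core, ``tf_bindable`` per linker bead (concatenated run by run).
    """

    n_cores: int
    linker_runs: tuple[int, ...]
    linker_bp: tuple[int, ...]
    nfr_spans: tuple[tuple[int, int], ...] = ()
    lh_occupied: tuple[bool, ...] = ()
    acetylated: tuple[bool, ...] = ()
    tf_bindable: tuple[bool, ...] = ()
    nrl_bp: int | None = None

    def __post_init__(self) -> None:
        if self.n_cores < 1:
            raise ValueError("a fiber needs at least one core")
        if len(self.linker_runs) != self.n_cores - 1:
            raise ValueError(
                f"{self.n_cores} cores require {self.n_cores - 1} linker runs, "
                f"got {len(self.linker_runs)}"
            )
        if any(n < 1 for n in self.linker_runs):
            raise ValueError("every linker run needs at least one bead")
        if len(self.linker_bp) != len(self.linker_runs):
            raise ValueError("linker_bp and linker_runs must be parallel")
        n = self.n_linker_beads
        object.__setattr__(
            self,
            "lh_occupied",
            tuple(self.lh_occupied) if self.lh_occupied else (False,) * self.n_cores,
        )
        object.__setattr__(
            self,
            "acetylated",
            tuple(self.acetylated) if self.acetylated else (False,) * self.n_cores,
        )
        object.__setattr__(
            self,
            "tf_bindable",
            tuple(self.tf_bindable) if self.tf_bindable else (False,) * n,
        )
        if len(self.lh_occupied) != self.n_cores:
            raise ValueError("lh_occupied must have one flag per core")
        if len(self.acetylated) != self.n_cores:
            raise ValueError("acetylated must have one flag per core")
        if len(self.tf_bindable) != n:
            raise ValueError(
                f"tf_bindable must have one flag per linker bead ({n}), "
                f"got {len(self.tf_bindable)}"
            )
        for li, bp in self.nfr_spans:
            if not (0 <= li < len(self.linker_runs)):
                raise ValueError(f"NFR attached to nonexistent linker {li}")
            if bp <= 0:
                raise ValueError("NFR length must be positive")

    # -- derived quantities -------------------------------------------------

    @property
    def n_linker_beads(self) -> int:
        return int(sum(self.linker_runs))

    @property
    def run_offsets(self) -> np.ndarray:
        """Start index of each linker run in the global linker-bead vector."""
        return np.concatenate(([0], np.cumsum(self.linker_runs)))

    @property
    def lh_density(self) -> float:
        return float(np.mean(self.lh_occupied)) if self.n_cores else 0.0

    def run_of_bead(self, bead: int) -> int:
        """Linker-run index containing global linker bead ``bead``."""
        return int(np.searchsorted(self.run_offsets, bead, side="right") - 1)

    def bead_bp_spans(self) -> np.ndarray:
        """Genomic (start, end) bp span of every linker bead, run by run.

        Cores occupy 147 bp each; each run's bp (NFRs included) is divided
        evenly among its beads. Coordinates are fiber-relative. Used for
        bp-resolution contact maps.
        """
        spans = np.empty((self.n_linker_beads, 2))
        g = float(CORE_BP)  # after core 0
        k = 0
        for nb, bp in zip(self.linker_runs, self.linker_bp):
            per = bp / nb
            for b in range(nb):
                spans[k] = (g + b * per, g + (b + 1) * per)
                k += 1
            g += bp + CORE_BP
        return spans

    def core_bp_positions(self) -> np.ndarray:
        """Fiber-relative bp midpoint of every core."""
        mids = np.empty(self.n_cores)
        g = 0.0
        for i in range(self.n_cores):
            mids[i] = g + CORE_BP / 2
            if i < self.n_cores - 1:
                g += CORE_BP + self.linker_bp[i]
        return mids

    # -- serialization ------------------------------------------------------

    _SCHEMA = 1

    def to_json(self) -> str:
        doc = {
            "schema": self._SCHEMA,
            "n_cores": self.n_cores,
            "linker_runs": list(self.linker_runs),
            "linker_bp": list(self.linker_bp),
            "nfr_spans": [list(x) for x in self.nfr_spans],
            "lh_occupied": [int(x) for x in self.lh_occupied],
            "acetylated": [int(x) for x in self.acetylated],
            "tf_bindable": [int(x) for x in self.tf_bindable],
            "nrl_bp": self.nrl_bp,
        }
        return json.dumps(doc, separators=(",", ":"))

    @classmethod
    def from_json(cls, text: str) -> "FiberTopology":
        doc = json.loads(text)
        schema = doc.pop("schema", None)
        if schema != cls._SCHEMA:
            raise ValueError(f"unsupported topology schema {schema!r}")
        return cls(
            n_cores=doc["n_cores"],
            linker_runs=tuple(doc["linker_runs"]),
            linker_bp=tuple(doc["linker_bp"]),
            nfr_spans=tuple(tuple(x) for x in doc["nfr_spans"]),
            lh_occupied=tuple(bool(x) for x in doc["lh_occupied"]),
            acetylated=tuple(bool(x) for x in doc["acetylated"]),
            tf_bindable=tuple(bool(x) for x in doc["tf_bindable"]),
            nrl_bp=doc.get("nrl_bp"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "FiberTopology":
        return cls.from_json(Path(path).read_text())


# -- TF binding patterns ----------------------------------------------------

#: The four canonical binding patterns on a 50-nucleosome fiber:
#: (region_count, region_span_nucleosomes, placement)
_CANONICAL_PATTERNS = {
    1: (5, 5, "evenly"),
    2: (2, 15, "ends"),
    3: (1, 15, "middle"),
    4: (2, 5, "near-ends"),
}


@dataclass(frozen=True)
class TFTopologySpec:
    """Spatial pattern of TF-bindable regions along a fiber.

    The four canonical patterns (``pattern_id`` 1-4) fix their parameters;
    scaled variants use ``pattern_id=None`` with explicit parameters.
    """

    region_count: int
    region_span_nucleosomes: int
    placement: str  # evenly | ends | middle | near-ends
    pattern_id: int | None = None

    def __post_init__(self) -> None:
        if self.placement not in ("evenly", "ends", "middle", "near-ends"):
            raise ValueError(f"unknown placement {self.placement!r}")
        if self.region_count < 1 or self.region_span_nucleosomes < 2:
            raise ValueError("regions need >= 1 count and >= 2 nucleosomes of span")
        if self.pattern_id is not None:
            expected = _CANONICAL_PATTERNS.get(self.pattern_id)
            if expected is None:
                raise ValueError(f"pattern_id must be 1-4, got {self.pattern_id}")
            if (self.region_count, self.region_span_nucleosomes, self.placement) != expected:
                raise ValueError(
                    f"pattern {self.pattern_id} requires parameters {expected}"
                )

    @classmethod
    def pattern(cls, pattern_id: int) -> "TFTopologySpec":
        count, span, placement = _CANONICAL_PATTERNS[pattern_id]
        return cls(count, span, placement, pattern_id)

    def region_starts(self, n_cores: int) -> list[int]:
        """1-based first nucleosome of each region on an ``n_cores`` fiber."""
        c, s = self.region_count, self.region_span_nucleosomes
        if c * s > n_cores:
            raise ValueError(
                f"pattern needs {c * s} nucleosomes but fiber has {n_cores}"
            )
        if self.placement == "middle":
            return [(n_cores - s) // 2 + 1] * c if c == 1 else _even(n_cores, c, s)
        if self.placement == "ends":
            if c == 1:
                return [1]
            return _even(n_cores, c, s)  # first at 1, last ending at n_cores
        if self.placement == "near-ends":
            margin = max(1, int(np.floor(0.1 * n_cores + 0.5)))
            margin = min(margin, (n_cores - c * s) // (c + 1) if c > 1 else n_cores - s)
            if c == 1:
                return [margin + 1]
            inner = n_cores - 2 * margin
            return [x + margin for x in _even(inner, c, s)]
        return _even(n_cores, c, s)


def _even(n_cores: int, count: int, span: int) -> list[int]:
    """Evenly place ``count`` regions of ``span`` nucleosomes on 1..n_cores."""
    if count == 1:
        return [(n_cores - span) // 2 + 1]
    step = (n_cores - span) / (count - 1)
    starts = [1 + int(np.floor(i * step + 0.5)) for i in range(count)]
    for a, b in zip(starts, starts[1:]):
        if b < a + span:
            raise ValueError("regions overlap; pattern does not fit fiber")
    return starts


# -- builders ---------------------------------------------------------------


def build_uniform_fiber(n_cores: int, linker_bp: float) -> FiberTopology:
    """Fiber with ``n_cores`` nucleosomes and a single linker length."""
    if n_cores < 1:
        raise ValueError(f"n_cores must be >= 1, got {n_cores}")
    nb = beads_for_bp(linker_bp)
    n_runs = n_cores - 1
    return FiberTopology(
        n_cores=n_cores,
        linker_runs=(nb,) * n_runs,
        linker_bp=(int(linker_bp),) * n_runs,
        nrl_bp=int(CORE_BP + linker_bp),
    )


def build_lifelike_fiber(
    n_cores: int,
    linker_distribution: dict[int, float] | None = None,
    seed: int = 0,
) -> FiberTopology:
    """Fiber whose linker lengths are drawn from a bp-class distribution.

    Defaults to the mESC distribution. Reproducible for equal seeds.
    """
    if n_cores < 1:
        raise ValueError(f"n_cores must be >= 1, got {n_cores}")
    dist = MESC_LINKER_DISTRIBUTION if linker_distribution is None else linker_distribution
    classes = sorted(dist)
    fracs = np.array([dist[c] for c in classes], dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError(f"linker fractions must sum to 1, got {fracs.sum():.12f}")
    rng = np.random.default_rng(seed)
    bp = rng.choice(classes, size=n_cores - 1, p=fracs) if n_cores > 1 else np.array([], int)
    return FiberTopology(
        n_cores=n_cores,
        linker_runs=tuple(beads_for_bp(x) for x in bp),
        linker_bp=tuple(int(x) for x in bp),
    )


def apply_tf_topology(topology: FiberTopology, spec: TFTopologySpec) -> FiberTopology:
    """Mark the linker beads of the pattern's regions as TF-bindable.

    A region of ``k`` consecutive nucleosomes contributes its ``k - 1``
    internal linker runs; all other beads are unmarked.
    """
    starts = spec.region_starts(topology.n_cores)
    flags = np.zeros(topology.n_linker_beads, dtype=bool)
    offsets = topology.run_offsets
    for a in starts:  # region covers nucleosomes a .. a+span-1 (1-based)
        b = a + spec.region_span_nucleosomes - 1
        for run in range(a - 1, b - 1):  # 0-based runs internal to the region
            flags[offsets[run] : offsets[run + 1]] = True
    return replace(topology, tf_bindable=tuple(bool(x) for x in flags))


def set_tf_concentration(
    topology: FiberTopology, percent: float, seed: int = 0
) -> FiberTopology:
    """Mark floor(percent% of linker beads) as TF-bindable, uniformly at random.

    For a fixed seed the marked sets are nested across concentrations (a
    seeded permutation is truncated), so the marked count is monotone in
    ``percent``.
    """
    if not (0 <= percent <= 100):
        raise ValueError(f"percent must be in [0, 100], got {percent}")
    n = topology.n_linker_beads
    m = int(np.floor(percent / 100.0 * n))
    order = np.random.default_rng(seed).permutation(n)
    flags = np.zeros(n, dtype=bool)
    flags[order[:m]] = True
    return replace(topology, tf_bindable=tuple(bool(x) for x in flags))


def place_linker_histones(
    topology: FiberTopology,
    density: float,
    mode: str = "uniform",
    positions: list[int] | None = None,
    seed: int = 0,
) -> FiberTopology:
    """Flag floor(density * n_cores) cores as LH-occupied.

    ``mode`` is ``uniform`` (evenly spaced), ``random`` (seeded), or
    ``explicit`` (``positions`` is a 0-based core index list; ``density``
    is ignored).
    """
    nc = topology.n_cores
    flags = np.zeros(nc, dtype=bool)
    if mode == "explicit":
        if positions is None:
            raise ValueError("explicit mode requires positions")
        idx = np.asarray(positions, dtype=int)
        if idx.size and (idx.min() < 0 or idx.max() >= nc):
            raise ValueError("explicit LH position out of range")
        flags[idx] = True
    else:
        if not (0 <= density <= 1):
            raise ValueError(f"LH density must be in [0, 1], got {density}")
        m = int(np.floor(density * nc))
        if mode == "uniform":
            idx = np.floor(np.arange(m) * nc / m).astype(int) if m else np.array([], int)
        elif mode == "random":
            idx = np.random.default_rng(seed).permutation(nc)[:m]
        else:
            raise ValueError(f"unknown LH placement mode {mode!r}")
        flags[idx] = True
    return replace(topology, lh_occupied=tuple(bool(x) for x in flags))


def mark_acetylation(
    topology: FiberTopology, islands: list[tuple[int, int]]
) -> FiberTopology:
    """Flag cores inside 1-based inclusive ``(first, last)`` islands as acetylated."""
    flags = np.zeros(topology.n_cores, dtype=bool)
    for first, last in islands:
        if not (1 <= first <= last <= topology.n_cores):
            raise ValueError(
                f"island ({first}, {last}) outside 1..{topology.n_cores}"
            )
        flags[first - 1 : last] = True
    return replace(topology, acetylated=tuple(bool(x) for x in flags))


def build_gene_fiber(
    region_bp: int,
    nfr_track: GenomicTrack,
    nrl_bp: int = 189,
    linker_distribution: dict[int, float] | None = None,
    lh_track: GenomicTrack | float | None = None,
    tf_track: GenomicTrack | None = None,
    seed: int = 0,
    n_cores: int | None = None,
) -> FiberTopology:
    """Tile a genomic region with nucleosomes around its NFRs.

    NFR intervals become runs of free DNA beads folded into the enclosing
    linker; the remaining sequence is tiled with ``n_cores`` nucleosomes
    (default: round of non-NFR length / NRL) whose linker lengths are drawn
    from ``linker_distribution`` (default mESC). Cores overlapping
    ``lh_track`` intervals are LH-occupied (or, if ``lh_track`` is a float,
    LHs are placed randomly at that density); linker beads whose genomic
    footprint overlaps ``tf_track`` are TF-bindable.
    """
    if nrl_bp <= CORE_BP:
        raise ValueError(f"NRL must exceed {CORE_BP} bp, got {nrl_bp}")
    nfr_track.check_disjoint()
    for s, e, _ in nfr_track:
        if s < 0 or e > region_bp:
            raise ValueError(f"NFR ({s}, {e}) outside region [0, {region_bp})")
    if tf_track is not None:
        for s, e, _ in tf_track:
            if s < 0 or e > region_bp:
                raise ValueError(f"TF interval ({s}, {e}) outside region")
    dist = MESC_LINKER_DISTRIBUTION if linker_distribution is None else linker_distribution
    classes = sorted(dist)
    fracs = np.array([dist[c] for c in classes], dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("linker fractions must sum to 1")
    nfr_bp_total = nfr_track.total_bp()
    if n_cores is None:
        n_cores = int(np.floor((region_bp - nfr_bp_total) / nrl_bp + 0.5))
    if n_cores < 2:
        raise ValueError("gene fiber needs at least two cores")

    rng = np.random.default_rng(seed)
    nfrs = list(nfr_track)
    runs: list[int] = []
    run_bp: list[int] = []
    nfr_spans: list[tuple[int, int]] = []
    tf_flags: list[bool] = []
    lh_flags: list[bool] = []

    def core_overlaps_lh(start: float) -> bool:
        if isinstance(lh_track, GenomicTrack):
            return lh_track.overlaps(int(start), int(start + CORE_BP))
        return False

    g = 0.0  # genomic cursor
    next_nfr = 0
    if nfrs and nfrs[0][0] < CORE_BP:
        raise ValueError("NFR before the first nucleosome is not supported")
    lh_flags.append(core_overlaps_lh(g))
    g += CORE_BP
    for i in range(n_cores - 1):
        bp = int(rng.choice(classes, p=fracs))
        nfr_here = 0
        # fold any NFR starting inside this linker into the run
        while next_nfr < len(nfrs) and nfrs[next_nfr][0] < g + bp + CORE_BP:
            s, e, _ = nfrs[next_nfr]
            if e > region_bp - CORE_BP and i < n_cores - 2:
                raise ValueError("NFR after the last nucleosome is not supported")
            nfr_here += e - s
            next_nfr += 1
        total_bp = bp + nfr_here
        nb = beads_for_bp(total_bp)
        if nfr_here:
            nfr_spans.append((i, nfr_here))
        # per-bead genomic footprint for TF marking
        per = total_bp / nb
        for b in range(nb):
            bs, be = g + b * per, g + (b + 1) * per
            tf_flags.append(
                tf_track is not None and tf_track.overlaps(int(bs), int(np.ceil(be)))
            )
        runs.append(nb)
        run_bp.append(total_bp)
        g += total_bp
        lh_flags.append(core_overlaps_lh(g))
        g += CORE_BP

    topo = FiberTopology(
        n_cores=n_cores,
        linker_runs=tuple(runs),
        linker_bp=tuple(run_bp),
        nfr_spans=tuple(nfr_spans),
        lh_occupied=tuple(lh_flags),
        tf_bindable=tuple(tf_flags),
        nrl_bp=nrl_bp,
    )
    if isinstance(lh_track, (int, float)) and lh_track is not None:
        topo = place_linker_histones(topo, float(lh_track), mode="random", seed=seed + 1)
    return topo
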