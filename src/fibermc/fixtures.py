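"""Named, offline-buildable system fixtures.

The Eed fixtures encode the mouse Eed locus as characterized by public
MNase-seq and ChIP-seq data (mm9 chr7:97,103,164-97,129,486, ~26 kbp):
seven nucleosome-free
regions (NFRs 1-2 ~350 bp, NFRs 3-7 ~200 bp), an mESC nucleosome repeat
length of 189 bp giving 129 nucleosomes over the non-NFR sequence, two
ChIP-derived Myc:Max binding regions, and a linker-histone density of 0.37
(or 0.8, randomly placed, for the somatic-cell variants).

The exact NFR and LH peak coordinates are not published at bp precision;
the tracks emitted here are synthetic instances consistent with the stated
summary statistics (sizes, counts, densities). The two TF intervals are the
published genomic coordinates, clipped to the locus.
"""

from __future__ import annotations

from pathlib import Path

from .topology import (
    CORE_BP,
    FiberTopology,
    TFTopologySpec,
    apply_tf_topology,
    build_gene_fiber,
    build_lifelike_fiber,
    build_uniform_fiber,
    place_linker_histones,
)
from .tracks import GenomicTrack

__all__ = ["FIXTURE_NAMES", "make_fixture", "write_fixture", "EED_REGION_BP"]

# mm9 Eed locus; the UCSC start is treated as the 0-based region origin.
EED_CHROM = "chr7"
EED_START = 97_103_164
EED_END = 97_129_486
EED_REGION_BP = EED_END - EED_START  # 26,322 bp
EED_NRL = 189
EED_N_CORES = 129
EED_LH_DENSITY = 0.37
_EED_SEED = 20_240_119  # fixed: fixtures are deterministic

# Synthetic NFR placement (sizes per the locus description; positions spread
# across the region, interior to the fiber).
_EED_NFRS = [
    (1_800, 2_150, "NFR1"),  # ~350 bp
    (5_200, 5_550, "NFR2"),  # ~350 bp
    (9_000, 9_200, "NFR3"),
    (12_400, 12_600, "NFR4"),
    (15_600, 15_800, "NFR5"),
    (18_900, 19_100, "NFR6"),
    (22_300, 22_500, "NFR7"),
]

# Published Myc:Max ChIP regions, region-relative (0-based half-open);
# region 1 (the promoter-overlapping one) is clipped to the locus end.
_EED_TF = [
    (97_124_070 - EED_START, 97_124_896 - EED_START, "TF_region2"),
    (97_128_221 - EED_START, min(97_129_793, EED_END) - EED_START, "TF_region1"),
]

FIXTURE_NAMES = (
    "eed_wt",
    "eed_tf",
    "eed_lh08",
    "eed_lh08_tf",
    "uniform_topology1",
    "uniform_topology2",
    "uniform_topology3",
    "uniform_topology4",
    "lifelike",
)


def _eed(tf: bool, lh_density: float, lh_mode: str) -> tuple[FiberTopology, dict]:
    nfr_track = GenomicTrack(tuple(_EED_NFRS), chrom=EED_CHROM)
    tf_track = GenomicTrack(tuple(_EED_TF), chrom=EED_CHROM) if tf else None
    topo = build_gene_fiber(
        region_bp=EED_REGION_BP,
        nfr_track=nfr_track,
        nrl_bp=EED_NRL,
        lh_track=None,
        tf_track=tf_track,
        seed=_EED_SEED,
        n_cores=EED_N_CORES,
    )
    topo = place_linker_histones(topo, lh_density, mode=lh_mode, seed=_EED_SEED + 7)
    # LH BED track derived from the occupied cores' genomic footprints
    mids = topo.core_bp_positions()
    lh_ivals = tuple(
        (int(mids[i] - CORE_BP / 2), int(mids[i] + CORE_BP / 2), f"LH_core{i + 1}")
        for i in range(topo.n_cores)
        if topo.lh_occupied[i]
    )
    tracks = {
        "nfr": nfr_track,
        "lh": GenomicTrack(lh_ivals, chrom=EED_CHROM),
    }
    if tf_track is not None:
        tracks["tf"] = tf_track
    return topo, tracks


def make_fixture(name: str, linker_bp: int = 44, n_cores: int = 50,
                 seed: int = 0) -> tuple[FiberTopology, dict[str, GenomicTrack]]:
    """Build a named fixture; returns (topology, tracks it was built from)."""
    if name == "eed_wt":
        return _eed(tf=False, lh_density=EED_LH_DENSITY, lh_mode="random")
    if name == "eed_tf":
        return _eed(tf=True, lh_density=EED_LH_DENSITY, lh_mode="random")
    if name == "eed_lh08":
        return _eed(tf=False, lh_density=0.8, lh_mode="random")
    if name == "eed_lh08_tf":
        return _eed(tf=True, lh_density=0.8, lh_mode="random")
    if name.startswith("uniform_topology"):
        pattern = int(name.removeprefix("uniform_topology"))
        topo = build_uniform_fiber(n_cores, linker_bp)
        topo = apply_tf_topology(topo, TFTopologySpec.pattern(pattern))
        return topo, {}
    if name == "lifelike":
        return build_lifelike_fiber(n_cores, seed=seed), {}
    raise ValueError(f"unknown fixture {name!r}; known: {', '.join(FIXTURE_NAMES)}")


def write_fixture(name: str, out_dir: str | Path, **kwargs) -> Path:
    """Materialize a fixture: topology JSON plus its BED tracks."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    topo, tracks = make_fixture(name, **kwargs)
    topo_path = out / f"{name}.topology.json"
    topo.save(topo_path)
    for kind, track in tracks.items():
        track.to_bed(out / f"{name}.{kind}.bed")
    return topo_path
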