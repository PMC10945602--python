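"""BED-like genomic interval tracks.

Tracks use the BED convention throughout: 0-based, half-open intervals on a
single region/chromosome. They annotate fiber topologies with nucleosome-free
regions, linker-histone positions, and TF-bindable regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = ["GenomicTrack"]


@dataclass(frozen=True)
class GenomicTrack:
    """An ordered set of labelled genomic intervals (0-based, half-open)."""

    intervals: tuple[tuple[int, int, str], ...] = field(default_factory=tuple)
    chrom: str = "region"

    def __post_init__(self) -> None:
        prev_start = -1
        for start, end, _ in self.intervals:
            if start < 0:
                raise ValueError(f"negative coordinate in interval ({start}, {end})")
            if start >= end:
                raise ValueError(f"empty or inverted interval ({start}, {end})")
            if start < prev_start:
                raise ValueError("intervals must be sorted by start")
            prev_start = start

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def total_bp(self) -> int:
        return sum(end - start for start, end, _ in self.intervals)

    def overlaps(self, start: int, end: int) -> bool:
        """True if [start, end) overlaps any interval of the track."""
        return any(s < end and start < e for s, e, _ in self.intervals)

    def shifted(self, offset: int) -> "GenomicTrack":
        """Translate all intervals by ``offset`` bp (e.g. UCSC -> region-relative)."""
        return GenomicTrack(
            tuple((s + offset, e + offset, n) for s, e, n in self.intervals), self.chrom
        )

    def check_disjoint(self) -> None:
        for (s0, e0, _), (s1, e1, _) in zip(self.intervals, self.intervals[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping intervals ({s0},{e0}) and ({s1},{e1})")

    @classmethod
    def from_bed(cls, path: str | Path) -> "GenomicTrack":
        df = pd.read_csv(
            path,
            sep="\t",
            comment="#",
            header=None,
            names=["chrom", "start", "end", "name"],
            dtype={"chrom": str, "start": int, "end": int, "name": str},
        )
        chroms = df["chrom"].unique()
        if len(chroms) > 1:
            raise ValueError(f"track spans multiple chromosomes: {list(chroms)}")
        df = df.sort_values("start", kind="stable")
        ivals = tuple(
            (int(r.start), int(r.end), "" if pd.isna(r.name) else str(r.name))
            for r in df.itertuples(index=False)
        )
        return cls(ivals, chrom=str(chroms[0]) if len(chroms) else "region")

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for start, end, name in self.intervals:
                fh.write(f"{self.chrom}\t{start}\t{end}\t{name or '.'}\n")
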