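"""Genomic regions snapped to a fixed bin resolution.

All coordinates are 0-based, half-open (BED convention). Bin ``k`` of a
region covers ``[start + k*resolution, start + (k+1)*resolution)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

_REGION_RE = re.compile(r"^([\w.]+):([\d,]+)-([\d,]+)$")


@dataclass(frozen=True)
class GenomicRegion:
    """A chromosome window aligned to a bin grid.

    Parameters
    ----------
    chrom : str
        Chromosome name as it appears in the source files.
    start, end : int
        0-based half-open interval; both must be multiples of ``resolution``.
    resolution : int
        Bin width in base pairs.
    """

    chrom: str
    start: int
    end: int
    resolution: int

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"resolution must be positive, got {self.resolution}")
        if not self.start < self.end:
            raise ValueError(f"start must be < end, got [{self.start}, {self.end})")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.start % self.resolution or self.end % self.resolution:
            raise ValueError(
                f"[{self.start}, {self.end}) is not aligned to the {self.resolution} bp "
                "grid; use GenomicRegion.snap to snap it"
            )

    @property
    def n_bins(self) -> int:
        return (self.end - self.start) // self.resolution

    @classmethod
    def snap(cls, chrom: str, start: int, end: int, resolution: int) -> "GenomicRegion":
        """Snap an arbitrary window onto the grid: start floored, end ceiled."""
        if resolution <= 0:
            raise ValueError(f"resolution must be positive, got {resolution}")
        s = (start // resolution) * resolution
        e = -(-end // resolution) * resolution
        return cls(chrom, s, e, resolution)

    @classmethod
    def parse(cls, text: str, resolution: int) -> "GenomicRegion":
        """Parse ``chrom:start-end`` (0-based half-open), snapping to the grid."""
        m = _REGION_RE.match(text.strip())
        if m is None:
            raise ValueError(f"cannot parse region {text!r}; expected chrom:start-end")
        chrom, s, e = m.group(1), m.group(2), m.group(3)
        return cls.snap(chrom, int(s.replace(",", "")), int(e.replace(",", "")), resolution)

    def bin_start(self, k: int) -> int:
        return self.start + k * self.resolution

    def bin_of(self, pos: int) -> int:
        """Bin index containing base position ``pos`` (must lie inside the region)."""
        if not self.start <= pos < self.end:
            raise ValueError(f"position {pos} outside {self}")
        return (pos - self.start) // self.resolution

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}@{self.resolution}"
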