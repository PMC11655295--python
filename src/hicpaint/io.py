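"""Readers for contact matrices and 1D genomic tracks.

Supported sources:

* contact matrices — single-resolution ``.cool`` / multi-resolution ``.mcool``
  (HDF5, read via :mod:`h5py` following the public cooler schema) and
  whitespace-delimited dense text;
* 1D signal — bigWig (via pyBigWig) and bedGraph;
* intervals — BED3+ (converted to a unit-valued track) and chromHMM BED9
  with an ``itemRgb`` column.

Missing-data convention: bigWig/bedGraph gaps are *missing* (NaN) — the assay
reports nothing there — while bases not covered by any BED interval are *zero*,
because a peak file asserts absence outside its peaks.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

from .regions import GenomicRegion

__all__ = [
    "ContactMatrix",
    "BinnedTrack",
    "ChromHMMSegmentation",
    "read_contact_matrix",
    "read_track",
    "bed_to_track",
    "read_chromhmm",
    "write_cool",
    "write_dense_text",
]


@dataclass
class ContactMatrix:
    """Square symmetric matrix of contact frequencies over a region's bins.

    ``values`` is float64 with NaN marking missing entries; ``normalization_tag``
    is one of ``raw``, ``balanced``, ``distnorm``, ``unit-scaled``.
    """

    region: GenomicRegion
    values: np.ndarray
    normalization_tag: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        n = self.region.n_bins
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match region {self.region} "
                f"with {n} bins"
            )
        both = ~np.isnan(self.values) & ~np.isnan(self.values.T)
        if both.any():
            a, b = self.values[both], self.values.T[both]
            if not np.allclose(a, b, rtol=1e-6, atol=1e-8):
                raise ValueError("contact matrix is not symmetric")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and finite.min() < 0:
            raise ValueError("contact matrix has negative entries")

    @property
    def n_bins(self) -> int:
        return self.region.n_bins


@dataclass
class BinnedTrack:
    """Per-bin 1D signal over a region; NaN marks bins with no data."""

    region: GenomicRegion
    values: np.ndarray
    name: str = ""
    signed_flag: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.values.size != self.region.n_bins:
            raise ValueError(
                f"track length {self.values.size} does not match region {self.region} "
                f"with {self.region.n_bins} bins"
            )
        if not self.signed_flag:
            finite = self.values[~np.isnan(self.values)]
            if finite.size and finite.min() < 0:
                raise ValueError(
                    f"track {self.name!r} has negative values; pass signed_flag=True "
                    "for signed tracks (e.g. a compartment eigenvector)"
                )


@dataclass
class ChromHMMSegmentation:
    """Labeled, non-overlapping intervals each carrying an RGB color.

    ``intervals`` is a list of ``(chrom, start, end, state, (r, g, b))``;
    ``states`` maps state label -> RGB in stable first-seen order.
    """

    intervals: list[tuple[str, int, int, str, tuple[int, int, int]]]
    states: dict[str, tuple[int, int, int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.states:
            for _, _, _, label, rgb in self.intervals:
                self.states.setdefault(label, rgb)
        for label, rgb in self.states.items():
            if len(rgb) != 3 or any(not (0 <= v <= 255) for v in rgb):
                raise ValueError(f"state {label!r} has invalid RGB {rgb}")


# ---------------------------------------------------------------------------
# contact matrices
# ---------------------------------------------------------------------------

def read_contact_matrix(
    source: str | os.PathLike,
    region: GenomicRegion,
    balance: bool = False,
) -> ContactMatrix:
    """Read the symmetric contact submatrix for ``region``.

    ``source`` may be a ``.cool``/``.mcool`` file or a whitespace-delimited
    dense text matrix whose dimension equals the region's bin count. For
    cooler input, ``balance=True`` applies the stored balancing weights when
    present (bins with NaN weight become missing); raw counts are used
    otherwise.
    """
    source = os.fspath(source)
    if not os.path.exists(source):
        raise FileNotFoundError(f"contact matrix source not found: {source}")
    if h5py.is_hdf5(source):
        return _read_cool(source, region, balance)
    return _read_dense_text(source, region)


def _read_dense_text(path: str, region: GenomicRegion) -> ContactMatrix:
    values = np.loadtxt(path, dtype=np.float64, ndmin=2)
    if values.shape[0] != values.shape[1]:
        raise ValueError(
            f"dense text matrix {path} is not square: shape {values.shape}"
        )
    if values.shape[0] != region.n_bins:
        raise ValueError(
            f"dense text matrix {path} has {values.shape[0]} bins but region "
            f"{region} has {region.n_bins}"
        )
    return ContactMatrix(region, values, normalization_tag="raw")


def _cool_group(f: h5py.File, resolution: int) -> h5py.Group:
    if "bins" in f:
        return f["/"]
    if "resolutions" in f:
        key = str(resolution)
        if key not in f["resolutions"]:
            avail = sorted(int(k) for k in f["resolutions"])
            raise ValueError(
                f"resolution {resolution} not stored; available: {avail}"
            )
        return f["resolutions"][key]
    raise ValueError("not a cooler file: no bins or resolutions group")


def _read_cool(path: str, region: GenomicRegion, balance: bool) -> ContactMatrix:
    with h5py.File(path, "r") as f:
        grp = _cool_group(f, region.resolution)
        binsize = int(grp.attrs.get("bin-size", region.resolution))
        if binsize != region.resolution:
            raise ValueError(
                f"resolution {region.resolution} not stored in {path} (bin size {binsize})"
            )
        names = [n.decode() if isinstance(n, bytes) else str(n) for n in grp["chroms/name"][:]]
        lengths = grp["chroms/length"][:]
        if region.chrom not in names:
            raise ValueError(f"unknown chromosome {region.chrom!r} in {path}")
        ci = names.index(region.chrom)
        if region.end > int(lengths[ci]):
            raise ValueError(
                f"region {region} extends past chromosome end {int(lengths[ci])}"
            )
        chrom_offset = grp["indexes/chrom_offset"][:]
        lo = int(chrom_offset[ci]) + region.start // region.resolution
        hi = int(chrom_offset[ci]) + region.end // region.resolution
        n = hi - lo

        bin1_offset = grp["indexes/bin1_offset"][:]
        p0, p1 = int(bin1_offset[lo]), int(bin1_offset[hi])
        b1 = grp["pixels/bin1_id"][p0:p1]
        b2 = grp["pixels/bin2_id"][p0:p1]
        count = grp["pixels/count"][p0:p1].astype(np.float64)
        keep = (b2 >= lo) & (b2 < hi)
        b1, b2, count = b1[keep] - lo, b2[keep] - lo, count[keep]

        values = np.zeros((n, n), dtype=np.float64)
        values[b1, b2] = count
        values[b2, b1] = count
        tag = "raw"
        if balance and "weight" in grp["bins"]:
            w = grp["bins/weight"][lo:hi].astype(np.float64)
            values = values * np.outer(w, w)
            bad = np.isnan(w)
            values[bad, :] = np.nan
            values[:, bad] = np.nan
            tag = "balanced"
    return ContactMatrix(region, values, normalization_tag=tag)


def write_cool(
    path: str | os.PathLike,
    region: GenomicRegion,
    values: np.ndarray,
    weights: np.ndarray | None = None,
) -> str:
    """Write a single-resolution .cool file holding ``values`` for ``region``.

    The chromosome spans exactly ``[0, region.end)``; bins before
    ``region.start`` are empty. Follows the cooler HDF5 schema (format
    version 3, symmetric-upper storage).
    """
    path = os.fspath(path)
    values = np.asarray(values, dtype=np.float64)
    n = region.n_bins
    if values.shape != (n, n):
        raise ValueError(f"values shape {values.shape} != ({n}, {n})")
    res = region.resolution
    nbins_total = region.end // res
    offset = region.start // res

    iu, ju = np.triu_indices(n)
    c = values[iu, ju]
    keep = ~np.isnan(c) & (c != 0)
    b1 = (iu[keep] + offset).astype(np.int64)
    b2 = (ju[keep] + offset).astype(np.int64)
    count = c[keep]
    order = np.lexsort((b2, b1))
    b1, b2, count = b1[order], b2[order], count[order]

    with h5py.File(path, "w") as f:
        f.attrs["format"] = "HDF5::Cooler"
        f.attrs["format-version"] = 3
        f.attrs["bin-type"] = "fixed"
        f.attrs["bin-size"] = res
        f.attrs["nbins"] = nbins_total
        f.attrs["nchroms"] = 1
        f.attrs["nnz"] = int(b1.size)
        f.attrs["storage-mode"] = "symmetric-upper"
        g = f.create_group("chroms")
        g.create_dataset("name", data=np.array([region.chrom.encode()]))
        g.create_dataset("length", data=np.array([region.end], dtype=np.int64))
        g = f.create_group("bins")
        g.create_dataset("chrom", data=np.zeros(nbins_total, dtype=np.int32))
        starts = np.arange(nbins_total, dtype=np.int64) * res
        g.create_dataset("start", data=starts)
        g.create_dataset("end", data=np.minimum(starts + res, region.end))
        if weights is not None:
            w = np.full(nbins_total, np.nan)
            w[offset : offset + n] = np.asarray(weights, dtype=np.float64)
            g.create_dataset("weight", data=w)
        g = f.create_group("pixels")
        g.create_dataset("bin1_id", data=b1)
        g.create_dataset("bin2_id", data=b2)
        g.create_dataset("count", data=count)
        g = f.create_group("indexes")
        g.create_dataset(
            "chrom_offset", data=np.array([0, nbins_total], dtype=np.int64)
        )
        bin1_offset = np.searchsorted(b1, np.arange(nbins_total + 1), side="left")
        g.create_dataset("bin1_offset", data=bin1_offset.astype(np.int64))
    return path


def write_dense_text(path: str | os.PathLike, matrix: ContactMatrix | np.ndarray) -> str:
    values = matrix.values if isinstance(matrix, ContactMatrix) else np.asarray(matrix)
    np.savetxt(os.fspath(path), values, fmt="%.10g")
    return os.fspath(path)


# ---------------------------------------------------------------------------
# 1D tracks
# ---------------------------------------------------------------------------

_BIGWIG_EXTS = {".bw", ".bigwig"}


def read_track(source: str | os.PathLike, region: GenomicRegion, name: str | None = None) -> BinnedTrack:
    """Bin a bigWig or bedGraph signal onto the region's grid.

    Each bin's value is the per-base average over the *full* bin width, with
    uncovered bases inside a partially covered bin counting as zero; bins with
    no coverage at all are missing (NaN). Negative values are allowed and flag
    the returned track as signed.
    """
    source = os.fspath(source)
    if not os.path.exists(source):
        raise FileNotFoundError(f"track source not found: {source}")
    ext = os.path.splitext(source)[1].lower()
    if name is None:
        name = os.path.splitext(os.path.basename(source))[0]
    if ext in _BIGWIG_EXTS:
        values = _bin_bigwig(source, region)
    else:
        values = _bin_bedgraph(source, region)
    signed = bool(np.nanmin(values) < 0) if not np.all(np.isnan(values)) else False
    return BinnedTrack(region, values, name=name, signed_flag=signed)


def _bin_bigwig(path: str, region: GenomicRegion) -> np.ndarray:
    import pyBigWig

    bw = pyBigWig.open(path)
    try:
        chroms = bw.chroms()
        if region.chrom not in chroms:
            raise ValueError(f"unknown chromosome {region.chrom!r} in {path}")
        if region.end > chroms[region.chrom]:
            raise ValueError(
                f"region {region} extends past chromosome end {chroms[region.chrom]}"
            )
        sums = bw.stats(
            region.chrom, region.start, region.end,
            type="sum", nBins=region.n_bins, exact=True,
        )
    finally:
        bw.close()
    values = np.array(
        [np.nan if s is None else s / region.resolution for s in sums],
        dtype=np.float64,
    )
    return values


def _read_bedgraph_frame(path: str) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep=r"\s+", header=None, comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
        skiprows=_count_header_lines(path),
    )
    if df["value"].isna().any() or df[["start", "end"]].isna().any().any():
        raise ValueError(f"malformed bedGraph {path}: missing fields")
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    df["value"] = df["value"].astype(np.float64)
    return df


def _count_header_lines(path: str) -> int:
    n = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith(("track", "browser")):
                n += 1
            else:
                break
    return n


def _bin_bedgraph(path: str, region: GenomicRegion) -> np.ndarray:
    df = _read_bedgraph_frame(path)
    if region.chrom not in set(df["chrom"]):
        raise ValueError(f"unknown chromosome {region.chrom!r} in {path}")
    sub = df[df["chrom"] == region.chrom]
    starts, ends = sub["start"].to_numpy(), sub["end"].to_numpy()
    if np.any(starts[1:] < starts[:-1]) or np.any(starts[1:] < ends[:-1]):
        raise ValueError(
            f"bedGraph {path} has unsorted or overlapping intervals on {region.chrom}"
        )
    sums, cov = _accumulate(starts, ends, sub["value"].to_numpy(), region)
    values = sums / region.resolution
    values[cov == 0] = np.nan
    return values


def _accumulate(
    starts: np.ndarray, ends: np.ndarray, vals: np.ndarray, region: GenomicRegion
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin sum(value * overlap) and covered-base counts for clipped intervals."""
    n, res, r0 = region.n_bins, region.resolution, region.start
    sums = np.zeros(n)
    cov = np.zeros(n)
    for s, e, v in zip(starts, ends, vals):
        s, e = max(int(s), r0), min(int(e), region.end)
        if s >= e:
            continue
        b0 = (s - r0) // res
        b1 = (e - 1 - r0) // res
        for b in range(b0, b1 + 1):
            lo = max(s, r0 + b * res)
            hi = min(e, r0 + (b + 1) * res)
            sums[b] += v * (hi - lo)
            cov[b] += hi - lo
    return sums, cov


def bed_to_track(source: str | os.PathLike, region: GenomicRegion, name: str | None = None) -> BinnedTrack:
    """Convert a BED3+ interval file to a per-bin coverage-fraction track.

    Equivalent to reading a bedGraph whose every interval has value 1, except
    that bins untouched by any interval are 0 rather than missing. Overlapping
    intervals are unioned first, so values stay in [0, 1].
    """
    source = os.fspath(source)
    if not os.path.exists(source):
        raise FileNotFoundError(f"BED source not found: {source}")
    if name is None:
        name = os.path.splitext(os.path.basename(source))[0]
    rows = []
    with open(source) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"malformed BED line {lineno} in {source}: {line!r}")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2])))
            except ValueError as exc:
                raise ValueError(
                    f"malformed BED line {lineno} in {source}: {line!r}"
                ) from exc
    ivals = sorted((s, e) for c, s, e in rows if c == region.chrom)
    merged: list[list[int]] = []
    for s, e in ivals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    if merged:
        starts = np.array([m[0] for m in merged])
        ends = np.array([m[1] for m in merged])
        sums, _ = _accumulate(starts, ends, np.ones(len(merged)), region)
    else:
        sums = np.zeros(region.n_bins)
    return BinnedTrack(region, sums / region.resolution, name=name)


# ---------------------------------------------------------------------------
# chromHMM
# ---------------------------------------------------------------------------

def read_chromhmm(source: str | os.PathLike, region: GenomicRegion) -> ChromHMMSegmentation:
    """Parse a chromHMM BED9 segmentation, clipped to ``region``.

    The 9th column must be an ``R,G,B`` itemRgb triple. States are collected
    in stable first-seen order among the clipped intervals.
    """
    source = os.fspath(source)
    if not os.path.exists(source):
        raise FileNotFoundError(f"chromHMM source not found: {source}")
    intervals: list[tuple[str, int, int, str, tuple[int, int, int]]] = []
    with open(source) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 9:
                raise ValueError(
                    f"chromHMM line {lineno} in {source} has {len(parts)} fields; "
                    "BED9 with an itemRgb column is required"
                )
            chrom, start, end, label = parts[0], int(parts[1]), int(parts[2]), parts[3]
            try:
                rgb = tuple(int(v) for v in parts[8].split(","))
                if len(rgb) != 3:
                    raise ValueError
            except ValueError as exc:
                raise ValueError(
                    f"unparsable itemRgb {parts[8]!r} at line {lineno} in {source}"
                ) from exc
            if chrom != region.chrom:
                continue
            s, e = max(start, region.start), min(end, region.end)
            if s < e:
                intervals.append((chrom, s, e, label, rgb))  # type: ignore[arg-type]
    return ChromHMMSegmentation(intervals)
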