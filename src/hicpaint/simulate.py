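"""Synthetic Hi-C scenes with planted compartment structure.

The generator emulates the features the rest of the package visualizes: a
distance-decay contact background, a plaid same-state affinity pattern over a
planted per-bin state vector, optional punctate loops, per-mark ChIP-like
tracks that are high on their own state's bins, an eigenvector-like signed
track (positive on A bins, negative on B), and a chromHMM-style segmentation.
Counts are gamma-Poisson (negative-binomial-like) to mimic Hi-C
overdispersion; dispersion 0 switches sampling off entirely so the matrix
equals its mean model.

The default scene has 200 bins at 10 kb: three marks, each high on a planted
20-bin domain (two separated 10-bin blocks, giving the plaid), over a 140-bin
background. Domains are exactly 10% of bins so that the default top-decile
classification threshold falls cleanly between background and domain signal.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

from .io import (
    BinnedTrack,
    ChromHMMSegmentation,
    ContactMatrix,
    write_cool,
    write_dense_text,
)
from .regions import GenomicRegion

__all__ = ["SceneSpec", "Scene", "make_scene", "DEFAULT_LAYOUT"]

# (state, length-in-bins) segments; "bg" is unmarked background chromatin
DEFAULT_LAYOUT: tuple[tuple[str, int], ...] = (
    ("bg", 20), ("A", 10), ("bg", 15), ("B", 10), ("bg", 15), ("A", 10),
    ("bg", 15), ("B", 10), ("bg", 15), ("C", 10), ("bg", 15), ("C", 10),
    ("bg", 45),
)

DEFAULT_MARKS: dict[str, str] = {
    "H3K27ac": "A",   # active chromatin
    "H3K9me3": "B",   # constitutive heterochromatin
    "H3K27me3": "C",  # facultative / Polycomb chromatin
}

DEFAULT_STATE_COLORS: dict[str, tuple[int, int, int]] = {
    "A": (0, 200, 0),
    "B": (128, 0, 180),
    "C": (255, 165, 0),
    "bg": (200, 200, 200),
}


def _default_affinity() -> dict[frozenset, float]:
    aff: dict[frozenset, float] = {}
    for s in ("A", "B", "C"):
        aff[frozenset([s])] = 1.5
    aff[frozenset(["bg"])] = 0.8
    for s in ("A", "B", "C"):
        aff[frozenset(["bg", s])] = 0.7
    aff[frozenset(["A", "B"])] = 0.3
    aff[frozenset(["A", "C"])] = 0.5
    aff[frozenset(["B", "C"])] = 0.5
    return aff


@dataclass
class SceneSpec:
    """Parameters of a synthetic scene; the defaults are the tested conditions."""

    resolution: int = 10_000
    chrom: str = "chrS"
    seed: int = 0
    layout: tuple[tuple[str, int], ...] = DEFAULT_LAYOUT
    marks: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MARKS))
    affinity: dict[frozenset, float] = field(default_factory=_default_affinity)
    decay_gamma: float = 1.0      # contact decay exponent, (|i-j|+1)^(-gamma)
    depth: float = 100.0          # contact counts at distance 0, same state
    dispersion: float = 0.1       # gamma-Poisson overdispersion; 0 = noise-free
    loops: tuple[tuple[int, int, float], ...] = ()  # (bin_i, bin_j, boost)
    loop_width: float = 1.0       # gaussian loop radius, in bins
    mark_high: float = 10.0       # mark level on its own state's bins
    mark_low: float = 0.5         # background mark level
    mark_noise: float = 0.2       # sd of half-normal noise added to marks
    eigen_noise: float = 0.05     # sd of noise on the signed compartment track
    state_colors: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_STATE_COLORS)
    )

    @property
    def n_bins(self) -> int:
        return sum(length for _, length in self.layout)

    @property
    def region(self) -> GenomicRegion:
        return GenomicRegion(self.chrom, 0, self.n_bins * self.resolution, self.resolution)

    def state_of_bin(self) -> list[str]:
        states: list[str] = []
        for state, length in self.layout:
            states.extend([state] * length)
        return states


@dataclass
class Scene:
    """A generated scene plus any files written to disk (``paths``)."""

    spec: SceneSpec
    region: GenomicRegion
    contacts: ContactMatrix
    mean: np.ndarray
    mark_tracks: dict[str, BinnedTrack]
    eigen_track: BinnedTrack
    segmentation: ChromHMMSegmentation
    state_of_bin: list[str]
    paths: dict[str, str] = field(default_factory=dict)


def _mean_matrix(spec: SceneSpec, states: list[str]) -> np.ndarray:
    n = spec.n_bins
    idx = np.arange(n)
    decay = (np.abs(idx[:, None] - idx[None, :]) + 1.0) ** (-spec.decay_gamma)
    aff = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            a = spec.affinity[frozenset([states[i], states[j]])]
            aff[i, j] = aff[j, i] = a
    mu = spec.depth * decay * aff
    for (li, lj, boost) in spec.loops:
        bump = boost * np.exp(
            -((idx[:, None] - li) ** 2 + (idx[None, :] - lj) ** 2)
            / (2.0 * spec.loop_width**2)
        )
        mu += bump + bump.T
    return mu


def make_scene(spec: SceneSpec | None = None, outdir: str | os.PathLike | None = None) -> Scene:
    """Generate a scene; optionally write cooler/dense-text/bedGraph/bigWig/BED9
    files into ``outdir`` (recorded in ``Scene.paths``).

    Deterministic for a fixed spec (including seed); with ``dispersion`` 0 the
    contact matrix equals the mean model exactly.
    """
    spec = spec or SceneSpec()
    rng = np.random.default_rng(spec.seed)
    states = spec.state_of_bin()
    region = spec.region
    n = spec.n_bins

    mu = _mean_matrix(spec, states)
    if spec.dispersion > 0:
        iu, ju = np.triu_indices(n)
        lam = rng.gamma(
            shape=1.0 / spec.dispersion, scale=mu[iu, ju] * spec.dispersion
        )
        counts = rng.poisson(lam).astype(np.float64)
        values = np.zeros((n, n))
        values[iu, ju] = counts
        values[ju, iu] = counts
    else:
        values = mu.copy()
    contacts = ContactMatrix(region, values, normalization_tag="raw")

    state_arr = np.array(states)
    mark_tracks: dict[str, BinnedTrack] = {}
    for mark, state in spec.marks.items():
        base = np.where(state_arr == state, spec.mark_high, spec.mark_low)
        noise = np.abs(rng.normal(0.0, spec.mark_noise, size=n))
        mark_tracks[mark] = BinnedTrack(region, base + noise, name=mark)

    eig = (
        (state_arr == "A").astype(float)
        - (state_arr == "B").astype(float)
        + rng.normal(0.0, spec.eigen_noise, size=n)
    )
    eigen_track = BinnedTrack(region, eig, name="eigen", signed_flag=True)

    intervals = []
    pos = 0
    for state, length in spec.layout:
        s, e = pos * spec.resolution, (pos + length) * spec.resolution
        intervals.append((spec.chrom, s, e, state, spec.state_colors[state]))
        pos += length
    segmentation = ChromHMMSegmentation(intervals)

    scene = Scene(spec, region, contacts, mu, mark_tracks, eigen_track,
                  segmentation, states)
    if outdir is not None:
        scene.paths = _write_scene(scene, os.fspath(outdir))
    return scene


def _write_bedgraph(path: str, track: BinnedTrack) -> str:
    region = track.region
    with open(path, "w") as fh:
        for k, v in enumerate(track.values):
            if np.isnan(v):
                continue
            fh.write(
                f"{region.chrom}\t{region.bin_start(k)}\t"
                f"{region.bin_start(k) + region.resolution}\t{v:.6g}\n"
            )
    return path


def _write_bigwig(path: str, track: BinnedTrack) -> str:
    import pyBigWig

    region = track.region
    bw = pyBigWig.open(path, "w")
    bw.addHeader([(region.chrom, region.end)])
    keep = ~np.isnan(track.values)
    starts = [int(region.bin_start(k)) for k in np.flatnonzero(keep)]
    ends = [s + region.resolution for s in starts]
    values = [float(v) for v in track.values[keep]]
    bw.addEntries([region.chrom] * len(starts), starts, ends=ends, values=values)
    bw.close()
    return path


def _write_chromhmm(path: str, seg: ChromHMMSegmentation) -> str:
    with open(path, "w") as fh:
        for chrom, s, e, label, rgb in seg.intervals:
            fh.write(
                f"{chrom}\t{s}\t{e}\t{label}\t0\t.\t{s}\t{e}\t"
                f"{rgb[0]},{rgb[1]},{rgb[2]}\n"
            )
    return path


def _write_scene(scene: Scene, outdir: str) -> dict[str, str]:
    os.makedirs(outdir, exist_ok=True)
    paths: dict[str, str] = {}
    paths["cool"] = write_cool(
        os.path.join(outdir, "scene.cool"), scene.region, scene.contacts.values
    )
    paths["dense"] = write_dense_text(
        os.path.join(outdir, "scene_matrix.txt"), scene.contacts
    )
    for mark, track in scene.mark_tracks.items():
        paths[f"{mark}.bedGraph"] = _write_bedgraph(
            os.path.join(outdir, f"{mark}.bedGraph"), track
        )
        paths[f"{mark}.bw"] = _write_bigwig(
            os.path.join(outdir, f"{mark}.bw"), track
        )
    paths["eigen.bedGraph"] = _write_bedgraph(
        os.path.join(outdir, "eigen.bedGraph"), scene.eigen_track
    )
    paths["chromhmm.bed"] = _write_chromhmm(
        os.path.join(outdir, "chromhmm.bed"), scene.segmentation
    )
    return paths
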