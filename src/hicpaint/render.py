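"""Assemble color layers into exported images.

A :class:`RenderSpec` describes one scene end to end: where the contact
matrix comes from, the normalization chain (balance -> distance normalization
-> unit scaling), the tracks with their colors and flags, the coloring mode,
and the output file. :func:`render` executes it deterministically — the same
spec always produces byte-identical PNG output.

PNG output flattens the blended layers over a white background (optionally on
top of a grayscale contact-map underlay whose strength is
``1 - overlay_strength``); SVG output keeps one group per layer with
per-pixel opacity, plus genomic coordinate labels on both axes.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

from .color import (
    BlendedImage,
    ColorLayer,
    WHITE,
    blend_layers,
    chromhmm_layers,
    compose_layer,
    eigen_layers,
    parse_color,
)
from .io import ContactMatrix, bed_to_track, read_chromhmm, read_contact_matrix, read_track
from .regions import GenomicRegion
from .signal import (
    distance_normalize,
    scale_contacts,
    scale_unit,
    signal_matrix,
    signal_matrix_vs,
)

__all__ = ["TrackSpec", "RenderSpec", "build_layers", "render", "write_png", "write_svg"]

MODES = ("individual", "blended", "vs", "eigen", "chromhmm")


@dataclass
class TrackSpec:
    """One 1D input: file path, layer color, and transform flags."""

    path: str
    color: str = "#FF0000"
    use_log: bool = False
    signed: bool = False


@dataclass
class RenderSpec:
    """Everything needed to render one image."""

    region: GenomicRegion
    matrix_path: str
    out_path: str
    tracks: list[TrackSpec] = field(default_factory=list)
    mode: str = "blended"
    balance: bool = False
    distnorm: bool = False
    overlay_strength: float = 1.0
    underlay: bool = False
    chromhmm_path: str | None = None
    chromhmm_states: list[str] | None = None
    eigen_color_b: str = "#0000FF"
    background: str = "#FFFFFF"

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.mode == "vs" and len(self.tracks) != 2:
            raise ValueError("vs mode requires exactly two tracks")
        if self.mode == "individual" and len(self.tracks) != 1:
            raise ValueError("individual mode requires exactly one track")
        if self.mode == "eigen" and len(self.tracks) != 1:
            raise ValueError("eigen mode requires exactly one (signed) track")
        if self.mode == "chromhmm" and not self.chromhmm_path:
            raise ValueError("chromhmm mode requires a segmentation path")
        if self.mode in ("individual", "blended", "vs") and not self.tracks:
            raise ValueError(f"{self.mode} mode requires at least one track")


def _load_track(ts: TrackSpec, region: GenomicRegion):
    ext = os.path.splitext(ts.path)[1].lower()
    if ext == ".bed":
        track = bed_to_track(ts.path, region)
    else:
        track = read_track(ts.path, region)
    if ts.signed:
        track.signed_flag = True
    return track


def load_contacts(spec: RenderSpec) -> ContactMatrix:
    """Read and normalize the contact matrix: balance -> distnorm -> unit scale."""
    contacts = read_contact_matrix(spec.matrix_path, spec.region, balance=spec.balance)
    if spec.distnorm:
        contacts = distance_normalize(contacts)
    return scale_contacts(contacts)


def build_layers(spec: RenderSpec) -> tuple[list[ColorLayer], ContactMatrix]:
    """Execute the pipeline up to (but not including) blending."""
    scaled = load_contacts(spec)
    layers: list[ColorLayer] = []
    if spec.mode in ("individual", "blended"):
        for ts in spec.tracks:
            track = _load_track(ts, spec.region)
            if track.signed_flag:
                raise ValueError(
                    f"track {track.name!r} is signed; use eigen mode for signed tracks"
                )
            s = scale_unit(track, use_log=ts.use_log)
            layers.append(
                compose_layer(signal_matrix(s), scaled, ts.color,
                              spec.overlay_strength, label=track.name)
            )
    elif spec.mode == "vs":
        t1 = _load_track(spec.tracks[0], spec.region)
        t2 = _load_track(spec.tracks[1], spec.region)
        s1 = scale_unit(t1, use_log=spec.tracks[0].use_log)
        s2 = scale_unit(t2, use_log=spec.tracks[1].use_log)
        if isinstance(s1, tuple) or isinstance(s2, tuple):
            raise ValueError("vs mode requires unsigned tracks")
        m = signal_matrix_vs(s1, s2)
        layers.append(
            compose_layer(m, scaled, spec.tracks[0].color, spec.overlay_strength,
                          label=f"{t1.name}_vs_{t2.name}")
        )
    elif spec.mode == "eigen":
        track = _load_track(spec.tracks[0], spec.region)
        track.signed_flag = True
        la, lb = eigen_layers(
            track, scaled, rgb_a=spec.tracks[0].color, rgb_b=spec.eigen_color_b,
            use_log=spec.tracks[0].use_log, overlay_strength=spec.overlay_strength,
        )
        layers.extend([la, lb])
    elif spec.mode == "chromhmm":
        seg = read_chromhmm(spec.chromhmm_path, spec.region)
        layers.extend(
            chromhmm_layers(seg, spec.region, scaled, states=spec.chromhmm_states,
                            overlay_strength=spec.overlay_strength)
        )
    return layers, scaled


def _underlay_alpha(scaled: ContactMatrix, overlay_strength: float) -> np.ndarray:
    """Grayscale contact underlay opacity: (1 - strength) * c * 255."""
    c = np.nan_to_num(scaled.values, nan=0.0)
    return (1.0 - overlay_strength) * c * 255.0


def _flatten(
    blended: BlendedImage,
    spec: RenderSpec,
    scaled: ContactMatrix,
) -> np.ndarray:
    bg = np.asarray(parse_color(spec.background), dtype=np.float64)
    n = blended.alpha.shape[0]
    out = np.broadcast_to(bg, (n, n, 3)).astype(np.float64)
    if spec.underlay:
        ua = (_underlay_alpha(scaled, spec.overlay_strength) / 255.0)[..., None]
        out = out * (1.0 - ua)  # composite black underlay
    a = blended.alpha.astype(np.float64)[..., None] / 255.0
    out = out * (1.0 - a) + blended.rgb_channels.astype(np.float64) * a
    return np.floor(out + 0.5).astype(np.uint8)


def write_png(path: str, blended: BlendedImage, spec: RenderSpec, scaled: ContactMatrix) -> str:
    img = Image.fromarray(_flatten(blended, spec, scaled), mode="RGB")
    img.save(path, format="PNG")  # no metadata -> byte-stable output
    return path


def _svg_rects(alpha: np.ndarray, indent: str = "    ") -> list[str]:
    rows = []
    ii, jj = np.nonzero(alpha)
    a = alpha[ii, jj]
    for i, j, av in zip(ii, jj, a):
        # x = column (j), y = row (i): square full-matrix orientation
        rows.append(
            f'{indent}<rect x="{j}" y="{i}" width="1" height="1" '
            f'fill-opacity="{av / 255.0:.4f}"/>'
        )
    return rows


def write_svg(
    path: str,
    layers: list[ColorLayer],
    spec: RenderSpec,
    scaled: ContactMatrix,
) -> str:
    n = spec.region.n_bins
    margin = 6  # bin-units reserved for coordinate labels
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        f'<svg xmlns="http://www.w3.org/2000/svg" viewBox="0 0 {n + margin} {n + margin}" '
        f'width="{(n + margin) * 4}" height="{(n + margin) * 4}">',
        f'<g transform="translate({margin},0)">',
        f'  <rect x="0" y="0" width="{n}" height="{n}" fill="none" '
        'stroke="#000000" stroke-width="0.2"/>',
    ]
    if spec.underlay:
        ua = np.floor(_underlay_alpha(scaled, spec.overlay_strength) + 0.5).astype(np.uint8)
        lines.append('  <g id="underlay" fill="#000000">')
        lines.extend(_svg_rects(ua))
        lines.append("  </g>")
    for k, ly in enumerate(layers):
        hexcolor = "#{:02X}{:02X}{:02X}".format(*ly.rgb)
        lines.append(f'  <g id="layer-{k}-{ly.label}" fill="{hexcolor}">')
        lines.extend(_svg_rects(ly.alpha))
        lines.append("  </g>")
    # genomic coordinates on both axes
    lines.append('  <g id="axes" font-size="2" fill="#000000">')
    for frac in (0.0, 0.25, 0.5, 0.75, 1.0):
        b = int(round(frac * n))
        pos = spec.region.start + b * spec.region.resolution
        label = f"{spec.region.chrom}:{pos}"
        lines.append(f'    <text x="{b}" y="{n + 3}" text-anchor="middle">{label}</text>')
        lines.append(
            f'    <text x="-1" y="{b}" text-anchor="end" dominant-baseline="middle">'
            f"{label}</text>"
        )
    lines.append("  </g>")
    lines.append("</g>")
    lines.append("</svg>")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path


def render(spec: RenderSpec) -> str:
    """Run the full pipeline for ``spec`` and write the image file.

    The output format follows the ``out_path`` extension (.png or .svg).
    """
    layers, scaled = build_layers(spec)
    ext = os.path.splitext(spec.out_path)[1].lower()
    if ext == ".png":
        blended = blend_layers(layers, background=parse_color(spec.background))
        return write_png(spec.out_path, blended, spec, scaled)
    if ext == ".svg":
        return write_svg(spec.out_path, layers, spec, scaled)
    raise ValueError(f"unsupported output format {ext!r}; use .png or .svg")
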