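"""RGBA layer construction and alpha blending.

Each 1D signal yields one translucent layer of a single color whose per-pixel
opacity is the signal matrix weighted by contact intensity,
``alpha = round(m * c * strength * 255)``. Layers are combined by linear
interpolation: per pixel, each layer's blend ratio is its share of the total
alpha, mixed channels are the ratio-weighted sum of layer colors, and the
final alpha is the total clipped to the 8-bit maximum.

Rounding to 8 bits happens exactly once per quantity (half away from zero);
blending itself works in real-valued ratios, which keeps the result exactly
invariant under reordering of the layer list.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import ImageColor

from .io import BinnedTrack, ChromHMMSegmentation, ContactMatrix
from .regions import GenomicRegion
from .signal import SignalMatrix, scale_unit, signal_matrix

__all__ = [
    "ColorLayer",
    "BlendedImage",
    "parse_color",
    "compose_layer",
    "blend_layers",
    "eigen_layers",
    "chromhmm_layers",
    "assign_bins_to_states",
]

WHITE = (255, 255, 255)


def parse_color(color: str | tuple[int, int, int]) -> tuple[int, int, int]:
    """Accept '#RRGGBB', common color names, or an (r, g, b) triple."""
    if isinstance(color, str):
        rgb = ImageColor.getrgb(color)[:3]
    else:
        rgb = tuple(int(v) for v in color)
    if len(rgb) != 3 or any(not (0 <= v <= 255) for v in rgb):
        raise ValueError(f"invalid color {color!r}")
    return rgb  # type: ignore[return-value]


def _round_half_away(x: np.ndarray) -> np.ndarray:
    # np.round rounds half to even; the 8-bit conversion here rounds half away
    # from zero (all quantities are nonnegative, so floor(x + 0.5)).
    return np.floor(x + 0.5)


@dataclass
class ColorLayer:
    """One signal rendered as a single-color translucent image.

    ``rgb`` is the layer color; ``alpha`` is an n x n uint8 opacity matrix
    (missing pixels have alpha 0); ``label`` names the source track.
    """

    rgb: tuple[int, int, int]
    alpha: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        self.rgb = parse_color(self.rgb)
        a = np.asarray(self.alpha)
        if np.issubdtype(a.dtype, np.floating):
            if np.nanmin(a) < 0 or np.nanmax(a) > 255:
                raise ValueError("alpha entries must lie in [0, 255]")
            a = np.nan_to_num(a, nan=0.0)
        self.alpha = a.astype(np.uint8)
        if self.alpha.ndim != 2 or self.alpha.shape[0] != self.alpha.shape[1]:
            raise ValueError(f"alpha must be square, got {self.alpha.shape}")

    @property
    def n(self) -> int:
        return self.alpha.shape[0]


@dataclass
class BlendedImage:
    """Mixed color channels plus a combined alpha channel."""

    rgb_channels: np.ndarray  # (n, n, 3) uint8
    alpha: np.ndarray  # (n, n) uint8

    def __post_init__(self) -> None:
        self.rgb_channels = np.asarray(self.rgb_channels, dtype=np.uint8)
        self.alpha = np.asarray(self.alpha, dtype=np.uint8)
        if self.rgb_channels.shape != self.alpha.shape + (3,):
            raise ValueError("rgb_channels and alpha shapes disagree")

    def flatten(self, background: tuple[int, int, int] = WHITE) -> np.ndarray:
        """Composite over an opaque background; returns (n, n, 3) uint8."""
        a = self.alpha.astype(np.float64)[..., None] / 255.0
        bg = np.asarray(background, dtype=np.float64)
        out = bg * (1.0 - a) + self.rgb_channels.astype(np.float64) * a
        return _round_half_away(out).astype(np.uint8)


def compose_layer(
    m: SignalMatrix | np.ndarray,
    c: ContactMatrix,
    rgb: str | tuple[int, int, int],
    overlay_strength: float = 1.0,
    label: str = "",
) -> ColorLayer:
    """Build a layer: alpha[i, j] = round(m[i, j] * c[i, j] * strength * 255).

    ``c`` must be unit-scaled; missing entries in either factor give alpha 0.
    """
    mv = m.values if isinstance(m, SignalMatrix) else np.asarray(m, dtype=np.float64)
    if c.normalization_tag != "unit-scaled":
        raise ValueError(
            f"contact matrix must be unit-scaled (got {c.normalization_tag!r}); "
            "apply scale_contacts first"
        )
    if mv.shape != c.values.shape:
        raise ValueError(f"dimension mismatch: {mv.shape} vs {c.values.shape}")
    if not 0.0 <= overlay_strength <= 1.0:
        raise ValueError(f"overlay_strength must be in [0, 1], got {overlay_strength}")
    prod = mv * c.values * overlay_strength * 255.0
    alpha = _round_half_away(np.nan_to_num(prod, nan=0.0))
    return ColorLayer(parse_color(rgb), alpha, label=label)


def blend_layers(
    layers: list[ColorLayer] | tuple[ColorLayer, ...],
    background: tuple[int, int, int] = WHITE,
) -> BlendedImage:
    """Linear-interpolation blend of one or more layers.

    Per pixel: total = sum of layer alphas; each layer contributes its color
    weighted by alpha / total; output alpha = clip(total, 0, 255). Pixels with
    zero total alpha carry ``background`` with alpha 0.
    """
    if len(layers) == 0:
        raise ValueError("blend_layers requires at least one layer")
    n = layers[0].n
    if any(ly.n != n for ly in layers):
        raise ValueError("layers have mismatched dimensions")
    alphas = np.stack([ly.alpha.astype(np.float64) for ly in layers])
    colors = np.array([ly.rgb for ly in layers], dtype=np.float64)  # (b, 3)
    total = alphas.sum(axis=0)  # (n, n)
    # sum_b rgb_b * alpha_b has an exact integer value, so the single division
    # makes the mix independent of layer order.
    numer = np.einsum("bij,bk->ijk", alphas, colors)
    with np.errstate(invalid="ignore", divide="ignore"):
        mixed = numer / total[..., None]
    rgb = _round_half_away(np.nan_to_num(mixed, nan=0.0)).astype(np.uint8)
    rgb[total == 0] = background
    alpha = np.clip(total, 0, 255).astype(np.uint8)
    return BlendedImage(rgb, alpha)


def eigen_layers(
    eig: BinnedTrack,
    c: ContactMatrix,
    rgb_a: str | tuple[int, int, int] = "#FF0000",
    rgb_b: str | tuple[int, int, int] = "#0000FF",
    use_log: bool = False,
    overlay_strength: float = 1.0,
) -> tuple[ColorLayer, ColorLayer]:
    """Two-color compartment mode for a signed track (eigenvector).

    The positive branch colors A-A interactions with ``rgb_a``, the negative
    branch colors B-B with ``rgb_b``; pixels whose two bins disagree in sign
    are transparent in both layers.
    """
    if not eig.signed_flag:
        raise ValueError(
            f"track {eig.name!r} is not signed; eigen mode needs a signed track"
        )
    pos, neg = scale_unit(eig, use_log=use_log)
    layer_a = compose_layer(signal_matrix(pos), c, rgb_a, overlay_strength,
                            label=f"{eig.name}:A")
    layer_b = compose_layer(signal_matrix(neg), c, rgb_b, overlay_strength,
                            label=f"{eig.name}:B")
    return layer_a, layer_b


def assign_bins_to_states(
    seg: ChromHMMSegmentation, region: GenomicRegion
) -> list[str | None]:
    """Per-bin state assignment by largest base-pair overlap.

    Ties go to the state seen first in file order; bins with no overlap get
    ``None``.
    """
    n = region.n_bins
    order = list(seg.states)
    overlap = np.zeros((n, len(order)))
    for chrom, s, e, label, _ in seg.intervals:
        if chrom != region.chrom:
            continue
        s, e = max(s, region.start), min(e, region.end)
        if s >= e:
            continue
        si = order.index(label)
        b0 = (s - region.start) // region.resolution
        b1 = (e - 1 - region.start) // region.resolution
        for b in range(b0, b1 + 1):
            lo = max(s, region.bin_start(b))
            hi = min(e, region.bin_start(b) + region.resolution)
            overlap[b, si] += hi - lo
    assigned: list[str | None] = []
    for b in range(n):
        if overlap[b].max() == 0:
            assigned.append(None)
        else:
            # argmax returns the first maximum, i.e. first-seen state wins ties
            assigned.append(order[int(np.argmax(overlap[b]))])
    return assigned


def chromhmm_layers(
    seg: ChromHMMSegmentation,
    region: GenomicRegion,
    c: ContactMatrix,
    states: list[str] | None = None,
    overlay_strength: float = 1.0,
) -> list[ColorLayer]:
    """One layer per chromHMM state, colored by the segmentation's own RGB.

    Each bin belongs to the state with the largest overlap; a state's layer is
    the outer product of its binary membership track, contact-weighted. The
    returned layers are ready for :func:`blend_layers`.
    """
    if not seg.intervals:
        raise ValueError("segmentation does not overlap the region")
    if states is None:
        states = list(seg.states)
    missing = [s for s in states if s not in seg.states]
    if missing:
        raise ValueError(f"requested states absent from segmentation: {missing}")
    assigned = assign_bins_to_states(seg, region)
    layers = []
    for state in states:
        member = np.array([1.0 if a == state else 0.0 for a in assigned])
        m = SignalMatrix(np.outer(member, member))
        layers.append(
            compose_layer(m, c, seg.states[state], overlay_strength, label=state)
        )
    return layers
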