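"""Numeric transforms that turn 1D signal and contact maps into unit-scaled
matrices ready for coloring.

The central construction: a scaled 1D signal ``s`` (values in [0, 1] over the
displayed region) becomes a 2D signal matrix via the outer product
``m[i, j] = s[i] * s[j]`` — so a pixel is bright only when *both* of its bins
carry signal. A "vs" variant crosses two different signals,
``m[i, j] = s1[i] * s2[j]``, to highlight interactions whose two anchors are
occupied by different factors.

Scaling is local: min -> 0 and max -> 1 over the region's non-missing values,
optionally after a log(1 + x) transform and/or clamping. Signed tracks (a
compartment eigenvector) are split into a positive and a negative branch;
negatives are multiplied by -1 first and each branch is scaled independently.

Distance normalization divides out the contact-frequency decay with genomic
separation: expected(d) is the mean observed value on diagonal offset d, and
each entry becomes (observed + 1) / (expected + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import BinnedTrack, ContactMatrix

__all__ = [
    "UnitSignal",
    "SignalMatrix",
    "scale_unit",
    "signal_matrix",
    "signal_matrix_vs",
    "scale_contacts",
    "distance_normalize",
]


@dataclass
class UnitSignal:
    """A per-bin signal scaled to [0, 1]; NaN marks missing bins.

    ``branch`` records provenance for signed tracks: ``positive`` /
    ``negative`` branches came from one signed track split at zero (negatives
    negated before any transform); ``unsigned`` is the ordinary case.
    """

    values: np.ndarray
    transform_log: bool = False
    branch: str = "unsigned"
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.branch not in ("unsigned", "positive", "negative"):
            raise ValueError(f"unknown branch {self.branch!r}")
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (finite.min() < -1e-12 or finite.max() > 1 + 1e-12):
            raise ValueError("UnitSignal values must lie in [0, 1]")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class SignalMatrix:
    """n x n outer-product signal matrix with entries in [0, 1]."""

    values: np.ndarray
    mode: str = "standard"  # standard (symmetric) | vs (generally asymmetric)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError(f"signal matrix must be square, got {self.values.shape}")
        if self.mode not in ("standard", "vs"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _minmax(v: np.ndarray) -> np.ndarray:
    """Min-max scale the non-missing entries to [0, 1]; a constant vector maps
    to all zeros (a flat signal carries no local enrichment)."""
    out = v.copy()
    finite = ~np.isnan(out)
    if not finite.any():
        raise ValueError("all values missing; cannot scale")
    lo = out[finite].min()
    hi = out[finite].max()
    if hi == lo:
        out[finite] = 0.0
        return out
    out[finite] = (out[finite] - lo) / (hi - lo)
    return out


def _scale_vector(
    v: np.ndarray,
    use_log: bool,
    clamp: tuple[float, float] | None,
    clamp_percentile: bool,
) -> np.ndarray:
    out = v.astype(np.float64, copy=True)
    finite = ~np.isnan(out)
    if clamp is not None:
        lo, hi = clamp
        if clamp_percentile:
            lo, hi = np.nanpercentile(out, [lo, hi])
        out[finite] = np.clip(out[finite], lo, hi)
    if use_log:
        if finite.any() and out[finite].min() < 0:
            raise ValueError("log transform requires nonnegative values")
        out[finite] = np.log1p(out[finite])
    return _minmax(out)


def scale_unit(
    track: BinnedTrack,
    use_log: bool = False,
    clamp: tuple[float, float] | None = None,
    clamp_percentile: bool = False,
) -> UnitSignal | tuple[UnitSignal, UnitSignal]:
    """Scale a track to [0, 1] over the region's local min and max.

    Pipeline per value: optional clamp (absolute bounds, or percentile bounds
    when ``clamp_percentile``), optional log(1 + x), then min-max. Missing
    values stay missing and never enter the min/max.

    A signed track returns a ``(positive, negative)`` branch pair: negatives
    are multiplied by -1 before transformation, opposite-sign bins enter each
    branch as 0, and the two branches are scaled independently.
    """
    v = track.values
    if np.all(np.isnan(v)):
        raise ValueError(f"track {track.name!r} has no non-missing values")
    if track.signed_flag:
        pos = np.where(np.isnan(v), np.nan, np.maximum(v, 0.0))
        neg = np.where(np.isnan(v), np.nan, np.maximum(-v, 0.0))
        return (
            UnitSignal(_scale_vector(pos, use_log, clamp, clamp_percentile),
                       transform_log=use_log, branch="positive", name=track.name),
            UnitSignal(_scale_vector(neg, use_log, clamp, clamp_percentile),
                       transform_log=use_log, branch="negative", name=track.name),
        )
    return UnitSignal(
        _scale_vector(v, use_log, clamp, clamp_percentile),
        transform_log=use_log, branch="unsigned", name=track.name,
    )


def signal_matrix(s: UnitSignal) -> SignalMatrix:
    """Outer product m[i, j] = s[i] * s[j]; missing factors make missing entries."""
    return SignalMatrix(np.outer(s.values, s.values), mode="standard")


def signal_matrix_vs(s1: UnitSignal, s2: UnitSignal) -> SignalMatrix:
    """Crossed product m[i, j] = s1[i] * s2[j] (signal 1 on rows, 2 on columns)."""
    if len(s1) != len(s2):
        raise ValueError(f"signal lengths differ: {len(s1)} vs {len(s2)}")
    return SignalMatrix(np.outer(s1.values, s2.values), mode="vs")


def scale_contacts(c: ContactMatrix) -> ContactMatrix:
    """Min-max scale the contact map to [0, 1] over its non-missing entries."""
    if np.all(np.isnan(c.values)):
        raise ValueError("contact matrix is entirely missing; cannot scale")
    return ContactMatrix(c.region, _minmax(c.values), normalization_tag="unit-scaled")


def distance_normalize(c: ContactMatrix) -> ContactMatrix:
    """Observed-over-expected normalization, (obs + 1) / (exp + 1).

    expected(d) is the mean of non-missing observed values at diagonal offset
    |d| within the displayed region. Diagonals that are entirely missing keep
    their entries missing.
    """
    v = c.values
    n = v.shape[0]
    out = np.full_like(v, np.nan)
    for d in range(n):
        upper = np.diagonal(v, offset=d)
        lower = np.diagonal(v, offset=-d) if d else upper
        pooled = upper if d == 0 else np.concatenate([upper, lower])
        finite = pooled[~np.isnan(pooled)]
        if finite.size == 0:
            continue
        expected = finite.mean()
        idx = np.arange(n - d)
        out[idx, idx + d] = (v[idx, idx + d] + 1.0) / (expected + 1.0)
        if d:
            out[idx + d, idx] = (v[idx + d, idx] + 1.0) / (expected + 1.0)
    return ContactMatrix(c.region, out, normalization_tag="distnorm")
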