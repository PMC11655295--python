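"""Quantify how exclusively each mark's colored interactions occupy its own
high-signal bins.

Bins are first classified by dominant mark: a bin belongs to mark M when M's
signal is in its top quantile there and no other mark's signal is in its own
top quantile at the same bin (exclusive assignment; ambiguous bins stay
unassigned). Within each class, every layer's alpha values are collected over
the pixels whose two bins share the class, and the matched layer (same mark as
the class) is compared against each other layer with a two-sided Wilcoxon
rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .color import ColorLayer
from .io import BinnedTrack
from .regions import GenomicRegion

__all__ = ["BinClassification", "OverlapQuantResult", "classify_bins", "quantify_overlap"]

UNASSIGNED = "unassigned"


@dataclass
class BinClassification:
    """Per-bin dominant-mark labels; ``class_of_bin`` holds a label or
    ``'unassigned'``."""

    region: GenomicRegion
    labels: list[str]
    class_of_bin: np.ndarray  # dtype=object, entries in labels or UNASSIGNED
    threshold_rule: str = ""

    def bins_of(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.class_of_bin == label)


@dataclass
class OverlapQuantResult:
    """Alpha-value samples per (class, layer) and the rank-sum comparison table.

    ``table`` columns: class, layer, matched, n, median, statistic, p. The
    statistic and p-value compare that layer against the class's matched layer
    (NaN on the matched row itself and for empty classes, which are reported,
    not fatal).
    """

    samples: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_tsv(self, path: str) -> str:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")
        return path


def classify_bins(
    tracks: list[BinnedTrack], quantile: float = 0.9
) -> BinClassification:
    """Assign each bin to the single mark whose signal is high there.

    A mark is "high" at a bin when the bin's value reaches the mark's
    ``quantile`` level over the region (default 0.9, i.e. the top decile).
    Bins high for zero or for several marks are left unassigned.
    """
    if not tracks:
        raise ValueError("classify_bins needs at least one track")
    if not 0.0 < quantile < 1.0:
        raise ValueError(f"quantile must be in (0, 1), got {quantile}")
    region = tracks[0].region
    for t in tracks[1:]:
        if t.region != region:
            raise ValueError(
                f"track {t.name!r} region {t.region} differs from {region}"
            )
    labels = [t.name for t in tracks]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate track names: {labels}")
    n = region.n_bins
    high = np.zeros((len(tracks), n), dtype=bool)
    for k, t in enumerate(tracks):
        if np.all(np.isnan(t.values)):
            raise ValueError(f"track {t.name!r} has no non-missing values")
        thresh = np.nanquantile(t.values, quantile)
        with np.errstate(invalid="ignore"):
            high[k] = t.values >= thresh
    counts = high.sum(axis=0)
    class_of_bin = np.array([UNASSIGNED] * n, dtype=object)
    for k, label in enumerate(labels):
        class_of_bin[high[k] & (counts == 1)] = label
    return BinClassification(
        region, labels, class_of_bin,
        threshold_rule=f"top-quantile q={quantile}, exclusive",
    )


def _class_pixels(alpha: np.ndarray, bins: np.ndarray) -> np.ndarray:
    """Alpha values over unordered pixel pairs (i <= j) with both bins in
    ``bins`` — the diagonal included, each pair counted once."""
    sub = alpha[np.ix_(bins, bins)]
    iu, ju = np.triu_indices(len(bins))
    return sub[iu, ju]


def _ranksum(
    matched: np.ndarray,
    other: np.ndarray,
    method: str,
    rng: np.random.Generator,
    n_resamples: int,
) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U of the matched sample).

    ``asymptotic`` uses the normal approximation with tie correction;
    ``permutation`` estimates the p-value by Monte-Carlo resampling of the U
    statistic, for small samples where the approximation is doubtful.
    """
    res = stats.mannwhitneyu(matched, other, alternative="two-sided",
                             method="asymptotic")
    if method == "asymptotic":
        return float(res.statistic), float(res.pvalue)
    if method != "permutation":
        raise ValueError(f"unknown method {method!r}")
    pooled = np.concatenate([matched, other])
    n1 = len(matched)
    observed = float(res.statistic)
    mu = n1 * len(other) / 2.0
    hits = 0
    for _ in range(n_resamples):
        perm = rng.permutation(pooled)
        u = stats.mannwhitneyu(perm[:n1], perm[n1:],
                               alternative="two-sided", method="asymptotic").statistic
        if abs(u - mu) >= abs(observed - mu) - 1e-12:
            hits += 1
    return observed, (hits + 1) / (n_resamples + 1)


def quantify_overlap(
    classification: BinClassification,
    layers: list[ColorLayer],
    method: str = "asymptotic",
    n_resamples: int = 2000,
    rng: np.random.Generator | int | None = None,
) -> OverlapQuantResult:
    """Collect per-layer alpha within each class's interactions and test
    matched vs non-matched layers.

    For class C the pixels are all (i, j) with i <= j and both bins classed C.
    The matched layer is the one whose label equals C; each other layer is
    compared to it with a two-sided rank-sum test. Classes without pixels or
    without a matched layer are reported with NaN statistics.
    """
    if not layers:
        raise ValueError("quantify_overlap needs at least one layer")
    n = classification.region.n_bins
    if any(ly.n != n for ly in layers):
        raise ValueError("layer dimensions do not match the classification region")
    rng = np.random.default_rng(rng)
    by_label = {ly.label: ly for ly in layers}
    result = OverlapQuantResult()
    rows = []
    for cls in classification.labels:
        bins = classification.bins_of(cls)
        for ly in layers:
            vals = (
                _class_pixels(ly.alpha.astype(np.float64), bins)
                if bins.size else np.array([])
            )
            result.samples[(cls, ly.label)] = vals
        matched = by_label.get(cls)
        matched_vals = result.samples.get((cls, cls), np.array([]))
        for ly in layers:
            vals = result.samples[(cls, ly.label)]
            is_matched = matched is not None and ly.label == cls
            if (
                is_matched
                or matched is None
                or matched_vals.size == 0
                or vals.size == 0
            ):
                statistic, p = np.nan, np.nan
            else:
                statistic, p = _ranksum(matched_vals, vals, method, rng, n_resamples)
            rows.append({
                "class": cls,
                "layer": ly.label,
                "matched": is_matched,
                "n": int(vals.size),
                "median": float(np.median(vals)) if vals.size else np.nan,
                "statistic": statistic,
                "p": p,
            })
    result.table = pd.DataFrame(rows)
    return result
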