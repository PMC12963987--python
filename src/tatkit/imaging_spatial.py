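"""Autoradiography-immunofluorescence co-registration, block-parametric
spatial correlation, and immune-cell (CD45) area quantification.

The spatial-correlation statistic tiles both registered images into
non-overlapping square blocks (default 20 x 20 pixels of the
autoradiography grid), averages gray values per block, and reports the
Pearson correlation R of the two block-mean vectors.  Autoradiographs
are photographically inverted before overlay so that high signal maps to
high gray value in both modalities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from skimage.filters import threshold_otsu
from skimage.transform import resize

from .core_io import GrayImage


@dataclass
class ImagePair:
    """A registered (inverted autoradiograph, resampled IF) image pair."""

    autorad: GrayImage
    fluor: GrayImage
    scale_factors: tuple[float, float] = (1.0, 1.0)
    inverted: bool = False
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.autorad.shape != self.fluor.shape:
            raise ValueError("registered pair must share one pixel grid")


@dataclass
class BlockCorrelationResult:
    block_size: int
    n_blocks: int
    block_means_autorad: np.ndarray
    block_means_fluor: np.ndarray
    r: float
    coefficient: str = "pearson"
    n_excluded: int = 0
    exclusion_reason: str | None = None

    def __post_init__(self) -> None:
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError("correlation outside [-1, 1]")


@dataclass
class Cd45Snapshot:
    mouse: str
    group: str
    positive_fraction_pct: float
    threshold: float


def register_pair(autorad: GrayImage, fluor: GrayImage,
                  aspect_tolerance: float = 0.05,
                  invert_autorad: bool = True) -> ImagePair:
    """Register an IF image onto an autoradiograph's grid.

    The IF image is bicubically resampled to the autoradiograph's shape
    (the coarser modality) and the autoradiograph is inverted
    (``max_gray - pixel``) so that signal is bright in both images.
    Consecutive tissue sections are not pixel-identical, so an
    aspect-ratio mismatch beyond tolerance is recorded as a warning, not
    an error.
    """
    notes: list[str] = []
    ha, wa = autorad.shape
    hf, wf = fluor.shape
    aspect_a, aspect_f = wa / ha, wf / hf
    if abs(aspect_a - aspect_f) / aspect_a > aspect_tolerance:
        msg = (f"aspect-ratio mismatch: autoradiograph {aspect_a:.3f} vs "
               f"IF {aspect_f:.3f}; resampling anisotropically")
        warnings.warn(msg, stacklevel=2)
        notes.append(msg)
    if fluor.shape != autorad.shape:
        resampled = resize(fluor.pixels, autorad.shape, order=3,
                           preserve_range=True, anti_aliasing=False)
        resampled = np.clip(resampled, 0.0, None)
    else:
        resampled = fluor.pixels.copy()
    auto = autorad.inverted() if invert_autorad else autorad
    return ImagePair(
        autorad=auto,
        fluor=GrayImage(resampled, fluor.bit_depth, fluor.pixel_size_um),
        scale_factors=(ha / hf, wa / wf),
        inverted=invert_autorad,
        warnings=notes,
    )


def _block_means(arr: np.ndarray, b: int) -> np.ndarray:
    """Means of non-overlapping b x b tiles; partial edge tiles dropped."""
    h, w = arr.shape
    nh, nw = h // b, w // b
    trimmed = arr[: nh * b, : nw * b]
    return trimmed.reshape(nh, b, nw, b).mean(axis=(1, 3)).ravel()


def block_correlation(pair: ImagePair, block_size: int = 20,
                      mask: GrayImage | None = None,
                      coefficient: str = "pearson",
                      pooled_pixels: bool = False) -> BlockCorrelationResult:
    """Block-parametric spatial correlation R of a registered pair.

    Both grids are tiled into non-overlapping ``block_size`` squares
    (partial edge tiles dropped); block-mean gray values are correlated.
    Tiles falling entirely outside the mask are excluded.  With
    ``pooled_pixels`` the per-pixel values of all retained tiles are
    pooled instead of their means (off by default).
    """
    if block_size < 2:
        raise ValueError("block_size must be >= 2")
    a, f = pair.autorad.pixels, pair.fluor.pixels
    h, w = a.shape
    b = block_size
    nh, nw = h // b, w // b
    if mask is not None:
        if mask.shape != a.shape:
            raise ValueError("mask shape must match the registered pair")
        m = mask.pixels[: nh * b, : nw * b] > 0
        tile_cover = m.reshape(nh, b, nw, b).any(axis=(1, 3)).ravel()
    else:
        tile_cover = np.ones(nh * nw, dtype=bool)
    means_a = _block_means(a, b)
    means_f = _block_means(f, b)
    n_excluded = int((~tile_cover).sum())
    means_a, means_f = means_a[tile_cover], means_f[tile_cover]
    if len(means_a) < 3:
        raise ValueError("fewer than 3 usable tiles; cannot report R")
    if pooled_pixels:
        keep = np.repeat(tile_cover.reshape(nh, nw), b, axis=0)
        keep = np.repeat(keep, b, axis=1)
        xa, xf = a[: nh * b, : nw * b][keep], f[: nh * b, : nw * b][keep]
    else:
        xa, xf = means_a, means_f
    if np.std(xa) == 0 or np.std(xf) == 0:
        raise ValueError("zero variance in block means; R undefined")
    if coefficient == "pearson":
        r = float(stats.pearsonr(xa, xf).statistic)
    elif coefficient == "spearman":
        r = float(stats.spearmanr(xa, xf).statistic)
    else:
        raise ValueError(f"unknown coefficient {coefficient!r}")
    return BlockCorrelationResult(
        block_size=b, n_blocks=len(means_a),
        block_means_autorad=means_a, block_means_fluor=means_f,
        r=r, coefficient=coefficient, n_excluded=n_excluded,
        exclusion_reason="outside mask" if n_excluded else None,
    )


def cd45_fraction(cd45: GrayImage, tumor_mask: GrayImage,
                  threshold: float | str = "otsu",
                  mouse: str = "", group: str = "") -> Cd45Snapshot:
    """Positive-area fraction (%) of an immune-cell stain inside the
    tumor mask.

    ``threshold`` is either a gray value or ``"otsu"``, in which case
    Otsu's method is applied to the in-mask pixels — a stated,
    reproducible replacement for manual thresholding above background.
    """
    if cd45.shape != tumor_mask.shape:
        raise ValueError("stain and mask must share one pixel grid")
    inside = tumor_mask.pixels > 0
    if not inside.any():
        raise ValueError("empty tumor mask")
    vals = cd45.pixels[inside]
    if threshold == "otsu":
        cut = float(threshold_otsu(vals))
    else:
        cut = float(threshold)
    frac = 100.0 * float(np.count_nonzero(vals > cut)) / vals.size
    return Cd45Snapshot(mouse=mouse, group=group,
                        positive_fraction_pct=frac, threshold=cut)


def summarize_cd45(snapshots: pd.DataFrame, min_snapshots: int = 10,
                   comparisons: list[tuple[str, str]] | None = None
                   ) -> dict:
    """Group-level CD45 analysis with the mouse as the analysis unit.

    Mice with fewer than ``min_snapshots`` snapshots are excluded, then
    groups with fewer than 2 remaining mice are dropped with a warning.
    One-way ANOVA across groups on the per-mouse means, followed by
    Sidak-adjusted pairwise t-tests (pooled within-group variance) over
    the configured comparison set (default: all pairs).
    """
    counts = snapshots.groupby("mouse").size()
    excluded_mice = counts.index[counts < min_snapshots].tolist()
    kept = snapshots[~snapshots["mouse"].isin(excluded_mice)]
    mouse_means = (kept.groupby(["group", "mouse"])["positive_fraction_pct"]
                   .mean().reset_index())
    dropped_groups = []
    for g, sub in mouse_means.groupby("group"):
        if len(sub) < 2:
            dropped_groups.append(g)
            warnings.warn(f"group {g!r} has < 2 mice after snapshot filter; "
                          "excluded", stacklevel=2)
    mouse_means = mouse_means[~mouse_means["group"].isin(dropped_groups)]
    groups = sorted(mouse_means["group"].unique())
    if len(groups) < 2:
        raise ValueError("need >= 2 groups after exclusions")
    arrays = {g: mouse_means.loc[mouse_means["group"] == g,
                                 "positive_fraction_pct"].to_numpy()
              for g in groups}
    samples = [arrays[g] for g in groups]
    if np.ptp(np.concatenate(samples)) == 0:
        f_stat, p_anova = 0.0, 1.0  # degenerate all-identical case
    else:
        f_stat, p_anova = stats.f_oneway(*samples)
    # pooled within-group variance for the pairwise comparisons
    n_total = sum(len(v) for v in samples)
    df_within = n_total - len(groups)
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in samples)
    mse = ss_within / df_within if df_within > 0 else 0.0
    if comparisons is None:
        comparisons = [(groups[i], groups[j])
                       for i in range(len(groups))
                       for j in range(i + 1, len(groups))]
    m = len(comparisons)
    pairwise = []
    for ga, gb in comparisons:
        a, b = arrays[ga], arrays[gb]
        se = np.sqrt(mse * (1 / len(a) + 1 / len(b)))
        if se == 0:
            p = 1.0 if a.mean() == b.mean() else 0.0
            tval = 0.0 if a.mean() == b.mean() else np.inf
        else:
            tval = (a.mean() - b.mean()) / se
            p = 2 * stats.t.sf(abs(tval), df_within)
        pairwise.append({
            "pair": (ga, gb), "t": float(tval), "p_raw": float(p),
            "p_sidak": float(1 - (1 - p) ** m),
        })
    return {
        "mouse_means": mouse_means,
        "group_means": {g: float(arrays[g].mean()) for g in groups},
        "anova_F": float(f_stat),
        "anova_p": float(p_anova),
        "pairwise": pairwise,
        "excluded_mice": excluded_mice,
        "excluded_groups": dropped_groups,
    }


__all__ = [
    "BlockCorrelationResult",
    "Cd45Snapshot",
    "ImagePair",
    "block_correlation",
    "cd45_fraction",
    "register_pair",
    "summarize_cd45",
]
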