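"""Per-nucleus colocalization quantification for multi-channel explant images.

The pipeline mirrors a standard Fiji-based workflow for calling transcript /
protein double-positive nuclei in maximum-intensity projections:

1. the nuclear (DAPI) channel is binarized with Bernsen's local contrast
   threshold and connected clusters of at least ``min_size`` pixels are kept
   as nuclei;
2. the signal channels (here nascent *pax3* transcript and Sox3 protein) are
   binarized with the Renyi-entropy automatic histogram threshold;
3. nuclei are scored positive per channel, regions of a fixed number of
   nuclei are sampled, and the fraction of pax3-positive nuclei that are also
   Sox3-positive is reported per region, then summarized per stage with
   Tukey outlier flags.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

logger = logging.getLogger(__name__)

CHANNELS = ("dapi", "sox3", "pax3")


class PackingError(RuntimeError):
    """Raised by the image generator when nuclei cannot be packed."""


@dataclass
class ImageStack:
    """Named 2D channels of one explant image (equal shapes, intensities >= 0)."""

    dapi: np.ndarray
    sox3: np.ndarray
    pax3: np.ndarray
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        shapes = {c: getattr(self, c).shape for c in CHANNELS}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel shapes differ: {shapes}")
        for c in CHANNELS:
            arr = np.asarray(getattr(self, c))
            if arr.ndim != 2:
                raise ValueError(f"channel {c!r} is not 2D")
            if arr.min() < 0:
                raise ValueError(f"channel {c!r} has negative intensities")
            setattr(self, c, arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.dapi.shape

    def channel(self, name: str) -> np.ndarray:
        if name not in CHANNELS:
            raise KeyError(f"unknown channel {name!r}")
        return getattr(self, name)


@dataclass
class ColocConfig:
    """Tunable knobs of the quantification pipeline.

    Defaults follow the widely used parameterization of the underlying
    algorithms: Bernsen radius 15 px with contrast threshold 15, a 20-px
    minimum nucleus size, 8-connectivity, and a 10% per-nucleus positivity
    rule (a nucleus is channel-positive when at least ``pos_frac`` of its
    pixels exceed that channel's Renyi-entropy threshold).
    """

    bernsen_radius: int = 15
    bernsen_contrast: float = 15.0
    min_size: int = 20
    connectivity: int = 8
    pos_frac: float = 0.10
    bit_depth: int = 8
    n_bins: int = 256


def image_histogram(image: np.ndarray, n_bins: int = 256, bit_depth: int = 8) -> np.ndarray:
    """Integer-binned intensity histogram over the full bit-depth range."""
    max_val = 2**bit_depth - 1
    vals = np.clip(np.asarray(image).ravel(), 0, max_val)
    scaled = np.floor(vals * n_bins / (max_val + 1)).astype(np.int64)
    return np.bincount(scaled, minlength=n_bins)


def _renyi_phi(p: np.ndarray, cum: np.ndarray, t: int, alpha: float) -> float:
    """Renyi entropy sum of the two classes split strictly above bin t."""
    p1, p2 = cum[t], 1.0 - cum[t]
    fg = p[t + 1 :]
    bg = p[: t + 1]
    if alpha == 1.0:
        # Shannon limit (Kapur's maximum-entropy criterion)
        b = bg[bg > 0] / p1
        f = fg[fg > 0] / p2
        return float(-(b * np.log(b)).sum() - (f * np.log(f)).sum())
    ia = 1.0 / (1.0 - alpha)
    return float(ia * np.log(((bg / p1) ** alpha).sum()) + ia * np.log(((fg / p2) ** alpha).sum()))


def _renyi_argmax(p: np.ndarray, cum: np.ndarray, alpha: float) -> int:
    # valid splits leave occupied bins on both sides (exact, not float-based)
    occupied = np.flatnonzero(p > 0)
    best_t, best_val = -1, -np.inf
    for t in range(occupied[0], occupied[-1]):
        val = _renyi_phi(p, cum, t, alpha)
        if val > best_val:
            best_val, best_t = val, t
    return best_t


def renyi_entropy_threshold(
    histogram: np.ndarray, alpha_set: tuple[float, ...] = (1.0, 0.5, 2.0)
) -> tuple[int, bool]:
    """Combined Renyi-entropy threshold of a histogram.

    For each order alpha the threshold maximizing the summed foreground +
    background Renyi entropies is found by exhaustive scan; the three
    per-alpha optima are then merged with the Sahoo weighting rule (the same
    combination used by the popular "RenyiEntropy" auto-threshold).
    Foreground is *strictly above* the returned threshold.

    Returns ``(threshold, degenerate)``; ``degenerate`` is True when the
    histogram has fewer than two occupied bins, in which case the single
    occupied bin is returned (zero foreground).
    """
    h = np.asarray(histogram, dtype=float)
    if h.ndim != 1 or len(h) < 2:
        raise ValueError("histogram must be a 1D array with >= 2 bins")
    if h.sum() <= 0:
        raise ValueError("histogram is empty")
    occupied = np.flatnonzero(h > 0)
    if len(occupied) < 2:
        warnings.warn("histogram has a single occupied bin; zero foreground", stacklevel=2)
        return int(occupied[0]), True

    p = h / h.sum()
    cum = np.cumsum(p)
    t_stars = sorted(_renyi_argmax(p, cum, a) for a in alpha_set)
    t1, t2, t3 = t_stars

    # Sahoo weighting of the three per-alpha optima
    if abs(t1 - t2) <= 5:
        if abs(t2 - t3) <= 5:
            b1, b2, b3 = 1, 2, 1
        else:
            b1, b2, b3 = 0, 1, 3
    else:
        if abs(t2 - t3) <= 5:
            b1, b2, b3 = 3, 1, 0
        else:
            b1, b2, b3 = 1, 2, 1

    omega = cum[t3] - cum[t1]
    thr = int(
        t1 * (cum[t1] + 0.25 * omega * b1)
        + 0.25 * t2 * omega * b2
        + t3 * (1.0 - cum[t3] + 0.25 * omega * b3)
    )
    return thr, False


def bernsen_local_threshold(
    image: np.ndarray,
    radius: int = 15,
    contrast_threshold: float = 15.0,
    bit_depth: int = 8,
) -> np.ndarray:
    """Bernsen local mid-gray threshold.

    Per pixel: local min/max over the (2r+1)^2 edge-clamped window; where the
    local contrast (max - min) reaches ``contrast_threshold`` the pixel is
    foreground iff its intensity >= local mid-gray; low-contrast windows are
    assigned wholesale by whether the local mid-gray reaches the global
    mid-gray of the bit depth.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    img = np.asarray(image, dtype=float)
    size = 2 * radius + 1
    lo = ndimage.minimum_filter(img, size=size, mode="nearest")
    hi = ndimage.maximum_filter(img, size=size, mode="nearest")
    mid = (lo + hi) / 2.0
    global_mid = (2**bit_depth - 1) / 2.0
    high_contrast = (hi - lo) >= contrast_threshold
    mask = np.where(high_contrast, img >= mid, mid >= global_mid)
    return mask.astype(bool)


_STRUCTS = {
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], bool),
    8: np.ones((3, 3), bool),
}


def label_components(mask: np.ndarray, connectivity: int = 8, min_size: int = 20) -> np.ndarray:
    """Connected components of a binary mask, size-filtered and relabeled densely.

    Components smaller than ``min_size`` pixels are discarded; surviving
    components are renumbered 1..K in scan order.
    """
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be 4 or 8")
    labels, n = ndimage.label(np.asarray(mask, bool), structure=_STRUCTS[connectivity])
    if n == 0:
        return labels
    sizes = np.bincount(labels.ravel())
    keep = np.flatnonzero(sizes >= min_size)
    keep = keep[keep > 0]
    remap = np.zeros(n + 1, dtype=labels.dtype)
    remap[keep] = np.arange(1, len(keep) + 1)
    return remap[labels]


def call_nuclei(stack: ImageStack, cfg: ColocConfig | None = None) -> pd.DataFrame:
    """Segment nuclei from DAPI and score pax3/Sox3 positivity per nucleus.

    Returns a NucleusTable DataFrame with columns
    ``id, row, col, area, pax3_positive, sox3_positive``.
    """
    cfg = cfg or ColocConfig()
    mask = bernsen_local_threshold(
        stack.dapi, cfg.bernsen_radius, cfg.bernsen_contrast, cfg.bit_depth
    )
    labels = label_components(mask, cfg.connectivity, cfg.min_size)
    n = labels.max()
    if n == 0:
        warnings.warn("no nuclei found", stacklevel=2)
        return pd.DataFrame(
            columns=["id", "row", "col", "area", "pax3_positive", "sox3_positive"]
        )

    ids = np.arange(1, n + 1)
    areas = np.bincount(labels.ravel())[1:]
    centroids = ndimage.center_of_mass(np.ones_like(labels), labels, ids)
    rows, cols = zip(*centroids)

    table = pd.DataFrame({"id": ids, "row": rows, "col": cols, "area": areas})
    max_val = 2**cfg.bit_depth - 1
    for channel in ("pax3", "sox3"):
        img = stack.channel(channel)
        hist = image_histogram(img, cfg.n_bins, cfg.bit_depth)
        thr_bin, degenerate = renyi_entropy_threshold(hist)
        thr = thr_bin * (max_val + 1) / cfg.n_bins  # bin index -> intensity
        logger.info("channel %s: Renyi threshold %s (degenerate=%s)", channel, thr, degenerate)
        above = ndimage.sum_labels((img > thr).astype(float), labels, ids)
        table[f"{channel}_positive"] = (above / areas) >= cfg.pos_frac
    return table


def sample_regions(
    nuclei: pd.DataFrame,
    n_regions: int = 3,
    cells_per_region: int = 50,
    seed: int | np.random.Generator = 0,
) -> dict[int, dict]:
    """Randomly sample spatial regions of a fixed number of nuclei.

    Each region is a uniformly drawn seed nucleus (seeds distinct across
    regions) plus its ``cells_per_region - 1`` nearest neighbours by centroid
    Euclidean distance; ties in distance are broken by the lower nucleus id.
    Regions may overlap. Returns ``{region_id: {"seed_id": id, "members": ids}}``.
    """
    n = len(nuclei)
    if n < cells_per_region:
        raise ValueError(
            f"cannot sample regions of {cells_per_region} cells from {n} nuclei"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nuclei = nuclei.sort_values("id").reset_index(drop=True)
    coords = nuclei[["row", "col"]].to_numpy(float)
    ids = nuclei["id"].to_numpy()
    seed_idx = rng.choice(n, size=n_regions, replace=False)

    regions: dict[int, dict] = {}
    for r, si in enumerate(seed_idx, start=1):
        d = np.hypot(*(coords - coords[si]).T)
        order = np.lexsort((ids, d))  # distance, then lower id
        members = ids[order[:cells_per_region]]
        regions[r] = {"seed_id": int(ids[si]), "members": set(int(i) for i in members)}
    return regions


def colocalization_fraction(nuclei: pd.DataFrame, regions: dict[int, dict]) -> pd.DataFrame:
    """Per-region double-positive statistic Sox3&pax3++ / total pax3+.

    Regions with no pax3-positive nuclei get fraction NA (excluded from any
    downstream mean) with a logged warning.
    """
    known = set(nuclei["id"].astype(int))
    by_id = nuclei.set_index("id")
    out = []
    for rid, reg in regions.items():
        members = reg["members"]
        missing = members - known
        if missing:
            raise ValueError(f"region {rid} references unknown nuclei: {sorted(missing)[:5]}")
        sub = by_id.loc[sorted(members)]
        n_pax3 = int(sub["pax3_positive"].sum())
        n_sox3 = int(sub["sox3_positive"].sum())
        n_double = int((sub["pax3_positive"] & sub["sox3_positive"]).sum())
        if n_pax3 == 0:
            logger.warning("region %s has no pax3-positive nuclei; fraction is NA", rid)
            frac = np.nan
        else:
            frac = n_double / n_pax3
        out.append(
            dict(region=rid, n_dapi=len(sub), n_pax3=n_pax3, n_sox3=n_sox3,
                 n_double=n_double, fraction=frac)
        )
    return pd.DataFrame(out)


def tukey_outliers(values: np.ndarray) -> np.ndarray:
    """Boolean flags for values outside [Q1 - 1.5*IQR, Q3 + 1.5*IQR]."""
    v = np.asarray(values, float)
    q1, q3 = np.percentile(v, [25, 75])
    iqr = q3 - q1
    return (v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)


def summarize_stages(fractions_by_stage: dict) -> pd.DataFrame:
    """Stage-level summary of region fractions: mean, quartiles, outlier count.

    NA fractions are dropped per stage; a stage with no defined fraction is an
    error (nothing to summarize).
    """
    rows = []
    for stage, values in fractions_by_stage.items():
        v = np.asarray(values, float)
        v = v[~np.isnan(v)]
        if len(v) == 0:
            raise ValueError(f"stage {stage!r} has no defined colocalization fractions")
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        rows.append(
            dict(stage=stage, n=len(v), mean=v.mean(), q1=q1, median=med, q3=q3,
                 n_outliers=int(tukey_outliers(v).sum()))
        )
    return pd.DataFrame(rows)


def max_intensity_projection(zstack: np.ndarray) -> np.ndarray:
    """Maximum-intensity projection over the leading (z) axis."""
    return np.asarray(zstack).max(axis=0)


def read_image_stack(path, channel_order: tuple[str, str, str] = CHANNELS) -> ImageStack:
    """Read a multi-channel TIFF (channels on the leading axis)."""
    arr = tifffile.imread(path)
    if arr.ndim != 3 or arr.shape[0] != 3:
        raise ValueError(f"expected a 3-channel TIFF, got shape {arr.shape}")
    kwargs = {name: arr[i] for i, name in enumerate(channel_order)}
    return ImageStack(**kwargs)


def write_image_stack(path, stack: ImageStack, channel_order: tuple[str, str, str] = CHANNELS) -> None:
    arr = np.stack([stack.channel(c) for c in channel_order]).astype(np.uint16)
    tifffile.imwrite(path, arr, photometric="minisblack")
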