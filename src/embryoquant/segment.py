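"""Embryo mapping from DIC texture and the AB/P1 cell split.

DIC imaging shows fine intracellular texture inside the embryo and a
smooth background outside, so a smoothed local standard-deviation map of
the DIC channel separates embryo from background by Otsu thresholding.
The two touching blastomeres are then split by a distance-transform
watershed where the outline has concave features (the contact neck), or
— for convex outlines where watershed has nothing to grab — by the line
through the centroid along the minor axis of the moment-fitted ellipse.
Identities follow the embryo's stereotyped anatomy: the larger cell is
AB, the smaller is P1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import label as cc_label
from skimage.measure import regionprops
from skimage.morphology import disk
from skimage.segmentation import watershed

from .errors import DegenerateHistogram, ParameterError, SegmentationFailure

AB_LABEL, P1_LABEL = 1, 2


class SplitMethod(str, Enum):
    WATERSHED = "watershed"
    ELLIPSE_MINOR_AXIS = "ellipse_minor_axis"


@dataclass
class CellLabelMap:
    """Per-frame two-cell segmentation.

    ``labels``: 0 background, 1 AB, 2 P1. ``split_axis_angle_deg`` is the
    orientation of the dividing line (degrees from the +x axis, in
    [0, 180)) when the ellipse fallback was used.
    """

    labels: np.ndarray
    split_method: SplitMethod
    areas: dict[int, int] = field(default_factory=dict)
    split_axis_angle_deg: float | None = None

    def __post_init__(self) -> None:
        if not self.areas:
            self.areas = {
                int(l): int((self.labels == l).sum())
                for l in np.unique(self.labels)
                if l != 0
            }

    def mask(self, lbl: int) -> np.ndarray:
        return self.labels == lbl


def local_std_map(
    image: np.ndarray, window_radius: int, smooth_sigma: float = 0.0
) -> np.ndarray:
    """Per-pixel population standard deviation of a (2r+1)^2 neighbourhood.

    Edges are handled by reflect padding (edge pixel included in the
    reflection). With ``smooth_sigma > 0`` the std map is Gaussian
    smoothed before being returned, which is how the embryo-mask stage
    consumes it.
    """
    if window_radius < 1:
        raise ParameterError("window_radius must be >= 1")
    image = np.asarray(image, dtype=float)
    size = 2 * window_radius + 1
    mean = ndi.uniform_filter(image, size=size, mode="reflect")
    mean_sq = ndi.uniform_filter(image * image, size=size, mode="reflect")
    var = np.clip(mean_sq - mean * mean, 0.0, None)
    std = np.sqrt(var)
    if smooth_sigma > 0:
        std = ndi.gaussian_filter(std, smooth_sigma, mode="reflect")
    return std


def _check_histogram(hist: np.ndarray) -> np.ndarray:
    hist = np.asarray(hist, dtype=float)
    if hist.ndim != 1 or (hist < 0).any():
        raise ParameterError("histogram must be a 1D array of non-negative counts")
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogram("histogram has fewer than two occupied bins")
    return hist


def otsu_threshold(hist: np.ndarray) -> int:
    """Otsu's threshold on a histogram of bin counts.

    Returns the bin index t maximizing the between-class variance of the
    split {<= t} / {> t}; pixels strictly above t are foreground. Ties
    resolve to the lowest t.
    """
    hist = _check_histogram(hist)
    bins = np.arange(hist.size, dtype=float)
    w0 = np.cumsum(hist)
    s0 = np.cumsum(hist * bins)
    total, s_total = w0[-1], s0[-1]
    w1 = total - w0
    valid = (w0 > 0) & (w1 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = s0 / w0
        mu1 = (s_total - s0) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between[~valid] = -np.inf
    return int(np.argmax(between))


def quantize_to_8bit(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Min-max rescale to integers 0..255 plus the 256-bin histogram.

    Histogram thresholds are bin-sensitive; fixing the binning here makes
    thresholding reproducible across images of any dynamic range.
    """
    image = np.asarray(image, dtype=float)
    lo, hi = image.min(), image.max()
    if hi == lo:
        raise DegenerateHistogram("constant image cannot be quantized")
    scaled = np.rint((image - lo) / (hi - lo) * 255).astype(np.int64)
    return scaled, np.bincount(scaled.ravel(), minlength=256)


@dataclass(frozen=True)
class EmbryoMaskParams:
    """Knobs of the DIC texture-mapping stage (all in pixels)."""

    window_radius: int = 2
    # 4 px: the local-std estimate of a grainy texture is itself patchy at
    # the window scale; heavier smoothing stops background-level patches
    # inside the embryo from biting into the mask
    smooth_sigma: float = 4.0
    # off by default: speckle is already removed by keeping the largest
    # component, and an opening can sever the thin cell-contact neck
    opening_radius: int = 0
    min_area_fraction: float = 0.05  # of the frame; rejects pure-noise "embryos"
    # foreground must be genuinely more textured than background; pure noise
    # still "splits" under Otsu but with near-unit contrast between the sides
    min_contrast_ratio: float = 2.0


def embryo_mask(
    dic_image: np.ndarray, params: EmbryoMaskParams | None = None
) -> np.ndarray:
    """Binary embryo mask from one DIC frame.

    Smoothed local-std map -> Otsu threshold -> fill holes -> opening ->
    largest 4-connected component. Invariant to constant intensity
    offsets of the input (std maps ignore offsets).
    """
    params = params or EmbryoMaskParams()
    dic_image = np.asarray(dic_image, dtype=float)
    std_map = local_std_map(dic_image, params.window_radius, params.smooth_sigma)
    try:
        scaled, hist = quantize_to_8bit(std_map)
    except DegenerateHistogram as exc:
        raise SegmentationFailure("DIC frame has no texture contrast") from exc
    t = otsu_threshold(hist)
    fg = scaled > t
    if fg.any() and (~fg).any():
        contrast = std_map[fg].mean() / max(std_map[~fg].mean(), 1e-12)
        if contrast < params.min_contrast_ratio:
            raise SegmentationFailure(
                f"foreground/background texture contrast {contrast:.2f} below "
                f"{params.min_contrast_ratio} — no textured region of plausible size"
            )
    fg = ndi.binary_fill_holes(fg)
    if params.opening_radius > 0:
        fg = ndi.binary_opening(fg, structure=disk(params.opening_radius))
    lab, n = cc_label(fg, connectivity=1, return_num=True)
    if n == 0:
        raise SegmentationFailure("no foreground after thresholding")
    sizes = np.bincount(lab.ravel())[1:]
    biggest = int(np.argmax(sizes)) + 1
    if sizes[biggest - 1] < params.min_area_fraction * dic_image.size:
        raise SegmentationFailure(
            "no textured region of plausible embryo size "
            f"(largest component {sizes[biggest - 1]} px)"
        )
    return lab == biggest


def _principal_axes(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Centroid and unit major/minor axes from second-order moments."""
    ys, xs = np.nonzero(mask)
    centroid = np.array([ys.mean(), xs.mean()])
    cov = np.cov(np.stack([ys, xs]))
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, int(np.argmax(evals))]  # (dy, dx) unit vector
    minor = np.array([-major[1], major[0]])
    return centroid, major, minor


def _split_by_minor_axis(mask: np.ndarray) -> tuple[np.ndarray, float]:
    """Divide the mask by the line through its centroid along the fitted
    ellipse's minor axis; returns (labels, split-line angle in degrees)."""
    centroid, major, minor = _principal_axes(mask)
    ys, xs = np.nonzero(mask)
    side = (ys - centroid[0]) * major[0] + (xs - centroid[1]) * major[1]
    labels = np.zeros(mask.shape, dtype=np.uint8)
    labels[ys[side < 0], xs[side < 0]] = 1
    labels[ys[side >= 0], xs[side >= 0]] = 2
    angle = np.degrees(np.arctan2(-minor[0], minor[1])) % 180.0  # image y points down
    return labels, angle


@dataclass(frozen=True)
class SplitParams:
    """Watershed-vs-fallback decision thresholds."""

    # thresholded outlines carry pixel-scale boundary wobble that costs
    # ~0.04-0.06 solidity; 0.92 sits between the convex (~0.93+) and
    # necked/peanut (~0.89-) shape populations at that roughness level
    solidity_threshold: float = 0.92
    min_cell_fraction: float = 0.2
    # None: adaptive, a quarter of sqrt(mask area) — keeps the two seeds in
    # different cells instead of splitting the larger cell across a noisy
    # distance-map plateau
    peak_min_distance: int | None = None
    distance_smooth_sigma: float = 3.0
    # solidity is measured on a morphologically closed copy of the mask so
    # the concavity test responds to the cell-contact neck, not to pixel-scale
    # boundary roughness left by thresholding
    solidity_closing_radius: int = 5


def split_two_cells(
    mask: np.ndarray, params: SplitParams | None = None
) -> CellLabelMap:
    """Split a connected embryo mask into two cells.

    A distance-transform watershed seeded at the two strongest internal
    maxima is attempted first; it counts as successful only if the
    outline has concave features (solidity < solidity_threshold) and it
    yields exactly two regions, each at least ``min_cell_fraction`` of
    the mask. Otherwise the mask is divided by the minor axis of its
    moment-fitted ellipse. Deterministic; labels are provisional (1/2 by
    geometry) until :func:`assign_identities` applies the area rule.
    """
    params = params or SplitParams()
    mask = np.asarray(mask, dtype=bool)
    lab, n = cc_label(mask, connectivity=1, return_num=True)
    if n != 1:
        raise ParameterError(f"mask must be a single connected component (got {n})")

    solidity = _smoothed_solidity(mask, params.solidity_closing_radius)
    if solidity < params.solidity_threshold:
        result = _try_watershed(mask, params)
        if result is not None:
            return CellLabelMap(labels=result, split_method=SplitMethod.WATERSHED)
    labels, angle = _split_by_minor_axis(mask)
    return CellLabelMap(
        labels=labels,
        split_method=SplitMethod.ELLIPSE_MINOR_AXIS,
        split_axis_angle_deg=angle,
    )


def _smoothed_solidity(mask: np.ndarray, closing_radius: int) -> float:
    if closing_radius > 0:
        pad = closing_radius + 1
        padded = np.pad(mask, pad)
        padded = ndi.binary_closing(padded, structure=disk(closing_radius))
        mask = padded[pad:-pad, pad:-pad]
    lab = cc_label(mask, connectivity=1)
    return float(max(r.solidity for r in regionprops(lab)))


def _try_watershed(mask: np.ndarray, params: SplitParams) -> np.ndarray | None:
    dist = ndi.distance_transform_edt(mask)
    smooth = ndi.gaussian_filter(dist, params.distance_smooth_sigma)
    min_dist = params.peak_min_distance
    if min_dist is None:
        min_dist = max(10, int(round(0.25 * np.sqrt(mask.sum()))))
    peaks = peak_local_max(
        smooth,
        min_distance=min_dist,
        labels=mask,
        num_peaks=2,
        exclude_border=False,
    )
    if len(peaks) < 2:
        return None
    markers = np.zeros(mask.shape, dtype=np.int32)
    for i, (py, px) in enumerate(peaks, start=1):
        markers[py, px] = i
    regions = watershed(-smooth, markers, mask=mask)
    counts = np.bincount(regions.ravel(), minlength=3)[1:3]
    if (counts == 0).any() or counts.min() < params.min_cell_fraction * mask.sum():
        return None
    return regions.astype(np.uint8)


def assign_identities(label_map: CellLabelMap, anterior_left: bool = True) -> CellLabelMap:
    """Rename regions so the larger is AB (1) and the smaller P1 (2).

    An exact area tie is broken by centroid x: with the usual
    anterior-left mounting convention the leftmost region is AB (set
    ``anterior_left=False`` to flip).
    """
    labels = label_map.labels
    present = [int(l) for l in np.unique(labels) if l != 0]
    if len(present) != 2:
        raise ParameterError(f"expected exactly 2 regions, got {len(present)}")
    stats = []
    for l in present:
        region = labels == l
        area = int(region.sum())
        cx = float(np.nonzero(region)[1].mean())
        stats.append((l, area, cx))
    a, b = stats
    if a[1] != b[1]:
        ab_old = a[0] if a[1] > b[1] else b[0]
    else:
        leftmost = a[0] if a[2] < b[2] else b[0]
        ab_old = leftmost if anterior_left else (b[0] if leftmost == a[0] else a[0])
    out = np.zeros_like(labels, dtype=np.uint8)
    out[labels == ab_old] = AB_LABEL
    out[(labels > 0) & (labels != ab_old)] = P1_LABEL
    return CellLabelMap(
        labels=out,
        split_method=label_map.split_method,
        split_axis_angle_deg=label_map.split_axis_angle_deg,
    )


def segment_frame(
    dic_image: np.ndarray,
    mask_params: EmbryoMaskParams | None = None,
    split_params: SplitParams | None = None,
) -> CellLabelMap:
    """Full per-frame chain: embryo mask -> split -> identity assignment."""
    mask = embryo_mask(dic_image, mask_params)
    return assign_identities(split_two_cells(mask, split_params))
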