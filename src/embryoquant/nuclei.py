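"""Nucleus detection in the fluorescence channel.

Nuclei are bright blobs on a dimmer cytoplasm. They are segmented from
the maximum-intensity z-projection with a difference-of-Gaussians (DoG)
band-pass followed by Kapur's maximum-entropy threshold on the 8-bit
quantized DoG response. The threshold is computed per cell, on the DoG
histogram restricted to that cell's interior: the two nuclei can differ
several-fold in brightness, and a single global entropy threshold locks
onto the bright nucleus and misses the dim one. The interior excludes a
boundary band one large-sigma wide, where the cytoplasm-to-background
edge produces its own DoG response. Each cell keeps its largest
surviving component, clipped to the cell's region. A cell with no
surviving component has no nucleus in that frame — which is exactly how
nuclear-envelope breakdown manifests, so absence is a result, not an
error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.measure import label as cc_label

from .errors import DegenerateHistogram, ParameterError
from .segment import AB_LABEL, P1_LABEL, CellLabelMap, _check_histogram

CELL_OF_LABEL = {AB_LABEL: "AB", P1_LABEL: "P1"}


@dataclass
class NucleusRecord:
    """One cell's nucleus (or its absence) in one frame."""

    frame: int
    cell: str
    mask: np.ndarray
    area: int
    mean_intensity: float
    present: bool


def max_projection(zstack: np.ndarray) -> np.ndarray:
    """Per-pixel maximum over z of a (Z, Y, X) stack."""
    zstack = np.asarray(zstack)
    if zstack.ndim != 3 or zstack.shape[0] < 1:
        raise ParameterError("zstack must be (Z, Y, X) with at least one slice")
    return zstack.max(axis=0)


def dog_filter(
    image: np.ndarray, sigma_small: float, sigma_large: float
) -> np.ndarray:
    """Difference of Gaussians: blur(small) - blur(large).

    Band-passes blob-like structure between the two scales; constant
    images map to zero everywhere.
    """
    if not 0 < sigma_small < sigma_large:
        raise ParameterError("require 0 < sigma_small < sigma_large")
    image = np.asarray(image, dtype=float)
    return ndi.gaussian_filter(image, sigma_small, mode="reflect") - ndi.gaussian_filter(
        image, sigma_large, mode="reflect"
    )


def kapur_threshold(hist: np.ndarray) -> int:
    """Kapur's maximum-entropy threshold on a histogram of counts.

    Maximizes the sum of Shannon entropies of the below- and
    above-threshold normalized sub-distributions (0*log 0 = 0); pixels
    strictly above the returned bin index are foreground. Ties resolve
    to the lowest index.
    """
    hist = _check_histogram(hist)
    p = hist / hist.sum()
    cum = np.cumsum(p)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
    s = np.cumsum(plogp)
    s_total = s[-1]
    valid = (cum > 0) & (cum < 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        h_below = np.log(cum) - s / cum
        h_above = np.log1p(-cum) - (s_total - s) / (1.0 - cum)
        objective = h_below + h_above
    objective[~valid] = -np.inf
    return int(np.argmax(objective))


@dataclass(frozen=True)
class NucleusParams:
    """Detection knobs.

    DoG sigmas default to (2, 8) px for nuclei of ~6-12 px radius at the
    generator's default scale. Component-size bounds derive from the
    expected nucleus area: [25%, 400%] of pi*r^2.
    """

    sigma_small: float = 2.0
    sigma_large: float = 8.0
    expected_radius_px: float = 10.0
    min_area_fraction: float = 0.25
    max_area_fraction: float = 4.0
    # a candidate must rise above the cell's own intensity spread: mean over
    # the component minus the in-cell median, in robust-sd units. Rejects the
    # speckle the per-cell entropy threshold digs up once the nucleus is gone.
    min_contrast_sigma: float = 4.0

    @property
    def min_area(self) -> int:
        return int(self.min_area_fraction * np.pi * self.expected_radius_px**2)

    @property
    def max_area(self) -> int:
        return int(self.max_area_fraction * np.pi * self.expected_radius_px**2)


def segment_nuclei(
    fluor_zstack: np.ndarray,
    cell_labels: CellLabelMap,
    params: NucleusParams | None = None,
    frame: int = 0,
) -> dict[str, NucleusRecord]:
    """Detect at most one nucleus per cell from a fluorescence z-stack.

    Chain: max projection -> DoG -> per-cell Kapur threshold on the
    quantized in-cell DoG response -> connected components -> size
    filter -> per cell, keep the largest surviving component (ties:
    brighter mean, then lower centroid y). Masks never cross cell
    boundaries.
    """
    params = params or NucleusParams()
    proj = max_projection(fluor_zstack)
    if proj.shape != cell_labels.labels.shape:
        raise ParameterError("fluorescence stack and cell labels disagree in (Y, X)")
    dog = dog_filter(proj, params.sigma_small, params.sigma_large)
    border = max(1, int(np.ceil(params.sigma_large)))

    records: dict[str, NucleusRecord] = {}
    for cell_lbl, cell in CELL_OF_LABEL.items():
        region = cell_labels.labels == cell_lbl
        core = ndi.binary_erosion(region, iterations=border)
        best_mask = None
        best_key = None
        cell_median = float(np.median(proj[region])) if region.any() else 0.0
        mad = (
            float(np.median(np.abs(proj[region] - cell_median))) if region.any() else 0.0
        )
        robust_sd = 1.4826 * mad
        if core.any():
            vals = dog[core]
            lo, hi = vals.min(), vals.max()
            if hi > lo:
                scaled = np.rint((vals - lo) / (hi - lo) * 255).astype(np.int64)
                hist = np.bincount(scaled, minlength=256)
                try:
                    t = kapur_threshold(hist)
                except DegenerateHistogram:
                    t = None
                if t is not None:
                    scaled_img = np.rint((dog - lo) / (hi - lo) * 255)
                    fg = core & (scaled_img > t)
                    comps, n = cc_label(fg, connectivity=1, return_num=True)
                    for cid in range(1, n + 1):
                        piece = comps == cid
                        area = int(piece.sum())
                        if not params.min_area <= area <= params.max_area:
                            continue
                        mean = float(proj[piece].mean())
                        if mean - cell_median < params.min_contrast_sigma * robust_sd:
                            continue
                        cy = float(np.nonzero(piece)[0].mean())
                        key = (area, mean, -cy)  # larger, brighter, lower y
                        if best_key is None or key > best_key:
                            best_key, best_mask = key, piece
        if best_mask is None:
            records[cell] = NucleusRecord(
                frame=frame, cell=cell, mask=np.zeros_like(region),
                area=0, mean_intensity=float("nan"), present=False,
            )
        else:
            records[cell] = NucleusRecord(
                frame=frame, cell=cell, mask=best_mask,
                area=int(best_mask.sum()),
                mean_intensity=float(proj[best_mask].mean()),
                present=True,
            )
    return records
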