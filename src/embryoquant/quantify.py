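"""Background-corrected intensity traces and normalized quantities.

The central measurement is the mean nuclear and cytoplasmic fluorescence
of each cell, corrected by the background estimated outside the embryo,
tracked over time. From these come the asymmetry readouts used in
two-cell embryo work: the per-embryo P1/AB nuclear ratio (with a cohort
mean and 95% CI), normalization of whole traces to the AB cytoplasmic
signal with a designated reference group set to 1, and normalization of
per-cell values to a named reference cell (e.g. ABa at the four-cell
stage). All normalized quantities are invariant to affine changes of
the raw intensity scale: the offset is removed by background correction
and the gain by the normalization itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .errors import (
    BackgroundUnavailable,
    MeasurementError,
    NormalizationError,
    RatioUndefined,
)
from .nuclei import NucleusRecord
from .segment import AB_LABEL, P1_LABEL, CellLabelMap
from .stats import summarize_ci


class Normalization(str, Enum):
    RAW = "raw"
    P1_OVER_AB = "p1_over_ab"
    AB_CYTO_REF = "ab_cyto_ref"
    NAMED_CELL_REF = "named_cell_ref"


@dataclass
class CellSignal:
    """One cell's background-corrected means in one frame (AU).

    ``nuclear`` is NaN when the nucleus is absent (post-NEB); the
    cytoplasmic mean then covers the whole cell, since the protein is
    entirely cytoplasmic after nuclear-envelope breakdown. ``clipped``
    records whether negative corrected values were clipped to 0.
    """

    cell: str
    nuclear: float
    cytoplasmic: float
    nuclear_integrated: float
    cytoplasmic_integrated: float
    nucleus_present: bool
    clipped: bool = False


@dataclass
class IntensityTrace:
    """Per-cell time series of corrected means.

    ``time_s`` = frame index * frame interval; strictly increasing with
    constant step.
    """

    cell: str
    time_s: np.ndarray
    nuclear: np.ndarray
    cytoplasmic: np.ndarray
    background: np.ndarray
    nucleus_present: np.ndarray
    normalization: Normalization = Normalization.RAW
    reference: str = ""


@dataclass
class RatioResult:
    """Cohort-level P1/AB ratio with a t-based 95% CI."""

    ratio: float
    n: int
    ci95: tuple[float, float]
    per_embryo: np.ndarray = field(default_factory=lambda: np.empty(0))
    scope: str = "per_embryo"


def background_estimate(
    image: np.ndarray, embryo_mask: np.ndarray, dilation_px: int = 3
) -> float:
    """Median intensity outside the (dilated) embryo mask.

    The mask is dilated to keep boundary glow out of the estimate; the
    median is robust to stray fluorescent debris in the medium.
    """
    image = np.asarray(image, dtype=float)
    embryo_mask = np.asarray(embryo_mask, dtype=bool)
    if not embryo_mask.any():
        raise BackgroundUnavailable("empty embryo mask")
    outside = ~ndi.binary_dilation(embryo_mask, iterations=dilation_px)
    if not outside.any():
        raise BackgroundUnavailable("mask covers the full frame")
    return float(np.median(image[outside]))


def measure_cell_signals(
    image: np.ndarray,
    cell_labels: CellLabelMap,
    nuclei: dict[str, NucleusRecord],
    background: float,
    clip_negative: bool = True,
    nucleus_erosion_px: int = 3,
) -> dict[str, CellSignal]:
    """Background-corrected nuclear and cytoplasmic means per cell.

    nuclear = mean over nucleus mask - background; cytoplasmic = mean
    over (cell minus nucleus) - background. When the nucleus is absent
    the cytoplasmic region is the whole cell and nuclear is NaN.

    The nuclear mean is taken over an eroded core of the detected mask
    (``nucleus_erosion_px``, default 3): thresholded nucleus masks carry
    a partial-volume halo of cytoplasm-level pixels that would otherwise
    dilute the mean. The cytoplasmic region still excludes the full
    detected mask, so the halo is counted in neither compartment. If
    erosion would empty the mask the full mask is used instead.
    """
    image = np.asarray(image, dtype=float)
    out: dict[str, CellSignal] = {}
    for lbl, cell in ((AB_LABEL, "AB"), (P1_LABEL, "P1")):
        region = cell_labels.labels == lbl
        rec = nuclei.get(cell)
        present = rec is not None and rec.present
        clipped = False
        if present:
            full_mask = rec.mask & region
            cyto_mask = region & ~full_mask
            nuc_mask = full_mask
            if nucleus_erosion_px > 0:
                core = ndi.binary_erosion(full_mask, iterations=nucleus_erosion_px)
                if core.any():
                    nuc_mask = core
            if not full_mask.any():
                present = False
        if present:
            nuclear = float(image[nuc_mask].mean()) - background
            nuclear_int = float(image[nuc_mask].sum()) - background * nuc_mask.sum()
        else:
            cyto_mask = region
            nuclear, nuclear_int = float("nan"), float("nan")
        if not cyto_mask.any():
            raise MeasurementError(f"empty cytoplasmic region for {cell}")
        cyto = float(image[cyto_mask].mean()) - background
        cyto_int = float(image[cyto_mask].sum()) - background * cyto_mask.sum()
        if clip_negative:
            if present and nuclear < 0:
                nuclear, clipped = 0.0, True
            if cyto < 0:
                cyto, clipped = 0.0, True
        out[cell] = CellSignal(
            cell=cell,
            nuclear=nuclear,
            cytoplasmic=cyto,
            nuclear_integrated=nuclear_int,
            cytoplasmic_integrated=cyto_int,
            nucleus_present=present,
            clipped=clipped,
        )
    return out


def build_traces(
    signals_per_frame: list[dict[str, CellSignal]],
    backgrounds: list[float],
    frame_interval_s: float,
) -> dict[str, IntensityTrace]:
    """Stack per-frame signals into per-cell time series."""
    n = len(signals_per_frame)
    time_s = np.arange(n) * frame_interval_s
    traces = {}
    for cell in ("AB", "P1"):
        traces[cell] = IntensityTrace(
            cell=cell,
            time_s=time_s,
            nuclear=np.array([s[cell].nuclear for s in signals_per_frame]),
            cytoplasmic=np.array([s[cell].cytoplasmic for s in signals_per_frame]),
            background=np.asarray(backgrounds, dtype=float),
            nucleus_present=np.array(
                [s[cell].nucleus_present for s in signals_per_frame]
            ),
        )
    return traces


def embryo_ratio(
    traces: dict[str, IntensityTrace],
    ab_neb_frame: int | None = None,
    use_nuclear: bool = True,
) -> float:
    """One embryo's P1/AB ratio.

    Averages the frames in which both nuclei are present (and, when the
    AB NEB frame is known, strictly before it): ratio = mean P1 signal /
    mean AB signal over those frames. ``use_nuclear=False`` switches to
    whole-cell (cytoplasm-inclusive) means.
    """
    both = traces["AB"].nucleus_present & traces["P1"].nucleus_present
    if ab_neb_frame is not None:
        both = both & (np.arange(both.size) < ab_neb_frame)
    if not both.any():
        raise RatioUndefined("no frames with both nuclei present")
    if use_nuclear:
        ab = traces["AB"].nuclear[both]
        p1 = traces["P1"].nuclear[both]
    else:
        ab = traces["AB"].cytoplasmic[both]
        p1 = traces["P1"].cytoplasmic[both]
    ab_mean = float(np.nanmean(ab))
    if ab_mean <= 0:
        raise RatioUndefined("AB signal non-positive after background correction")
    return float(np.nanmean(p1)) / ab_mean


def p1_ab_ratio(per_embryo_ratios) -> RatioResult:
    """Cohort summary: mean of per-embryo P1/AB ratios with 95% CI."""
    ratios = np.asarray(list(per_embryo_ratios), dtype=float)
    if ratios.size == 0:
        raise RatioUndefined("no embryos")
    if ratios.size == 1:
        return RatioResult(
            ratio=float(ratios[0]), n=1,
            ci95=(float(ratios[0]), float(ratios[0])), per_embryo=ratios,
        )
    mean, lo, hi = summarize_ci(ratios)
    return RatioResult(ratio=mean, n=int(ratios.size), ci95=(lo, hi), per_embryo=ratios)


def normalize_traces(
    df: pd.DataFrame,
    scheme: Normalization,
    reference_cell: str = "ABa",
    reference_group: str | None = None,
) -> pd.DataFrame:
    """Apply one of the reference normalizations to tidy measurements.

    ``df`` columns: embryo_id, cell, value, plus (scheme-dependent)
    ab_cyto for ab_cyto_ref and group for the reference-group rescale.

    ab_cyto_ref: each embryo's values are divided by that embryo's AB
    cytoplasmic signal, then the cohort is rescaled so the reference
    group's mean AB nuclear value equals 1.

    named_cell_ref: each embryo's per-cell values are divided by that
    embryo's reference cell (default ABa) value.
    """
    df = df.copy()
    if scheme == Normalization.AB_CYTO_REF:
        if "ab_cyto" not in df.columns:
            raise NormalizationError("ab_cyto_ref needs an 'ab_cyto' column")
        if (df["ab_cyto"] <= 0).any():
            raise NormalizationError("non-positive AB cytoplasmic reference")
        df["value"] = df["value"] / df["ab_cyto"]
        ref_rows = df[df["cell"] == "AB"]
        if reference_group is not None:
            ref_rows = ref_rows[ref_rows["group"] == reference_group]
        ref_mean = ref_rows["value"].mean()
        if not np.isfinite(ref_mean) or ref_mean <= 0:
            raise NormalizationError("reference-group mean AB nuclear value <= 0")
        df["value"] = df["value"] / ref_mean
    elif scheme == Normalization.NAMED_CELL_REF:
        ref = (
            df[df["cell"] == reference_cell]
            .set_index("embryo_id")["value"]
            .rename("ref")
        )
        df = df.join(ref, on="embryo_id")
        if df["ref"].isna().any() or (df["ref"] <= 0).any():
            raise NormalizationError(
                f"reference cell {reference_cell!r} missing or non-positive"
            )
        df["value"] = df["value"] / df["ref"]
        df = df.drop(columns="ref")
    elif scheme == Normalization.RAW:
        pass
    else:
        raise NormalizationError(f"unsupported scheme {scheme}")
    df["normalization"] = scheme.value
    return df
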