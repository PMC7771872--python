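"""End-to-end orchestration of the two-cell quantification pipeline.

Per frame: the best-focused DIC slice drives embryo mapping and the
AB/P1 split; nuclei come from the max projection of the fluorescence
z-stack; intensities are measured on the best-focused fluorescence slice
(or the projection) against the outside-embryo background. Per movie:
presence traces give NEB frames, cycle metrics, and the P1/AB ratio.
A frame whose segmentation fails is skipped with a logged warning and
appears as a gap in the traces — never silently interpolated.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .errors import EmbryoQuantError, NoNEBDetected, RatioUndefined, SegmentationFailure
from .focus import best_focus_slice
from .io import Hyperstack, read_hyperstack
from .nuclei import NucleusParams, NucleusRecord, max_projection, segment_nuclei
from .quantify import (
    CellSignal,
    IntensityTrace,
    background_estimate,
    build_traces,
    embryo_ratio,
    measure_cell_signals,
)
from .segment import (
    CellLabelMap,
    EmbryoMaskParams,
    SplitParams,
    assign_identities,
    embryo_mask,
    split_two_cells,
)
from .simulate import generate_two_cell_movie, preset
from .timing import CycleMetrics, NEBParams, cycle_metrics, detect_neb

log = logging.getLogger("embryoquant")


@dataclass
class FrameResult:
    frame: int
    cell_labels: CellLabelMap | None
    nuclei: dict[str, NucleusRecord] | None
    signals: dict[str, CellSignal] | None
    background: float
    failed: bool = False


@dataclass
class QuantificationResult:
    """Everything one movie yields, plus provenance."""

    movie_id: str
    config: PipelineConfig
    frames: list[FrameResult]
    traces: dict[str, IntensityTrace]
    neb_frames: dict[str, int | None]
    cycle: CycleMetrics | None
    ratio: float | None
    frame_interval_s: float
    split_methods: list[str | None] = field(default_factory=list)

    def trace_frame(self) -> pd.DataFrame:
        """Tidy per-frame table mirroring the CSV the CLI writes."""
        rows = []
        for cell, tr in self.traces.items():
            for i in range(tr.time_s.size):
                rows.append(
                    {
                        "movie_id": self.movie_id,
                        "config_hash": self.config.config_hash,
                        "frame": i,
                        "time_s": tr.time_s[i],
                        "cell": cell,
                        "nuclear_AU": tr.nuclear[i],
                        "cytoplasmic_AU": tr.cytoplasmic[i],
                        "background_AU": tr.background[i],
                        "nucleus_present": bool(tr.nucleus_present[i]),
                        "split_method": self.split_methods[i],
                    }
                )
        return pd.DataFrame(rows)

    def manifest(self) -> dict:
        return {
            "movie_id": self.movie_id,
            "version": __version__,
            "config": self.config.model_dump(mode="json"),
            "config_hash": self.config.config_hash,
            "seed": self.config.seed,
            "frame_interval_s": self.frame_interval_s,
            "neb_frames": self.neb_frames,
            "ratio_p1_over_ab": self.ratio,
        }


def analyse_frame(
    fluor_zstack: np.ndarray,
    dic_zstack: np.ndarray,
    config: PipelineConfig,
    frame: int = 0,
) -> FrameResult:
    """Run segmentation + measurement on one frame's pair of z-stacks."""
    dic_best = dic_zstack[best_focus_slice(dic_zstack).best_index]
    mask_params = EmbryoMaskParams(
        window_radius=config.local_std_radius,
        smooth_sigma=config.smooth_sigma,
        min_area_fraction=config.min_embryo_fraction,
    )
    split_params = SplitParams(
        solidity_threshold=config.solidity_threshold,
        min_cell_fraction=config.min_cell_fraction,
    )
    mask = embryo_mask(dic_best, mask_params)
    labels = assign_identities(split_two_cells(mask, split_params))

    nuc_params = NucleusParams(
        sigma_small=config.dog_sigma_small,
        sigma_large=config.dog_sigma_large,
        expected_radius_px=config.expected_nucleus_radius_px,
    )
    nuclei = segment_nuclei(fluor_zstack, labels, nuc_params, frame=frame)

    if config.measure_on == "projection":
        measure_img = max_projection(fluor_zstack)
    else:
        measure_img = fluor_zstack[best_focus_slice(fluor_zstack).best_index]
    background = background_estimate(measure_img, labels.labels > 0)
    signals = measure_cell_signals(measure_img, labels, nuclei, background)
    return FrameResult(
        frame=frame, cell_labels=labels, nuclei=nuclei,
        signals=signals, background=background,
    )


def run_quantification(
    movie: Hyperstack | str, config: PipelineConfig | None = None,
    movie_id: str = "movie",
) -> QuantificationResult:
    """Quantify one movie (a Hyperstack, a named fixture, or a TIFF path)."""
    config = config or PipelineConfig()
    if isinstance(movie, str):
        try:
            params = preset(movie, seed=config.seed)
            movie, _ = generate_two_cell_movie(params)
            movie_id = movie_id if movie_id != "movie" else movie_id + "_" + str(config.seed)
        except EmbryoQuantError:
            movie = read_hyperstack(movie)
    interval = config.frame_interval_s or movie.frame_interval_s

    fluor = movie.channel(config.fluorescence_channel)
    dic = movie.channel(config.dic_channel)
    frames: list[FrameResult] = []
    for t in range(movie.n_frames):
        try:
            frames.append(analyse_frame(fluor[t], dic[t], config, frame=t))
        except (SegmentationFailure, EmbryoQuantError) as exc:
            log.warning("frame %d skipped: %s", t, exc)
            frames.append(
                FrameResult(
                    frame=t, cell_labels=None, nuclei=None,
                    signals=None, background=float("nan"), failed=True,
                )
            )

    good = [f for f in frames if not f.failed]
    if not good:
        raise SegmentationFailure("every frame failed segmentation")
    signals_seq = [f.signals for f in good]
    backgrounds = [f.background for f in good]
    traces = build_traces(signals_seq, backgrounds, interval)
    # re-index trace time to the original frame numbers when frames were skipped
    kept = np.array([f.frame for f in good])
    for tr in traces.values():
        tr.time_s = kept * interval

    neb_params = NEBParams(
        persistence=config.neb_persistence, contrast_min=config.neb_contrast_min
    )
    neb_frames: dict[str, int | None] = {}
    for cell in ("AB", "P1"):
        presence = traces[cell].nucleus_present
        try:
            idx_in_kept = detect_neb(presence, neb_params)
            neb_frames[cell] = int(kept[idx_in_kept])
        except (NoNEBDetected, EmbryoQuantError):
            neb_frames[cell] = None

    cycle = None
    if neb_frames["AB"] is not None and neb_frames["P1"] is not None:
        try:
            cycle = cycle_metrics(
                config.fusion_frame, neb_frames["AB"], neb_frames["P1"], interval
            )
        except EmbryoQuantError:
            cycle = None

    try:
        ab_neb_kept = (
            int(np.searchsorted(kept, neb_frames["AB"]))
            if neb_frames["AB"] is not None
            else None
        )
        ratio = embryo_ratio(traces, ab_neb_kept, use_nuclear=config.ratio_uses_nuclear)
    except RatioUndefined:
        ratio = None

    return QuantificationResult(
        movie_id=movie_id,
        config=config,
        frames=frames,
        traces=traces,
        neb_frames=neb_frames,
        cycle=cycle,
        ratio=ratio,
        frame_interval_s=interval,
        split_methods=[
            f.cell_labels.split_method.value if f.cell_labels is not None else None
            for f in frames
        ],
    )


def write_outputs(result: QuantificationResult, outdir) -> None:
    """Tidy CSV traces + JSON run manifest (+ per-frame label TIFFs)."""
    import pathlib

    import tifffile

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.trace_frame().to_csv(
        outdir / f"{result.movie_id}_traces.csv", index=False, float_format="%.9g"
    )
    with open(outdir / f"{result.movie_id}_manifest.json", "w") as fh:
        json.dump(result.manifest(), fh, indent=2, sort_keys=True)
    labels = np.stack(
        [
            f.cell_labels.labels
            if f.cell_labels is not None
            else np.zeros_like(result.frames[0].cell_labels.labels)
            for f in result.frames
        ]
    )
    tifffile.imwrite(outdir / f"{result.movie_id}_cell_labels.tif", labels)
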