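"""Nuclear-envelope-breakdown detection and cell-cycle timing.

NEB is the timing landmark: the nucleus stops being segmentable because
its contents disperse into the cytoplasm. Detection scans the per-frame
nucleus-presence trace for the first sustained disappearance; a
persistence requirement (default 2 frames) suppresses single-frame
segmentation dropouts. Cycle lengths follow the standard convention for
the two-cell embryo: time from pronuclei fusion to each cell's NEB, in
seconds (frames x frame interval; the timing movies here use an 8 s
interval). The AB-to-P1 NEB delay may be negative — mutants can invert
the normal AB-first order — so no ordering is assumed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NoNEBDetected, ParameterError


@dataclass(frozen=True)
class NEBParams:
    persistence: int = 2
    contrast_min: float = 0.0  # threshold when the trace is a contrast signal


@dataclass
class CycleMetrics:
    """Cycle lengths and AB->P1 NEB delay, all in seconds."""

    fusion_frame: int
    neb_frame_ab: int
    neb_frame_p1: int
    frame_interval_s: float

    @property
    def ab_cycle_s(self) -> float:
        return (self.neb_frame_ab - self.fusion_frame) * self.frame_interval_s

    @property
    def p1_cycle_s(self) -> float:
        return (self.neb_frame_p1 - self.fusion_frame) * self.frame_interval_s

    @property
    def ab_p1_delay_s(self) -> float:
        return (self.neb_frame_p1 - self.neb_frame_ab) * self.frame_interval_s


def detect_neb(trace, params: NEBParams | None = None) -> int:
    """First frame of the first absence run lasting >= persistence frames.

    ``trace`` is either a boolean nucleus-presence series or a float
    nuclear/cytoplasmic contrast series (absent where contrast <
    ``contrast_min``). Raises :class:`NoNEBDetected` if the nucleus
    never disappears for long enough.
    """
    params = params or NEBParams()
    trace = np.asarray(trace)
    if trace.size < 3:
        raise ParameterError("trace must cover at least 3 frames")
    if trace.dtype == bool:
        present = trace
    else:
        present = trace.astype(float) >= params.contrast_min
    run_start = None
    run_len = 0
    for i, p in enumerate(present):
        if not p:
            if run_start is None:
                run_start = i
            run_len += 1
            if run_len >= params.persistence:
                return run_start
        else:
            run_start, run_len = None, 0
    raise NoNEBDetected(
        f"no absence run of >= {params.persistence} frames in {trace.size}-frame trace"
    )


def cycle_metrics(
    fusion_frame: int,
    neb_frame_ab: int,
    neb_frame_p1: int,
    frame_interval_s: float,
) -> CycleMetrics:
    """Cycle lengths from fusion to each cell's NEB.

    The fusion frame is an input annotation (scored on the movie, as in
    live-imaging practice), not auto-detected.
    """
    if frame_interval_s <= 0:
        raise ParameterError("frame_interval_s must be positive")
    for name, neb in (("AB", neb_frame_ab), ("P1", neb_frame_p1)):
        if neb <= fusion_frame:
            raise ParameterError(f"{name} NEB frame must come after fusion")
    return CycleMetrics(
        fusion_frame=fusion_frame,
        neb_frame_ab=neb_frame_ab,
        neb_frame_p1=neb_frame_p1,
        frame_interval_s=frame_interval_s,
    )
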