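"""Cut the beat-level series into per-calcium-bolus segments.

Every drug injection (calcium, epinephrine, bicarbonate) delimits segments:
a calcium bolus owns the interval from half-way to the previous injection to
half-way to the next one (recording edges when there is no neighbor).  A
segment is usable for the before/after comparison only when at least
``min_context_s`` of context exists on both sides of the bolus; unusable
segments are retained with ``usable=False`` so bolus counts stay auditable.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np

from .beats import BeatHemodynamics, PerfusionSeries
from .io import Drug, DrugEvent

logger = logging.getLogger(__name__)

__all__ = ["BolusSegment", "segment_boluses"]

DEFAULT_MIN_CONTEXT_S = 40.0


@dataclasses.dataclass
class BolusSegment:
    """The slice of the beat-level series attributed to one calcium bolus."""

    bolus: DrugEvent
    t_start_s: float
    t_end_s: float
    beats: BeatHemodynamics
    perfusion: PerfusionSeries
    usable: bool

    def __post_init__(self) -> None:
        if not (self.t_start_s <= self.bolus.time_s <= self.t_end_s):
            raise ValueError("bolus time must lie within the segment boundaries")

    @property
    def context_before_s(self) -> float:
        return self.bolus.time_s - self.t_start_s

    @property
    def context_after_s(self) -> float:
        return self.t_end_s - self.bolus.time_s


def segment_boluses(
    events: list[DrugEvent],
    beats: BeatHemodynamics,
    perfusion: PerfusionSeries,
    span: tuple[float, float],
    min_context_s: float = DEFAULT_MIN_CONTEXT_S,
) -> list[BolusSegment]:
    """One segment per calcium event, usable or not.

    Boundaries sit half-way to the nearest neighboring injection of any
    drug, or at the recording edge when there is none.  Consecutive calcium
    boluses closer than twice ``min_context_s`` therefore produce two
    unusable segments, never a merged one.
    """
    t0, t1 = span
    events = sorted(events, key=lambda e: e.time_s)
    segments: list[BolusSegment] = []
    for i, ev in enumerate(events):
        if ev.drug is not Drug.CALCIUM:
            continue
        if not (t0 <= ev.time_s <= t1):
            raise ValueError(
                f"calcium event at {ev.time_s} s lies outside the recording span [{t0}, {t1}] s"
            )
        prev_t = max((e.time_s for e in events[:i]), default=None)
        next_t = min((e.time_s for e in events[i + 1 :]), default=None)
        t_start = t0 if prev_t is None else 0.5 * (prev_t + ev.time_s)
        t_end = t1 if next_t is None else 0.5 * (ev.time_s + next_t)
        usable = (ev.time_s - t_start) >= min_context_s and (t_end - ev.time_s) >= min_context_s

        bt = beats.beat_time_s
        # half-open on the right so adjacent segments never share a beat;
        # the final segment keeps its right edge
        closed_right = next_t is None
        mask = (bt >= t_start) & ((bt <= t_end) if closed_right else (bt < t_end))
        pmask = mask if len(perfusion) == len(beats) else np.empty(0, dtype=bool)
        seg = BolusSegment(
            bolus=ev,
            t_start_s=t_start,
            t_end_s=t_end,
            beats=beats.slice(mask),
            perfusion=perfusion.slice(pmask) if len(perfusion) else PerfusionSeries.empty(),
            usable=usable,
        )
        logger.info(
            "segment for calcium @ %.1f s: [%.1f, %.1f] s, %d beats, usable=%s",
            ev.time_s, t_start, t_end, len(seg.beats), usable,
        )
        segments.append(seg)
    return segments
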