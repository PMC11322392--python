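"""Deformation (%) and deformation-rate (%/s) curves from tracked ROIs.

Deformation is the percentage change of ROI length from its reference
(rest) length: d_k = 100 (L_k - L_ref) / L_ref, elongation positive. The
deformation rate is the time derivative in percent per second, estimated
with central differences (one-sided at the ends). The analyzed segment is
the tenth rotation cycle, isolated with the contact-switch sync channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import FrameSequence, SyncEvent
from .speckle_tracking import TrackedROI


class SegmentationError(RuntimeError):
    """The sync channel does not contain the requested cycle."""


@dataclass
class DeformationCurve:
    """Percent length change versus time for one muscle and direction."""

    times_s: np.ndarray
    values_percent: np.ndarray
    reference_length_mm: float
    valid: np.ndarray
    muscle: str = ""
    direction: str = ""

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.values_percent = np.asarray(self.values_percent, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)

    @property
    def frame_interval_s(self) -> float:
        return float(self.times_s[1] - self.times_s[0])


@dataclass
class DeformationRateCurve:
    """Time derivative of a deformation curve, percent per second."""

    times_s: np.ndarray
    values_percent_per_s: np.ndarray
    valid: np.ndarray


def to_deformation(tracked: TrackedROI, reference_frame: int = 0,
                   frames: slice | None = None,
                   direction: str = "") -> DeformationCurve:
    """Deformation curve of a tracked ROI relative to ``reference_frame``.

    ``frames`` restricts the curve to a segment (e.g. the analyzed tenth
    cycle); the reference frame index refers to the full sequence.
    """
    if not tracked.valid[reference_frame]:
        raise ValueError(f"reference frame {reference_frame} is not valid")
    l_ref = tracked.lengths_mm[reference_frame]
    sel = frames if frames is not None else slice(None)
    lengths = tracked.lengths_mm[sel]
    values = 100.0 * (lengths - l_ref) / l_ref
    return DeformationCurve(
        times_s=tracked.times_s[sel],
        values_percent=values,
        reference_length_mm=float(l_ref),
        valid=tracked.valid[sel].copy(),
        muscle=tracked.roi.muscle,
        direction=direction,
    )


def to_rate(curve: DeformationCurve) -> DeformationRateCurve:
    """Finite-difference deformation rate.

    Central differences in the interior, one-sided at the two ends. A rate
    sample is valid only if every curve sample in its stencil is valid.
    """
    d = curve.values_percent
    if curve.valid.sum() < 2 or len(d) < 2:
        raise ValueError("need at least 2 valid samples for a rate")
    dt = np.diff(curve.times_s)
    if not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12):
        raise ValueError("rate requires a uniform frame interval")
    dt = dt[0]
    rate = np.empty_like(d)
    rate[0] = (d[1] - d[0]) / dt
    rate[-1] = (d[-1] - d[-2]) / dt
    rate[1:-1] = (d[2:] - d[:-2]) / (2.0 * dt)

    v = curve.valid
    rate_valid = v.copy()
    rate_valid[0] &= v[1]
    rate_valid[-1] &= v[-2]
    rate_valid[1:-1] &= v[2:] & v[:-2]
    return DeformationRateCurve(curve.times_s.copy(), rate, rate_valid)


def segment_cycle(sync_events: list[SyncEvent] | FrameSequence,
                  cycle_index: int = 10) -> tuple[int, int]:
    """Half-open frame interval [start, stop) of the requested rotation
    cycle (1-based; the study analyzes cycle 10).

    The sync channel must contain complete start / reach / stop triplets
    in order; anything else raises :class:`SegmentationError` listing what
    was found.
    """
    events = sync_events.sync_events if isinstance(sync_events, FrameSequence) \
        else list(sync_events)
    triplets = []
    expecting = ["start", "reach", "stop"]
    pending: list[SyncEvent] = []
    for ev in sorted(events, key=lambda e: e.frame):
        if ev.label != expecting[len(pending)]:
            raise SegmentationError(
                f"sync events out of order: got {ev.label!r} at frame "
                f"{ev.frame} while expecting {expecting[len(pending)]!r}; "
                f"events found: {[(e.frame, e.label) for e in events]}")
        pending.append(ev)
        if len(pending) == 3:
            triplets.append(tuple(pending))
            pending = []
    if pending:
        raise SegmentationError(
            f"incomplete final sync triplet: {[(e.frame, e.label) for e in pending]}")
    if not 1 <= cycle_index <= len(triplets):
        raise SegmentationError(
            f"cycle {cycle_index} requested but only {len(triplets)} "
            f"complete cycles are marked")
    start, _, stop = triplets[cycle_index - 1]
    return start.frame, stop.frame


def analyzed_segment(tracked: TrackedROI, sequence: FrameSequence,
                     cycle_index: int = 10, direction: str = "") \
        -> tuple[DeformationCurve, DeformationRateCurve]:
    """Deformation and rate curves of the analyzed rotation cycle.

    The reference (rest) frame is the cycle's start event at the midline,
    so deformation is zero at the start of the analyzed segment.
    """
    start, stop = segment_cycle(sequence, cycle_index)
    curve = to_deformation(tracked, reference_frame=start,
                           frames=slice(start, stop), direction=direction)
    return curve, to_rate(curve)
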