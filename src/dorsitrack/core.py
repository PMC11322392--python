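"""Shared containers and conventions for the deformation pipeline.

Coordinate convention (used everywhere): image axis 0 is the axial
(depth/row) direction, axis 1 the lateral (width/column) direction.
Muscle fibers run laterally in the longitudinal view, so ROIs are
(near-)horizontal segments. Pixel indices are 0-based and converted to
millimetres through ``pixel_spacing_mm = (axial, lateral)``.

Sign convention: elongation positive, shortening negative, fixed across
the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Dorsal neck muscles, superficial to deep: trapezius, splenius,
#: semispinalis capitis, semispinalis cervicis, multifidus.
MUSCLES = ("TR", "SP", "Scap", "Scerv", "MF")

#: Post-hoc contrast levels: superficial / middle / deep.
MUSCLE_LEVELS = {
    "superficial": ("TR", "SP"),
    "middle": ("Scap",),
    "deep": ("Scerv", "MF"),
}

#: Per-muscle summary statistics of one deformation curve.
AREA_STATS = ("total", "under", "over", "difference", "rate_rms")

#: The 25 feature columns of the subject-level table, fixed order.
FEATURE_COLUMNS = tuple(f"{m}_{s}" for m in MUSCLES for s in AREA_STATS)

#: Metadata columns carried alongside the features.
METADATA_COLUMNS = ("subject", "group", "sex", "age", "wad_grade",
                    "timepoint", "direction")

SYNC_LABELS = ("start", "reach", "stop")


class ConfigError(ValueError):
    """An invalid configuration value."""


@dataclass(frozen=True)
class SyncEvent:
    """One contact-switch event: rotation start (midline), 20-degree
    reach, or stop (back to midline)."""

    frame: int
    label: str  # one of SYNC_LABELS

    def __post_init__(self) -> None:
        if self.label not in SYNC_LABELS:
            raise ConfigError(f"unknown sync label {self.label!r}")


@dataclass
class FrameSequence:
    """A B-mode-like video: grayscale frames plus acquisition metadata.

    Parameters
    ----------
    frames
        Array of shape (n_frames, rows, cols); uint8 or float.
    frame_interval_s
        Time between consecutive frames (s); 0.02 for 50 frames/s.
    pixel_spacing_mm
        (axial, lateral) spacing of one pixel in mm.
    sync_events
        Contact-switch events marking rotation starts, 20-degree
        reaches, and stops.
    """

    frames: np.ndarray
    frame_interval_s: float
    pixel_spacing_mm: tuple[float, float]
    sync_events: list[SyncEvent] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ConfigError("frames must be (n_frames, rows, cols)")
        if self.frame_interval_s <= 0:
            raise ConfigError("frame_interval_s must be positive")
        if min(self.pixel_spacing_mm) <= 0:
            raise ConfigError("pixel spacing must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    def frame_as_float(self, k: int) -> np.ndarray:
        """Frame ``k`` as float in [0, 1] regardless of storage dtype."""
        f = self.frames[k]
        if f.dtype == np.uint8:
            return f.astype(np.float64) / 255.0
        return f.astype(np.float64)

    def sync_channel(self) -> np.ndarray:
        """Per-frame integer channel: 0 none, 1 start, 2 reach, 3 stop."""
        ch = np.zeros(self.n_frames, dtype=np.int8)
        for ev in self.sync_events:
            ch[ev.frame] = SYNC_LABELS.index(ev.label) + 1
        return ch
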