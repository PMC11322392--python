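"""Readers and writers for the pipeline's interchange formats.

Videos travel as multi-frame TIFF (one file per subject per direction)
with a JSON sidecar holding the frame interval, pixel spacing and sync
events; curves, areas and feature tables are CSV (UTF-8, '.' decimal,
documented column order) with JSON schema sidecars. Directories of
ordered per-frame PNG/TIFF images are also accepted as input.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .core import (AREA_STATS, FEATURE_COLUMNS, METADATA_COLUMNS, MUSCLES,
                   FrameSequence, SyncEvent)
from .curve_areas import AreaDecomposition
from .deformation_curves import DeformationCurve, DeformationRateCurve
from .speckle_tracking import TrackedROI
from .synth_cohort import GroundTruth


class FormatError(ValueError):
    """Malformed or inconsistent input files."""


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json") if path.is_dir() \
        else path.with_suffix(".json")


def write_sequence(seq: FrameSequence, path: str | Path) -> Path:
    """Write a multi-frame TIFF plus its JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, seq.frames)
    meta = {
        "frame_interval_s": seq.frame_interval_s,
        "pixel_spacing_mm": list(seq.pixel_spacing_mm),
        "sync_events": [[ev.frame, ev.label] for ev in seq.sync_events],
        "coordinates": "axis 0 axial (rows), axis 1 lateral (cols); "
                       "0-based pixel indices, mm via pixel_spacing_mm",
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))
    return path


def read_sequence(path: str | Path) -> FrameSequence:
    """Read a multi-frame TIFF or a directory of ordered frame images.

    The JSON sidecar (``<stem>.json`` next to the file or directory) must
    provide ``frame_interval_s`` and ``pixel_spacing_mm``.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".png", ".tif", ".tiff"))
        if not files:
            raise FormatError(f"no frame images in {path}")
        frames = []
        shape = None
        for f in files:
            img = iio.imread(f)
            if img.ndim == 3:
                img = img[..., 0]
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise FormatError(
                    f"frame {f.name} has shape {img.shape}, expected {shape}")
            frames.append(img)
        frames = np.stack(frames)
        sidecar = path / "metadata.json"
    else:
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
        sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"metadata sidecar {sidecar} not found")
    meta = json.loads(sidecar.read_text())
    if "frame_interval_s" not in meta:
        raise FormatError(f"{sidecar} lacks required key 'frame_interval_s'")
    if "pixel_spacing_mm" not in meta:
        raise FormatError(f"{sidecar} lacks required key 'pixel_spacing_mm'")
    events = [SyncEvent(int(f), lab) for f, lab in meta.get("sync_events", [])]
    return FrameSequence(frames, float(meta["frame_interval_s"]),
                         tuple(meta["pixel_spacing_mm"]), events)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    """Ground-truth deformation curves as CSV (frame, time_s, one column
    per muscle)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"frame": np.arange(len(truth.times_s)),
                       "time_s": truth.times_s})
    for j, lab in enumerate(truth.labels):
        df[lab] = truth.deformation_percent[:, j]
    df.to_csv(path, index=False)
    return path


def write_tracked_roi(tracked: TrackedROI, path: str | Path) -> Path:
    """Per-frame tracking CSV: frame, time_s, length_mm, strain_increment,
    residual, valid."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "frame": np.arange(tracked.n_frames),
        "time_s": tracked.times_s,
        "length_mm": tracked.lengths_mm,
        "strain_increment": tracked.strain_increments,
        "residual": tracked.residuals,
        "valid": tracked.valid.astype(int),
    }).to_csv(path, index=False)
    return path


def write_curves(curve: DeformationCurve, rate: DeformationRateCurve,
                 path: str | Path) -> Path:
    """Deformation + rate CSV for one analyzed segment."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "frame": np.arange(len(curve.times_s)),
        "time_s": curve.times_s,
        "deformation_percent": curve.values_percent,
        "rate_percent_per_s": rate.values_percent_per_s,
        "valid": (curve.valid & rate.valid).astype(int),
    }).to_csv(path, index=False)
    return path


def write_feature_table(table: pd.DataFrame, path: str | Path) -> Path:
    """Feature table CSV plus a JSON schema sidecar documenting columns,
    units and sign conventions."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)
    schema = {
        "metadata_columns": list(METADATA_COLUMNS),
        "feature_columns": list(FEATURE_COLUMNS),
        "muscles": list(MUSCLES),
        "statistics": list(AREA_STATS),
        "units": {"total": "%*s", "under": "%*s", "over": "%*s",
                  "difference": "%*s", "rate_rms": "%/s"},
        "conventions": "elongation positive; under/over relative to the "
                       "0% deformation line; difference = over - under",
    }
    _sidecar_path(path).write_text(json.dumps(schema, indent=1))
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Round-trip reader for :func:`write_feature_table` output."""
    table = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"feature table lacks columns {missing}")
    return table


def write_area_decompositions(areas: dict[str, AreaDecomposition],
                              path: str | Path) -> Path:
    """Per-muscle area statistics CSV for one subject/direction."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = [{"muscle": m, **dec.as_dict(), "n_valid": dec.n_valid}
            for m, dec in areas.items()]
    pd.DataFrame(rows).to_csv(path, index=False)
    return path
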