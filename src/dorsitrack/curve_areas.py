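"""Deformation-curve area statistics and the 25-variable feature table.

The per-muscle summary of one rotation cycle is the trapezoidal area of
the deformation curve, split at the 0 % line: extra sample points are
inserted by linear interpolation wherever the curve crosses zero, so the
elongation area (over the line) and the shortening area (under the line,
reported as a magnitude) separate exactly for piecewise-linear curves.
Five statistics per muscle — total (= over + under), under, over,
difference (= over - under), and the RMS of the deformation rate — times
five muscles give the 25 feature columns consumed by the statistics
modules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AREA_STATS, FEATURE_COLUMNS, METADATA_COLUMNS, MUSCLES
from .deformation_curves import DeformationCurve, DeformationRateCurve

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AreaDecomposition:
    """Areas of one deformation curve split at the 0 % line (units %*s).

    ``area_above`` is the elongation area over the line, ``area_below``
    the magnitude of the shortening area under it; ``total = above +
    below`` and ``difference = above - below`` (the signed trapezoid
    integral). ``rate_rms`` is the root mean square of the valid
    deformation-rate samples in %/s.
    """

    area_above: float
    area_below: float
    total: float
    difference: float
    rate_rms: float
    n_valid: int = 0

    def as_dict(self) -> dict[str, float]:
        return {"total": self.total, "under": self.area_below,
                "over": self.area_above, "difference": self.difference,
                "rate_rms": self.rate_rms}


def trapezoid_area(values, sample_interval: float) -> float:
    """Composite trapezoid area A = (t/2)(y1 + 2 y2 + ... + 2 y_{n-1} + yn)."""
    y = np.asarray(values, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    if sample_interval <= 0:
        raise ValueError("sample interval must be positive")
    return float(np.trapezoid(y, dx=sample_interval))


def split_zero_crossings(times, values) -> tuple[np.ndarray, np.ndarray]:
    """Insert linearly interpolated zero points wherever the curve changes
    sign between consecutive samples.

    Samples that are exactly zero are crossing points already; nothing is
    inserted next to them. Returns the augmented (times, values) arrays.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("values must be finite")
    sign_change = y[:-1] * y[1:] < 0
    idx = np.flatnonzero(sign_change)
    if idx.size == 0:
        return t.copy(), y.copy()
    t_cross = t[idx] - y[idx] * (t[idx + 1] - t[idx]) / (y[idx + 1] - y[idx])
    insert_at = idx + 1
    t_aug = np.insert(t, insert_at, t_cross)
    y_aug = np.insert(y, insert_at, 0.0)
    return t_aug, y_aug


def decompose(curve: DeformationCurve,
              rate: DeformationRateCurve | None = None) -> AreaDecomposition:
    """Area decomposition of a deformation curve plus the rate RMS.

    Only valid samples enter; masked samples are dropped (their intervals
    are bridged by the trapezoid on the remaining non-uniform grid). After
    zero-crossing insertion the curve is piecewise linear with nodes at
    every crossing, so integrating its positive and negative parts with
    the trapezoid rule is exact.
    """
    v = curve.valid
    if v.sum() < 2:
        raise ValueError("need at least 2 valid samples")
    t, y = split_zero_crossings(curve.times_s[v], curve.values_percent[v])
    above = float(np.trapezoid(np.maximum(y, 0.0), t)) + 0.0
    below = float(-np.trapezoid(np.minimum(y, 0.0), t)) + 0.0  # +0.0 kills -0.0
    rate_rms = float("nan")
    n_valid = int(v.sum())
    if rate is not None:
        rv = rate.valid
        if not rv.any():
            raise ValueError("all rate samples masked")
        rate_rms = float(np.sqrt(np.mean(
            rate.values_percent_per_s[rv] ** 2)))
    return AreaDecomposition(area_above=above, area_below=below,
                             total=above + below, difference=above - below,
                             rate_rms=rate_rms, n_valid=n_valid)


def build_feature_table(results: list[dict]) -> pd.DataFrame:
    """Assemble the subjects x 25-variable feature table.

    Each input record is a dict with the metadata keys (subject, group,
    sex, age, wad_grade, timepoint, direction) and a ``muscles`` mapping
    muscle label -> :class:`AreaDecomposition`. Records missing any of the
    five muscles are rejected with a logged reason. Column order is fixed:
    metadata first, then the 25 features muscle-major
    (TR_total, TR_under, ... MF_rate_rms).
    """
    rows = []
    for rec in results:
        muscles = rec.get("muscles", {})
        missing = [m for m in MUSCLES if m not in muscles]
        if missing:
            logger.warning("rejecting %s/%s/%s: missing muscles %s",
                           rec.get("subject"), rec.get("timepoint"),
                           rec.get("direction"), missing)
            continue
        row = {k: rec.get(k) for k in METADATA_COLUMNS}
        for m in MUSCLES:
            d = muscles[m].as_dict()
            for s in AREA_STATS:
                row[f"{m}_{s}"] = d[s]
        rows.append(row)
    table = pd.DataFrame(rows, columns=list(METADATA_COLUMNS) + list(FEATURE_COLUMNS))
    return table


def feature_matrix(table: pd.DataFrame) -> np.ndarray:
    """The 25-column numeric block of a feature table, fixed order."""
    return table[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
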