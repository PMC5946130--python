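"""Ant-activity estimation from fixed-camera frame sequences.

Consecutive frames are registered by an exhaustive integer-translation
search maximising mutual information, the absolute difference image is
summed inside a mound mask, and the raw sum of absolute differences (SAD)
is mapped onto manually assigned activity categories by a per-sensor
polynomial (first order for the daytime sensor, third order for the
nighttime sensor) fitted to centered/scaled data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import FrameSequence

logger = logging.getLogger("antnest_seep")

#: polynomial degree per sensor
SENSOR_DEGREES = {"day": 1, "night": 3}
DEFAULT_BINS = 64
DEFAULT_MAX_SHIFT = 5


# ---------------------------------------------------------------------------
# Mutual information & registration
# ---------------------------------------------------------------------------

def mutual_information(a: np.ndarray, b: np.ndarray,
                       bins: int = DEFAULT_BINS) -> float:
    """Mutual information (bits) of the joint intensity histogram.

    MI = sum_ij p(i,j) * log2( p(i,j) / (p(i) p(j)) ) >= 0, with the joint
    histogram binned over each image's own intensity range.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"frame dimensions differ: {a.shape} vs {b.shape}")
    if bins < 2:
        raise ValueError("bins must be >= 2")
    joint, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    pj = joint / joint.sum()
    px = pj.sum(axis=1)
    py = pj.sum(axis=0)
    nz = pj > 0
    outer = np.outer(px, py)
    return float(np.sum(pj[nz] * np.log2(pj[nz] / outer[nz])))


def _overlap(ref: np.ndarray, cur: np.ndarray,
             dx: int, dy: int) -> tuple[np.ndarray, np.ndarray] | None:
    """Aligned views for the hypothesis cur[y, x] == ref[y - dy, x - dx]."""
    h, w = ref.shape
    y0, y1 = max(dy, 0), h + min(dy, 0)
    x0, x1 = max(dx, 0), w + min(dx, 0)
    if y1 <= y0 or x1 <= x0:
        return None
    return ref[y0 - dy:y1 - dy, x0 - dx:x1 - dx], cur[y0:y1, x0:x1]


def register_translation(ref: np.ndarray, cur: np.ndarray,
                         max_shift: int = DEFAULT_MAX_SHIFT,
                         bins: int = DEFAULT_BINS) -> tuple[int, int]:
    """Integer translation (dx, dy) of ``cur`` relative to ``ref``.

    Exhaustive search over [-max_shift, max_shift]^2 maximising mutual
    information of the overlapping region; ties broken by smallest shift
    norm, then lexicographically. Shifts with empty overlap are skipped.
    """
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    candidates = sorted(
        ((dx, dy) for dx in range(-max_shift, max_shift + 1)
         for dy in range(-max_shift, max_shift + 1)),
        key=lambda s: (s[0] * s[0] + s[1] * s[1], s))
    best, best_mi = (0, 0), -np.inf
    for dx, dy in candidates:
        views = _overlap(np.asarray(ref, float), np.asarray(cur, float), dx, dy)
        if views is None:
            continue
        mi = mutual_information(views[0], views[1], bins=bins)
        if mi > best_mi:
            best, best_mi = (dx, dy), mi
    return best


# ---------------------------------------------------------------------------
# Difference-image activity
# ---------------------------------------------------------------------------

def activity_raw(prev: np.ndarray, cur: np.ndarray, mask: np.ndarray,
                 shift: tuple[int, int] = (0, 0)) -> float:
    """Sum of absolute differences inside the mask after registration.

    ``shift`` is the (dx, dy) of ``cur`` relative to ``prev`` as returned by
    :func:`register_translation`; pixels lost to the shift are excluded.
    """
    prev = np.asarray(prev, dtype=float)
    cur = np.asarray(cur, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != prev.shape:
        raise ValueError("mask dimensions do not match frames")
    if not mask.any():
        raise ValueError("mask is empty (all zero)")
    dx, dy = shift
    views = _overlap(prev, cur, dx, dy)
    if views is None:
        raise ValueError("registration shift leaves no overlap")
    h, w = prev.shape
    y0, y1 = max(dy, 0), h + min(dy, 0)
    x0, x1 = max(dx, 0), w + min(dx, 0)
    m = mask[y0:y1, x0:x1]
    return float(np.abs(views[1] - views[0])[m].sum())


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationModel:
    """Per-sensor polynomial mapping raw SAD to activity categories.

    The raw series is standardised with the stored ``center_mean`` and
    ``center_sd`` before evaluating the polynomial (coefficients in
    ascending order).
    """

    sensor: str
    degree: int
    coefficients: np.ndarray
    center_mean: float
    center_sd: float

    def __call__(self, raw) -> np.ndarray:
        return apply_calibration(self, raw)


def fit_calibration(raw: np.ndarray, labels: np.ndarray,
                    sensor: str, degree: int | None = None) -> CalibrationModel:
    """Least-squares polynomial from raw SAD to manual activity categories.

    Raw values are centered and scaled (mean / SD of the calibration
    window) before the fit; the sensor decides the default degree (day: 1,
    night: 3).
    """
    raw = np.asarray(raw, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if degree is None:
        degree = SENSOR_DEGREES[sensor]
    if np.unique(raw).size < degree + 1:
        raise ValueError(f"need >= {degree + 1} distinct raw values")
    mean = float(raw.mean())
    sd = float(raw.std(ddof=0))
    if sd <= 0:
        raise ValueError("zero variance in raw SAD; cannot scale")
    z = (raw - mean) / sd
    coef = np.polynomial.polynomial.polyfit(z, labels, degree)
    return CalibrationModel(sensor=sensor, degree=degree, coefficients=coef,
                            center_mean=mean, center_sd=sd)


def apply_calibration(model: CalibrationModel, raw) -> np.ndarray | float:
    """Evaluate the calibration polynomial on standardised raw SAD."""
    z = (np.asarray(raw, dtype=float) - model.center_mean) / model.center_sd
    out = np.polynomial.polynomial.polyval(z, model.coefficients)
    return float(out) if np.ndim(raw) == 0 else out


# ---------------------------------------------------------------------------
# Sequence scoring
# ---------------------------------------------------------------------------

def score_frames(seq: FrameSequence,
                 calibrations: dict[str, CalibrationModel] | None = None,
                 max_shift: int = DEFAULT_MAX_SHIFT,
                 bins: int = DEFAULT_BINS) -> pd.DataFrame:
    """Register + difference + mask + sum every consecutive frame pair.

    Returns one row per frame after the first: ``timestamp, raw_sad,
    activity, sensor`` (activity NaN when no calibration is supplied for
    that sensor).
    """
    rows = []
    for i in range(1, len(seq)):
        shift = register_translation(seq.frames[i - 1], seq.frames[i],
                                     max_shift=max_shift, bins=bins)
        raw = activity_raw(seq.frames[i - 1], seq.frames[i], seq.mask,
                           shift=shift)
        sensor = str(seq.sensors[i])
        act = np.nan
        if calibrations and sensor in calibrations:
            act = apply_calibration(calibrations[sensor], raw)
        rows.append((seq.timestamps[i], raw, act, sensor))
    out = pd.DataFrame(rows, columns=["timestamp", "raw_sad", "activity",
                                      "sensor"])
    logger.info("score_frames: scored %d frame pairs", len(out))
    return out


def aggregate_activity(activity: pd.DataFrame,
                       interval: str = "5min") -> pd.DataFrame:
    """Median activity per time bin (the statistic used downstream)."""
    g = activity.set_index("timestamp")[["raw_sad", "activity"]]
    return g.resample(interval).median().dropna(how="all").reset_index()


def read_frames(directory) -> FrameSequence:
    """Read ``frame_<epoch-ms>_<D|N>.png`` frames plus ``mask.png``."""
    import os
    import re

    import imageio.v3 as iio

    pat = re.compile(r"frame_(\d+)_([DN])\.png$")
    entries = []
    for name in os.listdir(directory):
        m = pat.match(name)
        if m:
            entries.append((int(m.group(1)), m.group(2), name))
    if not entries:
        raise FileNotFoundError(f"no frame_<epoch-ms>_<D|N>.png in {directory}")
    entries.sort()
    frames = np.stack([iio.imread(os.path.join(directory, e[2]))
                       for e in entries])
    ts = pd.to_datetime([e[0] for e in entries], unit="ms", utc=True)
    sensors = np.where([e[1] == "D" for e in entries], "day", "night")
    mask_path = os.path.join(directory, "mask.png")
    mask = (iio.imread(mask_path) > 0 if os.path.exists(mask_path)
            else np.ones(frames.shape[1:], dtype=bool))
    n = len(entries)
    return FrameSequence(frames=frames, timestamps=pd.DatetimeIndex(ts),
                         sensors=sensors, mask=mask,
                         jitter=np.zeros((n, 2), dtype=int),
                         truth_moved=np.zeros(n, dtype=int))
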