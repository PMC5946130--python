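"""CH4 / delta-13C anomaly detection and Keeling source partitioning.

Peaks in the CH4 record are samples above the robust median + k*MAD
threshold; delta-13C peaks are flagged either by the literal fixed bounds
(< -35 permil or > 0 permil) or by a robust deviation rule (|d13c -
median| > k*MAD). Only samples flagged in both records at the same time
form true peak windows. The Keeling plot — ordinary least squares of
delta-13C on 1/CH4 — estimates the isotopic signature of the added source
as its intercept, by two-reservoir mass conservation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("antnest_seep")

#: literal delta-13C peak bounds, permil
D13C_LITERAL_LOW = -35.0
D13C_LITERAL_HIGH = 0.0
DEFAULT_MAD_K = 2.0
#: windows closer than this merge; shorter windows are discarded as noise
DEFAULT_MIN_GAP = 60.0  # seconds
DEFAULT_MIN_SAMPLES = 10
#: a window must contain this many *consecutive* coincident samples —
#: chance double-flags of the two noise processes are serially independent,
#: so requiring a run kills them at any record length
DEFAULT_MIN_RUN = 5


# ---------------------------------------------------------------------------
# Robust thresholding
# ---------------------------------------------------------------------------

def mad_threshold(values, k: float = DEFAULT_MAD_K,
                  scale: float = 1.0) -> float:
    """median + k * MAD anomaly threshold.

    The MAD is raw, median(|x - median(x)|), without the Gaussian
    consistency constant 1.4826 (pass ``scale=1.4826`` for the scaled
    convention).
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need >= 2 finite values")
    med = float(np.median(x))
    mad = float(np.median(np.abs(x - med)))
    return med + k * scale * mad


def flag_ch4_peaks(ch4, threshold: float) -> np.ndarray:
    """Strictly above-threshold CH4 samples."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    return np.asarray(ch4, dtype=float) > threshold


def flag_d13c_peaks(d13c, mode: str, low: float = D13C_LITERAL_LOW,
                    high: float = D13C_LITERAL_HIGH,
                    k: float = DEFAULT_MAD_K) -> np.ndarray:
    """delta-13C peak flags.

    ``literal``: the fixed-bound rule as published (d13c < low or
    d13c > high). ``deviation``: robust two-sided rule,
    |d13c - median| > k * MAD. The mode must be chosen explicitly; the
    literal bounds flag an entire biogenic-range record, so pipelines
    default to ``deviation``.
    """
    x = np.asarray(d13c, dtype=float)
    if mode == "literal":
        return (x < low) | (x > high)
    if mode == "deviation":
        med = float(np.median(x[np.isfinite(x)]))
        mad = float(np.median(np.abs(x[np.isfinite(x)] - med)))
        return np.abs(x - med) > k * mad
    raise ValueError(f"mode must be 'literal' or 'deviation', got {mode!r}")


# ---------------------------------------------------------------------------
# Coincident peak windows
# ---------------------------------------------------------------------------

@dataclass
class PeakSet:
    """Disjoint coincident-anomaly windows.

    ``windows`` rows: start, end, n (coincident samples), plus which rule
    combination fired; ``member`` marks every sample inside a window.
    """

    windows: pd.DataFrame
    member: np.ndarray  # bool per input sample
    flags: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.windows)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """[start, stop) index runs of True."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.r_[idx[0], idx[breaks + 1]]
    stops = np.r_[idx[breaks] + 1, idx[-1] + 1]
    return list(zip(starts, stops))


def _longest_run(mask: np.ndarray) -> int:
    best = cur = 0
    for v in mask:
        cur = cur + 1 if v else 0
        if cur > best:
            best = cur
    return best


def coincident_peaks(timestamps, ch4_flags, d13c_flags,
                     tolerance: float = 0.0,
                     min_gap: float = DEFAULT_MIN_GAP,
                     min_samples: int = DEFAULT_MIN_SAMPLES,
                     min_run: int = DEFAULT_MIN_RUN) -> PeakSet:
    """True peaks: maximal runs flagged in both records at the same time.

    ``tolerance`` dilates each flag series by that many seconds before the
    intersection; runs separated by less than ``min_gap`` seconds merge. A
    merged window survives only if it holds at least ``min_samples``
    coincident samples of which at least ``min_run`` are consecutive — the
    consecutive-run requirement is what separates genuine emission episodes
    (serially coherent) from chance coincidences of the two noise
    processes (serially independent).
    """
    ts = pd.DatetimeIndex(timestamps)
    ch4_flags = np.asarray(ch4_flags, dtype=bool)
    d13c_flags = np.asarray(d13c_flags, dtype=bool)
    if not (len(ts) == len(ch4_flags) == len(d13c_flags)):
        raise ValueError("timestamps and flag series must align")
    if len(ts) == 0:
        empty = pd.DataFrame(columns=["start", "end", "n", "rule"])
        return PeakSet(windows=empty, member=np.zeros(0, dtype=bool))

    dt = 1.0
    if len(ts) > 1:
        dt = float(np.median(np.diff(ts.view("int64"))) / 1e9)
    if tolerance > 0:
        w = int(round(tolerance / dt))
        if w > 0:
            kernel = np.ones(2 * w + 1, dtype=bool)
            ch4_flags = np.convolve(ch4_flags, kernel, mode="same") > 0
            d13c_flags = np.convolve(d13c_flags, kernel, mode="same") > 0
    both = ch4_flags & d13c_flags

    runs = _runs(both)
    # merge runs separated by < min_gap seconds
    merged: list[list[int]] = []
    gap_n = max(1, int(round(min_gap / dt)))
    for s, e in runs:
        if merged and s - merged[-1][1] < gap_n:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    member = np.zeros(len(ts), dtype=bool)
    rows = []
    for s, e in merged:
        n = int(both[s:e].sum())
        if n < min_samples or _longest_run(both[s:e]) < min_run:
            continue
        member[s:e] = both[s:e]
        rows.append((ts[s], ts[e - 1], n, "both"))
    windows = pd.DataFrame(rows, columns=["start", "end", "n", "rule"])
    logger.info("coincident_peaks: %d windows (%d coincident samples)",
                len(windows), int(member.sum()))
    return PeakSet(windows=windows, member=member)


# ---------------------------------------------------------------------------
# Percentile split
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PercentileSummary:
    subset: str
    n: int
    mean: float
    se: float
    min: float
    max: float


def percentile_summary(values, q: float = 0.90
                       ) -> tuple[PercentileSummary, PercentileSummary]:
    """Descriptive statistics for all samples and those strictly above the
    q-quantile (type-7 / linear-interpolation quantile)."""
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError("need >= 10 samples")

    def summ(sub: np.ndarray, name: str) -> PercentileSummary:
        if sub.size == 0:
            return PercentileSummary(name, 0, np.nan, np.nan, np.nan, np.nan)
        return PercentileSummary(
            name, int(sub.size), float(sub.mean()),
            float(sub.std(ddof=1) / np.sqrt(sub.size)) if sub.size > 1 else np.nan,
            float(sub.min()), float(sub.max()))

    cut = float(np.quantile(x, q))  # numpy default = linear (type 7)
    return summ(x, "all"), summ(x[x > cut], "above_q")


# ---------------------------------------------------------------------------
# Keeling regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KeelingFit:
    """OLS of delta-13C on 1/CH4: the intercept estimates the source
    signature added onto a constant background."""

    intercept: float  # permil, source signature estimate
    slope: float  # permil * ppm
    r2: float
    ci95: tuple[float, float]  # on the intercept
    n: int
    intercept_se: float


def keeling_fit(ch4, d13c) -> KeelingFit:
    """Fit the Keeling plot.

    Under two-reservoir mass conservation the mixing points satisfy
    delta = delta_s + C_a (delta_a - delta_s) * (1 / C_obs), so the
    intercept at 1/C -> 0 is the source signature delta_s. The 95% CI uses
    the standard OLS intercept SE with the t quantile on n - 2 df.
    """
    c = np.asarray(ch4, dtype=float)
    d = np.asarray(d13c, dtype=float)
    ok = np.isfinite(c) & np.isfinite(d) & (c > 0)
    c, d = c[ok], d[ok]
    if c.size < 3:
        raise ValueError("need >= 3 samples for a Keeling fit")
    x = 1.0 / c
    if np.ptp(x) == 0:
        raise ValueError("degenerate Keeling fit: all CH4 values equal")
    res = stats.linregress(x, d)
    tq = stats.t.ppf(0.975, c.size - 2)
    half = tq * res.intercept_stderr
    return KeelingFit(
        intercept=float(res.intercept), slope=float(res.slope),
        r2=float(res.rvalue ** 2),
        ci95=(float(res.intercept - half), float(res.intercept + half)),
        n=int(c.size), intercept_se=float(res.intercept_stderr))


def keeling_per_window(gas: pd.DataFrame, peaks: PeakSet,
                       samples: str = "window") -> list[KeelingFit]:
    """One Keeling fit per coincident-peak window.

    ``samples="window"`` (default) fits every observation inside the
    window span, the usual Keeling-plot practice for an identified
    emission episode; it is free of the selection-on-noise tilt that
    arises when only threshold-exceeding samples enter the regression.
    ``samples="flagged"`` restricts to the coincident-flagged members.
    Windows with too few samples or degenerate CH4 spread are skipped
    with a log entry.
    """
    if samples not in ("window", "flagged"):
        raise ValueError("samples must be 'window' or 'flagged'")
    ts = pd.DatetimeIndex(gas["timestamp"])
    fits = []
    for _, w in peaks.windows.iterrows():
        sel = (ts >= w["start"]) & (ts <= w["end"])
        if samples == "flagged":
            sel &= peaks.member
        try:
            fits.append(keeling_fit(gas.loc[sel, "ch4"], gas.loc[sel, "d13c"]))
        except ValueError as exc:
            logger.warning("window %s skipped: %s", w["start"], exc)
    return fits


def cluster_intercepts(intercepts, n_clusters: int = 2
                       ) -> tuple[np.ndarray, np.ndarray]:
    """1-D two-means split of per-window Keeling intercepts.

    Deterministic extreme-point initialisation; returns (labels, centers)
    with centers sorted ascending. With fewer intercepts than clusters all
    points share label 0.
    """
    x = np.asarray(intercepts, dtype=float).reshape(-1, 1)
    if len(x) < n_clusters or np.ptp(x) == 0:
        return np.zeros(len(x), dtype=int), np.sort(np.unique(x.ravel()))
    from sklearn.cluster import KMeans

    init = np.linspace(x.min(), x.max(), n_clusters).reshape(-1, 1)
    km = KMeans(n_clusters=n_clusters, init=init, n_init=1).fit(x)
    order = np.argsort(km.cluster_centers_.ravel())
    remap = np.empty_like(order)
    remap[order] = np.arange(n_clusters)
    return remap[km.labels_], np.sort(km.cluster_centers_.ravel())


# ---------------------------------------------------------------------------
# Isotope notation & drift correction
# ---------------------------------------------------------------------------

def delta_from_ratio(r_sample: float, r_standard: float) -> float:
    """delta (permil) = (R_sample / R_standard - 1) * 1000."""
    if r_standard == 0:
        raise ValueError("r_standard must be nonzero")
    return (r_sample / r_standard - 1.0) * 1000.0


def drift_correct(gas: pd.DataFrame, reference_ch4: float,
                  reference_d13c: float, max_ch4_offset: float = 0.5,
                  max_d13c_offset: float = 10.0,
                  run_gap: float = 600.0) -> pd.DataFrame:
    """Piecewise-linear instrument-drift correction from reference-gas runs.

    Each run of the ``reference`` channel yields a mean offset against the
    known cylinder values; offsets are linearly interpolated in time (edge
    values extended) and subtracted from the nest and ambient channels.
    Runs with implausible offsets are excluded with a warning.
    """
    ref = gas[gas["channel"] == "reference"]
    if ref.empty:
        raise ValueError("no reference-channel samples present")
    ts = pd.DatetimeIndex(ref["timestamp"]).view("int64") / 1e9
    gaps = np.r_[np.inf, np.diff(ts)]
    run_id = np.cumsum(gaps > run_gap)
    mids, off_c, off_d = [], [], []
    for rid in np.unique(run_id):
        sel = run_id == rid
        oc = float(ref.loc[sel, "ch4"].mean() - reference_ch4)
        od = float(ref.loc[sel, "d13c"].mean() - reference_d13c)
        if abs(oc) > max_ch4_offset or abs(od) > max_d13c_offset:
            logger.warning("reference run %d offset implausible "
                           "(%.3f ppm, %.2f permil); excluded", rid, oc, od)
            continue
        mids.append(float(ts[sel].mean()))
        off_c.append(oc)
        off_d.append(od)
    if not mids:
        raise ValueError("no plausible reference runs remain")

    out = gas.copy()
    target = out["channel"].isin(["nest", "ambient"])
    t_all = pd.DatetimeIndex(out.loc[target, "timestamp"]).view("int64") / 1e9
    corr_c = np.interp(t_all, mids, off_c)
    corr_d = np.interp(t_all, mids, off_d)
    out.loc[target, "ch4"] = out.loc[target, "ch4"] - corr_c
    out.loc[target, "d13c"] = out.loc[target, "d13c"] - corr_d
    return out


def peakset_to_frame(peaks: PeakSet) -> pd.DataFrame:
    """Interval-table (BED-like) serialisation of a PeakSet."""
    return peaks.windows.copy()
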