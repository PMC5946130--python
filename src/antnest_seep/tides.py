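"""Harmonic solid-earth-tide model.

An equilibrium-tide approximation: vertical displacement as a sum of
cosine constituents (defaults M2, S2, K1, O1), giving the semidiurnal
phase structure needed for cross-correlation against the gas record. Not
a geodetic ephemeris — amplitudes and phases are configurable, accuracy
is spectral, not absolute.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .envstats import CrossCorrelation, aggregate_median, cross_correlation
from .synthetic_data import DEFAULT_TIDE_CONSTITUENTS


def tide_series(start, end, step: float = 300.0,
                constituents=DEFAULT_TIDE_CONSTITUENTS) -> pd.DataFrame:
    """displacement(t) = sum_i A_i cos(2 pi t / T_i + phi_i).

    ``step`` in seconds; constituents are (name, period_h, amplitude_mm,
    phase_rad) tuples. Deterministic.
    """
    if step <= 0:
        raise ValueError("step must be > 0")
    if not constituents:
        raise ValueError("need at least one constituent")
    start = pd.Timestamp(start)
    end = pd.Timestamp(end)
    t = np.arange(0.0, (end - start).total_seconds(), step)
    hours = t / 3600.0
    disp = np.zeros_like(t)
    for _name, period_h, amp, phase in constituents:
        disp += amp * np.cos(2 * np.pi * hours / period_h + phase)
    return pd.DataFrame({
        "timestamp": start + pd.to_timedelta(t, unit="s"),
        "displacement": disp,
    })


def dominant_period(tides: pd.DataFrame) -> float:
    """Periodogram-argmax period (hours) of a tide series."""
    disp = tides["displacement"].to_numpy()
    ts = pd.DatetimeIndex(tides["timestamp"])
    dt_h = float(np.median(np.diff(ts.view("int64"))) / 1e9) / 3600.0
    power = np.abs(np.fft.rfft(disp - disp.mean())) ** 2
    freqs = np.fft.rfftfreq(disp.size, d=dt_h)
    k = int(np.argmax(power[1:]) + 1)
    return 1.0 / freqs[k]


def tide_gas_ccf(tides: pd.DataFrame, gas: pd.DataFrame, max_lag: int,
                 interval: str = "5min",
                 gas_col: str = "ch4") -> CrossCorrelation:
    """Cross-correlate gas against tidal displacement on a common grid.

    Both series are median-aggregated to ``interval`` bins, trimmed to
    their overlap, and passed to
    :func:`antnest_seep.envstats.cross_correlation` (lags in bins;
    positive lag = gas trailing the tide).
    """
    tg = aggregate_median(tides, ["displacement"], interval)
    gg = aggregate_median(gas, [gas_col], interval)
    joined = tg.join(gg, how="inner").dropna()
    return cross_correlation(joined["displacement"].to_numpy(),
                             joined[gas_col].to_numpy(), max_lag)
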