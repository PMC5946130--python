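"""Synthetic monitoring-campaign generator.

Emulates an 8-day continuous in-situ record at a red wood-ant nest: 1-Hz
nest-gas CH4 (ppm) and delta-13C-CH4 (permil VPDB) on an atmospheric
background with episodic source injections mixed by two-reservoir isotope
mass balance, an ambient-air channel sampled 15 min every 4 h, periodic
reference-gas runs, 5-min weather, harmonic earth tides, a sparse
micro-earthquake catalog, and fixed-camera frame sequences with moving
bright blobs plus integer camera jitter.

Every stream carries known ground truth and is reproducible bit-for-bit
from the scenario seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

logger = logging.getLogger("antnest_seep")

#: Default atmospheric CH4 background, ppm.
ATM_CH4_PPM = 1.82
#: Default atmospheric delta-13C-CH4, permil VPDB (modern-atmosphere convention;
#: configurable, the campaign never measured it directly).
ATM_D13C_PERMIL = -47.0

#: Default harmonic tide constituents: (name, period in hours, amplitude in mm
#: vertical displacement, phase in radians).
DEFAULT_TIDE_CONSTITUENTS: tuple[tuple[str, float, float, float], ...] = (
    ("M2", 12.4206, 120.0, 0.0),
    ("S2", 12.0000, 56.0, 0.0),
    ("K1", 23.9345, 80.0, 0.0),
    ("O1", 25.8193, 57.0, 0.0),
)

GAS_COLUMNS = ["timestamp", "ch4", "d13c", "channel"]
WEATHER_COLUMNS = [
    "timestamp", "temperature", "pressure", "dewpoint",
    "humidity", "rainfall", "windspeed",
]


@dataclass(frozen=True)
class SourceEvent:
    """One episodic CH4 injection into the nest gas stream.

    ``start`` is seconds from campaign start; ``d13c_source`` is the
    end-member signature delta_s the Keeling chain should recover.
    """

    d13c_source: float
    start: float
    duration: float
    peak_excess: float
    shape: str = "gaussian"  # boxcar | triangular | gaussian

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("SourceEvent.duration must be > 0")
        if self.peak_excess < 0:
            raise ValueError("SourceEvent.peak_excess must be >= 0")
        if self.shape not in ("boxcar", "triangular", "gaussian"):
            raise ValueError(f"unknown source shape {self.shape!r}")

    def excess(self, t: np.ndarray) -> np.ndarray:
        """Concentration excess (ppm) contributed at times ``t`` (seconds)."""
        u = (np.asarray(t, dtype=float) - self.start) / self.duration
        inside = (u >= 0.0) & (u < 1.0)
        if self.shape == "boxcar":
            prof = inside.astype(float)
        elif self.shape == "triangular":
            prof = np.where(inside, 1.0 - np.abs(2.0 * u - 1.0), 0.0)
        else:  # gaussian bump truncated to the event window, sigma = T/6
            prof = np.where(inside, np.exp(-0.5 * ((u - 0.5) / (1.0 / 6.0)) ** 2), 0.0)
        return self.peak_excess * prof


@dataclass(frozen=True)
class QuakeEvent:
    """One catalog entry of a local micro-earthquake."""

    time: pd.Timestamp
    magnitude: float
    depth: float  # km
    distance: float  # km from the nest
    lat: float
    lon: float

    def __post_init__(self) -> None:
        if self.depth < 0 or self.distance < 0:
            raise ValueError("QuakeEvent depth and distance must be >= 0")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full generative description of one synthetic campaign.

    Defaults are the study conditions: 8 days at 1 Hz on a 1.82-ppm
    atmospheric background, instrument-level noise (CH4 0.005 ppm,
    delta-13C 0.8 permil), ambient air 15 min every 4 h, reference gas
    every 8 h, 5-min weather, semidiurnal-dominated tides.
    """

    duration: float = 8 * 86400.0
    gas_rate: float = 1.0
    start: pd.Timestamp = pd.Timestamp("2016-08-04T00:00:00Z")
    background_ch4: float = ATM_CH4_PPM
    background_d13c: float = ATM_D13C_PERMIL
    sources: tuple[SourceEvent, ...] = ()
    ch4_noise_sd: float = 0.005
    d13c_noise_sd: float = 0.8
    ch4_floor: float = 1e-3
    drift_ch4_per_day: float = 0.0
    drift_d13c_per_day: float = 0.0
    ambient_interval: float = 4 * 3600.0
    ambient_duration: float = 900.0
    reference_interval: float = 8 * 3600.0
    reference_duration: float = 300.0
    reference_offset: float = 7200.0
    reference_ch4: float = 2.0
    reference_d13c: float = -40.0
    weather_interval: float = 300.0
    temp_mean: float = 16.2
    temp_amplitude: float = 8.0
    temp_noise_sd: float = 1.2
    pressure_mean: float = 988.0
    pressure_sd: float = 2.24
    humidity_base: float = 70.0
    humidity_coupling: float = 2.5  # % per degC, anti-correlating with temperature
    humidity_noise_sd: float = 4.0
    rain_prob: float = 0.004
    rain_scale: float = 0.3
    wind_mean: float = 1.67
    tide_constituents: tuple[tuple[str, float, float, float], ...] = DEFAULT_TIDE_CONSTITUENTS
    quake_list: tuple[QuakeEvent, ...] = ()
    frame_rate: float = 1.0
    frame_size: int = 64
    n_ants: int = 6
    jitter_px: int = 2
    frame_window: float = 600.0
    day_start_hour: int = 6
    day_end_hour: int = 18
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_ch4 <= 0:
            raise ValueError("background_ch4 must be > 0")
        if self.gas_rate <= 0:
            raise ValueError("gas_rate must be > 0")
        if self.ch4_noise_sd < 0 or self.d13c_noise_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent substream generator; all randomness flows from ``seed``."""
        return np.random.default_rng([int(self.seed) & 0x7FFFFFFF, stream])

    def times(self, step: float, duration: float | None = None,
              offset: float = 0.0) -> np.ndarray:
        dur = self.duration if duration is None else duration
        return offset + np.arange(int(round(dur / step))) * step

    def to_timestamps(self, seconds: np.ndarray) -> pd.DatetimeIndex:
        return self.start + pd.to_timedelta(seconds, unit="s")


# ---------------------------------------------------------------------------
# Gas
# ---------------------------------------------------------------------------

def mixing_d13c(c_excess: np.ndarray, d13c_sources: np.ndarray,
                c_a: float, d_a: float) -> np.ndarray:
    """Two-reservoir isotope mass balance.

    delta_obs = (C_a*delta_a + sum_i C_i*delta_i) / (C_a + sum_i C_i), with
    ``c_excess`` of shape (n_sources, n_times).
    """
    c_excess = np.atleast_2d(np.asarray(c_excess, dtype=float))
    d13c_sources = np.asarray(d13c_sources, dtype=float)
    total = c_a + c_excess.sum(axis=0)
    weighted = c_a * d_a + (c_excess * d13c_sources[:, None]).sum(axis=0)
    return weighted / total


def total_excess(config: ScenarioConfig, t: np.ndarray) -> np.ndarray:
    """Summed true concentration excess (ppm) at times ``t`` (seconds)."""
    out = np.zeros_like(np.asarray(t, dtype=float))
    for src in config.sources:
        out += src.excess(t)
    return out


def _drift(config: ScenarioConfig, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    days = np.asarray(t, dtype=float) / 86400.0
    return config.drift_ch4_per_day * days, config.drift_d13c_per_day * days


def _channel_frame(config: ScenarioConfig, t: np.ndarray, ch4: np.ndarray,
                   d13c: np.ndarray, channel: str) -> pd.DataFrame:
    floor = config.ch4_floor
    n_clip = int(np.count_nonzero(ch4 < floor))
    if n_clip:
        logger.warning("%s channel: %d CH4 samples below floor %.3g ppm clipped",
                       channel, n_clip, floor)
        ch4 = np.maximum(ch4, floor)
    return pd.DataFrame({
        "timestamp": config.to_timestamps(t),
        "ch4": ch4,
        "d13c": d13c,
        "channel": channel,
    })


def simulate_gas(config: ScenarioConfig) -> pd.DataFrame:
    """Simulate the nest, ambient and reference gas channels.

    Nest: C_obs = C_a + sum_i C_excess_i + drift + eps_C and delta_obs from
    the mass-balance mixing of all active sources, plus eps_delta. Ambient:
    background only, sampled ``ambient_duration`` every ``ambient_interval``.
    Reference: known cylinder values measured every ``reference_interval``
    (carrying any instrument drift, which :func:`antnest_seep.gaschem.
    drift_correct` can remove).

    Returns a tidy frame with columns ``timestamp, ch4, d13c, channel``.
    """
    step = 1.0 / config.gas_rate
    rng = config.rng(1)

    # nest channel
    t = config.times(step)
    if config.sources:
        per_source = np.vstack([src.excess(t) for src in config.sources])
        d_src = np.array([src.d13c_source for src in config.sources])
        d_true = mixing_d13c(per_source, d_src,
                             config.background_ch4, config.background_d13c)
        c_true = config.background_ch4 + per_source.sum(axis=0)
    else:
        c_true = np.full(t.shape, config.background_ch4)
        d_true = np.full(t.shape, config.background_d13c)
    dc, dd = _drift(config, t)
    ch4 = c_true + dc + rng.normal(0.0, config.ch4_noise_sd, t.size)
    d13c = d_true + dd + rng.normal(0.0, config.d13c_noise_sd, t.size)
    frames = [_channel_frame(config, t, ch4, d13c, "nest")]

    # ambient channel: background + noise, 15 min every 4 h
    amb_t = []
    w0 = 0.0
    while w0 < config.duration:
        n_w = int(round(min(config.ambient_duration, config.duration - w0) / step))
        amb_t.append(w0 + np.arange(n_w) * step)
        w0 += config.ambient_interval
    if amb_t:
        ta = np.concatenate(amb_t)
        dca, dda = _drift(config, ta)
        ch4_a = config.background_ch4 + dca + rng.normal(0.0, config.ch4_noise_sd, ta.size)
        d13c_a = config.background_d13c + dda + rng.normal(0.0, config.d13c_noise_sd, ta.size)
        frames.append(_channel_frame(config, ta, ch4_a, d13c_a, "ambient"))

    # reference channel: cylinder gas every 8 h
    ref_t = []
    r0 = config.reference_offset
    while r0 + config.reference_duration <= config.duration:
        n_r = int(round(config.reference_duration / step))
        ref_t.append(r0 + np.arange(n_r) * step)
        r0 += config.reference_interval
    if ref_t:
        tr = np.concatenate(ref_t)
        dcr, ddr = _drift(config, tr)
        ch4_r = config.reference_ch4 + dcr + rng.normal(0.0, config.ch4_noise_sd, tr.size)
        d13c_r = config.reference_d13c + ddr + rng.normal(0.0, config.d13c_noise_sd, tr.size)
        frames.append(_channel_frame(config, tr, ch4_r, d13c_r, "reference"))

    gas = pd.concat(frames, ignore_index=True)
    logger.info("simulate_gas: %d samples (%d nest)", len(gas),
                int((gas["channel"] == "nest").sum()))
    return gas


# ---------------------------------------------------------------------------
# Weather
# ---------------------------------------------------------------------------

def simulate_weather(config: ScenarioConfig) -> pd.DataFrame:
    """Simulate the six-variable 5-min weather table.

    Temperature is a diurnal sinusoid (peak mid-afternoon) plus Gaussian
    noise; humidity is anti-correlated with temperature; pressure is a slow
    AR(1) walk; rainfall is sparse and non-negative.
    """
    if config.duration < config.weather_interval:
        raise ValueError("duration shorter than weather_interval")
    rng = config.rng(2)
    t = config.times(config.weather_interval)
    hours = t / 3600.0
    # peak at 15:00 local solar time
    diurnal = np.sin(2 * np.pi * (hours - 9.0) / 24.0)
    temp = config.temp_mean + config.temp_amplitude * diurnal \
        + rng.normal(0.0, config.temp_noise_sd, t.size)
    ar = np.empty(t.size)
    ar[0] = 0.0
    innov = rng.normal(0.0, 1.0, t.size)
    for i in range(1, t.size):
        ar[i] = 0.995 * ar[i - 1] + 0.1 * innov[i]
    pressure = config.pressure_mean + config.pressure_sd * ar
    humidity = np.clip(
        config.humidity_base
        - config.humidity_coupling * (temp - config.temp_mean)
        + rng.normal(0.0, config.humidity_noise_sd, t.size),
        0.0, 100.0)
    dewpoint = temp - (100.0 - humidity) / 5.0  # Magnus-style rule of thumb
    rain = np.where(rng.random(t.size) < config.rain_prob,
                    rng.exponential(config.rain_scale, t.size), 0.0)
    wind = np.abs(rng.normal(config.wind_mean, config.wind_mean, t.size))
    return pd.DataFrame({
        "timestamp": config.to_timestamps(t),
        "temperature": temp,
        "pressure": pressure,
        "dewpoint": dewpoint,
        "humidity": humidity,
        "rainfall": rain,
        "windspeed": wind,
    })


# ---------------------------------------------------------------------------
# Frames
# ---------------------------------------------------------------------------

@dataclass
class FrameSequence:
    """Simulated camera frames with generator ground truth.

    ``jitter[i]`` is the (dx, dy) global translation applied to frame ``i``
    relative to the jitter-free scene; ``truth_moved[i]`` counts pixels whose
    jitter-free intensity changed from frame ``i－1`` (blob motion only).
    """

    frames: np.ndarray  # (n, H, W) uint8
    timestamps: pd.DatetimeIndex
    sensors: np.ndarray  # (n,) "day"/"night"
    mask: np.ndarray  # (H, W) bool, True = inside analysis region
    jitter: np.ndarray  # (n, 2) int, (dx, dy)
    truth_moved: np.ndarray  # (n,) int

    def __len__(self) -> int:
        return len(self.frames)


def _nest_mask(size: int) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    cy = cx = (size - 1) / 2.0
    return ((xx - cx) ** 2 / (0.38 * size) ** 2
            + (yy - cy) ** 2 / (0.30 * size) ** 2) <= 1.0


def simulate_frames(config: ScenarioConfig) -> FrameSequence:
    """Simulate a grayscale frame sequence of blobs walking on a mound.

    Static textured background, ``n_ants`` 3x3 bright blobs random-walking
    inside the mound mask, per-frame global integer translation bounded by
    ``jitter_px`` (wrap-around), and a day/night sensor flag from the hour
    of day.
    """
    size = int(config.frame_size)
    if size < 16:
        raise ValueError("frame_size too small for the nest mask")
    if config.n_ants < 0:
        raise ValueError("n_ants must be >= 0")
    rng = config.rng(3)
    n_frames = max(1, int(round(config.frame_window * config.frame_rate)))
    step = 1.0 / config.frame_rate

    mask = _nest_mask(size)
    background = gaussian_filter(rng.normal(0.0, 1.0, (size, size)), 3.0)
    background = 40.0 + 70.0 * (background - background.min()) \
        / max(float(np.ptp(background)), 1e-12)

    # ant positions random-walk inside the mask
    inside = np.argwhere(mask)
    pos = inside[rng.integers(0, len(inside), config.n_ants)].astype(float)

    frames = np.empty((n_frames, size, size), dtype=np.uint8)
    jitter = np.zeros((n_frames, 2), dtype=int)
    truth_moved = np.zeros(n_frames, dtype=int)
    prev_clean = None
    for i in range(n_frames):
        clean = background.copy()
        for k in range(config.n_ants):
            while True:
                stp = rng.normal(0.0, 1.5, 2)
                cand = pos[k] + stp
                r, c = int(round(cand[0])), int(round(cand[1]))
                if 1 <= r < size - 1 and 1 <= c < size - 1 and mask[r, c]:
                    pos[k] = cand
                    break
            r, c = int(round(pos[k][0])), int(round(pos[k][1]))
            clean[r - 1:r + 2, c - 1:c + 2] = 230.0
        if prev_clean is not None:
            truth_moved[i] = int(np.count_nonzero(
                np.abs(clean - prev_clean) > 0.5))
        prev_clean = clean
        if i > 0 and config.jitter_px > 0:
            jitter[i] = rng.integers(-config.jitter_px, config.jitter_px + 1, 2)
        shifted = np.roll(clean, (jitter[i, 1], jitter[i, 0]), axis=(0, 1))
        frames[i] = np.clip(shifted, 0, 255).astype(np.uint8)

    t = np.arange(n_frames) * step
    ts = config.to_timestamps(t)
    hour = ts.hour
    sensors = np.where((hour >= config.day_start_hour)
                       & (hour < config.day_end_hour), "day", "night")
    return FrameSequence(frames=frames, timestamps=ts, sensors=sensors,
                         mask=mask, jitter=jitter, truth_moved=truth_moved)


# ---------------------------------------------------------------------------
# Quakes & scenario presets
# ---------------------------------------------------------------------------

def quake_catalog(config: ScenarioConfig) -> pd.DataFrame:
    """Quake list as a tidy catalog frame."""
    rows = [{
        "time": q.time, "magnitude": q.magnitude, "depth": q.depth,
        "distance": q.distance, "lat": q.lat, "lon": q.lon,
    } for q in config.quake_list]
    return pd.DataFrame(rows, columns=["time", "magnitude", "depth",
                                       "distance", "lat", "lon"])


_START = pd.Timestamp("2016-08-04T00:00:00Z")

# eight evening-to-early-morning injection events (hours from campaign start;
# all fall in the 17:39-06:54 UTC window the nightly emissions occupy)
_EVENT_HOURS = (19.5, 43.0, 70.2, 90.5, 116.8, 140.3, 162.5, 186.0)
_EVENT_EXCESS = (1.05, 0.55, 0.85, 0.45, 0.95, 0.60, 0.75, 0.50)


def _events(d13c_sources: Sequence[float]) -> tuple[SourceEvent, ...]:
    return tuple(
        SourceEvent(d13c_source=d, start=h * 3600.0, duration=3600.0,
                    peak_excess=e, shape="gaussian")
        for h, e, d in zip(_EVENT_HOURS, _EVENT_EXCESS, d13c_sources)
    )


_QUAKE = QuakeEvent(time=_START + pd.Timedelta(days=5, hours=5),
                    magnitude=0.8, depth=3.0, distance=20.0,
                    lat=50.42, lon=7.23)


def scenario(name: str, seed: int = 0) -> ScenarioConfig:
    """Named scenario presets.

    - ``microbial-default``: eight nightly injections, all at -69 permil
      (microbial end member).
    - ``fault-default``: the same schedule at -37 permil (fault-related
      thermogenic/abiotic end member).
    - ``two-source-default``: the schedule alternating between the two end
      members.
    - ``null-default``: one day, no injections (background + noise only).
    """
    base = ScenarioConfig(seed=seed, quake_list=(_QUAKE,))
    if name == "microbial-default":
        return replace(base, sources=_events([-69.0] * 8))
    if name == "fault-default":
        return replace(base, sources=_events([-37.0] * 8))
    if name == "two-source-default":
        return replace(base, sources=_events([-69.0, -37.0] * 4))
    if name == "null-default":
        return replace(base, duration=86400.0, sources=())
    raise KeyError(f"unknown scenario {name!r}; known: microbial-default, "
                   "fault-default, two-source-default, null-default")


SCENARIOS = ("microbial-default", "fault-default",
             "two-source-default", "null-default")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_csv(df: pd.DataFrame, path) -> None:
    """RFC-4180 CSV with ISO-8601 UTC timestamps."""
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%dT%H:%M:%S.%fZ")
    out.to_csv(path, index=False)


def write_frames(seq: FrameSequence, directory) -> list:
    """Frames as 8-bit grayscale PNGs named ``frame_<epoch-ms>_<D|N>.png``
    plus ``mask.png`` (nonzero = inside)."""
    import os

    import imageio.v3 as iio

    os.makedirs(directory, exist_ok=True)
    paths = []
    for i in range(len(seq)):
        ms = int(seq.timestamps[i].value // 1_000_000)
        flag = "D" if seq.sensors[i] == "day" else "N"
        p = os.path.join(directory, f"frame_{ms}_{flag}.png")
        iio.imwrite(p, seq.frames[i])
        paths.append(p)
    iio.imwrite(os.path.join(directory, "mask.png"),
                (seq.mask * 255).astype(np.uint8))
    return paths
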