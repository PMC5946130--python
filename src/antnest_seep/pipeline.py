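"""Campaign orchestration: simulate or load a campaign, run the activity,
anomaly, Keeling and environmental-association stages, and emit a
structured report (JSON plus CSV sidecars)."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from . import antcam, envstats, gaschem, tides
from .synthetic_data import (
    GAS_COLUMNS,
    WEATHER_COLUMNS,
    ScenarioConfig,
    quake_catalog,
    scenario,
    simulate_frames,
    simulate_gas,
    simulate_weather,
    write_csv,
)

logger = logging.getLogger("antnest_seep")


@dataclass
class CampaignConfig:
    """One self-contained description of a campaign analysis run.

    Either ``scenario`` names a synthetic preset or ``paths`` points at CSV
    inputs in the archive dialect. Threshold and aggregation settings are
    the pipeline defaults of every stage.
    """

    scenario: str | None = "microbial-default"
    paths: dict = field(default_factory=dict)
    seed: int = 0
    mad_k: float = gaschem.DEFAULT_MAD_K
    quantile: float = 0.90
    d13c_mode: str = "deviation"
    min_gap: float = gaschem.DEFAULT_MIN_GAP
    min_samples: int = gaschem.DEFAULT_MIN_SAMPLES
    aggregation: str = "5min"
    max_lag: int = 96  # 5-min bins: +/- 8 h
    decompose_period: int = 288  # one day of 5-min bins
    include_frames: bool = False
    outdir: str | None = None

    def digest(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class CampaignReport:
    """Structured results of one campaign run; every number is produced by
    a library stage on the configured inputs."""

    thresholds: dict
    peaks: pd.DataFrame
    keeling: pd.DataFrame
    percentiles: dict
    pca_cumvar: list
    anova: dict
    ccf: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "thresholds": self.thresholds,
            "n_peaks": int(len(self.peaks)),
            "keeling": self.keeling.to_dict(orient="records"),
            "percentiles": self.percentiles,
            "pca_cumulative_variance": self.pca_cumvar,
            "anova": self.anova,
            "ccf": self.ccf,
            "provenance": self.provenance,
        }


# ---------------------------------------------------------------------------
# Archive-dialect reader
# ---------------------------------------------------------------------------

#: expected CSV schemas (fixture dialect; see docs/methods.md)
HF305_SCHEMAS = {
    "gas": ["datetime", "ch4.ppm", "d13c.permil", "channel"],
    "weather": ["datetime", "airt", "pressure", "dewp", "rh", "rain", "wspd"],
    "activity": ["datetime", "activity"],
}


def read_hf305(path: str, kind: str) -> pd.DataFrame:
    """Read one archive-dialect CSV table (``gas``/``weather``/``activity``).

    Rows with unparseable timestamps are rejected and counted; unknown
    column layouts raise with the expected schema.
    """
    if kind not in HF305_SCHEMAS:
        raise ValueError(f"kind must be one of {sorted(HF305_SCHEMAS)}")
    raw = pd.read_csv(path)
    expected = HF305_SCHEMAS[kind]
    if list(raw.columns) != expected:
        raise ValueError(
            f"unexpected columns {list(raw.columns)} in {path}; "
            f"expected schema for {kind!r}: {expected}")
    ts = pd.to_datetime(raw["datetime"], utc=True, errors="coerce",
                        format="mixed")
    bad = int(ts.isna().sum())
    if bad:
        logger.warning("read_hf305: %d malformed timestamp rows rejected", bad)
    raw = raw[ts.notna()].copy()
    raw["timestamp"] = ts[ts.notna()]
    if kind == "gas":
        out = raw.rename(columns={"ch4.ppm": "ch4", "d13c.permil": "d13c"})
        out = out[GAS_COLUMNS]
    elif kind == "weather":
        out = raw.rename(columns={"airt": "temperature", "dewp": "dewpoint",
                                  "rh": "humidity", "rain": "rainfall",
                                  "wspd": "windspeed"})
        out = out[WEATHER_COLUMNS]
    else:
        out = raw[["timestamp", "activity"]]
    logger.info("read_hf305: %d %s rows from %s", len(out), kind, path)
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Stage runners
# ---------------------------------------------------------------------------

def gas_peak_chain(gas: pd.DataFrame, mad_k: float = gaschem.DEFAULT_MAD_K,
                   d13c_mode: str = "deviation",
                   min_gap: float = gaschem.DEFAULT_MIN_GAP,
                   min_samples: int = gaschem.DEFAULT_MIN_SAMPLES
                   ) -> tuple[dict, gaschem.PeakSet, pd.DataFrame]:
    """Threshold -> flag -> coincidence -> per-window Keeling + clusters.

    Nest and ambient channels are thresholded separately; peaks and Keeling
    fits come from the nest channel.
    """
    nest = gas[gas["channel"] == "nest"].reset_index(drop=True)
    thresholds = {"nest_ch4": gaschem.mad_threshold(nest["ch4"], k=mad_k)}
    amb = gas[gas["channel"] == "ambient"]
    if len(amb) >= 2:
        thresholds["ambient_ch4"] = gaschem.mad_threshold(amb["ch4"], k=mad_k)
    ch4_flags = gaschem.flag_ch4_peaks(nest["ch4"], thresholds["nest_ch4"])
    d13c_flags = gaschem.flag_d13c_peaks(nest["d13c"], mode=d13c_mode,
                                         k=mad_k)
    peaks = gaschem.coincident_peaks(nest["timestamp"], ch4_flags, d13c_flags,
                                     min_gap=min_gap, min_samples=min_samples)
    fits = gaschem.keeling_per_window(nest, peaks)
    rows = []
    if fits:
        labels, centers = gaschem.cluster_intercepts(
            [f.intercept for f in fits],
            n_clusters=min(2, len(fits)))
        for f, lab in zip(fits, labels):
            rows.append({
                "intercept": f.intercept, "slope": f.slope, "r2": f.r2,
                "ci_low": f.ci95[0], "ci_high": f.ci95[1], "n": f.n,
                "cluster": int(lab),
                "cluster_center": float(centers[int(lab)]),
            })
    keeling = pd.DataFrame(rows, columns=["intercept", "slope", "r2",
                                          "ci_low", "ci_high", "n",
                                          "cluster", "cluster_center"])
    return thresholds, peaks, keeling


def run_campaign(config: CampaignConfig) -> CampaignReport:
    """Run the full campaign analysis from one config; deterministic given
    config + seed."""
    stage = "inputs"
    try:
        if config.scenario is not None:
            scen = scenario(config.scenario, seed=config.seed)
            gas = simulate_gas(scen)
            weather = simulate_weather(scen)
            quakes = quake_catalog(scen)
            tide = tides.tide_series(scen.start,
                                     scen.start + pd.Timedelta(seconds=scen.duration),
                                     step=scen.weather_interval,
                                     constituents=scen.tide_constituents)
            activity = None
            if config.include_frames:
                stage = "antcam"
                seq = simulate_frames(scen)
                scored = antcam.score_frames(seq, max_shift=scen.jitter_px)
                activity = scored
        else:
            gas = read_hf305(config.paths["gas"], "gas")
            weather = read_hf305(config.paths["weather"], "weather")
            activity = (read_hf305(config.paths["activity"], "activity")
                        if "activity" in config.paths else None)
            quakes = pd.DataFrame()
            t0 = gas["timestamp"].min()
            tide = tides.tide_series(t0, gas["timestamp"].max(), step=300.0)

        stage = "gaschem"
        thresholds, peaks, keeling = gas_peak_chain(
            gas, mad_k=config.mad_k, d13c_mode=config.d13c_mode,
            min_gap=config.min_gap, min_samples=config.min_samples)
        nest = gas[gas["channel"] == "nest"]
        all_s, above = gaschem.percentile_summary(nest["ch4"],
                                                 q=config.quantile)
        percentiles = {"all": asdict(all_s), "above_q": asdict(above)}

        stage = "envstats"
        pca = envstats.weather_pca(weather)
        gas_5m = envstats.aggregate_median(nest, ["ch4", "d13c"],
                                           config.aggregation)
        wx_5m = weather.set_index("timestamp").resample(
            config.aggregation).median()
        pcs = pca.scores.copy()
        pcs.index = weather.loc[pca.scores.index, "timestamp"]
        pcs_5m = pcs.resample(config.aggregation).median()
        aligned = gas_5m.join(pcs_5m, how="inner").dropna()
        anova_out = {}
        for resp in ("ch4", "d13c"):
            try:
                tab = envstats.pc_regression_anova(aligned[resp],
                                                   aligned[[c for c in
                                                            aligned.columns
                                                            if c.startswith("PC")]])
                anova_out[resp] = {"r2": tab.r2, "F": tab.f_overall,
                                   "df": [tab.df_model, tab.df_resid],
                                   "p": tab.p_overall, "n": tab.n}
            except ValueError as exc:
                logger.warning("ANOVA for %s skipped: %s", resp, exc)

        ccf_out = {}
        if len(gas_5m) - config.max_lag >= 10:
            cc = tides.tide_gas_ccf(tide, nest, config.max_lag,
                                    interval=config.aggregation)
            k = int(np.argmax(np.abs(cc.r)))
            ccf_out["tide_ch4"] = {"lag": int(cc.lags[k]),
                                   "r": float(cc.r[k])}
        if activity is not None and len(activity) >= 30:
            act_5m = envstats.aggregate_median(activity, ["raw_sad"],
                                               config.aggregation)
            j = act_5m.join(gas_5m, how="inner").dropna()
            max_lag_act = min(config.max_lag, max(1, (len(j) - 10) // 2))
            if len(j) - max_lag_act >= 10:
                cc = envstats.cross_correlation(j["raw_sad"], j["ch4"],
                                                max_lag_act)
                k = int(np.argmax(np.abs(cc.r)))
                ccf_out["activity_ch4"] = {"lag": int(cc.lags[k]),
                                           "r": float(cc.r[k])}

        kde_out = None
        if len(quakes) >= 2:
            xs, ys, dens = envstats.gaussian_kde2d(quakes["lon"],
                                                   quakes["lat"])
            kde_out = {"integral": envstats.grid_integral(xs, ys, dens)}
    except Exception as exc:
        raise RuntimeError(f"campaign stage {stage!r} failed: {exc}") from exc

    import importlib.metadata

    try:
        version = importlib.metadata.version("antnest-seep")
    except importlib.metadata.PackageNotFoundError:
        version = "unknown"
    report = CampaignReport(
        thresholds=thresholds,
        peaks=gaschem.peakset_to_frame(peaks),
        keeling=keeling,
        percentiles=percentiles,
        pca_cumvar=[float(v) for v in pca.cumulative_variance[:3]],
        anova=anova_out,
        ccf={**ccf_out, **({"quake_kde": kde_out} if kde_out else {})},
        provenance={"config_digest": config.digest(), "seed": config.seed,
                    "scenario": config.scenario, "version": version},
    )
    if config.outdir:
        write_report(report, config.outdir)
    return report


def write_report(report: CampaignReport, outdir: str) -> None:
    """report.json plus CSV sidecars for the peak and Keeling tables."""
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, default=str)
    write_csv(report.peaks, os.path.join(outdir, "peaks.csv"))
    report.keeling.to_csv(os.path.join(outdir, "keeling.csv"), index=False)
    logger.info("report written to %s", outdir)
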