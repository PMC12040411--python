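"""Seeded synthetic ecoregion collections.

Emulates the data structure of a multi-ecoregion rangeland monitoring
campaign: each ecoregion carries a set of field plots with fractional-cover
indicators (percent), plot-level model predictors, daily climate series, and
multi-year seasonal raster time series sampled at a handful of pixels.

The generative model is built around a latent "ecological space": every
ecoregion has a latent coordinate vector, and

* ecoregion indicator means are an orthonormal linear map of the latent
  coordinates, rescaled into percent units;
* the amplitude and phase of each seasonal variable's annual harmonics are
  affine in the latent coordinates, so ecoregions far apart in latent space
  differ in both the magnitude and the timing of their seasonal cycles;
* the plot-level predictor -> indicator mapping drifts linearly with latent
  position (the ``nonstationarity`` knob), so a model trained in one
  ecoregion degrades in proportion to ecological dissimilarity when applied
  in another;
* geographic centroids are a convex combination of a projection of the
  latent coordinates and an independent random layout (the ``geo_coupling``
  knob), giving geographic distance only partial correlation with ecological
  dissimilarity.

All randomness flows from one master seed through named substreams, so the
draws of one stage never depend on whether another stage ran.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "INDICATOR_NAMES_20",
    "SERIES_VARIABLES_6",
    "CLIMATE_VARIABLES",
    "SyntheticConfig",
    "Collection",
    "generate_collection",
    "derive_climate_predictors",
    "climate_predictor_table",
    "write_collection",
    "indicator_columns",
    "predictor_columns",
]

#: Default 20 fractional-cover indicators (line-point intercept "any hit"
#: covers and canopy-gap fractions, all in percent of transect).
INDICATOR_NAMES_20 = [
    "AHAFC", "AHAGC", "AHAHC", "AHHC", "AHPFC", "AHPGC", "AHPHC",
    "AHSBC", "AHSC", "AHSSuC", "AHSuC", "AHTLC", "AHTC", "AHWC",
    "BGC", "BSC", "TFC", "Ggt25", "Ggt100", "Ggt200",
]

#: Default six seasonal variables summarized by harmonic regression:
#: BRDF NIR/visible volumetric parameters, a soil-adjusted vegetation index,
#: a water index, land surface temperature, and soil moisture.
SERIES_VARIABLES_6 = ["NirVol", "VisVol", "MSAVI", "NDWI", "LST", "SM"]

#: Daily surface-weather variables (daylength s, precipitation mm/day,
#: shortwave radiation W/m^2, max/min 2-m air temperature degC).
CLIMATE_VARIABLES = ["dayl", "prcp", "srad", "tmax", "tmin"]

# Named substreams of the master seed. Fixed indices, never reordered.
_STREAMS = {
    "ecoregions": 0,
    "geography": 1,
    "plots": 2,
    "series": 3,
    "predictors": 4,
    "climate": 5,
}

_BASE_YEAR = 2020  # calendar year in which collection dates fall


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=int(seed), spawn_key=(_STREAMS[stream],))
    )


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic collection.

    Counts must all be >= 1; ``geo_coupling`` lies in [0, 1];
    ``nonstationarity`` is a non-negative drift rate of the
    predictor -> indicator mapping per unit latent distance.
    """

    n_ecoregions: int = 8
    plots_per_ecoregion: int = 120
    latent_dim: int = 3
    n_indicators: int = 20
    n_series_variables: int = 6
    pixels_per_ecoregion: int = 10
    series_years: int = 3
    series_step_days: int = 16
    n_predictors: int = 8
    geo_coupling: float = 0.7
    nonstationarity: float = 1.0
    indicator_sd: float = 5.0
    series_sd: float = 0.1
    predictor_sd: float = 0.05
    indicator_mean_scale: float = 8.0
    include_climate: bool = True
    climate_lookback_days: int = 120
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_ecoregions": self.n_ecoregions,
            "plots_per_ecoregion": self.plots_per_ecoregion,
            "latent_dim": self.latent_dim,
            "n_indicators": self.n_indicators,
            "n_series_variables": self.n_series_variables,
            "pixels_per_ecoregion": self.pixels_per_ecoregion,
            "series_years": self.series_years,
            "series_step_days": self.series_step_days,
            "n_predictors": self.n_predictors,
        }
        for name, v in counts.items():
            if int(v) != v or v < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {v!r}")
        reals = {
            "geo_coupling": self.geo_coupling,
            "nonstationarity": self.nonstationarity,
            "indicator_sd": self.indicator_sd,
            "series_sd": self.series_sd,
            "predictor_sd": self.predictor_sd,
            "indicator_mean_scale": self.indicator_mean_scale,
        }
        for name, v in reals.items():
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if not 0.0 <= self.geo_coupling <= 1.0:
            raise ValueError(f"geo_coupling must be in [0, 1], got {self.geo_coupling}")
        if self.nonstationarity < 0:
            raise ValueError("nonstationarity must be >= 0")
        if min(self.indicator_sd, self.series_sd, self.predictor_sd) < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if self.latent_dim > self.n_indicators:
            raise ValueError(
                f"latent_dim ({self.latent_dim}) cannot exceed "
                f"n_indicators ({self.n_indicators})"
            )

    @property
    def indicator_names(self) -> list[str]:
        if self.n_indicators == len(INDICATOR_NAMES_20):
            return list(INDICATOR_NAMES_20)
        return [f"ind{i + 1:02d}" for i in range(self.n_indicators)]

    @property
    def series_variable_names(self) -> list[str]:
        if self.n_series_variables == len(SERIES_VARIABLES_6):
            return list(SERIES_VARIABLES_6)
        return [f"var{i + 1:02d}" for i in range(self.n_series_variables)]

    @property
    def predictor_names(self) -> list[str]:
        return [f"pred{i + 1:02d}" for i in range(self.n_predictors)]


@dataclass
class Collection:
    """In-memory synthetic collection.

    ``plots`` is one row per field plot (ids, coordinates, collection date,
    indicator columns in percent, predictor columns). ``series`` is long-form
    (ecoregion_id, pixel_id, variable, time_years, value). ``climate`` is
    long-form daily (plot_id, variable, date, value) or ``None`` when climate
    generation was disabled. ``ecoregions`` carries centroids and the latent
    coordinates used to generate everything.
    """

    config: SyntheticConfig
    ecoregions: pd.DataFrame
    plots: pd.DataFrame
    series: pd.DataFrame
    climate: pd.DataFrame | None = None
    indicator_names: list[str] = field(default_factory=list)
    predictor_names: list[str] = field(default_factory=list)


def _wrap_phase(p: np.ndarray) -> np.ndarray:
    """Wrap angles into (-pi, pi]."""
    out = np.mod(p + np.pi, 2 * np.pi) - np.pi
    return np.where(out == -np.pi, np.pi, out)


def generate_collection(config: SyntheticConfig) -> Collection:
    """Draw a full synthetic collection from ``config``.

    Identical config and seed give identical output frames. See the module
    docstring for the generative model.
    """
    config.validate()
    K, P, D = config.n_ecoregions, config.plots_per_ecoregion, config.latent_dim
    n_ind = config.n_indicators
    ind_names = config.indicator_names
    var_names = config.series_variable_names

    # --- latent ecological coordinates and indicator means -----------------
    rng_eco = _rng(config.seed, "ecoregions")
    latent = rng_eco.standard_normal((K, D))
    g = rng_eco.standard_normal((n_ind, max(D, 1)))[:, :D]
    q, _ = np.linalg.qr(g)  # n_ind x D with orthonormal columns
    eco_means = 50.0 + config.indicator_mean_scale * latent @ q.T  # K x n_ind

    # --- geographic layout --------------------------------------------------
    rng_geo = _rng(config.seed, "geography")
    indep_lat = rng_geo.uniform(33.0, 47.0, K)
    indep_lon = rng_geo.uniform(-122.0, -104.0, K)
    z0 = latent[:, 0]
    z1 = latent[:, 1] if D >= 2 else np.zeros(K)
    coupled_lat = 40.0 + 3.0 * z0
    coupled_lon = -113.0 + 3.0 * z1
    gmix = config.geo_coupling
    cen_lat = gmix * coupled_lat + (1 - gmix) * indep_lat
    cen_lon = gmix * coupled_lon + (1 - gmix) * indep_lon

    eco_ids = [f"E{k + 1:03d}" for k in range(K)]
    ecoregions = pd.DataFrame({"ecoregion_id": eco_ids, "lat": cen_lat, "lon": cen_lon})
    for d in range(D):
        ecoregions[f"latent{d + 1}"] = latent[:, d]

    # --- plots: indicators, coordinates, collection dates -------------------
    rng_plots = _rng(config.seed, "plots")
    ind_values = np.clip(
        np.repeat(eco_means, P, axis=0)
        + rng_plots.normal(0.0, config.indicator_sd, (K * P, n_ind)),
        0.0,
        100.0,
    )
    plot_lat = np.repeat(cen_lat, P) + rng_plots.normal(0.0, 0.05, K * P)
    plot_lon = np.repeat(cen_lon, P) + rng_plots.normal(0.0, 0.05, K * P)
    day_offsets = rng_plots.integers(0, 365, K * P)
    base = date(_BASE_YEAR, 1, 1)
    coll_dates = [base + timedelta(days=int(d)) for d in day_offsets]

    plots = pd.DataFrame(
        {
            "plot_id": [f"P{i + 1:06d}" for i in range(K * P)],
            "ecoregion_id": np.repeat(eco_ids, P),
            "lat": plot_lat,
            "lon": plot_lon,
            "collection_date": coll_dates,
        }
    )
    for j, name in enumerate(ind_names):
        plots[name] = ind_values[:, j]

    # --- plot predictors: latent-drifting linear map of the indicators ------
    rng_pred = _rng(config.seed, "predictors")
    n_pred = config.n_predictors
    b0 = rng_pred.standard_normal((n_pred, n_ind)) / math.sqrt(n_ind)
    drift = rng_pred.standard_normal((D, n_pred, n_ind)) / math.sqrt(n_ind)
    x_scaled = (ind_values - 50.0) / 10.0
    preds = np.empty((K * P, n_pred))
    for k in range(K):
        b_k = b0 + config.nonstationarity * np.tensordot(latent[k], drift, axes=1)
        rows = slice(k * P, (k + 1) * P)
        preds[rows] = x_scaled[rows] @ b_k.T
    preds += rng_pred.normal(0.0, config.predictor_sd, preds.shape)
    for j, name in enumerate(config.predictor_names):
        plots[name] = preds[:, j]

    # --- seasonal series: two harmonics affine in latent space --------------
    rng_ser = _rng(config.seed, "series")
    n_var, J = config.n_series_variables, 2
    amp0 = rng_ser.uniform(0.5, 2.0, (n_var, J))
    amp_dir = rng_ser.standard_normal((n_var, J, D))
    amp_dir /= np.linalg.norm(amp_dir, axis=2, keepdims=True)
    phase0 = rng_ser.uniform(-np.pi, np.pi, (n_var, J))
    phase_dir = rng_ser.standard_normal((n_var, J, D))
    phase_dir /= np.linalg.norm(phase_dir, axis=2, keepdims=True)
    intercepts = rng_ser.uniform(1.0, 3.0, n_var)
    trends = rng_ser.uniform(-0.02, 0.02, n_var)

    n_days = config.series_years * 365
    t = np.arange(0, n_days, config.series_step_days) / 365.25  # fractional years
    n_t = t.size
    n_px = config.pixels_per_ecoregion

    amp = np.maximum(0.05, amp0 + 0.4 * np.einsum("vjd,kd->kvj", amp_dir, latent))
    phs = _wrap_phase(phase0 + 0.5 * np.einsum("vjd,kd->kvj", phase_dir, latent))

    harmonics = np.stack(
        [np.cos(2 * np.pi * (j + 1) * t) for j in range(J)]
        + [np.sin(2 * np.pi * (j + 1) * t) for j in range(J)]
    )  # (2J, n_t)
    frames = []
    for k in range(K):
        # clean per-(variable) curve, shared by all pixels of the ecoregion
        b2 = amp[k] * np.cos(phs[k])  # (n_var, J)
        b3 = amp[k] * np.sin(phs[k])
        coef = np.concatenate([b2, b3], axis=1)  # (n_var, 2J)
        clean = (
            intercepts[:, None] + trends[:, None] * t[None, :] + coef @ harmonics
        )  # (n_var, n_t)
        vals = (
            np.repeat(clean[None, :, :], n_px, axis=0)
            + rng_ser.normal(0.0, config.series_sd, (n_px, n_var, n_t))
        )
        frames.append(
            pd.DataFrame(
                {
                    "ecoregion_id": eco_ids[k],
                    "pixel_id": np.repeat(
                        [f"{eco_ids[k]}_px{p + 1:03d}" for p in range(n_px)],
                        n_var * n_t,
                    ),
                    "variable": np.tile(np.repeat(var_names, n_t), n_px),
                    "time_years": np.tile(t, n_px * n_var),
                    "value": vals.ravel(),
                }
            )
        )
    series = pd.concat(frames, ignore_index=True)

    # --- daily climate series per plot --------------------------------------
    climate = None
    if config.include_climate:
        climate = _generate_climate(config, plots)

    return Collection(
        config=config,
        ecoregions=ecoregions,
        plots=plots,
        series=series,
        climate=climate,
        indicator_names=ind_names,
        predictor_names=list(config.predictor_names),
    )


def _generate_climate(config: SyntheticConfig, plots: pd.DataFrame) -> pd.DataFrame:
    """Daily climate series per plot over a fixed lookback window.

    Each plot's series covers ``climate_lookback_days`` days before its own
    collection date through the collection date itself, which covers the 30-
    and 90-day aggregation windows used for derived predictors. Curves are
    smooth annual sinusoids (per-variable timing) plus day-level noise and a
    small per-plot offset; precipitation is clipped at zero.
    """
    rng = _rng(config.seed, "climate")
    look = config.climate_lookback_days
    n_days = look + 1
    n_plots = len(plots)

    coll = pd.to_datetime(plots["collection_date"]).to_numpy()
    offsets = np.arange(-look, 1)
    dates = coll[:, None] + offsets[None, :].astype("timedelta64[D]")
    doy = (
        pd.DatetimeIndex(dates.ravel()).dayofyear.to_numpy().reshape(n_plots, n_days)
    )
    ang = 2 * np.pi * doy / 365.0

    # per-variable annual curve: (base, seasonal amplitude, peak day-of-year, noise sd)
    curves = {
        "dayl": (43200.0, 9000.0, 172, 600.0),
        "prcp": (1.5, 1.0, 172, 1.2),
        "srad": (330.0, 150.0, 172, 25.0),
        "tmax": (18.0, 12.0, 200, 2.0),
        "tmin": (4.0, 10.0, 200, 2.0),
    }
    plot_offset = rng.normal(0.0, 1.0, n_plots)

    frames = []
    for var in CLIMATE_VARIABLES:
        base, amp, peak, sd = curves[var]
        seasonal = base + amp * np.cos(ang - 2 * np.pi * peak / 365.0)
        vals = seasonal + 0.05 * amp * plot_offset[:, None]
        vals = vals + rng.normal(0.0, sd, (n_plots, n_days))
        if var == "prcp":
            vals = np.maximum(vals, 0.0)
        frames.append(
            pd.DataFrame(
                {
                    "plot_id": np.repeat(plots["plot_id"].to_numpy(), n_days),
                    "variable": var,
                    "date": dates.ravel(),
                    "value": vals.ravel(),
                }
            )
        )
    climate = pd.concat(frames, ignore_index=True)
    climate["date"] = pd.to_datetime(climate["date"])
    return climate


def derive_climate_predictors(
    climate: pd.DataFrame,
    collection_date,
    windows: tuple[int, ...] = (30, 90),
    variables: list[str] | None = None,
) -> dict[str, float]:
    """Window min/max climate summaries for one plot.

    For each climate variable and each window length ``w`` (days), takes the
    minimum and maximum of the daily values over the inclusive window
    ``[collection_date - w, collection_date]`` — five variables x two windows
    x two statistics = 20 derived predictors with the defaults.

    ``climate`` is a long-form frame (``variable``, ``date``, ``value``) for
    a single plot. Raises ``ValueError`` on a missing variable or a window
    not fully covered by the series.
    """
    variables = list(variables) if variables is not None else list(CLIMATE_VARIABLES)
    cdate = pd.Timestamp(collection_date)
    out: dict[str, float] = {}
    for var in variables:
        sub = climate.loc[climate["variable"] == var]
        if sub.empty:
            raise ValueError(f"climate variable {var!r} missing from series")
        dates = pd.to_datetime(sub["date"])
        vals = sub["value"].to_numpy(float)
        for w in windows:
            start = cdate - pd.Timedelta(days=w)
            mask = (dates >= start) & (dates <= cdate)
            got = pd.DatetimeIndex(dates[mask]).normalize().unique()
            if len(got) < w + 1:
                raise ValueError(
                    f"{var!r}: {w}-day window ending {cdate.date()} not fully "
                    f"covered (have {len(got)} of {w + 1} days)"
                )
            wv = vals[mask.to_numpy()]
            out[f"{var}_min_{w}d"] = float(wv.min())
            out[f"{var}_max_{w}d"] = float(wv.max())
    return out


def climate_predictor_table(
    climate: pd.DataFrame, plots: pd.DataFrame, windows: tuple[int, ...] = (30, 90)
) -> pd.DataFrame:
    """Derived climate predictors for every plot, one row per plot."""
    rows = []
    coll = dict(zip(plots["plot_id"], plots["collection_date"]))
    for plot_id, grp in climate.groupby("plot_id", sort=False):
        rec = derive_climate_predictors(grp, coll[plot_id], windows=windows)
        rec["plot_id"] = plot_id
        rows.append(rec)
    out = pd.DataFrame(rows)
    return out[["plot_id"] + [c for c in out.columns if c != "plot_id"]]


# --- column conventions and CSV I/O -----------------------------------------

_META_COLUMNS = {"plot_id", "ecoregion_id", "lat", "lon", "collection_date"}


def indicator_columns(plots: pd.DataFrame) -> list[str]:
    """Indicator columns of a plot table (default names or ``indNN``)."""
    known = set(INDICATOR_NAMES_20)
    return [
        c
        for c in plots.columns
        if c in known or (c.startswith("ind") and c[3:].isdigit())
    ]


def predictor_columns(plots: pd.DataFrame) -> list[str]:
    """Predictor columns: everything that is neither metadata nor indicator."""
    ind = set(indicator_columns(plots))
    return [c for c in plots.columns if c not in _META_COLUMNS and c not in ind]


def write_collection(collection: Collection, outdir: str | Path) -> dict[str, Path]:
    """Write plots/series/climate/ecoregions CSVs (UTF-8, ISO dates)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    plots = collection.plots.copy()
    plots["collection_date"] = pd.to_datetime(plots["collection_date"]).dt.strftime(
        "%Y-%m-%d"
    )
    paths = {
        "plots": (plots, outdir / "plots.csv"),
        "series": (collection.series, outdir / "series.csv"),
        "ecoregions": (collection.ecoregions, outdir / "ecoregions.csv"),
    }
    if collection.climate is not None:
        climate = collection.climate.copy()
        climate["date"] = pd.to_datetime(climate["date"]).dt.strftime("%Y-%m-%d")
        paths["climate"] = (climate, outdir / "climate.csv")
    for key, (frame, path) in paths.items():
        frame.to_csv(path, index=False, lineterminator="\n")
        written[key] = path
    return written


def read_plots(path: str | Path) -> pd.DataFrame:
    plots = pd.read_csv(path)
    plots["collection_date"] = pd.to_datetime(plots["collection_date"])
    return plots


def read_series(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
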