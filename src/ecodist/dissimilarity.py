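"""Pairwise and bulk separation measures between ecoregions.

Four measures are computed for ordered ecoregion pairs:

* ``geoDist`` — centroid-to-centroid geographic distance in kilometres
  (equirectangular projection by default);
* ``ecoDisIS`` — Euclidean distance between ecoregion centroids in the
  z-scored space of in-situ cover indicators ("IS" = in situ);
* ``ecoDisRS`` — an index built from remote-sensing harmonic descriptors:
  with the mean absolute scaled-amplitude difference dA in [0, 1] and the
  mean normalized circular phase difference dP in [0, 1],

      ecoDisRS = (1 + dA) * (sin(dP - pi/2) + 2) = (1 + dA) * (2 - cos dP),

  which equals 1 exactly when dA = dP = 0 and increases strictly in both
  arguments, with supremum 2 * (2 - cos 1) ~= 2.919;
* ``ecoDisINT`` — a bulk measure: the first interquartile mean (mean of the
  smallest ceil(n/4) values) of an ecoregion's pairwise dissimilarities to a
  reference set of ecoregions with in-situ data.

Pairwise values are stratified into quartiles (Q1 = least separated) using
linear-interpolation percentiles over the pooled pairwise set.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd

from .harmonics import HarmonicDescriptor

__all__ = [
    "EARTH_RADIUS_KM",
    "geo_distance",
    "indicator_centroids",
    "eco_dis_is",
    "delta_amplitude",
    "delta_phase",
    "eco_dis_rs",
    "pairwise_table",
    "interquartile_mean",
    "eco_dis_int",
    "bulk_table",
    "quartile_assign",
]

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0088
KM_PER_DEGREE = math.pi * EARTH_RADIUS_KM / 180.0  # 111.195 km

GEO_MODES = ("equirectangular", "degrees-euclidean")


def geo_distance(centroid_a, centroid_b, mode: str = "equirectangular") -> float:
    """Distance in km between two (lat, lon) points in decimal degrees.

    ``equirectangular`` scales the longitude difference by the cosine of the
    mean latitude; ``degrees-euclidean`` is the plain Euclidean distance in
    degree space times km-per-degree (a planar reading of "latitude/longitude
    distance converted to kilometres").
    """
    if mode not in GEO_MODES:
        raise ValueError(f"mode must be one of {GEO_MODES}, got {mode!r}")
    lat_a, lon_a = float(centroid_a[0]), float(centroid_a[1])
    lat_b, lon_b = float(centroid_b[0]), float(centroid_b[1])
    for lat, lon in ((lat_a, lon_a), (lat_b, lon_b)):
        if not (-90.0 <= lat <= 90.0):
            raise ValueError(f"latitude {lat} outside [-90, 90]")
        if not (-180.0 <= lon <= 180.0):
            raise ValueError(f"longitude {lon} outside [-180, 180]")
    dlat = (lat_a - lat_b) * KM_PER_DEGREE
    if mode == "equirectangular":
        mean_lat = math.radians(0.5 * (lat_a + lat_b))
        dlon = (lon_a - lon_b) * KM_PER_DEGREE * math.cos(mean_lat)
    else:
        dlon = (lon_a - lon_b) * KM_PER_DEGREE
    return math.hypot(dlat, dlon)


def indicator_centroids(
    plots: pd.DataFrame,
    indicator_cols: list[str],
    min_plots: int = 100,
    zscore: str = "pooled-plots",
) -> pd.DataFrame:
    """Per-ecoregion centroids in z-scored indicator space.

    Only ecoregions with at least ``min_plots`` plots qualify. In the default
    ``pooled-plots`` mode, each indicator is z-scored over all plots of the
    qualifying ecoregions pooled, then averaged per ecoregion; in
    ``centroids`` mode raw per-ecoregion means are computed first and
    z-scored across ecoregions. Zero-variance indicators are dropped with a
    warning. Returns a frame indexed by ecoregion_id with the retained
    indicator columns plus ``n_plots``.
    """
    if zscore not in ("pooled-plots", "centroids"):
        raise ValueError(f"unknown zscore mode {zscore!r}")
    counts = plots.groupby("ecoregion_id").size()
    qualifying = counts[counts >= min_plots].index
    if len(qualifying) < 2:
        raise ValueError(
            f"need >= 2 ecoregions with at least {min_plots} plots, "
            f"got {len(qualifying)}"
        )
    sub = plots[plots["ecoregion_id"].isin(qualifying)]

    if zscore == "pooled-plots":
        x = sub[indicator_cols].to_numpy(float)
        mu = x.mean(axis=0)
        sd = x.std(axis=0)
    else:
        means = sub.groupby("ecoregion_id")[indicator_cols].mean()
        x = means.to_numpy(float)
        mu = x.mean(axis=0)
        sd = x.std(axis=0)

    keep = sd > 0
    dropped = [c for c, k in zip(indicator_cols, keep) if not k]
    if dropped:
        logger.warning("dropping zero-variance indicators: %s", ", ".join(dropped))
    if not keep.any():
        raise ValueError("all indicators have zero variance")
    kept_cols = [c for c, k in zip(indicator_cols, keep) if k]

    if zscore == "pooled-plots":
        z = (sub[kept_cols].to_numpy(float) - mu[keep]) / sd[keep]
        zf = pd.DataFrame(z, columns=kept_cols, index=sub.index)
        zf["ecoregion_id"] = sub["ecoregion_id"].to_numpy()
        cent = zf.groupby("ecoregion_id")[kept_cols].mean()
    else:
        means = sub.groupby("ecoregion_id")[kept_cols].mean()
        cent = (means - mu[keep]) / sd[keep]
    cent["n_plots"] = counts.loc[cent.index]
    return cent


def eco_dis_is(c_m, c_n) -> float:
    """Euclidean distance between two indicator-space centroids."""
    a = np.asarray(c_m, float)
    b = np.asarray(c_n, float)
    if a.shape != b.shape:
        raise ValueError(f"centroid arity mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))


def delta_amplitude(d_m: HarmonicDescriptor, d_n: HarmonicDescriptor) -> float:
    """Mean absolute scaled-amplitude difference over all (variable, harmonic)."""
    if not (d_m.scaled and d_n.scaled):
        raise ValueError("delta_amplitude requires min–max scaled descriptors")
    if d_m.amplitude.shape != d_n.amplitude.shape:
        raise ValueError("descriptor shape mismatch")
    return float(np.mean(np.abs(d_m.amplitude - d_n.amplitude)))


def delta_phase(d_m: HarmonicDescriptor, d_n: HarmonicDescriptor) -> float:
    """Mean circular phase difference, normalized by pi into [0, 1].

    Per (variable, harmonic) the circular absolute difference
    min(|Pm - Pn|, 2*pi - |Pm - Pn|) in [0, pi] is averaged over all pairs
    and divided by pi.
    """
    if d_m.phase.shape != d_n.phase.shape:
        raise ValueError("descriptor shape mismatch")
    d = np.abs(d_m.phase - d_n.phase)
    circ = np.minimum(d, 2 * np.pi - d)
    return float(np.mean(circ) / np.pi)


def eco_dis_rs(delta_a, delta_p):
    """Remote-sensing dissimilarity index (1 + dA) * (sin(dP - pi/2) + 2).

    Accepts scalars or broadcasting arrays with dA and dP in [0, 1]
    (out-of-range or non-finite input raises). Equals 1 iff dA = dP = 0.
    """
    a = np.asarray(delta_a, float)
    p = np.asarray(delta_p, float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(p))):
        raise ValueError("delta_a and delta_p must be finite")
    if np.any(a < 0) or np.any(a > 1) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("delta_a and delta_p must lie in [0, 1]")
    out = (1.0 + a) * (np.sin(p - np.pi / 2.0) + 2.0)
    return float(out) if out.ndim == 0 else out


MEASURE_COLUMNS = {
    "geoDist": "geoDist",
    "ecoDisIS": "ecoDisIS",
    "ecoDisRS": "ecoDisRS",
}


def pairwise_table(
    centroids: pd.DataFrame,
    descriptors: list[HarmonicDescriptor],
    geo_centroids: pd.DataFrame,
    geo_mode: str = "equirectangular",
) -> pd.DataFrame:
    """All four separation measures for every ordered ecoregion pair.

    ``centroids`` is the output of :func:`indicator_centroids`;
    ``descriptors`` must be scaled; ``geo_centroids`` has columns
    ``ecoregion_id``, ``lat``, ``lon``. The three inputs must cover the same
    ecoregion ids. One row per ordered pair (m != n) with columns ``eco_m``,
    ``eco_n``, ``geoDist``, ``ecoDisIS``, ``deltaA``, ``deltaP``,
    ``ecoDisRS`` and quartile labels ``geoDist_quartile``,
    ``ecoDisIS_quartile``, ``ecoDisRS_quartile`` computed over the pooled
    table.
    """
    ids = sorted(centroids.index)
    desc_by_id = {d.ecoregion_id: d for d in descriptors}
    geo = geo_centroids.set_index("ecoregion_id")
    for label, got in (
        ("descriptors", set(desc_by_id)),
        ("geographic centroids", set(geo.index)),
    ):
        if got != set(ids):
            missing = set(ids) ^ got
            raise ValueError(f"ecoregion ids of {label} do not match centroids: "
                             f"{sorted(missing)}")
    ind_cols = [c for c in centroids.columns if c != "n_plots"]

    rows = []
    for i, m in enumerate(ids):
        for n in ids[i + 1 :]:
            gd = geo_distance(
                (geo.at[m, "lat"], geo.at[m, "lon"]),
                (geo.at[n, "lat"], geo.at[n, "lon"]),
                mode=geo_mode,
            )
            dis = eco_dis_is(centroids.loc[m, ind_cols], centroids.loc[n, ind_cols])
            da = delta_amplitude(desc_by_id[m], desc_by_id[n])
            dp = delta_phase(desc_by_id[m], desc_by_id[n])
            rs = eco_dis_rs(da, dp)
            rows.append((m, n, gd, dis, da, dp, rs))
            rows.append((n, m, gd, dis, da, dp, rs))
    table = pd.DataFrame(
        rows,
        columns=["eco_m", "eco_n", "geoDist", "ecoDisIS", "deltaA", "deltaP",
                 "ecoDisRS"],
    )
    for measure in MEASURE_COLUMNS:
        _, labels = quartile_assign(table[measure].to_numpy())
        table[f"{measure}_quartile"] = labels
    return table


def interquartile_mean(values, ids=None) -> float:
    """Mean of the smallest ceil(n/4) values (the first interquartile mean).

    Ties are broken by the associated ``ids`` (ascending) when given, so the
    summary is deterministic for repeated values.
    """
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("interquartile_mean of empty input")
    if ids is not None:
        order = np.lexsort((np.asarray(ids), v))
    else:
        order = np.argsort(v, kind="stable")
    k = math.ceil(0.25 * v.size)
    return float(v[order[:k]].mean())


def eco_dis_int(
    pairwise: pd.DataFrame,
    target_id: str,
    reference_ids,
    measure: str = "ecoDisRS",
) -> dict:
    """Bulk dissimilarity of one ecoregion to a reference set.

    Collects ``measure`` from ``target_id`` to every reference ecoregion
    (the target itself is excluded) and returns its first interquartile mean
    together with the reference-set size used.
    """
    if measure not in MEASURE_COLUMNS:
        raise ValueError(f"measure must be one of {sorted(MEASURE_COLUMNS)}")
    refs = [r for r in reference_ids if r != target_id]
    if not refs:
        raise ValueError("reference set empty after excluding the target")
    sub = pairwise[
        (pairwise["eco_m"] == target_id) & (pairwise["eco_n"].isin(refs))
    ]
    if len(sub) != len(refs):
        missing = set(refs) - set(sub["eco_n"])
        raise ValueError(f"pairwise table lacks pairs to references: {sorted(missing)}")
    value = interquartile_mean(sub[measure].to_numpy(), ids=sub["eco_n"].to_numpy())
    return {
        "ecoregion_id": target_id,
        "measure": measure,
        "value": value,
        "reference_set_size": len(refs),
        "k": math.ceil(0.25 * len(refs)),
    }


def bulk_table(
    pairwise: pd.DataFrame,
    reference_ids,
    target_ids=None,
) -> pd.DataFrame:
    """ecoDisINT (RS and IS) for every target ecoregion.

    ``reference_ids`` are ecoregions with in-situ data. Targets default to
    every ecoregion present in the pairwise table. The in-situ column is the
    bulk ecoDisIS; for targets without in-situ data callers should pass a
    pairwise table whose IS column is absent or drop the column downstream.
    A quartile label over the RS column is attached when n >= 4.
    """
    if target_ids is None:
        target_ids = sorted(set(pairwise["eco_m"]))
    rows = []
    for tid in target_ids:
        rec = {"ecoregion_id": tid}
        rs = eco_dis_int(pairwise, tid, reference_ids, measure="ecoDisRS")
        rec["ecoDisINT_RS"] = rs["value"]
        rec["reference_set_size"] = rs["reference_set_size"]
        if "ecoDisIS" in pairwise.columns:
            rec["ecoDisINT_IS"] = eco_dis_int(
                pairwise, tid, reference_ids, measure="ecoDisIS"
            )["value"]
        rows.append(rec)
    out = pd.DataFrame(rows)
    if len(out) >= 4:
        _, labels = quartile_assign(out["ecoDisINT_RS"].to_numpy())
        out["quartile"] = labels
    else:
        out["quartile"] = None
    return out


def quartile_assign(values) -> tuple[dict, np.ndarray]:
    """Quartile boundaries and labels for a pooled set of values.

    Cut points are the 25th/50th/75th linear-interpolation percentiles.
    Bins are right-open ([lo, cut) goes to the lower quartile, a value equal
    to a cut point to the higher one) except the last, which is closed.
    Returns ``(boundaries, labels)`` with labels in {"Q1".."Q4"}.
    """
    v = np.asarray(values, float)
    if v.size < 4:
        raise ValueError(f"quartile assignment needs n >= 4, got {v.size}")
    q25, q50, q75 = np.percentile(v, [25, 50, 75])
    labels = np.full(v.shape, "Q4", dtype=object)
    labels[v < q75] = "Q3"
    labels[v < q50] = "Q2"
    labels[v < q25] = "Q1"
    boundaries = {
        "min": float(v.min()),
        "q25": float(q25),
        "q50": float(q50),
        "q75": float(q75),
        "max": float(v.max()),
    }
    return boundaries, labels
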