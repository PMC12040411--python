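"""End-to-end pipeline: simulate -> harmonics -> dissimilarity -> transfer -> report.

Every stage reads/writes plain CSV/JSON beside a manifest recording inputs,
outputs, row counts, the seed and wall time, so a run is fully reproducible
from its output directory alone.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import dissimilarity as dis
from . import harmonics as har
from . import synthetic as syn
from . import transfer as tra
from .config import RunConfig, dump_config

__all__ = ["run_pipeline", "render_report"]

logger = logging.getLogger(__name__)


def _geo_centroids_from_plots(plots: pd.DataFrame) -> pd.DataFrame:
    cen = plots.groupby("ecoregion_id")[["lat", "lon"]].mean().reset_index()
    return cen


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Run all stages under ``config``; returns the manifest.

    Any stage error aborts with the stage name and the propagated cause.
    Outputs: plots.csv, series.csv, climate.csv (optional), ecoregions.csv,
    descriptors.csv, pairwise.csv, bulk.csv, cross_mae.csv, test1a.csv,
    test1b.csv, test2.json, slopes.csv, report.txt, manifest.json,
    effective_config.yaml.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dump_config(config, outdir / "effective_config.yaml")
    manifest: dict = {"seed": int(config.seed), "stages": []}
    state: dict = {}

    stages = [
        ("simulate", _stage_simulate),
        ("harmonics", _stage_harmonics),
        ("dissim", _stage_dissim),
        ("transfer", _stage_transfer),
        ("report", _stage_report),
    ]
    for name, fn in stages:
        t0 = time.perf_counter()
        logger.info("stage %s: starting", name)
        try:
            entry = fn(config, outdir, state)
        except Exception as err:
            raise RuntimeError(f"pipeline stage {name!r} failed: {err}") from err
        entry["stage"] = name
        entry["seconds"] = round(time.perf_counter() - t0, 3)
        manifest["stages"].append(entry)
        logger.info(
            "stage %s: done in %.2fs (%s)", name, entry["seconds"],
            ", ".join(f"{k}={v}" for k, v in entry.get("row_counts", {}).items()),
        )

    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def _stage_simulate(config: RunConfig, outdir: Path, state: dict) -> dict:
    collection = syn.generate_collection(config.synthetic)
    if collection.climate is not None:
        derived = syn.climate_predictor_table(collection.climate, collection.plots)
        collection.plots = collection.plots.merge(derived, on="plot_id", how="left")
        collection.predictor_names += [c for c in derived.columns if c != "plot_id"]
    written = syn.write_collection(collection, outdir)
    state["collection"] = collection
    return {
        "inputs": [],
        "outputs": [str(p) for p in written.values()],
        "row_counts": {
            "plots": len(collection.plots),
            "series": len(collection.series),
            "climate": 0 if collection.climate is None else len(collection.climate),
        },
    }


def _stage_harmonics(config: RunConfig, outdir: Path, state: dict) -> dict:
    collection = state["collection"]
    hc = config.harmonic
    raw = har.descriptor_sets(
        collection.series, J=hc.J, frequency_mode=hc.frequency_mode,
        phase_average=hc.phase_average,
    )
    scaled = har.scale_amplitudes(raw, mode=config.dissimilarity.amplitude_scaling)
    frame = har.descriptors_to_frame(raw, scaled)
    path = outdir / "descriptors.csv"
    frame.to_csv(path, index=False, lineterminator="\n")
    state["descriptors"] = scaled
    return {
        "inputs": [str(outdir / "series.csv")],
        "outputs": [str(path)],
        "row_counts": {"descriptors": len(frame)},
    }


def _stage_dissim(config: RunConfig, outdir: Path, state: dict) -> dict:
    collection = state["collection"]
    dc = config.dissimilarity
    plots = collection.plots
    centroids = dis.indicator_centroids(
        plots, collection.indicator_names, min_plots=dc.min_plots,
        zscore=dc.zscore_mode,
    )
    descriptors = [
        d for d in state["descriptors"] if d.ecoregion_id in set(centroids.index)
    ]
    geo = _geo_centroids_from_plots(plots[plots["ecoregion_id"].isin(centroids.index)])
    pairwise = dis.pairwise_table(centroids, descriptors, geo, geo_mode=dc.geo_mode)
    bulk = dis.bulk_table(pairwise, reference_ids=list(centroids.index))
    pairwise.to_csv(outdir / "pairwise.csv", index=False, lineterminator="\n")
    bulk.to_csv(outdir / "bulk.csv", index=False, lineterminator="\n")
    state["pairwise"] = pairwise
    state["bulk"] = bulk
    return {
        "inputs": [str(outdir / "plots.csv"), str(outdir / "descriptors.csv")],
        "outputs": [str(outdir / "pairwise.csv"), str(outdir / "bulk.csv")],
        "row_counts": {"pairwise": len(pairwise), "bulk": len(bulk)},
    }


def _stage_transfer(config: RunConfig, outdir: Path, state: dict) -> dict:
    collection = state["collection"]
    tc = config.transfer
    dc = config.dissimilarity
    plots = collection.plots
    predictor_cols = collection.predictor_names
    pairwise = state["pairwise"]

    missing = [i for i in tc.indicators if i not in plots.columns]
    if missing:
        raise ValueError(f"configured indicators not in plot table: {missing}")

    cross = tra.cross_matrix(
        plots, tc.indicators, predictor_cols, min_plots=dc.min_plots,
        rf_config=tc.rf, seed=config.seed,
    )
    t1a = pd.concat(
        [
            tra.test_exclusion(
                plots, pairwise, measure, ind, predictor_cols,
                min_plots=dc.min_plots, rf_config=tc.rf, seed=config.seed,
            )
            for measure in tc.measures
            for ind in tc.indicators
        ],
        ignore_index=True,
    )
    t1b = pd.concat(
        [
            tra.test_inclusion(
                plots, pairwise, measure, ind, predictor_cols,
                min_plots=dc.min_plots, rf_config=tc.rf, seed=config.seed,
            )
            for measure in tc.measures
            for ind in tc.indicators
        ],
        ignore_index=True,
    )
    t2 = tra.test_interquartile_correlation(state["bulk"])
    slopes = pd.concat(
        [
            tra.mae_vs_geodist_by_quartile(cross, pairwise, measure, ind)
            for measure in tc.measures
            if measure != "geoDist"
            for ind in tc.indicators
        ],
        ignore_index=True,
    )

    cross.to_csv(outdir / "cross_mae.csv", index=False, lineterminator="\n")
    t1a.to_csv(outdir / "test1a.csv", index=False, lineterminator="\n")
    t1b.to_csv(outdir / "test1b.csv", index=False, lineterminator="\n")
    slopes.to_csv(outdir / "slopes.csv", index=False, lineterminator="\n")
    with open(outdir / "test2.json", "w", encoding="utf-8") as fh:
        json.dump(t2, fh, indent=2)
    state.update({"cross": cross, "t1a": t1a, "t1b": t1b, "t2": t2, "slopes": slopes})
    return {
        "inputs": [str(outdir / "plots.csv"), str(outdir / "pairwise.csv")],
        "outputs": [
            str(outdir / n)
            for n in ("cross_mae.csv", "test1a.csv", "test1b.csv", "test2.json",
                      "slopes.csv")
        ],
        "row_counts": {
            "cross_mae": len(cross), "test1a": len(t1a), "test1b": len(t1b),
            "slopes": len(slopes),
        },
    }


def _stage_report(config: RunConfig, outdir: Path, state: dict) -> dict:
    text = render_report(state["t1a"], state["t1b"], state["t2"], state["slopes"])
    path = outdir / "report.txt"
    path.write_text(text, encoding="utf-8")
    return {"inputs": [], "outputs": [str(path)], "row_counts": {}}


def render_report(
    t1a: pd.DataFrame, t1b: pd.DataFrame, t2: dict, slopes: pd.DataFrame
) -> str:
    """Plain-text summary of Tests 1A, 1B and 2."""
    lines = ["Cross-ecoregion transfer evaluation", "=" * 37, ""]

    lines.append("Test 1A — MAE after excluding the most similar quartiles")
    summary = (
        t1a.groupby(["measure", "condition"], sort=False)["mae"]
        .mean()
        .reset_index()
    )
    for measure, grp in summary.groupby("measure", sort=False):
        lines.append(f"  measure {measure}:")
        for _, row in grp.iterrows():
            mae = "empty pool" if np.isnan(row["mae"]) else f"{row['mae']:.3f}"
            lines.append(f"    {row['condition']:<22s} mean MAE = {mae}")
    lines.append("")

    lines.append("Test 1B — MAE training on a single quartile")
    summary = (
        t1b.groupby(["measure", "condition"], sort=False)["mae"]
        .mean()
        .reset_index()
    )
    for measure, grp in summary.groupby("measure", sort=False):
        lines.append(f"  measure {measure}:")
        for _, row in grp.iterrows():
            mae = "empty pool" if np.isnan(row["mae"]) else f"{row['mae']:.3f}"
            lines.append(f"    {row['condition']:<22s} mean MAE = {mae}")
    lines.append("")

    lines.append("Test 2 — bulk dissimilarity agreement (ecoDisINT_IS vs ecoDisINT_RS)")
    lines.append(
        f"  n = {t2['n']}, Spearman rho = {t2['spearman_rho']:.3f} "
        f"(p = {t2['spearman_p']:.2e}), Pearson r = {t2['pearson_r']:.3f}"
    )
    for q, rec in t2.get("per_quartile", {}).items():
        lines.append(
            f"  RS quartile {q}: n = {rec['n']}, "
            f"mean IS = {rec['mean_ecoDisINT_IS']:.3f}, "
            f"median IS = {rec['median_ecoDisINT_IS']:.3f}"
        )
    lines.append("")

    lines.append("MAE vs geoDist slopes by quartile")
    for (measure, ind), grp in slopes.groupby(["measure", "indicator"], sort=False):
        lines.append(f"  measure {measure}, indicator {ind}:")
        for _, row in grp.iterrows():
            lines.append(
                f"    {row['quartile']}: slope = {row['slope']:.5f} "
                f"MAE/km (n = {row['n']})"
            )
    lines.append("")
    return "\n".join(lines)
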