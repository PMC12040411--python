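"""Cross-ecoregion model-transfer evaluation with random forests.

A random-forest regressor is trained on the plots of one ecoregion
(predictors -> one cover indicator) and evaluated on the plots of every
other qualifying ecoregion, giving a K*(K-1) matrix of mean absolute errors
(MAE, percent cover). Three follow-up analyses probe whether pairwise
separation measures predict transfer error:

* Test 1A (exclusion ladder): for each test ecoregion, train on all other
  qualifying ecoregions after excluding progressively more of the most
  similar quartiles ({}, {Q1}, {Q1,Q2}, {Q1,Q2,Q3}) of a chosen separation
  measure; MAE should rise along the ladder if similarity encodes training
  data relevance.
* Test 1B (single-quartile inclusion): train only on the ecoregions in one
  quartile of the measure; MAE should rise from Q1 to Q4.
* Test 2: correlation between the bulk in-situ and remote-sensing
  dissimilarities (first interquartile means) across ecoregions.

Additionally MAE is regressed on geographic distance within quartiles of a
dissimilarity measure, reproducing the slope-by-quartile analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor

from .dissimilarity import MEASURE_COLUMNS, quartile_assign

__all__ = [
    "RFConfig",
    "EXCLUSION_LADDER",
    "INCLUSION_QUARTILES",
    "train_test_pair",
    "cross_matrix",
    "test_exclusion",
    "test_inclusion",
    "test_interquartile_correlation",
    "mae_vs_geodist_by_quartile",
]

#: Test 1A rungs: quartile sets removed from the training pool.
EXCLUSION_LADDER = ((), ("Q1",), ("Q1", "Q2"), ("Q1", "Q2", "Q3"))
#: Test 1B rungs: the single quartile retained as the training pool.
INCLUSION_QUARTILES = ("Q1", "Q2", "Q3", "Q4")


@dataclass(frozen=True)
class RFConfig:
    """Random-forest hyperparameters.

    100 trees, one third of the predictors tried per split, unlimited depth
    — a conventional regression-forest setup; all knobs exposed.
    """

    n_trees: int = 100
    max_features: float = 1.0 / 3.0
    max_depth: int | None = None
    min_samples_leaf: int = 1

    def build(self, seed: int) -> RandomForestRegressor:
        return RandomForestRegressor(
            n_estimators=self.n_trees,
            max_features=self.max_features,
            max_depth=self.max_depth,
            min_samples_leaf=self.min_samples_leaf,
            random_state=int(seed),
            n_jobs=1,
        )


def derive_seed(base: int, *keys) -> int:
    """Deterministic sub-seed from a base seed and hashable keys (< 2**31)."""
    h = np.uint64(base) * np.uint64(2654435761) % np.uint64(2**31)
    for key in keys:
        for ch in str(key).encode():
            h = (h * np.uint64(31) + np.uint64(ch)) % np.uint64(2**31)
    return int(h)


def _check_columns(frame: pd.DataFrame, cols: list[str], what: str) -> None:
    missing = [c for c in cols if c not in frame.columns]
    if missing:
        raise ValueError(f"{what} missing columns: {missing}")


def train_test_pair(
    train_plots: pd.DataFrame,
    test_plots: pd.DataFrame,
    indicator: str,
    predictor_cols: list[str],
    rf_config: RFConfig,
    seed: int,
) -> dict:
    """Fit on one plot set, score MAE on another.

    Returns a record with train/test ecoregion ids (taken from the frames
    when unambiguous), the indicator, sample sizes and the MAE in the
    indicator's percent-cover units.
    """
    if len(train_plots) == 0 or len(test_plots) == 0:
        raise ValueError("train and test plot sets must be non-empty")
    _check_columns(train_plots, predictor_cols + [indicator], "training plots")
    _check_columns(test_plots, predictor_cols + [indicator], "test plots")

    model = rf_config.build(seed)
    model.fit(train_plots[predictor_cols].to_numpy(), train_plots[indicator].to_numpy())
    pred = model.predict(test_plots[predictor_cols].to_numpy())
    mae = float(np.mean(np.abs(pred - test_plots[indicator].to_numpy())))

    def _single(frame):
        ids = frame["ecoregion_id"].unique() if "ecoregion_id" in frame else []
        return str(ids[0]) if len(ids) == 1 else None

    return {
        "train_ecoregion": _single(train_plots),
        "test_ecoregion": _single(test_plots),
        "indicator": indicator,
        "n_train": int(len(train_plots)),
        "n_test": int(len(test_plots)),
        "mae": mae,
    }


def _qualifying(plots: pd.DataFrame, min_plots: int) -> list[str]:
    counts = plots.groupby("ecoregion_id").size()
    return sorted(counts[counts >= min_plots].index)


def cross_matrix(
    plots: pd.DataFrame,
    indicators: list[str],
    predictor_cols: list[str],
    min_plots: int = 100,
    rf_config: RFConfig = RFConfig(),
    seed: int = 0,
) -> pd.DataFrame:
    """Every-ecoregion-predicts-every-other MAE matrix.

    One forest per (training ecoregion, indicator), reused against all other
    qualifying test ecoregions — identical to per-pair training because the
    training set does not depend on the test ecoregion. Emits K*(K-1) rows
    per indicator for K qualifying ecoregions.
    """
    ids = _qualifying(plots, min_plots)
    if len(ids) < 2:
        raise ValueError(f"need >= 2 ecoregions with {min_plots}+ plots, got {len(ids)}")
    groups = {eco: grp for eco, grp in plots.groupby("ecoregion_id") if eco in ids}

    rows = []
    for indicator in indicators:
        for train_eco in ids:
            train = groups[train_eco]
            model = rf_config.build(derive_seed(seed, train_eco, indicator))
            model.fit(
                train[predictor_cols].to_numpy(), train[indicator].to_numpy()
            )
            for test_eco in ids:
                if test_eco == train_eco:
                    continue
                test = groups[test_eco]
                pred = model.predict(test[predictor_cols].to_numpy())
                mae = float(np.mean(np.abs(pred - test[indicator].to_numpy())))
                rows.append(
                    {
                        "train_ecoregion": train_eco,
                        "test_ecoregion": test_eco,
                        "indicator": indicator,
                        "n_train": len(train),
                        "n_test": len(test),
                        "mae": mae,
                    }
                )
    return pd.DataFrame(rows)


def _pair_quartiles(
    pairwise: pd.DataFrame, test_eco: str, measure: str
) -> pd.Series:
    """Quartile label of every training candidate relative to ``test_eco``."""
    col = f"{measure}_quartile"
    if col not in pairwise.columns:
        raise ValueError(f"pairwise table lacks column {col!r}")
    sub = pairwise[pairwise["eco_n"] == test_eco]
    return pd.Series(sub[col].to_numpy(), index=sub["eco_m"].to_numpy())


def _pool_experiment(
    plots: pd.DataFrame,
    pairwise: pd.DataFrame,
    measure: str,
    indicator: str,
    predictor_cols: list[str],
    min_plots: int,
    rf_config: RFConfig,
    seed: int,
    conditions,
    keep,
    label,
) -> pd.DataFrame:
    """Shared engine of Tests 1A/1B: pooled-training runs over a condition set."""
    if measure not in MEASURE_COLUMNS:
        raise ValueError(f"measure must be one of {sorted(MEASURE_COLUMNS)}")
    ids = _qualifying(plots, min_plots)
    if len(ids) < 2:
        raise ValueError("need >= 2 qualifying ecoregions")
    missing = set(ids) - set(pairwise["eco_m"]).union(pairwise["eco_n"])
    if missing:
        raise ValueError(f"pairwise table does not cover ecoregions: {sorted(missing)}")
    groups = {eco: grp for eco, grp in plots.groupby("ecoregion_id") if eco in ids}

    rows = []
    for test_eco in ids:
        quart = _pair_quartiles(pairwise, test_eco, measure)
        test = groups[test_eco]
        for cond in conditions:
            train_ids = [
                e for e in ids if e != test_eco and keep(quart.get(e), cond)
            ]
            rec = {
                "test_ecoregion": test_eco,
                "measure": measure,
                "condition": label(cond),
                "indicator": indicator,
                "n_train_ecoregions": len(train_ids),
            }
            if not train_ids:
                rec.update({"n_train": 0, "mae": np.nan, "empty_pool": True})
            else:
                pool = pd.concat([groups[e] for e in train_ids])
                model = rf_config.build(
                    derive_seed(seed, test_eco, label(cond), indicator)
                )
                model.fit(
                    pool[predictor_cols].to_numpy(), pool[indicator].to_numpy()
                )
                pred = model.predict(test[predictor_cols].to_numpy())
                rec.update(
                    {
                        "n_train": len(pool),
                        "mae": float(
                            np.mean(np.abs(pred - test[indicator].to_numpy()))
                        ),
                        "empty_pool": False,
                    }
                )
            rows.append(rec)
    return pd.DataFrame(rows)


def exclusion_condition_label(excluded) -> str:
    return "exclude:" + ("+".join(excluded) if excluded else "none")


def inclusion_condition_label(quartile: str) -> str:
    return f"include:{quartile}"


def test_exclusion(
    plots: pd.DataFrame,
    pairwise: pd.DataFrame,
    measure: str,
    indicator: str,
    predictor_cols: list[str],
    min_plots: int = 100,
    rf_config: RFConfig = RFConfig(),
    seed: int = 0,
    ladder=EXCLUSION_LADDER,
) -> pd.DataFrame:
    """Test 1A: MAE after excluding the most similar training quartiles.

    Quartile membership of a training ecoregion is its pairwise ``measure``
    quartile (globally pooled boundaries) relative to the specific test
    ecoregion. An empty training pool at a rung is surfaced as a record with
    ``empty_pool=True`` and NaN MAE, never silently skipped.
    """
    return _pool_experiment(
        plots, pairwise, measure, indicator, predictor_cols, min_plots,
        rf_config, seed,
        conditions=ladder,
        keep=lambda q, excluded: q is not None and q not in excluded,
        label=exclusion_condition_label,
    )


def test_inclusion(
    plots: pd.DataFrame,
    pairwise: pd.DataFrame,
    measure: str,
    indicator: str,
    predictor_cols: list[str],
    min_plots: int = 100,
    rf_config: RFConfig = RFConfig(),
    seed: int = 0,
    quartiles=INCLUSION_QUARTILES,
) -> pd.DataFrame:
    """Test 1B: MAE when training only on one quartile of the measure."""
    return _pool_experiment(
        plots, pairwise, measure, indicator, predictor_cols, min_plots,
        rf_config, seed,
        conditions=quartiles,
        keep=lambda q, quartile: q == quartile,
        label=inclusion_condition_label,
    )


def test_interquartile_correlation(bulk: pd.DataFrame) -> dict:
    """Test 2: relationship between bulk IS and RS dissimilarities.

    ``bulk`` must carry matched ``ecoDisINT_IS`` and ``ecoDisINT_RS``
    columns per ecoregion (n >= 3, both with positive variance). Returns
    Spearman and Pearson correlations plus the mean/median of the IS bulk
    value within each quartile of the RS bulk value (when n >= 4).
    """
    for col in ("ecoDisINT_IS", "ecoDisINT_RS"):
        if col not in bulk.columns:
            raise ValueError(f"bulk table missing column {col!r}")
    x = bulk["ecoDisINT_RS"].to_numpy(float)
    y = bulk["ecoDisINT_IS"].to_numpy(float)
    if x.size < 3:
        raise ValueError("need n >= 3 ecoregions")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in a bulk dissimilarity vector")
    rho = stats.spearmanr(x, y)
    pea = stats.pearsonr(x, y)
    result = {
        "n": int(x.size),
        "spearman_rho": float(rho.statistic),
        "spearman_p": float(rho.pvalue),
        "pearson_r": float(pea.statistic),
        "pearson_p": float(pea.pvalue),
        "per_quartile": {},
    }
    if x.size >= 4:
        _, labels = quartile_assign(x)
        for q in ("Q1", "Q2", "Q3", "Q4"):
            mask = labels == q
            if mask.any():
                result["per_quartile"][q] = {
                    "n": int(mask.sum()),
                    "mean_ecoDisINT_IS": float(y[mask].mean()),
                    "median_ecoDisINT_IS": float(np.median(y[mask])),
                }
    return result


def mae_vs_geodist_by_quartile(
    cross: pd.DataFrame,
    pairwise: pd.DataFrame,
    measure: str,
    indicator: str,
) -> pd.DataFrame:
    """OLS of MAE against geoDist within quartiles of a dissimilarity measure.

    Joins the cross-matrix records for ``indicator`` with the pairwise table
    on the (train, test) pair and fits MAE ~ geoDist separately per quartile
    of ``measure``. Requires >= 3 pairs and non-degenerate geoDist variance
    per quartile.
    """
    if measure not in MEASURE_COLUMNS:
        raise ValueError(f"measure must be one of {sorted(MEASURE_COLUMNS)}")
    col = f"{measure}_quartile"
    sub = cross[cross["indicator"] == indicator]
    merged = sub.merge(
        pairwise[["eco_m", "eco_n", "geoDist", col]],
        left_on=["train_ecoregion", "test_ecoregion"],
        right_on=["eco_m", "eco_n"],
        how="inner",
    )
    if len(merged) != len(sub):
        raise ValueError("pairwise table does not cover all cross-matrix pairs")
    rows = []
    for q in ("Q1", "Q2", "Q3", "Q4"):
        grp = merged[merged[col] == q]
        if len(grp) < 3:
            raise ValueError(f"quartile {q} has fewer than 3 pairs")
        g = grp["geoDist"].to_numpy(float)
        if np.ptp(g) == 0:
            raise ValueError(f"degenerate geoDist variance in quartile {q}")
        fit = stats.linregress(g, grp["mae"].to_numpy(float))
        rows.append(
            {
                "measure": measure,
                "indicator": indicator,
                "quartile": q,
                "slope": float(fit.slope),
                "intercept": float(fit.intercept),
                "r": float(fit.rvalue),
                "n": int(len(grp)),
            }
        )
    return pd.DataFrame(rows)
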