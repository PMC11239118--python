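"""Imputation-reliability metrics and the cross-validated reporting harness.

Four metrics, computed between imputed and observed values on held-out
folds: Pearson correlation and regression slope (imputed ~ observed; slope
above 1 reads as overestimation), NRMSE (RMSE divided by the spread of the
observed values, so mean-imputation scores exactly 1), and, for binary
attributes, classification accuracy. Continuous metrics operate on the
log10 scale, matching how the imputation models are trained.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .engine import ImputationConfig, multiply_impute
from .filters import FilterSet
from .tables import PROV_MISSING, TraitTable

__all__ = [
    "ValidationReport",
    "accuracy",
    "crossvalidate",
    "nrmse",
    "pearson_r",
    "regression_slope",
]


def _check_pair(imputed, observed, min_n=2):
    imputed = np.asarray(imputed, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if imputed.shape != observed.shape:
        raise ValueError("imputed and observed must have equal length")
    if len(imputed) < min_n:
        raise ValueError(f"need at least {min_n} pairs")
    return imputed, observed


def pearson_r(imputed, observed) -> float:
    """Product-moment correlation between imputed and observed values."""
    imputed, observed = _check_pair(imputed, observed, min_n=3)
    if np.all(imputed == imputed[0]) or np.all(observed == observed[0]):
        raise ValueError("correlation undefined for a constant vector")
    return float(np.corrcoef(imputed, observed)[0, 1])


def regression_slope(imputed, observed) -> float:
    """Least-squares slope of imputed regressed on observed."""
    imputed, observed = _check_pair(imputed, observed, min_n=3)
    var = np.var(observed)
    if var == 0:
        raise ValueError("slope undefined: observed values are constant")
    cov = np.mean((observed - observed.mean()) * (imputed - imputed.mean()))
    return float(cov / var)


def nrmse(imputed, observed, norm: str = "sd") -> float:
    """Root mean square error normalised by the observed spread.

    ``norm="sd"`` divides by the population standard deviation of the
    observed values, so imputing every entry at the observed mean gives
    exactly 1 (the no-skill baseline); ``norm="range"`` divides by
    max - min instead.
    """
    imputed, observed = _check_pair(imputed, observed)
    rmse = float(np.sqrt(np.mean((imputed - observed) ** 2)))
    if norm == "sd":
        denom = float(np.std(observed))
    elif norm == "range":
        denom = float(observed.max() - observed.min())
    else:
        raise ValueError(f"norm must be 'sd' or 'range', got {norm!r}")
    if denom == 0:
        raise ValueError("NRMSE undefined: observed values have no spread")
    return rmse / denom


def accuracy(imputed_binary, observed_binary) -> float:
    """Proportion of correctly classified binary entries."""
    imputed = np.asarray(imputed_binary)
    observed = np.asarray(observed_binary)
    if imputed.shape != observed.shape:
        raise ValueError("inputs must have equal length")
    if len(imputed) == 0:
        raise ValueError("empty input")
    if not (np.isin(imputed, (0, 1)).all() and np.isin(observed, (0, 1)).all()):
        raise ValueError("inputs must be 0/1")
    return float(np.mean(imputed == observed))


# ---------------------------------------------------------------------------
# cross-validated harness


@dataclass
class ValidationReport:
    """Stored held-out predictions plus tidy per-fold and pooled metrics.

    ``predictions`` columns: species, attribute, fold, truth, imputed,
    majority. Metrics are a pure function of this table and can be
    recomputed from it at any time via :meth:`metrics`.
    """

    predictions: pd.DataFrame
    objectives: dict[str, str]

    def metrics(self) -> pd.DataFrame:
        rows = []
        for attr, grp in self.predictions.groupby("attribute"):
            objective = self.objectives[attr]
            folds = [(f, g) for f, g in grp.groupby("fold")]
            for fold, g in folds + [("pooled", grp)]:
                rows.extend(_metric_rows(attr, fold, g, objective))
        return pd.DataFrame(rows)


def _metric_rows(attr, fold, g, objective):
    rows = []
    base = {"attribute": attr, "fold": fold, "n_test": len(g)}
    if objective == "regression":
        truth = np.log10(g["truth"].to_numpy(dtype=float))
        imp = np.log10(g["imputed"].to_numpy(dtype=float))
        for name, fn in (("pearson_r", pearson_r),
                         ("slope", regression_slope),
                         ("nrmse", nrmse)):
            try:
                value = fn(imp, truth)
            except ValueError:
                value = np.nan
            rows.append({**base, "metric": name, "value": value})
    else:
        rows.append({**base, "metric": "accuracy",
                     "value": accuracy(g["majority"].astype(int),
                                       g["truth"].astype(int))})
    return rows


def crossvalidate(
    table: TraitTable,
    filters: list[FilterSet] | FilterSet,
    config: ImputationConfig | None = None,
    tuned: dict[str, dict] | None = None,
    attributes: list[str] | None = None,
) -> ValidationReport:
    """Mask-and-recover cross-validation on the complete-case subset.

    Complete rows are partitioned into ``config.n_folds`` folds; in each
    iteration the test fold's target cells are hidden, the engine imputes
    them from the remaining rows (across the whole tree set), and point
    summaries are scored against the hidden truth. Every complete row
    appears in exactly one test fold, so pooled n_test equals the
    complete-case count.
    """
    config = config or ImputationConfig()
    if isinstance(filters, FilterSet):
        filters = [filters]
    attributes = attributes or table.trait_columns
    complete = table.provenance[attributes].eq("observed").all(axis=1)
    complete_idx = table.data.index[complete]
    if len(complete_idx) < 2 * config.n_folds:
        raise ValueError(
            f"need at least {2 * config.n_folds} complete-case rows, "
            f"have {len(complete_idx)}"
        )
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(complete_idx))
    fold_of = np.empty(len(complete_idx), dtype=int)
    for f, chunk in enumerate(np.array_split(order, config.n_folds)):
        fold_of[chunk] = f
    records = []
    for f in range(config.n_folds):
        test_sp = complete_idx[fold_of == f]
        masked = table.copy()
        for attr in attributes:
            masked.data.loc[test_sp, attr] = np.nan
            masked.provenance.loc[test_sp, attr] = PROV_MISSING
        inner = replace(config, n_folds=1, seed=config.seed + 1000 * (f + 1))
        result = multiply_impute(masked, filters, inner, tuned=tuned,
                                 attributes=attributes)
        summary = result.summarize()
        for row in summary.itertuples():
            if row.species not in test_sp:
                continue
            truth = table.data.at[row.species, row.attribute]
            records.append({
                "species": row.species, "attribute": row.attribute, "fold": f,
                "truth": float(truth), "imputed": row.point,
                "majority": row.majority,
            })
    predictions = pd.DataFrame(records)
    objectives = {
        a: ("regression" if a in table.continuous_columns else "binary")
        for a in attributes
    }
    return ValidationReport(predictions, objectives)
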