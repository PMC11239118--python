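"""Boosted-tree multiple imputation with predictive mean matching (PMM).

For every phylogeny in a tree set, an XGBoost model per target attribute and
cross-validation fold predicts the missing entries from the retained
phylogenetic filters plus all other trait columns; PMM then replaces each
model prediction by the observed value of one of the k nearest donors in
prediction space, repeated m times. A cell missing everywhere therefore
accumulates m x folds x trees draws, whose spread carries the imputation
uncertainty. Observed cells are never altered.

The boosted-tree learner is a pluggable engine; the bespoke parts — filter
predictors, PMM, fold/tree replication, and draw bookkeeping — live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.model_selection import KFold

from .filters import FilterSet
from .tables import PROV_PHYLO, TraitTable

__all__ = [
    "DEFAULT_PARAMS",
    "ImputationConfig",
    "MultipleImputationResult",
    "TuningSpec",
    "multiply_impute",
    "pmm_draw",
    "summarize_imputations",
    "tune_hyperparameters",
]

#: Sensible fixed hyperparameters used when no tuning run is supplied.
DEFAULT_PARAMS = {
    "eta": 0.1,
    "max_depth": 6,
    "subsample": 0.9,
    "min_child_weight": 1.0,
    "nrounds": 150,
}


@dataclass
class TuningSpec:
    """Two-stage uniform random search over the five key XGBoost knobs.

    Stage 1 draws ``n_draws_stage1`` parameter sets uniformly from the
    ranges; stage 2 redraws inside the axis-aligned bounding box of the top
    ``top_fraction`` of stage-1 sets. Published-scale runs use 1,000 draws
    per stage; desk-scale defaults are 100.
    """

    eta_range: tuple[float, float] = (0.01, 0.3)
    depth_range: tuple[int, int] = (3, 12)
    subsample_range: tuple[float, float] = (0.7, 1.0)
    min_child_weight_range: tuple[float, float] = (0.5, 1.5)
    nrounds_range: tuple[int, int] = (30, 1000)
    n_draws_stage1: int = 100
    n_draws_stage2: int = 100
    top_fraction: float = 0.05

    def __post_init__(self):
        for name in ("eta_range", "depth_range", "subsample_range",
                     "min_child_weight_range", "nrounds_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} bounds out of order")
        if self.n_draws_stage1 < 1 or self.n_draws_stage2 < 1:
            raise ValueError("draw counts must be >= 1")
        if not 0.0 < self.top_fraction <= 1.0:
            raise ValueError("top_fraction must be in (0, 1]")


@dataclass
class ImputationConfig:
    """Scale knobs of the multiple-imputation run. Published-scale values are
    k=10 donors, m=10 imputations, 10 folds, 100 trees; desk-scale default
    for the tree set is 5."""

    k_donors: int = 10
    m_imputations: int = 10
    n_folds: int = 10
    n_trees: int | None = 5
    seed: int = 0
    params: dict = field(default_factory=lambda: dict(DEFAULT_PARAMS))

    def __post_init__(self):
        if self.k_donors < 1 or self.m_imputations < 1 or self.n_folds < 1:
            raise ValueError("k_donors, m_imputations and n_folds must be >= 1")


# ---------------------------------------------------------------------------
# learner wrapper


def _fit_predict(X_train, y_train, X_eval, params, objective, seed):
    common = dict(
        n_estimators=int(params["nrounds"]),
        learning_rate=float(params["eta"]),
        max_depth=int(params["max_depth"]),
        subsample=float(params["subsample"]),
        min_child_weight=float(params["min_child_weight"]),
        n_jobs=1,
        random_state=int(seed) % (2**31),
        tree_method="hist",
        verbosity=0,
    )
    if objective == "regression":
        model = xgb.XGBRegressor(objective="reg:squarederror", **common)
        model.fit(X_train, y_train)
        return model.predict(X_eval)
    if objective == "binary":
        if len(np.unique(y_train)) < 2:  # degenerate class: constant output
            return np.full(len(X_eval), float(y_train[0]))
        model = xgb.XGBClassifier(objective="binary:logistic", **common)
        model.fit(X_train, y_train.astype(int))
        return model.predict_proba(X_eval)[:, 1]
    raise ValueError(f"objective must be 'regression' or 'binary', got {objective!r}")


# ---------------------------------------------------------------------------
# hyperparameter search


def _draw_params(rng, box):
    return {
        "eta": rng.uniform(*box["eta"]),
        "max_depth": int(rng.integers(box["max_depth"][0], box["max_depth"][1] + 1)),
        "subsample": rng.uniform(*box["subsample"]),
        "min_child_weight": rng.uniform(*box["min_child_weight"]),
        "nrounds": int(rng.integers(box["nrounds"][0], box["nrounds"][1] + 1)),
    }


def _cv_score(X, y, params, objective, n_folds, seed):
    """Pooled CV error: NRMSE for regression, misclassification for binary."""
    preds = np.empty(len(y))
    for f, (tr, te) in enumerate(
        KFold(n_folds, shuffle=True, random_state=seed % (2**31)).split(X)
    ):
        preds[te] = _fit_predict(X.iloc[tr], y[tr], X.iloc[te], params,
                                 objective, seed + f)
    if objective == "regression":
        return float(np.sqrt(np.mean((preds - y) ** 2)) / np.std(y))
    return float(np.mean((preds >= 0.5).astype(int) != y.astype(int)))


def tune_hyperparameters(
    X: pd.DataFrame,
    y: np.ndarray,
    spec: TuningSpec | None = None,
    objective: str = "regression",
    seed: int = 0,
    n_folds: int = 3,
) -> tuple[dict, pd.DataFrame]:
    """Two-stage random search; returns (best parameter set, search trace).

    The trace has one row per evaluated draw with its stage and CV score
    (lower is better). Deterministic given the seed.
    """
    spec = spec or TuningSpec()
    y = np.asarray(y, dtype=float)
    if len(y) < 2 * n_folds:
        raise ValueError(f"need at least {2 * n_folds} complete rows")
    if np.all(y == y[0]):
        raise ValueError("degenerate (constant) response")
    rng = np.random.default_rng(seed)
    box1 = {
        "eta": spec.eta_range,
        "max_depth": spec.depth_range,
        "subsample": spec.subsample_range,
        "min_child_weight": spec.min_child_weight_range,
        "nrounds": spec.nrounds_range,
    }
    trace = []

    def run_stage(stage, box, n_draws):
        for _ in range(n_draws):
            params = _draw_params(rng, box)
            score = _cv_score(X, y, params, objective, n_folds,
                              int(rng.integers(2**31)))
            trace.append({"stage": stage, **params, "score": score})

    run_stage(1, box1, spec.n_draws_stage1)
    stage1 = pd.DataFrame(trace)
    n_top = max(1, int(np.ceil(spec.top_fraction * len(stage1))))
    top = stage1.nsmallest(n_top, "score")
    box2 = {
        key: (top[col].min(), top[col].max())
        for key, col in (("eta", "eta"), ("max_depth", "max_depth"),
                         ("subsample", "subsample"),
                         ("min_child_weight", "min_child_weight"),
                         ("nrounds", "nrounds"))
    }
    run_stage(2, box2, spec.n_draws_stage2)
    trace_df = pd.DataFrame(trace)
    best = trace_df.loc[trace_df["score"].idxmin()]
    params = {
        "eta": float(best["eta"]),
        "max_depth": int(best["max_depth"]),
        "subsample": float(best["subsample"]),
        "min_child_weight": float(best["min_child_weight"]),
        "nrounds": int(best["nrounds"]),
    }
    return params, trace_df


# ---------------------------------------------------------------------------
# predictive mean matching


def pmm_draw(pred_missing, pred_observed, y_observed, k, rng):
    """One PMM draw: among observed entries, find the k whose predictions are
    closest to ``pred_missing`` (ties at the k-th distance broken at random),
    pick one donor uniformly, and return its observed value."""
    pred_observed = np.asarray(pred_observed, dtype=float)
    y_observed = np.asarray(y_observed)
    if len(pred_observed) == 0:
        raise ValueError("empty observed pool")
    if k > len(pred_observed):
        raise ValueError("k exceeds the observed pool size")
    dist = np.abs(pred_observed - pred_missing)
    kth = np.partition(dist, k - 1)[k - 1]
    inner = np.where(dist < kth)[0]
    border = np.where(dist == kth)[0]
    need = k - len(inner)
    if need < len(border):
        border = rng.choice(border, size=need, replace=False)
    donors = np.concatenate([inner, border]).astype(int)
    return y_observed[int(rng.choice(donors))]


def _pmm_draws(pred_missing_vec, pred_observed, y_observed, k, m, rng):
    out = np.empty((len(pred_missing_vec), m), dtype=float)
    for i, pm in enumerate(pred_missing_vec):
        for j in range(m):
            out[i, j] = pmm_draw(pm, pred_observed, y_observed, k, rng)
    return out


# ---------------------------------------------------------------------------
# multiple imputation over trees x folds


@dataclass
class MultipleImputationResult:
    """Long-format store of every PMM draw plus the config that made it.

    ``draws`` columns: species, attribute, tree_id, fold, m, value. For
    continuous attributes the values are on the raw (untransformed) scale —
    PMM returns observed values, so summaries stay inside the observed
    range.
    """

    draws: pd.DataFrame
    config: ImputationConfig
    objectives: dict[str, str]

    def summarize(self) -> pd.DataFrame:
        return summarize_imputations(self)

    def draw_counts(self) -> pd.DataFrame:
        return (
            self.draws.groupby(["species", "attribute"])["value"]
            .size()
            .rename("n_draws")
            .reset_index()
        )

    def apply_to(self, table: TraitTable) -> TraitTable:
        """Fill the table's missing cells with point summaries (median for
        continuous, majority call for binary), provenance ``phylo_imputed``.
        If every category of a species' activity or microhabitat block ends
        up 0 after majority calls, the category with the largest mean draw is
        switched on (activity ties give both, i.e. cathemeral), keeping the
        one-category-minimum guarantee of the schema."""
        from .tables import ACTIVITY_COLS, MICROHABITAT_COLS, PROV_MISSING

        out = table.copy()
        summary = self.summarize()
        for row in summary.itertuples():
            if out.provenance.at[row.species, row.attribute] != PROV_MISSING:
                continue
            value = row.point if self.objectives[row.attribute] == "regression" else row.majority
            out.data.at[row.species, row.attribute] = value
            out.provenance.at[row.species, row.attribute] = PROV_PHYLO
        means = summary.set_index(["species", "attribute"])["point"]
        for block in (ACTIVITY_COLS, MICROHABITAT_COLS):
            cols = [c for c in block if c in out.data.columns]
            if not cols:
                continue
            filled = (out.provenance[cols] == PROV_PHYLO).any(axis=1)
            zero = out.data[cols].fillna(0).sum(axis=1) == 0
            for sp in out.data.index[filled & zero]:
                frac = np.array(
                    [means.get((sp, c), 0.0) for c in cols], dtype=float
                )
                best = frac == frac.max()
                if block is ACTIVITY_COLS and best.all():
                    chosen = cols  # exact tie: cathemeral
                else:
                    chosen = [cols[int(np.argmax(frac))]]
                for c in chosen:
                    out.data.at[sp, c] = 1
        return out


def _objective_for(table: TraitTable, attr: str) -> str:
    return "regression" if attr in table.continuous_columns else "binary"


def _predictor_frame(table: TraitTable, fs: FilterSet, target: str) -> pd.DataFrame:
    """Retained filters plus all other trait columns, continuous ones on the
    log10 scale; missing predictor cells stay NaN (filled per fold)."""
    X = fs.vectors.loc[table.data.index].copy()
    for col in table.trait_columns:
        if col == target:
            continue
        if col in table.continuous_columns:
            X[col] = np.log10(table.data[col].astype(float))
        else:
            X[col] = table.data[col].astype(float)
    return X


def _prune_uninformative(X, table, target, mis_idx):
    """Drop predictor columns with no observed value among the rows being
    predicted: they cannot inform those predictions (co-missing blocks), and
    any imputed fill for them injects the observed pool's bias. Remaining
    missing predictor cells are passed through as NaN — the boosted-tree
    learner routes them by its learned default directions."""
    drop = [
        col
        for col in X.columns
        if col in table.trait_columns and table.data[col].iloc[mis_idx].isna().all()
    ]
    return X.drop(columns=drop)


def multiply_impute(
    table: TraitTable,
    filters: list[FilterSet] | FilterSet,
    config: ImputationConfig | None = None,
    tuned: dict[str, dict] | None = None,
    attributes: list[str] | None = None,
) -> MultipleImputationResult:
    """Run the full trees x folds x imputations PMM pipeline.

    ``tuned`` optionally maps attribute -> hyperparameter dict (as returned
    by :func:`tune_hyperparameters`); otherwise ``config.params`` is used for
    every attribute. Attributes with fewer than max(20, 2 k) usable rows are
    skipped with a warning. Fully deterministic given ``config.seed``.
    """
    config = config or ImputationConfig()
    if isinstance(filters, FilterSet):
        filters = [filters]
    if config.n_trees is not None and config.n_trees != len(filters):
        config = replace(config, n_trees=len(filters))
    for fs in filters:
        missing_sp = table.data.index.difference(fs.species)
        if len(missing_sp):
            raise ValueError(
                f"species absent from FilterSet {fs.tree_id!r}: {sorted(missing_sp)[:5]}"
            )
    attrs = attributes or [
        c for c in table.trait_columns if table.data[c].isna().any()
    ]
    floor = max(20, 2 * config.k_donors)
    records = []
    ss = np.random.SeedSequence(config.seed)
    for t_idx, fs in enumerate(filters):
        for attr in attrs:
            objective = _objective_for(table, attr)
            obs_mask = table.observed_mask(attr)
            obs_idx = np.where(obs_mask.to_numpy())[0]
            mis_idx = np.where((table.provenance[attr] == "missing").to_numpy())[0]
            if len(mis_idx) == 0:
                continue
            if len(obs_idx) < floor:
                warnings.warn(
                    f"{attr}: only {len(obs_idx)} usable rows (< {floor}), skipped"
                )
                continue
            X = _predictor_frame(table, fs, attr)
            X = _prune_uninformative(X, table, attr, mis_idx)
            y_raw = table.data[attr].to_numpy(dtype=float)
            y_model = np.log10(y_raw) if objective == "regression" else y_raw
            params = (tuned or {}).get(attr, config.params)
            folds = _fold_splits(obs_idx, config.n_folds, config.seed + t_idx)
            for f_idx, train_rows in enumerate(folds):
                child = np.random.default_rng(
                    ss.spawn(1)[0]
                )  # fresh, deterministic stream per (tree, attr, fold)
                preds = _fit_predict(
                    X.iloc[train_rows],
                    y_model[train_rows],
                    X.iloc[np.concatenate([train_rows, mis_idx])],
                    params,
                    objective,
                    seed=config.seed + 97 * t_idx + 13 * f_idx,
                )
                pred_train = preds[: len(train_rows)]
                pred_mis = preds[len(train_rows):]
                draws = _pmm_draws(
                    pred_mis, pred_train, y_raw[train_rows],
                    config.k_donors, config.m_imputations, child,
                )
                for i, row in enumerate(mis_idx):
                    sp = table.data.index[row]
                    for m in range(config.m_imputations):
                        records.append(
                            (sp, attr, fs.tree_id, f_idx, m, draws[i, m])
                        )
    draws_df = pd.DataFrame(
        records, columns=["species", "attribute", "tree_id", "fold", "m", "value"]
    )
    objectives = {a: _objective_for(table, a) for a in attrs}
    return MultipleImputationResult(draws_df, config, objectives)


def _fold_splits(obs_idx, n_folds, seed):
    """Training-row index arrays, one per fold. n_folds=1 trains on all
    observed rows (used by the validation harness, which handles its own
    masking)."""
    if n_folds == 1:
        return [obs_idx]
    splits = []
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed % (2**31))
    for train, _test in kf.split(obs_idx):
        splits.append(obs_idx[train])
    return splits


def summarize_imputations(result: MultipleImputationResult) -> pd.DataFrame:
    """Per missing cell: the point summary (median of draws for continuous,
    mean for binary) and a majority call (mean >= 0.5 -> 1) for scores."""
    if result.draws.empty:
        return pd.DataFrame(columns=["species", "attribute", "point", "majority"])
    rows = []
    for (sp, attr), grp in result.draws.groupby(["species", "attribute"], sort=False):
        vals = grp["value"].to_numpy()
        if result.objectives[attr] == "regression":
            point = float(np.median(vals))
            majority = np.nan
        else:
            point = float(np.mean(vals))
            majority = int(point >= 0.5)
        rows.append({"species": sp, "attribute": attr, "point": point,
                     "majority": majority, "n_draws": len(vals)})
    return pd.DataFrame(rows)
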