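"""Imputation engine: PMM, hyperparameter search, and the trees x folds
bookkeeping."""

import numpy as np
import pandas as pd
import pytest

import traitgaps as tg
from traitgaps.engine import _fold_splits


class TestPmmDraw:
    def test_exact_prediction_returns_that_donor(self, rng):
        pred_obs = np.array([1.0, 2.0, 5.0, 9.0])
        y_obs = np.array([10.0, 20.0, 50.0, 90.0])
        assert tg.pmm_draw(5.0, pred_obs, y_obs, k=1, rng=rng) == 50.0

    def test_draws_always_come_from_observed_values(self, rng):
        pred_obs = rng.normal(size=30)
        y_obs = rng.normal(size=30)
        for _ in range(100):
            v = tg.pmm_draw(rng.normal(), pred_obs, y_obs, k=5, rng=rng)
            assert v in y_obs

    def test_equidistant_pool_selected_uniformly(self, rng):
        """All donors equidistant with k = pool size: selection frequencies
        uniform within 3 binomial sd over 10,000 draws."""
        pred_obs = np.full(4, 2.0)
        y_obs = np.array([0.0, 1.0, 2.0, 3.0])
        draws = [tg.pmm_draw(2.0, pred_obs, y_obs, k=4, rng=rng) for _ in range(10_000)]
        counts = pd.Series(draws).value_counts()
        expected = 10_000 / 4
        sd = np.sqrt(10_000 * 0.25 * 0.75)
        assert ((counts - expected).abs() < 3 * sd).all()

    def test_empty_pool_and_oversized_k_rejected(self, rng):
        with pytest.raises(ValueError):
            tg.pmm_draw(1.0, np.array([]), np.array([]), k=1, rng=rng)
        with pytest.raises(ValueError):
            tg.pmm_draw(1.0, np.array([1.0]), np.array([1.0]), k=2, rng=rng)


class TestTuning:
    _SPEC = tg.TuningSpec(
        nrounds_range=(20, 40), n_draws_stage1=6, n_draws_stage2=6
    )

    def _data(self, n=60, seed=0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame({"x1": rng.normal(size=n), "x2": rng.normal(size=n)})
        return X, 2.0 * X["x1"].to_numpy()

    def test_deterministic_given_seed(self):
        X, y = self._data()
        a, _ = tg.tune_hyperparameters(X, y, self._SPEC, seed=5)
        b, _ = tg.tune_hyperparameters(X, y, self._SPEC, seed=5)
        assert a == b

    def test_stage_two_box_inside_stage_one_ranges(self):
        X, y = self._data()
        _, trace = tg.tune_hyperparameters(X, y, self._SPEC, seed=5)
        s2 = trace[trace["stage"] == 2]
        assert s2["eta"].between(*self._SPEC.eta_range).all()
        assert s2["nrounds"].between(*self._SPEC.nrounds_range).all()

    def test_beats_mean_prediction_on_linear_response(self):
        X, y = self._data(n=90, seed=2)
        _, trace = tg.tune_hyperparameters(X, y, self._SPEC, seed=1)
        assert trace["score"].min() < 1.0  # NRMSE of mean prediction is 1

    def test_constant_response_rejected(self):
        X, _ = self._data()
        with pytest.raises(ValueError, match="constant"):
            tg.tune_hyperparameters(X, np.ones(len(X)), self._SPEC, seed=0)


@pytest.fixture(scope="module")
def masked_setup():
    clade = tg.build_clade(n_tips=90, n_genera=9, n_families=3, seed=17)
    spec = tg.MissingnessSpec(
        {
            "body_length": tg.AttributeMissingness("MCAR", 0.2),
            "activity": tg.AttributeMissingness("MCAR", 0.2),
        }
    )
    masked, mask = tg.impose_missingness(clade.traits_true, spec, seed=4)
    cov = tg.tree_to_covariance(clade.tree)
    fs = tg.derive_filters(cov, tree_id="t0")
    return clade, masked, mask, fs


class TestMultiplyImpute:
    CFG = tg.ImputationConfig(k_donors=5, m_imputations=3, n_folds=3, seed=8)

    def test_no_missing_cells_yields_empty_result(self, small_clade, small_filterset):
        res = tg.multiply_impute(small_clade.traits_true, small_filterset, self.CFG)
        assert res.draws.empty
        assert res.summarize().empty

    def test_draw_count_bookkeeping(self, masked_setup):
        clade, masked, _, fs = masked_setup
        jittered = tg.perturb_branch_lengths(clade.tree, 0.2, seed=1)
        trees = [fs, tg.derive_filters(tg.tree_to_covariance(jittered), tree_id="t1")]
        res = tg.multiply_impute(masked, trees, self.CFG)
        counts = res.draw_counts()
        expected = self.CFG.m_imputations * self.CFG.n_folds * len(trees)
        assert (counts["n_draws"] == expected).all()

    def test_continuous_summaries_within_observed_range(self, masked_setup):
        _, masked, _, fs = masked_setup
        res = tg.multiply_impute(masked, fs, self.CFG)
        summ = res.summarize()
        obs = masked.data.loc[masked.observed_mask("BodyLength_mm"), "BodyLength_mm"]
        pts = summ[summ["attribute"] == "BodyLength_mm"]["point"]
        assert pts.between(obs.min(), obs.max()).all()

    def test_observed_cells_never_altered(self, masked_setup):
        _, masked, _, fs = masked_setup
        res = tg.multiply_impute(masked, fs, self.CFG)
        filled = res.apply_to(masked)
        obs = masked.observed_mask("BodyLength_mm")
        pd.testing.assert_series_equal(
            filled.data.loc[obs, "BodyLength_mm"],
            masked.data.loc[obs, "BodyLength_mm"],
        )
        filled.validate()

    def test_deterministic_draw_vectors(self, masked_setup):
        _, masked, _, fs = masked_setup
        a = tg.multiply_impute(masked, fs, self.CFG).draws
        b = tg.multiply_impute(masked, fs, self.CFG).draws
        pd.testing.assert_frame_equal(a, b)

    def test_recovers_hidden_truth_direction(self, masked_setup):
        clade, masked, mask, fs = masked_setup
        res = tg.multiply_impute(masked, fs, self.CFG)
        filled = res.apply_to(masked)
        hid = mask["body_length"]
        truth = np.log10(clade.traits_true.data.loc[hid, "BodyLength_mm"])
        imp = np.log10(filled.data.loc[hid, "BodyLength_mm"])
        assert tg.pearson_r(imp, truth) > 0

    def test_thin_attribute_skipped_with_warning(self, masked_setup):
        _, masked, _, fs = masked_setup
        thin = masked.copy()
        keep = thin.data.index[:15]  # below the max(20, 2k) usable-row floor
        thin.data.loc[~thin.data.index.isin(keep), "BodyMass_g"] = np.nan
        thin.provenance.loc[~thin.data.index.isin(keep), "BodyMass_g"] = "missing"
        with pytest.warns(UserWarning, match="skipped"):
            res = tg.multiply_impute(
                thin, fs, self.CFG, attributes=["BodyMass_g"]
            )
        assert res.draws.empty


class TestSummaries:
    def test_median_and_majority_rules(self):
        draws = pd.DataFrame(
            {
                "species": ["a"] * 3 + ["b"] * 4,
                "attribute": ["BodyLength_mm"] * 3 + ["Noc"] * 4,
                "tree_id": "t",
                "fold": 0,
                "m": [0, 1, 2, 0, 1, 2, 3],
                "value": [1.0, 2.0, 3.0, 1, 1, 0, 0],
            }
        )
        res = tg.MultipleImputationResult(
            draws, tg.ImputationConfig(),
            {"BodyLength_mm": "regression", "Noc": "binary"},
        )
        summ = res.summarize().set_index("attribute")
        assert summ.loc["BodyLength_mm", "point"] == 2.0
        assert summ.loc["Noc", "point"] == 0.5
        assert summ.loc["Noc", "majority"] == 1  # boundary: mean >= 0.5

    def test_median_invariant_to_draw_order(self, rng):
        vals = rng.normal(size=9)
        for perm in (vals, vals[::-1], rng.permutation(vals)):
            draws = pd.DataFrame(
                {"species": "a", "attribute": "BodyLength_mm", "tree_id": "t",
                 "fold": 0, "m": range(9), "value": perm}
            )
            res = tg.MultipleImputationResult(
                draws, tg.ImputationConfig(), {"BodyLength_mm": "regression"}
            )
            assert res.summarize()["point"].iloc[0] == np.median(vals)


def test_fold_splits_cover_observed_rows():
    obs = np.arange(20)
    splits = _fold_splits(obs, 4, seed=0)
    assert len(splits) == 4
    for train in splits:
        assert len(train) == 15
    assert _fold_splits(obs, 1, seed=0) == [obs]


def test_filters_add_information_on_phylogenetic_signal():
    """Average NRMSE with phylogenetic filters <= without them, over 20
    replicate Brownian-motion simulations (length plus one weak binary
    predictor only, so relatedness is the main signal)."""
    cfg = tg.ImputationConfig(k_donors=3, m_imputations=2, n_folds=2, seed=0)
    with_f, without_f = [], []
    for rep in range(20):
        tree = tg.simulate_tree(60, seed=300 + rep)
        cont = tg.simulate_continuous_traits(tree, seed=rep)
        binary = tg.simulate_binary_traits(tree, ["Noc", "Diu"], seed=rep)
        data = pd.DataFrame(
            {"BodyLength_mm": 10.0 ** cont["log10_length"],
             "Diu": binary["Diu"], "Noc": binary["Noc"]}
        )
        table = tg.TraitTable.from_complete(data)
        spec = tg.MissingnessSpec(
            {"body_length": tg.AttributeMissingness("MCAR", 0.25)}
        )
        masked, mask = tg.impose_missingness(table, spec, seed=rep)
        truth = np.log10(table.data.loc[mask["body_length"], "BodyLength_mm"])
        if len(truth) < 3:
            continue
        fs = tg.derive_filters(tg.tree_to_covariance(tree), tree_id="t")
        flat = tg.FilterSet(
            eigenvalues=np.array([1.0]),
            vectors=pd.DataFrame(
                {"PF1": np.full(60, 1.0 / np.sqrt(60))}, index=table.data.index
            ),
            retained=1,
            tree_id="flat",
        )
        for fset, bucket in ((fs, with_f), (flat, without_f)):
            res = tg.multiply_impute(masked, fset, cfg)
            pts = res.summarize().set_index("species")["point"]
            imp = np.log10(pts.reindex(truth.index))
            bucket.append(tg.nrmse(imp, truth))
    assert np.mean(with_f) <= np.mean(without_f)
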