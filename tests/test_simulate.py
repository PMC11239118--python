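"""Generator behaviour: tree shape, taxonomy nesting, trait models,
ranges, and the three missingness mechanisms."""

import numpy as np
import pandas as pd
import pytest

import traitgaps as tg
from traitgaps.simulate import tip_labels


class TestSimulateTree:
    def test_two_tips_is_a_cherry_with_equal_depths(self):
        tree = tg.simulate_tree(2, seed=1)
        depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
        assert len(depths) == 2
        assert depths[0] == pytest.approx(depths[1], abs=1e-12)

    def test_deterministic_newick_under_fixed_seed(self):
        a = tg.simulate_tree(16, seed=42).as_string(schema="newick")
        b = tg.simulate_tree(16, seed=42).as_string(schema="newick")
        assert a == b

    def test_bifurcating_node_count_and_ultrametricity(self):
        tree = tg.simulate_tree(16, seed=7)
        assert len(tree.leaf_nodes()) == 16
        assert sum(1 for _ in tree.preorder_internal_node_iter()) == 15
        depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
        assert max(depths) - min(depths) < 1e-9
        assert max(depths) == pytest.approx(1.0)

    def test_birth_death_prunes_to_requested_tips(self):
        tree = tg.simulate_tree(20, model="birth-death", seed=3, death_rate=0.4)
        assert len(tree.leaf_nodes()) == 20
        depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
        assert max(depths) - min(depths) < 1e-9

    def test_too_few_tips_rejected(self):
        with pytest.raises(ValueError):
            tg.simulate_tree(1)


class TestAssignTaxonomy:
    def test_degenerate_single_group(self):
        tree = tg.simulate_tree(10, seed=2)
        tax = tg.assign_taxonomy(tree, 1, 1)
        assert tax["Genus"].nunique() == 1
        assert tax["Family"].nunique() == 1

    def test_each_tip_its_own_genus(self):
        tree = tg.simulate_tree(10, seed=2)
        tax = tg.assign_taxonomy(tree, 2, 10)
        assert tax["Genus"].nunique() == 10

    def test_genus_nests_within_family(self):
        tree = tg.simulate_tree(40, seed=9)
        tax = tg.assign_taxonomy(tree, 4, 11)
        assert tax["Genus"].nunique() == 11
        assert tax["Family"].nunique() == 4
        assert (tax.groupby("Genus")["Family"].nunique() == 1).all()

    def test_groups_are_monophyletic(self):
        tree = tg.simulate_tree(30, seed=4)
        tax = tg.assign_taxonomy(tree, 3, 7)
        # a monophyletic group's tips form the full leaf set of their MRCA
        labels = {leaf.taxon.label: leaf for leaf in tree.leaf_node_iter()}
        for _, members in tax.groupby("Genus").groups.items():
            nodes = [labels[sp] for sp in members]
            mrca = tree.mrca(taxa=[n.taxon for n in nodes])
            assert {l.taxon.label for l in mrca.leaf_iter()} == set(members)

    def test_infeasible_counts_named(self):
        tree = tg.simulate_tree(5, seed=2)
        with pytest.raises(ValueError, match="5"):
            tg.assign_taxonomy(tree, 1, 6)


class TestContinuousTraits:
    def test_noise_free_allometry_exact(self):
        tree = tg.simulate_tree(20, seed=5)
        traits = tg.simulate_continuous_traits(tree, allometry=(-4.0, 3.0, 0.0), seed=1)
        np.testing.assert_allclose(
            traits["log10_mass"], 3.0 * traits["log10_length"] - 4.0
        )

    def test_vanishing_variance_collapses_to_root_state(self):
        tree = tg.simulate_tree(12, seed=5)
        traits = tg.simulate_continuous_traits(tree, sigma_bm=1e-9, seed=1)
        np.testing.assert_allclose(traits["log10_length"], 1.5, atol=1e-6)

    def test_brownian_covariance_structure(self):
        """Sibling tips on short branches differ less, on average, than
        distant tips — Monte-Carlo over 200 replicate simulations."""
        tree = tg.simulate_tree(24, seed=6)
        cov = tg.tree_to_covariance(tree)
        labels = list(cov.index)
        shared = cov.to_numpy().copy()
        np.fill_diagonal(shared, -np.inf)
        i, j = np.unravel_index(np.argmax(shared), shared.shape)
        close = (labels[i], labels[j])  # deepest MRCA: most covariance
        k = int(np.argmin(cov.loc[close[0]].to_numpy()))
        far = (close[0], labels[k])
        d_close, d_far = [], []
        for rep in range(200):
            t = tg.simulate_continuous_traits(tree, seed=rep)["log10_length"]
            d_close.append((t[close[0]] - t[close[1]]) ** 2)
            d_far.append((t[far[0]] - t[far[1]]) ** 2)
        assert np.mean(d_close) < np.mean(d_far)


class TestBinaryTraits:
    def test_extreme_thresholds(self):
        tree = tg.simulate_tree(15, seed=3)
        fixed = tg.simulate_binary_traits(
            tree, ["Noc"], thresholds={"Noc": -np.inf}, seed=1, repair=False
        )
        assert (fixed["Noc"] == 1).all()
        empty = tg.simulate_binary_traits(
            tree, ["Noc"], thresholds={"Noc": np.inf}, seed=1, repair=False
        )
        assert (empty["Noc"] == 0).all()

    def test_prevalence_tracks_liability_tail(self):
        """Attribute prevalence across replicate tips approximates the
        normal tail probability at the root-level variance (depth 1)."""
        from scipy.stats import norm

        thr = 0.6
        hits, total = 0, 0
        for rep in range(25):
            tree = tg.simulate_tree(20, seed=100 + rep)
            b = tg.simulate_binary_traits(
                tree, ["Arb"], liability_sigma=1.0,
                thresholds={"Arb": thr}, seed=rep, repair=False,
            )
            hits += int(b["Arb"].sum())
            total += len(b)
        expected = norm.sf(thr)
        assert abs(hits / total - expected) < 4 * np.sqrt(expected * (1 - expected) / 25)

    def test_repair_guarantees_one_category(self):
        tree = tg.simulate_tree(40, seed=8)
        cols = ["Fos", "Ter", "Aqu", "Arb", "Aer", "Diu", "Noc"]
        b = tg.simulate_binary_traits(
            tree, cols, thresholds={c: 3.0 for c in cols}, seed=2
        )
        assert (b[["Fos", "Ter", "Aqu", "Arb", "Aer"]].sum(axis=1) >= 1).all()
        assert (b[["Diu", "Noc"]].sum(axis=1) >= 1).all()


class TestRanges:
    def test_single_cell_holds_everyone(self):
        tree = tg.simulate_tree(8, seed=1)
        r = tg.simulate_ranges(tree, 1, np.arange(8.0), seed=0)
        assert (r.iloc[:, 0] == 1).all()

    def test_constant_covariate_equal_widths(self):
        tree = tg.simulate_tree(8, seed=1)
        r = tg.simulate_ranges(tree, 10, np.ones(8), seed=0)
        assert r.sum(axis=1).nunique() == 1

    def test_range_size_tracks_covariate_rank(self):
        from scipy.stats import spearmanr

        rhos = []
        for rep in range(50):
            tree = tg.simulate_tree(30, seed=200 + rep)
            cov = np.random.default_rng(rep).normal(size=30)
            r = tg.simulate_ranges(tree, 40, cov, seed=rep)
            rhos.append(spearmanr(cov, r.sum(axis=1)).statistic)
        assert np.mean(rhos) >= 0.9


class TestImposeMissingness:
    def _spec(self, **kw):
        return tg.MissingnessSpec(
            {"body_length": tg.AttributeMissingness(**kw)}, shared_gap_strength=0.0
        )

    def test_zero_rate_hides_nothing(self, small_clade):
        masked, mask = tg.impose_missingness(
            small_clade.traits_true, self._spec(mechanism="MCAR", rate=0.0), seed=1
        )
        assert mask.values.sum() == 0
        assert not masked.data["BodyLength_mm"].isna().any()

    def test_unit_rate_hides_everything(self, small_clade):
        masked, mask = tg.impose_missingness(
            small_clade.traits_true, self._spec(mechanism="MCAR", rate=1.0), seed=1
        )
        assert mask["body_length"].all()
        assert masked.data["BodyLength_mm"].isna().all()

    def test_mnar_negative_coefficient_targets_small_species(self, small_clade):
        """Below-median sizes go missing more often than above-median ones in
        at least 95 of 100 replicates."""
        spec = self._spec(mechanism="MNAR", rate=0.3, coefficient=-1.5)
        wins = 0
        sizes = small_clade.traits_true.data["BodyLength_mm"]
        small = sizes < sizes.median()
        for rep in range(100):
            _, mask = tg.impose_missingness(small_clade.traits_true, spec, seed=rep)
            if mask.loc[small, "body_length"].mean() > mask.loc[~small, "body_length"].mean():
                wins += 1
        assert wins >= 95

    def test_mcar_mask_independent_of_value(self):
        """Point-biserial correlation between MCAR mask and true value stays
        near zero on average."""
        clade = tg.build_clade(n_tips=150, n_genera=10, n_families=3, seed=21)
        spec = self._spec(mechanism="MCAR", rate=0.3)
        rs = []
        x = np.log10(clade.traits_true.data["BodyLength_mm"].to_numpy())
        for rep in range(100):
            _, mask = tg.impose_missingness(clade.traits_true, spec, seed=rep)
            m = mask["body_length"].to_numpy().astype(float)
            if m.std() > 0:
                rs.append(np.corrcoef(m, x)[0, 1])
        assert abs(np.mean(rs)) < 0.05

    def test_shared_factor_increases_multi_attribute_gaps(self, small_clade):
        """shared_gap_strength > 0 raises the expected count of species
        missing two or more attributes at equal marginal base rates."""
        blocks = {
            b: tg.AttributeMissingness("MCAR", 0.3) for b in ("body_length", "body_mass", "activity")
        }
        counts = {0.0: [], 0.9: []}
        for strength in counts:
            spec = tg.MissingnessSpec(dict(blocks), shared_gap_strength=strength)
            for rep in range(100):
                _, mask = tg.impose_missingness(small_clade.traits_true, spec, seed=rep)
                counts[strength].append(int((mask.sum(axis=1) >= 2).sum()))
        assert np.mean(counts[0.9]) > np.mean(counts[0.0])

    def test_mar_driver_must_be_observed(self, small_clade):
        spec = tg.MissingnessSpec(
            {
                "body_length": tg.AttributeMissingness("MAR", 0.3, driver="BodyMass_g"),
                "body_mass": tg.AttributeMissingness("MCAR", 0.3),
            }
        )
        with pytest.raises(ValueError, match="invalid configuration"):
            tg.impose_missingness(small_clade.traits_true, spec, seed=1)

    def test_reproducible_given_seed(self, small_clade):
        spec = self._spec(mechanism="MNAR", rate=0.4, coefficient=-1.0)
        a, ma = tg.impose_missingness(small_clade.traits_true, spec, seed=5)
        b, mb = tg.impose_missingness(small_clade.traits_true, spec, seed=5)
        pd.testing.assert_frame_equal(a.data, b.data)
        pd.testing.assert_frame_equal(ma, mb)


def test_missingness_spec_json_round_trip(tmp_path):
    spec = tg.MissingnessSpec(
        {
            "body_length": tg.AttributeMissingness("MNAR", 0.3, -1.0),
            "activity": tg.AttributeMissingness("MCAR", 0.2),
        },
        shared_gap_strength=0.4,
    )
    path = tmp_path / "spec.json"
    spec.to_json(path)
    assert tg.MissingnessSpec.from_json(path) == spec


def test_clade_invariants(small_clade):
    small_clade.validate()
    tips = tip_labels(small_clade.tree)
    assert len(tips) == len(small_clade.traits_true.data)
    assert (small_clade.assemblages.sum(axis=1) >= 1).all()
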