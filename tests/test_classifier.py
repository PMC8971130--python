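import numpy as np
import pandas as pd
import pytest

from cfrna import classifier as clf
from cfrna import degs, io, metrics, normalize, pipeline, simulate
from cfrna.io import OUTCOME_PE


@pytest.fixture(scope="module")
def classifier_cohort():
    """Two-cohort design sized like a discovery/validation split."""
    design = simulate.SimulationDesign(
        cohorts={"discovery": (61, 24), "validation": (35, 8)},
        n_genes=800,
        frac_deg=0.05,
        seed=17,
    )
    cm, meta, truth = simulate.simulate_cohort(design)
    kept = normalize.filter_genes(
        cm, meta.loc[meta["cohort"] == "discovery", "sample_id"]
    )
    cm = cm.subset(genes=kept)
    cm = normalize.logcpm(cm, normalize.tmm_factors(cm))
    return cm, meta, truth


@pytest.fixture(scope="module")
def fitted(classifier_cohort):
    cm, meta, truth = classifier_cohort
    cohorts = meta.set_index("sample_id")["cohort"]
    disc = meta[meta["cohort"] == "discovery"]
    early = pipeline._early_first_samples(disc, 16.0)
    em = disc.set_index("sample_id").loc[early]
    pe = early[(em["outcome"] == OUTCOME_PE).to_numpy()]
    nt = early[(em["outcome"] != OUTCOME_PE).to_numpy()]
    deg = degs.rank_test_degs(cm.logcpm, pe, nt)
    scheme = clf.fit_normalization(
        cm.logcpm, cohorts, "discovery", deg["bh_adjusted_p"]
    )
    normalized = clf.apply_normalization(scheme, cm.logcpm, cohorts)
    y = meta.set_index("sample_id")["outcome"].eq(OUTCOME_PE)
    parts = meta.set_index("sample_id")["participant_id"]
    candidates = deg.index[deg["significant"]].tolist()
    model = clf.train(
        normalized[early].T, y.loc[early], parts.loc[early], candidates, seed=17
    )
    clf.tune_threshold(model, normalized[early].T, y.loc[early])
    return cm, meta, truth, deg, scheme, normalized, model, y


class TestNormalizationScheme:
    def test_cohort_median_centering(self):
        lc = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        cohorts = pd.Series(["d"] * 3, index=list("abc"))
        adj_p = pd.Series({"g": 1.0})
        scheme = clf.fit_normalization(lc, cohorts, "d", adj_p)
        assert scheme.center.loc["g", "d"] == 2.0

    def test_scaling_uses_discovery_iqr_only(self, rng):
        disc = rng.normal(0, 1, size=10)
        val = rng.normal(0, 5, size=10)
        lc = pd.DataFrame([np.concatenate([disc, val])], index=["g"],
                          columns=[f"s{i}" for i in range(20)])
        lc.loc["null"] = rng.normal(size=20)
        cohorts = pd.Series(["d"] * 10 + ["v"] * 10, index=lc.columns)
        adj_p = pd.Series({"g": 1.0, "null": 1.0})
        scheme = clf.fit_normalization(lc, cohorts, "d", adj_p)
        q = np.quantile(disc, [0.25, 0.75])
        assert scheme.scale["g"] == pytest.approx(q[1] - q[0], rel=1e-6)

    def test_control_set_is_nearly_pure_null(self, fitted):
        """Genes at adjusted p > 0.99 should essentially all be non-planted."""
        cm, meta, truth, deg, scheme, *_ = fitted
        planted = set(truth.deg_trends)
        controls = set(scheme.control_genes)
        assert len(controls) > 0
        purity = len(controls - planted) / len(controls)
        assert purity >= 0.9

    def test_no_controls_is_an_error(self):
        lc = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=list("abc"))
        cohorts = pd.Series(["d"] * 3, index=list("abc"))
        with pytest.raises(io.ValidationError, match="control"):
            clf.fit_normalization(lc, cohorts, "d", pd.Series({"g": 0.5}))

    def test_zero_iqr_gene_dropped(self):
        lc = pd.DataFrame(
            [[1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0]],
            index=["g", "flat"], columns=list("abcd"),
        )
        cohorts = pd.Series(["d"] * 4, index=list("abcd"))
        scheme = clf.fit_normalization(lc, cohorts, "d", pd.Series({"g": 1.0}))
        assert "flat" not in scheme.scale.index


class TestApplyNormalization:
    def _scheme(self, lc, cohorts, controls):
        return clf.NormalizationScheme(
            center=pd.DataFrame(0.0, index=lc.index, columns=pd.unique(cohorts)),
            scale=pd.Series(1.0, index=lc.index),
            control_genes=controls,
        )

    def test_control_median_subtracted(self):
        lc = pd.DataFrame(
            {"s1": [0.2, 0.4, 0.6, 5.0]},
            index=["c1", "c2", "c3", "g"],
        )
        cohorts = pd.Series({"s1": "d"})
        out = clf.apply_normalization(
            self._scheme(lc, cohorts, ["c1", "c2", "c3"]), lc, cohorts
        )
        assert out.loc["g", "s1"] == pytest.approx(5.0 - 0.4)

    def test_zero_logcpm_control_excluded_from_median(self):
        lc = pd.DataFrame(
            {"s1": [0.0, 0.4, 0.6, 5.0]},
            index=["c1", "c2", "c3", "g"],
        )
        cohorts = pd.Series({"s1": "d"})
        out = clf.apply_normalization(
            self._scheme(lc, cohorts, ["c1", "c2", "c3"]), lc, cohorts
        )
        # c1 is dropped (raw 0); median of (0.4, 0.6) = 0.5
        assert out.loc["g", "s1"] == pytest.approx(5.0 - 0.5)

    def test_all_zero_controls_leave_sample_unshifted(self):
        lc = pd.DataFrame({"s1": [0.0, 0.0, 5.0]}, index=["c1", "c2", "g"])
        cohorts = pd.Series({"s1": "d"})
        out = clf.apply_normalization(
            self._scheme(lc, cohorts, ["c1", "c2"]), lc, cohorts
        )
        assert out.loc["g", "s1"] == 5.0

    def test_constant_sample_shift_removed_exactly(self, rng):
        genes = [f"g{i}" for i in range(10)]
        base = pd.DataFrame(
            rng.normal(2, 1, size=(10, 2)) + 1.0, index=genes, columns=["s1", "s2"]
        )
        shifted = base.copy()
        shifted["s2"] = base["s1"] + 0.7  # s2 = s1 plus a global shift
        cohorts = pd.Series({"s1": "d", "s2": "d"})
        scheme = self._scheme(shifted, cohorts, genes[:5])
        out = clf.apply_normalization(scheme, shifted, cohorts)
        assert np.allclose(out["s1"], out["s2"])


class TestPreselection:
    def _records(self):
        return pd.DataFrame(
            {
                "log2fc": [1.2, -0.9, 0.3, 0.0, 2.0],
                "cv": [0.2, 0.4, 0.1, np.nan, 1.5],
            },
            index=[f"g{i}" for i in range(5)],
        )

    def test_identity_cuts_keep_everything_defined(self):
        out = clf.preselect_features(self._records(), fc_cut=0.0, cv_cut=np.inf)
        assert list(out) == ["g0", "g1", "g2", "g4"]  # g3 has undefined CV

    def test_zero_fold_change_never_selected(self):
        out = clf.preselect_features(self._records(), fc_cut=0.0, cv_cut=np.inf)
        assert "g3" not in out

    def test_cuts_applied_jointly(self):
        out = clf.preselect_features(self._records(), fc_cut=0.5, cv_cut=1.0)
        assert list(out) == ["g0", "g1"]


class TestTraining:
    def test_linearly_separable_training_auroc_one(self, rng):
        n = 60
        y = pd.Series([False] * 30 + [True] * 30,
                      index=[f"s{i}" for i in range(n)])
        x = pd.DataFrame(
            {"g1": np.where(y, 2.0, -2.0) + rng.normal(0, 0.1, n),
             "g2": rng.normal(size=n)},
            index=y.index,
        )
        parts = pd.Series([f"p{i}" for i in range(n)], index=y.index)
        model = clf.train(x, y, parts, ["g1", "g2"], seed=0,
                          c_grid=(1.0,), l1_ratio_grid=(0.5,), n_boot=100)
        from sklearn.metrics import roc_auc_score
        assert roc_auc_score(y, model.predict_proba(x)) == 1.0

    def test_shuffled_labels_give_chance_performance(self, rng):
        n = 80
        x = pd.DataFrame(
            rng.normal(size=(n, 5)), columns=[f"g{i}" for i in range(5)],
            index=[f"s{i}" for i in range(n)],
        )
        y = pd.Series(rng.permutation([True] * 30 + [False] * 50), index=x.index)
        parts = pd.Series([f"p{i}" for i in range(n)], index=x.index)
        model = clf.train(x, y, parts, list(x.columns), seed=1,
                          c_grid=(1.0,), l1_ratio_grid=(0.5,), n_boot=100)
        # held-out data from the same null process
        x_new = pd.DataFrame(
            rng.normal(size=(200, 5)), columns=x.columns,
            index=[f"t{i}" for i in range(200)],
        )
        y_new = pd.Series(rng.permutation([True] * 75 + [False] * 125),
                          index=x_new.index)
        auc = metrics.auroc(model.predict_proba(x_new), y_new).estimate
        assert 0.35 <= auc <= 0.65

    def test_seed_determinism_of_selection(self, fitted):
        cm, meta, truth, deg, scheme, normalized, model, y = fitted
        disc = meta[meta["cohort"] == "discovery"]
        early = pipeline._early_first_samples(disc, 16.0)
        parts = meta.set_index("sample_id")["participant_id"]
        again = clf.train(
            normalized[early].T, y.loc[early], parts.loc[early],
            deg.index[deg["significant"]].tolist(), seed=17,
        )
        assert again.hyperparameters == model.hyperparameters
        assert again.genes == model.genes
        assert np.allclose(again.estimator.coef_, model.estimator.coef_)

    def test_leakage_guard_validation_data_cannot_change_model(self, fitted):
        """Perturbing non-discovery samples must not alter the fitted model."""
        cm, meta, truth, deg, scheme, normalized, model, y = fitted
        cohorts = meta.set_index("sample_id")["cohort"]
        perturbed = cm.logcpm.copy()
        val_cols = cohorts.index[(cohorts == "validation").to_numpy()]
        perturbed[val_cols] = perturbed[val_cols] + 5.0
        # refit scheme and model from the perturbed matrix
        scheme2 = clf.fit_normalization(
            perturbed, cohorts, "discovery", deg["bh_adjusted_p"]
        )
        assert np.allclose(scheme2.scale, scheme.scale)
        normalized2 = clf.apply_normalization(scheme2, perturbed, cohorts)
        disc = meta[meta["cohort"] == "discovery"]
        early = pipeline._early_first_samples(disc, 16.0)
        parts = meta.set_index("sample_id")["participant_id"]
        model2 = clf.train(
            normalized2[early].T, y.loc[early], parts.loc[early],
            deg.index[deg["significant"]].tolist(), seed=17,
        )
        assert model2.genes == model.genes
        assert np.allclose(model2.estimator.coef_, model.estimator.coef_)


class TestThreshold:
    @pytest.mark.parametrize(
        "raw,expected", [(0.37, 0.35), (0.12, 0.10), (0.425, 0.45), (0.5, 0.5)]
    )
    def test_rounding_rule(self, raw, expected):
        assert clf.round_threshold(raw, grain=0.05) == expected

    def test_tuned_threshold_is_on_the_grain(self, fitted):
        *_, model, y = fitted
        assert model.threshold is not None
        assert model.threshold == pytest.approx(
            clf.round_threshold(model.threshold), abs=1e-12
        )

    def test_sample_at_threshold_called_positive(self, fitted):
        cm, meta, truth, deg, scheme, normalized, model, y = fitted
        x = normalized.T.iloc[:1]
        prob = model.predict_proba(x).iloc[0]
        saved = model.threshold
        try:
            model.threshold = float(prob)
            pred = clf.predict(model, x)
            assert bool(pred["predicted"].iloc[0])
        finally:
            model.threshold = saved


class TestPrediction:
    def test_out_of_window_samples_excluded(self, fitted):
        cm, meta, truth, deg, scheme, normalized, model, y = fitted
        val = meta[meta["cohort"] == "validation"]
        all_val = normalized[val["sample_id"]].T
        pred = clf.predict(model, all_val, meta)
        kept_meta = meta.set_index("sample_id").loc[pred["sample_id"]]
        assert (kept_meta["ga_collection"] <= 16.0).all()
        assert (~kept_meta["postpartum"]).all()
        assert len(pred) < len(val)

    def test_heldout_synthetic_auroc_high(self, fitted):
        cm, meta, truth, deg, scheme, normalized, model, y = fitted
        val = meta[meta["cohort"] == "validation"]
        val_early = pipeline._early_first_samples(val, 16.0)
        pred = clf.predict(model, normalized[val_early].T, meta)
        auc = metrics.auroc(
            pred["probability"], y.loc[pred["sample_id"]]
        ).estimate
        assert auc >= 0.9

    def test_participant_aggregation_is_maximum(self):
        pred = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c"],
                "probability": [0.2, 0.8, 0.5],
                "predicted": [False, True, True],
                "participant_id": ["p1", "p1", "p2"],
            }
        )
        agg = clf.aggregate_by_participant(pred).set_index("participant_id")
        assert agg.loc["p1", "probability"] == 0.8
        assert bool(agg.loc["p1", "predicted"])

    def test_constant_model_gives_chance_auroc(self, fitted):
        cm, meta, truth, deg, scheme, normalized, model, y = fitted
        zeroed = clf.ClassifierModel(
            genes=model.genes,
            estimator=model.estimator,
            hyperparameters=model.hyperparameters,
            threshold=0.5,
            seed=0,
        )
        zeroed.estimator = _zero_coef_clone(model)
        val = meta[meta["cohort"] == "validation"]
        val_early = pipeline._early_first_samples(val, 16.0)
        pred = clf.predict(zeroed, normalized[val_early].T, meta)
        auc = metrics.auroc(pred["probability"], y.loc[pred["sample_id"]]).estimate
        assert auc == pytest.approx(0.5)


def _zero_coef_clone(model):
    from copy import deepcopy

    est = deepcopy(model.estimator)
    est.coef_ = np.zeros_like(est.coef_)
    est.intercept_ = np.zeros_like(est.intercept_)
    return est


class TestSubsetSweep:
    def test_full_panel_and_monotone_trend(self, fitted):
        cm, meta, truth, deg, scheme, normalized, model, y = fitted
        disc = meta[meta["cohort"] == "discovery"]
        early = pipeline._early_first_samples(disc, 16.0)
        val = meta[meta["cohort"] == "validation"]
        val_early = pipeline._early_first_samples(val, 16.0)
        parts = meta.set_index("sample_id")["participant_id"]
        panel = model.genes[:6]
        sweep = clf.feature_subset_sweep(
            panel,
            normalized[early].T, y.loc[early], parts.loc[early],
            normalized[val_early].T, y.loc[val_early],
            n_per_size=2, sizes=[1, 3, 6], seed=0,
            c_grid=(1.0,), l1_ratio_grid=(0.5,),
        )
        assert (sweep["n_genes"] == 6).any()
        by_size = sweep.groupby("n_genes")["test_auroc"].mean()
        assert by_size.loc[6] >= by_size.loc[1] - 0.05
        assert sweep.loc[sweep["n_genes"] == 6, "weakly_predictive"].all()

    def test_deterministic_given_seed(self, fitted):
        cm, meta, truth, deg, scheme, normalized, model, y = fitted
        disc = meta[meta["cohort"] == "discovery"]
        early = pipeline._early_first_samples(disc, 16.0)
        parts = meta.set_index("sample_id")["participant_id"]
        kw = dict(
            n_per_size=2, sizes=[2], seed=4, c_grid=(1.0,), l1_ratio_grid=(0.5,)
        )
        a = clf.feature_subset_sweep(
            model.genes[:5], normalized[early].T, y.loc[early], parts.loc[early],
            normalized[early].T, y.loc[early], **kw,
        )
        b = clf.feature_subset_sweep(
            model.genes[:5], normalized[early].T, y.loc[early], parts.loc[early],
            normalized[early].T, y.loc[early], **kw,
        )
        pd.testing.assert_frame_equal(a, b)
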