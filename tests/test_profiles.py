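import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cfrna import io, profiles, simulate
from cfrna.io import WINDOW_POSTPARTUM


class TestGini:
    def test_uniform_vector_zero(self):
        assert profiles.gini_coefficient([3, 3, 3, 3]) == 0.0

    @pytest.mark.parametrize("t", range(2, 11))
    def test_one_hot_maximal(self, t):
        x = np.zeros(t)
        x[0] = 5.0
        assert profiles.gini_coefficient(x) == pytest.approx((t - 1) / t)

    def test_pairwise_enumeration_example(self):
        # sum of ordered |xi-xj| over [2,1,1,0] is 12; 12 / (2*4*4) = 0.375
        assert profiles.gini_coefficient([2, 1, 1, 0]) == pytest.approx(0.375)

    def test_matches_pairwise_definition_on_random_vectors(self, rng):
        for _ in range(20):
            x = rng.random(size=rng.integers(2, 12)) * 10
            expected = sum(
                abs(a - b) for a, b in itertools.product(x, repeat=2)
            ) / (2 * x.size * x.sum())
            assert profiles.gini_coefficient(x) == pytest.approx(expected)

    def test_all_zero_undefined(self):
        with pytest.raises(io.ValidationError):
            profiles.gini_coefficient([0.0, 0.0])

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(st.floats(min_value=0.01, max_value=1e3), min_size=2, max_size=20),
        st.floats(min_value=0.01, max_value=100.0),
    )
    def test_scale_invariance(self, x, c):
        x = np.asarray(x)
        assert profiles.gini_coefficient(c * x) == pytest.approx(
            profiles.gini_coefficient(x), abs=1e-9
        )


class TestTissueProfiles:
    def test_noiseless_atlas_recovered_exactly(self):
        atlas, truth = simulate.simulate_reference_atlas(
            n_categories=6, genes_per_category=8, background_noise=0.0, seed=1
        )
        prof = profiles.build_tissue_profiles(atlas, gini_cut=0.6)
        recovered = prof.groupby("category")["gene"].apply(set).to_dict()
        assert recovered == {c: set(g) for c, g in truth.items()}

    def test_gini_boundary_is_inclusive(self):
        # an even two-hot vector over 5 tissues has Gini exactly (5-2)/5 = 0.6;
        # spreading to a third tissue drops below the cut, sharpening the
        # max raises above it
        atlas = pd.DataFrame(
            {
                "t1": [10.0, 10.0, 12.0],
                "t2": [10.0, 10.0, 10.0],
                "t3": [1.0, 0.0, 0.0],
                "t4": [0.0, 0.0, 0.0],
                "t5": [0.0, 0.0, 0.0],
            },
            index=["below", "exact", "above"],
        )
        gini = profiles.gini_per_gene(atlas)
        assert gini["below"] < 0.6 == pytest.approx(gini["exact"])
        assert gini["above"] > 0.6
        prof = profiles.build_tissue_profiles(atlas, gini_cut=0.6)
        assert set(prof["gene"]) == {"exact", "above"}  # >= cut is inclusive

    def test_strict_mode_requires_annotation(self):
        atlas, _ = simulate.simulate_reference_atlas(n_categories=4, seed=0)
        with pytest.raises(io.ValidationError, match="annotation"):
            profiles.build_tissue_profiles(atlas, strict=True)
        ann = pd.Series("Tissue-enriched", index=atlas.index[:10])
        prof = profiles.build_tissue_profiles(atlas, strict=True, annotation=ann)
        assert set(prof["gene"]).issubset(set(atlas.index[:10]))
        assert prof["strict"].all()

    def test_group_enriched_gene_excluded_from_strict_only(self):
        # expressed equally in 2 of 10 categories: Gini passes 0.6 but the
        # strict reference drops it without the annotation
        x = np.zeros(10)
        x[:2] = 50.0
        assert profiles.gini_coefficient(x) >= 0.6
        atlas = pd.DataFrame([x], index=["shared"],
                             columns=[f"t{i}" for i in range(10)])
        atlas.loc["filler"] = np.linspace(1, 10, 10)
        nonstrict = profiles.build_tissue_profiles(atlas, gini_cut=0.6)
        assert "shared" in set(nonstrict["gene"])
        strict = profiles.build_tissue_profiles(
            atlas, gini_cut=0.6, strict=True,
            annotation=pd.Series(dtype=object),
        )
        assert "shared" not in set(strict["gene"])


class TestCelltypeProfiles:
    def test_celltype_cut_stricter_than_tissue(self):
        atlas, _ = simulate.simulate_reference_atlas(
            n_categories=5, genes_per_category=6, background_noise=0.25, seed=2
        )
        tis = profiles.build_tissue_profiles(atlas, gini_cut=0.6)
        cel = profiles.build_celltype_profiles(atlas, gini_cut=0.8)
        assert set(cel["gene"]).issubset(set(tis["gene"]))

    def test_subtypes_pooled_before_gini(self):
        atlas = pd.DataFrame(
            {
                "neutrophil-1": [10.0, 0.0],
                "neutrophil-2": [0.0, 0.0],
                "t-cell": [0.0, 8.0],
            },
            index=["gN", "gT"],
        )
        merged = profiles.build_celltype_profiles(
            atlas, gini_cut=0.4,
            subtype_map={"neutrophil-1": "neutrophil", "neutrophil-2": "neutrophil"},
        )
        row = merged.set_index("gene").loc["gN"]
        assert row["category"] == "neutrophil"
        # pooled mean is (10+0)/2 = 5 against 0: Gini of [5, 0] = 0.5
        assert row["gini"] == pytest.approx(0.5)


class TestMergeReferences:
    def _prof(self, entries, source=profiles.SOURCE_CELL):
        return pd.DataFrame(
            [
                {"gene": g, "category": c, "gini": 0.9, "source": source,
                 "strict": False}
                for g, c in entries
            ]
        )

    def test_disjoint_inputs_concatenate(self):
        a = self._prof([("g1", "x"), ("g2", "y")])
        b = self._prof([("g3", "z")])
        merged = profiles.merge_references(a, b)
        assert len(merged) == 3

    def test_conflict_resolved_to_individual_atlas(self):
        base = self._prof([("g1", "endothelial")])
        ind = self._prof([("g1", "syncytiotrophoblast")])
        merged = profiles.merge_references(base, ind)
        assert merged.set_index("gene").loc["g1", "category"] == "syncytiotrophoblast"
        assert merged.set_index("gene").loc["g1", "source"] == profiles.SOURCE_INDIVIDUAL

    def test_individual_genes_must_pass_tissue_specificity(self):
        base = self._prof([("g1", "x")])
        ind = self._prof([("g2", "y"), ("g3", "z")])
        gini = pd.Series({"g2": 0.7, "g3": 0.4})
        merged = profiles.merge_references(base, ind, tissue_gini=gini)
        assert set(merged["gene"]) == {"g1", "g2"}

    def test_size_equals_union_count(self, rng):
        genes_a = [f"g{i}" for i in range(20)]
        genes_b = [f"g{i}" for i in range(10, 25)]
        a = self._prof([(g, "x") for g in genes_a])
        b = self._prof([(g, "y") for g in genes_b])
        merged = profiles.merge_references(a, b)
        assert len(merged) == len(set(genes_a) | set(genes_b))


class TestEnrichment:
    def test_exact_small_example(self):
        # M=10, n=5, N=4, k=4 -> C(5,4)/C(10,4) = 5/210
        prof = pd.DataFrame(
            {
                "gene": [f"g{i}" for i in range(10)],
                "category": ["a"] * 5 + ["b"] * 5,
                "gini": 0.9, "source": "cell-atlas", "strict": False,
            }
        )
        universe = [f"g{i}" for i in range(10)]
        degs = ["g0", "g1", "g2", "g3"]  # all in category a
        out = profiles.enrichment_test(degs, prof, universe)
        row = out.set_index("category").loc["a"]
        assert (row["M"], row["n"], row["N"], row["k"]) == (10, 5, 4, 4)
        assert row["p_value"] == pytest.approx(5 / 210)

    def test_matches_brute_force_enumeration_small_universes(self, rng):
        from itertools import combinations

        from scipy.stats import hypergeom

        for M, n, N in [(8, 3, 4), (10, 5, 4), (12, 6, 5), (9, 4, 3)]:
            pop = list(range(M))
            for k in range(2, min(n, N) + 1):
                p = float(hypergeom.sf(k - 1, M, n, N))
                total = hits = 0
                for draw in combinations(pop, N):
                    total += 1
                    if sum(1 for d in draw if d < n) >= k:
                        hits += 1
                assert p == pytest.approx(hits / total, abs=1e-12)

    def test_certain_event_p_one(self):
        from scipy.stats import hypergeom
        assert hypergeom.sf(4 - 1, 4, 4, 4) == pytest.approx(1.0)

    def test_categories_below_min_k_skipped(self):
        prof = pd.DataFrame(
            {
                "gene": ["g0", "g1", "g2", "g3"],
                "category": ["a", "a", "b", "b"],
                "gini": 0.9, "source": "cell-atlas", "strict": False,
            }
        )
        out = profiles.enrichment_test(["g0", "g2"], prof, [f"g{i}" for i in range(4)])
        assert len(out) == 0  # each category has only one differential gene


class TestSignatureScores:
    def test_score_is_sum_of_logcpm(self, small_cohort):
        cm, meta, truth = small_cohort
        atlas, _ = simulate.simulate_reference_atlas(
            planted=truth.category_profiles, background_noise=0.0, seed=0
        )
        prof = profiles.build_tissue_profiles(atlas, gini_cut=0.6)
        scores = profiles.signature_scores(cm.logcpm, prof, meta)
        row = scores.iloc[0]
        genes = prof.loc[prof["category"] == row["category"], "gene"]
        genes = [g for g in genes if g in cm.logcpm.index]
        assert row["score"] == pytest.approx(
            cm.logcpm.loc[genes, row["sample_id"]].sum()
        )

    def test_postpartum_relative_score_exactly_zero(self, small_cohort):
        cm, meta, truth = small_cohort
        atlas, _ = simulate.simulate_reference_atlas(
            planted=truth.category_profiles, background_noise=0.0, seed=0
        )
        prof = profiles.build_tissue_profiles(atlas)
        scores = profiles.signature_scores(cm.logcpm, prof, meta)
        pp = scores[scores["window"] == WINDOW_POSTPARTUM]
        assert len(pp) > 0
        assert (pp["relative_score"] == 0.0).all()
        assert (pp["scaled_score"] == 0.0).all()

    def test_small_profile_skipped(self, small_cohort):
        cm, meta, _ = small_cohort
        prof = pd.DataFrame(
            {
                "gene": cm.genes[:4],
                "category": "tiny",
                "gini": 0.9, "source": "cell-atlas", "strict": False,
            }
        )
        with pytest.raises(io.ValidationError):
            profiles.signature_scores(cm.logcpm, prof, meta)

    def test_planted_category_elevated_in_cases_early(self, small_cohort):
        cm, meta, truth = small_cohort
        atlas, _ = simulate.simulate_reference_atlas(
            planted=truth.category_profiles, background_noise=0.0, seed=0
        )
        prof = profiles.build_tissue_profiles(atlas)
        scores = profiles.signature_scores(cm.logcpm, prof, meta)
        cat = scores[scores["category"] == "cat01"]
        early = cat[cat["window"] == io.WINDOW_EARLY]
        pe = early.loc[early["outcome"] == io.OUTCOME_PE, "scaled_score"]
        nt = early.loc[early["outcome"] == io.OUTCOME_NT, "scaled_score"]
        assert pe.median() > nt.median()

    def test_null_category_trajectory_covers_zero(self, small_cohort):
        cm, meta, truth = small_cohort
        atlas, _ = simulate.simulate_reference_atlas(
            planted=truth.category_profiles, background_noise=0.0, seed=0
        )
        prof = profiles.build_tissue_profiles(atlas)
        scores = profiles.signature_scores(cm.logcpm, prof, meta)
        traj = profiles.signature_trajectories(scores, n_boot=300, seed=0)
        null = traj[(traj["category"] == "cat03")]
        inside = (null["ci_low"] <= 0.35) & (null["ci_high"] >= -0.35)
        assert inside.mean() >= 0.9


class TestAtlasIO:
    def test_round_trip(self, tmp_path):
        atlas, _ = simulate.simulate_reference_atlas(
            n_categories=3, genes_per_category=4, seed=0
        )
        path = tmp_path / "atlas.tsv"
        profiles.write_atlas(atlas, path)
        back = profiles.read_atlas(path)
        pd.testing.assert_frame_equal(
            back.sort_index(), atlas.sort_index(), check_names=False
        )
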