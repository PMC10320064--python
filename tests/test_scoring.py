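import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, strategies as st
from sklearn.base import clone
from statsmodels.stats.multitest import multipletests

from proact import (
    DEMatrix,
    ProcessActivityScorer,
    ProcessCatalog,
    ProcessTerm,
    ScoreTable,
    TrimConfig,
    bh_adjust,
    compute_scores,
    score_significance,
    trimmed_mean,
)
from proact.scoring import _trimmed_mean_rows
from proact.synth import PlantSpec, make_catalog, make_de_matrix

from conftest import brute_force_bh, brute_force_trimmed_mean


class TestTrimmedMean:
    @pytest.mark.parametrize("mode,n_used", [("extreme", 2), ("tails", 3), ("none", 3)])
    def test_constant_input_returns_constant(self, mode, n_used):
        mean, n = trimmed_mean([5.0, 5.0, 5.0], TrimConfig(0.10, mode))
        assert mean == 5.0 and n == n_used

    def test_single_outlier_dropped_by_extreme_mode(self):
        # n=3, ceil(0.1*3)=1 dropped: the 10 (deviation 10 from median 0)
        mean, n = trimmed_mean([0.0, 0.0, 10.0], TrimConfig(0.10, "extreme"))
        assert mean == 0.0 and n == 2

    def test_extreme_drops_either_direction(self):
        mean, n = trimmed_mean([0.0, 0.1, -0.1, -10.0], TrimConfig(0.10, "extreme"))
        assert n == 3 and mean == pytest.approx(0.0)

    def test_tie_broken_by_larger_absolute_value(self):
        # median 0; -4 and 4 tie on deviation, the larger |v|... equal; falls
        # back to input order: the later 4 survives only if -4 is listed first
        mean, n = trimmed_mean([-4.0, 0.0, 4.0], TrimConfig(0.10, "extreme"))
        assert n == 2 and mean == pytest.approx(2.0)  # -4 (input-first) dropped

    def test_fraction_zero_and_none_mode_reduce_to_mean(self):
        v = [1.0, 2.0, 7.0]
        assert trimmed_mean(v, TrimConfig(0.0, "extreme")) == (np.mean(v), 3)
        assert trimmed_mean(v, TrimConfig(0.3, "none")) == (np.mean(v), 3)

    def test_trimming_everything_falls_back_to_plain_mean(self):
        mean, n = trimmed_mean([3.0], TrimConfig(0.5, "extreme"))
        assert mean == 3.0 and n == 1

    def test_empty_or_nonfinite_input_errors(self):
        with pytest.raises(ValueError):
            trimmed_mean([])
        with pytest.raises(ValueError):
            trimmed_mean([1.0, np.nan])

    @pytest.mark.parametrize("mode", ["extreme", "tails"])
    def test_matches_brute_force_oracle_on_random_vectors(self, mode):
        rng = np.random.default_rng(17)
        for _ in range(300):
            n = int(rng.integers(3, 101))
            v = rng.normal(0, 1, size=n)
            got = trimmed_mean(v, TrimConfig(0.10, mode))
            assert got == brute_force_trimmed_mean(v, 0.10, mode)

    @pytest.mark.parametrize("mode", ["extreme", "tails", "none"])
    def test_rowwise_variant_agrees_with_scalar(self, mode):
        rng = np.random.default_rng(23)
        V = rng.normal(size=(40, 17))
        rows = _trimmed_mean_rows(V, TrimConfig(0.10, mode))
        for i in range(V.shape[0]):
            assert rows[i] == trimmed_mean(V[i], TrimConfig(0.10, mode))[0]

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=60))
    def test_translation_equivariance(self, values):
        # Holds whenever no two values tie on deviation from the median (the
        # |v| tie-break is deliberately sign-aware, hence not shift-invariant).
        dev = np.sort(np.abs(np.asarray(values) - np.median(values)))
        assume(len(values) < 2 or np.diff(dev).min() > 1e-6)
        delta = 1.7
        base, n0 = trimmed_mean(values, TrimConfig())
        shifted, n1 = trimmed_mean([v + delta for v in values], TrimConfig())
        assert n0 == n1
        assert shifted == pytest.approx(base + delta, abs=1e-9)


def double_loop_scores(dem, catalog, cfg, min_genes=3):
    """Independent oracle: explicit loop over (term, context) with the
    brute-force trimmed mean."""
    out = {}
    for term in catalog:
        for ctx in dem.contexts:
            vals = [
                dem.data.loc[g, ctx]
                for g in sorted(term.genes)
                if g in dem.data.index and np.isfinite(dem.data.loc[g, ctx])
            ]
            if len(vals) >= min_genes:
                out[(term.process_id, ctx)] = brute_force_trimmed_mean(
                    vals, cfg.fraction, cfg.mode
                )
            else:
                out[(term.process_id, ctx)] = (np.nan, 0)
    return out


class TestComputeScores:
    def test_constant_term_scores_the_constant(self):
        df = pd.DataFrame({"C1": [2.0, 2.0, 2.0], "C2": [0.0, 0.0, 0.0]},
                          index=["G1", "G2", "G3"])
        cat = ProcessCatalog([ProcessTerm("T", "t", frozenset({"G1", "G2", "G3"}))])
        table = compute_scores(DEMatrix(df), cat)
        rec = table.records.set_index("context")
        assert rec.loc["C1", "score"] == 2.0
        assert rec.loc["C2", "score"] == 0.0

    def test_matches_double_loop_oracle_on_synthetic_fixture(self):
        spec = PlantSpec(n_genes=20, n_contexts=3, n_terms=4,
                         term_size_range=(3, 8), seed=9)
        cat = make_catalog(spec)
        dem = make_de_matrix(spec, cat)
        cfg = TrimConfig()
        table = compute_scores(dem, cat, cfg)
        oracle = double_loop_scores(dem, cat, cfg)
        assert len(table.records) == 12
        for _, r in table.records.iterrows():
            exp_score, exp_used = oracle[(r["process_id"], r["context"])]
            assert r["score"] == pytest.approx(exp_score, rel=1e-12)
            assert r["n_genes_used"] == exp_used

    def test_missing_value_reduces_observed_count(self):
        df = pd.DataFrame({"C1": [1.0, np.nan, 2.0, 1.5], "C2": [0.0, 1.0, 0.0, 0.5]},
                          index=["G1", "G2", "G3", "G4"])
        cat = ProcessCatalog([ProcessTerm("T", "t", frozenset({"G1", "G2", "G3", "G4"}))])
        rec = compute_scores(DEMatrix(df), cat).records.set_index("context")
        assert rec.loc["C1", "n_genes_observed"] == 3
        assert rec.loc["C1", "n_genes_annotated"] == 4
        assert rec.loc["C2", "n_genes_observed"] == 4

    def test_below_min_genes_flagged_unavailable_not_dropped(self):
        df = pd.DataFrame({"C1": [1.0, np.nan, np.nan], "C2": [0.0, 1.0, 2.0]},
                          index=["G1", "G2", "G3"])
        cat = ProcessCatalog([ProcessTerm("T", "t", frozenset({"G1", "G2", "G3"}))])
        rec = compute_scores(DEMatrix(df), cat).records.set_index("context")
        assert np.isnan(rec.loc["C1", "score"])
        assert rec.loc["C1", "n_genes_observed"] == 1
        assert not np.isnan(rec.loc["C2", "score"])

    def test_no_catalog_gene_in_matrix_errors(self, small_dem):
        cat = ProcessCatalog([ProcessTerm("T", "t", frozenset({"X1", "X2", "X3"}))])
        with pytest.raises(ValueError, match="no catalog gene"):
            compute_scores(small_dem, cat)

    def test_translation_equivariance_of_one_context(self, small_catalog, small_dem):
        delta = 1.7
        base = compute_scores(small_dem, small_catalog).records
        shifted_df = small_dem.data.copy()
        shifted_df["liver"] += delta
        shifted = compute_scores(DEMatrix(shifted_df), small_catalog).records
        merged = base.merge(shifted, on=["process_id", "context"], suffixes=("_b", "_s"))
        merged = merged.dropna(subset=["score_b", "score_s"])
        liver = merged[merged["context"] == "liver"]
        other = merged[merged["context"] != "liver"]
        assert np.allclose(liver["score_s"], liver["score_b"] + delta)
        assert np.allclose(other["score_s"], other["score_b"])

    def test_invariant_to_row_and_column_order(self, small_catalog, small_dem):
        base = compute_scores(small_dem, small_catalog).records
        rng = np.random.default_rng(2)
        perm = small_dem.data.iloc[
            rng.permutation(small_dem.shape[0]), rng.permutation(small_dem.shape[1])
        ]
        permuted = compute_scores(DEMatrix(perm), small_catalog).records
        key = ["process_id", "context"]
        pd.testing.assert_frame_equal(
            base.set_index(key).sort_index()[["score"]],
            permuted.set_index(key).sort_index()[["score"]],
        )


class TestSignificance:
    def test_degenerate_constant_context_gives_p_one(self):
        df = pd.DataFrame({"C1": [3.0] * 6, "C2": [0.0] * 6},
                          index=[f"G{i}" for i in range(6)])
        cat = ProcessCatalog([ProcessTerm("T", "t", frozenset({"G0", "G1", "G2"}))])
        table = compute_scores(DEMatrix(df), cat)
        table = score_significance(DEMatrix(df), table, n_null=100, seed=0)
        rec = table.records.set_index("context")
        assert rec.loc["C1", "p"] == 1.0 and rec.loc["C1", "z"] == 0.0
        assert bool(rec.loc["C1", "degenerate_null"])

    def test_q_never_below_p(self, small_catalog, small_dem):
        table = compute_scores(small_dem, small_catalog)
        table = score_significance(small_dem, table, n_null=200, seed=1)
        rec = table.records.dropna(subset=["p"])
        assert (rec["q"] >= rec["p"] - 1e-12).all()
        assert rec["p"].between(0, 1).all() and rec["q"].between(0, 1).all()

    def test_same_seed_reproduces_z_and_p(self, small_catalog, small_dem):
        t1 = score_significance(
            small_dem, compute_scores(small_dem, small_catalog), n_null=150, seed=42
        )
        t2 = score_significance(
            small_dem, compute_scores(small_dem, small_catalog), n_null=150, seed=42
        )
        pd.testing.assert_frame_equal(t1.records, t2.records)

    def test_planted_strong_term_is_significant(self):
        # all term genes at +3 sd of the background
        for seed in range(5):
            spec = PlantSpec(n_genes=300, n_contexts=4, n_terms=8,
                             term_size_range=(10, 20), noise_sd=1.0,
                             planted=[("T001", "C01", 3.0)], seed=seed)
            cat = make_catalog(spec)
            dem = make_de_matrix(spec, cat)
            table = score_significance(dem, compute_scores(dem, cat),
                                       n_null=500, seed=seed)
            rec = table.records.set_index(["process_id", "context"])
            assert rec.loc[("T001", "C01"), "p"] < 0.01

    def test_n_null_floor_enforced(self, small_catalog, small_dem):
        with pytest.raises(ValueError, match="n_null"):
            score_significance(small_dem, compute_scores(small_dem, small_catalog),
                               n_null=10, seed=0)


class TestBHAdjust:
    def test_three_value_example(self):
        assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_single_value_identity(self):
        assert bh_adjust([0.5]) == pytest.approx([0.5])

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_adjust([0.1, 1.5])
        with pytest.raises(ValueError):
            bh_adjust([-0.1])

    def test_matches_brute_force_step_up_exactly(self):
        rng = np.random.default_rng(99)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            assert (bh_adjust(p) == brute_force_bh(p)).all()

    def test_agrees_with_statsmodels_reference(self):
        rng = np.random.default_rng(100)
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.allclose(bh_adjust(p), ref, rtol=1e-12, atol=0)

    def test_bounded_and_monotone(self):
        rng = np.random.default_rng(101)
        p = np.sort(rng.uniform(size=30))
        q = bh_adjust(p)
        assert ((q >= 0) & (q <= 1)).all()
        assert (np.diff(q) >= -1e-15).all()  # monotone input -> monotone output


class TestScoreTableIO:
    def test_tsv_round_trip_preserves_records_and_params(self, tmp_path,
                                                         small_catalog, small_dem):
        table = score_significance(
            small_dem, compute_scores(small_dem, small_catalog), n_null=120, seed=3
        )
        path = tmp_path / "scores.tsv"
        table.to_tsv(path)
        back = ScoreTable.read_tsv(path)
        assert back.params == table.params
        pd.testing.assert_frame_equal(back.records, table.records)


class TestEstimatorAPI:
    def test_get_set_params_and_clone(self, small_catalog):
        scorer = ProcessActivityScorer(small_catalog, trim_fraction=0.2, n_null=150)
        params = scorer.get_params()
        assert params["trim_fraction"] == 0.2 and params["n_null"] == 150
        other = clone(scorer).set_params(trim_mode="tails")
        assert other.get_params()["trim_mode"] == "tails"
        assert other.get_params()["catalog"].process_ids == small_catalog.process_ids

    def test_transform_matrix_matches_score_table(self, small_catalog, small_dem):
        scorer = ProcessActivityScorer(small_catalog).fit(small_dem)
        mat = scorer.transform(small_dem)
        table = scorer.score_table(small_dem, significance=False)
        assert list(mat.index) == small_dem.contexts
        for _, r in table.records.dropna(subset=["score"]).iterrows():
            assert mat.loc[r["context"], r["process_id"]] == r["score"]

    def test_band_filter_applied_at_fit(self, small_catalog, small_dem):
        scorer = ProcessActivityScorer(small_catalog, min_genes=3, max_genes=100).fit(small_dem)
        assert set(scorer.get_feature_names_out()) == {"GO:1", "GO:2", "GO:4"}

    def test_samples_frame_orientation_equivalent_to_dematrix(self, small_catalog,
                                                              small_dem):
        frame = small_dem.to_samples_frame()
        a = ProcessActivityScorer(small_catalog).fit(small_dem).transform(small_dem)
        b = ProcessActivityScorer(small_catalog).fit(frame).transform(frame)
        pd.testing.assert_frame_equal(a, b)

    def test_unfitted_transform_raises(self, small_catalog, small_dem):
        with pytest.raises(RuntimeError, match="not fitted"):
            ProcessActivityScorer(small_catalog).transform(small_dem)
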