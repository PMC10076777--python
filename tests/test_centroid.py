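"""Centroid signatures: building, scoring, cutoffs, calls, persistence."""

import numpy as np
import pandas as pd
import pytest

from recurrisk.centroid import (
    DEFAULT_CUTOFFS,
    CentroidSignature,
    build_signature,
    classify,
    load_model,
    optimize_cutoff,
    save_model,
    score_samples,
)
from recurrisk.exceptions import ConfigError, CoverageError, DataError, FormatError
from recurrisk.preprocessing import StandardizationParams, standardize


def toy_signature(metric="uncentered", cutoff=None, name="subgroup1", genes=None):
    genes = genes or ["G1", "G2", "G3"]
    return CentroidSignature(
        name=name, genes=genes,
        centroid_high=np.array([1.0, 0.0, -1.0]),
        centroid_low=np.array([-1.0, 0.0, 1.0]),
        cutoff=cutoff, metric=metric,
    )


def as_expr(vectors, genes=("G1", "G2", "G3")):
    return pd.DataFrame(np.array(vectors).T, index=list(genes),
                        columns=[f"S{i}" for i in range(len(vectors))])


class TestBuild:
    def test_single_sample_centroid_is_that_profile(self):
        z = as_expr([[0.3, -0.2, 1.0], [1.0, 1.0, 1.0]])
        sig = build_signature(z, ["S0"], ["S1"], ["G1", "G2", "G3"], "s")
        np.testing.assert_allclose(sig.centroid_high, [0.3, -0.2, 1.0])

    def test_identical_sets_warn(self):
        z = as_expr([[0.0, 0.0, 0.0]])
        with pytest.warns(UserWarning, match="identical"):
            build_signature(z, ["S0"], ["S0"], ["G1"], "s")

    def test_unknown_gene(self):
        z = as_expr([[0.0, 0.0, 0.0], [1, 1, 1]])
        with pytest.raises(KeyError, match="GX"):
            build_signature(z, ["S0"], ["S1"], ["GX"], "s")

    def test_planted_direction_recovered(self, strong_cohort):
        cohort = strong_cohort
        gt = cohort.gene_truth
        p1 = list(gt.index[gt["role"].isin(["program1_epi", "program1_prolif"])])
        truth = cohort.sample_truth["planted_class"]
        clin = cohort.clinical
        high = [s for s in clin.index if truth[s] == "high1"]
        norec = list(clin.index[clin["event"] == 0])
        low = [s for s in norec if truth[s] == "low"]
        z, _ = standardize(cohort.expression)
        sig = build_signature(z, high, low, p1, "s")
        # program 1 genes are planted as losses in class high1
        frac_negative = (sig.centroid_high - sig.centroid_low < 0).mean()
        assert frac_negative >= 0.95


class TestScore:
    def test_perfect_correlation_scores_two(self):
        sig = toy_signature()
        z = as_expr([[1.0, 0.0, -1.0]])
        assert score_samples(sig, z, is_z=True).iloc[0] == pytest.approx(2.0)

    def test_equidistant_sample_scores_zero(self):
        sig = toy_signature()
        z = as_expr([[0.0, 5.0, 0.0]])
        assert score_samples(sig, z, is_z=True).iloc[0] == pytest.approx(0.0)

    def test_pearson_affine_invariance(self):
        sig = toy_signature(metric="pearson")
        z = as_expr([[0.5, -0.1, -0.9]])
        z2 = 3.0 * z + 7.0
        a = score_samples(sig, z, is_z=True)
        b = score_samples(sig, z2, is_z=True)
        assert a.iloc[0] == pytest.approx(b.iloc[0], abs=1e-12)

    def test_uncentered_positive_scale_invariance(self):
        sig = toy_signature()
        z = as_expr([[0.5, -0.1, -0.9]])
        a = score_samples(sig, z, is_z=True)
        b = score_samples(sig, 4.0 * z, is_z=True)
        assert a.iloc[0] == pytest.approx(b.iloc[0], abs=1e-12)

    def test_coverage_below_95_percent_raises(self):
        genes = [f"G{i}" for i in range(20)]
        sig = CentroidSignature("s", genes, np.ones(20), -np.ones(20))
        expr = pd.DataFrame(np.zeros((10, 1)), index=genes[:10], columns=["S0"])
        with pytest.raises(CoverageError) as exc:
            score_samples(sig, expr, is_z=True)
        assert "G19" in str(exc.value)

    def test_few_missing_genes_dropped_pairwise(self):
        genes = [f"G{i}" for i in range(40)]
        rng = np.random.default_rng(0)
        hi = rng.normal(size=40)
        sig = CentroidSignature("s", genes, hi, -hi)
        z = pd.DataFrame(rng.normal(size=(39, 3)), index=genes[:39],
                         columns=["A", "B", "C"])
        scores = score_samples(sig, z, is_z=True)  # 97.5% coverage passes
        assert np.isfinite(scores).all()

    def test_raw_matrix_requires_standardization(self):
        sig = toy_signature()
        with pytest.raises(ConfigError, match="standardization"):
            score_samples(sig, as_expr([[1.0, 0, 0]]), is_z=False)


class TestCutoff:
    def clin(self, times, events, ids):
        return pd.DataFrame({"time_months": times, "event": events},
                            index=pd.Index(ids, name="sample_id"))

    def test_perfect_separation_lands_between_clusters(self):
        ids = list("ABCDEF")
        scores = pd.Series([-1, -1, -1, 1, 1, 1], index=ids, dtype=float)
        clin = self.clin([50, 50, 50, 5, 8, 12], [0, 0, 0, 1, 1, 1], ids)
        cut = optimize_cutoff(scores, clin)
        assert -1 < cut < 1
        assert ((scores > cut) == (scores == 1)).all()

    def test_all_scores_equal_rejected(self):
        ids = list("ABCD")
        scores = pd.Series([2.0] * 4, index=ids)
        clin = self.clin([1, 2, 3, 4], [1, 1, 0, 0], ids)
        with pytest.raises(DataError, match="cutpoint"):
            optimize_cutoff(scores, clin)

    def test_minimum_arm_constraint(self):
        # the split isolating the single extreme sample is inadmissible at 30%
        ids = list("ABCDEFGH")
        scores = pd.Series([0, 1, 2, 3, 4, 5, 6, 100], index=ids, dtype=float)
        clin = self.clin([9, 8, 7, 6, 5, 4, 3, 1], [1, 1, 0, 1, 0, 1, 1, 1], ids)
        cut = optimize_cutoff(scores, clin, min_group_frac=0.30)
        assert (scores > cut).sum() >= 2

    def test_recovers_planted_high_risk_fraction(self, strong_cohort):
        cohort = strong_cohort
        truth = cohort.sample_truth["planted_class"]
        z, params = standardize(cohort.expression)
        gt = cohort.gene_truth
        p1 = list(gt.index[gt["role"].isin(["program1_epi", "program1_prolif"])])
        high = list(truth.index[truth == "high1"])
        low = list(truth.index[truth == "low"])
        sig = build_signature(z, high, low, p1, "s", standardization=params)
        scores = score_samples(sig, z, is_z=True)
        cut = optimize_cutoff(scores, cohort.clinical)
        called_frac = (scores > cut).mean()
        planted_frac = (truth == "high1").mean()
        assert abs(called_frac - planted_frac) <= 0.10


class TestClassify:
    def two_sigs(self, cutoffs=DEFAULT_CUTOFFS):
        genes1 = ["A1", "A2", "A3"]
        genes2 = ["B1", "B2", "B3"]
        sig1 = CentroidSignature("subgroup1", genes1, np.array([1.0, 0, -1]),
                                 np.array([-1.0, 0, 1]), cutoff=cutoffs[0])
        sig2 = CentroidSignature("subgroup2", genes2, np.array([1.0, 0, -1]),
                                 np.array([-1.0, 0, 1]), cutoff=cutoffs[1])
        return sig1, sig2

    def expr(self, v1, v2):
        data = {"S0": list(v1) + list(v2)}
        return pd.DataFrame(data, index=["A1", "A2", "A3", "B1", "B2", "B3"])

    def test_above_first_cutoff_only_is_subgroup_one(self):
        # published constants: score1 = 0.10 > -0.0850, score2 well below -0.0005
        sig1, sig2 = self.two_sigs()
        ex = self.expr([0.06, 0.04, -0.05], [-1.0, 0.0, 1.0])
        calls = classify(sig1, sig2, ex, is_z=True)
        assert calls.loc["S0", "score1"] > sig1.cutoff
        assert calls.loc["S0", "score2"] < sig2.cutoff
        assert calls.loc["S0", "label"] == "high_risk_1"

    def test_both_margins_negative_is_low_risk(self):
        sig1, sig2 = self.two_sigs(cutoffs=(0.5, 0.5))
        ex = self.expr([0.0, 1.0, 0.0], [0.0, 1.0, 0.0])  # orthogonal to centroids
        calls = classify(sig1, sig2, ex, is_z=True)
        assert (calls["margin1"] <= 0).all() and (calls["margin2"] <= 0).all()
        assert calls.loc["S0", "label"] == "low_risk"

    def test_margin_tie_goes_to_subgroup_one(self):
        sig1, sig2 = self.two_sigs(cutoffs=(-0.2, -0.2))
        ex = self.expr([1.0, 0.0, -1.0], [1.0, 0.0, -1.0])  # equal scores
        calls = classify(sig1, sig2, ex, is_z=True)
        assert calls.loc["S0", "margin1"] == calls.loc["S0", "margin2"] > 0
        assert calls.loc["S0", "label"] == "high_risk_1"

    def test_low_risk_iff_both_margins_nonpositive(self, trained_model,
                                                   strong_cohort):
        calls = trained_model.risk_table(strong_cohort.expression.T)
        low = calls["label"] == "low_risk"
        both_neg = (calls["margin1"] <= 0) & (calls["margin2"] <= 0)
        assert (low == both_neg).all()

    def test_combined_score_is_max_margin(self, trained_model, strong_cohort):
        calls = trained_model.risk_table(strong_cohort.expression.T)
        np.testing.assert_allclose(
            calls["combined_score"],
            np.maximum(calls["margin1"], calls["margin2"]))

    def test_missing_cutoff_rejected(self):
        sig1, sig2 = self.two_sigs()
        sig1.cutoff = None
        with pytest.raises(ConfigError, match="cutoff"):
            classify(sig1, sig2, self.expr([0, 0, 0], [0, 0, 0]), is_z=True)


class TestPersistence:
    def test_round_trip_preserves_calls(self, tmp_path, trained_model,
                                        strong_cohort):
        model = trained_model
        path = tmp_path / "model.json"
        save_model(path, model.signature1_, model.signature2_,
                   config={"cv_rounds": 5}, seed=7)
        sig1, sig2, meta = load_model(path)
        expr = strong_cohort.expression
        before = classify(model.signature1_, model.signature2_, expr)
        after = classify(sig1, sig2, expr)
        pd.testing.assert_frame_equal(before, after)
        assert meta["seed"] == 7

    def test_tampered_gene_list_rejected(self, tmp_path, trained_model):
        import json
        path = tmp_path / "model.json"
        save_model(path, trained_model.signature1_, trained_model.signature2_)
        doc = json.loads(path.read_text())
        doc["signatures"][0]["genes"] = doc["signatures"][0]["genes"][:-1]
        path.write_text(json.dumps(doc))
        with pytest.raises(FormatError, match="centroid length"):
            load_model(path)

    def test_corrupted_file_rejected(self, tmp_path):
        path = tmp_path / "model.json"
        path.write_text("{not json")
        with pytest.raises(FormatError, match="corrupted"):
            load_model(path)

    def test_version_mismatch_warns(self, tmp_path, trained_model):
        import json
        path = tmp_path / "model.json"
        save_model(path, trained_model.signature1_, trained_model.signature2_)
        doc = json.loads(path.read_text())
        doc["package_version"] = "0.0.0"
        path.write_text(json.dumps(doc))
        with pytest.warns(UserWarning, match="0.0.0"):
            load_model(path)

    def test_missing_cutoffs_install_documented_defaults(self, tmp_path,
                                                         trained_model):
        import json
        path = tmp_path / "model.json"
        save_model(path, trained_model.signature1_, trained_model.signature2_)
        doc = json.loads(path.read_text())
        for sd in doc["signatures"]:
            sd["cutoff"] = None
        path.write_text(json.dumps(doc))
        with pytest.warns(UserWarning, match="default"):
            sig1, sig2, _ = load_model(path)
        assert (sig1.cutoff, sig2.cutoff) == DEFAULT_CUTOFFS
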