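import numpy as np
import pandas as pd
import pytest
from scipy import stats

from progsig.matrix import ExpressionMatrix
from progsig.scoring import (
    centroid_correlations,
    centroid_risk,
    classify_nearest_centroid,
    difference_of_means,
    grouped_threshold,
    ror_linear,
    score_all,
    score_signature,
    weighted_sum,
)
from progsig.signatures import (
    GeneEntry,
    GroupSpec,
    SignatureDefinition,
    map_signature,
)


def _expr(values, genes, samples):
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def _centroid_sig(centroids, name="cent", **kw):
    return SignatureDefinition(
        name=name,
        archetype="centroid_subtype",
        centroids=centroids,
        ror_coefficients={c: 0.0 for c in centroids},
        **kw,
    )


class TestCentroidCorrelations:
    genes = ["g1", "g2", "g3", "g4"]
    centroids = {
        "A": {"g1": 1.0, "g2": 2.0, "g3": 3.0, "g4": 4.0},
        "B": {"g1": 4.0, "g2": 1.0, "g3": 3.0, "g4": 2.0},
    }

    def _mapped(self, expr):
        return map_signature(_centroid_sig(self.centroids), expr)

    def test_self_correlation_is_one(self):
        expr = _expr([[1.0], [2.0], [3.0], [4.0]], self.genes, ["s"])
        corr = centroid_correlations(expr, self._mapped(expr), "pearson")
        assert corr.loc["s", "A"] == pytest.approx(1.0)

    def test_negated_centered_centroid_gives_minus_one(self):
        centered = np.array([1.0, 2.0, 3.0, 4.0]) - 2.5
        expr = _expr((-centered)[:, None], self.genes, ["s"])
        corr = centroid_correlations(expr, self._mapped(expr), "pearson")
        assert corr.loc["s", "A"] == pytest.approx(-1.0)

    def test_matches_scipy_pearson(self):
        x = np.array([0.3, -1.2, 2.0, 0.7])
        expr = _expr(x[:, None], self.genes, ["s"])
        corr = centroid_correlations(expr, self._mapped(expr), "pearson")
        for cls in ("A", "B"):
            expected = stats.pearsonr(x, [self.centroids[cls][g] for g in self.genes])[0]
            assert corr.loc["s", cls] == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_spearman(self):
        x = np.array([0.3, -1.2, 2.0, 0.7])
        expr = _expr(x[:, None], self.genes, ["s"])
        corr = centroid_correlations(expr, self._mapped(expr), "spearman")
        for cls in ("A", "B"):
            expected = stats.spearmanr(x, [self.centroids[cls][g] for g in self.genes])[0]
            assert corr.loc["s", cls] == pytest.approx(expected, abs=1e-12)

    def test_too_few_shared_genes_marks_missing(self):
        vals = np.array([[1.0], [2.0], [np.nan], [np.nan]])
        expr = _expr(vals, self.genes, ["s"])
        corr = centroid_correlations(expr, self._mapped(expr), "pearson")
        assert np.isnan(corr.loc["s", "A"])


class TestClassification:
    def test_unique_argmax(self):
        corr = pd.DataFrame(
            [[0.9, 0.1, 0.0, -0.2, -0.5]], index=["s"], columns=list("ABCDE")
        )
        assert classify_nearest_centroid(corr).loc["s", "call"] == "A"

    def test_tie_breaks_to_first_declared_class(self):
        corr = pd.DataFrame([[0.1, 0.8, 0.8]], index=["s"], columns=list("ABC"))
        out = classify_nearest_centroid(corr)
        assert out.loc["s", "call"] == "B"
        assert bool(out.loc["s", "ambiguous"])

    def test_all_missing_is_unknown(self):
        corr = pd.DataFrame([[np.nan, np.nan]], index=["s"], columns=list("AB"))
        assert classify_nearest_centroid(corr).loc["s", "call"] == "unknown"

    def test_noise_free_centroid_copies_classified_perfectly(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(12)]
        centroids = {
            cls: {g: float(v) for g, v in zip(genes, rng.normal(0, 2, len(genes)))}
            for cls in ("A", "B", "C")
        }
        labels = ["A", "B", "C"] * 10
        vals = np.column_stack([[centroids[c][g] for g in genes] for c in labels])
        expr = _expr(vals, genes, [f"s{i}" for i in range(30)])
        sig = _centroid_sig(centroids)
        corr = centroid_correlations(expr, map_signature(sig, expr), "pearson")
        calls = classify_nearest_centroid(corr)["call"]
        assert list(calls) == labels

    def test_accuracy_degrades_with_noise(self):
        rng = np.random.default_rng(1)
        genes = [f"g{i}" for i in range(10)]
        centroids = {
            cls: {g: float(v) for g, v in zip(genes, rng.normal(0, 1.5, len(genes)))}
            for cls in ("A", "B", "C")
        }
        labels = np.array(["A", "B", "C"])[rng.integers(0, 3, 200)]
        clean = np.column_stack([[centroids[c][g] for g in genes] for c in labels])
        sig = _centroid_sig(centroids)
        accs = []
        for noise in (0.0, 1.0, 4.0):
            vals = clean + rng.normal(0, noise, clean.shape)
            expr = _expr(vals, genes, [f"s{i}" for i in range(200)])
            corr = centroid_correlations(expr, map_signature(sig, expr), "pearson")
            accs.append((classify_nearest_centroid(corr)["call"] == labels).mean())
        assert accs[0] == 1.0
        assert accs[0] > accs[1] > accs[2]


class TestRorLinear:
    corr = pd.DataFrame([[0.5, -0.2, 0.1, 0.7, -0.9]], index=["s"], columns=list("ABCDE"))

    def test_zero_coefficients_give_zero(self):
        score = ror_linear(self.corr, {c: 0.0 for c in "ABCDE"})
        assert score.loc["s"] == 0.0

    def test_indicator_coefficients_project(self):
        coef = {"A": 1.0, "B": 0.0, "C": 0.0, "D": 0.0, "E": 0.0}
        assert ror_linear(self.corr, coef).loc["s"] == pytest.approx(0.5)

    def test_hand_dot_product(self):
        coef = {"A": 0.05, "B": 0.1, "C": -0.2, "D": 0.1, "E": -0.05}
        expected = 0.05 * 0.5 + 0.1 * -0.2 + -0.2 * 0.1 + 0.1 * 0.7 + -0.05 * -0.9
        assert ror_linear(self.corr, coef).loc["s"] == pytest.approx(expected, abs=1e-15)

    def test_class_mismatch_rejected(self):
        with pytest.raises(ValueError, match="do not match"):
            ror_linear(self.corr, {"A": 1.0})


class TestCentroidRisk:
    def test_equals_reversed_correlation(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(8)]
        centroids = {
            "good": {g: float(v) for g, v in zip(genes, rng.normal(0, 1, 8))},
            "bad": {g: float(v) for g, v in zip(genes, rng.normal(0, 1, 8))},
        }
        sig = SignatureDefinition(
            name="c",
            archetype="centroid_risk",
            centroids=centroids,
            reference_class="good",
            risk_direction=-1,
        )
        expr = _expr(rng.normal(0, 1, (8, 20)), genes, [f"s{i}" for i in range(20)])
        mapped = map_signature(sig, expr)
        score = centroid_risk(expr, mapped)
        corr = centroid_correlations(expr, mapped, "pearson")
        pd.testing.assert_series_equal(score, -corr["good"], check_names=False)

    def test_extremes(self):
        genes = ["g1", "g2", "g3", "g4"]
        good = np.array([1.0, 2.0, 3.0, 4.0])
        centroids = {"good": dict(zip(genes, good))}
        sig = SignatureDefinition(
            name="c",
            archetype="centroid_risk",
            centroids=centroids,
            reference_class="good",
            risk_direction=-1,
        )
        expr = _expr(
            np.column_stack([good, -(good - good.mean())]), genes, ["best", "worst"]
        )
        score = centroid_risk(expr, map_signature(sig, expr))
        assert score.loc["best"] == pytest.approx(-1.0)  # minimal possible risk
        assert score.loc["worst"] == pytest.approx(1.0)  # maximal possible risk


class TestWeightedSum:
    def _sig(self, weights, strata=None):
        strata = strata or [None] * len(weights)
        return SignatureDefinition(
            name="w",
            archetype="weighted_sum",
            genes=[
                GeneEntry(gene_id=f"g{i}", weight=w, stratum=s)
                for i, (w, s) in enumerate(zip(weights, strata))
            ],
        )

    def test_zero_weights(self):
        expr = _expr([[1.0], [2.0]], ["g0", "g1"], ["s"])
        sig = self._sig([0.0, 0.0])
        assert weighted_sum(expr, map_signature(sig, expr)).loc["s"] == 0.0

    def test_single_gene_weight_one(self):
        expr = _expr([[3.7]], ["g0"], ["s"])
        sig = self._sig([1.0])
        assert weighted_sum(expr, map_signature(sig, expr)).loc["s"] == pytest.approx(3.7)

    def test_five_gene_hand_sum(self):
        x = np.array([1.0, -2.0, 0.5, 3.0, -1.5])
        w = [0.2, -0.1, 0.4, 0.05, -0.3]
        expr = _expr(x[:, None], [f"g{i}" for i in range(5)], ["s"])
        sig = self._sig(w)
        assert weighted_sum(expr, map_signature(sig, expr)).loc["s"] == pytest.approx(
            float(np.dot(w, x)), abs=1e-12
        )

    def test_missing_gene_renormalizes_weights(self):
        x = np.array([2.0, np.nan])
        expr = _expr(x[:, None], ["g0", "g1"], ["s"])
        sig = self._sig([0.5, 0.5])
        # observed weighted sum 1.0 rescaled by total/observed weight = 2
        assert weighted_sum(expr, map_signature(sig, expr)).loc["s"] == pytest.approx(2.0)

    def test_stratified_sample_without_label_is_missing(self):
        expr = _expr([[1.0, 2.0]], ["g0"], ["s1", "s2"])
        sig = self._sig([1.0], strata=["pos"])
        labels = pd.Series({"s1": "pos", "s2": None})
        out = weighted_sum(expr, map_signature(sig, expr), labels)
        assert out.loc["s1"] == pytest.approx(1.0)
        assert np.isnan(out.loc["s2"])

    def test_stratified_requires_labels(self):
        expr = _expr([[1.0]], ["g0"], ["s"])
        sig = self._sig([1.0], strata=["pos"])
        with pytest.raises(ValueError, match="stratified"):
            weighted_sum(expr, map_signature(sig, expr))


class TestDifferenceOfMeans:
    def _sig(self, n_up, n_down):
        return SignatureDefinition(
            name="d",
            archetype="difference_of_means",
            genes=[GeneEntry(gene_id=f"u{i}", group="up") for i in range(n_up)]
            + [GeneEntry(gene_id=f"d{i}", group="down") for i in range(n_down)],
        )

    def test_equal_means_give_zero(self):
        expr = _expr([[2.0], [2.0]], ["u0", "d0"], ["s"])
        sig = self._sig(1, 1)
        assert difference_of_means(expr, map_signature(sig, expr), rescale=False).loc[
            "s"
        ] == pytest.approx(0.0)

    def test_constant_sets(self):
        expr = _expr([[1.0], [1.0], [-1.0], [-1.0]], ["u0", "u1", "d0", "d1"], ["s"])
        sig = self._sig(2, 2)
        assert difference_of_means(expr, map_signature(sig, expr), rescale=False).loc[
            "s"
        ] == pytest.approx(2.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(0, 1, (12, 7))
        genes = [f"u{i}" for i in range(6)] + [f"d{i}" for i in range(6)]
        expr = _expr(vals, genes, [f"s{i}" for i in range(7)])
        sig = self._sig(6, 6)
        raw = difference_of_means(expr, map_signature(sig, expr), rescale=False)
        expected = vals[:6].mean(axis=0) - vals[6:].mean(axis=0)
        np.testing.assert_allclose(raw.to_numpy(), expected, atol=1e-12)

    def test_rescaled_range_is_symmetric_unit(self):
        rng = np.random.default_rng(5)
        vals = rng.normal(0, 1, (4, 50))
        genes = ["u0", "u1", "d0", "d1"]
        expr = _expr(vals, genes, [f"s{i}" for i in range(50)])
        sig = self._sig(2, 2)
        scaled = difference_of_means(expr, map_signature(sig, expr))
        assert scaled.min() == pytest.approx(-1.0)
        assert scaled.max() == pytest.approx(1.0)

    def test_empty_set_rejected(self):
        expr = _expr([[1.0]], ["u0"], ["s"])
        sig = self._sig(1, 1)
        mapped = map_signature(sig, expr, min_coverage=0.0, warn_coverage=0.0)
        with pytest.raises(ValueError, match="down"):
            difference_of_means(expr, mapped)


class TestGroupedThreshold:
    def test_single_gene_single_group(self):
        sig = SignatureDefinition(
            name="g",
            archetype="grouped_threshold",
            genes=[GeneEntry(gene_id="g0", group="a")],
            groups={"a": GroupSpec(weight=1.0)},
        )
        expr = _expr([[2.5]], ["g0"], ["s"])
        assert grouped_threshold(expr, map_signature(sig, expr)).loc["s"] == pytest.approx(2.5)

    def test_reference_normalized_all_equal_gives_intercept(self):
        sig = SignatureDefinition(
            name="g",
            archetype="grouped_threshold",
            genes=[
                GeneEntry(gene_id="g0", group="a"),
                GeneEntry(gene_id="g1", group="b"),
                GeneEntry(gene_id="r0", is_reference=True),
                GeneEntry(gene_id="r1", is_reference=True),
            ],
            groups={"a": GroupSpec(weight=2.0), "b": GroupSpec(weight=-1.0)},
            intercept=7.5,
        )
        expr = _expr([[5.0], [5.0], [5.0], [5.0]], ["g0", "g1", "r0", "r1"], ["s"])
        assert grouped_threshold(expr, map_signature(sig, expr)).loc["s"] == pytest.approx(7.5)

    def test_hand_evaluated_toy_with_clipping(self):
        # 6 genes: ref mean = 10; group a = mean(12, 14) - 10 = 3, clipped at 2;
        # group b = mean(9, 8) - 10 = -1.5, unclipped
        sig = SignatureDefinition(
            name="g",
            archetype="grouped_threshold",
            genes=[
                GeneEntry(gene_id="a0", group="a"),
                GeneEntry(gene_id="a1", group="a"),
                GeneEntry(gene_id="b0", group="b"),
                GeneEntry(gene_id="b1", group="b"),
                GeneEntry(gene_id="r0", is_reference=True),
                GeneEntry(gene_id="r1", is_reference=True),
            ],
            groups={
                "a": GroupSpec(weight=1.5, clip_high=2.0),
                "b": GroupSpec(weight=0.5),
            },
            intercept=1.0,
        )
        expr = _expr(
            [[12.0], [14.0], [9.0], [8.0], [9.0], [11.0]],
            ["a0", "a1", "b0", "b1", "r0", "r1"],
            ["s"],
        )
        expected = 1.0 + 1.5 * 2.0 + 0.5 * (-1.5)
        assert grouped_threshold(expr, map_signature(sig, expr)).loc["s"] == pytest.approx(
            expected, abs=1e-12
        )

    def test_empty_group_rejected(self):
        sig = SignatureDefinition(
            name="g",
            archetype="grouped_threshold",
            genes=[GeneEntry(gene_id="g0", group="a"), GeneEntry(gene_id="g1", group="b")],
            groups={"a": GroupSpec(), "b": GroupSpec()},
        )
        expr = _expr([[1.0]], ["g0"], ["s"])
        mapped = map_signature(sig, expr, min_coverage=0.0, warn_coverage=0.0)
        with pytest.raises(ValueError, match="'b'"):
            grouped_threshold(expr, mapped)

    def test_reduces_to_weighted_sum_without_clipping_or_references(self):
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(6)]
        expr = _expr(rng.normal(0, 1, (6, 15)), genes, [f"s{i}" for i in range(15)])
        grouped_sig = SignatureDefinition(
            name="g",
            archetype="grouped_threshold",
            genes=[GeneEntry(gene_id=g, group="a" if i < 4 else "b") for i, g in enumerate(genes)],
            groups={"a": GroupSpec(weight=1.2), "b": GroupSpec(weight=-0.7)},
        )
        sum_sig = SignatureDefinition(
            name="w",
            archetype="weighted_sum",
            genes=[
                GeneEntry(gene_id=g, weight=(1.2 / 4 if i < 4 else -0.7 / 2))
                for i, g in enumerate(genes)
            ],
        )
        a = grouped_threshold(expr, map_signature(grouped_sig, expr))
        b = weighted_sum(expr, map_signature(sum_sig, expr))
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-12)


class TestAffineInvariance:
    def test_centroid_scores_invariant_to_per_sample_affine(self, cohort):
        expr = cohort.expression
        transformed = ExpressionMatrix(expr.values * 3.5 + 12.0)
        for sig in cohort.signatures:
            if sig.archetype not in ("centroid_subtype", "centroid_risk"):
                continue
            mapped = map_signature(sig, expr)
            mapped_t = map_signature(sig, transformed)
            s1, c1, _ = score_signature(expr, mapped)
            s2, c2, _ = score_signature(transformed, mapped_t)
            np.testing.assert_allclose(s1.to_numpy(), s2.to_numpy(), atol=1e-9)
            if c1 is not None:
                assert (c1 == c2).all()


class TestScoreAll:
    def test_smoke_nine_signatures_no_missing(self, cohort, score_table):
        assert len(score_table.signatures) == len(cohort.signatures) == 9
        assert not score_table.scores.isna().any().any()
        assert all(v == "ok" for v in score_table.status.values())

    def test_orientation_negation_flips_score(self, cohort):
        sig = next(s for s in cohort.signatures if s.name == "proliferation_sum")
        flipped = sig.model_copy(update={"risk_direction": -1})
        mapped = map_signature(sig, cohort.expression)
        base, _, _ = score_signature(cohort.expression, mapped)
        neg, _, _ = score_signature(
            cohort.expression, map_signature(flipped, cohort.expression)
        )
        np.testing.assert_allclose(neg.to_numpy(), -base.to_numpy(), atol=1e-12)

    def test_dispatch_equals_direct_calls(self, cohort, score_table):
        clin = cohort.clinical.indexed()
        strat = clin["er_status"]
        for sig in cohort.signatures:
            mapped = map_signature(sig, cohort.expression)
            direct, _, _ = score_signature(cohort.expression, mapped, strat)
            np.testing.assert_allclose(
                score_table.scores[sig.name].to_numpy(), direct.to_numpy(), atol=1e-12
            )

    def test_failed_signature_reported_not_fatal(self, cohort):
        bad = SignatureDefinition(
            name="absent",
            archetype="weighted_sum",
            genes=[GeneEntry(gene_id="NOPE")],
        )
        table = score_all(
            cohort.expression, [cohort.signatures[3], bad], cohort.clinical
        )
        assert table.status["absent"].startswith("failed")
        assert cohort.signatures[3].name in table.scores.columns
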