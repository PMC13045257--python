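"""Signature scores, group summaries, correlation and over-representation."""

import numpy as np
import pandas as pd
import pytest

from tcdtyper import (
    ExpressionMatrix,
    GeneSetCollection,
    InputError,
    anticorrelated_targets,
    group_summary,
    overrepresentation,
    pearson_matrix,
    signature_score,
)
from tcdtyper.consensus import SubtypeAssignment


def _em(values: pd.DataFrame) -> ExpressionMatrix:
    return ExpressionMatrix(values, {str(c): "tumour" for c in values.columns})


class TestSignatureScore:
    def test_hand_zscore_two_samples(self):
        em = _em(pd.DataFrame({"s1": [1.0], "s2": [3.0]}, index=["g"]))
        scores = signature_score(em, GeneSetCollection({"set": ["g"]}))
        # population sd of (1, 3) is 1 -> z = (-1, +1)/sqrt(2)... sd = 1
        assert scores.scores.loc["set", "s1"] == pytest.approx(-1.0)
        assert scores.scores.loc["set", "s2"] == pytest.approx(1.0)

    def test_population_sd_convention(self):
        em = _em(pd.DataFrame({"s1": [1.0], "s2": [2.0], "s3": [3.0]}, index=["g"]))
        scores = signature_score(em, GeneSetCollection({"set": ["g"]}))
        sd = np.std([1, 2, 3])  # ddof 0
        assert scores.scores.loc["set", "s3"] == pytest.approx((3 - 2) / sd)

    def test_mean_z_averages_to_zero(self, rng):
        genes = [f"g{i}" for i in range(20)]
        em = _em(pd.DataFrame(rng.uniform(1, 9, (20, 15)), index=genes))
        sets = GeneSetCollection({"a": ["g0", "g3", "g7"], "b": ["g1", "g2", "g4"]})
        scores = signature_score(em, sets)
        assert abs(scores.scores.loc["a"].mean()) < 1e-8

    def test_constant_matrix_rejected(self):
        em = _em(pd.DataFrame(np.ones((4, 5)), index=list("abcd")))
        with pytest.warns(UserWarning), pytest.raises(InputError, match="set"):
            signature_score(em, GeneSetCollection({"set": ["a", "b"]}))

    def test_affine_invariance_of_mean_z(self, rng):
        genes = [f"g{i}" for i in range(10)]
        vals = pd.DataFrame(rng.uniform(1, 9, (10, 12)), index=genes)
        scaled = vals.copy()
        scaled.iloc[3] = scaled.iloc[3] * 7.0 + 2.0
        sets = GeneSetCollection({"s": ["g3", "g4", "g5"]})
        a = signature_score(_em(vals), sets).scores
        b = signature_score(_em(scaled), sets).scores
        pd.testing.assert_frame_equal(a, b)

    def test_rank_z_monotone_invariance(self, rng):
        genes = [f"g{i}" for i in range(10)]
        vals = pd.DataFrame(rng.uniform(1, 9, (10, 12)), index=genes)
        transformed = np.exp(vals / 3.0)  # strictly monotone per column
        sets = GeneSetCollection({"s": ["g0", "g2", "g8"]})
        a = signature_score(_em(vals), sets, method="rank-z").scores
        b = signature_score(_em(transformed), sets, method="rank-z").scores
        pd.testing.assert_frame_equal(a, b)

    def test_planted_severity_gradient(self, small_cohort):
        from tcdtyper.scores import signature_score as score

        co = small_cohort
        tum = co.expression.subset_samples(co.expression.tumour_ids)
        scores = score(tum, co.signatures).scores
        sev = co.truth.subtype
        means = [
            float(scores.loc["exhaustion", sev.index[sev == s]].mean())
            for s in range(4)
        ]
        assert all(b > a for a, b in zip(means, means[1:]))


class TestGroupSummary:
    def test_single_group_equals_global(self, rng):
        vals = pd.DataFrame(rng.normal(size=(3, 6)))
        labels = pd.Series(["g"] * 6, index=vals.columns)
        out = group_summary(vals, labels, stat="median")
        pd.testing.assert_series_equal(
            out["g"], vals.median(axis=1), check_names=False
        )

    def test_hand_median_and_reference_proportion(self):
        vals = pd.DataFrame([[1.0, 2.0, 3.0, 10.0]], columns=list("abcd"))
        labels = pd.Series(["A", "A", "A", "B"], index=list("abcd"))
        out = group_summary(vals, labels, stat="median")
        assert out.loc[0, "A"] == 2.0
        assert out.loc[0, "B"] == 10.0
        rel = group_summary(vals, labels, stat="median", reference="B")
        assert rel.loc[0, "A"] == pytest.approx(0.2)
        assert rel.loc[0, "B"] == 1.0

    def test_unknown_reference_rejected(self):
        vals = pd.DataFrame([[1.0, 2.0]], columns=["a", "b"])
        labels = pd.Series(["A", "B"], index=["a", "b"])
        with pytest.raises(InputError):
            group_summary(vals, labels, reference="Z")

    def test_unlabelled_sample_rejected(self):
        vals = pd.DataFrame([[1.0, 2.0]], columns=["a", "b"])
        with pytest.raises(InputError):
            group_summary(vals, pd.Series(["A"], index=["a"]))


class TestPearson:
    def test_identity_and_antisymmetry(self, rng):
        x = rng.normal(size=10)
        X = pd.DataFrame({"x": x, "negx": -x}).T
        R = pearson_matrix(X)
        assert R.loc["x", "x"] == 1.0
        assert R.loc["x", "negx"] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self, rng):
        X = pd.DataFrame(rng.normal(size=(5, 50)))
        R = pearson_matrix(X).to_numpy()
        for i in range(5):
            for j in range(5):
                a, b = X.iloc[i], X.iloc[j]
                cov = ((a - a.mean()) * (b - b.mean())).mean()
                ref = cov / (a.std(ddof=0) * b.std(ddof=0))
                assert R[i, j] == pytest.approx(ref, abs=1e-10)

    def test_zero_variance_reported_missing(self, rng):
        X = pd.DataFrame(np.vstack([np.ones(10), rng.normal(size=10)]))
        with pytest.warns(UserWarning, match="zero-variance"):
            R = pearson_matrix(X)
        assert np.isnan(R.iloc[0, 1])

    def test_too_few_samples_rejected(self):
        with pytest.raises(InputError):
            pearson_matrix(pd.DataFrame([[1.0, 2.0]]))


def _assignment(low_ids, high_ids) -> SubtypeAssignment:
    labels = pd.Series(
        [0] * len(low_ids) + [1] * len(high_ids), index=list(low_ids) + list(high_ids)
    )
    return SubtypeAssignment(
        labels=labels, severity_rank={0: 1, 1: 2}, names={0: "T-low", 1: "T-high"}
    )


class TestAnticorrelatedTargets:
    def test_positive_control_excluded_and_forced_inclusion(self, rng):
        samples = [f"s{i}" for i in range(10)]
        mir = pd.Series(rng.normal(size=10) + np.linspace(0, 3, 10), index=samples)
        genes = pd.DataFrame(
            {"same": mir, "anti": -mir + 10.0}, index=samples
        ).T
        assign = _assignment(samples[:5], samples[5:])
        got = anticorrelated_targets(mir, genes, assign)
        assert "same" not in got  # r = +1
        assert "anti" in got  # r = -1 and higher where miRNA is low (T-low)

    def test_planted_targets_recovered_exactly(self, rng):
        n = 200
        samples = [f"s{i}" for i in range(n)]
        sev = np.repeat([0, 1], n // 2)
        mir = pd.Series(rng.normal(scale=0.3, size=n) + 2.0 * sev, index=samples)
        rows = {}
        for i in range(10):  # true anti-regulated targets
            rows[f"tgt{i}"] = 8.0 - 1.5 * mir + rng.normal(scale=0.3, size=n)
        for i in range(40):  # co-regulated genes, rising with the miRNA
            rows[f"pos{i}"] = 2.0 + 1.0 * mir + rng.normal(scale=0.3, size=n)
        genes = pd.DataFrame(rows, index=samples).T
        assign = _assignment(samples[: n // 2], samples[n // 2 :])
        got = set(anticorrelated_targets(mir, genes, assign))
        assert got == {f"tgt{i}" for i in range(10)}

    def test_missing_group_rejected(self, rng):
        samples = [f"s{i}" for i in range(6)]
        labels = pd.Series([0] * 6, index=samples)
        assign = SubtypeAssignment(labels=labels, severity_rank={0: 1}, names={0: "T-low"})
        mir = pd.Series(rng.normal(size=6), index=samples)
        with pytest.raises(InputError):
            anticorrelated_targets(mir, pd.DataFrame({"g": mir}).T, assign)


class TestOverrepresentation:
    def test_disjoint_pathway_has_unit_p(self):
        uni = [f"g{i}" for i in range(10)]
        out = overrepresentation(uni[:4], uni, GeneSetCollection({"p": uni[4:6]}))
        row = out.set_index("pathway").loc["p"]
        assert row["k"] == 0
        assert row["p"] == 1.0

    def test_matches_enrichment_tail(self):
        uni = [f"g{i}" for i in range(1, 11)]
        hits = ["g1", "g2", "g3", "g4"]
        paths = GeneSetCollection({"sig": ["g1", "g2", "g3", "g7", "g8"]})
        out = overrepresentation(hits, uni, paths)
        assert out.loc[0, "p"] == pytest.approx(66 / 252, abs=1e-12)

    def test_bh_over_pathways(self):
        uni = [f"g{i}" for i in range(40)]
        # three pathways engineered to give increasing p
        paths = GeneSetCollection(
            {"a": uni[:6], "b": uni[:4] + uni[30:32], "c": uni[:2] + uni[30:34]}
        )
        out = overrepresentation(uni[:6], uni, paths).set_index("pathway")
        ps = out["p"]
        m = 3
        # q must satisfy the BH step-up relation computed by hand
        order = ps.sort_values()
        qs = {}
        prev = 1.0
        for rank in range(m, 0, -1):
            name = order.index[rank - 1]
            prev = min(prev, order.iloc[rank - 1] * m / rank)
            qs[name] = prev
        for name in ps.index:
            assert out.loc[name, "q"] == pytest.approx(qs[name], abs=1e-12)

    def test_stray_hits_rejected(self):
        with pytest.raises(InputError, match="x9"):
            overrepresentation(["x9"], ["g1"], GeneSetCollection({"p": ["g1"]}))
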