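"""Pearson engine, sample matching and genotype-stratified correlation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from mirsnpflow import (
    CombinedCandidate,
    Config,
    CorrelationResult,
    ExpressionMatrix,
    GenotypeTable,
    Variant,
    correlate_candidates,
    expression_concordance,
    match_samples,
    pearson,
    stratified_correlation,
)


def _expr(data, kind):
    return ExpressionMatrix(pd.DataFrame(data), kind)


class TestMatchSamples:
    def test_pair_intersection(self):
        a = _expr(pd.DataFrame(0.0, index=list("abc"), columns=["m1"]), "mirna")
        b = _expr(pd.DataFrame(0.0, index=list("bcd"), columns=["g1"]), "mrna")
        assert match_samples(a, b) == ["b", "c"]

    def test_identity(self):
        a = _expr(pd.DataFrame(0.0, index=list("abc"), columns=["m1"]), "mirna")
        b = _expr(pd.DataFrame(0.0, index=list("abc"), columns=["g1"]), "mrna")
        assert match_samples(a, b) == ["a", "b", "c"]

    def test_triple_intersection(self):
        a = _expr(pd.DataFrame(0.0, index=list("abc"), columns=["m1"]), "mirna")
        b = _expr(pd.DataFrame(0.0, index=list("bcd"), columns=["g1"]), "mrna")
        g = GenotypeTable(pd.DataFrame(0, index=list("cde"), columns=["rs1"]))
        assert match_samples(a, b, g) == ["c"]

    def test_empty_intersection_raises(self):
        a = _expr(pd.DataFrame(0.0, index=list("ab"), columns=["m1"]), "mirna")
        b = _expr(pd.DataFrame(0.0, index=list("cd"), columns=["g1"]), "mrna")
        with pytest.raises(ValueError, match="no samples"):
            match_samples(a, b)


class TestPearson:
    def test_exact_linearity(self):
        r, p, n = pearson([1, 2, 3], [2, 4, 6])
        assert r == pytest.approx(1.0) and n == 3

    def test_exact_anti_linearity(self):
        r, _, _ = pearson([1, 2, 3], [6, 4, 2])
        assert r == pytest.approx(-1.0)

    def test_hand_computed_cov_sum(self):
        r, _, _ = pearson([1, 2, 3, 4], [1, 3, 2, 4])
        assert r == pytest.approx(0.8)

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="n >= 3"):
            pearson([1, 2], [3, 4])

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson([1, 1, 1], [1, 2, 3])

    def test_matches_brute_force_covariance(self):
        """r equals the explicit sum-of-products formula to 1e-12, and the
        t-based P matches an independent library computation."""
        rng = np.random.default_rng(23)
        for _ in range(100):
            n = int(rng.integers(3, 60))
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            r, p, _ = pearson(x, y)
            xd, yd = x - x.mean(), y - y.mean()
            r_oracle = float((xd * yd).sum() / np.sqrt((xd**2).sum() * (yd**2).sum()))
            assert abs(r - r_oracle) < 1e-12
            r_sp, p_sp = sps.pearsonr(x, y)
            assert abs(r - r_sp) < 1e-12
            assert p == pytest.approx(p_sp, rel=1e-9)

    @given(st.floats(0.1, 10), st.floats(-5, 5))
    def test_affine_invariance_positive_slope(self, a, b):
        x = np.array([0.3, 1.2, 2.8, 3.1, 4.9])
        y = np.array([1.0, 0.2, 2.2, 1.8, 3.0])
        r0, _, _ = pearson(x, y)
        r1, _, _ = pearson(a * x + b, y)
        assert r1 == pytest.approx(r0, abs=1e-10)
        r2, _, _ = pearson(-a * x + b, y)
        assert r2 == pytest.approx(-r0, abs=1e-10)

    def test_null_significance_rate(self):
        """Type-I error of the t test sits near alpha = 0.05 under
        independent Gaussian pairs (n = 100, 1,000 replicates)."""
        rng = np.random.default_rng(29)
        hits = 0
        for _ in range(1000):
            x = rng.normal(size=100)
            y = rng.normal(size=100)
            _, p, _ = pearson(x, y)
            hits += p < 0.05
        assert 0.03 <= hits / 1000 <= 0.07


class TestCorrelateCandidates:
    def test_missing_feature_skipped(self, caplog):
        a = _expr(pd.DataFrame(np.random.default_rng(0).normal(size=(10, 1)),
                               index=[f"s{i}" for i in range(10)], columns=["m1"]), "mirna")
        b = _expr(pd.DataFrame(np.random.default_rng(1).normal(size=(10, 1)),
                               index=[f"s{i}" for i in range(10)], columns=["g1"]), "mrna")
        import logging
        with caplog.at_level(logging.INFO, logger="mirsnpflow.expression"):
            out = correlate_candidates([("m1", "g1"), ("mAbsent", "g1")], a, b)
        assert len(out) == 1
        assert "mAbsent" in caplog.text

    def test_planted_anticorrelation_recovered(self):
        rng = np.random.default_rng(31)
        n = 200
        x = rng.normal(5, 1, size=n)
        y = 8.0 - 0.8 * (x - 5.0) + rng.normal(0, 0.5, size=n)
        samples = [f"s{i}" for i in range(n)]
        a = _expr(pd.DataFrame({"m1": x}, index=samples), "mirna")
        b = _expr(pd.DataFrame({"g1": y}, index=samples), "mrna")
        [res] = correlate_candidates([("m1", "g1")], a, b)
        assert res.r < 0 and res.significant


class TestStratified:
    def _inputs(self, dosages, n=None):
        n = n or len(dosages)
        samples = [f"s{i}" for i in range(n)]
        rng = np.random.default_rng(37)
        a = _expr(pd.DataFrame({"m1": rng.normal(size=n)}, index=samples), "mirna")
        b = _expr(pd.DataFrame({"g1": rng.normal(size=n)}, index=samples), "mrna")
        g = GenotypeTable(pd.DataFrame({"rs1": pd.array(dosages, dtype="Int64")},
                                       index=samples))
        return a, b, g

    def test_small_stratum_flagged_undefined(self):
        a, b, g = self._inputs([0, 0, 1, 2, 2, 2])
        ref, minor = stratified_correlation(("m1", "g1"), a, b, g, "rs1")
        assert not ref.ok and ref.n == 2
        assert minor.ok and minor.n == 3

    def test_all_het_both_undefined(self):
        a, b, g = self._inputs([1, 1, 1, 1, 1, 1])
        ref, minor = stratified_correlation(("m1", "g1"), a, b, g, "rs1")
        assert not ref.ok and not minor.ok

    def test_absent_rsid_raises(self):
        a, b, g = self._inputs([0, 1, 2])
        with pytest.raises(KeyError):
            stratified_correlation(("m1", "g1"), a, b, g, "rsX")

    def test_stratum_sizes_partition_matched_samples(self):
        dosages = [0, 0, 0, 1, 2, 2, 2, None, 1, 0]
        a, b, g = self._inputs(dosages)
        ref, minor = stratified_correlation(("m1", "g1"), a, b, g, "rs1")
        n_het = sum(1 for d in dosages if d == 1)
        n_missing = sum(1 for d in dosages if d is None)
        assert ref.n + minor.n + n_het + n_missing == len(dosages)

    def test_planted_genotype_dependent_signal(self, default_bundle, config):
        """A truth coupled only in minor-allele homozygotes shows a
        significant correlation of the planted sign in that stratum,
        wherever the stratum is large enough to carry the test (a slope
        of 0.8 against unit noise gives |r| ~ 0.6, well powered at
        n >= 20 but not in the handful-sized strata low MAFs produce)."""
        coupled = [t for t in default_bundle.truths if t.expression_coupled]
        hits = checked = 0
        for t in coupled:
            ref, minor = stratified_correlation(
                (t.mirna, t.gene), default_bundle.mirna_expr,
                default_bundle.mrna_expr, default_bundle.genotypes, t.rsid, config)
            if not minor.ok or minor.n < 20:
                continue
            checked += 1
            expected_sign = -1 if t.effect == "create" else 1
            if minor.significant and np.sign(minor.r) == expected_sign:
                hits += 1
        assert checked >= 5
        assert hits / checked >= 0.8


class TestExpressionConcordance:
    def _cand(self, effect):
        return CombinedCandidate(
            variant=Variant("rs1", "1", 100, "A", "G", 0.2),
            mirna="hsa-miR-326", gene="IKZF3", unit_scores={"polymirts": 0.99},
            nbc_score=0.99, effect=effect,
        )

    def _res(self, r, p, significant=True):
        return CorrelationResult(mirna="hsa-miR-326", gene="IKZF3", stratum="hom_minor",
                                 n=50, r=r, p_value=p, significant=significant)

    def test_create_negative_correlation_concordant(self):
        assert expression_concordance(self._cand("create"), self._res(-0.35, 0.006)) == "yes"

    def test_create_positive_correlation_discordant(self):
        assert expression_concordance(self._cand("create"), self._res(0.43, 0.01)) == "no"

    def test_disrupt_positive_correlation_concordant(self):
        assert expression_concordance(self._cand("disrupt"), self._res(0.4, 0.01)) == "yes"

    def test_non_significant_not_applicable(self):
        res = self._res(-0.1, 0.5, significant=False)
        assert expression_concordance(self._cand("create"), res) == "not_applicable"
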