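import numpy as np
import pytest
from scipy import stats

from spsnet import (
    ExpressionMatrix,
    PhenotypeAssignment,
    gfs_transform,
    passes_candidate_filter,
    relevance_factor,
    run_spsnet,
    select_representatives,
    sscore,
    vote_vector,
)
from spsnet import test_subnetwork as subnetwork_ttest
from spsnet.gfs import FuzzyMatrix
from spsnet.subnetworks import Subnetwork
from reference_impl import pipeline_ref, t_test_ref


def _fuzzy(scores, genes=None, samples=None):
    scores = np.asarray(scores, dtype=float)
    genes = genes or [f"g{i}" for i in range(scores.shape[0])]
    samples = samples or [f"p{j}" for j in range(scores.shape[1])]
    return FuzzyMatrix(genes, samples, scores, 0.05, 0.15)


class TestRelevanceFactor:
    def test_bounds_and_hand_mean(self):
        fz = _fuzzy([[1.0, 0.5, 0.0]])
        assert relevance_factor(fz, "g0", ["p0", "p1", "p2"]) == pytest.approx(0.5)
        fz1 = _fuzzy(np.ones((1, 4)))
        assert relevance_factor(fz1, "g0", ["p0", "p1", "p2", "p3"]) == 1.0

    def test_matches_mean_oracle(self, rng):
        scores = rng.random((3, 10))
        fz = _fuzzy(scores)
        pats = [f"p{j}" for j in range(10)]
        assert relevance_factor(fz, "g1", pats) == pytest.approx(scores[1].mean(), abs=1e-12)

    def test_empty_patient_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            relevance_factor(_fuzzy([[1.0, 0.0]]), "g0", [])


class TestVoteVector:
    def test_extremes(self):
        sub = Subnetwork("s", "P", "g0", frozenset([f"g{i}" for i in range(5)]))
        fz = _fuzzy(np.ones((5, 3)))
        np.testing.assert_array_equal(vote_vector(fz, sub, ["p0", "p1", "p2"]), [5, 5, 5])
        fz0 = _fuzzy(np.zeros((5, 3)))
        np.testing.assert_array_equal(vote_vector(fz0, sub, ["p0", "p1"]), [0, 0])

    def test_matches_double_loop(self, rng):
        scores = rng.random((5, 6))
        fz = _fuzzy(scores)
        sub = Subnetwork("s", "P", "g0", frozenset([f"g{i}" for i in range(5)]))
        pats = [f"p{j}" for j in range(6)]
        expected = [sum(scores[i, j] for i in range(5)) for j in range(6)]
        np.testing.assert_allclose(vote_vector(fz, sub, pats), expected, atol=1e-12)


class TestRepresentativeSelection:
    def test_top_x(self):
        pats = ["a", "b", "c", "d"]
        assert select_representatives(np.array([3.0, 9, 1, 7]), pats, 2) == ("b", "d")

    def test_full_phenotype_in_pfsnet_limit(self):
        pats = ["a", "b", "c"]
        assert select_representatives(np.array([1.0, 2, 3]), pats, 3) == ("c", "b", "a")
        assert set(select_representatives(np.array([1.0, 2, 3]), pats, 99)) == set(pats)

    def test_ties_break_lexicographically(self):
        pats = ["d", "b", "a", "c"]
        votes = np.array([5.0, 5.0, 5.0, 1.0])
        assert select_representatives(votes, pats, 2) == ("a", "b")


class TestSScoreAndFilter:
    def test_sscore_extremes_and_oracle(self, rng):
        genes = [f"g{i}" for i in range(5)]
        sub = Subnetwork("s", "P", "g0", frozenset(genes))
        fz = _fuzzy(np.ones((5, 2)))
        assert sscore(fz, "p0", sub, {g: 1.0 for g in genes}) == pytest.approx(5.0)
        assert sscore(fz, "p0", sub, {g: 0.0 for g in genes}) == 0.0
        scores = rng.random((5, 2))
        fzr = _fuzzy(scores)
        beta = {g: float(rng.random()) for g in genes}
        expected = sum(scores[i, 1] * beta[f"g{i}"] for i in range(5))
        assert sscore(fzr, "p1", sub, beta) == pytest.approx(expected, abs=1e-12)

    def test_filter_boundary_inclusive(self):
        assert passes_candidate_filter(dict(zip("abcde", [0.6, 0.5, 0.9, 0.7, 0.5])))
        assert not passes_candidate_filter(dict(zip("abcde", [0.6, 0.6, 0.6, 0.6, 0.49])))

    def test_filter_matches_counting_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 12))
            beta = {f"g{i}": float(rng.random()) for i in range(n)}
            expected = sum(b >= 0.5 for b in beta.values()) >= 5
            assert passes_candidate_filter(beta) == expected


class TestTTest:
    def test_symmetric_scores_give_p_one(self):
        t, p, _ = subnetwork_ttest(np.array([-2.0, -1.0, 0.0, 1.0, 2.0]))
        assert t == 0.0 and p == 1.0

    def test_shifted_scores_significant(self, rng):
        scores = 1.0 + 0.01 * rng.standard_normal(5)
        t, p, direction = subnetwork_ttest(scores)
        assert p < 0.05 and direction == "up-in-test"
        t_ref, p_ref = t_test_ref(list(scores))
        assert t == pytest.approx(t_ref, rel=1e-10)
        assert p == pytest.approx(p_ref, rel=1e-10)

    def test_zero_variance_cases(self):
        _, p, _ = subnetwork_ttest(np.zeros(5))
        assert p == 1.0
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            t, p, direction = subnetwork_ttest(np.full(5, 2.0))
        assert p == 0.0 and direction == "up-in-test"

    def test_too_few_scores_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            subnetwork_ttest(np.array([1.0, 2.0]))

    def test_null_calibration_monte_carlo(self):
        """Type-I error at 0.05 within the binomial 99% CI (10,000 draws, n=30)."""
        r = np.random.default_rng(1234)
        draws = r.standard_normal((10_000, 30))
        rejections = 0
        for row in draws:
            _, p, _ = subnetwork_ttest(row)
            rejections += p < 0.05
        rate = rejections / 10_000
        half_width = 2.576 * np.sqrt(0.05 * 0.95 / 10_000)
        assert abs(rate - 0.05) < half_width


class TestFullPipeline:
    def test_worked_example_matches_reference_everywhere(self, worked_example):
        """Every intermediate (F, V, Q, beta, SScore, SPS, t, p) matches the
        brute-force reference on the 6-gene, 8-patient fixture."""
        expr, phen, sub = worked_example
        control = phen.ordered_control(expr)
        test = phen.ordered_test(expr)
        theta1, theta2, x = 1 / 3, 2 / 3, 2
        ref = pipeline_ref(expr.values.tolist(), expr.genes, expr.samples,
                           control, test, sorted(sub.genes), theta1, theta2, x)
        fz = gfs_transform(expr, theta1, theta2)
        np.testing.assert_allclose(fz.scores, ref["F"], atol=1e-12)
        # per-sample fuzzy profile by rank is the hand value [1, 1, .8, .2, 0, 0]
        for j in range(expr.n_samples):
            np.testing.assert_allclose(sorted(fz.scores[:, j], reverse=True),
                                       [1, 1, 0.8, 0.2, 0, 0], atol=1e-12)
        votes_c = vote_vector(fz, sub, control)
        np.testing.assert_allclose(votes_c, ref["control"]["votes"], atol=1e-12)
        reps_c = select_representatives(votes_c, control, x)
        assert list(reps_c) == ref["control"]["representatives"]
        [res] = run_spsnet(expr, phen, [sub], theta1=theta1, theta2=theta2, x=x, min_size=5)
        for g in sub.genes:
            gi = expr.gene_index(g)
            cols = [expr.sample_index(p) for p in res.representatives_control]
            np.testing.assert_allclose(fz.scores[gi, cols].mean(),
                                       ref["control"]["beta"][g], atol=1e-12)
        for p in expr.samples:
            assert res.sps_score[p] == pytest.approx(ref["sps"][p], abs=1e-12)
        assert res.t_statistic == pytest.approx(ref["t"], rel=1e-10)
        assert res.p_value == pytest.approx(ref["p"], rel=1e-10)

    def test_eq8_identity_and_score_bounds(self, rng):
        genes = [f"g{i}" for i in range(30)]
        samples = [f"p{j}" for j in range(16)]
        expr = ExpressionMatrix(genes, samples, np.exp(rng.normal(0, 1, (30, 16))))
        phen = PhenotypeAssignment(frozenset(samples[:8]), frozenset(samples[8:]))
        subs = [Subnetwork(f"s{k}", "P", genes[k], frozenset(genes[k:k + 6]))
                for k in range(0, 24, 6)]
        results = run_spsnet(expr, phen, subs, theta1=0.2, theta2=0.6, x=3)
        for r in results:
            n = len(r.subnetwork.genes)
            for p in samples:
                assert abs(r.sps_score[p]
                           - (r.sscore_test[p] - r.sscore_control[p])) < 1e-12
                assert 0.0 <= r.sscore_control[p] <= n
                assert 0.0 <= r.sscore_test[p] <= n
                assert abs(r.sps_score[p]) <= n

    def test_pfsnet_limit_equivalence_bitwise(self, rng):
        genes = [f"g{i}" for i in range(40)]
        samples = [f"p{j}" for j in range(12)]
        expr = ExpressionMatrix(genes, samples, np.exp(rng.normal(0, 1, (40, 12))))
        phen = PhenotypeAssignment(frozenset(samples[:6]), frozenset(samples[6:]))
        subs = [Subnetwork(f"s{k}", "P", genes[k], frozenset(genes[k:k + 7]))
                for k in range(0, 35, 7)]
        res_sps = run_spsnet(expr, phen, subs, x=6, theta1=0.2, theta2=0.6)
        res_pfs = run_spsnet(expr, phen, subs, mode="pfsnet", theta1=0.2, theta2=0.6)
        for a, b in zip(res_sps, res_pfs):
            assert a.sps_score == b.sps_score  # bitwise
            assert a.t_statistic == b.t_statistic
            assert a.p_value == b.p_value

    def test_beta_monotone_in_representative_fuzzy_score(self, worked_example):
        """Raising a representative patient's fuzzy score for a gene cannot
        lower that side's relevance factor for the gene."""
        expr, phen, sub = worked_example
        fz = gfs_transform(expr, 1 / 3, 2 / 3)
        control = phen.ordered_control(expr)
        votes = vote_vector(fz, sub, control)
        reps = select_representatives(votes, control, 2)
        beta_before = relevance_factor(fz, "g0", list(reps))
        bumped = fz.scores.copy()
        bumped[expr.gene_index("g0"), expr.sample_index(reps[0])] = 1.0
        fz2 = FuzzyMatrix(fz.genes, fz.samples, bumped, fz.theta1, fz.theta2)
        assert relevance_factor(fz2, "g0", list(reps)) >= beta_before

    def test_small_phenotype_rejected_and_x_clamped(self, rng, caplog):
        genes = [f"g{i}" for i in range(10)]
        samples = [f"p{j}" for j in range(6)]
        expr = ExpressionMatrix(genes, samples, np.exp(rng.normal(0, 1, (10, 6))))
        subs = [Subnetwork("s", "P", "g0", frozenset(genes[:5]))]
        tiny = PhenotypeAssignment(frozenset(samples[:2]), frozenset(samples[2:]))
        with pytest.raises(ValueError, match="at least 3"):
            run_spsnet(expr, tiny, subs)
        ok = PhenotypeAssignment(frozenset(samples[:3]), frozenset(samples[3:]))
        import logging
        with caplog.at_level(logging.WARNING, logger="spsnet.scoring"):
            run_spsnet(expr, ok, subs, x=10, theta1=0.2, theta2=0.6)
        assert any("clamp" in r.message for r in caplog.records)

    def test_permutation_null_agrees_with_t_null_direction(self, rng):
        """Permutation p-values for whole-phenotype scoring rank subnetworks
        consistently with the theoretical t null on a shifted fixture."""
        from spsnet.scoring import pfsnet_permutation_pvalues

        genes = [f"g{i}" for i in range(40)]
        samples = [f"p{j}" for j in range(12)]
        values = np.exp(rng.normal(0, 1, (40, 12)))
        values[:6, 6:] *= 8.0  # strong shift for the first subnetwork's genes
        expr = ExpressionMatrix(genes, samples, values)
        phen = PhenotypeAssignment(frozenset(samples[:6]), frozenset(samples[6:]))
        subs = [Subnetwork(f"s{k}", "P", genes[k * 6], frozenset(genes[k * 6:(k + 1) * 6]))
                for k in range(4)]
        pvals = pfsnet_permutation_pvalues(expr, phen, subs, n_permutations=99,
                                           seed=3, theta1=0.2, theta2=0.6)
        t_res = run_spsnet(expr, phen, subs, mode="pfsnet", theta1=0.2, theta2=0.6)
        assert pvals["s0"] <= min(pvals.values())
        assert min(t_res, key=lambda r: r.p_value).subnetwork.id == "s0"
        assert all(0 < p <= 1 for p in pvals.values())

    def test_null_data_rarely_significant(self):
        """Duplicated phenotypes: significance no more often than chance."""
        r = np.random.default_rng(99)
        genes = [f"g{i}" for i in range(300)]
        half = np.exp(r.normal(0, 1, (300, 10)))
        values = np.hstack([half, half * (1 + 1e-9 * r.random((300, 10)))])
        samples = [f"c{j}" for j in range(10)] + [f"t{j}" for j in range(10)]
        expr = ExpressionMatrix(genes, samples, values)
        phen = PhenotypeAssignment(frozenset(samples[:10]), frozenset(samples[10:]))
        subs = [Subnetwork(f"s{k}", "P", genes[k * 6], frozenset(genes[k * 6:(k + 1) * 6]))
                for k in range(50)]
        results = run_spsnet(expr, phen, subs, theta1=0.2, theta2=0.6, x=10)
        frac = np.mean([rr.significant for rr in results])
        assert frac <= 0.10
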