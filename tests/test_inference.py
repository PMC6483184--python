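"""Beta-binomial MLE and the ensemble comparison statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from langshift import (
    BetaBinomialModel,
    EnsembleNormalFit,
    SpeakerCounts,
    betabinom_loglik,
    ensemble_interval,
    fit_betabinom_mle,
    joint_tail_probability,
    overlap_fit_check,
    select_min_mse,
)
from langshift.synthetic import CorpusSpec, generate_speaker_counts


def _counts(pairs, year=1993):
    return SpeakerCounts(
        pd.DataFrame(
            [(f"s{i}", year, n, x) for i, (n, x) in enumerate(pairs)],
            columns=SpeakerCounts.COLUMNS,
        )
    )


class TestSpeakerCounts:
    def test_invalid_rows_rejected(self):
        with pytest.raises(ValueError):
            _counts([(5, 6)])  # novel > tokens
        with pytest.raises(ValueError):
            _counts([(0, 0)])  # no tokens

    def test_pooled_proportion(self):
        counts = _counts([(10, 2), (10, 3)])
        assert counts.pooled_proportion() == pytest.approx(0.25)


class TestLoglik:
    def test_single_bernoulli_uniform_beta(self):
        counts = _counts([(1, 1)])
        assert betabinom_loglik(counts, 1.0, 1.0) == pytest.approx(np.log(0.5))

    def test_single_bernoulli_closed_form(self):
        counts = _counts([(1, 1)])
        a, b = 2.3, 5.7
        assert betabinom_loglik(counts, a, b) == pytest.approx(np.log(a / (a + b)))

    def test_nonpositive_shapes_rejected(self):
        with pytest.raises(ValueError):
            betabinom_loglik(_counts([(3, 1)]), 0.0, 1.0)

    @pytest.mark.parametrize("alpha,beta", [(0.7, 1.9), (4.0, 4.0), (12.0, 2.5)])
    def test_matches_quadrature_oracle(self, alpha, beta):
        """The marginal likelihood equals the binomial integrated against the
        beta density (numerical quadrature, independent of the log-gamma path)."""
        rng = np.random.default_rng(0)
        pairs = [(int(n), int(x)) for n, x in
                 zip(rng.integers(1, 15, 6), rng.integers(0, 4, 6))]
        pairs = [(n, min(x, n)) for n, x in pairs]
        counts = _counts(pairs)
        expected = 0.0
        for n, x in pairs:
            f = lambda q: stats.binom.pmf(x, n, q) * stats.beta.pdf(q, alpha, beta)
            val, _ = integrate.quad(f, 0.0, 1.0, epsabs=1e-13, limit=200)
            expected += np.log(val)
        assert betabinom_loglik(counts, alpha, beta) == pytest.approx(
            expected, abs=1e-8
        )

    def test_matches_scipy_betabinom(self):
        counts = _counts([(12, 3), (7, 0), (20, 11)])
        a, b = 1.8, 6.2
        n, x = counts.arrays()
        expected = stats.betabinom.logpmf(x, n, a, b).sum()
        assert betabinom_loglik(counts, a, b) == pytest.approx(expected, abs=1e-10)


class TestFit:
    def test_all_zero_counts_boundary(self):
        res = fit_betabinom_mle(_counts([(10, 0), (8, 0), (12, 0)]), bootstrap_reps=0)
        assert res.boundary and res.mean == 0.0

    def test_all_saturated_counts_boundary(self):
        res = fit_betabinom_mle(_counts([(10, 10), (8, 8)]), bootstrap_reps=0)
        assert res.boundary and res.mean == 1.0

    def test_mirror_symmetric_counts_give_half(self):
        pairs = [(10, 3), (10, 7), (20, 5), (20, 15), (8, 4)]
        res = fit_betabinom_mle(_counts(pairs), bootstrap_reps=0)
        assert res.mean == pytest.approx(0.5, abs=1e-3)

    def test_recovery_on_synthetic_corpus(self):
        counts = generate_speaker_counts(
            CorpusSpec.single(
                year=1993, n_speakers=200, tokens=20, mean=0.2, concentration=10.0
            ),
            seed=5,
        )
        res = BetaBinomialModel(counts).fit(bootstrap_reps=100, seed=1)
        assert res.ci_lo <= 0.2 <= res.ci_hi
        assert abs(res.mean - 0.2) < 0.04
        assert res.ci_lo <= res.mean <= res.ci_hi

    def test_summary_mentions_key_quantities(self):
        res = fit_betabinom_mle(_counts([(10, 3), (12, 2), (9, 4)]), bootstrap_reps=50,
                                seed=0)
        text = res.summary()
        assert "mean usage" in text and "95% CI" in text


class TestEnsembleInterval:
    def test_constant_values(self):
        assert ensemble_interval([0.3, 0.3, 0.3]) == (0.3, 0.3, 0.3)

    def test_two_point_values(self):
        m, lo, hi = ensemble_interval([0.0, 1.0])
        half = 1.96 * np.sqrt(0.5)
        assert (m, lo, hi) == pytest.approx((0.5, 0.5 - half, 0.5 + half))

    def test_normal_draws_recover_quantiles(self):
        v = np.random.default_rng(2).normal(size=10_000)
        m, lo, hi = ensemble_interval(v)
        assert abs(lo - (-1.96)) < 0.05 and abs(hi - 1.96) < 0.05

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            ensemble_interval([0.5])


def _fit(moments):
    return EnsembleNormalFit({int(y): (m, s) for y, (m, s) in moments.items()})


class TestOverlapCheck:
    def test_mle_at_ensemble_mean_passes(self):
        fit = _fit({1993: (0.1, 0.02), 2007: (0.2, 0.02)})
        assert overlap_fit_check(fit, {1993: 0.1, 2007: 0.2})

    def test_one_distant_year_fails(self):
        fit = _fit({1993: (0.1, 0.02), 2007: (0.2, 0.02)})
        assert not overlap_fit_check(fit, {1993: 0.1, 2007: 0.2 + 2.5 * 0.02})

    def test_year_order_irrelevant(self):
        fit = _fit({1993: (0.1, 0.02), 2007: (0.2, 0.02)})
        pts = {2007: 0.21, 1993: 0.09}
        assert overlap_fit_check(fit, pts) == overlap_fit_check(
            fit, dict(reversed(pts.items()))
        )

    def test_missing_year_raises(self):
        with pytest.raises(KeyError):
            overlap_fit_check(_fit({1993: (0.1, 0.02)}), {2007: 0.2})


class TestMinMse:
    def test_hand_computed_mses(self):
        mle = {1: 0.1, 2: 0.2}
        cands = {
            0.01: _fit({1: (0.2, 1), 2: (0.2, 1)}),    # mse 0.005
            0.02: _fit({1: (0.14, 1), 2: (0.22, 1)}),  # mse 0.001
            0.03: _fit({1: (0.3, 1), 2: (0.4, 1)}),    # mse 0.04
        }
        best, mse = select_min_mse(cands, mle)
        assert best == 0.02 and mse == pytest.approx(0.001)

    def test_exact_match_always_selected(self):
        mle = {1: 0.1, 2: 0.2}
        cands = {
            0.05: _fit({1: (0.1, 1), 2: (0.2, 1)}),
            0.01: _fit({1: (0.11, 1), 2: (0.2, 1)}),
        }
        assert select_min_mse(cands, mle)[0] == 0.05

    def test_tie_breaks_to_smaller_setting(self):
        mle = {1: 0.1}
        same = {0.02: _fit({1: (0.15, 1)}), 0.01: _fit({1: (0.05, 1)})}
        assert select_min_mse(same, mle)[0] == 0.01

    def test_empty_candidates_rejected(self):
        with pytest.raises(ValueError):
            select_min_mse({}, {1: 0.1})


class TestJointTailProbability:
    def test_mle_at_means_gives_one(self):
        fit = _fit({1993: (0.1, 0.01), 2007: (0.2, 0.01)})
        assert joint_tail_probability(fit, {1993: 0.1, 2007: 0.2}) == pytest.approx(1.0)

    def test_z_196_both_years(self):
        fit = _fit({1: (0.0, 1.0), 2: (0.0, 1.0)})
        p = joint_tail_probability(fit, {1: 1.959964, 2: 1.959964})
        assert p == pytest.approx(0.0025, abs=1e-4)

    def test_z_one_and_zero(self):
        fit = _fit({1: (0.0, 1.0), 2: (0.0, 1.0)})
        p = joint_tail_probability(fit, {1: 1.0, 2: 0.0})
        assert p == pytest.approx(0.3173, abs=1e-3)

    def test_monotone_in_distance(self):
        fit = _fit({1: (0.0, 1.0)})
        ps = [joint_tail_probability(fit, {1: z}) for z in (0.0, 0.5, 1.0, 2.0, 3.0)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert all(0 < p <= 1 for p in ps)

    def test_one_sided_is_half_of_two_sided(self):
        fit = _fit({1: (0.0, 1.0)})
        two = joint_tail_probability(fit, {1: 1.3}, tails="two")
        one = joint_tail_probability(fit, {1: 1.3}, tails="one")
        assert two == pytest.approx(2 * one)

    def test_degenerate_spread_rejected(self):
        with pytest.raises(ValueError):
            joint_tail_probability(_fit({1: (0.1, 0.0)}), {1: 0.2})
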