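"""JZS Bayes factors against independent oracles; labels; bootstrap CIs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from camosim.bayes import (
    DEFAULT_PRIOR_SCALE,
    DegenerateDataError,
    bootstrap_group_ci,
    classify_evidence,
    jzs_bf_from_t,
    jzs_bf_one_sample,
    jzs_bf_paired,
)


def grid_oracle_bf(t: float, n: int, r: float = DEFAULT_PRIOR_SCALE) -> float:
    """Brute-force trapezoid integration of the JZS marginal likelihood ratio.

    Independent of the package's adaptive quadrature: integrates the
    noncentral-t likelihood against the Cauchy effect-size prior on a dense
    fixed grid wide enough to capture the posterior mass at |t| <= 8.
    """
    nu = n - 1
    delta = np.linspace(-60.0, 60.0, 120_001)
    like = stats.nct.pdf(t, nu, delta * np.sqrt(n))
    prior = stats.cauchy.pdf(delta, 0.0, r)
    m1 = np.trapezoid(like * prior, delta)
    return float(m1 / stats.t.pdf(t, nu))


class TestJZS:
    @pytest.mark.parametrize(
        "t, n", [(0.0, 26), (1.5, 5), (2.0, 26), (3.0, 100), (4.2, 26)]
    )
    def test_matches_grid_oracle_to_four_sig_figs(self, t, n):
        mine = jzs_bf_from_t(t, n)
        oracle = grid_oracle_bf(t, n)
        assert mine == pytest.approx(oracle, rel=5e-4)

    @pytest.mark.parametrize("n", [3, 5, 26, 100])
    def test_null_t_favours_the_null(self, n):
        assert jzs_bf_from_t(0.0, n) < 1.0

    def test_strictly_increasing_in_t(self):
        ts = np.linspace(0, 6, 13)
        bfs = [jzs_bf_from_t(t, 26) for t in ts]
        assert np.all(np.diff(bfs) > 0)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        for t, n in [(0.0, 26), (2.5, 26), (4.0, 10)]:
            theirs = float(
                pingouin.bayesfactor_ttest(t, n, paired=True, r=DEFAULT_PRIOR_SCALE)
            )
            assert jzs_bf_from_t(t, n) == pytest.approx(theirs, rel=1e-8)

    def test_larger_n_at_proportional_t_increases_evidence(self):
        # same standardised effect observed with more data: oracle comparison
        d = 0.6
        bf_small = grid_oracle_bf(d * np.sqrt(13), 13)
        bf_large = grid_oracle_bf(d * np.sqrt(26), 26)
        assert bf_large > bf_small
        assert jzs_bf_from_t(d * np.sqrt(26), 26) > jzs_bf_from_t(d * np.sqrt(13), 13)

    def test_one_sided_doubles_evidence_for_positive_effects(self):
        two = jzs_bf_from_t(3.0, 26)
        one = jzs_bf_from_t(3.0, 26, one_sided=True)
        assert two < one < 2 * two + 1e-9
        assert jzs_bf_from_t(-3.0, 26, one_sided=True) < 0.1


class TestPairedAndOneSample:
    def test_paired_on_synthetic_effect_matches_oracle(self):
        rng = np.random.default_rng(1)
        d = rng.normal(0.8, 1.0, 26)  # effect size d = 0.8
        x = np.zeros(26) + d
        y = np.zeros(26)
        res = jzs_bf_paired(x, y)
        t = d.mean() / (d.std(ddof=1) / np.sqrt(26))
        assert res.t_stat == pytest.approx(t)
        assert res.bf10 == pytest.approx(grid_oracle_bf(t, 26), rel=5e-4)

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(1.2, 0.1, 20), rng.normal(1.1, 0.1, 20)
        a = jzs_bf_paired(x, y).bf10
        b = jzs_bf_paired(1000 * x, 1000 * y).bf10
        assert a == pytest.approx(b, rel=1e-9)

    def test_zero_variance_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            jzs_bf_paired(np.ones(20), np.ones(20))
        with pytest.raises(DegenerateDataError):
            jzs_bf_one_sample(np.full(10, 1.0), mu0=1.0)

    def test_one_sample_against_baseline(self):
        rng = np.random.default_rng(3)
        x = rng.normal(1.12, 0.05, 26)  # all thresholds well above baseline
        res = jzs_bf_one_sample(x, mu0=1.0)
        assert res.bf10 > 100
        assert "extreme" in res.evidence_label

    def test_mismatched_lengths(self):
        with pytest.raises(ValueError):
            jzs_bf_paired(np.ones(5), np.ones(6))


class TestEvidenceLabels:
    @pytest.mark.parametrize(
        "bf, expected",
        [
            (21.375, "strong evidence for H1"),
            (181.107, "extreme evidence for H1"),
            (86.509, "very strong evidence for H1"),
            (1.0, "no evidence"),
            (2.0, "anecdotal evidence for H1"),
            (3.0, "anecdotal evidence for H1"),
            (3.0001, "moderate evidence for H1"),
            (10.0, "moderate evidence for H1"),
            (30.0, "strong evidence for H1"),
            (100.0, "very strong evidence for H1"),
            (0.5, "anecdotal evidence for H0"),
            (1 / 40, "very strong evidence for H0"),
            (1e-4, "extreme evidence for H0"),
        ],
    )
    def test_band_mapping(self, bf, expected):
        assert classify_evidence(bf) == expected

    @pytest.mark.parametrize("bad", [0.0, -2.0, np.inf, np.nan])
    def test_invalid_inputs(self, bad):
        with pytest.raises(ValueError):
            classify_evidence(bad)


class TestBootstrap:
    def make_table(self, rng, n=26):
        return pd.DataFrame(
            {
                "a": rng.normal(1.1, 0.05, n),
                "b": np.full(n, 1.2),
            }
        )

    def test_constant_column_zero_width(self):
        rng = np.random.default_rng(0)
        summary = bootstrap_group_ci(self.make_table(rng), n_resamples=2000, seed=1)
        row = summary.table.loc["b"]
        assert row["ci_lo"] == pytest.approx(row["ci_hi"], abs=1e-12)
        assert row["mean"] == pytest.approx(1.2)

    def test_ci_brackets_mean_and_is_deterministic(self):
        rng = np.random.default_rng(5)
        tab = self.make_table(rng)
        s1 = bootstrap_group_ci(tab, n_resamples=2000, seed=9)
        s2 = bootstrap_group_ci(tab, n_resamples=2000, seed=9)
        pd.testing.assert_frame_equal(s1.table, s2.table)
        row = s1.table.loc["a"]
        assert row["ci_lo"] <= row["mean"] <= row["ci_hi"]

    def test_coverage_of_true_mean(self):
        """Percentile bootstrap of a Normal(0,1) mean covers 0 ~95% of the time."""
        rng = np.random.default_rng(11)
        hits = 0
        reps = 400
        for _ in range(reps):
            tab = pd.DataFrame({"x": rng.normal(0, 1, 26)})
            t = bootstrap_group_ci(tab, n_resamples=2000, seed=rng).table.loc["x"]
            hits += t["ci_lo"] <= 0 <= t["ci_hi"]
        assert hits / reps >= 0.90

    def test_preconditions(self):
        rng = np.random.default_rng(2)
        with pytest.raises(ValueError):
            bootstrap_group_ci(self.make_table(rng, n=4))
        with pytest.raises(ValueError):
            bootstrap_group_ci(self.make_table(rng), n_resamples=10)
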