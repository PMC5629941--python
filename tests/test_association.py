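"""Logistic engine, LRT omnibus test, PCs, onset regression, Wilcoxon."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats
from scipy.special import expit

from mhcmap.association import (
    compute_pcs,
    conditional_association,
    fit_logistic,
    likelihood_ratio_test,
    omnibus_association,
    onset_linear_association,
    wald_log10_p,
    wilcoxon_rank_sum,
)
from mhcmap.catalog import AA_RESIDUE, SNP, DosageMatrix, Marker, group_markers


def _design(*cols):
    return np.column_stack([np.ones(len(cols[0]))] + list(cols))


class TestFitLogistic:
    def test_intercept_only_balanced(self):
        y = np.repeat([0.0, 1.0], 50)
        fit = fit_logistic(y, np.ones((100, 1)), names=["intercept"])
        assert fit.converged
        assert fit.params[0] == pytest.approx(0.0, abs=1e-9)
        assert fit.llf == pytest.approx(100 * math.log(0.5), rel=1e-12)

    def test_two_by_two_closed_form_odds_ratio(self):
        # exposed cases 20, unexposed cases 10, exposed controls 10,
        # unexposed controls 20 -> OR = (20*20)/(10*10) = 4
        y = np.array([1.0] * 30 + [0.0] * 30)
        x = np.array([1.0] * 20 + [0.0] * 10 + [1.0] * 10 + [0.0] * 20)
        fit = fit_logistic(y, _design(x), names=["intercept", "x"])
        assert math.exp(fit.coef("x")) == pytest.approx(4.0, rel=1e-7)

    def test_matches_generic_optimizer_maximum(self, rng):
        n = 50
        X = _design(rng.normal(size=n), rng.normal(size=n))
        beta_true = np.array([-0.3, 0.8, -0.5])
        y = (rng.random(n) < expit(X @ beta_true)).astype(float)

        def negll(b):
            eta = X @ b
            return -(y * eta - np.logaddexp(0, eta)).sum()

        res = optimize.minimize(negll, np.zeros(3), method="BFGS",
                                options={"gtol": 1e-10})
        fit = fit_logistic(y, X)
        assert fit.llf == pytest.approx(-res.fun, abs=1e-6)

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        n = 400
        X = _design(rng.binomial(2, 0.3, n).astype(float), rng.normal(size=n))
        y = (rng.random(n) < expit(0.2 + 0.5 * X[:, 1] - 0.3 * X[:, 2])).astype(float)
        ref = sm.Logit(y, X).fit(disp=0)
        fit = fit_logistic(y, X)
        np.testing.assert_allclose(fit.params, ref.params, atol=1e-6)
        np.testing.assert_allclose(fit.bse, ref.bse, rtol=1e-4)
        assert fit.llf == pytest.approx(ref.llf, abs=1e-8)

    def test_collinear_column_dropped_with_warning(self, rng):
        x = rng.normal(size=80)
        y = (rng.random(80) < 0.5).astype(float)
        X = _design(x, 2 * x)
        with pytest.warns(UserWarning, match="collinear"):
            fit = fit_logistic(y, X, names=["intercept", "x", "x2"])
        assert len(fit.dropped) == 1
        assert len(fit.names) == 2

    def test_constant_outcome_raises(self):
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(np.ones(20), np.ones((20, 1)))

    def test_missing_rows_deleted_listwise(self, rng):
        x = rng.normal(size=60)
        y = (rng.random(60) < 0.5).astype(float)
        x_miss = x.copy()
        x_miss[:10] = np.nan
        fit = fit_logistic(y, _design(x_miss))
        ref = fit_logistic(y[10:], _design(x[10:]))
        assert fit.n_used == 50
        np.testing.assert_allclose(fit.params, ref.params, atol=1e-10)

    def test_separation_flagged(self):
        y = np.repeat([0.0, 1.0], 20)
        x = y.copy()  # perfect separation
        fit = fit_logistic(y, _design(x), names=["intercept", "x"])
        assert "x" in fit.quasi_separated


class TestLikelihoodRatioTest:
    def _fit(self, llf):
        from mhcmap.association import FitResult

        return FitResult(names=[], params=np.array([]), bse=np.array([]),
                         llf=llf, converged=True, n_used=10)

    def test_identical_likelihoods_give_p_one(self):
        assert likelihood_ratio_test(self._fit(-12.0), self._fit(-12.0), 1) == 0.0

    def test_known_chi_square_quantile(self):
        # deviance 3.841 on 1 df is the 0.95 quantile -> p = 0.05
        lp = likelihood_ratio_test(self._fit(0.0), self._fit(3.841 / 2), 1)
        assert 10**lp == pytest.approx(0.05, rel=1e-3)

    def test_negative_deviance_raises(self):
        with pytest.raises(ValueError, match="nested"):
            likelihood_ratio_test(self._fit(0.0), self._fit(-1.0), 1)

    def test_tiny_negative_deviance_clamped(self):
        assert likelihood_ratio_test(self._fit(0.0), self._fit(-1e-10), 1) == 0.0

    def test_extreme_deviance_survives_on_log_scale(self):
        lp = likelihood_ratio_test(self._fit(0.0), self._fit(200.0), 1)
        assert -90 < lp < -80  # p ~ 1e-88, well past double underflow of exp

    def test_null_calibration_small(self, rng):
        # no-effect data: LRT p-values should be uniform (quick screen at
        # 200 replicates; the full 2000-replicate KS check runs in the
        # acceptance suite)
        hits = 0
        for _ in range(200):
            X = _design(rng.normal(size=120))
            y = (rng.random(120) < 0.5).astype(float)
            full = fit_logistic(y, X)
            null = fit_logistic(y, X[:, :1])
            if 10 ** likelihood_ratio_test(null, full, 1) < 0.05:
                hits += 1
        assert 1 <= hits <= 25


def _residue_cohort(rng, n, freqs, betas, intercept=-0.5):
    """Multinomial residue diplotypes + logistic outcome; returns dm, y."""
    labels = list(freqs)
    p = np.array([freqs[l] for l in labels])
    p = p / p.sum()
    draws = rng.choice(len(labels), size=(n, 2), p=p)
    dosage = np.zeros((n, len(labels)))
    for hap in range(2):
        np.add.at(dosage, (np.arange(n), draws[:, hap]), 1.0)
    markers = [Marker(f"AA_B_97_{l}", AA_RESIDUE, "B_97", l) for l in labels]
    dm = DosageMatrix(markers=markers, samples=[f"s{i}" for i in range(n)],
                      dosage=dosage)
    eta = intercept + sum(
        betas.get(l, 0.0) * dosage[:, j] for j, l in enumerate(labels)
    )
    y = pd.Series((rng.random(n) < expit(eta)).astype(float), index=dm.samples)
    return dm, y


TABLE_FREQS = {"R": 0.4619, "S": 0.2785, "T": 0.1003, "V": 0.0751,
               "N": 0.0474, "W": 0.0384}


class TestOmnibus:
    def test_reference_is_most_common_control_residue(self, rng):
        dm, y = _residue_cohort(rng, 3000, TABLE_FREQS, {})
        (group,) = group_markers(dm.markers, dm.allele_frequencies())
        res = omnibus_association(group, dm, y)
        assert res.reference_label == "R"
        assert res.df == 5
        ref_row = res.per_member.iloc[0]
        assert ref_row["label"] == "R" and np.isnan(ref_row["OR"])

    def test_two_residue_group_equals_single_term_lrt(self, rng):
        dm, y = _residue_cohort(rng, 800, {"R": 0.6, "N": 0.4},
                                {"N": math.log(1.8)})
        (group,) = group_markers(dm.markers, dm.allele_frequencies())
        res = omnibus_association(group, dm, y)
        x = dm.column("AA_B_97_N")
        full = fit_logistic(y.to_numpy(), _design(x))
        null = fit_logistic(y.to_numpy(), np.ones((800, 1)))
        assert res.df == 1
        assert res.p_omnibus_log10 == pytest.approx(
            likelihood_ratio_test(null, full, 1), abs=1e-9
        )

    def test_reference_choice_does_not_change_omnibus_p(self, rng):
        dm, y = _residue_cohort(rng, 2000, TABLE_FREQS, {"N": 0.7})
        markers = list(dm.markers)
        (group,) = group_markers(markers, dm.allele_frequencies())
        res = omnibus_association(group, dm, y)
        assert res.reference_label == "R"
        # same model with serine as the excluded member: only the coefficient
        # parameterization changes, the omnibus LRT p must not
        x_cols = [dm.column(m.marker_id) for m in markers if m.label != "S"]
        full = fit_logistic(y.to_numpy(), _design(*x_cols))
        null = fit_logistic(y.to_numpy(), np.ones((2000, 1)))
        alt = likelihood_ratio_test(null, full, 5)
        assert res.p_omnibus_log10 == pytest.approx(alt, abs=1e-8)

    def test_monomorphic_member_dropped_reduces_df(self, rng):
        freqs = dict(TABLE_FREQS)
        dm, y = _residue_cohort(rng, 500, freqs, {})
        # zero out one non-reference residue entirely
        j = dm.marker_ids.index("AA_B_97_W")
        dm.dosage[:, j] = 0.0
        (group,) = group_markers(dm.markers, dm.allele_frequencies())
        res = omnibus_association(group, dm, y)
        assert res.df == 4
        assert "AA_B_97_W" in res.dropped_members

    def test_permutation_oracle_small(self, rng):
        # modest version of the permutation equivalence (the full 10,000-
        # permutation comparison runs in the acceptance suite)
        dm, y = _residue_cohort(rng, 300, {"R": 0.5, "N": 0.3, "S": 0.2},
                                {"N": 0.6})
        (group,) = group_markers(dm.markers, dm.allele_frequencies())
        res = omnibus_association(group, dm, y)
        observed_dev = 2 * (res.fit_full.llf - res.fit_null.llf)
        count = 0
        n_perm = 300
        yv = y.to_numpy()
        x_cols = _design(*[dm.column(m.marker_id)
                           for m in group.members[1:]])
        for _ in range(n_perm):
            yp = rng.permutation(yv)
            full = fit_logistic(yp, x_cols)
            null = fit_logistic(yp, x_cols[:, :1])
            if 2 * (full.llf - null.llf) >= observed_dev:
                count += 1
        p_perm = (count + 1) / (n_perm + 1)
        p_lrt = 10**res.p_omnibus_log10
        se = math.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p_perm - p_lrt) < 3 * se + 0.01


class TestConditional:
    def test_empty_conditioning_set_is_identity(self, rng):
        dm, y = _residue_cohort(rng, 600, TABLE_FREQS, {"N": 0.5})
        (group,) = group_markers(dm.markers, dm.allele_frequencies())
        a = omnibus_association(group, dm, y)
        b = conditional_association(group, dm, y, None, [])
        assert a.p_omnibus_log10 == b.p_omnibus_log10

    def test_self_conditioning_gives_p_one(self, rng):
        dm, y = _residue_cohort(rng, 400, TABLE_FREQS, {"N": 0.5})
        (group,) = group_markers(dm.markers, dm.allele_frequencies())
        res = conditional_association(group, dm, y, None, [group])
        assert res.self_conditioned
        assert res.p_omnibus_log10 == 0.0

    def test_orthogonal_groups_do_not_move_each_other(self, rng):
        # two independent planted effects; conditioning on one changes the
        # other's log10 p by < 0.5
        n = 2000
        g1 = rng.binomial(2, 0.3, n).astype(float)
        g2 = rng.binomial(2, 0.4, n).astype(float)
        y = pd.Series(
            (rng.random(n) < expit(-0.2 + 0.5 * g1 + 0.4 * g2)).astype(float),
            index=[f"s{i}" for i in range(n)],
        )
        markers = [Marker("m1", SNP, "m1", "alt"), Marker("m2", SNP, "m2", "alt")]
        dm = DosageMatrix(markers=markers, samples=list(y.index),
                          dosage=np.column_stack([g1, g2]))
        grp1, grp2 = group_markers(markers, dm.allele_frequencies())
        marginal = omnibus_association(grp1, dm, y)
        conditioned = conditional_association(grp1, dm, y, None, [grp2])
        assert abs(marginal.p_omnibus_log10 - conditioned.p_omnibus_log10) < 0.5


class TestComputePcs:
    def test_recovers_two_subpopulations(self, rng):
        n, m = 600, 50
        labels = np.repeat([0, 1], n // 2)
        base = rng.uniform(0.1, 0.35, size=m)
        shift = np.where(labels[:, None] == 1, 0.2, 0.0)
        dosage = rng.binomial(2, np.clip(base + shift, 0, 1)).astype(float)
        pcs = compute_pcs(dosage, k=2)
        r = np.corrcoef(pcs[:, 0], labels)[0, 1]
        assert abs(r) > 0.9

    def test_sign_convention_deterministic(self, rng):
        dosage = rng.binomial(2, 0.4, size=(200, 30)).astype(float)
        a = compute_pcs(dosage, k=2)
        b = compute_pcs(dosage.copy(), k=2)
        np.testing.assert_allclose(a, b)

    def test_identical_rows_raise(self):
        with pytest.raises(ValueError, match="zero variance"):
            compute_pcs(np.ones((50, 10)), k=2)


class TestOnsetLinear:
    def test_closed_form_slope_and_se(self):
        dosage = np.array([0, 0, 0, 1, 1, 1, 1, 2, 2, 2], dtype=float)
        onset = np.array([40, 35, 38, 30, 28, 33, 27, 20, 24, 18], dtype=float)
        fit, log10_p = onset_linear_association(onset, dosage)
        # hand OLS: slope = Sxy/Sxx, SE = sqrt(RSS/(n-2)/Sxx)
        xbar, ybar = dosage.mean(), onset.mean()
        sxx = ((dosage - xbar) ** 2).sum()
        slope = ((dosage - xbar) * (onset - ybar)).sum() / sxx
        resid = onset - (ybar + slope * (dosage - xbar))
        se = math.sqrt((resid**2).sum() / (len(onset) - 2) / sxx)
        assert fit.coef("dosage") == pytest.approx(slope, rel=1e-10)
        assert fit.se("dosage") == pytest.approx(se, rel=1e-10)
        t = slope / se
        p = 2 * stats.t.sf(abs(t), len(onset) - 2)
        assert 10**log10_p == pytest.approx(p, rel=1e-9)

    def test_null_slope_within_three_se(self, rng):
        n = 5000
        dosage = rng.binomial(2, 0.3, n).astype(float)
        onset = rng.normal(30, 10, n)
        fit, log10_p = onset_linear_association(onset, dosage)
        assert abs(fit.coef("dosage")) < 3 * fit.se("dosage")

    def test_zero_variance_dosage_raises(self):
        with pytest.raises(ValueError, match="zero variance"):
            onset_linear_association(np.array([20.0, 30.0]), np.array([1.0, 1.0]))


class TestWilcoxon:
    def test_identical_samples(self):
        p, diff = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0 and diff == 0.0

    def test_exact_enumeration_three_vs_three(self):
        # all C(6,3) = 20 rank assignments; only the two extreme splits give
        # rank sums as extreme as {1,2,3} vs {4,5,6} -> p = 2/20
        p, diff = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, rel=1e-12)
        assert diff == 3.0

    def test_large_sample_uses_normal_approximation(self, rng):
        a = rng.normal(0, 1, 200)
        b = rng.normal(0.5, 1, 200)
        p, diff = wilcoxon_rank_sum(a, b)
        assert p < 1e-4 and diff > 0

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError, match="nonempty"):
            wilcoxon_rank_sum([], [1.0])


def test_wald_log10_p_matches_normal_tail():
    assert 10 ** wald_log10_p(1.96, 1.0) == pytest.approx(0.05, rel=2e-2)
    assert wald_log10_p(30.0, 1.0) < -190  # far below naive underflow


class TestScanInvariants:
    def test_orthogonal_covariate_barely_moves_log10p(self, rng):
        n = 8000
        dm, y = _residue_cohort(rng, n, {"R": 0.6, "N": 0.4},
                                {"N": math.log(1.6)})
        (group,) = group_markers(dm.markers, dm.allele_frequencies())
        plain = omnibus_association(group, dm, y)
        noise_cov = pd.DataFrame({"z": rng.normal(size=n)}, index=list(y.index))
        with_cov = omnibus_association(group, dm, y, covariates=noise_cov)
        assert abs(plain.p_omnibus_log10 - with_cov.p_omnibus_log10) < 0.1

    def test_wald_and_lrt_agree_for_biallelic_marker(self, rng):
        n = 2000
        x = rng.binomial(2, 0.3, n).astype(float)
        y_vals = (rng.random(n) < expit(-0.2 + 0.35 * x)).astype(float)
        markers = [Marker("snp", SNP, "snp", "alt")]
        dm = DosageMatrix(markers=markers,
                          samples=[f"s{i}" for i in range(n)],
                          dosage=x[:, None])
        y = pd.Series(y_vals, index=dm.samples)
        (group,) = group_markers(markers, dm.allele_frequencies())
        res = omnibus_association(group, dm, y)
        wald = res.per_member.iloc[0]["log10_p"]
        assert res.df == 1
        assert abs(wald - res.p_omnibus_log10) < 0.1 * abs(res.p_omnibus_log10)
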