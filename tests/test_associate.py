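"""Association models: age groups, censored-level model, count trend,
disease ORs, BH correction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from t1dglyco.associate import (
    assign_age_group,
    bh_adjust,
    disease_association,
    fit_autoantibody_count_model,
    fit_censored_autoantibody_model,
    fit_sex_age_model,
)
from t1dglyco.tables import SampleMetadata


def make_metadata(n, rng, sexes=None, ages=None, status=None, families=None):
    return SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": [f"S{i}" for i in range(n)],
                "family_id": families if families is not None else [f"F{i}" for i in range(n)],
                "sex": sexes if sexes is not None else rng.choice(["F", "M"], n),
                "age": ages if ages is not None else rng.uniform(1, 19, n),
                "status": status if status is not None else rng.integers(0, 2, n),
                "batch": "b1",
            }
        )
    )


class TestAgeGroups:
    @pytest.mark.parametrize(
        "age,sex,expected",
        [
            (4.2, "F", "child"),
            (8.8, "F", "pre-pubertal"),
            (12.6, "F", "pubertal"),
            (16.0, "F", "post-pubertal"),
            (4.0, "M", "child"),
            (10.3, "M", "pre-pubertal"),
            (14.3, "M", "pubertal"),
            (17.4, "M", "post-pubertal"),
        ],
    )
    def test_sex_specific_boundaries(self, age, sex, expected):
        assert assign_age_group(age, sex) == expected

    def test_rejects_nonpositive_age(self):
        with pytest.raises(ValueError):
            assign_age_group(0.0, "F")


class TestSexAgeModel:
    def test_contrast_count_full_design(self, rng):
        n = 400
        meta = make_metadata(n, rng)
        res = fit_sex_age_model(rng.normal(size=n), meta)
        # 2 sexes x C(4,2) age pairs + 4 age groups x 1 sex pair
        assert len(res.contrasts) == 2 * 6 + 4

    def test_single_age_group_emits_only_sex_contrasts(self, rng):
        n = 60
        meta = make_metadata(n, rng, ages=np.full(n, 3.0))  # all "child"
        res = fit_sex_age_model(rng.normal(size=n), meta)
        assert len(res.contrasts) == 1
        assert set(res.contrasts["group1"]) == {"F/child"}

    def test_null_rejection_rate_controlled(self, rng):
        rejections, total = 0, 0
        for _ in range(100):
            n = 240
            meta = make_metadata(n, rng)
            res = fit_sex_age_model(rng.normal(size=n), meta)
            rejections += (res.contrasts["q"] < 0.05).sum()
            total += len(res.contrasts)
        assert rejections / total <= 0.05 + 2.58 * np.sqrt(0.05 * 0.95 / total)

    def test_sex_effect_detected_in_every_age_group(self, rng):
        n = 800
        meta = make_metadata(n, rng)
        male = (meta.table["sex"] == "M").to_numpy()
        y = rng.normal(size=n) + 0.5 * male
        res = fit_sex_age_model(y, meta)
        between_sex = res.contrasts[
            res.contrasts["group1"].str.split("/").str[1]
            == res.contrasts["group2"].str.split("/").str[1]
        ]
        assert len(between_sex) == 4
        assert (between_sex["q"] < 0.05).all()

    def test_empty_cell_rejected(self, rng):
        n = 40
        ages = np.r_[np.full(20, 3.0), np.full(20, 8.0)]
        sexes = np.r_[["F"] * 20, ["M"] * 20]  # no F in pre-pubertal cell
        meta = make_metadata(n, rng, sexes=sexes, ages=ages)
        with pytest.raises(ValueError, match="cell"):
            fit_sex_age_model(rng.normal(size=n), meta)


class TestCensoredModel:
    def simulate(self, rng, n=300, b0=0.0, b1=0.59, b2=0.8, loq=2.0, noise=0.3):
        c = rng.lognormal(0.5, 0.6, size=n)
        I = c < loq
        y = b0 + np.where(I, b1 * c, b2) + rng.normal(0, noise, n)
        recorded = np.minimum(c, loq)
        return y, recorded

    def test_parameter_recovery(self, rng):
        b1s, b2s = [], []
        for _ in range(100):
            y, c = self.simulate(rng)
            res = fit_censored_autoantibody_model(y, c, 2.0)
            b1s.append(res.b1)
            b2s.append(res.b2)
        for est, truth in ((b1s, 0.59), (b2s, 0.8)):
            est = np.array(est)
            assert abs(est.mean() - truth) < 3 * est.std(ddof=1) / np.sqrt(len(est))

    def test_no_censoring_collapses_to_plain_regression(self, rng):
        y, c = self.simulate(rng, loq=1e9)
        res = fit_censored_autoantibody_model(y, c, 1e9)
        assert res.b2 is None
        assert res.n_censored == 0
        # oracle: normal-equations solve of the simple regression y ~ c
        X = np.column_stack([np.ones_like(c), c])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        assert res.b0 == pytest.approx(beta[0], abs=1e-10)
        assert res.b1 == pytest.approx(beta[1], abs=1e-10)

    def test_translation_equivariance(self, rng):
        y, c = self.simulate(rng)
        shift = 5.0
        a = fit_censored_autoantibody_model(y, c, 2.0)
        b = fit_censored_autoantibody_model(y, c + shift, 2.0 + shift)
        assert b.b1 == pytest.approx(a.b1, rel=1e-9)
        # b2 measures (effect at LOQ side) relative to the intercept, and the
        # slope branch shifts by b1*shift, so b2 absorbs the difference
        assert b.b2 == pytest.approx(a.b2 + a.b1 * shift, rel=1e-6)

    def test_conventional_direction_flips_indicator(self, rng):
        # fully quantified levels on both sides of the LOQ, so either
        # indicator direction is identifiable
        c = rng.lognormal(0.5, 0.6, size=300)
        y = np.where(c < 2.0, 0.59 * c, 0.8) + rng.normal(0, 0.3, 300)
        up = fit_censored_autoantibody_model(y, c, 2.0, direction="upper")
        lo = fit_censored_autoantibody_model(y, c, 2.0, direction="lower")
        assert up.n_uncensored + up.n_censored == lo.n_uncensored + lo.n_censored
        assert up.b1 != lo.b1


class TestCountModel:
    def test_trend_recovery(self, rng):
        beta_true = -0.93
        ests, ses = [], []
        for _ in range(100):
            n = 300
            count = rng.integers(1, 5, n).astype(float)
            meta = make_metadata(n, rng)
            y = beta_true * count + rng.normal(0, 1, n)
            res = fit_autoantibody_count_model(y, count, meta)
            ests.append(res.effect)
        ests = np.array(ests)
        assert abs(ests.mean() - beta_true) < 3 * ests.std(ddof=1) / np.sqrt(len(ests))

    def test_null_type_one_error(self, rng):
        hits = 0
        reps = 200
        for _ in range(reps):
            n = 120
            count = rng.integers(1, 5, n).astype(float)
            meta = make_metadata(n, rng)
            res = fit_autoantibody_count_model(rng.normal(size=n), count, meta)
            hits += res.p < 0.05
        assert abs(hits / reps - 0.05) < 2.58 * np.sqrt(0.05 * 0.95 / reps)

    def test_single_level_rejected(self, rng):
        meta = make_metadata(20, rng)
        with pytest.raises(ValueError, match="distinct"):
            fit_autoantibody_count_model(rng.normal(size=20), np.full(20, 2.0), meta)


class TestDiseaseAssociation:
    def test_log_odds_recovery_and_ci_coverage(self, rng):
        """Glycan drawn N(0,1), status ~ Bernoulli(expit(0.7*g)): the OR per
        SD is exp(0.7); CIs should cover it ~95% of the time."""
        truth = 0.7
        covered, ests = 0, []
        reps = 150
        for _ in range(reps):
            n = 400
            g = rng.normal(size=n)
            status = (rng.random(n) < 1 / (1 + np.exp(-truth * g))).astype(int)
            meta = make_metadata(n, rng, status=status)
            res = disease_association(g, meta)
            ests.append(np.log(res.effect))
            covered += res.ci_low <= np.exp(truth * g.std()) <= res.ci_high
        ests = np.array(ests)
        assert abs(ests.mean() - truth) < 3 * ests.std(ddof=1) / np.sqrt(reps)
        assert covered / reps > 0.95 - 2.58 * np.sqrt(0.95 * 0.05 / reps) - 0.01

    def test_null_or_centred_on_one(self, rng):
        ests = []
        for _ in range(100):
            n = 200
            meta = make_metadata(n, rng)
            ests.append(np.log(disease_association(rng.normal(size=n), meta).effect))
        ests = np.array(ests)
        assert abs(ests.mean()) < 3 * ests.std(ddof=1) / np.sqrt(len(ests))

    def test_perfect_separation_flagged(self, rng):
        n = 60
        status = np.r_[np.ones(30, int), np.zeros(30, int)]
        meta = make_metadata(n, rng, status=status)
        res = disease_association(status.astype(float) + rng.normal(0, 1e-6, n), meta)
        assert any("separation" in f for f in res.flags)

    def test_cluster_matches_plain_logit_without_family_structure(self, rng):
        """Every sample its own family: point estimates equal plain logistic."""
        import statsmodels.api as sm

        n = 300
        g = rng.normal(size=n)
        status = (rng.random(n) < 1 / (1 + np.exp(-0.5 * g))).astype(int)
        meta = make_metadata(n, rng, status=status)
        res = disease_association(g, meta)
        gz = (g - g.mean()) / g.std(ddof=0)
        X = sm.add_constant(
            np.column_stack(
                [gz, meta.table["age"], (meta.table["sex"] == "M").astype(float)]
            )
        )
        ref = sm.Logit(status, X).fit(disp=0)
        assert np.log(res.effect) == pytest.approx(ref.params[1], abs=1e-3)


class TestBH:
    def test_forced_arithmetic(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_identity(self):
        assert bh_adjust([0.05])[0] == pytest.approx(0.05)

    @given(
        st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=200)
    )
    def test_dominates_p_and_order_preserving(self, ps):
        p = np.asarray(ps)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1 + 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])
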