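"""Penalized mixed logistic discrimination, grouped CV, ROC/AUC, bootstrap."""

import numpy as np
import pandas as pd
import pytest

from t1dglyco.discriminate import (
    EnetMixedSpec,
    compare_auc_bootstrap,
    fit_enet_mixed,
    grouped_kfold_predict,
    roc_auc,
    run_full_vs_null,
)
from t1dglyco.preprocess import run_preprocessing
from t1dglyco.simulate import SimulationConfig, simulate_cohort
from t1dglyco.tables import BatchDesign, PeakTable


def irls_logistic(X, y, max_iter=200, tol=1e-12):
    """Independent oracle: Newton-Raphson logistic regression."""
    Xi = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Xi.shape[1])
    for _ in range(max_iter):
        eta = Xi @ beta
        mu = 1 / (1 + np.exp(-eta))
        w = mu * (1 - mu)
        grad = Xi.T @ (y - mu)
        hess = (Xi * w[:, None]).T @ Xi
        step = np.linalg.solve(hess, grad)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta


def brute_force_auc(scores, labels):
    """Exhaustive concordant-pair counting; ties count 1/2."""
    scores, labels = np.asarray(scores), np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def logistic_data(rng, n=200, p=8, beta_scale=0.6):
    X = rng.normal(size=(n, p))
    X = (X - X.mean(0)) / X.std(0)
    beta = rng.normal(scale=beta_scale, size=p)
    y = (rng.random(n) < 1 / (1 + np.exp(-(X @ beta)))).astype(int)
    return X, y


class TestEnetMixed:
    def test_unpenalized_no_random_effect_matches_irls(self, rng):
        X, y = logistic_data(rng)
        spec = EnetMixedSpec(alpha=0.1, lam=0.0, sigma2=0.0, tol=1e-9)
        m = fit_enet_mixed(X, y, np.arange(len(y)), spec)
        oracle = irls_logistic(X, y)
        assert np.max(np.abs(np.r_[m.intercept, m.coef] - oracle)) < 1e-4

    def test_huge_penalty_shrinks_all_to_zero(self, rng):
        X, y = logistic_data(rng)
        m = fit_enet_mixed(X, y, np.arange(len(y)), EnetMixedSpec(alpha=0.5, lam=50.0, sigma2=0.0))
        assert np.all(m.coef == 0.0)

    def test_unpenalized_columns_escape_shrinkage(self, rng):
        X, y = logistic_data(rng, p=4)
        pen = np.array([True, True, True, False])
        m = fit_enet_mixed(X, y, np.arange(len(y)), EnetMixedSpec(alpha=1.0, lam=50.0, penalized=pen, sigma2=0.0))
        assert np.all(m.coef[:3] == 0.0)
        assert m.coef[3] != 0.0

    def test_objective_nonincreasing(self, rng):
        X, y = logistic_data(rng)
        groups = np.repeat(np.arange(50), 4)
        m = fit_enet_mixed(X, y, groups, EnetMixedSpec(alpha=0.1, lam=1e-3, sigma2=0.5))
        assert np.all(np.diff(m.objective_path) <= 1e-10)

    def test_l1_norm_nonincreasing_in_lambda(self, rng):
        X, y = logistic_data(rng, n=150, p=10)
        norms = []
        for lam in [0.0, 0.01, 0.05, 0.2, 1.0]:
            m = fit_enet_mixed(X, y, np.arange(len(y)), EnetMixedSpec(alpha=0.9, lam=lam, sigma2=0.0))
            norms.append(np.abs(m.coef).sum())
        assert np.all(np.diff(norms) <= 1e-6)

    def test_family_variance_recovery(self, rng):
        """sigma_hat centred on the simulated family-intercept SD."""
        truth = 1.0
        ests = []
        for _ in range(30):
            n_fam = 200
            sizes = rng.integers(2, 4, n_fam)
            g = np.repeat(np.arange(n_fam), sizes)
            u = rng.normal(0, truth, n_fam)
            X = rng.normal(size=(len(g), 3))
            y = (rng.random(len(g)) < 1 / (1 + np.exp(-(0.5 * X[:, 0] + u[g])))).astype(int)
            m = fit_enet_mixed(X, y, g, EnetMixedSpec(alpha=0.1, lam=1e-4))
            ests.append(np.sqrt(m.sigma2_family))
        ests = np.array(ests)
        assert abs(ests.mean() - truth) < 3 * ests.std(ddof=1) / np.sqrt(len(ests))

    def test_negative_lambda_rejected(self):
        with pytest.raises(ValueError):
            EnetMixedSpec(lam=-1.0)


class TestGroupedKFold:
    def test_leave_one_out_when_singleton_families(self, rng):
        X, y = logistic_data(rng, n=40, p=3)
        spec = EnetMixedSpec(lam=1e-4, sigma2=0.0)
        proba, fold = grouped_kfold_predict(X, y, np.arange(40), spec, k=40, seed=0)
        assert len(np.unique(fold)) == 40  # every sample alone in its fold

    def test_determinism(self, rng):
        X, y = logistic_data(rng, n=80, p=3)
        groups = rng.integers(0, 30, 80)
        spec = EnetMixedSpec(lam=1e-4, sigma2=0.0)
        p1, f1 = grouped_kfold_predict(X, y, groups, spec, k=5, seed=3)
        p2, f2 = grouped_kfold_predict(X, y, groups, spec, k=5, seed=3)
        assert np.array_equal(f1, f2)
        assert np.array_equal(p1, p2)

    def test_families_never_split(self, rng):
        for rep in range(30):
            n = 120
            groups = rng.integers(0, 35, n)
            X = rng.normal(size=(n, 2))
            y = rng.integers(0, 2, n)
            if len(set(y)) < 2:
                continue
            _, fold = grouped_kfold_predict(
                X, y, groups, EnetMixedSpec(lam=1e-2, sigma2=0.0), k=5, seed=rep
            )
            df = pd.DataFrame({"g": groups, "f": fold})
            assert (df.groupby("g")["f"].nunique() == 1).all()

    def test_too_few_families_rejected(self, rng):
        X, y = logistic_data(rng, n=20, p=2)
        with pytest.raises(ValueError, match="families"):
            grouped_kfold_predict(X, y, np.zeros(20), EnetMixedSpec(), k=5)


class TestROC:
    def test_perfect_and_constant_scores(self):
        labels = np.array([0, 0, 1, 1])
        assert roc_auc(labels.astype(float), labels).auc == 1.0
        assert roc_auc(np.full(4, 0.3), labels).auc == 0.5

    def test_worked_example(self):
        r = roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1])
        assert r.auc == 0.75  # 3 of 4 pos/neg pairs concordant

    def test_matches_brute_force_and_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(40):
            n = rng.integers(4, 60)
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            scores = np.round(rng.normal(size=n), 1)  # force some ties
            r = roc_auc(scores, labels)
            assert r.auc == pytest.approx(brute_force_auc(scores, labels), abs=1e-12)
            assert r.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_curve_is_monotone_staircase(self, rng):
        labels = rng.integers(0, 2, 50)
        labels[0], labels[1] = 0, 1
        r = roc_auc(rng.normal(size=50), labels)
        assert np.all(np.diff(r.sensitivity) >= 0)
        assert np.all(np.diff(r.specificity) <= 0)


class TestBootstrapComparison:
    def test_identical_scores_give_null_delta(self, rng):
        n = 100
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        s = rng.normal(size=n)
        res = compare_auc_bootstrap(s, s, labels, np.arange(n), n_reps=200, seed=1)
        assert res.delta == 0.0
        assert res.p == 1.0

    def test_determinism(self, rng):
        n = 80
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        a, b = rng.normal(size=n), rng.normal(size=n)
        groups = rng.integers(0, 30, n)
        r1 = compare_auc_bootstrap(a, b, labels, groups, n_reps=300, seed=9)
        r2 = compare_auc_bootstrap(a, b, labels, groups, n_reps=300, seed=9)
        assert r1.p == r2.p
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_detects_true_auc_gap(self, rng):
        hits = 0
        reps = 20
        for _ in range(reps):
            n = 400
            labels = rng.integers(0, 2, n)
            labels[:2] = [0, 1]
            good = labels + rng.normal(0, 0.55, n)  # AUC ~0.9
            bad = rng.normal(size=n)
            res = compare_auc_bootstrap(good, bad, labels, np.arange(n), n_reps=300, seed=int(rng.integers(1 << 30)))
            hits += res.p < 0.001
        assert hits >= int(0.8 * reps)


class TestFullVsNull:
    def make_processed(self, effect, seed, n_families=90):
        cfg = SimulationConfig(n_families=n_families, seed=seed, disease_effect=effect)
        cohort = simulate_cohort(cfg)
        rn = run_preprocessing(
            cohort.peak_table, BatchDesign.from_metadata(cohort.metadata), until="rank_normal"
        )
        return rn, cohort.metadata

    def test_strong_effect_beats_null(self):
        effect = np.zeros(39)
        effect[:8] = 0.5
        rn, meta = self.make_processed(effect, seed=21)
        res = run_full_vs_null(rn, meta, n_boot=300, seed=5)
        assert res["comparison"].auc_full > res["comparison"].auc_null
        assert res["comparison"].p < 0.05

    def test_defaults_match_reported_settings(self):
        spec = EnetMixedSpec()
        assert spec.alpha == 0.1
        assert spec.lam == 1e-4

    def test_derived_trait_columns_rejected(self):
        rn, meta = self.make_processed(np.zeros(39), seed=22, n_families=30)
        bad = PeakTable(
            rn.values.rename(columns={"GP1": "HM"}), state="rank_normal"
        )
        with pytest.raises(ValueError, match="directly measured"):
            run_full_vs_null(bad, meta)
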