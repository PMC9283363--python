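"""Per-glycan association models.

Four model families, all operating on one rank-normalized glycan vector at
a time, plus Benjamini-Hochberg control across a panel:

* sex x age-group general linear model with post-hoc pairwise contrasts
  (within sex across age groups, within age group between sexes);
* the censored autoantibody-level model
  ``glycan = b0 + I*b1*c + (1-I)*b2 + sex + age`` where the indicator I is
  1 when the level c is below the assay's limit of quantification.  Note
  the direction: the slope b1 applies to quantified (below-LOQ) levels and
  the constant b2 to levels at or above the LOQ, the reverse of common
  lower-LOQ handling; a switch offers the conventional direction;
* a linear trend model on the number of autoantibodies (ordered 1..4),
  adjusted for sex and age;
* disease-status logistic regression (status ~ glycan + age + sex) with
  family-clustered uncertainty, reporting an odds ratio per 1 SD of
  glycan.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import PeakTable, SampleMetadata

__all__ = [
    "AGE_GROUPS",
    "assign_age_group",
    "fit_sex_age_model",
    "fit_censored_autoantibody_model",
    "fit_autoantibody_count_model",
    "disease_association",
    "disease_association_panel",
    "bh_adjust",
    "AssociationResult",
    "CensoredFitResult",
    "SexAgeModelResult",
]

AGE_GROUPS = ("child", "pre-pubertal", "pubertal", "post-pubertal")

#: Sex-specific age cut-offs (years) separating child / pre-pubertal /
#: pubertal / post-pubertal.
DEFAULT_AGE_CUTOFFS = {"F": (6.0, 11.0, 15.0), "M": (6.0, 13.0, 17.0)}


def assign_age_group(age: float, sex: str, cutoffs: dict | None = None) -> str:
    """Pubertal age group for one child, with sex-specific boundaries.

    Female: child < 6 <= pre-pubertal < 11 <= pubertal < 15 <= post-pubertal;
    male boundaries are 6 / 13 / 17.
    """
    if age <= 0:
        raise ValueError(f"age must be positive, got {age}")
    if sex not in ("F", "M"):
        raise ValueError(f"sex must be 'F' or 'M', got {sex!r}")
    lo, mid, hi = (cutoffs or DEFAULT_AGE_CUTOFFS)[sex]
    if age < lo:
        return AGE_GROUPS[0]
    if age < mid:
        return AGE_GROUPS[1]
    if age < hi:
        return AGE_GROUPS[2]
    return AGE_GROUPS[3]


@dataclass
class AssociationResult:
    """Effect of one glycan: OR (per SD) or beta, with CI, SE, p and BH q."""

    name: str
    effect: float
    ci_low: float
    ci_high: float
    se: float
    p: float
    q: float | None = None
    scale: str = "beta"
    flags: list = field(default_factory=list)


@dataclass
class CensoredFitResult:
    """Fit of the censored autoantibody-level model."""

    b0: float
    b1: float | None
    b2: float | None
    se: dict
    p: dict
    n_censored: int
    n_uncensored: int
    covariates: dict
    warnings: list = field(default_factory=list)


@dataclass
class SexAgeModelResult:
    """Sex x age-group GLM: cell means and post-hoc pairwise contrasts."""

    cell_means: pd.DataFrame  # index (sex, age_group): mean, n
    contrasts: pd.DataFrame  # group1, group2, estimate, se, t, p, q
    residual_df: int
    sigma2: float


def _sex_numeric(meta: pd.DataFrame) -> np.ndarray:
    return (meta["sex"].to_numpy() == "M").astype(float)


def fit_sex_age_model(glycan, metadata: SampleMetadata) -> SexAgeModelResult:
    """Sex crossed with age group, with post-hoc pairwise t contrasts.

    Fits the saturated two-way layout by least squares and compares
    estimated marginal (cell) means pairwise: between age groups within
    each sex, and between sexes within each age group, using two-tailed t
    tests on the pooled residual variance.  BH adjustment is applied across
    all emitted contrasts.
    """
    y = np.asarray(glycan, dtype=float)
    meta = metadata.table
    if len(y) != len(meta):
        raise ValueError("glycan vector and metadata length mismatch")
    groups = [assign_age_group(a, s) for a, s in zip(meta["age"], meta["sex"])]
    df = pd.DataFrame({"y": y, "sex": meta["sex"].to_numpy(), "age_group": groups})

    sexes = sorted(df["sex"].unique())
    ages = [g for g in AGE_GROUPS if g in set(df["age_group"])]
    counts = df.groupby(["sex", "age_group"], observed=True)["y"].count()
    for s in sexes:
        for a in ages:
            if (s, a) not in counts.index or counts[(s, a)] < 2:
                raise ValueError(f"design cell (sex={s}, age_group={a}) has < 2 samples")

    cells = df.groupby(["sex", "age_group"], observed=True)["y"].agg(["mean", "count"])
    n = len(df)
    k = len(cells)
    fitted = df.merge(
        cells["mean"].rename("cell_mean"),
        left_on=["sex", "age_group"],
        right_index=True,
    )["cell_mean"].to_numpy()
    resid_df = n - k
    if resid_df <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = float(np.sum((y - fitted) ** 2) / resid_df)

    rows = []

    def add_contrast(c1, c2):
        m1, n1 = cells.loc[c1, "mean"], cells.loc[c1, "count"]
        m2, n2 = cells.loc[c2, "mean"], cells.loc[c2, "count"]
        est = m1 - m2
        se = np.sqrt(sigma2 * (1.0 / n1 + 1.0 / n2))
        t = est / se
        p = 2 * stats.t.sf(abs(t), resid_df)
        rows.append(
            {
                "group1": f"{c1[0]}/{c1[1]}",
                "group2": f"{c2[0]}/{c2[1]}",
                "estimate": est,
                "se": se,
                "t": t,
                "p": p,
            }
        )

    # within sex, across age groups
    for s in sexes:
        for i in range(len(ages)):
            for j in range(i + 1, len(ages)):
                add_contrast((s, ages[i]), (s, ages[j]))
    # within age group, between sexes
    for a in ages:
        for i in range(len(sexes)):
            for j in range(i + 1, len(sexes)):
                add_contrast((sexes[i], a), (sexes[j], a))

    contrasts = pd.DataFrame(rows)
    contrasts["q"] = bh_adjust(contrasts["p"].to_numpy())
    return SexAgeModelResult(
        cell_means=cells, contrasts=contrasts, residual_df=resid_df, sigma2=sigma2
    )


def fit_censored_autoantibody_model(
    glycan,
    level,
    loq: float,
    metadata: SampleMetadata | None = None,
    direction: str = "upper",
) -> CensoredFitResult:
    """Fit ``glycan = b0 + I*b1*c + (1-I)*b2 (+ sex + age)``.

    ``direction="upper"`` (default) sets I = 1 when c < LOQ, so the slope
    b1 acts on quantified levels and b2 is a constant offset for levels at
    or above the LOQ.  ``direction="lower"`` reverses the indicator for
    assays censored from below.  Observations with missing levels are
    dropped.  When every observation falls on one side of the LOQ the
    unidentifiable parameter is dropped and recorded in ``warnings``.
    """
    if loq <= 0:
        raise ValueError("LOQ must be positive")
    if direction not in ("upper", "lower"):
        raise ValueError("direction must be 'upper' or 'lower'")
    y = np.asarray(glycan, dtype=float)
    c = np.asarray(level, dtype=float)
    keep = np.isfinite(c) & np.isfinite(y)
    y, c = y[keep], c[keep]
    if len(y) < 3:
        raise ValueError("too few observations with recorded levels")
    below = c < loq
    I = below if direction == "upper" else ~below

    cols, names = [np.ones(len(y))], ["b0"]
    warns = []
    have_b1 = I.any()
    have_b2 = (~I).any()
    if have_b1:
        cols.append(I * c)
        names.append("b1")
    else:
        warns.append("no observations on the slope side of the LOQ; b1 dropped")
    if have_b2 and have_b1:
        cols.append((~I).astype(float))
        names.append("b2")
    elif have_b2:
        warns.append("all observations on the constant side; b2 absorbed into b0")

    cov_names = []
    if metadata is not None:
        meta = metadata.table.loc[keep] if len(metadata.table) == len(keep) else metadata.table
        if len(meta) != len(y):
            raise ValueError("metadata does not align with level vector")
        cols.append(_sex_numeric(meta))
        cols.append(meta["age"].to_numpy(dtype=float))
        cov_names = ["sex_M", "age"]
        names += cov_names

    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear design matrix")
    fit = sm.OLS(y, X).fit()
    params = dict(zip(names, fit.params))
    ses = dict(zip(names, fit.bse))
    ps = dict(zip(names, fit.pvalues))
    return CensoredFitResult(
        b0=params["b0"],
        b1=params.get("b1"),
        b2=params.get("b2"),
        se=ses,
        p=ps,
        n_censored=int((~below).sum()),
        n_uncensored=int(below.sum()),
        covariates={k: params[k] for k in cov_names},
        warnings=warns,
    )


def fit_autoantibody_count_model(
    glycan, n_autoantibodies, metadata: SampleMetadata, name: str = "glycan"
) -> AssociationResult:
    """Linear trend of glycan on the number of autoantibodies (1..4).

    The ordered count enters as a numeric score, so the reported beta is
    the change in (rank-normalized) glycan per additional autoantibody,
    adjusted for sex and age.
    """
    y = np.asarray(glycan, dtype=float)
    count = np.asarray(n_autoantibodies, dtype=float)
    keep = np.isfinite(count) & np.isfinite(y)
    y, count = y[keep], count[keep]
    if len(np.unique(count)) < 2:
        raise ValueError("need >= 2 distinct autoantibody counts")
    meta = metadata.table.loc[keep]
    X = sm.add_constant(
        np.column_stack([count, _sex_numeric(meta), meta["age"].to_numpy(dtype=float)])
    )
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int()[1]
    return AssociationResult(
        name=name,
        effect=float(fit.params[1]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        se=float(fit.bse[1]),
        p=float(fit.pvalues[1]),
        scale="beta",
    )


def _firth_logit(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8):
    """Firth bias-reduced logistic regression (Jeffreys-prior score)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        XW = X * w[:, None]
        info = X.T @ XW
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", XW, info_inv, X)
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    se = np.sqrt(np.diag(info_inv))
    return beta, se


def disease_association(
    glycan,
    metadata: SampleMetadata,
    name: str = "glycan",
    method: str = "cluster",
) -> AssociationResult:
    """Odds ratio for disease status per 1 SD of glycan.

    Logistic regression ``status ~ glycan + age + sex``.  The glycan is
    standardized so the OR is per standard deviation.  ``method="cluster"``
    (default) uses family-clustered robust standard errors;
    ``method="mixed"`` adds a family random intercept (penalized
    quasi-likelihood point estimates) and falls back to the cluster-robust
    fit when the estimated family variance degenerates to ~0.  Perfect
    separation triggers a Firth bias-reduced fallback, flagged in the
    result.
    """
    y = metadata.table["status"].to_numpy(dtype=float)
    if len(set(y)) < 2:
        raise ValueError("both affected and unaffected samples are required")
    g = np.asarray(glycan, dtype=float)
    g = (g - g.mean()) / g.std(ddof=0)
    meta = metadata.table
    X = sm.add_constant(
        np.column_stack([g, meta["age"].to_numpy(dtype=float), _sex_numeric(meta)])
    )
    flags = []

    if method == "mixed":
        from .discriminate import EnetMixedSpec, fit_enet_mixed

        spec = EnetMixedSpec(alpha=0.0, lam=0.0, penalized=np.zeros(3, dtype=bool))
        model = fit_enet_mixed(
            X[:, 1:], y.astype(int), meta["family_id"].to_numpy(), spec
        )
        if model.sigma2_family > 1e-3:
            beta = model.coef[0]
            se = model.coef_se[0]
            p = 2 * stats.norm.sf(abs(beta / se))
            flags.append(f"mixed: sigma2_family={model.sigma2_family:.3g}")
            return AssociationResult(
                name=name,
                effect=float(np.exp(beta)),
                ci_low=float(np.exp(beta - 1.96 * se)),
                ci_high=float(np.exp(beta + 1.96 * se)),
                se=float(se),
                p=float(p),
                scale="OR",
                flags=flags,
            )
        flags.append("mixed variance degenerate; cluster-robust fallback")

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(
                disp=False,
                cov_type="cluster",
                cov_kwds={"groups": pd.factorize(meta["family_id"])[0]},
            )
        beta, se = float(fit.params[1]), float(fit.bse[1])
        p = float(fit.pvalues[1])
        separated = not np.isfinite(se) or abs(beta) > 15
    except Exception:  # statsmodels raises on perfect separation
        separated = True
    if separated:
        flags.append("perfect separation: Firth bias-reduced fallback")
        params, ses = _firth_logit(X, y)
        beta, se = float(params[1]), float(ses[1])
        p = float(2 * stats.norm.sf(abs(beta / se)))
    return AssociationResult(
        name=name,
        effect=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.96 * se)),
        ci_high=float(np.exp(beta + 1.96 * se)),
        se=se,
        p=p,
        scale="OR",
        flags=flags,
    )


def disease_association_panel(
    table: PeakTable,
    metadata: SampleMetadata,
    traits: pd.DataFrame | None = None,
    method: str = "cluster",
) -> pd.DataFrame:
    """Disease ORs for every peak (and optionally every derived trait).

    One BH family spans the whole panel (all peaks plus traits), matching
    per-table multiple-testing correction.  Derived traits are
    rank-normalized before modelling so their ORs are also per SD.
    """
    table.require_state("rank_normal")
    from .preprocess import rank_inverse_normal

    meta = metadata.aligned_to(table)
    results = []
    for peak in table.peak_ids:
        results.append(
            disease_association(
                table.values[peak].to_numpy(), meta, name=peak, method=method
            )
        )
    if traits is not None:
        traits = traits.loc[table.sample_ids]
        for trait in traits.columns:
            results.append(
                disease_association(
                    rank_inverse_normal(traits[trait].to_numpy()),
                    meta,
                    name=trait,
                    method=method,
                )
            )
    out = pd.DataFrame(
        {
            "glycan": [r.name for r in results],
            "OR": [r.effect for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "SE": [r.se for r in results],
            "p": [r.p for r in results],
        }
    )
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, order-preserving)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
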