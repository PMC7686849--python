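"""Genotype/haplotype-phenotype association models.

Genetic-model encodings (additive 0/1/2, dominant 0/1 with AA the
homozygous-major reference), ordinary least squares, the covariate-adjusted
Gaussian GLM (identity link) used for hemoglobin, and a negative-binomial
(NB2, log link) regression of haplotype chromosome counts on per-haplotype
mean phenotype.  The NB fit alternates a GLM for the coefficients (IRLS,
via statsmodels) with one-dimensional maximum-likelihood estimation of the
dispersion theta (variance = mu + mu**2 / theta), the glm.nb scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats

from .core_data import GenotypeMatrix, PhenotypeTable

__all__ = [
    "ModelEncoding",
    "FitResult",
    "encode",
    "linear_regression",
    "glm_gaussian",
    "nb_glm",
    "bonferroni_threshold",
]

MODELS = ("additive", "dominant")


@dataclass(frozen=True)
class ModelEncoding:
    snp_id: str
    model: str
    values: np.ndarray  # int per sample; missing genotypes encoded as -1
    missing: np.ndarray

    def series(self, sample_ids: Sequence[str]) -> pd.Series:
        s = pd.Series(self.values.astype(float), index=sample_ids)
        s[self.missing] = np.nan
        return s


@dataclass
class FitResult:
    """Regression fit: coefficient table plus family metadata.

    ``params`` has one row per term with columns beta, se, p (two-sided
    Wald).  For negative-binomial fits ``dispersion`` is theta, with
    variance mu + mu**2/theta.
    """

    family: str
    params: pd.DataFrame
    n: int
    loglik: float
    dispersion: float | None = None

    def beta(self, term: str) -> float:
        return float(self.params.loc[term, "beta"])

    def p(self, term: str) -> float:
        return float(self.params.loc[term, "p"])


def encode(gm: GenotypeMatrix, snp_id: str, model: str) -> ModelEncoding:
    """Numeric genetic-model encoding.

    additive: 0 = AA, 1 = AB, 2 = BB; dominant: 0 = AA, 1 = AB or BB,
    with A the designated major allele (dosage is already the minor-allele
    count, so additive equals dosage).
    """
    if model not in MODELS:
        raise ValueError(f"model must be one of {MODELS}")
    dos, miss = gm.column(snp_id)
    vals = dos.astype(np.int16).copy()
    if model == "dominant":
        vals = (vals > 0).astype(np.int16)
    vals[miss] = -1
    return ModelEncoding(snp_id=snp_id, model=model, values=vals, missing=miss)


def _wald_table(names, beta, se, dist="t", df=None) -> pd.DataFrame:
    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
    if dist == "t":
        p = 2 * stats.t.sf(np.abs(z), df)
    else:
        p = 2 * stats.norm.sf(np.abs(z))
    return pd.DataFrame(
        {"beta": beta, "se": se, "p": p}, index=pd.Index(names, name="term")
    )


def _design(x, covariates) -> tuple[pd.DataFrame, list[str]]:
    x = pd.Series(np.asarray(x, dtype=float), name="x")
    cols = {"const": np.ones(len(x)), "x": x.to_numpy()}
    names = ["const", "x"]
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True)
        for c in cov.columns:
            cols[str(c)] = cov[c].to_numpy(dtype=float)
            names.append(str(c))
    return pd.DataFrame(cols), names


def linear_regression(y, x, covariates=None) -> FitResult:
    """OLS of y on x (plus optional covariates); t-based two-sided p."""
    y = np.asarray(y, dtype=float)
    X, names = _design(x, covariates)
    keep = ~(np.isnan(y) | X.isna().any(axis=1).to_numpy())
    y, X = y[keep], X.loc[keep]
    if len(y) <= len(names):
        raise ValueError("not enough complete observations for OLS")
    fit = sm.OLS(y, X).fit()
    params = _wald_table(
        names, fit.params.to_numpy(), fit.bse.to_numpy(), "t", fit.df_resid
    )
    return FitResult(
        family="gaussian-ols", params=params, n=int(len(y)), loglik=float(fit.llf)
    )


def glm_gaussian(
    y,
    x,
    covariates=None,
) -> FitResult:
    """Gaussian GLM with identity link (equivalent to OLS with covariates).

    For the study model hb ~ encoding + age + sex + altitude, pass the
    covariates as a DataFrame with sex coded 0 = female, 1 = male and
    altitude as the higher-cohort indicator.
    """
    y = np.asarray(y, dtype=float)
    X, names = _design(x, covariates)
    keep = ~(np.isnan(y) | X.isna().any(axis=1).to_numpy())
    y, X = y[keep], X.loc[keep]
    if len(y) <= len(names):
        raise ValueError("not enough complete observations for GLM")
    fit = sm.GLM(y, X, family=sm.families.Gaussian()).fit()
    # Wald t with OLS residual df (identical to OLS inference)
    params = _wald_table(
        names,
        fit.params.to_numpy(),
        fit.bse.to_numpy(),
        "t",
        len(y) - len(names),
    )
    return FitResult(
        family="gaussian-glm",
        params=params,
        n=int(len(y)),
        loglik=float(fit.llf),
    )


def _nb_loglik(y: np.ndarray, mu: np.ndarray, theta: float) -> float:
    return float(
        np.sum(
            special.gammaln(y + theta)
            - special.gammaln(theta)
            - special.gammaln(y + 1)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
    )


def nb_glm(counts, predictor, max_outer: int = 50, tol: float = 1e-8) -> FitResult:
    """NB2 regression of nonnegative counts on one predictor (log link).

    Alternates IRLS for the coefficients at fixed theta with 1-D
    maximum-likelihood for theta, until the joint log-likelihood is stable.
    """
    y = np.asarray(counts, dtype=float)
    x = np.asarray(predictor, dtype=float)
    if len(y) < 3:
        raise ValueError("need at least 3 rows")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise ValueError("counts must be nonnegative integers")
    if y.sum() == 0:
        raise ValueError("all counts are zero")
    X = pd.DataFrame({"const": np.ones(len(y)), "x": x})
    # moment start for theta from a Poisson fit
    pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    mu = pois.mu
    excess = np.sum((y - mu) ** 2 - mu)
    theta = float(np.sum(mu**2) / excess) if excess > 0 else 1e4
    theta = float(np.clip(theta, 1e-3, 1e7))
    ll_old = -np.inf
    trace: list[float] = []
    fit = pois
    for _ in range(max_outer):
        fit = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=1.0 / theta)
        ).fit(start_params=fit.params)
        mu = fit.mu

        def neg(log_theta: float) -> float:
            return -_nb_loglik(y, mu, float(np.exp(log_theta)))

        res = optimize.minimize_scalar(
            neg, bounds=(np.log(1e-3), np.log(1e7)), method="bounded"
        )
        theta = float(np.exp(res.x))
        ll = _nb_loglik(y, mu, theta)
        trace.append(ll)
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    else:
        raise RuntimeError(
            "NB dispersion alternation did not converge; "
            f"log-likelihood trace tail: {trace[-5:]}"
        )
    params = _wald_table(
        ["const", "x"], fit.params.to_numpy(), fit.bse.to_numpy(), "z"
    )
    return FitResult(
        family="negative-binomial",
        params=params,
        n=int(len(y)),
        loglik=float(trace[-1]),
        dispersion=theta,
    )


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Family-wise significance threshold alpha / m."""
    if m < 1:
        raise ValueError("number of tests must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return alpha / m


def covariate_frame(
    pheno: PhenotypeTable,
    sample_ids: Sequence[str],
    sex_reference: str = "female",
    altitude_reference: str | None = None,
) -> pd.DataFrame:
    """age/sex/altitude design columns in genotype sample order.

    sex is an indicator against ``sex_reference`` (default 0 = female,
    1 = male); altitude becomes an indicator for the non-reference cohort
    when exactly two cohort altitudes are present, else is kept numeric.
    """
    f = pheno.frame.reindex(sample_ids)
    out = pd.DataFrame(index=f.index)
    if "age" in f.columns:
        out["age"] = f["age"].astype(float)
    if "sex" in f.columns:
        out["sex"] = (f["sex"] != sex_reference).astype(float)
    if "altitude" in f.columns:
        alts = sorted(f["altitude"].dropna().unique())
        if len(alts) == 2:
            ref = alts[0] if altitude_reference is None else altitude_reference
            out["altitude"] = (f["altitude"] != ref).astype(float)
        else:
            out["altitude"] = f["altitude"].astype(float)
    return out.reset_index(drop=True)
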