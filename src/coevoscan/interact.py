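"""SNP x SNP and SNP x SNP x sex interaction regressions.

Models follow the standard epistatic-eQTL / biobank formulation:
``y ~ g1 * g2 + covariates`` for the two-way interaction and
``y ~ g1 * g2 * sex + covariates`` for the three-way, with Gaussian (least
squares) or binomial (logistic maximum likelihood) families. SNPs enter
either additively (count of non-reference alleles) or genotypically (dummy
coding with the homozygous-reference class as baseline); interaction blocks
are tested with likelihood-ratio tests whose d.f. equals the number of
interaction parameters dropped. Average marginal effects of the focal SNP
are computed per stratum with delta-method standard errors. Continuous
outcomes can be pre-cleaned by removing gross outliers on externally
studentized residuals of the covariate-only model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genio import MISSING

ENCODINGS = ("additive", "genotypic")


@dataclass
class EncodedGenotype:
    """A SNP's design columns under one encoding.

    additive: one column counting non-reference alleles (0/1/2).
    genotypic: two mutually exclusive indicators (het, hom-alt), homozygous
    reference as baseline. Missing dosages propagate as NaN.
    """

    encoding: str
    columns: pd.DataFrame
    constant: bool = False


def encode(g, mode: str = "additive", name: str = "g") -> EncodedGenotype:
    if mode not in ENCODINGS:
        raise ValueError(f"unknown encoding {mode!r}; choose from {ENCODINGS}")
    g = np.asarray(g, dtype=float)
    g = np.where(g == MISSING, np.nan, g)
    ok = ~np.isnan(g)
    if not np.isin(g[ok], (0.0, 1.0, 2.0)).all():
        raise ValueError("dosages must be in {0,1,2,missing}")
    if mode == "additive":
        cols = pd.DataFrame({name: g})
    else:
        cols = pd.DataFrame(
            {
                f"{name}_het": np.where(np.isnan(g), np.nan, (g == 1).astype(float)),
                f"{name}_homalt": np.where(np.isnan(g), np.nan, (g == 2).astype(float)),
            }
        )
    constant = bool(ok.any() and (np.nanstd(g) == 0))
    return EncodedGenotype(encoding=mode, columns=cols, constant=constant)


def _interaction_block(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    out = {}
    for ca in a.columns:
        for cb in b.columns:
            out[f"{ca}:{cb}"] = a[ca] * b[cb]
    return pd.DataFrame(out)


@dataclass
class InteractionFit:
    """A fitted interaction model plus its nested-model LRT."""

    family: str
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    llf: float
    n: int
    interaction_terms: list[str]
    wald_p: pd.Series
    lrt_stat: float
    lrt_df: int
    lrt_p: float
    stratum: str = "all"
    separation: bool = False
    # internals for marginal effects / diagnostics
    design: pd.DataFrame | None = field(default=None, repr=False)
    y: np.ndarray | None = field(default=None, repr=False)
    raw: dict | None = field(default=None, repr=False)

    @property
    def interaction_beta(self) -> pd.Series:
        return self.params[self.interaction_terms]

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        z = stats.norm.ppf(1 - alpha / 2)
        return pd.DataFrame(
            {"low": self.params - z * self.bse, "high": self.params + z * self.bse}
        )


def _fit_ll(y: np.ndarray, X: pd.DataFrame, family: str):
    """Fit and return (statsmodels result, log-likelihood, separation flag)."""
    if family == "gaussian":
        res = sm.OLS(y, X).fit()
        return res, float(res.llf), False
    if family == "binomial":
        sep = False
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
            except Exception:
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit_regularized(
                    alpha=1e-6
                )
                sep = True
        if not sep and np.abs(np.asarray(res.params)).max() > 15:
            sep = True
        return res, float(res.llf), sep
    raise ValueError(f"unknown family {family!r}")


def _assemble(
    y,
    g1,
    g2,
    covariates,
    sex,
    encoding1,
    encoding2,
    three_way,
):
    """Complete-case design matrices (full, reduced) and metadata."""
    y = np.asarray(y, dtype=float)
    e1 = encode(g1, encoding1, "g1").columns
    e2 = encode(g2, encoding2, "g2").columns
    parts = [e1, e2]
    if covariates is not None:
        cov = pd.DataFrame(covariates).reset_index(drop=True).astype(float)
        parts.append(cov)
    else:
        cov = None
    sex_col = None
    if sex is not None:
        sex = np.asarray(sex)
        sex_col = pd.DataFrame({"sex_male": (sex == "male").astype(float)})
        sex_col[~np.isin(sex, ("male", "female"))] = np.nan
        parts.append(sex_col)
    inter12 = _interaction_block(e1, e2)
    blocks = [pd.DataFrame({"const": np.ones(len(y))}), *parts, inter12]
    three_way_terms: list[str] = []
    if three_way:
        if sex_col is None:
            raise ValueError("three-way model requires sex labels")
        blocks.append(_interaction_block(e1, sex_col))
        blocks.append(_interaction_block(e2, sex_col))
        tw = _interaction_block(inter12, sex_col)
        three_way_terms = list(tw.columns)
        blocks.append(tw)
    X = pd.concat([b.reset_index(drop=True) for b in blocks], axis=1)
    ok = ~(np.isnan(y) | X.isna().any(axis=1).to_numpy())
    X = X.loc[ok].reset_index(drop=True)
    yv = y[ok]
    drop_terms = three_way_terms if three_way else list(inter12.columns)
    return yv, X, drop_terms, ok


def fit_interaction(
    y,
    g1,
    g2,
    covariates=None,
    family: str = "gaussian",
    encoding1: str = "additive",
    encoding2: str = "additive",
    sex=None,
    stratum: str = "all",
    standardize_y: bool = False,
) -> InteractionFit:
    """Fit ``y ~ g1 * g2 + covariates`` and test the interaction block.

    The full model carries main effects, covariates (and sex when given) and
    all g1 x g2 product terms; the reduced model drops the product terms.
    Inference: two-sided Wald p per coefficient plus a likelihood-ratio test
    for the whole interaction block (df = number of product terms). Listwise
    deletion on missing y/genotypes/covariates. Under a binomial family,
    (quasi-)separation is flagged and the LRT is the primary inference.
    ``standardize_y`` z-scores a continuous outcome before fitting (the
    usual pre-step for biomarker models).
    """
    if standardize_y:
        if family != "gaussian":
            raise ValueError("standardize_y applies to gaussian outcomes only")
        y = np.asarray(y, dtype=float)
        y = (y - np.nanmean(y)) / np.nanstd(y, ddof=1)
    yv, X, inter_terms, ok = _assemble(
        y, g1, g2, covariates, sex, encoding1, encoding2, three_way=False
    )
    fit = _fit_and_test(yv, X, inter_terms, family, stratum)
    fit.raw = {
        "g1": np.asarray(g1, float)[ok],
        "g2": np.asarray(g2, float)[ok],
        "sex": None if sex is None else np.asarray(sex)[ok],
        "encoding1": encoding1,
        "encoding2": encoding2,
    }
    return fit


def _fit_and_test(yv, X, drop_terms, family, stratum) -> InteractionFit:
    if len(yv) <= X.shape[1] + 5:
        raise ValueError(
            f"n = {len(yv)} too small for {X.shape[1]} parameters"
        )
    resid_rank = np.linalg.matrix_rank(X.to_numpy())
    if resid_rank < X.shape[1]:
        raise ValueError("design matrix is rank deficient (perfect collinearity)")
    full, ll_full, sep = _fit_ll(yv, X, family)
    X_red = X.drop(columns=drop_terms)
    _, ll_red, _ = _fit_ll(yv, X_red, family)
    lrt = max(0.0, 2.0 * (ll_full - ll_red))
    df = len(drop_terms)
    lrt_p = float(stats.chi2.sf(lrt, df)) if df else 1.0
    params = pd.Series(np.asarray(full.params), index=X.columns)
    bse = pd.Series(np.asarray(full.bse), index=X.columns)
    if family == "gaussian":
        wald_p = pd.Series(np.asarray(full.pvalues), index=X.columns)
    else:
        z = params / bse
        wald_p = pd.Series(2 * stats.norm.sf(np.abs(z)), index=X.columns)
    cov = pd.DataFrame(np.asarray(full.cov_params()), index=X.columns, columns=X.columns)
    return InteractionFit(
        family=family,
        params=params,
        bse=bse,
        cov_params=cov,
        llf=ll_full,
        n=len(yv),
        interaction_terms=list(drop_terms),
        wald_p=wald_p,
        lrt_stat=lrt,
        lrt_df=df,
        lrt_p=lrt_p,
        stratum=stratum,
        separation=sep,
        design=X,
        y=yv,
        raw=None,
    )


def lrt_interaction(full: InteractionFit, reduced: InteractionFit) -> tuple[float, int, float]:
    """Likelihood-ratio test between two nested fits on the same observations.

    statistic = 2 (ll_full - ll_reduced); df = parameter-count difference.
    """
    full_cols = set(full.params.index)
    red_cols = set(reduced.params.index)
    if not red_cols <= full_cols:
        raise ValueError("models are not nested")
    if full.n != reduced.n:
        raise ValueError("models were fit on different observation sets")
    df = len(full_cols) - len(red_cols)
    stat = max(0.0, 2.0 * (full.llf - reduced.llf))
    p = float(stats.chi2.sf(stat, df)) if df else 1.0
    return stat, df, p


def three_way_sex(
    y,
    g1,
    g2,
    sex,
    covariates=None,
    family: str = "gaussian",
    encoding1: str = "additive",
    encoding2: str = "additive",
) -> InteractionFit:
    """Full factorial g1 x g2 x sex model; LRT against the no-three-way model.

    The reduced model keeps every lower-order term (main effects, all
    pairwise interactions with sex and between SNPs) and drops only the
    g1 x g2 x sex products; df equals the number of dropped terms.
    """
    sex = np.asarray(sex)
    present = set(sex[np.isin(sex, ("male", "female"))])
    if len(present) < 2:
        raise ValueError("three_way_sex requires both sexes in the data")
    yv, X, tw_terms, ok = _assemble(
        y, g1, g2, covariates, sex, encoding1, encoding2, three_way=True
    )
    fit = _fit_and_test(yv, X, tw_terms, family, stratum="all")
    fit.raw = {
        "g1": np.asarray(g1, float)[ok],
        "g2": np.asarray(g2, float)[ok],
        "sex": sex[ok],
        "encoding1": encoding1,
        "encoding2": encoding2,
    }
    return fit


def _focal_derivative_design(X: pd.DataFrame, focal: str) -> pd.DataFrame:
    """dX/d(focal) for a design linear in the focal additive column.

    Every column whose name contains the focal token as a ':'-separated
    factor is a product of the focal column with the remaining factors; its
    derivative is that product with the focal factor replaced by 1.
    """
    if focal not in X.columns:
        raise ValueError(f"focal column {focal!r} not in design (additive encoding required)")
    dX = pd.DataFrame(0.0, index=X.index, columns=X.columns)
    for col in X.columns:
        factors = col.split(":")
        if focal in factors:
            others = [f for f in factors if f != focal]
            if focal in others:
                raise ValueError("focal column appears nonlinearly")
            prod = np.ones(len(X))
            for f in others:
                prod = prod * X[f].to_numpy()
            dX[col] = prod
    return dX


def average_marginal_effects(
    fit: InteractionFit,
    focal: str = "g2",
    strata: pd.Series | np.ndarray | dict | None = None,
) -> pd.DataFrame:
    """Average marginal effect of the focal (additively coded) SNP per stratum.

    For a binomial fit, AME = mean over stratum observations of
    dP/d(focal) = p (1 - p) * d(eta)/d(focal); for a gaussian fit it is the
    mean linear derivative. Standard errors are delta-method, using the
    analytic gradient of the AME with respect to the coefficient vector.
    ``strata`` maps each observation to a stratum label (e.g. g1 genotype x
    sex); None computes a single overall AME. Empty strata are omitted.
    """
    X = fit.design
    theta = fit.params.to_numpy()
    V = fit.cov_params.to_numpy()
    dX = _focal_derivative_design(X, focal)
    eta = X.to_numpy() @ theta
    deta = dX.to_numpy() @ theta
    if fit.family == "binomial":
        p = 1.0 / (1.0 + np.exp(-eta))
        w1 = p * (1 - p)  # sigma'
        w2 = w1 * (1 - 2 * p)  # sigma''
        unit = w1 * deta
        # d(unit_i)/d(theta) = sigma''(eta) x_i deta_i + sigma'(eta) dx_i
        grad_rows = w2[:, None] * X.to_numpy() * deta[:, None] + w1[:, None] * dX.to_numpy()
    else:
        unit = deta
        grad_rows = dX.to_numpy()
    if strata is None:
        groups = {"all": np.ones(len(X), dtype=bool)}
    elif isinstance(strata, dict):
        groups = {k: np.asarray(v, bool) for k, v in strata.items()}
    else:
        lab = np.asarray(strata)
        groups = {k: lab == k for k in pd.unique(lab)}
    rows = []
    for name, mask in groups.items():
        m = int(mask.sum())
        if m == 0:
            warnings.warn(f"stratum {name!r} is empty; omitted", stacklevel=2)
            continue
        ame = float(unit[mask].mean())
        g = grad_rows[mask].mean(axis=0)
        se = float(np.sqrt(g @ V @ g))
        rows.append({"stratum": name, "ame": ame, "se": se, "n": m})
    return pd.DataFrame(rows)


def studentized_outlier_filter(
    y, X, cutoff: float = 4.0
) -> tuple[np.ndarray, int]:
    """Remove gross outliers on externally studentized residuals.

    Fits the covariate-only linear model, computes externally studentized
    residuals and drops observations with |t| > cutoff (default 4, which
    removes essentially nothing from clean Gaussian data). Returns the
    retained index array (into the original observations) and the removed
    count; warns when more than 10% of samples are dropped.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not (X == 1).all(axis=0).any():
        X = np.column_stack([np.ones(len(y)), X])
    res = sm.OLS(y, X).fit()
    from statsmodels.stats.outliers_influence import OLSInfluence

    t = OLSInfluence(res).resid_studentized_external
    keep = np.abs(t) <= cutoff
    n_removed = int((~keep).sum())
    if n_removed > 0.10 * len(y):
        warnings.warn(
            f"outlier filter removed {n_removed}/{len(y)} observations (> 10%)",
            stacklevel=2,
        )
    return np.flatnonzero(keep), n_removed
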