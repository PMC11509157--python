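"""Log-link count regression: Poisson and negative binomial GLMs with an
optional log-exposure offset, likelihood-ratio analysis of deviance,
backward AIC term selection, Pearson chi-square goodness of fit, one-way
ANOVA and Wald contrasts.

The negative binomial family is NB2 (variance mu + mu^2/theta) with the
dispersion theta estimated jointly with the coefficients by maximum
likelihood; statsmodels provides the optimizer. Random grouping effects are
out of scope — repeated assessment dates enter as a fixed factor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import patsy
from scipy import stats
import statsmodels.formula.api as smf

Family = Literal["poisson", "negative_binomial"]

__all__ = [
    "ModelSpec",
    "FittedCountModel",
    "LRTResult",
    "GofResult",
    "AnovaResult",
    "fit",
    "anova_deviance",
    "deviance_table",
    "backward_aic",
    "pearson_gof",
    "oneway_anova",
    "wald_contrast",
    "ConvergenceError",
    "RankDeficiencyError",
    "DegenerateDataError",
]


class ConvergenceError(RuntimeError):
    """The likelihood maximizer did not converge."""


class RankDeficiencyError(ValueError):
    """The design matrix is not full column rank."""


class DegenerateDataError(ValueError):
    """The data admit no well-defined statistic (e.g. zero variance ANOVA)."""


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one count regression.

    ``terms`` are patsy term strings over data-frame columns, e.g.
    ``"distance_to_border"``, ``"C(variety)"`` or the interaction
    ``"has_traps:distance_to_border"``. ``offset`` names a strictly positive
    exposure column that enters as log(exposure).
    """

    family: Family
    response: str
    terms: tuple[str, ...]
    offset: str | None = None

    def __post_init__(self) -> None:
        if self.family not in ("poisson", "negative_binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        object.__setattr__(self, "terms", tuple(self.terms))

    @property
    def formula(self) -> str:
        rhs = " + ".join(self.terms) if self.terms else "1"
        return f"{self.response} ~ {rhs}"

    def without(self, term: str) -> "ModelSpec":
        if term not in self.terms:
            raise ValueError(f"term {term!r} not in spec")
        return ModelSpec(
            self.family, self.response,
            tuple(t for t in self.terms if t != term), self.offset,
        )


def _term_factors(term: str) -> frozenset[str]:
    return frozenset(f.strip() for f in term.split(":"))


def _is_marginal_to(term: str, other: str) -> bool:
    """True when `term` is a lower-order component of `other` (e.g. a main
    effect of an interaction), so marginality forbids dropping it first."""
    a, b = _term_factors(term), _term_factors(other)
    return a != b and a < b


@dataclass
class FittedCountModel:
    """A converged count regression: coefficients, covariance and fit stats.

    ``coefficients``/``covariance`` cover the linear predictor only; for a
    negative binomial fit the jointly estimated dispersion is ``theta``
    (``None`` for Poisson) but it still counts toward ``p`` and the AIC.
    """

    spec: ModelSpec
    coefficients: pd.Series
    covariance: pd.DataFrame
    theta: float | None
    loglik: float
    aic: float
    n: int
    p: int
    fitted_means: np.ndarray
    _design_info: object = field(repr=False, default=None)
    _result: object = field(repr=False, default=None)

    @property
    def family(self) -> Family:
        return self.spec.family

    def design_matrix(self, data: pd.DataFrame) -> np.ndarray:
        """Design matrix for new data under this model's factor coding."""
        (mat,) = patsy.build_design_matrices([self._design_info], data)
        return np.asarray(mat)

    def predict(
        self, data: pd.DataFrame, offset: np.ndarray | float = 0.0
    ) -> pd.DataFrame:
        """Mean predictions with delta-method standard errors.

        ``offset`` is the log-exposure for the new rows; the default 0 gives
        rates per unit exposure. Returns columns ``mean``, ``se``,
        ``linpred``, ``se_linpred``.
        """
        X = self.design_matrix(data)
        beta = self.coefficients.to_numpy()
        eta = X @ beta + np.asarray(offset)
        var_eta = np.einsum("ij,jk,ik->i", X, self.covariance.to_numpy(), X)
        se_eta = np.sqrt(np.maximum(var_eta, 0.0))
        mu = np.exp(eta)
        return pd.DataFrame(
            {"mean": mu, "se": mu * se_eta, "linpred": eta, "se_linpred": se_eta}
        )


def _validate(spec: ModelSpec, data: pd.DataFrame) -> np.ndarray | None:
    y = data[spec.response].to_numpy()
    if np.any(y < 0):
        raise ValueError(f"response {spec.response!r} has negative values")
    if not np.allclose(y, np.round(y)):
        raise ValueError(f"response {spec.response!r} must be integer counts")
    if spec.offset is None:
        return None
    exposure = data[spec.offset].to_numpy(dtype=float)
    if np.any(exposure <= 0):
        raise ValueError(f"offset column {spec.offset!r} must be strictly positive")
    return np.log(exposure)


def fit(spec: ModelSpec, data: pd.DataFrame) -> FittedCountModel:
    """Maximum-likelihood fit of the spec on a data frame.

    Raises ``RankDeficiencyError`` for collinear designs, ``ConvergenceError``
    when the optimizer fails, ``ValueError`` for invalid responses/offsets.
    """
    offset = _validate(spec, data)
    kwargs = {} if offset is None else {"offset": offset}
    cls = smf.poisson if spec.family == "poisson" else smf.negativebinomial
    model = cls(spec.formula, data=data, **kwargs)
    exog = np.asarray(model.exog)
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise RankDeficiencyError(f"design matrix of {spec.formula!r} is rank deficient")
    if exog.shape[0] < exog.shape[1]:  # saturated designs are allowed
        raise ValueError("need at least as many observations as parameters")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        start = None
        pois = None
        boundary = False
        if spec.family == "negative_binomial":
            # seed the NB optimizer from the Poisson solution
            pois = smf.poisson(spec.formula, data=data, **kwargs).fit(
                disp=0, maxiter=200
            )
            start = np.append(pois.params.to_numpy(), 0.1)
            # equi/underdispersed residuals put the NB MLE on the alpha=0
            # boundary (the moment estimate of alpha is <= 0): skip straight
            # to the Poisson limit instead of letting Newton oscillate there
            mu = np.asarray(pois.predict())
            y = np.asarray(model.endog)
            chi2 = float(np.sum((y - mu) ** 2 / mu))
            disp = chi2 / (exog.shape[0] - exog.shape[1])
            boundary = disp <= 1.0
        res = None
        methods = () if boundary else ("newton", "bfgs", "lbfgs", "nm")
        for method in methods:
            try:
                cand = model.fit(
                    disp=0, maxiter=500, method=method, start_params=start
                )
                if not cand.mle_retvals.get("converged", False):
                    continue
                if not np.all(np.isfinite(cand.params)):
                    continue
                if "alpha" in cand.params and cand.params["alpha"] < 1e-5:
                    # equi/underdispersed data push alpha to its 0 boundary,
                    # where the NB Hessian is singular: use the Poisson limit
                    boundary = True
                    continue
                if method == "nm":  # no Hessian from Nelder-Mead: polish
                    cand = model.fit(
                        disp=0, maxiter=200, method="bfgs",
                        start_params=cand.params.to_numpy(),
                    )
                if not np.all(np.isfinite(np.asarray(cand.cov_params()))):
                    continue
            except Exception:
                continue
            res = cand
            break

    # fall back to the Poisson limit on the alpha=0 boundary, or when the
    # data are barely overdispersed and no interior optimum is reachable
    if res is None and pois is not None and pois.mle_retvals.get(
        "converged", False
    ) and (boundary or disp < 1.2):
        p = int(pois.df_model + 2)  # alpha still counts as estimated
        return FittedCountModel(
            spec=spec,
            coefficients=pois.params,
            covariance=pois.cov_params(),
            theta=1e6,
            loglik=float(pois.llf),
            aic=float(2 * p - 2 * pois.llf),
            n=int(pois.nobs),
            p=p,
            fitted_means=np.asarray(pois.predict()),
            _design_info=model.data.design_info,
            _result=pois,
        )
    if res is None:
        raise ConvergenceError(f"fit of {spec.formula!r} did not converge")

    params = res.params
    cov = res.cov_params()
    theta = None
    if spec.family == "negative_binomial":
        alpha = float(params["alpha"])
        theta = 1.0 / max(alpha, 1e-6)
        params = params.drop("alpha")
        cov = cov.drop(index="alpha", columns="alpha")
    p = int(res.df_model + 1 + (1 if spec.family == "negative_binomial" else 0))
    return FittedCountModel(
        spec=spec,
        coefficients=params,
        covariance=cov,
        theta=theta,
        loglik=float(res.llf),
        aic=float(res.aic),
        n=int(res.nobs),
        p=p,
        fitted_means=np.asarray(res.predict()),
        _design_info=model.data.design_info,
        _result=res,
    )


@dataclass(frozen=True)
class LRTResult:
    statistic: float
    df: int
    pvalue: float
    term: str | None = None


def anova_deviance(full: FittedCountModel, reduced: FittedCountModel) -> LRTResult:
    """Likelihood-ratio test of a reduced model nested in a full model."""
    if full.spec.family != reduced.spec.family or full.n != reduced.n:
        raise ValueError("models must share family and data")
    if not set(reduced.spec.terms) <= set(full.spec.terms):
        raise ValueError("reduced model is not nested in the full model")
    stat = max(0.0, 2.0 * (full.loglik - reduced.loglik))
    df = full.p - reduced.p
    if df < 0:
        raise ValueError("reduced model has more parameters than the full model")
    pvalue = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return LRTResult(stat, df, pvalue)


def deviance_table(
    spec: ModelSpec, data: pd.DataFrame, kind: Literal["II", "III"] = "II"
) -> list[LRTResult]:
    """Analysis of deviance: one likelihood-ratio test per term.

    Type III drops each term from the full model. Type II compares, for each
    term, the model of all terms not containing it plus the term against the
    same model without it, so main effects are tested ignoring their own
    interactions. Treatment coding throughout.
    """
    out: list[LRTResult] = []
    for term in spec.terms:
        if kind == "III":
            full_terms = spec.terms
        else:
            full_terms = tuple(
                t for t in spec.terms
                if t == term or not _is_marginal_to(term, t)
            )
        full = fit(ModelSpec(spec.family, spec.response, full_terms, spec.offset), data)
        red_terms = tuple(t for t in full_terms if t != term)
        red = fit(ModelSpec(spec.family, spec.response, red_terms, spec.offset), data)
        r = anova_deviance(full, red)
        out.append(LRTResult(r.statistic, r.df, r.pvalue, term))
    return out


def _term_max_abs_z(model: FittedCountModel, term: str) -> float:
    di = model._design_info
    cols = []
    for t, sl in zip(di.terms, di.term_slices.values()):
        if t.name() == term:
            cols = list(range(sl.start, sl.stop))
    if not cols:
        return np.inf
    beta = model.coefficients.to_numpy()
    se = np.sqrt(np.diag(model.covariance.to_numpy()))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.abs(beta[cols] / se[cols])
    return float(np.nanmax(z))


def backward_aic(
    spec: ModelSpec, data: pd.DataFrame
) -> tuple[FittedCountModel, list[dict]]:
    """Backward elimination on AIC with marginality respected.

    At each step every currently droppable term (one not contained in a
    remaining interaction) is removed in turn; the drop lowering AIC most is
    taken, AIC ties broken by the smaller maximum |Wald z| of the term.
    Returns the minimum-AIC model and a drop log.
    """
    current = fit(spec, data)
    log: list[dict] = []
    while current.spec.terms:
        droppable = [
            t for t in current.spec.terms
            if not any(_is_marginal_to(t, o) for o in current.spec.terms)
        ]
        candidates = []
        for term in droppable:
            sub_spec = current.spec.without(term)
            try:
                sub = fit(sub_spec, data)
            except (ConvergenceError, RankDeficiencyError) as exc:
                raise type(exc)(f"while dropping {term!r}: {exc}") from exc
            candidates.append((sub.aic, _term_max_abs_z(current, term), term, sub))
        best = min(candidates, key=lambda c: (c[0], c[1]))
        if best[0] >= current.aic:
            break
        log.append({"dropped": best[2], "aic_before": current.aic, "aic_after": best[0]})
        current = best[3]
    return current, log


@dataclass(frozen=True)
class GofResult:
    statistic: float
    df: int
    pvalue: float
    dispersion: float


def pearson_gof(model: FittedCountModel, y: np.ndarray | None = None) -> GofResult:
    """Pearson chi-square goodness of fit with the family variance.

    The dispersion ratio chi2/df is the single-number check for residual
    overdispersion (about 1 for a well-specified model).
    """
    if y is None:
        y = np.asarray(model._result.model.endog)
    mu = model.fitted_means
    var = mu if model.theta is None else mu + mu**2 / model.theta
    chi2 = float(np.sum((y - mu) ** 2 / var))
    df = model.n - model.p
    return GofResult(chi2, df, float(stats.chi2.sf(chi2, df)), chi2 / df)


@dataclass(frozen=True)
class AnovaResult:
    statistic: float
    df1: int
    df2: int
    pvalue: float


def oneway_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA across >= 2 groups."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least two nonempty groups")
    n = sum(len(g) for g in groups)
    k = len(groups)
    if n <= k:
        raise ValueError("need more observations than groups")
    grand = np.concatenate(groups).mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1, df2 = k - 1, n - k
    if ss_within == 0:
        raise DegenerateDataError("zero within-group variance: F undefined")
    f = (ss_between / df1) / (ss_within / df2)
    return AnovaResult(float(f), df1, df2, float(stats.f.sf(f, df1, df2)))


def wald_contrast(
    model: FittedCountModel, contrast: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wald z-test of c'beta = 0. Returns (z, p)."""
    c = np.asarray(contrast, dtype=float)
    beta = model.coefficients.to_numpy()
    if c.shape != beta.shape:
        raise ValueError(f"contrast length {c.size} != {beta.size} coefficients")
    num = float(c @ beta)
    var = float(c @ model.covariance.to_numpy() @ c)
    if var <= 0:
        if num == 0:
            return 0.0, 1.0
        raise ValueError("singular covariance for this contrast")
    z = num / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))
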