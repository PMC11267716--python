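"""Copy-number / insecticide-survival association via logistic regression.

The response is the bioassay outcome after insecticide exposure (alive = 1,
i.e. resistant, so an odds ratio above 1 for the copy-number term indicates
a resistance association). Copy number enters as a linear integer dose; a
covariate locus (e.g. Ace1 copy number, the established organophosphate
resistance locus) is included to control for confounding. Fits use
iteratively reweighted least squares with step-halving, which guarantees the
log-likelihood is non-decreasing across iterations; Wald standard errors
give 95% confidence intervals and p-values. Multi-site data are pooled with
fixed-effect location indicators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "AssociationResult",
    "fit_logistic",
    "per_location_association",
    "pooled_association",
]

SEPARATION_BOUND = 15.0
_Z95 = 1.96


@dataclass
class AssociationResult:
    """Fitted logistic model: per-term estimates and model-level summaries.

    ``table`` is indexed by term with columns ``estimate`` (log-odds), ``se``,
    ``odds_ratio``, ``ci_low``, ``ci_high`` (Wald 95%, on the OR scale) and
    ``p_value`` (Wald z). ``loglik_trace`` records the log-likelihood at each
    IRLS iteration (non-decreasing by construction).
    """

    table: pd.DataFrame
    deviance: float
    n: int
    converged: bool
    separation: bool = False
    loglik_trace: list[float] = field(default_factory=list)

    def odds_ratio(self, term: str) -> float:
        return float(self.table.loc[term, "odds_ratio"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.table.loc[term]
        return float(row["ci_low"]), float(row["ci_high"])

    def p_value(self, term: str) -> float:
        return float(self.table.loc[term, "p_value"])


def _bernoulli_loglik(y: np.ndarray, eta: np.ndarray) -> float:
    # numerically stable: log p = -log(1+exp(-eta)) for y=1, etc.
    return float(-(np.logaddexp(0.0, -eta) * y + np.logaddexp(0.0, eta) * (1 - y)).sum())


def fit_logistic(
    design: pd.DataFrame | np.ndarray,
    response: np.ndarray,
    *,
    term_names: list[str] | None = None,
    add_intercept: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> AssociationResult:
    """Maximum-likelihood logistic fit by IRLS with step-halving.

    Convergence is declared when the maximum absolute coefficient change
    falls below ``tol``. Perfect (or quasi-) separation is detected as a
    coefficient diverging beyond ``SEPARATION_BOUND``; the fit is then
    flagged non-converged and a warning is emitted, but estimates are still
    reported. A constant response is an error.
    """
    if isinstance(design, pd.DataFrame):
        term_names = list(design.columns)
        X = design.to_numpy(dtype=float)
    else:
        X = np.asarray(design, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if term_names is None:
            term_names = [f"x{i}" for i in range(X.shape[1])]
    y = np.asarray(response, dtype=float)
    if y.ndim != 1 or X.shape[0] != y.size:
        raise ValueError("design and response dimensions do not match")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("response must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("response is constant; logistic model is undefined")
    if add_intercept:
        X = np.column_stack([np.ones(y.size), X])
        term_names = ["intercept"] + term_names
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than predictors ({p})")

    beta = np.zeros(p)
    loglik = _bernoulli_loglik(y, X @ beta)
    trace = [loglik]
    converged = False
    for _ in range(max_iter):
        eta = X @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        xtw = X.T * w
        try:
            new_beta = np.linalg.solve(xtw @ X, xtw @ z)
        except np.linalg.LinAlgError as exc:
            raise ValueError("singular design matrix in IRLS") from exc
        # step-halving keeps the log-likelihood non-decreasing
        step = new_beta - beta
        new_loglik = _bernoulli_loglik(y, X @ (beta + step))
        halvings = 0
        while new_loglik < loglik and halvings < 30:
            step /= 2.0
            new_loglik = _bernoulli_loglik(y, X @ (beta + step))
            halvings += 1
        delta = float(np.abs(step).max())
        beta = beta + step
        loglik = max(new_loglik, loglik)
        trace.append(loglik)
        if delta < tol:
            converged = True
            break

    separation = bool(np.abs(beta).max() > SEPARATION_BOUND)
    if separation:
        converged = False
        warnings.warn(
            "possible perfect separation: a coefficient exceeds "
            f"|{SEPARATION_BOUND}|; estimates are unreliable",
            stacklevel=2,
        )

    mu = expit(X @ beta)
    w = np.clip(mu * (1 - mu), 1e-10, None)
    cov = np.linalg.inv((X.T * w) @ X)
    se = np.sqrt(np.diag(cov))
    zscores = beta / se
    pvals = 2 * norm.sf(np.abs(zscores))
    with np.errstate(over="ignore"):  # separated fits can overflow exp()
        table = pd.DataFrame(
            {
                "estimate": beta,
                "se": se,
                "odds_ratio": np.exp(beta),
                "ci_low": np.exp(beta - _Z95 * se),
                "ci_high": np.exp(beta + _Z95 * se),
                "p_value": pvals,
            },
            index=pd.Index(term_names, name="term"),
        )
    return AssociationResult(
        table=table,
        deviance=-2.0 * loglik,
        n=n,
        converged=converged,
        separation=separation,
        loglik_trace=trace,
    )


@dataclass
class LocationAssociation:
    """Single-location association outcome: either a fit or a skip reason."""

    location: str
    result: AssociationResult | None
    skip_reason: str | None = None


def _check_columns(samples: pd.DataFrame, cols: list[str]) -> None:
    missing = [c for c in cols if c not in samples.columns]
    if missing:
        raise ValueError(f"samples table lacks columns: {missing}")


def per_location_association(
    samples: pd.DataFrame,
    location: str,
    *,
    cnv_col: str = "cnv_copy_number",
    covariate_col: str = "covariate_copy_number",
    phenotype_col: str = "phenotype",
    location_col: str = "location",
    min_samples: int = 20,
) -> LocationAssociation:
    """Copy-number association at a single location.

    Fits phenotype ~ CNV copy number + covariate copy number on the
    location's samples. If the CNV is monomorphic at the location the test is
    skipped with an explicit reason (no information in the predictor) rather
    than raising.
    """
    _check_columns(samples, [cnv_col, covariate_col, phenotype_col, location_col])
    sub = samples[samples[location_col] == location]
    if len(sub) < min_samples:
        raise ValueError(
            f"location {location!r} has {len(sub)} samples; need >= {min_samples}"
        )
    if sub[phenotype_col].nunique() < 2:
        raise ValueError(f"location {location!r} has a single phenotype class")
    if sub[cnv_col].nunique() < 2:
        return LocationAssociation(
            location,
            None,
            skip_reason=(
                f"CNV copy number is monomorphic (= {int(sub[cnv_col].iloc[0])}) "
                f"across all {len(sub)} samples at {location!r}"
            ),
        )
    design = sub[[cnv_col, covariate_col]].astype(float)
    result = fit_logistic(design, sub[phenotype_col].to_numpy())
    return LocationAssociation(location, result)


def pooled_association(
    samples: pd.DataFrame,
    *,
    cnv_col: str = "cnv_copy_number",
    covariate_col: str = "covariate_copy_number",
    phenotype_col: str = "phenotype",
    location_col: str = "location",
) -> AssociationResult:
    """Association pooled across locations with fixed location effects.

    Fits phenotype ~ CNV + covariate + location indicators (first location,
    in sorted order, is the reference). Requires the CNV to segregate in at
    least two locations; with a single location use
    :func:`per_location_association` instead.
    """
    _check_columns(samples, [cnv_col, covariate_col, phenotype_col, location_col])
    locations = sorted(samples[location_col].unique())
    segregating = [
        loc
        for loc in locations
        if samples.loc[samples[location_col] == loc, cnv_col].nunique() > 1
    ]
    if len(locations) < 2:
        raise ValueError(
            "pooled model needs >= 2 locations; use per_location_association"
        )
    if len(segregating) < 2:
        raise ValueError(
            f"CNV segregates in only {len(segregating)} location(s) "
            f"({segregating}); pooling is not informative"
        )
    design = samples[[cnv_col, covariate_col]].astype(float).copy()
    for loc in locations[1:]:
        design[f"location[{loc}]"] = (samples[location_col] == loc).astype(float)
    return fit_logistic(design, samples[phenotype_col].to_numpy())
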