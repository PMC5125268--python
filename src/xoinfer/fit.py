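"""Maximum-likelihood fitting of the interference-escape parameters.

Optimization runs on transformed coordinates (log nu, logit p) with
Nelder-Mead; standard errors come from the inverse numerical Hessian of
the negative log-likelihood at the optimum, mapped back to the natural
scale by the delta method.  Fits are available for a pooled dataset, per
chromosome (with the interference-vs-map-length regression), and per
parent (with the offspring-count inclusion thresholds used for
association phenotypes).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize

from .core import EstimateRecord, HSParameters, IntervalData
from .model import CompiledDataset

logger = logging.getLogger(__name__)

_LOGIT_CLIP = 1e-6
DEFAULT_INIT = HSParameters(7.0, 0.05)
START_GRID = [
    HSParameters(nu, p) for nu in (3.0, 7.0, 12.0) for p in (0.01, 0.1)
]
MIN_OFFSPRING_MALE = 15  # strictly more than this many offspring required
MIN_OFFSPRING_FEMALE = 3

__all__ = [
    "fit_hs",
    "fit_per_individual",
    "fit_per_chromosome",
    "DEFAULT_INIT",
    "MIN_OFFSPRING_MALE",
    "MIN_OFFSPRING_FEMALE",
]


def _to_theta(params: HSParameters) -> np.ndarray:
    p = np.clip(params.p, _LOGIT_CLIP, 1.0 - _LOGIT_CLIP)
    return np.array([np.log(params.nu), np.log(p / (1.0 - p))])


def _from_theta(theta: np.ndarray) -> HSParameters:
    nu = float(np.exp(np.clip(theta[0], -20.0, 20.0)))
    p = float(1.0 / (1.0 + np.exp(-np.clip(theta[1], -40.0, 40.0))))
    return HSParameters(nu, p)


def _hessian_se(
    objective, theta: np.ndarray, step: float = 1e-4
) -> tuple[float | None, float | None]:
    """Delta-method SEs of (nu, p) from a central-difference Hessian of the
    negative log-likelihood on the transformed scale."""
    k = len(theta)
    hess = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k)
            ej = np.zeros(k)
            ei[i] = step
            ej[j] = step
            fpp = objective(theta + ei + ej)
            fpm = objective(theta + ei - ej)
            fmp = objective(theta - ei + ej)
            fmm = objective(theta - ei - ej)
            hess[i, j] = hess[j, i] = (fpp - fpm - fmp + fmm) / (4.0 * step**2)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        return None, None
    if np.any(np.diag(cov) <= 0) or not np.all(np.isfinite(cov)):
        return None, None
    params = _from_theta(theta)
    # dnu/dlog(nu) = nu ; dp/dlogit(p) = p (1 - p)
    jac = np.array([params.nu, params.p * (1.0 - params.p)])
    se = np.sqrt(np.diag(cov)) * jac
    return float(se[0]), float(se[1])


def fit_hs(
    dataset: Sequence[IntervalData] | CompiledDataset,
    init: HSParameters | None = None,
    scope: str = "genome",
    xatol: float = 1e-6,
    maxfev: int = 2000,
    compute_se: bool = True,
) -> EstimateRecord:
    """Fit (nu, p) by Nelder-Mead on (log nu, logit p).

    The log-likelihood is first screened on a small (nu, p) grid and the
    simplex starts from the best grid point (or a caller-supplied init if
    it scores better), which selects the right basin without the cost of
    a full restart per grid point.
    """
    compiled = (
        dataset if isinstance(dataset, CompiledDataset) else CompiledDataset(dataset)
    )

    def objective(theta: np.ndarray) -> float:
        return -compiled.loglik(_from_theta(theta))

    starts = list(START_GRID) + ([init] if init is not None else [])
    best_start = max(starts, key=lambda s: compiled.loglik(s))
    res = minimize(
        objective,
        _to_theta(best_start),
        method="Nelder-Mead",
        options={"xatol": xatol, "fatol": xatol, "maxfev": maxfev},
    )
    params = _from_theta(res.x)
    se_nu = se_p = None
    if compute_se and res.success:
        se_nu, se_p = _hessian_se(objective, res.x)
    if not res.success:
        logger.warning("fit (%s) did not converge: %s", scope, res.message)
    return EstimateRecord(
        scope=scope,
        nu_hat=params.nu,
        p_hat=params.p,
        se_nu=se_nu,
        se_p=se_p,
        loglik=float(-res.fun),
        n_meioses=compiled.n_meioses,
        converged=bool(res.success),
    )


def fit_per_individual(
    intervals_by_parent: Mapping[str, Sequence[IntervalData]],
    sex_by_parent: Mapping[str, str],
    n_offspring_by_parent: Mapping[str, int] | None = None,
    min_offspring_male: int = MIN_OFFSPRING_MALE,
    min_offspring_female: int = MIN_OFFSPRING_FEMALE,
    compute_se: bool = True,
    xatol: float = 1e-4,
) -> list[EstimateRecord]:
    """Per-parent fits over pooled autosomes, for association phenotypes.

    A parent enters only with strictly more offspring than the
    sex-specific threshold (bulls: >15, cows: >3).  When offspring counts
    are not supplied, each interval record is assumed to be one offspring;
    pass counts explicitly for multi-chromosome data, where a parent
    contributes several records per offspring.
    """
    records = []
    for parent, data in intervals_by_parent.items():
        n_off = (
            n_offspring_by_parent[parent]
            if n_offspring_by_parent is not None
            else len(data)
        )
        sex = sex_by_parent[parent]
        threshold = min_offspring_male if sex == "male" else min_offspring_female
        if n_off <= threshold:
            continue
        rec = fit_hs(
            list(data), scope=f"parent:{parent}", compute_se=compute_se, xatol=xatol
        )
        records.append(rec)
    return records


def fit_per_chromosome(
    intervals_by_chromosome: Mapping[str, Sequence[IntervalData]],
    lengths_morgans: Mapping[str, float] | None = None,
) -> tuple[list[EstimateRecord], pd.DataFrame | None]:
    """One fit per chromosome plus the interference/escape vs map-length
    ordinary regressions (intercept, slope, P, R-squared per parameter)."""
    records = []
    lengths = []
    for chrom, data in intervals_by_chromosome.items():
        if len(data) == 0:
            logger.warning("chromosome %s has no meioses; skipped", chrom)
            continue
        rec = fit_hs(list(data), scope=f"chrom:{chrom}")
        records.append(rec)
        if lengths_morgans is not None:
            lengths.append(lengths_morgans[chrom])
        else:
            lengths.append(max(d.length for d in data))
    if len(records) < 3:
        return records, None
    x = sm.add_constant(np.asarray(lengths, dtype=float))
    rows = []
    for name, y in (
        ("interference", np.array([r.nu_hat for r in records])),
        ("escape", np.array([r.p_hat for r in records])),
    ):
        ols = sm.OLS(y, x).fit()
        rows.append(
            {
                "parameter": name,
                "intercept": float(ols.params[0]),
                "slope": float(ols.params[1]),
                "p_value": float(ols.pvalues[1]),
                "r_squared": float(ols.rsquared),
            }
        )
    return records, pd.DataFrame(rows)
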