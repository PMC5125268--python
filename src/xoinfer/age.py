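"""Maternal-age grouping, count-matched subsampling, and trend tests.

Female meioses are split into K age quantile groups (default 8).  To
remove the recombination-rate confound — older or younger dams with more
crossovers necessarily have shorter inter-crossover distances — groups
are subsampled so that every group carries the *exact same* distribution
of crossover counts per meiosis: for each count x, n(x) = min over
groups of N_i(x) meioses with that count are drawn without replacement
from each group, and the draw is repeated several times (default 10).
Group-level parameter estimates are then regressed on mean group age.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .core import EstimateRecord

__all__ = [
    "AgeGroupAssignment",
    "assign_age_groups",
    "stratified_subsample",
    "fit_age_trend",
    "age_trend_pipeline",
]


@dataclass
class AgeGroupAssignment:
    """One age quantile group with its members and count tallies."""

    group_index: int  # 1..K
    age_low: float
    age_high: float
    member_ids: list[str]

    def count_tally(self, counts: Mapping[str, int]) -> dict[int, int]:
        """N_i(x): members with x crossovers, per x."""
        tally: dict[int, int] = {}
        for m in self.member_ids:
            x = int(counts[m])
            tally[x] = tally.get(x, 0) + 1
        return tally


def assign_age_groups(
    ages: Mapping[str, float] | pd.Series, k: int = 8
) -> list[AgeGroupAssignment]:
    """Partition meioses into K age quantile groups.

    Boundary ages go to the lower group; with distinct ages the group
    sizes differ by at most one.
    """
    ages = pd.Series(dict(ages), dtype=float) if not isinstance(ages, pd.Series) else ages
    if ages.isna().any():
        raise ValueError("all meioses must carry an age")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > ages.nunique():
        raise ValueError(f"k={k} exceeds the {ages.nunique()} distinct ages")
    cuts = np.quantile(ages.to_numpy(), np.arange(1, k) / k)
    group = np.searchsorted(cuts, ages.to_numpy(), side="left")
    out = []
    for g in range(k):
        members = ages.index[group == g].tolist()
        in_g = ages.to_numpy()[group == g]
        out.append(
            AgeGroupAssignment(
                group_index=g + 1,
                age_low=float(in_g.min()) if len(in_g) else float("nan"),
                age_high=float(in_g.max()) if len(in_g) else float("nan"),
                member_ids=members,
            )
        )
    return out


def stratified_subsample(
    groups: Sequence[AgeGroupAssignment],
    counts: Mapping[str, int],
    repeats: int = 10,
    seed: int | np.random.Generator = 0,
) -> list[dict[int, list[str]]]:
    """Count-matched subsets: one dict {group_index: member ids} per repeat.

    For every crossover count x, each group contributes exactly
    n(x) = min_i N_i(x) meioses with that count, drawn without
    replacement, so the count distribution is identical across groups by
    construction.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g.member_ids) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    tallies = [g.count_tally(counts) for g in groups]
    all_x = sorted(set().union(*[set(t) for t in tallies]))
    n_of_x = {x: min(t.get(x, 0) for t in tallies) for x in all_x}
    by_count = [
        {
            x: [m for m in g.member_ids if int(counts[m]) == x]
            for x in all_x
        }
        for g in groups
    ]
    out: list[dict[int, list[str]]] = []
    for _ in range(repeats):
        draw: dict[int, list[str]] = {}
        for g, pools in zip(groups, by_count):
            chosen: list[str] = []
            for x in all_x:
                n = n_of_x[x]
                if n == 0:
                    continue
                pool = pools[x]
                pick = rng.choice(len(pool), size=n, replace=False)
                chosen.extend(pool[i] for i in pick)
            draw[g.group_index] = chosen
        out.append(draw)
    return out


def fit_age_trend(
    group_estimates: Sequence[tuple[float, EstimateRecord]],
) -> dict[str, pd.DataFrame]:
    """Regress per-group estimates on mean group age.

    ``group_estimates`` pairs each group's mean age (months) with its
    fitted record.  Returns a trend table (slope, R-squared, P per
    parameter) and a per-group table with 95% confidence intervals
    (estimate +/- 1.96 SE).
    """
    if len(group_estimates) < 3:
        raise ValueError("need at least three groups for a trend")
    ages = np.array([a for a, _ in group_estimates], dtype=float)
    x = sm.add_constant(ages)
    trend_rows = []
    for name, vals in (
        ("interference", np.array([r.nu_hat for _, r in group_estimates])),
        ("escape", np.array([r.p_hat for _, r in group_estimates])),
    ):
        if np.ptp(vals) == 0:
            trend_rows.append(
                {"parameter": name, "intercept": float(vals[0]), "slope": 0.0,
                 "p_value": 1.0, "r_squared": 0.0}
            )
            continue
        ols = sm.OLS(vals, x).fit()
        trend_rows.append(
            {
                "parameter": name,
                "intercept": float(ols.params[0]),
                "slope": float(ols.params[1]),
                "p_value": float(ols.pvalues[1]),
                "r_squared": float(ols.rsquared),
            }
        )
    group_rows = []
    for age, rec in group_estimates:
        for name, est, se in (
            ("interference", rec.nu_hat, rec.se_nu),
            ("escape", rec.p_hat, rec.se_p),
        ):
            half = 1.96 * se if se is not None and np.isfinite(se) else np.nan
            group_rows.append(
                {
                    "mean_age_months": age,
                    "parameter": name,
                    "estimate": est,
                    "ci_low": est - half if np.isfinite(half) else np.nan,
                    "ci_high": est + half if np.isfinite(half) else np.nan,
                    "n_meioses": rec.n_meioses,
                }
            )
    return {
        "trend": pd.DataFrame(trend_rows),
        "groups": pd.DataFrame(group_rows),
    }


def age_trend_pipeline(
    intervals_by_meiosis: Mapping[str, "object"],
    ages: Mapping[str, float],
    k: int = 8,
    repeats: int = 10,
    seed: int = 0,
    matched: bool = True,
) -> dict[str, pd.DataFrame]:
    """Group, (optionally) count-match, fit per group, and test the trend.

    ``intervals_by_meiosis`` maps meiosis id to one chromosome's
    ``IntervalData`` (the confound-removal subsampling is defined on a
    single chromosome).  Per-group estimates are averaged over the
    subsampling repeats before the trend regression.
    """
    from .fit import fit_hs  # local import to avoid a cycle

    aged = {m: a for m, a in ages.items() if m in intervals_by_meiosis}
    groups = assign_age_groups(aged, k=k)
    counts = {m: intervals_by_meiosis[m].n for m in aged}
    if matched:
        draws = stratified_subsample(groups, counts, repeats=repeats, seed=seed)
    else:
        draws = [{g.group_index: list(g.member_ids) for g in groups}]

    group_estimates = []
    for g in groups:
        mean_age = float(np.mean([aged[m] for m in g.member_ids]))
        fits = []
        for draw in draws:
            members = draw[g.group_index]
            if not members:
                continue
            fits.append(
                fit_hs(
                    [intervals_by_meiosis[m] for m in members],
                    scope=f"group:{g.group_index}",
                )
            )
        if not fits:
            continue
        avg = EstimateRecord(
            scope=f"group:{g.group_index}",
            nu_hat=float(np.mean([f.nu_hat for f in fits])),
            p_hat=float(np.mean([f.p_hat for f in fits])),
            se_nu=float(np.nanmean([np.nan if f.se_nu is None else f.se_nu for f in fits])),
            se_p=float(np.nanmean([np.nan if f.se_p is None else f.se_p for f in fits])),
            loglik=float(np.mean([f.loglik for f in fits])),
            n_meioses=fits[0].n_meioses,
            converged=all(f.converged for f in fits),
        )
        group_estimates.append((mean_age, avg))
    return fit_age_trend(group_estimates)
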