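"""Cross-species comparative statistics on trait tables.

Survivor curves (fraction of species whose trait exceeds a threshold),
per-taxon medians, ordinary least-squares scaling exponents on log10-log10
axes, and the equality diagnostic between lifetime cumulated neonate mass
and ultimate weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SurvivorCurve",
    "ScalingFit",
    "survivor_curve",
    "loglog_slope",
    "group_medians",
    "equality_diagnostic",
]


@dataclass(frozen=True)
class SurvivorCurve:
    """Empirical survivor function of a trait over a species group.

    ``S(x)`` is the fraction of species whose trait value strictly
    exceeds ``x``; ties count as not exceeding.
    """

    values: np.ndarray          #: sorted non-missing trait values
    group: str = ""             #: group label (e.g. taxon)
    n_missing: int = 0          #: excluded missing values

    @property
    def n(self) -> int:
        return self.values.size

    def __call__(self, x):
        """Evaluate S(x) = P(value > x) at scalar or array x."""
        x = np.asarray(x, dtype=float)
        # number of sorted values <= x, via right-bisection
        n_le = np.searchsorted(self.values, x, side="right")
        return (self.values.size - n_le) / self.values.size


@dataclass(frozen=True)
class ScalingFit:
    """OLS fit of log10(y) on log10(x)."""

    slope: float
    intercept: float
    stderr_slope: float
    stderr_intercept: float
    r_squared: float
    n: int
    log_base: float = 10.0


def survivor_curve(values, group: str = "") -> SurvivorCurve:
    """Build the empirical survivor curve of one trait for one group.

    Missing values (NaN) are excluded and counted; an all-missing input
    is an error.
    """
    values = np.asarray(values, dtype=float)
    missing = ~np.isfinite(values)
    clean = np.sort(values[~missing])
    if clean.size == 0:
        raise ValueError(f"survivor curve for {group or 'group'}: no non-missing values")
    return SurvivorCurve(values=clean, group=group, n_missing=int(missing.sum()))


def loglog_slope(x, y) -> ScalingFit:
    """Ordinary least squares of log10(y) on log10(x).

    Both inputs must be paired, positive and finite with n >= 3; offending
    rows are listed in the error message otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have the same length")
    bad = ~(np.isfinite(x) & np.isfinite(y) & (x > 0) & (y > 0))
    if bad.any():
        rows = np.flatnonzero(bad)
        shown = ", ".join(map(str, rows[:10])) + ("..." if rows.size > 10 else "")
        raise ValueError(
            f"loglog_slope: {rows.size} non-positive/non-finite rows: {shown}"
        )
    if x.size < 3:
        raise ValueError(f"loglog_slope needs n >= 3, got n = {x.size}")
    X = sm.add_constant(np.log10(x))
    res = sm.OLS(np.log10(y), X).fit()
    return ScalingFit(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        stderr_slope=float(res.bse[1]),
        stderr_intercept=float(res.bse[0]),
        r_squared=float(res.rsquared),
        n=int(x.size),
    )


def group_medians(
    table: pd.DataFrame, trait: str, grouping: str = "taxon"
) -> pd.DataFrame:
    """Per-group median of one trait over non-missing values.

    Returns a frame indexed by group with columns ``median`` and ``n``
    (non-missing count).  Even-sized groups use the mean of the central
    pair (the ordinary sample median).
    """
    if trait not in table.columns:
        raise KeyError(f"unknown trait {trait!r}")
    if grouping not in table.columns:
        raise KeyError(f"unknown grouping column {grouping!r}")
    grouped = table.groupby(grouping)[trait]
    out = pd.DataFrame({"median": grouped.median(), "n": grouped.count()})
    out.index.name = grouping
    return out


def equality_diagnostic(table: pd.DataFrame) -> dict:
    """Compare lifetime cumulated neonate mass with ultimate weight.

    Across many taxa the two are observed to be about equal.  The
    diagnostic reports, without asserting: the per-species ratio
    N_mass_life / Ww_i, their geometric mean, and the log-log scaling fit
    of N_mass_life on Ww_i (slope 1 and geometric-mean ratio 1 would be
    exact equality).  Rows with missing inputs propagate as missing in
    the ratios and are excluded from the summary statistics.
    """
    ratio = table["N_mass_life"] / table["Ww_i"]
    ok = np.isfinite(ratio) & (ratio > 0)
    if not ok.any():
        raise ValueError("equality_diagnostic: no complete rows")
    geomean = float(10 ** np.mean(np.log10(ratio[ok])))
    fit = loglog_slope(table.loc[ok, "Ww_i"], table.loc[ok, "N_mass_life"])
    return {
        "ratio": ratio,
        "geometric_mean_ratio": geomean,
        "fit": fit,
        "n": int(ok.sum()),
        "n_missing": int((~ok).sum()),
    }
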