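"""Cumulative water deficit and climate covariate assembly.

Cumulative water deficit (CWD) summarises the drought stress a location
experiences over the annual cycle.  The monthly water balance is
precipitation minus evapotranspiration; deficits carry over month to
month while surplus months reset the running deficit to zero (surplus
water runs off rather than banking):

    D_t = min(0, P_t - E_t + D_{t-1})

CWD is the minimum (most negative) D_t over the year, so CWD <= 0 with
CWD = 0 for a climate wet in every month.  The recursion is run
cyclically (December feeds January) until the 12-month deficit vector is
stable, so the result does not depend on the month the bookkeeping
starts in.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "compute_cwd",
    "compute_cwd_table",
    "covariate_correlations",
    "climate_covariate_table",
]

_MAX_CYCLES = 10


def compute_cwd(precipitation, evapotranspiration) -> float:
    """Cumulative water deficit (mm, <= 0) from 12 monthly values.

    Parameters
    ----------
    precipitation, evapotranspiration : array_like
        12 non-negative monthly totals in mm.

    Returns
    -------
    float
        Minimum cumulative deficit over the converged annual cycle; 0.0
        when precipitation covers evapotranspiration in every month.  A
        year in permanent net deficit never converges; the value after 10
        cycles is returned with a warning.
    """
    p = np.asarray(precipitation, dtype=float)
    e = np.asarray(evapotranspiration, dtype=float)
    if p.shape != (12,) or e.shape != (12,):
        raise ValueError("need exactly 12 monthly values of each series")
    if np.any(p < 0) or np.any(e < 0):
        raise ValueError("monthly precipitation and evapotranspiration must be >= 0")
    balance = p - e
    if np.all(balance >= 0):
        return 0.0
    d = np.zeros(12)
    carry = 0.0
    for cycle in range(_MAX_CYCLES):
        prev = d.copy()
        for t in range(12):
            carry = min(0.0, balance[t] + carry)
            d[t] = carry
        if np.allclose(d, prev, atol=1e-9):
            return float(d.min())
    warnings.warn(
        "cumulative deficit did not stabilise in 10 annual cycles "
        "(net-deficit year with no surplus month); returning capped value"
    )
    return float(d.min())


def compute_cwd_table(monthly: pd.DataFrame) -> pd.DataFrame:
    """CWD per site from a long monthly table.

    ``monthly`` must have columns ``site_id``, ``month`` (1-12),
    ``precipitation`` and ``evapotranspiration``.
    """
    rows = []
    for site_id, grp in monthly.groupby("site_id", sort=False):
        grp = grp.sort_values("month")
        if list(grp["month"]) != list(range(1, 13)):
            raise ValueError(f"site {site_id!r}: need months 1..12 exactly")
        rows.append(
            {
                "site_id": site_id,
                "cwd": compute_cwd(
                    grp["precipitation"].to_numpy(),
                    grp["evapotranspiration"].to_numpy(),
                ),
            }
        )
    return pd.DataFrame(rows)


def climate_covariate_table(
    points: pd.DataFrame, monthly: pd.DataFrame
) -> pd.DataFrame:
    """Per-point climate covariates joined by site.

    Computes CWD from the monthly series and joins it (with MTCM and the
    optional precomputed climate-suitability score carried on the point
    table) onto each point count.  Per-site climate is broadcast to the
    points of the site; per-point values already on ``points`` are kept.
    """
    cwd = compute_cwd_table(monthly).set_index("site_id")["cwd"]
    out = points[["point_count_id", "site_id"]].copy()
    out["cwd"] = points["site_id"].map(cwd).to_numpy()
    if out["cwd"].isna().any():
        missing = sorted(set(points["site_id"]) - set(cwd.index))
        raise ValueError(f"no climate series for sites: {missing}")
    for col in ("mtcm", "climate_sdm"):
        if col in points.columns:
            out[col] = points[col].to_numpy()
    return out


def covariate_correlations(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Pairwise Pearson correlations between design covariates.

    A design diagnostic (e.g. residence time vs climate), not an
    inferential tool.  Zero-variance columns yield NaN entries and a
    warning rather than failing silently.
    """
    cols = list(columns) if columns is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
    ]
    sub = table[cols].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 complete rows")
    degenerate = [c for c in cols if sub[c].nunique() <= 1]
    if degenerate:
        warnings.warn(f"zero-variance columns, correlations undefined: {degenerate}")
    return sub.corr(method="pearson")
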