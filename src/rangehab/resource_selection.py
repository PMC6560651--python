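"""Jacobs-index resource selection from scan-sample focal watches.

At each focal-watch location, habitat availability is recorded as
percentage covers in a 6 x 6 grid of 30 m sub-squares (180 m x 180 m)
centred on a transect the observer walks, and habitat use is recorded as
scan-sample observations of feeding or sheltering groups.  Because a
group in dense cover far from the observer is less likely to be seen
than one nearby, raw cover overstates the availability of distant
habitat: availability is therefore weighted by a detection curve
``g(distance)`` evaluated at each sub-square's distance from the
transect before being turned into expected proportional use.

Selection is summarised by Jacobs' index

    J = (O - E) / (O + E - 2 O E)

with ``O`` the observed and ``E`` the expected proportional use of a
habitat.  J ranges from -1 (total avoidance) through 0 (use proportional
to availability) to +1 (exclusive use).  Significance is assessed by
simultaneous Bonferroni confidence intervals on the observed use
proportions: selection is flagged when the expected proportion falls
outside the interval.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ACTIVITIES",
    "bonferroni_selection_test",
    "detectability_weighted_availability",
    "jacobs_index",
    "selection_table",
]

ACTIVITIES = ("feeding", "shelter")


def detectability_weighted_availability(scans: pd.DataFrame, detection_curve) -> pd.Series:
    """Expected proportional use of each habitat under random selection.

    Parameters
    ----------
    scans : DataFrame
        Long-format availability grid with columns ``location_id``,
        ``cell_id``, ``distance`` (sub-square centre to the transect,
        metres) and one cover column per habitat, or the tidy columns
        ``habitat`` / ``cover``.
    detection_curve : callable
        Maps distance (metres) to a relative detection weight; typically
        a fitted gamma key.  Any uniform rescaling of the curve cancels.

    Returns
    -------
    Series
        Availability proportions indexed by habitat, summing to 1.
    """
    if "habitat" not in scans.columns:
        raise ValueError("scans must be in long format with a 'habitat' column")
    per_cell = scans.groupby(["location_id", "cell_id"])["cover"].sum()
    if (per_cell > 100.0 + 1e-9).any():
        bad = per_cell[per_cell > 100.0 + 1e-9].index[0]
        raise ValueError(f"cover sums to more than 100% in sub-square {bad}")
    w = np.asarray(detection_curve(scans["distance"].to_numpy(float)), dtype=float)
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValueError("detection weights must be finite and non-negative")
    weighted = scans["cover"].to_numpy(float) * w
    totals = pd.Series(weighted).groupby(scans["habitat"].to_numpy()).sum()
    grand = totals.sum()
    if grand <= 0:
        raise ValueError("all detectability-weighted covers are zero")
    avail = totals / grand
    avail.index.name = "habitat"
    avail.name = "availability"
    return avail


def jacobs_index(o_prop: float, e_prop: float) -> float:
    """Jacobs' selectivity index ``J = (O - E) / (O + E - 2 O E)``.

    ``o_prop`` and ``e_prop`` are the observed and expected use
    *proportions* in ``[0, 1]``.  J = 0 when a habitat is used in
    proportion to its availability, 1 for exclusive use of an
    incompletely available habitat, -1 for total avoidance of an
    available habitat.
    """
    o, e = float(o_prop), float(e_prop)
    for name, v in (("o_prop", o), ("e_prop", e)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    denom = o + e - 2.0 * o * e
    if denom == 0.0:  # (0, 0) or (1, 1)
        raise ValueError("Jacobs index undefined when O and E are both 0 or both 1")
    return (o - e) / denom


def bonferroni_selection_test(
    o_counts: pd.Series, e_prop: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Simultaneous Bonferroni confidence intervals on proportional use.

    For ``k`` habitats the per-interval level is ``1 - alpha / (2k)``
    (normal approximation), so all ``k`` intervals cover jointly at
    ``1 - alpha``.  A habitat is flagged as significantly selected or
    avoided when its expected proportion falls outside the interval on
    its observed proportion.

    Returns one row per habitat: ``O``, ``O_prop``, ``E_prop``, ``J``,
    ``ci_low``, ``ci_high``, ``significant``.  An activity with zero
    observations yields an empty frame.
    """
    o_counts = o_counts.astype(float)
    habitats = o_counts.index
    if not habitats.equals(e_prop.index):
        e_prop = e_prop.reindex(habitats)
        if e_prop.isna().any():
            missing = list(e_prop.index[e_prop.isna()])
            raise ValueError(f"no availability for habitats: {missing}")
    n = float(o_counts.sum())
    if n == 0:
        return pd.DataFrame(
            columns=["habitat", "O", "O_prop", "E_prop", "J", "ci_low", "ci_high", "significant"]
        )
    k = len(habitats)
    if k < 2:
        raise ValueError("need at least 2 habitats")
    z = stats.norm.ppf(1.0 - alpha / (2.0 * k))
    rows = []
    for h in habitats:
        o_p = o_counts[h] / n
        half = z * np.sqrt(o_p * (1.0 - o_p) / n)
        lo, hi = max(0.0, o_p - half), min(1.0, o_p + half)
        e_p = float(e_prop[h])
        rows.append(
            {
                "habitat": h,
                "O": int(o_counts[h]),
                "O_prop": o_p,
                "E_prop": e_p,
                "J": jacobs_index(o_p, e_p) if (o_p, e_p) not in ((0.0, 0.0), (1.0, 1.0)) else 0.0,
                "ci_low": lo,
                "ci_high": hi,
                "significant": bool(e_p < lo or e_p > hi),
            }
        )
    return pd.DataFrame(rows)


def selection_table(
    scans: pd.DataFrame,
    uses: pd.DataFrame,
    detection_curve,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Habitat selection per activity: the package's selection summary.

    Combines detectability-weighted availability with use observations
    into one row per habitat x activity carrying N, Jacobs' J and the
    Bonferroni significance flag.  Records flagged ``excluded`` (e.g.
    ground-feeding birds whose microhabitat was uncertain, or birds
    perched on bare ground) never enter the counts but are tallied in
    ``result.attrs["excluded"]`` so the bookkeeping
    ``sum(N) + excluded == total observations`` stays visible.
    """
    avail = detectability_weighted_availability(scans, detection_curve)
    excluded_col = uses["excluded"] if "excluded" in uses.columns else pd.Series(False, index=uses.index)
    active = uses.loc[~excluded_col.astype(bool)]
    unknown = sorted(set(active["habitat"]) - set(avail.index))
    if unknown:
        raise ValueError(f"habitat(s) in use observations absent from scans: {unknown}")
    parts = []
    excluded = {}
    for activity in ACTIVITIES:
        sub = active.loc[active["activity"] == activity]
        excluded[activity] = int(
            (excluded_col.astype(bool) & (uses["activity"] == activity)).sum()
        )
        o = sub.groupby("habitat").size().reindex(avail.index, fill_value=0)
        res = bonferroni_selection_test(o, avail, alpha=alpha)
        if not res.empty:
            res.insert(0, "activity", activity)
            res["stars"] = np.where(res["significant"], "*", "")
        parts.append(res)
    out = pd.concat(parts, ignore_index=True)
    out.attrs["excluded"] = excluded
    out.attrs["availability"] = avail
    return out
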