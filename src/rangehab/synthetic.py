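"""Synthetic point-count surveys with known ground truth.

The field data this analysis is designed for are not publicly deposited,
so the package ships a generator that emulates the study design end to
end: 41 sites (10 x 10 km squares) in four residence-time strata
(8/10/10/13 sites colonised <10, 10-20, 20-30 and >30 years ago), five
to twelve 100-m-radius point counts per site (349 in total, always more
than 200 m apart), habitat recorded at a 7 x 7 grid of points spaced
30 m (49 nodes, so habitat proportions are multiples of 1/49), three
seasonal survey rounds, scan-sample focal watches on 180 m x 180 m
grids of 36 sub-squares, and per-site monthly climate series.

Presence at a point count is simulated from the same model family the
analysis fits: a logistic model with a site random intercept and the
logit of the true average detectability as an offset.  Distances of
detected groups are simulated by proposing from the uniform-in-area
density ``2r/w^2`` and thinning through the true gamma key, i.e. exactly
the sampling model the detection step assumes.  Everything stochastic is
driven by ``config.seed`` through independent child streams, so each
product (survey, scans, climate) is reproducible on its own.

Residence time is generated and modelled as continuous years since
colonisation; the strata are used only for site allocation and
reporting, because the occurrence models use polynomial residence-time
terms that need a continuous scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from rangehab.detection import point_detection_probability, sample_distances

__all__ = [
    "SCAN_HABITATS",
    "SurveyConfig",
    "SyntheticTruth",
    "generate_climate_series",
    "generate_scan_samples",
    "generate_survey",
    "table1_fixture",
    "table2_fixture",
    "write_survey",
]

#: habitat categories recorded in scan-sample sub-squares
SCAN_HABITATS = (
    "rough_grass",
    "emergent_veg",
    "forbs",
    "houses_gardens",
    "arundo_donax",
    "trees_bushes",
    "crops",
)

#: habitat categories recorded at point-count grid nodes (with a filler class)
POINT_HABITATS = ("emergent_veg", "trees_bushes", "forbs", "rough_grass", "other")


def _default_detection_params():
    # gamma-key truth: shared shape, log-scale intercept and covariate slopes
    return {
        "shape": 3.0,
        "intercept": float(np.log(30.0)),
        "flock_size": 0.05,
        "trees_bushes": -0.8,
        "emergent_veg": 0.0,
    }


def _default_occupancy_params():
    # Generating coefficients of the occurrence model, on raw covariate
    # scales (habitat covers as proportions, residence time standardised
    # internally).  Humped habitat responses, saturating residence-time
    # effect, and habitat-by-residence-time interactions: the emergent-
    # vegetation hump flattens, the river effect fades, and tolerance
    # shifts from forbs toward rough grass as residence time grows.  The
    # intercept sets the design prevalence near 37% of point counts.
    return {
        "intercept": -2.4,
        "date": 0.3,
        "emergent_veg": (5.0, -9.0),
        "forbs": (4.0, -8.0),
        "rough_grass": (3.0, -6.0),
        "trees_bushes": (-2.5, 0.0),
        "river": 0.8,
        "residence_time": (1.0, -0.5),
        "interactions": {
            ("emergent_veg", 2): 7.5,
            ("river", 1): -0.85,
            ("forbs", 1): -2.5,
            ("rough_grass", 1): 2.5,
        },
        "sigma_site": 1.0,
    }


def _default_climate_field():
    return {
        "rho_cwd": 0.33,     # corr(residence time, CWD)
        "rho_mtcm": 0.55,    # corr(residence time, MTCM)
        "rho_sdm": 0.72,     # corr(residence time, climate-suitability score)
        "cwd_base": 150.0,   # mean summer deficit magnitude, mm
        "cwd_slope": -60.0,  # deficit change per unit climate latent, mm
        "mtcm_mean": 9.0,
        "mtcm_sd": 2.5,
        "sdm_mean": 0.55,
        "sdm_sd": 0.18,
    }


def _default_scan_selection():
    # log selection weights per activity; zero = use proportional to
    # availability.  Signs follow the feeding/shelter pattern the
    # selection analysis is built to detect.
    return {
        "feeding": {
            "rough_grass": 0.8,
            "emergent_veg": 1.0,
            "forbs": 0.3,
            "houses_gardens": -0.5,
            "arundo_donax": 0.0,
            "trees_bushes": -1.2,
            "crops": -1.5,
        },
        "shelter": {
            "rough_grass": -1.5,
            "emergent_veg": 1.5,
            "forbs": -0.2,
            "houses_gardens": -0.8,
            "arundo_donax": 1.5,
            "trees_bushes": 0.2,
            "crops": -2.0,
        },
    }


@dataclass
class SurveyConfig:
    """Generator parameters; defaults reproduce the study design."""

    n_sites: int = 41
    strata_sizes: tuple = (8, 10, 10, 13)          # <10, 10-20, 20-30, >30 years
    strata_bounds: tuple = ((2.0, 10.0), (10.0, 20.0), (20.0, 30.0), (30.0, 45.0))
    points_per_site_range: tuple = (5, 12)
    n_points_total: int = 349
    truncation_radius: float = 100.0
    grid_spacing: float = 30.0
    grid_extent: float = 180.0                     # 7 x 7 nodes -> 49 per point
    scan_extent: float = 180.0                     # 6 x 6 sub-squares of 30 m
    n_survey_rounds: int = 3
    site_extent: float = 10_000.0                  # 10 km site square, metres
    min_point_spacing: float = 200.0
    detection_params: dict = field(default_factory=_default_detection_params)
    occupancy_params: dict = field(default_factory=_default_occupancy_params)
    flock_size_lambda: float = 3.0                 # zero-truncated Poisson rate
    groups_per_presence: float = 0.8               # extra detected groups ~ Poisson
    habitat_dirichlet: tuple = (0.6, 0.7, 0.5, 0.6, 1.6)  # over POINT_HABITATS; patchy mosaic
    river_prob: float = 0.4
    climate_field: dict = field(default_factory=_default_climate_field)
    scan_selection: dict = field(default_factory=_default_scan_selection)
    scan_feeding_rate: float = 106.0 / 68.0        # events per location, incl. excluded
    scan_shelter_rate: float = 100.0 / 68.0
    scan_excluded_frac: dict = field(
        default_factory=lambda: {"feeding": 10.0 / 106.0, "shelter": 2.0 / 100.0}
    )
    seed: int = 20110401

    def validate(self):
        if sum(self.strata_sizes) != self.n_sites:
            raise ValueError("strata_sizes must sum to n_sites")
        lo, hi = self.points_per_site_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid points_per_site_range")
        if self.truncation_radius <= 0:
            raise ValueError("truncation_radius must be positive")
        ratio = self.grid_extent / self.grid_spacing
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("grid_extent must be an integer multiple of grid_spacing")
        if not self.n_sites * lo <= self.n_points_total <= self.n_sites * hi:
            raise ValueError("n_points_total incompatible with points_per_site_range")
        return self

    @property
    def nodes_per_point(self) -> int:
        side = int(round(self.grid_extent / self.grid_spacing)) + 1
        return side * side


@dataclass
class SyntheticTruth:
    """Ground truth behind one generated survey, for recovery tests."""

    config: SurveyConfig
    sites: pd.DataFrame
    occupancy_prob: np.ndarray      # per point: P(presence), incl. offset & site effect
    detection_prob: np.ndarray      # per point: average detectability at flock = 1
    site_effects: np.ndarray        # realised random intercepts, one per site
    detections: pd.DataFrame        # one row per detected group
    coefficients: dict              # generating parameters


def _rng(config: SurveyConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def _make_sites(config: SurveyConfig) -> pd.DataFrame:
    """Sites with strata, continuous residence times, centres and rounds.

    Deterministic given ``config.seed``; shared by the survey and the
    climate generators so their site tables always agree.
    """
    rng = _rng(config, 1)
    rows = []
    site_idx = 0
    for s, (n_s, (lo, hi)) in enumerate(zip(config.strata_sizes, config.strata_bounds)):
        for j in range(n_s):
            rows.append(
                {
                    "site_id": f"S{site_idx + 1:02d}",
                    "stratum": s,
                    "residence_time": float(rng.uniform(lo, hi)),
                    "center_x": float(rng.uniform(0, 200_000.0)),
                    "center_y": float(rng.uniform(0, 200_000.0)),
                    "survey_round": j % config.n_survey_rounds,
                }
            )
            site_idx += 1
    return pd.DataFrame(rows)


def _points_per_site(config: SurveyConfig, rng) -> np.ndarray:
    lo, hi = config.points_per_site_range
    counts = rng.integers(lo, hi + 1, size=config.n_sites)
    # nudge to the requested total while respecting the per-site bounds
    diff = config.n_points_total - counts.sum()
    while diff != 0:
        i = rng.integers(config.n_sites)
        if diff > 0 and counts[i] < hi:
            counts[i] += 1
            diff -= 1
        elif diff < 0 and counts[i] > lo:
            counts[i] -= 1
            diff += 1
    return counts


def _place_points(rng, n, extent, min_spacing, max_tries=2000):
    pts = np.empty((n, 2))
    placed = 0
    tries = 0
    while placed < n:
        cand = rng.uniform(0, extent, size=2)
        if placed == 0 or np.all(
            np.hypot(*(pts[:placed] - cand).T) > min_spacing
        ):
            pts[placed] = cand
            placed += 1
            tries = 0
        else:
            tries += 1
            if tries > max_tries:
                raise RuntimeError(
                    f"cannot place {n} points >= {min_spacing} m apart in a "
                    f"{extent:.0f} m square"
                )
    return pts


def _zero_truncated_poisson(rng, lam, size):
    out = rng.poisson(lam, size=size)
    bad = out == 0
    while bad.any():
        out[bad] = rng.poisson(lam, size=int(bad.sum()))
        bad = out == 0
    return out


def _rt_standardise(rt):
    return (np.asarray(rt, dtype=float) - 20.0) / 12.5


def _occupancy_lp(points: pd.DataFrame, params: dict) -> np.ndarray:
    """Generating fixed-effect linear predictor on raw covariates."""
    date_z = (points["date"].to_numpy(float) - points["date"].mean()) / (
        points["date"].std() or 1.0
    )
    rt_z = _rt_standardise(points["residence_time"].to_numpy(float))
    lp = np.full(len(points), float(params["intercept"]))
    lp = lp + params["date"] * date_z
    for v in ("emergent_veg", "forbs", "rough_grass", "trees_bushes"):
        b1, b2 = params[v]
        x = points[v].to_numpy(float)
        lp = lp + b1 * x + b2 * x * x
    lp = lp + params["river"] * points["river"].to_numpy(float)
    c1, c2 = params["residence_time"]
    lp = lp + c1 * rt_z + c2 * rt_z * rt_z
    for (v, order), b in params.get("interactions", {}).items():
        x = points[v].to_numpy(float) ** order
        lp = lp + b * x * rt_z
    return lp


def generate_survey(config: SurveyConfig) -> tuple:
    """Generate one complete point-count survey.

    Returns ``(points, truth)``: ``points`` has one row per point count
    (covariates, climate, presence, detection summary) and ``truth`` the
    generating probabilities, site effects and the long-format detection
    table (one row per detected group with distance and flock size).
    """
    config.validate()
    sites = _make_sites(config)
    climate = _site_climate(config, sites)
    rng = _rng(config, 2)
    det_rng = _rng(config, 3)

    counts = _points_per_site(config, rng)
    round_starts = 91.0 + 30.0 * np.arange(config.n_survey_rounds)

    rows = []
    for (_, site), n_pts in zip(sites.iterrows(), counts):
        xy = _place_points(rng, n_pts, config.site_extent, config.min_point_spacing)
        node_probs = rng.dirichlet(config.habitat_dirichlet, size=n_pts)
        nodes = np.vstack([rng.multinomial(config.nodes_per_point, p) for p in node_probs])
        props = nodes / config.nodes_per_point
        dates = round_starts[int(site["survey_round"])] + rng.uniform(0, 25.0, size=n_pts)
        for j in range(n_pts):
            rows.append(
                {
                    "point_count_id": f"{site['site_id']}P{j + 1:02d}",
                    "site_id": site["site_id"],
                    "stratum": int(site["stratum"]),
                    "residence_time": site["residence_time"],
                    "x": site["center_x"] - config.site_extent / 2 + xy[j, 0],
                    "y": site["center_y"] - config.site_extent / 2 + xy[j, 1],
                    "date": float(dates[j]),
                    "survey_round": int(site["survey_round"]),
                    **{h: props[j, k] for k, h in enumerate(POINT_HABITATS)},
                    "river": int(rng.uniform() < config.river_prob),
                }
            )
    points = pd.DataFrame(rows)
    for col in ("mtcm", "cwd", "climate_sdm"):
        points[col] = points["site_id"].map(climate.set_index("site_id")[col]).to_numpy()

    # true detectability per point at flock size one
    dp = config.detection_params
    scale_pt = np.exp(
        dp["intercept"]
        + dp["flock_size"] * 1.0
        + dp["trees_bushes"] * points["trees_bushes"].to_numpy(float)
        + dp["emergent_veg"] * points["emergent_veg"].to_numpy(float)
    )
    p_detect = np.atleast_1d(
        point_detection_probability(scale_pt, dp["shape"], config.truncation_radius)
    )

    op = config.occupancy_params
    site_effects = _rng(config, 6).normal(0.0, op["sigma_site"], size=config.n_sites)
    site_idx = points["site_id"].map(
        {sid: i for i, sid in enumerate(sites["site_id"])}
    ).to_numpy()
    lp = _occupancy_lp(points, op) + site_effects[site_idx]
    with np.errstate(invalid="ignore"):
        eta = lp + special.logit(np.clip(p_detect, 1e-12, 1 - 1e-12))
    p_presence = special.expit(eta)
    presence = (rng.uniform(size=len(points)) < p_presence).astype(int)
    points["presence"] = presence

    # detections at occupied points: flock sizes then distances thinned
    # through the gamma key (flock size feeds back into the scale)
    det_rows = []
    for i in np.where(presence == 1)[0]:
        n_groups = 1 + det_rng.poisson(config.groups_per_presence)
        flocks = _zero_truncated_poisson(det_rng, config.flock_size_lambda, n_groups)
        scales = np.exp(
            dp["intercept"]
            + dp["flock_size"] * flocks
            + dp["trees_bushes"] * points.at[i, "trees_bushes"]
            + dp["emergent_veg"] * points.at[i, "emergent_veg"]
        )
        dists = sample_distances(
            det_rng, n_groups, scales, dp["shape"], config.truncation_radius
        )
        for fs, r in zip(flocks, dists):
            det_rows.append(
                {
                    "point_count_id": points.at[i, "point_count_id"],
                    "distance": float(r),
                    "flock_size": int(fs),
                    "emergent_veg": points.at[i, "emergent_veg"],
                    "trees_bushes": points.at[i, "trees_bushes"],
                }
            )
    detections = pd.DataFrame(
        det_rows,
        columns=["point_count_id", "distance", "flock_size", "emergent_veg", "trees_bushes"],
    )
    points["n_detections"] = (
        points["point_count_id"]
        .map(detections.groupby("point_count_id").size())
        .fillna(0)
        .astype(int)
    )

    truth = SyntheticTruth(
        config=config,
        sites=sites,
        occupancy_prob=p_presence,
        detection_prob=p_detect,
        site_effects=site_effects,
        detections=detections,
        coefficients={"detection": dict(dp), "occupancy": dict(op)},
    )
    return points, truth


# ---------------------------------------------------------------------------
# climate series

def _site_climate(config: SurveyConfig, sites: pd.DataFrame) -> pd.DataFrame:
    cf = config.climate_field
    rng = _rng(config, 4)
    rt_z = _rt_standardise(sites["residence_time"].to_numpy())
    rt_z = (rt_z - rt_z.mean()) / (rt_z.std() or 1.0)
    n = len(sites)

    def latent(rho):
        return rho * rt_z + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.normal(size=n)

    deficit = np.maximum(0.0, cf["cwd_base"] + cf["cwd_slope"] * latent(cf["rho_cwd"]))
    mtcm = cf["mtcm_mean"] + cf["mtcm_sd"] * latent(cf["rho_mtcm"])
    sdm = np.clip(cf["sdm_mean"] + cf["sdm_sd"] * latent(cf["rho_sdm"]), 0.01, 0.99)
    return pd.DataFrame(
        {
            "site_id": sites["site_id"],
            "deficit": deficit,
            "mtcm": mtcm,
            "cwd": -deficit,
            "climate_sdm": sdm,
        }
    )


#: monthly evapotranspiration curve, mm (temperate-Mediterranean shape)
_PET = np.array([40.0, 50, 70, 90, 120, 150, 170, 160, 120, 80, 50, 40])
_SUMMER = np.array([5, 6, 7, 8])  # June-September (0-based month indices)


def generate_climate_series(config: SurveyConfig) -> pd.DataFrame:
    """Monthly precipitation/evapotranspiration per site (long format).

    A fixed seasonal evapotranspiration curve with winter precipitation
    surplus and a summer deficit whose magnitude is driven by a site
    latent correlated with residence time (``climate_field['rho_cwd']``),
    so residence time and cumulative water deficit are only weakly
    confounded, as in the sampling design being emulated.  The summer
    deficit is spread over four months, so the downstream CWD equals
    minus the site's deficit magnitude.
    """
    config.validate()
    sites = _make_sites(config)
    clim = _site_climate(config, sites)
    rows = []
    for _, site in clim.iterrows():
        precip = _PET + 60.0  # surplus everywhere, then carve the summer deficit
        precip = precip.copy()
        precip[_SUMMER] = np.maximum(0.0, _PET[_SUMMER] - site["deficit"] / len(_SUMMER))
        for m in range(12):
            rows.append(
                {
                    "site_id": site["site_id"],
                    "month": m + 1,
                    "precipitation": float(precip[m]),
                    "evapotranspiration": float(_PET[m]),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scan samples

def generate_scan_samples(config: SurveyConfig, n_locations: int = 68) -> tuple:
    """Generate focal-watch availability grids and use observations.

    Each location is a 180 m x 180 m square of 36 sub-squares of 30 m
    whose centre distance to the central transect is recorded; per-cell
    percentage covers over the scan habitat set sum to <= 100.  Use
    events pick a (cell, habitat) with probability proportional to
    ``cover x g_true(distance) x exp(selection weight)``, so zero
    weights yield use proportional to detectability-weighted
    availability (Jacobs index ~ 0 downstream).  A configured fraction
    of events is flagged ``excluded`` (ground-feeding birds of uncertain
    microhabitat; shelter on bare ground) and never enters the counts.
    """
    config.validate()
    rng = _rng(config, 5)
    n_side = int(round(config.scan_extent / config.grid_spacing))
    centers = (np.arange(n_side) + 0.5) * config.grid_spacing
    cell_dist = np.abs(np.repeat(centers, n_side) - config.scan_extent / 2.0)

    dp = config.detection_params
    g_scale = float(np.exp(dp["intercept"] + dp["flock_size"] * 1.0))
    from rangehab.detection import gamma_key

    scan_rows, use_rows = [], []
    n_cells = n_side * n_side
    for loc in range(n_locations):
        loc_id = f"L{loc + 1:02d}"
        # covers: Dirichlet over the habitat set plus a bare/other filler
        alloc = rng.dirichlet(np.array([1.0] * len(SCAN_HABITATS) + [1.5]), size=n_cells)
        covers = alloc[:, : len(SCAN_HABITATS)] * 100.0
        if np.any(covers.sum(axis=1) > 100.0 + 1e-9):
            raise RuntimeError("generated cover sums exceed 100%")  # unreachable
        for c in range(n_cells):
            for k, h in enumerate(SCAN_HABITATS):
                scan_rows.append(
                    {
                        "location_id": loc_id,
                        "cell_id": c,
                        "distance": float(cell_dist[c]),
                        "habitat": h,
                        "cover": float(covers[c, k]),
                    }
                )
        g = gamma_key(cell_dist, g_scale, dp["shape"])
        for activity, rate in (
            ("feeding", config.scan_feeding_rate),
            ("shelter", config.scan_shelter_rate),
        ):
            weights = np.array(
                [config.scan_selection[activity][h] for h in SCAN_HABITATS]
            )
            probs = covers * g[:, None] * np.exp(weights)[None, :]
            probs = probs / probs.sum()
            n_events = rng.poisson(rate)
            for _ in range(n_events):
                flat = rng.choice(n_cells * len(SCAN_HABITATS), p=probs.ravel())
                c, k = divmod(flat, len(SCAN_HABITATS))
                excluded = rng.uniform() < config.scan_excluded_frac[activity]
                use_rows.append(
                    {
                        "location_id": loc_id,
                        "activity": activity,
                        "habitat": (
                            "ground_unknown" if (excluded and activity == "feeding")
                            else "bare_ground" if excluded
                            else SCAN_HABITATS[k]
                        ),
                        "distance": float(
                            np.clip(
                                cell_dist[c] + rng.uniform(-15.0, 15.0),
                                0.0,
                                config.scan_extent / 2.0,
                            )
                        ),
                        "excluded": bool(excluded),
                    }
                )
    scans = pd.DataFrame(scan_rows)
    uses = pd.DataFrame(use_rows, columns=["location_id", "activity", "habitat", "distance", "excluded"])
    return scans, uses


# ---------------------------------------------------------------------------
# fixtures reproducing the printed survey margins

def table1_fixture() -> pd.DataFrame:
    """Presence/total point counts by habitat class and residence stratum.

    The fixed contingency table of the survey the generator emulates:
    130 of 349 point counts held the focal bird, split over three
    aggregated land-cover classes and four residence-time strata.
    """
    cells = {
        ">30": {"irrigated_agriculture": (19, 39), "wetland": (10, 40), "heterogeneous_agriculture": (13, 27)},
        "20-30": {"irrigated_agriculture": (13, 23), "wetland": (15, 28), "heterogeneous_agriculture": (12, 22)},
        "10-20": {"irrigated_agriculture": (9, 31), "wetland": (12, 30), "heterogeneous_agriculture": (10, 30)},
        "<10": {"irrigated_agriculture": (5, 21), "wetland": (8, 36), "heterogeneous_agriculture": (4, 22)},
    }
    rows = [
        {"stratum": s, "habitat_class": h, "present": p, "total": t}
        for s, by_h in cells.items()
        for h, (p, t) in by_h.items()
    ]
    return pd.DataFrame(rows)


def table2_fixture() -> pd.DataFrame:
    """Observed use counts and Jacobs indices per habitat and activity.

    Fixed selection summary of the focal watches the generator emulates:
    86 attributable feeding and 96 attributable shelter observations
    (plus 10 ground-feeding and 2 bare-ground records excluded from the
    habitat counts, reported in ``attrs['excluded']``).
    """
    feeding = [
        ("rough_grass", 34, 0.35, True),
        ("emergent_veg", 19, 0.45, True),
        ("forbs", 18, 0.14, False),
        ("houses_gardens", 1, -0.23, False),
        ("arundo_donax", 3, -0.03, False),
        ("trees_bushes", 5, -0.58, True),
        ("crops", 6, -0.63, True),
    ]
    shelter = [
        ("rough_grass", 6, -0.70, True),
        ("emergent_veg", 44, 0.75, True),
        ("forbs", 13, -0.07, False),
        ("houses_gardens", 1, -0.43, False),
        ("arundo_donax", 12, 0.77, True),
        ("trees_bushes", 17, 0.10, False),
        ("crops", 3, -0.84, True),
    ]
    rows = [
        {"activity": act, "habitat": h, "N": n, "J": j, "significant": sig}
        for act, table in (("feeding", feeding), ("shelter", shelter))
        for h, n, j, sig in table
    ]
    out = pd.DataFrame(rows)
    out.attrs["excluded"] = {"feeding": 10, "shelter": 2}
    return out


# ---------------------------------------------------------------------------
# delimited-text output

def write_survey(points: pd.DataFrame, truth: SyntheticTruth, outdir) -> dict:
    """Write the survey as delimited text files; returns name -> path."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in (
        ("point_counts", points),
        ("detections", truth.detections),
        ("sites", truth.sites),
    ):
        path = outdir / f"{name}.csv"
        frame.to_csv(path, index=False)
        paths[name] = path
    return paths
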