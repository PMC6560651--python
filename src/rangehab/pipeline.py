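"""End-to-end orchestration: survey -> detection -> selection -> models.

The pipeline runs the full two-step analysis behind a single
configuration object: generate (or ingest and validate) a point-count
survey, fit and rank the detection functions, predict per-point
detectability, compute the Jacobs-index selection table from the scan
samples, derive climate covariates (CWD from monthly water balances),
fit the ten-model occurrence hypothesis set, and write every product as
delimited text together with a manifest recording the seed, package
versions, stage log and SHA-256 checksums of all outputs.  All
randomness flows from the single configured seed, so a rerun with the
same configuration is bit-identical.
"""

from __future__ import annotations

import hashlib
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from rangehab import climate as climate_mod
from rangehab import occupancy as occ
from rangehab import synthetic
from rangehab.detection import (
    gamma_key,
    predict_point_detectability,
    rank_detection_models,
)
from rangehab.resource_selection import selection_table

log = logging.getLogger("rangehab")

__all__ = ["PipelineConfig", "PipelineError", "ValidationError", "run_pipeline", "validate_inputs"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage, message):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


class ValidationError(RuntimeError):
    """Input validation found violations."""


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of ``input_paths`` (ingest mode: paths to delimited
    files) and ``synthetic`` (generation mode: overrides applied to
    :class:`~rangehab.synthetic.SurveyConfig`) must be provided.
    """

    output_dir: str = "rangehab_out"
    seed: int = 20110401
    synthetic: dict | None = None
    input_paths: dict | None = None
    truncation_radius: float = 100.0
    alpha: float = 0.05
    n_quad: int = 25
    n_scan_locations: int = 68
    write_predictions: bool = True
    spatial_check: bool = False

    def __post_init__(self):
        if (self.synthetic is None) == (self.input_paths is None):
            raise ValueError(
                "exactly one of 'synthetic' and 'input_paths' must be configured"
            )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def survey_config(self) -> synthetic.SurveyConfig:
        overrides = dict(self.synthetic or {})
        overrides.setdefault("seed", self.seed)
        overrides.setdefault("truncation_radius", self.truncation_radius)
        return synthetic.SurveyConfig(**overrides)


# ---------------------------------------------------------------------------
# validation

_POINT_COLUMNS = (
    "point_count_id", "site_id", "residence_time", "date",
    "emergent_veg", "trees_bushes", "forbs", "rough_grass", "river", "presence",
)
_DETECTION_COLUMNS = ("point_count_id", "distance", "flock_size")


def validate_inputs(points: pd.DataFrame, detections: pd.DataFrame,
                    truncation: float = 100.0, n_nodes: int = 49) -> pd.DataFrame:
    """Schema and integrity checks; returns a violation report (may be empty).

    Checks required columns, covariate ranges, habitat proportions being
    multiples of ``1/n_nodes``, distances within the truncation radius,
    and referential integrity of detections against point counts.
    """
    rows = []

    def flag(check, detail):
        rows.append({"check": check, "detail": str(detail)})

    for col in _POINT_COLUMNS:
        if col not in points.columns:
            flag("missing_column", f"point_counts.{col}")
    for col in _DETECTION_COLUMNS:
        if col not in detections.columns:
            flag("missing_column", f"detections.{col}")
    if rows:
        return pd.DataFrame(rows)

    if points["point_count_id"].duplicated().any():
        flag("duplicate_id", "point_count_id not unique")
    for col in ("emergent_veg", "trees_bushes", "forbs", "rough_grass"):
        v = points[col].to_numpy(float)
        if np.any((v < 0) | (v > 1)):
            flag("range", f"{col} outside [0, 1]")
        off_grid = np.abs(v * n_nodes - np.round(v * n_nodes)) > 1e-6
        if off_grid.any():
            flag("grid", f"{col}: {int(off_grid.sum())} values not multiples of 1/{n_nodes}")
    if not set(points["river"].unique()) <= {0, 1}:
        flag("range", "river must be binary 0/1")
    if not set(points["presence"].unique()) <= {0, 1}:
        flag("range", "presence must be binary 0/1")

    too_far = detections["distance"].to_numpy(float) > truncation
    if too_far.any():
        flag("truncation", f"{int(too_far.sum())} detections beyond {truncation} m")
    if (detections["flock_size"].to_numpy(float) < 1).any():
        flag("range", "flock_size must be a positive count")
    orphans = set(detections["point_count_id"]) - set(points["point_count_id"])
    if orphans:
        flag("referential_integrity", f"orphan detection ids: {sorted(orphans)[:5]}")
    detected_at = points.set_index("point_count_id")["presence"]
    absent = [
        pid for pid in detections["point_count_id"].unique()
        if pid in detected_at.index and detected_at[pid] == 0
    ]
    if absent:
        flag("consistency", f"detections at points marked absent: {absent[:5]}")
    return pd.DataFrame(rows, columns=["check", "detail"])


# ---------------------------------------------------------------------------
# the pipeline

def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(frame: pd.DataFrame, outdir: Path, name: str, outputs: dict):
    path = outdir / f"{name}.csv"
    frame.to_csv(path, index=False, float_format="%.10g")
    outputs[name] = path
    return path


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and return the manifest (also written to disk)."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    stage_log = []
    caught: list[str] = []

    def stage(name):
        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                log.info("stage %s: start", name)
                return self_inner

            def __exit__(self_inner, exc_type, exc, tb):
                elapsed = time.perf_counter() - self_inner.t0
                if exc is not None:
                    (outdir / "FAILED").write_text(f"{name}: {exc}\n")
                    raise PipelineError(name, exc) from exc
                stage_log.append({"stage": name, "seconds": round(elapsed, 3)})
                log.info("stage %s: done in %.2fs", name, elapsed)

        return _Ctx()

    with warnings.catch_warnings(record=True) as wrec:
        warnings.simplefilter("always")

        with stage("ingest"):
            if config.synthetic is not None:
                scfg = config.survey_config()
                points, truth = synthetic.generate_survey(scfg)
                detections = truth.detections
                scans, uses = synthetic.generate_scan_samples(scfg, config.n_scan_locations)
                monthly = synthetic.generate_climate_series(scfg)
            else:
                paths = config.input_paths
                points = pd.read_csv(paths["point_counts"])
                detections = pd.read_csv(paths["detections"])
                scans = pd.read_csv(paths["scans"])
                uses = pd.read_csv(paths["uses"])
                monthly = pd.read_csv(paths["climate"])
            report = validate_inputs(points, detections, config.truncation_radius)
            _write(report, outdir, "validation_report", outputs)
            if len(report):
                raise ValidationError(f"{len(report)} validation violations; see report")
            for name, frame in (
                ("point_counts", points), ("detections", detections),
                ("scan_availability", scans), ("scan_uses", uses),
                ("climate_monthly", monthly),
            ):
                _write(frame, outdir, name, outputs)

        with stage("detect"):
            ranking = rank_detection_models(detections, config.truncation_radius)
            _write(
                ranking.table.assign(
                    covariates=[" + ".join(c) if c else "(none)" for c in ranking.table["covariates"]]
                ),
                outdir, "detection_ranking", outputs,
            )
            best = ranking.best
            detectability = predict_point_detectability(best, points)
            _write(detectability, outdir, "detectability", outputs)

        with stage("select"):
            curve = lambda d: gamma_key(
                np.clip(d, 1e-9, None),
                float(np.exp(best.scale_coefficients["intercept"]
                             + best.scale_coefficients.get("flock_size", 0.0))),
                best.shape,
            )
            sel = selection_table(scans, uses, curve, alpha=config.alpha)
            _write(sel, outdir, "selection_table", outputs)

        with stage("climate"):
            covs = climate_mod.climate_covariate_table(points, monthly)
            _write(covs, outdir, "climate_covariates", outputs)
            corr_cols = ["residence_time", "mtcm", "cwd", "climate_sdm",
                         "emergent_veg", "trees_bushes", "forbs", "rough_grass"]
            diag = points.drop(columns=["cwd"], errors="ignore").merge(
                covs[["point_count_id", "cwd"]], on="point_count_id"
            )
            corr = climate_mod.covariate_correlations(diag, [c for c in corr_cols if c in diag])
            _write(corr.reset_index(names="variable"), outdir, "covariate_correlations", outputs)

        with stage("fit"):
            data = points.drop(columns=["cwd"], errors="ignore").merge(
                covs[["point_count_id", "cwd"]], on="point_count_id"
            ).merge(detectability[["point_count_id", "p_detect", "logit_p_detect"]],
                    on="point_count_id")
            fits = [
                occ.fit_occurrence_model(data, spec, n_quad=config.n_quad)
                for spec in occ.build_hypothesis_set()
            ]
            comparison = occ.compare_models(fits)
            _write(comparison, outdir, "model_comparison", outputs)
            coef_rows = []
            for fit in fits:
                for name, b in zip(fit.colnames, fit.beta):
                    coef_rows.append(
                        {"model": fit.spec.name, "term": name, "estimate": b,
                         "sigma_site": fit.sigma_site, "converged": fit.converged}
                    )
            _write(pd.DataFrame(coef_rows), outdir, "model_coefficients", outputs)

        with stage("report"):
            cont = (
                data.assign(stratum=data["stratum"])
                .groupby("stratum")
                .agg(present=("presence", "sum"), total=("presence", "size"))
                .reset_index()
            )
            cont["proportion"] = cont["present"] / cont["total"]
            _write(cont, outdir, "contingency_by_stratum", outputs)
            if config.write_predictions:
                best_fit = next(
                    f for f in fits
                    if f.spec.name == comparison.iloc[0]["model"]
                )
                focal_vars = [v for v in best_fit.spec.variables
                              if v not in ("date",) + tuple(occ.MODERATORS)]
                rt = data["residence_time"]
                mod_vals = (
                    [float(rt.quantile(0.1)), float(rt.quantile(0.9))]
                    if best_fit.spec.moderator == "residence_time" else None
                )
                for v in focal_vars:
                    curves = occ.predict_curves(best_fit, v, moderator_values=mod_vals)
                    _write(curves, outdir, f"predictions_{v}", outputs)
            if config.spatial_check:
                coords = data[["x", "y"]].to_numpy(float)
                chk = occ.residual_spatial_check(fits[0], coords, seed=config.seed)
                _write(chk, outdir, "spatial_autocorrelation", outputs)

        caught = sorted({str(w.message) for w in wrec})

    import rangehab

    manifest = {
        "seed": int(config.seed),
        "package_version": rangehab.__version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "stages": stage_log,
        "warnings": caught,
        "checksums": {name: _sha256(path) for name, path in sorted(outputs.items())},
    }
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest


def fixture_report(outdir) -> dict:
    """Write the fixed survey-margin fixtures and their summary totals."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t1 = synthetic.table1_fixture()
    t2 = synthetic.table2_fixture()
    t1.to_csv(outdir / "table1_contingency.csv", index=False)
    t2.to_csv(outdir / "table2_selection.csv", index=False)
    summary = {
        "point_counts_present": int(t1["present"].sum()),
        "point_counts_total": int(t1["total"].sum()),
        "feeding_observations": int(t2.loc[t2.activity == "feeding", "N"].sum()
                                    + t2.attrs["excluded"]["feeding"]),
        "shelter_observations": int(t2.loc[t2.activity == "shelter", "N"].sum()
                                    + t2.attrs["excluded"]["shelter"]),
    }
    with open(outdir / "fixture_summary.yaml", "w") as fh:
        yaml.safe_dump(summary, fh, sort_keys=True)
    return summary
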