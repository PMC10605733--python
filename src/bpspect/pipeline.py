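"""End-to-end orchestration: study -> hypercube -> ACE -> blobs -> statistics.

``run_patient`` processes one study into per-threshold blob features;
``run_cohort`` maps it over a cohort (one failing patient is recorded
and skipped, never fatal), then fits the statistics layer and writes
flat CSV reports.  Everything is deterministic given the seed, and each
report carries the seed plus a hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import blobs as blobmod
from .ace import ace_score, compute_background_stats, derive_signature, Signature
from .phantom import CohortSpec, PhantomStudy, generate_cohort
from .registration import register_study
from .stats import (
    FEATURE_COLUMNS,
    StatsError,
    fit_multivariate,
    logistic_split_auc,
    threshold_sweep,
)

log = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.90, 0.92, 0.94, 0.96)
CLINICAL_COLUMNS = ("psa_ng_ml", "age_years", "prostate_volume_ml")


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    min_blob_voxels: int = 5
    auc_reps: int = 1000
    train_frac: float = 0.7
    seed: int = 0
    extra_shifts: dict[str, tuple[int, int]] = field(default_factory=dict)
    signature: tuple[float, float, float] | None = None  # explicit override
    squared_ace: bool = True
    eccentricity_definition: str = "normalized-difference"
    out_dir: str | None = None
    write_plots: bool = False

    def __post_init__(self) -> None:
        thr = tuple(float(t) for t in self.thresholds)
        if len(set(thr)) != len(thr) or any(not 0.0 < t < 1.0 for t in thr):
            raise ConfigError("thresholds must be unique values in (0, 1)")
        self.thresholds = tuple(sorted(thr))
        if self.min_blob_voxels < 1:
            raise ConfigError("min_blob_voxels must be >= 1")
        if not 0.0 < self.train_frac < 1.0:
            raise ConfigError("train_frac must be in (0, 1)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["extra_shifts"] = {k: list(v) for k, v in self.extra_shifts.items()}
        return d

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PatientResult:
    patient_id: str
    features: pd.DataFrame              # one row per threshold
    blob_tables: dict[float, pd.DataFrame]
    n_background_voxels: int
    signature: np.ndarray
    elapsed_s: float


def run_patient(study: PhantomStudy, config: RunConfig) -> PatientResult:
    """Register, detect and blob one study at every configured threshold."""
    t0 = time.perf_counter()
    cube, masks = register_study(
        study.sequences,
        masks={"prostate": study.prostate_mask, "tumor": study.tumor_mask},
        extra_shifts=config.extra_shifts,
    )
    prostate = masks["prostate"].astype(bool)
    stats = compute_background_stats(cube, prostate)
    if config.signature is not None:
        sig = Signature(np.asarray(config.signature, dtype=float),
                        provenance="config")
    else:
        seed_region = masks.get("tumor")
        if seed_region is None or not np.any(seed_region):
            raise ConfigError(
                f"{study.patient_id}: no seed region available and no explicit "
                "signature configured"
            )
        sig = derive_signature(cube, seed_region > 0, stats=stats)
    det = ace_score(cube, stats, sig, squared=config.squared_ace)

    scene = prostate | (masks.get("tumor", np.zeros_like(prostate)) > 0)
    rows = []
    tables: dict[float, pd.DataFrame] = {}
    det_mosaic = cube.stitch_like(det.scores)
    scene_mosaic = cube.stitch_like(scene.astype(float)) > 0
    for thr in config.thresholds:
        mask = (det_mosaic > thr) & scene_mosaic
        found = blobmod.label_blobs(mask, cube.slice_index_map)
        kept = blobmod.filter_blobs(found, min_voxels=config.min_blob_voxels)
        blobmod.measure_blobs(kept, cube.voxel_volume_ml,
                              definition=config.eccentricity_definition)
        feats = blobmod.extract_features(kept)
        if feats["empty"]:
            log.info("%s: no blobs survive at threshold %.2f",
                     study.patient_id, thr)
        rows.append({"patient_id": study.patient_id, "threshold": thr, **feats})
        tables[thr] = blobmod.blob_table(kept)
    features = pd.DataFrame(rows)
    return PatientResult(
        patient_id=study.patient_id,
        features=features,
        blob_tables=tables,
        n_background_voxels=stats.n_voxels,
        signature=sig.vector,
        elapsed_s=time.perf_counter() - t0,
    )


@dataclass
class CohortReport:
    features: pd.DataFrame
    sweep: pd.DataFrame | None
    multivariate: pd.DataFrame | None
    clinical: pd.DataFrame | None
    errors: dict[str, str]
    meta: dict

    @property
    def ok(self) -> bool:
        return not self.errors


def _multivariate_table(features: pd.DataFrame, cohort: pd.DataFrame,
                        config: RunConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Two-predictor fits (eccentricity + each volume) per threshold."""
    merged = features.merge(cohort, on="patient_id", validate="many_to_one")
    rows = []
    for thr in sorted(merged["threshold"].unique()):
        sub = merged[merged["threshold"] == thr]
        y = sub["isup_grade"].to_numpy(dtype=float)
        labels = sub["cspca"].to_numpy(dtype=bool)
        ecc = sub["max_blob_ecc"].to_numpy(dtype=float)
        for volcol in ("ave_blob_vol_ml", "max_blob_vol_ml"):
            vol = sub[volcol].to_numpy(dtype=float)
            row = {"threshold": thr, "variable_1": "max_blob_ecc",
                   "variable_2": volcol, "n": len(sub)}
            try:
                fit = fit_multivariate(ecc, vol, y, names=("max_blob_ecc", volcol))
                row.update(
                    r1=fit.r["max_blob_ecc"], p1=fit.p_values["max_blob_ecc"],
                    r2=fit.r[volcol], p2=fit.p_values[volcol],
                    r12=fit.r_multiple, f_pvalue=fit.f_pvalue,
                )
            except StatsError as exc:
                log.info("multivariate fit skipped at %.2f: %s", thr, exc)
                row.update(r1=np.nan, p1=np.nan, r2=np.nan, p2=np.nan,
                           r12=np.nan, f_pvalue=np.nan)
            try:
                roc = logistic_split_auc(
                    np.column_stack([ecc, vol]), labels,
                    train_frac=config.train_frac, reps=config.auc_reps,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                row.update(auc=roc.mean_auc, auc_ci_low=roc.ci_95[0],
                           auc_ci_high=roc.ci_95[1])
            except StatsError:
                row.update(auc=np.nan, auc_ci_low=np.nan, auc_ci_high=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


def _clinical_table(cohort: pd.DataFrame, config: RunConfig,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Univariate fits and AUCs of the clinical covariates (no imaging)."""
    from .stats import fit_univariate

    y = cohort["isup_grade"].to_numpy(dtype=float)
    labels = cohort["cspca"].to_numpy(dtype=bool)
    rows = []
    for col in CLINICAL_COLUMNS:
        if col not in cohort.columns:
            continue
        x = cohort[col].to_numpy(dtype=float)
        row = {"feature": col, "n": len(cohort)}
        try:
            fit = fit_univariate(x, y, name=col)
            row.update(r=fit.r[col], p_value=fit.p_values[col])
        except StatsError:
            row.update(r=np.nan, p_value=np.nan)
        try:
            roc = logistic_split_auc(
                x, labels, train_frac=config.train_frac, reps=config.auc_reps,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            row.update(auc=roc.mean_auc, auc_ci_low=roc.ci_95[0],
                       auc_ci_high=roc.ci_95[1])
        except StatsError:
            row.update(auc=np.nan, auc_ci_low=np.nan, auc_ci_high=np.nan)
        rows.append(row)
    return pd.DataFrame(rows)


def run_cohort(studies: list[PhantomStudy], cohort: pd.DataFrame,
               config: RunConfig) -> CohortReport:
    """Process every patient, then fit the statistics layer.

    Per-patient failures are collected in ``report.errors``; the
    statistics stage runs on the surviving patients (and is skipped with
    a message when the cohort is degenerate, e.g. one class only).
    """
    if len(studies) < 2:
        raise ConfigError("need at least 2 patients")
    rng = np.random.default_rng(config.seed)
    frames, errors = [], {}
    for study in studies:
        try:
            result = run_patient(study, config)
            frames.append(result.features)
            log.info("%s: %d bg voxels, %.3f s", study.patient_id,
                     result.n_background_voxels, result.elapsed_s)
        except Exception as exc:  # graceful degradation, never abort the cohort
            errors[study.patient_id] = str(exc)
            log.warning("%s failed: %s", study.patient_id, exc)
    if not frames:
        raise ConfigError("every patient failed; nothing to analyse")
    features = pd.concat(frames, ignore_index=True)
    kept = cohort[cohort["patient_id"].isin(features["patient_id"])]

    sweep = multivariate = clinical = None
    if kept["cspca"].nunique() < 2:
        log.warning("cohort has a single CsPCa class; statistics stage skipped")
    else:
        sweep = threshold_sweep(
            features, kept, auc_reps=config.auc_reps,
            train_frac=config.train_frac,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        multivariate = _multivariate_table(features, kept, config, rng)
        clinical = _clinical_table(kept, config, rng)

    meta = {
        "seed": config.seed,
        "config_hash": config.config_hash,
        "config": config.to_dict(),
        "n_patients": len(studies),
        "n_failed": len(errors),
    }
    report = CohortReport(features=features, sweep=sweep,
                          multivariate=multivariate, clinical=clinical,
                          errors=errors, meta=meta)
    if config.out_dir:
        write_report(report, Path(config.out_dir), config)
    return report


def write_report(report: CohortReport, out_dir: Path, config: RunConfig) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    report.features.to_csv(out_dir / "features.csv", index=False)
    if report.sweep is not None:
        report.sweep.to_csv(out_dir / "univariate_sweep.csv", index=False)
    if report.multivariate is not None:
        report.multivariate.to_csv(out_dir / "multivariate_fits.csv", index=False)
    if report.clinical is not None:
        report.clinical.to_csv(out_dir / "clinical_fits.csv", index=False)
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump({**report.meta, "errors": report.errors}, fh, indent=2)
    if config.write_plots and report.sweep is not None:
        from .viz import sweep_plot

        sweep_plot(report.sweep, out_dir / "sweep.png")


def simulate_and_run(cspec: CohortSpec, config: RunConfig) -> CohortReport:
    studies, cohort = generate_cohort(cspec)
    return run_cohort(studies, cohort, config)
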