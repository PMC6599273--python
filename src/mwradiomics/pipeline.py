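"""End-to-end orchestration: simulate -> segment -> VDT -> features ->
select -> model -> report.

One :func:`run_all` call executes every stage on a phantom cohort and
writes all artifacts (growth table, feature tables, selection reports,
model and performance JSONs, nomogram) plus a reproducibility manifest
with per-stage digests.  All randomness flows through the seeds recorded
in the config.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .growth import AGGRESSIVE, ScanInterval, classify_interval, compute_vdt
from .models import (build_nomogram, combine_clinical, evaluate, fit_logistic,
                     plot_nomogram, radiomics_score)
from .phantoms import CTVolume, PhantomConfig, generate_cohort
from .radiomics import CATALOGUE, RadiomicsExtractor
from .selection import GrowthFeatureSelector
from .windows import build_mask_set

__all__ = ["RunConfig", "run_all", "build_feature_table"]


@dataclass
class RunConfig:
    """Configuration of one full pipeline run."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    alpha: float = 0.05
    n_boot_feature: int = 200
    auroc_floor: float = 0.5
    r_threshold: float = 0.8
    p_enter: float = 0.05
    p_remove: float = 0.10
    #: bootstrap replicates for model validation (demo default keeps the
    #: one-command run fast; raise for production-quality intervals)
    n_boot_eval: int = 500
    seed: int = 1
    out_dir: str | None = None
    make_plots: bool = True


def _segment_interval(vols: list[CTVolume], k: int):
    """Masks and volumes for interval k (baseline scan k, follow-up k+1)."""
    base = vols[k]
    follow = vols[k + 1]
    center = tuple(int(s // 2) for s in base.data.shape)
    masks0 = build_mask_set(base.data, center, base.spacing)
    masks1 = build_mask_set(follow.data, center, follow.spacing)
    return base, masks0, masks1


def build_feature_table(
    cohort: list[list[CTVolume]],
    extractor: RadiomicsExtractor | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment, measure and extract features for every screening interval.

    Returns ``(features, growth)``: one row per interval observation.  The
    feature table has ``LW_F*`` and ``DR_F*`` columns (lung-window and
    difference-region roles); the growth table carries volumes, VDT and the
    interval class observed from the measured volumes.
    """
    extractor = extractor or RadiomicsExtractor()
    feat_rows, growth_rows = [], []
    for vols in cohort:
        pid = vols[0].patient_id
        for k in range(len(vols) - 1):
            base, masks0, masks1 = _segment_interval(vols, k)
            v0 = masks0.volumes_mm3["lung_window"]
            v1 = masks1.volumes_mm3["lung_window"]
            ti = vols[k + 1].acquisition_day - vols[k].acquisition_day
            vdt = compute_vdt(ScanInterval(V0=v0, Vi=v1, Ti=ti))
            cls = classify_interval(vdt)
            growth_rows.append({
                "patient_id": pid, "nodule_id": pid, "interval_index": k,
                "V0": v0, "Vi": v1, "Ti": ti, "vdt": vdt,
                "interval_class": cls,
                "mw_volume_mm3": masks0.volumes_mm3["mediastinal_window"],
                "dr_volume_mm3": masks0.volumes_mm3["difference_region"],
            })
            lw = extractor.extract(base.data, masks0.lw_mask, base.spacing,
                                   role="lung_window")
            dr = extractor.extract(base.data, masks0.dr_mask, base.spacing,
                                   role="difference_region")
            row = {"patient_id": pid, "interval_index": k}
            row.update({f"LW_{c}": v for c, v in lw.values.items()})
            row.update({f"DR_{c}": v for c, v in dr.values.items()})
            feat_rows.append(row)
    return pd.DataFrame(feat_rows), pd.DataFrame(growth_rows)


def _digest_frame(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()[:16]


def _select_and_fit(features: pd.DataFrame, y: np.ndarray, cols: list[str],
                    cfg: RunConfig, family: str):
    sel = GrowthFeatureSelector(
        alpha=cfg.alpha, n_boot=cfg.n_boot_feature, auroc_floor=cfg.auroc_floor,
        r_threshold=cfg.r_threshold, p_enter=cfg.p_enter,
        p_remove=cfg.p_remove, random_state=cfg.seed)
    sel.fit(features[cols], y)
    chosen = sel.selected_features_
    complete = features[chosen].notna().all(axis=1) if chosen else \
        pd.Series(True, index=features.index)
    model = fit_logistic(features.loc[complete, chosen] if chosen
                         else features.loc[complete, []],
                         y[complete.to_numpy()], covariates=chosen,
                         family=family)
    return sel, model, complete


def run_all(config: RunConfig) -> dict:
    """Run the full analysis and return the result bundle.

    The returned dict holds the manifest, tables, selection reports, fitted
    models and performance summaries; artifacts are also written under
    ``config.out_dir`` when set.
    """
    t_start = time.time()
    stage_times: dict[str, float] = {}
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    t0 = time.time()
    phantom_cfg = config.phantom
    cohort, truth, clinical = generate_cohort(phantom_cfg)
    stage_times["simulate"] = time.time() - t0

    t0 = time.time()
    features, growth = build_feature_table(cohort)
    stage_times["segment_features"] = time.time() - t0

    y = (growth["interval_class"] == AGGRESSIVE).to_numpy().astype(int)
    if y.min() == y.max():
        raise RuntimeError("pipeline halted at stage 'select': cohort has a "
                           "single growth class; enlarge n_patients")
    lw_cols = [c for c in features.columns if c.startswith("LW_")]
    dr_cols = [c for c in features.columns if c.startswith("DR_")]

    t0 = time.time()
    results: dict[str, dict] = {}
    scores: dict[str, np.ndarray] = {}
    clin_rows = clinical.set_index("patient_id").loc[
        features["patient_id"]].reset_index()
    for family, cols in (("lung_window", lw_cols),
                         ("difference_region", dr_cols),
                         ("combined", lw_cols + dr_cols)):
        sel, model, complete = _select_and_fit(features, y, cols, config, family)
        score = np.full(len(features), np.nan)
        if model.covariates:
            score[complete.to_numpy()] = radiomics_score(
                model, features.loc[complete, model.covariates])
        else:
            score[complete.to_numpy()] = model.intercept
        perf = evaluate(score[complete.to_numpy()], y[complete.to_numpy()],
                        n_boot=config.n_boot_eval, seed=config.seed)
        scores[family] = score
        # clinical augmentation: radiomics score + sex + COPD
        comb = combine_clinical(score[complete.to_numpy()],
                                clin_rows.loc[complete.to_numpy()],
                                y[complete.to_numpy()],
                                family=f"nomogram_{family}")
        comb_X = clin_rows.loc[complete.to_numpy(),
                               ["sex_female", "copd"]].reset_index(drop=True).copy()
        comb_X.insert(0, "radiomics_score", score[complete.to_numpy()])
        comb_perf = evaluate(comb.linear_predictor(comb_X), y[complete.to_numpy()],
                             n_boot=config.n_boot_eval, seed=config.seed)
        nomogram = build_nomogram(comb, comb_X)
        results[family] = {
            "selection": sel.report_.to_dict(),
            "model": model.to_dict(),
            "performance": perf.to_dict(),
            "nomogram_model": comb.to_dict(),
            "nomogram_performance": comb_perf.to_dict(),
            "nomogram": nomogram.to_dict(),
        }
        if out and config.make_plots:
            plot_nomogram(nomogram, out / f"nomogram_{family}.png")

    clin_model = fit_logistic(clin_rows[["sex_female", "copd"]], y,
                              family="clinical")
    clin_perf = evaluate(clin_model.linear_predictor(
        clin_rows[["sex_female", "copd"]]), y,
        n_boot=config.n_boot_eval, seed=config.seed)
    results["clinical"] = {"model": clin_model.to_dict(),
                           "performance": clin_perf.to_dict()}
    stage_times["model"] = time.time() - t0

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "phantom_config": asdict(phantom_cfg),
        "catalogue_digest": CATALOGUE.digest(),
        "digests": {
            "features": _digest_frame(features),
            "growth": _digest_frame(growth),
            "clinical": _digest_frame(clinical),
        },
        "stage_seconds": stage_times,
        "total_seconds": time.time() - t_start,
        "n_observations": int(len(features)),
        "class_counts": {
            "aggressive": int(y.sum()),
            "indolent": int((1 - y).sum()),
        },
    }

    bundle = {
        "manifest": manifest,
        "features": features,
        "growth": growth,
        "clinical": clinical,
        "truth": truth,
        "results": results,
    }
    if out:
        features.to_csv(out / "features.csv", index=False)
        growth.to_csv(out / "growth.csv", index=False)
        clinical.to_csv(out / "clinical.csv", index=False)
        truth.intervals.to_csv(out / "truth_intervals.csv", index=False)
        truth.nodules.to_csv(out / "truth_nodules.csv", index=False)
        with open(out / "results.json", "w") as fh:
            json.dump(results, fh, indent=2, default=float)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=float)
    return bundle
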