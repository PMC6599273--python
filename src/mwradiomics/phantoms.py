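"""Synthetic longitudinal CT nodule phantoms.

Generates cohorts of part-solid lung nodules with known ground truth so the
whole analysis chain (window segmentation, VDT labelling, feature
extraction, selection, modelling) can be exercised and validated without
access to screening-trial images.

Each phantom nodule is the superposition of an ellipsoidal *solid core*
(soft-tissue HU, visible in the mediastinal window) and a concentric,
angularly perturbed *ground-glass rim* (intermediate HU, visible only in
the lung window), embedded in noisy lung-parenchyma background.  Growth is
exact isotropic scaling about the nodule centroid at an assigned
volume-doubling time, so the generated volume ratio over an interval is
``2**(dt / VDT)`` up to voxelization error.  The class-conditional
rim-to-total volume fraction is the planted radiomic effect: indolent
lesions are predominantly ground-glass, aggressive lesions predominantly
solid, mirroring the clinical association between subsolid morphology and
slow growth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .growth import AGGRESSIVE, INDOLENT, classify_interval, label_patient

__all__ = ["PhantomConfig", "PhantomTruth", "CTVolume", "generate_cohort", "generate_clinical"]


@dataclass(frozen=True)
class CTVolume:
    """A 3D CT-like volume in Hounsfield units, axis order (z, y, x)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    acquisition_day: float
    patient_id: int
    timepoint: int


@dataclass
class PhantomConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate the screening-cohort structure the analysis targets:
    ~26% indolent nodules, class-median VDTs near 583 vs 148 days, annual
    screening intervals, and clinical covariates (sex, COPD) whose
    class-conditional frequencies mirror the observed imbalance
    (70% vs 31% female; 0% vs 21% COPD in indolent vs aggressive).
    """

    n_patients: int = 60
    timepoints: int = 2
    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    background_hu: float = -850.0
    noise_sd: float = 20.0
    core_hu: tuple[float, float] = (20.0, 60.0)
    rim_hu: tuple[float, float] = (-650.0, -350.0)
    indolent_fraction: float = 0.26
    #: (mu, sigma) of log(VDT/days); indolent truncated to (400, inf),
    #: aggressive to [vdt_min, 400).  Medians exp(mu): ~583 and ~148 days.
    vdt_indolent: tuple[float, float] = (math.log(583.0), 0.35)
    vdt_aggressive: tuple[float, float] = (math.log(148.0), 0.45)
    vdt_min: float = 80.0
    #: probability that a 3-timepoint patient switches class between intervals
    mixed_fraction: float = 17.0 / 36.0
    #: Beta(a, b) parameters of rim-to-total volume fraction per class —
    #: the planted radiomic effect (indolent: mostly ground-glass)
    rim_fraction_by_class: dict = field(
        default_factory=lambda: {INDOLENT: (8.0, 4.0), AGGRESSIVE: (4.0, 8.0)}
    )
    #: class-conditional Bernoulli probabilities for the clinical covariates
    female_prob_by_class: dict = field(
        default_factory=lambda: {INDOLENT: 0.70, AGGRESSIVE: 0.3117}
    )
    copd_prob_by_class: dict = field(
        default_factory=lambda: {INDOLENT: 0.0, AGGRESSIVE: 0.2078}
    )
    #: baseline whole-nodule volume range (mm^3), drawn log-uniform
    baseline_volume_mm3: tuple[float, float] = (250.0, 700.0)
    #: screening interval range in days
    interval_days: tuple[float, float] = (300.0, 430.0)
    #: amplitude of the angular rim perturbation (fraction of radius)
    rim_perturbation: float = 0.12
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.indolent_fraction <= 1.0:
            raise ValueError("indolent_fraction must be in [0, 1]")
        if self.timepoints not in (2, 3):
            raise ValueError("timepoints must be 2 or 3")
        for name, (mu, sigma) in (("vdt_indolent", self.vdt_indolent),
                                  ("vdt_aggressive", self.vdt_aggressive)):
            if sigma <= 0 or not math.isfinite(mu):
                raise ValueError(f"{name} log-normal parameters invalid: ({mu}, {sigma})")
        if self.vdt_min <= 0:
            raise ValueError("vdt_min must be positive")
        if not 0.0 <= self.mixed_fraction <= 1.0:
            raise ValueError("mixed_fraction must be in [0, 1]")
        for d in (self.female_prob_by_class, self.copd_prob_by_class):
            for cls, p in d.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"clinical probability for {cls} out of [0, 1]: {p}")
        if min(self.grid_shape) < 16:
            raise ValueError("grid too small to contain a nodule plus margin")


@dataclass
class PhantomTruth:
    """Ground truth of a generated cohort.

    ``nodules``: one row per patient/nodule (class, rim fraction, covariate
    draws pending); ``intervals``: one row per screening interval with the
    assigned VDT, true rasterized volumes and the class implied by the
    400-day rule.
    """

    nodules: pd.DataFrame
    intervals: pd.DataFrame


# ---------------------------------------------------------------------------
# geometry helpers


def _rim_radius_factor(theta: np.ndarray, phi: np.ndarray, coeffs: np.ndarray,
                       amplitude: float) -> np.ndarray:
    """Low-order angular perturbation 1 + amplitude * f(theta, phi).

    f is a fixed combination of low-degree spherical-harmonic-like terms
    with per-nodule random coefficients in [-1, 1], normalized so
    |f| <= 1 (hence the radius factor stays within 1 +/- amplitude).
    """
    c = coeffs
    f = (
        c[0] * 0.5 * (3.0 * np.cos(theta) ** 2 - 1.0)
        + c[1] * np.sin(theta) ** 2 * np.cos(2.0 * phi)
        + c[2] * np.sin(2.0 * theta) * np.cos(phi)
        + c[3] * np.sin(theta) ** 3 * np.cos(3.0 * phi)
    )
    norm = np.abs(c).sum() or 1.0
    return 1.0 + amplitude * f / norm


def _rasterize_nodule(
    grid_shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
    center_mm: np.ndarray,
    rim_radius_mm: float,
    core_semiaxes_mm: np.ndarray,
    coeffs: np.ndarray,
    amplitude: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary (rim_total, core) voxel masks of one nodule on the grid."""
    sp = np.asarray(spacing, float)
    # bounding box around the nodule to keep evaluation local
    rmax = rim_radius_mm * (1.0 + amplitude) + 2.0 * sp.max()
    lo = np.maximum(np.floor((center_mm - rmax) / sp).astype(int), 0)
    hi = np.minimum(np.ceil((center_mm + rmax) / sp).astype(int) + 1,
                    np.asarray(grid_shape))
    zz, yy, xx = np.meshgrid(
        *(np.arange(lo[i], hi[i]) * sp[i] - center_mm[i] for i in range(3)),
        indexing="ij",
    )
    r = np.sqrt(zz ** 2 + yy ** 2 + xx ** 2)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(np.where(r > 0, zz / np.where(r > 0, r, 1.0), 1.0), -1, 1))
    phi = np.arctan2(yy, xx)
    rim_local = r <= rim_radius_mm * _rim_radius_factor(theta, phi, coeffs, amplitude)
    core_local = ((zz / core_semiaxes_mm[0]) ** 2
                  + (yy / core_semiaxes_mm[1]) ** 2
                  + (xx / core_semiaxes_mm[2]) ** 2) <= 1.0
    rim = np.zeros(grid_shape, dtype=bool)
    core = np.zeros(grid_shape, dtype=bool)
    sl = tuple(slice(lo[i], hi[i]) for i in range(3))
    rim[sl] = rim_local
    core[sl] = core_local & rim_local
    return rim, core


def _mean_cubed_radius_factor(coeffs: np.ndarray, amplitude: float) -> float:
    """Angular mean of (R/R0)^3, for converting target volume to R0."""
    t = np.linspace(0.0, math.pi, 64)
    p = np.linspace(-math.pi, math.pi, 128, endpoint=False)
    tt, pp = np.meshgrid(t, p, indexing="ij")
    fac = _rim_radius_factor(tt, pp, coeffs, amplitude) ** 3
    w = np.sin(tt)
    return float((fac * w).sum() / w.sum())


def _draw_truncated_lognormal(rng: np.random.Generator, mu: float, sigma: float,
                              lo: float, hi: float) -> float:
    for _ in range(1000):
        v = float(rng.lognormal(mu, sigma))
        if lo < v < hi:
            return v
    raise RuntimeError(
        f"could not draw log-normal({mu:.3g}, {sigma:.3g}) within ({lo}, {hi})"
    )


# ---------------------------------------------------------------------------
# cohort generation


def _assign_classes(rng: np.random.Generator, cfg: PhantomConfig) -> list[list[str]]:
    """Per-patient list of per-interval classes."""
    n_intervals = cfg.timepoints - 1
    out = []
    for _ in range(cfg.n_patients):
        base = INDOLENT if rng.random() < cfg.indolent_fraction else AGGRESSIVE
        classes = [base] * n_intervals
        if n_intervals >= 2 and rng.random() < cfg.mixed_fraction:
            other = AGGRESSIVE if base == INDOLENT else INDOLENT
            classes = [base] + [other] * (n_intervals - 1)
        out.append(classes)
    return out


def generate_cohort(
    config: PhantomConfig,
) -> tuple[list[list[CTVolume]], PhantomTruth, pd.DataFrame]:
    """Generate a longitudinal phantom cohort.

    Returns per-patient lists of :class:`CTVolume` (one per timepoint), the
    ground-truth tables, and the clinical covariate table.  Identical
    config and seed reproduce bit-identical volumes.
    """
    config.validate()
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    sp = np.asarray(cfg.voxel_spacing, float)
    voxel_vol = float(np.prod(sp))
    grid = tuple(cfg.grid_shape)
    center_mm = (np.asarray(grid, float) - 1.0) / 2.0 * sp

    interval_classes = _assign_classes(rng, cfg)
    volumes: list[list[CTVolume]] = []
    nod_rows, int_rows = [], []

    for pid, classes in enumerate(interval_classes):
        # class-conditional planted effect: rim fraction of total volume
        rf_a, rf_b = cfg.rim_fraction_by_class[classes[0]]
        rim_fraction = float(rng.beta(rf_a, rf_b))
        core_fraction = 1.0 - rim_fraction

        v0 = float(np.exp(rng.uniform(*np.log(cfg.baseline_volume_mm3))))
        coeffs = rng.uniform(-1.0, 1.0, size=4)
        mean_fac = _mean_cubed_radius_factor(coeffs, cfg.rim_perturbation)
        r0 = (3.0 * v0 / (4.0 * math.pi * mean_fac)) ** (1.0 / 3.0)

        # per-interval VDTs from the class-conditional truncated log-normals
        vdts, dts = [], []
        for cls in classes:
            if cls == INDOLENT:
                mu, sigma = cfg.vdt_indolent
                v = _draw_truncated_lognormal(rng, mu, sigma, 400.0, math.inf)
            else:
                mu, sigma = cfg.vdt_aggressive
                v = _draw_truncated_lognormal(rng, mu, sigma, cfg.vdt_min, 400.0)
            vdts.append(v)
            dts.append(float(rng.uniform(*cfg.interval_days)))

        # cumulative isotropic scale factor per timepoint
        scales = [1.0]
        for vdt, dt in zip(vdts, dts):
            scales.append(scales[-1] * 2.0 ** (dt / vdt / 3.0))

        # grid-capacity check: largest extent plus 3-voxel margin
        r_final = r0 * scales[-1] * (1.0 + cfg.rim_perturbation)
        half_extent = (np.asarray(grid, float) / 2.0 - 3.0) * sp
        if r_final > half_extent.min():
            raise ValueError(
                f"patient {pid}: nodule (final radius {r_final:.1f} mm) outside "
                f"grid {grid} with a 3-voxel margin; enlarge grid_shape or "
                f"reduce baseline_volume_mm3 / growth"
            )

        core_hu = float(rng.uniform(*cfg.core_hu))
        rim_hu = float(rng.uniform(*cfg.rim_hu))
        # ellipsoidal core: random mild anisotropy, volume = core_fraction*v0
        ax = rng.uniform(0.75, 1.3, size=3)
        ax /= ax.prod() ** (1.0 / 3.0)
        core_r = (3.0 * core_fraction * v0 / (4.0 * math.pi)) ** (1.0 / 3.0)
        semiaxes = np.minimum(core_r * ax, 0.92 * r0 * (1.0 - cfg.rim_perturbation))

        day = 0.0
        days = [0.0]
        for dt in dts:
            day += dt
            days.append(day)

        pat_vols: list[CTVolume] = []
        true_vols = []
        for t, scale in enumerate(scales):
            rim_mask, core_mask = _rasterize_nodule(
                grid, tuple(sp), center_mm, r0 * scale,
                semiaxes * scale, coeffs, cfg.rim_perturbation,
            )
            hu = np.full(grid, cfg.background_hu, dtype=np.float64)
            hu[rim_mask] = rim_hu
            hu[core_mask] = core_hu
            hu = ndimage.gaussian_filter(hu, sigma=0.5)  # partial-volume blur
            hu += rng.normal(0.0, cfg.noise_sd, size=grid)
            pat_vols.append(CTVolume(data=hu, spacing=tuple(sp),
                                     acquisition_day=days[t],
                                     patient_id=pid, timepoint=t))
            true_vols.append(float(rim_mask.sum() * voxel_vol))

        volumes.append(pat_vols)
        label, direction = label_patient(classes)
        nod_rows.append({
            "patient_id": pid,
            "n_timepoints": cfg.timepoints,
            "rim_fraction": rim_fraction,
            "core_hu": core_hu,
            "rim_hu": rim_hu,
            "patient_label": label,
            "mixed_direction": direction,
            "final_class": classes[-1],
        })
        for k, (vdt, dt, cls) in enumerate(zip(vdts, dts, classes)):
            assert classify_interval(vdt) == cls
            int_rows.append({
                "patient_id": pid,
                "interval_index": k,
                "t0_day": days[k],
                "t1_day": days[k + 1],
                "interval_days": dt,
                "vdt_assigned": vdt,
                "class_assigned": cls,
                "V0_true_mm3": true_vols[k],
                "V1_true_mm3": true_vols[k + 1],
            })

    truth = PhantomTruth(nodules=pd.DataFrame(nod_rows),
                         intervals=pd.DataFrame(int_rows))
    clinical = generate_clinical(cfg, truth, rng=rng)
    return volumes, truth, clinical


def generate_clinical(
    config: PhantomConfig,
    truth: PhantomTruth,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Clinical covariates with class-conditional sex and COPD frequencies.

    Sex and COPD are Bernoulli draws conditional on each patient's final
    growth class; age, pack-years, smoking status and family history are
    drawn independent of class.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    if "final_class" not in truth.nodules.columns:
        raise ValueError("truth.nodules must contain the per-patient final class")
    rows = []
    for r in truth.nodules.itertuples():
        cls = r.final_class
        rows.append({
            "patient_id": r.patient_id,
            "sex_female": int(rng.random() < config.female_prob_by_class[cls]),
            "copd": int(rng.random() < config.copd_prob_by_class[cls]),
            "age": float(np.clip(rng.normal(65.0, 5.3), 55.0, 80.0)),
            "pack_years": float(np.clip(rng.normal(62.0, 24.0), 30.0, 160.0)),
            "smoking_current": int(rng.random() < 0.55),
            "family_history": int(rng.random() < 0.26),
        })
    return pd.DataFrame(rows)


def config_to_dict(config: PhantomConfig) -> dict:
    """JSON/YAML-serializable form of a config."""
    return asdict(config)
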