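"""Volume-doubling time (VDT) and growth-pattern classification.

Assuming exponential growth, the doubling time over a screening interval is

    VDT = ln(2) * T / ln(V_i / V_0)

with T the interval in days and V_0, V_i the earlier and later volumes.
Nodules with VDT >= 400 days are *indolent* (slow-growing, the range in
which overdiagnosis is a concern); VDT < 400 days is *aggressive*.
Non-growing lesions (V_i == V_0 -> infinite VDT; V_i < V_0 -> negative VDT,
i.e. shrinkage) are classified indolent: a lesion that does not grow cannot
be fast-growing.  A patient whose consecutive intervals disagree has a
*mixed* growth pattern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "VDT_THRESHOLD_DAYS",
    "INDOLENT",
    "AGGRESSIVE",
    "MIXED",
    "ScanInterval",
    "GrowthRecord",
    "compute_vdt",
    "classify_interval",
    "label_patient",
    "growth_table",
    "cohort_summary",
]

VDT_THRESHOLD_DAYS = 400.0

INDOLENT = "indolent"
AGGRESSIVE = "aggressive"
MIXED = "mixed"


@dataclass(frozen=True)
class ScanInterval:
    """One pair of scans: earlier volume V0, later volume Vi, interval Ti days."""

    V0: float
    Vi: float
    Ti: float

    def __post_init__(self) -> None:
        if self.Ti <= 0:
            raise ValueError(f"interval time must be positive, got {self.Ti}")
        if self.V0 <= 0:
            raise ValueError(f"baseline volume must be positive, got {self.V0}")


def compute_vdt(interval: ScanInterval | None = None, *, V0: float | None = None,
                Vi: float | None = None, Ti: float | None = None) -> float:
    """Volume-doubling time in days for one scan interval.

    Returns ``math.inf`` when the volume is unchanged and a negative value
    when the lesion shrank.  Raises on a non-positive later volume (an empty
    follow-up mask must be handled by the caller).
    """
    if interval is None:
        interval = ScanInterval(V0=float(V0), Vi=float(Vi), Ti=float(Ti))
    if interval.Vi <= 0:
        raise ValueError(f"later volume must be positive, got {interval.Vi}")
    ratio = interval.Vi / interval.V0
    if ratio == 1.0:
        return math.inf
    return math.log(2.0) * interval.Ti / math.log(ratio)


def classify_interval(vdt: float) -> str:
    """Growth class of one interval: aggressive iff 0 < VDT < 400 days.

    VDT >= 400 (including the 400-day boundary and the infinite sentinel)
    and negative VDTs (shrinking lesions) are indolent.
    """
    if 0.0 < vdt < VDT_THRESHOLD_DAYS:
        return AGGRESSIVE
    return INDOLENT


@dataclass
class GrowthRecord:
    """Per-interval VDTs and classes plus the patient-level pattern label."""

    vdts: list[float]
    interval_classes: list[str]
    patient_label: str
    mixed_direction: str | None = None


def label_patient(interval_classes: Sequence[str]) -> tuple[str, str | None]:
    """Patient-level growth pattern from per-interval classes.

    Returns ``(label, direction)``; direction is ``"indolent->aggressive"``
    or ``"aggressive->indolent"`` for mixed patterns, else None.
    """
    classes = list(interval_classes)
    if not classes:
        raise ValueError("at least one interval class is required")
    bad = set(classes) - {INDOLENT, AGGRESSIVE}
    if bad:
        raise ValueError(f"unknown interval classes: {sorted(bad)}")
    if len(set(classes)) == 1:
        return classes[0], None
    return MIXED, f"{classes[0]}->{classes[-1]}"


def growth_record(intervals: Sequence[ScanInterval]) -> GrowthRecord:
    """Compute VDT and class per interval and the patient pattern label."""
    vdts = [compute_vdt(iv) for iv in intervals]
    classes = [classify_interval(v) for v in vdts]
    label, direction = label_patient(classes)
    return GrowthRecord(vdts=vdts, interval_classes=classes,
                        patient_label=label, mixed_direction=direction)


def growth_table(volumes: pd.DataFrame) -> pd.DataFrame:
    """VDT and growth class per interval from a long volume table.

    Parameters
    ----------
    volumes : DataFrame with columns ``patient_id``, ``nodule_id``, ``V0``,
        ``Vi``, ``Ti`` (one row per consecutive scan interval).

    Returns the same rows with ``vdt``, ``interval_class`` and the
    patient-level ``patient_label`` appended.
    """
    required = {"patient_id", "nodule_id", "V0", "Vi", "Ti"}
    missing = required - set(volumes.columns)
    if missing:
        raise ValueError(f"volume table missing columns: {sorted(missing)}")
    out = volumes.copy()
    out["vdt"] = [
        compute_vdt(ScanInterval(V0=r.V0, Vi=r.Vi, Ti=r.Ti))
        for r in out.itertuples()
    ]
    out["interval_class"] = out["vdt"].map(classify_interval)
    labels = (
        out.groupby("nodule_id", sort=False)["interval_class"]
        .apply(lambda c: label_patient(list(c))[0])
        .rename("patient_label")
    )
    return out.merge(labels, on="nodule_id", how="left")


def cohort_summary(labels: Sequence[str] | pd.Series,
                   clinical: pd.DataFrame | None = None,
                   covariates: Sequence[str] = ("sex_female", "copd")) -> dict:
    """Demographic-style cohort summary: class fractions and, when a
    clinical table is given, per-class covariate percentages.

    Percentages are reported to two decimals, as in screening-cohort
    demographic tables (``n (x.xx%)``).
    """
    lab = pd.Series(list(labels), name="label")
    n = len(lab)
    counts = lab.value_counts().to_dict()
    out = {
        "n": n,
        "class_counts": {k: int(v) for k, v in counts.items()},
        "class_percent": {k: round(100.0 * v / n, 2) for k, v in counts.items()},
    }
    if clinical is not None:
        per_class: dict[str, dict[str, float]] = {}
        cl = clinical.reset_index(drop=True)
        for cls in counts:
            sel = cl[(lab == cls).to_numpy()]
            per_class[cls] = {
                cov: round(100.0 * float(sel[cov].mean()), 2)
                for cov in covariates if cov in sel.columns
            }
        out["covariate_percent"] = per_class
    return out
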