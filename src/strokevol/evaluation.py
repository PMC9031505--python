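"""Segmentation and volumetry evaluation metrics.

Pixel-overlap metrics are computed from per-patient confusion counts:

* sensitivity          TP / (TP + FN)
* specificity (as printed in the source tables)  TP / (TP + FP) — note this
  formula is conventionally precision/PPV; the conventional specificity
  TN / (TN + FP) is additionally reported as ``true_specificity``
* F1                   harmonic mean of precision and recall
* Jaccard              TP / (TP + FP + FN)
* volume similarity    VS = 1 - |FN - FP| / (2 TP + FP + FN)

Volumetry error is the mean absolute difference between estimated and
reference volumes in cc.  Cohort aggregation is macro (average of per-patient
rates) by default; patients whose rate denominator is zero (e.g. lesion-free
controls) are excluded from rate averages unless requested, matching the
practice of evaluating control cohorts by volume error only.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .dicom_io import DwiStudy, LesionMask
from .volumetry import estimate_volume

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "sensitivity",
    "specificity_as_printed",
    "true_specificity",
    "precision",
    "f1",
    "jaccard",
    "volume_similarity",
    "mean_absolute_error",
    "evaluate_cohort",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Pixel tallies of one prediction against one label."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred: LesionMask, label: LesionMask) -> ConfusionCounts:
    """Elementwise confusion tally of two aligned binary masks."""
    p, y = pred.voxels, label.voxels
    if p.shape != y.shape:
        raise ValueError(f"pred shape {p.shape} != label shape {y.shape}")
    p = p.astype(bool)
    y = y.astype(bool)
    tp = int(np.count_nonzero(p & y))
    fp = int(np.count_nonzero(p & ~y))
    fn = int(np.count_nonzero(~p & y))
    tn = int(np.count_nonzero(~p & ~y))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _rate(num: int, den: int) -> float:
    # Degenerate denominators are defined as 0; evaluate_cohort decides
    # whether such patients enter the macro average.
    return num / den if den > 0 else 0.0


def sensitivity(c: ConfusionCounts) -> float:
    return _rate(c.tp, c.tp + c.fn)


def specificity_as_printed(c: ConfusionCounts) -> float:
    """TP / (TP + FP), verbatim from the source's metric table.

    Conventionally this ratio is precision/PPV; it is kept under this name
    because the evaluated tables report it as "specificity"."""
    return _rate(c.tp, c.tp + c.fp)


def true_specificity(c: ConfusionCounts) -> float:
    """TN / (TN + FP), the conventional specificity."""
    return _rate(c.tn, c.tn + c.fp)


def precision(c: ConfusionCounts) -> float:
    return _rate(c.tp, c.tp + c.fp)


def f1(c: ConfusionCounts) -> float:
    p, r = precision(c), sensitivity(c)
    return 2.0 * p * r / (p + r) if (p + r) > 0 else 0.0


def jaccard(c: ConfusionCounts) -> float:
    return _rate(c.tp, c.tp + c.fp + c.fn)


def volume_similarity(c: ConfusionCounts) -> float:
    """VS = 1 - |FN - FP| / (2 TP + FP + FN).

    Equals 1 - ||m| - |g|| / (|m| + |g|) with |m| = TP+FP predicted-positive
    and |g| = TP+FN labeled-positive pixels; it measures volume agreement
    irrespective of localization.  Two empty masks are identical, so VS is
    defined as 1 in that degenerate case.
    """
    den = 2 * c.tp + c.fp + c.fn
    if den == 0:
        return 1.0
    return 1.0 - abs(c.fn - c.fp) / den


def mean_absolute_error(pairs: Sequence[tuple[float, float]]) -> float:
    """Mean |estimated - reference| over patients, in cc."""
    if len(pairs) == 0:
        raise ValueError("mean_absolute_error needs at least one pair")
    return float(np.mean([abs(e - t) for e, t in pairs]))


@dataclass(frozen=True)
class MetricsReport:
    """Cohort summary mirroring the segmentation/volumetry result tables.

    Rate fields are fractions in [0, 1]; ``as_percent_dict`` renders the
    percent scale used for reporting.
    """

    sensitivity: float
    specificity_as_printed: float
    true_specificity: float
    f1: float
    jaccard: float
    vs: float
    mae_cc: float
    n_patients: int
    n_rate_patients: int  # patients entering the rate macro averages
    per_patient: tuple[dict, ...] = field(default_factory=tuple, repr=False)

    def as_percent_dict(self) -> dict:
        return {
            "Sensitivity (%)": round(100 * self.sensitivity, 2),
            "Specificity (%)": round(100 * self.specificity_as_printed, 2),
            "True specificity (%)": round(100 * self.true_specificity, 2),
            "F1-Score (%)": round(100 * self.f1, 2),
            "Jaccard Index (%)": round(100 * self.jaccard, 2),
            "VS (%)": round(100 * self.vs, 2),
            "MAE (cc)": round(self.mae_cc, 3),
            "n_patients": self.n_patients,
        }

    def write_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_percent_dict(), indent=2))

    def write_csv(self, path: str | Path) -> None:
        rows = list(self.per_patient)
        if not rows:
            return
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()))
            writer.writeheader()
            writer.writerows(rows)


def evaluate_cohort(
    predictions: Sequence[LesionMask],
    labels: Sequence[LesionMask],
    studies: Sequence[DwiStudy],
    *,
    pooled: bool = False,
    include_degenerate: bool = False,
) -> MetricsReport:
    """Per-patient confusion counts and volumes, aggregated over a cohort.

    Rates are macro-averaged over patients by default (``pooled=True`` sums
    counts first).  Patients with no labeled-positive pixels — lesion-free
    controls — contribute to MAE but are excluded from the rate averages
    unless ``include_degenerate``.  MAE compares the estimated volume of the
    prediction against that of the label, both through the same
    spacing-aware volumetry.
    """
    if not (len(predictions) == len(labels) == len(studies)):
        raise ValueError("predictions, labels and studies must align 1:1")
    if len(predictions) == 0:
        raise ValueError("cannot evaluate an empty cohort")

    per_patient: list[dict] = []
    counts: list[ConfusionCounts] = []
    vol_pairs: list[tuple[float, float]] = []
    for pred, label, study in zip(predictions, labels, studies):
        c = confusion(pred, label)
        counts.append(c)
        est = estimate_volume(pred, study)
        ref = estimate_volume(label, study)
        vol_pairs.append((est.volume_cc, ref.volume_cc))
        per_patient.append(
            {
                "patient_id": study.patient_id,
                "tp": c.tp, "fp": c.fp, "fn": c.fn, "tn": c.tn,
                "sensitivity": sensitivity(c),
                "specificity_as_printed": specificity_as_printed(c),
                "true_specificity": true_specificity(c),
                "f1": f1(c),
                "jaccard": jaccard(c),
                "vs": volume_similarity(c),
                "volume_pred_cc": est.volume_cc,
                "volume_label_cc": ref.volume_cc,
                "degenerate": c.tp + c.fn == 0,
            }
        )

    if pooled:
        pool = ConfusionCounts(
            tp=sum(c.tp for c in counts),
            fp=sum(c.fp for c in counts),
            fn=sum(c.fn for c in counts),
            tn=sum(c.tn for c in counts),
        )
        rates = {
            "sensitivity": sensitivity(pool),
            "specificity_as_printed": specificity_as_printed(pool),
            "true_specificity": true_specificity(pool),
            "f1": f1(pool),
            "jaccard": jaccard(pool),
            "vs": volume_similarity(pool),
        }
        n_rate = len(counts)
    else:
        rate_rows = [
            r for r in per_patient if include_degenerate or not r["degenerate"]
        ]
        n_rate = len(rate_rows)
        keys = ("sensitivity", "specificity_as_printed", "true_specificity",
                "f1", "jaccard", "vs")
        if rate_rows:
            rates = {k: float(np.mean([r[k] for r in rate_rows])) for k in keys}
        else:
            rates = {k: 0.0 for k in keys}

    return MetricsReport(
        sensitivity=rates["sensitivity"],
        specificity_as_printed=rates["specificity_as_printed"],
        true_specificity=rates["true_specificity"],
        f1=rates["f1"],
        jaccard=rates["jaccard"],
        vs=rates["vs"],
        mae_cc=mean_absolute_error(vol_pairs),
        n_patients=len(predictions),
        n_rate_patients=n_rate,
        per_patient=tuple(per_patient),
    )
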