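"""Segmentation evaluation: overlap metrics, volumetry and reproducibility.

Per class the package reports the similarity index 2|X∩Y|/(|X|+|Y|) — the
Dice coefficient between the predicted and reference voxel sets — together
with one-vs-rest accuracy, sensitivity and specificity over the in-mask
voxels; volumetry converts voxel counts to milliliters and intracranial
volume fractions (over GM+WM+CSF, background excluded); reproducibility of
repeated measurements is summarized as the coefficient of variation
CV% = 100 * sd / mean (sample sd, n-1).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix

from .types import BG, CLASS_NAMES, LABEL_CODES, TISSUE_CODES, BrainMask, LabelVolume


def similarity_index(x: np.ndarray, y: np.ndarray) -> float:
    """2|X∩Y| / (|X| + |Y|) for two voxel sets given as boolean arrays.

    Symmetric, bounded in [0, 1], equal to 1 iff the sets coincide.  Both
    sets empty is undefined (0/0) and rejected.
    """
    xb = np.asarray(x, dtype=bool)
    yb = np.asarray(y, dtype=bool)
    if xb.shape != yb.shape:
        raise ValueError(f"set domains differ: {xb.shape} vs {yb.shape}")
    nx, ny = int(xb.sum()), int(yb.sum())
    if nx + ny == 0:
        raise ValueError("similarity index undefined: both sets are empty")
    return 2.0 * int((xb & yb).sum()) / (nx + ny)


@dataclass
class ConfusionTable:
    """4x4 in-mask cross-tabulation; rows = truth, columns = predicted."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (4, 4):
            raise ValueError("confusion table must be 4x4 (BG, CSF, GM, WM)")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        names = [CLASS_NAMES[c] for c in LABEL_CODES]
        return pd.DataFrame(self.counts, index=names, columns=names)


def confusion(truth: LabelVolume, predicted: LabelVolume,
              mask: BrainMask | None = None) -> ConfusionTable:
    if predicted.grid_shape != truth.grid_shape:
        raise ValueError(
            f"grids differ: truth {truth.grid_shape} vs predicted {predicted.grid_shape}"
        )
    if mask is not None:
        if mask.grid_shape != truth.grid_shape:
            raise ValueError("mask grid mismatches label grids")
        t = truth.labels[mask.mask]
        p = predicted.labels[mask.mask]
    else:
        t = truth.labels.ravel()
        p = predicted.labels.ravel()
    return ConfusionTable(confusion_matrix(t, p, labels=list(LABEL_CODES)))


def class_metrics(table: ConfusionTable, code: int) -> Dict[str, Optional[float]]:
    """One-vs-rest accuracy, sensitivity and specificity for one class.

    A class absent from both truth and prediction has undefined sensitivity;
    it is reported as ``None`` (missing), never as 0.
    """
    if code not in LABEL_CODES:
        raise ValueError(f"unknown class code {code}")
    if table.total == 0:
        raise ValueError("empty confusion table")
    i = LABEL_CODES.index(code)
    tp = int(table.counts[i, i])
    fn = int(table.counts[i].sum()) - tp
    fp = int(table.counts[:, i].sum()) - tp
    tn = table.total - tp - fn - fp
    accuracy = (tp + tn) / table.total
    sensitivity = tp / (tp + fn) if tp + fn > 0 else None
    specificity = tn / (tn + fp) if tn + fp > 0 else None
    return {"accuracy": accuracy, "sensitivity": sensitivity, "specificity": specificity}


@dataclass
class OverlapReport:
    """Per-tissue similarity/accuracy/sensitivity/specificity, serializable."""

    per_class: Mapping[int, Dict[str, Optional[float]]]
    table: ConfusionTable

    def to_frame(self) -> pd.DataFrame:
        rows = {CLASS_NAMES[c]: m for c, m in self.per_class.items()}
        return pd.DataFrame(rows).T[
            ["accuracy", "sensitivity", "specificity", "similarity_index"]
        ]

    def to_json(self, path) -> None:
        payload = {CLASS_NAMES[c]: m for c, m in self.per_class.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="class")


def evaluate_against_truth(predicted: LabelVolume, truth: LabelVolume,
                           mask: BrainMask | None = None,
                           classes: Sequence[int] = TISSUE_CODES) -> OverlapReport:
    """All four metrics per tissue class over the in-mask voxels."""
    table = confusion(truth, predicted, mask)
    if mask is not None:
        t = truth.labels[mask.mask]
        p = predicted.labels[mask.mask]
    else:
        t = truth.labels.ravel()
        p = predicted.labels.ravel()
    per_class: Dict[int, Dict[str, Optional[float]]] = {}
    for code in classes:
        m = dict(class_metrics(table, code))
        tb, pb = t == code, p == code
        if tb.any() or pb.any():
            m["similarity_index"] = similarity_index(tb, pb)
        else:
            m["similarity_index"] = None
        per_class[int(code)] = m
    return OverlapReport(per_class=per_class, table=table)


@dataclass
class VolumeReport:
    """Absolute tissue volumes (ml) and intracranial volume fractions (%)."""

    volumes_ml: Mapping[int, float]      # all four classes
    fractions_percent: Mapping[int, float]  # tissues only, sums to 100
    voxel_volume_mm3: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for code in LABEL_CODES:
            rows.append({
                "class": CLASS_NAMES[code],
                "volume_ml": self.volumes_ml[code],
                "fraction_percent": self.fractions_percent.get(code, float("nan")),
            })
        return pd.DataFrame(rows).set_index("class")

    def to_json(self, path) -> None:
        payload = {
            "voxel_volume_mm3": self.voxel_volume_mm3,
            "volumes_ml": {CLASS_NAMES[c]: v for c, v in self.volumes_ml.items()},
            "fractions_percent": {CLASS_NAMES[c]: v for c, v in self.fractions_percent.items()},
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def tissue_volumes(labels: LabelVolume,
                   voxel_size_mm: Sequence[float] | None = None) -> VolumeReport:
    """Per-class ml = voxel count x voxel volume / 1000; fractions over
    GM+WM+CSF only (background excluded), x100."""
    vs = labels.voxel_size_mm if voxel_size_mm is None else tuple(float(v) for v in voxel_size_mm)
    voxel_mm3 = float(np.prod(vs))
    counts = labels.class_counts()
    if sum(counts[c] for c in TISSUE_CODES) == 0:
        raise ValueError("no tissue voxels (only background) — volumes undefined")
    volumes = {c: counts[c] * voxel_mm3 / 1000.0 for c in LABEL_CODES}
    icv = sum(volumes[c] for c in TISSUE_CODES)
    fractions = {c: 100.0 * volumes[c] / icv for c in TISSUE_CODES}
    return VolumeReport(volumes_ml=volumes, fractions_percent=fractions,
                        voxel_volume_mm3=voxel_mm3)


def volume_fractions_from_ml(volumes_ml: Mapping[str, float]) -> Dict[str, float]:
    """Fractions (%) over GM+WM+CSF from already-measured absolute volumes.

    Accepts a mapping with keys 'GM', 'WM', 'CSF' in milliliters — e.g. the
    printed per-subject volumes of a volumetry report — and returns each
    tissue's percentage share of their sum.
    """
    required = ("GM", "WM", "CSF")
    missing = [k for k in required if k not in volumes_ml]
    if missing:
        raise ValueError(f"missing tissue volumes: {missing}")
    icv = sum(float(volumes_ml[k]) for k in required)
    if icv <= 0:
        raise ValueError("total tissue volume must be positive")
    return {k: 100.0 * float(volumes_ml[k]) / icv for k in required}


def coefficient_of_variation(measurements: Sequence[float]) -> float:
    """CV% = 100 * sample standard deviation / mean of repeated measurements."""
    x = np.asarray(list(measurements), dtype=np.float64)
    if x.size < 2:
        raise ValueError("CV needs at least 2 measurements")
    mean = x.mean()
    if mean == 0:
        raise ValueError("CV undefined for zero mean")
    return float(100.0 * x.std(ddof=1) / mean)


@dataclass
class VariabilityReport:
    """Mean, sd and CV% per class and quantity over repeated measurements."""

    rows: pd.DataFrame  # columns: class, quantity, mean, sd, cv_percent

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.rows.to_dict(orient="records"), fh, indent=2)


def variability_report(reports: Sequence[VolumeReport]) -> VariabilityReport:
    """CV table across >= 2 repeated volume measurements (e.g. operators)."""
    if len(reports) < 2:
        raise ValueError("variability needs at least 2 repeated measurements")
    rows = []
    for code in LABEL_CODES:
        for quantity, getter in (
            ("volume_ml", lambda r: r.volumes_ml[code]),
            ("fraction_percent", lambda r: r.fractions_percent.get(code)),
        ):
            vals = [getter(r) for r in reports]
            if any(v is None for v in vals):
                continue
            arr = np.asarray(vals, dtype=np.float64)
            mean = arr.mean()
            sd = arr.std(ddof=1)
            rows.append({
                "class": CLASS_NAMES[code], "quantity": quantity,
                "mean": mean, "sd": sd,
                "cv_percent": 100.0 * sd / mean if mean != 0 else float("nan"),
            })
    return VariabilityReport(rows=pd.DataFrame(rows))
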