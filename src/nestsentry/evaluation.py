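"""Frame-level scoring of detections against ground-truth labels.

Each evaluated frame yields exactly one of TP / FP / FN / TN:

* TP — the frame's detection lies inside a nest label bbox;
* FP — a detection with no label containing it;
* FN — nest label(s) present but no matching detection;
* TN — neither labels nor detection.

Labels can be restricted to a maximum evaluation distance: a nest farther
than ``max_eval_distance_m`` (from its label field, or from the image row
of the bbox bottom under the flat-ground model) is dropped before
scoring, which moves undetectably small far-away nests out of the FN
pool.  From the aggregated confusion matrix the true positive rate
TPR = TP / (TP + FN) and precision PPV = TP / (TP + FP) derive.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd

from .fusion import Detection
from .geometry import CameraGeometry, pixel_row_to_distance

__all__ = [
    "ObjectClass",
    "GroundTruthLabel",
    "ConfusionMatrix",
    "Outcome",
    "UndefinedMetricError",
    "score_frame",
    "aggregate",
    "tpr",
    "ppv",
    "printed_rate",
    "evaluate_sequence",
    "metrics_vs_distance",
    "detection_distance_stats",
    "read_labels",
    "write_labels",
]


class ObjectClass(str, Enum):
    NEST = "nest"
    COOLING_BOX = "cooling_box"
    OTHER = "other"


class Outcome(str, Enum):
    TP = "TP"
    FP = "FP"
    FN = "FN"
    TN = "TN"


class UndefinedMetricError(ZeroDivisionError):
    """Metric denominator is zero; the rate is undefined, not zero."""


@dataclass
class GroundTruthLabel:
    frame_index: int
    object_class: ObjectClass
    bbox: tuple[float, float, float, float]  # x0, y0, x1, y1
    ground_distance_m: float | None = None
    object_id: int | None = None  # stable identity across frames (per nest)

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.bbox
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"degenerate bbox {self.bbox}")
        self.object_class = ObjectClass(self.object_class)

    def contains(self, x: float, y: float) -> bool:
        x0, y0, x1, y1 = self.bbox
        return x0 <= x <= x1 and y0 <= y <= y1


@dataclass
class ConfusionMatrix:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _label_distance(label: GroundTruthLabel, geom: CameraGeometry) -> float:
    if label.ground_distance_m is not None:
        return label.ground_distance_m
    bottom_row = min(label.bbox[3], geom.image_height - 1)
    return pixel_row_to_distance(bottom_row, geom)


def score_frame(detection: Detection | None, labels: list[GroundTruthLabel],
                max_eval_distance_m: float | None = None,
                geom: CameraGeometry | None = None) -> Outcome:
    """Four-way outcome of one frame.

    ``labels`` are this frame's labels; non-nest classes are ignored
    (cooling-box labels are handled upstream by suppression).  With a
    distance limit, labels beyond it are dropped before the outcome rule
    applies.
    """
    geom = geom or CameraGeometry()
    nests = []
    for lab in labels:
        if lab.object_class == ObjectClass.NEST:
            nests.append(lab)
        elif lab.object_class not in (ObjectClass.COOLING_BOX, ObjectClass.OTHER):
            raise ValueError(f"unknown label class {lab.object_class!r}")
    if max_eval_distance_m is not None:
        nests = [l for l in nests if _label_distance(l, geom) <= max_eval_distance_m]
    if detection is not None:
        hit = any(l.contains(detection.x, detection.y) for l in nests)
        return Outcome.TP if hit else Outcome.FP
    return Outcome.FN if nests else Outcome.TN


def aggregate(outcomes) -> ConfusionMatrix:
    """Count outcomes into a confusion matrix (order-invariant)."""
    cm = ConfusionMatrix()
    for o in outcomes:
        o = Outcome(o)
        if o == Outcome.TP:
            cm.tp += 1
        elif o == Outcome.FP:
            cm.fp += 1
        elif o == Outcome.FN:
            cm.fn += 1
        else:
            cm.tn += 1
    return cm


def tpr(cm: ConfusionMatrix) -> float:
    """True positive rate TP / (TP + FN)."""
    if cm.tp + cm.fn == 0:
        raise UndefinedMetricError("TPR undefined: no positive frames")
    return cm.tp / (cm.tp + cm.fn)


def ppv(cm: ConfusionMatrix) -> float:
    """Precision (positive predictive value) TP / (TP + FP)."""
    if cm.tp + cm.fp == 0:
        raise UndefinedMetricError("PPV undefined: no predicted positives")
    return cm.tp / (cm.tp + cm.fp)


def printed_rate(value: float, decimals: int = 2) -> float:
    """Truncate a rate to the given number of decimals (0.385 -> 0.38)."""
    scale = 10 ** decimals
    return np.floor(value * scale + 1e-12) / scale


def _group_by_frame(labels: list[GroundTruthLabel]) -> dict[int, list[GroundTruthLabel]]:
    out: dict[int, list[GroundTruthLabel]] = {}
    for lab in labels:
        out.setdefault(lab.frame_index, []).append(lab)
    return out


def evaluate_sequence(detections: dict[int, Detection | None],
                      labels: list[GroundTruthLabel],
                      geom: CameraGeometry | None = None,
                      max_eval_distance_m: float | None = None) -> ConfusionMatrix:
    """Score every frame of a sequence and aggregate.

    ``detections`` maps frame index -> detection (or None); every frame
    index present in the mapping is evaluated.
    """
    geom = geom or CameraGeometry()
    by_frame = _group_by_frame(labels)
    outcomes = [
        score_frame(det, by_frame.get(fi, []), max_eval_distance_m, geom)
        for fi, det in sorted(detections.items())
    ]
    return aggregate(outcomes)


def metrics_vs_distance(detections: dict[int, Detection | None],
                        labels: list[GroundTruthLabel],
                        geom: CameraGeometry | None = None,
                        distance_grid=None) -> pd.DataFrame:
    """TPR and PPV as a function of the maximum evaluation distance.

    Undefined rates (zero denominator) are reported as NaN.
    """
    geom = geom or CameraGeometry()
    if distance_grid is None:
        from .geometry import ground_range
        near, far = ground_range(geom)
        distance_grid = np.linspace(max(near, 1.0), far, 15)
    rows = []
    for d in np.asarray(distance_grid, dtype=float):
        cm = evaluate_sequence(detections, labels, geom, float(d))
        def _safe(fn):
            try:
                return fn(cm)
            except UndefinedMetricError:
                return np.nan
        rows.append({"distance_m": float(d), "tp": cm.tp, "fp": cm.fp,
                     "fn": cm.fn, "tn": cm.tn,
                     "tpr": _safe(tpr), "ppv": _safe(ppv)})
    return pd.DataFrame(rows)


def detection_distance_stats(confirmed_log: list[tuple[int, int, float, float]],
                             labels: list[GroundTruthLabel],
                             geom: CameraGeometry | None = None) -> dict:
    """First-confirmation ground distance per ground-truth nest.

    For each nest identity (label ``object_id``), finds the first frame in
    the confirmed detection stream whose position falls inside that
    nest's bbox and reports the nest's ground distance in that frame.
    Returns detected / undetected nest ids, the per-nest distances, and
    their mean (NaN when no nest was detected).
    """
    geom = geom or CameraGeometry()
    nests: dict[int, dict[int, GroundTruthLabel]] = {}
    for lab in labels:
        if lab.object_class != ObjectClass.NEST or lab.object_id is None:
            continue
        nests.setdefault(lab.object_id, {})[lab.frame_index] = lab
    distances: dict[int, float] = {}
    for frame, _tid, x, y in sorted(confirmed_log):
        for nid, per_frame in nests.items():
            if nid in distances:
                continue
            lab = per_frame.get(frame)
            if lab is not None and lab.contains(x, y):
                distances[nid] = _label_distance(lab, geom)
    detected = sorted(distances)
    return {
        "per_nest_distance_m": distances,
        "detected_nests": detected,
        "undetected_nests": sorted(set(nests) - set(distances)),
        "n_nests": len(nests),
        "n_detected": len(detected),
        "mean_detection_distance_m":
            float(np.mean([distances[n] for n in detected])) if detected else float("nan"),
    }


# ---------------------------------------------------------------------------
# label file I/O: CSV with header frame,class,x0,y0,x1,y1,distance_m[,object_id]
# ---------------------------------------------------------------------------

def read_labels(path) -> list[GroundTruthLabel]:
    df = pd.read_csv(path)
    labels = []
    for _, row in df.iterrows():
        dist = row.get("distance_m")
        oid = row.get("object_id")
        labels.append(GroundTruthLabel(
            frame_index=int(row["frame"]),
            object_class=ObjectClass(row["class"]),
            bbox=(float(row["x0"]), float(row["y0"]),
                  float(row["x1"]), float(row["y1"])),
            ground_distance_m=None if pd.isna(dist) else float(dist),
            object_id=None if oid is None or pd.isna(oid) else int(oid),
        ))
    return labels


def write_labels(labels: list[GroundTruthLabel], path) -> None:
    rows = [{
        "frame": l.frame_index, "class": l.object_class.value,
        "x0": l.bbox[0], "y0": l.bbox[1], "x1": l.bbox[2], "y1": l.bbox[3],
        "distance_m": l.ground_distance_m, "object_id": l.object_id,
    } for l in labels]
    pd.DataFrame(rows, columns=["frame", "class", "x0", "y0", "x1", "y1",
                                "distance_m", "object_id"]).to_csv(path, index=False)
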