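"""Sequence I/O, configuration, and the per-frame detection pipeline.

Per frame: saliency map -> HSI conversion -> foreground classification
against the running background model -> saliency-gated model update ->
fusion (most-salient region AND foreground, blob filtering) -> at most
one detection -> temporal tracking.  The background model is seeded from
the near-field trapezoid of the first frame before any classification.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from skimage.transform import resize

from .background import BackgroundConfig, BackgroundModel
from .evaluation import (ConfusionMatrix, GroundTruthLabel, ObjectClass,
                         UndefinedMetricError, evaluate_sequence,
                         metrics_vs_distance, ppv, tpr)
from .frames import ImageFrame
from .fusion import Detection, FusionConfig, detect_frame
from .geometry import CameraGeometry
from .saliency import SaliencyConfig, compute_saliency
from .tracking import Tracker, TrackerConfig

logger = logging.getLogger("nestsentry")

__all__ = ["PipelineConfig", "PipelineResult", "read_sequence", "run_pipeline"]

IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg", ".tif", ".tiff")


def _build(cls, data: dict, path: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config key(s) in {path}: {sorted(unknown)}")
    return cls(**data)


@dataclass(frozen=True)
class PipelineConfig:
    """Nested configuration for every pipeline stage."""

    saliency: SaliencyConfig = field(default_factory=SaliencyConfig)
    background: BackgroundConfig = field(default_factory=BackgroundConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    geometry: CameraGeometry = field(default_factory=CameraGeometry)
    max_eval_distance_m: float | None = None
    rescale_width: int = 640
    rescale_height: int = 480

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data or {})
        sections = {
            "saliency": SaliencyConfig,
            "background": BackgroundConfig,
            "fusion": FusionConfig,
            "tracker": TrackerConfig,
            "geometry": CameraGeometry,
        }
        kwargs = {}
        for key, klass in sections.items():
            sub = data.pop(key, {})
            if sub:
                sub = {k: tuple(v) if isinstance(v, list) else v
                       for k, v in sub.items()}
            kwargs[key] = _build(klass, sub, key)
        top = {f.name for f in dataclasses.fields(cls)} - set(sections)
        unknown = set(data) - top
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        kwargs.update(data)
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def read_sequence(path, rescale: tuple[int, int] | None = (640, 480)):
    """Iterate the image files of a directory as normalized frames.

    Files are taken in lexicographic order; frames are rescaled to
    ``rescale`` (width, height), values normalized to [0, 1], and indexed
    0, 1, 2, ...  Unreadable files are logged and skipped; an empty
    directory is a fatal error.
    """
    import imageio.v3 as iio

    p = Path(path)
    files = sorted(f for f in p.iterdir()
                   if f.suffix.lower() in IMAGE_SUFFIXES) if p.is_dir() else []
    if not files:
        raise FileNotFoundError(f"no image frames found in {path}")
    idx = 0
    for f in files:
        try:
            arr = iio.imread(f)
        except Exception as exc:  # unreadable frame: skip, keep going
            logger.warning("skipping unreadable frame %s: %s", f.name, exc)
            continue
        arr = np.asarray(arr, dtype=float)
        if arr.ndim == 2:
            arr = np.stack([arr] * 3, axis=-1)
        if arr.shape[2] > 3:
            arr = arr[..., :3]
        if arr.max() > 1.0:
            arr = arr / 255.0
        if rescale is not None:
            tw, th = rescale
            if arr.shape[:2] != (th, tw):
                arr = resize(arr, (th, tw), order=1, mode="edge",
                             anti_aliasing=True, preserve_range=True)
        yield ImageFrame(np.clip(arr, 0.0, 1.0), idx)
        idx += 1


@dataclass
class PipelineResult:
    detections: dict[int, Detection | None]
    tracker: Tracker
    frame_log: pd.DataFrame | None = None
    confusion: ConfusionMatrix | None = None
    metrics: dict | None = None
    distance_curve: pd.DataFrame | None = None

    @property
    def detection_table(self) -> pd.DataFrame:
        rows = [{"frame": fi, "x": d.x, "y": d.y, "area": d.area}
                for fi, d in sorted(self.detections.items()) if d is not None]
        return pd.DataFrame(rows, columns=["frame", "x", "y", "area"])

    @property
    def confirmed_table(self) -> pd.DataFrame:
        rows = [{"frame": f, "track_id": t, "x": x, "y": y}
                for f, t, x, y in self.tracker.confirmed_log]
        return pd.DataFrame(rows, columns=["frame", "track_id", "x", "y"])


def _suppression_masks(labels: list[GroundTruthLabel] | None,
                       shape: tuple[int, int]) -> dict[int, np.ndarray]:
    """Per-frame masks of labeled exclusion boxes (cooling box etc.)."""
    masks: dict[int, np.ndarray] = {}
    if not labels:
        return masks
    for lab in labels:
        if lab.object_class != ObjectClass.COOLING_BOX:
            continue
        m = masks.setdefault(lab.frame_index, np.zeros(shape, dtype=bool))
        x0, y0, x1, y1 = (int(round(v)) for v in lab.bbox)
        m[max(y0, 0):y1 + 1, max(x0, 0):x1 + 1] = True
    return masks


def run_pipeline(frames, cfg: PipelineConfig | None = None,
                 labels: list[GroundTruthLabel] | None = None,
                 debug_dir=None) -> PipelineResult:
    """Run the detector over an iterable of frames.

    ``labels`` are optional ground truth: cooling-box labels become
    suppression masks during detection, nest labels drive the evaluation
    attached to the result.  ``debug_dir`` dumps per-frame saliency /
    foreground / fused masks as PNGs.
    """
    cfg = cfg or PipelineConfig()
    model = BackgroundModel(cfg.background)
    tracker = Tracker(cfg.tracker)
    detections: dict[int, Detection | None] = {}
    suppression: dict[int, np.ndarray] = {}
    log_rows = []

    for frame in frames:
        fi = frame.frame_index
        try:
            sal = compute_saliency(frame, cfg.saliency)
            hsi = model.prepare(frame)
            if model.histogram is None:
                # first frame: seed the model from the trapezoid before
                # any classification
                model.initialize(hsi)
                if labels:
                    suppression = _suppression_masks(labels, hsi.shape)
            else:
                # incremental update with this frame's non-salient pixels,
                # then classify against the updated model (the dark frame
                # of an intensity dip is judged by the model that has
                # already absorbed it)
                model.update(hsi, sal)
            fg = model.classify(hsi)
            det = detect_frame(sal, fg, cfg.fusion, fi,
                               suppression.get(fi))
        except Exception as exc:
            raise RuntimeError(f"pipeline failed at frame {fi}: {exc}") from exc
        detections[fi] = det
        tracker.observe(det, fi)
        log_rows.append({"frame": fi, "fg_fraction": float(np.mean(fg)),
                         "detected": det is not None,
                         "live_tracks": len(tracker.tracks)})
        logger.info(
            "frame %d: fg=%.4f det=%s tracks=%d",
            fi, float(np.mean(fg)),
            f"({det.x:.1f},{det.y:.1f},a={det.area})" if det else "none",
            len(tracker.tracks),
        )
        if debug_dir is not None:
            _dump_debug(debug_dir, fi, sal.values, fg)

    result = PipelineResult(detections, tracker, pd.DataFrame(log_rows))
    if labels:
        nests = [l for l in labels if l.object_class == ObjectClass.NEST]
        cm = evaluate_sequence(detections, nests, cfg.geometry,
                               cfg.max_eval_distance_m)
        result.confusion = cm
        metrics = {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn}
        for name, fn in (("tpr", tpr), ("ppv", ppv)):
            try:
                metrics[name] = fn(cm)
            except UndefinedMetricError:
                metrics[name] = None
        result.metrics = metrics
        result.distance_curve = metrics_vs_distance(detections, nests,
                                                    cfg.geometry)
    return result


def _dump_debug(debug_dir, frame_index: int, sal: np.ndarray,
                fg: np.ndarray) -> None:
    import imageio.v3 as iio

    out = Path(debug_dir)
    out.mkdir(parents=True, exist_ok=True)
    iio.imwrite(out / f"saliency_{frame_index:05d}.png",
                (sal * 255).round().astype(np.uint8))
    iio.imwrite(out / f"foreground_{frame_index:05d}.png",
                (fg.astype(np.uint8) * 255))
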