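"""Region-of-interest stage: face localization, eye-pair band derivation and
canonical eye-patch extraction.

Face detection is a pluggable contract: a backend exposes
``detect(gray_image) -> list[(BBox, confidence)]``.  Two backends ship with
the package — an annotation-file backend (ground-truth boxes keyed by frame
id) and a bright-region heuristic that locates the dominant bright oval, good
enough for the synthetic frames the generator produces.  Cascade / landmark
model training is out of scope; any externally trained detector can be
plugged in through the same contract.

Boxes are 0-based, half-open: ``[x, x+w) x [y, y+h)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Protocol

import numpy as np
from scipy import ndimage

from .errors import AnnotationParseError, BackendError, ExtractionError, ParameterError
from .imageprep import resample

logger = logging.getLogger(__name__)

#: canonical eye-patch size (width, height); both multiples of the 8 px cell
CANONICAL_SIZE = (64, 32)

# Anthropometric eye-band fractions of the face box: the eye pair sits in the
# horizontal middle 70% of the face, between 25% and 55% of its height.
EYE_BAND = (0.15, 0.85, 0.25, 0.55)


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box, 0-based, half-open on both axes."""

    x: int
    y: int
    w: int
    h: int

    def __post_init__(self):
        if self.w <= 0 or self.h <= 0:
            raise ParameterError(f"degenerate box {self}")

    @property
    def area(self) -> int:
        return self.w * self.h

    def clip(self, width: int, height: int) -> "BBox | None":
        """Intersect with image bounds; None if empty."""
        x0, y0 = max(self.x, 0), max(self.y, 0)
        x1, y1 = min(self.x + self.w, width), min(self.y + self.h, height)
        if x1 <= x0 or y1 <= y0:
            return None
        return BBox(x0, y0, x1 - x0, y1 - y0)

    def iou(self, other: "BBox") -> float:
        x0 = max(self.x, other.x)
        y0 = max(self.y, other.y)
        x1 = min(self.x + self.w, other.x + other.w)
        y1 = min(self.y + self.h, other.y + other.h)
        inter = max(0, x1 - x0) * max(0, y1 - y0)
        union = self.area + other.area - inter
        return inter / union if union else 0.0


@dataclass(frozen=True)
class EyePatch:
    """Canonical-size grayscale eye-pair patch with its source box."""

    pixels: np.ndarray  # canonical_h x canonical_w floats in [0, 1]
    source_box: BBox


class FaceDetectorBackend(Protocol):
    def detect(self, gray: np.ndarray) -> list[tuple[BBox, float]]: ...


class AnnotationBackend:
    """Detection backend that replays stored ground-truth boxes.

    ``frame_id`` selects which annotation record ``detect`` returns; set it
    (or use :meth:`at`) before each call when iterating over frames.
    """

    def __init__(self, annotations: Mapping[int, BBox], frame_id: int = 0):
        self.annotations = dict(annotations)
        self.frame_id = frame_id

    def at(self, frame_id: int) -> "AnnotationBackend":
        return AnnotationBackend(self.annotations, frame_id)

    def detect(self, gray: np.ndarray) -> list[tuple[BBox, float]]:
        box = self.annotations.get(self.frame_id)
        return [] if box is None else [(box, 1.0)]


class BrightRegionBackend:
    """Heuristic face finder: largest bright connected component.

    Thresholds at the midpoint between the image's minimum and maximum
    intensity, labels connected bright regions and returns the bounding box
    of the largest one.  Constant (featureless) images yield no detection.
    """

    def __init__(self, min_area: int = 100):
        self.min_area = min_area

    def detect(self, gray: np.ndarray) -> list[tuple[BBox, float]]:
        gray = np.asarray(gray, dtype=np.float64)
        lo, hi = float(gray.min()), float(gray.max())
        if hi - lo < 1e-6:
            return []
        mask = gray > (lo + hi) / 2.0
        labels, n = ndimage.label(mask)
        if n == 0:
            return []
        out = []
        for sl in ndimage.find_objects(labels):
            if sl is None:
                continue
            ys, xs = sl
            box = BBox(xs.start, ys.start, xs.stop - xs.start, ys.stop - ys.start)
            area = int(mask[sl].sum())
            if area < self.min_area:
                continue
            out.append((box, area / box.area))
        return out


def detect_face(gray: np.ndarray, detector: FaceDetectorBackend) -> BBox | None:
    """Best face box from the backend, clipped to image bounds, or None.

    Among detections the highest confidence wins; confidence ties go to the
    largest area (the driver is the face closest to the camera).
    """
    try:
        detections = detector.detect(gray)
    except Exception as exc:  # noqa: BLE001 - backend contract boundary
        raise BackendError(f"face detector backend failed: {exc}") from exc
    if not detections:
        return None
    box, _ = max(detections, key=lambda d: (d[1], d[0].area))
    return box.clip(gray.shape[1], gray.shape[0])


def eye_pair_from_face(face: BBox) -> BBox:
    """Eye-pair band at fixed anthropometric fractions of the face box."""
    fx0, fx1, fy0, fy1 = EYE_BAND
    x0 = face.x + int(round(fx0 * face.w))
    x1 = face.x + int(round(fx1 * face.w))
    y0 = face.y + int(round(fy0 * face.h))
    y1 = face.y + int(round(fy1 * face.h))
    return BBox(x0, y0, x1 - x0, y1 - y0)


def extract_patch(gray: np.ndarray, box: BBox, canonical: tuple[int, int] = CANONICAL_SIZE) -> EyePatch:
    """Crop ``box`` (zero-padded beyond image bounds) and resize to the
    canonical patch size: area averaging when shrinking, bilinear when
    growing.  An identity-size in-bounds box is returned without resampling.
    """
    gray = np.asarray(gray, dtype=np.float64)
    h, w = gray.shape
    inside = box.clip(w, h)
    if inside is None:
        raise ExtractionError(f"box {box} does not intersect a {w}x{h} image")
    canvas = np.zeros((box.h, box.w))
    canvas[inside.y - box.y : inside.y - box.y + inside.h, inside.x - box.x : inside.x - box.x + inside.w] = gray[
        inside.y : inside.y + inside.h, inside.x : inside.x + inside.w
    ]
    cw, ch = canonical
    patch = canvas if (box.w, box.h) == (cw, ch) else resample(canvas, (ch, cw))
    return EyePatch(pixels=np.clip(patch, 0.0, 1.0), source_box=box)


def read_roi_annotations(path: str | Path) -> dict[int, BBox]:
    """Parse a ``frame_id,x,y,w,h`` CSV of ROI boxes.

    ``#`` starts a comment; blank lines are skipped; on duplicate frame ids
    the last record wins (with a warning).
    """
    mapping: dict[int, BBox] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = [p.strip() for p in line.split(",")]
            if len(parts) != 5:
                raise AnnotationParseError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
            try:
                frame, x, y, w, h = (int(p) for p in parts)
                box = BBox(x, y, w, h)
            except (ValueError, ParameterError) as exc:
                raise AnnotationParseError(f"{path}:{lineno}: {exc}") from exc
            if frame in mapping:
                logger.warning("%s:%d: duplicate frame id %d, last record wins", path, lineno, frame)
            mapping[frame] = box
    return mapping


def write_roi_annotations(path: str | Path, annotations: Mapping[int, BBox] | Iterable[tuple[int, BBox]]) -> None:
    items = annotations.items() if isinstance(annotations, Mapping) else annotations
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# frame_id,x,y,w,h\n")
        for frame, box in items:
            fh.write(f"{frame},{box.x},{box.y},{box.w},{box.h}\n")
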