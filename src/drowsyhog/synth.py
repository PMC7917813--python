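"""Synthetic eye-patch and frame generator.

The generator emulates what the descriptor pipeline actually measures —
gradient texture differences between open eyes (bright sclera, dark
iris/pupil discs, strong local edges) and closed eyes (smooth eyelid skin
with a faint crease) — under five illumination/occlusion scenarios shaped
after common driver-monitoring recording conditions: bare face, glasses
(semi-transparent dark frame band over the upper eye margin), sunglasses
(strong occlusion of the whole eye band), and the two night variants
(global gain 0.35, emulating active-IR exposure).  It makes no attempt at
photorealism: the target is the statistical structure the classifier
assumes, not appearance.

Everything is a pure function of its parameters; the per-sample RNG seed is
derived from the master seed as ``seed XOR sample_index``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .errors import ParameterError
from .roi import BBox, EyePatch, eye_pair_from_face
from .imageprep import resample

SCENARIOS = ("bareface", "glasses", "sunglasses", "night_bareface", "night_glasses")
EYE_STATES = ("open", "closed")

PATCH_W, PATCH_H = 64, 32
NIGHT_GAIN = 0.35
GLASSES_ALPHA = 0.35
SUNGLASSES_ALPHA = 0.65
DEFAULT_NOISE_SD = 0.02

# aperture sampling ranges at full separability
CLOSED_RANGE = (0.0, 0.15)
OPEN_RANGE = (0.5, 1.0)


@dataclass(frozen=True)
class SynthParams:
    eye_state: str = "open"
    scenario: str = "bareface"
    aperture: float | None = None  # default: 0.85 open, 0.05 closed
    noise_sd: float = DEFAULT_NOISE_SD
    illum_gain: float | None = None  # default set by scenario
    illum_offset: float = 0.0
    occlusion_alpha: float | None = None  # default set by scenario
    seed: int = 0

    def resolved(self) -> "SynthParams":
        if self.eye_state not in EYE_STATES:
            raise ParameterError(f"unknown eye_state {self.eye_state!r}")
        if self.scenario not in SCENARIOS:
            raise ParameterError(f"unknown scenario {self.scenario!r}")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        aperture = self.aperture
        if aperture is None:
            aperture = 0.85 if self.eye_state == "open" else 0.05
        if not (0.0 <= aperture <= 1.0):
            raise ParameterError(f"aperture must be in [0, 1], got {aperture}")
        gain = self.illum_gain
        if gain is None:
            gain = NIGHT_GAIN if self.scenario.startswith("night") else 1.0
        alpha = self.occlusion_alpha
        if alpha is None:
            if self.scenario == "sunglasses":
                alpha = SUNGLASSES_ALPHA
            elif self.scenario in ("glasses", "night_glasses"):
                alpha = GLASSES_ALPHA
            else:
                alpha = 0.0
        return replace(self, aperture=aperture, illum_gain=gain, occlusion_alpha=alpha)


@dataclass(frozen=True)
class SynthSample:
    patch: EyePatch
    label: str
    scenario: str
    params: SynthParams
    frame: np.ndarray | None = None
    face_box: BBox | None = None
    eye_box: BBox | None = None


def _render_eye(img: np.ndarray, cx: float, cy: float, aperture: float) -> None:
    """Draw one eye: almond sclera, iris/pupil discs, eyelid chord at the
    opening fraction.  A closed eye is lid skin plus a soft crease line."""
    rx, ry = 11.0, 7.0
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    ellipse = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
    # a pixel row is visible only when it lies fully inside the opening, so
    # aperture 0 exposes nothing
    open_band = np.abs(yy - cy) + 0.5 <= aperture * ry
    visible = ellipse & open_band
    lid = ellipse & ~open_band

    img[visible] = 0.92  # sclera
    iris = visible & ((xx - cx) ** 2 + (yy - cy) ** 2 <= 4.5**2)
    pupil = visible & ((xx - cx) ** 2 + (yy - cy) ** 2 <= 2.0**2)
    img[iris] = 0.18
    img[pupil] = 0.05
    img[lid] = 0.62  # eyelid skin
    # lid crease: a subdued line along the eye axis, the only closed-eye texture
    crease = lid & (np.abs(yy - (cy - aperture * ry)) <= 0.6)
    img[crease] = 0.48


def generate_patch(params: SynthParams) -> SynthSample:
    """Render one 64x32 eye-pair patch, fully determined by ``params``."""
    p = params.resolved()
    rng = np.random.default_rng(p.seed)
    yy, xx = np.mgrid[0:PATCH_H, 0:PATCH_W]
    img = 0.55 + 0.18 * xx / PATCH_W + 0.04 * yy / PATCH_H  # skin shading
    for cx in (16.0, 48.0):
        _render_eye(img, cx, 16.0, p.aperture)

    if p.scenario in ("glasses", "night_glasses"):
        band = slice(7, 12)  # frame bar across the upper eye margin
        img[band] = (1.0 - p.occlusion_alpha) * img[band] + p.occlusion_alpha * 0.1
    elif p.scenario == "sunglasses":
        band = slice(6, 27)  # whole eye band behind a dark lens
        img[band] = (1.0 - p.occlusion_alpha) * img[band] + p.occlusion_alpha * 0.1

    img = p.illum_gain * img + p.illum_offset
    if p.noise_sd > 0:
        img = img + rng.normal(0.0, p.noise_sd, img.shape)
    img = np.clip(img, 0.0, 1.0)
    patch = EyePatch(pixels=img, source_box=BBox(0, 0, PATCH_W, PATCH_H))
    return SynthSample(patch=patch, label=p.eye_state, scenario=p.scenario, params=p)


def _aperture_ranges(separability: float) -> tuple[tuple[float, float], tuple[float, float]]:
    """Class aperture ranges; the inter-class gap shrinks as separability -> 0."""
    widen = 0.25 * (1.0 - separability)
    closed = (CLOSED_RANGE[0], CLOSED_RANGE[1] + widen)
    open_ = (OPEN_RANGE[0] - widen, OPEN_RANGE[1])
    return closed, open_


def generate_dataset(
    n_per_class: int,
    scenario_mix: Mapping[str, float] | None = None,
    separability: float = 1.0,
    seed: int = 0,
    noise_sd: float = DEFAULT_NOISE_SD,
) -> list[SynthSample]:
    """Balanced open/closed sample list under a scenario mixture.

    Apertures are drawn uniformly from class-specific ranges whose gap
    narrows as ``separability`` decreases; scenarios are drawn from
    ``scenario_mix`` (uniform over the five scenarios by default).  Sample
    ``i`` renders with pixel seed ``seed XOR i``, so the dataset is
    reproducible element-wise.
    """
    if n_per_class < 1:
        raise ParameterError("n_per_class must be >= 1")
    if not (0.0 < separability <= 1.0):
        raise ParameterError("separability must be in (0, 1]")
    if scenario_mix is None:
        scenario_mix = {s: 1.0 / len(SCENARIOS) for s in SCENARIOS}
    names = list(scenario_mix)
    probs = np.array([scenario_mix[s] for s in names], dtype=np.float64)
    if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
        raise ParameterError(f"scenario proportions must be >= 0 and sum to 1, got {dict(scenario_mix)}")
    unknown = set(names) - set(SCENARIOS)
    if unknown:
        raise ParameterError(f"unknown scenarios {sorted(unknown)}")

    closed_rng, open_rng = _aperture_ranges(separability)
    rng = np.random.default_rng(seed)
    samples = []
    for i in range(2 * n_per_class):
        state = "open" if i < n_per_class else "closed"
        lo, hi = open_rng if state == "open" else closed_rng
        aperture = float(rng.uniform(lo, hi))
        scenario = names[int(rng.choice(len(names), p=probs))]
        params = SynthParams(eye_state=state, scenario=scenario, aperture=aperture,
                             noise_sd=noise_sd, seed=seed ^ i)
        samples.append(generate_patch(params))
    return samples


def generate_frame(params: SynthParams, frame_size: tuple[int, int] = (320, 240)) -> SynthSample:
    """Render a full frame: bright face oval on a dark background with the
    eye patch composited at the anthropometric eye-band position; ground
    truth face and eye boxes are recorded."""
    p = params.resolved()
    fw_px, fh_px = frame_size
    rng = np.random.default_rng(p.seed)
    face_w = int(rng.integers(90, 130))
    face_h = int(round(1.3 * face_w))
    fx = int(rng.integers(20, fw_px - face_w - 20))
    fy = int(rng.integers(10, fh_px - face_h - 10))
    face_box = BBox(fx, fy, face_w, face_h)

    frame = np.full((fh_px, fw_px), 0.15)
    yy, xx = np.mgrid[0:fh_px, 0:fw_px]
    cx, cy = fx + face_w / 2.0, fy + face_h / 2.0
    oval = ((xx - cx) / (face_w / 2.0)) ** 2 + ((yy - cy) / (face_h / 2.0)) ** 2 <= 1.0
    frame[oval] = 0.7

    eye_box = eye_pair_from_face(face_box)
    patch_sample = generate_patch(replace(p, noise_sd=0.0, seed=p.seed))
    resized = resample(patch_sample.patch.pixels, (eye_box.h, eye_box.w))
    frame[eye_box.y : eye_box.y + eye_box.h, eye_box.x : eye_box.x + eye_box.w] = resized
    if p.noise_sd > 0:
        frame = frame + rng.normal(0.0, p.noise_sd, frame.shape)
    frame = np.clip(frame, 0.0, 1.0)
    return SynthSample(patch=patch_sample.patch, label=p.eye_state, scenario=p.scenario,
                       params=p, frame=frame, face_box=face_box, eye_box=eye_box)
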