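"""Flat key-value pipeline configuration.

Config files are plain text, one ``key = value`` per line, ``#`` comments.
Unknown keys are rejected so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .errors import ParameterError

DEFAULTS: dict[str, object] = {
    "preprocess.gaussian_kernel": 3,
    "preprocess.gaussian_sigma": 0.5,
    "preprocess.clahe_clip": 2.0,
    "preprocess.clahe_tiles": "8,8",
    "preprocess.downscale": 1.0,
    "roi.canonical_w": 64,
    "roi.canonical_h": 32,
    "hog.cell_size": 8,
    "hog.bins": 8,
    "hog.gradient_method": "central",
    "hog.gradient_sigma": 1.0,
    "bosh.pair_scope": "block",
    "nb.m_weight": 2.0,
    "nb.variance_floor": 1e-9,
    "synth.noise_sd": 0.02,
    "synth.separability": 1.0,
    "eval.positive": "closed",
    "predict.smooth_window": 0,  # 0 = instantaneous per-frame decisions
}


@dataclass
class PipelineConfig:
    values: dict[str, object] = field(default_factory=lambda: dict(DEFAULTS))

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        cfg = cls()
        with open(path, "r", encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ParameterError(f"{path}:{lineno}: expected 'key = value'")
                key, _, value = line.partition("=")
                cfg.set(key.strip(), value.strip())
        return cfg

    def set(self, key: str, value: str) -> None:
        if key not in DEFAULTS:
            raise ParameterError(f"unknown config key {key!r}")
        default = DEFAULTS[key]
        try:
            if isinstance(default, bool):
                self.values[key] = value.lower() in ("1", "true", "yes")
            elif isinstance(default, int):
                self.values[key] = int(value)
            elif isinstance(default, float):
                self.values[key] = float(value)
            else:
                self.values[key] = value
        except ValueError as exc:
            raise ParameterError(f"config key {key!r}: {exc}") from exc

    def get(self, key: str):
        if key not in DEFAULTS:
            raise ParameterError(f"unknown config key {key!r}")
        return self.values.get(key, DEFAULTS[key])

    @property
    def clahe_tiles(self) -> tuple[int, int]:
        a, _, b = str(self.get("preprocess.clahe_tiles")).partition(",")
        return int(a), int(b or a)

    @property
    def canonical(self) -> tuple[int, int]:
        return int(self.get("roi.canonical_w")), int(self.get("roi.canonical_h"))

    def dump(self) -> str:
        return "".join(f"{k} = {self.get(k)}\n" for k in sorted(DEFAULTS))
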