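"""End-to-end glue: patch -> preprocessing -> gradients -> cell histograms
-> descriptor, and batch featurization used by training, prediction and
evaluation."""

from __future__ import annotations

import numpy as np

from . import bosh as bosh_mod
from .config import PipelineConfig
from .hog import cell_histograms, compute_gradients
from .imageprep import gaussian_smooth


def patch_cell_grid(pixels: np.ndarray, config: PipelineConfig | None = None, preprocess: bool = True):
    cfg = config or PipelineConfig()
    img = np.asarray(pixels, dtype=np.float64)
    if preprocess:
        img = gaussian_smooth(img, int(cfg.get("preprocess.gaussian_kernel")),
                              float(cfg.get("preprocess.gaussian_sigma")))
    grad = compute_gradients(img, method=str(cfg.get("hog.gradient_method")),
                             sigma=float(cfg.get("hog.gradient_sigma")))
    return cell_histograms(grad, cell_size=int(cfg.get("hog.cell_size")), m=int(cfg.get("hog.bins")))


def patch_descriptor(pixels: np.ndarray, features: str = "bosh",
                     config: PipelineConfig | None = None, preprocess: bool = True) -> np.ndarray:
    """Descriptor vector for one patch: BOSH bits or baseline HOG values."""
    cfg = config or PipelineConfig()
    grid = patch_cell_grid(pixels, cfg, preprocess=preprocess)
    if features == "bosh":
        return bosh_mod.extract_bosh(grid, pair_scope=str(cfg.get("bosh.pair_scope"))).bits
    if features == "hog":
        return bosh_mod.extract_hog_baseline(grid).values
    raise ValueError(f"unknown feature path {features!r}")


def descriptor_layout(features: str, config: PipelineConfig | None = None) -> bosh_mod.DescriptorLayout:
    cfg = config or PipelineConfig()
    w, h = cfg.canonical
    return bosh_mod.DescriptorLayout(
        patch_w=w, patch_h=h, cell_size=int(cfg.get("hog.cell_size")),
        m=int(cfg.get("hog.bins")), scheme=features,
        pair_scope=str(cfg.get("bosh.pair_scope")) if features == "bosh" else "block",
    )


def featurize(patches, features: str = "bosh", config: PipelineConfig | None = None,
              preprocess: bool = True) -> np.ndarray:
    """Stack descriptors for an iterable of patch pixel arrays."""
    return np.vstack([patch_descriptor(p, features, config, preprocess) for p in patches])
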