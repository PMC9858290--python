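"""Synthetic single-cell image generator.

Emulates the structure of a stained peripheral-blood-smear single-cell
dataset: one dominant cell per square RGB crop on a pale background, with 15
classes (8 atypical + 7 typical). Class identity is encoded through the
morphological cues a hematologist uses — cell size, nucleus-to-cell area
ratio, nucleus lobation, stain color, and cytoplasmic granularity — so the
classes are genuinely separable and confusable in the qualitatively expected
ways (e.g. promyelocyte vs myeloblast differ mainly by granules).

The generator is not photorealistic and does not simulate staining physics;
it exists to give every downstream stage (augmentation, autoencoding,
classification, evaluation) a realistic, fully labelled workload.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .dataset import ImageSample, Manifest, write_image
from .taxonomy import ATYPICAL_CLASSES, DEFAULT_TYPICAL_CLASSES
import pandas as pd


class GeneratorConfigError(ValueError):
    """Spec parameters that cannot produce a valid image."""


@dataclass(frozen=True)
class CellClassSpec:
    """Morphology recipe for one WBC class.

    Sizes are fractions of the image width; colors are RGB in [0, 1].
    ``granularity`` is the standard deviation of the cytoplasmic speckle
    noise that renders azurophilic granules.
    """

    label: str
    cell_radius_range: tuple[float, float] = (0.25, 0.33)
    nucleus_to_cell_ratio_range: tuple[float, float] = (0.4, 0.6)
    nucleus_lobes: int = 1
    nucleus_elongation: float = 1.0  # major/minor axis ratio of each lobe
    nucleus_color_mean: tuple[float, float, float] = (0.35, 0.20, 0.50)
    nucleus_color_std: float = 0.02
    cytoplasm_color_mean: tuple[float, float, float] = (0.75, 0.70, 0.85)
    cytoplasm_color_std: float = 0.02
    granularity: float = 0.0

    def __post_init__(self) -> None:
        lo, hi = self.nucleus_to_cell_ratio_range
        if not (0.0 < lo <= hi <= 1.0):
            raise GeneratorConfigError(f"{self.label}: nucleus ratio range must lie in (0, 1]")
        rlo, rhi = self.cell_radius_range
        if not (0.0 < rlo <= rhi):
            raise GeneratorConfigError(f"{self.label}: invalid cell radius range")
        if rhi > 0.42:  # with center jitter the cell must stay inside the frame
            raise GeneratorConfigError(f"{self.label}: cell radius {rhi} cannot fit in frame")
        if self.nucleus_lobes < 1:
            raise GeneratorConfigError(f"{self.label}: nucleus_lobes must be >= 1")
        if self.granularity < 0:
            raise GeneratorConfigError(f"{self.label}: granularity must be >= 0")


@dataclass(frozen=True)
class GeneratorConfig:
    """Full dataset recipe: one spec per class, plus size/count/seed."""

    specs: tuple[CellClassSpec, ...]
    images_per_class: int = 200
    image_size: int = 224
    seed: int = 0
    background_color: tuple[float, float, float] = (0.92, 0.90, 0.94)

    def __post_init__(self) -> None:
        if self.images_per_class < 1:
            raise GeneratorConfigError("images_per_class must be >= 1")
        if self.image_size < 8:
            raise GeneratorConfigError("image_size too small")


def _ellipse_alpha(size, cy, cx, a, b, theta):
    """Anti-aliased coverage mask of an ellipse (1 inside, 0 outside).

    The edge is softened over ~1.2 px using the normalised radial coordinate.
    """
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float32)
    y = yy - cy
    x = xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    xr = x * ct + y * st
    yr = -x * st + y * ct
    q = np.sqrt((xr / a) ** 2 + (yr / b) ** 2)
    edge = 1.2 / min(a, b)
    return np.clip((1.0 - q) / edge + 0.5, 0.0, 1.0).astype(np.float32)


def _nucleus_alpha(size, cy, cx, lobe_r, lobes, elong, theta):
    """Union coverage of ``lobes`` overlapping elliptical lobes."""
    alpha = np.zeros((size, size), dtype=np.float32)
    # lobes laid out along the orientation axis, centre-to-centre 1.1 radii
    offsets = (np.arange(lobes) - (lobes - 1) / 2.0) * 1.1 * lobe_r
    a = lobe_r * np.sqrt(elong)
    b = lobe_r / np.sqrt(elong)
    for off in offsets:
        ly = cy + off * np.sin(theta)
        lx = cx + off * np.cos(theta)
        alpha = np.maximum(alpha, _ellipse_alpha(size, ly, lx, a, b, theta))
    return alpha


def generate_cell_image(
    spec: CellClassSpec,
    rng: np.random.Generator,
    image_size: int = 224,
    background_color: tuple[float, float, float] = (0.92, 0.90, 0.94),
) -> ImageSample:
    """Render one labelled cell image.

    The nucleus is drawn as ``spec.nucleus_lobes`` overlapping ellipses
    clipped to the cell; its rasterised area is iteratively rescaled so the
    realised nucleus-to-cell area ratio lands within the spec's range.
    """
    size = image_size
    bg = np.asarray(background_color, dtype=np.float32)

    # cell geometry
    r_frac = rng.uniform(*spec.cell_radius_range)
    aspect = rng.uniform(0.85, 1.0)
    cell_a = r_frac * size
    cell_b = cell_a * aspect
    jitter = 0.05 * size
    cy = size / 2 + rng.uniform(-jitter, jitter)
    cx = size / 2 + rng.uniform(-jitter, jitter)
    theta = rng.uniform(0, np.pi)
    cell = _ellipse_alpha(size, cy, cx, cell_a, cell_b, theta)
    cell_area = float(cell.sum())

    # nucleus: scale lobe radius until the clipped area matches the target
    target_ratio = rng.uniform(*spec.nucleus_to_cell_ratio_range)
    ncy = cy + rng.uniform(-0.1, 0.1) * cell_b
    ncx = cx + rng.uniform(-0.1, 0.1) * cell_a
    ntheta = rng.uniform(0, np.pi)
    lobe_r = np.sqrt(target_ratio / spec.nucleus_lobes) * np.sqrt(cell_a * cell_b)
    nucleus = np.zeros_like(cell)
    for _ in range(4):
        nucleus = np.minimum(
            _nucleus_alpha(size, ncy, ncx, lobe_r, spec.nucleus_lobes,
                           spec.nucleus_elongation, ntheta),
            cell,
        )
        realised = float(nucleus.sum()) / cell_area
        if abs(realised - target_ratio) < 0.01:
            break
        lobe_r *= np.sqrt(np.clip(target_ratio / max(realised, 1e-6), 0.25, 4.0))

    # colors, jittered per image
    nuc_col = np.clip(np.asarray(spec.nucleus_color_mean)
                      + spec.nucleus_color_std * rng.normal(size=3), 0, 1)
    cyt_col = np.clip(np.asarray(spec.cytoplasm_color_mean)
                      + spec.cytoplasm_color_std * rng.normal(size=3), 0, 1)

    img = np.empty((size, size, 3), dtype=np.float32)
    img[:] = bg
    img = img * (1 - cell[..., None]) + cyt_col[None, None, :] * cell[..., None]
    img = img * (1 - nucleus[..., None]) + nuc_col[None, None, :] * nucleus[..., None]

    if spec.granularity > 0:
        speckle = rng.normal(0.0, spec.granularity, size=(size, size, 3)).astype(np.float32)
        img = img + speckle * cell[..., None]

    img = np.clip(img, 0.0, 1.0)
    return ImageSample(img, label=spec.label)


# ---------------------------------------------------------------------------
# default class morphology

def _spec(label, **kw) -> CellClassSpec:
    return CellClassSpec(label=label, **kw)


def default_class_specs() -> tuple[CellClassSpec, ...]:
    """Morphology recipes for the full 15-class taxonomy.

    Atypical classes encode the qualitative cues that make them separable yet
    confusable along the myelopoiesis lineage: blasts have large smooth
    nuclei, promyelocytes add granules, the bilobed variant adds lobation,
    myelocyte/metamyelocyte shrink the nucleus and elongate it.
    """
    atypical = (
        _spec("erythroblast", cell_radius_range=(0.18, 0.24),
              nucleus_to_cell_ratio_range=(0.35, 0.5),
              nucleus_color_mean=(0.20, 0.10, 0.35), cytoplasm_color_mean=(0.55, 0.60, 0.80)),
        _spec("lymphocyte_atypical", cell_radius_range=(0.28, 0.36),
              nucleus_to_cell_ratio_range=(0.40, 0.55),
              nucleus_color_mean=(0.40, 0.25, 0.55), cytoplasm_color_mean=(0.62, 0.78, 0.85)),
        _spec("metamyelocyte", cell_radius_range=(0.24, 0.30),
              nucleus_to_cell_ratio_range=(0.30, 0.45), nucleus_elongation=2.6,
              nucleus_color_mean=(0.45, 0.30, 0.55), cytoplasm_color_mean=(0.85, 0.72, 0.72),
              granularity=0.02),
        _spec("monoblast", cell_radius_range=(0.30, 0.38),
              nucleus_to_cell_ratio_range=(0.60, 0.75),
              nucleus_color_mean=(0.45, 0.35, 0.65), cytoplasm_color_mean=(0.70, 0.72, 0.88)),
        _spec("myeloblast", cell_radius_range=(0.28, 0.36),
              nucleus_to_cell_ratio_range=(0.75, 0.9),
              nucleus_color_mean=(0.35, 0.25, 0.60), cytoplasm_color_mean=(0.72, 0.70, 0.90)),
        _spec("myelocyte", cell_radius_range=(0.24, 0.30),
              nucleus_to_cell_ratio_range=(0.40, 0.55), nucleus_elongation=1.4,
              nucleus_color_mean=(0.40, 0.25, 0.50), cytoplasm_color_mean=(0.88, 0.75, 0.70),
              granularity=0.04),
        _spec("promyelocyte", cell_radius_range=(0.28, 0.36),
              nucleus_to_cell_ratio_range=(0.55, 0.70),
              nucleus_color_mean=(0.38, 0.26, 0.58), cytoplasm_color_mean=(0.78, 0.68, 0.82),
              granularity=0.08),
        _spec("promyelocyte_bilobed", cell_radius_range=(0.28, 0.36),
              nucleus_to_cell_ratio_range=(0.55, 0.70), nucleus_lobes=2,
              nucleus_color_mean=(0.38, 0.26, 0.58), cytoplasm_color_mean=(0.78, 0.68, 0.82),
              granularity=0.08),
    )
    typical = (
        _spec("basophil", cell_radius_range=(0.22, 0.28),
              nucleus_to_cell_ratio_range=(0.4, 0.55),
              nucleus_color_mean=(0.25, 0.15, 0.40), cytoplasm_color_mean=(0.45, 0.40, 0.65),
              granularity=0.10),
        _spec("eosinophil", cell_radius_range=(0.22, 0.28),
              nucleus_to_cell_ratio_range=(0.3, 0.45), nucleus_lobes=2,
              nucleus_color_mean=(0.40, 0.28, 0.55), cytoplasm_color_mean=(0.92, 0.55, 0.50),
              granularity=0.09),
        _spec("lymphocyte_typical", cell_radius_range=(0.16, 0.22),
              nucleus_to_cell_ratio_range=(0.7, 0.85),
              nucleus_color_mean=(0.30, 0.18, 0.48), cytoplasm_color_mean=(0.60, 0.72, 0.90)),
        _spec("monocyte", cell_radius_range=(0.30, 0.38),
              nucleus_to_cell_ratio_range=(0.45, 0.6), nucleus_elongation=1.9,
              nucleus_color_mean=(0.48, 0.38, 0.62), cytoplasm_color_mean=(0.72, 0.76, 0.82)),
        _spec("neutrophil_band", cell_radius_range=(0.22, 0.28),
              nucleus_to_cell_ratio_range=(0.3, 0.45), nucleus_elongation=3.5,
              nucleus_color_mean=(0.42, 0.30, 0.52), cytoplasm_color_mean=(0.90, 0.80, 0.75),
              granularity=0.03),
        _spec("neutrophil_segmented", cell_radius_range=(0.22, 0.28),
              nucleus_to_cell_ratio_range=(0.3, 0.45), nucleus_lobes=3,
              nucleus_color_mean=(0.42, 0.30, 0.52), cytoplasm_color_mean=(0.90, 0.82, 0.78),
              granularity=0.03),
        _spec("smudge", cell_radius_range=(0.26, 0.34),
              nucleus_to_cell_ratio_range=(0.85, 0.99),
              nucleus_color_mean=(0.55, 0.45, 0.65), nucleus_color_std=0.06,
              cytoplasm_color_mean=(0.70, 0.62, 0.75), granularity=0.06),
    )
    return atypical + typical


def default_config(images_per_class: int = 200, image_size: int = 224,
                   seed: int = 0) -> GeneratorConfig:
    return GeneratorConfig(specs=default_class_specs(),
                           images_per_class=images_per_class,
                           image_size=image_size, seed=seed)


# ---------------------------------------------------------------------------
# dataset-level generation

def _image_rng(seed: int, class_index: int, image_index: int) -> np.random.Generator:
    # one independent, reproducible stream per image
    return np.random.default_rng([seed, class_index, image_index])


def generate_samples(cfg: GeneratorConfig) -> list[ImageSample]:
    """Generate the full dataset in memory (deterministic under cfg.seed)."""
    out: list[ImageSample] = []
    for ci, spec in enumerate(cfg.specs):
        for ii in range(cfg.images_per_class):
            rng = _image_rng(cfg.seed, ci, ii)
            s = generate_cell_image(spec, rng, cfg.image_size, cfg.background_color)
            s.source_id = f"{spec.label}_{ii:05d}"
            out.append(s)
    return out


def generate_dataset(cfg: GeneratorConfig, out_dir) -> Manifest:
    """Render the dataset to ``out_dir`` as PNGs and write ``manifest.csv``."""
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_test"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise IOError(f"output directory not writable: {out_dir}: {exc}") from exc

    rows = []
    for ci, spec in enumerate(cfg.specs):
        cls_dir = out_dir / spec.label
        cls_dir.mkdir(exist_ok=True)
        for ii in range(cfg.images_per_class):
            rng = _image_rng(cfg.seed, ci, ii)
            s = generate_cell_image(spec, rng, cfg.image_size, cfg.background_color)
            rel = f"{spec.label}/{spec.label}_{ii:05d}.png"
            write_image(s, out_dir / rel)
            rows.append({"path": rel, "label": spec.label, "split": "unassigned"})
    m = Manifest(pd.DataFrame(rows), root=out_dir)
    m.save(out_dir / "manifest.csv")
    return m
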