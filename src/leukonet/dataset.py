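"""Image and manifest I/O plus the stratified train/test split.

A *manifest* is a CSV file with header ``path,label,split`` describing a
directory of single-cell images. Images are loaded as square RGB float arrays
in [0, 1]; the canonical working size is 224x224 so that three 2x poolings of
the autoencoder reach the 28x28 latent grid.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from PIL import Image

from .taxonomy import Taxonomy, TaxonomyError, default_taxonomy

#: Default side length of a single-cell crop (three halvings -> 28).
DEFAULT_IMAGE_SIZE = 224

TRAIN, TEST, UNASSIGNED = "train", "test", "unassigned"
_SPLITS = {TRAIN, TEST, UNASSIGNED}


class ManifestError(ValueError):
    """Structurally invalid manifest."""


@dataclass
class ImageSample:
    """A single-cell RGB image with optional class label.

    ``pixels`` is an H×W×3 float array with intensities in [0, 1]; H == W.
    """

    pixels: np.ndarray
    label: str | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float32)
        if px.ndim != 3 or px.shape[2] != 3 or px.shape[0] != px.shape[1]:
            raise ValueError(f"expected square HxWx3 pixels, got shape {px.shape}")
        self.pixels = px

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass
class Manifest:
    """A table of (path, label, split) records rooted at a directory."""

    records: pd.DataFrame
    root: Path = Path(".")

    def __post_init__(self) -> None:
        df = self.records
        for col in ("path", "label"):
            if col not in df.columns:
                raise ManifestError(f"manifest missing required column {col!r}")
        if "split" not in df.columns:
            df = df.assign(split=UNASSIGNED)
        df = df.fillna({"split": UNASSIGNED})
        bad_split = set(df["split"]) - _SPLITS
        if bad_split:
            raise ManifestError(f"unknown split values: {sorted(bad_split)}")
        dup = df["path"].duplicated()
        if dup.any():
            raise ManifestError(f"duplicate paths in manifest: {df['path'][dup].tolist()[:5]}")
        self.records = df.reset_index(drop=True)
        self.root = Path(self.root)

    def __len__(self) -> int:
        return len(self.records)

    def subset(self, split: str) -> "Manifest":
        return Manifest(self.records[self.records["split"] == split].copy(), self.root)

    def paths(self) -> list[Path]:
        return [self.root / p for p in self.records["path"]]

    def class_counts(self) -> pd.Series:
        return self.records["label"].value_counts()

    def save(self, path: str | os.PathLike) -> Path:
        path = Path(path)
        self.records.to_csv(path, index=False)
        return path


def load_manifest(
    path: str | os.PathLike,
    taxonomy: Taxonomy | None = None,
    check_files: bool = True,
) -> Manifest:
    """Read and validate a manifest CSV.

    Labels are validated against the taxonomy (error names the offending row);
    relative paths are resolved against the CSV's directory. With
    ``check_files`` every referenced image must exist.
    """
    path = Path(path)
    taxonomy = taxonomy or default_taxonomy()
    df = pd.read_csv(path, dtype=str)
    m = Manifest(df, root=path.parent)
    for i, lab in enumerate(m.records["label"]):
        if lab not in taxonomy:
            raise TaxonomyError(f"unknown class label {lab!r} in manifest row {i}")
    if check_files:
        missing = [str(p) for p in m.paths() if not p.exists()]
        if missing:
            raise IOError(f"manifest references missing files: {missing[:10]}")
    return m


def stratified_split(manifest: Manifest, test_fraction: float, seed: int) -> Manifest:
    """Assign every record to train or test, stratified by class.

    Per class, ``round(test_fraction * n)`` records go to test, so the
    realised fraction is within one record of the request. Deterministic for a
    fixed seed; returns a new manifest (the input is not modified).
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    if len(manifest) == 0:
        raise ManifestError("cannot split an empty manifest")
    rng = np.random.default_rng(seed)
    df = manifest.records.copy()
    split = pd.Series(TRAIN, index=df.index)
    # iterate classes in sorted order so the rng stream is reproducible
    for label in sorted(df["label"].unique()):
        idx = df.index[df["label"] == label].to_numpy()
        n_test = int(round(test_fraction * len(idx)))
        chosen = rng.choice(idx, size=n_test, replace=False)
        split.loc[chosen] = TEST
    df["split"] = split
    return Manifest(df, manifest.root)


def read_image(
    path: str | os.PathLike,
    label: str | None = None,
    target_size: int | None = None,
) -> ImageSample:
    """Load a PNG/TIFF image as an RGB float sample in [0, 1].

    Grayscale images are replicated to 3 channels; non-square or off-size
    images are resized bilinearly to ``target_size`` (default 224).
    """
    path = Path(path)
    try:
        img = Image.open(path)
        img.load()
    except Exception as exc:  # PIL raises several unrelated types
        raise IOError(f"cannot read image {path}: {exc}") from exc
    img = img.convert("RGB")
    size = target_size or DEFAULT_IMAGE_SIZE
    if img.size != (size, size):
        img = img.resize((size, size), Image.BILINEAR)
    px = np.asarray(img, dtype=np.float32) / 255.0
    return ImageSample(px, label=label, source_id=path.stem)


def write_image(sample: ImageSample, path: str | os.PathLike) -> Path:
    """Write a sample as an 8-bit PNG/TIFF; round-trip error <= 1/255."""
    path = Path(path)
    arr = np.clip(sample.pixels, 0.0, 1.0)
    img = Image.fromarray(np.round(arr * 255.0).astype(np.uint8), mode="RGB")
    img.save(path)
    return path


def load_samples(manifest: Manifest, target_size: int | None = None) -> list[ImageSample]:
    """Load every record of a manifest as :class:`ImageSample`."""
    out = []
    for p, lab in zip(manifest.paths(), manifest.records["label"]):
        out.append(read_image(p, label=lab, target_size=target_size))
    return out


def as_array(samples: Sequence[ImageSample]) -> np.ndarray:
    """Stack samples into an (N, H, W, 3) float32 array."""
    return np.stack([s.pixels for s in samples]).astype(np.float32)
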