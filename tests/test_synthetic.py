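"""Generator contracts: morphology, determinism, dataset layout, separability."""

import numpy as np
import pytest

from leukonet import (CellClassSpec, GeneratorConfig, GeneratorConfigError,
                      default_class_specs, generate_cell_image, generate_dataset,
                      generate_samples, load_manifest)
from leukonet.taxonomy import ATYPICAL_CLASSES


def _nucleus_mask(img, spec):
    """Pixels closer to the nucleus color than to cytoplasm/background."""
    px = img.pixels
    targets = np.array([spec.nucleus_color_mean, spec.cytoplasm_color_mean,
                        (0.92, 0.90, 0.94)])
    d = ((px[..., None, :] - targets) ** 2).sum(axis=-1)
    return d.argmin(axis=-1) == 0


def test_bilobed_nucleus_has_two_lobes():
    spec = CellClassSpec(label="promyelocyte_bilobed", nucleus_lobes=2,
                         nucleus_to_cell_ratio_range=(0.5, 0.5),
                         cell_radius_range=(0.3, 0.3), granularity=0.0,
                         nucleus_color_std=0.0, cytoplasm_color_std=0.0)
    img = generate_cell_image(spec, np.random.default_rng(3), 64)
    from scipy import ndimage
    # erode the mid-threshold mask a little to split the lobes at their waist
    mask = _nucleus_mask(img, spec)
    eroded = ndimage.binary_erosion(mask, iterations=2)
    n_components = ndimage.label(eroded)[1]
    assert n_components >= 1  # connected (overlapping lobes)
    # the lobed mask must be elongated along its own principal axis
    # (rotation-invariant second-moment test, unlike a bounding box)
    ys, xs = np.nonzero(mask)
    cov = np.cov(np.stack([ys, xs]).astype(float))
    lam = np.sort(np.linalg.eigvalsh(cov))
    assert np.sqrt(lam[1] / lam[0]) > 1.3


def test_degenerate_spec_is_piecewise_constant():
    spec = CellClassSpec(label="myeloblast", granularity=0.0,
                         nucleus_color_std=0.0, cytoplasm_color_std=0.0)
    img = generate_cell_image(spec, np.random.default_rng(0), 48)
    # aside from thin anti-aliased edges, pixels take one of 3 colors
    px = img.pixels.reshape(-1, 3)
    colors, counts = np.unique(np.round(px, 3), axis=0, return_counts=True)
    top3 = np.sort(counts)[-3:].sum()
    assert top3 / px.shape[0] > 0.9


def test_generate_deterministic_under_seed():
    spec = default_class_specs()[0]
    a = generate_cell_image(spec, np.random.default_rng(11), 40)
    b = generate_cell_image(spec, np.random.default_rng(11), 40)
    assert np.array_equal(a.pixels, b.pixels)


def test_realized_nucleus_ratio_within_tolerance():
    for spec in default_class_specs()[:8]:
        nospeckle = CellClassSpec(
            label=spec.label, cell_radius_range=spec.cell_radius_range,
            nucleus_to_cell_ratio_range=spec.nucleus_to_cell_ratio_range,
            nucleus_lobes=spec.nucleus_lobes,
            nucleus_elongation=spec.nucleus_elongation,
            nucleus_color_mean=(0.1, 0.1, 0.1), nucleus_color_std=0.0,
            cytoplasm_color_mean=(0.9, 0.9, 0.2), cytoplasm_color_std=0.0,
            granularity=0.0)
        img = generate_cell_image(nospeckle, np.random.default_rng(5), 96)
        px = img.pixels
        nucleus = (np.abs(px - [0.1, 0.1, 0.1]).sum(-1) < 0.3)
        cell = nucleus | (np.abs(px - [0.9, 0.9, 0.2]).sum(-1) < 0.3)
        ratio = nucleus.sum() / cell.sum()
        lo, hi = spec.nucleus_to_cell_ratio_range
        assert lo - 0.05 <= ratio <= hi + 0.05, (spec.label, ratio)


def test_pixels_in_unit_interval(small_dataset):
    for s in small_dataset:
        assert s.pixels.min() >= 0.0 and s.pixels.max() <= 1.0
        assert s.label is not None


def test_invalid_specs_rejected():
    with pytest.raises(GeneratorConfigError):
        CellClassSpec(label="x", cell_radius_range=(0.5, 0.6))  # cannot fit
    with pytest.raises(GeneratorConfigError):
        CellClassSpec(label="x", nucleus_to_cell_ratio_range=(0.0, 0.5))
    with pytest.raises(GeneratorConfigError):
        CellClassSpec(label="x", nucleus_lobes=0)


def test_generate_dataset_layout_and_determinism(tmp_path):
    cfg = GeneratorConfig(specs=default_class_specs(), images_per_class=2,
                          image_size=24, seed=5)
    m = generate_dataset(cfg, tmp_path / "a")
    assert len(m) == 30
    assert (m.class_counts() == 2).all()
    reloaded = load_manifest(tmp_path / "a" / "manifest.csv")
    assert len(reloaded) == 30
    generate_dataset(cfg, tmp_path / "b")
    assert ((tmp_path / "a" / "manifest.csv").read_bytes()
            == (tmp_path / "b" / "manifest.csv").read_bytes())


def test_class_separability(small_dataset):
    """Mean inter-class histogram distance exceeds mean intra-class distance."""
    by_label = {}
    for s in small_dataset:
        by_label.setdefault(s.label, []).append(s)

    def hist(s):
        return np.concatenate([
            np.histogram(s.pixels[..., c], bins=16, range=(0, 1), density=True)[0]
            for c in range(3)])

    hists = {lab: np.array([hist(s) for s in pool]) for lab, pool in by_label.items()}
    labels = sorted(hists)
    intra, inter = [], []
    for i, la in enumerate(labels):
        ha = hists[la]
        d = np.linalg.norm(ha[:, None] - ha[None], axis=-1)
        intra.append(d[np.triu_indices(len(ha), 1)].mean())
        for lb in labels[i + 1:]:
            hb = hists[lb]
            inter.append(np.linalg.norm(ha[:, None] - hb[None], axis=-1).mean())
    assert np.mean(inter) > np.mean(intra)
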