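"""End-to-end orchestration: class balancing, two-stage inference, experiments.

The workflow mirrors the four-phase design: (I) augment rare atypical
classes with GT or GT-DCAE synthesis — one autoencoder per atypical subtype
— until every class reaches its target count; (II) encode every image into
its latent representation; (III) train the Stage-I gate and Stage-II subtype
CNNs; (IV) evaluate with confusion matrices, per-class rates and ROC/AUC.

``run_experiment`` executes that workflow on synthetic data at a configurable
scale; ``run_ablation_grid`` crosses {DCAE latent vs raw-pixel features} x
{GT vs GT-DCAE augmentation} and returns the four Stage-II reports.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .classifiers import (Stage1Classifier, Stage1Spec, Stage2Classifier,
                          Stage2Spec, argmax_class)
from .dataset import ImageSample, Manifest, as_array
from .dcae import DCAE, DCAESpec
from .gt import GTPlan, flip, rotate
from .metrics import EvaluationReport, roc_auc
from .synthetic import GeneratorConfig, default_class_specs, generate_samples
from .taxonomy import ATYPICAL_CLASSES, Taxonomy, default_taxonomy
from .training import TrainingConfig


class BalanceError(ValueError):
    """Balancing plan cannot be executed (e.g. a per-class model is missing)."""


GT = "gt"
GT_DCAE = "gt-dcae"


@dataclass(frozen=True)
class BalancePlan:
    """Per-class synthesis targets and the augmentation method.

    ``target`` is either one count applied to every atypical class (the
    reference protocol used 10,000 per subtype) or a mapping per label.
    Synthesis draws only from the chosen source split (train, to avoid
    leakage into evaluation).
    """

    target: int | Mapping[str, int] = 10_000
    method: str = GT_DCAE
    source_split: str = "train"

    def __post_init__(self) -> None:
        if self.method not in (GT, GT_DCAE):
            raise BalanceError(f"unknown augmentation method {self.method!r}")

    def target_for(self, label: str) -> int:
        if isinstance(self.target, Mapping):
            return int(self.target[label])
        return int(self.target)


def _random_gt(img: ImageSample, rng: np.random.Generator,
               plan: GTPlan) -> ImageSample:
    lo, hi = plan.angle_domain
    if plan.include_flips and rng.random() < 0.2:
        return flip(img, "horizontal" if rng.random() < 0.5 else "vertical")
    return rotate(img, rng.uniform(lo, hi))


def balance_classes(
    samples_by_label: Mapping[str, Sequence[ImageSample]],
    plan: BalancePlan,
    models: Mapping[str, DCAE] | None = None,
    gt_plan: GTPlan | None = None,
    seed: int = 0,
) -> dict[str, list[ImageSample]]:
    """Synthesise images so each class reaches its target count.

    Returns only the *new* synthetic samples per label. With
    ``method='gt-dcae'`` a trained autoencoder per label is required and each
    output is a reconstruction of a GT-transformed source; with
    ``method='gt'`` outputs are the GT transforms themselves. Classes already
    at target are left unchanged (empty list).
    """
    gt_plan = gt_plan or GTPlan()
    out: dict[str, list[ImageSample]] = {}
    for li, (label, pool) in enumerate(sorted(samples_by_label.items())):
        need = plan.target_for(label) - len(pool)
        if need <= 0:
            out[label] = []
            continue
        rng = np.random.default_rng([seed, li])
        if plan.method == GT_DCAE:
            if models is None or label not in models:
                raise BalanceError(f"no trained DCAE for class {label!r}")
            out[label] = models[label].synthesize(
                list(pool), need, gt_plan, seed=int(rng.integers(2**31)))
        else:
            synth = []
            for i in range(need):
                src = pool[int(rng.integers(len(pool)))]
                g = _random_gt(src, rng, gt_plan)
                g.source_id = f"{src.source_id}_gt{i:05d}"
                synth.append(g)
            out[label] = synth
    return out


# ---------------------------------------------------------------------------
# two-stage inference

@dataclass
class ClassificationResult:
    """Outcome of the two-stage dispatch for one cell."""

    source_id: str
    stage1_probability: float
    final_label: str
    pi: np.ndarray | None  # present iff final_label is an atypical subtype


def classify_cells(
    images,
    dcae: DCAE,
    stage1: Stage1Classifier,
    stage2: Stage2Classifier,
    threshold: float = 0.5,
    batch_size: int = 32,
) -> list[ClassificationResult]:
    """Batched two-stage rule: gate on P(atypical), then subtype by argmax.

    Every input receives exactly one final label: ``"typical"`` (no
    probability vector) or one of the eight atypical subtypes.
    """
    if isinstance(images, ImageSample):
        images = [images]
    ids = [getattr(s, "source_id", str(i)) for i, s in enumerate(images)]
    z = dcae.encode(images, batch_size)
    p1 = stage1.predict_proba(z, batch_size)
    results: list[ClassificationResult] = []
    atypical_idx = np.nonzero(p1 >= threshold)[0]
    pis = {}
    if len(atypical_idx):
        probs = stage2.predict_proba(z[atypical_idx], batch_size)
        pis = dict(zip(atypical_idx.tolist(), probs))
    for i, (sid, p) in enumerate(zip(ids, p1)):
        if i in pis:
            pi = pis[i]
            results.append(ClassificationResult(sid, float(p),
                                                argmax_class(pi, stage2.taxonomy), pi))
        else:
            results.append(ClassificationResult(sid, float(p), "typical", None))
    return results


def classify_cell(img: ImageSample, dcae: DCAE, stage1: Stage1Classifier,
                  stage2: Stage2Classifier, threshold: float = 0.5) -> ClassificationResult:
    return classify_cells([img], dcae, stage1, stage2, threshold)[0]


# ---------------------------------------------------------------------------
# experiments

@dataclass(frozen=True)
class ExperimentConfig:
    """Desk-scale experiment settings (defaults: 56x56, 200 images/class)."""

    image_size: int = 56
    images_per_class: int = 200
    test_fraction: float = 0.2
    seed: int = 0

    features: str = "dcae"          # 'dcae' latent | 'raw' pixel thumbnail
    augmentation: str = GT_DCAE     # 'gt-dcae' | 'gt'
    balance_target: int | None = None   # default: 1.5x the per-class train count

    feature_dcae_epochs: int = 4
    feature_dcae_subsample: int = 256
    synth_dcae_epochs: int = 12          # cap; stops early at the target MSE
    synth_dcae_target_mse: float | None = 0.01
    synth_dcae_subsample: int = 64
    synth_dcae_batch_size: int = 8  # small pool needs small batches for enough updates
    stage1_epochs: int = 10
    stage2_epochs: int = 30
    finetune_epochs: int = 10       # extra epochs at 1/5 the classifier lr
    dcae_learning_rate: float = 0.2
    classifier_learning_rate: float = 0.05
    batch_size: int = 32
    stage1_threshold: float = 0.5
    atypical_only: bool = False     # skip typical classes and Stage I


@dataclass
class ExperimentResults:
    """Bundle of trained models, learning curves and evaluation reports."""

    config: ExperimentConfig
    feature_dcae_history: dict | None
    stage1_history: dict | None
    stage2_history: dict
    stage1_auc: float | None
    stage1_report: dict | None
    stage2_report: EvaluationReport
    two_stage_counts: dict | None
    n_train: int
    n_test: int

    def summary(self) -> str:
        lines = [f"experiment (features={self.config.features}, "
                 f"augmentation={self.config.augmentation}, seed={self.config.seed})",
                 f"  train/test images: {self.n_train}/{self.n_test}"]
        if self.stage1_auc is not None:
            lines.append(f"  Stage-I held-out AUC: {self.stage1_auc:.4f}")
        lines.append(f"  Stage-II overall accuracy: {self.stage2_report.accuracy:.4f}, "
                     f"macro sensitivity: {self.stage2_report.macro_sensitivity():.4f}")
        if self.stage2_report.macro_auc is not None:
            lines.append(f"  Stage-II macro AUC: {self.stage2_report.macro_auc:.4f}")
        return "\n".join(lines)


def _pools_for_grid(pool_after: tuple[int, ...], grid: int) -> tuple[int, ...]:
    """Keep only as many 2x2 pooling stages as the feature grid can halve."""
    max_pools = max(int(np.log2(grid)), 0) if grid > 1 else 0
    return tuple(sorted(pool_after)[:max_pools])


def split_samples(samples: Sequence[ImageSample], test_fraction: float,
                  seed: int) -> tuple[list[ImageSample], list[ImageSample]]:
    """Stratified in-memory split (per class within one sample of the ratio)."""
    rng = np.random.default_rng(seed)
    by_label: dict[str, list[ImageSample]] = {}
    for s in samples:
        by_label.setdefault(s.label, []).append(s)
    train, test = [], []
    for label in sorted(by_label):
        pool = by_label[label]
        n_test = int(round(test_fraction * len(pool)))
        order = rng.permutation(len(pool))
        for j, i in enumerate(order):
            (test if j < n_test else train).append(pool[i])
    return train, test


def raw_thumbnail_features(images: np.ndarray, grid: int) -> np.ndarray:
    """Bilinear thumbnails (grid x grid x 3) as the no-DCAE ablation features."""
    from PIL import Image as _PILImage
    out = np.empty((len(images), grid, grid, 3), dtype=np.float32)
    for i, px in enumerate(images):
        im = _PILImage.fromarray(np.round(np.clip(px, 0, 1) * 255).astype(np.uint8))
        out[i] = np.asarray(im.resize((grid, grid), _PILImage.BILINEAR),
                            dtype=np.float32) / 255.0
    return out


def _spawn_seeds(seed: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(8)]


def _generate_and_split(cfg: ExperimentConfig, gen_seed: int, split_seed: int):
    taxonomy = default_taxonomy()
    specs = default_class_specs()
    if cfg.atypical_only:
        specs = tuple(s for s in specs if s.label in ATYPICAL_CLASSES)
    samples = generate_samples(GeneratorConfig(
        specs=specs, images_per_class=cfg.images_per_class,
        image_size=cfg.image_size, seed=gen_seed))
    train, test = split_samples(samples, cfg.test_fraction, split_seed)
    by_label: dict[str, list[ImageSample]] = {}
    for s in train:
        by_label.setdefault(s.label, []).append(s)
    atyp_train = {k: v for k, v in by_label.items() if taxonomy.is_atypical(k)}
    return taxonomy, train, test, by_label, atyp_train


def _build_featurizer(cfg: ExperimentConfig, train, fdcae_seed: int):
    grid = cfg.image_size // 8
    if cfg.features == "dcae":
        feature_dcae = DCAE(DCAESpec(input_size=cfg.image_size), seed=fdcae_seed)
        sub = train[:: max(1, len(train) // cfg.feature_dcae_subsample)]
        fres = feature_dcae.fit(sub, TrainingConfig(
            learning_rate=cfg.dcae_learning_rate, epochs=cfg.feature_dcae_epochs,
            batch_size=cfg.batch_size, seed=fdcae_seed))

        def featurize(imgs: Sequence[ImageSample]) -> np.ndarray:
            return feature_dcae.encode(list(imgs), cfg.batch_size)
        return featurize, fres.history, grid, DCAESpec().encoder_filters[-1]
    if cfg.features == "raw":
        def featurize(imgs: Sequence[ImageSample]) -> np.ndarray:
            return raw_thumbnail_features(as_array(list(imgs)), grid)
        return featurize, None, grid, 3
    raise ValueError(f"unknown feature mode {cfg.features!r}")


def _train_synthesis_dcaes(cfg: ExperimentConfig, atyp_train,
                           sdcae_seed: int) -> dict[str, DCAE]:
    """One autoencoder per atypical class, trained on that class alone."""
    dspec = DCAESpec(input_size=cfg.image_size)
    dcae_cfg = TrainingConfig(learning_rate=cfg.dcae_learning_rate,
                              epochs=cfg.synth_dcae_epochs,
                              batch_size=cfg.synth_dcae_batch_size,
                              seed=sdcae_seed,
                              target_loss=cfg.synth_dcae_target_mse)
    models: dict[str, DCAE] = {}
    for label in ATYPICAL_CLASSES:
        model = DCAE(dspec, seed=sdcae_seed)
        pool = atyp_train[label][: cfg.synth_dcae_subsample]
        model.fit(pool, dcae_cfg)
        models[label] = model
    return models


def _synthesize(cfg: ExperimentConfig, method: str, atyp_train,
                sdcae_seed: int, bal_seed: int) -> dict[str, list[ImageSample]]:
    """Train per-class DCAEs if needed and synthesise up to the balance target."""
    n_per_class = min(len(v) for v in atyp_train.values())
    target = cfg.balance_target or int(round(1.5 * n_per_class))
    plan = BalancePlan(target=target, method=method)
    models = (_train_synthesis_dcaes(cfg, atyp_train, sdcae_seed)
              if method == GT_DCAE else None)
    return balance_classes(atyp_train, plan, models, seed=bal_seed)


def _fit_stage2_latents(cfg: ExperimentConfig, z2_train, y2_train, z2_test,
                        y2_test, grid: int, channels: int, taxonomy,
                        s2_seed: int):
    stage2 = Stage2Classifier(
        Stage2Spec(input_shape=(grid, grid, channels),
                   pool_after=_pools_for_grid(Stage2Spec.pool_after, grid)),
        seed=s2_seed)
    r2 = stage2.fit(z2_train, y2_train, TrainingConfig(
        learning_rate=cfg.classifier_learning_rate, epochs=cfg.stage2_epochs,
        batch_size=cfg.batch_size, seed=s2_seed))
    if cfg.finetune_epochs > 0:
        r2b = stage2.fit(z2_train, y2_train, TrainingConfig(
            learning_rate=cfg.classifier_learning_rate / 5,
            epochs=cfg.finetune_epochs, batch_size=cfg.batch_size, seed=s2_seed))
        for k in r2.history:
            r2.history[k].extend(r2b.history.get(k, []))
    probs2 = stage2.predict_proba(z2_test, cfg.batch_size)
    pred2 = [argmax_class(p, taxonomy) for p in probs2]
    report = EvaluationReport.from_predictions(
        y2_test, pred2, ATYPICAL_CLASSES, probs2)
    return stage2, r2, report


def _fit_and_eval_stage2(cfg: ExperimentConfig, featurize, grid: int,
                         channels: int, taxonomy, atyp_train, synthetic, test,
                         s2_seed: int):
    s2_train = [s for lab in ATYPICAL_CLASSES
                for s in list(atyp_train[lab]) + synthetic[lab]]
    s2_test = [s for s in test if taxonomy.is_atypical(s.label)]
    return _fit_stage2_latents(
        cfg, featurize(s2_train), [s.label for s in s2_train],
        featurize(s2_test), [s.label for s in s2_test],
        grid, channels, taxonomy, s2_seed)


def run_experiment(config: ExperimentConfig, out_dir=None) -> ExperimentResults:
    """Execute the full pipeline on synthetic data and evaluate it."""
    cfg = config
    (gen_seed, split_seed, fdcae_seed, sdcae_seed,
     bal_seed, s1_seed, s2_seed, _) = _spawn_seeds(cfg.seed)

    taxonomy, train, test, by_label, atyp_train = _generate_and_split(
        cfg, gen_seed, split_seed)
    synthetic = _synthesize(cfg, cfg.augmentation, atyp_train, sdcae_seed, bal_seed)
    featurize, feature_history, grid, channels = _build_featurizer(
        cfg, train, fdcae_seed)
    stage2, r2, stage2_report = _fit_and_eval_stage2(
        cfg, featurize, grid, channels, taxonomy, atyp_train, synthetic, test,
        s2_seed)

    # --- stage I + two-stage dispatch ----------------------------------------
    stage1_history = stage1_auc = stage1_report = two_stage_counts = None
    if not cfg.atypical_only:
        s1_train = [s for lab, pool in by_label.items() for s in pool]
        s1_train += [s for lab in ATYPICAL_CLASSES for s in synthetic[lab]]
        z1_train = featurize(s1_train)
        y1_train = np.array([taxonomy.is_atypical(s.label) for s in s1_train],
                            dtype=np.float32)
        z1_test = featurize(test)
        y1_test = np.array([taxonomy.is_atypical(s.label) for s in test],
                           dtype=np.float32)
        stage1 = Stage1Classifier(
            Stage1Spec(input_shape=(grid, grid, channels),
                       pool_after=_pools_for_grid(Stage1Spec.pool_after, grid)),
            seed=s1_seed)
        r1 = stage1.fit(z1_train, y1_train, TrainingConfig(
            learning_rate=cfg.classifier_learning_rate, epochs=cfg.stage1_epochs,
            batch_size=cfg.batch_size, seed=s1_seed))
        stage1_history = r1.history
        p1 = stage1.predict_proba(z1_test, cfg.batch_size)
        stage1_auc = roc_auc(y1_test, p1)
        pred_bin = np.where(p1 >= cfg.stage1_threshold, "atypical", "typical")
        true_bin = np.where(y1_test > 0.5, "atypical", "typical")
        stage1_report = EvaluationReport.from_predictions(
            true_bin.tolist(), pred_bin.tolist(), ("typical", "atypical")).to_dict()

        # full dispatch on the held-out set (one final label per cell)
        final = []
        probs_test = stage2.predict_proba(z1_test[p1 >= cfg.stage1_threshold],
                                          cfg.batch_size) if (p1 >= cfg.stage1_threshold).any() else []
        it = iter(probs_test)
        for flag in (p1 >= cfg.stage1_threshold):
            final.append(argmax_class(next(it), taxonomy) if flag else "typical")
        counts: dict[str, int] = {}
        for lab in final:
            counts[lab] = counts.get(lab, 0) + 1
        two_stage_counts = counts

    results = ExperimentResults(
        config=cfg, feature_dcae_history=feature_history,
        stage1_history=stage1_history, stage2_history=r2.history,
        stage1_auc=stage1_auc, stage1_report=stage1_report,
        stage2_report=stage2_report, two_stage_counts=two_stage_counts,
        n_train=len(train), n_test=len(test))

    if out_dir is not None:
        _write_artifacts(results, Path(out_dir))
    return results


def run_ablation_grid(base: ExperimentConfig, out_dir=None) -> dict[tuple[str, str], ExperimentResults]:
    """The 2x2 grid {dcae, raw features} x {gt-dcae, gt augmentation}."""
    grid = {}
    for feat in ("dcae", "raw"):
        for aug in (GT_DCAE, GT):
            cfg = replace(base, features=feat, augmentation=aug)
            sub = Path(out_dir) / f"{feat}_{aug}" if out_dir is not None else None
            grid[(feat, aug)] = run_experiment(cfg, sub)
    return grid


def run_augmentation_comparison(
    config: ExperimentConfig,
    methods: Sequence[str] = (GT_DCAE, GT),
    real_per_class: int | None = None,
) -> dict[str, EvaluationReport]:
    """Paired comparison of augmentation methods on Stage-II performance.

    Data generation, the train/test split and the feature extractor are
    computed once and shared, so the arms differ only in how the minority
    classes are synthesised — a matched comparison that is also much cheaper
    than independent :func:`run_experiment` calls per arm.

    ``real_per_class`` caps the real training images per atypical class
    before augmentation, emulating the rare-class regime the augmentation is
    designed for (few real sources, mostly synthetic training data). The
    held-out test set is unaffected.
    """
    cfg = config
    (gen_seed, split_seed, fdcae_seed, sdcae_seed,
     bal_seed, _, s2_seed, _) = _spawn_seeds(cfg.seed)
    taxonomy, train, test, _, atyp_train = _generate_and_split(
        cfg, gen_seed, split_seed)
    if real_per_class is not None:
        atyp_train = {k: v[:real_per_class] for k, v in atyp_train.items()}
    featurize, _, grid, channels = _build_featurizer(cfg, train, fdcae_seed)

    # real-sample latents are identical across arms — encode them once
    real = [s for lab in ATYPICAL_CLASSES for s in atyp_train[lab]]
    z_real = featurize(real)
    y_real = [s.label for s in real]
    s2_test = [s for s in test if taxonomy.is_atypical(s.label)]
    z_test = featurize(s2_test)
    y_test = [s.label for s in s2_test]

    # the GT samples are drawn once; the GT-DCAE arm reconstructs those same
    # samples through the per-class autoencoders, so the arms differ only in
    # the reconstruction step itself
    synth_by_method: dict[str, list[ImageSample]] = {}
    if GT in methods or GT_DCAE in methods:
        gt_synth = _synthesize(cfg, GT, atyp_train, sdcae_seed, bal_seed)
        synth_by_method[GT] = [s for lab in ATYPICAL_CLASSES
                               for s in gt_synth[lab]]
    if GT_DCAE in methods:
        models = _train_synthesis_dcaes(cfg, atyp_train, sdcae_seed)
        recon = []
        for lab in ATYPICAL_CLASSES:
            batch = gt_synth[lab]
            if batch:
                rec = models[lab].reconstruct(as_array(batch), cfg.batch_size)
                recon.extend(ImageSample(rec[i], label=lab,
                                         source_id=f"{s.source_id}_dcae")
                             for i, s in enumerate(batch))
        synth_by_method[GT_DCAE] = recon

    reports: dict[str, EvaluationReport] = {}
    for method in methods:
        syn = synth_by_method[method]
        z2_train = np.concatenate([z_real, featurize(syn)], axis=0)
        y2_train = y_real + [s.label for s in syn]
        _, _, reports[method] = _fit_stage2_latents(
            cfg, z2_train, y2_train, z_test, y_test, grid, channels,
            taxonomy, s2_seed)
    return reports


def _write_artifacts(res: ExperimentResults, out_dir: Path) -> None:
    """Persist metrics (JSON), per-sample predictions (CSV) and curves (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir.mkdir(parents=True, exist_ok=True)
    payload = {
        "seed": res.config.seed,
        "config": {k: getattr(res.config, k) for k in vars(res.config)},
        "stage1": {"auc": res.stage1_auc, "report": res.stage1_report},
        "stage2": res.stage2_report.to_dict(),
        "two_stage_counts": res.two_stage_counts,
    }
    (out_dir / "metrics.json").write_text(json.dumps(payload, indent=2))

    fig, ax = plt.subplots(figsize=(5, 3.5))
    if res.feature_dcae_history:
        ax.plot(res.feature_dcae_history["loss"], label="DCAE MSE")
    if res.stage1_history:
        ax.plot(res.stage1_history["loss"], label="Stage-I loss")
    ax.plot(res.stage2_history["loss"], label="Stage-II loss")
    ax.set_xlabel("epoch")
    ax.set_ylabel("training loss")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_dir / "loss_curves.png", dpi=100)
    plt.close(fig)
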