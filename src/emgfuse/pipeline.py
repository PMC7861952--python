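"""End-to-end gesture-classification pipeline under threefold CV.

Stage order per fold: spectrogram representation (per-trial, no fitting) →
standardization (fit on the training fold) → class-conditional Gaussian
augmentation (training fold only) → tensor view / coordinate transform
(identity by default) → stacked sparse autoencoder (trained on the augmented
fold) → classifier bank with per-class fusion → subject-averaged accuracy
reports for both splits.

The public face follows the Model/Results convention: build a
:class:`GestureFusionModel` from a :class:`LabeledSignalSet` or a
:class:`FeatureTable`, call :meth:`~GestureFusionModel.fit`, and read the
returned :class:`GestureFusionResults` (reports, fusion tables, fold
artifacts, ``summary()``).

Every source of randomness derives from one master seed through a documented
fan-out: ``SeedSequence(master)`` spawns one child per fold, and each fold
child spawns stage children in the fixed order (cv-unused, augmentation,
autoencoder, inner-split, ELM, SL).  Identical config + master seed
reproduces every reported number exactly.  No test-fold row ever reaches a
fitting stage; the per-stage trial ids that did are recorded in the fold
artifacts so tests (and users) can audit the split.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler

from . import classify_fuse as cf
from .augmentation import AugmentationSpec, augment_training_set
from .containers import FeatureTable, LabeledSignalSet
from .deep_features import AutoencoderSpec, encode_stack, train_encoder_stack
from .signal_io import AccuracyReport, make_cv_folds, subject_average
from .spectrogram import SpectrogramSpec, dataset_features
from .tensorize import CoordinateTransform

__all__ = [
    "ClassifierConfig",
    "PipelineConfig",
    "GestureFusionModel",
    "GestureFusionResults",
    "run_pipeline",
]

log = logging.getLogger(__name__)


@dataclass
class ClassifierConfig:
    elm_hidden: int = 500
    elm_ridge: float = 1e-6
    elm_activations: tuple[str, ...] = tuple(cf.ELM_ACTIVATIONS)
    svm_kernels: tuple[str, ...] = cf.SVM_KERNELS
    svm_box_constraint: float = 1.0
    softmax_l2: float = 1e-4
    selection_fraction: float = 0.25  # inner validation share of the training fold


@dataclass
class PipelineConfig:
    spectrogram: SpectrogramSpec = field(default_factory=SpectrogramSpec)
    augmentation: AugmentationSpec = field(default_factory=AugmentationSpec)
    autoencoder: AutoencoderSpec = field(default_factory=AutoencoderSpec)
    classifiers: ClassifierConfig = field(default_factory=ClassifierConfig)
    transform: CoordinateTransform | None = None  # None -> identity
    n_folds: int = 3
    seed: int = 0

    @classmethod
    def full_profile(cls, seed: int = 0) -> "PipelineConfig":
        """Full-scale constants: R = 1000 virtual rows per original, hidden
        sizes 1200/900, lambda 0.001, beta 4, rho 0.05, linear encoder."""
        return cls(
            augmentation=AugmentationSpec(replication_factor=1000, seed=seed),
            autoencoder=AutoencoderSpec(hidden_sizes=(1200, 900), seed=seed),
            seed=seed,
        )

    @classmethod
    def test_profile(cls, seed: int = 0) -> "PipelineConfig":
        """Shrunken profile for CI-scale runs: R = 10, hidden sizes [40, 20]."""
        return cls(
            augmentation=AugmentationSpec(replication_factor=10, seed=seed),
            autoencoder=AutoencoderSpec(hidden_sizes=(40, 20), max_epochs=150, seed=seed),
            classifiers=ClassifierConfig(elm_hidden=100),
            seed=seed,
        )


@dataclass
class FoldArtifacts:
    fold: int
    fusion: cf.FusionTable
    selected_variants: dict[str, str]
    fitted_trial_ids: dict[str, list[int]]  # stage -> sorted original-trial ids seen at fit
    test_trial_ids: list[int]
    stage_seeds: dict[str, int]


@dataclass
class GestureFusionResults:
    """Fitted pipeline: aggregated reports plus per-fold artifacts."""

    train_report: AccuracyReport
    test_report: AccuracyReport
    folds: list[FoldArtifacts]
    config: PipelineConfig
    master_seed: int

    def summary(self) -> str:
        lines = [
            "Gesture fusion pipeline — threefold cross-validation",
            "=" * 52,
            f"folds: {len(self.folds)}   master seed: {self.master_seed}",
            f"overall accuracy   train: {self.train_report.overall_accuracy:.2%}   "
            f"test: {self.test_report.overall_accuracy:.2%}",
            "",
            "per-subject accuracy (train / test):",
        ]
        for s in sorted(self.test_report.per_subject_accuracy):
            tr = self.train_report.per_subject_accuracy.get(s, float("nan"))
            te = self.test_report.per_subject_accuracy[s]
            lines.append(f"  subject {s}: {tr:.2%} / {te:.2%}")
        lines.append("")
        lines.append("per-class accuracy (test):")
        for c, a in sorted(self.test_report.per_class_accuracy.items()):
            lines.append(f"  class {c}: {a:.2%}")
        lines.append("")
        lines.append("per-class classifier assignment (fold 0):")
        for c, (fam, var) in sorted(self.folds[0].fusion.assignment.items()):
            lines.append(f"  class {c}: {fam} ({var})")
        return "\n".join(lines)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.train_report.write_json(out / "train_report.json")
        self.test_report.write_json(out / "test_report.json")
        folds = []
        for f in self.folds:
            folds.append(
                {
                    "fold": f.fold,
                    "selected_variants": f.selected_variants,
                    "assignment": {str(k): list(v) for k, v in f.fusion.assignment.items()},
                    "fitted_trial_ids": f.fitted_trial_ids,
                    "test_trial_ids": f.test_trial_ids,
                    "stage_seeds": f.stage_seeds,
                }
            )
        (out / "folds.json").write_text(json.dumps({"master_seed": self.master_seed, "folds": folds}, indent=1))
        (out / "summary.txt").write_text(self.summary() + "\n")


def _seen_ids(tab: FeatureTable) -> list[int]:
    if tab.trial_id is None:
        return []
    ids = np.asarray(tab.trial_id)
    return sorted(int(i) for i in np.unique(ids[ids >= 0]))


class GestureFusionModel:
    """The multistage classifier, configured on a dataset.

    Parameters
    ----------
    data
        Either raw recordings (:class:`LabeledSignalSet`) — the spectrogram
        stage then produces one feature row per trial — or a ready
        :class:`FeatureTable`, which skips the spectrogram stage.
    config
        Stage hyperparameters; :meth:`PipelineConfig.full_profile` and
        :meth:`PipelineConfig.test_profile` bundle the full-scale and
        CI-scale constants.
    """

    def __init__(self, data: LabeledSignalSet | FeatureTable, config: PipelineConfig | None = None):
        self.config = config or PipelineConfig()
        if isinstance(data, LabeledSignalSet):
            self.dataset = data
            log.info("extracting spectrogram features for %d trials", len(data))
            self.features = dataset_features(data, self.config.spectrogram)
        elif isinstance(data, FeatureTable):
            self.dataset = None
            self.features = data
            if self.features.trial_id is None:
                self.features.trial_id = np.arange(self.features.n_rows)
            if self.features.subject_id is None:
                self.features.subject_id = np.zeros(self.features.n_rows, dtype=int)
        else:
            raise TypeError("data must be a LabeledSignalSet or FeatureTable")

    # -- fitting ---------------------------------------------------------

    def fit(self, seed: int | None = None) -> GestureFusionResults:
        cfg = self.config
        master = cfg.seed if seed is None else seed
        feats = self.features
        transform = cfg.transform or CoordinateTransform.identity(feats.n_features)

        plan = self._make_plan(master)
        fold_ss = np.random.SeedSequence(master).spawn(len(plan.folds))

        pred_rows = {"train": [], "test": []}  # (subject, true, pred)
        fold_artifacts: list[FoldArtifacts] = []

        for k, (train_ids, test_ids) in enumerate(plan.folds):
            stage_seeds = {
                name: int(s.generate_state(1)[0] % (2**31))
                for name, s in zip(
                    ("augmentation", "autoencoder", "inner_split", "elm", "softmax"),
                    fold_ss[k].spawn(5),
                )
            }
            train_tab = feats.select_trials(train_ids)
            test_tab = feats.select_trials(test_ids)
            fitted: dict[str, list[int]] = {}

            # standardization: statistics from the training fold only
            scaler = StandardScaler().fit(train_tab.X)
            fitted["standardization"] = _seen_ids(train_tab)
            train_std = train_tab.select(np.ones(train_tab.n_rows, dtype=bool))
            train_std.X = scaler.transform(train_tab.X)
            test_std = test_tab.select(np.ones(test_tab.n_rows, dtype=bool))
            test_std.X = scaler.transform(test_tab.X)

            # Gaussian virtual-sample augmentation of the training fold
            aug_spec = replace(cfg.augmentation, seed=stage_seeds["augmentation"])
            aug = augment_training_set(train_std, aug_spec)
            fitted["augmentation"] = _seen_ids(train_std)

            # coordinate transform (identity unless configured otherwise)
            X_aug = transform(aug.X)
            X_train = transform(train_std.X)
            X_test = transform(test_std.X)

            # stacked sparse autoencoder on the augmented training fold
            ae_spec = replace(cfg.autoencoder, seed=stage_seeds["autoencoder"])
            stack = train_encoder_stack(X_aug, ae_spec)
            fitted["autoencoder"] = _seen_ids(aug)
            Z_aug = encode_stack(stack, X_aug)
            Z_train = encode_stack(stack, X_train)
            Z_test = encode_stack(stack, X_test)

            # classifier bank, selection and fusion
            fusion, variants, bank = self._train_bank(
                Z_aug, aug, Z_train, train_std, stage_seeds
            )
            fitted["classifiers"] = _seen_ids(aug)

            classes = np.unique(aug.y)
            for split, Z, tab in (("train", Z_train, train_std), ("test", Z_test, test_std)):
                scores = {fam: m.predict_scores(Z) for fam, m in bank.items()}
                pred = cf.fuse_predict(fusion, scores, classes)
                pred_rows[split].append((tab.subject_id, tab.y, pred))

            fold_artifacts.append(
                FoldArtifacts(
                    fold=k,
                    fusion=fusion,
                    selected_variants=variants,
                    fitted_trial_ids=fitted,
                    test_trial_ids=sorted(int(i) for i in test_ids),
                    stage_seeds=stage_seeds,
                )
            )

        reports = {}
        for split, rows in pred_rows.items():
            subj = np.concatenate([r[0] for r in rows])
            yt = np.concatenate([r[1] for r in rows])
            yp = np.concatenate([r[2] for r in rows])
            reports[split] = subject_average(subj, yt, yp, split_name=split)

        return GestureFusionResults(
            train_report=reports["train"],
            test_report=reports["test"],
            folds=fold_artifacts,
            config=cfg,
            master_seed=master,
        )

    # -- helpers ---------------------------------------------------------

    def _make_plan(self, master: int):
        if self.dataset is not None:
            return make_cv_folds(self.dataset, self.config.n_folds, seed=master)
        # feature-table input: stratify trials by (subject, class)
        from .containers import Trial

        pseudo = LabeledSignalSet(
            [
                Trial(
                    signal=np.zeros((1, 1)),
                    subject_id=int(s),
                    class_label=y if isinstance(y, (int, np.integer)) else int(np.nonzero(self.features.classes == y)[0][0]),
                    repetition=i,
                    sampling_rate=1.0,
                    trial_id=int(t),
                )
                for i, (s, y, t) in enumerate(
                    zip(self.features.subject_id, self.features.y, self.features.trial_id)
                )
            ]
        )
        return make_cv_folds(pseudo, self.config.n_folds, seed=master)

    def _train_bank(self, Z_aug, aug, Z_train, train_std, stage_seeds):
        """Variant selection on an inner validation split of the original
        training rows, then a refit of the chosen variants on the full
        augmented fold."""
        ccfg = self.config.classifiers
        is_original = (
            np.asarray(aug.trial_id) >= 0 if aug.trial_id is not None else np.ones(aug.n_rows, bool)
        )
        orig_idx = np.nonzero(is_original)[0]
        virt_idx = np.nonzero(~is_original)[0]

        inner_train, inner_val = train_test_split(
            orig_idx,
            test_size=ccfg.selection_fraction,
            stratify=aug.y[orig_idx],
            random_state=stage_seeds["inner_split"] % (2**31),
        )
        sel_rows = np.concatenate([np.sort(inner_train), virt_idx])
        Xs, ys = Z_aug[sel_rows], aug.y[sel_rows]
        Xv, yv = Z_aug[np.sort(inner_val)], aug.y[np.sort(inner_val)]

        # candidate variants per family, trained on the selection split
        elm_cands = [
            (act, cf.train_elm(Xs, ys, ccfg.elm_hidden, act, ccfg.elm_ridge, seed=stage_seeds["elm"]))
            for act in ccfg.elm_activations
        ]
        svm_cands = [
            (kern, cf.train_svm(Xs, ys, cf.SvmSpec(kern, ccfg.svm_box_constraint)))
            for kern in ccfg.svm_kernels
        ]
        sl = cf.train_softmax(Xs, ys, ccfg.softmax_l2, seed=stage_seeds["softmax"])

        elm_id, _, _ = cf.select_best_variant(elm_cands, Xv, yv)
        svm_id, _, _ = cf.select_best_variant(svm_cands, Xv, yv)
        variants = {"ELM": elm_id, "SVM": svm_id, "SL": "softmax"}

        # per-class accuracies on the inner validation split drive fusion
        classes = np.unique(aug.y)
        sel_models = {
            "ELM": dict(elm_cands)[elm_id],
            "SVM": dict(svm_cands)[svm_id],
            "SL": sl,
        }
        acc_tables = {
            fam: cf.per_class_accuracy(m.predict(Xv), yv, classes=classes)
            for fam, m in sel_models.items()
        }
        fusion = cf.select_local_classifiers(acc_tables, variant_ids=variants)

        # final bank: chosen variants refitted on the full augmented fold
        bank = {
            "ELM": cf.train_elm(Z_aug, aug.y, ccfg.elm_hidden, elm_id, ccfg.elm_ridge, seed=stage_seeds["elm"]),
            "SVM": cf.train_svm(Z_aug, aug.y, cf.SvmSpec(svm_id, ccfg.svm_box_constraint)),
            "SL": cf.train_softmax(Z_aug, aug.y, ccfg.softmax_l2, seed=stage_seeds["softmax"]),
        }
        return fusion, variants, bank


def run_pipeline(
    data: LabeledSignalSet | FeatureTable,
    config: PipelineConfig | None = None,
    out_dir: str | Path | None = None,
) -> GestureFusionResults:
    """Convenience wrapper: build the model, fit it, optionally save artifacts."""
    results = GestureFusionModel(data, config).fit()
    if out_dir is not None:
        results.save(out_dir)
    return results
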