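"""Subject-independent evaluation protocol and figures of merit.

Subjects (never recordings) are partitioned into folds, so no speaker
contributes to both training and test of any fold. Per fold the pipeline is:
centric data selection → universal-model training → MAP class adaptation →
likelihood classification of the held-out recordings. Accuracy, precision,
recall and F1 (Depressed = positive class) are reported per fold and as
mean ± std, in percent.

Ablation switches reproduce the design variants: feature subsets (upstream,
via FeatureConfig), ``no_ubm`` class-specific HMMs, a left-right topology,
and clustering (Euclidean mean-vector) data selection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    precision_score,
    recall_score,
)

from .data_selection import SelectionSplit, select_training_adaptation
from .features import FeatureMatrix
from .hmm_core import ERGODIC, baum_welch, init_model
from .classification import classify
from .signal_io import DEPRESSED, HEALTHY
from .synthetic import Corpus
from .ubm_map import (
    AdaptedPair,
    DEFAULT_TAU,
    UniversalModel,
    build_class_models,
    train_ubm,
)

logger = logging.getLogger(__name__)

DEFAULT_STATES_GRID = (3, 4, 5, 6, 7)
DEFAULT_MIXTURES_GRID = (2, 4, 8, 16, 32, 64, 128)


class ProtocolError(ValueError):
    """Raised on protocol violations (e.g. fewer subjects than folds)."""


@dataclass
class FoldPlan:
    """Subject-level fold assignments."""

    n_folds: int
    fold_assignments: dict[str, int]
    seed: int

    def subjects_in(self, fold: int) -> list[str]:
        return [s for s, f in self.fold_assignments.items() if f == fold]


@dataclass
class ProtocolConfig:
    """Model, selection and ablation knobs for one protocol run."""

    n_states: int = 3
    n_mixtures: int = 2
    topology: str = ERGODIC
    tau: float = DEFAULT_TAU
    selection: str = "cca"          # or "clustering"
    k_clusters: int = 2
    train_fraction: float = 0.5
    no_ubm: bool = False            # ablation: class-specific HMMs
    max_iter: int = 25


@dataclass
class MetricsReport:
    """Per-fold metrics plus mean ± std aggregates (percent)."""

    folds: list[dict]
    config: ProtocolConfig | None = None

    def _agg(self, key: str) -> tuple[float, float]:
        vals = [f[key] for f in self.folds if key in f]
        return float(np.mean(vals)), float(np.std(vals))

    @property
    def complete(self) -> bool:
        return all("error" not in f for f in self.folds)

    def summary(self) -> dict:
        out = {}
        for key in ("accuracy", "precision", "recall", "f1"):
            mean, std = self._agg(key)
            out[key] = mean
            out[f"{key}_std"] = std
        out["n_folds"] = len(self.folds)
        out["complete"] = self.complete
        return out


def make_folds(manifest, n_folds: int = 5, seed: int = 0,
               fold_file=None) -> FoldPlan:
    """Randomly partition subjects into folds, stratified by label.

    ``manifest`` needs ``subject`` and ``label`` columns; every recording of
    a subject lands in that subject's fold. A published fold assignment (CSV
    with columns ``subject,fold``) is accepted verbatim via ``fold_file``.
    """
    pairs = manifest[["subject", "label"]].drop_duplicates()
    dup = pairs["subject"].duplicated()
    if dup.any():
        raise ProtocolError("a subject carries conflicting labels")
    subjects = pairs["subject"].tolist()
    labels = pairs["label"].tolist()
    if fold_file is not None:
        import pandas as pd

        df = pd.read_csv(fold_file, dtype={"subject": str, "fold": int})
        assignments = dict(zip(df["subject"], df["fold"]))
        missing = set(subjects) - set(assignments)
        if missing:
            raise ProtocolError(f"fold file misses subjects {sorted(missing)}")
        return FoldPlan(n_folds=int(df["fold"].max()) + 1,
                        fold_assignments={s: assignments[s]
                                          for s in subjects}, seed=seed)
    if len(subjects) < n_folds:
        raise ProtocolError(
            f"{len(subjects)} subjects cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    assignments: dict[str, int] = {}
    for cls in sorted(set(labels)):
        cls_subjects = [s for s, l in zip(subjects, labels) if l == cls]
        order = rng.permutation(len(cls_subjects))
        for i, idx in enumerate(order):
            assignments[cls_subjects[idx]] = i % n_folds
    return FoldPlan(n_folds=n_folds, fold_assignments=assignments, seed=seed)


def compute_metrics(truth: list[str], predicted: list[str],
                    positive_class: str = DEPRESSED) -> dict:
    """Accuracy/precision/recall/F1 in percent, plus confusion counts."""
    if len(truth) != len(predicted) or not truth:
        raise ProtocolError("truth and predictions must align, non-empty")
    if positive_class not in set(truth) | set(predicted):
        logger.warning("positive class %s absent from data", positive_class)
    y_true = [1 if t == positive_class else 0 for t in truth]
    y_pred = [1 if p == positive_class else 0 for p in predicted]
    if sum(y_pred) == 0:
        logger.warning("no predicted positives; precision defined as 0")
    cm = confusion_matrix(y_true, y_pred, labels=[0, 1])
    return {
        "accuracy": 100.0 * accuracy_score(y_true, y_pred),
        "precision": 100.0 * precision_score(y_true, y_pred, zero_division=0),
        "recall": 100.0 * recall_score(y_true, y_pred, zero_division=0),
        "f1": 100.0 * f1_score(y_true, y_pred, zero_division=0),
        "confusion": {"tn": int(cm[0, 0]), "fp": int(cm[0, 1]),
                      "fn": int(cm[1, 0]), "tp": int(cm[1, 1])},
    }


def _by_class(features: dict[str, FeatureMatrix],
              ids: list[str]) -> dict[str, list[FeatureMatrix]]:
    out: dict[str, list[FeatureMatrix]] = {HEALTHY: [], DEPRESSED: []}
    for i in ids:
        out[features[i].label].append(features[i])
    return out


def _fit_pair(features: dict[str, FeatureMatrix], train_ids: list[str],
              config: ProtocolConfig, seed: int) -> AdaptedPair:
    """Selection → UBM → MAP (or the class-specific-HMM ablation)."""
    by_class = _by_class(features, train_ids)
    if config.no_ubm:
        models = {}
        for cls, feats in by_class.items():
            m = init_model(feats, config.n_states, config.n_mixtures,
                           topology=config.topology, seed=seed)
            models[cls] = baum_welch(m, feats, max_iter=config.max_iter)
        return AdaptedPair(healthy=models[HEALTHY],
                           depressed=models[DEPRESSED],
                           tau=float("nan"), parent_digest="no_ubm")
    split = select_training_adaptation(
        by_class, k=config.k_clusters,
        train_fraction=config.train_fraction, seed=seed,
        metric=config.selection)
    ubm = train_ubm(split, features, config.n_states, config.n_mixtures,
                    topology=config.topology, seed=seed,
                    max_iter=config.max_iter)
    return build_class_models(ubm, split, features, tau=config.tau)


def grid_search(
    features: dict[str, FeatureMatrix],
    train_ids: list[str],
    config: ProtocolConfig,
    states_set=DEFAULT_STATES_GRID,
    mixtures_set=DEFAULT_MIXTURES_GRID,
    validation_fraction: float = 0.1,
    seed: int = 0,
) -> tuple[int, int, float]:
    """Exhaustive (states, mixtures) search on a subject-held-out validation set.

    10% of the training subjects (at least one per class) are held out,
    stratified by label; each candidate pipeline is trained on the rest and
    scored on them. Ties prefer the smaller model (fewer states, then fewer
    mixtures); infeasible combinations are skipped with a log entry.
    """
    subj_label = {}
    for i in train_ids:
        subj_label[features[i].subject_id] = features[i].label
    rng = np.random.default_rng(seed)
    val_subjects: set[str] = set()
    for cls in (HEALTHY, DEPRESSED):
        cls_subj = sorted(s for s, l in subj_label.items() if l == cls)
        if not cls_subj:
            raise ProtocolError(f"no training subjects of class {cls}")
        n_val = max(1, int(round(validation_fraction * len(cls_subj))))
        if n_val >= len(cls_subj):
            raise ProtocolError("training set too small to hold out 10%")
        val_subjects |= set(rng.permutation(cls_subj)[:n_val])
    fit_ids = [i for i in train_ids
               if features[i].subject_id not in val_subjects]
    val_ids = [i for i in train_ids if features[i].subject_id in val_subjects]

    total_frames = sum(features[i].n_frames for i in fit_ids)
    best = None
    for S in sorted(states_set):
        for K in sorted(mixtures_set):
            if S * K > total_frames:
                logger.info("skipping infeasible grid point S=%d K=%d", S, K)
                continue
            cand = replace(config, n_states=S, n_mixtures=K)
            try:
                pair = _fit_pair(features, fit_ids, cand, seed)
            except Exception as exc:  # noqa: BLE001 - degenerate grid point
                logger.info("grid point S=%d K=%d failed: %s", S, K, exc)
                continue
            preds = [classify(pair, features[i]).label for i in val_ids]
            truth = [features[i].label for i in val_ids]
            acc = compute_metrics(truth, preds)["accuracy"]
            if best is None or acc > best[2] + 1e-12:
                best = (S, K, acc)
    if best is None:
        raise ProtocolError("no feasible grid point")
    return best


def run_protocol(
    corpus: Corpus,
    config: ProtocolConfig | None = None,
    n_folds: int = 5,
    seed: int = 0,
) -> MetricsReport:
    """Run the full subject-independent cross-validation protocol.

    Per fold: fit on the other folds' subjects (selection → UBM → MAP, or
    the ablation variant), classify the fold's recordings, score. A fold
    that errors is recorded as incomplete rather than aborting the run.
    The subject-independence invariant is asserted on every fold.
    """
    config = config or ProtocolConfig()
    features = corpus.features
    plan = make_folds(corpus.manifest, n_folds=n_folds, seed=seed)
    all_ids = list(features)
    folds = []
    for fold in range(n_folds):
        test_subjects = set(plan.subjects_in(fold))
        test_ids = [i for i in all_ids
                    if features[i].subject_id in test_subjects]
        train_ids = [i for i in all_ids
                     if features[i].subject_id not in test_subjects]
        train_subjects = {features[i].subject_id for i in train_ids}
        assert not (train_subjects & test_subjects), \
            "subject straddles train/test"
        if not test_ids:
            folds.append({"fold": fold, "error": "empty test fold"})
            continue
        try:
            pair = _fit_pair(features, train_ids, config, seed + fold)
            preds = [classify(pair, features[i]).label for i in test_ids]
            truth = [features[i].label for i in test_ids]
            entry = compute_metrics(truth, preds)
            entry["fold"] = fold
            entry["n_test"] = len(test_ids)
            folds.append(entry)
        except Exception as exc:  # noqa: BLE001 - fold-level diagnosis
            logger.error("fold %d failed: %s", fold, exc)
            folds.append({"fold": fold, "error": str(exc)})
    return MetricsReport(folds=folds, config=config)
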