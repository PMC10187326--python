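"""Participant-grouped, class-stratified cross-validation harness.

Participants are split into k folds of near-equal size; one fold is held
out for testing while the remainder is split 80/20 (participant-level) into
training and validation.  Stratification uses each participant's
walking-epoch fraction, so folds have comparable class balance even though
grouping by participant makes exact label stratification impossible.  Every
round trains the classifier, fits the HMM smoother on validation
predictions, tunes the peak heuristics on validation recordings, and
evaluates end-to-end on the held-out fold.  Participant-disjointness of
train/validation/test is asserted inside the harness itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .classifier import (ClassifierConfig, concat_datasets, extract_windows,
                         predict_epochs, train_classifier)
from .hmm import fit_hmm
from .io import NONWALK, WALK
from .metrics import EvalReport
from .peaks import PeakGrid, PeakParams, hybrid_count, tune_peak_params


@dataclass
class CVConfig:
    k: int = 10
    seed: int = 0
    val_fraction: float = 0.2
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    peak_grid: PeakGrid = field(default_factory=PeakGrid)
    epoch_length: float = 10.0


def grouped_stratified_kfold(participant_ids, walk_fractions, k: int = 10,
                             seed: int = 0) -> dict[str, int]:
    """Assign each participant to one of k folds.

    Fold sizes differ by at most one; participants are ordered by their
    walking-epoch fraction (seeded jitter breaks ties) and dealt round-robin
    so per-fold class shares track the global share.  Same seed, same
    assignment.
    """
    ids = list(participant_ids)
    fracs = np.asarray(walk_fractions, dtype=float)
    if len(ids) < k:
        raise ValueError(f"need at least k={k} participants, got {len(ids)}")
    rng = np.random.default_rng(seed)
    jitter = rng.uniform(0, 1e-9, len(ids))
    order = np.lexsort((jitter, fracs))
    folds = {}
    deal = rng.permutation(k)  # randomise which fold gets the extras
    for pos, idx in enumerate(order):
        folds[ids[idx]] = int(deal[pos % k])
    return folds


def train_val_split(participant_ids, rng: np.random.Generator,
                    val_fraction: float = 0.2) -> tuple[list, list]:
    """Participant-level random split of the non-test folds (default 80/20)."""
    ids = list(participant_ids)
    perm = rng.permutation(len(ids))
    n_val = max(1, int(round(val_fraction * len(ids))))
    val = [ids[i] for i in perm[:n_val]]
    train = [ids[i] for i in perm[n_val:]]
    if not train:
        raise ValueError("not enough participants for a train/val split")
    return train, val


def _walk_fraction(p) -> float:
    lab = p.epochs.true_label[p.epochs.valid]
    return float(np.mean(lab == WALK)) if len(lab) else 0.0


def _has_both_classes(participants) -> bool:
    labs = np.concatenate([p.epochs.true_label[p.epochs.valid]
                           for p in participants])
    return WALK in labs and NONWALK in labs


@dataclass
class FoldResult:
    fold: int
    test_participants: list[str]
    report: EvalReport
    peak_params: PeakParams


@dataclass
class CVResults:
    """Per-fold and pooled evaluation of the full pipeline."""

    folds: list[FoldResult]
    pooled: EvalReport
    mean_fold_mape: float   # mean over folds of within-fold participant MAPE
    config: CVConfig

    def summary(self) -> str:
        lines = [f"{len(self.folds)}-fold grouped cross-validation",
                 self.pooled.summary(),
                 f"  Mean within-fold MAPE: {self.mean_fold_mape:.2f} %"]
        return "\n".join(lines)


def run_cv(dataset, config: CVConfig | None = None) -> CVResults:
    """Run the full cross-validated pipeline on a labelled cohort.

    ``dataset`` is a sequence of participant records (``participant_id``,
    ``recording``, ``step_times``, ``epochs`` with ground-truth labels), as
    produced by :func:`wriststep.simulate.simulate_cohort` or assembled from
    annotated real recordings.
    """
    config = config or CVConfig()
    dataset = list(dataset)
    by_id = {p.participant_id: p for p in dataset}
    folds = grouped_stratified_kfold(
        [p.participant_id for p in dataset],
        [_walk_fraction(p) for p in dataset],
        k=config.k, seed=config.seed)
    rng = np.random.default_rng(config.seed + 1)

    fold_results: list[FoldResult] = []
    pooled_ids: list[str] = []
    pooled_true: list[float] = []
    pooled_pred: list[float] = []
    pooled_true_lab: list[np.ndarray] = []
    pooled_pred_lab: list[np.ndarray] = []

    for fold in sorted(set(folds.values())):
        test_ids = [pid for pid, f in folds.items() if f == fold]
        rest = [pid for pid, f in folds.items() if f != fold]
        train_ids, val_ids = train_val_split(rest, rng, config.val_fraction)
        assert not (set(train_ids) & set(val_ids) | set(train_ids) & set(test_ids)
                    | set(val_ids) & set(test_ids)), "participant leakage"

        train_p = [by_id[i] for i in train_ids]
        val_p = [by_id[i] for i in val_ids]
        test_p = [by_id[i] for i in test_ids]
        if not (_has_both_classes(train_p) and _has_both_classes(val_p)):
            warnings.warn(f"fold {fold}: single-class train or validation "
                          "set; fold skipped")
            continue

        cfg = ClassifierConfig(**vars(config.classifier))
        cfg.seed = int(rng.integers(0, 2**31 - 1))
        train_ds = concat_datasets(
            [extract_windows(p.recording, p.epochs, p.participant_id)
             for p in train_p])
        val_ds = concat_datasets(
            [extract_windows(p.recording, p.epochs, p.participant_id)
             for p in val_p])
        model = train_classifier(train_ds, val_ds, cfg)

        # HMM fitted on per-participant validation prediction sequences
        val_pred_seqs, val_true_seqs = [], []
        for p in val_p:
            prob, lab = predict_epochs(model, p.recording, p.epochs)
            ok = p.epochs.valid & (lab != -1)
            val_pred_seqs.append(lab[ok])
            val_true_seqs.append(p.epochs.true_label[ok])
        hmm = fit_hmm(val_pred_seqs, val_true_seqs)

        peak_params = tune_peak_params(val_p, config.peak_grid,
                                       config.epoch_length)

        ids, true_tot, pred_tot = [], [], []
        t_lab, p_lab = [], []
        for p in test_p:
            ev = hybrid_count(p.recording, model, hmm, peak_params,
                              config.epoch_length)
            ids.append(p.participant_id)
            true_tot.append(float(len(p.step_times)))
            pred_tot.append(float(ev.total))
            ok = p.epochs.valid & (ev.epochs.pred_label != -1)
            t_lab.append(p.epochs.true_label[ok])
            p_lab.append(ev.epochs.pred_label[ok])

        fold_labels_t = np.concatenate(t_lab)
        fold_labels_p = np.concatenate(p_lab)
        report = EvalReport.from_counts(
            ids, true_tot, pred_tot,
            fold_labels_t if len(np.unique(fold_labels_t)) == 2 else None,
            fold_labels_p if len(np.unique(fold_labels_t)) == 2 else None,
            stratum=f"fold {fold}")
        fold_results.append(FoldResult(fold, test_ids, report, peak_params))
        pooled_ids += ids
        pooled_true += true_tot
        pooled_pred += pred_tot
        pooled_true_lab.append(fold_labels_t)
        pooled_pred_lab.append(fold_labels_p)

    if not fold_results:
        raise ValueError("all folds were skipped")
    pooled = EvalReport.from_counts(
        pooled_ids, pooled_true, pooled_pred,
        np.concatenate(pooled_true_lab), np.concatenate(pooled_pred_lab),
        stratum="pooled")
    mean_fold_mape = float(np.mean([f.report.mape for f in fold_results]))
    return CVResults(fold_results, pooled, mean_fold_mape, config)
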