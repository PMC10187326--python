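"""Model/Results interface tying the pipeline together.

:class:`StepModel` is built from a labelled cohort (recordings with
ground-truth step times and epoch labels).  ``fit()`` reproduces the final
deployment fit - an 80/20 participant-level train/validation split, epoch
classifier training, HMM smoother fitting on validation predictions, and
peak-heuristic tuning on validation recordings - and returns a
:class:`StepModelResults` carrying all fitted components, the validation
report and a ``summary()`` table.  ``cross_validate()`` runs the k-fold
harness for internal validation.  Results objects count steps on new
recordings and serialise to a JSON checkpoint.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import __version__
from .classifier import (ClassifierConfig, TrainedClassifier, concat_datasets,
                         extract_windows, predict_epochs, train_classifier)
from .crossval import CVConfig, CVResults, run_cv, train_val_split
from .hmm import HMMParams, fit_hmm
from .io import RawRecording
from .metrics import EvalReport
from .peaks import PeakGrid, PeakParams, StepEvents, hybrid_count

CHECKPOINT_VERSION = 1


@dataclass
class StepModelConfig:
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    peak_grid: PeakGrid = field(default_factory=PeakGrid)
    epoch_length: float = 10.0
    val_fraction: float = 0.2


class StepModel:
    """Hybrid walk-classification + peak-detection step counter.

    Parameters
    ----------
    participants : sequence
        Labelled participant records (``participant_id``, ``recording``,
        ``step_times``, ``epochs``), e.g. from
        :func:`wriststep.simulate.simulate_cohort`.
    config : StepModelConfig, optional
    """

    def __init__(self, participants, config: StepModelConfig | None = None):
        self.participants = list(participants)
        if not self.participants:
            raise ValueError("need at least one labelled participant")
        self.config = config or StepModelConfig()

    def fit(self, seed: int | None = None) -> "StepModelResults":
        """Final-deployment fit with an 80/20 train/validation split."""
        cfg = self.config
        rng = np.random.default_rng(cfg.classifier.seed if seed is None else seed)
        ids = [p.participant_id for p in self.participants]
        by_id = {p.participant_id: p for p in self.participants}
        train_ids, val_ids = train_val_split(ids, rng, cfg.val_fraction)
        train_p = [by_id[i] for i in train_ids]
        val_p = [by_id[i] for i in val_ids]

        clf_cfg = ClassifierConfig(**vars(cfg.classifier))
        clf_cfg.seed = int(rng.integers(0, 2**31 - 1))
        train_ds = concat_datasets(
            [extract_windows(p.recording, p.epochs, p.participant_id)
             for p in train_p])
        val_ds = concat_datasets(
            [extract_windows(p.recording, p.epochs, p.participant_id)
             for p in val_p])
        classifier = train_classifier(train_ds, val_ds, clf_cfg)

        pred_seqs, true_seqs = [], []
        for p in val_p:
            _, lab = predict_epochs(classifier, p.recording, p.epochs)
            ok = p.epochs.valid & (lab != -1)
            pred_seqs.append(lab[ok])
            true_seqs.append(p.epochs.true_label[ok])
        hmm = fit_hmm(pred_seqs, true_seqs)

        from .peaks import tune_peak_params
        peak_params = tune_peak_params(val_p, cfg.peak_grid, cfg.epoch_length)

        # validation-set end-to-end report (diagnostic, not a test-set claim)
        ids_v, true_v, pred_v = [], [], []
        for p in val_p:
            ev = hybrid_count(p.recording, classifier, hmm, peak_params,
                              cfg.epoch_length)
            ids_v.append(p.participant_id)
            true_v.append(float(len(p.step_times)))
            pred_v.append(float(ev.total))
        report = (EvalReport.from_counts(ids_v, true_v, pred_v,
                                         stratum="validation")
                  if len(ids_v) >= 2 else None)
        return StepModelResults(classifier, hmm, peak_params, cfg, report,
                                train_ids, val_ids)

    def cross_validate(self, k: int = 10, seed: int = 0) -> CVResults:
        """Grouped, stratified k-fold internal validation of the pipeline."""
        cv_cfg = CVConfig(k=k, seed=seed, val_fraction=self.config.val_fraction,
                          classifier=self.config.classifier,
                          peak_grid=self.config.peak_grid,
                          epoch_length=self.config.epoch_length)
        return run_cv(self.participants, cv_cfg)


@dataclass
class StepModelResults:
    """Fitted pipeline: classifier + HMM smoother + tuned peak heuristics."""

    classifier: TrainedClassifier
    hmm: HMMParams
    peak_params: PeakParams
    config: StepModelConfig
    validation_report: EvalReport | None
    train_participants: list[str]
    val_participants: list[str]

    def count_steps(self, rec: RawRecording) -> StepEvents:
        """Apply the fitted hybrid pipeline to a new recording."""
        return hybrid_count(rec, self.classifier, self.hmm, self.peak_params,
                            self.config.epoch_length)

    def summary(self) -> str:
        c = self.classifier
        lines = [
            "Hybrid step-count model",
            "=" * 55,
            f"Classifier backend:   {c.backend_name}",
            f"  training epochs:    {len(c.history)} "
            f"(best validation epoch {c.best_epoch})",
            f"  final val loss:     {c.history[-1]['val_loss']:.4f}"
            if c.history else "",
            f"HMM smoother (rows nonwalk, walk):",
            f"  prior:      {np.round(self.hmm.prior, 3)}",
            f"  transition: {np.round(self.hmm.transition, 3).tolist()}",
            f"  emission:   {np.round(self.hmm.emission, 3).tolist()}",
            f"Peak heuristics: prominence {self.peak_params.prominence:.2f} g, "
            f"distance {self.peak_params.distance:.2f} s, "
            f"width <= {self.peak_params.width_max:.2f} s",
            f"Train/val participants: {len(self.train_participants)}/"
            f"{len(self.val_participants)}",
        ]
        if self.validation_report is not None:
            lines += ["-" * 55, self.validation_report.summary()]
        return "\n".join(x for x in lines if x)

    # -- checkpointing -----------------------------------------------------

    def save(self, path) -> None:
        """Serialise the fitted pipeline to a JSON checkpoint."""
        payload = {
            "version": CHECKPOINT_VERSION,
            "software": __version__,
            "config": {
                "epoch_length": self.config.epoch_length,
                "val_fraction": self.config.val_fraction,
                "classifier": {k: (list(v) if isinstance(v, tuple) else v)
                               for k, v in vars(self.config.classifier).items()},
            },
            "classifier": {
                "backend": self.classifier.backend_name,
                "params": {k: np.asarray(v).tolist()
                           for k, v in self.classifier.params.items()},
                "norm_mean": np.asarray(self.classifier.norm[0]).tolist(),
                "norm_sd": np.asarray(self.classifier.norm[1]).tolist(),
                "sample_rate": self.classifier.sample_rate,
                "samples_per_epoch": self.classifier.samples_per_epoch,
                "best_epoch": self.classifier.best_epoch,
            },
            "hmm": {
                "prior": self.hmm.prior.tolist(),
                "transition": self.hmm.transition.tolist(),
                "emission": self.hmm.emission.tolist(),
            },
            "peak_params": vars(self.peak_params),
            "train_participants": self.train_participants,
            "val_participants": self.val_participants,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path) -> "StepModelResults":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("version") != CHECKPOINT_VERSION:
            raise ValueError(
                f"checkpoint version {payload.get('version')} does not match "
                f"supported version {CHECKPOINT_VERSION}")
        ccfg = payload["config"]["classifier"]
        ccfg["class_balance_target"] = tuple(ccfg["class_balance_target"])
        clf_cfg = ClassifierConfig(**ccfg)
        c = payload["classifier"]
        classifier = TrainedClassifier(
            c["backend"], clf_cfg,
            {k: np.asarray(v) for k, v in c["params"].items()},
            (np.asarray(c["norm_mean"]), np.asarray(c["norm_sd"])),
            c["sample_rate"], c["samples_per_epoch"], [], c["best_epoch"])
        hmm = HMMParams(np.asarray(payload["hmm"]["prior"]),
                        np.asarray(payload["hmm"]["transition"]),
                        np.asarray(payload["hmm"]["emission"]))
        peak_params = PeakParams(**payload["peak_params"])
        cfg = StepModelConfig(classifier=clf_cfg,
                              epoch_length=payload["config"]["epoch_length"],
                              val_fraction=payload["config"]["val_fraction"])
        return cls(classifier, hmm, peak_params, cfg, None,
                   payload["train_participants"], payload["val_participants"])
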