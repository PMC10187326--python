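"""Validation statistics for step counting and walk classification.

Step-count agreement is summarised per participant: MAPE (unweighted mean of
per-participant absolute percent errors), signed mean bias percent (negative
= undercounting), Spearman rank correlation, and Bland-Altman limits of
agreement.  Walk classification is summarised by precision, recall, F1,
Cohen's kappa and accuracy with walking as the positive class.  Annotator
agreement uses the two-way random-effects, absolute-agreement, single-rater
ICC (ICC2,1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import accuracy_score, cohen_kappa_score

from .io import NONWALK, WALK


def _check_counts(true, pred):
    t = np.asarray(true, dtype=float)
    p = np.asarray(pred, dtype=float)
    if t.shape != p.shape:
        raise ValueError("true and pred must have equal length")
    if np.any(t <= 0):
        raise ValueError("percent errors are undefined for true counts <= 0")
    return t, p


def mape(true, pred) -> float:
    """Mean absolute percent error over participants, in percent."""
    t, p = _check_counts(true, pred)
    return float(np.mean(np.abs(p - t) / t) * 100.0)


def mean_bias_percent(true, pred) -> float:
    """Signed mean percent bias over participants (negative = undercount)."""
    t, p = _check_counts(true, pred)
    return float(np.mean((p - t) / t) * 100.0)


def spearman(true, pred) -> float:
    """Spearman rank correlation with average-rank tie handling.

    Returns NaN with a warning when either vector is constant.
    """
    t = np.asarray(true, dtype=float)
    p = np.asarray(pred, dtype=float)
    if len(t) < 3:
        raise ValueError("Spearman correlation needs n >= 3")
    if np.all(t == t[0]) or np.all(p == p[0]):
        warnings.warn("constant vector: Spearman correlation undefined")
        return float("nan")
    return float(sps.spearmanr(t, p).statistic)


@dataclass
class BlandAltman:
    """Mean difference and 95% limits of agreement for paired counts."""

    mean_diff: float
    lower: float
    upper: float
    means: np.ndarray = field(repr=False, default=None)  # type: ignore
    diffs: np.ndarray = field(repr=False, default=None)  # type: ignore


def bland_altman(true, pred) -> BlandAltman:
    """Bland-Altman agreement: differences pred - true, limits mean +/- 1.96 sd."""
    t = np.asarray(true, dtype=float)
    p = np.asarray(pred, dtype=float)
    if len(t) != len(p) or len(t) < 2:
        raise ValueError("Bland-Altman needs n >= 2 pairs")
    d = p - t
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(md, md - 1.96 * sd, md + 1.96 * sd, (t + p) / 2, d)


def icc_agreement(annotator_a, annotator_b) -> float:
    """Two-way random-effects absolute-agreement single-rater ICC (ICC2,1)."""
    a = np.asarray(annotator_a, dtype=float)
    b = np.asarray(annotator_b, dtype=float)
    if a.shape != b.shape or len(a) < 2:
        raise ValueError("ICC needs n >= 2 paired counts")
    if np.all(a == a[0]) and np.all(b == b[0]):
        warnings.warn("zero variance in both raters; ICC 1.0 by convention"
                      if np.allclose(a, b) else
                      "zero variance in both raters")
        return 1.0 if np.allclose(a, b) else 0.0
    import pingouin as pg
    n = len(a)
    df = pd.DataFrame({
        "target": np.tile(np.arange(n), 2),
        "rater": np.repeat(["a", "b"], n),
        "score": np.concatenate([a, b]),
    })
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # exact agreement -> inf F
        res = pg.intraclass_corr(df, targets="target", raters="rater",
                                 ratings="score")
    # two-way random absolute agreement, single rater: labelled ICC2 or ICC(A,1)
    row = res[res["Type"].isin(["ICC2", "ICC(A,1)"])]
    return float(row["ICC"].iloc[0])


@dataclass
class ClassificationMetrics:
    precision: float
    recall: float
    f1: float
    kappa: float
    accuracy: float


def classification_metrics(true_labels, pred_labels) -> ClassificationMetrics:
    """Binary walk-classification metrics; walking is the positive class.

    Precision is NaN (with a warning) when no walking epochs are predicted.
    """
    t = np.asarray(true_labels, dtype=int)
    p = np.asarray(pred_labels, dtype=int)
    if t.shape != p.shape:
        raise ValueError("label vectors must have equal length")
    if not {WALK, NONWALK} <= set(np.unique(t)):
        raise ValueError("true labels must contain both classes")
    tp = float(np.sum((t == WALK) & (p == WALK)))
    fp = float(np.sum((t == NONWALK) & (p == WALK)))
    fn = float(np.sum((t == WALK) & (p == NONWALK)))
    if tp + fp == 0:
        warnings.warn("no positive predictions; precision undefined")
        precision = float("nan")
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall > 0 else float("nan"))
    kappa = float(cohen_kappa_score(t, p))
    acc = float(accuracy_score(t, p))
    return ClassificationMetrics(precision, recall, f1, kappa, acc)


@dataclass
class EvalReport:
    """Step-count and classification agreement for one evaluation set."""

    participants: pd.DataFrame          # participant, true_steps, pred_steps, ape, bias
    mape: float
    mean_bias: float
    spearman_r: float
    bland_altman: BlandAltman
    classification: ClassificationMetrics | None = None
    icc: float | None = None
    stratum: str = "overall"

    @classmethod
    def from_counts(cls, participant_ids, true_steps, pred_steps,
                    true_labels=None, pred_labels=None,
                    stratum: str = "overall") -> "EvalReport":
        t = np.asarray(true_steps, dtype=float)
        p = np.asarray(pred_steps, dtype=float)
        table = pd.DataFrame({
            "participant": list(participant_ids),
            "true_steps": t,
            "pred_steps": p,
            "ape_pct": np.abs(p - t) / t * 100.0,
            "bias_pct": (p - t) / t * 100.0,
        })
        cl = None
        if true_labels is not None and pred_labels is not None:
            cl = classification_metrics(true_labels, pred_labels)
        r = spearman(t, p) if len(t) >= 3 else float("nan")
        return cls(table, mape(t, p), mean_bias_percent(t, p), r,
                   bland_altman(t, p), cl, stratum=stratum)

    def summary(self) -> str:
        lines = [f"Evaluation report [{self.stratum}] "
                 f"(n={len(self.participants)} participants)",
                 f"  MAPE:        {self.mape:8.2f} %",
                 f"  Mean bias:   {self.mean_bias:+8.2f} %",
                 f"  Spearman r:  {self.spearman_r:8.3f}",
                 f"  Bland-Altman: mean {self.bland_altman.mean_diff:+.1f}, "
                 f"LoA [{self.bland_altman.lower:+.1f}, "
                 f"{self.bland_altman.upper:+.1f}] steps"]
        if self.classification is not None:
            c = self.classification
            lines.append(
                f"  Walk classification: precision {c.precision:.3f}, "
                f"recall {c.recall:.3f}, F1 {c.f1:.3f}, "
                f"kappa {c.kappa:.3f}, accuracy {c.accuracy:.3f}")
        if self.icc is not None:
            lines.append(f"  ICC(2,1): {self.icc:.3f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        d = {
            "stratum": self.stratum,
            "n_participants": int(len(self.participants)),
            "mape_pct": self.mape,
            "mean_bias_pct": self.mean_bias,
            "spearman_r": self.spearman_r,
            "bland_altman": {
                "mean_diff": self.bland_altman.mean_diff,
                "lower": self.bland_altman.lower,
                "upper": self.bland_altman.upper,
            },
        }
        if self.classification is not None:
            d["classification"] = vars(self.classification)
        if self.icc is not None:
            d["icc"] = self.icc
        return d
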