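"""Two-state Hidden Markov label smoother.

The epoch classifier's hard labels are treated as noisy emissions of a
hidden walk/non-walk state.  Parameters are fitted from validation-set
predictions and their ground truth by pseudo-count-smoothed counting, and
smoothing decodes the maximum a-posteriori state path (Viterbi).  Posterior
marginal decoding is available as an alternative.  Ties in the decoder are
broken toward the non-walk state (conservative step counting).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import NONWALK, UNKNOWN, WALK

_STATES = (NONWALK, WALK)  # row/column order everywhere


@dataclass
class HMMParams:
    """Prior, transition and emission probabilities (rows/cols: nonwalk, walk).

    Emission rows are the true state, columns the predicted label.
    """

    prior: np.ndarray
    transition: np.ndarray
    emission: np.ndarray

    def validate(self) -> None:
        for name, arr, shape in (("prior", self.prior, (2,)),
                                 ("transition", self.transition, (2, 2)),
                                 ("emission", self.emission, (2, 2))):
            a = np.asarray(arr, dtype=float)
            if a.shape != shape:
                raise ValueError(f"{name} must have shape {shape}")
            if np.any(a < 0) or np.any(a > 1):
                raise ValueError(f"{name} entries must lie in [0, 1]")
            sums = a.sum(axis=-1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError(f"{name} rows must sum to 1")


def _as_sequences(seqs) -> list[np.ndarray]:
    if isinstance(seqs, np.ndarray) and seqs.ndim == 1:
        return [seqs.astype(int)]
    return [np.asarray(s, dtype=int) for s in seqs]


def fit_hmm(val_predicted, val_true, pseudo_count: float = 1.0) -> HMMParams:
    """Fit smoother parameters from aligned predicted and true label sequences.

    Emissions are row-normalised confusion counts (true -> predicted),
    transitions row-normalised true-label bigram counts, the prior the
    smoothed true-label frequencies; ``pseudo_count`` is added to every cell
    so no probability is exactly zero even when a validation fold misses a
    transition entirely.
    """
    preds = _as_sequences(val_predicted)
    trues = _as_sequences(val_true)
    if len(preds) != len(trues):
        raise ValueError("number of predicted and true sequences differ")
    emit = np.full((2, 2), float(pseudo_count))
    trans = np.full((2, 2), float(pseudo_count))
    prior = np.full(2, float(pseudo_count))
    for p, t in zip(preds, trues):
        if len(p) != len(t):
            raise ValueError("predicted and true sequences have different lengths")
        if np.any((p != NONWALK) & (p != WALK)) or np.any((t != NONWALK) & (t != WALK)):
            raise ValueError("labels must be binary walk/non-walk")
        for ti, pi in zip(t, p):
            emit[ti, pi] += 1
        for a, b in zip(t[:-1], t[1:]):
            trans[a, b] += 1
        for ti in t:
            prior[ti] += 1
    with np.errstate(invalid="ignore"):
        emit = emit / emit.sum(axis=1, keepdims=True)
        trans = trans / trans.sum(axis=1, keepdims=True)
        prior = prior / prior.sum()
    if np.any(~np.isfinite(emit)) or np.any(~np.isfinite(trans)):
        raise ValueError("degenerate counts; use a positive pseudo_count")
    params = HMMParams(prior, trans, emit)
    params.validate()
    return params


def viterbi_smooth(params: HMMParams, predicted) -> np.ndarray:
    """Maximum a-posteriori hidden state path given predicted labels.

    Ties in the backtrace are broken toward the non-walk state; score ties
    are detected with a small log-space tolerance because structural ties
    (symmetric observation runs) would otherwise resolve by floating-point
    noise.  The returned sequence has the same length as the input.
    """
    tol = 1e-9
    params.validate()
    obs = np.asarray(predicted, dtype=int)
    if obs.size == 0:
        raise ValueError("cannot smooth an empty sequence")
    with np.errstate(divide="ignore"):
        lp_prior = np.log(params.prior)
        lp_trans = np.log(params.transition)
        lp_emit = np.log(params.emission)
    T = len(obs)
    delta = np.empty((T, 2))
    back = np.zeros((T, 2), dtype=int)
    delta[0] = lp_prior + lp_emit[:, obs[0]]
    for t in range(1, T):
        scores = delta[t - 1][:, None] + lp_trans  # scores[i, j]: i -> j
        choose0 = scores[0] >= scores[1] - tol     # prefer non-walk on ties
        back[t] = np.where(choose0, 0, 1)
        delta[t] = np.where(choose0, scores[0], scores[1]) + lp_emit[:, obs[t]]
    path = np.empty(T, dtype=int)
    path[-1] = 0 if delta[-1, 0] >= delta[-1, 1] - tol else 1
    for t in range(T - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def posterior_smooth(params: HMMParams, predicted) -> np.ndarray:
    """Alternative decoder: per-epoch argmax of forward-backward marginals."""
    params.validate()
    obs = np.asarray(predicted, dtype=int)
    if obs.size == 0:
        raise ValueError("cannot smooth an empty sequence")
    T = len(obs)
    alpha = np.empty((T, 2))
    beta = np.empty((T, 2))
    alpha[0] = params.prior * params.emission[:, obs[0]]
    alpha[0] /= alpha[0].sum()
    for t in range(1, T):
        a = (alpha[t - 1] @ params.transition) * params.emission[:, obs[t]]
        alpha[t] = a / a.sum()
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        b = params.transition @ (params.emission[:, obs[t + 1]] * beta[t + 1])
        beta[t] = b / b.sum()
    post = alpha * beta
    # ties resolve to non-walk because argmax returns the first maximum
    return np.argmax(post / post.sum(axis=1, keepdims=True), axis=1)


def smooth_epoch_labels(params: HMMParams, labels: np.ndarray,
                        valid: np.ndarray,
                        method: str = "viterbi") -> np.ndarray:
    """Smooth an epoch label sequence, skipping invalid/unknown epochs.

    Each contiguous run of valid epochs with known predictions is smoothed
    independently (per-recording, never across gaps); unknown or invalid
    epochs stay unknown and downstream contribute zero steps.
    """
    decode = viterbi_smooth if method == "viterbi" else posterior_smooth
    labels = np.asarray(labels)
    out = np.full(len(labels), UNKNOWN, dtype=np.int8)
    usable = np.asarray(valid, dtype=bool) & (labels != UNKNOWN)
    i = 0
    n = len(labels)
    while i < n:
        if not usable[i]:
            i += 1
            continue
        j = i
        while j < n and usable[j]:
            j += 1
        out[i:j] = decode(params, labels[i:j])
        i = j
    return out
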