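"""Slow reference implementations used as independent cross-checks.

These re-derive the peak heuristics and the Viterbi decoder from their
definitions (per-peak contour scans, exhaustive path enumeration) without
sharing code with the fast implementations in :mod:`wriststep.peaks` and
:mod:`wriststep.hmm`.  They are quadratic/exponential and intended only for
small inputs in tests and the acceptance checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def naive_find_peaks(values: np.ndarray, sample_rate: float,
                     prominence: float, distance: float,
                     width_max: float) -> np.ndarray:
    """O(n^2) peak detection straight from the heuristic definitions.

    For every strict local maximum the prominence contour is found by
    scanning outwards to the nearest higher sample (or the signal end) and
    taking the minimum on each side; the width is measured at half
    prominence by walking from the peak toward each base with linear
    interpolation at the crossing.  Peaks passing the prominence and width
    screens are then pruned greedily in descending height order so that
    retained peaks are at least ``distance`` seconds apart.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    peaks = [i for i in range(1, n - 1) if v[i - 1] < v[i] > v[i + 1]]

    kept: list[tuple[int, float]] = []  # (index, height) passing prom+width
    for i in peaks:
        # left contour: scan to the nearest strictly higher sample
        lmin, lbase = v[i], i
        j = i - 1
        while j >= 0 and v[j] <= v[i]:
            if v[j] < lmin:
                lmin, lbase = v[j], j
            j -= 1
        # right contour
        rmin, rbase = v[i], i
        j = i + 1
        while j < n and v[j] <= v[i]:
            if v[j] < rmin:
                rmin, rbase = v[j], j
            j += 1
        prom = v[i] - max(lmin, rmin)
        if prom < prominence:
            continue
        # width at half prominence
        h = v[i] - 0.5 * prom
        j = i
        while j > lbase and v[j] > h:
            j -= 1
        left_ip = float(j)
        if v[j] < h:
            left_ip = j + (h - v[j]) / (v[j + 1] - v[j])
        j = i
        while j < rbase and v[j] > h:
            j += 1
        right_ip = float(j)
        if v[j] < h:
            right_ip = j - (h - v[j]) / (v[j - 1] - v[j])
        if (right_ip - left_ip) / sample_rate > width_max:
            continue
        kept.append((i, v[i]))

    # greedy distance pruning, highest first (ties: earlier index first)
    min_samples = distance * sample_rate
    kept.sort(key=lambda p: (-p[1], p[0]))
    retained: list[int] = []
    for i, _ in kept:
        if all(abs(i - q) >= min_samples for q in retained):
            retained.append(i)
    return np.array(sorted(retained), dtype=int)


def brute_force_viterbi(prior: np.ndarray, transition: np.ndarray,
                        emission: np.ndarray,
                        observed: np.ndarray) -> np.ndarray:
    """Exhaustive maximum a-posteriori state path over all 2^T candidates.

    States are 0 (non-walk) and 1 (walk); ``observed`` is the sequence of
    predicted labels treated as emissions.  Exact probability ties between
    paths are structural (symmetric observation runs), and a backtracing
    decoder that prefers the non-walk state at every local tie returns the
    optimal path whose reversed state tuple is lexicographically smallest;
    the same global rule is applied here.
    """
    obs = np.asarray(observed, dtype=int)
    T = len(obs)
    if T == 0:
        raise ValueError("empty sequence")
    lp_prior = np.log(prior)
    lp_trans = np.log(transition)
    lp_emit = np.log(emission)
    best_path: tuple[int, ...] | None = None
    best_lp = -np.inf
    for path in itertools.product((0, 1), repeat=T):
        lp = lp_prior[path[0]] + lp_emit[path[0], obs[0]]
        for t in range(1, T):
            lp += lp_trans[path[t - 1], path[t]] + lp_emit[path[t], obs[t]]
        if lp > best_lp + 1e-9 or (lp >= best_lp - 1e-9
                                   and path[::-1] < best_path[::-1]):
            best_lp, best_path = max(lp, best_lp), path
    assert best_path is not None
    return np.array(best_path, dtype=int)


def path_log_prob(prior: np.ndarray, transition: np.ndarray,
                  emission: np.ndarray, path: np.ndarray,
                  observed: np.ndarray) -> float:
    """Joint log probability of a state path and an observed label sequence."""
    path = np.asarray(path, dtype=int)
    obs = np.asarray(observed, dtype=int)
    lp = np.log(prior[path[0]]) + np.log(emission[path[0], obs[0]])
    for t in range(1, len(obs)):
        lp += np.log(transition[path[t - 1], path[t]])
        lp += np.log(emission[path[t], obs[t]])
    return float(lp)
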