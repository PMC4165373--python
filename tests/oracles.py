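"""Independent reference implementations used to gate the package.

These deliberately avoid the code paths they check: the LRT oracle
maximises the two Poisson likelihoods numerically instead of using the
closed forms, and the clustering oracle recomputes the full distance matrix
from the raw equivalence classes at every iteration instead of maintaining
state through merges.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import optimize

from contigclust.alignment_io import ExperimentDesign
from contigclust.ratio_test import lrt_statistic, pseudocounts

# ---------------------------------------------------------------------------
# Numeric likelihood-ratio oracle


def _maximise(nll_grad, x0):
    res = optimize.minimize(
        nll_grad,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={"gtol": 1e-12, "ftol": 1e-15, "maxiter": 10_000},
    )
    return res.fun


def numeric_lrt(x_a, x_b) -> float:
    """Brute-force -2(ln l0 - ln l1) by numeric maximisation in log-space.

    The Poisson log-likelihood is evaluated with real-valued observations as
    sum(x ln mu - mu); the x-only terms cancel in the difference.
    """
    x_a = np.asarray(x_a, dtype=float)
    x_b = np.asarray(x_b, dtype=float)
    n = len(x_a)

    def nll1(theta):
        la, lb = theta[:n], theta[n:]
        nll = -np.sum(x_a * la - np.exp(la) + x_b * lb - np.exp(lb))
        grad = -np.concatenate([x_a - np.exp(la), x_b - np.exp(lb)])
        return nll, grad

    def nll0(theta):
        lf, lb = theta[0], theta[1:]
        mu_a = np.exp(lf + lb)
        mu_b = np.exp(lb)
        nll = -np.sum(x_a * (lf + lb) - mu_a + x_b * lb - mu_b)
        grad = np.empty(n + 1)
        grad[0] = -(np.sum(x_a) - np.sum(mu_a))
        grad[1:] = -(x_a + x_b - mu_a - mu_b)
        return nll, grad

    start1 = np.concatenate([np.log(x_a), np.log(x_b)])
    start0 = np.concatenate([[0.0], np.log((x_a + x_b) / 2.0)])
    best1 = _maximise(nll1, start1)
    best0 = _maximise(nll0, start0)
    return 2.0 * (best0 - best1)


# ---------------------------------------------------------------------------
# Naive clustering oracle


def _raw_counts(classes, group, n_samples):
    """Per-sample fragments hitting any contig of ``group``."""
    out = np.zeros(n_samples, dtype=np.int64)
    for key, vec in classes.items():
        if key & group:
            out += vec
    return out


def _raw_shared(classes, g1, g2, n_samples):
    out = np.zeros(n_samples, dtype=np.int64)
    for key, vec in classes.items():
        if key & g1 and key & g2:
            out += vec
    return out


def naive_cluster(
    classes: dict[frozenset, np.ndarray],
    design: ExperimentDesign,
    d_thresh: float,
    test_enabled: bool,
    stat_threshold: float,
) -> set[frozenset]:
    """From-scratch agglomerative clustering over raw equivalence classes.

    Clusters are contig sets; R quantities are recomputed by scanning the
    original classes every iteration, so no linkage bookkeeping is trusted.
    Tie-breaking matches the engine: smallest (min contig, other min contig).
    """
    n_samples = len(design.samples)
    cond_idx = [
        [design.sample_index(s) for s in design.replicates(cond)]
        for cond in design.conditions
    ]
    contigs = sorted(set().union(*classes))
    clusters = [frozenset([c]) for c in contigs]
    while len(clusters) > 1:
        best = None
        for g1, g2 in itertools.combinations(clusters, 2):
            shared = _raw_shared(classes, g1, g2, n_samples)
            r_ab = int(shared.sum())
            if r_ab == 0:
                continue
            ca = _raw_counts(classes, g1, n_samples)
            cb = _raw_counts(classes, g2, n_samples)
            if test_enabled and design.n_conditions >= 2:
                r_a = [(ca - shared)[ix] for ix in cond_idx]
                r_b = [(cb - shared)[ix] for ix in cond_idx]
                r_s = [shared[ix] for ix in cond_idx]
                res = lrt_statistic(pseudocounts(r_a, r_b, r_s), stat_threshold)
                if res.reject:
                    continue  # distance forced to 1, never mergeable
            dist = 1.0 - r_ab / min(int(ca.sum()), int(cb.sum()))
            key = tuple(sorted((min(g1), min(g2))))
            cand = (dist, key)
            if best is None or cand < best[0]:
                best = (cand, g1, g2)
        if best is None:
            break
        (dist, _), g1, g2 = best
        if dist > d_thresh or dist >= 1.0:
            break
        clusters = [g for g in clusters if g not in (g1, g2)] + [g1 | g2]
    return set(clusters)
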