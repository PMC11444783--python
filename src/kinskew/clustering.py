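"""Bayesian admixture clustering via Gibbs sampling, with K selection.

The model: each allele copy originates from one of K clusters; clusters carry
independent Dirichlet(1) allele frequencies per locus; individual admixture
proportions Q follow a symmetric Dirichlet(alpha) prior with alpha updated by
a Metropolis step.  The data log-likelihood is traced every sweep and the
model score is the harmonic-approximation estimator

    LnPD = mean(logL) - var(logL) / 2

over post-burn-in sweeps.  ``select_k`` tabulates mean/SD of LnPD across
independent runs per K, the first/second-order rate-of-change statistics and
Delta-K, and reports the K chosen by max Delta-K and by max mean LnPD side by
side.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .genotypes import MISSING, GenotypeMatrix

__all__ = ["ClusterRun", "KSelection", "fit_admixture", "select_k"]

ALPHA_MAX = 10.0
ALPHA_PROP_SD = 0.05


@dataclass
class ClusterRun:
    K: int
    Q: np.ndarray               # (n, K) posterior-mean admixture
    freqs: np.ndarray           # (K, L, A) posterior-mean cluster frequencies
    loglik_trace: np.ndarray    # post-burn-in logL per sweep
    lnpd: float
    seed: int
    burn_in: int
    iters: int
    alpha: float


def _init_state(rng: np.random.Generator, k: int, n: int, L: int, A: int,
                Xi: np.ndarray, typed: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Symmetry-breaking start: whole individuals dropped into random clusters
    and P seeded from that partition (a flat random P start frequently sticks
    in merged-cluster modes)."""
    init_assign = rng.integers(k, size=n)
    counts = np.zeros((k, L, A))
    for i in range(n):
        for c in range(2):
            np.add.at(counts,
                      (np.full(L, init_assign[i]), np.arange(L), Xi[i, :, c]),
                      typed[i].astype(float))
    P = rng.gamma(1.0 + counts)
    P /= P.sum(axis=2, keepdims=True)
    Q = np.full((n, k), 1.0 / k)
    return P, Q


def fit_admixture(matrix: GenotypeMatrix, k: int, burn_in: int = 2000,
                  iters: int = 2000, seed: int = 0,
                  alpha_init: float = 1.0, n_starts: int = 4,
                  pilot_sweeps: int = 40) -> ClusterRun:
    """Run the admixture Gibbs sampler at a fixed K.

    ``n_starts`` short pilot chains are run first and the highest-likelihood
    state is carried into the main chain, which guards against the sampler
    settling into a merged-cluster local mode.
    """
    if k < 1:
        raise ValueError("K must be >= 1")
    if k > matrix.n_individuals:
        raise ValueError("K exceeds the number of individuals")
    if burn_in < 1 or iters < 1:
        raise ValueError("burn_in and iters must be >= 1")
    rng = np.random.default_rng(seed)
    n, L = matrix.n_individuals, matrix.n_loci
    X = matrix.alleles  # (n, L, 2)
    A = int(X.max())
    typed = X[:, :, 0] != MISSING          # (n, L)
    copy_mask = np.repeat(typed[:, :, None], 2, axis=2)
    Xi = np.clip(X - 1, 0, None)           # 0-based allele index for gathering
    lix = np.arange(L)[None, :, None]

    ind_ix = np.repeat(np.arange(n), L * 2)

    def sweep_once(P, Q, alpha):
        # allele-origin indicators
        W = P[:, lix, Xi]                          # (k, n, L, 2)
        probs = Q.T[:, :, None, None] * W          # (k, n, L, 2)
        total = probs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            cum = np.cumsum(probs / total, axis=0)
        u = rng.random((n, L, 2))
        Z = (u[None, :, :, :] > cum).sum(axis=0)   # (n, L, 2) in 0..k-1
        Z = np.clip(Z, 0, k - 1)

        # cluster allele frequencies
        counts = np.zeros((k, L, A))
        zf = Z.ravel()[copy_mask.ravel()]
        lf = np.broadcast_to(lix, (n, L, 2)).ravel()[copy_mask.ravel()]
        af = Xi.ravel()[copy_mask.ravel()]
        np.add.at(counts, (zf, lf, af), 1.0)
        P = rng.gamma(1.0 + counts)
        P /= P.sum(axis=2, keepdims=True)

        # admixture proportions
        m = np.zeros((n, k))
        np.add.at(m, (ind_ix[copy_mask.ravel()], zf), 1.0)
        Q = rng.gamma(alpha + m)
        Q /= Q.sum(axis=1, keepdims=True)
        Q = np.clip(Q, 1e-12, None)
        Q /= Q.sum(axis=1, keepdims=True)

        # Metropolis update for alpha (uniform prior on (0, ALPHA_MAX))
        if k > 1:
            prop = alpha + rng.normal(0.0, ALPHA_PROP_SD)
            if 0.0 < prop < ALPHA_MAX:
                slq = float(np.log(Q).sum())

                def logp(a: float) -> float:
                    return n * (gammaln(k * a) - k * gammaln(a)) + (a - 1.0) * slq

                if np.log(rng.random()) < logp(prop) - logp(alpha):
                    alpha = prop

        # data log-likelihood under current (P, Q)
        W = P[:, lix, Xi]
        mix = np.einsum("ik,kilc->ilc", Q, W)
        ll = float(np.log(mix[copy_mask]).sum())
        return P, Q, alpha, ll

    # pilot chains: keep the best state by likelihood
    best = None
    for _ in range(max(n_starts, 1) if k > 1 else 1):
        P, Q = _init_state(rng, k, n, L, A, Xi, typed)
        alpha = float(alpha_init)
        ll = -np.inf
        for _ in range(pilot_sweeps):
            P, Q, alpha, ll = sweep_once(P, Q, alpha)
        if best is None or ll > best[3]:
            best = (P, Q, alpha, ll)
    P, Q, alpha, _ = best

    q_sum = np.zeros((n, k))
    p_sum = np.zeros((k, L, A))
    logliks = []

    for sweep in range(burn_in + iters):
        P, Q, alpha, ll = sweep_once(P, Q, alpha)
        if not np.isfinite(ll):
            raise RuntimeError(f"non-finite likelihood at sweep {sweep}")
        if sweep >= burn_in:
            q_sum += Q
            p_sum += P
            logliks.append(ll)

    trace = np.array(logliks)
    lnpd = float(trace.mean() - trace.var(ddof=1) / 2.0) if len(trace) > 1 \
        else float(trace.mean())
    return ClusterRun(k, q_sum / iters, p_sum / iters, trace, lnpd,
                      seed, burn_in, iters, alpha)


@dataclass
class KSelection:
    evanno: pd.DataFrame
    best_by_lnpd: int
    best_by_delta_k: int | None


def select_k(runs: list[ClusterRun]) -> KSelection:
    """Evanno table over a K grid plus both selection criteria.

    Needs >= 2 runs per K and >= 3 consecutive K values.  Delta-K =
    |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / SD(L(K)), defined only for
    interior K with SD > 0.
    """
    by_k: dict[int, list[float]] = {}
    for run in runs:
        by_k.setdefault(run.K, []).append(run.lnpd)
    ks = sorted(by_k)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need >= 3 consecutive K values")
    for k in ks:
        if len(by_k[k]) < 2:
            raise ValueError(f"K={k} has a single run; SD undefined")
    mean_l = {k: float(np.mean(by_k[k])) for k in ks}
    sd_l = {k: float(np.std(by_k[k], ddof=1)) for k in ks}
    rows = []
    for k in ks:
        lp = mean_l.get(k - 1)
        ln = mean_l.get(k + 1)
        l1 = mean_l[k] - lp if lp is not None else np.nan
        l2 = (ln - 2 * mean_l[k] + lp) if (lp is not None and ln is not None) \
            else np.nan
        if not np.isnan(l2) and sd_l[k] > 0:
            dk = abs(l2) / sd_l[k]
        else:
            dk = np.nan
            if not np.isnan(l2):
                warnings.warn(f"SD = 0 at K={k}; Delta-K undefined there")
        rows.append((k, len(by_k[k]), mean_l[k], sd_l[k], l1, l2, dk))
    evanno = pd.DataFrame(rows, columns=["K", "n_runs", "mean_lnpd", "sd_lnpd",
                                         "l_prime", "l_double_prime", "delta_k"])
    best_lnpd = int(evanno.loc[evanno["mean_lnpd"].idxmax(), "K"])
    valid = evanno.dropna(subset=["delta_k"])
    best_dk = int(valid.loc[valid["delta_k"].idxmax(), "K"]) if len(valid) else None
    return KSelection(evanno, best_lnpd, best_dk)
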