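"""Maximum-likelihood K-cluster admixture, replicate consensus, K selection, PCA.

The admixture model treats each individual's genome as a mixture over K
clusters: genotype g_il ~ Binomial(2, sum_k q_ik p_kl), with Q the individuals
x K ancestry proportions and P the K x loci cluster allele frequencies. The
likelihood is maximized by monotone EM (alternating convex updates); missing
genotypes contribute nothing to the likelihood. Label switching across
replicate fits is resolved by permutation alignment (exhaustive, hence exact,
for K <= 4) and the aligned replicates averaged into a consensus Q. K is
chosen by masked-entry cross-validation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .genodata import SnpMatrix

_EPS = 1e-9


@dataclass
class AncestryResult:
    Q: np.ndarray  # (n, K) ancestry proportions, rows sum to 1
    P: np.ndarray  # (K, L) cluster allele frequencies
    loglik_trace: np.ndarray  # per-iteration log-likelihood, non-decreasing
    K: int
    seed: int

    def __post_init__(self) -> None:
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("Q rows must sum to 1")
        if np.any(self.Q < -1e-12) or np.any(self.P < -1e-12):
            raise ValueError("Q and P must be non-negative")
        if np.any(np.diff(self.loglik_trace) < -1e-6):
            raise ValueError("log-likelihood trace must be non-decreasing")


@dataclass
class ConsensusQ:
    """Element-wise mean of label-aligned replicate Q matrices."""

    Q_mean: np.ndarray
    permutations: list[tuple[int, ...]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.allclose(self.Q_mean.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("consensus Q rows must sum to 1")


def _loglik(G: np.ndarray, obs: np.ndarray, F: np.ndarray) -> float:
    with np.errstate(invalid="ignore"):
        ll = np.where(obs, G * np.log(F) + (2 - G) * np.log1p(-F), 0.0)
    return float(ll.sum())


def fit_admixture(
    m: SnpMatrix,
    K: int,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 2000,
) -> AncestryResult:
    """EM fit of the binomial admixture likelihood.

    Stops when the log-likelihood improves by less than ``tol`` between
    iterations (default 1e-4). K = 1 reduces to the closed form Q = 1,
    P = observed allele frequencies.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if m.n_samples < K:
        raise ValueError(f"K={K} exceeds the {m.n_samples} individuals")
    G = m.as_float()  # NaN at missing
    obs = ~np.isnan(G)
    if not obs.any(axis=0).all():
        raise ValueError("matrix contains all-missing loci; filter first")
    Gz = np.nan_to_num(G)  # zeros at missing; masked by `obs` in updates
    n, L = G.shape
    rng = np.random.default_rng(seed)

    freqs = np.nansum(G, axis=0) / (2 * obs.sum(axis=0))
    if K == 1:
        Q = np.ones((n, 1))
        P = freqs[None, :].copy()
        ll = _loglik(Gz, obs, np.clip(P, _EPS, 1 - _EPS))
        return AncestryResult(Q, P, np.array([ll]), K, seed)

    Q = rng.dirichlet(np.ones(K), size=n)
    P = np.clip(
        freqs[None, :] + 0.1 * rng.standard_normal((K, L)), 0.01, 0.99
    )
    n_obs = obs.sum(axis=1)  # loci observed per individual

    def em_step(Q: np.ndarray, P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        F = np.clip(Q @ P, _EPS, 1 - _EPS)
        Qnew = np.empty_like(Q)
        Pnew = np.empty_like(P)
        ratio_a = np.where(obs, Gz / F, 0.0)
        ratio_b = np.where(obs, (2 - Gz) / (1 - F), 0.0)
        for k in range(K):  # accumulate per cluster to bound memory
            a_k = ratio_a * (Q[:, k : k + 1] * P[k][None, :])
            b_k = ratio_b * (Q[:, k : k + 1] * (1 - P[k])[None, :])
            Qnew[:, k] = (a_k + b_k).sum(axis=1) / (2 * n_obs)
            denom = (a_k + b_k).sum(axis=0)
            Pnew[k] = np.where(
                denom > 0, a_k.sum(axis=0) / np.maximum(denom, _EPS), P[k]
            )
        Qnew = Qnew / Qnew.sum(axis=1, keepdims=True)
        Pnew = np.clip(Pnew, _EPS, 1 - _EPS)
        return Qnew, Pnew

    def project(Q: np.ndarray, P: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        Q = np.clip(Q, _EPS, None)
        return Q / Q.sum(axis=1, keepdims=True), np.clip(P, _EPS, 1 - _EPS)

    def ll_of(Q: np.ndarray, P: np.ndarray) -> float:
        return _loglik(Gz, obs, np.clip(Q @ P, _EPS, 1 - _EPS))

    # SQUAREM-accelerated EM: the extrapolated step is accepted only when it
    # improves the likelihood, otherwise the plain double EM step is kept, so
    # every recorded iterate still ascends (monotone, like block relaxation;
    # acceleration changes speed, not the optimum).
    trace: list[float] = [ll_of(Q, P)]
    for _ in range(max_iter):
        Q1, P1 = em_step(Q, P)
        Q2, P2 = em_step(Q1, P1)
        rQ, rP = Q1 - Q, P1 - P
        vQ, vP = (Q2 - Q1) - rQ, (P2 - P1) - rP
        r_norm = np.sqrt(np.sum(rQ**2) + np.sum(rP**2))
        v_norm = np.sqrt(np.sum(vQ**2) + np.sum(vP**2))
        ll_fallback = ll_of(Q2, P2)
        if v_norm > 0:
            alpha = min(-r_norm / v_norm, -1.0)
            Qs, Ps = project(Q - 2 * alpha * rQ + alpha**2 * vQ,
                             P - 2 * alpha * rP + alpha**2 * vP)
            Qs, Ps = em_step(Qs, Ps)  # stabilizing EM step
            ll_acc = ll_of(Qs, Ps)
            if ll_acc >= ll_fallback:
                Q, P, ll = Qs, Ps, ll_acc
            else:
                Q, P, ll = Q2, P2, ll_fallback
        else:
            Q, P, ll = Q2, P2, ll_fallback
        trace.append(ll)
        if ll - trace[-2] < tol:
            break
    return AncestryResult(Q, P, np.asarray(trace), K, seed)


# ---------------------------------------------------------------------------
# Replicate alignment (label switching)
# ---------------------------------------------------------------------------


def _best_permutation(Q: np.ndarray, ref: np.ndarray, K: int) -> tuple[int, ...]:
    """Permutation of Q's columns maximizing sum_i <Q_perm[i], ref[i]>.

    Exhaustive over all K! permutations for K <= 4 (<= 24 candidates), so the
    greedy search is exact in the range this analysis uses; for larger K a
    greedy column matching is applied.
    """
    if K <= 4:
        best, best_score = None, -np.inf
        for perm in itertools.permutations(range(K)):
            score = float(np.sum(Q[:, perm] * ref))
            if score > best_score:
                best, best_score = perm, score
        return best
    sim = Q.T @ ref  # sim[src, dst]: moving source column `src` to slot `dst`
    work = sim.copy()
    perm = [-1] * K
    for _ in range(K):
        src, dst = np.unravel_index(np.argmax(work), work.shape)
        perm[dst] = int(src)
        work[src, :] = -np.inf
        work[:, dst] = -np.inf
    return tuple(perm)


def align_replicates(results: list[AncestryResult]) -> ConsensusQ:
    """CLUMPP-style consensus: align each replicate's cluster labels, average Q."""
    if not results:
        raise ValueError("no replicates")
    K = results[0].K
    n = results[0].Q.shape[0]
    for r in results:
        if r.K != K or r.Q.shape[0] != n:
            raise ValueError("replicates differ in K or individuals")
    ref = results[0].Q.copy()
    total = ref.copy()
    perms: list[tuple[int, ...]] = [tuple(range(K))]
    for i, r in enumerate(results[1:], start=2):
        running_mean = total / (i - 1)
        perm = _best_permutation(r.Q, running_mean, K)
        perms.append(perm)
        total += r.Q[:, perm]
    Q_mean = total / len(results)
    Q_mean = Q_mean / Q_mean.sum(axis=1, keepdims=True)
    return ConsensusQ(Q_mean, perms)


# ---------------------------------------------------------------------------
# K selection by masked-entry cross-validation
# ---------------------------------------------------------------------------


def select_k(
    m: SnpMatrix,
    k_range: range | list[int] = range(1, 6),
    folds: int = 10,
    replicates: int = 100,
    seed: int = 0,
    tol: float = 1e-4,
    max_iter: int = 500,
) -> tuple[dict[int, float], int]:
    """Choose K by cross-validated prediction of held-out genotype entries.

    Non-missing entries are partitioned into ``folds`` folds; each fold is
    masked in turn, the model refitted, and the masked genotypes scored by
    squared error against their fitted expectation 2 * sum_k q_ik p_kl. The
    optimum K minimizes the mean CV error over folds and replicates.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    obs_idx = np.argwhere(m.genotypes != -1)
    if len(obs_idx) < folds:
        raise ValueError("too few non-missing entries for the requested folds")
    rng = np.random.default_rng(seed)
    cv: dict[int, float] = {}
    for K in k_range:
        errs: list[float] = []
        for rep in range(replicates):
            order = rng.permutation(len(obs_idx))
            fold_of = np.empty(len(obs_idx), dtype=int)
            fold_of[order] = np.arange(len(obs_idx)) % folds
            for f in range(folds):
                mask = obs_idx[fold_of == f]
                geno = m.genotypes.copy()
                geno[mask[:, 0], mask[:, 1]] = -1
                # loci fully masked by the fold cannot be fit; keep one entry
                masked_m = SnpMatrix(geno, m.locus_meta, m.sample_ids)
                try:
                    fit = fit_admixture(
                        masked_m, K, seed=int(rng.integers(2**31)),
                        tol=tol, max_iter=max_iter,
                    )
                except ValueError:
                    continue  # degenerate fold (all-missing locus); skip
                pred = 2 * fit.Q @ fit.P
                truth = m.genotypes[mask[:, 0], mask[:, 1]].astype(float)
                errs.append(float(np.mean((truth - pred[mask[:, 0], mask[:, 1]]) ** 2)))
        cv[K] = float(np.mean(errs))
    best = min(cv, key=cv.get)
    return cv, best


def pca(m: SnpMatrix) -> tuple[np.ndarray, np.ndarray]:
    """PCA of mean-centered genotypes (missing entries mean-imputed).

    Returns (coordinates, percent variance per component); the percentages
    sum to <= 100.
    """
    if m.n_samples < 2:
        raise ValueError("need >= 2 individuals")
    G = m.as_float()
    mu = np.nanmean(G, axis=0)
    mu = np.where(np.isnan(mu), 0.0, mu)
    X = np.where(np.isnan(G), mu, G) - mu
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    coords = U * S
    total = np.sum(S**2)
    pct = 100 * S**2 / total if total > 0 else np.zeros_like(S)
    return coords, pct
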