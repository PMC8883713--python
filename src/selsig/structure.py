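"""Genetic structure: PCA of the genotype matrix and an admixture EM.

PCA mean-imputes missing dosages, centres each SNP by twice its allele
frequency and scales by the binomial standard deviation sqrt(2 p (1-p))
(Patterson scaling), then eigendecomposes the sample covariance.

The admixture model is the standard K-ancestral-population binomial
likelihood: genotype g_il ~ Binomial(2, sum_k q_ik p_kl) with ancestry
proportions Q (rows sum to 1) and ancestral allele frequencies P. It is
fitted by plain EM block updates (monotone in the log-likelihood); model
choice over K uses masked-entry cross-validation: a seeded random fraction
of called genotypes is hidden, the model fitted on the rest, and the
squared dosage-scale prediction error on the hidden entries is the CV error.
The K with the lowest replicate-mean CV error is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import MISSING

_EPS = 1e-6


@dataclass
class PcaResult:
    scores: np.ndarray            # samples x components
    explained_fraction: np.ndarray
    n_snps_used: int


@dataclass
class AdmixtureFit:
    K: int
    Q: np.ndarray                 # samples x K
    P: np.ndarray                 # K x SNPs
    loglik_trace: np.ndarray
    cv_error: float | None = None

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])


def pca(G: np.ndarray, n_components: int = 10) -> PcaResult:
    """Patterson-scaled PCA of the genotype matrix."""
    G = np.asarray(G)
    X = G.astype(float)
    X[G == MISSING] = np.nan
    p = np.nanmean(X, axis=0) / 2.0
    keep = np.isfinite(p) & (p > 0) & (p < 1)
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} monomorphic/uncalled SNPs from PCA"
        )
    X = X[:, keep]
    p = p[keep]
    if X.shape[1] == 0:
        raise ValueError("no polymorphic SNPs available for PCA")
    mu = 2.0 * p
    sd = np.sqrt(2.0 * p * (1.0 - p))
    X = (X - mu) / sd
    X[np.isnan(X)] = 0.0  # mean imputation after centring
    n = X.shape[0]
    U, S, _ = np.linalg.svd(X, full_matrices=False)
    total = float((S**2).sum())
    if total == 0:
        raise ValueError("genotype matrix has no variance")
    k = min(n_components, len(S))
    return PcaResult(
        scores=U[:, :k] * S[:k],
        explained_fraction=(S[:k] ** 2) / total,
        n_snps_used=X.shape[1],
    )


def _loglik(G, W, nhet_log2, Q, P):
    f = np.clip(Q @ P, _EPS, 1 - _EPS)
    ll = np.where(W, G * np.log(f) + (2 - G) * np.log1p(-f), 0.0).sum()
    return ll + nhet_log2


def admixture_fit(
    G: np.ndarray,
    K: int,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-4,
) -> AdmixtureFit:
    """Fit the K-population admixture model by EM.

    Missing genotypes are skipped in the likelihood. The log-likelihood
    trace is non-decreasing (EM guarantee); iteration stops when the
    increment falls below ``tol`` or at ``max_iter``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    Gi = np.asarray(G)
    W = Gi != MISSING
    if not W.any(axis=0).all():
        raise ValueError("admixture requires every SNP to have >= 1 call")
    Gf = np.where(W, Gi, 0).astype(np.float64)
    n, m = Gf.shape
    nhet_log2 = float((Gi == 1).sum()) * np.log(2.0)

    rng = np.random.default_rng(seed)
    Q = rng.dirichlet(np.ones(K), size=n)
    P = rng.uniform(0.05, 0.95, size=(K, m))
    if K == 1:
        called = W.sum(axis=0) * 2.0
        P = (Gf.sum(axis=0) / called)[None, :]
        Q = np.ones((n, 1))
        ll = _loglik(Gf, W, nhet_log2, Q, np.clip(P, _EPS, 1 - _EPS))
        return AdmixtureFit(K=1, Q=Q, P=P, loglik_trace=np.array([ll]))

    L_i = W.sum(axis=1).astype(float)
    trace = []
    ll_prev = -np.inf
    for _ in range(max_iter):
        f = np.clip(Q @ P, _EPS, 1 - _EPS)
        R1 = np.where(W, Gf / f, 0.0)
        R0 = np.where(W, (2.0 - Gf) / (1.0 - f), 0.0)
        ll = float(np.where(W, Gf * np.log(f) + (2 - Gf) * np.log1p(-f),
                            0.0).sum()) + nhet_log2
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite admixture log-likelihood")
        trace.append(ll)
        if ll - ll_prev < tol and len(trace) > 1:
            break
        ll_prev = ll

        Q_new = np.empty_like(Q)
        P_new = np.empty_like(P)
        for k in range(K):
            t1 = R1 @ P[k]              # per sample: sum_l g a / q
            t0 = R0 @ (1.0 - P[k])
            Q_new[:, k] = Q[:, k] * (t1 + t0) / (2.0 * L_i)
            s1 = Q[:, k] @ R1           # per SNP
            s0 = Q[:, k] @ R0
            num = P[k] * s1
            den = num + (1.0 - P[k]) * s0
            with np.errstate(invalid="ignore", divide="ignore"):
                P_new[k] = np.where(den > 0, num / den, P[k])
        Q = Q_new / Q_new.sum(axis=1, keepdims=True)
        P = np.clip(P_new, _EPS, 1 - _EPS)

    return AdmixtureFit(K=K, Q=Q, P=P, loglik_trace=np.array(trace))


@dataclass
class CVResult:
    cv_errors: dict                      # K -> list of replicate errors
    mean_cv_error: dict = field(default_factory=dict)  # K -> mean
    best_K: int = 0

    def __post_init__(self):
        self.mean_cv_error = {
            k: float(np.mean(v)) for k, v in self.cv_errors.items()
        }
        self.best_K = min(self.mean_cv_error, key=self.mean_cv_error.get)


def admixture_cv(
    G: np.ndarray,
    K_values,
    n_replicates: int = 5,
    fold_fraction: float = 0.1,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-3,
) -> CVResult:
    """Masked-entry cross-validation over K.

    Per replicate a seeded random ``fold_fraction`` of called entries is
    hidden, the model fitted on the rest, and the CV error is the mean
    squared difference between the hidden dosages and their fitted
    expectation 2 (Q P). SNPs left with no calls after masking are skipped
    for that replicate.
    """
    K_values = list(K_values)
    if not K_values:
        raise ValueError("K_values must be non-empty")
    Gi = np.asarray(G)
    called = np.argwhere(Gi != MISSING)
    errors = {K: [] for K in K_values}
    for rep in range(n_replicates):
        rng = np.random.default_rng([seed, rep])
        n_mask = max(1, int(round(fold_fraction * len(called))))
        sel = rng.choice(len(called), size=n_mask, replace=False)
        mi, ml = called[sel, 0], called[sel, 1]
        G_train = Gi.copy()
        G_train[mi, ml] = MISSING
        usable_snp = (G_train != MISSING).any(axis=0)
        keep_entry = usable_snp[ml]
        G_fit = G_train[:, usable_snp]
        col_of = np.cumsum(usable_snp) - 1
        for K in K_values:
            fit = admixture_fit(G_fit, K, seed=int(rng.integers(2**31)),
                                max_iter=max_iter, tol=tol)
            pred = 2.0 * fit.Q @ fit.P
            obs = Gi[mi[keep_entry], ml[keep_entry]].astype(float)
            est = pred[mi[keep_entry], col_of[ml[keep_entry]]]
            errors[K].append(float(np.mean((obs - est) ** 2)))
    return CVResult(cv_errors=errors)


def match_columns(Q_a: np.ndarray, Q_b: np.ndarray) -> np.ndarray:
    """Permutation of B's columns best matching A (Hungarian assignment on
    mean absolute difference)."""
    from scipy.optimize import linear_sum_assignment

    K = Q_a.shape[1]
    cost = np.empty((K, K))
    for i in range(K):
        for j in range(K):
            cost[i, j] = np.abs(Q_a[:, i] - Q_b[:, j]).mean()
    _, perm = linear_sum_assignment(cost)
    return perm
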