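"""Co-abundance clustering by a Poisson mixture over experimental groups.

Feature i in library j, belonging to latent cluster k, is modeled as

    y_ij | k  ~  Poisson(w_i * s_j * lambda_{g(j), k})

where w_i is the feature's total count, s_j the library-size proportion
(sum_j s_j = 1), and lambda_gk the cluster's group-proportion parameter,
tied within each experimental group g (line x feeding condition) and
normalized so sum_g S_g lambda_gk = 1 with S_g the group's library share.
Thus a cluster is a profile of how its members' reads distribute across
the four groups.  Parameters are estimated by EM; the number of clusters
is chosen by the Integrated Completed Likelihood (ICL) criterion, a BIC
penalized further by the assignment entropy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = [
    "PoissonMixtureFit",
    "fit_mixture",
    "select_K",
    "interpret_clusters",
    "adjusted_rand_index",
]


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected agreement between two labelings."""
    from scipy.special import comb

    a, b = np.asarray(a), np.asarray(b)
    ct = pd.crosstab(a, b).to_numpy()
    n = len(a)
    sum_comb = comb(ct, 2).sum()
    sum_a = comb(ct.sum(axis=1), 2).sum()
    sum_b = comb(ct.sum(axis=0), 2).sum()
    expected = sum_a * sum_b / comb(n, 2)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0
    return float((sum_comb - expected) / (max_index - expected))


@dataclass
class PoissonMixtureFit:
    K: int
    pi: np.ndarray            # (K,)
    lam: np.ndarray           # (G, K), sum_g S_g lam_gk = 1
    s: np.ndarray             # (n_samples,) library-size proportions
    group_share: np.ndarray   # (G,) S_g
    groups: list              # group labels, order matches lam rows
    w: np.ndarray             # (n_features,) totals
    posterior: np.ndarray     # (n_features, K)
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = False

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]

    @property
    def n_params(self) -> int:
        return (self.K - 1) + self.K * (len(self.groups) - 1)

    @property
    def bic(self) -> float:
        return self.loglik - 0.5 * self.n_params * np.log(len(self.w))

    @property
    def entropy(self) -> float:
        t = self.posterior
        tl = np.zeros_like(t)
        mask = t > 0
        tl[mask] = t[mask] * np.log(t[mask])
        return float(tl.sum())

    @property
    def icl(self) -> float:
        return self.bic + self.entropy

    @property
    def labels(self) -> np.ndarray:
        return np.argmax(self.posterior, axis=1)


def _prepare(counts, groups):
    if isinstance(counts, pd.DataFrame):
        Y = counts.to_numpy(dtype=float)
        sample_groups = pd.Series(groups).reindex(counts.columns)
        if sample_groups.isna().any():
            raise ValueError("every sample needs a group label")
        glabels = list(sample_groups)
    else:
        Y = np.asarray(counts, dtype=float)
        glabels = list(groups)
    if (Y.sum(axis=1) == 0).any():
        raise ValueError("counts contain all-zero rows; filter first")
    uniq = sorted(set(glabels), key=str)
    gidx = np.array([uniq.index(g) for g in glabels])
    if len(uniq) < 1 or any((gidx == u).sum() == 0 for u in range(len(uniq))):
        raise ValueError("empty experimental group")
    return Y, uniq, gidx


def _loglik_and_post(Yg, w, pi, lam, const):
    """(loglik, posterior): Yg is (n, G) per-group sums."""
    log_lam = np.log(np.clip(lam, 1e-300, None))
    score = Yg @ log_lam + np.log(pi)[None, :]        # (n, K)
    norm = logsumexp(score, axis=1)
    post = np.exp(score - norm[:, None])
    return float(norm.sum() + const), post


def fit_mixture(
    counts,
    groups,
    K: int,
    init: np.ndarray | str = "small-em",
    tol: float = 1e-6,
    max_iter: int = 1000,
    n_init: int = 20,
    init_iters: int = 10,
    rng: np.random.Generator | int | None = None,
) -> PoissonMixtureFit:
    """EM fit of the K-cluster Poisson mixture.

    ``init`` is a (n_features, K) posterior matrix, or "small-em": from
    ``n_init`` random posteriors, run ``init_iters`` EM steps each and
    continue the best to convergence.  Convergence: relative log-likelihood
    change < tol.  The log-likelihood trace is non-decreasing (EM).
    """
    Y, uniq, gidx = _prepare(counts, groups)
    n, J = Y.shape
    G = len(uniq)
    if not 1 <= K <= n:
        raise ValueError(f"K={K} outside 1..n_features={n}")
    rng = np.random.default_rng(rng)

    w = Y.sum(axis=1)
    s = Y.sum(axis=0) / Y.sum()
    S = np.array([s[gidx == g].sum() for g in range(G)])
    Yg = np.stack([Y[:, gidx == g].sum(axis=1) for g in range(G)], axis=1)  # (n, G)
    # terms of the Poisson loglik constant in (pi, lambda):
    # sum_ij y_ij log(w_i s_j) - sum_i w_i - sum_ij log(y_ij!)
    const = float(
        (Y * np.log(np.outer(w, s))).sum() - w.sum() - gammaln(Y + 1).sum()
    )

    def m_step(t):
        pi = t.mean(axis=0)
        pi = np.clip(pi, 1e-12, None)
        pi /= pi.sum()
        denom = S[:, None] * (t * w[:, None]).sum(axis=0)[None, :]
        lam = (t.T @ Yg).T / np.clip(denom, 1e-300, None)
        return pi, lam

    def run_em(t0, iters, tol_):
        pi, lam = m_step(t0)
        trace: list[float] = []
        post = t0
        for _ in range(iters):
            ll, post = _loglik_and_post(Yg, w, pi, lam, const)
            trace.append(ll)
            if len(trace) > 1 and abs(trace[-1] - trace[-2]) <= tol_ * abs(trace[-2]):
                return pi, lam, post, trace, True
            pi, lam = m_step(post)
        ll, post = _loglik_and_post(Yg, w, pi, lam, const)
        trace.append(ll)
        return pi, lam, post, trace, False

    if isinstance(init, str):
        if K == 1:
            t0 = np.ones((n, 1))
        else:
            best_t0, best_ll = None, -np.inf
            for _ in range(n_init):
                t = rng.dirichlet(np.ones(K), size=n)
                _, _, post, trace, _ = run_em(t, init_iters, 0.0)
                if trace[-1] > best_ll:
                    best_ll, best_t0 = trace[-1], post
            t0 = best_t0
    else:
        t0 = np.asarray(init, dtype=float)
        if t0.shape != (n, K):
            raise ValueError("init posterior must be (n_features, K)")

    pi, lam, post, trace, conv = run_em(t0, max_iter, tol)
    return PoissonMixtureFit(
        K=K, pi=pi, lam=lam, s=s, group_share=S, groups=uniq, w=w,
        posterior=post, loglik_trace=trace, converged=conv,
    )


def select_K(
    counts,
    groups,
    K_range=range(1, 13),
    restarts: int = 5,
    rng: np.random.Generator | int | None = None,
    **fit_kw,
) -> tuple[int, dict[int, PoissonMixtureFit]]:
    """Best-of-restarts EM per K; K* maximizes ICL."""
    K_range = list(K_range)
    if not K_range:
        raise ValueError("empty K range")
    rng = np.random.default_rng(rng)
    fits: dict[int, PoissonMixtureFit] = {}
    for K in K_range:
        best = None
        for _ in range(restarts if K > 1 else 1):
            f = fit_mixture(counts, groups, K, rng=rng, **fit_kw)
            if best is None or f.loglik > best.loglik:
                best = f
        fits[K] = best
    K_star = max(fits, key=lambda K: fits[K].icl)
    return K_star, fits


def interpret_clusters(fit: PoissonMixtureFit) -> pd.DataFrame:
    """Per-cluster table of group read proportions S_g * lambda_gk.

    Each cluster's proportions sum to 1 over groups; also reports mixing
    proportions and MAP cluster sizes.
    """
    prop = fit.group_share[:, None] * fit.lam  # (G, K)
    table = pd.DataFrame(
        prop.T, columns=[str(g) for g in fit.groups],
        index=[f"cluster_{k + 1}" for k in range(fit.K)],
    )
    table["pi"] = fit.pi
    table["size_map"] = np.bincount(fit.labels, minlength=fit.K)
    return table
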