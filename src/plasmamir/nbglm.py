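"""Negative-binomial GLM differential abundance with likelihood-ratio tests.

Counts y_gj for feature g in library j are modeled as
NB(mean mu_gj = exp(x_j' beta_g + o_j), dispersion phi_g) with offsets
o_j = log(library size_j x TMM factor_j).  Dispersions are estimated by
maximizing the Cox-Reid adjusted profile likelihood (APL): a common phi
over all features, then per-feature ("tagwise") values shrunk toward the
common profile by weighted-likelihood averaging with a prior weight
equivalent to ``prior_n`` features.  Nested models are compared by the LRT
(D = 2 * delta log-likelihood ~ chi2), and p-values are BH-adjusted to
control the FDR at 5%.

The six study contrasts over the 2 (line) x 2 (feeding condition) design
are: Condition (RF vs FD), Line (R+ vs R-), Line within each condition and
Condition within each line (from a cell-means parameterization), plus the
line x condition interaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

__all__ = [
    "NbFit",
    "nb_loglik",
    "fit_nb_glm",
    "fit_nb_glm_many",
    "estimate_dispersions",
    "lrt_contrast",
    "adjust_bh",
    "logfc_cluster",
    "LogFcHeatmap",
    "build_designs",
    "run_differential",
    "CONTRASTS",
]

_MIN_PHI = 1e-10
_ETA_CLIP = 30.0


def nb_loglik(y: np.ndarray, mu: np.ndarray, phi: float | np.ndarray) -> np.ndarray:
    """Row-wise NB log-likelihood (phi -> 0 reduces to Poisson)."""
    y = np.atleast_2d(np.asarray(y, dtype=float))
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    phi = np.broadcast_to(np.asarray(phi, dtype=float), (y.shape[0],)).copy()
    out = np.empty(y.shape[0])
    pois = phi < _MIN_PHI
    if pois.any():
        m = mu[pois]
        out[pois] = np.sum(y[pois] * np.log(m) - m - gammaln(y[pois] + 1), axis=1)
    if (~pois).any():
        r = 1.0 / phi[~pois, None]
        m = mu[~pois]
        yy = y[~pois]
        out[~pois] = np.sum(
            gammaln(yy + r) - gammaln(r) - gammaln(yy + 1)
            + r * np.log(r / (r + m)) + yy * np.log(m / (r + m)),
            axis=1,
        )
    return out


@dataclass
class NbFit:
    beta: np.ndarray          # (G, p)
    loglik: np.ndarray        # (G,)
    mu: np.ndarray            # (G, n)
    converged: np.ndarray     # (G,) bool
    zero_fitted: np.ndarray   # (G,) bool: all-zero feature, zero-mean limit
    design: np.ndarray = field(repr=False, default=None)


def fit_nb_glm_many(
    Y: np.ndarray,
    X: np.ndarray,
    offset: np.ndarray,
    phi: float | np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> NbFit:
    """Batch IRLS maximum likelihood for many features sharing one design.

    Y is (G, n); X is (n, p); offset is (n,) or (G, n); phi scalar or (G,).
    Convergence: max |delta beta| < tol per feature, or ``max_iter``.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    X = np.asarray(X, dtype=float)
    G, n = Y.shape
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        # name the collinear columns for the caller
        _, R = np.linalg.qr(X)
        bad = [j for j in range(p) if abs(R[j, j]) < 1e-10]
        raise ValueError(f"design matrix is not full rank (columns {bad})")
    O = np.broadcast_to(np.asarray(offset, dtype=float), (G, n))
    phi_v = np.broadcast_to(np.asarray(phi, dtype=float), (G,)).copy()

    zero = Y.sum(axis=1) == 0
    beta = np.zeros((G, p))
    # init from a log-linear least squares fit
    z0 = np.log(Y + 0.5) - O
    beta = np.linalg.lstsq(X, z0.T, rcond=None)[0].T
    converged = np.zeros(G, dtype=bool)
    active = ~zero
    for _ in range(max_iter):
        if not active.any():
            break
        eta = np.clip(beta[active] @ X.T + O[active], -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta)
        W = mu / (1.0 + phi_v[active, None] * mu)
        z = eta + (Y[active] - mu) / mu
        A = np.einsum("ji,gj,jk->gik", X, W, X)
        b = np.einsum("ji,gj,gj->gi", X, W, z - O[active])
        try:
            new = np.linalg.solve(A, b[..., None])[..., 0]
        except np.linalg.LinAlgError:
            new = np.stack(
                [np.linalg.lstsq(A[g], b[g], rcond=None)[0] for g in range(A.shape[0])]
            )
        delta = np.abs(new - beta[active]).max(axis=1)
        beta[active] = new
        done = delta < tol
        idx = np.nonzero(active)[0]
        converged[idx[done]] = True
        active[idx[done]] = False
    if zero.any():
        # zero-mean limit: drive the linear predictor to the floor
        beta[zero] = np.linalg.lstsq(
            X, np.full(n, -_ETA_CLIP), rcond=None
        )[0]
        converged[zero] = True
    eta = np.clip(beta @ X.T + O, -_ETA_CLIP, _ETA_CLIP)
    mu = np.exp(eta)
    ll = nb_loglik(Y, mu, phi_v)
    return NbFit(beta=beta, loglik=ll, mu=mu, converged=converged,
                 zero_fitted=zero, design=X)


def fit_nb_glm(y, X, offset, phi, **kw) -> NbFit:
    """Single-feature convenience wrapper around :func:`fit_nb_glm_many`."""
    return fit_nb_glm_many(np.atleast_2d(y), X, offset, phi, **kw)


def _apl(Y, X, O, phi) -> np.ndarray:
    """Cox-Reid adjusted profile log-likelihood per feature at phi."""
    fit = fit_nb_glm_many(Y, X, O, phi)
    W = fit.mu / (1.0 + np.broadcast_to(phi, (Y.shape[0],))[:, None] * fit.mu)
    info = np.einsum("ji,gj,jk->gik", X, W, X)
    sign, logdet = np.linalg.slogdet(info)
    logdet = np.where(sign > 0, logdet, np.inf)
    return fit.loglik - 0.5 * logdet


def estimate_dispersions(
    counts: np.ndarray | pd.DataFrame,
    design: np.ndarray,
    offsets: np.ndarray,
    prior_n: float = 10.0,
    grid: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """(phi_common, phi_tagwise) by CR-APL over a dispersion grid.

    phi_common maximizes the summed APL; each tagwise value maximizes
    APL_g(phi) + prior_n * mean_APL(phi), shrinking per-feature estimates
    toward the common profile (prior weight = ``prior_n`` features).
    A parabolic refinement in log phi sharpens both argmaxima.
    """
    Y = counts.to_numpy(dtype=float) if isinstance(counts, pd.DataFrame) else np.asarray(counts, dtype=float)
    Y = np.atleast_2d(Y)
    G, n = Y.shape
    O = np.broadcast_to(np.asarray(offsets, dtype=float), (G, n))
    if grid is None:
        grid = np.concatenate([[1e-8], np.exp(np.linspace(np.log(1e-4), np.log(8.0), 24))])
    grid = np.asarray(grid, dtype=float)
    apl = np.stack([_apl(Y, design, O, phi) for phi in grid], axis=1)  # (G, S)

    def refine(values: np.ndarray) -> float:
        k = int(np.argmax(values))
        if k == 0 or k == len(grid) - 1:
            return float(grid[k])
        x = np.log(grid[k - 1: k + 2])
        v = values[k - 1: k + 2]
        denom = (x[1] - x[0]) * (v[1] - v[2]) - (x[1] - x[2]) * (v[1] - v[0])
        if denom == 0:
            return float(grid[k])
        vertex = -0.5 * (
            (x[1] - x[0]) ** 2 * (v[1] - v[2]) - (x[1] - x[2]) ** 2 * (v[1] - v[0])
        ) / denom
        xs = x[1] + np.clip(vertex, x[0] - x[1], x[2] - x[1])
        return float(np.exp(xs))

    phi_common = refine(apl.sum(axis=0))
    shared = apl.mean(axis=0)
    phi_tag = np.array([refine(apl[g] + prior_n * shared) for g in range(G)])
    return phi_common, phi_tag


def lrt_contrast(full: NbFit, reduced: NbFit, df: int) -> tuple[np.ndarray, np.ndarray]:
    """Likelihood-ratio test of nested fits: D = 2(ll_full - ll_reduced)."""
    Xf, Xr = full.design, reduced.design
    # nesting check: every reduced column must lie in the full column space
    resid = Xr - Xf @ np.linalg.lstsq(Xf, Xr, rcond=None)[0]
    if np.abs(resid).max() > 1e-8:
        raise ValueError("reduced design is not nested in the full design")
    D = 2.0 * (full.loglik - reduced.loglik)
    if (D < -1e-6).any():
        raise RuntimeError("LRT statistic significantly negative; fit failed")
    D = np.maximum(D, 0.0)
    return D, chi2.sf(D, df)


def adjust_bh(p: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted p-values and significance flags."""
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    _, adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return adj, adj <= alpha


# ---------------------------------------------------------------------------
# Study designs and contrasts

LINE_LEVELS = ("R-", "R+")
COND_LEVELS = ("FD", "RF")

# name -> (model, spec); "additive" contrasts drop one main-effect column,
# "cells" contrasts equate two cells of the 2x2 cell-means parameterization.
CONTRASTS: dict[str, dict] = {
    "RF_vs_FD": {"model": "additive", "drop": "condition",
                 "fc": ("RF", "FD")},
    "Rplus_vs_Rminus": {"model": "additive", "drop": "line",
                        "fc": ("R+", "R-")},
    "Rplus_vs_Rminus_RF": {"model": "cells", "cells": (("R+", "RF"), ("R-", "RF"))},
    "Rplus_vs_Rminus_FD": {"model": "cells", "cells": (("R+", "FD"), ("R-", "FD"))},
    "RF_vs_FD_Rminus": {"model": "cells", "cells": (("R-", "RF"), ("R-", "FD"))},
    "RF_vs_FD_Rplus": {"model": "cells", "cells": (("R+", "RF"), ("R+", "FD"))},
}


def build_designs(meta: pd.DataFrame) -> dict[str, np.ndarray]:
    """Design matrices for the 2x2 study from per-sample metadata.

    ``meta`` needs 'line' (R-/R+) and 'condition' (FD/RF) columns.  Returns
    the additive model (intercept, line R+, condition RF), its two reduced
    forms, and the cell-means model with its four columns ordered as
    ``cells`` labels.
    """
    line = meta["line"].astype(str).to_numpy()
    cond = meta["condition"].astype(str).to_numpy()
    n = len(meta)
    ones = np.ones(n)
    x_line = (line == "R+").astype(float)
    x_cond = (cond == "RF").astype(float)
    cells = [(l, c) for l in LINE_LEVELS for c in COND_LEVELS]
    X_cells = np.stack(
        [((line == l) & (cond == c)).astype(float) for l, c in cells], axis=1
    )
    if (X_cells.sum(axis=0) == 0).any():
        raise ValueError("every line x condition cell needs at least one sample")
    return {
        "additive": np.stack([ones, x_line, x_cond], axis=1),
        "additive_no_condition": np.stack([ones, x_line], axis=1),
        "additive_no_line": np.stack([ones, x_cond], axis=1),
        "cells": X_cells,
        "cell_labels": cells,
    }


def _merge_cells(X_cells: np.ndarray, labels, a, b) -> np.ndarray:
    """Reduced cell-means design equating cells a and b."""
    ia, ib = labels.index(a), labels.index(b)
    keep = [j for j in range(X_cells.shape[1]) if j not in (ia, ib)]
    merged = X_cells[:, ia] + X_cells[:, ib]
    return np.column_stack([X_cells[:, keep], merged])


def run_differential(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    factors: pd.Series | None = None,
    alpha: float = 0.05,
    prior_n: float = 10.0,
) -> dict:
    """The six-contrast NB-GLM analysis on a filtered count matrix.

    Returns per-contrast result frames (log2FC, D, p, adjusted p, flag),
    the interaction test, dispersions, and a Table-1-style flag matrix.
    """
    from .normalization import tmm_factors

    meta = meta.loc[counts.columns]
    if factors is None:
        factors = tmm_factors(counts)
    lib = counts.sum(axis=0).astype(float)
    offsets = np.log(lib.to_numpy() * np.asarray(factors, dtype=float))
    Y = counts.to_numpy(dtype=float)
    d = build_designs(meta)
    labels = d["cell_labels"]

    phi_common, phi_tag = estimate_dispersions(Y, d["cells"], offsets, prior_n)

    fits: dict[str, NbFit] = {}
    for key in ("additive", "additive_no_condition", "additive_no_line", "cells"):
        fits[key] = fit_nb_glm_many(Y, d[key], offsets, phi_tag)

    # prior-shifted normalized group means, for log2FC reporting on zero cells
    norm = Y / np.exp(offsets)[None, :]
    cell_means = {
        lab: norm[:, d["cells"][:, j] == 1].mean(axis=1)
        for j, lab in enumerate(labels)
    }
    ln2 = np.log(2.0)

    results: dict[str, pd.DataFrame] = {}
    for name, spec in CONTRASTS.items():
        if spec["model"] == "additive":
            full = fits["additive"]
            reduced = fits["additive_no_" + spec["drop"]]
            coef_idx = 2 if spec["drop"] == "condition" else 1
            lfc = full.beta[:, coef_idx] / ln2
            if spec["drop"] == "condition":
                m_a = (cell_means[("R-", "RF")] + cell_means[("R+", "RF")]) / 2
                m_b = (cell_means[("R-", "FD")] + cell_means[("R+", "FD")]) / 2
            else:
                m_a = (cell_means[("R+", "FD")] + cell_means[("R+", "RF")]) / 2
                m_b = (cell_means[("R-", "FD")] + cell_means[("R-", "RF")]) / 2
        else:
            a, b = spec["cells"]
            full = fits["cells"]
            reduced_X = _merge_cells(d["cells"], labels, a, b)
            reduced = fit_nb_glm_many(Y, reduced_X, offsets, phi_tag)
            lfc = (full.beta[:, labels.index(a)] - full.beta[:, labels.index(b)]) / ln2
            m_a, m_b = cell_means[a], cell_means[b]
        degenerate = (m_a == 0) | (m_b == 0) | ~np.isfinite(lfc)
        lfc = np.where(
            degenerate, np.log2((m_a + 0.125) / (m_b + 0.125)), lfc
        )
        D, p = lrt_contrast(full, reduced, df=1)
        adj, flag = adjust_bh(p, alpha)
        results[name] = pd.DataFrame(
            {"log2FC": lfc, "D": D, "p": p, "p_adj": adj, "significant": flag},
            index=counts.index,
        )

    D_int, p_int = lrt_contrast(fits["cells"], fits["additive"], df=1)
    adj_int, flag_int = adjust_bh(p_int, alpha)
    interaction = pd.DataFrame(
        {"D": D_int, "p": p_int, "p_adj": adj_int, "significant": flag_int},
        index=counts.index,
    )

    flag_matrix = pd.DataFrame(
        {name: res["significant"] for name, res in results.items()},
        index=counts.index,
    )
    return {
        "contrasts": results,
        "interaction": interaction,
        "flags": flag_matrix,
        "phi_common": phi_common,
        "phi_tagwise": phi_tag,
        "factors": np.asarray(factors, dtype=float),
        "log2fc_matrix": pd.DataFrame(
            {name: res["log2FC"] for name, res in results.items()},
            index=counts.index,
        ),
    }


# ---------------------------------------------------------------------------
# log-fold-change heatmap clustering


@dataclass
class LogFcHeatmap:
    matrix: pd.DataFrame
    row_linkage: np.ndarray
    col_linkage: np.ndarray | None

    @property
    def row_order(self):
        from scipy.cluster.hierarchy import leaves_list

        return list(self.matrix.index[leaves_list(self.row_linkage)])

    def to_tsv(self, path) -> None:
        self.matrix.to_csv(path, sep="\t")

    def plot(self, path) -> None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from scipy.cluster.hierarchy import leaves_list

        order = leaves_list(self.row_linkage)
        m = self.matrix.iloc[order]
        if self.col_linkage is not None:
            m = m.iloc[:, leaves_list(self.col_linkage)]
        fig, ax = plt.subplots(figsize=(6, max(3, 0.18 * len(m))))
        v = np.nanmax(np.abs(m.to_numpy())) or 1.0
        im = ax.imshow(m.to_numpy(), aspect="auto", cmap="RdBu_r", vmin=-v, vmax=v)
        ax.set_xticks(range(m.shape[1]), m.columns, rotation=45, ha="right")
        ax.set_yticks(range(m.shape[0]), m.index, fontsize=5)
        fig.colorbar(im, ax=ax, label="log2 fold change")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def logfc_cluster(matrix: pd.DataFrame) -> LogFcHeatmap:
    """Complete-linkage, Euclidean-distance clustering of rows and columns."""
    from scipy.cluster.hierarchy import linkage

    X = matrix.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("log2FC matrix must be finite")
    row_l = linkage(X, method="complete", metric="euclidean")
    col_l = linkage(X.T, method="complete", metric="euclidean") if X.shape[1] > 1 else None
    return LogFcHeatmap(matrix=matrix, row_linkage=row_l, col_linkage=col_l)
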