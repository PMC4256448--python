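"""qPCR validation statistics: -dCt abundance, intra-animal consensus
correlation, GLS fixed-effect models, and empirical-Bayes moderated t.

Abundance is quantified as -dCt = -(Ct_target - Ct_reference), a log2-scale
relative measure (one cycle lower Ct = twice the template).  For plasma,
each animal is measured in both feeding conditions, so a per-animal random
intercept induces correlation between its two measurements; that
correlation is summarized across miRNAs by a consensus value rho and
absorbed into a generalized-least-squares fit of the fixed line, feeding
and batch effects.  Residual variances are shrunk toward a common prior by
moment-matching on log s^2 (digamma/trigamma inversion), giving moderated
t-statistics with d0 + d_g degrees of freedom.  Liver mode drops the
animal and batch terms (different animals per condition, single batch).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist

from .nbglm import adjust_bh

__all__ = [
    "delta_ct",
    "consensus_correlation",
    "squeeze_var",
    "fit_moderated",
    "QpcrFit",
]

MAX_D0 = 200.0
MAX_RHO = 0.99


def delta_ct(
    records: pd.DataFrame,
    reference: str = "reference_ct",
) -> pd.DataFrame:
    """-dCt abundance table (miRNA x sample) from long-format Ct records.

    ``records`` columns: mirna, animal, line, condition, batch (optional),
    ct, and a reference column.  ``reference`` names the reference-assay Ct
    column, or "global-mean" to use each sample's mean Ct over miRNAs.
    Technical replicates are averaged on the Ct scale first.  Samples are
    (animal, condition) pairs labelled "<animal>:<condition>".
    """
    rec = records.copy()
    if (~np.isfinite(rec["ct"])).any() or (rec["ct"] <= 0).any():
        raise ValueError("Ct values must be finite and positive")
    rec["sample"] = rec["animal"].astype(str) + ":" + rec["condition"].astype(str)
    keys = ["mirna", "sample"]
    if reference == "global-mean":
        ct = rec.groupby(keys)["ct"].mean().unstack("sample")
        ref = ct.mean(axis=0)
        return -(ct - ref)
    if reference not in rec.columns:
        raise KeyError(f"reference column {reference!r} not found")
    grouped = rec.groupby(keys)[["ct", reference]].mean()
    missing = grouped[reference].isna()
    if missing.any():
        warnings.warn(
            f"{int(missing.sum())} records dropped: missing reference Ct",
            stacklevel=2,
        )
        grouped = grouped[~missing]
    ct = grouped["ct"].unstack("sample")
    ref = grouped[reference].unstack("sample")
    return -(ct - ref)


def _sample_meta(records: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in ("animal", "line", "condition", "batch") if c in records]
    meta = records.assign(
        sample=records["animal"].astype(str) + ":" + records["condition"].astype(str)
    )[["sample"] + cols].drop_duplicates("sample").set_index("sample")
    return meta


def _fixed_design(meta: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Intercept + line + condition (+ batch) indicators; single-level
    batch columns are dropped automatically."""
    n = len(meta)
    cols = [np.ones(n)]
    names = ["intercept"]
    preferred = {"line": ["R-", "R+"], "condition": ["FD", "RF"]}
    for var in ("line", "condition", "batch"):
        if var not in meta.columns:
            continue
        levels = sorted(meta[var].astype(str).unique())
        if var in preferred and set(levels) <= set(preferred[var]):
            levels = [l for l in preferred[var] if l in levels]
        for lev in levels[1:]:
            cols.append((meta[var].astype(str) == lev).to_numpy(float))
            names.append(f"{var}[{lev}]")
    return np.stack(cols, axis=1), names


def consensus_correlation(
    abundance: pd.DataFrame,
    meta: pd.DataFrame,
    blocks: str = "animal",
) -> float:
    """Consensus intra-block (intra-animal) correlation across miRNAs.

    Per miRNA, a single-random-intercept model is fitted by REML
    (statsmodels MixedLM; a paired-residual moment estimate is the fallback
    when REML fails) and the ICC sigma_a^2/(sigma_a^2+sigma_e^2) extracted;
    the consensus is tanh(mean(atanh(.))) with estimates capped at 0.99.
    Returns 0 with a warning when no block repeats exist.
    """
    meta = meta.loc[abundance.columns]
    block = meta[blocks].astype(str)
    if block.value_counts().max() < 2:
        warnings.warn("no repeated blocks; using fixed-effects mode (rho = 0)",
                      stacklevel=2)
        return 0.0
    X, _ = _fixed_design(meta.drop(columns=[blocks], errors="ignore"))
    rhos = []
    for _, y in abundance.iterrows():
        yv = y.to_numpy(float)
        rho = _icc_reml(yv, X, block.to_numpy())
        if rho is None:
            rho = _icc_moment(yv, X, block.to_numpy())
        rhos.append(min(max(rho, -MAX_RHO), MAX_RHO))
    return float(np.tanh(np.mean(np.arctanh(rhos))))


def _icc_reml(y: np.ndarray, X: np.ndarray, block: np.ndarray) -> float | None:
    import statsmodels.api as sm

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MixedLM(y, X, groups=block).fit(reml=True, method="lbfgs")
        va = float(np.asarray(res.cov_re).ravel()[0])
        ve = float(res.scale)
        if not np.isfinite(va) or not np.isfinite(ve) or va + ve <= 0:
            return None
        return va / (va + ve)
    except Exception:
        return None


def _icc_moment(y: np.ndarray, X: np.ndarray, block: np.ndarray) -> float:
    """Moment ICC from within-block products of OLS residuals."""
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ beta
    tot = float(r @ r / max(len(y) - X.shape[1], 1)) or 1.0
    prods = []
    for b in np.unique(block):
        rb = r[block == b]
        for i in range(len(rb)):
            for j in range(i + 1, len(rb)):
                prods.append(rb[i] * rb[j])
    if not prods:
        return 0.0
    return float(np.mean(prods) / tot)


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (y > 0)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = float(polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def squeeze_var(s2: np.ndarray, df: np.ndarray | float) -> tuple[float, float, np.ndarray]:
    """Empirical-Bayes variance shrinkage: (d0, s0^2, posterior s2).

    Moment-matching on z = log s^2: with s^2 ~ s0^2 * F(d, d0),
    E[z] and Var[z] involve digamma/trigamma of d/2 and d0/2; inverting the
    trigamma relation yields d0, then s0^2.  d0 is capped at ``MAX_D0``
    (effectively full pooling); the posterior value is the
    degrees-of-freedom-weighted combination (d0 s0^2 + d s^2)/(d0 + d).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    if s2.size < 2:
        warnings.warn("fewer than 2 variances; no moderation (d0 = 0)", stacklevel=2)
        return 0.0, float(s2.mean()) if s2.size else 0.0, s2.copy()
    z = np.log(np.clip(s2, 1e-300, None))
    e = z - digamma(df / 2) + np.log(df / 2)
    emean = float(e.mean())
    evar = float(np.var(e, ddof=1)) - float(np.mean(polygamma(1, df / 2)))
    if evar <= 0:
        d0 = MAX_D0
    else:
        d0 = min(2.0 * trigamma_inverse(evar), MAX_D0)
    s02 = float(np.exp(emean + digamma(d0 / 2) - np.log(d0 / 2)))
    post = (d0 * s02 + df * s2) / (d0 + df)
    return float(d0), s02, post


@dataclass
class QpcrFit:
    coefficients: pd.DataFrame    # miRNA x coefficient
    stderr: pd.DataFrame
    s2: pd.Series                 # residual variances
    df_residual: pd.Series
    d0: float
    s02: float
    s2_post: pd.Series
    rho: float
    tests: dict[str, pd.DataFrame]  # contrast -> (coef, t, p, p_adj, flag)


def fit_moderated(
    abundance: pd.DataFrame,
    meta: pd.DataFrame,
    rho: float | None = None,
    contrasts: tuple[str, ...] = ("line", "condition"),
    blocks: str = "animal",
    alpha: float = 0.05,
    d0_override: float | None = None,
) -> QpcrFit:
    """Moderated-t analysis of a -dCt table.

    Per miRNA: GLS with the exchangeable within-animal correlation implied
    by ``rho`` (estimated via :func:`consensus_correlation` when None),
    then variance shrinkage across miRNAs and moderated t per contrast
    coefficient, BH-adjusted across miRNAs.  ``d0_override=0`` reproduces
    ordinary (unmoderated) GLS t-tests.
    """
    meta = meta.loc[abundance.columns]
    use_blocks = blocks in meta.columns
    if rho is None:
        rho = consensus_correlation(abundance, meta, blocks) if use_blocks else 0.0
    X, names = _fixed_design(meta.drop(columns=[blocks], errors="ignore"))
    n, p = X.shape
    if n <= p:
        raise ValueError("more coefficients than samples")

    # whitening transform for the block-exchangeable correlation
    if use_blocks and rho != 0.0:
        block = meta[blocks].astype(str).to_numpy()
        R = (block[:, None] == block[None, :]).astype(float) * rho
        np.fill_diagonal(R, 1.0)
        L = np.linalg.cholesky(R)
        Linv = np.linalg.inv(L)
    else:
        Linv = np.eye(n)
    Xw = Linv @ X
    XtX_inv = np.linalg.inv(Xw.T @ Xw)

    coefs, ses, s2s = [], [], []
    for _, y in abundance.iterrows():
        yw = Linv @ y.to_numpy(float)
        beta = XtX_inv @ Xw.T @ yw
        resid = yw - Xw @ beta
        s2 = float(resid @ resid) / (n - p)
        coefs.append(beta)
        s2s.append(s2)
        ses.append(np.sqrt(np.diag(XtX_inv)))  # unit-variance SE; scaled below
    coefs = pd.DataFrame(coefs, index=abundance.index, columns=names)
    unit_se = pd.DataFrame(ses, index=abundance.index, columns=names)
    s2 = pd.Series(s2s, index=abundance.index, name="s2")
    df_res = pd.Series(float(n - p), index=abundance.index, name="df")

    if d0_override is not None:
        d0 = float(d0_override)
        if d0 == 0.0:
            s02, s2_post = float("nan"), s2.copy()
        else:
            _, s02, _ = squeeze_var(s2.to_numpy(), n - p)
            s2_post = (d0 * s02 + (n - p) * s2) / (d0 + (n - p))
    else:
        d0, s02, post = squeeze_var(s2.to_numpy(), n - p)
        s2_post = pd.Series(post, index=abundance.index)

    tests: dict[str, pd.DataFrame] = {}
    for contrast in contrasts:
        matches = [c for c in names if c.startswith(contrast + "[")]
        if not matches:
            continue
        col = matches[0]
        tval = coefs[col] / (unit_se[col] * np.sqrt(s2_post))
        df_t = d0 + (n - p)
        pval = 2.0 * t_dist.sf(np.abs(tval), df_t)
        adj, flag = adjust_bh(pval, alpha)
        tests[contrast] = pd.DataFrame(
            {
                "coef": coefs[col],
                "t": tval,
                "df": df_t,
                "p": pval,
                "p_adj": adj,
                "significant": flag,
            },
            index=abundance.index,
        )
    return QpcrFit(
        coefficients=coefs,
        stderr=unit_se.mul(np.sqrt(s2), axis=0),
        s2=s2,
        df_residual=df_res,
        d0=d0,
        s02=s02,
        s2_post=pd.Series(np.asarray(s2_post), index=abundance.index),
        rho=float(rho),
        tests=tests,
    )
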