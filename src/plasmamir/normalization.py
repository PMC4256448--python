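"""Between-sample normalization for count matrices.

Trimmed mean of M-values (TMM): each sample's factor is a doubly-trimmed,
precision-weighted mean of per-feature log2 ratios against a reference
sample, so that composition differences (a few very abundant features
soaking up sequencing depth) do not masquerade as global shifts.  Factors
are rescaled to geometric mean 1; effective library size = depth x factor.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["tmm_factors", "normalized_counts"]


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_M: float,
    trim_A: float,
) -> float:
    """log2 TMM factor of one sample against the reference."""
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        return 0.0
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    p, q = obs / lib_obs, ref / lib_ref
    M = np.log2(p / q)
    A = 0.5 * np.log2(p * q)
    # asymptotic (delta-method) variance of M; weights are its inverse
    v = (lib_obs - obs) / (lib_obs * obs) + (lib_ref - ref) / (lib_ref * ref)
    n = len(M)
    loM = np.floor(n * trim_M) + 1
    hiM = n + 1 - loM
    loA = np.floor(n * trim_A) + 1
    hiA = n + 1 - loA
    rM, rA = rankdata(M), rankdata(A)
    keep2 = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
    if not keep2.any() or v[keep2].sum() == 0:
        return 0.0
    f = np.sum(M[keep2] / v[keep2]) / np.sum(1.0 / v[keep2])
    return 0.0 if not np.isfinite(f) else float(f)


def tmm_factors(
    counts: pd.DataFrame | np.ndarray,
    trim_M: float = 0.30,
    trim_A: float = 0.05,
    ref_column: int | str | None = None,
) -> pd.Series | np.ndarray:
    """Per-sample TMM normalization factors, geometric mean 1.

    Columns are samples.  The reference sample is the highest-depth column
    unless ``ref_column`` names one.  Raises on all-zero samples.
    """
    is_df = isinstance(counts, pd.DataFrame)
    X = counts.to_numpy(dtype=float) if is_df else np.asarray(counts, dtype=float)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need a features x samples matrix with >= 2 samples")
    lib = X.sum(axis=0)
    if (lib == 0).any():
        bad = np.nonzero(lib == 0)[0]
        raise ValueError(f"sample(s) with all-zero counts: {bad.tolist()}")
    if ref_column is None:
        ref_idx = int(np.argmax(lib))
    elif is_df and isinstance(ref_column, str):
        ref_idx = counts.columns.get_loc(ref_column)
    else:
        ref_idx = int(ref_column)
    logf = np.array(
        [
            _tmm_pair(X[:, j], X[:, ref_idx], lib[j], lib[ref_idx], trim_M, trim_A)
            for j in range(X.shape[1])
        ]
    )
    f = 2.0 ** logf
    f /= np.exp(np.mean(np.log(f)))
    if is_df:
        return pd.Series(f, index=counts.columns, name="tmm_factor")
    return f


def normalized_counts(
    counts: pd.DataFrame, factors: pd.Series | None = None
) -> pd.DataFrame:
    """Counts rescaled to a common effective depth.

    Each column is divided by (library size x TMM factor) and multiplied by
    the mean library size, keeping values on a count-like scale.
    """
    if factors is None:
        factors = tmm_factors(counts)
    lib = counts.sum(axis=0).astype(float)
    eff = lib * np.asarray(factors, dtype=float)
    return counts / eff * lib.mean()
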