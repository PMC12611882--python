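"""Shared statistical primitives used across the analysis modules.

Everything here is deliberately small and heavily exercised by the test
suite: Benjamini–Hochberg q-values (the single FDR routine shared by the
pQTL, differential-expression and motif modules) and a NaN-aware row-wise
simple-regression engine used by the genome scan and the trait-association
step.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_qvalues", "row_ols", "ols_line"]


def bh_qvalues(pvalues) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (q-values).

    NaN entries are passed through untouched and do not count toward the
    number of tests. q >= p always; q is monotone nondecreasing in p and
    invariant to the order of the input.
    """
    p = np.asarray(pvalues, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


def row_ols(Y, x, min_n: int = 4):
    """Simple OLS of every row of ``Y`` on the vector ``x``, NaN-aware.

    For each row the regression uses the complete cases of that row only.
    Rows with fewer than ``min_n`` complete cases, or whose complete-case
    predictor is constant (e.g. a marker monomorphic within the observed
    strains), come back as NaN.

    Returns a dict of arrays: beta, intercept, se, t, p, n, r2.
    A perfect fit yields t = +/-inf and p = 0.
    """
    Y = np.asarray(Y, dtype=float)
    x = np.asarray(x, dtype=float)
    if Y.ndim == 1:
        Y = Y[None, :]
    mask = np.isfinite(Y) & np.isfinite(x)[None, :]
    n = mask.sum(axis=1).astype(float)
    Ym = np.where(mask, Y, 0.0)
    xm = np.where(np.isfinite(x), x, 0.0)

    sx = mask @ xm
    sxx = mask @ (xm * xm)
    sy = Ym.sum(axis=1)
    sxy = Ym @ xm
    syy = (Ym * Ym).sum(axis=1)

    with np.errstate(divide="ignore", invalid="ignore"):
        vx = sxx - sx * sx / n            # sum (x - xbar)^2 over the mask
        cxy = sxy - sx * sy / n
        vy = syy - sy * sy / n
        beta = cxy / vx
        intercept = (sy - beta * sx) / n
        sse = np.clip(vy - beta * cxy, 0.0, None)
        df = n - 2
        sigma2 = sse / df
        se = np.sqrt(sigma2 / vx)
        t = beta / se
        # perfect fit: sse == 0 -> se == 0 -> t = +/-inf, p = 0
        # (a constant response is not a fit; it is flagged invalid below)
        exact = (se == 0) & np.isfinite(beta) & (vy > 0)
        t[exact] = np.sign(beta[exact]) * np.inf
        p = 2.0 * stats.t.sf(np.abs(t), np.maximum(df, 1))
        p[exact] = 0.0
        r2 = np.where(vy > 0, cxy * cxy / (vx * vy), np.nan)

    bad = (n < min_n) | (vx <= 0) | (vy <= 0) | (df < 1)
    for arr in (beta, intercept, se, t, p, r2):
        arr[bad] = np.nan
    return {
        "beta": beta,
        "intercept": intercept,
        "se": se,
        "t": t,
        "p": p,
        "n": n.astype(int),
        "r2": r2,
    }


def ols_line(x, y):
    """Slope/intercept/R^2/p of a single simple regression (complete cases).

    Thin convenience wrapper around :func:`row_ols` for 1-D inputs.
    """
    res = row_ols(np.asarray(y, dtype=float)[None, :], x, min_n=3)
    return {k: (v[0] if isinstance(v, np.ndarray) else v) for k, v in res.items()}
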