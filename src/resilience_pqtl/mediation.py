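"""PCA over the resilience-associated protein module and Baron-Kenny
mediation of genotype -> module PC1 -> resilience.

The module proteins are strongly co-regulated, so regressing the trait
on them jointly would be collinear; the first principal component of the
z-scored module serves as a single, collinearity-free mediator. The
mediation model is three OLS fits on strain-level data:

    M ~ X          -> a          (genotype -> mediator)
    Y ~ X + M      -> c', b      (direct effect, mediator -> trait)
    Y ~ X          -> c          (total effect)

with the OLS identity c = c' + a*b holding exactly on complete-case
data. Uncertainty of the indirect effect a*b comes from a stratified
(by genotype) case-resampling bootstrap of strains with
bias-corrected-and-accelerated (BCa) confidence intervals; the
acceleration constant is estimated by a leave-one-strain-out jackknife.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)

__all__ = ["module_pca", "mediate", "ModulePCA", "MediationResult"]


@dataclass
class ModulePCA:
    loadings: pd.DataFrame          # proteins x components (orthonormal)
    scores: pd.DataFrame            # strains x components
    variance_fractions: np.ndarray  # sums to 1

    @property
    def pc1(self) -> pd.Series:
        return self.scores["PC1"]


def module_pca(module: pd.DataFrame) -> ModulePCA:
    """PCA of a strain x protein module matrix.

    Each protein is z-scored across strains (so the decomposition is of
    the correlation structure), strains with any missing value are
    dropped, and the PC1 sign is fixed so the mean loading is positive —
    higher PC1 then means "module high" for the majority-sign members.
    """
    complete = module.dropna(axis=0)
    if complete.shape[0] < 3:
        raise ValueError("need >= 3 complete strains for PCA")
    if complete.shape[1] < 2:
        raise ValueError("need >= 2 module proteins for PCA")
    sd = complete.std(ddof=1)
    if (sd == 0).any():
        bad = sd.index[sd == 0][0]
        raise ValueError(f"zero-variance protein in module: {bad!r}")
    Z = (complete - complete.mean()) / sd
    U, s, Vt = np.linalg.svd(Z.to_numpy(dtype=float), full_matrices=False)
    frac = s ** 2 / (s ** 2).sum()
    loadings = Vt.T
    scores = U * s
    if loadings[:, 0].mean() < 0:
        loadings[:, 0] *= -1
        scores[:, 0] *= -1
    names = [f"PC{i + 1}" for i in range(len(s))]
    return ModulePCA(
        loadings=pd.DataFrame(loadings, index=complete.columns, columns=names),
        scores=pd.DataFrame(scores, index=complete.index, columns=names),
        variance_fractions=frac,
    )


@dataclass
class MediationResult:
    a: float
    b: float
    c_total: float
    c_direct: float
    indirect: float
    ci_lower: float
    ci_upper: float
    p_indirect: float
    n: int
    n_boot: int
    seed: int | None
    ci_method: str = "bca"
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in
             ("a", "b", "c_total", "c_direct", "indirect", "ci_lower",
              "ci_upper", "p_indirect", "n", "n_boot", "seed", "ci_method")}
        d["diagnostics"] = self.diagnostics
        return d


def _paths(X: np.ndarray, M: np.ndarray, Y: np.ndarray):
    """Closed-form OLS paths for 1-D or batched (replicates x n) inputs."""
    X = np.atleast_2d(X)
    M = np.atleast_2d(M)
    Y = np.atleast_2d(Y)
    n = X.shape[1]
    xc = X - X.mean(axis=1, keepdims=True)
    mc = M - M.mean(axis=1, keepdims=True)
    yc = Y - Y.mean(axis=1, keepdims=True)
    sxx = (xc * xc).sum(axis=1)
    smm = (mc * mc).sum(axis=1)
    sxm = (xc * mc).sum(axis=1)
    sxy = (xc * yc).sum(axis=1)
    smy = (mc * yc).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = sxm / sxx
        c = sxy / sxx
        det = sxx * smm - sxm * sxm
        c_dir = (smm * sxy - sxm * smy) / det
        b = (sxx * smy - sxm * sxy) / det
    return a, b, c, c_dir


def _bca_interval(boot: np.ndarray, z0: float, accel: float,
                  level: float = 0.95) -> tuple[float, float]:
    """BCa quantiles of a bootstrap sample given bias and acceleration.

    With z0 = 0 and accel = 0 this is exactly the percentile interval.
    """
    alpha = (1.0 - level) / 2.0
    lo_z = z0 + (z0 + norm.ppf(alpha)) / (1.0 - accel * (z0 + norm.ppf(alpha)))
    hi_z = z0 + (z0 + norm.ppf(1 - alpha)) / (1.0 - accel * (z0 + norm.ppf(1 - alpha)))
    lo_q, hi_q = norm.cdf(lo_z), norm.cdf(hi_z)
    return float(np.quantile(boot, lo_q)), float(np.quantile(boot, hi_q))


def mediate(x: pd.Series, m: pd.Series, y: pd.Series, n_boot: int = 1000,
            seed: int | None = None, level: float = 0.95) -> MediationResult:
    """Mediation of a genotype code through a module score to the trait.

    ``x``: per-strain genotype code at a marker (0/1); ``m``: mediator
    (PC1 score); ``y``: strain-mean resilience. Complete-case strains
    only (the count is reported). The bootstrap resamples strains within
    each genotype group so every replicate keeps the marker polymorphic;
    the two-sided bootstrap p-value for the indirect effect is floored at
    1/(n_boot + 1).
    """
    df = pd.DataFrame({"x": x, "m": m, "y": y}).dropna()
    n = len(df)
    if n < 6:
        raise ValueError("need >= 6 complete strains for mediation")
    X = df["x"].to_numpy(dtype=float)
    M = df["m"].to_numpy(dtype=float)
    Y = df["y"].to_numpy(dtype=float)
    if np.ptp(X) == 0:
        raise ValueError("marker monomorphic after complete-case filtering")

    a, b, c, c_dir = (v[0] for v in _paths(X, M, Y))
    indirect = a * b

    rng = np.random.default_rng(seed)
    g0 = np.flatnonzero(X == X.min())
    g1 = np.flatnonzero(X != X.min())
    i0 = g0[rng.integers(0, len(g0), size=(n_boot, len(g0)))]
    i1 = g1[rng.integers(0, len(g1), size=(n_boot, len(g1)))]
    idx = np.concatenate([i0, i1], axis=1)
    ab_boot, bb, _, _ = _paths(X[idx], M[idx], Y[idx])
    boot = ab_boot * bb
    boot = boot[np.isfinite(boot)]
    if boot.size < n_boot // 2:
        raise ValueError("bootstrap degenerate: most replicates undefined")

    # two-sided bootstrap p for the indirect effect
    p_lo = np.mean(boot <= 0.0)
    p_hi = np.mean(boot >= 0.0)
    p_ind = max(2.0 * min(p_lo, p_hi), 1.0 / (n_boot + 1.0))

    # BCa: bias from the bootstrap distribution, acceleration by jackknife
    method = "bca"
    prop = np.mean(boot < indirect)
    if boot.min() == boot.max() or prop in (0.0, 1.0):
        warnings.warn("degenerate bootstrap distribution; falling back to "
                      "percentile interval")
        method = "percentile"
        lo, hi = (float(np.quantile(boot, (1 - level) / 2)),
                  float(np.quantile(boot, 1 - (1 - level) / 2)))
    else:
        z0 = norm.ppf(prop)
        accel = 0.0
        if min(len(g0), len(g1)) >= 2:   # delete-1 keeps the marker polymorphic
            jack = np.empty(n)
            for i in range(n):
                keep = np.delete(np.arange(n), i)
                ja, jb, _, _ = _paths(X[keep], M[keep], Y[keep])
                jack[i] = ja[0] * jb[0]
            jm = jack.mean()
            num = ((jm - jack) ** 3).sum()
            den = 6.0 * (((jm - jack) ** 2).sum()) ** 1.5
            if den > 0 and np.isfinite(num):
                accel = num / den
        lo, hi = _bca_interval(boot, z0, accel, level)

    return MediationResult(
        a=float(a), b=float(b), c_total=float(c), c_direct=float(c_dir),
        indirect=float(indirect), ci_lower=lo, ci_upper=hi,
        p_indirect=float(min(p_ind, 1.0)), n=n, n_boot=n_boot, seed=seed,
        ci_method=method,
        diagnostics={
            "n_bb": int(len(g0)), "n_bd": int(len(g1)),
            "boot_used": int(boot.size),
            "decomposition_gap": float(c - (c_dir + a * b)),
        },
    )
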