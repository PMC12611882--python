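"""Differential expression against the resilience trait and between
genotype groups.

Two designs:

* ``trait_association`` — per protein, OLS of strain-level abundance on
  the strain-mean resilience trait; the beta coefficient carries the
  strength and direction of association, with BH FDR over the tested set
  (typically the pQTL-significant proteins when chained after the scan).
* ``stratified_de`` — strains stratified by genotype at one marker
  (homozygous B/B vs heterozygous B/D); log2 fold change is
  mean(BB) - mean(BD), tested with an empirical-Bayes moderated t: each
  protein's sample variance is shrunk toward a pooled prior whose degrees
  of freedom and scale are estimated by moment matching on the observed
  distribution of per-protein sample variances (a scaled inverse
  chi-square compound model). An ``ordinary`` escape hatch skips the
  shrinkage.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_qvalues, row_ols
from .containers import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["trait_association", "stratified_de", "fit_variance_prior"]


def trait_association(values: pd.DataFrame, trait: pd.Series,
                      fdr: float = 0.05) -> pd.DataFrame:
    """Per-protein regression of strain-level abundance on the trait.

    ``values``: protein x strain; ``trait``: per-strain resilience.
    Proteins with constant abundance or fewer than 4 complete strains are
    skipped (NaN statistics, logged). BH q-values span exactly the tested
    set, so chaining after a pQTL filter keeps the FDR universe honest.
    """
    shared = [s for s in values.columns if s in trait.index]
    if len(shared) < 4:
        raise ValueError("need >= 4 strains with both abundance and trait")
    res = row_ols(values[shared].to_numpy(dtype=float),
                  trait.loc[shared].to_numpy(dtype=float), min_n=4)
    skipped = int(np.isnan(res["p"]).sum())
    if skipped:
        logger.info("trait_association: %d proteins skipped (constant or sparse)",
                    skipped)
    out = pd.DataFrame({
        "protein": values.index,
        "beta": res["beta"],
        "t": res["t"],
        "p": res["p"],
        "n": res["n"],
    })
    out["q"] = bh_qvalues(out["p"].to_numpy())
    out["significant"] = out["q"] < fdr
    out["direction"] = np.where(out["beta"] > 0, "+", "-")
    out.loc[out["beta"].isna(), "direction"] = pd.NA
    return out


def fit_variance_prior(s2: np.ndarray, df: np.ndarray) -> tuple[float, float]:
    """Moment-matched prior (d0, s0^2) for per-protein sample variances.

    Under the compound model s_g^2 ~ s0^2 * F(d_g, d0), the first two
    moments of the variance distribution give

        (d0 - 2) / (d0 - 4) = (CV^2 + 1) * d / (d + 2)

    with CV the coefficient of variation of the observed s_g^2 and d the
    mean residual df. A right-hand side <= 1 (variances at least as
    concentrated as chi-square sampling alone predicts) yields an
    infinite prior df — complete shrinkage to the common variance, where
    the moderated t reduces to the ordinary t when all variances are
    equal.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = np.isfinite(s2) & (s2 > 0)
    s2 = s2[ok]
    if s2.size < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    d = float(np.mean(np.asarray(df, dtype=float)[ok]))
    m1 = s2.mean()
    v = s2.var(ddof=1)
    if v <= 0:
        return np.inf, float(m1)
    R = (v / m1 ** 2 + 1.0) * d / (d + 2.0)
    if R <= 1.0:
        return np.inf, float(m1)
    d0 = 2.0 * (2.0 * R - 1.0) / (R - 1.0)
    s02 = m1 * (d0 - 2.0) / d0
    return float(d0), float(s02)


def stratified_de(values: pd.DataFrame, g: GenotypeMatrix, marker: str,
                  fdr: float = 0.05, ordinary: bool = False,
                  prior_df: float | None = None) -> pd.DataFrame:
    """Between-genotype comparison of strain-level abundances at a marker.

    log2FC = mean(log2 abundance | BB) - mean(log2 abundance | BD), i.e.
    positive values are higher in the homozygous B/B group. Moderated t
    by default; ``ordinary=True`` (or ``prior_df=0``) uses the plain
    two-sample pooled-variance t. ``prior_df`` overrides the estimated
    prior degrees of freedom.
    """
    codes = g.codes.loc[marker]
    shared = [s for s in values.columns if s in codes.index]
    codes = codes.loc[shared]
    bb = [s for s in shared if codes[s] == 0]
    bd = [s for s in shared if codes[s] == 1]
    if len(bb) < 2 or len(bd) < 2:
        raise ValueError("each genotype group needs >= 2 strains")

    y_bb = values[bb].to_numpy(dtype=float)
    y_bd = values[bd].to_numpy(dtype=float)
    n1 = np.isfinite(y_bb).sum(axis=1).astype(float)
    n2 = np.isfinite(y_bd).sum(axis=1).astype(float)
    m1 = np.nanmean(np.where(np.isfinite(y_bb), y_bb, np.nan), axis=1)
    m2 = np.nanmean(np.where(np.isfinite(y_bd), y_bd, np.nan), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ss1 = np.nansum((y_bb - m1[:, None]) ** 2, axis=1)
        ss2 = np.nansum((y_bd - m2[:, None]) ** 2, axis=1)
        df = n1 + n2 - 2.0
        s2 = (ss1 + ss2) / df
    log2fc = m1 - m2
    valid = (n1 >= 2) & (n2 >= 2) & (df >= 1)

    if ordinary or (prior_df is not None and prior_df == 0):
        s2_used = s2
        df_used = df
        d0 = 0.0
        s02 = np.nan
    else:
        if prior_df is None:
            d0, s02 = fit_variance_prior(s2[valid], df[valid])
        else:
            d0 = float(prior_df)
            _, s02 = fit_variance_prior(s2[valid], df[valid])
        if np.isinf(d0):
            s2_used = np.full_like(s2, s02)
            df_used = np.full_like(df, np.inf)
        else:
            s2_used = (d0 * s02 + df * s2) / (d0 + df)
            df_used = df + d0

    with np.errstate(invalid="ignore", divide="ignore"):
        se = np.sqrt(s2_used * (1.0 / n1 + 1.0 / n2))
        t = log2fc / se
        finite_df = np.where(np.isfinite(df_used), df_used, 1e12)
        p = 2.0 * stats.t.sf(np.abs(t), finite_df)

    t = np.where(valid, t, np.nan)
    p = np.where(valid, p, np.nan)
    out = pd.DataFrame({
        "protein": values.index,
        "log2fc": np.where(valid, log2fc, np.nan),
        "t": t,
        "p": p,
        "n_bb": n1.astype(int),
        "n_bd": n2.astype(int),
        "s2": s2,
        "s2_moderated": s2_used,
        "df": np.where(valid, df_used, np.nan),
    })
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s02
    out["q"] = bh_qvalues(out["p"].to_numpy())
    out["significant"] = out["q"] < fdr
    out["direction"] = np.where(out["log2fc"] > 0, "+", "-")
    out.loc[out["log2fc"].isna(), "direction"] = pd.NA
    n_up = int((out["significant"] & (out["log2fc"] > 0)).sum())
    n_dn = int((out["significant"] & (out["log2fc"] < 0)).sum())
    logger.info("stratified_de at %s: %d up / %d down (q < %.3g)",
                marker, n_up, n_dn, fdr)
    return out
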