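"""Quantitative cognitive-resilience trait and heritability estimates.

The trait asks: given its genetic background, does a transgenic animal
freeze more or less than expected? The expectation for each AD animal is
set by the mean contextual-fear-memory (CFM) score of the non-transgenic
(Ntg) animals of the same strain. Individual AD CFM scores are regressed
on these Ntg strain means with weights 1/n_s (n_s = AD replicates of the
animal's strain), which makes the fitted line identical to the unweighted
regression of AD strain means on Ntg strain means — the property that
lets per-animal residuals and strain-level effects share one line. The
z-scored residuals are the quantitative resilience trait.

Heritability is the one-way-ANOVA sum-of-squares fraction

    h2 = SS_strain / (SS_strain + SS_residual)

over strains with n >= 2, and its strain-mean (replicate-adjusted) form

    h2_rix = h2 / (h2 + (1 - h2) / n),   n = mean replicates per strain.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["strain_means", "resilience_scores", "heritability",
            "strain_mean_h2", "ResilienceResult", "Heritability"]


def strain_means(pheno: pd.DataFrame, group: str, trait: str = "cfm") -> pd.Series:
    """Arithmetic mean of ``trait`` per strain within one transgene group.

    Strains with no animals in the group are simply absent from the
    result.
    """
    sub = pheno[pheno["group"] == group]
    return sub.groupby("strain")[trait].mean()


@dataclass
class Heritability:
    h2: float
    h2_rix: float
    n: float            # mean replicates per strain after the n >= 2 filter
    n_strains: int
    ss_strain: float
    ss_residual: float


def strain_mean_h2(h2: float, n: float) -> float:
    """Replicate-adjusted (strain-mean) heritability h2/(h2 + (1-h2)/n)."""
    return h2 / (h2 + (1.0 - h2) / n)


def heritability(values: pd.Series, strains: pd.Series) -> Heritability:
    """One-way-ANOVA heritability of a trait grouped by strain.

    Strains with fewer than two values are excluded before the sums of
    squares are formed. ``n`` is the arithmetic mean replicate count over
    the retained strains.
    """
    df = pd.DataFrame({"y": np.asarray(values, dtype=float),
                       "strain": np.asarray(strains)}).dropna()
    counts = df.groupby("strain").size()
    keep = counts.index[counts >= 2]
    if len(keep) < 2:
        raise ValueError("need >= 2 strains with >= 2 replicates each")
    df = df[df["strain"].isin(keep)]
    grand = df["y"].mean()
    per = df.groupby("strain")["y"]
    ss_strain = float((per.size() * (per.mean() - grand) ** 2).sum())
    ss_resid = float(((df["y"] - per.transform("mean")) ** 2).sum())
    total = ss_strain + ss_resid
    if total == 0:
        raise ValueError("zero total sum of squares; trait is constant")
    h2 = ss_strain / total
    n_bar = float(per.size().mean())
    return Heritability(
        h2=h2,
        h2_rix=strain_mean_h2(h2, n_bar),
        n=n_bar,
        n_strains=len(keep),
        ss_strain=ss_strain,
        ss_residual=ss_resid,
    )


@dataclass
class ResilienceResult:
    """Fit of the resilience regression plus derived quantities."""

    slope: float
    intercept: float
    r2: float
    p_value: float
    animals: pd.DataFrame           # animal, strain, cfm, ntg_mean, fitted, residual, z
    strain_resilience: pd.Series    # mean z-score of member animals
    h2: float | None = None
    h2_rix: float | None = None
    n_mean: float | None = None
    n_strains: int = 0
    n_animals: int = 0


def resilience_scores(ad: pd.DataFrame, ntg_means: pd.Series) -> ResilienceResult:
    """Per-animal resilience z-scores from the weighted CFM regression.

    ``ad`` is the AD phenotype table (one row per animal, columns animal,
    strain, cfm); ``ntg_means`` maps strain -> Ntg strain-mean CFM. AD
    animals from strains without an Ntg counterpart are dropped with a
    warning. The weighted (1/n_s) individual regression reproduces the
    strain-mean regression exactly; the slope/intercept/R^2/p reported
    here are those of the strain-mean fit.
    """
    ad = ad[ad["group"] == "AD"] if "group" in ad.columns else ad
    known = ad["strain"].isin(ntg_means.index)
    if not known.all():
        dropped = sorted(set(ad.loc[~known, "strain"]))
        warnings.warn(f"dropping AD animals from strains without Ntg data: {dropped}")
        ad = ad[known]
    strains = sorted(set(ad["strain"]))
    if len(strains) < 3:
        raise ValueError("need >= 3 strains present in both groups")

    x_animal = ntg_means.loc[ad["strain"]].to_numpy(dtype=float)
    y_animal = ad["cfm"].to_numpy(dtype=float)
    n_s = ad.groupby("strain")["cfm"].transform("size").to_numpy(dtype=float)
    w = 1.0 / n_s

    # weighted least squares; with w = 1/n_s this equals the OLS of strain
    # means on strain means (the within-strain part of the objective does
    # not involve the line)
    sw = w.sum()
    xb = (w * x_animal).sum() / sw
    yb = (w * y_animal).sum() / sw
    sxx = (w * (x_animal - xb) ** 2).sum()
    if sxx == 0:
        raise ValueError("Ntg strain means are constant; slope undefined")
    slope = (w * (x_animal - xb) * (y_animal - yb)).sum() / sxx
    intercept = yb - slope * xb

    # strain-mean fit statistics (identical line; R^2/p on the strain means)
    sm_x = ntg_means.loc[strains].to_numpy(dtype=float)
    sm_y = ad.groupby("strain")["cfm"].mean().loc[strains].to_numpy(dtype=float)
    from ._stats import ols_line
    line = ols_line(sm_x, sm_y)
    if not (np.isclose(line["beta"], slope, atol=1e-8 * max(1, abs(slope)))
            and np.isclose(line["intercept"], intercept,
                           atol=1e-6 * max(1.0, abs(intercept)))):  # pragma: no cover
        raise AssertionError("weighted fit diverged from the strain-mean fit")

    fitted = intercept + slope * x_animal
    resid = y_animal - fitted
    sd = resid.std(ddof=1)
    if sd == 0:
        raise ValueError("zero residual SD; resilience z-scores undefined")
    z = (resid - resid.mean()) / sd

    animals = pd.DataFrame({
        "animal": ad["animal"].to_numpy() if "animal" in ad.columns else ad.index,
        "strain": ad["strain"].to_numpy(),
        "cfm": y_animal,
        "ntg_mean": x_animal,
        "fitted": fitted,
        "residual": resid,
        "z": z,
    })
    strain_res = animals.groupby("strain")["z"].mean()

    result = ResilienceResult(
        slope=float(slope),
        intercept=float(intercept),
        r2=float(line["r2"]),
        p_value=float(line["p"]),
        animals=animals,
        strain_resilience=strain_res,
        n_strains=len(strains),
        n_animals=len(animals),
    )
    try:
        h = heritability(animals["z"], animals["strain"])
        result.h2, result.h2_rix, result.n_mean = h.h2, h.h2_rix, h.n
    except ValueError:
        warnings.warn("heritability not estimable (too few replicated strains)")
    return result
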