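"""Protein-QTL genome scan, cis/trans classification and haplotype blocks.

Genotypes are coded additively (0 = homozygous B, 1 = heterozygous B/D)
and each protein's strain-level abundance is regressed on each marker's
code with simple OLS; two-sided t p-values are corrected jointly across
the full protein x marker test matrix with Benjamini-Hochberg FDR
(a per-protein universe is available as an option). Significant
associations are cis when the marker lies within 5 Mb of the encoding
gene on the same chromosome, trans otherwise. Linkage disequilibrium is
the squared Pearson correlation of genotype codes, and a haplotype block
is the set of markers in complete LD (r^2 = 1) with a peak marker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._stats import bh_qvalues, row_ols
from .containers import AbundanceMatrix, GenotypeMatrix

logger = logging.getLogger(__name__)

CIS_WINDOW_BP = 5_000_000

__all__ = ["filter_proteins", "qtl_scan", "classify_cis_trans", "ld_r2",
           "haplotype_block", "protein_peaks", "HaplotypeBlock", "CIS_WINDOW_BP"]


def filter_proteins(values: pd.DataFrame, min_strains: int = 10) -> pd.DataFrame:
    """Keep proteins observed (non-missing) in at least ``min_strains``
    strains. ``values`` is a protein x strain DataFrame."""
    keep = values.notna().sum(axis=1) >= min_strains
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_proteins: dropped %d of %d proteins (< %d strains)",
                    dropped, len(values), min_strains)
    return values.loc[keep]


def qtl_scan(values: pd.DataFrame, g: GenotypeMatrix, fdr: float = 0.05,
             per_protein_fdr: bool = False) -> pd.DataFrame:
    """Additive OLS scan of every protein on every marker.

    ``values`` is strain-level (protein x strain). Only strains present in
    both matrices are used; each test uses the complete cases of its
    protein. Markers monomorphic within a protein's observed strains are
    skipped (NaN statistics, excluded from the FDR universe). Returns a
    tidy record table with q-values over all tests jointly (or per
    protein when ``per_protein_fdr``) and a ``significant`` flag at
    ``q < fdr``.
    """
    shared = [s for s in values.columns if s in g.codes.columns]
    if len(shared) < 4:
        raise ValueError("need >= 4 strains shared between abundance and genotypes")
    Y = values[shared].to_numpy(dtype=float)
    markers = g.markers
    pos = g.positions

    frames = []
    codes = g.codes[shared].to_numpy(dtype=float)
    for m_i, marker in enumerate(markers):
        res = row_ols(Y, codes[m_i], min_n=4)
        frames.append(pd.DataFrame({
            "protein": values.index,
            "marker": marker,
            "beta": res["beta"],
            "t": res["t"],
            "p": res["p"],
            "n": res["n"],
        }))
    records = pd.concat(frames, ignore_index=True)
    records["chrom"] = pos.loc[records["marker"], "chrom"].to_numpy()
    records["bp"] = pos.loc[records["marker"], "bp"].to_numpy()

    skipped = int(records["p"].isna().sum())
    if skipped:
        logger.info("qtl_scan: %d tests skipped (monomorphic or too few cases)",
                    skipped)
    if per_protein_fdr:
        records["q"] = records.groupby("protein")["p"].transform(
            lambda s: pd.Series(bh_qvalues(s.to_numpy()), index=s.index))
    else:
        records["q"] = bh_qvalues(records["p"].to_numpy())
    records["significant"] = records["q"] < fdr
    return records


def _chrom_sort_key(chrom: pd.Series) -> pd.Series:
    num = pd.to_numeric(chrom, errors="coerce")
    return num.fillna(10_000)


def protein_peaks(records: pd.DataFrame, significant_only: bool = True) -> pd.DataFrame:
    """Per-protein peak marker: the minimum-p test, ties broken by lowest
    chromosome then position. With ``significant_only`` the peak is
    reported only for proteins that have at least one q < threshold
    record."""
    recs = records.dropna(subset=["p"])
    if significant_only:
        sig_prot = recs.loc[recs["significant"], "protein"].unique()
        recs = recs[recs["protein"].isin(sig_prot)]
    if recs.empty:
        return recs.copy()
    recs = recs.assign(_ck=_chrom_sort_key(recs["chrom"]))
    recs = recs.sort_values(["protein", "p", "_ck", "bp"], kind="mergesort")
    peaks = recs.groupby("protein", sort=False).head(1).drop(columns="_ck")
    return peaks.reset_index(drop=True)


def classify_cis_trans(records: pd.DataFrame, gene_positions: pd.DataFrame,
                       window: int = CIS_WINDOW_BP) -> pd.DataFrame:
    """Attach a cis/trans class to each record with a known gene position.

    cis: marker on the gene's chromosome with distance from the marker to
    the gene interval [start, end] of at most ``window`` bp. trans:
    further away or on a different chromosome. Records for proteins
    without a position keep class NaN (logged).
    """
    out = records.copy()
    gp = gene_positions
    known = out["protein"].isin(gp.index)
    if (~known).any():
        logger.info("classify_cis_trans: %d records lack a gene position",
                    int((~known).sum()))
    out["cis_trans"] = pd.Series(pd.NA, index=out.index, dtype="string")
    sub = out.loc[known]
    gchrom = gp.loc[sub["protein"], "chrom"].to_numpy()
    gstart = gp.loc[sub["protein"], "start"].to_numpy(dtype=float)
    gend = gp.loc[sub["protein"], "end"].to_numpy(dtype=float)
    bp = sub["bp"].to_numpy(dtype=float)
    same = sub["chrom"].to_numpy() == gchrom
    dist = np.maximum.reduce([gstart - bp, bp - gend, np.zeros_like(bp)])
    cls = np.where(same & (dist <= window), "cis", "trans")
    out.loc[known, "cis_trans"] = cls
    return out


def ld_r2(g: GenotypeMatrix, marker_a: str, marker_b: str) -> float:
    """Squared Pearson correlation of two markers' genotype codes."""
    a = g.codes.loc[marker_a].to_numpy(dtype=float)
    b = g.codes.loc[marker_b].to_numpy(dtype=float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("monomorphic marker; LD undefined")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


@dataclass
class HaplotypeBlock:
    peak: str
    chrom: str
    members: pd.DataFrame    # index marker; columns r2, bp
    start: int
    end: int

    @property
    def marker_ids(self) -> list[str]:
        return list(self.members.index)


def haplotype_block(g: GenotypeMatrix, peak: str, candidates=None,
                    r2_threshold: float = 1.0) -> HaplotypeBlock:
    """Markers in LD r^2 >= threshold with ``peak`` (1e-12 slack for the
    exact r^2 = 1 membership rule).

    ``candidates`` defaults to all markers on the peak's chromosome.
    Monomorphic candidates are skipped. The block interval spans the
    member positions.
    """
    chrom = g.positions.loc[peak, "chrom"]
    if candidates is None:
        candidates = g.chrom_markers(chrom)
    x = g.codes.loc[peak].to_numpy(dtype=float)
    if x.std() == 0:
        raise ValueError(f"peak marker {peak!r} is monomorphic")
    rows = []
    for m in candidates:
        y = g.codes.loc[m].to_numpy(dtype=float)
        if y.std() == 0:
            continue
        r = np.corrcoef(x, y)[0, 1]
        r2 = r * r
        if r2 >= r2_threshold - 1e-12:
            rows.append((m, r2, int(g.positions.loc[m, "bp"])))
    members = pd.DataFrame(rows, columns=["marker", "r2", "bp"]).set_index("marker")
    return HaplotypeBlock(
        peak=peak,
        chrom=str(chrom),
        members=members,
        start=int(members["bp"].min()),
        end=int(members["bp"].max()),
    )
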