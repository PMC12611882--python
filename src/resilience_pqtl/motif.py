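"""Transcription-factor binding-site integration.

Connects the haplotype SNPs to candidate regulators: intersect marker
positions with TF-binding-site intervals (BED, 0-based half-open,
GRCm39-style), correlate each TF's protein abundance with the resilience
trait, and fit the trait-on-TF relation within each genotype group at a
marker of interest.

Coordinate rule (fixed and tested at the boundaries): BED sites are
half-open [start, end) in 0-based coordinates; markers carry 1-based bp
positions, so a SNP at bp p falls in a site iff start <= p - 1 < end.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from ._stats import bh_qvalues, ols_line
from .containers import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["MotifSite", "read_sites", "snps_in_sites", "tf_trait_correlation",
           "genotype_stratified_fit"]


@dataclass(frozen=True)
class MotifSite:
    chrom: str
    start: int        # 0-based, inclusive
    end: int          # 0-based, exclusive
    tf: str
    accession: str | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval for {self.tf}: "
                             f"[{self.start}, {self.end})")


def read_sites(path) -> list[MotifSite]:
    """Parse TF-binding sites from a BED file.

    Requires at least four columns (chrom, start, end, name); the name is
    ``TF`` or ``TF:accession``. Browser/track/comment lines are skipped;
    any other malformed line raises with its line number.
    """
    sites: list[MotifSite] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 4:
                raise ValueError(f"line {lineno}: expected >= 4 BED columns")
            chrom, start, end, name = parts[0], parts[1], parts[2], parts[3]
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as err:
                raise ValueError(f"line {lineno}: non-integer coordinates") from err
            if start_i >= end_i:
                raise ValueError(f"line {lineno}: start >= end")
            tf, _, acc = name.partition(":")
            sites.append(MotifSite(chrom=chrom.removeprefix("chr"), start=start_i,
                                   end=end_i, tf=tf, accession=acc or None))
    return sites


def snps_in_sites(snps: pd.DataFrame, sites: list[MotifSite],
                  alleles: pd.DataFrame | None = None) -> pd.DataFrame:
    """Markers falling inside TF-binding sites.

    ``snps``: DataFrame indexed by marker id with columns chrom and bp
    (1-based). ``alleles`` (optional): per-marker B6/D2 alleles to carry
    through. Returns one row per (marker, site) intersection.
    """
    trees: dict[str, IntervalTree] = {}
    for s in sites:
        trees.setdefault(s.chrom, IntervalTree()).addi(s.start, s.end, s)
    rows = []
    for marker, rec in snps.iterrows():
        chrom = str(rec["chrom"]).removeprefix("chr")
        tree = trees.get(chrom)
        if tree is None:
            continue
        pos0 = int(rec["bp"]) - 1          # 1-based bp -> 0-based coordinate
        for hit in sorted(tree[pos0], key=lambda iv: (iv.begin, iv.end)):
            site: MotifSite = hit.data
            row = {
                "marker": marker, "chrom": chrom, "bp": int(rec["bp"]),
                "tf": site.tf, "accession": site.accession,
                "site_start": site.start, "site_end": site.end,
            }
            if alleles is not None and marker in alleles.index:
                row["allele_b6"] = alleles.loc[marker, "b6"]
                row["allele_d2"] = alleles.loc[marker, "d2"]
            rows.append(row)
    return pd.DataFrame(rows)


def tf_trait_correlation(tf_values: pd.DataFrame, trait: pd.Series) -> pd.DataFrame:
    """Pearson correlation of each TF's strain-level abundance with the
    trait (two-sided t-based p), sorted by r descending.

    ``tf_values``: TF x strain. Constant vectors are skipped with a log
    message. Raw p-values are the primary report; BH q over the tested
    TFs rides along as an extra column.
    """
    shared = [s for s in tf_values.columns if s in trait.index]
    if len(shared) < 4:
        raise ValueError("need >= 4 shared strains for TF-trait correlation")
    y = trait.loc[shared]
    rows = []
    for tf in tf_values.index:
        v = tf_values.loc[tf, shared]
        pair = pd.DataFrame({"v": v, "y": y}).dropna()
        if len(pair) < 4 or pair["v"].std() == 0 or pair["y"].std() == 0:
            logger.info("tf_trait_correlation: skipping %s (constant or sparse)", tf)
            continue
        r, p = stats.pearsonr(pair["v"], pair["y"])
        rows.append((tf, float(r), float(p), len(pair)))
    out = pd.DataFrame(rows, columns=["tf", "r", "p", "n"])
    out["q"] = bh_qvalues(out["p"].to_numpy())
    return out.sort_values("r", ascending=False, ignore_index=True)


def genotype_stratified_fit(trait: pd.Series, tf_values: pd.Series,
                            g: GenotypeMatrix, marker: str,
                            min_strains: int = 3) -> pd.DataFrame:
    """Per-genotype-group OLS of the trait on TF abundance.

    Strains are split by their code at ``marker`` (0 -> "BB",
    1 -> "BD"); each group with at least ``min_strains`` strains gets a
    slope/R^2/p/n row, smaller groups are omitted with a warning.
    """
    codes = g.codes.loc[marker]
    df = pd.DataFrame({"trait": trait, "tf": tf_values}).dropna()
    df = df[df.index.isin(codes.index)]
    df["genotype"] = codes.loc[df.index].map({0: "BB", 1: "BD"})
    rows = []
    for label, sub in df.groupby("genotype"):
        if len(sub) < min_strains:
            warnings.warn(f"genotype group {label} has {len(sub)} strains "
                          f"(< {min_strains}); omitted")
            continue
        line = ols_line(sub["tf"].to_numpy(), sub["trait"].to_numpy())
        rows.append((label, float(line["beta"]), float(line["r2"]),
                     float(line["p"]), len(sub)))
    return pd.DataFrame(rows, columns=["genotype", "slope", "r2", "p", "n"]
                        ).set_index("genotype")
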