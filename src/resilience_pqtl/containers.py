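"""In-memory containers shared by the pipeline stages.

The panel under study is a recombinant-inbred backcross: every animal
carries, at each locus, either a homozygous B6 genotype (coded 0, "B") or
a heterozygous B6/D2 genotype (coded 1, "H"). Genotypes are therefore a
binary strains x markers matrix with genomic positions attached.

Protein (or peptide) quantities travel as a features x samples matrix with
a sample-metadata table (strain, group, batch, sex, age) and, at the
peptide level, a peptide -> protein-group map.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PHENO_COLUMNS = ["animal", "strain", "group", "sex", "age_months", "cfm", "cfa"]


@dataclass
class GenotypeMatrix:
    """Marker x strain genotype codes plus marker positions.

    ``codes``: DataFrame indexed by marker id, one column per strain,
    values in {0, 1} (0 = homozygous B, 1 = heterozygous B/D).
    ``positions``: DataFrame indexed by marker id with columns
    ``chrom`` (str) and ``bp`` (1-based position, GRCm39-style).
    """

    codes: pd.DataFrame
    positions: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.codes.index.equals(self.positions.index):
            raise ValueError("codes and positions must share the same marker index")
        if self.codes.index.has_duplicates:
            dup = self.codes.index[self.codes.index.duplicated()][0]
            raise ValueError(f"duplicate marker id: {dup!r}")
        vals = self.codes.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("genotype codes must be 0 (BB) or 1 (BD)")
        for chrom, sub in self.positions.groupby("chrom", sort=False):
            bp = sub["bp"].to_numpy()
            if not (np.diff(bp) > 0).all():
                raise ValueError(f"marker positions not strictly increasing on chr{chrom}")

    @property
    def strains(self) -> list[str]:
        return list(self.codes.columns)

    @property
    def markers(self) -> list[str]:
        return list(self.codes.index)

    def marker_codes(self, marker: str) -> pd.Series:
        """Genotype codes of one marker across strains."""
        return self.codes.loc[marker]

    def chrom_markers(self, chrom: str) -> list[str]:
        return list(self.positions.index[self.positions["chrom"] == chrom])


@dataclass
class AbundanceMatrix:
    """Feature x sample quantitative matrix with sample metadata.

    ``log2`` flags the value scale (False = linear intensities).
    ``feature_map`` (peptide level only) maps each peptide id to its
    protein-group id. ``level`` is a free-text processing tag
    ("2", "3A", "3B").
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    log2: bool = True
    # peptide -> protein group: Series (1:1) or (feature, protein) DataFrame
    feature_map: pd.Series | pd.DataFrame | None = None
    level: str | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate feature id: {dup!r}")
        if list(self.values.columns) != list(self.samples.index):
            raise ValueError("sample metadata index must match value columns")

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy_with(self, **kw) -> "AbundanceMatrix":
        base = dict(
            values=self.values,
            samples=self.samples,
            log2=self.log2,
            feature_map=self.feature_map,
            level=self.level,
        )
        base.update(kw)
        return AbundanceMatrix(**base)


def strain_mean_matrix(m: AbundanceMatrix, group: str | None = "AD") -> pd.DataFrame:
    """Collapse an animal-level matrix to strain level (feature x strain).

    Replicate animals of a strain are averaged (NaN-aware). ``group``
    restricts to one transgene group when the metadata has a ``group``
    column; reference/pooled samples are excluded that way too.
    """
    samples = m.samples
    cols = samples.index
    if group is not None and "group" in samples.columns:
        cols = samples.index[samples["group"] == group]
    strains = samples.loc[cols, "strain"]
    return m.values[cols].T.groupby(strains).mean().T


def validate_phenotypes(df: pd.DataFrame) -> pd.DataFrame:
    """Check a phenotype table: required columns, one row per animal,
    freezing percentages within [0, 100]."""
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    if df["animal"].duplicated().any():
        dup = df.loc[df["animal"].duplicated(), "animal"].iloc[0]
        raise ValueError(f"animal listed more than once: {dup!r}")
    for col in ("cfm", "cfa"):
        v = df[col].to_numpy(dtype=float)
        ok = np.isnan(v) | ((v >= 0) & (v <= 100))
        if not ok.all():
            raise ValueError(f"{col} outside [0, 100]")
    bad = set(df["group"]) - {"AD", "Ntg"}
    if bad:
        raise ValueError(f"unknown transgene group labels: {sorted(bad)}")
    return df


@dataclass
class TruthTable:
    """Planted ground truth recorded by the cohort generator.

    Serves as the oracle for parameter-recovery tests: which proteins were
    made trait-associated (and with which sign), which belong to the
    block-driven module, the planted haplotype block, the true per-strain
    resilience values, the standardized mediation paths, and any decoy
    cis effects planted on null proteins.
    """

    trait_proteins: pd.DataFrame        # protein, sign (+1/-1), in_module, cis_trans
    module_proteins: list[str]
    block_chrom: str
    block_markers: list[str]
    block_interval: tuple[int, int]
    peak_marker: str
    strain_resilience: pd.Series        # true strain-level trait (percent units)
    paths: dict                          # a, b, direct, indirect, total (standardized)
    tf_correlations: dict = field(default_factory=dict)
    cis_null: pd.DataFrame | None = None  # protein, marker
    baseline: dict = field(default_factory=dict)  # intercept, slope, ntg strain means

    def __post_init__(self) -> None:
        prot = self.trait_proteins["protein"]
        if prot.duplicated().any():
            raise ValueError("a planted protein appears more than once")
        if not set(self.trait_proteins["sign"]) <= {-1, 1}:
            raise ValueError("planted signs must be +1 or -1")
        if self.cis_null is not None and len(self.cis_null):
            overlap = set(self.cis_null["protein"]) & set(prot)
            if overlap:
                raise ValueError(f"protein planted twice: {sorted(overlap)}")

    def to_json(self, path) -> None:
        payload = {
            "trait_proteins": self.trait_proteins.to_dict(orient="records"),
            "module_proteins": self.module_proteins,
            "block_chrom": self.block_chrom,
            "block_markers": self.block_markers,
            "block_interval": list(self.block_interval),
            "peak_marker": self.peak_marker,
            "strain_resilience": {k: float(v) for k, v in self.strain_resilience.items()},
            "paths": self.paths,
            "tf_correlations": self.tf_correlations,
            "cis_null": (self.cis_null.to_dict(orient="records")
                         if self.cis_null is not None else None),
            "baseline": {
                k: (dict(v) if isinstance(v, (dict, pd.Series)) else v)
                for k, v in self.baseline.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "TruthTable":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            trait_proteins=pd.DataFrame(d["trait_proteins"]),
            module_proteins=d["module_proteins"],
            block_chrom=d["block_chrom"],
            block_markers=d["block_markers"],
            block_interval=tuple(d["block_interval"]),
            peak_marker=d["peak_marker"],
            strain_resilience=pd.Series(d["strain_resilience"]),
            paths=d["paths"],
            tf_correlations=d.get("tf_correlations", {}),
            cis_null=(pd.DataFrame(d["cis_null"]) if d.get("cis_null") else None),
            baseline=d.get("baseline", {}),
        )


def asdict_shallow(obj) -> dict:
    """dataclasses.asdict without deep-copying DataFrames."""
    return {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}
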