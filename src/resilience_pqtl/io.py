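"""Readers and writers for the pipeline's plain-text formats.

Genotypes travel as GeneNetwork-style TSV (marker, chrom, bp, then one
column per strain with codes B/H or 0/1); phenotypes as CSV; abundance
matrices as CSV with a ``# level=... scale=...`` header comment and a
sidecar sample-metadata CSV; gene positions as TSV; motif sites as BED.
Every writer/reader pair round-trips its content exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, GenotypeMatrix, validate_phenotypes

_CODE_MAP = {"B": 0, "H": 1, "0": 0, "1": 1, 0: 0, 1: 1}
_CODE_OUT = {0: "B", 1: "H"}


def write_genotype_file(g: GenotypeMatrix, path) -> None:
    out = pd.DataFrame({"marker": g.markers,
                        "chrom": g.positions["chrom"].to_numpy(),
                        "bp": g.positions["bp"].to_numpy()})
    for strain in g.strains:
        out[strain] = g.codes[strain].map(_CODE_OUT).to_numpy()
    out.to_csv(path, sep="\t", index=False)


def read_genotype_file(path) -> GenotypeMatrix:
    """Parse a genotype TSV; B -> 0, H -> 1 (numeric codes accepted).

    Raises with the offending row/column on unknown codes, on duplicate
    marker ids, and on positions not strictly increasing within a
    chromosome.
    """
    raw = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"marker", "chrom", "bp"}
    if not required <= set(raw.columns):
        raise ValueError(f"genotype file must have columns {sorted(required)}")
    if raw["marker"].duplicated().any():
        dup = raw.loc[raw["marker"].duplicated(), "marker"].iloc[0]
        raise ValueError(f"duplicate marker id: {dup!r}")
    strains = [c for c in raw.columns if c not in required]
    codes = {}
    for strain in strains:
        col = raw[strain].astype(str).str.strip()
        bad = ~col.isin([str(k) for k in _CODE_MAP])
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise ValueError(
                f"unknown genotype code {col.iloc[i]!r} at row {i + 2}, "
                f"column {strain!r} (expected B/H/0/1)")
        codes[strain] = col.map(lambda v: _CODE_MAP[v]).to_numpy(dtype=np.int8)
    codes_df = pd.DataFrame(codes, index=raw["marker"])
    positions = raw.set_index("marker")[["chrom", "bp"]]
    return GenotypeMatrix(codes=codes_df, positions=positions)


def write_phenotype_csv(pheno: pd.DataFrame, path) -> None:
    validate_phenotypes(pheno).to_csv(path, index=False)


def read_phenotype_csv(path) -> pd.DataFrame:
    return validate_phenotypes(pd.read_csv(path, dtype={"strain": str}))


def write_abundance_csv(m: AbundanceMatrix, path) -> None:
    """Matrix CSV with a header comment, plus ``<stem>.samples.csv`` and,
    when a peptide map exists, ``<stem>.features.csv``."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# level={m.level or 'NA'} scale={'log2' if m.log2 else 'linear'}\n")
        m.values.to_csv(fh, index_label="feature")
    m.samples.to_csv(path.with_suffix(".samples.csv"), index_label="sample")
    if m.feature_map is not None:
        m.feature_map.rename("protein").to_csv(
            path.with_suffix(".features.csv"), index_label="feature")


def read_abundance_csv(path) -> AbundanceMatrix:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        values = pd.read_csv(fh, index_col="feature")
    level, scale = None, "log2"
    if header.startswith("#"):
        fields = dict(tok.split("=", 1) for tok in header[1:].split() if "=" in tok)
        level = fields.get("level")
        scale = fields.get("scale", "log2")
    samples = pd.read_csv(path.with_suffix(".samples.csv"), index_col="sample",
                          dtype={"strain": str})
    fmap_path = path.with_suffix(".features.csv")
    fmap = None
    if fmap_path.exists():
        fmap = pd.read_csv(fmap_path, index_col="feature")["protein"]
    return AbundanceMatrix(values=values, samples=samples, log2=(scale == "log2"),
                           feature_map=fmap, level=None if level == "NA" else level)


def write_gene_positions(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", index_label="gene")


def read_gene_positions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene", dtype={"chrom": str})
    missing = {"chrom", "start", "end"} - set(df.columns)
    if missing:
        raise ValueError(f"gene-position table missing columns: {sorted(missing)}")
    return df


def write_bed(sites: pd.DataFrame, path) -> None:
    """Write chrom/start/end/name rows as 4-column BED."""
    sites[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.Series):
        return o.to_dict()
    raise TypeError(f"not JSON-serializable: {type(o)}")
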