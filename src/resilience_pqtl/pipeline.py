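"""End-to-end orchestration of the analysis chain.

Stage order: simulate -> normalize -> resilience -> scan -> associate ->
mediate -> motif. Each stage writes its outputs to fresh files inside
the run directory and the report collects the headline numbers (fit and
heritability, pQTL counts, module membership with the planted truth
alongside, mediation paths, motif hits). A single integer seed fans out
to per-stage substreams via ``numpy.random.SeedSequence(seed).spawn``
in a fixed stage order, so identical config + seed gives a
byte-identical report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, io
from .association import stratified_de, trait_association
from .containers import strain_mean_matrix
from .mediation import mediate, module_pca
from .motif import genotype_stratified_fit, read_sites, snps_in_sites, \
    tf_trait_correlation
from .normalize import log2_median_normalize, pca_qc, remove_batch_effect, \
    rollup_proteins
from .pqtl import classify_cis_trans, filter_proteins, haplotype_block, \
    protein_peaks, qtl_scan
from .resilience import resilience_scores, strain_means
from .simulate import SimConfig, generate_cohort, generate_genotypes, \
    generate_peptide_batches, gene_positions, motif_sites_bed

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "normalize", "resilience", "scan", "associate",
           "mediate", "motif")


@dataclass
class PipelineConfig:
    outdir: str = "run"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in _STAGES})
    fdr: float = 0.05
    min_strains: int = 10
    cis_window_mb: float = 5.0
    r2_threshold: float = 1.0
    n_boot: int = 1000
    sim: dict = field(default_factory=dict)     # SimConfig overrides

    def __post_init__(self) -> None:
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")
        if not 0 <= self.r2_threshold <= 1:
            raise ValueError("r2_threshold must be in [0, 1]")
        if self.min_strains < 1 or self.n_boot < 1:
            raise ValueError("min_strains and n_boot must be positive")
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for s in _STAGES:
            self.stages.setdefault(s, True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def config_hash(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("outdir")          # a location, not an analysis parameter
        payload = json.dumps(d, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage_seeds(seed: int) -> dict[str, np.random.SeedSequence]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return dict(zip(_STAGES, children))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages, write artifacts, return the report."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    report: dict = {
        "manifest": {
            "package": "resilience-pqtl",
            "version": __version__,
            "seed": cfg.seed,
            "config_hash": cfg.config_hash(),
            "stages": {s: bool(cfg.stages[s]) for s in _STAGES},
        }
    }

    if not cfg.stages["simulate"]:
        io.write_json(report, outdir / "report.json")
        return report

    # --- simulate ---------------------------------------------------------
    sim_cfg = SimConfig(**cfg.sim)
    rng = np.random.default_rng(seeds["simulate"])
    genotypes = generate_genotypes(sim_cfg, rng)
    pheno, proteins, truth = generate_cohort(sim_cfg, genotypes, rng)
    genes = gene_positions(sim_cfg, genotypes, truth, rng)
    peptides = generate_peptide_batches(proteins, sim_cfg, rng)
    sites_df = motif_sites_bed(truth, genotypes, rng)

    io.write_genotype_file(genotypes, outdir / "genotypes.tsv")
    io.write_phenotype_csv(pheno, outdir / "phenotypes.csv")
    io.write_abundance_csv(peptides, outdir / "peptides.csv")
    io.write_gene_positions(genes, outdir / "genes.tsv")
    io.write_bed(sites_df, outdir / "tf_sites.bed")
    truth.to_json(outdir / "truth.json")
    report["simulate"] = {
        "n_strains": len(genotypes.strains),
        "n_markers": len(genotypes.markers),
        "n_animals": int(len(pheno)),
        "n_peptides": int(peptides.values.shape[0]),
        "planted_module": truth.module_proteins,
        "planted_paths": truth.paths,
    }

    # --- normalize --------------------------------------------------------
    if cfg.stages["normalize"]:
        level2 = log2_median_normalize(peptides)
        level3a = remove_batch_effect(level2)
        frac, _, batch_score = pca_qc(level3a)
        level3b = rollup_proteins(level3a)
        # analysis below runs on experimental samples at strain level
        protein_values = strain_mean_matrix(level3b, group="AD")
        io.write_abundance_csv(level3b, outdir / "proteins.csv")
        report["normalize"] = {
            "n_proteins": int(level3b.values.shape[0]),
            "pc1_fraction": float(frac[0]),
            "batch_separation_score": batch_score,
        }
    else:
        protein_values = strain_mean_matrix(proteins, group="AD")

    # --- resilience -------------------------------------------------------
    if not cfg.stages["resilience"]:
        io.write_json(report, outdir / "report.json")
        return report
    ntg = strain_means(pheno, "Ntg")
    res = resilience_scores(pheno[pheno["group"] == "AD"], ntg)
    res.animals.to_csv(outdir / "resilience_animals.csv", index=False)
    res.strain_resilience.rename("resilience").to_csv(
        outdir / "resilience_strains.tsv", sep="\t")
    report["resilience"] = {
        "slope": res.slope, "intercept": res.intercept,
        "r2": res.r2, "p": res.p_value,
        "h2": res.h2, "h2_rix": res.h2_rix, "n_mean": res.n_mean,
        "n_strains": res.n_strains, "n_animals": res.n_animals,
    }

    # --- scan -------------------------------------------------------------
    if not cfg.stages["scan"]:
        io.write_json(report, outdir / "report.json")
        return report
    tested = filter_proteins(protein_values, cfg.min_strains)
    records = qtl_scan(tested, genotypes, fdr=cfg.fdr)
    records = classify_cis_trans(records, genes,
                                 window=int(cfg.cis_window_mb * 1e6))
    peaks = protein_peaks(records)
    records[records["significant"]].sort_values("q").to_csv(
        outdir / "pqtl_records.tsv", sep="\t", index=False)
    sig = records[records["significant"]]
    cls = sig["cis_trans"].value_counts()
    top = peaks.sort_values("p").iloc[0] if len(peaks) else None
    report["scan"] = {
        "n_proteins_tested": int(tested.shape[0]),
        "n_tests": int(records["p"].notna().sum()),
        "n_significant_records": int(sig.shape[0]),
        "n_significant_proteins": int(sig["protein"].nunique()),
        "cis_records": int(cls.get("cis", 0)),
        "trans_records": int(cls.get("trans", 0)),
        "top_marker": None if top is None else str(top["marker"]),
    }

    # --- associate --------------------------------------------------------
    if not cfg.stages["associate"]:
        io.write_json(report, outdir / "report.json")
        return report
    sig_proteins = sorted(sig["protein"].unique())
    assoc = trait_association(tested.loc[sig_proteins], res.strain_resilience,
                              fdr=cfg.fdr)
    assoc.sort_values("q").to_csv(outdir / "trait_association.tsv", sep="\t",
                                  index=False)
    trait_sig = assoc[assoc["significant"]]
    # the resilience locus: the modal peak marker among the trait-associated
    # proteins (the locus most of them map to), expanded to its haplotype
    # block by the complete-LD rule
    block = None
    peak_of = peaks.set_index("protein")
    if len(trait_sig):
        shared_peaks = peak_of.loc[
            peak_of.index.intersection(trait_sig["protein"]), "marker"]
        if len(shared_peaks):
            locus = shared_peaks.mode().iloc[0]
            block = haplotype_block(genotypes, locus,
                                    r2_threshold=cfg.r2_threshold)
    de = None
    if block is not None:
        de = stratified_de(tested, genotypes, block.peak, fdr=cfg.fdr)
        de.sort_values("q").to_csv(outdir / "stratified_de.tsv", sep="\t",
                                   index=False)
    # module: trait-associated proteins whose peak is inside the block and
    # whose gene is local (cis) — the co-regulated, locally encoded set
    module_proteins: list[str] = []
    if block is not None and len(trait_sig):
        block_set = set(block.marker_ids)
        for prot in trait_sig["protein"]:
            if prot not in peak_of.index:
                continue
            cls = peak_of.loc[prot, "cis_trans"]
            if peak_of.loc[prot, "marker"] in block_set \
                    and pd.notna(cls) and cls == "cis":
                module_proteins.append(prot)
    report["associate"] = {
        "n_trait_significant": int(trait_sig.shape[0]),
        "n_positive": int((trait_sig["beta"] > 0).sum()),
        "n_negative": int((trait_sig["beta"] < 0).sum()),
        "trait_proteins": sorted(trait_sig["protein"]),
        "module_proteins": sorted(module_proteins),
        "planted_module": sorted(truth.module_proteins),
        "module_recovered": sorted(module_proteins) == sorted(truth.module_proteins),
        "block_peak": None if block is None else block.peak,
        "block_markers": None if block is None else block.marker_ids,
        "block_interval": None if block is None else [block.start, block.end],
        "de_up": None if de is None else int(
            (de["significant"] & (de["log2fc"] > 0)).sum()),
        "de_down": None if de is None else int(
            (de["significant"] & (de["log2fc"] < 0)).sum()),
    }

    # --- mediate ----------------------------------------------------------
    if cfg.stages["mediate"] and block is not None and len(module_proteins) >= 2:
        module_matrix = tested.loc[module_proteins].T
        pca = module_pca(module_matrix)
        med_seed = int(seeds["mediate"].generate_state(1)[0] % (2 ** 31))
        med = mediate(
            genotypes.codes.loc[block.peak],
            pca.pc1,
            res.strain_resilience,
            n_boot=cfg.n_boot,
            seed=med_seed,
        )
        io.write_json(med.to_dict(), outdir / "mediation.json")
        report["mediate"] = {
            "pc1_fraction": float(pca.variance_fractions[0]),
            **med.to_dict(),
        }

    # --- motif ------------------------------------------------------------
    if cfg.stages["motif"] and block is not None:
        sites = read_sites(outdir / "tf_sites.bed")
        block_snps = genotypes.positions.loc[block.marker_ids]
        hits = snps_in_sites(block_snps, sites)
        tf_names = [t for t in truth.tf_correlations] + \
            [f"TF{k + 1:02d}" for k in range(sim_cfg.tf_count)]
        tf_values = protein_values.loc[
            [t for t in tf_names if t in protein_values.index]]
        corr = tf_trait_correlation(tf_values, res.strain_resilience)
        corr.to_csv(outdir / "tf_correlations.tsv", sep="\t", index=False)
        if len(hits):
            hits.to_csv(outdir / "motif_hits.tsv", sep="\t", index=False)
        strat = None
        if len(corr):
            top_tf = corr.iloc[0]["tf"]
            strat = genotype_stratified_fit(
                res.strain_resilience, protein_values.loc[top_tf],
                genotypes, block.peak)
        report["motif"] = {
            "n_sites": len(sites),
            "n_snp_hits": int(len(hits)),
            "top_tf": None if not len(corr) else str(corr.iloc[0]["tf"]),
            "top_tf_r": None if not len(corr) else float(corr.iloc[0]["r"]),
            "top_tf_p": None if not len(corr) else float(corr.iloc[0]["p"]),
            "stratified": None if strat is None else
                strat.reset_index().to_dict(orient="records"),
        }

    io.write_json(report, outdir / "report.json")
    return report
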