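"""Synthetic recombinant-inbred backcross cohorts with planted ground truth.

The generator emulates the statistical structure of an AD mouse reference
panel: 49 strains with 2-17 replicate animals per strain and transgene
group, contextual-fear-memory (CFM) phenotypes whose AD strain means track
the non-transgenic (Ntg) baseline, a quantitative resilience trait with a
dialled-in strain-level heritability, a haplotype block of perfectly
linked markers on chromosome 1 driving a correlated protein module, decoy
cis effects on null proteins, transcription-factor abundance tracks
correlated with the trait, and batch-shifted peptide-level intensities.

Calibration notes
-----------------
* ``h2_strain`` is the expected one-way-ANOVA sum-of-squares fraction of
  the resilience trait (the statistic the analysis computes), not the raw
  variance-component fraction: the within-strain noise variance is solved
  from  E[SS_strain / SS_total] = h2  at the mean replicate count.
* ``baseline_r2`` is the expected R^2 of the OBSERVED AD-vs-Ntg
  strain-mean regression; sampling noise of both groups' strain means is
  folded into the slope calibration, so a finite cohort reproduces the
  dial rather than an attenuated value.
* All path coefficients (``snp_module_effect`` a, ``module_trait_effect``
  b, ``snp_direct_effect`` c') are standardized; the planted indirect
  effect is a*b and total = a*b + c' by linear construction.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix, GenotypeMatrix, TruthTable

logger = logging.getLogger(__name__)

# Planted haplotype-block interval on chromosome 1 (GRCm39-style bp).
BLOCK_START = 173_200_610
BLOCK_END = 175_596_722
_CHROM_MIN_BP = 3_000_000
_CHROM_MAX_BP = 190_000_000

# Canonical feature names used when the module has its default size:
# seven positive members, one negative member, plus one negative
# trait-associated protein outside the module whose gene sits on another
# chromosome (so its block pQTL is trans).
_MODULE8 = ["Akr1a1", "Gars1", "Nudt3", "Ogdh", "Ptpn1", "Iars2", "Uba1", "Ppt1"]
_EXTRA_TRANS = "Tmem223"


@dataclass
class SimConfig:
    """All dials of the synthetic cohort. Defaults are the study conditions."""

    # panel layout
    n_strains: int = 49
    replicates_range: tuple[int, int] = (2, 17)
    ntg_replicates_range: tuple[int, int] | None = None  # None -> same as AD

    # genome / markers
    n_chromosomes: int = 20
    n_markers_per_chrom: int = 50
    recomb_prob: float = 0.1
    block_chrom: str = "1"
    block_markers: int = 10

    # trait structure
    h2_strain: float = 0.26
    baseline_r2: float = 0.38
    ntg_mean: float = 50.0
    ntg_strain_sd: float = 12.0
    ntg_within_sd: float = 5.0
    ad_mean: float = 40.0
    trait_scale: float = 5.0          # percent freezing per trait SD

    # protein module and mediation paths (standardized)
    module_size: int = 8
    module_rho: float = 0.463
    snp_module_effect: float = 0.9    # a: block SNP -> module latent
    module_trait_effect: float = 0.75  # b: latent -> trait deviation
    snp_direct_effect: float = 0.0    # c': block SNP -> trait deviation

    # nuisance proteome
    n_null_proteins: int = 200
    n_cis_null: int = 20
    cis_marker_corr: float = 0.8
    tf_count: int = 26
    tf_trait_r: float = 0.55
    tf_trait_r2: float = 0.39
    protein_base_mean: float = 20.0
    protein_base_sd: float = 2.0
    protein_strain_sd: float = 0.7    # log2 units per strain-level SD
    measurement_sd: float = 0.3       # per-animal log2 noise
    missing_rate: float = 0.0

    # peptide / batch layer
    peptides_range: tuple[int, int] = (2, 5)
    peptide_noise_sd: float = 0.2
    batch_size: int = 14
    batch_count: int | None = None    # None -> ceil(n_samples / batch_size)
    batch_references: int = 2
    batch_shift: float = 0.5          # log2 units between consecutive batches

    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("recomb_prob", "h2_strain", "baseline_r2", "module_rho",
                     "missing_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_strains", "n_chromosomes", "n_markers_per_chrom",
                     "block_markers", "module_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("replicates_range", "peptides_range"):
            lo, hi = getattr(self, name)
            if lo < 1 or lo > hi:
                raise ValueError(f"{name} must satisfy 1 <= low <= high")
        if self.ntg_replicates_range is not None:
            lo, hi = self.ntg_replicates_range
            if lo < 1 or lo > hi:
                raise ValueError("ntg_replicates_range must satisfy 1 <= low <= high")
        if self.n_markers_per_chrom < self.block_markers:
            raise ValueError("block_markers cannot exceed n_markers_per_chrom")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _chrom_names(n: int) -> list[str]:
    return [str(i + 1) for i in range(n)]


def _standardize(v: np.ndarray) -> np.ndarray:
    """Empirical z-scores (population SD) — keeps planted variances exact."""
    sd = v.std()
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return (v - v.mean()) / sd


# --------------------------------------------------------------------------
# genotypes
# --------------------------------------------------------------------------

def _draw_unique(rng: np.random.Generator, lo: int, hi: int, k: int,
                 exclude: tuple[int, int] | None = None) -> np.ndarray:
    """k distinct integer positions in [lo, hi), optionally avoiding an
    interval. Rejection sampling; duplicates are astronomically rare at
    genomic scales but handled anyway."""
    got: set[int] = set()
    while len(got) < k:
        cand = rng.integers(lo, hi, size=max(2 * (k - len(got)), 8))
        if exclude is not None:
            cand = cand[(cand < exclude[0]) | (cand > exclude[1])]
        got.update(cand.tolist())
    return np.array(sorted(got)[:k] if len(got) == k else
                    sorted(rng.choice(np.array(sorted(got)), k, replace=False)))


def generate_genotypes(cfg: SimConfig, rng=None) -> GenotypeMatrix:
    """Simulate panel genotypes with a planted perfectly-linked block.

    Each strain's chromosome is an independent two-state Markov chain over
    markers ordered by position (switch probability ``recomb_prob``),
    which produces the monotone LD decay characteristic of a
    recombinant-inbred panel. Inside the declared block interval on
    ``block_chrom`` exactly ``block_markers`` markers share one strain
    distribution pattern (pairwise r^2 = 1); when ``recomb_prob`` > 0 the
    remaining markers of that chromosome are guaranteed NOT to be in
    perfect LD with the block, so the block boundary is identifiable.
    Monomorphic columns are resampled.
    """
    if cfg.n_strains < 4:
        raise ValueError("need at least 4 strains for downstream regressions")
    rng = _as_rng(rng if rng is not None else cfg.seed)
    n_s = cfg.n_strains
    chroms = _chrom_names(cfg.n_chromosomes)
    if cfg.block_chrom not in chroms:
        raise ValueError(f"block_chrom {cfg.block_chrom!r} not among chromosomes {chroms}")

    frames = []
    pos_frames = []
    for chrom in chroms:
        n_m = cfg.n_markers_per_chrom
        if chrom == cfg.block_chrom:
            block_bp = _draw_unique(rng, BLOCK_START, BLOCK_END, cfg.block_markers)
            n_out = n_m - cfg.block_markers
            out = _draw_unique(rng, _CHROM_MIN_BP, _CHROM_MAX_BP, n_out,
                               exclude=(BLOCK_START, BLOCK_END))
            bp = np.sort(np.concatenate([block_bp, out]))
            in_block = (bp >= BLOCK_START) & (bp <= BLOCK_END)
        else:
            bp = np.sort(_draw_unique(rng, _CHROM_MIN_BP, _CHROM_MAX_BP, n_m))
            in_block = np.zeros(n_m, dtype=bool)

        codes = np.empty((n_m, n_s), dtype=np.int8)
        codes[0] = rng.integers(0, 2, size=n_s)
        for i in range(1, n_m):
            switch = rng.random(n_s) < cfg.recomb_prob
            codes[i] = np.where(switch, 1 - codes[i - 1], codes[i - 1])

        if in_block.any():
            pattern = codes[np.flatnonzero(in_block)[0]].copy()
            # the block pattern must be decently polymorphic (both genotype
            # groups populated downstream: stratified DE needs >= 2 each)
            tries = 0
            while min(pattern.sum(), n_s - pattern.sum()) < 2:
                pattern = rng.integers(0, 2, size=n_s).astype(np.int8)
                tries += 1
                if tries > 1000:  # pragma: no cover
                    raise RuntimeError("could not draw a polymorphic block pattern")
            codes[in_block] = pattern

        # resample monomorphic columns; on the block chromosome also break
        # accidental perfect LD (r = +/-1) between flanking markers and the
        # planted block, so the block is exactly block_markers wide
        for i in range(n_m):
            if in_block.any() and in_block[i]:
                continue
            col = codes[i]
            bad = _is_monomorphic(col)
            if in_block.any() and cfg.recomb_prob > 0:
                bad = bad or _perfect_ld(col, pattern)
            tries = 0
            while bad:
                col = rng.integers(0, 2, size=n_s).astype(np.int8)
                bad = _is_monomorphic(col) or (
                    in_block.any() and cfg.recomb_prob > 0 and _perfect_ld(col, pattern)
                )
                tries += 1
                if tries > 1000:  # pragma: no cover
                    raise RuntimeError("could not resample a polymorphic marker")
            codes[i] = col

        markers = [f"m{chrom}_{j:04d}" for j in range(n_m)]
        frames.append(pd.DataFrame(codes, index=markers))
        pos_frames.append(pd.DataFrame({"chrom": chrom, "bp": bp}, index=markers))

    strains = [f"BXD{i + 1:03d}" for i in range(n_s)]
    codes_df = pd.concat(frames)
    codes_df.columns = strains
    positions = pd.concat(pos_frames)
    return GenotypeMatrix(codes=codes_df, positions=positions)


def _is_monomorphic(col: np.ndarray) -> bool:
    return col.min() == col.max()


def _perfect_ld(a: np.ndarray, b: np.ndarray) -> bool:
    """True when two 0/1 columns are identical or complementary."""
    return bool((a == b).all() or (a == 1 - b).all())


def block_marker_ids(g: GenotypeMatrix, cfg: SimConfig) -> list[str]:
    """Markers inside the declared block interval on the block chromosome."""
    pos = g.positions
    sel = (pos["chrom"] == cfg.block_chrom) & pos["bp"].between(BLOCK_START, BLOCK_END)
    return list(pos.index[sel])


# --------------------------------------------------------------------------
# cohort: phenotypes + proteome + truth
# --------------------------------------------------------------------------

def _mean_inv_n(lo: int, hi: int) -> float:
    return float(np.mean([1.0 / k for k in range(lo, hi + 1)]))


def _within_variance_for_h2(h2: float, n_bar: float) -> float:
    """Solve E[SS_strain/SS_total] = h2 for the within-strain variance,
    with unit between-strain variance and n_bar replicates per strain."""
    denom = h2 * (n_bar - 1.0) / (1.0 - h2) - 1.0
    if denom <= 0:
        raise ValueError(
            f"h2_strain={h2} is unreachable with ~{n_bar:.1f} replicates per "
            "strain (the ANOVA SS fraction cannot drop below 1/n)"
        )
    return n_bar / denom


def generate_cohort(cfg: SimConfig, genotypes: GenotypeMatrix, rng=None):
    """Phenotypes, protein-level abundances and the planted truth.

    Returns ``(phenotypes, proteins, truth)`` where phenotypes is a
    per-animal DataFrame (both transgene groups), proteins is a log2
    protein x AD-animal AbundanceMatrix, and truth records everything that
    was planted.
    """
    rng = _as_rng(rng if rng is not None else cfg.seed)
    strains = genotypes.strains
    n_s = len(strains)

    block = block_marker_ids(genotypes, cfg)
    if len(block) == 0:
        raise ValueError("genotypes do not contain the planted block")
    peak = block[0]
    x = genotypes.codes.loc[peak].to_numpy(dtype=float)
    # orientation: the homozygous B allele (code 0) carries the
    # enhancer-active variant, so B/B strains get the higher module latent
    # and the higher resilience deviation
    x_std = _standardize(-x)

    a = cfg.snp_module_effect
    b = cfg.module_trait_effect
    c_dir = cfg.snp_direct_effect
    eps_var = 1.0 - (c_dir ** 2 + b ** 2 + 2.0 * a * b * c_dir)
    if eps_var < 0:
        raise ValueError(
            "infeasible path coefficients: direct + mediated variance exceeds "
            "the unit trait-deviation variance"
        )

    # latent module driver and standardized trait deviation
    latent = a * x_std + np.sqrt(max(1.0 - a ** 2, 0.0)) * rng.standard_normal(n_s)
    deviation = c_dir * x_std + b * latent + np.sqrt(eps_var) * rng.standard_normal(n_s)

    # --- phenotype calibration -------------------------------------------
    ad_lo, ad_hi = cfg.replicates_range
    ntg_lo, ntg_hi = cfg.ntg_replicates_range or cfg.replicates_range
    n_bar_ad = 0.5 * (ad_lo + ad_hi)
    w_z = _within_variance_for_h2(cfg.h2_strain, n_bar_ad)   # within var, trait-SD^2

    su2 = cfg.ntg_strain_sd ** 2
    vx = cfg.ntg_within_sd ** 2 * _mean_inv_n(ntg_lo, ntg_hi)
    vy = cfg.trait_scale ** 2 * w_z * _mean_inv_n(ad_lo, ad_hi)
    denom = su2 ** 2 - cfg.baseline_r2 * su2 * (su2 + vx)
    if denom <= 0:
        raise ValueError(
            "infeasible baseline_r2: exceeds the reliability ceiling set by "
            "the Ntg strain-mean sampling noise"
        )
    slope = np.sqrt(cfg.baseline_r2 * (su2 + vx) * (cfg.trait_scale ** 2 + vy) / denom)
    intercept = cfg.ad_mean - slope * cfg.ntg_mean

    ntg_means = cfg.ntg_mean + cfg.ntg_strain_sd * rng.standard_normal(n_s)
    ad_strain_mean = intercept + slope * ntg_means + cfg.trait_scale * deviation

    rows = []
    n_ad = rng.integers(ad_lo, ad_hi + 1, size=n_s)
    n_ntg = rng.integers(ntg_lo, ntg_hi + 1, size=n_s)
    for s_i, strain in enumerate(strains):
        for j in range(n_ntg[s_i]):
            cfm = ntg_means[s_i] + cfg.ntg_within_sd * rng.standard_normal()
            cfa = 40.0 + 10.0 * rng.standard_normal()
            rows.append((f"{strain}_N{j + 1}", strain, "Ntg", "F", 6.0,
                         float(np.clip(cfm, 0, 100)), float(np.clip(cfa, 0, 100))))
        for j in range(n_ad[s_i]):
            cfm = (ad_strain_mean[s_i]
                   + cfg.trait_scale * np.sqrt(w_z) * rng.standard_normal())
            cfa = 35.0 + 10.0 * rng.standard_normal()
            rows.append((f"{strain}_A{j + 1}", strain, "AD", "F", 6.0,
                         float(np.clip(cfm, 0, 100)), float(np.clip(cfa, 0, 100))))
    pheno = pd.DataFrame(
        rows, columns=["animal", "strain", "group", "sex", "age_months", "cfm", "cfa"]
    )

    # --- strain-level protein structures ---------------------------------
    loading = np.sqrt(cfg.module_rho)
    if cfg.module_size == 8:
        module_names = list(_MODULE8)
    else:
        module_names = [f"MOD{j + 1:02d}" for j in range(cfg.module_size)]
    module_signs = np.ones(cfg.module_size)
    module_signs[-1] = -1.0   # one negative member inside the PCA module
    extra_name = _EXTRA_TRANS if cfg.module_size == 8 else "XTRANS1"

    def _loaded(sign: float) -> np.ndarray:
        noise = rng.standard_normal(n_s)
        return sign * (loading * latent + np.sqrt(1.0 - loading ** 2) * noise)

    strain_z: dict[str, np.ndarray] = {}
    records = []
    for name, sign in zip(module_names, module_signs):
        strain_z[name] = _loaded(sign)
        records.append((name, int(sign), True, "cis"))
    strain_z[extra_name] = _loaded(-1.0)
    records.append((extra_name, -1, False, "trans"))

    # transcription factors: first two planted, the rest null
    tf_names: list[str] = []
    tf_truth: dict[str, float] = {}
    dev_std = _standardize(deviation)
    planted_tf = [("Nr1d1", cfg.tf_trait_r), ("Dlx3", cfg.tf_trait_r2)]
    for k in range(cfg.tf_count):
        if k < len(planted_tf):
            name, r = planted_tf[k]
            strain_z[name] = r * dev_std + np.sqrt(1 - r ** 2) * rng.standard_normal(n_s)
            tf_truth[name] = r
        else:
            name = f"TF{k + 1:02d}"
            strain_z[name] = rng.standard_normal(n_s)
        tf_names.append(name)

    # null proteins, a subset with decoy cis effects at random markers
    non_block = [m for m in genotypes.markers if m not in set(block)]
    n_cis = min(cfg.n_cis_null, cfg.n_null_proteins, len(non_block))
    cis_markers = list(rng.choice(non_block, size=n_cis, replace=False))
    cis_rows = []
    for k in range(cfg.n_null_proteins):
        name = f"NULL{k + 1:03d}"
        if k < n_cis:
            xm = _standardize(genotypes.codes.loc[cis_markers[k]].to_numpy(float))
            g_r = cfg.cis_marker_corr
            strain_z[name] = g_r * xm + np.sqrt(1 - g_r ** 2) * rng.standard_normal(n_s)
            cis_rows.append((name, cis_markers[k]))
        else:
            strain_z[name] = rng.standard_normal(n_s)

    # --- per-animal log2 abundances (AD animals carry the proteome) ------
    ad_animals = pheno.loc[pheno["group"] == "AD", ["animal", "strain"]]
    strain_idx = pd.Index(strains).get_indexer(ad_animals["strain"])
    feature_names = list(strain_z)
    base = cfg.protein_base_mean + cfg.protein_base_sd * rng.standard_normal(
        len(feature_names))
    Z = np.stack([strain_z[f] for f in feature_names])          # features x strains
    vals = (base[:, None]
            + cfg.protein_strain_sd * Z[:, strain_idx]
            + cfg.measurement_sd * rng.standard_normal((len(feature_names),
                                                        len(ad_animals))))
    if cfg.missing_rate > 0:
        vals[rng.random(vals.shape) < cfg.missing_rate] = np.nan
    values = pd.DataFrame(vals, index=feature_names,
                          columns=ad_animals["animal"].to_list())
    samples = pd.DataFrame(
        {
            "strain": ad_animals["strain"].to_numpy(),
            "group": "AD",
            "sex": "F",
            "age_months": 6.0,
        },
        index=ad_animals["animal"].to_list(),
    )
    proteins = AbundanceMatrix(values=values, samples=samples, log2=True, level="3B")

    truth = TruthTable(
        trait_proteins=pd.DataFrame(
            records, columns=["protein", "sign", "in_module", "cis_trans"]),
        module_proteins=module_names,
        block_chrom=cfg.block_chrom,
        block_markers=block,
        block_interval=(BLOCK_START, BLOCK_END),
        peak_marker=peak,
        strain_resilience=pd.Series(cfg.trait_scale * deviation, index=strains),
        paths={
            "a": a, "b": b, "direct": c_dir,
            "indirect": a * b, "total": a * b + c_dir,
            "x_orientation": "BB_high",
        },
        tf_correlations=tf_truth,
        cis_null=pd.DataFrame(cis_rows, columns=["protein", "marker"]),
        baseline={
            "intercept": float(intercept),
            "slope": float(slope),
            "within_trait_var": float(w_z),
            "ntg_strain_means": {s: float(v) for s, v in zip(strains, ntg_means)},
        },
    )
    return pheno, proteins, truth


def gene_positions(cfg: SimConfig, genotypes: GenotypeMatrix, truth: TruthTable,
                   rng=None) -> pd.DataFrame:
    """Gene coordinates consistent with the planted cis/trans classes.

    Module genes are placed inside the block interval (cis to the block);
    the extra trans member's gene goes to another chromosome; decoy
    cis-null genes sit next to their planted marker; everything else is
    scattered uniformly.
    """
    rng = _as_rng(rng)
    pos = genotypes.positions
    chroms = list(dict.fromkeys(pos["chrom"]))
    out = []
    for j, name in enumerate(truth.module_proteins):
        start = BLOCK_START + 120_000 * j
        out.append((name, truth.block_chrom, start, start + 40_000))
    extra = truth.trait_proteins.loc[~truth.trait_proteins["in_module"], "protein"]
    other = [c for c in chroms if c != truth.block_chrom]
    for name in extra:
        if other:
            chrom = "19" if "19" in other else other[-1]
            start = int(rng.integers(10_000_000, 100_000_000))
        else:  # single-chromosome panel: far from the block, still trans
            chrom = truth.block_chrom
            start = 20_000_000
        out.append((name, chrom, start, start + 40_000))
    if truth.cis_null is not None:
        for _, row in truth.cis_null.iterrows():
            chrom = pos.loc[row["marker"], "chrom"]
            bp = int(pos.loc[row["marker"], "bp"])
            start = max(bp - 200_000, 1)
            out.append((row["protein"], chrom, start, start + 40_000))
    known = {r[0] for r in out}
    return pd.DataFrame(out, columns=["gene", "chrom", "start", "end"]).set_index("gene")


# --------------------------------------------------------------------------
# peptide level with batch structure
# --------------------------------------------------------------------------

def generate_peptide_batches(proteins: AbundanceMatrix, cfg: SimConfig,
                             rng=None) -> AbundanceMatrix:
    """Peptide-level linear intensities with planted batch shifts.

    Each protein spawns 2-5 peptides (protein log2 value plus a fixed
    peptide offset and small noise). Samples are assigned to batches of
    ``batch_size`` with balanced strain representation (round-robin over a
    strain-ordered list); each batch additionally carries
    ``batch_references`` pooled reference samples. Batch ``k`` receives an
    additive log2 shift of ``k * batch_shift``.
    """
    rng = _as_rng(rng)
    if cfg.batch_count is not None and cfg.batch_count < 1:
        raise ValueError("batch_count must be >= 1")
    if not proteins.log2:
        raise ValueError("protein matrix must be on the log2 scale")

    prot_vals = proteins.values
    n_samples = prot_vals.shape[1]
    n_batches = cfg.batch_count or int(np.ceil(n_samples / cfg.batch_size))

    # balanced assignment: order samples by strain, then deal round-robin
    order = proteins.samples.sort_values("strain").index
    batch_of = pd.Series(
        [i % n_batches for i in range(n_samples)], index=order
    ).reindex(proteins.values.columns)

    pep_rows = []
    pep_names = []
    pep_map = {}
    lo, hi = cfg.peptides_range
    for prot in prot_vals.index:
        k = int(rng.integers(lo, hi + 1))
        for p_i in range(k):
            name = f"{prot}_pep{p_i + 1}"
            offset = rng.normal(0.0, 1.0)
            noise = rng.normal(0.0, cfg.peptide_noise_sd, size=n_samples)
            pep_rows.append(prot_vals.loc[prot].to_numpy() + offset + noise)
            pep_names.append(name)
            pep_map[name] = prot

    values = pd.DataFrame(pep_rows, index=pep_names, columns=prot_vals.columns)
    samples = proteins.samples.copy()
    samples["batch"] = batch_of.astype(int)

    # pooled reference samples, batch_references per batch
    pooled = values.mean(axis=1)
    ref_cols = {}
    for b in range(n_batches):
        for r in range(cfg.batch_references):
            ref_id = f"Batch{b + 1}_ref{r + 1}"
            ref_cols[ref_id] = pooled + rng.normal(0.0, cfg.peptide_noise_sd,
                                                   size=len(values))
            samples.loc[ref_id] = {
                "strain": "Reference", "group": "Reference",
                "sex": "NA", "age_months": np.nan, "batch": b,
            }
    values = pd.concat([values, pd.DataFrame(ref_cols, index=values.index)],
                       axis=1)

    shift = samples["batch"].to_numpy(dtype=float) * cfg.batch_shift
    values = values + shift[None, :]

    return AbundanceMatrix(
        values=np.power(2.0, values),
        samples=samples,
        log2=False,
        feature_map=pd.Series(pep_map, name="protein"),
        level="2",
    )


# --------------------------------------------------------------------------
# standalone helpers used by calibration checks
# --------------------------------------------------------------------------

def equicorrelated_module(n_strains: int, size: int = 8, rho: float = 0.463,
                          rng=None, signs=None) -> pd.DataFrame:
    """Draw a strain x protein matrix with common pairwise correlation rho.

    Single-factor construction: each protein = sqrt(rho) * shared latent +
    sqrt(1 - rho) * own noise, optionally sign-flipped. Used to check the
    first-principal-component variance fraction (1 + (size-1)*rho)/size.
    """
    rng = _as_rng(rng)
    latent = rng.standard_normal(n_strains)
    signs = np.ones(size) if signs is None else np.asarray(signs, dtype=float)
    cols = {}
    for j in range(size):
        noise = rng.standard_normal(n_strains)
        cols[f"P{j + 1}"] = signs[j] * (
            np.sqrt(rho) * latent + np.sqrt(1.0 - rho) * noise)
    return pd.DataFrame(cols, index=[f"BXD{i + 1:03d}" for i in range(n_strains)])


def motif_sites_bed(truth: TruthTable, genotypes: GenotypeMatrix, rng=None,
                    n_sites: int = 484) -> pd.DataFrame:
    """Synthetic TF-binding-site intervals over the planted block region.

    Emulates a JASPAR/ReMap export for the enhancer region: ``n_sites``
    half-open BED intervals on the block chromosome, one of which is an
    Nr1d1 site (accession MA1531.2) containing the planted peak marker.
    Returns a DataFrame with columns chrom/start/end/name.
    """
    rng = _as_rng(rng)
    start_bp, end_bp = truth.block_interval
    peak_bp = int(genotypes.positions.loc[truth.peak_marker, "bp"])
    tf_pool = list(truth.tf_correlations) or ["Nr1d1"]
    extra = [f"TF{k + 1:02d}" for k in range(26)]
    # the planted regulatory site: half-open interval covering the peak SNP
    rows = [(truth.block_chrom, peak_bp - 5, peak_bp + 10, "Nr1d1:MA1531.2")]
    for i in range(n_sites - 1):
        s = int(rng.integers(start_bp, end_bp - 30))
        w = int(rng.integers(8, 25))
        tf = (tf_pool + extra)[int(rng.integers(0, len(tf_pool) + len(extra)))]
        rows.append((truth.block_chrom, s, s + w, f"{tf}:MA{1000 + i}.1"))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
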