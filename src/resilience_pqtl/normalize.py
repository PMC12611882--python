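"""Quantitative signal processing: log2/median normalization, batch
correction to regression residuals, peptide -> protein roll-up, and a PCA
quality check.

The stage semantics follow the common DIA processing ladder: raw peptide
peak areas (level 2) are log2-transformed and median-normalized, batch
effects are regressed out per feature (level 3A), and peptides are summed
into protein groups (level 3B).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import AbundanceMatrix

logger = logging.getLogger(__name__)

__all__ = ["log2_median_normalize", "remove_batch_effect", "rollup_proteins",
           "pca_qc", "flag_sparse_features"]


def log2_median_normalize(m: AbundanceMatrix) -> AbundanceMatrix:
    """log2-transform and median-normalize samples to a common scale.

    Every sample is shifted by a constant so its median log2 value equals
    the global median of the per-sample medians. Missing values are
    ignored in the medians and preserved in the output.
    """
    if m.log2:
        raise ValueError("input is already log2; expected linear intensities")
    vals = m.values.to_numpy(dtype=float)
    if np.nanmin(vals) <= 0:
        raise ValueError("nonpositive intensity encountered; cannot log2-transform")
    log = np.log2(vals)
    if np.all(np.isnan(log), axis=0).any():
        bad = m.values.columns[np.all(np.isnan(log), axis=0)][0]
        raise ValueError(f"sample {bad!r} has no observed values")
    medians = np.nanmedian(log, axis=0)
    target = np.median(medians)
    out = log - (medians - target)[None, :]
    return m.copy_with(
        values=pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        log2=True,
        level="2-normalized",
    )


def remove_batch_effect(m: AbundanceMatrix) -> AbundanceMatrix:
    """Regress each feature on batch (categorical) and keep the residuals.

    The feature's grand mean is added back so abundances stay on an
    interpretable scale; a constant offset relative to raw residuals that
    cannot affect any downstream regression or correlation. After the
    correction the per-batch feature means are equal (to numerical
    precision), and applying the correction twice is a no-op.
    """
    if not m.log2:
        raise ValueError("batch correction expects log2-scale values")
    if "batch" not in m.samples.columns:
        raise ValueError("sample metadata has no 'batch' column")
    batches = m.samples["batch"]
    counts = batches.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two batches to estimate a batch effect")
    if (counts < 2).any():
        bad = counts.index[counts < 2][0]
        raise ValueError(f"batch {bad!r} has a single sample; residuals degenerate")

    vals = m.values
    grand = vals.mean(axis=1, skipna=True)
    batch_means = vals.T.groupby(batches).transform("mean").T
    out = vals - batch_means + grand.to_numpy()[:, None]
    return m.copy_with(values=out, level="3A")


def rollup_proteins(m: AbundanceMatrix, on_unmapped: str = "raise") -> AbundanceMatrix:
    """Sum peptides into protein groups (linear space), return log2.

    Intensities are physically additive, so peptide quantities are
    back-transformed to the linear scale, summed within each protein
    group, and re-logged. The feature map may be a Series (peptide ->
    protein) or a two-column (feature, protein) DataFrame allowing shared
    peptides; protein ids claiming identical peptide sets are
    indistinguishable and merge into a single ``"A;B"`` node whose
    peptides are summed once. Peptides absent from the map either raise
    (``on_unmapped="raise"``) or are dropped with a warning (``"drop"``).
    """
    if m.feature_map is None:
        raise ValueError("peptide matrix has no feature -> protein-group map")
    fmap = m.feature_map
    if isinstance(fmap, pd.Series):
        pairs = pd.DataFrame({"feature": fmap.index, "protein": fmap.to_numpy()})
    else:
        pairs = fmap[["feature", "protein"]]
    unmapped = m.values.index.difference(pairs["feature"])
    if len(unmapped):
        if on_unmapped == "drop":
            logger.warning("dropping %d unmapped peptides", len(unmapped))
        else:
            raise ValueError(f"unmapped peptides: {list(unmapped[:5])} ...")
    pairs = pairs[pairs["feature"].isin(m.values.index)]
    linear = np.power(2.0, m.values) if m.log2 else m.values

    pepset_of = pairs.groupby("protein")["feature"].apply(frozenset)
    rows = {}
    for pepset, proteins in pepset_of.groupby(pepset_of).groups.items():
        node = ";".join(sorted(proteins))
        rows[node] = linear.loc[sorted(pepset)].sum(min_count=1)
    out = np.log2(pd.DataFrame(rows).T.sort_index())
    return AbundanceMatrix(values=out, samples=m.samples, log2=True,
                           feature_map=None, level="3B")


def flag_sparse_features(m: AbundanceMatrix, max_missing: float = 0.5) -> pd.Series:
    """Boolean flag per feature: missing in more than ``max_missing`` of
    samples. Reported, not removed — downstream filters decide."""
    frac = m.values.isna().mean(axis=1)
    return frac > max_missing


def pca_qc(m: AbundanceMatrix):
    """PCA over samples on complete-case features, plus a batch score.

    Returns ``(variance_fractions, scores, batch_score)``: variance
    fractions over all computed components (they sum to 1), sample scores
    (samples x components), and the between-batch fraction of the total
    variance of the PC1-PC2 scores (None when no batch labels exist).
    Chance level for the batch score is roughly (B-1)/(n-1).
    """
    complete = m.values.dropna(axis=0)
    if complete.shape[0] < 2:
        raise ValueError("fewer than 2 complete-case features; PCA undefined")
    if complete.shape[1] < 3:
        raise ValueError("need at least 3 samples for a PCA quality check")
    X = complete.T.to_numpy(dtype=float)           # samples x features
    X = X - X.mean(axis=0, keepdims=True)
    total_var = (X ** 2).sum()
    if total_var == 0:
        raise ValueError("zero total variance; identical samples")
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    frac = s ** 2 / (s ** 2).sum()
    scores = pd.DataFrame(
        U * s, index=complete.columns,
        columns=[f"PC{i + 1}" for i in range(len(s))],
    )
    batch_score = None
    if "batch" in m.samples.columns:
        pcs = scores.iloc[:, : min(2, scores.shape[1])]
        grp = pcs.groupby(m.samples["batch"])
        between = sum(
            len(sub) * ((sub.mean() - pcs.mean()) ** 2).sum() for _, sub in grp
        )
        total = ((pcs - pcs.mean()) ** 2).sum().sum()
        batch_score = float(between / total) if total > 0 else None
    return frac, scores, batch_score
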