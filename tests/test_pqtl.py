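"""Genome scan, FDR, cis/trans rule and LD blocks."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from resilience_pqtl._stats import bh_qvalues
from resilience_pqtl.containers import GenotypeMatrix
from resilience_pqtl.pqtl import (
    classify_cis_trans, filter_proteins, haplotype_block, ld_r2,
    protein_peaks, qtl_scan)


def _geno(codes: dict, chrom="1", spacing=1_000_000) -> GenotypeMatrix:
    markers = list(codes)
    n = len(next(iter(codes.values())))
    df = pd.DataFrame(codes, index=[f"BXD{i:03d}" for i in range(n)]).T
    pos = pd.DataFrame({"chrom": chrom,
                        "bp": [spacing * (i + 1) for i in range(len(markers))]},
                       index=df.index)
    return GenotypeMatrix(codes=df.astype(np.int8), positions=pos)


class TestScan:
    def test_hand_regression(self):
        # y = (1.0, 1.2, 2.0, 2.2) on g = (0, 0, 1, 1):
        # beta 1.0, SE 0.1414, t 7.07, df 2, p ~ 0.019
        g = _geno({"m1": [0, 0, 1, 1]})
        vals = pd.DataFrame([[1.0, 1.2, 2.0, 2.2]], index=["P"],
                            columns=g.strains)
        rec = qtl_scan(vals, g).iloc[0]
        assert rec["beta"] == pytest.approx(1.0)
        assert rec["t"] == pytest.approx(7.0711, abs=1e-3)
        assert rec["p"] == pytest.approx(0.0194, abs=1e-3)

    def test_perfect_fit_underflows(self):
        g = _geno({"m1": [0, 0, 1, 1]})
        vals = pd.DataFrame([[0.0, 0.0, 1.0, 1.0]], index=["P"],
                            columns=g.strains)
        rec = qtl_scan(vals, g).iloc[0]
        assert rec["beta"] == pytest.approx(1.0)
        assert rec["p"] == 0.0

    def test_matches_bruteforce_oracle(self):
        # naive per-pair regression loop on a 20-strain panel with missing
        # values, compared to the vectorized scan at 1e-10
        from scipy import stats as ss
        rng = np.random.default_rng(99)
        n_s, n_p, n_m = 20, 50, 100
        codes = {f"m{j}": rng.integers(0, 2, n_s) for j in range(n_m)}
        g = _geno(codes)
        vals = rng.normal(20, 1, size=(n_p, n_s))
        vals[rng.random(vals.shape) < 0.1] = np.nan
        values = pd.DataFrame(vals, index=[f"P{i}" for i in range(n_p)],
                              columns=g.strains)
        rec = qtl_scan(values, g).set_index(["protein", "marker"])
        for i in range(0, n_p, 7):
            for j in range(0, n_m, 13):
                y = values.iloc[i].to_numpy()
                x = g.codes.iloc[j].to_numpy(dtype=float)
                ok = np.isfinite(y)
                row = rec.loc[(f"P{i}", f"m{j}")]
                if ok.sum() < 4 or x[ok].std() == 0:
                    assert np.isnan(row["p"])
                    continue
                fit = ss.linregress(x[ok], y[ok])
                assert row["beta"] == pytest.approx(fit.slope, abs=1e-10)
                assert row["p"] == pytest.approx(fit.pvalue, rel=1e-8)

    def test_block_markers_share_statistics(self, small_cohort, strain_values):
        _, g, _, _, truth, _ = small_cohort
        rec = qtl_scan(strain_values, g)
        block = rec[rec["marker"].isin(truth.block_markers)]
        for _, sub in block.groupby("protein"):
            assert sub["t"].nunique() == 1

    def test_monomorphic_marker_skipped(self):
        g = _geno({"m1": [0, 0, 1, 1], "m2": [1, 1, 1, 1]})
        # m2 is monomorphic; GenotypeMatrix allows it, the scan skips it
        vals = pd.DataFrame([[1.0, 1.2, 2.0, 2.2]], index=["P"],
                            columns=g.strains)
        rec = qtl_scan(vals, g).set_index("marker")
        assert np.isnan(rec.loc["m2", "p"])

    def test_planted_cis_drivers_recovered(self, recovery_cohort):
        # every decoy cis effect and every module protein must clear the
        # whole-matrix FDR with the large planted effects
        from resilience_pqtl.containers import strain_mean_matrix
        cfg, g, _, proteins, truth, _ = recovery_cohort
        vals = strain_mean_matrix(proteins)
        rec = qtl_scan(filter_proteins(vals), g)
        sig = set(rec.loc[rec["significant"], "protein"])
        assert set(truth.cis_null["protein"]) <= sig
        assert set(truth.trait_proteins["protein"]) <= sig


class TestFilter:
    def test_min_strain_boundary(self):
        vals = pd.DataFrame(np.ones((2, 10)),
                            index=["nine", "ten"],
                            columns=[f"S{i}" for i in range(10)])
        vals.iloc[0, 0] = np.nan
        out = filter_proteins(vals, min_strains=10)
        assert list(out.index) == ["ten"]

    def test_min_one_keeps_everything_observed(self):
        vals = pd.DataFrame([[1.0, np.nan], [np.nan, np.nan]],
                            index=["a", "b"], columns=["S0", "S1"])
        out = filter_proteins(vals, min_strains=1)
        assert list(out.index) == ["a"]


class TestCisTrans:
    GENES = pd.DataFrame({"chrom": ["1"], "start": [10_000_000],
                          "end": [10_040_000]}, index=["P"])

    def _records(self, chrom, bp):
        return pd.DataFrame({"protein": ["P"], "marker": ["m"],
                             "chrom": [chrom], "bp": [bp],
                             "significant": [True]})

    def test_just_inside_window_is_cis(self):
        out = classify_cis_trans(self._records("1", 15_039_999), self.GENES)
        assert out["cis_trans"].iloc[0] == "cis"

    def test_just_outside_window_is_trans(self):
        out = classify_cis_trans(self._records("1", 15_040_001), self.GENES)
        assert out["cis_trans"].iloc[0] == "trans"

    def test_other_chromosome_is_trans(self):
        out = classify_cis_trans(self._records("2", 10_000_000), self.GENES)
        assert out["cis_trans"].iloc[0] == "trans"

    def test_inside_gene_is_cis(self):
        out = classify_cis_trans(self._records("1", 10_020_000), self.GENES)
        assert out["cis_trans"].iloc[0] == "cis"

    def test_unknown_gene_left_unset(self):
        rec = pd.DataFrame({"protein": ["Q"], "marker": ["m"], "chrom": ["1"],
                            "bp": [1], "significant": [True]})
        out = classify_cis_trans(rec, self.GENES)
        assert pd.isna(out["cis_trans"].iloc[0])


class TestLd:
    def test_identical_columns(self):
        g = _geno({"a": [0, 0, 1, 1], "b": [0, 0, 1, 1]})
        assert ld_r2(g, "a", "b") == pytest.approx(1.0)

    def test_orthogonal_columns(self):
        g = _geno({"a": [0, 0, 1, 1], "b": [0, 1, 0, 1]})
        assert ld_r2(g, "a", "b") == pytest.approx(0.0, abs=1e-12)

    def test_hand_correlation(self):
        g = _geno({"a": [0, 0, 1, 1], "b": [0, 1, 1, 1]})
        assert ld_r2(g, "a", "b") == pytest.approx(1.0 / 3.0)

    def test_symmetry(self):
        g = _geno({"a": [0, 1, 1, 0, 1], "b": [0, 1, 0, 0, 1]})
        assert ld_r2(g, "a", "b") == ld_r2(g, "b", "a")

    def test_monomorphic_rejected(self):
        g = _geno({"a": [0, 0, 0, 0], "b": [0, 1, 0, 1]})
        with pytest.raises(ValueError, match="monomorphic"):
            ld_r2(g, "a", "b")


class TestHaplotypeBlock:
    def test_planted_block_recovered(self, small_cohort):
        _, g, _, _, truth, _ = small_cohort
        blk = haplotype_block(g, truth.peak_marker)
        assert sorted(blk.marker_ids) == sorted(truth.block_markers)
        assert (blk.members["r2"] == 1.0).all()
        assert blk.start >= truth.block_interval[0]
        assert blk.end <= truth.block_interval[1]

    def test_threshold_zero_takes_all_polymorphic(self):
        g = _geno({"a": [0, 0, 1, 1], "b": [0, 1, 0, 1], "c": [1, 0, 0, 1]})
        blk = haplotype_block(g, "a", r2_threshold=0.0)
        assert sorted(blk.marker_ids) == ["a", "b", "c"]

    def test_lonely_peak(self):
        g = _geno({"a": [0, 0, 1, 1], "b": [0, 1, 0, 1]})
        blk = haplotype_block(g, "a", r2_threshold=1.0)
        assert blk.marker_ids == ["a"]
        assert blk.peak == "a"


class TestBh:
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=60))
    def test_q_at_least_p_and_order_invariant(self, ps):
        p = np.array(ps)
        q = bh_qvalues(p)
        assert (q >= p - 1e-15).all()
        perm = np.random.default_rng(0).permutation(len(p))
        assert np.allclose(bh_qvalues(p[perm]), q[perm])

    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=60))
    def test_monotone_in_p(self, ps):
        p = np.sort(np.array(ps))
        q = bh_qvalues(p)
        assert (np.diff(q) >= -1e-15).all()

    def test_nan_passthrough(self):
        q = bh_qvalues([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and np.isfinite(q[0])


def test_peak_tie_breaks_by_chromosome_then_bp():
    rec = pd.DataFrame({
        "protein": ["P"] * 3,
        "marker": ["m_a", "m_b", "m_c"],
        "chrom": ["2", "1", "1"],
        "bp": [5, 9, 3],
        "p": [0.001, 0.001, 0.001],
        "significant": [True, True, True],
    })
    peaks = protein_peaks(rec)
    assert peaks["marker"].iloc[0] == "m_c"


def test_rollup_then_scan_matches_protein_scan(small_cohort, strain_values):
    # noise-free peptide copies: summing k identical linear peptides only
    # shifts the protein log2 value by log2(k), so the scan statistics match
    from resilience_pqtl.containers import AbundanceMatrix
    from resilience_pqtl.normalize import rollup_proteins
    _, g, _, proteins, _, _ = small_cohort
    sub = proteins.values.iloc[:10]
    pep_vals = pd.concat([sub.set_axis(sub.index + "_pep1"),
                          sub.set_axis(sub.index + "_pep2")])
    fmap = pd.Series({f"{p}_pep{k}": p for p in sub.index for k in (1, 2)})
    peptides = AbundanceMatrix(values=pep_vals, samples=proteins.samples,
                               log2=True, feature_map=fmap)
    rolled = rollup_proteins(peptides)
    from resilience_pqtl.containers import strain_mean_matrix
    direct = qtl_scan(strain_values.loc[sub.index], g)
    via_rollup = qtl_scan(strain_mean_matrix(rolled).loc[sub.index], g)
    assert np.allclose(direct["t"].to_numpy(), via_rollup["t"].to_numpy(),
                       equal_nan=True)
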