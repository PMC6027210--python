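"""RBH orthology, permutation enrichment, ratio tests, sliding windows."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ranabias.chromomap import (
    enrichment_permutation,
    ratio_wilcoxon,
    rbh_orthologs,
    sliding_window,
)
from ranabias.io_formats import HitRecord


def _hit(q, s, evalue=1e-50, pident=95.0, aln=900, qlen=900, slen=900, bits=500.0):
    return HitRecord(q, s, pident, aln, 0, 0, 1, aln, 1, aln, evalue, bits,
                     qlen, slen)


class TestRBH:
    def test_perfect_reciprocal_pair_accepted(self):
        out = rbh_orthologs([_hit("g1", "p1", evalue=0.0, pident=99.0)],
                            [_hit("p1", "g1", evalue=0.0, pident=99.0)])
        assert [(a.gene_id, a.ortholog_id) for a in out] == [("g1", "p1")]

    @pytest.mark.parametrize("kwargs", [
        {"evalue": 1e-9},                      # e-value threshold is strict
        {"pident": 39.9},                      # identity floor
        {"aln": 400, "qlen": 900, "slen": 900},  # overlap < 50%
    ])
    def test_threshold_violations_rejected(self, kwargs):
        out = rbh_orthologs([_hit("g1", "p1", **kwargs)], [_hit("p1", "g1")])
        assert out == []

    def test_non_reciprocal_best_rejected(self):
        fwd = [_hit("g1", "p1"), _hit("g2", "p1", evalue=1e-80)]
        rev = [_hit("p1", "g2", evalue=1e-80)]
        out = rbh_orthologs(fwd, rev)
        assert [(a.gene_id, a.ortholog_id) for a in out] == [("g2", "p1")]

    def test_output_is_a_matching_and_order_invariant(self):
        rng = np.random.default_rng(17)
        fwd, rev = [], []
        for i in range(30):
            ev = float(10.0 ** -rng.uniform(20, 100))
            fwd.append(_hit(f"g{i}", f"p{i}", evalue=ev))
            rev.append(_hit(f"p{i}", f"g{i}", evalue=ev))
            fwd.append(_hit(f"g{i}", f"p{(i+1) % 30}", evalue=ev * 1e3))
        out = rbh_orthologs(fwd, rev)
        genes = [a.gene_id for a in out]
        orth = [a.ortholog_id for a in out]
        assert len(set(genes)) == len(genes) and len(set(orth)) == len(orth)
        perm = rng.permutation(len(fwd))
        out2 = rbh_orthologs([fwd[i] for i in perm], rev[::-1])
        assert [(a.gene_id, a.ortholog_id) for a in out] == \
               [(a.gene_id, a.ortholog_id) for a in out2]

    def test_missing_table_rejected(self):
        with pytest.raises(ValueError):
            rbh_orthologs([_hit("g1", "p1")], [])


def _assignments(chromosomes, positions=None):
    genes = [f"g{i}" for i in range(len(chromosomes))]
    return pd.DataFrame({
        "gene": genes,
        "chromosome": chromosomes,
        "position": positions if positions is not None
        else np.arange(1, len(genes) + 1) * 1000,
    })


def _biastable(genes, directions):
    return pd.DataFrame({
        "gene": genes,
        "direction": directions,
        "biased": [d != "none" for d in directions],
        "log2fc": [1.5 if d == "male" else (-1.5 if d == "female" else 0.0)
                   for d in directions],
        "class": "gonad",
    })


class TestEnrichment:
    def test_no_biased_genes_gives_p_one(self):
        asg = _assignments([1] * 10 + [2] * 10)
        bias = _biastable(asg["gene"], ["none"] * 20)
        res = enrichment_permutation(bias, asg, n_perm=1000, seed=0)
        assert (res["p_perm"] == 1.0).all()

    def test_small_instance_matches_hypergeometric_tail(self):
        """Chromosome of 4 genes holding all of a 5-biased set of 20."""
        chroms = [1] * 4 + [2] * 16
        asg = _assignments(chroms)
        dirs = ["male"] * 4 + ["none"] * 15 + ["male"]
        bias = _biastable(asg["gene"], dirs)
        res = enrichment_permutation(bias, asg, n_perm=10_000, seed=1)
        row = res[(res["chromosome"] == 1) & (res["direction"] == "male")].iloc[0]
        # P(X >= 4), X ~ Hypergeom(N=20, K=5, n=4)
        expected = stats.hypergeom.sf(3, 20, 5, 4)
        mc_sd = np.sqrt(expected * (1 - expected) / 10_000)
        assert abs(row["p_perm"] - expected) < 4 * mc_sd + 2e-4

    def test_pvalues_never_zero_and_bonferroni_capped(self):
        asg = _assignments(np.tile(np.arange(1, 6), 20))
        rng = np.random.default_rng(2)
        dirs = rng.choice(["male", "female", "none"], 100)
        res = enrichment_permutation(_biastable(asg["gene"], dirs), asg,
                                     n_perm=1000, seed=3)
        assert (res["p_perm"] >= 1 / 1001).all()
        assert (res["p_bonf"] <= 1.0).all()
        assert np.allclose(res["p_bonf"],
                           np.minimum(1.0, res["p_perm"] * len(res)))

    def test_low_permutation_count_rejected(self):
        asg = _assignments([1, 2])
        with pytest.raises(ValueError):
            enrichment_permutation(_biastable(asg["gene"], ["male", "none"]),
                                   asg, n_perm=10)


class TestRatioWilcoxon:
    def test_shifted_sex_chromosomes_detected(self):
        rng = np.random.default_rng(21)
        chroms = np.concatenate([np.repeat([1, 2], 100),
                                 rng.integers(3, 11, 2000)])
        asg = _assignments(chroms)
        lfc = rng.normal(0, 1, len(chroms))
        lfc[chroms <= 2] += 1.0
        bias = pd.DataFrame({"gene": asg["gene"], "log2fc": lfc})
        res = ratio_wilcoxon(bias, asg)
        assert (res["pvalue"] < 0.001).all()

    def test_deterministic(self):
        rng = np.random.default_rng(22)
        chroms = np.tile(np.arange(1, 11), 30)
        asg = _assignments(chroms)
        bias = pd.DataFrame({"gene": asg["gene"],
                             "log2fc": rng.normal(0, 1, len(chroms))})
        r1 = ratio_wilcoxon(bias, asg)
        r2 = ratio_wilcoxon(bias, asg)
        assert r1.equals(r2)

    def test_empty_stratum_rejected(self):
        asg = _assignments([3] * 10)
        bias = pd.DataFrame({"gene": asg["gene"], "log2fc": np.zeros(10)})
        with pytest.raises(ValueError):
            ratio_wilcoxon(bias, asg)


class TestSlidingWindow:
    def test_constant_values(self):
        asg = _assignments([1] * 45)
        vals = pd.Series(2.0, index=asg["gene"])
        res = sliding_window(vals, asg, window=40)
        assert len(res) == 6
        assert np.allclose(res["mean_value"], 2.0)

    def test_below_window_chromosome_yields_nothing(self):
        asg = _assignments([1] * 39)
        res = sliding_window(pd.Series(1.0, index=asg["gene"]), asg, window=40)
        assert res.empty

    def test_arithmetic_series_means(self):
        asg = _assignments([1] * 50)
        vals = pd.Series(np.arange(1.0, 51.0), index=asg["gene"])
        res = sliding_window(vals, asg, window=40)
        assert res["mean_value"].iloc[0] == pytest.approx(20.5)
        assert res["mean_value"].iloc[-1] == pytest.approx(30.5)

    def test_matches_brute_force_and_respects_boundaries(self):
        rng = np.random.default_rng(23)
        chroms = np.repeat([1, 2, 3], [50, 7, 41])
        positions = rng.choice(np.arange(1, 10_000), size=len(chroms),
                               replace=False)
        asg = _assignments(chroms, positions)
        vals = pd.Series(rng.normal(0, 1, len(chroms)), index=asg["gene"])
        res = sliding_window(vals, asg, window=10)
        assert set(res["chromosome"]) == {1, 3}  # chromosome 2 too short
        for chrom in (1, 3):
            grp = asg[asg["chromosome"] == chrom].sort_values("position")
            v = vals.reindex(grp["gene"]).to_numpy()
            expected = [v[i:i + 10].mean() for i in range(len(v) - 9)]
            got = res[res["chromosome"] == chrom]["mean_value"].to_numpy()
            assert np.allclose(got, expected)
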