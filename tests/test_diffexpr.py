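"""Filtering, TMM scaling, the NB exact test and BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ranabias.diffexpr import (
    bh_adjust,
    call_sex_bias,
    cpm,
    filter_expressed,
    fold_change_category,
    nb_exact_test,
    tmm_factors,
    tpm,
)
from ranabias.io_formats import CountsMatrix


def _cohort_frame(gene_counts: dict[str, list[int]], sample_ids: list[str],
                  sexes: list[str], cls: str = "gonad"):
    counts = pd.DataFrame(gene_counts, index=sample_ids).T
    counts.index.name = "gene"
    cm = CountsMatrix(counts=counts.astype(np.int64),
                      lengths=pd.Series(900, index=counts.index, name="length"))
    samples = pd.DataFrame({
        "sample_id": sample_ids,
        "class": cls,
        "sex": sexes,
        "replicate": [f"r{i}" for i in range(len(sample_ids))],
    })
    return cm, samples


class TestFilterExpressed:
    def test_rules_on_constructed_cpms(self):
        # library size 2e6 per sample via the filler gene, so counts of
        # 6,6,1,1 give CPMs 3,3,0.5,0.5 for the focal gene
        lib = 2_000_000
        focal = [6, 6, 1, 1]
        strong = [4000, 4000, 4000, 4000]  # CPM 2.0 everywhere
        filler = [lib - f - s for f, s in zip(focal, strong)]
        cm, samples = _cohort_frame(
            {"halfsex": focal, "steady": strong, "filler": filler, "zero": [0] * 4},
            ["a", "b", "c", "d"], ["XX", "XX", "XY", "XY"],
        )
        kept = filter_expressed(cm, samples, "gonad")
        assert "zero" not in kept            # all-zero gene removed
        assert "steady" in kept              # CPM 2.0 in every sample
        # mean log-CPM is positive but CPM <= 1 in both XY samples
        assert "halfsex" not in kept

    def test_empty_class_errors(self, cohort):
        _, cm, samples, _ = cohort
        with pytest.raises(ValueError, match="no samples"):
            filter_expressed(cm, samples, "spleen")


class TestTMM:
    def test_identical_libraries_give_unit_factors(self):
        rng = np.random.default_rng(0)
        col = rng.integers(0, 500, size=200)
        counts = pd.DataFrame({f"s{i}": col for i in range(4)})
        f = tmm_factors(counts)
        assert np.allclose(f, 1.0)

    def test_pure_depth_difference_normalizes_away(self):
        """Doubling depth with no composition change leaves factors at 1."""
        rng = np.random.default_rng(1)
        a = rng.integers(10, 1000, size=500)
        counts = pd.DataFrame({"A": a, "B": 2 * a})
        f = tmm_factors(counts)
        assert np.allclose(f.to_numpy(), 1.0, atol=1e-6)

    def test_gene_order_permutation_invariance(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.integers(0, 400, size=(300, 5)),
                              columns=list("abcde"))
        perm = rng.permutation(300)
        f1 = tmm_factors(counts)
        f2 = tmm_factors(counts.iloc[perm])
        assert np.allclose(f1, f2)

    def test_factors_have_unit_geometric_mean(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.negative_binomial(5, 0.01, size=(400, 6)),
                              columns=list("abcdef"))
        f = tmm_factors(counts)
        assert np.isclose(np.exp(np.mean(np.log(f))), 1.0, atol=1e-9)

    def test_degenerate_sample_rejected(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [0, 0, 5]})
        with pytest.raises(ValueError, match="degenerate"):
            tmm_factors(counts)


class TestExactTest:
    def test_equal_groups_equal_counts_p_one(self):
        counts = pd.DataFrame({"a": [50, 7], "b": [50, 7], "c": [50, 7],
                               "d": [50, 7]}, index=["g1", "g2"])
        p = nb_exact_test(counts, ["a", "b"], ["c", "d"], dispersion=0.1)
        assert np.allclose(p, 1.0)

    def test_zero_total_gene_defined_p_one(self):
        counts = pd.DataFrame({"a": [0, 10], "b": [0, 12], "c": [0, 9],
                               "d": [0, 11]}, index=["g1", "g2"])
        eff = pd.Series(1000.0, index=counts.columns)
        p = nb_exact_test(counts, ["a", "b"], ["c", "d"], eff_libs=eff)
        assert p["g1"] == 1.0

    def test_extreme_imbalance_tiny_p(self):
        counts = pd.DataFrame({"a": [0], "b": [0], "c": [5000], "d": [5000]},
                              index=["g1"])
        eff = pd.Series(10_000.0, index=counts.columns)
        p = nb_exact_test(counts, ["a", "b"], ["c", "d"], dispersion=0.05,
                          eff_libs=eff)
        assert p["g1"] < 1e-6

    def test_pvalues_symmetric_in_group_order(self):
        rng = np.random.default_rng(4)
        counts = pd.DataFrame(rng.negative_binomial(10, 0.05, size=(50, 6)),
                              columns=list("abcdef"))
        p1 = nb_exact_test(counts, ["a", "b", "c"], ["d", "e", "f"], dispersion=0.1)
        p2 = nb_exact_test(counts, ["d", "e", "f"], ["a", "b", "c"], dispersion=0.1)
        assert np.allclose(p1, p2)


def _bh_oracle(p):
    """Brute-force BH step-up: independent of the implementation path."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * n / rank)
        q[i] = val
        prev = val
    return q


class TestBH:
    def test_hand_computed_step_up(self):
        q = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_degenerate_vectors(self):
        assert np.allclose(bh_adjust(np.ones(5)), 1.0)
        assert np.allclose(bh_adjust(np.array([0.123])), 0.123)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_brute_force_oracle(self, pvals):
        assert np.allclose(bh_adjust(np.array(pvals)), _bh_oracle(pvals),
                           atol=1e-12)


class TestSexBiasCalls:
    def test_gates_and_direction_consistency(self, cohort):
        _, cm, samples, _ = cohort
        tbl = call_sex_bias(cm, samples, "gonad")
        gate = (tbl["qvalue"] < 0.05) & (tbl["log2fc"].abs() >= 1)
        assert (tbl["biased"] == gate).all()
        biased = tbl[tbl["biased"]]
        assert ((biased["log2fc"] > 0) == (biased["direction"] == "male")).all()
        assert (tbl.loc[~tbl["biased"], "direction"] == "none").all()
        assert (tbl.loc[~tbl["biased"], "category"] == "none").all()

    def test_no_direction_flips_among_strong_true_positives(self, cohort):
        """Implanted strong effects are never called in the wrong direction."""
        _, cm, samples, truth = cohort
        tbl = call_sex_bias(cm, samples, "gonad").merge(truth, on="gene")
        strong = tbl[(tbl["bias_class"] == "gonad")
                     & (tbl["true_lfc"].abs() >= 2) & tbl["biased"]]
        assert len(strong) > 0
        assert (strong["direction"] == strong["true_direction"]).all()

    @pytest.mark.parametrize("l2fc,biased,expected", [
        (0.8, False, "none"),
        (1.0, True, "low"),
        (-1.5, True, "mild"),
        (2.0, True, "high"),
        (-3.5, True, "very_high"),
    ])
    def test_fold_change_categories(self, l2fc, biased, expected):
        assert fold_change_category(l2fc, biased) == expected


def test_tpm_columns_sum_to_one_million(cohort):
    _, cm, _, _ = cohort
    t = tpm(cm.counts, cm.lengths)
    assert np.allclose(t.sum(axis=0), 1e6)


def test_cpm_columns_sum_to_one_million(cohort):
    _, cm, _, _ = cohort
    assert np.allclose(cpm(cm.counts).sum(axis=0), 1e6)
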