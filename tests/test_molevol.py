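"""NG86 dN/dS against an independent enumeration oracle, plus rate models."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ranabias.molevol import (
    AlignmentError,
    CodonAlignment,
    dnds_group_compare,
    jukes_cantor,
    ng86_dnds,
    sqrt_lm,
)
from ranabias.simulate import SENSE_CODONS, STOP_CODONS, _CODON_TABLE

# ---------------------------------------------------------------------------
# independent oracle: naive recursive pathway enumeration and site counting
# ---------------------------------------------------------------------------

def _oracle_sites(codon):
    """Synonymous site count of one codon by direct enumeration."""
    syn = 0
    for pos, base in itertools.product(range(3), "ACGT"):
        if base == codon[pos]:
            continue
        alt = codon[:pos] + base + codon[pos + 1:]
        if alt not in STOP_CODONS and _CODON_TABLE[alt] == _CODON_TABLE[codon]:
            syn += 1
    return syn / 3.0


def _oracle_paths(a, b):
    """All stop-free substitution paths a -> b as (syn, nonsyn) step counts."""
    if a == b:
        return [(0, 0)]
    results = []
    for pos in range(3):
        if a[pos] == b[pos]:
            continue
        step = a[:pos] + b[pos] + a[pos + 1:]
        if step in STOP_CODONS:
            continue
        syn_step = 1 if _CODON_TABLE[step] == _CODON_TABLE[a] else 0
        for s, n in _oracle_paths(step, b):
            results.append((s + syn_step, n + (1 - syn_step)))
    return results


def _oracle_counts(seq_a, seq_b):
    s_sites = sd = nd = 0.0
    codons = 0
    for i in range(0, len(seq_a), 3):
        ca, cb = seq_a[i:i + 3], seq_b[i:i + 3]
        paths = _oracle_paths(ca, cb)
        if not paths:
            continue
        codons += 1
        s_sites += (_oracle_sites(ca) + _oracle_sites(cb)) / 2
        sd += np.mean([p[0] for p in paths])
        nd += np.mean([p[1] for p in paths])
    return s_sites, 3.0 * codons - s_sites, sd, nd


def _random_pair(rng, n_codons=30):
    a = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=n_codons)]
    b = list(a)
    for _ in range(int(rng.integers(1, 3 * n_codons // 2))):
        ci = int(rng.integers(n_codons))
        cand = SENSE_CODONS[int(rng.integers(len(SENSE_CODONS)))]
        b[ci] = cand
    return "".join(a), "".join(b)


class TestNG86:
    def test_identical_sequences(self):
        rec = ng86_dnds(CodonAlignment("x", "ATGAAATTT", "ATGAAATTT"))
        assert rec.dn == 0.0 and rec.ds == 0.0
        assert np.isnan(rec.omega)

    def test_jukes_cantor_closed_form(self):
        assert jukes_cantor(0.1) == pytest.approx(-0.75 * np.log(1 - 0.4 / 3))
        assert jukes_cantor(0.1) == pytest.approx(0.10732, abs=1e-5)
        with pytest.raises(ValueError):
            jukes_cantor(0.75)

    def test_counts_match_enumeration_oracle(self):
        """Sites and differences agree with brute-force pathway enumeration
        to 1e-9 on 100 random 30-codon pairs."""
        rng = np.random.default_rng(31)
        for _ in range(100):
            sa, sb = _random_pair(rng)
            rec = ng86_dnds(CodonAlignment("p", sa, sb))
            s_sites, n_sites, sd, nd = _oracle_counts(sa, sb)
            assert rec.s_sites == pytest.approx(s_sites, abs=1e-9)
            assert rec.n_sites == pytest.approx(n_sites, abs=1e-9)
            assert rec.sd == pytest.approx(sd, abs=1e-9)
            assert rec.nd == pytest.approx(nd, abs=1e-9)

    def test_symmetric_in_sequence_order(self):
        rng = np.random.default_rng(32)
        for _ in range(20):
            sa, sb = _random_pair(rng)
            r1 = ng86_dnds(CodonAlignment("p", sa, sb))
            r2 = ng86_dnds(CodonAlignment("p", sb, sa))
            for fld in ("s_sites", "n_sites", "sd", "nd", "ds", "dn"):
                assert getattr(r1, fld) == pytest.approx(getattr(r2, fld),
                                                         abs=1e-12, nan_ok=True)

    def test_site_counts_conserved(self):
        rng = np.random.default_rng(33)
        for _ in range(20):
            sa, sb = _random_pair(rng, n_codons=20)
            rec = ng86_dnds(CodonAlignment("p", sa, sb))
            total = 3 * (20 - rec.skipped_codons)
            assert rec.s_sites + rec.n_sites == pytest.approx(total, abs=1e-9)

    @pytest.mark.parametrize("a,b,msg", [
        ("ATGAA", "ATGAA", "multiple of 3"),
        ("ATGAAA", "ATG", "length"),
        ("ATGNNN", "ATGAAA", "non-ACGT"),
        ("ATGTAATTT", "ATGTAATTT", "internal stop"),
    ])
    def test_malformed_alignments_rejected(self, a, b, msg):
        with pytest.raises(AlignmentError, match=msg):
            CodonAlignment("x", a, b)

    def test_terminal_stop_stripped(self):
        aln = CodonAlignment("x", "ATGAAATAA", "ATGAAGTAA")
        assert aln.n_codons == 2


class TestSqrtLm:
    @staticmethod
    def _dataset(seed, tau_beta=0.3, bias_shift=0.0, interaction=0.0, n=300):
        rng = np.random.default_rng(seed)
        tau = rng.uniform(0, 1, n)
        bias = rng.choice(["male", "female", "unbiased"], n)
        is_male = (bias == "male").astype(float)
        sqrt_omega = (0.3 + tau_beta * tau + bias_shift * is_male
                      + interaction * is_male * tau
                      + rng.normal(0, 0.1, n))
        omega = np.clip(sqrt_omega, 0.01, None) ** 2
        return pd.Series(omega), pd.Series(bias), pd.Series(tau)

    def test_tau_only_signal_drops_bias_not_tau(self):
        omega, bias, tau = self._dataset(seed=41)
        res = sqrt_lm(omega, bias, tau)
        drops = res["drop_tests"].set_index("term")["pvalue"]
        assert drops["tau"] < 1e-6
        assert drops["bias"] > 0.05

    def test_interaction_detected_when_present(self):
        omega, bias, tau = self._dataset(seed=42, interaction=0.3)
        res = sqrt_lm(omega, bias, tau)
        drops = res["drop_tests"].set_index("term")["pvalue"]
        assert drops["interaction"] < 0.05

    def test_rank_deficient_design_named(self):
        omega, bias, tau = self._dataset(seed=43)
        with pytest.raises(ValueError, match="tau"):
            sqrt_lm(omega, bias, pd.Series(np.full(len(tau), 0.5)))

    def test_sparse_class_rejected(self):
        omega, bias, tau = self._dataset(seed=44)
        bias.iloc[:] = "unbiased"
        bias.iloc[:3] = "male"
        with pytest.raises(ValueError, match="male"):
            sqrt_lm(omega, bias, tau)


class TestGroupCompare:
    def test_shifted_group_flagged(self):
        rng = np.random.default_rng(51)
        omega = pd.Series(np.concatenate([rng.gamma(2, 0.1, 300),
                                          rng.gamma(2, 0.1, 300) + 0.05]))
        groups = pd.Series(["unbiased"] * 300 + ["male-biased"] * 300)
        res = dnds_group_compare(omega, groups)
        assert res["pvalue"].iloc[0] < 0.005

    def test_singleton_group_skipped(self):
        omega = pd.Series([0.1, 0.2, 0.3, 0.9])
        groups = pd.Series(["a", "a", "a", "b"])
        res = dnds_group_compare(omega, groups)
        assert np.isnan(res["pvalue"].iloc[0])

    def test_all_na_group_rejected(self):
        omega = pd.Series([0.1, 0.2, np.nan, np.nan])
        groups = pd.Series(["a", "a", "b", "b"])
        with pytest.raises(ValueError, match="b"):
            dnds_group_compare(omega, groups)
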