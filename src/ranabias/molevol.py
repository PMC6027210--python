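"""Pairwise dN/dS from codon alignments and rate-vs-bias models.

The estimator is Nei-Gojobori (1986) counting: per-codon synonymous site
fractions from the universal genetic code (averaged over the two
sequences), observed synonymous/nonsynonymous differences with multi-hit
codons averaged over all equally weighted substitution pathways that avoid
stop codons, and a Jukes-Cantor multiple-hit correction
d = -(3/4) ln(1 - (4/3) p) applied separately to pS and pN. omega = dN/dS
is defined only when dS > 0.

Downstream, sqrt-transformed omega is modeled by OLS on sex-bias class,
tissue specificity (Tau) and their interaction, with drop-term F-tests.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

from ranabias._stats import mann_whitney
from ranabias.simulate import STOP_CODONS, _CODON_TABLE

logger = logging.getLogger(__name__)

_BASES = "ACGT"


class AlignmentError(ValueError):
    """Raised for malformed codon alignments."""


@dataclass(frozen=True)
class CodonAlignment:
    """A pair of aligned, gap-free, stop-free coding sequences."""

    id: str
    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        a, b = self.seq_a.upper(), self.seq_b.upper()
        if len(a) != len(b):
            raise AlignmentError(f"{self.id}: sequences differ in length")
        if len(a) % 3 != 0:
            raise AlignmentError(f"{self.id}: length not a multiple of 3")
        if set(a + b) - set(_BASES):
            raise AlignmentError(f"{self.id}: non-ACGT characters")
        # strip a terminal stop codon present in either sequence
        if len(a) >= 3 and (a[-3:] in STOP_CODONS or b[-3:] in STOP_CODONS):
            a, b = a[:-3], b[:-3]
        for i in range(0, len(a), 3):
            if a[i:i + 3] in STOP_CODONS or b[i:i + 3] in STOP_CODONS:
                raise AlignmentError(f"{self.id}: internal stop codon at {i}")
        object.__setattr__(self, "seq_a", a)
        object.__setattr__(self, "seq_b", b)

    @property
    def n_codons(self) -> int:
        return len(self.seq_a) // 3


@dataclass(frozen=True)
class DnDsRecord:
    id: str
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    ps: float
    pn: float
    ds: float
    dn: float
    omega: float  # NaN when dS == 0 or the correction is undefined
    valid: bool
    skipped_codons: int = 0


@lru_cache(maxsize=None)
def _syn_site_fraction(codon: str) -> float:
    """Synonymous sites of a codon (0..3); stop-creating changes count as
    nonsynonymous so that S + N = 3 per codon."""
    aa = _CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            alt = codon[:pos] + base + codon[pos + 1:]
            if alt not in STOP_CODONS and _CODON_TABLE[alt] == aa:
                s += 1.0 / 3.0
    return s


@lru_cache(maxsize=None)
def _codon_pair_diffs(codon_a: str, codon_b: str) -> tuple[float, float, bool]:
    """(synonymous, nonsynonymous) differences between two codons.

    Codons differing at several positions are averaged over all
    substitution orderings that never pass through a stop codon, each
    equally weighted. The flag is False when every pathway is blocked.
    """
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0, True
    total_s = total_n = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        cur = codon_a
        path_s = path_n = 0.0
        ok = True
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            if _CODON_TABLE[nxt] == _CODON_TABLE[cur]:
                path_s += 1
            else:
                path_n += 1
            cur = nxt
        if ok:
            total_s += path_s
            total_n += path_n
            n_paths += 1
    if n_paths == 0:
        return 0.0, 0.0, False
    return total_s / n_paths, total_n / n_paths, True


def jukes_cantor(p: float) -> float:
    """JC69 distance; undefined (raises) for p >= 0.75."""
    if p < 0 or p >= 0.75:
        raise ValueError(f"proportion {p} outside [0, 0.75)")
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def ng86_dnds(aln: CodonAlignment) -> DnDsRecord:
    """Nei-Gojobori dN/dS with Jukes-Cantor correction for one pair."""
    s_sites = 0.0
    sd = nd = 0.0
    skipped = 0
    effective_codons = 0
    for i in range(0, len(aln.seq_a), 3):
        ca, cb = aln.seq_a[i:i + 3], aln.seq_b[i:i + 3]
        ds_, dn_, ok = _codon_pair_diffs(ca, cb)
        if not ok:
            skipped += 1
            continue
        effective_codons += 1
        s_sites += 0.5 * (_syn_site_fraction(ca) + _syn_site_fraction(cb))
        sd += ds_
        nd += dn_
    n_sites = 3.0 * effective_codons - s_sites
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0
    if ps >= 0.75 or pn >= 0.75:
        return DnDsRecord(aln.id, s_sites, n_sites, sd, nd, ps, pn,
                          float("nan"), float("nan"), float("nan"),
                          valid=False, skipped_codons=skipped)
    ds = jukes_cantor(ps)
    dn = jukes_cantor(pn)
    omega = dn / ds if ds > 0 else float("nan")
    return DnDsRecord(aln.id, s_sites, n_sites, sd, nd, ps, pn, ds, dn,
                      omega, valid=True, skipped_codons=skipped)


def dnds_table(pairs: list[tuple[str, str, str]]) -> pd.DataFrame:
    """Run :func:`ng86_dnds` over ``(id, seq_a, seq_b)`` tuples."""
    rows = []
    for pid, sa, sb in pairs:
        rec = ng86_dnds(CodonAlignment(pid, sa, sb))
        rows.append({
            "pair": rec.id, "s_sites": rec.s_sites, "n_sites": rec.n_sites,
            "sd": rec.sd, "nd": rec.nd, "ps": rec.ps, "pn": rec.pn,
            "ds": rec.ds, "dn": rec.dn, "omega": rec.omega,
            "valid": rec.valid, "skipped_codons": rec.skipped_codons,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# models and comparisons
# ---------------------------------------------------------------------------

def sqrt_lm(omega: pd.Series, bias_class: pd.Series, tau: pd.Series,
            min_per_class: int = 10, continuous: bool = False) -> dict:
    """OLS of sqrt(omega) on sex bias, Tau and their interaction.

    ``bias_class`` is a 3-level factor (male/female/unbiased) by default,
    or a continuous bias measure with ``continuous=True``. Returns the
    coefficient table and drop-term F-tests: interaction against the full
    model, then each main effect against the additive model.
    """
    df = pd.DataFrame({"omega": omega, "bias": bias_class, "tau": tau}).dropna()
    df = df[df["omega"] >= 0]
    df["y"] = np.sqrt(df["omega"])
    if df["tau"].nunique() < 2:
        raise ValueError("rank-deficient design: tau is constant")
    if continuous:
        df["bias"] = pd.to_numeric(df["bias"])
        if df["bias"].nunique() < 2:
            raise ValueError("rank-deficient design: bias is constant")
        bias_term = "bias"
    else:
        levels = df["bias"].value_counts()
        if len(levels) < 2:
            raise ValueError("rank-deficient design: single bias class")
        low = levels[levels < min_per_class]
        if not low.empty:
            raise ValueError(
                f"bias class {low.index[0]!r} has {low.iloc[0]} observations "
                f"(< {min_per_class})"
            )
        bias_term = "C(bias)"
    full = smf.ols(f"y ~ {bias_term} * tau", data=df).fit()
    additive = smf.ols(f"y ~ {bias_term} + tau", data=df).fit()
    no_bias = smf.ols("y ~ tau", data=df).fit()
    no_tau = smf.ols(f"y ~ {bias_term}", data=df).fit()
    drops = []
    for term, reduced, reference in (
        ("interaction", additive, full),
        ("bias", no_bias, additive),
        ("tau", no_tau, additive),
    ):
        tbl = anova_lm(reduced, reference)
        drops.append({
            "term": term,
            "F": float(tbl["F"].iloc[1]),
            "pvalue": float(tbl["Pr(>F)"].iloc[1]),
        })
    return {
        "model": full,
        "coefficients": pd.DataFrame({
            "estimate": full.params, "se": full.bse, "pvalue": full.pvalues,
        }),
        "drop_tests": pd.DataFrame(drops),
        "n": len(df),
    }


def dnds_group_compare(omegas: pd.Series, groups: pd.Series) -> pd.DataFrame:
    """Pairwise Mann-Whitney comparisons of omega between gene groups.

    Invalid/NA omegas are excluded (count logged); groups of size 1 are
    skipped; a group with no valid omega at all raises.
    """
    df = pd.DataFrame({"omega": omegas, "group": groups})
    n_na = int(df["omega"].isna().sum())
    if n_na:
        logger.info("excluding %d genes with undefined omega", n_na)
    valid = df.dropna(subset=["omega"])
    for name in df["group"].dropna().unique():
        if (valid["group"] == name).sum() == 0:
            raise ValueError(f"group {name!r} has no valid omega values")
    names = sorted(valid["group"].unique())
    rows = []
    for a, b in itertools.combinations(names, 2):
        va = valid.loc[valid["group"] == a, "omega"].to_numpy()
        vb = valid.loc[valid["group"] == b, "omega"].to_numpy()
        row = {"group_a": a, "group_b": b, "n_a": va.size, "n_b": vb.size,
               "median_a": float(np.median(va)), "median_b": float(np.median(vb))}
        if va.size < 2 or vb.size < 2:
            logger.info("comparison %s vs %s skipped: group of size 1", a, b)
            row["pvalue"] = np.nan
        else:
            _, row["pvalue"] = mann_whitney(va, vb)
        rows.append(row)
    return pd.DataFrame(rows)
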