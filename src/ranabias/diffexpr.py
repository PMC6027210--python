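"""Expression filtering, normalization and negative-binomial sex-bias testing.

The workflow per stage/tissue class is: filter weakly expressed genes on
pre-normalization CPM, compute TMM scaling factors (trimmed mean of
M-values), test XY vs XX samples with a conditional negative-binomial exact
test under a common moment-estimated dispersion, adjust p-values with
Benjamini-Hochberg, and call a gene sex-biased when both FDR < 0.05 and
|log2 fold change| >= 1 hold.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from ranabias.io_formats import CountsMatrix

logger = logging.getLogger(__name__)

#: Floor for the common NB dispersion (quasi-Poisson limit).
MIN_DISPERSION = 1e-4


# ---------------------------------------------------------------------------
# expression units
# ---------------------------------------------------------------------------

def lib_sizes(counts: pd.DataFrame) -> pd.Series:
    return counts.sum(axis=0)


def cpm(counts: pd.DataFrame, eff_lib_sizes: pd.Series | None = None,
        prior_count: float = 0.0) -> pd.DataFrame:
    """Counts per million. ``eff_lib_sizes`` allows TMM-adjusted libraries.

    With ``prior_count`` > 0 the edgeR-style shifted version
    ``(count + prior) / (lib + 2 * prior) * 1e6`` is returned, which keeps
    log-CPM finite for zero counts.
    """
    libs = lib_sizes(counts) if eff_lib_sizes is None else eff_lib_sizes
    if prior_count > 0:
        return (counts + prior_count).div(libs + 2 * prior_count, axis=1) * 1e6
    return counts.div(libs, axis=1) * 1e6


def rpkm(counts: pd.DataFrame, lengths: pd.Series,
         eff_lib_sizes: pd.Series | None = None) -> pd.DataFrame:
    """Reads per kilobase per million mapped reads."""
    libs = lib_sizes(counts) if eff_lib_sizes is None else eff_lib_sizes
    return counts.div(libs / 1e6, axis=1).div(lengths / 1e3, axis=0)


def tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: length-normalized, then scaled to 1e6."""
    rate = counts.div(lengths, axis=0)
    return rate.div(rate.sum(axis=0), axis=1) * 1e6


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def tmm_factors(counts: pd.DataFrame, ref_sample: str | None = None,
                m_trim: float = 0.30, a_trim: float = 0.05) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference sample is the one whose CPM upper quartile is closest to
    the mean upper quartile. M (log ratio) and A (log abundance) values of
    genes nonzero in both libraries are trimmed two-sided (30% on M, 5% on
    A) and averaged with inverse asymptotic-variance (binomial) weights.
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    libs = lib_sizes(counts).to_numpy(dtype=float)
    mat = counts.to_numpy(dtype=float)
    nonzero_per_sample = (mat > 0).sum(axis=0)
    if (nonzero_per_sample < 2).any():
        bad = counts.columns[nonzero_per_sample < 2][0]
        raise ValueError(f"degenerate sample {bad!r}: fewer than two nonzero genes")
    q75 = np.quantile(mat / libs, 0.75, axis=0)
    if ref_sample is None:
        ref_idx = int(np.argmin(np.abs(q75 - q75.mean())))
    else:
        ref_idx = counts.columns.get_loc(ref_sample)
    ref = mat[:, ref_idx]
    ref_lib = libs[ref_idx]

    log_factors = np.zeros(counts.shape[1])
    for j in range(counts.shape[1]):
        if j == ref_idx:
            continue
        obs = mat[:, j]
        keep = (obs > 0) & (ref > 0)
        p_obs = obs[keep] / libs[j]
        p_ref = ref[keep] / ref_lib
        m = np.log2(p_obs / p_ref)
        a = 0.5 * np.log2(p_obs * p_ref)
        if np.allclose(m.max(initial=0.0), m.min(initial=0.0)):
            log_factors[j] = float(m[0]) if m.size else 0.0
            continue
        n = m.size
        m_rank = pd.Series(m).rank(method="first").to_numpy()
        a_rank = pd.Series(a).rank(method="first").to_numpy()
        lo_m, hi_m = np.floor(n * m_trim) + 1, n - np.floor(n * m_trim)
        lo_a, hi_a = np.floor(n * a_trim) + 1, n - np.floor(n * a_trim)
        keep2 = (m_rank >= lo_m) & (m_rank <= hi_m) & (a_rank >= lo_a) & (a_rank <= hi_a)
        if not keep2.any():
            keep2 = np.ones(n, dtype=bool)
        w = 1.0 / (
            (libs[j] - obs[keep]) / (libs[j] * obs[keep])
            + (ref_lib - ref[keep]) / (ref_lib * ref[keep])
        )
        log_factors[j] = float(np.sum(w[keep2] * m[keep2]) / np.sum(w[keep2]))

    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns, name="tmm_factor")


def effective_lib_sizes(counts: pd.DataFrame,
                        factors: pd.Series | None = None) -> pd.Series:
    if factors is None:
        factors = tmm_factors(counts)
    return lib_sizes(counts) * factors


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def filter_expressed(cm: CountsMatrix, samples: pd.DataFrame, class_name: str) -> list[str]:
    """Genes considered expressed in a class.

    A gene is kept when its mean log2(CPM) across the class's samples is
    > 0 AND its CPM exceeds 1 in at least half of the samples of each
    genetic sex. CPM is computed before TMM scaling; the log uses a 0.5
    prior count so zeros stay finite.
    """
    sub = samples[samples["class"] == class_name]
    if sub.empty:
        raise ValueError(f"class {class_name!r} has no samples")
    for sex in ("XX", "XY"):
        if (sub["sex"] == sex).sum() < 2:
            raise ValueError(f"class {class_name!r} needs >=2 {sex} samples")
    ids = list(sub["sample_id"])
    counts = cm.counts[ids]
    raw_cpm = cpm(counts)
    log_cpm = np.log2(cpm(counts, prior_count=0.5))
    keep = log_cpm.mean(axis=1) > 0
    for sex in ("XX", "XY"):
        sex_ids = list(sub.loc[sub["sex"] == sex, "sample_id"])
        frac = (raw_cpm[sex_ids] > 1).sum(axis=1)
        keep &= frac >= np.ceil(len(sex_ids) / 2)
    return list(counts.index[keep])


# ---------------------------------------------------------------------------
# NB exact test
# ---------------------------------------------------------------------------

def estimate_common_dispersion(scaled: np.ndarray, groups: list[np.ndarray],
                               min_mean: float = 20.0) -> float:
    """Moment estimator of a common NB dispersion.

    Applies the within-group relation Var = mu + phi * mu^2 gene by gene on
    depth-equalized counts (restricted to group means above ``min_mean``,
    where the quadratic term dominates), then averages the per-gene
    estimates weighted by residual degrees of freedom. Each well-expressed
    gene contributes equally, so the estimate is not dominated by the most
    abundant genes, and only within-group variability enters, so implanted
    group differences do not inflate it. Floored at :data:`MIN_DISPERSION`.
    """
    ests = []
    weights = []
    for idx in groups:
        if len(idx) < 2:
            continue
        sub = scaled[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m >= min_mean
        ests.append((v[ok] - m[ok]) / m[ok] ** 2)
        weights.append(np.full(ok.sum(), len(idx) - 1, dtype=float))
    if not ests:
        return MIN_DISPERSION
    phi_g = np.concatenate(ests)
    w = np.concatenate(weights)
    if phi_g.size == 0 or w.sum() == 0:
        return MIN_DISPERSION
    phi = float(np.sum(w * phi_g) / np.sum(w))
    return float(max(phi, MIN_DISPERSION))


def _exact_pvalue(y_a: int, y_b: int, n_a: int, n_b: int, phi: float) -> float:
    """Two-sided conditional NB exact p-value.

    Conditional on the total, the group-A sum follows a negative
    hypergeometric law with shape parameters n_a/phi and n_b/phi; the
    two-sided p-value sums all outcomes no more probable than the observed
    one.
    """
    t = y_a + y_b
    if t == 0:
        return 1.0
    r_a, r_b = n_a / phi, n_b / phi
    mu = t * n_a / (n_a + n_b)
    # support window around the mode; tails beyond 60 SD are negligible
    sd = np.sqrt(mu * (1 + mu * phi / n_a))
    lo = int(max(0, np.floor(min(mu - 60 * sd, y_a - 1))))
    hi = int(min(t, np.ceil(max(mu + 60 * sd, y_a + 1))))
    y = np.arange(lo, hi + 1)
    lw = (
        gammaln(y + r_a) - gammaln(y + 1)
        + gammaln(t - y + r_b) - gammaln(t - y + 1)
    )
    lw -= logsumexp(lw)
    obs = lw[y_a - lo]
    return float(min(1.0, np.exp(logsumexp(lw[lw <= obs + 1e-12]))))


def nb_exact_test(counts: pd.DataFrame, group_a: list[str], group_b: list[str],
                  dispersion: float | None = None,
                  eff_libs: pd.Series | None = None) -> pd.Series:
    """Per-gene two-sided p-values for equal NB means between two groups.

    Counts are rescaled to a common effective depth (geometric mean of the
    TMM-adjusted library sizes), summed within groups and compared with a
    conditional exact test. The common dispersion defaults to the pooled
    moment estimate across genes.
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be nonempty")
    ids = list(group_a) + list(group_b)
    sub = counts[ids]
    if eff_libs is None:
        eff_libs = effective_lib_sizes(sub)
    eff = eff_libs[ids].to_numpy(dtype=float)
    common = float(np.exp(np.mean(np.log(eff))))
    scaled = sub.to_numpy(dtype=float) * (common / eff)
    n_a, n_b = len(group_a), len(group_b)
    idx_a = np.arange(n_a)
    idx_b = np.arange(n_a, n_a + n_b)
    if dispersion is None:
        dispersion = estimate_common_dispersion(scaled, [idx_a, idx_b])
    y_a = np.rint(scaled[:, idx_a].sum(axis=1)).astype(np.int64)
    y_b = np.rint(scaled[:, idx_b].sum(axis=1)).astype(np.int64)
    pvals = np.array([
        _exact_pvalue(int(a), int(b), n_a, n_b, dispersion)
        for a, b in zip(y_a, y_b)
    ])
    return pd.Series(pvals, index=counts.index, name="pvalue")


def bh_adjust(pvalues: pd.Series | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# sex-bias calling
# ---------------------------------------------------------------------------

def fold_change_category(log2fc: float, biased: bool) -> str:
    """Fold-change band label: 2 (low), 2-4 (mild), 4-8 (high), >8 (very high)."""
    if not biased:
        return "none"
    a = abs(log2fc)
    if a == 1.0:
        return "low"
    if a < 2.0:
        return "mild"
    if a < 3.0:
        return "high"
    return "very_high"


def call_sex_bias(cm: CountsMatrix, samples: pd.DataFrame, class_name: str,
                  fdr: float = 0.05, lfc_threshold: float = 1.0,
                  dispersion: float | None = None,
                  prior_count: float = 0.5) -> pd.DataFrame:
    """Call sex-biased genes in one stage/tissue class.

    Returns one row per expressed gene with the male/female log2 fold
    change (negative = female-biased), p- and BH q-values, the bias call
    (q < ``fdr`` AND |log2FC| >= ``lfc_threshold``), its direction, and the
    fold-change category.
    """
    genes = filter_expressed(cm, samples, class_name)
    sub = samples[samples["class"] == class_name]
    males = list(sub.loc[sub["sex"] == "XY", "sample_id"])
    females = list(sub.loc[sub["sex"] == "XX", "sample_id"])
    counts = cm.counts.loc[genes, males + females]
    eff = effective_lib_sizes(counts)
    pvals = nb_exact_test(counts, males, females, dispersion=dispersion, eff_libs=eff)
    qvals = bh_adjust(pvals)
    norm_cpm = cpm(counts, eff_lib_sizes=eff)
    mean_m = norm_cpm[males].mean(axis=1)
    mean_f = norm_cpm[females].mean(axis=1)
    log2fc = np.log2((mean_m + prior_count) / (mean_f + prior_count))
    biased = (qvals < fdr) & (np.abs(log2fc) >= lfc_threshold)
    direction = np.where(~biased, "none", np.where(log2fc > 0, "male", "female"))
    out = pd.DataFrame({
        "gene": genes,
        "class": class_name,
        "log2fc": log2fc.to_numpy(),
        "pvalue": pvals.to_numpy(),
        "qvalue": qvals,
        "biased": biased.to_numpy(),
        "direction": direction,
        "mean_cpm_male": mean_m.to_numpy(),
        "mean_cpm_female": mean_f.to_numpy(),
    })
    out["category"] = [
        fold_change_category(l, b) for l, b in zip(out["log2fc"], out["biased"])
    ]
    return out.reset_index(drop=True)
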