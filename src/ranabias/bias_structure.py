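"""Structure of sex bias: direction-excess tests and expression-driver bins.

Covers three questions about a class's sex-biased gene set: is one
direction in excess (chi-square against 50:50), how should sex-specific
genes be kept in expression summaries (pseudo-count rule), and which sex
drives increasing bias (mean log2 RPKM per sex across nested fold-change
bins, compared with Wilcoxon rank-sum tests).
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats

from ranabias._stats import mann_whitney

logger = logging.getLogger(__name__)

#: Signed log2FC thresholds that define the driver bins.
DRIVER_THRESHOLDS = (1, 3, 5, 7)


def chi_square_excess(n_female: int, n_male: int) -> tuple[float, float]:
    """One-df chi-square goodness of fit of a 50:50 direction split.

    No continuity correction. Returns ``(chi2, p)``.
    """
    if n_female < 0 or n_male < 0:
        raise ValueError("counts must be non-negative")
    total = n_female + n_male
    if total == 0:
        raise ValueError("at least one biased gene required")
    expected = total / 2.0
    chi2 = (n_female - expected) ** 2 / expected + (n_male - expected) ** 2 / expected
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def excess_table(sexbias: pd.DataFrame,
                 fc_thresholds: tuple[float, ...] = (1.0, 2.0, 3.0)) -> pd.DataFrame:
    """Direction-excess tests at the FDR-only and fold-change thresholds.

    ``fc_thresholds`` are |log2FC| cut-offs applied on top of the FDR
    gate (1, 2, 3 correspond to fold changes 2, 4 and 8).
    """
    rows = []
    for cls, sub in sexbias.groupby("class"):
        biased = sub[sub["biased"]]
        levels = [("FDR_only", 0.0)] + [
            (f"FC{int(2 ** t)}", t) for t in fc_thresholds
        ]
        for label, thr in levels:
            sel = biased[biased["log2fc"].abs() >= thr] if thr else biased
            n_f = int((sel["direction"] == "female").sum())
            n_m = int((sel["direction"] == "male").sum())
            if n_f + n_m == 0:
                rows.append({"class": cls, "threshold": label, "n_female": 0,
                             "n_male": 0, "chi2": np.nan, "pvalue": np.nan})
                continue
            chi2, p = chi_square_excess(n_f, n_m)
            rows.append({"class": cls, "threshold": label, "n_female": n_f,
                         "n_male": n_m, "chi2": chi2, "pvalue": p})
    return pd.DataFrame(rows)


def apply_sexspecific_pseudocount(
    rpkm_mat: pd.DataFrame, samples: pd.DataFrame
) -> pd.DataFrame:
    """Keep sex-specific genes analyzable: replace their zeros by min/10.

    For genes with zero expression in every sample of one sex, the zero
    entries are replaced by one tenth of the smallest positive RPKM in the
    whole matrix. Other entries are untouched, so the operation is
    idempotent: after one pass those genes have no zeros left.
    """
    mat = rpkm_mat.to_numpy(dtype=float)
    positive = mat[mat > 0]
    if positive.size == 0:
        raise ValueError("all-zero expression matrix")
    pseudo = positive.min() / 10.0
    out = rpkm_mat.copy()
    meta = samples.set_index("sample_id")
    sexes = meta.loc[rpkm_mat.columns, "sex"].to_numpy()
    for sex in ("XX", "XY"):
        cols = rpkm_mat.columns[sexes == sex]
        if len(cols) == 0:
            continue
        zero_in_sex = (rpkm_mat[cols] == 0).all(axis=1)
        for col in cols:
            out.loc[zero_in_sex, col] = out.loc[zero_in_sex, col].replace(0.0, pseudo)
    return out


def driver_bins(
    sexbias: pd.DataFrame,
    rpkm_mat: pd.DataFrame,
    samples: pd.DataFrame,
    class_name: str,
    min_biased: int = 100,
) -> pd.DataFrame:
    """Mean log2 RPKM per sex in nested signed fold-change bins.

    For each signed threshold t in +/-{1,3,5,7}, the bin holds the biased
    genes with log2FC beyond t (male-biased bins nest upward, female-biased
    downward). Per bin and sex the mean log2 RPKM across the class's
    samples of that sex is summarized per gene; Wilcoxon rank-sum
    p-values compare successive bins within a sex and the two sexes within
    a bin. A negative mean log2 RPKM marks raw RPKM below 1, flagged
    non-interpretable.
    """
    sub = sexbias[(sexbias["class"] == class_name) & sexbias["biased"]]
    if len(sub) < min_biased:
        raise ValueError(
            f"class {class_name!r} has {len(sub)} biased genes (< {min_biased})"
        )
    meta = samples[samples["class"] == class_name].set_index("sample_id")
    cols = [c for c in rpkm_mat.columns if c in meta.index]
    sex_of = meta.loc[cols, "sex"]
    rpkm_cls = apply_sexspecific_pseudocount(
        rpkm_mat[cols], samples[samples["class"] == class_name]
    )
    log_rpkm = np.log2(rpkm_cls.where(rpkm_cls > 0))

    per_sex_mean = {
        sex: log_rpkm[[c for c in cols if sex_of[c] == sex]].mean(axis=1)
        for sex in ("XX", "XY")
    }

    rows = []
    bin_members: dict[tuple[str, int], pd.Index] = {}
    for sign, direction in ((1, "male"), (-1, "female")):
        for t in DRIVER_THRESHOLDS:
            if sign > 0:
                genes = sub.loc[sub["log2fc"] >= t, "gene"]
            else:
                genes = sub.loc[sub["log2fc"] <= -t, "gene"]
            idx = pd.Index(genes)
            bin_members[(direction, t)] = idx
            row = {"class": class_name, "direction": direction,
                   "threshold": sign * t, "n_genes": len(idx)}
            for sex, label in (("XY", "male"), ("XX", "female")):
                vals = per_sex_mean[sex].reindex(idx).dropna()
                mean = float(vals.mean()) if len(vals) else np.nan
                row[f"mean_log2rpkm_{label}"] = mean
                row[f"interpretable_{label}"] = bool(np.isfinite(mean) and mean > 0)
            # between-sex comparison within the bin
            a = per_sex_mean["XY"].reindex(idx).dropna()
            b = per_sex_mean["XX"].reindex(idx).dropna()
            if len(a) >= 2 and len(b) >= 2:
                _, row["p_between_sex"] = mann_whitney(a, b)
            else:
                row["p_between_sex"] = np.nan
            rows.append(row)
    out = pd.DataFrame(rows)

    # successive-bin comparisons within each sex
    cmp_rows = []
    for direction in ("male", "female"):
        for t0, t1 in itertools.pairwise(DRIVER_THRESHOLDS):
            g0 = bin_members[(direction, t0)]
            g1 = bin_members[(direction, t1)]
            for sex, label in (("XY", "male"), ("XX", "female")):
                a = per_sex_mean[sex].reindex(g0).dropna()
                b = per_sex_mean[sex].reindex(g1).dropna()
                if len(a) >= 2 and len(b) >= 2:
                    _, p = mann_whitney(a, b)
                else:
                    p = np.nan
                    logger.info("empty/small bin %s >=%d vs >=%d (%s): skipped",
                                direction, t0, t1, label)
                cmp_rows.append({
                    "class": class_name, "direction": direction,
                    "bins": f">={t0}_vs_>={t1}", "sex": label, "pvalue": p,
                })
    out.attrs["between_bin_tests"] = pd.DataFrame(cmp_rows)
    return out
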