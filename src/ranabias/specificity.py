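"""Tissue/stage specificity: pooled TPM profiles and the Tau index.

Expression is pooled into eleven stage/tissue classes (five sex-pooled,
six sex-limited) and summarized per gene by Tau,

    tau = sum_i [1 - log(TPM_i) / log(TPM_max)] / (N - 1),

which is 0 for uniform expression and 1 for expression confined to a
single class. TPM values below 1 are floored to 1 before taking logs, the
convention of the benchmark tissue-specificity literature: it suppresses
transcriptional leakage and keeps the index defined. Genes with no class
above 1 TPM have undefined Tau and are excluded from specificity analyses.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ranabias.constants import POOLED_CLASSES, PROFILE_CLASSES
from ranabias.diffexpr import tpm
from ranabias.io_formats import CountsMatrix

logger = logging.getLogger(__name__)


def pool_profiles(cm: CountsMatrix, samples: pd.DataFrame) -> pd.DataFrame:
    """Mean TPM per gene over the eleven stage/tissue classes.

    The five pooled classes average both sexes; G43/G46 split by genetic
    sex; the gonad class splits into testis (XY) and ovary (XX). Columns
    follow :data:`~ranabias.constants.PROFILE_CLASSES` order.
    """
    tpm_mat = tpm(cm.counts, cm.lengths)
    sample_class: dict[str, str] = {}
    for _, row in samples.iterrows():
        cls, sex = row["class"], row["sex"]
        if cls in POOLED_CLASSES:
            profile = cls
        elif cls == "gonad":
            profile = "testis" if sex == "XY" else "ovary"
        else:
            profile = f"{cls}_{sex}"
        sample_class[row["sample_id"]] = profile
    present = set(sample_class.values())
    missing = [c for c in PROFILE_CLASSES if c not in present]
    if missing:
        raise ValueError(f"missing profile classes: {', '.join(missing)}")
    cols = {}
    for profile in PROFILE_CLASSES:
        ids = [s for s, p in sample_class.items() if p == profile]
        cols[profile] = tpm_mat[ids].mean(axis=1)
    return pd.DataFrame(cols, index=cm.counts.index)[list(PROFILE_CLASSES)]


def tau(profile: np.ndarray | pd.Series, floor: float = 1.0) -> float:
    """Tau specificity index of one expression profile.

    Values below ``floor`` (1 TPM) are floored before logs. Returns NaN
    when every class is at or below the floor (undefined specificity).
    The log base cancels in the ratio, so any base gives the same value.
    """
    x = np.asarray(profile, dtype=float)
    if (x < 0).any():
        raise ValueError("expression must be non-negative")
    x = np.maximum(x, floor)
    log_x = np.log(x)
    log_max = log_x.max()
    if log_max <= 0:
        return float("nan")
    return float(np.sum(1.0 - log_x / log_max) / (len(x) - 1))


def tau_table(profiles: pd.DataFrame, thresholds: tuple[float, float] = (0.8, 0.9)) -> pd.DataFrame:
    """Per-gene Tau with tissue-specific flags (tau > 0.8 / > 0.9).

    ``max_class`` records the class with the highest TPM.
    """
    taus = profiles.apply(lambda row: tau(row.to_numpy()), axis=1)
    out = pd.DataFrame({
        "gene": profiles.index,
        "tau": taus.to_numpy(),
        "max_class": profiles.idxmax(axis=1).to_numpy(),
    })
    out["specific_080"] = out["tau"] > thresholds[0]
    out["specific_090"] = out["tau"] > thresholds[1]
    out.loc[out["tau"].isna(), ["specific_080", "specific_090"]] = False
    return out.reset_index(drop=True)


def top_fraction_summary(
    profiles: pd.DataFrame,
    taus: pd.DataFrame,
    fractions: tuple[float, ...] = (0.10, 0.30, 0.70, 0.90),
) -> pd.DataFrame:
    """Mean Tau of each class's most expressed genes at several cut-offs.

    For each class, genes are ranked by that class's TPM (ties broken by
    gene id for determinism) and the mean Tau of the top fraction is
    reported. Genes with undefined Tau are excluded.
    """
    for f in fractions:
        if not 0.0 < f <= 1.0:
            raise ValueError(f"fraction {f} outside (0, 1]")
    tau_by_gene = taus.set_index("gene")["tau"].dropna()
    rows = []
    for cls in profiles.columns:
        expr = profiles.loc[tau_by_gene.index, cls]
        # deterministic ranking: descending TPM, ties by gene id
        lex = np.lexsort((expr.index.to_numpy(), -expr.to_numpy()))
        order = expr.iloc[lex]
        for f in fractions:
            k = max(1, int(np.ceil(f * len(order))))
            top = order.index[:k]
            rows.append({
                "class": cls,
                "fraction": f,
                "n_genes": k,
                "mean_tau": float(tau_by_gene.loc[top].mean()),
            })
    return pd.DataFrame(rows)


def spearman_bias_tau(
    sexbias: pd.DataFrame,
    taus: pd.DataFrame,
    class_name: str,
    min_biased: int = 100,
    signed: bool = False,
) -> tuple[float, float] | None:
    """Spearman correlation between sex-bias strength and Tau in one class.

    Uses |log2FC| by default (``signed=True`` correlates the raw signed
    ratio instead). Skips the class — returning None with a log message —
    when it has fewer than ``min_biased`` sex-biased genes.
    """
    sub = sexbias[sexbias["class"] == class_name]
    n_biased = int(sub["biased"].sum())
    if n_biased < min_biased:
        logger.info(
            "class %s skipped: %d sex-biased genes (< %d)",
            class_name, n_biased, min_biased,
        )
        return None
    merged = sub.merge(taus[["gene", "tau"]], on="gene").dropna(subset=["tau"])
    x = merged["log2fc"] if signed else merged["log2fc"].abs()
    if x.nunique() < 2 or merged["tau"].nunique() < 2:
        raise ValueError("constant vector: Spearman correlation undefined")
    rho, p = stats.spearmanr(x, merged["tau"])
    return float(rho), float(p)
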