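"""Sex-bias turnover between stage/tissue pairs.

A gene "turns over" when it is sex-biased in two classes with opposite
direction (male->female or female->male). Turnover is counted only among
genes sex-biased in both classes; genes biased in one class only are not
shared and do not count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ranabias._stats import mann_whitney

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TurnoverSummary:
    class_a: str
    class_b: str
    n_shared: int
    n_f2m: int
    n_m2f: int

    @property
    def n_turnover(self) -> int:
        return self.n_f2m + self.n_m2f

    @property
    def proportion(self) -> float:
        """Turnover fraction of shared sex-biased genes (NaN when none shared)."""
        if self.n_shared == 0:
            return float("nan")
        return self.n_turnover / self.n_shared

    @property
    def proportion_pct(self) -> float:
        """Proportion rounded to whole percent, as reported."""
        return turnover_proportion_pct(self.n_shared, self.n_f2m, self.n_m2f)


def turnover_proportion_pct(n_shared: int, n_f2m: int, n_m2f: int) -> float:
    """Turnover proportion in whole percent from the three counts."""
    if n_shared == 0:
        return float("nan")
    if n_f2m + n_m2f > n_shared:
        raise ValueError("turnover counts exceed shared genes")
    return float(round(100.0 * (n_f2m + n_m2f) / n_shared))


def _shared_directions(bias_a: pd.DataFrame, bias_b: pd.DataFrame) -> pd.DataFrame:
    a = bias_a.loc[bias_a["biased"], ["gene", "direction"]].rename(
        columns={"direction": "dir_a"})
    b = bias_b.loc[bias_b["biased"], ["gene", "direction"]].rename(
        columns={"direction": "dir_b"})
    return a.merge(b, on="gene")


def turnover_summary(bias_a: pd.DataFrame, bias_b: pd.DataFrame) -> TurnoverSummary:
    """Count shared sex-biased genes and direction switches between classes."""
    shared = _shared_directions(bias_a, bias_b)
    n_shared = len(shared)
    if n_shared == 0:
        logger.warning("no shared sex-biased genes between %s and %s",
                       bias_a["class"].iloc[0] if len(bias_a) else "?",
                       bias_b["class"].iloc[0] if len(bias_b) else "?")
    n_f2m = int(((shared["dir_a"] == "female") & (shared["dir_b"] == "male")).sum())
    n_m2f = int(((shared["dir_a"] == "male") & (shared["dir_b"] == "female")).sum())
    return TurnoverSummary(
        class_a=bias_a["class"].iloc[0] if len(bias_a) else "",
        class_b=bias_b["class"].iloc[0] if len(bias_b) else "",
        n_shared=n_shared,
        n_f2m=n_f2m,
        n_m2f=n_m2f,
    )


def turnover_table(bias_tables: dict[str, pd.DataFrame],
                   shared_min: int = 35) -> pd.DataFrame:
    """All class pairs with more than ``shared_min`` shared sex-biased genes."""
    rows = []
    names = sorted(bias_tables)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            s = turnover_summary(bias_tables[a], bias_tables[b])
            if s.n_shared > shared_min:
                rows.append({
                    "class_a": a, "class_b": b, "n_shared": s.n_shared,
                    "n_f2m": s.n_f2m, "n_m2f": s.n_m2f,
                    "proportion_pct": s.proportion_pct,
                })
    return pd.DataFrame(rows)


def consistency_classes(bias_a: pd.DataFrame, bias_b: pd.DataFrame) -> pd.Series:
    """Partition shared sex-biased genes into consistency classes.

    Returns a Series indexed by gene with values in
    {'consistent_male', 'consistent_female', 'turnover'}.
    """
    shared = _shared_directions(bias_a, bias_b)
    label = np.where(
        shared["dir_a"] == shared["dir_b"],
        np.where(shared["dir_a"] == "male", "consistent_male", "consistent_female"),
        "turnover",
    )
    return pd.Series(label, index=shared["gene"], name="consistency")


def class_compare(values: pd.Series, classes: pd.Series) -> pd.DataFrame:
    """Pairwise Mann-Whitney comparisons of a per-gene quantity by class.

    ``values`` (e.g. dN/dS or Tau) and ``classes`` are aligned on gene.
    Classes with fewer than two members are skipped with a log message.
    Raw two-sided p-values, no multiplicity correction.
    """
    merged = pd.DataFrame({"value": values, "cls": classes}).dropna()
    groups = {
        name: grp["value"].to_numpy()
        for name, grp in merged.groupby("cls")
        if len(grp) >= 1
    }
    names = sorted(groups)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            row = {
                "class_a": a, "class_b": b,
                "n_a": len(groups[a]), "n_b": len(groups[b]),
                "median_a": float(np.median(groups[a])),
                "median_b": float(np.median(groups[b])),
            }
            if len(groups[a]) < 2 or len(groups[b]) < 2:
                logger.info("comparison %s vs %s skipped: class too small", a, b)
                row["pvalue"] = np.nan
            else:
                _, row["pvalue"] = mann_whitney(groups[a], groups[b])
            rows.append(row)
    return pd.DataFrame(rows)
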