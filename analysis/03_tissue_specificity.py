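#!/usr/bin/env python
"""Tau tissue specificity over the eleven pooled stage/tissue classes.

Computes per-gene Tau from pooled TPM profiles, counts tissue-specific
genes (Tau > 0.8 and > 0.9) per maximally expressing class, summarizes the
specificity of each class's most expressed genes (top 10/30/70/90%), and
correlates |log2FC| with Tau per class with >= 100 sex-biased genes.

Reads results/cohort/ and results/sexbias_*.tsv; writes tau.tsv,
top_fractions.tsv and spearman.tsv under results/.
"""

from pathlib import Path

import pandas as pd

from ranabias import io_formats
from ranabias.constants import SAMPLE_CLASSES
from ranabias.specificity import (
    pool_profiles,
    spearman_bias_tau,
    tau_table,
    top_fraction_summary,
)

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cm = io_formats.read_counts(ROOT / "cohort" / "counts.tsv")
    samples = io_formats.read_sample_table(ROOT / "cohort" / "samples.tsv", cm)
    profiles = pool_profiles(cm, samples)
    taus = tau_table(profiles)
    io_formats.write_result_tsv(taus, ROOT / "tau.tsv")
    specific = taus[taus["specific_080"]]
    print(f"{len(specific)} of {len(taus)} genes are tissue-specific (tau > 0.8)")
    print(specific["max_class"].value_counts().to_string())

    top = top_fraction_summary(profiles, taus)
    io_formats.write_result_tsv(top, ROOT / "top_fractions.tsv")

    rows = []
    for cls in SAMPLE_CLASSES:
        bias = pd.read_csv(ROOT / f"sexbias_{cls}.tsv", sep="\t", comment="#")
        res = spearman_bias_tau(bias, taus, cls)
        if res is None:
            continue
        rows.append({"class": cls, "rho": res[0], "pvalue": res[1]})
        print(f"{cls}: Spearman rho(|log2FC|, tau) = {res[0]:.3f} (p = {res[1]:.2g})")
    if rows:
        io_formats.write_result_tsv(pd.DataFrame(rows), ROOT / "spearman.tsv")


if __name__ == "__main__":
    main()
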