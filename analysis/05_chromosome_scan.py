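#!/usr/bin/env python
"""Chromosome placement and sex-chromosome enrichment scans.

Assigns genes to chromosomes by reciprocal best hit against the synthetic
reference, then — for the class with the most sex-biased genes — runs the
permutation enrichment test (10^4 draws, Bonferroni over 10 chromosomes x 2
directions), the sex-chromosome vs autosome Wilcoxon on log2(male/female),
and a 40-gene sliding-window scan of the expression ratio.

Reads results/cohort/ hits and sexbias tables; writes orthologs.tsv,
enrichment.tsv, ratio_wilcoxon.tsv and windows.tsv under results/.
"""

from pathlib import Path

import pandas as pd

from ranabias import io_formats
from ranabias.chromomap import (
    assignments_frame,
    enrichment_permutation,
    ratio_wilcoxon,
    rbh_orthologs,
    sliding_window,
)

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    hits_ab = io_formats.read_blast_tab(ROOT / "cohort" / "hits_AB.tsv")
    hits_ba = io_formats.read_blast_tab(ROOT / "cohort" / "hits_BA.tsv")
    truth = pd.read_csv(ROOT / "cohort" / "truth.tsv", sep="\t", comment="#")
    assignments = assignments_frame(rbh_orthologs(hits_ab, hits_ba), truth)
    io_formats.write_result_tsv(assignments, ROOT / "orthologs.tsv")
    print(f"{len(assignments)} one-to-one orthologs assigned to chromosomes")

    bias = pd.read_csv(ROOT / "sexbias_gonad.tsv", sep="\t", comment="#")
    enrich = enrichment_permutation(bias, assignments, n_perm=10_000, seed=SEED)
    io_formats.write_result_tsv(enrich, ROOT / "enrichment.tsv", seed=SEED)
    hits = enrich[enrich["p_bonf"] < 0.05]
    if hits.empty:
        print("no chromosome enriched in sex-biased genes (all p_bonf >= 0.05)")
    else:
        print(hits.to_string(index=False))

    ratios = ratio_wilcoxon(bias, assignments)
    io_formats.write_result_tsv(ratios, ROOT / "ratio_wilcoxon.tsv")
    print(ratios[["stratum", "pvalue"]].to_string(index=False))

    lfc = bias.set_index("gene")["log2fc"]
    windows = sliding_window(lfc, assignments, window=40)
    io_formats.write_result_tsv(windows, ROOT / "windows.tsv")
    print(f"{len(windows)} sliding windows written")


if __name__ == "__main__":
    main()
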