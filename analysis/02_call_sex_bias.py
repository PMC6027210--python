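#!/usr/bin/env python
"""Call sex-biased genes per stage/tissue and test direction excess.

For each of the eight classes: filter weakly expressed genes, TMM-normalize,
run the NB exact test (XY vs XX), BH-adjust, and call bias at FDR < 0.05
with |log2FC| >= 1. Then chi-square the female/male direction split at the
FDR-only and fold-change 2/4/8 thresholds.

Reads results/cohort/, writes sexbias_<class>.tsv and excess.tsv under
results/.
"""

from pathlib import Path

import pandas as pd

from ranabias import io_formats
from ranabias.bias_structure import excess_table
from ranabias.constants import SAMPLE_CLASSES
from ranabias.diffexpr import call_sex_bias

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cm = io_formats.read_counts(ROOT / "cohort" / "counts.tsv")
    samples = io_formats.read_sample_table(ROOT / "cohort" / "samples.tsv", cm)
    tables = []
    for cls in SAMPLE_CLASSES:
        tbl = call_sex_bias(cm, samples, cls)
        io_formats.write_result_tsv(tbl, ROOT / f"sexbias_{cls}.tsv")
        n_m = (tbl["direction"] == "male").sum()
        n_f = (tbl["direction"] == "female").sum()
        print(f"{cls:>6}: {int(tbl['biased'].sum()):4d} sex-biased "
              f"({n_m} male / {n_f} female) of {len(tbl)} expressed")
        tables.append(tbl)
    excess = excess_table(pd.concat(tables, ignore_index=True))
    io_formats.write_result_tsv(excess, ROOT / "excess.tsv")
    sig = excess[excess["pvalue"] < 0.05]
    print(f"direction excess significant in {len(sig)} class/threshold cells")


if __name__ == "__main__":
    main()
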