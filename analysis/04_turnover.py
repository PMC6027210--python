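#!/usr/bin/env python
"""Sex-bias turnover between class pairs and properties of shared genes.

Counts direction switches (male<->female) among genes sex-biased in both
members of each class pair with > 35 shared sex-biased genes, partitions
shared genes into consistency classes, and compares their Tau.

Reads results/sexbias_*.tsv and results/tau.tsv; writes turnover.tsv and
turnover_tau_compare.tsv under results/.
"""

from pathlib import Path

import pandas as pd

from ranabias import io_formats
from ranabias.constants import SAMPLE_CLASSES
from ranabias.turnover import class_compare, consistency_classes, turnover_table

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    bias = {
        cls: pd.read_csv(ROOT / f"sexbias_{cls}.tsv", sep="\t", comment="#")
        for cls in SAMPLE_CLASSES
    }
    turn = turnover_table(bias, shared_min=35)
    io_formats.write_result_tsv(turn, ROOT / "turnover.tsv")
    if turn.empty:
        print("no class pair exceeds 35 shared sex-biased genes")
        return
    print(turn.to_string(index=False))

    taus = pd.read_csv(ROOT / "tau.tsv", sep="\t", comment="#").set_index("gene")
    frames = []
    for _, row in turn.iterrows():
        cls = consistency_classes(bias[row["class_a"]], bias[row["class_b"]])
        cmp_df = class_compare(taus["tau"].reindex(cls.index), cls)
        cmp_df.insert(0, "pair", f"{row['class_a']}|{row['class_b']}")
        frames.append(cmp_df)
    out = pd.concat(frames, ignore_index=True)
    io_formats.write_result_tsv(out, ROOT / "turnover_tau_compare.tsv")
    print(f"Tau comparisons written for {len(frames)} pairs")


if __name__ == "__main__":
    main()
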