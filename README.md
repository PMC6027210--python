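# ranabias

Sex-biased gene expression, tissue specificity and coding-sequence
evolution in a multi-stage, multi-tissue amphibian RNA-seq design.

`ranabias` is an analysis pipeline for studies of the common frog type:
expression is measured across five Gosner developmental stages (G23, G27,
G31, G43, G46; whole bodies) and three adult tissues (brain, liver, gonad)
in both genetic sexes (XX/XY — the sex chromosomes are homomorphic, so
sexing is genotypic). The package is aimed at evolutionary geneticists who
want to ask, in one coherent workflow:

- which genes are sex-biased at each stage/tissue, and in which direction;
- how tissue-specific each gene's expression is, and how specificity
  relates to the strength of sex bias;
- how often sex bias *turns over* (male-biased here, female-biased there);
- whether the sex chromosomes (chromosomes 1 and 2 in this system) are
  enriched in sex-biased genes;
- whether sex-biased genes evolve faster, and whether sex bias or
  pleiotropy (tissue specificity) better explains the rate.

Because raw reads for such studies are often unavailable, the package
ships a first-class synthetic-data generator that emulates the full study
design with known ground truth, so every stage of the pipeline is testable
end to end.

## Models and statistics

**Sex-bias calling.** Per class, genes are filtered (mean log2 CPM > 0 and
CPM > 1 in at least half the samples of each sex), libraries are scaled by
TMM (trimmed mean of M-values), and XY vs XX counts are compared with a
conditional negative-binomial exact test under a common moment-estimated
dispersion. A gene is *sex-biased* when both BH-FDR < 0.05 and
|log2FC| ≥ 1, with log2FC = log2(male/female) (negative = female-biased);
fold-change categories are 2 (low), 2–4 (mild), 4–8 (high), >8 (very high).

**Tissue specificity.** Expression is pooled into eleven stage/tissue
classes (G23, G27, G31, brain, liver pooled over sexes; female/male G43,
female/male G46, testis, ovary) and summarized by the Tau index

    tau = sum_i [ 1 − log(TPM_i) / log(TPM_max) ] / (N − 1),   N = 11,

with TPM floored at 1 before logs. Tau is 0 for uniform expression, 1 for
single-class expression; genes with tau > 0.8 are called tissue-specific.

**Chromosome enrichment.** Genes are placed on the 10 chromosomes via
reciprocal-best-hit orthology (e-value < 1e-10, ≥ 50% overlap of both
sequences, ≥ 40% identity) to a syntenic reference. Per chromosome and
direction, the observed biased-gene count is compared with 10^4 random
same-size draws from all assigned genes (add-one Monte-Carlo p,
Bonferroni over 10 chromosomes × 2 directions), complemented by Wilcoxon
tests on log2(male/female) and 40-gene sliding-window scans.

**Molecular evolution.** Pairwise dN/dS (ω) from codon alignments by
Nei–Gojobori (1986) counting with Jukes–Cantor correction; multi-hit
codons are averaged over all stop-free substitution pathways. Group
comparisons use Mann–Whitney tests; the joint model is OLS of sqrt(ω) on
sex-bias class × Tau with drop-term F-tests.

## Worked example

The numbered scripts under `analysis/` run the full study on a synthetic
cohort (2000 genes, seed 1) and write their tables under `results/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/02_call_sex_bias.py
...
python analysis/06_molecular_evolution.py
```

`02_call_sex_bias.py` prints, for this cohort:

```
   G23:    2 sex-biased (1 male / 1 female) of 1982 expressed
   G27:    3 sex-biased (1 male / 2 female) of 1978 expressed
   G31:    3 sex-biased (2 male / 1 female) of 1990 expressed
   G43:   26 sex-biased (10 male / 16 female) of 1980 expressed
   G46:  268 sex-biased (137 male / 131 female) of 1976 expressed
 brain:   18 sex-biased (9 male / 9 female) of 1989 expressed
 liver:   31 sex-biased (11 male / 20 female) of 1989 expressed
 gonad:  484 sex-biased (232 male / 252 female) of 1962 expressed
```

— the implanted pattern of sex bias ramping up through development and
peaking in gonads, recovered by the pipeline. Downstream, `04_turnover.py`
finds the one class pair with more than 35 shared sex-biased genes:

```
class_a class_b  n_shared  n_f2m  n_m2f  proportion_pct
    G46   gonad       104      9      8            16.0
```

i.e. 104 genes sex-biased in both the froglet stage and adult gonads, of
which 16% switched direction. `05_chromosome_scan.py` reports no
sex-chromosome enrichment (all Bonferroni p ≥ 0.05) for the default
generator, which implants none, and `06_molecular_evolution.py` recovers
the simulated evolutionary rates with a mean absolute ω error of 0.043.

The same pipeline runs from a single YAML config via the CLI:

```sh
ranabias run --config run.yaml     # or: ranabias simulate / debias / tau / ...
```

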