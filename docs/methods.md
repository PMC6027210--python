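# Methods

This note records the statistical models, parameter choices and numerical
conventions behind `ranabias`, and what the synthetic-data generator does
and does not emulate.

## Study design

Samples come from eight stage/tissue classes — Gosner stages G23, G27,
G31, G43 (metamorph), G46 (froglet) as whole bodies, and adult brain,
liver and gonad — each with replicates of both genetic sexes (XX/XY). No
sex differences are expected before gonadal histological differentiation,
so the three early stages and the two somatic adult tissues are pooled
over sexes for specificity profiles, while G43, G46 and gonad contribute
sex-limited classes (female/male G43, female/male G46, ovary, testis),
giving the N = 11 profile classes of the Tau index.

## Sex-bias calling

*Filtering* (per class, before any between-sample normalization): keep
genes with mean log2 CPM > 0 across the class's samples (CPM computed
with a 0.5 prior count so zeros stay finite) and raw CPM > 1 in at least
half of the samples of each sex. Filtering precedes normalization because
TMM factors should be computed on the retained genes.

*TMM normalization*: the reference sample is the one whose CPM upper
quartile is closest to the mean upper quartile. For each sample, M
(log2 expression ratio vs reference) and A (average log2 abundance) are
computed over genes nonzero in both libraries, the most extreme 30% of M
and 5% of A are trimmed two-sided, and the factor is the
inverse-asymptotic-variance weighted mean of the remaining M values.
Factors are rescaled to geometric mean 1; effective library size =
library size × factor.

*Testing*: counts are rescaled to a common effective depth (geometric mean
of effective library sizes) and summed within sexes. Conditional on the
total, the group-A sum under the null follows a negative hypergeometric
law with shape parameters n_A/φ and n_B/φ, which is free of the unknown
mean; the two-sided p-value sums all outcomes no more probable than the
one observed. The support is evaluated in a window of ±60 conditional SDs
around the mode (always including the observed value); truncation error
is far below double precision.

*Common dispersion* φ: per gene and sex, the moment relation
Var = μ + φμ² gives φ_g = (s² − m)/m²; genes with within-group mean ≥ 20
(where the quadratic term dominates) are averaged with weights equal to
their residual degrees of freedom. Only within-group variability enters,
so implanted sex differences do not inflate φ. The estimate is floored at
1e-4. On null simulations at the study's replicate numbers (3–5 per sex)
this test's empirical type-I error at nominal 0.05 is 0.042–0.051
(5000-gene simulations; the exact test's discreteness makes it slightly
conservative).

*Calling*: log2FC = log2((mean male CPM + 0.5)/(mean female CPM + 0.5))
on TMM-adjusted CPM; biased ⇔ BH-FDR < 0.05 and |log2FC| ≥ 1. Fold-change
categories follow the 2 / 2–4 / 4–8 / >8 banding, read as: exactly 2 →
low, (2,4) → mild, [4,8) → high, ≥ 8 → very high; below 2-fold a gene is
unbiased regardless of FDR.

## Tau

τ = Σ_i [1 − log(TPM_i)/log(TPM_max)]/(N−1) over the 11 class-mean TPM
values. TPM below 1 is floored to 1 before logs — the convention of the
tissue-specificity benchmark literature — which suppresses transcriptional
leakage and keeps the index defined; the log base cancels. If no class
exceeds 1 TPM, τ is undefined (NaN) and the gene is excluded from
specificity analyses rather than given an arbitrary value. Ranking for
the top-expression summaries breaks TPM ties by gene id so output is
deterministic.

The correlation between bias strength and τ uses |log2FC| by default: the
literal signed ratio makes the sign of ρ depend on each tissue's dominant
bias direction, whereas the scientific question is whether *stronger* bias
accompanies *narrower* expression. A `signed` flag gives the literal
reading.

## Turnover

Turnover is counted only among genes sex-biased in both classes of a
pair; biased-in-one-class-only genes are not shared and contribute
nothing. Pairs are reported when they share more than 35 sex-biased genes
(strictly greater). Proportions are rounded to whole percent for report
output. Consistency classes (consistent male / consistent female /
turnover) partition the shared set exactly.

## Chromosome placement and enrichment

Reciprocal best hits: best hit per query by lowest e-value, ties broken by
higher bitscore then lexicographic subject id; a pair is accepted iff
reciprocal and e-value < 1e-10, alignment covers ≥ 50% of both query and
subject, and identity ≥ 40%. The output is a one-to-one matching,
invariant to input row order.

Permutation enrichment: for each chromosome and bias direction the
observed count is compared to counts under random reassignment of genes
to chromosomes (one joint permutation per replicate gives every
chromosome a without-replacement draw of its own size; marginally this
equals the hypergeometric null, which the tests verify). p = (1 + #{draws
≥ observed})/(1 + n_perm) — the add-one correction keeps p > 0 — with
n_perm = 10^4 by default and Bonferroni over the 10 × 2 family. The test
is one-sided on excess per direction.

Sliding windows: step-1 rolling means over exactly 40 genes ordered by
(chromosome, position), never spanning chromosomes; a chromosome with
fewer than 40 assigned genes yields no windows. Window centers are the
mean member position.

## dN/dS (NG86 with Jukes–Cantor correction)

Synonymous site fractions per codon are computed from the universal code
with changes to stop codons counted as nonsynonymous, so S + N = 3 per
codon exactly; sites are averaged over the two sequences. Codons
differing at k > 1 positions are averaged over all k! substitution
orderings that avoid stop codons, equally weighted; if every pathway
crosses a stop, the codon pair is skipped and counted in
`skipped_codons`. pS and pN are corrected with d = −(3/4)·ln(1 − (4/3)p),
undefined at p ≥ 0.75 (record flagged invalid); ω = dN/dS only when
dS > 0, else NaN. A terminal stop codon in either sequence is stripped;
internal stops, gaps and ambiguity codes are rejected.

The implementation is verified against an independent brute-force
enumeration oracle (recursive pathway expansion, naive site counting) to
1e-9 on random codon pairs.

Rate models: OLS of sqrt(ω) on a three-level bias factor
(male/female/unbiased) × τ, with drop-term F-tests for the interaction
against the full model and for each main effect against the additive
model. Sex bias is modeled as a factor because bias class membership, not
effect size, is the quantity shared across the comparisons; a
`continuous` option substitutes a numeric bias measure. Classes need ≥ 10
observations; NA ω are excluded.

## Synthetic-data generator

The generator emulates: per-sex replicate counts matching the field
design (3 individuals per sex per stage, 5 samples per sex per adult
tissue); log-normal gene means (natural-log mean 4.0, sd 1.5, i.e. median
~55 counts) with log-normal library depths (sd 0.2); NB counts with a
single common dispersion 0.1 (typical bulk RNA-seq biological
variability); sex-biased fractions ramping up through development (0.1%
at G23 to 10% at G46) and peaking in gonads (25%), with |log2FC| uniform
on [1, 4] split symmetrically (±lfc/2) so sex-averaged abundance is
independent of bias direction; 5% of biased genes fully sex-specific
(mean zero in the disfavored sex); a secondary bias in a second class for
25% of biased genes, the second class drawn in proportion to the classes'
biased fractions (so sharing concentrates where bias is common, as
observed) and flipped in direction with probability 0.10 — the source of
shared and turnover genes; tissue-specific expression (25% of genes
elevated 2^2–2^6-fold in one class) — the source of Tau signal; a
10-chromosome map with equal sizes, uniform positions, and a configurable
relative odds that biased genes land on chromosomes 1–2 (default 1.0 —
no enrichment, as observed in this system); homology-hit tables whose
expected reciprocal-best set is recorded exactly, with sub-threshold,
secondary and reciprocity-breaking decoys; and codon pairs diverged from
a random ancestor by uniform proposals accepted always if synonymous and
with probability ω otherwise, never creating stops, scaled so the
expected synonymous difference proportion matches a target (default 0.2).

It does not emulate: read-level errors or mapping ambiguity, alternative
splicing, gene length biases in counting, tagwise (gene-specific)
dispersion, correlated expression between genes, batch effects, or more
than two lineages for divergence. Passing tests therefore demonstrate the
statistical machinery is correct and calibrated under the design's
assumptions, not robustness to those unmodeled features of real data.

A small known bias: because the generator never substitutes into stop
codons while NG86 counts stop-changes as available nonsynonymous sites,
ω estimates are depressed by a few percent at high ω (≈ −0.05 at ω = 1
for 300-codon pairs), well within one Monte-Carlo SD.

## Problem sizes

The shipped analyses and checks use 2000-gene cohorts (the synthetic
study's default), 5000-gene null simulations for test calibration,
200-seed uniformity checks for the permutation test at 500 genes, 10-seed
detection runs for implanted 5× sex-chromosome enrichment, 20 pairs per ω
at 300 codons for rate recovery, and 20 replicates of n = 300 for
rate-model term selection — sizes at which every stochastic check has
comfortable margins while the whole suite runs in minutes on one CPU.

## Determinism

Every stochastic component takes an explicit seed; the pipeline fans one
global seed out to stages by a fixed counter scheme (stage k uses
seed + k), and all result files carry a header comment with the config
hash and seed. Identical config and seed reproduce byte-identical output.

## Known limitations

- The NB exact test uses one common dispersion; genes with atypically
  high biological variability will be anticonservative.
- Tau's 1-TPM floor makes specificity insensitive to differences among
  very weakly expressed classes by construction.
- NG86 ignores transition/transversion and codon-usage biases; estimates
  on real alignments with strong such biases will differ from
  likelihood-based codon models.
- The permutation enrichment test conditions on the observed set of
  assigned genes; assignment bias (e.g. chromosome-specific ortholog
  recovery) propagates into the null.
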