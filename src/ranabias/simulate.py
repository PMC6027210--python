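"""Synthetic study generator with known ground truth.

Emulates the study design end to end: negative-binomial read counts for the
eight stage/tissue classes in both genetic sexes with implanted sex-biased
genes, a 10-chromosome map with optional enrichment of biased genes on the
sex chromosomes (1 and 2), reciprocal homology-hit tables with decoys, and
codon-pair sequences diverged under a known dN/dS ratio (omega).

Everything is deterministic given the configuration seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ranabias.constants import SAMPLE_CLASSES, SEX_CHROMOSOMES
from ranabias.io_formats import CountsMatrix, HitRecord

# codons, universal genetic code
_BASES = "ACGT"
STOP_CODONS = {"TAA", "TAG", "TGA"}
_CODON_TABLE = {
    c: aa
    for c, aa in zip(
        [a + b + d for a in _BASES for b in _BASES for d in _BASES],
        "KNKNTTTTRSRSIIMIQHQHPPPPRRRRLLLL"
        "EDEDAAAAGGGGVVVV*Y*YSSSS*CWCLFLF",
    )
}
SENSE_CODONS = sorted(c for c in _CODON_TABLE if c not in STOP_CODONS)


def _default_replicates() -> dict[str, int]:
    # per-sex replicate counts: ~3 individuals/sex/stage, 5 samples/sex for
    # each adult tissue, mirroring the field design
    reps = {c: 3 for c in ("G23", "G27", "G31", "G43", "G46")}
    reps.update({c: 5 for c in ("brain", "liver", "gonad")})
    return reps


def _default_biased_fraction() -> dict[str, float]:
    # sex bias ramps up through development and peaks in gonads
    return {
        "G23": 0.001,
        "G27": 0.001,
        "G31": 0.002,
        "G43": 0.01,
        "G46": 0.10,
        "brain": 0.005,
        "liver": 0.01,
        "gonad": 0.25,
    }


@dataclass
class SimConfig:
    """Configuration of the synthetic study.

    Parameters
    ----------
    n_genes
        Number of genes simulated.
    replicates
        Per-sex sample count for each stage/tissue class (>= 2 required).
    baseline_log_mean, baseline_log_sd
        Natural-log parameters of the log-normal gene mean counts.
    nb_dispersion
        Common negative-binomial dispersion (Var = mu + phi mu^2).
    biased_fraction
        Fraction of genes implanted as sex-biased, per class; a gene is
        biased in at most one class.
    lfc_range
        (min, max) of |log2 fold change| effect sizes, drawn uniformly.
    sexspecific_fraction
        Fraction of biased genes that are sex-specific (mean zero in the
        disfavored sex within the biased class).
    secondary_bias_fraction, secondary_flip_prob
        Fraction of biased genes that are also biased in a second class
        (chosen with probability proportional to the classes' biased
        fractions, so sharing concentrates where bias is common), and the
        probability that the second bias has the opposite direction
        (a turnover gene).
    tissuespecific_fraction, tissue_effect_log2
        Fraction of genes with elevated expression in one stage/tissue
        class, and the (min, max) of the log2 elevation — this is what
        makes the Tau index informative.
    lib_depth_log_sd
        Log-normal spread of per-library sequencing depth factors.
    n_chromosomes, sexchrom_enrichment
        Chromosome count, and the relative odds that a biased gene lands on
        chromosomes 1-2 (1.0 = no enrichment, as observed in this system).
    omega_grid, pairs_per_omega, ortholog_codons, target_ps
        Codon-pair generation: true omega values, replicate pairs per
        value, codons per sequence, and the target proportion of differing
        synonymous sites (< 0.75 for the distance correction to exist).
    """

    n_genes: int = 2000
    replicates: dict[str, int] = field(default_factory=_default_replicates)
    baseline_log_mean: float = 4.0
    baseline_log_sd: float = 1.5
    nb_dispersion: float = 0.1
    biased_fraction: dict[str, float] = field(default_factory=_default_biased_fraction)
    lfc_range: tuple[float, float] = (1.0, 4.0)
    sexspecific_fraction: float = 0.05
    secondary_bias_fraction: float = 0.25
    secondary_flip_prob: float = 0.10
    tissuespecific_fraction: float = 0.25
    tissue_effect_log2: tuple[float, float] = (2.0, 6.0)
    lib_depth_log_sd: float = 0.2
    n_chromosomes: int = 10
    chromosome_size: int = 200_000_000
    sexchrom_enrichment: float = 1.0
    omega_grid: tuple[float, ...] = (0.05, 0.2, 0.5, 1.0)
    pairs_per_omega: int = 3
    ortholog_codons: int = 300
    target_ps: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for cls, frac in self.biased_fraction.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"biased_fraction[{cls}] must lie in [0, 1]")
        if not 0.0 <= self.sexspecific_fraction <= 1.0:
            raise ValueError("sexspecific_fraction must lie in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        for cls, n in self.replicates.items():
            if n < 2:
                raise ValueError(
                    f"class {cls!r} has {n} replicates per sex; need >= 2"
                )
        if self.sexchrom_enrichment < 1.0:
            raise ValueError("sexchrom_enrichment must be >= 1")


def simulate_expression(cfg: SimConfig) -> tuple[CountsMatrix, pd.DataFrame, pd.DataFrame]:
    """Simulate counts, sample metadata and the per-gene truth table.

    Counts follow NB(lib_depth * gene_mean * sex_effect, dispersion); the
    sex effect 2^(+/- lfc/2) applies only in the class where the gene is
    biased, splitting the fold change symmetrically so the sex-averaged
    abundance is independent of bias direction. Sex-specific genes have
    mean zero in the disfavored sex.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_genes
    width = len(str(max(n - 1, 1)))
    genes = [f"g{str(i).zfill(width)}" for i in range(n)]
    lengths = pd.Series(rng.integers(100, 1001, size=n) * 3, index=genes, name="length")
    gene_mean = rng.lognormal(cfg.baseline_log_mean, cfg.baseline_log_sd, size=n)

    # implant sex bias: one primary biased class per gene, plus an optional
    # secondary bias in another class (the source of shared/turnover genes)
    direction = np.full(n, "none", dtype=object)
    bias_class = np.full(n, "", dtype=object)
    true_lfc = np.zeros(n)
    sex_specific = np.zeros(n, dtype=bool)
    bias_class2 = np.full(n, "", dtype=object)
    direction2 = np.full(n, "none", dtype=object)
    true_lfc2 = np.zeros(n)
    pool = rng.permutation(n)
    cursor = 0
    for cls in SAMPLE_CLASSES:
        k = int(round(cfg.biased_fraction.get(cls, 0.0) * n))
        chosen = pool[cursor:cursor + k]
        cursor += k
        dirs = rng.choice(["male", "female"], size=len(chosen))
        mags = rng.uniform(*cfg.lfc_range, size=len(chosen))
        direction[chosen] = dirs
        bias_class[chosen] = cls
        true_lfc[chosen] = np.where(dirs == "male", mags, -mags)
        sex_specific[chosen] = rng.random(len(chosen)) < cfg.sexspecific_fraction
        # secondary class drawn in proportion to where bias is common
        other = [c for c in SAMPLE_CLASSES if c != cls]
        weights = np.array([cfg.biased_fraction.get(c, 0.0) for c in other])
        if weights.sum() > 0 and cfg.secondary_bias_fraction > 0:
            weights = weights / weights.sum()
            for g in chosen:
                if rng.random() >= cfg.secondary_bias_fraction:
                    continue
                cls2 = other[int(rng.choice(len(other), p=weights))]
                flip = rng.random() < cfg.secondary_flip_prob
                d2 = ({"male": "female", "female": "male"}[direction[g]]
                      if flip else direction[g])
                m2 = float(rng.uniform(*cfg.lfc_range))
                bias_class2[g] = cls2
                direction2[g] = d2
                true_lfc2[g] = m2 if d2 == "male" else -m2

    # tissue-specific expression: elevated mean in one class (both sexes)
    specific_class = np.full(n, "", dtype=object)
    specific_log2 = np.zeros(n)
    is_specific = rng.random(n) < cfg.tissuespecific_fraction
    idx_specific = np.flatnonzero(is_specific)
    specific_class[idx_specific] = rng.choice(SAMPLE_CLASSES, size=len(idx_specific))
    specific_log2[idx_specific] = rng.uniform(*cfg.tissue_effect_log2,
                                              size=len(idx_specific))

    # chromosome map, with optional enrichment of biased genes on chr 1-2
    biased_mask = direction != "none"
    chrom = np.empty(n, dtype=np.int64)
    n_chrom = cfg.n_chromosomes
    chrom[~biased_mask] = rng.integers(1, n_chrom + 1, size=(~biased_mask).sum())
    w = np.ones(n_chrom)
    for c in SEX_CHROMOSOMES:
        if c <= n_chrom:
            w[c - 1] = cfg.sexchrom_enrichment
    w /= w.sum()
    chrom[biased_mask] = rng.choice(np.arange(1, n_chrom + 1), size=biased_mask.sum(), p=w)
    position = rng.integers(1, cfg.chromosome_size + 1, size=n)

    # samples and counts
    rows = []
    col_ids: list[str] = []
    col_counts: list[np.ndarray] = []
    for cls in SAMPLE_CLASSES:
        n_rep = cfg.replicates.get(cls, 0)
        for sex in ("XX", "XY"):
            for rep in range(1, n_rep + 1):
                sid = f"{cls}_{sex}_r{rep}"
                rows.append({"sample_id": sid, "class": cls, "sex": sex,
                             "replicate": f"r{rep}"})
                depth = rng.lognormal(0.0, cfg.lib_depth_log_sd)
                mu = gene_mean * depth
                mu = np.where(specific_class == cls, mu * 2.0 ** specific_log2, mu)
                this_sex = "male" if sex == "XY" else "female"
                in_class = bias_class == cls
                favored = direction == this_sex
                half = np.where(favored, np.abs(true_lfc) / 2, -np.abs(true_lfc) / 2)
                mu = np.where(in_class, mu * 2.0 ** half, mu)
                mu = np.where(in_class & sex_specific & ~favored, 0.0, mu)
                in_class2 = bias_class2 == cls
                favored2 = direction2 == this_sex
                half2 = np.where(favored2, np.abs(true_lfc2) / 2,
                                 -np.abs(true_lfc2) / 2)
                mu = np.where(in_class2, mu * 2.0 ** half2, mu)
                r = 1.0 / cfg.nb_dispersion
                p = r / (r + np.maximum(mu, 1e-300))
                counts = np.where(mu > 0, rng.negative_binomial(r, p), 0)
                col_ids.append(sid)
                col_counts.append(counts.astype(np.int64))
    counts_df = pd.DataFrame(
        np.column_stack(col_counts), index=genes, columns=col_ids
    )
    counts_df.index.name = "gene"
    samples = pd.DataFrame(rows)
    truth = pd.DataFrame({
        "gene": genes,
        "true_direction": direction,
        "true_lfc": true_lfc,
        "bias_class": bias_class,
        "true_direction2": direction2,
        "true_lfc2": true_lfc2,
        "bias_class2": bias_class2,
        "sex_specific": sex_specific,
        "specific_class": specific_class,
        "specific_log2": specific_log2,
        "chromosome": chrom,
        "position": position,
    })
    return CountsMatrix(counts=counts_df, lengths=lengths), samples, truth


# ---------------------------------------------------------------------------
# codon-pair divergence under known omega
# ---------------------------------------------------------------------------

def _evolve_branch(seq: list[str], omega: float, n_proposals: int,
                   rng: np.random.Generator) -> list[str]:
    """Propose point mutations uniformly; accept synonymous changes always,
    nonsynonymous ones with probability omega; never create a stop codon."""
    seq = list(seq)
    length = len(seq) * 3
    for _ in range(n_proposals):
        site = int(rng.integers(length))
        ci, off = divmod(site, 3)
        old_codon = seq[ci]
        base = old_codon[off]
        new_base = _BASES[(int(_BASES.index(base)) + 1 + int(rng.integers(3))) % 4]
        new_codon = old_codon[:off] + new_base + old_codon[off + 1:]
        if new_codon in STOP_CODONS:
            continue
        if _CODON_TABLE[new_codon] == _CODON_TABLE[old_codon]:
            seq[ci] = new_codon
        elif rng.random() < omega:
            seq[ci] = new_codon
    return seq


def simulate_orthologs(cfg: SimConfig) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Generate codon-sequence pairs diverged from a common ancestor.

    Returns ``(pairs, truth)`` where ``pairs`` holds
    ``(pair_id, seq_a, seq_b)`` tuples and ``truth`` records the true
    omega per pair. Divergence is set so that the expected proportion of
    differing synonymous sites equals ``cfg.target_ps``.
    """
    if len(cfg.omega_grid) == 0:
        raise ValueError("omega_grid must be nonempty")
    if cfg.target_ps >= 0.75:
        raise ValueError(
            "target_ps >= 0.75: synonymous divergence saturates and the "
            "Jukes-Cantor correction is undefined"
        )
    rng = np.random.default_rng(cfg.seed + 1)
    # proposals/site so that JC-saturated difference matches target_ps
    d_total = -0.75 * np.log(1.0 - 4.0 * cfg.target_ps / 3.0)
    length_nt = cfg.ortholog_codons * 3
    per_branch = d_total * length_nt / 2.0
    pairs: list[tuple[str, str, str]] = []
    rows = []
    for omega in cfg.omega_grid:
        for rep in range(cfg.pairs_per_omega):
            pid = f"pair_w{omega:g}_{rep}"
            ancestor = [SENSE_CODONS[i] for i in
                        rng.integers(len(SENSE_CODONS), size=cfg.ortholog_codons)]
            seqs = []
            for _ in range(2):
                n_prop = int(rng.poisson(per_branch))
                seqs.append("".join(_evolve_branch(ancestor, omega, n_prop, rng)))
            pairs.append((pid, seqs[0], seqs[1]))
            rows.append({"pair": pid, "true_omega": omega})
    return pairs, pd.DataFrame(rows)


def simulate_gene_orthologs(
    gene_omegas: pd.Series, cfg: SimConfig
) -> list[tuple[str, str, str]]:
    """Codon pair per gene, diverged under that gene's true omega.

    ``gene_omegas`` maps gene id -> true dN/dS. Used by the pipeline to
    give every chromosome-assigned gene an estimable evolutionary rate.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    d_total = -0.75 * np.log(1.0 - 4.0 * cfg.target_ps / 3.0)
    length_nt = cfg.ortholog_codons * 3
    per_branch = d_total * length_nt / 2.0
    pairs = []
    for gene, omega in gene_omegas.items():
        ancestor = [SENSE_CODONS[i] for i in
                    rng.integers(len(SENSE_CODONS), size=cfg.ortholog_codons)]
        seqs = []
        for _ in range(2):
            n_prop = int(rng.poisson(per_branch))
            seqs.append("".join(_evolve_branch(ancestor, float(omega), n_prop, rng)))
        pairs.append((str(gene), seqs[0], seqs[1]))
    return pairs


# ---------------------------------------------------------------------------
# homology hit tables with decoys
# ---------------------------------------------------------------------------

def simulate_hits(
    truth: pd.DataFrame,
    cfg: SimConfig,
    lengths: pd.Series | None = None,
    p_mappable: float = 1.0,
    decoy_fraction: float = 0.0,
) -> tuple[list[HitRecord], list[HitRecord], set[tuple[str, str]]]:
    """Build reciprocal homology-hit tables with known expected RBH set.

    Each mappable gene receives a reciprocal best pair passing the ortholog
    thresholds (e-value < 1e-10, >= 50% overlap of both sequences,
    >= 40% identity). A ``decoy_fraction`` of genes additionally receive
    sub-threshold hits, worse secondary hits, or have their forward best
    hit redirected to a neighbour's subject (breaking reciprocity).
    Returns ``(hits_ab, hits_ba, expected_rbh)``.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    genes = list(truth["gene"])
    if lengths is None:
        lengths = pd.Series(900, index=genes)
    hits_ab: list[HitRecord] = []
    hits_ba: list[HitRecord] = []
    expected: set[tuple[str, str]] = set()

    mappable = rng.random(len(genes)) < p_mappable
    decoy_roll = rng.random(len(genes))

    def _hit(q, s, pident, aln, qlen, slen, evalue, bitscore):
        return HitRecord(q, s, float(pident), int(aln), 0, 0, 1, int(aln), 1,
                         int(aln), float(evalue), float(bitscore), int(qlen), int(slen))

    for i, g in enumerate(genes):
        subj = f"XT_{g}"
        qlen = int(lengths.loc[g])
        slen = int(round(qlen * float(rng.uniform(0.9, 1.1))))
        if not mappable[i]:
            # only a hopeless sub-threshold hit
            hits_ab.append(_hit(g, subj, 30.0, max(30, qlen // 10),
                                qlen, slen, 1e-5, 40.0))
            continue
        aln = int(np.ceil(0.5 * max(qlen, slen)) + rng.integers(
            0, max(1, min(qlen, slen) // 3)))
        aln = min(aln, min(qlen, slen))
        if aln < np.ceil(0.5 * max(qlen, slen)):
            aln = min(qlen, slen)
        pident = float(rng.uniform(60, 99))
        ev = float(10.0 ** -rng.uniform(50, 180))
        bit = float(rng.uniform(200, 1200))
        is_decoy = decoy_roll[i] < decoy_fraction
        if is_decoy and i > 0:
            # forward best redirected to the previous gene's subject:
            # reciprocity breaks, so this gene must not appear in the truth
            other = f"XT_{genes[i - 1]}"
            hits_ab.append(_hit(g, other, pident, aln, qlen, slen, ev / 10, bit))
            hits_ab.append(_hit(g, subj, pident, aln, qlen, slen, ev, bit / 2))
            hits_ba.append(_hit(subj, g, pident, aln, slen, qlen, ev, bit))
            continue
        hits_ab.append(_hit(g, subj, pident, aln, qlen, slen, ev, bit))
        hits_ba.append(_hit(subj, g, pident, aln, slen, qlen, ev, bit))
        expected.add((g, subj))
        if is_decoy:
            # worse secondary hit plus a sub-threshold one: harmless decoys
            hits_ab.append(_hit(g, f"XT_decoy_{i}", pident, aln, qlen, slen,
                                min(ev * 1e6, 1e-12), bit / 2))
            hits_ab.append(_hit(g, f"XT_junk_{i}", 25.0, max(30, qlen // 10),
                                qlen, slen, 1e-5, 35.0))
    # a redirected gene may steal RBH status from its neighbour's subject:
    # the neighbour's own forward hit still has the better e-value, so the
    # neighbour keeps its pair; redirected genes simply drop out.
    return hits_ab, hits_ba, expected
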