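"""Chromosome assignment and sex-chromosome enrichment scans.

Transcripts are placed on chromosomes via reciprocal-best-hit (RBH)
orthology against a syntenic reference. Per-chromosome enrichment of
male- or female-biased genes is assessed with permutation tests (random
chromosome-sized draws from all assigned genes), expression ratios are
compared between sex chromosomes and autosomes with Wilcoxon tests, and
per-gene values are scanned along chromosomes with fixed-size rolling
windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ranabias._stats import mann_whitney
from ranabias.constants import SEX_CHROMOSOMES
from ranabias.io_formats import HitRecord

logger = logging.getLogger(__name__)

RBH_MAX_EVALUE = 1e-10
RBH_MIN_OVERLAP = 0.5
RBH_MIN_IDENTITY = 40.0


@dataclass(frozen=True)
class OrthologAssignment:
    gene_id: str
    ortholog_id: str
    pident: float
    evalue: float
    overlap_q: float
    overlap_s: float
    chromosome: int | None = None
    position: int | None = None


def _best_hits(hits: list[HitRecord]) -> dict[str, HitRecord]:
    """Best hit per query: lowest e-value, ties by bitscore then subject id."""
    best: dict[str, HitRecord] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None:
            best[h.query_id] = h
            continue
        key = (h.evalue, -h.bitscore, h.subject_id)
        cur_key = (cur.evalue, -cur.bitscore, cur.subject_id)
        if key < cur_key:
            best[h.query_id] = h
    return best


def rbh_orthologs(hits_ab: list[HitRecord],
                  hits_ba: list[HitRecord]) -> list[OrthologAssignment]:
    """One-to-one orthologs by reciprocal best hit with quality thresholds.

    A pair is accepted when the two sequences are each other's best match
    AND the forward hit has e-value < 1e-10, covers at least half of both
    query and subject, and has >= 40% identity.
    """
    if not hits_ab or not hits_ba:
        raise ValueError("both hit tables are required for reciprocal matching")
    best_fwd = _best_hits(hits_ab)
    best_rev = _best_hits(hits_ba)
    out = []
    for query, hit in sorted(best_fwd.items()):
        rev = best_rev.get(hit.subject_id)
        if rev is None or rev.subject_id != query:
            continue
        overlap_q = hit.aln_len / hit.qlen
        overlap_s = hit.aln_len / hit.slen
        if (hit.evalue < RBH_MAX_EVALUE
                and overlap_q >= RBH_MIN_OVERLAP
                and overlap_s >= RBH_MIN_OVERLAP
                and hit.pident >= RBH_MIN_IDENTITY):
            out.append(OrthologAssignment(
                gene_id=query, ortholog_id=hit.subject_id,
                pident=hit.pident, evalue=hit.evalue,
                overlap_q=overlap_q, overlap_s=overlap_s,
            ))
    return out


def assignments_frame(assignments: list[OrthologAssignment],
                      positions: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assignment list as a DataFrame, optionally joined with a gene map.

    ``positions`` carries columns gene, chromosome, position (1-based).
    """
    df = pd.DataFrame([{
        "gene": a.gene_id, "ortholog": a.ortholog_id, "pident": a.pident,
        "evalue": a.evalue, "overlap_q": a.overlap_q, "overlap_s": a.overlap_s,
    } for a in assignments])
    if positions is not None:
        df = df.merge(positions[["gene", "chromosome", "position"]], on="gene")
    return df


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def enrichment_permutation(
    sexbias: pd.DataFrame,
    assignments: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation test for per-chromosome excess of sex-biased genes.

    For each chromosome and bias direction, the observed biased-gene count
    is compared against counts in ``n_perm`` random draws of the same
    number of genes from all assigned genes (one-sided, count >= observed),
    with the add-one Monte-Carlo correction
    p = (1 + #{draws >= observed}) / (1 + n_perm). Bonferroni adjusts over
    the (chromosomes x 2 directions) family.
    """
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000")
    merged = assignments.merge(
        sexbias[["gene", "direction", "biased"]], on="gene", how="left")
    merged["direction"] = merged["direction"].fillna("none")
    chroms = np.sort(merged["chromosome"].unique())
    chrom_idx = merged["chromosome"].to_numpy()
    rng = np.random.default_rng(seed)
    rows = []
    family = 0
    for direction in ("male", "female"):
        is_dir = (merged["direction"] == direction).to_numpy().astype(np.int8)
        # one joint permutation per replicate gives every chromosome a
        # without-replacement draw of its own size
        perm_mat = rng.permuted(np.tile(is_dir, (n_perm, 1)), axis=1)
        for c in chroms:
            sel = chrom_idx == c
            n_assigned = int(sel.sum())
            if n_assigned == 0:
                logger.info("chromosome %s has no assigned genes; skipped", c)
                continue
            observed = int(is_dir[sel].sum())
            perm_counts = perm_mat[:, sel].sum(axis=1)
            p_perm = (1 + int((perm_counts >= observed).sum())) / (1 + n_perm)
            rows.append({
                "chromosome": int(c), "direction": direction,
                "n_assigned": n_assigned, "n_observed": observed,
                "p_perm": p_perm,
            })
            family += 1
    out = pd.DataFrame(rows)
    out["p_bonf"] = np.minimum(1.0, out["p_perm"] * family)
    return out


def ratio_wilcoxon(sexbias: pd.DataFrame, assignments: pd.DataFrame) -> pd.DataFrame:
    """Wilcoxon tests of log2(male/female) on sex chromosomes vs autosomes.

    Tests chromosomes 1 and 2 separately and jointly against all
    autosomes.
    """
    merged = assignments.merge(sexbias[["gene", "log2fc"]], on="gene")
    auto = merged[~merged["chromosome"].isin(SEX_CHROMOSOMES)]["log2fc"].to_numpy()
    rows = []
    strata: list[tuple[str, np.ndarray]] = [
        (str(c), merged[merged["chromosome"] == c]["log2fc"].to_numpy())
        for c in SEX_CHROMOSOMES
    ]
    joint = merged[merged["chromosome"].isin(SEX_CHROMOSOMES)]["log2fc"].to_numpy()
    strata.append(("1+2", joint))
    for label, vals in strata:
        if vals.size == 0 or auto.size == 0:
            raise ValueError(f"empty stratum in sex-chromosome comparison ({label})")
        _, p = mann_whitney(vals, auto)
        rows.append({
            "stratum": label, "n_sexchrom": vals.size, "n_autosome": auto.size,
            "median_sexchrom": float(np.median(vals)),
            "median_autosome": float(np.median(auto)),
            "pvalue": p,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sliding windows
# ---------------------------------------------------------------------------

def sliding_window(values: pd.Series, assignments: pd.DataFrame,
                   window: int = 40) -> pd.DataFrame:
    """Step-1 rolling means of a per-gene value along each chromosome.

    Genes are ordered by (chromosome, position); each window spans exactly
    ``window`` consecutive genes and never crosses a chromosome boundary.
    ``center_position`` is the mean position of the window's members.
    Chromosomes with fewer than ``window`` genes yield no windows.
    """
    if window < 1:
        raise ValueError("window must be positive")
    df = assignments[["gene", "chromosome", "position"]].copy()
    df["value"] = values.reindex(df["gene"]).to_numpy()
    df = df.dropna(subset=["value"])
    df = df.sort_values(["chromosome", "position", "gene"], kind="mergesort")
    rows = []
    for chrom, grp in df.groupby("chromosome", sort=True):
        if len(grp) < window:
            logger.info("chromosome %s: %d genes < window %d, no windows",
                        chrom, len(grp), window)
            continue
        vals = grp["value"].rolling(window).mean().to_numpy()[window - 1:]
        pos = grp["position"].rolling(window).mean().to_numpy()[window - 1:]
        for i, (m, c) in enumerate(zip(vals, pos)):
            rows.append({
                "chromosome": chrom, "window_start_index": i,
                "center_position": float(c), "mean_value": float(m),
            })
    return pd.DataFrame(rows)
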