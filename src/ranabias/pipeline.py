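"""End-to-end orchestration: simulate -> sex bias -> Tau -> structure ->
turnover -> chromosome scans -> molecular evolution, with a run manifest.

One global seed is fanned out to per-stage seeds by a fixed counter scheme
(stage k uses ``seed + k``), so stages are individually reproducible and
re-runnable from intermediate files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from ranabias import __version__
from ranabias.bias_structure import driver_bins, excess_table
from ranabias.chromomap import (
    assignments_frame,
    enrichment_permutation,
    ratio_wilcoxon,
    rbh_orthologs,
    sliding_window,
)
from ranabias.constants import SAMPLE_CLASSES
from ranabias.diffexpr import call_sex_bias, rpkm
from ranabias.io_formats import (
    write_blast_tab,
    write_codon_pairs,
    write_counts,
    write_result_tsv,
    write_sample_table,
)
from ranabias.molevol import dnds_group_compare, dnds_table, sqrt_lm
from ranabias.simulate import (
    SimConfig,
    simulate_expression,
    simulate_gene_orthologs,
    simulate_hits,
)
from ranabias.specificity import pool_profiles, spearman_bias_tau, tau_table
from ranabias.turnover import turnover_table

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "sexbias",
    "specificity",
    "bias_structure",
    "turnover",
    "orthology",
    "enrichment",
    "molevol",
)


@dataclass
class RunConfig:
    """Pipeline configuration (thresholds default to the study's values)."""

    sim: SimConfig = field(default_factory=SimConfig)
    fdr: float = 0.05
    lfc: float = 1.0
    tau_specific: float = 0.8
    window: int = 40
    n_perm: int = 10_000
    shared_min: int = 35
    min_biased: int = 100
    seed: int = 0
    outdir: str = "ranabias_run"

    def __post_init__(self) -> None:
        for name in ("fdr", "lfc", "tau_specific", "window", "n_perm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "sim" not in raw:
            raise ValueError("config must contain a 'sim' block (synthetic inputs)")
        sim = SimConfig(**(raw.pop("sim") or {}))
        cfg = cls(sim=sim, **raw)
        cfg.sim.seed = cfg.seed + hash_offset("simulate")
        return cfg

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("outdir", None)  # hash the analysis, not its destination
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def hash_offset(stage: str) -> int:
    """Deterministic per-stage seed offset: the stage's index in STAGES."""
    return STAGES.index(stage)


def run_all(cfg: RunConfig) -> dict:
    """Run every stage on a simulated cohort; write TSVs and a manifest."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    chash = cfg.config_hash()
    manifest: dict = {
        "config_hash": chash,
        "seed": cfg.seed,
        "version": __version__,
        "stages": {},
    }

    def _write(df: pd.DataFrame, name: str) -> None:
        write_result_tsv(df, out / name, config_hash=chash, seed=cfg.seed)

    def _fail(stage: str, exc: Exception):
        raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc

    # 1. simulate ----------------------------------------------------------
    try:
        cm, samples, truth = simulate_expression(cfg.sim)
        write_counts(cm, out / "counts.tsv")
        write_sample_table(samples, out / "samples.tsv")
        _write(truth, "truth.tsv")
    except Exception as exc:  # noqa: BLE001
        _fail("simulate", exc)
    manifest["stages"]["simulate"] = {"genes": cm.shape[0], "samples": cm.shape[1]}

    # 2. per-class sex-bias calling (deterministic; no stage seed needed) --
    bias_tables: dict[str, pd.DataFrame] = {}
    try:
        for cls in SAMPLE_CLASSES:
            tbl = call_sex_bias(cm, samples, cls, fdr=cfg.fdr, lfc_threshold=cfg.lfc)
            bias_tables[cls] = tbl
            _write(tbl, f"sexbias_{cls}.tsv")
    except Exception as exc:  # noqa: BLE001
        _fail("sexbias", exc)
    all_bias = pd.concat(bias_tables.values(), ignore_index=True)
    manifest["stages"]["sexbias"] = {
        cls: int(t["biased"].sum()) for cls, t in bias_tables.items()
    }

    # 3. specificity -------------------------------------------------------
    try:
        profiles = pool_profiles(cm, samples)
        taus = tau_table(profiles)
        _write(taus, "tau.tsv")
        spearman = {}
        for cls in SAMPLE_CLASSES:
            res = spearman_bias_tau(bias_tables[cls], taus, cls,
                                    min_biased=cfg.min_biased)
            if res is not None:
                spearman[cls] = {"rho": res[0], "pvalue": res[1]}
    except Exception as exc:  # noqa: BLE001
        _fail("specificity", exc)
    manifest["stages"]["specificity"] = {
        "genes_with_tau": int(taus["tau"].notna().sum()),
        "spearman": spearman,
    }

    # 4. bias structure ----------------------------------------------------
    try:
        excess = excess_table(all_bias)
        _write(excess, "excess.tsv")
        rpkm_mat = rpkm(cm.counts, cm.lengths)
        driver_classes = [
            cls for cls, t in bias_tables.items()
            if int(t["biased"].sum()) >= cfg.min_biased
        ]
        for cls in driver_classes:
            bins = driver_bins(all_bias, rpkm_mat, samples, cls,
                               min_biased=cfg.min_biased)
            _write(bins, f"drivers_{cls}.tsv")
    except Exception as exc:  # noqa: BLE001
        _fail("bias_structure", exc)
    manifest["stages"]["bias_structure"] = {"driver_classes": driver_classes}

    # 5. turnover ----------------------------------------------------------
    try:
        turn = turnover_table(bias_tables, shared_min=cfg.shared_min)
        _write(turn, "turnover.tsv")
    except Exception as exc:  # noqa: BLE001
        _fail("turnover", exc)
    manifest["stages"]["turnover"] = {"pairs": len(turn)}

    # 6. orthology ---------------------------------------------------------
    try:
        hits_ab, hits_ba, _ = simulate_hits(truth, cfg.sim, lengths=cm.lengths,
                                            p_mappable=0.9, decoy_fraction=0.2)
        write_blast_tab(hits_ab, out / "hits_AB.tsv")
        write_blast_tab(hits_ba, out / "hits_BA.tsv")
        assignments = assignments_frame(rbh_orthologs(hits_ab, hits_ba), truth)
        _write(assignments, "orthologs.tsv")
    except Exception as exc:  # noqa: BLE001
        _fail("orthology", exc)
    manifest["stages"]["orthology"] = {"assigned": len(assignments)}

    # 7. enrichment + windows ---------------------------------------------
    try:
        focus = max(bias_tables, key=lambda c: int(bias_tables[c]["biased"].sum()))
        enrich = enrichment_permutation(
            bias_tables[focus], assignments, n_perm=cfg.n_perm,
            seed=cfg.seed + hash_offset("enrichment"))
        _write(enrich, f"enrichment_{focus}.tsv")
        ratios = ratio_wilcoxon(bias_tables[focus], assignments)
        _write(ratios, f"ratio_wilcoxon_{focus}.tsv")
        lfc_series = bias_tables[focus].set_index("gene")["log2fc"]
        windows = sliding_window(lfc_series, assignments, window=cfg.window)
        _write(windows, f"windows_{focus}.tsv")
    except Exception as exc:  # noqa: BLE001
        _fail("enrichment", exc)
    manifest["stages"]["enrichment"] = {
        "class": focus,
        "min_p_bonf": float(enrich["p_bonf"].min()) if len(enrich) else None,
        "windows": len(windows),
    }

    # 8. molecular evolution ----------------------------------------------
    try:
        rng = np.random.default_rng(cfg.seed + hash_offset("molevol"))
        assigned_genes = assignments["gene"]
        true_omega = pd.Series(
            rng.gamma(shape=1.5, scale=0.15, size=len(assigned_genes)).clip(0.01, 1.5),
            index=assigned_genes,
        )
        pairs = simulate_gene_orthologs(true_omega, cfg.sim)
        write_codon_pairs(pairs, out / "orthologs.fasta")
        dnds = dnds_table(pairs)
        _write(dnds, "dnds.tsv")
        omega = dnds.set_index("pair")["omega"]
        biased_any = all_bias[all_bias["biased"]].groupby("gene")["direction"].first()
        group = pd.Series("unbiased", index=assigned_genes, dtype=object)
        hit = biased_any.reindex(assigned_genes).dropna()
        group.loc[hit.index] = hit + "-biased"
        compare = dnds_group_compare(omega, group)
        _write(compare, "dnds_groups.tsv")
        tau_series = taus.set_index("gene")["tau"].reindex(assigned_genes)
        lm_res = sqrt_lm(omega, group, tau_series)
        _write(lm_res["drop_tests"], "ratemodel_drop_tests.tsv")
    except Exception as exc:  # noqa: BLE001
        _fail("molevol", exc)
    manifest["stages"]["molevol"] = {
        "pairs": len(dnds),
        "valid_omega": int(dnds["valid"].sum()),
    }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
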