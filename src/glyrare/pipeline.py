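"""End-to-end driver: simulate -> cohort statistics -> meta-analysis -> report.

The pipeline realizes the full two-stage design on synthetic cohorts: a
haplotype pool with one common and many rare variants generates multiple
cohorts (optionally with family structure and cohort-specific haplotype
sets); each cohort is written to disk as VCF + TSV, read back, scored, and
the score sets are combined into single-variant, gene-based (SKAT/WST),
conditional, leave-one-out and haplotype meta-analysis results.  Every run
writes a provenance block with the resolved configuration and seeds so a
rerun is byte-identical apart from timestamps.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from glyrare import io as gio
from glyrare.cohort import (
    fit_null,
    freq_stats,
    recode_to_minor,
    score_stats,
    select_gene_variants,
)
from glyrare.haplotype import em_dosages, fit_hap_model, format_hap_table, meta_hap
from glyrare.meta import (
    bonferroni_threshold,
    combine_scores,
    conditional_adjust,
    loo_skat_scan,
    single_variant_meta,
    skat,
    wst_burden,
)
from glyrare.simulate import (
    EffectSpec,
    FamilySpec,
    build_g6pc2_like_pool,
    draw_consortium,
)

log = logging.getLogger("glyrare")

__all__ = ["RunConfig", "run_pipeline", "default_demo_config"]


@dataclass
class RunConfig:
    """Resolved pipeline configuration; defaults follow the study's filters."""

    trait: str = "FG"
    trait_kind: str = "quantitative"
    transform: str = "none"
    covariates: list[str] = field(default_factory=lambda: ["age", "sex"])
    family_col: str | None = "FID"
    gene: str = "G6PC2_like"
    # filters
    single_mac_min: float = 20.0
    gene_maf_max: float = 0.01
    gene_cmac_min_quantitative: float = 20.0
    gene_cmac_min_binary: float = 40.0
    alpha: float = 0.05
    n_single_tests: int = 1
    n_gene_tests: int = 1
    # tests and conditioning
    run_conditional: bool = True
    run_loo: bool = True
    run_haplotype: bool = True
    conditioning_variants: list[str] = field(default_factory=list)
    # simulation
    seed: int = 1
    n_cohorts: int = 3
    cohort_size: int = 1500
    sibship_sizes: dict[int, float] = field(default_factory=lambda: {1: 0.7, 2: 0.2, 3: 0.1})
    family_sd: float = 0.3
    residual_sd: float = 0.7
    common_effect: float = -0.07
    # keyed by frequency rank among rare haplotypes (1 = most frequent rare):
    # the contributing variants of the emulated locus are the commoner rares
    rare_effects: dict[int, float] = field(
        default_factory=lambda: {1: 0.45, 2: -0.35, 3: 0.40}
    )
    out_dir: str = "glyrare_run"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "sibship_sizes" in data:
            data["sibship_sizes"] = {int(k): float(v) for k, v in data["sibship_sizes"].items()}
        if "rare_effects" in data:
            data["rare_effects"] = {int(k): float(v) for k, v in data["rare_effects"].items()}
        return cls(**data)

    def provenance(self) -> dict:
        d = dataclasses.asdict(self)
        d["package"] = "glyrare"
        from glyrare import __version__

        d["version"] = __version__
        return d


def default_demo_config(out_dir: str = "glyrare_demo", seed: int = 1) -> RunConfig:
    return RunConfig(out_dir=out_dir, seed=seed)


def _build_effects(cfg: RunConfig, pool) -> EffectSpec:
    gamma = np.zeros(pool.n_haplotypes)
    # haplotype 1 carries the common allele; rare haplotypes start at index 2
    gamma[1] = cfg.common_effect
    rare_by_freq = 2 + np.argsort(pool.frequencies[2:])[::-1]
    for rank, eff in cfg.rare_effects.items():
        gamma[rare_by_freq[rank - 1]] = eff
    return EffectSpec(
        haplotype_effects=gamma,
        covariate_effects={"intercept": 5.0, "age": 0.005, "sex": 0.05},
        family_sd=cfg.family_sd,
        residual_sd=cfg.residual_sd,
        trait_kind=cfg.trait_kind,
    )


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute all configured stages; returns the machine-readable summary."""
    t0 = time.time()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")

    # ---- stage: simulate -------------------------------------------------
    log.info("stage simulate: %d cohorts of %d", cfg.n_cohorts, cfg.cohort_size)
    pool = build_g6pc2_like_pool(cfg.seed)
    effects = _build_effects(cfg, pool)
    fam = FamilySpec(cfg.sibship_sizes)
    specs = [
        {"name": f"cohort{i + 1}", "n": cfg.cohort_size, "effects": effects, "families": fam}
        for i in range(cfg.n_cohorts)
    ]
    cohorts, manifest = draw_consortium(pool, specs, seed=cfg.seed)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))

    annotation = {
        lab: ("other" if i == 0 else "nonsynonymous")
        for i, lab in enumerate(pool.variant_labels)
    }
    common_id = pool.variant_labels[0]
    conditioning = cfg.conditioning_variants or [common_id]

    score_sets = []
    hap_fits = []
    for gm, pheno, truth in cohorts:
        name = truth["cohort"]
        cdir = out / name
        cdir.mkdir(exist_ok=True)
        gio.write_vcf(gm, cdir / "genotypes.vcf")
        gio.write_phenotypes(pheno, cdir / "phenotypes.tsv")
        # read back through the file layer so the run exercises the formats
        gm2 = recode_to_minor(gio.read_vcf_minimal(cdir / "genotypes.vcf"))
        ph2 = gio.read_phenotypes(cdir / "phenotypes.tsv")
        nm = fit_null(
            ph2, cfg.covariates, trait_kind=cfg.trait_kind, family_col=cfg.family_col
        )
        ss = score_stats(nm, gm2, gene=cfg.gene, cohort=name)
        gio.write_scoreset(ss, cdir / "scores.json")
        score_sets.append(ss)
        log.info("cohort %s: n=%d, %d variants scored", name, nm.n, len(ss.U))
        if cfg.run_haplotype and cfg.trait_kind == "quantitative":
            hd = em_dosages(gm2.dosage, max_iter=10_000)
            hf = fit_hap_model(
                ph2, cfg.covariates, hd, family_col=cfg.family_col, cohort=name,
                reference="0" * pool.n_variants,
            )
            gio.write_hapfit(hf, cdir / "hapfit.json")
            hap_fits.append(hf)

    # ---- stage: meta -----------------------------------------------------
    ms = combine_scores(score_sets)
    summary: dict = {"config": cfg.provenance(), "gene": cfg.gene, "n_total": ms.n}

    single = [
        single_variant_meta(ms, v, mac_threshold=cfg.single_mac_min)
        for v in ms.variants["id"]
    ]
    import pandas as pd

    single_df = pd.DataFrame(single)
    single_df.to_csv(out / "single_variant.tsv", sep="\t", index=False)
    n_filtered = int(single_df["filtered"].sum())
    log.info("single-variant: %d tested, %d filtered (MAC<%g)",
             len(single_df) - n_filtered, n_filtered, cfg.single_mac_min)

    kept, passed, cmaf, cmac = select_gene_variants(
        list(ms.variants["id"]), annotation, ms.variants[["id", "maf", "mac"]],
        trait_kind=cfg.trait_kind, maf_threshold=cfg.gene_maf_max,
        cmac_threshold=(
            cfg.gene_cmac_min_binary
            if cfg.trait_kind == "binary"
            else cfg.gene_cmac_min_quantitative
        ),
    )
    log.info("gene filter: %d/%d variants kept, cMAF=%.4f cMAC=%g pass=%s",
             len(kept), len(ms.variants), cmaf, cmac, passed)
    summary["gene_filter"] = {"kept": kept, "passed": passed, "cmaf": cmaf, "cmac": cmac}

    if passed:
        gene_ms = ms.subset(kept)
        res_skat = skat(gene_ms)
        res_wst = wst_burden(gene_ms)
        summary["skat"] = {"Q": res_skat.statistic, "p": res_skat.p,
                           "method": res_skat.method}
        summary["wst"] = {"z": res_wst.statistic, "p": res_wst.p,
                          "direction": res_wst.direction}
        log.info("SKAT p=%.3g  WST p=%.3g", res_skat.p, res_wst.p)
        if cfg.run_conditional:
            adj = conditional_adjust(ms, conditioning)
            adj_gene = adj.subset([v for v in kept if v not in conditioning])
            c_skat = skat(adj_gene)
            c_wst = wst_burden(adj_gene)
            summary["conditional"] = {
                "on": conditioning,
                "skat_p": c_skat.p,
                "wst_p": c_wst.p,
            }
            log.info("conditional on %s: SKAT p=%.3g WST p=%.3g",
                     conditioning, c_skat.p, c_wst.p)
        if cfg.run_loo and len(kept) >= 2:
            loo = loo_skat_scan(gene_ms)
            loo.to_csv(out / "loo_skat.tsv", sep="\t", index=False)
            summary["loo"] = {
                "max_p_removed": str(loo.loc[loo["p"].idxmax(), "removed"]),
                "max_p": float(loo["p"].max()),
            }

    if cfg.run_haplotype and hap_fits:
        hres = meta_hap(hap_fits)
        table = format_hap_table(hres)
        table.to_csv(out / "haplotypes.tsv", sep="\t", index=False)
        summary["haplotype"] = {
            "global_stat": hres.global_stat,
            "df": hres.df,
            "global_p": hres.global_p,
            "n_haplotypes": hres.df + 1,
        }
        log.info("haplotype global test: chi2=%.2f df=%d p=%.3g",
                 hres.global_stat, hres.df, hres.global_p)

    summary["thresholds"] = {
        "single_variant": bonferroni_threshold(max(cfg.n_single_tests, 1), cfg.alpha),
        "gene_based": bonferroni_threshold(max(cfg.n_gene_tests, 1), cfg.alpha),
    }
    summary["elapsed_sec"] = round(time.time() - t0, 2)
    (out / "summary.json").write_text(json.dumps(_strip_times(summary), indent=1))
    log.info("pipeline complete in %.1fs -> %s", summary["elapsed_sec"], out)
    return summary


def _strip_times(summary: dict) -> dict:
    """Summary minus wall-clock fields, so reruns are byte-identical."""
    out = dict(summary)
    out.pop("elapsed_sec", None)
    return out
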