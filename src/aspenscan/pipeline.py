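"""End-to-end analysis pipeline on a cohort.

Order of stages mirrors the study design: SNP QC -> structure (PCA,
kinship, FST) -> tri-method adaptation scan -> consensus region ->
sweep statistics on the candidate region per population group
(South = populations 1-6, Mid = 7-8, North = 9-12) -> ABC dating on
the northern group. Every stage logs its thresholds and seeds; reruns
with the same config and seed are reproducible.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import abc as abcmod
from . import qc, scan, structure
from .core import GenotypeMatrix, SweepModel
from .haplostats import h_statistics, windowed_pi
from .io import _config_hash
from .simulate import CohortConfig, simulate_study_cohort


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    seed: int = 0
    fdr_level: float = 0.05
    latent_K: int = 2
    consensus_min_methods: int = 2
    consensus_gap: int = 50_000
    pi_window: int = 2_000
    pi_step: int = 1_000
    run_abc: bool = True
    abc_n_sims: int = 500
    abc_epsilon: float = 0.05
    abc_n_hap: int = 24

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d:
            d["cohort"] = CohortConfig(**d["cohort"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _group_of(populations: np.ndarray) -> np.ndarray:
    """South (1-6), Mid (7-8), North (9-12)."""
    g = np.where(populations <= 6, "South",
                 np.where(populations <= 8, "Mid", "North"))
    return g


def run_pipeline(config: PipelineConfig | None = None, outdir=None) -> dict:
    """Run the full synthetic-cohort analysis; returns a report bundle.

    The bundle maps stage names to their artifacts (DataFrames /
    arrays) plus 'log' (list of per-stage summary lines) and
    'config_hash'. With `outdir` set, the main tables are also written
    as TSV/JSON.
    """
    cfg = config or PipelineConfig()
    chash = _config_hash(dataclasses.asdict(cfg))
    log: list[str] = [f"config_hash={chash} seed={cfg.seed}"]
    bundle: dict = {"log": log, "config_hash": chash}

    stage = "simulate"
    try:
        G, region_haps, meta, truth = simulate_study_cohort(
            cfg.cohort, seed=cfg.seed)
        bundle.update(genotypes=G, region_haplotypes=region_haps,
                      metadata=meta, truth=truth)
        log.append(f"simulate: {G.n_individuals} individuals, "
                   f"{G.n_sites} SNPs, causal at {truth['causal_pos']}")

        stage = "qc"
        G_f, report = qc.filter_snps(G)
        bundle["qc_report"] = report
        log.append("qc: " + ", ".join(f"{k}={v}" for k, v in report.items()))

        stage = "structure"
        pops = meta.table["population"].to_numpy()
        pca = structure.genotype_pca(G_f, K=5)
        bg_mask = (G_f.sites["chrom"] == "chr1").to_numpy()
        G_bg = GenotypeMatrix(
            dosages=G_f.dosages[:, bg_mask],
            sites=G_f.sites[bg_mask].reset_index(drop=True),
            individuals=list(G_f.individuals))
        # kinship from the background chromosome only (leave the scanned
        # region out, so its own signal is not absorbed by the GRM)
        kin = structure.centered_kinship(G_bg)
        fst_bg = structure.mean_fst(G_bg, pops)
        bundle.update(pca=pca, kinship=kin, background_fst=fst_bg)
        log.append(f"structure: background mean FST={fst_bg:.4f}, "
                   f"PC1 TW p={pca.tw_pvalues[0]:.3g}")

        stage = "scan"
        p_pca = scan.pca_outlier_scan(G_f, pca)
        env = meta.table["environment_pc1"].to_numpy()
        lf = scan.latent_factor_scan(G_f, env, K=cfg.latent_K)
        gv = meta.table["genetic_value"].to_numpy()
        gwas = scan.lmm_gwas(G_f, gv, kin)
        q_pca, _ = scan.storey_qvalues(p_pca)
        q_env, _ = scan.storey_qvalues(lf["p"].to_numpy())
        q_gwas, _ = scan.storey_qvalues(gwas["p"].to_numpy())
        tab = gwas.copy()
        tab["p_pca"], tab["q_pca"] = p_pca, q_pca
        tab["p_env"], tab["q_env"] = lf["p"].to_numpy(), q_env
        tab["q_gwas"] = q_gwas
        tab["pve"] = [
            scan.pve(b, s, mf, n) if np.isfinite(b) and s > 0
            and 0 < mf <= 0.5 else np.nan
            for b, s, mf, n in zip(tab.beta, tab.se, tab.maf, tab.N)]
        bundle["scan_table"] = tab
        flags = {k: (q < cfg.fdr_level) & np.isfinite(q)
                 for k, q in (("pca", q_pca), ("env", q_env),
                              ("gwas", q_gwas))}
        cand, regions = scan.consensus_candidates(
            G_f.sites, flags, min_methods=cfg.consensus_min_methods,
            gap=cfg.consensus_gap)
        bundle.update(candidates=cand, candidate_regions=regions)
        log.append(f"scan: {len(cand)} consensus candidates in "
                   f"{len(regions)} regions")

        stage = "sweepstats"
        groups = _group_of(meta.table["population"].to_numpy())
        per_group = {}
        hap_groups = np.repeat(groups, 2)
        for gname in ("South", "Mid", "North"):
            sel = hap_groups == gname
            sub = dataclasses.replace(region_haps,
                                      alleles=region_haps.alleles[sel])
            pi = windowed_pi(sub, window=cfg.pi_window, step=cfg.pi_step)
            _, hh = h_statistics(sub, window=cfg.pi_window,
                                 step=cfg.pi_step)
            per_group[gname] = {"pi": pi, "h": hh}
        region_mask = (G_f.sites["chrom"] == "chr10").to_numpy()
        G_region = GenotypeMatrix(
            dosages=G_f.dosages[:, region_mask],
            sites=G_f.sites[region_mask].reset_index(drop=True),
            individuals=list(G_f.individuals))
        fst_region = structure.wc_fst(
            G_region, groups, mode="windowed",
            window=cfg.pi_window, step=cfg.pi_step)
        bundle.update(sweepstats=per_group, region_fst=fst_region)
        log.append("sweepstats: computed pi/H12/FST per population group")

        if cfg.run_abc:
            stage = "abc"
            north = hap_groups == "North"
            n_take = 2 * (int(north.sum()) // 2)
            sub = dataclasses.replace(
                region_haps,
                alleles=region_haps.alleles[north][:n_take])
            theta = cfg.cohort.theta_per_bp * cfg.cohort.region_length
            model = SweepModel.from_scaled(
                theta=theta, rho=cfg.cohort.rho_over_theta * theta,
                L=cfg.cohort.region_length, s=cfg.cohort.sweep_s,
                T_fix=cfg.cohort.sweep_T_fix,
                n_hap=min(cfg.abc_n_hap, n_take),
                Ne=cfg.cohort.sweep_Ne)
            sub = dataclasses.replace(
                sub, alleles=sub.alleles[: model.n_hap])
            priors = abcmod.ABCPriors(n_sims=cfg.abc_n_sims,
                                      seed=cfg.seed + 1)
            table = abcmod.build_reference_table(priors, model)
            res = abcmod.abc_reject(
                abcmod.summarize_region(sub), table,
                epsilon=cfg.abc_epsilon)
            bundle["abc"] = res
            log.append(
                f"abc: posterior median s={res.posterior_median['s']:.4f}, "
                f"T={res.posterior_median['T']:.4g} (4Ne gens)")
    except Exception as exc:  # noqa: BLE001 - annotate stage and re-raise
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(stage, exc) from exc

    if outdir is not None:
        import pathlib

        out = pathlib.Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        bundle["scan_table"].to_csv(out / "scan.tsv", sep="\t", index=False)
        bundle["candidate_regions"].to_csv(
            out / "candidate_regions.tsv", sep="\t", index=False)
        with open(out / "log.txt", "w") as fh:
            fh.write("\n".join(log) + "\n")
        with open(out / "truth.json", "w") as fh:
            json.dump(bundle["truth"], fh, indent=1, default=str)
    return bundle
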