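"""Synthetic-data generation.

Everything downstream of this package is exercised on data produced
here: fixation-conditioned Wright-Fisher trajectories, trajectory-
conditioned structured-coalescent sweep haplotypes, neutral coalescent
haplotypes, and a full study-like cohort (94 diploids from 12
populations on a latitudinal gradient, near-zero background
differentiation, one swept region whose derived allele follows a
latitude cline and drives a bud-set phenotype with partial dominance).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import CohortMetadata, GenotypeMatrix, HaplotypeMatrix, SweepModel
from .coalescent import ArgSimulator, RescalingError
from .trajectory import simulate_wf_trajectory, TrajectoryError

__all__ = [
    "simulate_wf_trajectory",
    "simulate_sweep_haplotypes",
    "simulate_neutral_haplotypes",
    "simulate_study_cohort",
    "CohortConfig",
    "TrajectoryError",
    "RescalingError",
]


def simulate_sweep_haplotypes(
    model: SweepModel,
    seed: int,
    N_cap: int = 5000,
    rescale_floor: float = 1.0,
    max_tries: int = 200_000,
) -> HaplotypeMatrix:
    """Sample haplotypes from a completed hard sweep.

    The population is rescaled to at most ``N_cap`` diploids with s, mu
    and r scaled up by the same factor, preserving 4*N*s, theta and rho.
    The history has three phases (backward in time): a neutral phase of
    duration ``T_fix * 4 * N`` generations after fixation, the
    structured-coalescent sweep phase along a conditioned Wright-Fisher
    trajectory, and a neutral phase before the origin of the allele.
    """
    N_sim = min(model.Ne, N_cap)
    f = model.Ne / N_sim
    s_sim = model.s * f
    if 4.0 * N_sim * s_sim < rescale_floor:
        raise RescalingError(
            f"rescaled 4*N*s = {4.0 * N_sim * s_sim:.3g} below floor "
            f"{rescale_floor}: the sweep would leave no detectable signal"
        )
    ss = np.random.SeedSequence(seed)
    traj_seed, arg_seed = ss.generate_state(2)
    traj = simulate_wf_trajectory(N_sim, s_sim, int(traj_seed),
                                  max_tries=max_tries)
    rng = np.random.default_rng(int(arg_seed))
    sim = ArgSimulator(model.n_hap, model.L, model.mu * f, model.r * f,
                       N_sim, rng)
    sweep_site = model.sweep_pos - 0.5
    sim.run_neutral(duration=model.T_fix * 4.0 * N_sim)
    sim.run_sweep_phase(traj.freqs, sweep_site)
    sim.run_neutral()
    return sim.haplotypes(model.L)


def simulate_neutral_haplotypes(
    theta_per_bp: float,
    rho_per_bp: float,
    L: int,
    n_hap: int,
    seed: int,
    N: int = 10_000,
) -> HaplotypeMatrix:
    """Standard coalescent-with-recombination sample.

    theta_per_bp and rho_per_bp are the scaled rates 4*N*mu and 4*N*r per
    bp; N only sets the internal time scale and does not affect the
    sampling distribution.
    """
    if L <= 0:
        raise ValueError("region length L must be positive")
    if theta_per_bp < 0 or rho_per_bp < 0:
        raise ValueError("scaled rates must be >= 0")
    rng = np.random.default_rng(seed)
    mu = theta_per_bp / (4.0 * N)
    r = rho_per_bp / (4.0 * N)
    sim = ArgSimulator(n_hap, L, mu, r, N, rng)
    sim.run_neutral()
    return sim.haplotypes(L)


@dataclass
class CohortConfig:
    """Generating parameters of the synthetic study cohort.

    Defaults emulate the study design: 94 diploids from 12 populations
    spanning ~10 degrees of latitude, background Weir-Cockerham FST
    around 0.0021, and a single swept region whose derived allele
    follows a logistic latitude cline, explains 65% of the variance in
    the bud-set genetic value, and advances bud set by 28 days in the
    derived homozygote with partial dominance (h = 0.75).
    """

    n_individuals: int = 94
    n_pops: int = 12
    background_fst: float = 0.0021
    n_background_snps: int = 5000
    lat_min: float = 56.0
    lat_max: float = 66.0
    # sweep-region parameters
    region_length: int = 25_000
    theta_per_bp: float = 0.0081
    rho_over_theta: float = 0.229
    sweep_s: float = 0.016
    sweep_T_fix: float = 0.0034       # units of 4*Ne generations
    sweep_Ne: int = 92_000
    pool_size: int = 120
    # phenotype model
    causal_pve: float = 0.65
    pve_definition: str = "additive"  # 'additive' (regression/Eq-2 sense)
    #                                   or 'genotypic' (one-way class R^2)
    genotype_effect: float = 28.0     # days, derived hom vs ancestral hom
    dominance: float = 0.75           # heterozygote displacement fraction
    grand_mean: float = 90.0          # bud-set day of the ancestral hom
    polygenic_share: float = 0.5      # of the non-causal variance
    null_residual_var: float = 25.0   # used when causal_pve = 0
    # environment score
    env_noise_sd: float = 0.3
    cline_slope: float = 1.0          # per degree latitude
    N_cap: int = 5000


def _pop_sizes(n_individuals: int, n_pops: int) -> list[int]:
    base = n_individuals // n_pops
    sizes = [base] * n_pops
    for i in range(n_individuals - base * n_pops):
        sizes[i] += 1
    return sizes


def simulate_study_cohort(config: CohortConfig | None = None, seed: int = 0):
    """Generate the full synthetic cohort.

    Returns
    -------
    (GenotypeMatrix, HaplotypeMatrix, CohortMetadata, dict)
        Unphased genotypes over background + region SNPs; phased region
        haplotypes (2 per individual, individual-major order); metadata;
        and a truth record holding every generating parameter plus
        realized quantities recomputed from the emitted matrices.
    """
    cfg = config or CohortConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = cfg.n_individuals
    sizes = _pop_sizes(n, cfg.n_pops)
    latitudes = np.linspace(cfg.lat_min, cfg.lat_max, cfg.n_pops)
    pop_of = np.repeat(np.arange(cfg.n_pops), sizes)
    lat_of = latitudes[pop_of]

    # --- background SNPs: Balding-Nichols island model -----------------
    F = cfg.background_fst
    m = cfg.n_background_snps
    p_anc = rng.uniform(0.05, 0.95, size=m)
    a = p_anc * (1.0 - F) / F
    b = (1.0 - p_anc) * (1.0 - F) / F
    p_pop = rng.beta(a[None, :], b[None, :],
                     size=(cfg.n_pops, m))          # pop x snp
    bg = rng.binomial(2, p_pop[pop_of, :]).astype(np.int8)

    # --- sweep region: northern sweep pool + southern neutral pool -----
    theta = cfg.theta_per_bp * cfg.region_length
    rho = cfg.rho_over_theta * theta
    model = SweepModel.from_scaled(
        theta=theta, rho=rho, L=cfg.region_length, s=cfg.sweep_s,
        T_fix=cfg.sweep_T_fix, n_hap=cfg.pool_size, Ne=cfg.sweep_Ne,
    )
    sweep_seed, neut_seed = np.random.SeedSequence(seed).spawn(2)
    sweep_pool = simulate_sweep_haplotypes(
        model, int(sweep_seed.generate_state(1)[0]) % 2**31, N_cap=cfg.N_cap)
    neutral_pool = simulate_neutral_haplotypes(
        cfg.theta_per_bp, cfg.rho_over_theta * cfg.theta_per_bp,
        cfg.region_length, cfg.pool_size,
        int(neut_seed.generate_state(1)[0]) % 2**31)

    # union of site coordinates; absent sites are ancestral in the other pool
    mid_lat = latitudes[cfg.n_pops // 2 - 1: cfg.n_pops // 2 + 1].mean()
    cline = 1.0 / (1.0 + np.exp(-cfg.cline_slope * (lat_of - mid_lat)))
    is_derived_hap = rng.random((n, 2)) < cline[:, None]

    causal_pos = model.sweep_pos
    taken = set(sweep_pool.positions) | set(neutral_pool.positions)
    while causal_pos in taken:
        causal_pos += 1
    union_pos = np.array(
        sorted(set(sweep_pool.positions) | set(neutral_pool.positions)
               | {causal_pos}), dtype=np.int64)
    n_sites = union_pos.size
    col_of = {p: j for j, p in enumerate(union_pos)}
    sweep_cols = np.array([col_of[p] for p in sweep_pool.positions], dtype=int)
    neut_cols = np.array([col_of[p] for p in neutral_pool.positions], dtype=int)
    causal_col = col_of[causal_pos]

    def _draw_order(size):
        order = rng.permutation(size)
        i = 0
        while True:
            if i == size:
                order = rng.permutation(size)
                i = 0
            yield order[i]
            i += 1

    sweep_iter = _draw_order(cfg.pool_size)
    neut_iter = _draw_order(cfg.pool_size)
    haps = np.zeros((2 * n, n_sites), dtype=np.int8)
    flat_derived = is_derived_hap.reshape(-1)
    for h in range(2 * n):
        if flat_derived[h]:
            src = sweep_pool.alleles[next(sweep_iter)]
            haps[h, sweep_cols] = src
            haps[h, causal_col] = 1
        else:
            src = neutral_pool.alleles[next(neut_iter)]
            haps[h, neut_cols] = src
    region_haps = HaplotypeMatrix(alleles=haps, positions=union_pos,
                                  region_length=cfg.region_length)
    region_dos = (haps[0::2] + haps[1::2]).astype(np.int8)

    # --- phenotype: partial dominance at the causal site ----------------
    g_causal = region_dos[:, causal_col].astype(float)
    eff = cfg.genotype_effect
    class_mean = np.select(
        [g_causal == 0, g_causal == 1],
        [0.0, -eff * cfg.dominance], default=-eff)
    var_gen = float(np.var(class_mean))
    vg = float(np.var(g_causal))
    var_add = (float(np.cov(class_mean, g_causal, bias=True)[0, 1]) ** 2
               / vg) if vg > 0 else 0.0
    if cfg.causal_pve == 0:
        class_mean = np.zeros(n)
        var_rest = cfg.null_residual_var
    else:
        if not (0 < cfg.causal_pve <= 1):
            raise ValueError("causal_pve must lie in [0, 1]")
        if var_gen == 0:
            raise ValueError(
                "requested causal PVE is unattainable: the causal genotype "
                "is monomorphic in this draw (feasible maximum PVE = 0)")
        if cfg.pve_definition == "genotypic":
            # PVE is the one-way R^2 of the three genotype classes
            var_rest = var_gen * (1.0 - cfg.causal_pve) / cfg.causal_pve
        elif cfg.pve_definition == "additive":
            # PVE is the additive (regression) share, the quantity a
            # single-SNP effect/se estimate measures; the dominance
            # deviation counts as residual here
            var_rest = (var_add * (1.0 - cfg.causal_pve) / cfg.causal_pve
                        - (var_gen - var_add))
            if var_rest < 0:
                raise ValueError(
                    "requested additive PVE is unattainable with this "
                    "dominance; feasible maximum = "
                    f"{var_add / var_gen:.3f}")
        else:
            raise ValueError(
                f"unknown pve_definition {cfg.pve_definition!r}")
    poly_var = cfg.polygenic_share * var_rest
    res_var = var_rest - poly_var
    bg_c = bg - bg.mean(0)
    raw_poly = bg_c @ rng.normal(0, 1, size=m)
    sd = raw_poly.std()
    poly = raw_poly / sd * np.sqrt(poly_var) if sd > 0 else np.zeros(n)
    genetic_value = (cfg.grand_mean + class_mean + poly
                     + rng.normal(0, np.sqrt(res_var), size=n))

    env = ((lat_of - lat_of.mean()) / lat_of.std()
           + rng.normal(0, cfg.env_noise_sd, size=n))

    # --- assemble matrices ----------------------------------------------
    ids = [f"aspen{i + 1:03d}" for i in range(n)]
    bg_sites = pd.DataFrame({
        "chrom": "chr1",
        "pos": np.arange(1, m + 1) * 1000,
        "ref": "A", "alt": "C", "aa": ".",
    })
    region_sites = pd.DataFrame({
        "chrom": "chr10",
        "pos": union_pos,
        "ref": np.where(union_pos == causal_pos, "T", "A"),
        "alt": np.where(union_pos == causal_pos, "G", "C"),
    })
    region_sites["aa"] = region_sites["ref"]  # region SNPs are polarized
    G = GenotypeMatrix(
        dosages=np.hstack([bg, region_dos]),
        sites=pd.concat([bg_sites, region_sites], ignore_index=True),
        individuals=ids,
    )
    meta = CohortMetadata(table=pd.DataFrame({
        "id": ids,
        "population": pop_of + 1,
        "latitude": lat_of,
        "environment_pc1": env,
        "genetic_value": genetic_value,
    }))

    # --- truth record: parameters + realized values ----------------------
    gv = genetic_value
    ss_tot = float(np.sum((gv - gv.mean()) ** 2))
    fitted = np.array([gv[g_causal == k].mean() if np.any(g_causal == k)
                       else 0.0 for k in (0, 1, 2)])[g_causal.astype(int)]
    ss_res = float(np.sum((gv - fitted) ** 2))
    realized_pve = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    realized_add = (float(np.corrcoef(gv, g_causal)[0, 1] ** 2)
                    if np.var(g_causal) > 0 and ss_tot > 0 else 0.0)
    pop_freq = [float(region_dos[pop_of == k, causal_col].mean() / 2.0)
                for k in range(cfg.n_pops)]
    truth = {
        "seed": int(seed),
        "config": asdict(cfg),
        "causal_chrom": "chr10",
        "causal_pos": int(causal_pos),
        "causal_index": int(m + causal_col),
        "region_span": [1, cfg.region_length],
        "cline_midpoint_lat": float(mid_lat),
        "realized_causal_freq_by_pop": pop_freq,
        "realized_causal_freq": float(region_dos[:, causal_col].mean() / 2.0),
        "realized_pve_genotypic": float(realized_pve),
        "realized_pve_additive": float(realized_add),
    }
    return G, region_haps, meta, truth
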