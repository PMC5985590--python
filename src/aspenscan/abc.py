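"""Rejection-ABC dating of a hard selective sweep, and the
sweep-footprint-size experiment.

The age T (time since fixation, units of 4*Ne generations) and strength
s of a completed sweep are inferred by simulating sweeps from log-
uniform priors with the trajectory-conditioned coalescent, summarizing
each region with a fixed statistic vector, and accepting the draws
closest to the observed summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import HaplotypeMatrix, SweepModel
from .coalescent import RescalingError
from .haplostats import (BackgroundSFS, _h_stats_window, clr_scan,
                         ihs_unstandardized)
from .simulate import (TrajectoryError, simulate_neutral_haplotypes,
                       simulate_sweep_haplotypes)

SUMMARY_NAMES = (
    [f"pi_w{i}" for i in range(5)]
    + [f"thetaw_w{i}" for i in range(5)]
    + [f"tajd_w{i}" for i in range(5)]
    + ["H1_c", "H12_c", "H2H1_c", "n_haplotypes", "max_abs_ihs_c"]
)


@dataclass
class ABCPriors:
    """Log-uniform priors for the sweep age and selection coefficient.

    T is in units of 4*Ne generations; both ranges are on log10 scale.
    """

    log10_T: tuple[float, float] = (-4.0, -0.5)
    log10_s: tuple[float, float] = (-4.0, -0.5)
    n_sims: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.log10_T, self.log10_s):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError("prior ranges must be finite with lo < hi")


@dataclass
class ABCResult:
    accepted: pd.DataFrame          # columns s, T, distance
    posterior_median: dict
    ci95: dict
    epsilon: float
    n_table: int


def _tajima_d(S: int, pi_sum: float, n: int) -> float:
    if S == 0:
        return np.nan
    a1 = np.sum(1.0 / np.arange(1, n))
    a2 = np.sum(1.0 / np.arange(1, n) ** 2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1.0)
    return float((pi_sum - S / a1) / np.sqrt(var)) if var > 0 else np.nan


def summarize_region(H: HaplotypeMatrix, n_windows: int = 5) -> np.ndarray:
    """Fixed-order summary vector for ABC.

    Per equal subwindow: pi/bp, Watterson theta/bp, Tajima's D; at the
    center subwindow: H1, H12, H2/H1; plus the number of distinct
    haplotypes and max |unstandardized iHS| among the 5 SNPs nearest
    the center. Fewer than 2 segregating sites gives an all-NaN vector.
    """
    out = np.full(len(SUMMARY_NAMES), np.nan)
    if H.n_sites < 2:
        return out
    n = H.n_hap
    L = H.region_length
    p = H.derived_freq()
    site_pi = 2.0 * p * (1.0 - p) * n / (n - 1)
    edges = np.linspace(0, L, n_windows + 1)
    a1 = np.sum(1.0 / np.arange(1, n))
    for w in range(n_windows):
        sel = (H.positions > edges[w]) & (H.positions <= edges[w + 1])
        wlen = edges[w + 1] - edges[w]
        S = int(sel.sum())
        pi_sum = float(site_pi[sel].sum())
        out[w] = pi_sum / wlen
        out[5 + w] = S / a1 / wlen
        out[10 + w] = _tajima_d(S, pi_sum, n)
    center = n_windows // 2
    sel = (H.positions > edges[center]) & (H.positions <= edges[center + 1])
    if sel.sum() >= 1:
        h1, h2, h12, h2h1 = _h_stats_window(H.alleles[:, sel])
        out[15], out[16], out[17] = h1, h12, h2h1
    else:  # no variation in the center: one haplotype class
        out[15], out[16], out[17] = 1.0, 1.0, 0.0
    out[18] = float(np.unique(H.alleles, axis=0).shape[0])
    # max |iHS| among the 5 informative SNPs nearest the center
    maf_ok = np.minimum(p, 1 - p) > 0.05
    idx = np.where(maf_ok)[0]
    if idx.size:
        nearest = idx[np.argsort(np.abs(H.positions[idx] - L / 2))][:5]
        sub = ihs_unstandardized(H, site_indices=np.sort(nearest))
        vals = sub["ihs"].to_numpy()
        if np.isfinite(vals).any():
            out[19] = float(np.nanmax(np.abs(vals)))
    return out


def build_reference_table(
    priors: ABCPriors,
    model_template: SweepModel,
    N_cap: int = 5000,
    progress: bool = False,
) -> pd.DataFrame:
    """Simulate the ABC reference table: (s, T, summaries) per row.

    Draws (s, T) from the priors, runs one sweep simulation each and
    attaches the summary vector. Simulation failures (rejection budget,
    rescaling floor) are recorded as all-NaN summary rows; the failure
    fraction is stored in DataFrame.attrs['failure_fraction'].
    """
    rng = np.random.default_rng(priors.seed)
    rows = np.empty((priors.n_sims, 2 + len(SUMMARY_NAMES)))
    failures = 0
    child_seeds = np.random.SeedSequence(priors.seed).generate_state(
        priors.n_sims) % 2**31
    for i in range(priors.n_sims):
        s = 10.0 ** rng.uniform(*priors.log10_s)
        T = 10.0 ** rng.uniform(*priors.log10_T)
        rows[i, 0], rows[i, 1] = s, T
        model = replace(model_template, s=s, T_fix=T)
        try:
            H = simulate_sweep_haplotypes(model, int(child_seeds[i]),
                                          N_cap=N_cap)
            rows[i, 2:] = summarize_region(H)
        except (TrajectoryError, RescalingError):
            failures += 1
            rows[i, 2:] = np.nan
    table = pd.DataFrame(rows, columns=["s", "T", *SUMMARY_NAMES])
    table.attrs["failure_fraction"] = failures / priors.n_sims
    return table


def abc_reject(
    observed: np.ndarray,
    table: pd.DataFrame,
    epsilon: float = 0.005,
    min_accept: int = 20,
) -> ABCResult:
    """Rejection ABC: accept the epsilon-quantile nearest draws.

    Summaries are standardized by the table SDs; remaining NaNs (failed
    statistics) are imputed with table column means before computing
    Euclidean distances. Posterior medians and equal-tailed 95% CIs of
    s and T are reported from the accepted draws.
    """
    S = table[list(SUMMARY_NAMES)].to_numpy(float)
    obs = np.asarray(observed, dtype=float).copy()
    col_mean = np.nanmean(S, axis=0)
    col_sd = np.nanstd(S, axis=0)
    use = np.isfinite(col_mean) & (col_sd > 0)
    S = np.where(np.isfinite(S), S, col_mean)
    obs = np.where(np.isfinite(obs), obs, col_mean)
    Z = (S[:, use] - col_mean[use]) / col_sd[use]
    z_obs = (obs[use] - col_mean[use]) / col_sd[use]
    d = np.sqrt(((Z - z_obs) ** 2).sum(1))
    n_accept = max(1, int(np.floor(epsilon * len(table))))
    if n_accept < min_accept:
        raise ValueError(
            f"epsilon={epsilon} accepts only {n_accept} draws "
            f"(< {min_accept}); increase epsilon or the table size")
    order = np.argsort(d)[:n_accept]
    acc = table.iloc[order][["s", "T"]].copy()
    acc["distance"] = d[order]
    med = {k: float(np.median(acc[k])) for k in ("s", "T")}
    ci = {k: (float(np.quantile(acc[k], 0.025)),
              float(np.quantile(acc[k], 0.975))) for k in ("s", "T")}
    return ABCResult(accepted=acc.reset_index(drop=True),
                     posterior_median=med, ci95=ci,
                     epsilon=epsilon, n_table=len(table))


# ---------------------------------------------------------------------
# sweep footprint experiment
# ---------------------------------------------------------------------
def _max_cluster_span(sig: np.ndarray, grid_spacing: int,
                      merge_gap: int) -> int:
    """Largest extent of significant grid points merged within a gap."""
    pos = np.where(sig)[0] * grid_spacing
    if pos.size == 0:
        return 0
    best = cur_start = prev = pos[0]
    best_span = grid_spacing
    for x in pos[1:]:
        if x - prev <= merge_gap:
            prev = x
        else:
            best_span = max(best_span, prev - cur_start + grid_spacing)
            cur_start = prev = x
    best_span = max(best_span, prev - cur_start + grid_spacing)
    return int(best_span)


def footprint_experiment(
    model: SweepModel,
    n_reps: int = 100,
    n_neutral: int = 30,
    seed: int = 0,
    grid_spacing: int = 2_000,
    merge_gap: int = 50_000,
    threshold_quantile: float = 0.99,
    n_alpha: int = 32,
    N_cap: int = 5000,
):
    """Distribution of CLR-significant footprint sizes around a sweep.

    Neutral replicates matched in theta/rho provide both the background
    SFS and the CLR significance threshold (the `threshold_quantile`
    of their pooled grid-point CLR values). Each sweep replicate is
    scanned on a `grid_spacing` grid; its footprint is the largest
    extent of significant grid points after merging points closer than
    `merge_gap`. Returns a dict with the spans, the neutral spans, the
    95% quantile and the threshold.
    """
    ss = np.random.SeedSequence(seed)
    neut_seeds, sweep_seeds = ss.spawn(2)
    neut_seeds = neut_seeds.generate_state(n_neutral) % 2**31
    sweep_seeds = sweep_seeds.generate_state(n_reps) % 2**31
    theta_bp = model.theta / model.L
    rho_bp = model.rho / model.L
    neutral = [
        simulate_neutral_haplotypes(theta_bp, rho_bp, model.L,
                                    model.n_hap, int(sd))
        for sd in neut_seeds
    ]
    counts = np.concatenate([h.alleles.sum(0) for h in neutral])
    bg = BackgroundSFS.from_derived_counts(counts, model.n_hap)
    null_clr = [
        clr_scan(h.positions, h.alleles.sum(0), model.n_hap, bg,
                 model.L, grid_spacing=grid_spacing, n_alpha=n_alpha)
        for h in neutral
    ]
    threshold = float(np.quantile(
        np.concatenate([c["clr"].to_numpy() for c in null_clr]),
        threshold_quantile))
    null_spans = [
        _max_cluster_span(c["clr"].to_numpy() > threshold, grid_spacing,
                          merge_gap) for c in null_clr
    ]
    spans = []
    for sd in sweep_seeds:
        H = simulate_sweep_haplotypes(model, int(sd), N_cap=N_cap)
        c = clr_scan(H.positions, H.alleles.sum(0), model.n_hap, bg,
                     model.L, grid_spacing=grid_spacing, n_alpha=n_alpha)
        spans.append(_max_cluster_span(
            c["clr"].to_numpy() > threshold, grid_spacing, merge_gap))
    result = {
        "spans": np.asarray(spans),
        "null_spans": np.asarray(null_spans),
        "span_q95": float(np.quantile(spans, 0.95)),
        "threshold": threshold,
        "quantile_stability_warning": n_reps < 20,
    }
    if n_reps < 20:
        warnings.warn("fewer than 20 replicates: footprint quantiles "
                      "are unstable", stacklevel=2)
    return result
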