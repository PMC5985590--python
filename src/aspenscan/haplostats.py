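"""Haplotype- and frequency-spectrum-based selection statistics.

Extended haplotype homozygosity (EHH) and its integrals (iHS), the
segregating-sites-by-length analog (nSL), frequency-bin
standardization, Garud's H1/H12/H2 haplotype-homozygosity statistics,
sliding-window nucleotide diversity, a composite likelihood ratio (CLR)
scan against a genome-wide background site frequency spectrum, and the
large-window enrichment test for |score| > 2 concentrations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom, hypergeom

from .core import HaplotypeMatrix

EHH_CUTOFF = 0.05


# ---------------------------------------------------------------------
# EHH
# ---------------------------------------------------------------------
@dataclass
class EHHCurve:
    core_index: int
    allele: int
    carrier_count: int
    left_ehh: np.ndarray    # sites core-1 .. 0, ordered outward
    right_ehh: np.ndarray   # sites core+1 .. end


def _ehh_walk(alleles: np.ndarray, carriers: np.ndarray, order,
              stop_below: float | None = None):
    """EHH values extending over `order` site columns, one per step.

    With `stop_below` set, the walk ends right after the first value
    under that cutoff; returns (values, reached_end) where reached_end
    means the region end was hit while EHH was still at/above cutoff.
    """
    n_c = carriers.size
    pairs_total = n_c * (n_c - 1) // 2
    groups = {0: list(carriers)}
    out = []
    reached_end = True
    for col in order:
        new_groups: dict = {}
        for key, members in groups.items():
            if len(members) < 2:
                continue
            for h in members:
                k = (key, int(alleles[h, col]))
                new_groups.setdefault(k, []).append(h)
        groups = {i: g for i, (k, g) in enumerate(new_groups.items())}
        hom = sum(len(g) * (len(g) - 1) // 2 for g in groups.values())
        e = hom / pairs_total
        out.append(e)
        if stop_below is not None and e < stop_below:
            reached_end = False
            break
    if stop_below is not None and not order:
        pass  # empty flank: reached_end stays True (edge at the core)
    return np.asarray(out), reached_end


def ehh(H: HaplotypeMatrix, core_index: int, allele: int) -> EHHCurve:
    """Extended haplotype homozygosity around a core SNP.

    EHH at flanking site x is the probability that two random carriers
    of `allele` at the core are identical over every SNP from the core
    out to x (inclusive). EHH at the core itself is 1 by definition.
    """
    a = H.alleles
    carriers = np.where(a[:, core_index] == allele)[0]
    if carriers.size < 2:
        raise ValueError(
            f"need >= 2 carriers of allele {allele} at the core, "
            f"got {carriers.size}")
    left, _ = _ehh_walk(a, carriers, range(core_index - 1, -1, -1))
    right, _ = _ehh_walk(a, carriers, range(core_index + 1, H.n_sites))
    return EHHCurve(core_index=core_index, allele=allele,
                    carrier_count=int(carriers.size),
                    left_ehh=left, right_ehh=right)


def _ihh_one_side(ehh_vals, dists):
    """Trapezoid integral of EHH against physical distance, truncated
    where EHH drops below the cutoff. Returns (ihh, hit_edge)."""
    area = 0.0
    prev_e, prev_d = 1.0, 0.0
    for e, d in zip(ehh_vals, dists):
        area += 0.5 * (prev_e + e) * (d - prev_d)
        if e < EHH_CUTOFF:
            return area, False
        prev_e, prev_d = e, d
    return area, True  # still above cutoff at the region edge


def ihs_unstandardized(H: HaplotypeMatrix, min_maf: float = 0.05,
                       site_indices=None,
                       allow_edge_truncation: bool = False):
    """Unstandardized iHS = ln(iHH_ancestral / iHH_derived) per SNP.

    Computed for polarized SNPs with MAF above `min_maf`; a SNP whose
    EHH curve reaches the ends of the region before decaying below the
    cutoff is reported as NaN with reason 'edge' - unless
    `allow_edge_truncation` is set, in which case the integral is
    truncated at the region end and kept (useful for small regions
    around incomplete sweeps). Low-frequency and single-class SNPs are
    skipped likewise. `site_indices` restricts the computation to a
    subset of core SNPs.

    Returns a DataFrame with columns pos, daf, ihs, reason.
    """
    a = H.alleles
    freqs = H.derived_freq()
    pos = H.positions.astype(float)
    rows = []
    cores = range(H.n_sites) if site_indices is None else site_indices
    for j in cores:
        f = freqs[j]
        reason = ""
        value = np.nan
        if min(f, 1 - f) <= min_maf:
            reason = "maf"
        else:
            ihh = {}
            edge = False
            skip = False
            dl = pos[j] - pos[np.arange(j - 1, -1, -1)]
            dr = pos[np.arange(j + 1, H.n_sites)] - pos[j]
            for al in (0, 1):
                carriers = np.where(a[:, j] == al)[0]
                if carriers.size < 2:
                    skip = True
                    break
                el, end_l = _ehh_walk(a, carriers,
                                      range(j - 1, -1, -1), EHH_CUTOFF)
                er, end_r = _ehh_walk(a, carriers,
                                      range(j + 1, H.n_sites), EHH_CUTOFF)
                il, e1 = _ihh_one_side(el, dl)
                ir, e2 = _ihh_one_side(er, dr)
                edge |= end_l or end_r
                ihh[al] = il + ir
            if skip:
                rows.append((H.positions[j], f, np.nan, "carriers"))
                continue
            if edge and not allow_edge_truncation:
                reason = "edge"
            elif ihh[1] == 0 or ihh[0] == 0:
                reason = "zero_ihh"
            else:
                value = float(np.log(ihh[0] / ihh[1]))
        rows.append((H.positions[j], f, value, reason))
    return pd.DataFrame(rows, columns=["pos", "daf", "ihs", "reason"])


# ---------------------------------------------------------------------
# nSL
# ---------------------------------------------------------------------
def _mean_pairwise_length(a: np.ndarray, members: np.ndarray, core: int):
    """Mean over haplotype pairs of the number of consecutive SNPs
    (including the core) shared identically around the core."""
    m = a.shape[1]
    tot = 0.0
    cnt = 0
    for ii in range(members.size):
        for jj in range(ii + 1, members.size):
            hi, hj = a[members[ii]], a[members[jj]]
            left = core
            while left > 0 and hi[left - 1] == hj[left - 1]:
                left -= 1
            right = core
            while right < m - 1 and hi[right + 1] == hj[right + 1]:
                right += 1
            tot += right - left + 1
            cnt += 1
    return tot / cnt


def nsl_unstandardized(H: HaplotypeMatrix, min_maf: float = 0.05):
    """Unstandardized nSL per SNP: ln(SL_ancestral / SL_derived).

    SL_c is the mean, over pairs of haplotypes carrying allele c at the
    core, of the length (in number of SNPs) of the maximal interval
    around the core over which the pair is identical. Positions are not
    used, so the statistic is invariant to coordinate rescaling.
    """
    a = H.alleles
    freqs = H.derived_freq()
    rows = []
    for j in range(H.n_sites):
        f = freqs[j]
        if min(f, 1 - f) <= min_maf:
            rows.append((H.positions[j], f, np.nan, "maf"))
            continue
        anc = np.where(a[:, j] == 0)[0]
        der = np.where(a[:, j] == 1)[0]
        if anc.size < 2 or der.size < 2:
            rows.append((H.positions[j], f, np.nan, "carriers"))
            continue
        sl_a = _mean_pairwise_length(a, anc, j)
        sl_d = _mean_pairwise_length(a, der, j)
        rows.append((H.positions[j], f, float(np.log(sl_a / sl_d)), ""))
    return pd.DataFrame(rows, columns=["pos", "daf", "nsl", "reason"])


# ---------------------------------------------------------------------
# frequency-bin standardization
# ---------------------------------------------------------------------
def standardize_by_frequency(scores, derived_freqs, n_bins: int = 100):
    """Standardize scores within equal-width derived-frequency bins.

    Within each populated bin (>= 2 finite values) the scores get zero
    mean and unit SD; other entries become NaN.
    """
    scores = np.asarray(scores, dtype=float)
    freqs = np.asarray(derived_freqs, dtype=float)
    bins = np.clip((freqs * n_bins).astype(int), 0, n_bins - 1)
    out = np.full(scores.size, np.nan)
    for b in np.unique(bins):
        sel = (bins == b) & np.isfinite(scores)
        if sel.sum() < 2:
            continue
        v = scores[sel]
        sd = v.std()
        if sd > 0:
            out[sel] = (v - v.mean()) / sd
    return out


# ---------------------------------------------------------------------
# Garud H statistics
# ---------------------------------------------------------------------
def _h_stats_window(a: np.ndarray):
    """H1, H2, H12, H2/H1 from the haplotype spectrum of one window."""
    uniq, counts = np.unique(a, axis=0, return_counts=True)
    p = np.sort(counts / a.shape[0])[::-1]
    h1 = float((p**2).sum())
    h2 = h1 - p[0] ** 2
    h12 = h1 if p.size < 2 else float((p[0] + p[1]) ** 2 + (p[2:] ** 2).sum())
    h2h1 = h2 / h1 if h1 > 0 else np.nan
    return h1, h2, h12, h2h1


def h_statistics(
    H: HaplotypeMatrix,
    snp_window: int = 200,
    window: int = 10_000,
    step: int = 5_000,
):
    """H1/H2/H12/H2-H1 in SNP windows, then sliding-window averaged.

    The statistics are computed in non-overlapping windows of
    `snp_window` SNPs (the full region if it holds fewer) and the
    SNP-window values, placed at their midpoint coordinate, are
    averaged in sliding physical windows of `window` bp moved by
    `step` bp. Returns (snp-window DataFrame, smoothed DataFrame).
    """
    if H.n_hap < 2:
        raise ValueError("need >= 2 haplotypes")
    m = H.n_sites
    rows = []
    starts = range(0, m, snp_window) if m >= snp_window else [0]
    for s0 in starts:
        e0 = min(s0 + snp_window, m)
        if e0 - s0 == 0:
            continue
        h1, h2, h12, h2h1 = _h_stats_window(H.alleles[:, s0:e0])
        mid = 0.5 * (H.positions[s0] + H.positions[e0 - 1])
        rows.append((mid, e0 - s0, h1, h2, h12, h2h1))
    per_win = pd.DataFrame(
        rows, columns=["mid", "n_snps", "H1", "H2", "H12", "H2H1"])
    out = []
    start0 = 0
    while start0 < H.region_length:
        end0 = start0 + window
        sel = per_win[(per_win["mid"] > start0) & (per_win["mid"] <= end0)]
        if len(sel):
            out.append((start0 + 1, min(end0, H.region_length),
                        int(sel["n_snps"].sum()),
                        *[float(sel[c].mean()) for c in
                          ("H1", "H2", "H12", "H2H1")]))
        start0 += step
    smoothed = pd.DataFrame(
        out, columns=["start", "end", "n_snps", "H1", "H2", "H12", "H2H1"])
    return per_win, smoothed


# ---------------------------------------------------------------------
# windowed nucleotide diversity
# ---------------------------------------------------------------------
def windowed_pi(
    H: HaplotypeMatrix,
    window: int = 10_000,
    step: int = 5_000,
    callable_fraction=None,
    min_callable: float = 0.10,
):
    """Average pairwise difference per callable bp in sliding windows.

    `callable_fraction`, if given, is a callable-site fraction per
    window (same order as the emitted windows assuming all-callable
    spacing); windows below `min_callable` are excluded. Without a
    mask every position is treated as callable.
    """
    n = H.n_hap
    p = H.derived_freq()
    site_pi = 2.0 * p * (1.0 - p) * n / (n - 1)
    rows = []
    start0 = 0
    w = 0
    while start0 < H.region_length:
        end0 = min(start0 + window, H.region_length)
        frac = 1.0 if callable_fraction is None else callable_fraction[w]
        w += 1
        if frac >= min_callable:
            sel = (H.positions > start0) & (H.positions <= end0)
            denom = (end0 - start0) * frac
            rows.append((start0 + 1, end0, int(sel.sum()),
                         float(site_pi[sel].sum() / denom)))
        start0 += step
    return pd.DataFrame(rows, columns=["start", "end", "n_snps", "pi"])


# ---------------------------------------------------------------------
# CLR scan (SweepFinder-style)
# ---------------------------------------------------------------------
@dataclass
class BackgroundSFS:
    """Genome-wide derived-allele-count spectrum for samples of size n.

    counts[j] is the number of sites with derived count j; classes are
    1..n-1 plus, when provided, the fixed-derived class n. A 0.5
    pseudo-count keeps empty polymorphic classes usable.
    """

    counts: np.ndarray
    n: int

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=float)
        if c.size != self.n + 1:
            raise ValueError("counts must have length n + 1")
        if c.sum() <= 0:
            raise ValueError("background SFS is empty")
        if np.any(c < 0):
            raise ValueError("counts must be >= 0")
        self.counts = c

    @classmethod
    def from_derived_counts(cls, derived_counts, n, include_fixed=False):
        counts = np.bincount(np.asarray(derived_counts), minlength=n + 1)
        if not include_fixed:
            counts = counts.astype(float)
            counts[n] = 0
        return cls(counts=np.asarray(counts, float), n=n)

    def support(self) -> np.ndarray:
        sup = np.arange(1, self.n)
        if self.counts[self.n] > 0:
            sup = np.append(sup, self.n)
        return sup

    def probs(self) -> np.ndarray:
        p = np.zeros(self.n + 1)
        sup = self.support()
        c = self.counts[sup] + 0.5
        p[sup] = c / c.sum()
        return p


def _escape_kernel(background: BackgroundSFS) -> np.ndarray:
    """A[h, b]: spectrum after a sweep that exactly h lineages escape.

    Escapees draw alleles without replacement from the pre-sweep sample
    configuration; all hitchhikers share one further draw (the sweeping
    ancestor). Cached on the background object.
    """
    cached = getattr(background, "_kernel", None)
    if cached is not None:
        return cached
    n = background.n
    pb = background.probs()
    sup = background.support()
    A = np.zeros((n + 1, n + 1))
    for h in range(n + 1):
        for j in sup:
            if pb[j] == 0:
                continue
            if h == n:
                A[h, j] += pb[j]
                continue
            x = np.arange(max(0, h - (n - j)), min(j, h) + 1)
            px = hypergeom.pmf(x, n, j, h)
            p_anc_derived = (j - x) / (n - h)
            np.add.at(A[h], x + (n - h), pb[j] * px * p_anc_derived)
            np.add.at(A[h], x, pb[j] * px * (1.0 - p_anc_derived))
    background._kernel = A
    return A


def sweep_transformed_sfs(background: BackgroundSFS, p_escape: float):
    """Post-sweep spectrum given per-lineage escape probability.

    Each of the n sampled lineages escapes the sweep independently with
    probability p_escape; see `_escape_kernel` for the allele draws. At
    p_escape = 1 the background spectrum is returned unchanged.
    Probabilities are renormalized over the observable classes.
    """
    n = background.n
    A = _escape_kernel(background)
    sup = background.support()
    q = binom.pmf(np.arange(n + 1), n, p_escape) @ A
    obs = q[sup].sum()
    out = np.zeros(n + 1)
    if obs > 0:
        out[sup] = q[sup] / obs
    return out


def clr_scan(
    positions,
    derived_counts,
    n: int,
    background: BackgroundSFS,
    region_length: int,
    grid_spacing: int = 2_000,
    n_alpha: int = 64,
    alpha_range: tuple[float, float] = (1e-6, 1e-1),
    ad_cutoff: float = 10.0,
):
    """Composite likelihood ratio for a sweep at each grid position.

    At every grid point the sweep-model composite likelihood (escape
    probability 1 - exp(-alpha*d) per site at distance d) is maximized
    over a log-spaced alpha grid and contrasted with the background
    likelihood: CLR = 2(lnL_sweep - lnL_background) >= 0. The
    transformed spectrum is precomputed on a log grid of alpha*d and
    interpolated; sites with alpha*d beyond `ad_cutoff` contribute
    nothing (their transform is indistinguishable from background).

    Returns DataFrame grid_pos, clr, alpha_hat.
    """
    positions = np.asarray(positions, dtype=float)
    counts = np.asarray(derived_counts, dtype=int)
    if background.counts.sum() <= 0:
        raise ValueError("empty background SFS")
    sup_mask = np.isin(counts, background.support())
    positions, counts = positions[sup_mask], counts[sup_mask]
    pb = background.probs()
    log_pb_site = np.log(pb[counts])
    # precompute transformed spectra over an alpha*d grid (cached per
    # background); the log is floored so that a fully hitchhiked
    # spectrum (no observable polymorphism) is penalized, not NaN
    cached = getattr(background, "_logQ_table", None)
    if cached is not None and cached[2] == ad_cutoff:
        ad_grid, logQ = cached[0], cached[1]
    else:
        ad_grid = np.concatenate([[0.0], np.geomspace(1e-4, ad_cutoff, 80)])
        Q = np.vstack([
            sweep_transformed_sfs(background, 1.0 - np.exp(-ad))
            for ad in ad_grid
        ])
        logQ = np.log(np.maximum(Q, 1e-300))
        background._logQ_table = (ad_grid, logQ, ad_cutoff)
    alphas = np.geomspace(*alpha_range, n_alpha)
    grid = np.arange(grid_spacing / 2, region_length, grid_spacing)
    rows = []
    order = np.argsort(positions)
    positions, counts, log_pb_site = (
        positions[order], counts[order], log_pb_site[order])
    for g in grid:
        d = np.abs(positions - g)
        best, best_alpha = 0.0, np.inf
        for alpha in alphas:
            ad = alpha * d
            sel = ad < ad_cutoff
            if not sel.any():
                continue
            idx = np.searchsorted(ad_grid, ad[sel])
            idx = np.clip(idx, 1, ad_grid.size - 1)
            # linear interpolation in alpha*d
            lo, hi = ad_grid[idx - 1], ad_grid[idx]
            wgt = (ad[sel] - lo) / (hi - lo)
            lq = ((1 - wgt) * logQ[idx - 1, counts[sel]]
                  + wgt * logQ[idx, counts[sel]])
            delta = np.sum(lq - log_pb_site[sel])
            if delta > best:
                best, best_alpha = delta, alpha
        rows.append((float(g), 2.0 * best, best_alpha))
    return pd.DataFrame(rows, columns=["grid_pos", "clr", "alpha_hat"])


# ---------------------------------------------------------------------
# large-window enrichment
# ---------------------------------------------------------------------
def window_enrichment(
    scores,
    positions,
    chroms=None,
    window: int = 700_000,
    threshold: float = 2.0,
    min_snps: int = 100,
):
    """Proportion of |score| > threshold in non-overlapping windows.

    Windows with fewer than `min_snps` scored SNPs are excluded.
    Returns (DataFrame chrom, start, end, n_snps, proportion, quantile,
    q95, q99) where `quantile` is the empirical rank of each window's
    proportion.
    """
    scores = np.asarray(scores, dtype=float)
    positions = np.asarray(positions)
    if chroms is None:
        chroms = np.repeat("chr", scores.size)
    chroms = np.asarray(chroms)
    rows = []
    for chrom in pd.unique(chroms):
        sel = chroms == chrom
        pos, sc = positions[sel], scores[sel]
        finite = np.isfinite(sc)
        pos, sc = pos[finite], sc[finite]
        if pos.size == 0:
            continue
        start0 = 0
        last = pos.max()
        while start0 < last:
            end0 = start0 + window
            w = (pos > start0) & (pos <= end0)
            nw = int(w.sum())
            if nw >= min_snps:
                rows.append((chrom, start0 + 1, end0, nw,
                             float((np.abs(sc[w]) > threshold).mean())))
            start0 = end0
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps",
                                     "proportion"])
    if len(df):
        props = df["proportion"].to_numpy()
        df["quantile"] = [float((props <= v).mean()) for v in props]
        df.attrs["q95"] = float(np.quantile(props, 0.95))
        df.attrs["q99"] = float(np.quantile(props, 0.99))
    return df
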