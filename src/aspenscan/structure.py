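"""Population structure, differentiation and linkage disequilibrium.

PCA on standardized dosages with Tracy-Widom axis significance, IBS
relatedness screening, Weir-Cockerham FST (per SNP, pairwise
populations, sliding windows), Mantel isolation-by-distance, the
centered genomic relationship (kinship) matrix, and the Hill-Weir LD
decay fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .core import MISSING, GenotypeMatrix
from .tracywidom import tw1_sf


# ---------------------------------------------------------------------
# PCA + Tracy-Widom
# ---------------------------------------------------------------------
@dataclass
class PCAResult:
    scores: np.ndarray        # n x K
    eigenvalues: np.ndarray   # K, of the n x n covariance (descending)
    loadings: np.ndarray      # m x K
    variance_fractions: np.ndarray
    tw_pvalues: np.ndarray
    kept_sites: np.ndarray    # indices of non-monomorphic sites used


def _imputed_dosages(G: GenotypeMatrix) -> np.ndarray:
    d = G.dosages.astype(float)
    d[G.dosages == MISSING] = np.nan
    mean = np.nanmean(d, axis=0)
    idx = np.where(np.isnan(d))
    d[idx] = mean[idx[1]]
    return d


def genotype_pca(G: GenotypeMatrix, K: int = 10) -> PCAResult:
    """PCA of allele-frequency-standardized dosages (smartpca-style).

    Missing dosages are mean-imputed per SNP; each column is centered
    and divided by sqrt(p(1-p)) with p the sample allele frequency;
    monomorphic columns are dropped. Axis signs are fixed by forcing the
    largest-|loading| SNP of each axis to have a positive loading.
    """
    d = _imputed_dosages(G)
    p = d.mean(0) / 2.0
    keep = (p > 0) & (p < 1)
    if keep.sum() < K:
        raise ValueError(f"only {int(keep.sum())} polymorphic sites for K={K}")
    X = (d[:, keep] - 2 * p[keep]) / np.sqrt(2 * p[keep] * (1 - p[keep]))
    m = X.shape[1]
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    eig = S**2 / m
    scores = U * S
    loadings = Vt.T
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    tw_p = tracy_widom_pvalues(eig, n=G.n_individuals, m=m)
    K = min(K, len(eig))
    return PCAResult(
        scores=scores[:, :K],
        eigenvalues=eig[:K],
        loadings=loadings[:, :K],
        variance_fractions=(eig / eig.sum())[:K],
        tw_pvalues=tw_p[:K],
        kept_sites=np.where(keep)[0],
    )


def tracy_widom_pvalues(eigenvalues: np.ndarray, n: int, m: int) -> np.ndarray:
    """Per-axis Tracy-Widom p-values with the effective-marker correction.

    For axis j the trailing eigenvalues lambda_j.. are used to estimate
    the effective number of markers, the leading one is standardized
    with the GOE centering/scaling constants, and the p-value is the
    TW1 upper tail. Following the usual practice, each axis is tested
    after removing the preceding ones.
    """
    lam = np.asarray(eigenvalues, dtype=float)
    lam = lam[lam > 1e-9 * lam.max()]  # drop rank-deficiency zeros
    if lam.size < 2:
        raise ValueError("need at least 2 eigenvalues")
    pvals = np.full(np.asarray(eigenvalues).size, np.nan)
    for j in range(lam.size - 1):
        tail = lam[j:]
        l = tail.size
        # effective marker count from the eigenvalues BELOW the tested
        # one, so a genuinely structured leading axis cannot mask itself
        low = lam[j + 1:]
        tot_l, tot2_l = low.sum(), (low**2).sum()
        denom = low.size * tot2_l - tot_l**2
        if denom <= 0:
            n_eff = float(m)
        else:
            n_eff = low.size * tot_l**2 / denom
        n_eff = min(n_eff, float(m))
        if n_eff <= 1:
            break
        L1 = l * tail[0] / tail.sum()
        a, b = np.sqrt(n_eff - 1), np.sqrt(l)
        mu = (a + b) ** 2 / n_eff
        sigma = (a + b) / n_eff * (1.0 / a + 1.0 / b) ** (1.0 / 3.0)
        pvals[j] = tw1_sf((L1 - mu) / sigma)
    return pvals


# ---------------------------------------------------------------------
# IBS relatedness
# ---------------------------------------------------------------------
def pairwise_ibs(G: GenotypeMatrix, threshold: float = 0.8):
    """Mean identity-by-state over non-missing sites for every pair.

    IBS(i, j) = mean over sites of (2 - |d_i - d_j|)/2. Returns
    (matrix, flagged_pairs, removal_set): pairs above the threshold are
    flagged and a greedy minimal removal set (always dropping the
    individual in most flagged pairs) is computed.
    """
    d = G.dosages.astype(float)
    d[G.dosages == MISSING] = np.nan
    n = G.n_individuals
    ibs = np.ones((n, n))
    for i in range(n):
        diff = np.abs(d - d[i])
        ibs[i] = np.nanmean((2.0 - diff) / 2.0, axis=1)
    ibs = (ibs + ibs.T) / 2.0
    iu = np.triu_indices(n, 1)
    flagged = [(int(i), int(j)) for i, j in zip(*iu) if ibs[i, j] > threshold]
    remove: set[int] = set()
    pairs = list(flagged)
    while pairs:
        counts: dict[int, int] = {}
        for i, j in pairs:
            counts[i] = counts.get(i, 0) + 1
            counts[j] = counts.get(j, 0) + 1
        worst = max(sorted(counts), key=lambda k: counts[k])
        remove.add(worst)
        pairs = [p for p in pairs if worst not in p]
    return ibs, flagged, remove


# ---------------------------------------------------------------------
# Weir-Cockerham FST
# ---------------------------------------------------------------------
def _wc_components(G: GenotypeMatrix, pops: np.ndarray):
    """Per-site Weir-Cockerham (1984) variance components (a, b, c)."""
    d = G.dosages
    labels = np.unique(pops)
    r = labels.size
    if r < 2:
        raise ValueError("need >= 2 populations")
    m = G.n_sites
    n_i = np.zeros((r, m))
    p_i = np.zeros((r, m))
    h_i = np.zeros((r, m))
    for k, lab in enumerate(labels):
        sub = d[pops == lab]
        if sub.shape[0] < 2:
            raise ValueError(f"population {lab!r} has < 2 samples")
        valid = sub != MISSING
        n_i[k] = valid.sum(0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_i[k] = np.where(valid, sub, 0).sum(0) / (2.0 * n_i[k])
            h_i[k] = (sub == 1).sum(0) / n_i[k]
    nbar = n_i.mean(0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n_i**2).sum(0) / (r * nbar)) / (r - 1)
        pbar = (n_i * p_i).sum(0) / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum(0) / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum(0) / (r * nbar)
        a = nbar / nc * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4.0)
            / (nbar - 1)
        )
        b = nbar / (nbar - 1) * (
            pbar * (1 - pbar) - (r - 1) / r * s2
            - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2.0
    mono = (pbar <= 0) | (pbar >= 1)
    a[mono] = b[mono] = c[mono] = np.nan
    return a, b, c


def wc_fst(
    G: GenotypeMatrix,
    pops,
    mode: str = "per-snp",
    window: int = 10_000,
    step: int = 5_000,
):
    """Weir-Cockerham FST.

    mode 'per-snp': theta = a/(a+b+c) per site (NaN for monomorphic
    sites). mode 'pairwise-pop': multi-locus ratio-of-sums for every
    population pair (DataFrame pop1, pop2, fst). mode 'windowed':
    ratio-of-sums in sliding windows per chromosome (DataFrame chrom,
    start, end, n_snps, fst; 1-based inclusive coordinates).
    """
    pops = np.asarray(pops)
    if mode == "per-snp":
        a, b, c = _wc_components(G, pops)
        with np.errstate(invalid="ignore", divide="ignore"):
            return a / (a + b + c)
    if mode == "pairwise-pop":
        labels = np.unique(pops)
        rows = []
        for i in range(labels.size):
            for j in range(i + 1, labels.size):
                sel = np.isin(pops, [labels[i], labels[j]])
                sub = GenotypeMatrix(
                    dosages=G.dosages[sel], sites=G.sites,
                    individuals=[G.individuals[k] for k in np.where(sel)[0]])
                a, b, c = _wc_components(sub, pops[sel])
                with np.errstate(invalid="ignore"):
                    fst = np.nansum(a) / np.nansum(a + b + c)
                rows.append((labels[i], labels[j], float(fst)))
        return pd.DataFrame(rows, columns=["pop1", "pop2", "fst"])
    if mode == "windowed":
        a, b, c = _wc_components(G, pops)
        tot = a + b + c
        rows = []
        pos = G.sites["pos"].to_numpy()
        for chrom, idx in G.sites.groupby("chrom").groups.items():
            idx = np.asarray(idx)
            cpos = pos[idx]
            last = cpos.max()
            start0 = 0
            while start0 < last:
                end0 = start0 + window
                sel = idx[(cpos > start0) & (cpos <= end0)]
                ok = sel[np.isfinite(tot[sel])] if sel.size else sel
                if ok.size:
                    fst = float(np.nansum(a[ok]) / np.nansum(tot[ok]))
                    rows.append((chrom, start0 + 1, end0, int(ok.size), fst))
                start0 += step
        return pd.DataFrame(rows, columns=["chrom", "start", "end",
                                           "n_snps", "fst"])
    raise ValueError(f"unknown mode {mode!r}")


def mean_fst(G: GenotypeMatrix, pops) -> float:
    """Genome-wide multi-locus (ratio-of-sums) Weir-Cockerham FST."""
    a, b, c = _wc_components(G, np.asarray(pops))
    return float(np.nansum(a) / np.nansum(a + b + c))


# ---------------------------------------------------------------------
# Mantel isolation by distance
# ---------------------------------------------------------------------
def mantel_ibd(
    fst_matrix: np.ndarray,
    distance_km: np.ndarray,
    n_perm: int = 9999,
    seed: int = 0,
):
    """Mantel test of linearized FST against geographic distance.

    Genetic distance is FST/(1-FST); the statistic is the Pearson
    correlation over off-diagonal pairs; significance comes from
    permuting population labels, p = (1 + #(r_perm >= r_obs))/(1 + n_perm).
    """
    F = np.asarray(fst_matrix, dtype=float)
    D = np.asarray(distance_km, dtype=float)
    for M, name in ((F, "fst_matrix"), (D, "distance_km")):
        if M.shape[0] != M.shape[1] or not np.allclose(M, M.T, equal_nan=True):
            raise ValueError(f"{name} must be symmetric")
    lin = F / (1.0 - F)
    iu = np.triu_indices(F.shape[0], 1)
    r_obs = np.corrcoef(lin[iu], D[iu])[0, 1]
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(F.shape[0])
        r_p = np.corrcoef(lin[np.ix_(perm, perm)][iu], D[iu])[0, 1]
        if r_p >= r_obs:
            count += 1
    return float(r_obs), (1.0 + count) / (1.0 + n_perm)


# ---------------------------------------------------------------------
# Kinship
# ---------------------------------------------------------------------
def centered_kinship(G: GenotypeMatrix) -> np.ndarray:
    """Centered genomic relationship matrix K = W W^T / m."""
    W = _imputed_dosages(G)
    W = W - W.mean(0)
    return W @ W.T / G.n_sites


# ---------------------------------------------------------------------
# LD decay
# ---------------------------------------------------------------------
def hill_weir_expectation(d: np.ndarray, C: float, n: int) -> np.ndarray:
    """Expected r^2 at scaled recombination Cd = C*d for sample size n."""
    Cd = C * d
    t1 = (10.0 + Cd) / ((2.0 + Cd) * (11.0 + Cd))
    t2 = 1.0 + ((3.0 + Cd) * (12.0 + 12.0 * Cd + Cd**2)) / (
        n * (2.0 + Cd) * (11.0 + Cd))
    return t1 * t2


def ld_decay_fit(r2: np.ndarray, distance_bp: np.ndarray, n: int):
    """Nonlinear least-squares fit of the Hill-Weir r^2 decay curve.

    Zero-distance pairs are excluded. Returns (C per bp, fitted
    callable).
    """
    r2 = np.asarray(r2, dtype=float)
    d = np.asarray(distance_bp, dtype=float)
    ok = d > 0
    r2, d = r2[ok], d[ok]
    if r2.size < 10:
        raise ValueError("need at least 10 nonzero-distance pairs")
    popt, _ = curve_fit(
        lambda dd, C: hill_weir_expectation(dd, C, n),
        d, r2, p0=[1.0 / np.median(d)], bounds=(1e-12, np.inf), maxfev=10000)
    C = float(popt[0])
    return C, (lambda dd: hill_weir_expectation(np.asarray(dd, float), C, n))
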