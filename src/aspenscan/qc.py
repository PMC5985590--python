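"""Post-VCF site and genotype quality control.

Site-level depth/mapping filters, SNP-level filters (indel proximity,
genotype-quality masking, call rate, excess-heterozygosity exact HWE
test, minor-allele frequency), greedy LD pruning, and two-outgroup
ancestral-state polarization.

Boundary semantics: depth thresholds are strict ("< 400x" and "> 4500x"
drop; ties are kept), matching the rule statements they implement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .core import MISSING, GenotypeMatrix


@dataclass
class SiteFilterThresholds:
    min_depth: int = 400
    max_depth: int = 4500
    max_mq0: int = 200
    drop_repeats: bool = True
    min_scaffold_length: int = 2000


def filter_sites(stats: pd.DataFrame,
                 thresholds: SiteFilterThresholds | None = None):
    """Apply the four site-level mapping filters.

    ``stats`` must have columns depth, mq0, repeat (bool),
    scaffold_length. Returns (keep_mask, reasons) where reasons is a
    same-length object array naming the first rule that fired ('' if
    kept).
    """
    th = thresholds or SiteFilterThresholds()
    for col in ("depth", "mq0", "repeat", "scaffold_length"):
        if col not in stats.columns:
            raise ValueError(f"site stats missing required column {col!r}")
    n = len(stats)
    reasons = np.full(n, "", dtype=object)
    depth = stats["depth"].to_numpy()
    mq0 = stats["mq0"].to_numpy()
    rep = stats["repeat"].to_numpy(bool)
    slen = stats["scaffold_length"].to_numpy()
    rules = [
        (depth < th.min_depth, "low_coverage"),
        (depth > th.max_depth, "high_coverage"),
        (mq0 > th.max_mq0, "excess_mq0"),
        (rep if th.drop_repeats else np.zeros(n, bool), "repeat"),
        (slen < th.min_scaffold_length, "short_scaffold"),
    ]
    for mask, label in rules:
        fire = mask & (reasons == "")
        reasons[fire] = label
    return reasons == "", reasons


def hwe_excess_het_test(nAA: int, nAa: int, naa: int) -> float:
    """One-sided exact test for heterozygote excess.

    Conditional on the observed allele counts, returns the probability
    of seeing at least the observed number of heterozygotes under
    Hardy-Weinberg (the Wigginton-style exact distribution, upper tail
    only). Monomorphic input returns 1 by convention.
    """
    if min(nAA, nAa, naa) < 0:
        raise ValueError("genotype counts must be >= 0")
    n = nAA + nAa + naa
    if n == 0:
        raise ValueError("no genotypes")
    nA = 2 * nAA + nAa
    na = 2 * naa + nAa
    if nA == 0 or na == 0:
        return 1.0
    # P(h hets | n, nA) = n! nA! na! 2^h / (nAA! h! naa! (2n)!)
    hets = np.arange(min(nA, na), -1, -2)  # same parity as nA
    homA = (nA - hets) // 2
    homa = (na - hets) // 2
    logp = (gammaln(n + 1) + gammaln(nA + 1) + gammaln(na + 1)
            + hets * np.log(2.0)
            - gammaln(homA + 1) - gammaln(hets + 1) - gammaln(homa + 1)
            - gammaln(2 * n + 1))
    p = np.exp(logp - logp.max())
    p /= p.sum()
    return float(p[hets >= nAa].sum())


def hwe_excess_het_pvalues(G: GenotypeMatrix) -> np.ndarray:
    d = G.dosages
    out = np.empty(G.n_sites)
    for j in range(G.n_sites):
        col = d[:, j]
        out[j] = hwe_excess_het_test(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )
    return out


@dataclass
class SnpFilterThresholds:
    min_indel_distance: int = 5       # keep if distance > this
    min_gq: int = 10
    min_call_rate: float = 0.70
    hwe_min_p: float = 1e-8
    min_maf: float = 0.05


def filter_snps(
    G: GenotypeMatrix,
    indel_distance: np.ndarray | None = None,
    gq: np.ndarray | None = None,
    thresholds: SnpFilterThresholds | None = None,
):
    """SNP-level filtering pipeline.

    Order of operations: genotypes with GQ below the threshold are set
    missing first; then sites are dropped for indel proximity, call rate
    (computed after GQ masking), heterozygote-excess HWE p below the
    cutoff, and MAF at or below the cutoff.

    Returns (filtered GenotypeMatrix, report dict of removal counts).
    """
    th = thresholds or SnpFilterThresholds()
    d = G.dosages.copy()
    if gq is not None:
        gq = np.asarray(gq)
        if gq.shape != d.shape:
            raise ValueError("gq must match dosage shape")
        d[gq < th.min_gq] = MISSING
    masked = GenotypeMatrix(dosages=d, sites=G.sites.copy(),
                            individuals=list(G.individuals))
    keep = np.ones(G.n_sites, dtype=bool)
    report: dict[str, int] = {}
    if indel_distance is not None:
        near = np.asarray(indel_distance) <= th.min_indel_distance
        report["near_indel"] = int((keep & near).sum())
        keep &= ~near
    low_call = masked.call_rate() < th.min_call_rate
    report["low_call_rate"] = int((keep & low_call).sum())
    keep &= ~low_call
    hwe_p = hwe_excess_het_pvalues(masked)
    bad_hwe = hwe_p < th.hwe_min_p
    report["excess_het"] = int((keep & bad_hwe).sum())
    keep &= ~bad_hwe
    low_maf = masked.maf() <= th.min_maf
    report["low_maf"] = int((keep & low_maf).sum())
    keep &= ~low_maf
    report["kept"] = int(keep.sum())
    out = GenotypeMatrix(
        dosages=masked.dosages[:, keep],
        sites=masked.sites.loc[keep].reset_index(drop=True),
        individuals=list(G.individuals),
    )
    return out, report


def polarize_site(
    tremula_alleles: tuple[str, str],
    trichocarpa_genotype: tuple[str, str] | None,
    tremuloides_genotype: tuple[str, str] | None,
) -> str | None:
    """Two-outgroup ancestral-state assignment for one biallelic site.

    Rule 1: if the more distant outgroup individual is homozygous and
    its allele matches one of the ingroup alleles, that allele is
    ancestral. Rule 2 (fallback): same criterion on the closer outgroup.
    Otherwise the ancestral state is unknown (None). The returned allele
    is always one of the ingroup alleles.
    """
    for geno in (trichocarpa_genotype, tremuloides_genotype):
        if geno is None:
            continue
        a, b = geno
        if a == b and a in tremula_alleles:
            return a
    return None


def ld_prune(
    G: GenotypeMatrix,
    r2_threshold: float = 0.2,
    window: int = 50,
    step: int = 5,
) -> np.ndarray:
    """Greedy window-based LD pruning; returns kept site indices.

    Within each window of `window` SNPs (slid by `step`), pairs with
    squared dosage correlation above the threshold lose one member:
    the SNP with the lower MAF, ties broken by removing the higher
    index. Deterministic given input order.
    """
    d = G.dosages.astype(float)
    d[G.dosages == MISSING] = np.nan
    col_mean = np.nanmean(d, axis=0)
    inds = np.where(np.isnan(d))
    d[inds] = col_mean[inds[1]]
    maf = G.maf()
    m = G.n_sites
    kept = np.ones(m, dtype=bool)
    start = 0
    while True:
        end = min(start + window, m)
        idx = np.arange(start, end)
        sub = d[:, idx]
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(sub.T)
        r2 = np.nan_to_num(r) ** 2
        for ii in range(len(idx)):
            if not kept[idx[ii]]:
                continue
            for jj in range(ii + 1, len(idx)):
                if not kept[idx[jj]] or not kept[idx[ii]]:
                    continue
                if r2[ii, jj] > r2_threshold:
                    gi, gj = idx[ii], idx[jj]
                    # lower MAF loses; on ties the higher index loses
                    drop = gi if maf[gi] < maf[gj] else gj
                    kept[drop] = False
        if end == m:
            break
        start += step
    return np.where(kept)[0]
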