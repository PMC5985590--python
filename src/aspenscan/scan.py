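"""Local-adaptation genome scan and downstream fine-mapping.

Three conceptually different scans — PCA-loading outliers, latent-factor
environmental association, and a kinship linear mixed-model GWAS on BLUP
genetic values — each FDR-controlled with Storey-Tibshirani q-values,
combined by a >= 2-of-3 consensus rule; per-SNP proportion of variance
explained; and an exhaustive-enumeration causal fine-mapper for small
loci.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import GenotypeMatrix
from .structure import PCAResult, _imputed_dosages


# ---------------------------------------------------------------------
# BLUP genetic values
# ---------------------------------------------------------------------
def blup_genetic_values(
    records: pd.DataFrame,
    exclude: list[tuple] | None = None,
) -> pd.Series:
    """Per-clone genetic values from a common-garden mixed model.

    The phenotype z_ijklm of replicate m of clone l in block j, year k
    at site i is modelled with site, block-within-site and
    year-within-site as fixed effects and clone as a random effect; the
    clone BLUPs (REML) are the genetic values.

    Parameters
    ----------
    records : DataFrame with columns site, block, year, clone, value.
    exclude : optional list of (site, year) pairs to drop (e.g. a
        drought year at one site).
    """
    df = records.copy()
    for col in ("site", "block", "year", "clone", "value"):
        if col not in df.columns:
            raise ValueError(f"records missing column {col!r}")
    if exclude:
        for site, year in exclude:
            df = df[~((df["site"] == site) & (df["year"] == year))]
    if df["clone"].nunique() < 2:
        raise ValueError("need >= 2 clones to estimate genetic variance")
    df = df.assign(
        site_block=df["site"].astype(str) + "/" + df["block"].astype(str),
        site_year=df["site"].astype(str) + "/" + df["year"].astype(str),
    )
    # nested factors are collinear with site; build the dummy design and
    # reduce it to full column rank before fitting
    parts = [pd.get_dummies(df[c], prefix=c, drop_first=True, dtype=float)
             for c in ("site", "site_block", "site_year")]
    X = pd.concat([pd.Series(1.0, index=df.index, name="intercept"),
                   *parts], axis=1).to_numpy()
    from scipy.linalg import qr
    _, Rq, piv = qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(Rq))
    rank = int((diag > diag[0] * 1e-10).sum())
    X = X[:, np.sort(piv[:rank])]
    import statsmodels.regression.mixed_linear_model as mlm
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = mlm.MixedLM(df["value"].to_numpy(float), X,
                            groups=df["clone"].to_numpy())
        fit = model.fit(reml=True)
    try:
        blups = pd.Series({k: float(v.iloc[0])
                           for k, v in fit.random_effects.items()})
    except (ValueError, np.linalg.LinAlgError):
        # clone variance estimated at zero: all BLUPs shrink to 0
        blups = pd.Series(0.0, index=pd.unique(df["clone"]))
    return blups.reindex(pd.unique(df["clone"]))


# ---------------------------------------------------------------------
# Scan 1: PCA-loading outliers
# ---------------------------------------------------------------------
def pca_outlier_scan(G: GenotypeMatrix, pca: PCAResult) -> np.ndarray:
    """Per-SNP p-values for association with the first PC.

    The squared correlation rho^2 between each (standardized) SNP and
    PC1 is rescaled by its genome-wide mean so the statistic has the
    chi-square(1) expectation, and the p-value is the chi-square upper
    tail. SNPs dropped from the PCA (monomorphic) get p = NaN.
    """
    if pca.scores.shape[1] < 1:
        raise ValueError("PC1 not available")
    d = _imputed_dosages(G)[:, pca.kept_sites]
    x = d - d.mean(0)
    pc1 = pca.scores[:, 0] - pca.scores[:, 0].mean()
    num = x.T @ pc1
    denom = np.sqrt((x**2).sum(0) * (pc1**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho2 = (num / denom) ** 2
    stat = rho2 / np.nanmean(rho2)
    p = stats.chi2.sf(stat, df=1)
    out = np.full(G.n_sites, np.nan)
    out[pca.kept_sites] = p
    return out


# ---------------------------------------------------------------------
# Scan 2: latent-factor environmental association
# ---------------------------------------------------------------------
def latent_factor_scan(
    G: GenotypeMatrix,
    env: np.ndarray,
    K: int = 2,
) -> pd.DataFrame:
    """SNP-environment association with latent confounding factors.

    A ridge/SVD analog of the latent-factor mixed model: the K latent
    factors are the top left singular vectors of the genotype matrix
    residualized on the environmental score; each SNP is then regressed
    on (env, factors) and the env t-statistic is taken as z. Reported
    p-values use genomic-control rescaling of z by the median chi-square.

    Returns a DataFrame with columns z (raw t-statistic), z_gc, p.
    """
    env = np.asarray(env, dtype=float)
    n = G.n_individuals
    if K >= n:
        raise ValueError("K must be smaller than the number of individuals")
    Y = _imputed_dosages(G)
    Y = Y - Y.mean(0)
    X = env - env.mean()
    if K > 0:
        coef = (X @ Y) / (X @ X)
        resid = Y - np.outer(X, coef)
        U, S, _ = np.linalg.svd(resid, full_matrices=False)
        F = U[:, :K]
        design = np.column_stack([np.ones(n), X, F])
    else:
        design = np.column_stack([np.ones(n), X])
    # per-SNP OLS of dosage on design; t-stat of the env column
    XtX_inv = np.linalg.inv(design.T @ design)
    beta = XtX_inv @ design.T @ Y                    # p x m
    resid = Y - design @ beta
    dof = n - design.shape[1]
    sigma2 = (resid**2).sum(0) / dof
    se_env = np.sqrt(sigma2 * XtX_inv[1, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta[1] / se_env
    lam = np.nanmedian(z**2) / stats.chi2.ppf(0.5, 1)
    z_gc = z / np.sqrt(max(lam, 1e-12))
    p = 2.0 * stats.norm.sf(np.abs(z_gc))
    return pd.DataFrame({"z": z, "z_gc": z_gc, "p": p})


# ---------------------------------------------------------------------
# Scan 3: kinship LMM GWAS
# ---------------------------------------------------------------------
def _reml_neg_loglik(log_delta, d, yt, Xt):
    """Restricted negative log-likelihood at variance ratio delta."""
    delta = 10.0 ** log_delta
    v = d + delta
    vinv = 1.0 / v
    XtVX = Xt.T @ (Xt * vinv[:, None])
    XtVy = Xt.T @ (yt * vinv)
    beta = np.linalg.solve(XtVX, XtVy)
    r = yt - Xt @ beta
    n, p = Xt.shape
    rss = r @ (r * vinv)
    sign, logdet_X = np.linalg.slogdet(XtVX)
    return 0.5 * ((n - p) * np.log(rss / (n - p)) + np.log(v).sum()
                  + logdet_X)


def lmm_gwas(
    G: GenotypeMatrix,
    y: np.ndarray,
    K: np.ndarray,
    log_delta_range: tuple[float, float] = (-5.0, 5.0),
) -> pd.DataFrame:
    """Univariate mixed-model association for every SNP.

    Model: y = mu + x beta + u + e with u ~ N(0, sg^2 K). K is
    eigendecomposed once; for each SNP the variance ratio
    delta = se^2/sg^2 is profiled by 1-D REML optimization and the Wald
    test on beta uses the t reference with n - 2 df.

    Returns DataFrame: beta, se, maf, N, p (one row per SNP).
    """
    from scipy.optimize import minimize_scalar

    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("phenotype contains non-finite values")
    K = np.asarray(K, dtype=float)
    w, U = np.linalg.eigh(K)
    if w.min() < -1e-8 * max(1.0, abs(w.max())):
        raise ValueError(
            f"kinship matrix is not PSD (smallest eigenvalue {w.min():.3g})")
    w = np.clip(w, 0.0, None)
    yt = U.T @ y
    ones_t = U.T @ np.ones(G.n_individuals)
    D = _imputed_dosages(G)
    maf = G.maf()
    n = G.n_individuals
    rows = []
    for j in range(G.n_sites):
        xt = U.T @ D[:, j]
        Xt = np.column_stack([ones_t, xt])
        if np.isclose(D[:, j].std(), 0):
            rows.append((np.nan, np.nan, maf[j], n, np.nan))
            continue
        res = minimize_scalar(
            _reml_neg_loglik, bounds=log_delta_range, args=(w, yt, Xt),
            method="bounded", options={"xatol": 1e-6})
        delta = 10.0 ** res.x
        v = w + delta
        vinv = 1.0 / v
        XtVX = Xt.T @ (Xt * vinv[:, None])
        XtVy = Xt.T @ (yt * vinv)
        beta = np.linalg.solve(XtVX, XtVy)
        r = yt - Xt @ beta
        sg2 = (r @ (r * vinv)) / (n - 2)
        cov = sg2 * np.linalg.inv(XtVX)
        se = np.sqrt(cov[1, 1])
        tstat = beta[1] / se
        p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
        rows.append((float(beta[1]), float(se), float(maf[j]), n, float(p)))
    out = pd.DataFrame(rows, columns=["beta", "se", "maf", "N", "p"])
    out.insert(0, "pos", G.sites["pos"].to_numpy())
    out.insert(0, "chrom", G.sites["chrom"].to_numpy())
    return out


# ---------------------------------------------------------------------
# PVE
# ---------------------------------------------------------------------
def pve(beta: float, se: float, maf: float, N: int) -> float:
    """Proportion of phenotypic variance explained by one SNP.

    PVE = 2 b^2 f(1-f) / (2 b^2 f(1-f) + se^2 * 2 N f(1-f)) with b the
    effect estimate, se its standard error, f the MAF and N the sample
    size.
    """
    if not (0 < maf <= 0.5):
        raise ValueError(f"MAF must lie in (0, 0.5], got {maf}")
    num = 2.0 * beta**2 * maf * (1.0 - maf)
    den = num + se**2 * 2.0 * N * maf * (1.0 - maf)
    if den == 0:
        return 0.0
    return float(num / den)


# ---------------------------------------------------------------------
# Storey-Tibshirani q-values
# ---------------------------------------------------------------------
def storey_qvalues(p: np.ndarray, lambdas: np.ndarray | None = None):
    """q-values with the smoothed-lambda pi0 estimate.

    pi0(lambda) = #{p > lambda}/(m (1 - lambda)) is smoothed with a
    cubic polynomial over a lambda grid and evaluated at the grid
    maximum; q-values are the usual step-up transform, monotone in p.
    """
    p = np.asarray(p, dtype=float)
    finite = np.isfinite(p)
    if np.any((p[finite] < 0) | (p[finite] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    pf = p[finite]
    m = pf.size
    if lambdas is None:
        lambdas = np.arange(0.05, 0.96, 0.05)
    pi0_l = np.array([(pf > l).sum() / (m * (1.0 - l)) for l in lambdas])
    if np.all(pi0_l == pi0_l[0]):
        pi0 = pi0_l[0]
    else:
        coef = np.polyfit(lambdas, pi0_l, deg=3)
        pi0 = np.polyval(coef, lambdas.max())
    pi0 = float(np.clip(pi0, 1e-8, 1.0))
    order = np.argsort(pf)
    q_sorted = pi0 * m * pf[order] / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.full(p.size, np.nan)
    q[np.where(finite)[0][order]] = np.clip(q_sorted, 0.0, 1.0)
    return q, pi0


# ---------------------------------------------------------------------
# Consensus + region clustering
# ---------------------------------------------------------------------
def consensus_candidates(
    sites: pd.DataFrame,
    flags: dict[str, np.ndarray],
    min_methods: int = 2,
    gap: int = 50_000,
):
    """SNPs significant in >= min_methods scans, clustered into regions.

    flags maps method name -> boolean array (q < threshold). Returns
    (candidate index array, regions DataFrame with chrom, start, end,
    n_candidates, ordered by n_candidates descending).
    """
    stack = np.vstack([np.asarray(v, bool) for v in flags.values()])
    n_hits = stack.sum(0)
    cand = np.where(n_hits >= min_methods)[0]
    regions = []
    if cand.size:
        sub = sites.iloc[cand]
        for chrom, grp in sub.groupby("chrom"):
            pos = np.sort(grp["pos"].to_numpy())
            start = prev = pos[0]
            count = 1
            for x in pos[1:]:
                if x - prev <= gap:
                    prev = x
                    count += 1
                else:
                    regions.append((chrom, int(start), int(prev), count))
                    start = prev = x
                    count = 1
            regions.append((chrom, int(start), int(prev), count))
    reg = pd.DataFrame(regions,
                       columns=["chrom", "start", "end", "n_candidates"])
    reg = reg.sort_values("n_candidates", ascending=False,
                          ignore_index=True)
    return cand, reg


# ---------------------------------------------------------------------
# Fine-mapping by exhaustive configuration enumeration
# ---------------------------------------------------------------------
@dataclass
class FinemapResult:
    inclusion_posterior: np.ndarray
    config_posterior: dict[tuple, float]
    causal_set: list[int]
    rho_star: float


def finemap_causal(
    z: np.ndarray,
    ld: np.ndarray,
    rho_star: float = 0.99,
    max_causal: int = 2,
    prior: float = 0.01,
    ncp_sd: float = 5.2,
    ridge: float = 1e-4,
    max_configs: int = 200_000,
) -> FinemapResult:
    """Causal-configuration posterior from summary z-scores and LD.

    Under configuration C the z vector is multivariate normal with mean
    zero and covariance R + ncp_sd^2 * R[:, C] R[C, :] (non-centrality
    at causal SNPs propagated through LD); configurations up to size
    max_causal are enumerated exhaustively with an independent per-SNP
    causal prior. The causal set is the smallest SNP set covering
    rho_star of the configuration posterior mass (greedy by coverage).
    """
    z = np.asarray(z, dtype=float)
    m = z.size
    R = np.asarray(ld, dtype=float) + ridge * np.eye(m)
    n_configs = sum(
        int(np.prod([m - i for i in range(k)]) / np.prod(range(1, k + 1)))
        for k in range(0, max_causal + 1))
    if n_configs > max_configs:
        raise ValueError(
            f"{n_configs} configurations exceed the enumeration budget; "
            "pre-filter the locus to fewer SNPs")

    def logpdf(cov):
        sign, logdet = np.linalg.slogdet(cov)
        return -0.5 * (logdet + z @ np.linalg.solve(cov, z)
                       + m * np.log(2 * np.pi))

    log_post = {}
    for k in range(0, max_causal + 1):
        for C in itertools.combinations(range(m), k):
            cov = R.copy()
            if C:
                Rc = R[:, list(C)]
                cov = R + ncp_sd**2 * (Rc @ Rc.T)
            lp = (logpdf(cov) + k * np.log(prior)
                  + (m - k) * np.log(1.0 - prior))
            log_post[C] = lp
    mx = max(log_post.values())
    total = sum(np.exp(v - mx) for v in log_post.values())
    config_post = {c: float(np.exp(v - mx) / total)
                   for c, v in log_post.items()}
    incl = np.zeros(m)
    for c, w in config_post.items():
        for j in c:
            incl[j] += w
    # greedy minimal set covering rho_star of configuration mass
    chosen: list[int] = []
    covered = config_post.get((), 0.0)
    remaining = set(range(m))
    while covered < rho_star and remaining:
        best, best_gain = None, -1.0
        for j in sorted(remaining):
            trial = set(chosen) | {j}
            mass = sum(w for c, w in config_post.items()
                       if set(c) <= trial)
            if mass - covered > best_gain:
                best, best_gain = j, mass - covered
        chosen.append(best)
        remaining.discard(best)
        covered += best_gain
    return FinemapResult(
        inclusion_posterior=incl,
        config_posterior=config_post,
        causal_set=sorted(chosen),
        rho_star=rho_star,
    )
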