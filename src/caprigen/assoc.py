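"""GRM construction, PCA, REML variance components and the mixed-model scan.

The association model for each variant is

    y = 1*mu + x*b + u + e,     u ~ N(0, G * sigma2_g),  e ~ N(0, I * sigma2_e)

with y the pre-adjusted phenotypes, x the 0/1/2 alternate-allele dosages,
b the additive allele-substitution effect and G a VanRaden genomic
relationship matrix computed from array genotypes.  Variance components are
estimated once by profile REML under the null model (no variant effect) and
the resulting covariance V = sigma2_g*G + sigma2_e*I is reused for every
variant: after a single eigendecomposition of G each variant costs one
weighted least-squares regression in the rotated basis.  The Wald statistic
b/se is referred to N(0, 1), two-sided.

Variants below a within-sample MAF floor (default 1%) are excluded; the
multiple-testing line is the average chromosomal Bonferroni threshold
alpha / (n_variants / n_chromosomes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io import MISSING, GenotypeMatrix, logger

__all__ = [
    "GRM",
    "VarianceComponents",
    "compute_grm",
    "pca",
    "reml_fit",
    "mlma_scan",
    "chromosomal_threshold",
    "MixedModelGWAS",
]


@dataclass
class GRM:
    """Symmetric genomic relationship matrix with its sample order."""

    sample_ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.sample_ids), len(self.sample_ids)):
            raise ValueError("GRM shape does not match sample count")
        if not np.allclose(m, m.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")
        self.matrix = m


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    loglik: float

    @property
    def h2(self) -> float:
        return self.sigma2_g / (self.sigma2_g + self.sigma2_e)


def _clean_dosage(g: GenotypeMatrix) -> np.ndarray:
    """Dosages as float with missing calls imputed to the variant mean."""
    d = g.dosage.astype(float)
    miss = g.dosage == MISSING
    if miss.any():
        obs = ~miss
        mean = np.where(obs, d, 0).sum(0) / np.maximum(obs.sum(0), 1)
        d[miss] = np.broadcast_to(mean, d.shape)[miss]
    return d


def compute_grm(g: GenotypeMatrix, maf_min: float = 0.0) -> GRM:
    """VanRaden GRM: G_jk = sum_i (x_ij - 2p_i)(x_ik - 2p_i) / sum_i 2p_i(1-p_i).

    Allele frequencies are taken from the analysed sample; monomorphic
    variants (and those below ``maf_min``) are excluded.  Missing dosages
    are imputed to the variant mean for the GRM only.
    """
    d = _clean_dosage(g)
    p = d.mean(axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    keep = (maf > 0) & (maf >= maf_min)
    if not keep.any():
        raise ValueError("no polymorphic variants for the GRM")
    d = d[:, keep]
    p = p[keep]
    z = d - 2 * p
    denom = (2 * p * (1 - p)).sum()
    return GRM(list(g.sample_ids), (z @ z.T) / denom)


def pca(g: GenotypeMatrix, k: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Principal components of the centered-standardized genotype covariance.

    Returns (coordinates (n, k), explained variance per component).  The sign
    convention is deterministic: the largest-magnitude loading of each
    component is positive.
    """
    n = g.n_samples
    if n < 2:
        raise ValueError("PCA needs at least 2 samples")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples {n}")
    d = _clean_dosage(g)
    p = d.mean(axis=0) / 2.0
    keep = (p > 0) & (p < 1)
    d, p = d[:, keep], p[keep]
    z = (d - 2 * p) / np.sqrt(2 * p * (1 - p))
    z -= z.mean(axis=0)
    cov = z @ z.T / z.shape[1]
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][:k]
    vals, vecs = vals[order], vecs[:, order]
    for j in range(vecs.shape[1]):
        if vecs[np.argmax(np.abs(vecs[:, j])), j] < 0:
            vecs[:, j] = -vecs[:, j]
    coords = vecs * np.sqrt(np.maximum(vals, 0))
    return coords, vals


def reml_fit(y: np.ndarray, grm: GRM, tol: float = 1e-8) -> VarianceComponents:
    """Profile REML for y = 1*mu + u + e, u ~ N(0, G*sigma2_g).

    One eigendecomposition of G reduces the restricted likelihood to a 1-D
    function of the heritability ratio, maximised by bounded scalar
    optimisation; deterministic.  A non-positive-semidefinite G is bent by
    adding a small ridge (logged).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n != len(grm.sample_ids):
        raise ValueError("phenotype length does not match GRM order")
    if np.var(y) == 0:
        raise ValueError("phenotype vector is constant")
    G = grm.matrix
    vals, U = np.linalg.eigh(G)
    if vals.min() < -1e-8:
        ridge = abs(vals.min()) + 1e-6
        logger.warning("bending non-PSD GRM by adding %.2e * I", ridge)
        vals = vals + ridge
    vals = np.maximum(vals, 0.0)
    yr = U.T @ y
    xr = U.T @ np.ones(n)

    def neg_restricted_ll(logit_h2: float) -> float:
        h2 = 1.0 / (1.0 + np.exp(-logit_h2))
        lam = h2 / (1.0 - h2)
        w = lam * vals + 1.0
        xwx = (xr * xr / w).sum()
        mu = (xr * yr / w).sum() / xwx
        rss = ((yr - mu * xr) ** 2 / w).sum()
        s2e = rss / (n - 1)
        ll = -0.5 * (np.log(w).sum() + (n - 1) * np.log(s2e) + np.log(xwx) + (n - 1))
        return -ll

    res = optimize.minimize_scalar(neg_restricted_ll, bounds=(-12.0, 12.0),
                                   method="bounded", options={"xatol": tol})
    h2 = 1.0 / (1.0 + np.exp(-res.x))
    lam = h2 / (1.0 - h2)
    w = lam * vals + 1.0
    xwx = (xr * xr / w).sum()
    mu = (xr * yr / w).sum() / xwx
    s2e = ((yr - mu * xr) ** 2 / w).sum() / (n - 1)
    vc = VarianceComponents(sigma2_g=float(lam * s2e), sigma2_e=float(s2e),
                            loglik=float(-res.fun - 0.5 * (n - 1) * np.log(2 * np.pi)))
    if h2 < 1e-4 or h2 > 1 - 1e-4:
        logger.warning("REML solution at the boundary (h2 = %.4f)", h2)
    return vc


def mlma_scan(
    y: np.ndarray,
    g: GenotypeMatrix,
    grm: GRM,
    vc: VarianceComponents,
    maf_min: float = 0.01,
) -> pd.DataFrame:
    """Per-variant GLS scan under fixed V = sigma2_g*G + sigma2_e*I.

    Returns a DataFrame with chrom, pos, ref, alt, maf, beta, se, p for every
    variant with within-sample MAF >= maf_min.  Variants with zero genotype
    variance after rotation are skipped (logged).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if list(g.sample_ids) != list(grm.sample_ids):
        raise ValueError("genotype and GRM sample orders differ")
    vals, U = np.linalg.eigh(grm.matrix)
    vals = np.maximum(vals, 0.0)
    w = vc.sigma2_g * vals + vc.sigma2_e          # eigenvalues of V
    sw = 1.0 / np.sqrt(w)
    yr = (U.T @ y) * sw
    onr = (U.T @ np.ones(n)) * sw

    d = _clean_dosage(g)
    p_freq = d.mean(axis=0) / 2.0
    maf = np.minimum(p_freq, 1 - p_freq)
    keep = maf >= maf_min
    idx = np.flatnonzero(keep)
    X = (U.T @ d[:, idx]) * sw[:, None]

    # per-variant 2x2 GLS with covariate = rotated intercept
    a11 = (onr * onr).sum()
    a12 = X.T @ onr
    a22 = (X * X).sum(axis=0)
    b1 = (onr * yr).sum()
    b2 = X.T @ yr
    det = a11 * a22 - a12 * a12
    ok = det > 1e-12 * a11 * np.maximum(a22, 1e-300)
    n_skip = int((~ok).sum())
    if n_skip:
        logger.info("mlma_scan: %d variants with no residual genotype variance skipped", n_skip)
    beta = np.where(ok, (a11 * b2 - a12 * b1) / np.where(ok, det, 1.0), np.nan)
    se = np.where(ok, np.sqrt(a11 / np.where(ok, det, 1.0)), np.nan)
    zstat = beta / se
    pval = 2.0 * stats.norm.sf(np.abs(zstat))
    pval = np.minimum(np.maximum(pval, np.finfo(float).tiny), 1.0)

    vt = g.variants.df.iloc[idx]
    out = pd.DataFrame({
        "chrom": vt["chrom"].to_numpy(),
        "pos": vt["pos"].to_numpy(),
        "ref": vt["ref"].to_numpy(),
        "alt": vt["alt"].to_numpy(),
        "maf": maf[idx],
        "beta": beta,
        "se": se,
        "p": pval,
    })
    return out[ok].reset_index(drop=True)


def chromosomal_threshold(n_variants: int, n_chrom: int = 29,
                          alpha: float = 0.05) -> tuple[float, float]:
    """Average chromosomal Bonferroni threshold alpha / (n_variants / n_chrom).

    Returns (p-value threshold, its -log10).  Strictly decreasing in
    ``n_variants``.
    """
    if n_variants <= 0:
        raise ValueError("n_variants must be positive")
    p = alpha / (n_variants / n_chrom)
    return p, float(-np.log10(p))


class MixedModelGWAS:
    """Estimator-style single-trait mixed-model association scan.

    ``fit(genotypes, y, grm_genotypes=None)`` computes the GRM (VanRaden, on
    ``grm_genotypes`` or on the scan genotypes), the null REML variance
    components and the per-variant scan.  Fitted attributes: ``grm_``,
    ``vc_``, ``results_`` (DataFrame), ``threshold_`` (chromosomal
    Bonferroni p-value for the scanned variant count).
    """

    def __init__(self, maf_min: float = 0.01, n_chrom: int = 29, alpha: float = 0.05):
        self.maf_min = maf_min
        self.n_chrom = n_chrom
        self.alpha = alpha

    def get_params(self, deep: bool = True) -> dict:
        return {"maf_min": self.maf_min, "n_chrom": self.n_chrom, "alpha": self.alpha}

    def set_params(self, **params) -> "MixedModelGWAS":
        for k, v in params.items():
            if not hasattr(self, k):
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, genotypes: GenotypeMatrix, y: np.ndarray,
            grm_genotypes: GenotypeMatrix | None = None,
            grm: GRM | None = None) -> "MixedModelGWAS":
        if grm is None:
            grm = compute_grm(grm_genotypes if grm_genotypes is not None else genotypes,
                              maf_min=self.maf_min)
        self.grm_ = grm
        self.vc_ = reml_fit(np.asarray(y, float), grm)
        self.results_ = mlma_scan(y, genotypes, grm, self.vc_, self.maf_min)
        self.threshold_, self.minus_log10_threshold_ = chromosomal_threshold(
            len(self.results_), self.n_chrom, self.alpha)
        return self

    def significant(self) -> pd.DataFrame:
        return self.results_[self.results_["p"] <= self.threshold_]
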