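"""Mixed-model association mapping for module eigenvalues (or any trait).

The model is the standard one-random-effect mixed linear model

    y = X b + u + e,   u ~ N(0, sg2 * K),   e ~ N(0, se2 * I)

with K a marker-based kinship matrix (Loiselle coancestry estimator) and X an
intercept plus population-structure covariates (genotype principal components
by default, or an externally supplied membership matrix).  Variance components
are estimated once on the null model by REML through the spectral
decomposition of K and a one-dimensional search over the variance ratio; the
per-SNP scan then reuses them (the P3D shortcut) and performs a generalized
least squares Wald test per SNP.  SNPs below the minor-allele-frequency floor
(default 5%) are excluded before testing, and raw p-values are FDR-adjusted
(Benjamini-Hochberg) with significance declared at two levels, 0.001 and 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

from .io import GenotypeMatrix

__all__ = [
    "KinshipMatrix",
    "StructureCovariates",
    "VarianceComponents",
    "loiselle_kinship",
    "structure_pcs",
    "fit_null_mlm",
    "scan_snps",
    "bh_adjust",
    "significant_sets",
    "concordance",
    "manhattan_export",
]


@dataclass
class KinshipMatrix:
    """Line x line pairwise relatedness (dimensionless coancestry estimates)."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("kinship must be finite")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("kinship must be symmetric")

    @property
    def line_ids(self) -> list[str]:
        return list(self.values.index)

    def psd(self, floor: float = 1e-8) -> np.ndarray:
        """Eigenvalue-floored positive semi-definite copy (for simulation or
        factorization); the shift, if any, only affects negative eigenvalues."""
        s, U = np.linalg.eigh(self.values.to_numpy(dtype=float))
        return (U * np.maximum(s, floor)) @ U.T


@dataclass
class StructureCovariates:
    """Line x q fixed-effect design for population structure (no intercept)."""

    values: pd.DataFrame

    @property
    def q(self) -> int:
        return self.values.shape[1]

    def design(self) -> np.ndarray:
        """Intercept column prepended; raises if rank-deficient."""
        n = self.values.shape[0]
        X = np.column_stack([np.ones(n), self.values.to_numpy(dtype=float)])
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("structure covariates are rank-deficient with intercept")
        return X


@dataclass
class VarianceComponents:
    """REML estimates of the null mixed model."""

    sigma_g2: float
    sigma_e2: float
    reml_ll: float

    @property
    def h2(self) -> float:
        tot = self.sigma_g2 + self.sigma_e2
        return float(self.sigma_g2 / tot) if tot > 0 else 0.0


def _imputed_dosage(g: GenotypeMatrix) -> np.ndarray:
    """Dosage with per-SNP mean imputation of missing calls."""
    d = g.dosage.to_numpy(dtype=float)
    means = np.nanmean(d, axis=0)
    idx = np.where(np.isnan(d))
    d = d.copy()
    d[idx] = means[idx[1]]
    return d


def loiselle_kinship(g: GenotypeMatrix) -> KinshipMatrix:
    """Marker-based coancestry after Loiselle et al. (1995).

    With within-individual allele frequency ``x_il = dosage/2`` and panel mean
    ``p_l``, the pairwise estimate is

        f_ij = sum_l [ (x_il - p_l)(x_jl - p_l) + p_l(1-p_l)/(n-1) ]
               / sum_l p_l (1 - p_l)

    i.e. cross-products of allele-frequency deviations normalized by the total
    expected heterozygosity term, with the small-sample bias correction.
    Missing dosages are mean-imputed per SNP; monomorphic SNPs contribute
    nothing and an all-monomorphic panel is an error.
    """
    n = g.dosage.shape[0]
    if n < 2:
        raise ValueError("kinship needs at least 2 lines")
    x = _imputed_dosage(g) / 2.0
    p = x.mean(axis=0)
    het = p * (1.0 - p)
    poly = het > 0
    if not poly.any():
        raise ValueError("no polymorphic SNP in the genotype matrix")
    x = x[:, poly]
    p = p[poly]
    het = het[poly]
    c = x - p
    denom = het.sum()
    bias = het.sum() / (n - 1)
    K = (c @ c.T + bias) / denom
    K = (K + K.T) / 2.0
    return KinshipMatrix(pd.DataFrame(K, index=g.line_ids, columns=g.line_ids))


def structure_pcs(g: GenotypeMatrix, q: int) -> StructureCovariates:
    """Top-q principal components of the centered dosage matrix.

    ``q = 0`` yields an empty covariate block (intercept-only design).
    """
    n = g.dosage.shape[0]
    if q < 0:
        raise ValueError("q must be >= 0")
    if q >= n:
        raise ValueError("q must be smaller than the number of lines")
    if q == 0:
        return StructureCovariates(pd.DataFrame(index=g.line_ids))
    d = _imputed_dosage(g)
    d = d - d.mean(axis=0)
    u, s, _ = np.linalg.svd(d, full_matrices=False)
    pcs = u[:, :q] * s[:q]
    cols = [f"PC{i + 1}" for i in range(q)]
    return StructureCovariates(pd.DataFrame(pcs, index=g.line_ids, columns=cols))


def _reml_profile(lam: float, s: np.ndarray, yr: np.ndarray, Xr: np.ndarray):
    """Profiled REML log-likelihood at variance ratio lam = sg2/se2.

    Operates in the eigenbasis of K: s are eigenvalues, yr/Xr the rotated
    response and design.  Returns (ll, sg2, se2, beta).
    """
    n, p = Xr.shape
    d = lam * s + 1.0
    w = 1.0 / d
    XtWX = Xr.T @ (Xr * w[:, None])
    XtWy = Xr.T @ (yr * w)
    beta = np.linalg.solve(XtWX, XtWy)
    r = yr - Xr @ beta
    rss = float(r @ (r * w))
    df = n - p
    se2 = rss / df
    sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    _, logdet_XtX = np.linalg.slogdet(Xr.T @ Xr)
    ll = -0.5 * (df * np.log(2.0 * np.pi * se2) + np.sum(np.log(d))
                 + logdet_XtWX - logdet_XtX + df)
    return ll, lam * se2, se2, beta


def fit_null_mlm(y, cov: StructureCovariates, K: KinshipMatrix,
                 psd_floor: float = 1e-8) -> VarianceComponents:
    """REML variance components of the null model (no SNP term).

    K is eigenvalue-floored to PSD, eigendecomposed once, and the REML
    log-likelihood is maximized over ``log10`` of the variance ratio
    ``sg2/se2`` by a grid pass refined with bounded scalar minimization.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("y must be finite")
    if np.allclose(y, y[0]):
        raise ValueError("y is constant")
    X = cov.design()
    s, U = np.linalg.eigh(K.psd(psd_floor))
    yr = U.T @ y
    Xr = U.T @ X
    grid = np.logspace(-6, 6, 61)
    lls = np.array([_reml_profile(l, s, yr, Xr)[0] for l in grid])
    i = int(np.argmax(lls))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    res = minimize_scalar(
        lambda t: -_reml_profile(10.0**t, s, yr, Xr)[0],
        bounds=(np.log10(lo), np.log10(hi)), method="bounded",
        options={"xatol": 1e-6})
    lam = 10.0**res.x
    ll, sg2, se2, _ = _reml_profile(lam, s, yr, Xr)
    # boundary check: pure-noise fit may prefer sg2 -> 0
    ll0 = _reml_profile(1e-12, s, yr, Xr)[0]
    if ll0 >= ll:
        ll, sg2, se2, _ = _reml_profile(1e-12, s, yr, Xr)
        sg2 = 0.0
    return VarianceComponents(float(sg2), float(se2), float(ll))


def scan_snps(y, g: GenotypeMatrix, cov: StructureCovariates, K: KinshipMatrix,
              maf_min: float = 0.05, vc: VarianceComponents | None = None,
              fdr_alphas: tuple[float, float] = (0.001, 0.05),
              psd_floor: float = 1e-8) -> pd.DataFrame:
    """Per-SNP generalized-least-squares Wald scan with P3D variance components.

    The null-model REML fit supplies (sg2, se2); each SNP is then tested as a
    fixed effect under V = sg2*K + se2*I.  SNPs with minor allele frequency
    below ``maf_min`` are dropped before testing, as are SNPs constant after
    imputation.  SNPs with missing calls are tested on the observed subset of
    lines (pairwise exclusion) against the corresponding submatrix of V.

    Returns the GWAS result table: snp, chrom, pos, maf, effect, p,
    fdr_p, and significance flags at the two declared levels.
    """
    y = np.asarray(y, dtype=float)
    if vc is None:
        vc = fit_null_mlm(y, cov, K)
    X = cov.design()
    n, p = X.shape
    Kp = KinshipMatrix(K.values).psd(psd_floor)
    V = vc.sigma_g2 * Kp + vc.sigma_e2 * np.eye(n)
    s, U = np.linalg.eigh(V)
    w = 1.0 / np.sqrt(np.maximum(s, 1e-12))
    yt = (U.T @ y) * w
    Xt = (U.T @ X) * w[:, None]
    Q, _ = np.linalg.qr(Xt)
    ry = yt - Q @ (Q.T @ yt)

    maf = g.minor_allele_freq()
    keep = maf >= maf_min
    dos = g.dosage.loc[:, keep]
    maf = maf[keep]
    has_missing = dos.isna().any(axis=0)

    snp_ids, effects, pvals = [], [], []
    # fast path: complete SNPs, all rotated at once
    complete = dos.loc[:, ~has_missing]
    if complete.shape[1]:
        Gm = complete.to_numpy(dtype=float)
        nonconst = Gm.std(axis=0) > 0  # all-heterozygous columns have MAF 0.5 but no variance
        Gm = Gm[:, nonconst]
        kept_ids = list(complete.columns[nonconst])
        Gt = (U.T @ Gm) * w[:, None]
        Rg = Gt - Q @ (Q.T @ Gt)
        gg = np.einsum("ij,ij->j", Rg, Rg)
        gy = Rg.T @ ry
        beta = gy / gg
        df = n - p - 1
        rss = float(ry @ ry) - beta**2 * gg
        sigma2 = rss / df
        tstat = beta / np.sqrt(sigma2 / gg)
        pv = 2.0 * stats.t.sf(np.abs(tstat), df)
        snp_ids += kept_ids
        effects += list(beta)
        pvals += list(pv)
    # slow path: SNPs with missing calls, observed-subset GLS
    for sid in dos.columns[has_missing]:
        col = dos[sid].to_numpy(dtype=float)
        obs = ~np.isnan(col)
        gobs = col[obs]
        if gobs.std() == 0 or obs.sum() <= p + 1:
            continue
        Vo = V[np.ix_(obs, obs)]
        so, Uo = np.linalg.eigh(Vo)
        wo = 1.0 / np.sqrt(np.maximum(so, 1e-12))
        Xo = np.column_stack([X[obs], gobs])
        Xot = (Uo.T @ Xo) * wo[:, None]
        yot = (Uo.T @ y[obs]) * wo
        beta_full, rss_arr, _, _ = np.linalg.lstsq(Xot, yot, rcond=None)
        resid = yot - Xot @ beta_full
        rss = float(resid @ resid)
        df = int(obs.sum()) - Xo.shape[1]
        XtX_inv = np.linalg.inv(Xot.T @ Xot)
        se = np.sqrt(rss / df * XtX_inv[-1, -1])
        tstat = beta_full[-1] / se
        snp_ids.append(sid)
        effects.append(float(beta_full[-1]))
        pvals.append(float(2.0 * stats.t.sf(abs(tstat), df)))

    res = pd.DataFrame({
        "snp": snp_ids,
        "effect": effects,
        "p": pvals,
    })
    res["maf"] = maf.reindex(res["snp"]).to_numpy()
    res["chrom"] = g.chrom.reindex(res["snp"]).to_numpy()
    res["pos"] = g.pos.reindex(res["snp"]).to_numpy()
    res["fdr_p"] = bh_adjust(res["p"].to_numpy()) if len(res) else []
    a_lo, a_hi = sorted(fdr_alphas)
    res[f"sig{str(a_lo).replace('0.', '')}"] = res["fdr_p"] < a_lo
    res[f"sig{str(a_hi).replace('0.', '')}"] = res["fdr_p"] < a_hi
    cols = ["snp", "chrom", "pos", "maf", "effect", "p", "fdr_p",
            f"sig{str(a_lo).replace('0.', '')}", f"sig{str(a_hi).replace('0.', '')}"]
    return res[cols].reset_index(drop=True)


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def significant_sets(res: pd.DataFrame,
                     alphas: tuple[float, float] = (0.001, 0.05)) -> dict[float, set]:
    """SNP-id sets passing each FDR level; the stricter set nests in the looser."""
    return {a: set(res.loc[res["fdr_p"] < a, "snp"]) for a in alphas}


def concordance(set_a: set, set_b: set):
    """Overlap accounting between two significant-SNP sets."""
    shared = sorted(set_a & set_b)
    return len(set_a), len(set_b), len(shared), shared


def manhattan_export(res: pd.DataFrame, path=None,
                     alphas: tuple[float, float] = (0.001, 0.05)) -> pd.DataFrame:
    """Per-chromosome position / -log10(p) table for plotting, sorted by
    (chrom, pos); FDR threshold lines recorded as metadata attributes."""
    out = res[["snp", "chrom", "pos"]].copy() if len(res) else pd.DataFrame(
        columns=["snp", "chrom", "pos", "neglog10_p"])
    if len(res):
        out["neglog10_p"] = -np.log10(np.clip(res["p"].to_numpy(), 1e-300, None))
        out = out.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    out.attrs["threshold_lines"] = {a: -np.log10(a) for a in alphas}
    if path is not None:
        with open(path, "w") as fh:
            for a, v in out.attrs["threshold_lines"].items():
                fh.write(f"# fdr_alpha={a}\tneglog10={v:.6f}\n")
            out.to_csv(fh, sep="\t", index=False)
    return out
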