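"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a structured inbred diversity panel profiled by
dual-channel LC-MS: Balding-Nichols genotypes (subpopulation allele
frequencies drawn around ancestral frequencies with an Fst-controlled Beta
spread, inbred dosages in {0, 2}), a factor-model metabolome (each latent
module variable driven by optional SNP effects plus standard-normal noise,
features loading on their module's latent with independent feature noise,
plus uncorrelated background features), a polygenic phenotype built from the
module latents at a target heritability, and paired low/high collision-energy
feature tables carrying isotope clusters and co-varying fragments for the
spectral-reconstruction stage.  Every stage draws from one seed through
spawned child generators, so stage-level outputs are independently
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import FeatureTable, GenotypeMatrix
from .spectra import ISOTOPE_SPACING

__all__ = [
    "QTL",
    "SimConfig",
    "SimTruth",
    "CompoundDef",
    "sim_genotypes",
    "sim_metabolome",
    "sim_phenotype",
    "sim_spectra_fixture",
    "simulate_cohort",
]


@dataclass
class QTL:
    """A causal SNP acting on a module latent or on one single feature."""

    snp_index: int
    effect: float  # per-SD-of-dosage effect on the target
    module: int | None = None
    feature_id: str | None = None


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the profiled panel the pipeline targets: ~200 inbred
    lines in 3 subpopulations at Fst 0.2, 500 genotyped SNPs, 2,000 molecular
    features of which 8 modules (sizes 10-200) are genuinely co-regulated with
    factor loadings 0.7-0.9 and feature noise SD 0.6, module QTLs explaining
    ~10% of their latent's variance, and a polygenic phenotype at h2 0.5.
    """

    seed: int
    n_lines: int = 200
    n_snps: int = 500
    n_subpops: int = 3
    fst: float = 0.2
    het_rate: float = 0.0
    n_features: int = 2000
    module_sizes: tuple[int, ...] = (200, 150, 100, 80, 60, 40, 20, 10)
    loading_range: tuple[float, float] = (0.7, 0.9)
    noise_sd: float = 0.6
    qtls: list[QTL] = field(default_factory=list)
    phenotype_weights: tuple[float, ...] = (1.0, 0.8, 0.6, 0.5)
    h2: float = 0.5

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        if not (0.0 < self.fst < 1.0):
            raise ValueError("Fst must lie in (0, 1)")
        if any(s <= 0 for s in self.module_sizes):
            raise ValueError("module sizes must be positive")
        if sum(self.module_sizes) > self.n_features:
            raise ValueError("module sizes exceed the feature budget")
        lo, hi = self.loading_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("loadings must lie in (0, 1]")

    def rngs(self, n: int):
        """Spawn n independent child generators from the master seed."""
        return [np.random.default_rng(s)
                for s in np.random.SeedSequence(self.seed).spawn(n)]


@dataclass
class SimTruth:
    """Everything the generator knows that the pipeline must rediscover."""

    subpop: pd.Series | None = None
    ancestral_freq: np.ndarray | None = None
    subpop_freq: np.ndarray | None = None
    latents: pd.DataFrame | None = None
    module_membership: pd.Series | None = None
    qtls: list[QTL] = field(default_factory=list)
    h2: float | None = None
    compounds: list["CompoundDef"] = field(default_factory=list)


def sim_genotypes(cfg: SimConfig, rng: np.random.Generator | None = None
                  ) -> tuple[GenotypeMatrix, SimTruth]:
    """Balding-Nichols structured genotypes for an inbred panel.

    Ancestral frequencies ~ Uniform(0.1, 0.9); each subpopulation draws its
    frequency from Beta(p(1-F)/F, (1-p)(1-F)/F); each inbred line draws
    dosage 2 with its subpopulation's frequency (heterozygotes at
    ``het_rate``).  SNP ids are ``S<chrom>_<pos>`` over 10 chromosomes.
    """
    if rng is None:
        rng = cfg.rngs(1)[0]
    p_anc = rng.uniform(0.1, 0.9, size=cfg.n_snps)
    f = cfg.fst
    a = p_anc * (1.0 - f) / f
    b = (1.0 - p_anc) * (1.0 - f) / f
    p_sub = rng.beta(a, b, size=(cfg.n_subpops, cfg.n_snps))
    subpop = np.arange(cfg.n_lines) % cfg.n_subpops
    probs = p_sub[subpop]  # lines x snps
    dosage = 2.0 * (rng.random((cfg.n_lines, cfg.n_snps)) < probs)
    if cfg.het_rate > 0:
        het = rng.random(dosage.shape) < cfg.het_rate
        dosage[het] = 1.0
    chroms = (np.arange(cfg.n_snps) % 10) + 1
    pos = np.zeros(cfg.n_snps, dtype=int)
    for c in range(1, 11):
        idx = np.where(chroms == c)[0]
        pos[idx] = np.sort(rng.integers(10_000, 300_000_000, size=idx.size))
    snp_ids = [f"S{c}_{p}" for c, p in zip(chroms, pos)]
    line_ids = [f"line{i + 1:03d}" for i in range(cfg.n_lines)]
    g = GenotypeMatrix(pd.DataFrame(dosage, index=line_ids, columns=snp_ids))
    truth = SimTruth(subpop=pd.Series(subpop, index=line_ids),
                     ancestral_freq=p_anc, subpop_freq=p_sub, qtls=list(cfg.qtls))
    return g, truth


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def sim_metabolome(g: GenotypeMatrix, cfg: SimConfig,
                   rng: np.random.Generator | None = None,
                   truth: SimTruth | None = None) -> tuple[FeatureTable, SimTruth]:
    """Factor-model metabolome over the genotyped lines.

    Module latent m: sum of its QTL effects on standardized dosage plus
    N(0, 1) noise.  Member feature: loading * latent + noise_sd * N(0, 1).
    Background features are pure noise.  Intensities are an affine transform
    (1000 + 50x, floored at 0) of the latent-scale values, so correlations are
    preserved exactly; m/z is drawn from the 50-1200 acquisition range and RT
    from 0-720 s.
    """
    if rng is None:
        rng = cfg.rngs(2)[1]
    if truth is None:
        truth = SimTruth(qtls=list(cfg.qtls))
    n = g.dosage.shape[0]
    n_mod = len(cfg.module_sizes)
    dos = g.dosage.to_numpy(dtype=float)
    latents = rng.standard_normal((n, n_mod))
    for q in cfg.qtls:
        if q.module is not None:
            latents[:, q.module] += q.effect * _standardize(dos[:, q.snp_index])
    # feature ids: unique "<mz>_<rt>" strings in the acquisition ranges
    ids, mzs, rts = [], [], []
    seen = set()
    while len(ids) < cfg.n_features:
        m = rng.uniform(50.0, 1200.0)
        t = rng.uniform(0.0, 720.0)
        fid = f"{m:.3f}_{t:.2f}"
        if fid in seen:
            continue
        seen.add(fid)
        ids.append(fid)
        mzs.append(round(m, 3))
        rts.append(round(t, 2))
    values = np.empty((n, cfg.n_features))
    membership = np.full(cfg.n_features, -1)
    col = 0
    for m_idx, size in enumerate(cfg.module_sizes):
        lo, hi = cfg.loading_range
        loadings = rng.uniform(lo, hi, size=size)
        noise = rng.standard_normal((n, size)) * cfg.noise_sd
        values[:, col:col + size] = latents[:, [m_idx]] * loadings + noise
        membership[col:col + size] = m_idx
        col += size
    values[:, col:] = rng.standard_normal((n, cfg.n_features - col))
    for q in cfg.qtls:
        if q.feature_id is not None:
            j = ids.index(q.feature_id) if q.feature_id in ids else None
            if j is None:
                raise ValueError(f"feature QTL target {q.feature_id!r} not generated")
            values[:, j] += q.effect * _standardize(dos[:, q.snp_index])
    intensities = np.clip(1000.0 + 50.0 * values, 0.0, None)
    ft = FeatureTable(
        pd.DataFrame(intensities, index=g.line_ids, columns=ids),
        pd.Series(mzs, index=ids), pd.Series(rts, index=ids), channel="MS")
    truth.latents = pd.DataFrame(
        latents, index=g.line_ids,
        columns=[f"module{m + 1}" for m in range(n_mod)])
    truth.module_membership = pd.Series(membership, index=ids)
    return ft, truth


def sim_phenotype(latents: pd.DataFrame, cfg: SimConfig,
                  rng: np.random.Generator | None = None
                  ) -> tuple[pd.DataFrame, float]:
    """Polygenic phenotype: weighted latent sum plus noise scaled to hit the
    target heritability exactly against the realized genetic variance."""
    if rng is None:
        rng = cfg.rngs(3)[2]
    w = np.zeros(latents.shape[1])
    w[:len(cfg.phenotype_weights)] = cfg.phenotype_weights[:latents.shape[1]]
    genetic = latents.to_numpy() @ w
    h2 = cfg.h2
    if h2 >= 1.0:
        y = genetic
    elif h2 <= 0.0:
        y = rng.standard_normal(len(genetic))
    else:
        var_g = genetic.var(ddof=1)
        y = genetic + rng.standard_normal(len(genetic)) * np.sqrt(
            var_g * (1.0 - h2) / h2)
    pheno = pd.DataFrame({"trait": y}, index=latents.index)
    return pheno, float(h2)


@dataclass
class CompoundDef:
    """One simulated compound for the dual-channel spectra fixture."""

    name: str
    precursor_mz: float
    rt: float
    charge: int = 1
    n_isotopes: int = 3
    fragments: tuple[tuple[float, float], ...] = ()  # (mz, relative intensity)
    mean_log_abundance: float = 7.0


def sim_spectra_fixture(compounds: list[CompoundDef], n_samples: int = 20,
                        noise_cv: float = 0.1, n_background: int = 20,
                        seed: int = 0) -> tuple[FeatureTable, FeatureTable, SimTruth]:
    """Paired low/high collision-energy tables for reconstruction tests.

    Each compound contributes an isotope cluster (spacing 1.003355/charge) to
    the low-CE channel and its fragment features to the high-CE channel, all
    within +-0.5 s of the precursor RT and sharing a lognormal per-sample
    abundance (so fragments pass the correlational filter by construction).
    Background features are uncorrelated noise at random RTs.
    """
    rng = np.random.default_rng(seed)
    # one shared abundance profile per compound: the fragments in the high-CE
    # channel must co-vary with their precursor across samples
    abundances = [np.exp(c.mean_log_abundance
                         + 0.5 * rng.standard_normal(n_samples))
                  for c in compounds]

    def _channel(build_high: bool) -> FeatureTable:
        cols, mzs, rts, mat = [], [], [], []
        for ci, c in enumerate(compounds):
            abund = abundances[ci]
            peaks = []
            if not build_high:
                iso_ratio = 0.55
                for k in range(c.n_isotopes):
                    peaks.append((c.precursor_mz + k * ISOTOPE_SPACING / c.charge,
                                  iso_ratio**k))
            else:
                peaks = list(c.fragments)
            for mz, rel in peaks:
                rt = c.rt + rng.uniform(-0.5, 0.5)
                fid = f"{mz:.3f}_{rt:.2f}"
                noise = 1.0 + noise_cv * rng.standard_normal(n_samples)
                cols.append(fid)
                mzs.append(round(mz, 3))
                rts.append(round(rt, 2))
                mat.append(np.clip(abund * rel * noise, 1.0, None))
        for _ in range(n_background):
            mz = rng.uniform(50.0, 1200.0)
            rt = rng.uniform(0.0, 720.0)
            fid = f"{mz:.3f}_{rt:.2f}"
            cols.append(fid)
            mzs.append(round(mz, 3))
            rts.append(round(rt, 2))
            mat.append(np.exp(6.0 + rng.standard_normal(n_samples)))
        index = [f"sample{i + 1:02d}" for i in range(n_samples)]
        if not cols:  # a channel can be legitimately empty (no fragments)
            df = pd.DataFrame(np.empty((n_samples, 0)), index=index)
        else:
            df = pd.DataFrame(np.column_stack(mat), index=index, columns=cols)
        return FeatureTable(df, pd.Series(mzs, index=cols),
                            pd.Series(rts, index=cols),
                            channel="MSE" if build_high else "MS")

    low = _channel(False)
    high = _channel(True)
    return low, high, SimTruth(compounds=list(compounds))


def simulate_cohort(cfg: SimConfig):
    """Full synthetic study: genotypes, metabolome, phenotype, and the truth.

    Returns ``(GenotypeMatrix, FeatureTable, phenotype DataFrame, SimTruth)``.
    """
    rng_g, rng_m, rng_p = cfg.rngs(3)
    g, truth = sim_genotypes(cfg, rng_g)
    ft, truth = sim_metabolome(g, cfg, rng_m, truth)
    pheno, h2 = sim_phenotype(truth.latents, cfg, rng_p)
    truth.h2 = h2
    return g, ft, pheno, truth
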