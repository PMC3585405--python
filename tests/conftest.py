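import numpy as np
import pandas as pd
import pytest

import eigentrait as et


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_feature_table(rng):
    """12 samples x 8 features with parseable ids."""
    ids = [f"{100 + i * 7.5:.3f}_{30 + i * 5.25:.2f}" for i in range(8)]
    vals = rng.uniform(10, 1000, size=(12, 8))
    df = pd.DataFrame(vals, index=[f"s{i:02d}" for i in range(12)], columns=ids)
    return et.FeatureTable.from_frame(df)


@pytest.fixture(scope="session")
def factor_cohort():
    """Full-scale synthetic study: 200 lines, 500 SNPs, 2,000 features in
    8 modules (sizes 10-200), one module QTL, phenotype at h2 = 0.5."""
    cfg = et.SimConfig(seed=11, qtls=[et.QTL(snp_index=5, effect=0.35, module=0)])
    g, ft, pheno, truth = et.simulate_cohort(cfg)
    return cfg, g, ft, pheno, truth


@pytest.fixture(scope="session")
def factor_network(factor_cohort):
    """Autoscaled matrix, unsigned network (beta 6) and detected modules."""
    _, _, ft, _, _ = factor_cohort
    sm = et.autoscale(ft)
    net = et.build_network(sm, 6)
    part = et.detect_modules(net)
    return sm, net, part


@pytest.fixture(scope="session")
def gwas_panel():
    """Structured inbred panel (200 lines, 500 SNPs) with kinship and PCs."""
    cfg = et.SimConfig(seed=55, n_lines=200, n_snps=500)
    g, truth = et.sim_genotypes(cfg)
    K = et.loiselle_kinship(g)
    cov = et.structure_pcs(g, 3)
    return g, truth, K, cov
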