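"""Condense a feature matrix into network modules and module eigenvalues.

Simulates a diversity panel's LC-MS feature table (2,000 features, 8 latent
modules), builds the unsigned weighted correlation network, detects modules,
computes per-line module eigenvalues, and prunes the network at 1, 4 and 6
SD above the mean connectivity.
"""

import eigentrait as et

cfg = et.SimConfig(seed=11, qtls=[et.QTL(snp_index=5, effect=0.35, module=0)])
genotypes, features, phenotype, truth = et.simulate_cohort(cfg)
print(f"cohort: {features.n_samples} lines x {features.n_features} features")

scaled = et.autoscale(features)
network = et.build_network(scaled, beta=6)
partition = et.detect_modules(network, min_module_size=10)
me = et.module_eigenvalues(scaled, partition)

sizes = partition.sizes()
print(f"detected {len(partition.modules)} modules "
      f"({int(sizes.get('grey', 0))} features left unassigned)")
for color in partition.modules[:3]:
    print(f"  {color:10s} {sizes[color]:4d} features, "
          f"eigenvalue explains {me.pve[color]:.0%} of module variance")

pruned = {k: et.prune_at_sd(network, k) for k in (1, 4, 6)}
print(et.network_summary(partition, pruned).to_string(index=False))

# Each eigenvalue row is one derived trait per line; pct_of_detected shows how
# much of the metabolome survives each connectivity threshold.
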