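"""Regress an external phenotype on module eigenvalues by stepwise selection.

The simulated phenotype is a weighted sum of the module latents plus noise;
mixed forward/backward selection on partial-F p-values should retain the
heavily weighted modules, and the partial-SS ANOVA table mirrors a standard
least-squares fit report.
"""

import eigentrait as et

cfg = et.SimConfig(seed=11, qtls=[et.QTL(snp_index=5, effect=0.35, module=0)])
genotypes, features, phenotype, truth = et.simulate_cohort(cfg)

scaled = et.autoscale(features)
partition = et.detect_modules(et.build_network(scaled, beta=6))
me = et.module_eigenvalues(scaled, partition)

model = et.stepwise_select(phenotype["trait"], me.as_traits(),
                           p_enter=0.05, p_leave=0.10)
print(f"selected {len(model.selected)} of {len(partition.modules)} "
      f"eigentraits: {model.selected}")

table = et.partial_anova(model, phenotype["trait"], me.as_traits())
print(table.to_frame().round(4).to_string(index=False))
print(f"adjusted R2 = {table.adj_r2:.3f}, model F = {table.model_f:.4f}")

# Each 1-DF row satisfies t^2 = F and partial SS = F x MSE; the Model row is
# the corrected total, so adj R2 and the model F derive from the Error row.
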