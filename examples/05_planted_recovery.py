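"""Replicated recovery of a planted trait module across synthetic cohorts.

Re-draws gene p-values 10 times over a fixed interactome with one planted
30-gene module (strong signal: Beta(0.05, 1) p-values) and reports how often
the module's sub-network reaches the top 2%, plus the stability contrast:
network percentiles of planted genes vary far less across cohorts than their
single-locus (gene-wise) percentiles.
"""

from netprior import RunConfig, SyntheticSpec, generate_interactome, plant_module, recovery_experiment

spec = SyntheticSpec(n_genes=1000, effect_beta_a=0.05, seed=23)
interactome = generate_interactome(spec)
spec.planted_module = plant_module(interactome, size=30, seed=23)

result = recovery_experiment(spec, RunConfig(), n_replicates=10)
s = result["summary"]
print(f"replicates with planted network in top 2%: {s['recovery_rate']:.0%}")
print(f"median planted-network percentile: {s['median_planted_percentile']:.2f}")
print(f"across-replicate variance of planted genes' percentile ranks:")
print(f"  gene-wise (single locus): {s['mean_var_gene_percentile']:.1f}")
print(f"  network-based:            {s['mean_var_network_percentile']:.1f}")
print("\nNetwork ranking is far more reproducible across cohorts than "
      "single-locus ranking of the same genes.")
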