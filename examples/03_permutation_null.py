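"""Diagnose "small-world" networks with the two permutation nulls.

Networks that reach the top 2% in many runs on permuted GWAS data are hub
artifacts (flag: recurrent); networks that almost never do are trait
specific. The same summary is available for node-label-permuted networks
(mode="networks").
"""

from netprior import SyntheticSpec, generate_gene_pvalues, generate_interactome, null_frequency

spec = SyntheticSpec(n_genes=500, seed=8)
interactome = generate_interactome(spec)
gene_table = generate_gene_pvalues(spec, interactome)  # uniform null p-values

nf = null_frequency(interactome, gene_table, runs=100, mode="gwas", seed=8)
print(nf["flag"].value_counts().to_string())
print(f"\nmean top-2% hit frequency: {nf['frequency'].mean():.4f} "
      "(matches the 0.02 top fraction under the null)")
print(nf.sort_values("frequency", ascending=False).head(3).to_string(index=False))
print("\nNetworks flagged 'recurrent' rank highly even on permuted data — "
      "treat their trait association with skepticism.")
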