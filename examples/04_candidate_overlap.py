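"""Candidate-gene overlap testing and cross-cohort top-network comparison.

First: the exact hypergeometric test — how surprising is it that 16 of 34
known trait candidate genes fall among the 1,232 genes of the top 2% of
sub-networks, when all sub-networks together cover 6,035 genes? Second: the
Venn partition of top network sets across two replicate "cohorts".
"""

from netprior import (
    RunConfig,
    SyntheticSpec,
    compare_rankings,
    generate_gene_pvalues,
    generate_interactome,
    hypergeom_overlap,
    plant_module,
    run_scoring,
)

res = hypergeom_overlap(6035, 34, 1232, 16)
print(f"P(X >= 16) = {res.p_upper:.3g}  (inclusive upper tail)")
res_gt = hypergeom_overlap(6035, 34, 1232, 16, tail="gt")
print(f"P(X > 16)  = {res_gt.p_upper:.3g}  (exclusive tail, as some legacy tools report)")
print("Either way the overlap is far beyond chance: top networks are enriched "
      "for known trait genes.\n")

spec = SyntheticSpec(n_genes=800, effect_beta_a=0.05, seed=19)
interactome = generate_interactome(spec)
spec.planted_module = plant_module(interactome, size=25, seed=19)
tables = {}
for name, seed in [("cohort_a", 1), ("cohort_b", 2)]:
    gene_table = generate_gene_pvalues(spec, interactome, seed=seed)
    tables[name], _ = run_scoring(interactome, gene_table, RunConfig())

partition = compare_rankings(tables, top_fraction=0.02)
for combo, ids in sorted(partition.items(), key=lambda kv: (len(kv[0]), kv[0])):
    print(f"top-2% networks in exactly {'+'.join(combo)}: {len(ids)}")
print("\nNetworks shared by both cohorts replicate; a trait module planted in "
      "the interactome recurs in the shared region.")
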