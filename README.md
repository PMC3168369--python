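# netprior

Network-based prioritization of genome-wide association study (GWAS) results.

Single-locus GWAS rankings are notoriously unstable across cohorts: the same
trait gene can rank near the top in one sample and in the middle of the pack
in the next, because individual effect sizes are small. `netprior` targets the
researchers doing post-GWAS interpretation: it combines gene-level association
p-values with a human protein–protein interaction (PPI) network and ranks
**trait prioritized sub-networks** — groups of interacting genes that are
jointly enriched for association signal — which replicate across cohorts far
better than single-locus ranks do.

## Method

1. **Sub-network construction.** Every protein in the cleaned interactome
   seeds one *two-step network*: all proteins within graph distance 2 of the
   seed, with interaction edges induced. Networks whose node set is contained
   in another's are dropped, then a 20–200-protein size filter is applied.

2. **Connectivity weights.** Within each sub-network, gene *A* receives a
   weight from a PageRank variant in which the damping factor is computed
   per node from the topology instead of being fixed at 0.85:

   d_A = deg(A) / Σ_{g∼A} deg(g),  w(A) = (1 − d_A)/(2N) + d_A · Σ_{H∼A} w(H)/deg(H)

   where N is the sub-network size. The 2N teleport keeps each network's
   total weight inside (0, 1). Hubs with well-connected partners get the
   largest weights.

3. **Signal combination (Liptak–Stouffer).** Gene p-values are standardized
   against the dataset, z_i = (mean_p − p_i)/sd_p, and combined per network as

   Z_comb = Σ w_i z_i / √(Σ w_i²),

   then converted to an upper-tail normal p-value and Bonferroni-corrected by
   (genes in network × number of networks). Networks are ranked by corrected
   p-value; a gene's *network percentile rank* is the percentile of the best
   network containing it.

4. **Null diagnostics.** Two permutation procedures — node-label permutation
   of the interactome and gene-label permutation of the GWAS table — flag
   sub-networks that reach the top ranks regardless of phenotype ("small-world"
   hub artifacts, flag `recurrent`) versus trait-specific ones. An exact
   hypergeometric test quantifies overlap between top-network genes and known
   candidate gene lists.

A synthetic-data module generates scale-free interactomes and gene p-values
with planted trait modules, so the entire pipeline is testable end to end
without any external downloads.

## Worked example

`examples/05_planted_recovery.py` fixes a 1,000-gene scale-free interactome,
plants one 30-gene module whose p-values are drawn from Beta(0.05, 1)
(strongly enriched for small values), re-draws the remaining p-values
uniformly ten times to mimic ten independent cohorts, and runs the full
pipeline on each:

```
replicates with planted network in top 2%: 100%
median planted-network percentile: 0.11
across-replicate variance of planted genes' percentile ranks:
  gene-wise (single locus): 204.3
  network-based:            0.0
```

The planted module's sub-network reaches the top 2% of the ranking in every
replicate cohort (median percentile 0.11, i.e. essentially rank 1), and the
network percentile of each planted gene is far more stable across cohorts
(variance ≈ 0) than its single-locus percentile (variance ≈ 204): the network
ranking replicates where the single-locus ranking does not. The other
example scripts cover building and weighting (`01`), scoring and the rescue
of weak-signal genes (`02`), the permutation nulls (`03`) and the
candidate-overlap test plus cross-cohort comparison (`04`).

A thin CLI mirrors the library stages:

```sh
netprior simulate --n-genes 500 --seed 1 --out-dir sim/
netprior build    --ppi sim/ppi.tsv --out-dir build/
netprior score    --networks build/networks.tsv --weights build/weights.tsv \
                  --genes sim/gene_pvalues.tsv --out-dir scores/
netprior null     --ppi sim/ppi.tsv --genes sim/gene_pvalues.tsv \
                  --mode gwas --runs 100 --seed 1 --out null.tsv
```

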