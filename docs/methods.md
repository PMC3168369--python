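# Methods

## Model and procedure

`netprior` treats genes (via their protein products) as nodes of an undirected
interactome and assumes that (i) genes, not SNPs, are the functional units,
(ii) a gene whose product interacts with many well-connected partners matters
more within its neighbourhood than a peripheral gene, and (iii) association
evidence and interaction structure are complementary: a group of interacting
genes that are jointly enriched for association signal is a better replication
unit than any single locus.

The pipeline has four stages.

**1. Interactome cleaning.** Raw interaction records (BioGRID TAB or a plain
two-column TSV) are reduced to unique undirected edges: symbols are
upper-cased (official symbols are upper case; mixed-case duplicates would
inflate node counts), an optional taxon filter drops records where either
organism label differs from the requested taxon (applied only where organism
columns exist), self-interactions are removed, and duplicate pairs across
orientations and experimental methods collapse to one edge. Duplicate rows in
the gene p-value table are an error rather than silently merged, since no
principled merge rule exists without knowing how the duplicates arose.

**2. Two-step sub-networks.** Each interactome node seeds one sub-network of
all nodes within graph distance 2, with induced edges. Seeding per node rather
than per interaction keeps one network per protein; a network seeded on an
edge is contained in the two-step networks of its endpoints, so no coverage is
lost. Sub-networks whose node set is contained in a retained network's node
set are removed (node sets determine induced edges, so comparing node sets
suffices); equal sets collapse to the lexicographically smallest seed, a
deterministic tie-break. Subset removal runs on the full collection first and
the size filter (20–200 nodes, inclusive) second; one-step neighbourhoods are
too small (median ≈ 3 on real interactomes) and three-step ones far too large
(median ≈ 815), while two-step networks land near a median of ~60 — large
enough to pool signal, small enough to annotate.

**3. Weights: PageRank with dynamic damping.** Within a sub-network of N
nodes, node A's damping factor is d_A = deg(A)/Σ_{g∼A} deg(g) and the weight
vector solves

    w(A) = (1 − d_A)/(2N) + d_A · Σ_{H∼A} w(H)/deg(H).

A fixed damping factor (the web convention, 0.85) ranks nodes of biological
networks inconsistently, so no fixed-damping mode is offered. The teleport
denominator is 2N rather than N so that the total weight per network stays in
(0, 1); weights are consumed as-is, with no renormalization. Undirected graphs
have no dangling nodes, so no node is excluded. The fixed point is found by
synchronous Jacobi iteration from the uniform start 1/(2N), stopping when the
max-norm change drops below `tol` (default 1e-10) or after `max_iter`
(default 1000) sweeps; the systems are small (≤ 200 nodes) and contractive in
practice, typically converging in tens of iterations. For any k-regular graph
d = 1/k and the solution is exactly uniform, w = 1/(2N) — a closed form used
as a test oracle alongside a dense linear solve of (I − D·M)w = (1 − d)/(2N).
An isolated node (possible only in a degenerate single-node network) gets
damping 0 and the pure teleport weight 1/(2N). Two numerical notes: the
2-node graph has both damping factors equal to 1, making the linear system
singular — the iteration still returns the uniform fixed point; and weights
are equivariant under node relabelling up to float summation order (~1e-15),
since the update sums neighbour contributions in label order.

**4. Scoring.** Gene p-values are standardized as z_i = (mean_p − p_i)/sd_p,
using the dataset-wide mean and sample (n−1) SD of the p-values. The sign
convention (small p ⇒ large positive z) pairs with an upper-tail normal
conversion of the combined score; both orientation and SD flavour are
explicit here because neither is universal. Per network,
Z_comb = Σ w_i z_i / √(Σ w_i²) over the genes present in both the network and
the gene table (members absent from the table are dropped and counted, never
imputed; a network with no scored member is excluded and logged). The
Bonferroni correction multiplies the network p-value by the number of scored
genes in that network and the number of scored networks. Ranking is by
corrected p ascending, ties broken by descending Z_comb then network id —
a deterministic total order; percentile = 100·rank/#networks. A gene's
network percentile rank is the percentile of the best-ranked network that
contains it. The gene partition written to the summary file uses a gene-wise
significance cutoff of 0.05.

**SNP-level fallback.** When only SNP association results are available, a
SNP is assigned to every gene whose span ± 50 kb (inclusive bounds) contains
its position, and the gene p-value is the Šidák-style 1 − (1 − min p)^m over
its m SNPs. This ignores linkage disequilibrium entirely and is deliberately
simple; LD-aware gene-based tests should be used instead whenever possible,
and their output fed in directly.

## Null procedures

Node-label permutation applies one uniformly random bijection of labels to
the **global** interactome per run, then rebuilds networks; this preserves
the degree multiset while destroying the label→hub assignment, and
reproduces "same node and edge counts per network" at the collection level.
(Permuting within each pre-built sub-network would instead freeze the
topology around each seed; the global variant matches the intent of
randomizing before topology is interpreted.) Gene-label permutation shuffles
the gene→p assignment, preserving the p multiset and hence mean_p/sd_p
exactly; because it cannot change topology, the implementation reuses the
baseline networks and weights and only re-scores — an exact algebraic
shortcut, not an approximation. Default run counts are 100 network
randomizations and 10,000 GWAS permutations (both configurable; tests and
the acceptance script use reduced counts, noted below). A network is a
top-hit when its percentile ≤ 100·top_fraction (default 0.02, the top 2%);
frequencies > 0.5 are flagged `recurrent`, < 0.05 `trait_specific`. One
master seed spawns per-run child seeds via `numpy.random.SeedSequence`, so
every result is reproducible from a single integer.

## Candidate overlap

The overlap between top-network genes and a candidate list is an exact
hypergeometric upper tail (scipy's implementation; an independent log-space
tail summation serves as the test oracle). Two conventions exist in the
wild: P(X ≥ k), the standard "at least as extreme" tail and the default, and
P(X > k), which some legacy tools report; `tail="gt"` selects the latter. The
enrichment universe convention is the union of genes in all scored networks.

## Synthetic data: what it emulates and what it does not

The generator emulates three things: a scale-free interactome (preferential
attachment, default m = 3, chosen to match the ~6 average degree of cleaned
human interactomes; this yields a median two-step network size of ~60, close
to empirically reported values), uniform-null gene p-values, and a planted
trait module whose p-values are Beta(a, 1) — stochastically small for a < 1,
exactly uniform at a = 1, a one-parameter family standard in p-value
simulation. The planted module is a centre gene plus its direct neighbours
(trimmed/extended to the requested size), the centre chosen so its
neighbourhood matches the module size — aligned by construction with a
buildable sub-network, and avoiding both leaves and the extreme hubs.

Not emulated: linkage disequilibrium and SNP-level structure (signal is
injected at the gene level), publication/ascertainment bias in interaction
coverage, tissue-specific or condition-dependent interactions, and correlated
p-values between neighbouring genes. Passing tests therefore demonstrate the
statistical machinery — calibration under the null, recovery of a module that
genuinely exists in the graph, stability across re-drawn cohorts — not
robustness to the biases of real interactome or GWAS data.

## Problem sizes used in tests and the acceptance script

Null calibration uses a 2,000-gene interactome with 200 GWAS permutations for
the top-2% hit frequency and 30 permutations (~53,000 network scores) for the
uncorrected-p calibration; planted recovery uses 20 replicate cohorts with a
30-gene module at a = 0.05. These scales give Monte-Carlo standard errors
well inside the tolerances asserted. The uncorrected network p-value is
calibrated only approximately (observed ≈ 0.04 at nominal 0.05): standardized
uniform p-values are bounded in [−√3, √3], so the combined score is slightly
platykurtic relative to the normal reference — conservative in the tail, and
the reason calibration is asserted with a ±0.02 band.

## Known limitations

* Gene symbols are taken verbatim (upper-cased); no alias resolution.
* The Bonferroni factor uses the per-network scored-gene count; alternatives
  (e.g. the maximum network size) would be more conservative.
* The SNP→gene fallback ignores LD (above).
* Cohort-scale published behaviour (absolute network counts on a given
  interactome snapshot, specific recurrent-network lists) depends on the
  interaction database version and real GWAS inputs and is out of scope; the
  pipeline instead logs its stage accounting (built / after subset removal /
  after size filter) for every run.
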