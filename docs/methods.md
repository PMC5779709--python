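# Methods

`netmark` infers rooted phylogenetic networks from unlinked bi-allelic
markers (SNPs, AFLP bands).  This note records the model, the algorithms,
the numerical choices, and what the synthetic-data generator does and does
not emulate.

## Model

A phylogenetic network is a rooted binary DAG whose leaves are taxa.
Nodes of in-degree 2 are reticulations (hybridizations); each of the two
incoming edges carries an inheritance probability γ, the pair summing
to 1.  Every branch b has a length τ_b in expected mutations per site and
a population mutation rate θ_b = 4N_b μ; a branch spans 2τ_b/θ_b
coalescent units.  An infinite branch above the root, with its own θ,
guarantees that all lineages eventually coalesce.

Gene genealogies arise from the multispecies network coalescent (MSNC):
sampled lineages coalesce within each branch as a Kingman process at
pairwise rate 2/θ_b (in mutation-time units), and a lineage entering a
reticulation node follows a parent edge with that edge's γ, independently
of other lineages.  Sites evolve on the gene tree under a two-state
mutation model with rate u (red→green) and v (green→red); the root state
is stationary (red with probability v/(u+v)).  The CLI exposes the
stationary green frequency `pi0`, mapped as u = 1/(2·pi0),
v = 1/(2(1−pi0)).

The likelihood of a network for one site is the integral of the site
probability over all gene trees.  Per site it is computed exactly, without
enumerating gene trees.

## Likelihood algorithm

The computation propagates partial-likelihood vectors F(n, r) — the joint
probability of the observed data below a point on a branch and of n
ancestral lineages there, r of them carrying the red allele — towards the
root with the matrix exponential of the coalescent-with-mutation rate
matrix Q over states (n, r): mutation moves r at rates (n−r+1)v and
(r+1)u within a level, coalescence moves (n, r) to (n−1, r) at
(n−1−r)n/θ and to (n−1, r−1) at (r−1)n/θ, and the diagonal is
−n(n−1)/θ − (n−r)v − ru.  Q is not a conservative generator; the deficit
is absorbed by the combinatorial weighting of F.  At the root, F is
contracted against the stationary vector x with Qx = 0 normalized so
x(1,0) + x(1,1) = 1, solved level-by-level in n (each within-level block
is strictly diagonally dominant).

On a network, the lineages entering a reticulation must be bipartitioned
in every possible way between the two parent edges.  Each bipartition of
each (n, r) entry produces a *pair* of vectors — the γ-weighted side
carries F(n_i,r_i)·C(n_i,n_y)·γ^{n_y}(1−γ)^{n_z} and the other side a
bare indicator — tagged with a fresh shared label at that reticulation's
coordinate.  At tree nodes, sets of labeled vectors from the two children
are combined pairwise when their labels are compatible (coordinatewise
equal or zero), convolving F with the hypergeometric interleaving weight
C(r,r_y)C(n−r,n_y−r_y)/C(n,n_y), so that the two halves of every split
recombine exactly once.  Two details are required for exactness and are
validated by the law-of-total-probability test (sum over all patterns
= 1, to 1e−12): the (0,0) "no lineages on this side" entry participates
in splits and merges as a scalar factor, and split combinations with more
reds than lineages are skipped.

Dominant markers (red dominant; heterozygote and red homozygote both show
the band) enter at the leaves with
F(2n_x, r) = n_x!/((r−r_x)!(2r_x−r)!(n_x−r_x)!)·2^{2r_x−r}/C(2n_x, r) for
r_x ≤ r ≤ 2r_x, the pairing-consistent form verified against exhaustive
enumeration of allele placements.

Cost control: site patterns are deduplicated and weighted; per-branch
matrix sizes use the number of lineages subtended by the branch; branch
propagators are cached by (θ, τ, M, u, v) so a proposal that moves one
parameter re-exponentiates only the touched branches; and at *collapse
nodes* all pending labeled vectors are summed into a single unlabeled one.
A node qualifies for collapsing when every reticulation among its
descendants has both parents among those descendants; such nodes are
articulation nodes, and the condition is exactly what makes all labels
below provably dead.  (The looser textbook criterion — any lowest
articulation node — admits networks where a descendant reticulation
escapes sideways, and collapsing there pairs split halves incorrectly;
`find_lowest_articulation_nodes` implements the classical definition for
structural queries, while the engine uses the safe subset.)  Equality of
the likelihood with and without collapsing is tested to 1e−12.

Computations are done in linear space per site, with logs taken per
pattern.  At the problem sizes this package targets (total sampled
lineages M ≲ 14) site likelihoods stay far above double-precision
underflow; no per-vector rescaling is performed.  `dataset_loglik`
accepts a `threads` argument for interface compatibility but evaluates
the deduplicated patterns sequentially in sorted order, so results never
depend on thread count or site order.

When a data set contains only polymorphic sites, the likelihood can be
conditioned on polymorphism by dividing each site likelihood by
1 − Pr[all red] − Pr[all green]; this is flag-gated and defaults to the
marker matrix's own `polymorphic_only` flag.

Missing genotypes ("?") drop the individual from that site's sample; under
the coalescent this equals marginalizing the leaf partial over the
unobserved allele (sampling consistency).

## Prior and sampler

The prior multiplies: a Poisson(ν) factor on the reticulation count k
(left unnormalized over the number of topologies per k, which has no
closed form — this re-weights the k posterior relative to a
topology-count-normalized prior and is the main deliberate deviation); an
Exp(η) density on each reticulation's diameter (the τ-length of the
undirected cycle through it; can be disabled); a divergence-time prior —
default i.i.d. Exp(δ) on every internal-node height, chosen because it
remains proper for hybridization source nodes above the root, with an
exponential-root-height + uniform-given-height alternative
(`time_prior="exp-height"`); Gamma(2, ζ) on every branch θ and on the
root-branch θ (mean 2ζ; the CLI maps `-ptheta` to ζ = ptheta/2); and
Beta(α, β) on each γ (default uniform).  Any structurally invalid
candidate — cycle, wrong degrees, negative branch lengths,
time-inconsistent heights — receives prior 0, which is how illegal
proposals are rejected; proposals never need to be "legal by
construction".

The reversible-jump kernel has seven move types, one drawn per iteration
with fixed probabilities (a draw that is infeasible in the current state
proposes nothing and counts as rejected, keeping the menu constant):

* node-height uniform window; all-heights log-scaler (Jacobian d·log c);
* per-branch θ multiplied by e^{U(−w,w)}; γ reflected uniform window;
* subtree relocation (rooted SPR respecting heights): detach a parent
  edge — a hybrid edge if the moved node is a reticulation, which makes
  this the relocate-reticulation-source move — suppress the vacated node,
  and reattach at a uniformly drawn time-compatible point on a random
  edge or exponentially above the root; the θ freed at the suppressed
  node and the θ drawn at the new split node enter the Hastings ratio;
* add-reticulation: draw a destination edge and a source attachment
  (another edge or above the root), two new node heights, γ from
  Beta(α, β), and three fresh θs from Gamma(2, ζ); delete-reticulation:
  remove one of a reticulation's two incoming edges chosen at random (so
  insert/remove compose to SPRs through reticulations), with the exact
  reverse-insertion density as the Hastings ratio.  Deletions whose
  suppression step would create parallel edges, or whose source node has
  no second child, are rejected; insertions never create such states.

Correctness of the jump bookkeeping is established by prior-only
sampling (likelihood ≡ const): on two taxa with at most one reticulation
and the diameter factor off, the reticulation-count marginal has the
closed form P(k=1)/P(k=0) = ν/3 — two insertion topology classes, each
with height-ordering probability 1/6 under i.i.d. exponential heights —
and the sampled marginal matches it (0.2515 observed vs 0.25, ESS ≈ 2·10⁴)
as well as a chi-square test against an enumeration + Monte-Carlo-ordering
oracle; θ, γ and conditional root-height marginals match their priors by
Kolmogorov–Smirnov, and 3-taxon tree topologies are sampled uniformly.

Metropolis-coupled pre-burn-in runs parallel chains on the posterior
raised to 1/T, attempting an adjacent swap every 10 iterations with the
standard coupled ratio, and returns the highest-likelihood network
visited, which seeds the main chain.

Posterior summaries group sampled networks into topology classes by
leaf-labeled digraph isomorphism, report the class frequencies, the MAP
sample's class, the reticulation-count distribution, parameter means over
samples matching a reference topology, and an initial-positive-sequence
effective sample size for the log posterior.

## Simulator

`simulate_markers` draws gene trees branch-by-branch under the MSNC
(exponential waiting times at rate j(j−1)/θ for j lineages, independent
γ-routing at reticulations, final coalescence on the root branch) and
runs the two-state mutation process down each tree from a stationary root
draw.  Options mirror common data-collection artifacts:

* `polymorphic_only`: a monomorphic site is discarded together with its
  gene tree and both are redrawn (for linked blocks, the site alone is
  redrawn on the block's gene tree);
* `sites_per_genetree`: linked blocks share one gene tree;
* rate variation mimicking invariant-sites + discrete-Gamma: a
  multiplier is 0 with probability i, otherwise one of g
  equal-probability category means of a mean-1 Gamma(a) (category means
  via the regularized incomplete gamma function); drawn per site
  (`markers`) or per gene-tree branch (`lineages` — the per-gene-tree
  reading of "across lineages");
* diploid encoding pairs the two fixed haploid lineages of each
  individual into genotypes 0/1/2, and dominant encoding collapses them
  to band presence.

The generator reproduces the model exactly (it is the engine's
Monte-Carlo cross-check), so passing tests demonstrate internal
consistency and correctness of the mathematics, not robustness to real
AFLP/SNP artifacts such as genotyping error, ascertainment beyond the
polymorphism filter, or linkage beyond the block structure.

## Problem sizes used in the checks

The test suite runs desk-scale versions of the validation experiments:
10,000 simulated sites for the polymorphism fraction and for network
recovery; a 2,300-iteration heated pre-burn-in plus an 8,000-iteration
main chain for the recovery check (the full-scale analysis in the
package's intended use runs 10–100× longer); 60,000 gene trees per
Monte-Carlo oracle case (20 cases, 3-SE comparison); 50 random networks
for the normalization identity; 100 random trees for the species-tree
cross-check; and 4·10⁵ prior-only iterations for kernel validation.

## Known limitations

* Cost grows roughly as O(n^{4k}) in the lineage count n under
  reticulations with k reticulations; the engine is practical for the
  tens-of-lineages, k ≤ 3 regime.
* The unnormalized Poisson prior over k means posterior reticulation
  counts are not directly comparable to a topology-count-normalized
  implementation; with weak data this shifts mass toward higher k.
* Bubbles (parallel edges) are outside the sampled state space.
* No per-site rescaling: extremely large samples (M of many dozens)
  would need the log-scale carry that is deliberately not implemented.
* The likelihood assumes a constant mutation rate across sites and
  lineages; rate variation exists only in the simulator, as a deliberate
  model violation for robustness experiments.
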