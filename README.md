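# netmark

Bayesian inference of rooted phylogenetic networks from unlinked
bi-allelic markers (SNPs, AFLP bands), for groups whose history includes
hybridization as well as incomplete lineage sorting.

Hybridizing lineages are modeled by a rooted DAG: reticulation nodes have
two parent edges carrying inheritance probabilities γ and 1−γ, every
branch has a length τ (expected mutations per site) and a population
mutation rate θ = 4Nμ (a branch spans 2τ/θ coalescent units).  Gene
genealogies follow the multispecies network coalescent; sites evolve under
a two-state mutation model (red→green rate u, green→red rate v) with a
stationary root state.  The likelihood of a network for the markers

L(Ψ | S) = ∏ᵢ ∫ p(Sᵢ | g) p(g | Ψ) dg

is computed **exactly**, integrating the gene trees out with a
labeled-partial-likelihood algorithm: partial likelihoods F(n, r) are
propagated up the network with matrix exponentials of a
coalescent-with-mutation rate matrix, bipartitioned in every possible way
at reticulations, and recombined exactly once via label bookkeeping.
Posterior sampling over networks and their parameters (including the
number of reticulations) uses reversible-jump MCMC with an optional
Metropolis-coupled pre-burn-in; a matching simulator generates bi-allelic
markers on any network, with polymorphic-site filtering, linked blocks,
rate variation, and diploid/dominant (AFLP-style) encoding.

## Worked example

Simulate 1,000 sites on a 5-taxon network with one hybridization (R→Q,
γ = 0.3), then compute the log-likelihood of the true network and sample
the posterior:

```sh
netmark fixtures -kind model_1retic -out fixtures/
netmark simulate -pi0 0.5 -sd 12345678 -num 1000 \
    -tm "<A:A_0; C:C_0;L:L_0;Q:Q_0;R:R_0>" \
    -truenet fixtures/model_1retic.rich_newick -out markers.tsv
# -> wrote 1000 sites to markers.tsv (polymorphic fraction 0.1990)
netmark likelihood -net fixtures/model_1retic.rich_newick \
    -markers markers.tsv -tm "<A:A_0; C:C_0;L:L_0;Q:Q_0;R:R_0>"
# -> log-likelihood  -1576.2216881414
netmark mcmc -sd 1 -markers markers.tsv \
    -tm "<A:A_0; C:C_0;L:L_0;Q:Q_0;R:R_0>" \
    -cl 20000 -bl 4000 -sf 50 -prebl 500 -premc3 "(2.0,4.0)" -premr 1 \
    -mr 2 -pp 1.0 -ee 2.0 -ptheta 0.006 -out run1
# -> collected 320 samples; MAP topology: [0.005505417489]((C:...)#H1:...
```

The polymorphic fraction ≈ 0.2 is the model-implied probability that a
site shows both alleles among the five sampled haploids (the exact value
under these parameters is 0.2091).  The sampled networks in
`run1.trace.tsv` are rich-Newick strings; `run1.summary.json` reports the
topology frequencies, the MAP network, the distribution of the
reticulation count, and an effective sample size — for this run 97.8% of
the 320 samples match the true 1-reticulation topology (the R→Q
hybridization), with posterior mean minor-edge inheritance 0.35 against
the true value 0.3.

The same functionality is available as a library:

```python
import numpy as np
from netmark import (MutationModel, SimConfig, parse_rich_newick,
                     simulate_markers, dataset_loglik)
from netmark.fixtures import MODEL_1RETIC, TAXON_MAP_5

net = parse_rich_newick(MODEL_1RETIC)
markers = simulate_markers(net, TAXON_MAP_5, MutationModel(1, 1),
                           SimConfig(n_sites=1000),
                           np.random.default_rng(12345678))
print(dataset_loglik(net, markers, MutationModel(1, 1)))
```

## Rich Newick

Networks are written in a rich-Newick dialect: per-node fields
`name:length:theta[:gamma]`, reticulation nodes appearing twice under a
shared `#H<i>` tag (γ on each hybrid edge; the pair must sum to 1), and
an optional leading `[theta]` for the infinite branch above the root:

```
[0.006](((((Q:0.004:0.006)I5#H1:0.002:0.005:0.7,A:0.006:0.006)I3:0.016:0.005,
L:0.022:0.006)I2:0.02:0.005,(I5#H1:0.003:0.005:0.3,R:0.007:0.006)I4:0.035:0.005)
I1:0.038:0.005,C:0.08:0.006);
```

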