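# ribopart

Partitioned Bayesian phylogenetics for ribosomal multi-locus data:
**simple indel coding** of gapped alignments, **GTR+Γ / binary-Markov /
mixture** likelihoods, **Metropolis–Hastings** sampling of trees and model
parameters, **Bayes-factor** comparison of partitioning regimes, and
**majority-rule consensus** trees with posterior supports.

## The problem

Multi-locus ribosomal datasets (SSU, ITS1–5.8S–ITS2, LSU) are routinely
concatenated into one supermatrix, but the loci — and regions within them —
evolve under visibly different processes: the spacers are fast, indel-rich
and AT-shifted, the core genes slow and conserved. How finely should such a
matrix be partitioned, and is a site-mixture of several GTR+Γ rate matrices
better still? `ribopart` implements the full evaluation loop for that
question:

1. **Preprocessing** — read FASTA/NEXUS alignments with charset partitions,
   convert per-taxon terminal gap runs to missing data (unsequenced flanks
   are absence of data, not indels), concatenate loci, count
   parsimony-informative sites per partition.
2. **Simple indel coding (SIC)** — every distinct interior gap extent
   becomes a binary presence/absence character: taxa bearing exactly that
   extent score 1, taxa whose gap strictly contains it score `?`
   (inapplicable), everything else 0. The resulting matrix is a partition of
   its own, modeled by a one- or two-parameter binary Markov process with a
   variable-only ascertainment correction (constant characters cannot occur
   in an indel matrix, so the likelihood conditions on variability).
3. **Likelihoods** — Felsenstein pruning over site patterns for GTR+Γ
   (4 discrete gamma categories, mean-of-category rates), the binary models,
   and K-component GTR+Γ site mixtures
   `L(site) = Σ_q w_q L(site | Q_q)` sharing branch lengths and gamma shape.
   All rate matrices are scaled to one expected substitution per site per
   unit branch length, so tree lengths are comparable across models.
4. **MCMC** — a single cold chain over topology (NNI), branch lengths
   (multiplier moves, exponential prior), and the unlinked per-partition
   parameters (Dirichlet moves on the exchangeability/frequency/weight
   simplices, log-multiplier on the gamma shape), with ML starting values.
5. **Model comparison** — mean −lnL and 95% HPD of the likelihood trace,
   harmonic-mean log marginal likelihoods (log-sum-exp stabilized, with
   block-bootstrap SEs), pairwise log Bayes factors (>2 positive, >5 strong),
   likelihood-saturation scans over mixture size K, and AICc screening.
6. **Trees** — Newick I/O, split frequencies, ASDSF convergence checks
   between runs, pooled-run 50% majority-rule consensus phylograms whose
   supports are the Bayesian posterior probabilities of the clades.

A catalog of 15 named partitioning regimes ("2 partitions A" … "6
partitions I") combines three partition layouts (all-nucleotides+indels;
ITS/LSU/SSU+indels; ITS1/5.8S/ITS2/LSU/SSU+indels), two binary indel-model
variants, and mixtures of K = 1…7 GTR+Γ matrices.

Everything is testable without downloads: `ribopart.synthetic_data`
simulates Yule trees, partition-heterogeneous and mixture sequence data,
and a superimposed branch-borne indel process with exact truth records.

## Worked example

```python
import ribopart as rp
from ribopart.inference import PartitionedPhylogeny
from ribopart.mcmc import McmcConfig
from ribopart.models import GtrGamma, PartitionedModel

# simulate a 3-partition heterogeneous dataset with known truth
aln, scheme, pm_true, tree = rp.partitioned_dataset(
    n_taxa=30, n_parts=3, sites_per_part=200, seed=11
)

cfg = McmcConfig(n_generations=3000, sample_interval=10,
                 burn_in_generations=1500, seed=99)

# fit the matched 3-partition regime and the 1-partition alternative
fit3 = PartitionedPhylogeny(
    aln, scheme,
    PartitionedModel(tuple((cs.name, GtrGamma()) for cs, _ in scheme.parts)),
).fit(cfg, initial_tree=tree)

one = rp.PartitionScheme("one", ((rp.CharacterSet("all", ((0, 600),)), "nuc"),))
fit1 = PartitionedPhylogeny(
    aln, one, PartitionedModel((("all", GtrGamma()),))
).fit(cfg, initial_tree=tree)

ml3, se3 = fit3.log_marginal_likelihood()
ml1, se1 = fit1.log_marginal_likelihood()
bf, verdict = rp.log_bayes_factor(ml3, ml1)
print(f"mean -lnL: 3-part {fit3.mean_neg_lnl:.1f}, 1-part {fit1.mean_neg_lnl:.1f}")
print(f"logBF(3-part vs 1-part) = {bf:.1f} ({verdict})")
```

Output from this exact script:

```
mean -lnL: 3-part 7118.2, 1-part 7540.1
logBF(3-part vs 1-part) = 420.8 (strong)
```

The matched partitioning fits the heterogeneous data ~420 log-likelihood
units better, and the Bayes factor flags it as strong evidence — the regime
comparison recovers the simulated structure. `fit3.summary()` tabulates
posterior means, 95% HPDs and ESS per parameter; `fit3.consensus_tree()`
returns the majority-rule phylogram with clade posterior probabilities.

The same pipeline is scriptable from the shell:

```bash
ribopart simulate --taxa 30 --parts 3 --sites 200 --indel-rate 1.0 --seed 1 --out data/
ribopart encode-indels --in data/alignment.nex --out data/indels.nex
ribopart stats --in data/alignment.nex
ribopart consensus --trees run/samples.nwk --out run/consensus.nwk
```

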