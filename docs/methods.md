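# Methods

## Models

**Nucleotide substitution.** Each nucleotide partition evolves under a
general time-reversible (GTR) model: exchangeabilities
(AC, AG, AT, CG, CT, GT) with GT as reference, stationary base frequencies
on the 4-simplex, and gamma-distributed among-site rate variation
discretized into 4 equiprobable categories whose rates are the
conditional means of their quantile bins (mean exactly 1). Four categories
is the field convention; the category count is configurable. A
proportion-of-invariant-sites term is deliberately absent: +I and a
low-shape gamma trade off against each other and are jointly poorly
identified, so rate heterogeneity is carried by Γ alone. Every generator is
rescaled to one expected substitution per site per unit branch length,
which (i) removes the scale redundancy between rates and branch lengths and
(ii) makes posterior tree lengths comparable across partitioning regimes —
the quantity of interest when richer models recover superimposed
substitutions as longer trees.

**Binary (indel) characters.** The indel partition uses a two-state Markov
model, either the symmetric one-parameter variant (stationary frequencies
fixed at ½,½) or the two-parameter variant with free frequencies. Because a
simple-indel-coding matrix cannot contain constant characters, the
likelihood is conditioned on variability: each character's likelihood is
divided by 1 − P(all-0) − P(all-1) evaluated on the same tree (the
"variable-only" ascertainment correction). No gamma rate variation is
applied to the binary partition.

**Site mixtures.** A K-component mixture assigns each site the weighted sum
of likelihoods under K GTR matrices, `L_i = Σ_q w_q L_i(Q_q)`, with the
weights on a K-simplex. Components share one gamma shape and the branch
lengths; exchangeabilities and frequencies are free per component. Sharing
the shape keeps the parameterization identifiable at desk-scale data sizes;
giving each component its own shape is a straightforward extension but
inflates the parameter count with little desk-scale signal.

**Partitioned likelihood.** A partition scheme maps disjoint column sets to
models; the total log-likelihood is the sum of per-partition terms. One
topology and one set of branch lengths are shared by all partitions;
substitution parameters are fully unlinked. No per-partition rate
multipliers are fitted — only statefreq/revmat/shape vary between
partitions — so likelihood differences between regimes reflect the
substitution-model fit, not a relative-rate layer.

## Likelihood engine

Felsenstein pruning runs over unique site patterns (column compression)
with per-pattern rescaling every sixth internal node; gamma categories are
batched through one traversal, and the category average is taken in log
space. IUPAC ambiguity codes, gaps and `?` enter as partial likelihood 1
over their compatible states; an all-missing column contributes exactly 0
to the log-likelihood. Transition matrices come from the symmetrized
eigendecomposition of the reversible generator
(B = D^{1/2} Q D^{-1/2}); the decomposition is verified against
`scipy.linalg.expm` in the test suite, and the full pruning path against
exhaustive enumeration over internal-node states on ≤6-taxon fixtures.
A numba-jitted kernel handles pattern counts up to 512 where loop overhead
dominates; above that the BLAS-backed numpy path wins, and both paths agree
to ~1e-14 (asserted in tests).

## MCMC

A single cold Metropolis–Hastings chain (no Metropolis coupling) samples:

| block | proposal | prior | default weight |
|---|---|---|---|
| branch lengths | multiplier `exp(λ(u−½))`, λ=1.1 | iid Exponential, mean 0.1 | 30 |
| topology | NNI across a random internal edge | uniform on topologies | 15 |
| exchangeabilities | Dirichlet centered on current value | Dirichlet(1) | 10 |
| base frequencies | Dirichlet centered on current value | Dirichlet(1) | 10 |
| gamma shape | log-multiplier, λ=0.8 | Exponential, mean 1 | 10 |
| mixture weights | Dirichlet centered on current value | Dirichlet(1) | 5 |
| any simplex | independence draw from Dirichlet(c·start) | (as above) | 10 |

Dirichlet random-walk proposals mix three concentrations (0.1×, 1×, 10× the
base, default 200) so the chain both traverses during burn-in and resolves
the posterior at equilibrium; the concentration factor is drawn
independently of the state, so each sub-kernel keeps the ordinary Dirichlet
Hastings ratio. The independence kernel draws simplices from a Dirichlet
centered on the chain's starting values with concentration ~2× the
partition's site count — when the start is an ML estimate this tracks the
posterior closely and mixing approaches iid. Chains start from
per-partition ML estimates obtained by L-BFGS-B on log-transformed
parameters (empirical base frequencies as seeds; an explicit
finite-difference step of 1e-4 because the log-likelihood magnitude puts
the default step below float noise). Mixture components start from an
EM-style split: sites ranked by AT content are divided into K quantile
blocks and one GTR+Γ is ML-fitted per block (shapes harmonized to their
geometric mean); identical starting components would leave the mixture
likelihood degenerate at K=1, which the sampler alone escapes only over
very long chains. The branch-length prior mean is a first-class configuration
item because marginal likelihoods — and hence Bayes factors between
regimes — are sensitive to it.

Proposals touching one partition's parameters re-evaluate only that
partition; tree moves re-evaluate all. A fixed seed reproduces every run
bit for bit. Burn-in is a fixed configured generation count, not
auto-detected; convergence is checked by likelihood ESS (Geyer initial
positive sequence, capped at n, constant series flagged) and by the average
standard deviation of split frequencies (ASDSF) between independent runs,
with 0.01 as the conventional "converged" reading. Replicate runs are
pooled for consensus only after the ASDSF check passes.

Known limitations: NNI-only topology moves are adequate at ≤50 taxa but mix
slowly on larger trees (no SPR); a single cold chain can be trapped by
strong multimodality where Metropolis-coupled chains would escape.

## Model comparison

Mean −lnL and the 95% HPD (shortest interval containing ⌈0.95n⌉ sorted
values, left-most tie-break) summarize the fit; the log marginal likelihood
is the harmonic mean of the post-burn-in likelihoods computed via
log-sum-exp, with a moving-block bootstrap SE (block ≈ √n) to respect chain
autocorrelation. The harmonic-mean estimator is upwardly biased and noisy —
the reason the SE is always carried and the reason regime comparisons here
rest on large logBF margins (the >2 positive / >5 strong convention), where
estimator noise is immaterial. The conjugate-normal oracle test quantifies
this calibration in a regime where prior and posterior overlap. Mean −lnL
and the Bayes factors are different functionals of the trace and are never
conflated. The saturation scan reports successive Δ mean lnL over mixture
size K and flags the plateau at the first K whose improvement drops below
10% of the first step. AICc = −2lnL + 2k + 2k(k+1)/(n−k−1) ranks candidate
models for the screening step.

## Synthetic data

The generator is the package's study-conditions definition, not a tuning
surface:

* **Trees.** Yule topologies (uniform random tip splitting) with iid
  exponential branch lengths rescaled to an exact target tree length
  (default TL = 3 on 30 taxa, mean branch ≈ 0.05 substitutions/site).
* **Sequences.** Site-wise CTMC simulation down the tree; mixture
  partitions record the per-site component; partition heterogeneity uses
  five preset GTR+Γ processes differing strongly in exchangeabilities, base
  composition (AT-rich vs GC-rich) and shape, emulating conserved-core vs
  fast-spacer contrasts.
* **Indels.** A superimposed annotation process: per branch, events are
  Poisson(rate × length); each event has a geometric length (mean 4) and a
  uniform start, and is inherited by all descendant leaves. The true extent
  list is recorded exactly. This is deliberately not a TKF-style integrated
  insertion–deletion substitution process: truth bookkeeping stays exact
  and the object under test is the coding step, not an aligner. Real rDNA
  features not emulated: secondary-structure covariation, concerted
  evolution, alignment error. Passing tests therefore validate the
  inference machinery, not the biological realism of any one dataset.

## Study conditions (desk scale)

Chosen once; paper-scale chain lengths (4×10⁶ generations, sample every
1000) remain available as the `paper` preset.

| experiment | conditions |
|---|---|
| regime recovery | 30 taxa, 3 partitions × 200 sites, 10 seeds, 3000 generations, 50% burn-in; success = logBF(matched vs single) > 5 |
| mixture saturation | 16 taxa, 400 sites from a 2-component mixture, K=1..3, 3000 generations |
| parameter recovery | 30 taxa × 2000 sites, GTR+Γ with α=0.5, 20 replicates, 6000 generations, topology fixed to truth; 95% HPD coverage tallied per parameter |
| prior recovery | 6 taxa, no data, 10⁵ generations; moments vs priors in ESS-based z-scores |

Coverage is tallied per parameter (the standard simulation-calibration
convention) because joint coverage of seven simultaneous 95% intervals has
a nominal rate of only ~0.95⁷ ≈ 0.70 even for a perfect sampler.

## Numerical choices and degenerate inputs

* Half-open 0-based column intervals internally; the NEXUS 1-based
  inclusive convention is converted exactly once at the I/O boundary.
* SIC scoring: strict containment → `?`, partial overlap → 0; character
  order sorted by (start, end) for deterministic emission. `?` nucleotide
  cells never open or close a gap run.
* Consensus: strictly-greater-than-threshold split inclusion (50% ties
  excluded), guaranteeing compatibility; supports are exact split
  frequencies; branch lengths average over supporting trees, with the two
  root-child edges of the rooted representation summed as one unrooted
  edge. Split identity uses taxon bitmasks normalized to exclude taxon 0.
* Proposals that would produce invalid states (non-positive rates,
  likelihood failures) are rejected in the acceptance step rather than
  patched; simplex proposals are floored at 1e-6 before renormalization.
* Degenerate inputs error early with the offending taxon/column named:
  ragged alignments, duplicate labels, unknown symbols, empty post-trim
  alignments, out-of-range charsets, zero-likelihood chain starts.
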