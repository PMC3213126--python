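"""Reference experiments: the study designs the package validates itself on.

Each function is a self-contained simulation + inference experiment with
every random choice driven by one base seed, sized to run on a single CPU
desk machine in minutes:

* :func:`regime_recovery` — data simulated under three strongly
  heterogeneous GTR+Gamma partitions; the matched 3-partition regime must
  beat the 1-partition regime by a strong Bayes factor, seed after seed.
* :func:`mixture_saturation` — data simulated under a 2-component mixture;
  the mean-lnL gain from K=1 to K=2 components must dwarf the gain from
  K=2 to K=3 (the saturation signature).
* :func:`parameter_recovery` — GTR+Gamma simulation on a 30-taxon tree;
  posterior 95% HPD intervals for the gamma shape and the exchangeability
  simplex are scored for coverage of the simulating values.
* :func:`prior_recovery` — the sampler run with no data must reproduce its
  own priors (branch lengths, shape, frequency simplex) within Monte-Carlo
  error.

The problem sizes are the package's desk-scale defaults (30 taxa, a few
hundred to 2000 sites, chains of a few thousand generations); paper-scale
chain lengths remain available through :class:`~ribopart.mcmc.McmcConfig`.
"""

from __future__ import annotations

import numpy as np

from .inference import PartitionedPhylogeny
from .mcmc import McmcConfig, effective_sample_size, run_chain
from .model_comparison import hpd_interval, log_marginal_likelihood
from .models import GtrGamma, MixtureSpec, PartitionedModel
from .seqio import CharacterSet, PartitionScheme
from .synthetic_data import evolve_alignment, partitioned_dataset, sample_tree

# proposal mix favouring parameter moves; topology moves are reweighted out
# automatically when the topology is fixed
_PARAM_HEAVY_WEIGHTS = tuple(
    sorted(
        {
            "branch": 15.0,
            "nni": 15.0,
            "exch": 20.0,
            "freqs": 10.0,
            "shape": 15.0,
            "weights": 5.0,
            "indep": 30.0,
        }.items()
    )
)


def _seed(base: int, *offsets: int) -> int:
    out = base
    for o in offsets:
        out = (out * 1_000_003 + o) % (2**31 - 1)
    return out


# ---------------------------------------------------------------------------


def regime_recovery(
    n_seeds: int = 10,
    n_taxa: int = 30,
    n_parts: int = 3,
    sites_per_part: int = 200,
    n_generations: int = 3000,
    base_seed: int = 1,
) -> dict:
    """Matched-partition vs one-partition Bayes factors over replicate seeds.

    For each seed, data are simulated under ``n_parts`` heterogeneous
    GTR+Gamma processes; both regimes are fitted by MCMC from ML starting
    values and compared by harmonic-mean log marginal likelihood.

    Returns logBF values (matched minus single), their strong-evidence wins
    (logBF > 5) and the per-seed detail.
    """
    logbfs = []
    for i in range(n_seeds):
        seed = _seed(base_seed, 17, i)
        aln, scheme, _pm_true, tree = partitioned_dataset(
            n_taxa=n_taxa, n_parts=n_parts, sites_per_part=sites_per_part, seed=seed
        )
        total = n_parts * sites_per_part
        scheme1 = PartitionScheme(
            "single", ((CharacterSet("all", ((0, total),)), "nuc"),)
        )
        cfg = McmcConfig(
            n_generations=n_generations,
            sample_interval=10,
            burn_in_generations=n_generations // 2,
            seed=_seed(seed, 3),
            proposal_weights=_PARAM_HEAVY_WEIGHTS,
        )
        pm_k = PartitionedModel(
            tuple((cs.name, GtrGamma()) for cs, _ in scheme.parts)
        )
        pm_1 = PartitionedModel((("all", GtrGamma()),))
        res_k = PartitionedPhylogeny(aln, scheme, pm_k).fit(cfg, initial_tree=tree)
        res_1 = PartitionedPhylogeny(aln, scheme1, pm_1).fit(cfg, initial_tree=tree)
        ml_k, _ = log_marginal_likelihood(res_k.lnl)
        ml_1, _ = log_marginal_likelihood(res_1.lnl)
        logbfs.append(ml_k - ml_1)
    logbfs = np.asarray(logbfs)
    return {
        "logbf": logbfs.tolist(),
        "wins_strong": int((logbfs > 5).sum()),
        "n_seeds": n_seeds,
        "median_logbf": float(np.median(logbfs)),
    }


def mixture_saturation(
    n_taxa: int = 16,
    n_sites: int = 400,
    n_generations: int = 3000,
    max_k: int = 3,
    base_seed: int = 1,
) -> dict:
    """Mean-lnL saturation over mixture size K on 2-component data.

    The simulating mixture pairs an AT-rich, transition-heavy process with
    a GC-rich, transversion-heavy one at equal weights.  Returns the mean
    post-burn-in lnL per K and the successive improvements.
    """
    comp_a = GtrGamma((2.0, 10.0, 1.0, 1.0, 10.0, 1.0), (0.38, 0.12, 0.12, 0.38), 0.8)
    comp_b = GtrGamma((6.0, 1.0, 4.0, 4.0, 1.0, 1.0), (0.12, 0.38, 0.38, 0.12), 0.8)
    mix_true = MixtureSpec((comp_a, comp_b), (0.5, 0.5))
    tree = sample_tree(n_taxa, seed=_seed(base_seed, 5), target_tree_length=2.5)
    cs = CharacterSet("locus", ((0, n_sites),))
    scheme = PartitionScheme("mix", ((cs, "nuc"),))
    aln, _ = evolve_alignment(
        tree, scheme, PartitionedModel((("locus", mix_true),)), seed=_seed(base_seed, 7)
    )
    means = []
    for k in range(1, max_k + 1):
        if k == 1:
            pm = PartitionedModel((("locus", GtrGamma()),))
        else:
            comps = tuple(GtrGamma() for _ in range(k))
            pm = PartitionedModel(
                (("locus", MixtureSpec(comps, tuple([1.0 / k] * k))),)
            )
        cfg = McmcConfig(
            n_generations=n_generations,
            sample_interval=10,
            burn_in_generations=n_generations // 2,
            seed=_seed(base_seed, 11, k),
            proposal_weights=_PARAM_HEAVY_WEIGHTS,
        )
        res = PartitionedPhylogeny(aln, scheme, pm).fit(cfg, initial_tree=tree)
        means.append(float(res.lnl.mean()))
    deltas = [b - a for a, b in zip(means, means[1:])]
    return {"K": list(range(1, max_k + 1)), "mean_lnl": means, "delta_lnl": deltas}


# ---------------------------------------------------------------------------


RECOVERY_TRUTH = GtrGamma(
    (2.0, 8.0, 1.5, 1.2, 9.0, 1.0), (0.30, 0.20, 0.22, 0.28), 0.5
)

RECOVERY_PARAMS = ("shape", "exch_AC", "exch_AG", "exch_AT", "exch_CG", "exch_CT", "exch_GT")


def parameter_recovery(
    n_replicates: int = 20,
    n_taxa: int = 30,
    n_sites: int = 2000,
    n_generations: int = 6000,
    base_seed: int = 1,
) -> dict:
    """HPD coverage of the simulating gamma shape and exchangeabilities.

    Each replicate simulates a fresh tree and alignment under
    :data:`RECOVERY_TRUTH`, runs a fixed-topology chain from ML starting
    values, and checks whether each parameter's 95% HPD interval covers its
    simulating value.  Coverage is tallied per parameter across replicates.
    """
    ex_true = np.asarray(RECOVERY_TRUTH.exchangeabilities)
    ex_true = ex_true / ex_true.sum()
    truth_by_param = dict(
        zip(RECOVERY_PARAMS, [RECOVERY_TRUTH.shape, *ex_true.tolist()])
    )
    coverage = {p: 0 for p in RECOVERY_PARAMS}
    min_ess = []
    for rep in range(n_replicates):
        tree = sample_tree(
            n_taxa, seed=_seed(base_seed, 23, rep), target_tree_length=3.0
        )
        cs = CharacterSet("all", ((0, n_sites),))
        scheme = PartitionScheme("s", ((cs, "nuc"),))
        aln, _ = evolve_alignment(
            tree,
            scheme,
            PartitionedModel((("all", RECOVERY_TRUTH),)),
            seed=_seed(base_seed, 29, rep),
        )
        cfg = McmcConfig(
            n_generations=n_generations,
            sample_interval=5,
            burn_in_generations=n_generations // 4,
            seed=_seed(base_seed, 31, rep),
            fix_topology=True,
            proposal_weights=_PARAM_HEAVY_WEIGHTS,
            dirichlet_concentration=2000.0,
        )
        res = PartitionedPhylogeny(aln, scheme, PartitionedModel((("all", GtrGamma()),))).fit(
            cfg, initial_tree=tree
        )
        ess = []
        for p in RECOVERY_PARAMS:
            values = res.trace.param_values(f"all.{p}")
            lo, hi = hpd_interval(values)
            if lo <= truth_by_param[p] <= hi:
                coverage[p] += 1
            ess.append(effective_sample_size(values))
        min_ess.append(float(min(ess)))
    return {
        "coverage": coverage,
        "n_replicates": n_replicates,
        "min_coverage": min(coverage.values()),
        "median_min_ess": float(np.median(min_ess)),
    }


# ---------------------------------------------------------------------------


def prior_recovery(
    n_taxa: int = 6,
    n_generations: int = 100_000,
    base_seed: int = 1,
) -> dict:
    """Prior-only sampling check: posterior moments must match the priors.

    With the likelihood absent the chain targets the prior, so the sampled
    branch lengths must average to the exponential prior mean, the gamma
    shape to its exponential prior mean, and each base frequency to 1/4
    (Dirichlet(1)).  Deviations are reported as z-scores against the
    ESS-based Monte-Carlo standard error.
    """
    cfg = McmcConfig(
        n_generations=n_generations,
        sample_interval=10,
        burn_in_generations=n_generations // 10,
        seed=_seed(base_seed, 41),
    )
    pm = PartitionedModel((("all", GtrGamma()),))
    trace = run_chain(None, pm, cfg, taxa=[f"t{i + 1}" for i in range(n_taxa)])
    post = trace.post_burn_in()

    def z(values: np.ndarray, target: float) -> tuple[float, float]:
        ess = effective_sample_size(values)
        se = values.std(ddof=1) / np.sqrt(ess)
        return float(values.mean()), float((values.mean() - target) / se)

    n_edges = int((trace.samples[0].tree.parent >= 0).sum())
    branch = np.array([s.TL / n_edges for s in post])
    shape = trace.param_values("all.shape")
    freq_a = trace.param_values("all.freq_A")
    bm, bz = z(branch, cfg.branch_prior_mean)
    sm, sz = z(shape, cfg.shape_prior_mean)
    fm, fz = z(freq_a, 0.25)
    return {
        "branch_mean": bm,
        "branch_z": bz,
        "branch_prior_mean": cfg.branch_prior_mean,
        "shape_mean": sm,
        "shape_z": sz,
        "freq_mean": fm,
        "freq_z": fz,
    }
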