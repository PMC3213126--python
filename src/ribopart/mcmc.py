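"""Metropolis-Hastings sampling of trees and substitution-model parameters.

A single cold chain samples the joint posterior of topology (NNI moves),
branch lengths (multiplier moves with an exponential prior), and the
unlinked per-partition substitution parameters: exchangeability and base
frequency simplices (Dirichlet-centered proposals, Dirichlet(1) priors),
gamma shape (log-multiplier, exponential prior) and mixture weights.
Partition likelihoods are cached, so a proposal touching one partition's
parameters re-evaluates only that partition; tree moves re-evaluate all.

Passing ``data=None`` (or a dataset with no columns) runs the chain on the
prior alone — the standard validation that the sampler integrates its own
priors correctly.  Everything is driven by one integer seed and is
bit-reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .models import (
    BinaryMarkov,
    GtrGamma,
    MixtureSpec,
    ModelError,
    PartitionedModel,
)
from .trees import Tree, TreeSampleSet, write_newick


class McmcError(RuntimeError):
    pass


DEFAULT_PROPOSAL_WEIGHTS = {
    "branch": 30.0,
    "nni": 15.0,
    "exch": 10.0,
    "freqs": 10.0,
    "shape": 10.0,
    "weights": 5.0,
    "indep": 10.0,
}


@dataclass(frozen=True)
class McmcConfig:
    """Chain design: run length, sampling, proposals and priors.

    branch_prior_mean is the mean of the iid exponential branch-length
    prior; shape_prior_mean that of the exponential prior on the gamma
    shape.  All simplex parameters carry flat Dirichlet(1) priors.
    """

    n_generations: int = 10_000
    sample_interval: int = 10
    burn_in_generations: int = 5_000
    seed: int = 0
    proposal_weights: tuple[tuple[str, float], ...] = tuple(
        sorted(DEFAULT_PROPOSAL_WEIGHTS.items())
    )
    branch_prior_mean: float = 0.1
    shape_prior_mean: float = 1.0
    branch_multiplier_lambda: float = 1.1
    shape_multiplier_lambda: float = 0.8
    dirichlet_concentration: float = 200.0
    fix_topology: bool = False

    def __post_init__(self):
        if not (0 <= self.burn_in_generations < self.n_generations):
            raise ValueError("burn_in must be < n_generations")
        if self.sample_interval < 1 or self.n_generations % self.sample_interval:
            raise ValueError("sample_interval must divide n_generations")

    @property
    def weights_dict(self) -> dict[str, float]:
        return dict(self.proposal_weights)


@dataclass
class McmcSample:
    generation: int
    lnL: float
    tree: Tree
    TL: float
    params: dict[str, float]


@dataclass
class McmcTrace:
    """Ordered chain samples plus the configuration that produced them."""

    samples: list[McmcSample]
    config: McmcConfig
    label: str = "run"
    acceptance: dict[str, tuple[int, int]] | None = None  # move -> (accepted, proposed)

    def __post_init__(self):
        gens = [s.generation for s in self.samples]
        if any(b <= a for a, b in zip(gens, gens[1:])):
            raise McmcError("sample generations must strictly increase")

    def post_burn_in(self) -> list[McmcSample]:
        out = [s for s in self.samples if s.generation > self.config.burn_in_generations]
        if len(out) < 2:
            raise McmcError("need >= 2 post-burn-in samples")
        return out

    def lnl_values(self, post_burn_in: bool = True) -> np.ndarray:
        src = self.post_burn_in() if post_burn_in else self.samples
        return np.array([s.lnL for s in src])

    def tl_values(self, post_burn_in: bool = True) -> np.ndarray:
        src = self.post_burn_in() if post_burn_in else self.samples
        return np.array([s.TL for s in src])

    def param_values(self, name: str, post_burn_in: bool = True) -> np.ndarray:
        src = self.post_burn_in() if post_burn_in else self.samples
        return np.array([s.params[name] for s in src])

    def tree_samples(self, post_burn_in: bool = True) -> TreeSampleSet:
        src = self.post_burn_in() if post_burn_in else self.samples
        return TreeSampleSet(
            [s.tree for s in src], [(self.label, s.generation) for s in src]
        )

    # -- on-disk round trip -------------------------------------------------

    def write_tsv(self, path) -> None:
        keys = sorted(self.samples[0].params) if self.samples else []
        with open(path, "w") as fh:
            fh.write("generation\tlnL\tTL" + "".join(f"\t{k}" for k in keys) + "\n")
            for s in self.samples:
                row = [str(s.generation), f"{s.lnL:.8f}", f"{s.TL:.8f}"]
                row += [f"{s.params[k]:.8g}" for k in keys]
                fh.write("\t".join(row) + "\n")

    def write_trees(self, path) -> None:
        with open(path, "w") as fh:
            for s in self.samples:
                fh.write(write_newick(s.tree, include_supports=False) + "\n")


def read_trace_tsv(path):
    """Load a written parameter trace as a DataFrame (generation, lnL, TL, ...).

    The columns feed straight into the posterior summaries: ``lnL`` into
    :func:`~ribopart.model_comparison.hpd_interval` and
    :func:`~ribopart.model_comparison.log_marginal_likelihood`, ``TL`` into
    tree-length summaries.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    for col in ("generation", "lnL", "TL"):
        if col not in df.columns:
            raise McmcError(f"trace file {path} lacks required column {col!r}")
    return df


# ---------------------------------------------------------------------------
# parameter state <-> model specs


def _init_params(pm: PartitionedModel) -> dict[str, dict]:
    state: dict[str, dict] = {}
    for name, model in pm.assignments:
        if isinstance(model, GtrGamma):
            ex = np.asarray(model.exchangeabilities, float)
            state[name] = {
                "kind": "gtr",
                "exch": ex / ex.sum(),
                "freqs": np.asarray(model.base_freqs, float),
                "shape": float(model.shape),
                "n_categories": model.n_categories,
            }
        elif isinstance(model, MixtureSpec):
            comps = []
            for c in model.components:
                ex = np.asarray(c.exchangeabilities, float)
                comps.append(
                    {"exch": ex / ex.sum(), "freqs": np.asarray(c.base_freqs, float)}
                )
            state[name] = {
                "kind": "mixture",
                "components": comps,
                "weights": np.asarray(model.weights, float),
                "shape": float(model.components[0].shape),
                "n_categories": model.components[0].n_categories,
            }
        elif isinstance(model, BinaryMarkov):
            state[name] = {
                "kind": "binary",
                "variant": model.variant,
                "correction": model.correction,
                "freqs": np.asarray(model.state_freqs, float),
            }
        else:
            raise ModelError(f"unsupported model for partition {name!r}")
    return state


def _build_model(p: dict):
    if p["kind"] == "gtr":
        return GtrGamma(tuple(p["exch"]), tuple(p["freqs"]), p["shape"], p["n_categories"])
    if p["kind"] == "mixture":
        comps = tuple(
            GtrGamma(tuple(c["exch"]), tuple(c["freqs"]), p["shape"], p["n_categories"])
            for c in p["components"]
        )
        return MixtureSpec(comps, tuple(p["weights"]))
    return BinaryMarkov(p["variant"], tuple(p["freqs"]), p["correction"])


def _flatten_params(state: dict[str, dict]) -> dict[str, float]:
    out: dict[str, float] = {}
    for name, p in state.items():
        if p["kind"] == "gtr":
            for lbl, v in zip(("AC", "AG", "AT", "CG", "CT", "GT"), p["exch"]):
                out[f"{name}.exch_{lbl}"] = float(v)
            for lbl, v in zip("ACGT", p["freqs"]):
                out[f"{name}.freq_{lbl}"] = float(v)
            out[f"{name}.shape"] = p["shape"]
        elif p["kind"] == "mixture":
            out[f"{name}.shape"] = p["shape"]
            for k, c in enumerate(p["components"]):
                for lbl, v in zip(("AC", "AG", "AT", "CG", "CT", "GT"), c["exch"]):
                    out[f"{name}.m{k}.exch_{lbl}"] = float(v)
                for lbl, v in zip("ACGT", c["freqs"]):
                    out[f"{name}.m{k}.freq_{lbl}"] = float(v)
            for k, w in enumerate(p["weights"]):
                out[f"{name}.weight_{k}"] = float(w)
        else:
            if p["variant"] == "two_parameter":
                out[f"{name}.freq_0"] = float(p["freqs"][0])
    return out


# ---------------------------------------------------------------------------
# priors and proposals


def _log_prior(tree: Tree, state: dict[str, dict], cfg: McmcConfig) -> float:
    mask = tree.parent >= 0
    lens = tree.length[mask]
    lp = float(-(lens / cfg.branch_prior_mean).sum() - mask.sum() * np.log(cfg.branch_prior_mean))
    for p in state.values():
        if p["kind"] in ("gtr", "mixture"):
            lp += -p["shape"] / cfg.shape_prior_mean - np.log(cfg.shape_prior_mean)
        # Dirichlet(1) simplex priors are constant on the simplex
    return lp


def _dirichlet_logpdf(x: np.ndarray, alpha: np.ndarray) -> float:
    from scipy.special import gammaln

    return float(
        gammaln(alpha.sum()) - gammaln(alpha).sum() + ((alpha - 1) * np.log(x)).sum()
    )


_CONC_SCALES = (0.1, 1.0, 10.0)  # bold / medium / timid proposal mixture


def _propose_dirichlet(rng, x: np.ndarray, conc: float) -> tuple[np.ndarray, float]:
    """Dirichlet proposal centered on x; returns (x', Hastings log-ratio).

    The concentration is scaled by a random factor so the kernel mixes bold
    traversal steps with fine equilibrium steps; the factor is drawn
    independently of the state, so each sub-kernel's Hastings ratio is the
    usual Dirichlet density ratio.
    """
    conc = conc * _CONC_SCALES[rng.integers(len(_CONC_SCALES))]
    eps = 1e-6
    a_fwd = conc * np.maximum(x, eps)
    y = rng.dirichlet(a_fwd)
    y = np.maximum(y, eps)
    y = y / y.sum()
    a_rev = conc * np.maximum(y, eps)
    h = _dirichlet_logpdf(x, a_rev) - _dirichlet_logpdf(y, a_fwd)
    return y, h


def _propose_independent(rng, x: np.ndarray, center: np.ndarray,
                         conc: float) -> tuple[np.ndarray, float]:
    """Independence proposal from Dirichlet(conc * center).

    The center is frozen at the chain's starting values (typically ML
    estimates), making this a valid independence MH kernel whose mixing is
    nearly iid when the proposal tracks the posterior.
    """
    conc = conc * (0.5 if rng.random() < 0.5 else 2.0)
    eps = 1e-4
    alpha = conc * np.maximum(center, eps)
    y = rng.dirichlet(alpha)
    y = np.maximum(y, 1e-8)
    y = y / y.sum()
    h = _dirichlet_logpdf(x, alpha) - _dirichlet_logpdf(y, alpha)
    return y, h


def _nni(tree: Tree, rng) -> bool:
    """In-place nearest-neighbour interchange across a random internal edge."""
    candidates = [
        v
        for v in range(tree.n_taxa, tree.n_nodes)
        if v != tree.root and tree.parent[v] >= 0
    ]
    if not candidates:
        return False
    c = candidates[rng.integers(len(candidates))]
    p = int(tree.parent[c])
    ch = tree.children()
    sibs = [d for d in ch[p] if d != c]
    if not sibs or not ch[c]:
        return False
    d = sibs[rng.integers(len(sibs))]
    x = ch[c][rng.integers(len(ch[c]))]
    tree.parent[x] = p
    tree.parent[d] = c
    tree.invalidate()
    return True


# ---------------------------------------------------------------------------
# the chain


def _random_tree(taxa: list[str], rng, mean_length: float) -> Tree:
    from .synthetic_data import _yule_topology

    tree = _yule_topology(list(taxa), rng)
    mask = tree.parent >= 0
    tree.length[mask] = rng.exponential(mean_length, mask.sum())
    return tree


def run_chain(
    data,
    pm: PartitionedModel,
    cfg: McmcConfig,
    initial_tree: Tree | None = None,
    taxa: list[str] | None = None,
    label: str = "run",
) -> McmcTrace:
    """Sample the posterior (or the prior, when ``data`` is None).

    Parameters
    ----------
    data : dict[str, PartitionLikelihood] or None
        Per-partition likelihood evaluators (see
        :func:`ribopart.models.build_partition_likelihoods`); None means
        prior-only sampling.
    pm : PartitionedModel
        Initial model specifications; partition names must match ``data``.
    initial_tree : Tree, optional
        Starting tree; a random Yule tree over ``taxa`` otherwise.
    """
    rng = np.random.default_rng(cfg.seed)
    part_names = [n for n, _ in pm.assignments]
    if data is not None:
        missing = [n for n in part_names if n not in data]
        if missing:
            raise McmcError(f"no likelihood evaluator for partitions {missing}")
    if initial_tree is not None:
        tree = initial_tree.copy()
    else:
        if taxa is None:
            if data is None:
                raise McmcError("prior-only run needs an explicit taxon list or tree")
            taxa = None
            for ev in data.values():
                taxa = [f"t{i}" for i in range(ev.n_taxa)]
                break
        tree = _random_tree(taxa, rng, cfg.branch_prior_mean)
    state = _init_params(pm)

    def part_lnl(name: str) -> float:
        if data is None:
            return 0.0
        return data[name].loglik(tree, _build_model(state[name]))

    lnls = {n: part_lnl(n) for n in part_names}
    if not all(np.isfinite(v) for v in lnls.values()):
        raise McmcError(
            "zero likelihood at the initial state; try another seed or starting tree"
        )
    log_prior = _log_prior(tree, state, cfg)

    weights = cfg.weights_dict
    moves = []
    wts = []
    has_mixture = any(p["kind"] == "mixture" for p in state.values())
    gtrlike = [n for n in part_names if state[n]["kind"] in ("gtr", "mixture")]
    bin2 = [
        n
        for n in part_names
        if state[n]["kind"] == "binary" and state[n]["variant"] == "two_parameter"
    ]
    # independence-move targets: every simplex in the state, with the chain's
    # starting values frozen as proposal centers
    indep_targets: list[tuple[str, str, int | None]] = []
    indep_centers: dict[tuple, np.ndarray] = {}
    for n in part_names:
        p = state[n]
        if p["kind"] == "gtr":
            for kind2 in ("exch", "freqs"):
                indep_targets.append((n, kind2, None))
                indep_centers[(n, kind2, None)] = p[kind2].copy()
        elif p["kind"] == "mixture":
            for k, c in enumerate(p["components"]):
                for kind2 in ("exch", "freqs"):
                    indep_targets.append((n, kind2, k))
                    indep_centers[(n, kind2, k)] = c[kind2].copy()
            indep_targets.append((n, "weights", None))
            indep_centers[(n, "weights", None)] = p["weights"].copy()
        elif p["variant"] == "two_parameter":
            indep_targets.append((n, "freqs", None))
            indep_centers[(n, "freqs", None)] = p["freqs"].copy()

    for m, w in weights.items():
        if m == "nni" and (cfg.fix_topology or tree.n_taxa < 4):
            continue
        if m in ("exch", "shape") and not gtrlike:
            continue
        if m == "freqs" and not (gtrlike or bin2):
            continue
        if m == "weights" and not has_mixture:
            continue
        if m == "indep" and not indep_targets:
            continue
        moves.append(m)
        wts.append(w)
    wts = np.asarray(wts) / np.sum(wts)

    samples: list[McmcSample] = []
    non_root = np.nonzero(tree.parent >= 0)[0]
    conc = cfg.dirichlet_concentration
    acc_count: dict[str, list[int]] = {m: [0, 0] for m in moves}

    for gen in range(1, cfg.n_generations + 1):
        move = moves[rng.choice(len(moves), p=wts)]
        hastings = 0.0
        affected: list[str] = []
        undo = None

        if move == "branch":
            v = int(non_root[rng.integers(len(non_root))])
            m = float(np.exp(cfg.branch_multiplier_lambda * (rng.random() - 0.5)))
            old = tree.length[v]
            tree.length[v] = old * m
            hastings = np.log(m)
            affected = part_names if data is not None else []
            undo = ("branch", v, old)
        elif move == "nni":
            snapshot = tree.parent.copy()
            if not _nni(tree, rng):
                continue
            affected = part_names if data is not None else []
            undo = ("topology", snapshot)
        elif move == "shape":
            name = gtrlike[rng.integers(len(gtrlike))]
            m = float(np.exp(cfg.shape_multiplier_lambda * (rng.random() - 0.5)))
            old = state[name]["shape"]
            state[name]["shape"] = old * m
            hastings = np.log(m)
            affected = [name] if data is not None else []
            undo = ("shape", name, old)
        elif move == "exch":
            name = gtrlike[rng.integers(len(gtrlike))]
            p = state[name]
            if p["kind"] == "gtr":
                old = p["exch"]
                p["exch"], hastings = _propose_dirichlet(rng, old, conc)
                undo = ("exch", name, None, old)
            else:
                k = int(rng.integers(len(p["components"])))
                old = p["components"][k]["exch"]
                p["components"][k]["exch"], hastings = _propose_dirichlet(rng, old, conc)
                undo = ("exch", name, k, old)
            affected = [name] if data is not None else []
        elif move == "freqs":
            pool = gtrlike + bin2
            name = pool[rng.integers(len(pool))]
            p = state[name]
            if p["kind"] == "gtr" or p["kind"] == "binary":
                old = p["freqs"]
                p["freqs"], hastings = _propose_dirichlet(rng, old, conc)
                undo = ("freqs", name, None, old)
            else:
                k = int(rng.integers(len(p["components"])))
                old = p["components"][k]["freqs"]
                p["components"][k]["freqs"], hastings = _propose_dirichlet(rng, old, conc)
                undo = ("freqs", name, k, old)
            affected = [name] if data is not None else []
        elif move == "weights":
            mixn = [n for n in part_names if state[n]["kind"] == "mixture"]
            name = mixn[rng.integers(len(mixn))]
            old = state[name]["weights"]
            state[name]["weights"], hastings = _propose_dirichlet(rng, old, conc)
            undo = ("weights", name, old)
            affected = [name] if data is not None else []
        elif move == "indep":
            name, kind2, k = indep_targets[rng.integers(len(indep_targets))]
            p = state[name]
            if kind2 == "weights":
                old = p["weights"]
            elif k is None:
                old = p[kind2]
            else:
                old = p["components"][k][kind2]
            conc0 = 2.0 * data[name].n_sites if data is not None else 200.0
            new, hastings = _propose_independent(
                rng, old, indep_centers[(name, kind2, k)], conc0
            )
            if kind2 == "weights":
                state[name]["weights"] = new
                undo = ("weights", name, old)
            elif k is None:
                p[kind2] = new
                undo = (kind2, name, None, old)
            else:
                p["components"][k][kind2] = new
                undo = (kind2, name, k, old)
            affected = [name] if data is not None else []

        new_lnls = dict(lnls)
        try:
            for n in affected:
                new_lnls[n] = part_lnl(n)
            new_prior = _log_prior(tree, state, cfg)
            log_ratio = (
                sum(new_lnls.values()) - sum(lnls.values()) + new_prior - log_prior + hastings
            )
            ok = np.isfinite(log_ratio) and np.log(rng.random()) < log_ratio
        except ModelError:
            ok = False

        acc_count[move][1] += 1
        if ok:
            acc_count[move][0] += 1
            lnls = new_lnls
            log_prior = new_prior
        else:
            kind = undo[0]
            if kind == "branch":
                tree.length[undo[1]] = undo[2]
            elif kind == "topology":
                tree.parent[:] = undo[1]
                tree.invalidate()
            elif kind == "shape":
                state[undo[1]]["shape"] = undo[2]
            elif kind in ("exch", "freqs"):
                _, name, k, old = undo
                key = "exch" if kind == "exch" else "freqs"
                if k is None:
                    state[name][key] = old
                else:
                    state[name]["components"][k][key] = old
            elif kind == "weights":
                state[undo[1]]["weights"] = undo[2]

        if gen % cfg.sample_interval == 0:
            samples.append(
                McmcSample(
                    generation=gen,
                    lnL=float(sum(lnls.values())),
                    tree=tree.copy(),
                    TL=tree.tree_length(),
                    params=_flatten_params(state),
                )
            )
    return McmcTrace(
        samples, cfg, label, {m: (a, p) for m, (a, p) in acc_count.items()}
    )


# ---------------------------------------------------------------------------
# diagnostics


def effective_sample_size(values) -> float:
    """Autocorrelation-time ESS (Geyer initial positive sequence), capped at n.

    A constant series has no information about mixing; it is reported as
    ESS = n with a RuntimeWarning.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 10:
        raise ValueError("need at least 10 values for an ESS estimate")
    if np.ptp(x) == 0:
        warnings.warn("constant series: ESS reported as n", RuntimeWarning)
        return float(n)
    x = x - x.mean()
    acf = np.correlate(x, x, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * x.var())
    tau = 1.0
    k = 1
    while k + 1 < n:
        pair = acf[k] + acf[k + 1]
        if pair < 0:
            break
        tau += 2.0 * pair
        k += 2
    return float(min(n, n / tau))


def split_frequency_divergence(traces: list[McmcTrace]) -> float:
    """Average standard deviation of split frequencies across runs (ASDSF).

    For every split observed in any run, the (population) SD of its
    per-run frequencies is computed; the mean over splits is returned.
    Zero iff all runs have identical split frequency distributions; the
    conventional "converged" reading is a value below 0.01.
    """
    from .trees import split_frequencies

    if len(traces) < 2:
        raise ValueError("need at least two runs to compare split frequencies")
    freq_maps = [split_frequencies(t.tree_samples()) for t in traces]
    taxa0 = set(traces[0].samples[0].tree.taxa)
    for t in traces[1:]:
        if set(t.samples[0].tree.taxa) != taxa0:
            raise ValueError("runs sample trees over different taxa")
    all_splits = sorted(set().union(*freq_maps))
    if not all_splits:
        return 0.0
    mat = np.array([[fm.get(s, 0.0) for fm in freq_maps] for s in all_splits])
    return float(mat.std(axis=1, ddof=0).mean())
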