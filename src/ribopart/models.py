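"""Substitution models and the pruning likelihood engine.

Implements the three model families the partition regimes combine:

* ``GtrGamma`` — general time-reversible nucleotide exchange with discrete
  gamma rate variation (mean-of-category discretization, 4 categories by
  default).  Exchangeabilities are kept as the 6 upper-triangle rates in the
  order AC, AG, AT, CG, CT, GT with GT as the reference rate; the rate matrix
  is always rescaled to one expected substitution per site per unit branch
  length, so tree lengths are comparable across regimes.
* ``BinaryMarkov`` — the two-state Markov model for the indel partition, in a
  symmetric one-parameter variant and a frequency-parameterized two-parameter
  variant, with an optional variable-only ascertainment correction for
  matrices that by construction contain no constant characters.
* ``MixtureSpec`` — a K-component site mixture of GTR+Gamma matrices sharing
  one gamma shape and the branch lengths; the per-site likelihood is the
  weighted sum over components.

All likelihoods run through one Felsenstein pruning routine, vectorized over
site patterns with per-node rescaling, so values stay finite on long trees.
Ambiguity codes, gaps and missing cells enter as partial likelihood 1 over
their compatible states.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.special import gammainc, logsumexp
from scipy.stats import gamma as gamma_dist

from .seqio import AMBIGUITY, DNA_STATES, GAP, MISSING, Alignment, PartitionScheme
from .trees import Tree

EXCH_ORDER = ("AC", "AG", "AT", "CG", "CT", "GT")
_PAIR_INDEX = {(0, 1): 0, (0, 2): 1, (0, 3): 2, (1, 2): 3, (1, 3): 4, (2, 3): 5}


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# model specifications


@dataclass(frozen=True)
class GtrGamma:
    """GTR+Gamma specification.

    exchangeabilities: relative rates (AC, AG, AT, CG, CT, GT); GT is the
    reference and the vector is stored rescaled so GT == 1.
    """

    exchangeabilities: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    base_freqs: tuple[float, ...] = (0.25, 0.25, 0.25, 0.25)
    shape: float = 1.0
    n_categories: int = 4

    def __post_init__(self):
        ex = np.asarray(self.exchangeabilities, dtype=float)
        fr = np.asarray(self.base_freqs, dtype=float)
        if ex.shape != (6,) or (ex <= 0).any() or not np.isfinite(ex).all():
            raise ModelError("need 6 positive finite exchangeabilities")
        if fr.shape != (4,) or (fr <= 0).any() or abs(fr.sum() - 1) > 1e-8:
            raise ModelError("base frequencies must be a positive 4-simplex")
        if not (self.shape > 0 and np.isfinite(self.shape)):
            raise ModelError("gamma shape must be positive and finite")
        if self.n_categories < 1:
            raise ModelError("need at least one rate category")
        object.__setattr__(self, "exchangeabilities", tuple(ex / ex[5]))
        object.__setattr__(self, "base_freqs", tuple(fr / fr.sum()))

    @property
    def n_states(self) -> int:
        return 4

    def rate_matrix(self) -> np.ndarray:
        return gtr_rate_matrix(self.exchangeabilities, self.base_freqs)

    def category_rates(self) -> np.ndarray:
        return discretize_gamma(self.shape, self.n_categories)

    @property
    def n_free_parameters(self) -> int:
        # 5 exchangeabilities + 3 frequencies + shape
        return 9


@dataclass(frozen=True)
class BinaryMarkov:
    """Two-state Markov model for presence/absence (indel) characters."""

    variant: str = "one_parameter"
    state_freqs: tuple[float, float] = (0.5, 0.5)
    correction: str = "variable_only"

    def __post_init__(self):
        if self.variant not in ("one_parameter", "two_parameter"):
            raise ModelError(f"unknown binary variant {self.variant!r}")
        if self.correction not in ("none", "variable_only"):
            raise ModelError(f"unknown correction {self.correction!r}")
        fr = np.asarray(self.state_freqs, dtype=float)
        if fr.shape != (2,) or (fr <= 0).any() or abs(fr.sum() - 1) > 1e-8:
            raise ModelError("state frequencies must be a positive 2-simplex")
        if self.variant == "one_parameter" and abs(fr[0] - fr[1]) > 1e-12:
            raise ModelError("one_parameter variant requires symmetric frequencies")
        object.__setattr__(self, "state_freqs", tuple(fr / fr.sum()))

    @property
    def n_states(self) -> int:
        return 2

    @property
    def base_freqs(self) -> tuple[float, float]:
        return self.state_freqs

    def rate_matrix(self) -> np.ndarray:
        p0, p1 = self.state_freqs
        q = np.array([[-p1, p1], [p0, -p0]])
        return q / (2 * p0 * p1)  # one expected substitution per unit branch

    def category_rates(self) -> np.ndarray:
        return np.ones(1)

    @property
    def n_free_parameters(self) -> int:
        return 0 if self.variant == "one_parameter" else 1


@dataclass(frozen=True)
class MixtureSpec:
    """K GTR+Gamma matrices sharing one gamma shape; per-site weighted sum."""

    components: tuple[GtrGamma, ...]
    weights: tuple[float, ...]

    def __post_init__(self):
        comps = tuple(self.components)
        w = np.asarray(self.weights, dtype=float)
        if len(comps) < 1:
            raise ModelError("mixture needs at least one component")
        if w.shape != (len(comps),) or (w < 0).any() or w.sum() <= 0:
            raise ModelError("weights must be non-negative and not all zero")
        shapes = {(c.shape, c.n_categories) for c in comps}
        if len(shapes) != 1:
            raise ModelError("mixture components must share gamma shape and categories")
        object.__setattr__(self, "components", comps)
        object.__setattr__(self, "weights", tuple(w / w.sum()))

    @property
    def K(self) -> int:
        return len(self.components)

    @property
    def n_states(self) -> int:
        return 4

    @property
    def n_free_parameters(self) -> int:
        return sum(c.n_free_parameters for c in self.components) - (self.K - 1) * 1 + (self.K - 1)


@dataclass(frozen=True)
class PartitionedModel:
    """Per-partition substitution models sharing one topology and branch lengths.

    ``assignments`` maps charset name -> GtrGamma | BinaryMarkov | MixtureSpec.
    Substitution parameters are unlinked between partitions; only the tree
    (topology + branch lengths) is shared.
    """

    assignments: tuple[tuple[str, object], ...]

    def __post_init__(self):
        names = [n for n, _ in self.assignments]
        if len(set(names)) != len(names):
            raise ModelError("duplicate partition assignment")
        object.__setattr__(self, "assignments", tuple(self.assignments))

    def model_for(self, name: str):
        for n, m in self.assignments:
            if n == name:
                return m
        raise ModelError(f"no model assigned to partition {name!r}")

    def replace_model(self, name: str, model) -> "PartitionedModel":
        return PartitionedModel(
            tuple((n, model if n == name else m) for n, m in self.assignments)
        )


# ---------------------------------------------------------------------------
# primitives


def gtr_rate_matrix(exchangeabilities, base_freqs) -> np.ndarray:
    """GTR generator scaled to one expected substitution per unit branch."""
    ex = np.asarray(exchangeabilities, dtype=float)
    pi = np.asarray(base_freqs, dtype=float)
    Q = np.zeros((4, 4))
    for (i, j), k in _PAIR_INDEX.items():
        Q[i, j] = ex[k] * pi[j]
        Q[j, i] = ex[k] * pi[i]
    np.fill_diagonal(Q, -Q.sum(axis=1))
    mu = -(pi * np.diag(Q)).sum()
    return Q / mu


def discretize_gamma(shape: float, n_categories: int) -> np.ndarray:
    """Mean-of-category discrete gamma rates (mean exactly 1).

    Categories are the equiprobable quantile bins of Gamma(shape, mean 1);
    each category rate is the conditional mean within its bin.
    """
    rates = _discretize_gamma_cached(float(shape), int(n_categories))
    return rates.copy()


from functools import lru_cache


@lru_cache(maxsize=4096)
def _discretize_gamma_cached(shape: float, n_categories: int) -> np.ndarray:
    if shape <= 0:
        raise ModelError("gamma shape must be positive")
    n = int(n_categories)
    if n < 1:
        raise ModelError("need at least one category")
    if n == 1:
        return np.ones(1)
    edges = gamma_dist.ppf(np.arange(n + 1) / n, shape, scale=1.0 / shape)
    # E[X; bin] under Gamma(a, 1/a) uses the regularized incomplete gamma at a+1
    upper = gammainc(shape + 1.0, edges[1:] * shape)
    lower = gammainc(shape + 1.0, edges[:-1] * shape)
    rates = n * (upper - lower)
    return rates / rates.mean()


def _eig(Q: np.ndarray, pi: np.ndarray):
    """Reversible-generator eigendecomposition via symmetrization.

    B = D^{1/2} Q D^{-1/2} is symmetric when pi Q satisfies detailed
    balance; then P(t) = D^{-1/2} U exp(w t) U^T D^{1/2}.
    """
    d = np.sqrt(pi)
    B = Q * (d[:, None] / d[None, :])
    w, U = np.linalg.eigh((B + B.T) / 2)
    return w, U / d[:, None], U * d[:, None]  # w; R; L with P = R e^{wt} L^T


_EIG_CACHE: dict[tuple, tuple] = {}


def _cached_eig(model) -> tuple:
    if isinstance(model, GtrGamma):
        key = ("gtr", model.exchangeabilities, model.base_freqs)
    else:
        key = ("bin", model.state_freqs)
    hit = _EIG_CACHE.get(key)
    if hit is None:
        if len(_EIG_CACHE) > 4096:
            _EIG_CACHE.clear()
        pi = np.asarray(model.base_freqs, dtype=float)
        hit = _EIG_CACHE[key] = (_eig(model.rate_matrix(), pi), pi)
    return hit


def transition_matrix(model, branch_length: float, rate_multiplier: float = 1.0) -> np.ndarray:
    """P(t) = exp(Q * t * r) for a reversible model; rows sum to 1."""
    t = branch_length * rate_multiplier
    if not np.isfinite(t) or t < 0:
        raise ModelError(f"invalid scaled branch length {t}")
    (w, R, LT), _pi = _cached_eig(model)
    P = (R * np.exp(np.minimum(w * t, 0.0))[None, :]) @ LT.T
    np.maximum(P, 0.0, out=P)
    return P / P.sum(axis=1, keepdims=True)


def _transition_stack(model, lengths: np.ndarray, rates: np.ndarray) -> np.ndarray:
    """P matrices for every (edge, rate category): shape (n_edges, n_rates, s, s)."""
    (w, R, LT), _pi = _cached_eig(model)
    t = lengths[:, None] * rates[None, :]
    # generator eigenvalues are <= 0 up to round-off; clamp the tiny positive
    # noise that extreme parameter corners can produce
    E = np.exp(np.minimum(w[None, None, :] * t[:, :, None], 0.0))  # (edges, rates, s)
    P = np.einsum("ik,erk,jk->erij", R, E, LT)
    np.maximum(P, 0.0, out=P)
    return P / P.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# tip encoding and pattern compression


def _nuc_partial(symbol: str) -> np.ndarray:
    v = np.zeros(4)
    if symbol in (GAP, MISSING):
        v[:] = 1.0
    elif symbol in DNA_STATES:
        v[DNA_STATES.index(symbol)] = 1.0
    elif symbol in AMBIGUITY:
        for s in AMBIGUITY[symbol]:
            v[DNA_STATES.index(s)] = 1.0
    else:
        raise ModelError(f"cannot encode symbol {symbol!r}")
    return v


def _bin_partial(symbol: str) -> np.ndarray:
    if symbol == "0":
        return np.array([1.0, 0.0])
    if symbol == "1":
        return np.array([0.0, 1.0])
    if symbol == MISSING:
        return np.array([1.0, 1.0])
    raise ModelError(f"cannot encode binary symbol {symbol!r}")


def encode_columns(matrix: np.ndarray, n_states: int) -> np.ndarray:
    """Tip partial likelihoods, shape (n_taxa, n_sites, n_states)."""
    enc = _nuc_partial if n_states == 4 else _bin_partial
    n_taxa, n_sites = matrix.shape
    out = np.empty((n_taxa, n_sites, n_states))
    lut = {}
    for i in range(n_taxa):
        for j in range(n_sites):
            s = matrix[i, j]
            if s not in lut:
                lut[s] = enc(s)
            out[i, j] = lut[s]
    return out


def compress_patterns(tip_partials: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique site patterns with multiplicities; returns (partials, weights, site->pattern)."""
    n_taxa, n_sites, n_states = tip_partials.shape
    flat = tip_partials.transpose(1, 0, 2).reshape(n_sites, -1)
    _, idx, inv, counts = np.unique(
        flat, axis=0, return_index=True, return_inverse=True, return_counts=True
    )
    uniq = tip_partials[:, idx, :]
    return uniq, counts.astype(float), inv


# ---------------------------------------------------------------------------
# pruning

try:  # the jitted kernel is a pure speedup; the numpy path is the reference
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


if _HAVE_NUMBA:

    @_njit(cache=True, fastmath=True)
    def _prune_kernel(order, child_ptr, child_idx, P, partial, logscale,
                      pi, n_taxa, root):
        n_cat, n_pat, s = partial.shape[1], partial.shape[2], partial.shape[3]
        acc = np.empty((n_cat, n_pat, s))
        done = 0
        for oi in range(order.shape[0]):
            v = order[oi]
            first = True
            for ci in range(child_ptr[v], child_ptr[v + 1]):
                c = child_idx[ci]
                for cat in range(n_cat):
                    for p in range(n_pat):
                        for k in range(s):
                            t = 0.0
                            for j in range(s):
                                t += partial[c, cat, p, j] * P[c, cat, k, j]
                            if first:
                                acc[cat, p, k] = t
                            else:
                                acc[cat, p, k] *= t
                first = False
            for p in range(n_pat):
                logscale[v, p] = 0.0
            for ci in range(child_ptr[v], child_ptr[v + 1]):
                c = child_idx[ci]
                for p in range(n_pat):
                    logscale[v, p] += logscale[c, p]
            done += 1
            if done % 6 == 0 or v == root:
                for p in range(n_pat):
                    m = 0.0
                    for cat in range(n_cat):
                        for k in range(s):
                            if acc[cat, p, k] > m:
                                m = acc[cat, p, k]
                    if m <= 0.0:
                        m = 1.0
                    inv = 1.0 / m
                    for cat in range(n_cat):
                        for k in range(s):
                            acc[cat, p, k] *= inv
                    logscale[v, p] += np.log(m)
            for cat in range(n_cat):
                for p in range(n_pat):
                    for k in range(s):
                        partial[v, cat, p, k] = acc[cat, p, k]
        out = np.empty(n_pat)
        for p in range(n_pat):
            tot = 0.0
            for cat in range(n_cat):
                lik = 0.0
                for k in range(s):
                    lik += partial[root, cat, p, k] * pi[k]
                tot += lik
            out[p] = np.log(tot / n_cat) + logscale[root, p]
        return out


def _tree_csr(tree: Tree) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Internal postorder + CSR children arrays for the jitted kernel (cached)."""
    if tree._csr is None:
        ch = tree.children()
        order = np.array(
            [v for v in tree.postorder() if v >= tree.n_taxa], dtype=np.int64
        )
        ptr = np.zeros(tree.n_nodes + 1, dtype=np.int64)
        idx = []
        for v in range(tree.n_nodes):
            ptr[v + 1] = ptr[v] + len(ch[v])
            idx.extend(ch[v])
        tree._csr = (order, ptr, np.array(idx, dtype=np.int64))
    return tree._csr


def _prune(tree: Tree, tip_partials: np.ndarray, P: np.ndarray, base_freqs,
           workspace: tuple | None = None) -> np.ndarray:
    """Per-pattern log-likelihood, rate categories batched through one pass.

    P has shape (n_nodes, n_cat, s, s), indexed by the child node of each
    edge; the per-pattern scale factors are shared across categories so the
    final category average can be taken in log space.  ``workspace`` is an
    optional (partial, logscale) buffer pair with leaf rows pre-filled.
    """
    n_taxa, n_pat, s = tip_partials.shape
    n_cat = P.shape[1]
    order = tree.postorder()
    children = tree.children()
    if workspace is not None:
        partial, logscale = workspace
    else:
        partial = np.empty((tree.n_nodes, n_cat, n_pat, s))
        logscale = np.zeros((tree.n_nodes, n_pat))
        partial[:n_taxa] = tip_partials[:, None, :, :]
    PT = np.swapaxes(P, -1, -2)
    # rescaling every node is wasted work at desk scale; every 6th level of
    # accumulated product keeps values far from underflow either way
    done = 0
    for v in order:
        if v < n_taxa:
            continue
        acc = None
        sc = None
        for c in children[v]:
            term = partial[c] @ PT[c]  # (cat, pat, s)
            acc = term if acc is None else acc * term
            sc = logscale[c] if sc is None else sc + logscale[c]
        done += 1
        if done % 6 == 0 or v == tree.root:
            m = acc.max(axis=(0, 2))
            m[m == 0] = 1.0
            acc = acc / m[None, :, None]
            sc = sc + np.log(m)
        partial[v] = acc
        logscale[v] = sc
    root = tree.root
    pi = np.asarray(base_freqs, dtype=float)
    lik = partial[root] @ pi  # (cat, pat)
    with np.errstate(divide="ignore"):
        lm = np.log(lik)
        mx = lm.max(axis=0)
        safe = np.where(np.isfinite(mx), mx, 0.0)
        avg = safe + np.log(np.exp(lm - safe[None, :]).mean(axis=0))
    return avg + logscale[root]


def _per_pattern_loglik(tree: Tree, tip_partials: np.ndarray, model,
                        workspace: tuple | None = None) -> np.ndarray:
    """Log-likelihood per pattern, averaged over gamma rate categories."""
    rates = model.category_rates()
    lengths = np.where(np.isnan(tree.length), 0.0, tree.length)
    P = _transition_stack(model, lengths, rates)  # (nodes, rates, s, s)
    return _prune(tree, tip_partials, P, model.base_freqs, workspace)


def pruning_loglik(tree: Tree, columns: np.ndarray, model) -> np.ndarray:
    """Per-site log-likelihoods for a character matrix under one model.

    ``columns`` is the (n_taxa, n_sites) symbol matrix in the tree's taxon
    order.  Ambiguity and missing symbols contribute partial likelihood 1
    over their compatible states; an all-missing column has lnL exactly 0.
    """
    columns = np.asarray(columns, dtype="U1")
    if columns.shape[0] != tree.n_taxa:
        raise ModelError(
            f"matrix has {columns.shape[0]} rows but tree has {tree.n_taxa} leaves"
        )
    tips = encode_columns(columns, model.n_states)
    uniq, _w, inv = compress_patterns(tips)
    if isinstance(model, MixtureSpec):
        per_pat = _mixture_per_pattern(tree, uniq, model)
    else:
        per_pat = _per_pattern_loglik(tree, uniq, model)
    return per_pat[inv]


def _mixture_per_pattern(tree: Tree, tip_partials: np.ndarray, mix: MixtureSpec) -> np.ndarray:
    logw = np.log(np.asarray(mix.weights))
    keep = np.isfinite(logw)
    if not keep.any():
        raise ModelError("all mixture weights are zero")
    comp = np.stack(
        [
            _per_pattern_loglik(tree, tip_partials, c)
            for c, k in zip(mix.components, keep)
            if k
        ]
    )
    return logsumexp(comp + logw[keep][:, None], axis=0)


def mixture_loglik(tree: Tree, columns: np.ndarray, mix: MixtureSpec) -> np.ndarray:
    """Per-site log Sum_q w_q L(site | component q); components share the tree."""
    return pruning_loglik(tree, columns, mix)


def ascertainment_corrected_loglik(tree: Tree, binary_matrix, model: BinaryMarkov) -> float:
    """Total lnL of a binary matrix conditioned on characters being variable.

    Each character's lnL is divided by (1 - P(constant)) where P(constant)
    is the probability of the all-0 plus the all-1 pattern on the tree; this
    is the variable-only ascertainment correction needed when constant
    characters are structurally absent (as in an indel matrix).
    """
    if model.correction != "variable_only":
        raise ModelError("model must request the variable_only correction")
    cells = binary_matrix.cells if hasattr(binary_matrix, "cells") else np.asarray(binary_matrix, dtype="U1")
    n_chars = cells.shape[1]
    per_site = pruning_loglik(tree, cells, replace(model, correction="none"))
    const = np.array(
        [["0"] * tree.n_taxa, ["1"] * tree.n_taxa], dtype="U1"
    ).T  # (n_taxa, 2)
    ln_const = pruning_loglik(tree, const, replace(model, correction="none"))
    p_const = float(np.exp(ln_const).sum())
    if p_const >= 1.0 - 1e-12:
        raise ModelError("P(constant) >= 1: tree has no substitution opportunity")
    return float(per_site.sum() - n_chars * np.log1p(-p_const))


# ---------------------------------------------------------------------------
# partitioned likelihood


class PartitionLikelihood:
    """Pattern-compressed likelihood evaluator for one partition.

    Built once per dataset; ``loglik(tree, model)`` is then cheap to call
    repeatedly inside MCMC.
    """

    def __init__(self, name: str, matrix: np.ndarray, n_states: int,
                 ascertainment: bool = False):
        self.name = name
        self.n_states = n_states
        self.ascertainment = ascertainment
        self.n_sites = matrix.shape[1]
        self.matrix = np.asarray(matrix, dtype="U1")
        tips = encode_columns(self.matrix, n_states)
        self.patterns, self.weights, self._inv = compress_patterns(tips)
        self.n_taxa = matrix.shape[0]
        self._workspace: dict[tuple, tuple] = {}

    def _buffers(self, n_nodes: int, n_cat: int):
        """Persistent pruning buffers; leaf rows are filled once."""
        key = (n_nodes, n_cat)
        ws = self._workspace.get(key)
        if ws is None:
            n_pat = self.patterns.shape[1]
            partial = np.empty((n_nodes, n_cat, n_pat, self.n_states))
            partial[: self.n_taxa] = self.patterns[:, None, :, :]
            logscale = np.zeros((n_nodes, n_pat))
            ws = self._workspace[key] = (partial, logscale)
        return ws

    # above ~512 patterns the BLAS-backed numpy path wins on memory traffic
    _KERNEL_MAX_PATTERNS = 512

    def _per_pattern(self, tree: Tree, model) -> np.ndarray:
        ncat = model.n_categories if isinstance(model, GtrGamma) else 1
        ws = self._buffers(tree.n_nodes, ncat)
        if _HAVE_NUMBA and self.patterns.shape[1] <= self._KERNEL_MAX_PATTERNS:
            rates = model.category_rates()
            lengths = np.where(np.isnan(tree.length), 0.0, tree.length)
            P = _transition_stack(model, lengths, rates)
            order, ptr, idx = _tree_csr(tree)
            partial, logscale = ws
            return _prune_kernel(
                order, ptr, idx, P, partial, logscale,
                np.asarray(model.base_freqs, dtype=float), self.n_taxa, tree.root,
            )
        return _per_pattern_loglik(tree, self.patterns, model, ws)

    def loglik(self, tree: Tree, model) -> float:
        if isinstance(model, MixtureSpec):
            logw = np.log(np.asarray(model.weights))
            keep = np.isfinite(logw)
            if not keep.any():
                raise ModelError("all mixture weights are zero")
            comp = np.stack(
                [
                    self._per_pattern(tree, c)
                    for c, k in zip(model.components, keep)
                    if k
                ]
            )
            per_pat = logsumexp(comp + logw[keep][:, None], axis=0)
        elif isinstance(model, BinaryMarkov) and (
            self.ascertainment or model.correction == "variable_only"
        ):
            base = replace(model, correction="none")
            per_pat = self._per_pattern(tree, base)
            const = np.array([["0"] * tree.n_taxa, ["1"] * tree.n_taxa], dtype="U1").T
            ln_const = pruning_loglik(tree, const, base)
            p_const = float(np.exp(ln_const).sum())
            if p_const >= 1.0 - 1e-12:
                raise ModelError("P(constant) >= 1 under the binary model")
            return float(self.weights @ per_pat - self.n_sites * np.log1p(-p_const))
        else:
            per_pat = self._per_pattern(tree, model)
        return float(self.weights @ per_pat)


def build_partition_likelihoods(
    alignment: Alignment,
    scheme: PartitionScheme,
    indel_matrix=None,
    indel_part_name: str = "indels",
) -> dict[str, PartitionLikelihood]:
    """One evaluator per scheme part; the indel part draws from the binary matrix."""
    out: dict[str, PartitionLikelihood] = {}
    covered = 0
    for cs, tag in scheme.parts:
        if tag == "indel":
            if indel_matrix is None:
                raise ModelError(f"scheme part {cs.name!r} needs an indel matrix")
            out[cs.name] = PartitionLikelihood(
                cs.name, indel_matrix.cells, 2, ascertainment=True
            )
        else:
            cols = cs.columns()
            if cols.size == 0:
                raise ModelError(f"scheme part {cs.name!r} selects no columns")
            out[cs.name] = PartitionLikelihood(cs.name, alignment.matrix[:, cols], 4)
            covered += cols.size
    nuc_cols = sum(
        cs.n_columns for cs, tag in scheme.parts if tag != "indel"
    )
    if covered != nuc_cols:
        raise ModelError("internal: column accounting mismatch")
    return out


def total_loglik(
    tree: Tree,
    alignment: Alignment,
    scheme: PartitionScheme,
    pm: PartitionedModel,
    indel_matrix=None,
) -> float:
    """Sum of per-partition log-likelihoods under a partitioned model.

    Every nucleotide column of the alignment must be covered by the scheme's
    non-indel parts.
    """
    nuc_cols = sum(cs.n_columns for cs, tag in scheme.parts if tag != "indel")
    if nuc_cols != alignment.length:
        raise ModelError(
            f"scheme covers {nuc_cols} of {alignment.length} alignment columns"
        )
    parts = build_partition_likelihoods(alignment, scheme, indel_matrix)
    return float(sum(parts[cs.name].loglik(tree, pm.model_for(cs.name)) for cs, _ in scheme.parts))
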