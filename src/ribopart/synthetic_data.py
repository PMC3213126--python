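"""Simulation of trees, partitioned sequence data and indel-bearing alignments.

Everything the pipeline consumes can be generated here with known truth:
a Yule-topology tree with exponential branch lengths, nucleotide partitions
evolved site-wise under distinct GTR+Gamma processes (optionally a
K-component mixture with per-site component assignment recorded), and an
ITS-like indel process superimposed on one partition — gap events placed on
branches with geometric lengths and inherited by all descendant taxa, so the
simple-indel-coding step can be scored against the exact list of true gap
extents.  Indels are an annotation process over an already-evolved
alignment, not an integrated insertion-deletion substitution process: truth
bookkeeping stays exact and the coding step, not the aligner, is the object
under test.

One integer seed fully determines every dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .indel_coding import IndelEvent
from .models import GtrGamma, MixtureSpec, PartitionedModel, transition_matrix
from .seqio import DNA_STATES, GAP, Alignment, CharacterSet, PartitionScheme, to_nexus
from .trees import Tree, write_newick


@dataclass
class SimulationTruth:
    """Everything needed to reproduce and score a simulated dataset."""

    tree: Tree
    partitioned_model: PartitionedModel
    site_components: dict[str, np.ndarray] = field(default_factory=dict)
    indel_events: list[IndelEvent] = field(default_factory=list)
    seed: int = 0

    def to_text(self) -> str:
        lines = [f"seed\t{self.seed}", f"tree\t{write_newick(self.tree)}"]
        for name, model in self.partitioned_model.assignments:
            lines.append(f"partition\t{name}\t{model!r}")
        for name, comp in self.site_components.items():
            lines.append(f"site_components\t{name}\t{','.join(map(str, comp))}")
        for ev in self.indel_events:
            taxa = ",".join(sorted(ev.supporting_taxa))
            lines.append(f"indel\t{ev.start}\t{ev.end}\t{taxa}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# trees


def _yule_topology(taxa: list[str], rng: np.random.Generator) -> Tree:
    """Pure-birth topology: split a uniformly chosen pending tip until n tips."""
    n = len(taxa)
    next_id = 1
    parent_map: dict[int, int] = {}
    tips = []
    for _ in range(2):
        parent_map[next_id] = 0
        tips.append(next_id)
        next_id += 1
    while len(tips) < n:
        t = tips.pop(int(rng.integers(len(tips))))
        for _ in range(2):
            parent_map[next_id] = t
            tips.append(next_id)
            next_id += 1
    perm = rng.permutation(n)
    leaf_of = {tip: int(perm[i]) for i, tip in enumerate(tips)}
    internals = [0] + sorted(x for x in parent_map if x not in leaf_of and x != 0)
    internal_of = {x: n + i for i, x in enumerate(internals)}
    n_nodes = n + len(internals)
    parent = np.full(n_nodes, -1, dtype=int)
    for child, par in parent_map.items():
        c = leaf_of.get(child, internal_of.get(child))
        parent[c] = internal_of[par]
    return Tree(taxa, parent, np.full(n_nodes, np.nan))


def sample_tree(
    n_taxa: int,
    birth_rate: float = 1.0,
    seed: int = 0,
    target_tree_length: float | None = None,
    taxa: list[str] | None = None,
) -> Tree:
    """Yule topology with iid exponential branch lengths (mean 1/birth_rate).

    When ``target_tree_length`` is given the lengths are rescaled so that
    TL equals it exactly.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    rng = np.random.default_rng(seed)
    taxa = list(taxa) if taxa is not None else [f"t{i + 1}" for i in range(n_taxa)]
    tree = _yule_topology(taxa, rng)
    mask = tree.parent >= 0
    tree.length[mask] = rng.exponential(1.0 / birth_rate, int(mask.sum()))
    if target_tree_length is not None:
        tree.length[mask] *= target_tree_length / tree.length[mask].sum()
    return tree


# ---------------------------------------------------------------------------
# sequence evolution


def _simulate_sites(tree: Tree, model: GtrGamma, n_sites: int, rng) -> np.ndarray:
    """Site-wise CTMC simulation down the tree; returns (n_taxa, n_sites) of ACGT."""
    rates = model.category_rates()
    cat = rng.integers(len(rates), size=n_sites)
    pi = np.asarray(model.base_freqs)
    order = tree.postorder()[::-1]  # root first
    states = np.empty((tree.n_nodes, n_sites), dtype=np.int8)
    states[tree.root] = rng.choice(4, size=n_sites, p=pi)
    for c in np.unique(cat):
        sel = np.nonzero(cat == c)[0]
        for v in order:
            p = tree.parent[v]
            if p < 0:
                continue
            P = transition_matrix(model, float(tree.length[v]), float(rates[c]))
            cum = P.cumsum(axis=1)
            u = rng.random(sel.size)
            states[v, sel] = (u[:, None] > cum[states[p, sel]]).sum(axis=1)
    alpha = np.array(list(DNA_STATES))
    return alpha[states[: tree.n_taxa]]


def evolve_alignment(
    tree: Tree,
    scheme: PartitionScheme,
    pm: PartitionedModel,
    seed: int = 0,
) -> tuple[Alignment, SimulationTruth]:
    """Evolve every nucleotide partition of the scheme under its assigned model.

    Mixture partitions draw a component per site (recorded in the truth);
    all partitions share the tree's topology and branch lengths.
    """
    rng = np.random.default_rng(seed)
    blocks: list[np.ndarray] = []
    site_components: dict[str, np.ndarray] = {}
    for cs, tag in scheme.parts:
        if tag == "indel":
            continue
        n_sites = cs.n_columns
        if n_sites == 0:
            raise ValueError(f"partition {cs.name!r} has zero columns")
        model = pm.model_for(cs.name)
        if isinstance(model, MixtureSpec):
            comp = rng.choice(model.K, size=n_sites, p=np.asarray(model.weights))
            block = np.empty((tree.n_taxa, n_sites), dtype="U1")
            for k in range(model.K):
                sel = np.nonzero(comp == k)[0]
                if sel.size:
                    block[:, sel] = _simulate_sites(
                        tree, model.components[k], sel.size, rng
                    )
            site_components[cs.name] = comp
        elif isinstance(model, GtrGamma):
            block = _simulate_sites(tree, model, n_sites, rng)
        else:
            raise ValueError(f"cannot evolve sequence under {type(model).__name__}")
        blocks.append(block)
    mat = np.concatenate(blocks, axis=1)
    aln = Alignment(
        tree.taxa,
        ["".join(r) for r in mat],
        {cs.name: cs for cs, tag in scheme.parts if tag != "indel"},
    )
    truth = SimulationTruth(tree.copy(), pm, site_components, [], seed)
    return aln, truth


# ---------------------------------------------------------------------------
# indels


def superimpose_indels(
    aln: Alignment,
    tree: Tree,
    indel_rate: float = 0.2,
    mean_length: float = 4.0,
    seed: int = 0,
    columns: tuple[int, int] | None = None,
) -> tuple[Alignment, list[IndelEvent]]:
    """Place deletion events on branches and propagate them to descendant taxa.

    Per branch the event count is Poisson(indel_rate x branch length); each
    event has a geometric length (mean ``mean_length``) and a uniform start
    inside ``columns`` (default: the whole alignment).  All leaves below the
    branch inherit the gap.  Returns the gapped alignment and the list of
    true distinct gap extents with their supporting taxa.
    """
    if indel_rate < 0 or mean_length < 1:
        raise ValueError("need indel_rate >= 0 and mean_length >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = columns if columns is not None else (0, aln.length)
    mat = aln.matrix.copy()
    taxa_index = {t: i for i, t in enumerate(aln.taxa)}
    if tree.taxa != aln.taxa and set(tree.taxa) != set(aln.taxa):
        raise ValueError("tree and alignment taxa differ")
    masks = tree.leafset_masks()
    support: dict[tuple[int, int], set[str]] = {}
    p_geom = 1.0 / mean_length
    for v in range(tree.n_nodes):
        if tree.parent[v] < 0:
            continue
        n_events = rng.poisson(indel_rate * float(tree.length[v]))
        for _ in range(n_events):
            glen = int(rng.geometric(p_geom))
            glen = min(glen, hi - lo - 1)
            if glen < 1:
                continue
            start = int(rng.integers(lo, hi - glen + 1))
            extent = (start, start + glen)
            bearers = {tree.taxa[i] for i in range(tree.n_taxa) if masks[v] >> i & 1}
            support.setdefault(extent, set()).update(bearers)
            for t in bearers:
                mat[taxa_index[t], start : start + glen] = GAP
    events = [
        IndelEvent(s, e, frozenset(support[(s, e)])) for s, e in sorted(support)
    ]
    gapped = Alignment(aln.taxa, ["".join(r) for r in mat], aln.charsets)
    return gapped, events


# ---------------------------------------------------------------------------
# study-condition presets


def heterogeneous_gtr_models(n_parts: int, shape: float = 0.5) -> list[GtrGamma]:
    """Strongly distinct GTR+Gamma processes, one per partition.

    The partitions differ in exchangeabilities, base composition and gamma
    shape, emulating the qualitative heterogeneity between ribosomal loci
    (a conserved core gene vs. fast AT-rich spacers).
    """
    presets = [
        GtrGamma((2.0, 8.0, 1.5, 1.2, 9.0, 1.0), (0.30, 0.20, 0.22, 0.28), shape),
        GtrGamma((0.8, 2.0, 4.0, 3.5, 1.0, 1.0), (0.38, 0.12, 0.13, 0.37), 2.0 * shape + 0.5),
        GtrGamma((5.0, 1.0, 0.7, 0.8, 1.1, 1.0), (0.18, 0.32, 0.31, 0.19), 4.0 * shape),
        GtrGamma((1.0, 4.0, 2.0, 2.0, 4.0, 1.0), (0.25, 0.25, 0.25, 0.25), shape),
        GtrGamma((3.0, 1.5, 5.0, 0.6, 2.5, 1.0), (0.33, 0.17, 0.20, 0.30), 1.5 * shape),
    ]
    if not (1 <= n_parts <= len(presets)):
        raise ValueError(f"supported partition counts: 1..{len(presets)}")
    return presets[:n_parts]


def partitioned_dataset(
    n_taxa: int = 30,
    n_parts: int = 3,
    sites_per_part: int = 200,
    tree_length: float = 3.0,
    seed: int = 0,
) -> tuple[Alignment, PartitionScheme, PartitionedModel, Tree]:
    """A heterogeneous multi-partition dataset with known truth.

    Default conditions: a 30-taxon Yule tree of total length 3, three
    nucleotide partitions of 200 sites evolving under the distinct GTR+Gamma
    processes of :func:`heterogeneous_gtr_models`.
    """
    tree = sample_tree(n_taxa, seed=seed, target_tree_length=tree_length)
    models = heterogeneous_gtr_models(n_parts)
    parts = []
    for i in range(n_parts):
        cs = CharacterSet(f"part{i + 1}", ((i * sites_per_part, (i + 1) * sites_per_part),))
        parts.append((cs, "nuc"))
    scheme = PartitionScheme(f"{n_parts}-partition truth", tuple(parts))
    pm = PartitionedModel(tuple((f"part{i + 1}", m) for i, m in enumerate(models)))
    aln, _truth = evolve_alignment(tree, scheme, pm, seed=seed + 1)
    return aln, scheme, pm, tree


def write_dataset(
    outdir,
    aln: Alignment,
    tree: Tree,
    truth: SimulationTruth | None = None,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "alignment.nex").write_text(to_nexus(aln))
    (outdir / "tree.nwk").write_text(write_newick(tree) + "\n")
    if truth is not None:
        (outdir / "truth.tsv").write_text(truth.to_text())
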