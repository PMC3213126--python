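"""Likelihood core: transition matrices, gamma discretization, pruning, mixtures."""

import itertools

import numpy as np
import pytest
from scipy import integrate
from scipy.linalg import expm
from scipy.stats import gamma as gamma_dist

import ribopart as rp
from ribopart.models import (
    BinaryMarkov,
    GtrGamma,
    MixtureSpec,
    ModelError,
    PartitionedModel,
    ascertainment_corrected_loglik,
    discretize_gamma,
    mixture_loglik,
    pruning_loglik,
    total_loglik,
    transition_matrix,
)
from ribopart.seqio import Alignment, CharacterSet, DNA_STATES, PartitionScheme


class TestTransitionMatrix:
    def test_zero_branch_is_identity(self, gtr_model):
        assert np.allclose(transition_matrix(gtr_model, 0.0), np.eye(4), atol=1e-12)

    def test_binary_one_parameter_closed_form(self):
        m = BinaryMarkov("one_parameter")
        for t in (0.0, 0.3, 1.7):
            stay = 0.5 * (1 + np.exp(-2 * t))
            P = transition_matrix(m, t)
            assert P[0, 0] == pytest.approx(stay, abs=1e-12)
            assert P[1, 1] == pytest.approx(stay, abs=1e-12)

    def test_equal_rates_equal_freqs_is_jukes_cantor(self):
        m = GtrGamma()
        for t in (0.05, 0.4, 2.0):
            P = transition_matrix(m, t)
            same = 0.25 + 0.75 * np.exp(-4 * t / 3)
            assert np.allclose(np.diag(P), same, atol=1e-12)

    def test_matches_scipy_expm(self, gtr_model):
        Q = gtr_model.rate_matrix()
        for t in (0.01, 0.5, 3.0):
            assert np.allclose(transition_matrix(gtr_model, t), expm(Q * t), atol=1e-12)

    @pytest.mark.parametrize("t", [0.05, 0.5, 2.5])
    def test_detailed_balance(self, gtr_model, t):
        P = transition_matrix(gtr_model, t)
        pi = np.asarray(gtr_model.base_freqs)
        flux = pi[:, None] * P
        assert np.abs(flux - flux.T).max() < 1e-10

    def test_rows_sum_to_one(self, gtr_model):
        P = transition_matrix(gtr_model, 1.3, rate_multiplier=2.0)
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_nonfinite_rejected(self):
        with pytest.raises(ModelError):
            transition_matrix(GtrGamma(), np.nan)

    def test_unit_scaling_one_substitution_per_unit_branch(self, gtr_model):
        Q = gtr_model.rate_matrix()
        pi = np.asarray(gtr_model.base_freqs)
        assert -(pi * np.diag(Q)).sum() == pytest.approx(1.0, abs=1e-12)


class TestDiscretizeGamma:
    def test_single_category_is_one(self):
        assert discretize_gamma(0.3, 1).tolist() == [1.0]

    def test_large_shape_limit_all_one(self):
        rates = discretize_gamma(1e6, 4)
        assert np.allclose(rates, 1.0, atol=1e-2)

    def test_mean_is_one(self):
        for shape in (0.1, 0.5, 2.0, 10.0):
            assert discretize_gamma(shape, 4).mean() == pytest.approx(1.0, abs=1e-12)

    def test_against_quadrature_oracle(self):
        """Category means via direct numeric integration of the gamma density."""
        shape, n = 0.5, 4
        edges = gamma_dist.ppf(np.arange(n + 1) / n, shape, scale=1 / shape)
        oracle = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            hi = min(hi, 1e4)
            val, _ = integrate.quad(
                lambda x: x * gamma_dist.pdf(x, shape, scale=1 / shape), lo, hi
            )
            oracle.append(val * n)
        assert np.allclose(discretize_gamma(shape, n), oracle, atol=1e-6)


def _brute_force_loglik(tree, columns, model):
    """Exhaustive sum over internal-node state assignments (oracle)."""
    rates = model.category_rates()
    pi = np.asarray(model.base_freqs)
    n_states = model.n_states
    internal = [v for v in range(tree.n_nodes) if v >= tree.n_taxa]
    out = []
    enc = {s: i for i, s in enumerate(DNA_STATES)} if n_states == 4 else {"0": 0, "1": 1}
    for j in range(columns.shape[1]):
        tot = 0.0
        for r in rates:
            Ps = {
                v: transition_matrix(model, float(tree.length[v]), float(r))
                for v in range(tree.n_nodes)
                if tree.parent[v] >= 0
            }
            s = 0.0
            for assign in itertools.product(range(n_states), repeat=len(internal)):
                st = dict(zip(internal, assign))
                ok = True
                for i in range(tree.n_taxa):
                    sym = columns[i, j]
                    if sym in enc:
                        st[i] = enc[sym]
                    else:
                        ok = False
                if not ok:
                    raise ValueError("oracle handles unambiguous symbols only")
                p = pi[st[tree.root]]
                for v in range(tree.n_nodes):
                    if tree.parent[v] >= 0:
                        p *= Ps[v][st[int(tree.parent[v])], st[v]]
                s += p
            tot += s / len(rates)
        out.append(np.log(tot))
    return np.array(out)


class TestPruning:
    def test_all_missing_column_has_zero_loglik(self, small_tree, gtr_model):
        cols = np.full((small_tree.n_taxa, 1), "?", dtype="U1")
        assert pruning_loglik(small_tree, cols, gtr_model)[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_enumeration_oracle(self, gtr_model):
        tree = rp.sample_tree(5, seed=4, target_tree_length=1.2)
        cs = CharacterSet("x", ((0, 12),))
        aln, _ = rp.evolve_alignment(
            tree,
            PartitionScheme("s", ((cs, "nuc"),)),
            PartitionedModel((("x", gtr_model),)),
            seed=8,
        )
        got = pruning_loglik(tree, aln.matrix, gtr_model)
        want = _brute_force_loglik(tree, aln.matrix, gtr_model)
        assert np.abs(got - want).max() < 1e-8

    def test_two_taxon_jc_closed_form(self):
        m = GtrGamma(n_categories=1)
        taxa = ["a", "b"]
        parent = np.array([2, 2, -1])
        t1, t2 = 0.3, 0.5
        tree = rp.Tree(taxa, parent, np.array([t1, t2, np.nan]))
        same = pruning_loglik(tree, np.array([["A"], ["A"]]), m)[0]
        diff = pruning_loglik(tree, np.array([["A"], ["C"]]), m)[0]
        t = t1 + t2
        p_same = 0.25 * (0.25 + 0.75 * np.exp(-4 * t / 3))
        p_diff = 0.25 * (0.25 - 0.25 * np.exp(-4 * t / 3))
        assert same == pytest.approx(np.log(p_same), abs=1e-10)
        assert diff == pytest.approx(np.log(p_diff), abs=1e-10)

    def test_label_mismatch_errors(self, small_tree, gtr_model):
        with pytest.raises(ModelError):
            pruning_loglik(small_tree, np.full((3, 2), "A", dtype="U1"), gtr_model)

    def test_loglik_decreases_with_growing_branch(self, simulated_small):
        aln, _scheme, pm, tree = simulated_small
        model = pm.model_for("locus")
        vals = []
        for length in (1.0, 4.0, 16.0, 64.0):  # past any plausible ML length
            t2 = tree.copy()
            edge = np.nonzero(t2.parent >= 0)[0][3]
            t2.length[edge] = length
            vals.append(pruning_loglik(t2, aln.matrix, model).sum())
        assert all(b < a for a, b in zip(vals, vals[1:]))


class TestAscertainment:
    def test_two_taxon_closed_form_denominator(self):
        m = BinaryMarkov("one_parameter", correction="variable_only")
        t1, t2 = 0.4, 0.0
        tree = rp.Tree(["a", "b"], np.array([2, 2, -1]), np.array([t1, t2, np.nan]))
        cells = np.array([["0", "1"], ["1", "1"]])  # two variable-ish characters

        class _M:
            pass

        matrix = _M()
        matrix.cells = cells
        total = ascertainment_corrected_loglik(tree, matrix, m)
        base = pruning_loglik(tree, cells, BinaryMarkov("one_parameter")).sum()
        p_const = 0.5 * (1 + np.exp(-2 * (t1 + t2)))  # P(00) + P(11)
        assert total == pytest.approx(base - 2 * np.log1p(-p_const), abs=1e-10)

    def test_correction_increases_per_site_loglik(self, small_tree):
        m = BinaryMarkov("one_parameter", correction="variable_only")
        cells = np.array([["0"], ["1"], ["0"], ["1"], ["0"], ["1"]])
        corrected = ascertainment_corrected_loglik(small_tree, cells, m)
        plain = pruning_loglik(small_tree, cells, BinaryMarkov("one_parameter")).sum()
        assert corrected > plain

    def test_infinite_branch_denominator_half(self):
        m = BinaryMarkov("one_parameter", correction="variable_only")
        tree = rp.Tree(["a", "b"], np.array([2, 2, -1]), np.array([50.0, 50.0, np.nan]))
        cells = np.array([["0"], ["1"]])
        total = ascertainment_corrected_loglik(tree, cells, m)
        base = pruning_loglik(tree, cells, BinaryMarkov("one_parameter")).sum()
        assert total == pytest.approx(base - np.log(0.5), abs=1e-6)

    def test_zero_tree_rejected(self):
        m = BinaryMarkov("one_parameter", correction="variable_only")
        tree = rp.Tree(["a", "b"], np.array([2, 2, -1]), np.array([0.0, 0.0, np.nan]))
        with pytest.raises(ModelError):
            ascertainment_corrected_loglik(tree, np.array([["0"], ["1"]]), m)


class TestMixture:
    def test_k1_equals_single_model(self, simulated_small):
        aln, _scheme, pm, tree = simulated_small
        model = pm.model_for("locus")
        mix = MixtureSpec((model,), (1.0,))
        single = pruning_loglik(tree, aln.matrix, model)
        mixed = mixture_loglik(tree, aln.matrix, mix)
        assert np.allclose(single, mixed, atol=1e-12)

    def test_identical_components_degenerate(self, simulated_small):
        aln, _scheme, pm, tree = simulated_small
        model = pm.model_for("locus")
        mix = MixtureSpec((model, model, model), (0.2, 0.5, 0.3))
        assert np.allclose(
            mixture_loglik(tree, aln.matrix, mix),
            pruning_loglik(tree, aln.matrix, model),
            atol=1e-12,
        )

    def test_k2_matches_direct_weighted_sum(self, simulated_small):
        aln, _scheme, _pm, tree = simulated_small
        cols = aln.matrix[:, :5]
        a = GtrGamma((1, 4, 1, 1, 4, 1), (0.25, 0.25, 0.25, 0.25), 0.5)
        b = GtrGamma((3, 1, 2, 1, 1, 1), (0.4, 0.1, 0.1, 0.4), 0.5)
        w = (0.7, 0.3)
        mix = MixtureSpec((a, b), w)
        direct = np.log(
            w[0] * np.exp(pruning_loglik(tree, cols, a))
            + w[1] * np.exp(pruning_loglik(tree, cols, b))
        )
        assert np.allclose(mixture_loglik(tree, cols, mix), direct, atol=1e-10)

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ModelError):
            MixtureSpec((GtrGamma(),), (0.0,))

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ModelError):
            MixtureSpec((GtrGamma(shape=1.0), GtrGamma(shape=2.0)), (0.5, 0.5))


class TestTotalLoglik:
    def test_single_part_equals_pruning_sum(self, simulated_small):
        aln, scheme, pm, tree = simulated_small
        total = total_loglik(tree, aln, scheme, pm)
        per_site = pruning_loglik(tree, aln.matrix, pm.model_for("locus"))
        assert total == pytest.approx(per_site.sum(), abs=1e-9)

    def test_part_order_irrelevant(self, gtr_model, small_tree):
        cs1 = CharacterSet("p1", ((0, 30),))
        cs2 = CharacterSet("p2", ((30, 60),))
        other = GtrGamma((1, 5, 1, 1, 5, 1), (0.4, 0.1, 0.2, 0.3), 1.2)
        s12 = PartitionScheme("a", ((cs1, "nuc"), (cs2, "nuc")))
        s21 = PartitionScheme("b", ((cs2, "nuc"), (cs1, "nuc")))
        pm = PartitionedModel((("p1", gtr_model), ("p2", other)))
        aln, _ = rp.evolve_alignment(small_tree, s12, pm, seed=3)
        assert total_loglik(small_tree, aln, s12, pm) == pytest.approx(
            total_loglik(small_tree, aln, s21, pm), abs=1e-9
        )

    def test_two_part_hand_sum(self, gtr_model, small_tree):
        cs1 = CharacterSet("p1", ((0, 30),))
        cs2 = CharacterSet("p2", ((30, 60),))
        scheme = PartitionScheme("a", ((cs1, "nuc"), (cs2, "nuc")))
        other = GtrGamma((1, 5, 1, 1, 5, 1), (0.4, 0.1, 0.2, 0.3), 1.2)
        pm = PartitionedModel((("p1", gtr_model), ("p2", other)))
        aln, _ = rp.evolve_alignment(small_tree, scheme, pm, seed=3)
        by_hand = (
            pruning_loglik(small_tree, aln.matrix[:, :30], gtr_model).sum()
            + pruning_loglik(small_tree, aln.matrix[:, 30:], other).sum()
        )
        assert total_loglik(small_tree, aln, scheme, pm) == pytest.approx(by_hand, abs=1e-9)

    def test_uncovered_columns_error(self, simulated_small, gtr_model):
        aln, _scheme, _pm, tree = simulated_small
        short = PartitionScheme("short", ((CharacterSet("x", ((0, 10),)), "nuc"),))
        with pytest.raises(ModelError):
            total_loglik(tree, aln, short, PartitionedModel((("x", gtr_model),)))


class TestRefinementNesting:
    def test_refined_partition_fits_no_worse_on_fixed_tree(self):
        """Maximized lnL under the true 2-partition split >= 1-partition fit."""
        from ribopart.inference import ml_fit_gtr
        from ribopart.models import build_partition_likelihoods

        tree = rp.sample_tree(8, seed=17, target_tree_length=2.0)
        a = GtrGamma((1, 6, 1, 1, 6, 1), (0.35, 0.15, 0.15, 0.35), 0.4)
        b = GtrGamma((4, 1, 3, 1, 1, 1), (0.15, 0.35, 0.35, 0.15), 2.0)
        cs1, cs2 = CharacterSet("p1", ((0, 150),)), CharacterSet("p2", ((150, 300),))
        fine = PartitionScheme("fine", ((cs1, "nuc"), (cs2, "nuc")))
        coarse = PartitionScheme("coarse", ((CharacterSet("all", ((0, 300),)), "nuc"),))
        aln, _ = rp.evolve_alignment(tree, fine, PartitionedModel((("p1", a), ("p2", b))), seed=29)
        ev_f = build_partition_likelihoods(aln, fine)
        ev_c = build_partition_likelihoods(aln, coarse)
        lnl_fine = sum(
            ev_f[n].loglik(tree, ml_fit_gtr(ev_f[n], tree)) for n in ("p1", "p2")
        )
        lnl_coarse = ev_c["all"].loglik(tree, ml_fit_gtr(ev_c["all"], tree))
        assert lnl_fine >= lnl_coarse - 1e-6
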