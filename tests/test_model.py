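"""Kernel-machine training, the constrained objective and collective
inference."""

import numpy as np
import pytest

from sbrgo.fuzzy import (Constraint, Implies, TruthAssignment, Var, fun_atom)
from sbrgo.kernels import KernelMatrix, pairwise_kernel
from sbrgo.model import (KernelMachineClassifier, SBRAnnotator,
                         collective_inference, minimize_gd)
from sbrgo.ontology import UNKNOWN, AnnotationTable, OntologyDAG
from sbrgo.synthetic import SyntheticGenomeSpec, generate_genome

from conftest import closed_table


def block_kernel(n_a: int, n_b: int) -> np.ndarray:
    """Two perfectly separated similarity blocks."""
    n = n_a + n_b
    K = np.zeros((n, n))
    K[:n_a, :n_a] = 1.0
    K[n_a:, n_a:] = 1.0
    K += 0.1 * np.eye(n)
    return K


class TestKernelMachine:
    def test_separable_toy_reaches_perfect_training_f1(self):
        K = block_kernel(5, 5)
        y = np.array([1.0] * 5 + [0.0] * 5)
        clf = KernelMachineClassifier(lam_l=10.0).fit(K, y)
        pred = clf.predict(K)
        assert (pred == y).all()

    def test_vanishing_supervision_weight_gives_flat_scores(self):
        K = block_kernel(3, 3)
        y = np.array([1.0] * 3 + [0.0] * 3)
        clf = KernelMachineClassifier(lam_l=1e-8).fit(K, y)
        assert np.abs(clf.w_).max() < 1e-4
        np.testing.assert_allclose(clf.predict_proba(K)[:, 1], 0.5, atol=1e-3)

    def test_quadratic_margin_loss_matches_ridge_closed_form(self):
        # min w'Kw + lam * ||y - Kw||^2  has solution w = lam (I + lam K)^-1 y
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 3))
        K = X @ X.T + 0.5 * np.eye(6)
        y = rng.random(6).round()
        lam = 3.0
        clf = KernelMachineClassifier(lam_l=lam, loss="squared_margin",
                                      max_iter=50000, tol=0.0).fit(K, y)
        w_star = lam * np.linalg.solve(np.eye(6) + lam * K, y)
        np.testing.assert_allclose(clf.w_, w_star, atol=1e-6)

    def test_objective_path_non_increasing(self):
        K = block_kernel(4, 4)
        y = np.array([1.0] * 4 + [0.0] * 4)
        clf = KernelMachineClassifier(lam_l=5.0).fit(K, y)
        path = np.array(clf.objective_path_)
        assert (np.diff(path) <= 1e-12).all()

    def test_non_psd_kernel_rejected(self):
        K = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError, match="PSD"):
            KernelMachineClassifier().fit(K, np.array([1.0, 0.0]))

    def test_invalid_lam(self):
        with pytest.raises(ValueError):
            KernelMachineClassifier(lam_l=0.0).fit(np.eye(2),
                                                   np.array([1.0, 0.0]))


class TestOptimizer:
    @pytest.mark.parametrize("seed", range(4))
    def test_convex_quadratic_reaches_same_objective_from_any_start(self,
                                                                    seed):
        # convex stage-1-style objective: multiple inits agree within 1e-6
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(5, 3))
        K = X @ X.T + 0.2 * np.eye(5)
        y = rng.random(5)

        def fg(w):
            m = K @ w
            return float(w @ m + 2.0 * ((y - m) ** 2).sum()), \
                2.0 * m + 2.0 * (K @ (-2.0 * (y - m)))

        finals = []
        for _ in range(3):
            x0 = rng.normal(size=5)
            _, path = minimize_gd(fg, x0, max_iter=20000, tol=1e-14)
            finals.append(path[-1])
        assert max(finals) - min(finals) < 1e-6


def single_eq1_constraint(weight: float) -> tuple[Constraint, list]:
    atoms = [fun_atom("child", "p"), fun_atom("parent", "p")]
    body = Implies(Var(0), Var(1))
    return Constraint("eq1[child]", "eq1", body, [atoms], "lukasiewicz",
                      weight), atoms


class TestCollectiveInference:
    def test_no_constraints_returns_prior_exactly(self):
        atoms = [fun_atom("t", "p"), fun_atom("t", "q")]
        assign = TruthAssignment(atoms, np.array([0.3, 0.9]),
                                 np.zeros(2, bool))
        out = collective_inference(assign, [])
        np.testing.assert_array_equal(out.values, assign.values)

    def test_crisp_consistent_priors_are_fixed_point(self):
        c, atoms = single_eq1_constraint(weight=5.0)
        assign = TruthAssignment(atoms, np.array([1.0, 1.0]),
                                 np.zeros(2, bool))
        out = collective_inference(assign, [c])
        np.testing.assert_allclose(out.values, [1.0, 1.0], atol=1e-9)

    def test_child_high_parent_low_matches_grid_search_oracle(self):
        # one eq1 grounding, child prior 1, parent prior 0, large weight
        lam = 10.0
        c, atoms = single_eq1_constraint(weight=lam)
        assign = TruthAssignment(atoms, np.array([1.0, 0.0]),
                                 np.zeros(2, bool))
        out = collective_inference(assign, [c], max_iter=5000, tol=1e-12)

        def objective(a, b):
            prior = ((a - 1.0) ** 2 + b ** 2) / 2.0
            return prior + lam * max(0.0, a - b)

        grid = np.linspace(0, 1, 401)
        vals = np.array([[objective(a, b) for b in grid] for a in grid])
        best = vals.min()
        got = objective(out.values[0], out.values[1])
        assert got <= best + 1e-4
        assert out.values[1] > 0.45  # parent pulled up toward consensus

    def test_known_atoms_never_move(self):
        c, atoms = single_eq1_constraint(weight=10.0)
        assign = TruthAssignment(atoms, np.array([1.0, 0.0]),
                                 np.array([True, False]))
        out = collective_inference(assign, [c])
        assert out.values[0] == 1.0       # clamped child unchanged
        assert out.values[1] > 0.9        # parent must satisfy the rule

    def test_objective_never_increases(self):
        rng = np.random.default_rng(3)
        c, atoms = single_eq1_constraint(weight=2.0)
        assign = TruthAssignment(atoms, rng.random(2), np.zeros(2, bool))
        prior = assign.values.copy()

        def cobj(x):
            work = assign.copy()
            work.values = x
            return float(((x - prior) ** 2).mean()) + \
                c.weight * (1.0 - c.satisfaction(work))

        out = collective_inference(assign, [c])
        assert cobj(out.values) <= cobj(prior) + 1e-12


@pytest.fixture(scope="module")
def tiny_genome():
    spec = SyntheticGenomeSpec(n_proteins=24, namespaces=("BP",), levels=2,
                               sparsity=(0.6, 0.5), n_ppi_positives=20,
                               latent_dim=4, seed=5)
    dag, table, features, pos = generate_genome(spec)
    from sbrgo.pipeline import build_kernel
    K = build_kernel(features)
    return dag, table, K, pos


class TestSBRAnnotator:
    def test_full_objective_gradient_matches_finite_differences(self,
                                                                tiny_genome):
        dag, table, K, pos = tiny_genome
        for tnorm in ("lukasiewicz", "minimum"):
            m = SBRAnnotator(rules="full", tnorm=tnorm, ppi_levels=(1, 2),
                             max_iter=30)
            m.fit(K, dag, table, pos, [1] * len(pos))
            rng = np.random.default_rng(11)
            W = 0.05 * rng.normal(size=m.W_.shape)
            wb = 0.05 * rng.normal(size=m.wb_.shape)
            v, gW, gb = m.objective_and_grad(W, wb)
            eps = 1e-5
            idx = [(0, 0), (3, 2), (7, 1)]
            for i, j in idx:
                Wp, Wm = W.copy(), W.copy()
                Wp[i, j] += eps
                Wm[i, j] -= eps
                fd = (m.objective_and_grad(Wp, wb)[0]
                      - m.objective_and_grad(Wm, wb)[0]) / (2 * eps)
                assert gW[i, j] == pytest.approx(fd, rel=1e-4, abs=1e-7)
            for k in (0, len(wb) // 2):
                bp, bm = wb.copy(), wb.copy()
                bp[k] += eps
                bm[k] -= eps
                fd = (m.objective_and_grad(W, bp)[0]
                      - m.objective_and_grad(W, bm)[0]) / (2 * eps)
                assert gb[k] == pytest.approx(fd, rel=1e-4, abs=1e-7)

    def test_full_training_without_constraints_equals_stage1(self,
                                                             tiny_genome):
        dag, table, K, pos = tiny_genome
        a = SBRAnnotator(rules="none", full_training=False)
        a.fit(K, dag, table, pos, [1] * len(pos))
        b = SBRAnnotator(rules="none", full_training=True)
        b.fit(K, dag, table, pos, [1] * len(pos))
        np.testing.assert_allclose(a.W_, b.W_, atol=1e-12)

    def test_full_training_reduces_constraint_violation(self, tiny_genome):
        dag, table, K, pos = tiny_genome
        m = SBRAnnotator(rules="go", full_training=False, lambda_go=5.0)
        m.fit(K, dag, table, pos, [1] * len(pos))

        def violation(model):
            Marg, mb = model.margins_()
            assign = model._assignment_from_margins(Marg, mb, False)
            return sum(c.weight * (1.0 - c.satisfaction(assign))
                       for c in model.constraints_)

        before = violation(m)
        m._fit_full()
        after = violation(m)
        assert m.full_path_[-1] <= m.full_path_[0]
        assert after <= before

    def test_transductive_without_rules_equals_inductive(self, tiny_genome):
        dag, table, K, pos = tiny_genome
        m = SBRAnnotator(rules="none")
        m.fit(K, dag, table, pos, [1] * len(pos))
        S_t, sb_t = m.predict_scores("transductive")
        S_i, sb_i = m.predict_scores("inductive")
        # free atoms identical; labeled atoms clamped to their labels
        free = ~m._M
        np.testing.assert_allclose(S_t[free], S_i[free], atol=1e-12)

    def test_clamped_training_atoms_keep_their_labels(self, tiny_genome):
        dag, table, K, pos = tiny_genome
        m = SBRAnnotator(rules="go", lambda_go=5.0)
        m.fit(K, dag, table, pos, [1] * len(pos))
        S, _ = m.predict_scores("transductive")
        labeled = m._M
        np.testing.assert_array_equal(S[labeled], m._Y[labeled])

    def test_unknown_labels_stay_free(self, tiny_genome):
        dag, table, K, pos = tiny_genome
        hidden = set(list(table.proteins)[:5])
        masked = AnnotationTable(list(table.proteins), default=UNKNOWN)
        for (p, t), v in table.values.items():
            masked.values[(p, t)] = UNKNOWN if p in hidden else v
        m = SBRAnnotator(rules="none")
        m.fit(K, dag, masked, pos, [1] * len(pos))
        ip = [i for i, p in enumerate(m.proteins_) if p in hidden]
        assert not m._M[ip, :].any()

    def test_deterministic_given_inputs(self, tiny_genome):
        dag, table, K, pos = tiny_genome
        runs = []
        for _ in range(2):
            m = SBRAnnotator(rules="go")
            m.fit(K, dag, table, pos, [1] * len(pos))
            S, sb = m.predict_scores("transductive")
            runs.append((S.copy(), sb.copy()))
        np.testing.assert_array_equal(runs[0][0], runs[1][0])
        np.testing.assert_array_equal(runs[0][1], runs[1][1])
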