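"""T-norm connectives, rule compilation and constraint evaluation."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sbrgo.fuzzy import (And, Constraint, Implies, Not, Or, TruthAssignment,
                         Var, bound_atom, compile_go_rules, compile_ppi_rules,
                         evaluate, fun_atom, t_and, t_implies, t_not, t_or)

TNORMS = ("lukasiewicz", "minimum")
unit = st.floats(0.0, 1.0, allow_nan=False)


# ---------------------------------------------------------------------------
# independent interpreters (used as oracles only)


def boolean_eval(node, row) -> bool:
    """Crisp Boolean interpreter, independent of the T-norm machinery."""
    if isinstance(node, Var):
        return bool(row[node.slot])
    if isinstance(node, Not):
        return not boolean_eval(node.child, row)
    if isinstance(node, And):
        return all(boolean_eval(c, row) for c in node.children)
    if isinstance(node, Or):
        return any(boolean_eval(c, row) for c in node.children)
    if isinstance(node, Implies):
        return (not boolean_eval(node.antecedent, row)) or \
            boolean_eval(node.consequent, row)
    raise TypeError(node)


def fuzzy_walk(node, row, tnorm) -> float:
    """Scalar re-implementation that re-walks the AST per grounding."""
    if isinstance(node, Var):
        return float(row[node.slot])
    if isinstance(node, Not):
        return 1.0 - fuzzy_walk(node.child, row, tnorm)
    if isinstance(node, And):
        vals = [fuzzy_walk(c, row, tnorm) for c in node.children]
        if tnorm == "lukasiewicz":
            return max(0.0, sum(vals) - (len(vals) - 1))
        return min(vals)
    if isinstance(node, Or):
        vals = [fuzzy_walk(c, row, tnorm) for c in node.children]
        if tnorm == "lukasiewicz":
            return min(1.0, sum(vals))
        return max(vals)
    if isinstance(node, Implies):
        a = fuzzy_walk(node.antecedent, row, tnorm)
        b = fuzzy_walk(node.consequent, row, tnorm)
        if tnorm == "lukasiewicz":
            return min(1.0, 1.0 - a + b)
        return 1.0 if a <= b else b
    raise TypeError(node)


def random_formula(rng, n_slots, depth=3):
    if depth == 0 or rng.random() < 0.3:
        return Var(int(rng.integers(n_slots)))
    kind = rng.integers(4)
    if kind == 0:
        return Not(random_formula(rng, n_slots, depth - 1))
    if kind == 1:
        return And(*(random_formula(rng, n_slots, depth - 1)
                     for _ in range(2)))
    if kind == 2:
        return Or(*(random_formula(rng, n_slots, depth - 1)
                    for _ in range(2)))
    return Implies(random_formula(rng, n_slots, depth - 1),
                   random_formula(rng, n_slots, depth - 1))


# ---------------------------------------------------------------------------
# connectives


class TestConnectives:
    @pytest.mark.parametrize("tnorm", TNORMS)
    def test_crisp_inputs_reproduce_boolean_truth_tables(self, tnorm):
        for a, b in itertools.product((0.0, 1.0), repeat=2):
            assert t_and(a, b, tnorm) == float(bool(a) and bool(b))
            assert t_or(a, b, tnorm) == float(bool(a) or bool(b))
            assert t_implies(a, b, tnorm) == float((not a) or bool(b))
        assert t_not(0.0) == 1.0 and t_not(1.0) == 0.0

    def test_lukasiewicz_hand_values(self):
        assert t_and(0.7, 0.6) == pytest.approx(0.3)
        assert t_implies(0.9, 0.2) == pytest.approx(0.3)
        assert t_or(0.7, 0.6) == 1.0
        assert t_not(0.25) == 0.75

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            t_and(1.2, 0.5)
        with pytest.raises(ValueError):
            t_not(-0.1)

    @pytest.mark.parametrize("tnorm", TNORMS)
    @given(a=unit, b=unit)
    @settings(deadline=None)
    def test_commutativity_and_range(self, tnorm, a, b):
        assert t_and(a, b, tnorm) == pytest.approx(t_and(b, a, tnorm))
        assert t_or(a, b, tnorm) == pytest.approx(t_or(b, a, tnorm))
        for v in (t_and(a, b, tnorm), t_or(a, b, tnorm),
                  t_implies(a, b, tnorm)):
            assert 0.0 <= v <= 1.0

    @pytest.mark.parametrize("tnorm", TNORMS)
    @given(a=unit, b=unit, c=unit)
    @settings(deadline=None)
    def test_monotone_and_boundary(self, tnorm, a, b, c):
        lo, hi = min(b, c), max(b, c)
        assert t_and(a, lo, tnorm) <= t_and(a, hi, tnorm) + 1e-12
        assert t_and(a, 1.0, tnorm) == pytest.approx(a)   # unit element
        assert t_and(a, 0.0, tnorm) == 0.0

    @given(a=unit, b=unit, da=st.floats(-0.1, 0.1))
    @settings(deadline=None)
    def test_lukasiewicz_lipschitz(self, a, b, da):
        a2 = min(1.0, max(0.0, a + da))
        for op in (t_and, t_or, t_implies):
            assert abs(op(a2, b) - op(a, b)) <= abs(a2 - a) + 1e-12


# ---------------------------------------------------------------------------
# constraint evaluation


def make_constraint(body, atom_rows, tnorm="lukasiewicz", weight=1.0):
    return Constraint("test", "test", body, atom_rows, tnorm, weight)


class TestEvaluate:
    def test_crisp_satisfied_gives_one(self):
        body = Implies(Var(0), Var(1))
        atoms = [[("Fun", "a", "p"), ("Fun", "b", "p")]]
        assign = TruthAssignment(atoms[0], np.array([1.0, 1.0]),
                                 np.zeros(2, bool))
        assert evaluate(make_constraint(body, atoms), assign) == 1.0

    def test_mean_over_groundings(self):
        body = Var(0)
        a1, a2 = ("Fun", "t", "p"), ("Fun", "t", "q")
        assign = TruthAssignment([a1, a2], np.array([0.4, 0.8]),
                                 np.zeros(2, bool))
        c = make_constraint(body, [[a1], [a2]])
        assert c.satisfaction(assign) == pytest.approx(0.6)

    def test_vacuous_constraint_is_one(self):
        c = make_constraint(Var(0), [])
        assign = TruthAssignment([("Fun", "t", "p")], np.array([0.3]),
                                 np.zeros(1, bool))
        with pytest.warns(UserWarning, match="vacuous"):
            assert evaluate(c, assign) == 1.0

    @pytest.mark.parametrize("tnorm", TNORMS)
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_independent_ast_interpreter(self, tnorm, seed):
        rng = np.random.default_rng(seed)
        n_slots = 4
        body = random_formula(rng, n_slots)
        atoms = [[("Fun", f"t{s}", f"p{g}") for s in range(n_slots)]
                 for g in range(6)]
        flat = [a for row in atoms for a in row]
        vals = rng.random(len(flat))
        assign = TruthAssignment(flat, vals, np.zeros(len(flat), bool))
        c = make_constraint(body, atoms, tnorm)
        got = c.satisfaction(assign)
        lookup = dict(zip(flat, vals))
        expect = np.mean([fuzzy_walk(body, [lookup[a] for a in row], tnorm)
                          for row in atoms])
        assert got == pytest.approx(expect, abs=1e-12)

    @pytest.mark.parametrize("tnorm", TNORMS)
    def test_gradient_matches_finite_differences(self, tnorm):
        rng = np.random.default_rng(7)
        body = random_formula(rng, 3, depth=2)
        atoms = [[("Fun", f"t{s}", f"p{g}") for s in range(3)]
                 for g in range(4)]
        flat = [a for row in atoms for a in row]
        vals = 0.05 + 0.9 * rng.random(len(flat))  # generic interior point
        assign = TruthAssignment(flat, vals, np.zeros(len(flat), bool))
        c = make_constraint(body, atoms, tnorm)
        phi, grad = c.satisfaction_grad(assign)
        eps = 1e-6
        for i in range(len(flat)):
            plus, minus = assign.copy(), assign.copy()
            plus.values[i] += eps
            minus.values[i] -= eps
            fd = (c.satisfaction(plus) - c.satisfaction(minus)) / (2 * eps)
            assert grad[i] == pytest.approx(fd, abs=1e-5)

    def test_missing_atom_raises(self):
        c = make_constraint(Var(0), [[("Fun", "t", "p")]])
        assign = TruthAssignment([("Fun", "other", "p")], np.array([0.5]),
                                 np.zeros(1, bool))
        with pytest.raises(KeyError, match="absent"):
            c.satisfaction(assign)


# ---------------------------------------------------------------------------
# compiled rule families


def crisp_assignment(atoms, bits):
    return TruthAssignment(list(atoms), np.array(bits, dtype=float),
                           np.zeros(len(atoms), bool))


class TestGoRules:
    def test_chain_child_without_parent_violates_eq1(self, chain_dag):
        cons = compile_go_rules(chain_dag, ["p"])
        eq1_b = next(c for c in cons if c.name == "eq1[b]")
        assign = crisp_assignment(
            [fun_atom(t, "p") for t in ("root", "a", "b")], [1, 0, 1])
        assert eq1_b.satisfaction(assign) == 0.0

    def test_consistent_crisp_assignment_satisfies_all(self, diamond_dag):
        cons = compile_go_rules(diamond_dag, ["p"])
        atoms = [fun_atom(t, "p") for t in ("root", "a", "b", "c")]
        assign = crisp_assignment(atoms, [1, 1, 1, 1])
        assert all(c.satisfaction(assign) == 1.0 for c in cons)

    def test_diamond_parent_without_children_violates_eq2(self, diamond_dag):
        cons = compile_go_rules(diamond_dag, ["p"])
        eq2_root = next(c for c in cons if c.name == "eq2[root]")
        atoms = [fun_atom(t, "p") for t in ("root", "a", "b", "c")]
        assign = crisp_assignment(atoms, [1, 0, 0, 0])
        assert eq2_root.satisfaction(assign) == 0.0

    def test_max_depth_restricts_rules(self, chain_dag):
        cons = compile_go_rules(chain_dag, ["p"], max_depth=1)
        names = {c.name for c in cons}
        assert "eq1[b]" not in names and "eq1[a]" in names


class TestPpiRules:
    def test_bound_false_makes_rule_vacuously_true(self, two_ns_dag):
        cons = compile_ppi_rules(two_ns_dag, [("p", "q")], ("BP",), (1,))
        atoms = [bound_atom("p", "q"), fun_atom("bp1", "p"),
                 fun_atom("bp1", "q")]
        assign = crisp_assignment(atoms, [0, 0, 0])
        assert cons[0].satisfaction(assign) == 1.0

    def test_shared_term_satisfies(self, two_ns_dag):
        cons = compile_ppi_rules(two_ns_dag, [("p", "q")], ("BP",), (1,))
        atoms = [bound_atom("p", "q"), fun_atom("bp1", "p"),
                 fun_atom("bp1", "q")]
        assign = crisp_assignment(atoms, [1, 1, 1])
        assert cons[0].satisfaction(assign) == 1.0

    def test_no_shared_term_violates(self, two_ns_dag):
        cons = compile_ppi_rules(two_ns_dag, [("p", "q")], ("BP",), (1,))
        atoms = [bound_atom("p", "q"), fun_atom("bp1", "p"),
                 fun_atom("bp1", "q")]
        assign = crisp_assignment(atoms, [1, 1, 0])
        assert cons[0].satisfaction(assign) == 0.0

    def test_empty_level_skipped_with_warning(self, two_ns_dag):
        with pytest.warns(UserWarning, match="skipped"):
            cons = compile_ppi_rules(two_ns_dag, [("p", "q")], ("BP",), (9,))
        assert cons == []

    def test_mf_rejected(self, two_ns_dag):
        with pytest.raises(ValueError, match="BP and CC"):
            compile_ppi_rules(two_ns_dag, [("p", "q")], ("MF",), (1,))


class TestCrispEquivalence:
    """Compiled rule families against the Boolean interpreter, exhaustively."""

    @pytest.mark.parametrize("tnorm", TNORMS)
    def test_all_crisp_assignments_match_boolean_oracle(self, diamond_dag,
                                                        tnorm):
        proteins = ["p"]
        cons = compile_go_rules(diamond_dag, proteins, tnorm=tnorm)
        cons += compile_ppi_rules(diamond_dag, [("p", "p2")], ("BP",), (1,),
                                  tnorm=tnorm)
        all_atoms = sorted({a for c in cons for row in c.atoms for a in row})
        assert len(all_atoms) <= 12
        for bits in itertools.product((0.0, 1.0), repeat=len(all_atoms)):
            assign = crisp_assignment(all_atoms, list(bits))
            lookup = dict(zip(all_atoms, bits))
            for c in cons:
                got = c.satisfaction(assign)
                expect = np.mean([
                    float(boolean_eval(c.body, [lookup[a] for a in row]))
                    for row in c.atoms])
                assert got == pytest.approx(expect, abs=1e-12)


class TestMonotonicity:
    def test_implication_monotone_in_consequent_antecedent(self):
        # Lukasiewicz residuum: non-decreasing in b, non-increasing in a
        grid = np.linspace(0, 1, 21)
        body = Implies(Var(0), Var(1))
        atoms = [[("Fun", "x", "p"), ("Fun", "y", "p")]]
        c = make_constraint(body, atoms)
        for a in grid:
            vals = [c.satisfaction(crisp_like(atoms[0], [a, b]))
                    for b in grid]
            assert all(x <= y + 1e-12 for x, y in zip(vals, vals[1:]))
        for b in grid:
            vals = [c.satisfaction(crisp_like(atoms[0], [a, b]))
                    for a in grid]
            assert all(x >= y - 1e-12 for x, y in zip(vals, vals[1:]))


def crisp_like(atoms, vals):
    return TruthAssignment(list(atoms), np.array(vals, dtype=float),
                           np.zeros(len(atoms), bool))
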