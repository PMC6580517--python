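"""T-norm fuzzy relaxation of first-order rules.

Rules are universally quantified implications over the ``Fun_f(p)`` and
``Bound(p,p')`` predicates.  A rule is compiled to a :class:`Constraint`:
a propositional body (an AST over atom slots) plus a matrix of groundings,
each grounding being a row of indices into a global truth-value vector.  The
degree of satisfaction of the rule is the average of the body's T-norm value
over its groundings, so crisp inputs reproduce Boolean logic exactly.

Two T-norms are supported:

* ``lukasiewicz`` — AND: max(0, a+b-1); OR: min(1, a+b); NOT: 1-a;
  IMPLIES (residuum): min(1, 1-a+b).  Piecewise linear and 1-Lipschitz.
* ``minimum`` — AND: min; OR: max; NOT: 1-a; IMPLIES (Gödel residuum):
  1 if a <= b else b.

Both value and subgradient are computed; at piecewise-linear kinks the
subgradient averages the active branches.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

TNORMS = ("lukasiewicz", "minimum")

FunAtom = tuple  # ("Fun", term, protein)
BoundAtom = tuple  # ("Bound", p, q) with p <= q


def fun_atom(term: str, protein: str) -> tuple:
    return ("Fun", term, protein)


def bound_atom(p: str, q: str) -> tuple:
    a, b = sorted((p, q))
    return ("Bound", a, b)


def _check_unit(x) -> None:
    x = np.asarray(x, dtype=float)
    if np.any(x < -1e-12) or np.any(x > 1 + 1e-12):
        raise ValueError("truth values must lie in [0, 1]")


# ---------------------------------------------------------------------------
# scalar / broadcast connectives


def t_not(a):
    _check_unit(a)
    return 1.0 - np.asarray(a, dtype=float)


def t_and(a, b, tnorm: str = "lukasiewicz"):
    _check_unit(a); _check_unit(b)
    a = np.asarray(a, dtype=float); b = np.asarray(b, dtype=float)
    if tnorm == "lukasiewicz":
        return np.maximum(0.0, a + b - 1.0)
    if tnorm == "minimum":
        return np.minimum(a, b)
    raise ValueError(f"unknown T-norm {tnorm!r}")


def t_or(a, b, tnorm: str = "lukasiewicz"):
    # derived from AND and NOT by De Morgan
    _check_unit(a); _check_unit(b)
    a = np.asarray(a, dtype=float); b = np.asarray(b, dtype=float)
    if tnorm == "lukasiewicz":
        return np.minimum(1.0, a + b)
    if tnorm == "minimum":
        return np.maximum(a, b)
    raise ValueError(f"unknown T-norm {tnorm!r}")


def t_implies(a, b, tnorm: str = "lukasiewicz"):
    # residuum of the T-norm
    _check_unit(a); _check_unit(b)
    a = np.asarray(a, dtype=float); b = np.asarray(b, dtype=float)
    if tnorm == "lukasiewicz":
        return np.minimum(1.0, 1.0 - a + b)
    if tnorm == "minimum":
        return np.where(a <= b, 1.0, b)
    raise ValueError(f"unknown T-norm {tnorm!r}")


# ---------------------------------------------------------------------------
# propositional AST with value + subgradient


class Node:
    """A propositional formula over grounding slots.

    ``value_grad(A, tnorm)`` takes an array of slot truth values with shape
    (n_groundings, n_slots) and returns the body value per grounding together
    with its (sub)gradient with respect to every slot.
    """

    def value_grad(self, A: np.ndarray, tnorm: str
                   ) -> tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError

    def value(self, A: np.ndarray, tnorm: str) -> np.ndarray:
        return self.value_grad(A, tnorm)[0]


@dataclass(frozen=True)
class Var(Node):
    slot: int

    def value_grad(self, A, tnorm):
        g = np.zeros_like(A)
        g[:, self.slot] = 1.0
        return A[:, self.slot].copy(), g

    def __repr__(self):
        return f"x{self.slot}"


@dataclass(frozen=True)
class Not(Node):
    child: Node

    def value_grad(self, A, tnorm):
        v, g = self.child.value_grad(A, tnorm)
        return 1.0 - v, -g

    def __repr__(self):
        return f"NOT({self.child!r})"


class And(Node):
    def __init__(self, *children: Node):
        if not children:
            raise ValueError("AND needs at least one operand")
        self.children = children

    def value_grad(self, A, tnorm):
        vals, grads = zip(*(c.value_grad(A, tnorm) for c in self.children))
        V = np.stack(vals)          # (k, G)
        if tnorm == "lukasiewicz":
            s = V.sum(axis=0) - (len(self.children) - 1)
            out = np.maximum(0.0, s)
            w = np.where(s > 0, 1.0, np.where(s == 0, 0.5, 0.0))
            g = sum(gr * w[:, None] for gr in grads)
        elif tnorm == "minimum":
            out = V.min(axis=0)
            is_min = (V == out[None, :])
            share = is_min / is_min.sum(axis=0)[None, :]  # ties averaged
            g = sum(gr * share[i][:, None] for i, gr in enumerate(grads))
        else:
            raise ValueError(f"unknown T-norm {tnorm!r}")
        return out, g

    def __repr__(self):
        return "AND(" + ", ".join(map(repr, self.children)) + ")"


class Or(Node):
    def __init__(self, *children: Node):
        if not children:
            raise ValueError("OR needs at least one operand")
        self.children = children

    def value_grad(self, A, tnorm):
        vals, grads = zip(*(c.value_grad(A, tnorm) for c in self.children))
        V = np.stack(vals)
        if tnorm == "lukasiewicz":
            s = V.sum(axis=0)
            out = np.minimum(1.0, s)
            w = np.where(s < 1, 1.0, np.where(s == 1, 0.5, 0.0))
            g = sum(gr * w[:, None] for gr in grads)
        elif tnorm == "minimum":
            out = V.max(axis=0)
            is_max = (V == out[None, :])
            share = is_max / is_max.sum(axis=0)[None, :]
            g = sum(gr * share[i][:, None] for i, gr in enumerate(grads))
        else:
            raise ValueError(f"unknown T-norm {tnorm!r}")
        return out, g

    def __repr__(self):
        return "OR(" + ", ".join(map(repr, self.children)) + ")"


@dataclass(frozen=True)
class Implies(Node):
    antecedent: Node
    consequent: Node

    def value_grad(self, A, tnorm):
        va, ga = self.antecedent.value_grad(A, tnorm)
        vb, gb = self.consequent.value_grad(A, tnorm)
        if tnorm == "lukasiewicz":
            s = 1.0 - va + vb
            out = np.minimum(1.0, s)
            w = np.where(s < 1, 1.0, np.where(s == 1, 0.5, 0.0))
            g = (gb - ga) * w[:, None]
        elif tnorm == "minimum":
            out = np.where(va <= vb, 1.0, vb)
            strict = va > vb
            tie = va == vb
            wb = np.where(strict, 1.0, np.where(tie, 0.5, 0.0))
            g = gb * wb[:, None]
        else:
            raise ValueError(f"unknown T-norm {tnorm!r}")
        return out, g

    def __repr__(self):
        return f"IMPLIES({self.antecedent!r}, {self.consequent!r})"


# ---------------------------------------------------------------------------
# grounded constraints


@dataclass
class TruthAssignment:
    """Values in [0,1] for every ground atom, with a known/target mask.

    Known atoms carry fixed crisp values; target atoms are free in [0,1].
    """

    atoms: list[tuple]
    values: np.ndarray
    known: np.ndarray
    index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.known = np.asarray(self.known, dtype=bool)
        if not (len(self.atoms) == self.values.size == self.known.size):
            raise ValueError("atoms/values/known lengths disagree")
        _check_unit(self.values)
        if not np.all(np.isin(self.values[self.known], (0.0, 1.0))):
            raise ValueError("known atoms must hold crisp values")
        self.index = {a: i for i, a in enumerate(self.atoms)}

    def __getitem__(self, atom):
        return float(self.values[self.index[atom]])

    def copy(self) -> "TruthAssignment":
        return TruthAssignment(list(self.atoms), self.values.copy(),
                               self.known.copy())


@dataclass
class Constraint:
    """A compiled rule: propositional body + grounding index matrix.

    ``groundings`` has shape (n_groundings, n_slots); entry (g, s) is the
    position, in the global truth-value vector, of the atom filling slot s in
    grounding g.  ``atoms`` gives the slot atoms per grounding for
    introspection.  Satisfaction is the mean body value over groundings
    (vacuously 1 when there are none).
    """

    name: str
    family: str
    body: Node
    atoms: list[list[tuple]]
    tnorm: str = "lukasiewicz"
    weight: float = 1.0

    def __post_init__(self):
        if self.tnorm not in TNORMS:
            raise ValueError(f"unknown T-norm {self.tnorm!r}")
        if self.weight < 0:
            raise ValueError("constraint weight must be >= 0")

    def grounding_matrix(self, assignment: TruthAssignment) -> np.ndarray:
        try:
            return np.array(
                [[assignment.index[a] for a in row] for row in self.atoms],
                dtype=int,
            ).reshape(len(self.atoms), -1)
        except KeyError as e:
            raise KeyError(f"constraint {self.name!r} references atom "
                           f"{e.args[0]!r} absent from the assignment")

    def grounding_values(self, assignment: TruthAssignment) -> np.ndarray:
        """Body value per grounding."""
        if not self.atoms:
            return np.empty(0)
        G = self.grounding_matrix(assignment)
        return self.body.value(assignment.values[G], self.tnorm)

    def satisfaction(self, assignment: TruthAssignment) -> float:
        vals = self.grounding_values(assignment)
        if vals.size == 0:
            return 1.0
        return float(vals.mean())

    def satisfaction_grad(self, assignment: TruthAssignment
                          ) -> tuple[float, np.ndarray]:
        """(Φ, dΦ/d value-vector); the gradient is scattered over atoms."""
        grad = np.zeros_like(assignment.values)
        if not self.atoms:
            return 1.0, grad
        G = self.grounding_matrix(assignment)
        v, g = self.body.value_grad(assignment.values[G], self.tnorm)
        np.add.at(grad, G.ravel(), (g / len(self.atoms)).ravel())
        return float(v.mean()), grad


def evaluate(constraint: Constraint, assignment: TruthAssignment) -> float:
    """Degree of satisfaction Φ in [0,1]; 1 for a vacuous constraint."""
    if not constraint.atoms:
        warnings.warn(f"constraint {constraint.name!r} has no groundings; "
                      "vacuously true")
    return constraint.satisfaction(assignment)


# ---------------------------------------------------------------------------
# rule compilation


def compile_go_rules(
    dag,
    proteins: Sequence[str],
    tnorm: str = "lukasiewicz",
    weight: float = 1.0,
    max_depth: int | None = None,
    explicit_converse: bool = False,
) -> list[Constraint]:
    """Hierarchy-consistency rules for every term, grounded over proteins.

    For every non-root term f:  Fun_f(p) => AND over parents f' of Fun_f'(p).
    For every non-leaf term f:  Fun_f(p) => OR over children f' of Fun_f'(p).
    The converse directions are consequences of the residuum semantics
    (contrapositive); ``explicit_converse`` adds them as separate formulas.
    ``max_depth`` restricts the rules to terms at that depth or above.
    """
    out: list[Constraint] = []
    proteins = list(proteins)
    for f in sorted(dag.terms):
        if max_depth is not None and dag.depth[f] > max_depth:
            continue
        parents = sorted(dag.parents(f))
        children = sorted(dag.children[f])
        if parents:
            body = Implies(Var(0), And(*(Var(i + 1) for i in range(len(parents)))))
            atoms = [[fun_atom(f, p)] + [fun_atom(fp, p) for fp in parents]
                     for p in proteins]
            out.append(Constraint(f"eq1[{f}]", "eq1", body, atoms, tnorm, weight))
            if explicit_converse:
                cbody = Implies(
                    Not(And(*(Var(i + 1) for i in range(len(parents))))),
                    Not(Var(0)))
                out.append(Constraint(f"eq1c[{f}]", "eq1", cbody,
                                      [list(a) for a in atoms], tnorm, weight))
        if children:
            body = Implies(Var(0), Or(*(Var(i + 1) for i in range(len(children)))))
            atoms = [[fun_atom(f, p)] + [fun_atom(fc, p) for fc in children]
                     for p in proteins]
            out.append(Constraint(f"eq2[{f}]", "eq2", body, atoms, tnorm, weight))
            if explicit_converse:
                cbody = Implies(
                    Not(Or(*(Var(i + 1) for i in range(len(children))))),
                    Not(Var(0)))
                out.append(Constraint(f"eq2c[{f}]", "eq2", cbody,
                                      [list(a) for a in atoms], tnorm, weight))
    return out


def compile_ppi_rules(
    dag,
    pairs: Sequence[tuple[str, str]],
    namespaces: Sequence[str] = ("BP", "CC"),
    levels: Sequence[int] = (1, 2, 3, 4, 5),
    tnorm: str = "lukasiewicz",
    weight: float = 1.0,
) -> list[Constraint]:
    """Function-interaction coupling rules.

    One constraint per (namespace, level l):
    Bound(p,p') => OR over terms f at depth l of (Fun_f(p) AND Fun_f(p')),
    grounded over the supplied pair list.  Applied to BP and CC only; levels
    with no terms are skipped with a warning.
    """
    from .ontology import terms_at_depth

    bad = set(namespaces) - {"BP", "CC"}
    if bad:
        raise ValueError(f"PPI rules apply to BP and CC only, got {bad}")
    if not levels:
        raise ValueError("levels must be nonempty")
    out: list[Constraint] = []
    pairs = list(pairs)
    for ns in namespaces:
        if ns not in dag.roots:
            continue
        for l in levels:
            terms = sorted(terms_at_depth(dag, ns, l))
            if not terms:
                warnings.warn(f"no {ns} terms at depth {l}; rule skipped")
                continue
            body = Implies(
                Var(0),
                Or(*(And(Var(2 * i + 1), Var(2 * i + 2))
                     for i in range(len(terms)))))
            atoms = []
            for p, q in pairs:
                row = [bound_atom(p, q)]
                for t in terms:
                    row += [fun_atom(t, p), fun_atom(t, q)]
                atoms.append(row)
            out.append(Constraint(f"eq3[{ns},{l}]", "eq3", body, atoms,
                                  tnorm, weight))
    return out


# ---------------------------------------------------------------------------
# rule-set serialization (versionable template listing)


def rules_to_text(constraints: Sequence[Constraint]) -> str:
    """Write the rule templates (one line per constraint) for versioning."""
    lines = ["# family\tname\ttnorm\tweight\tn_groundings\tbody"]
    for c in constraints:
        lines.append(
            f"{c.family}\t{c.name}\t{c.tnorm}\t{c.weight!r}\t"
            f"{len(c.atoms)}\t{c.body!r}")
    return "\n".join(lines) + "\n"
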