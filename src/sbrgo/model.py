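"""Kernel machines with semantic regularization.

Each predicate (one per retained GO term, plus one for the interaction
predicate) is a kernel machine f(x) = sum_i w_i K(x, x_i).  Training and
inference follow a two-stage strategy:

1. *Independent stage* — constraints are disabled and each machine minimizes
   a regularized supervised objective sum_k ||f_k||^2 + lambda_l L(y, f(X)),
   where ||f_k||^2 = w_k' G_k w_k.  With the quadratic-on-margin loss this is
   a convex problem solved to global optimality.
2. *Constrained stage* — the fuzzy rules are turned back on.  Either the
   weights themselves are refined by (sub)gradient descent on the full
   objective C_e (``fit_full``), or, at prediction time, the truth values are
   refined by *collective inference*, minimizing a prior-anchoring loss plus
   the weighted rule-violation terms, starting from the stage-1 predictions.

Estimators follow scikit-learn conventions (``get_params``/``set_params``,
fitted attributes with trailing underscores, precomputed-kernel ``fit``).
"""

from __future__ import annotations

import warnings
from typing import Callable, Sequence

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin

from .fuzzy import (Constraint, TruthAssignment, bound_atom, compile_go_rules,
                    compile_ppi_rules, fun_atom)
from .kernels import KernelMatrix, pairwise_kernel
from .ontology import NEGATIVE, POSITIVE, UNKNOWN, AnnotationTable, OntologyDAG


# ---------------------------------------------------------------------------
# squashes and losses


def _squash(margin: np.ndarray, kind: str) -> np.ndarray:
    if kind == "logistic":
        return expit(margin)
    if kind == "linear":
        return np.clip(margin, 0.0, 1.0)
    raise ValueError(f"unknown squash {kind!r}")


def _squash_grad(margin: np.ndarray, kind: str) -> np.ndarray:
    if kind == "logistic":
        s = _squash(margin, kind)
        return s * (1.0 - s)
    if kind == "linear":
        inside = (margin > 0) & (margin < 1)
        kink = (margin == 0) | (margin == 1)
        return inside.astype(float) + 0.5 * kink
    raise ValueError(f"unknown squash {kind!r}")


def _loss_grad(y: np.ndarray, margin: np.ndarray, loss: str, squash: str
               ) -> tuple[np.ndarray, np.ndarray]:
    """Per-atom supervised loss and its gradient w.r.t. the margin."""
    if loss == "squared":
        s = _squash(margin, squash)
        val = (y - s) ** 2
        grad = -2.0 * (y - s) * _squash_grad(margin, squash)
    elif loss == "squared_margin":
        val = (y - margin) ** 2
        grad = -2.0 * (y - margin)
    elif loss == "hinge":
        yy = 2.0 * y - 1.0
        m = 1.0 - yy * margin
        val = np.maximum(0.0, m)
        grad = -yy * (np.where(m > 0, 1.0, 0.0) + 0.5 * (m == 0))
    else:
        raise ValueError(f"unknown loss {loss!r}")
    return val, grad


# ---------------------------------------------------------------------------
# deterministic first-order optimizer


def minimize_gd(
    fun_grad: Callable[[np.ndarray], tuple[float, np.ndarray]],
    x0: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-6,
    project: Callable[[np.ndarray], np.ndarray] | None = None,
    step0: float = 1.0,
) -> tuple[np.ndarray, list[float]]:
    """Projected gradient descent with backtracking (Armijo) line search.

    Deterministic; the objective is non-increasing across iterations.  Stops
    on relative objective change below ``tol`` or a vanishing step.  Raises on
    ten consecutive non-decreasing accepted steps (divergence guard; cannot
    happen with backtracking unless ``fun_grad`` is inconsistent).
    """
    x = x0.copy()
    if project is not None:
        x = project(x)
    v, g = fun_grad(x)
    path = [v]
    step = step0
    bad = 0
    for _ in range(max_iter):
        gnorm2 = float(g @ g)
        if gnorm2 == 0.0:
            break
        accepted = False
        for _ in range(60):
            cand = x - step * g
            if project is not None:
                cand = project(cand)
            delta = cand - x
            if not np.any(delta):
                break
            vc, gc = fun_grad(cand)
            if vc <= v - 1e-4 / max(step, 1e-30) * float(delta @ delta):
                accepted = True
                break
            step *= 0.5
        if not accepted:
            break
        bad = bad + 1 if vc >= v else 0
        if bad >= 10:
            raise RuntimeError("optimizer diverged: objective not decreasing")
        stop = abs(v - vc) <= tol * (1.0 + abs(v))
        x, v, g = cand, vc, gc
        path.append(v)
        step = min(step * 2.0, 1e6)
        if stop:
            break
    return x, path


# ---------------------------------------------------------------------------
# single-predicate estimator


class KernelMachineClassifier(BaseEstimator, ClassifierMixin):
    """Binary kernel machine on a precomputed Gram matrix.

    Minimizes ``w' K w + lam_l * sum_i L(y_i, squash((Kw)_i))`` by
    deterministic full-batch gradient descent with backtracking.  With
    ``loss="squared_margin"`` the problem is the kernel ridge objective and
    the fit matches the closed-form solution.

    Parameters
    ----------
    lam_l : float
        Weight of the supervised loss term (must be > 0).
    loss : {"squared", "squared_margin", "hinge"}
        "squared" penalizes the squashed output, "squared_margin" the raw
        margin, "hinge" the +-1 margin.
    squash : {"logistic", "linear"}
        Monotone map from margin to [0,1] truth value.
    check_psd : bool
        Reject training kernels with eigenvalues below -1e-6.
    """

    def __init__(self, lam_l: float = 1.0, loss: str = "squared",
                 squash: str = "logistic", max_iter: int = 500,
                 tol: float = 1e-6, check_psd: bool = True,
                 random_state: int | None = None):
        self.lam_l = lam_l
        self.loss = loss
        self.squash = squash
        self.max_iter = max_iter
        self.tol = tol
        self.check_psd = check_psd
        self.random_state = random_state

    def fit(self, K, y, sample_mask=None):
        """Fit on a precomputed n x n Gram matrix and 0/1 labels.

        ``sample_mask`` marks the labeled entities; unmasked entities stay in
        the support (transductive setting) but contribute no loss.
        """
        K = np.asarray(K, dtype=float)
        y = np.asarray(y, dtype=float)
        n = K.shape[0]
        if K.shape != (n, n) or y.shape != (n,):
            raise ValueError("K must be square and aligned with y")
        if self.lam_l <= 0:
            raise ValueError("lam_l must be > 0")
        if self.check_psd and n and np.linalg.eigvalsh(K)[0] < -1e-6:
            raise ValueError("kernel matrix is not PSD (min eigenvalue < -1e-6)")
        mask = np.ones(n, bool) if sample_mask is None else \
            np.asarray(sample_mask, bool)

        def fg(w):
            m = K @ w
            lval, lgrad = _loss_grad(y, m, self.loss, self.squash)
            val = float(w @ m) + self.lam_l * float(lval[mask].sum())
            grad = 2.0 * m + self.lam_l * (K @ (lgrad * mask))
            return val, grad

        self.w_, self.objective_path_ = minimize_gd(
            fg, np.zeros(n), self.max_iter, self.tol)
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = n
        return self

    def decision_function(self, K):
        K = np.atleast_2d(np.asarray(K, dtype=float))
        return K @ self.w_

    def predict_proba(self, K):
        p = _squash(self.decision_function(K), self.squash)
        return np.column_stack([1.0 - p, p])

    def predict(self, K):
        return (self.predict_proba(K)[:, 1] >= 0.5).astype(int)


# ---------------------------------------------------------------------------
# collective inference


def collective_inference(
    assignment: TruthAssignment,
    constraints: Sequence[Constraint],
    prior: np.ndarray | None = None,
    frozen: np.ndarray | None = None,
    prior_weight: float = 1.0,
    max_iter: int = 1000,
    tol: float = 1e-8,
) -> TruthAssignment:
    """Minimize C_coll = L_coll(f̄, f) + sum_h lambda_h (1 - Phi_h(f̄)).

    ``prior`` defaults to the assignment's current values (the stage-1
    predictions, i.e. the warm start).  L_coll is the mean squared deviation
    from the prior over the free atoms, so prior anchoring and the
    grounding-averaged constraint terms live on comparable per-atom scales.
    Known atoms, and any extra ``frozen`` atoms, never move; free values are
    kept in [0,1] by projection.  The objective never increases.
    """
    prior = assignment.values.copy() if prior is None else \
        np.asarray(prior, dtype=float)
    frozen_mask = assignment.known.copy()
    if frozen is not None:
        frozen_mask |= np.asarray(frozen, bool)
    free = ~frozen_mask
    nfree = max(int(free.sum()), 1)
    base = assignment.values.copy()
    work = assignment.copy()

    def fg(x):
        work.values = x
        val = prior_weight * float(((x - prior)[free] ** 2).sum()) / nfree
        grad = np.zeros_like(x)
        grad[free] = 2.0 * prior_weight * (x - prior)[free] / nfree
        for c in constraints:
            phi, gphi = c.satisfaction_grad(work)
            val += c.weight * (1.0 - phi)
            grad -= c.weight * gphi
        grad[frozen_mask] = 0.0
        return val, grad

    def project(x):
        x = np.clip(x, 0.0, 1.0)
        x[frozen_mask] = base[frozen_mask]
        return x

    if not constraints:
        out = assignment.copy()
        out.values = project(prior.copy())
        return out

    x, _ = minimize_gd(fg, base, max_iter=max_iter, tol=tol, project=project)
    out = assignment.copy()
    out.values = x
    return out


# ---------------------------------------------------------------------------
# joint annotator


class SBRAnnotator(BaseEstimator):
    """Joint GO-term and interaction annotator with fuzzy consistency rules.

    One kernel machine per retained GO term plus one for the interaction
    predicate, mutually constrained by three rule families:

    * eq1 — a term implies all its parents (per protein);
    * eq2 — a term implies at least one of its children (per protein);
    * eq3 — interacting proteins share at least one term at each of the top
      levels of BP and CC (per pair).

    Parameters
    ----------
    rules : {"full", "go", "none"}
        "go" compiles eq1+eq2 only; "full" adds eq3; "none" disables the
        consistency layer entirely.
    lambda_go, lambda_ppi : float
        Constraint weights per family (uniform within a family).
    tnorm : {"lukasiewicz", "minimum"}
    go_rule_depth : int or None
        Restrict eq1/eq2 to terms at this depth or above (None = all).
    ppi_levels : sequence of int
        Depths at which eq3 is instantiated (default top 5 levels).
    clamp_bound : bool
        Freeze interaction atoms at their stage-1 values during collective
        inference, so function rules cannot move interaction predictions.
    full_training : bool
        After stage 1, refine the weights by subgradient descent on the full
        constrained objective C_e.
    """

    def __init__(self, lam_l: float = 10.0, loss: str = "squared",
                 squash: str = "logistic", tnorm: str = "lukasiewicz",
                 rules: str = "full", lambda_go: float = 1.0,
                 lambda_ppi: float = 1.0, go_rule_depth: int | None = None,
                 ppi_levels: tuple = (1, 2, 3, 4, 5),
                 ppi_namespaces: tuple = ("BP", "CC"),
                 clamp_bound: bool = True, full_training: bool = False,
                 max_iter: int = 500, coll_max_iter: int = 1000,
                 tol: float = 1e-6, check_psd: bool = True,
                 random_state: int | None = None):
        self.lam_l = lam_l
        self.loss = loss
        self.squash = squash
        self.tnorm = tnorm
        self.rules = rules
        self.lambda_go = lambda_go
        self.lambda_ppi = lambda_ppi
        self.go_rule_depth = go_rule_depth
        self.ppi_levels = ppi_levels
        self.ppi_namespaces = ppi_namespaces
        self.clamp_bound = clamp_bound
        self.full_training = full_training
        self.max_iter = max_iter
        self.coll_max_iter = coll_max_iter
        self.tol = tol
        self.check_psd = check_psd
        self.random_state = random_state

    # -- fitting --------------------------------------------------------------

    def fit(self, kernel: KernelMatrix, dag: OntologyDAG,
            annotations: AnnotationTable,
            pairs: Sequence[tuple[str, str]] | None = None,
            pair_labels: Sequence[int] | None = None,
            pair_kernel: KernelMatrix | None = None):
        """Fit all kernel machines.

        ``annotations`` provides 1/0/unknown labels over ``kernel.index``
        (unknown protein-term atoms contribute no supervised loss but remain
        in the support: the transductive setting).  ``pairs``/``pair_labels``
        supply the interaction supervision; the pairwise kernel is derived
        from the protein kernel unless given.
        """
        if self.rules not in ("full", "go", "none"):
            raise ValueError(f"unknown rules setting {self.rules!r}")
        self.proteins_ = list(kernel.index)
        self.terms_ = sorted(dag.terms)
        self.dag_ = dag
        self.kernel_ = kernel
        P, T = len(self.proteins_), len(self.terms_)

        Y = np.zeros((P, T))
        M = np.zeros((P, T), bool)
        for ip, p in enumerate(self.proteins_):
            for it, t in enumerate(self.terms_):
                v = annotations.get(p, t)
                if v != UNKNOWN:
                    Y[ip, it] = float(v == POSITIVE)
                    M[ip, it] = True
        self._Y, self._M = Y, M

        K = kernel.values
        if self.check_psd and np.linalg.eigvalsh(K)[0] < -1e-6:
            raise ValueError("protein kernel is not PSD (min eig < -1e-6)")

        def fg(wflat):
            W = wflat.reshape(P, T)
            Marg = K @ W
            lval, lgrad = _loss_grad(Y, Marg, self.loss, self.squash)
            val = float(np.einsum("ij,ij->", W, Marg)) \
                + self.lam_l * float(lval[M].sum())
            grad = 2.0 * Marg + self.lam_l * (K @ (lgrad * M))
            return val, grad.ravel()

        wflat, self.stage1_path_ = minimize_gd(
            fg, np.zeros(P * T), self.max_iter, self.tol)
        self.W_ = wflat.reshape(P, T)

        self.pairs_ = [tuple(sorted(p)) for p in pairs] if pairs else []
        if self.pairs_:
            self.pair_kernel_ = pair_kernel if pair_kernel is not None else \
                pairwise_kernel(kernel, self.pairs_)
            yb = np.array([float(v) if v in (0, 1) else np.nan
                           for v in pair_labels], dtype=float) \
                if pair_labels is not None else np.full(len(self.pairs_), np.nan)
            mb = ~np.isnan(yb)
            machine = KernelMachineClassifier(
                self.lam_l, self.loss, self.squash, self.max_iter, self.tol,
                self.check_psd)
            machine.fit(self.pair_kernel_.values, np.nan_to_num(yb), mb)
            self.bound_machine_ = machine
            self.wb_ = machine.w_
            self._yb, self._mb = np.nan_to_num(yb), mb
        else:
            self.pair_kernel_ = None
            self.wb_ = np.zeros(0)
            self._yb = np.zeros(0)
            self._mb = np.zeros(0, bool)

        self.constraints_ = self._compile_constraints()
        if self.full_training and self.constraints_:
            self._fit_full()
        return self

    def _compile_constraints(self) -> list[Constraint]:
        cons: list[Constraint] = []
        if self.rules in ("go", "full"):
            cons += compile_go_rules(self.dag_, self.proteins_, self.tnorm,
                                     self.lambda_go, self.go_rule_depth)
        if self.rules == "full" and self.pairs_:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cons += compile_ppi_rules(self.dag_, self.pairs_,
                                          self.ppi_namespaces,
                                          tuple(self.ppi_levels), self.tnorm,
                                          self.lambda_ppi)
        return cons

    # -- the full constrained objective ---------------------------------------

    def _atoms(self) -> list[tuple]:
        atoms = [fun_atom(t, p) for t in self.terms_ for p in self.proteins_]
        atoms += [bound_atom(p, q) for p, q in self.pairs_]
        return atoms

    def _assignment_from_margins(self, Marg: np.ndarray, mb: np.ndarray,
                                 clamp_labels: bool) -> TruthAssignment:
        values = np.concatenate([
            _squash(Marg, self.squash).T.ravel(),
            _squash(mb, self.squash) if mb.size else mb,
        ])
        known = np.zeros(values.size, bool)
        if clamp_labels:
            known[:Marg.size] = self._M.T.ravel()
            values[:Marg.size][self._M.T.ravel()] = self._Y.T.ravel()[
                self._M.T.ravel()]
            if mb.size:
                known[Marg.size:] = self._mb
                values[Marg.size:][self._mb] = self._yb[self._mb]
        return TruthAssignment(self._atoms(), values, known)

    def objective_and_grad(self, W: np.ndarray, wb: np.ndarray
                           ) -> tuple[float, np.ndarray, np.ndarray]:
        """Full objective C_e and its (sub)gradient w.r.t. all weights.

        C_e = sum_k ||f_k||^2 + lam_l L(y, f(X)) + sum_h lambda_h (1 - Phi_h),
        with the constraint terms evaluated on the squashed margins of every
        atom (labeled and unlabeled alike).
        """
        K = self.kernel_.values
        P, T = len(self.proteins_), len(self.terms_)
        Marg = K @ W
        lval, lgrad = _loss_grad(self._Y, Marg, self.loss, self.squash)
        val = float(np.einsum("ij,ij->", W, Marg)) \
            + self.lam_l * float(lval[self._M].sum())
        gM = 2.0 * Marg + self.lam_l * (K @ (lgrad * self._M))

        if self.pairs_:
            Kp = self.pair_kernel_.values
            mb = Kp @ wb
            lvb, lgb = _loss_grad(self._yb, mb, self.loss, self.squash)
            val += float(wb @ mb) + self.lam_l * float(lvb[self._mb].sum())
            gb = 2.0 * mb + self.lam_l * (Kp @ (lgb * self._mb))
        else:
            mb = np.zeros(0)
            gb = np.zeros(0)

        if self.constraints_:
            assign = self._assignment_from_margins(Marg, mb, clamp_labels=False)
            gv = np.zeros_like(assign.values)
            for c in self.constraints_:
                phi, gphi = c.satisfaction_grad(assign)
                val += c.weight * (1.0 - phi)
                gv -= c.weight * gphi
            gfun = gv[:P * T].reshape(T, P).T * _squash_grad(Marg, self.squash)
            gM += K @ gfun
            if self.pairs_:
                gb += self.pair_kernel_.values @ (
                    gv[P * T:] * _squash_grad(mb, self.squash))
        # d margin / d w through the (symmetric) Gram matrix
        return val, gM, gb

    def _fit_full(self) -> None:
        P, T = len(self.proteins_), len(self.terms_)
        nb = self.wb_.size

        def fg(x):
            W = x[:P * T].reshape(P, T)
            wb = x[P * T:]
            v, gW, gb = self.objective_and_grad(W, wb)
            return v, np.concatenate([gW.ravel(), gb])

        x0 = np.concatenate([self.W_.ravel(), self.wb_])
        x, self.full_path_ = minimize_gd(fg, x0, self.max_iter, self.tol)
        assert self.full_path_[-1] <= self.full_path_[0] + 1e-12
        self.W_ = x[:P * T].reshape(P, T)
        self.wb_ = x[P * T:]

    # -- prediction -----------------------------------------------------------

    def margins_(self) -> tuple[np.ndarray, np.ndarray]:
        Marg = self.kernel_.values @ self.W_
        mb = self.pair_kernel_.values @ self.wb_ if self.pairs_ else np.zeros(0)
        return Marg, mb

    def predict_assignment(self, mode: str = "transductive"
                           ) -> TruthAssignment:
        """Truth values for every Fun and Bound atom.

        inductive — squashed stage margins;
        transductive — collective inference from the stage-1 predictions with
        training labels clamped (equals inductive when no rules are active).
        """
        Marg, mb = self.margins_()
        if mode == "inductive":
            return self._assignment_from_margins(Marg, mb, clamp_labels=False)
        if mode != "transductive":
            raise ValueError(f"unknown mode {mode!r}")
        assign = self._assignment_from_margins(Marg, mb, clamp_labels=True)
        frozen = None
        if self.clamp_bound and self.pairs_:
            frozen = np.zeros(assign.values.size, bool)
            frozen[len(self.proteins_) * len(self.terms_):] = True
        return collective_inference(
            assign, self.constraints_, frozen=frozen,
            max_iter=self.coll_max_iter, tol=self.tol * 1e-2)

    def predict_scores(self, mode: str = "transductive"):
        """(protein x term score matrix, pair score vector) as ndarrays."""
        assign = self.predict_assignment(mode)
        P, T = len(self.proteins_), len(self.terms_)
        S = assign.values[:P * T].reshape(T, P).T
        sb = assign.values[P * T:]
        return S, sb
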