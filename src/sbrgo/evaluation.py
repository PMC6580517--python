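"""CAFA-style protein-centric and term-centric evaluation.

Protein-centric: Fmax (threshold-optimized F1), Smin (minimum semantic
distance from remaining uncertainty ru and misinformation mi, weighted by
term information content), plus precision/recall/F1 at the natural decision
threshold tau = 0.5.  Term-centric: mean ROC AUC over terms.  All metrics can
be broken down by term depth.

Scores enter as a pandas DataFrame (rows = proteins, columns = terms, values
in [0,1]); truth as a boolean DataFrame of the same shape.  Terms absent from
the score matrix contribute to no metric.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .ontology import POSITIVE, AnnotationTable, OntologyDAG, terms_at_depth


def table_to_frame(table: AnnotationTable, terms) -> pd.DataFrame:
    """Boolean protein x term truth frame from an annotation table."""
    terms = list(terms)
    data = np.zeros((len(table.proteins), len(terms)), bool)
    for ip, p in enumerate(table.proteins):
        for it, t in enumerate(terms):
            data[ip, it] = table.get(p, t) == POSITIVE
    return pd.DataFrame(data, index=list(table.proteins), columns=terms)


def _align(scores: pd.DataFrame, truth: pd.DataFrame
           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    if not scores.index.equals(truth.index) or \
            not scores.columns.equals(truth.columns):
        truth = truth.reindex(index=scores.index, columns=scores.columns,
                              fill_value=False)
    return scores, truth.astype(bool)


def precision_recall(scores: pd.DataFrame, truth: pd.DataFrame, tau: float
                     ) -> tuple[float, float, int, int]:
    """(pr, rc, m, n) at threshold tau.

    P_i(tau) = terms with score >= tau.  Precision averages |P∩T|/|P| over
    the m proteins with nonempty P_i; recall averages |P∩T|/|T| over the n
    proteins with nonempty truth sets (proteins with no true annotations are
    excluded from the recall denominator).
    """
    if not 0.0 <= tau <= 1.0:
        raise ValueError("tau must lie in [0, 1]")
    scores, truth = _align(scores, truth)
    P = scores.values >= tau
    T = truth.values
    np_i = P.sum(axis=1)
    nt_i = T.sum(axis=1)
    tp_i = (P & T).sum(axis=1)
    has_pred = np_i > 0
    has_truth = nt_i > 0
    m = int(has_pred.sum())
    n = int(has_truth.sum())
    pr = float((tp_i[has_pred] / np_i[has_pred]).mean()) if m else 0.0
    rc = float((tp_i[has_truth] / nt_i[has_truth]).mean()) if n else 0.0
    return pr, rc, m, n


def _f1(pr: float, rc: float) -> float:
    return 0.0 if pr + rc == 0 else 2.0 * pr * rc / (pr + rc)


def default_grid(scores: pd.DataFrame | None = None) -> np.ndarray:
    """101 evenly spaced thresholds, plus the distinct scores when few."""
    grid = np.linspace(0.0, 1.0, 101)
    if scores is not None:
        distinct = np.unique(np.round(scores.values.ravel(), 12))
        if distinct.size <= 1000:
            grid = np.unique(np.concatenate([grid, distinct]))
    return grid


def f_max(scores: pd.DataFrame, truth: pd.DataFrame,
          grid: np.ndarray | None = None) -> tuple[float, float]:
    """Maximum F1 over the threshold grid and the maximizing tau."""
    grid = default_grid(scores) if grid is None else np.asarray(grid, float)
    best, best_tau = 0.0, float(grid[0])
    for tau in grid:
        pr, rc, m, _ = precision_recall(scores, truth, float(tau))
        if m == 0:
            continue
        f1 = _f1(pr, rc)
        if f1 > best:
            best, best_tau = f1, float(tau)
    return best, best_tau


def f1_at(scores: pd.DataFrame, truth: pd.DataFrame, tau: float = 0.5
          ) -> float:
    pr, rc, _, _ = precision_recall(scores, truth, tau)
    return _f1(pr, rc)


def information_content(truth: AnnotationTable, dag: OntologyDAG,
                        variant: str = "conditional") -> dict[str, float]:
    """Term information content from a propagation-closed truth table.

    conditional (default, information-accretion style):
        ic(f) = -log2( n(f) / n(parents of f) ), where n(parents) counts the
        proteins positive for every parent of f; roots get ic 0.
    marginal: ic(f) = -log2( n(f) / n(proteins) ).
    Terms with no annotated protein are excluded with a warning.
    """
    if variant not in ("conditional", "marginal"):
        raise ValueError(f"unknown ic variant {variant!r}")
    pos = {t: truth.positives_for_term(t) for t in dag.terms}
    out: dict[str, float] = {}
    for t in dag.terms:
        n_t = len(pos[t])
        if n_t == 0:
            warnings.warn(f"term {t!r} has no annotated proteins; ic undefined")
            continue
        parents = dag.parents(t)
        if not parents:
            out[t] = 0.0
            continue
        if variant == "marginal":
            denom = len(truth.proteins)
        else:
            eligible = set(truth.proteins)
            for par in parents:
                eligible &= pos[par]
            denom = len(eligible)
        out[t] = float(max(0.0, -np.log2(n_t / denom)))
    return out


def s_min(scores: pd.DataFrame, truth: pd.DataFrame, ic: dict[str, float],
          grid: np.ndarray | None = None, printed_minus: bool = False
          ) -> tuple[float, float]:
    """Minimum semantic distance min_tau sqrt(ru^2 + mi^2) and its tau.

    ru(tau) — mean over proteins of the ic mass of missed true terms;
    mi(tau) — mean ic mass of falsely predicted terms.  ``printed_minus``
    switches to sqrt(max(0, ru^2 - mi^2)), a variant kept for comparison.
    Terms without an ic value are ignored.
    """
    scores, truth = _align(scores, truth)
    cols = [t for t in scores.columns if t in ic]
    S = scores[cols].values
    T = truth[cols].values
    w = np.array([ic[t] for t in cols])
    n = max(S.shape[0], 1)
    grid = default_grid(scores) if grid is None else np.asarray(grid, float)
    best, best_tau = np.inf, float(grid[0])
    for tau in grid:
        P = S >= tau
        ru = float((w * (~P & T)).sum()) / n
        mi = float((w * (P & ~T)).sum()) / n
        if printed_minus:
            d = float(np.sqrt(max(0.0, ru ** 2 - mi ** 2)))
        else:
            d = float(np.sqrt(ru ** 2 + mi ** 2))
        if d < best:
            best, best_tau = d, float(tau)
    return best, best_tau


def term_auc(scores: pd.DataFrame, truth: pd.DataFrame
             ) -> dict[str, float]:
    """Rank-based (Mann-Whitney) ROC AUC per term; ties get half credit.

    Terms with a single class among the proteins are excluded with a warning.
    """
    scores, truth = _align(scores, truth)
    out: dict[str, float] = {}
    for t in scores.columns:
        y = truth[t].values
        if y.all() or not y.any():
            warnings.warn(f"term {t!r} has a single class; AUC undefined")
            continue
        out[t] = float(roc_auc_score(y, scores[t].values))
    return out


# ---------------------------------------------------------------------------
# report


@dataclass
class EvalReport:
    """Per-namespace (and per-depth) metric rows plus the ic table used."""

    rows: list[dict] = field(default_factory=list)
    ic: dict[str, float] = field(default_factory=dict)

    COLUMNS = ("namespace", "depth", "n_terms", "fmax", "tau_fmax", "smin",
               "tau_smin", "precision_05", "recall_05", "f1_05", "mean_auc")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=list(self.COLUMNS))

    def to_tsv(self) -> str:
        return self.to_frame().to_csv(sep="\t", index=False,
                                      float_format="%.6f")

    def to_json(self) -> str:
        return json.dumps({"rows": self.rows,
                           "ic": {k: float(v) for k, v in self.ic.items()}},
                          indent=2, sort_keys=True)


def _metric_row(scores: pd.DataFrame, truth: pd.DataFrame,
                ic: dict[str, float], ns: str, depth) -> dict:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fmax, tau_f = f_max(scores, truth)
        smin, tau_s = s_min(scores, truth, ic)
        pr, rc, _, _ = precision_recall(scores, truth, 0.5)
        aucs = term_auc(scores, truth)
    return {
        "namespace": ns, "depth": depth, "n_terms": scores.shape[1],
        "fmax": fmax, "tau_fmax": tau_f, "smin": smin, "tau_smin": tau_s,
        "precision_05": pr, "recall_05": rc, "f1_05": _f1(pr, rc),
        "mean_auc": float(np.mean(list(aucs.values()))) if aucs else np.nan,
    }


def per_depth_report(scores: pd.DataFrame, truth_table: AnnotationTable,
                     dag: OntologyDAG, ic_variant: str = "conditional"
                     ) -> EvalReport:
    """Overall and per-depth metrics, namespaces reported separately.

    Only terms present in both the score matrix and the DAG enter the
    report; each depth row restricts the matrices to terms_at_depth.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ic = information_content(truth_table, dag, ic_variant)
    truth = table_to_frame(truth_table, scores.columns)
    report = EvalReport(ic=ic)
    for ns in dag.namespaces():
        ns_terms = [t for t in scores.columns if t in dag.terms
                    and dag.namespace[t] == ns]
        if not ns_terms:
            continue
        report.rows.append(_metric_row(scores[ns_terms], truth[ns_terms],
                                       ic, ns, "all"))
        max_d = max(dag.depth[t] for t in ns_terms)
        for l in range(max_d + 1):
            lvl = [t for t in ns_terms if t in terms_at_depth(dag, ns, l)]
            if not lvl:
                continue
            report.rows.append(_metric_row(scores[lvl], truth[lvl],
                                           ic, ns, l))
    return report
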