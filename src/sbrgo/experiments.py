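"""Reference experiments on synthetic genomes.

Two studies used by the test suite and the reproduction script:

* :func:`rule_variant_study` — train the annotator with no rules, hierarchy
  rules only, and the full rule set on the same genomes, and compare
  protein-centric F1 at the natural threshold per ontology depth, plus
  held-out interaction F1.  The qualitative expectation is that the
  consistency layer helps most at the deepest levels, while interaction
  predictions are unaffected by the function rules.
* :func:`violation_study` — measure the fraction of thresholded predictions
  violating the terms-imply-parents rule before and after collective
  inference.

Both are deterministic given their seeds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import f1_at, table_to_frame
from .kernels import pairwise_kernel
from .model import SBRAnnotator
from .pipeline import build_kernel, masked_table
from .synthetic import SyntheticGenomeSpec, generate_genome, \
    sample_negative_pairs

VARIANTS = ("none", "go", "full")


def _prepare(seed: int, n_proteins: int, coupling: float,
             test_fraction: float = 0.2):
    """One synthetic genome with a held-out protein and pair split."""
    spec = SyntheticGenomeSpec(n_proteins=n_proteins, ppi_coupling=coupling,
                               seed=seed)
    dag, table, features, pos = generate_genome(spec)
    neg = sample_negative_pairs(pos, table.proteins, seed=seed + 1000)
    pairs = [tuple(sorted(p)) for p in pos + neg]
    labels = [1] * len(pos) + [0] * len(neg)
    K = build_kernel(features)
    pk = pairwise_kernel(K, pairs)
    rng = np.random.default_rng(seed + 2000)
    n_test = int(round(test_fraction * len(table.proteins)))
    test = set(rng.choice(table.proteins, n_test, replace=False))
    test_pairs = {p for p in pairs if p[0] in test or p[1] in test}
    train_table = masked_table(table, test)
    masked_labels = [None if p in test_pairs else l
                     for p, l in zip(pairs, labels)]
    return dict(dag=dag, table=table, K=K, pk=pk, pairs=pairs, labels=labels,
                test=test, test_pairs=test_pairs, train_table=train_table,
                masked_labels=masked_labels, spec=spec)


def _pair_f1(pairs, labels, scores, subset) -> float:
    idx = [i for i, p in enumerate(pairs) if p in subset]
    y = np.array([labels[i] for i in idx])
    p = (scores[idx] >= 0.5).astype(int)
    tp = int(((p == 1) & (y == 1)).sum())
    fp = int(((p == 1) & (y == 0)).sum())
    fn = int(((p == 0) & (y == 1)).sum())
    return 0.0 if 2 * tp + fp + fn == 0 else 2 * tp / (2 * tp + fp + fn)


@dataclass
class VariantResult:
    """Per-variant, per-seed outcomes of the rule comparison."""

    depths: list[int]
    f1_by_depth: dict[str, np.ndarray]   # variant -> (n_seeds, n_depths)
    ppi_f1: dict[str, np.ndarray]        # variant -> (n_seeds,)

    def mean_f1(self, variant: str) -> np.ndarray:
        return self.f1_by_depth[variant].mean(axis=0)

    def mean_ppi_f1(self, variant: str) -> float:
        return float(self.ppi_f1[variant].mean())


def run_variant_on_genome(data: dict, rules: str,
                          ppi_levels=(1, 2, 3), **model_kw
                          ) -> tuple[dict[int, float], float]:
    """Fit one rule variant; return test-fold F1 per depth and pair F1."""
    dag = data["dag"]
    model = SBRAnnotator(rules=rules, ppi_levels=ppi_levels, **model_kw)
    model.fit(data["K"], dag, data["train_table"], data["pairs"],
              data["masked_labels"], pair_kernel=data["pk"])
    S, sb = model.predict_scores("transductive")
    scores = pd.DataFrame(S, index=model.proteins_, columns=model.terms_)
    truth = table_to_frame(data["table"], model.terms_)
    te = sorted(data["test"])
    depths = sorted({dag.depth[t] for t in model.terms_} - {0})
    f1s = {}
    for l in depths:
        terms = [t for t in model.terms_ if dag.depth[t] == l]
        f1s[l] = f1_at(scores.loc[te, terms], truth.loc[te, terms])
    ppi = _pair_f1(data["pairs"], data["labels"], sb, data["test_pairs"])
    return f1s, ppi


def rule_variant_study(seeds=range(10), n_proteins: int = 200,
                       coupling: float = 0.8, ppi_levels=(1, 2, 3),
                       **model_kw) -> VariantResult:
    """Compare no-rules / hierarchy-rules / full-rules over several genomes."""
    rows = {v: [] for v in VARIANTS}
    ppis = {v: [] for v in VARIANTS}
    depths = None
    for seed in seeds:
        data = _prepare(int(seed), n_proteins, coupling)
        for v in VARIANTS:
            f1s, ppi = run_variant_on_genome(data, v, ppi_levels, **model_kw)
            if depths is None:
                depths = sorted(f1s)
            rows[v].append([f1s[l] for l in depths])
            ppis[v].append(ppi)
    return VariantResult(depths,
                         {v: np.array(rows[v]) for v in VARIANTS},
                         {v: np.array(ppis[v]) for v in VARIANTS})


def eq1_violation_fraction(S: np.ndarray, model: SBRAnnotator,
                           tau: float = 0.5) -> float:
    """Fraction of (protein, child-term) slots predicted positive at *tau*
    while some parent is predicted negative."""
    dag = model.dag_
    ti = {t: i for i, t in enumerate(model.terms_)}
    P = S >= tau
    viol = total = 0
    for t in model.terms_:
        for parent in dag.parents(t):
            viol += int((P[:, ti[t]] & ~P[:, ti[parent]]).sum())
            total += S.shape[0]
    return viol / total if total else 0.0


def violation_study(seed: int = 0, n_proteins: int = 120,
                    lambda_go: float = 10.0) -> dict[str, float]:
    """Eq-1 violation fractions, unconstrained vs collectively constrained."""
    data = _prepare(int(seed), n_proteins, coupling=0.8)
    base = SBRAnnotator(rules="none")
    base.fit(data["K"], data["dag"], data["train_table"], data["pairs"],
             data["masked_labels"], pair_kernel=data["pk"])
    S0, _ = base.predict_scores("inductive")
    cons = SBRAnnotator(rules="go", lambda_go=lambda_go)
    cons.fit(data["K"], data["dag"], data["train_table"], data["pairs"],
             data["masked_labels"], pair_kernel=data["pk"])
    S1, _ = cons.predict_scores("transductive")
    return {
        "unconstrained": eq1_violation_fraction(S0, base),
        "constrained": eq1_violation_fraction(S1, cons),
    }
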