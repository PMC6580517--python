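"""End-to-end plumbing shared by the CLI and the scripts.

Ties together the synthetic generator, kernel construction, model fitting,
cross-validation and evaluation so that a full run is reproducible from
(config, seed) alone.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .evaluation import per_depth_report, table_to_frame
from .kernels import (GenomeFeatures, KernelMatrix, average_kernels,
                      coexpression_kernel, colocalization_kernel,
                      diffusion_kernel, domain_kernel, normalize,
                      pairwise_kernel, precondition, spectrum_kernel)
from .model import SBRAnnotator
from .ontology import UNKNOWN, AnnotationTable, OntologyDAG
from .synthetic import (FoldSplit, SyntheticGenomeSpec, generate_genome,
                        make_folds, sample_negative_pairs)


def build_kernel(features: GenomeFeatures, gamma: float = 1.0,
                 beta: float = 1.0, eps: float = 1e-6, spectrum_k: int = 3,
                 extra: list[KernelMatrix] | None = None) -> KernelMatrix:
    """Normalize, precondition and average every available kernel source."""
    parts: list[KernelMatrix] = []
    if features.positions is not None:
        parts.append(colocalization_kernel(features, gamma))
    if features.complex_graph is not None:
        parts.append(diffusion_kernel(features, beta))
    if features.expression is not None:
        parts.append(coexpression_kernel(features))
    if features.domains is not None:
        parts.append(domain_kernel(features))
    if features.sequences is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            parts.append(spectrum_kernel(features.sequences,
                                         features.proteins, spectrum_k))
    parts += list(extra or [])
    if not parts:
        raise ValueError("no kernel sources available")
    parts = [precondition(normalize(K, on_zero_diag="isolate"), eps)
             for K in parts]
    return average_kernels(parts)


def simulate_dataset(spec: SyntheticGenomeSpec, outdir) -> None:
    """Generate a genome and write every file the pipeline reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dag, table, features, positives = generate_genome(spec)
    negatives = sample_negative_pairs(positives, table.proteins,
                                      spec.n_negative_ppi_ratio,
                                      seed=spec.seed + 1)
    pairs = positives + negatives
    labels = [1] * len(positives) + [0] * len(negatives)
    sio.write_ontology_file(dag, outdir / "ontology.obo")
    sio.write_annotations(table, outdir / "annotations.tsv")
    sio.write_edges(pairs, outdir / "ppi.tsv", labels)
    sio.write_features(features, outdir)
    cfg = sio.RunConfig(seed=spec.seed)
    sio.write_config(cfg, outdir / "config.yaml")


def load_dataset(cfg: sio.RunConfig, base) -> tuple[
        OntologyDAG, AnnotationTable, GenomeFeatures, list, list]:
    base = Path(base)
    dag = sio.read_ontology_file(base / cfg.ontology)
    table = sio.read_annotations(base / cfg.annotations)
    pairs, labels = sio.read_edges(base / cfg.ppi, labeled=True)
    features = sio.read_features(base / cfg.features_dir, table.proteins)
    return dag, table, features, pairs, labels


def masked_table(table: AnnotationTable, hidden: set[str]) -> AnnotationTable:
    """Copy of *table* with every atom of the hidden proteins set to unknown."""
    out = AnnotationTable(list(table.proteins), default=UNKNOWN)
    for (p, t), v in table.values.items():
        out.values[(p, t)] = UNKNOWN if p in hidden else v
    return out


def fit_predict_fold(
    kernel: KernelMatrix, dag: OntologyDAG, table: AnnotationTable,
    pairs, labels, test_proteins: set[str], test_pairs: set,
    model_kwargs: dict, mode: str = "transductive",
    pair_kernel: KernelMatrix | None = None,
) -> tuple[pd.DataFrame, pd.Series, SBRAnnotator]:
    """Train with one fold hidden; return test-fold scores."""
    train_table = masked_table(table, test_proteins)
    masked_labels = [UNKNOWN if tuple(sorted(p)) in test_pairs else l
                     for p, l in zip(pairs, labels)]
    model = SBRAnnotator(**model_kwargs)
    model.fit(kernel, dag, train_table, pairs,
              [None if l == UNKNOWN else l for l in masked_labels],
              pair_kernel=pair_kernel)
    S, sb = model.predict_scores(mode)
    scores = pd.DataFrame(S, index=model.proteins_, columns=model.terms_)
    pair_scores = pd.Series(sb, index=pd.Index(model.pairs_))
    return scores, pair_scores, model


def crossval(cfg: sio.RunConfig, base, K: int | None = None,
             seed: int | None = None) -> dict:
    """K-fold cross-validation; returns scores, pair scores and the report.

    Folds are built by the greedy balanced procedure; each fold is held out
    in turn (labels masked, entities retained in the kernel index), the model
    is fit and the held-out scores are collected.
    """
    dag, table, features, pairs, labels = load_dataset(cfg, base)
    K = K if K is not None else cfg.folds
    seed = seed if seed is not None else cfg.seed
    kernel = sio.read_kernel_file(Path(base) / cfg.kernel) if cfg.kernel \
        else build_kernel(features, cfg.gamma, cfg.beta, cfg.eps,
                          cfg.spectrum_k)
    pk = pairwise_kernel(kernel, [tuple(sorted(p)) for p in pairs], cfg.eps)
    folds = make_folds(table, pairs, labels, K, seed)
    all_scores: list[pd.DataFrame] = []
    all_pair_scores: list[pd.Series] = []
    kwargs = cfg.model_kwargs()
    for k in range(K):
        test_p = set(folds.proteins_in(k))
        test_e = set(folds.pairs_in(k))
        scores, pscores, _ = fit_predict_fold(
            kernel, dag, table, pairs, labels, test_p, test_e, kwargs,
            cfg.mode, pair_kernel=pk)
        all_scores.append(scores.loc[sorted(test_p)])
        mask = [p in test_e for p in pscores.index]
        all_pair_scores.append(pscores[mask])
    scores = pd.concat(all_scores).sort_index()
    pair_scores = pd.concat(all_pair_scores)
    report = per_depth_report(scores, table, dag)
    return {"scores": scores, "pair_scores": pair_scores, "report": report,
            "folds": folds, "truth": table, "dag": dag,
            "pairs": pairs, "labels": labels}
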