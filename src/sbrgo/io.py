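"""Readers and writers for every on-disk format, plus the run configuration.

Dialects (all UTF-8, tab-separated, LF-normalized on write):

* annotation TSV — header ``protein_id<TAB>term_id<TAB>value`` with value in
  {1, 0}; unknown atoms are simply absent.
* edge TSV — header ``protein_a<TAB>protein_b[<TAB>label]``.
* positions TSV — ``protein<TAB>chromosome<TAB>start<TAB>end`` (1-based
  inclusive coordinates; the centroid is the midpoint of start/end).
* expression TSV — proteins x conditions matrix with header row.
* domains TSV — ``protein<TAB>domain_id`` membership list.
* FASTA — via Biopython.
* kernel TSV — square matrix with matching header row/column of ids
  (see :mod:`sbrgo.kernels`); round-trips bit-exactly.
* scores TSV — ``protein<TAB>term<TAB>score``; the interchange surface
  between prediction and evaluation.
* model bundle — a directory with a JSON manifest and an .npz of arrays.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .kernels import GenomeFeatures, KernelMatrix
from .ontology import (NEGATIVE, POSITIVE, AnnotationTable, OntologyDAG,
                       load_ontology, write_obo)

CONFIG_VERSION = 1


class FormatError(ValueError):
    """Malformed on-disk input, reported with a line number."""


def _read_lines(path) -> list[str]:
    text = Path(path).read_text(encoding="utf-8")
    return text.replace("\r\n", "\n").rstrip("\n").split("\n")


# ---------------------------------------------------------------------------
# annotations


def read_annotations(path, proteins: Sequence[str] | None = None,
                     default: int = NEGATIVE) -> AnnotationTable:
    lines = _read_lines(path)
    if lines[0].split("\t")[:2] != ["protein_id", "term_id"]:
        raise FormatError(f"{path}: line 1: missing annotation header")
    values: dict[tuple[str, str], int] = {}
    seen: list[str] = []
    for ln, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(f"{path}: line {ln}: expected 3 columns")
        p, t, v = parts
        if v not in ("0", "1"):
            raise FormatError(f"{path}: line {ln}: value must be 0 or 1")
        if p not in values and p not in seen:
            seen.append(p)
        values[(p, t)] = POSITIVE if v == "1" else NEGATIVE
    prots = list(proteins) if proteins is not None else seen
    return AnnotationTable(prots, values, default=default)


def write_annotations(table: AnnotationTable, path) -> None:
    rows = ["protein_id\tterm_id\tvalue"]
    for (p, t), v in sorted(table.values.items()):
        rows.append(f"{p}\t{t}\t{1 if v == POSITIVE else 0}")
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# edges


def read_edges(path, labeled: bool = False):
    lines = _read_lines(path)
    want = 3 if labeled else 2
    if len(lines[0].split("\t")) != want:
        raise FormatError(f"{path}: line 1: expected {want}-column header")
    pairs, labels = [], []
    for ln, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != want:
            raise FormatError(f"{path}: line {ln}: expected {want} columns")
        pairs.append((parts[0], parts[1]))
        if labeled:
            if parts[2] not in ("0", "1"):
                raise FormatError(f"{path}: line {ln}: label must be 0 or 1")
            labels.append(int(parts[2]))
    return (pairs, labels) if labeled else pairs


def write_edges(pairs, path, labels=None) -> None:
    if labels is None:
        rows = ["protein_a\tprotein_b"]
        rows += [f"{a}\t{b}" for a, b in pairs]
    else:
        rows = ["protein_a\tprotein_b\tlabel"]
        rows += [f"{a}\t{b}\t{l}" for (a, b), l in zip(pairs, labels)]
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# feature blocks


def write_features(features: GenomeFeatures, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if features.positions is not None:
        rows = ["protein\tchromosome\tstart\tend"]
        for p in features.proteins:
            c, mid = features.positions[p]
            start = int(round(mid - 0.5))
            rows.append(f"{p}\t{c}\t{start}\t{start + 1}")
        (outdir / "positions.tsv").write_text("\n".join(rows) + "\n")
    if features.expression is not None:
        E = pd.DataFrame(
            {p: features.expression[p] for p in features.proteins}).T
        E.columns = [f"cond{i + 1}" for i in range(E.shape[1])]
        E.index.name = "protein"
        E.to_csv(outdir / "expression.tsv", sep="\t")
    if features.domains is not None:
        rows = ["protein\tdomain_id"]
        for p in features.proteins:
            for k in np.flatnonzero(features.domains[p]):
                rows.append(f"{p}\tDOM{k:03d}")
        (outdir / "domains.tsv").write_text("\n".join(rows) + "\n")
    if features.complex_graph is not None:
        write_edges(sorted(tuple(sorted(e))
                           for e in features.complex_graph.edges),
                    outdir / "complexes.tsv")
    if features.sequences is not None:
        recs = [SeqRecord(Seq(features.sequences[p]), id=p, description="")
                for p in features.proteins]
        SeqIO.write(recs, str(outdir / "sequences.fasta"), "fasta")


def read_features(indir, proteins: Sequence[str]) -> GenomeFeatures:
    import networkx as nx
    indir = Path(indir)
    proteins = list(proteins)
    positions = expression = domains = graph = sequences = None
    if (indir / "positions.tsv").exists():
        positions = {}
        for ln, line in enumerate(_read_lines(indir / "positions.tsv")[1:],
                                  start=2):
            p, c, s, e = line.split("\t")
            positions[p] = (c, (int(s) + int(e)) / 2.0)
    if (indir / "expression.tsv").exists():
        E = pd.read_csv(indir / "expression.tsv", sep="\t", index_col=0)
        expression = {p: E.loc[p].to_numpy(float) for p in proteins}
    if (indir / "domains.tsv").exists():
        memb: dict[str, set[str]] = {p: set() for p in proteins}
        vocab: set[str] = set()
        for line in _read_lines(indir / "domains.tsv")[1:]:
            p, d = line.split("\t")
            memb.setdefault(p, set()).add(d)
            vocab.add(d)
        order = sorted(vocab)
        domains = {p: np.array([float(d in memb.get(p, ()))
                                for d in order]) for p in proteins}
    if (indir / "complexes.tsv").exists():
        graph = nx.Graph()
        graph.add_nodes_from(proteins)
        graph.add_edges_from(read_edges(indir / "complexes.tsv"))
    if (indir / "sequences.fasta").exists():
        sequences = {r.id: str(r.seq)
                     for r in SeqIO.parse(str(indir / "sequences.fasta"),
                                          "fasta")}
    return GenomeFeatures(proteins, positions, expression, domains, graph,
                          sequences)


# ---------------------------------------------------------------------------
# scores


def write_scores(scores: pd.DataFrame, path) -> None:
    rows = ["protein\tterm\tscore"]
    for p in scores.index:
        for t in scores.columns:
            rows.append(f"{p}\t{t}\t{scores.at[p, t]:.10f}")
    Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


def read_scores(path) -> pd.DataFrame:
    lines = _read_lines(path)
    if lines[0] != "protein\tterm\tscore":
        raise FormatError(f"{path}: line 1: bad scores header")
    recs = []
    for ln, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != 3:
            raise FormatError(f"{path}: line {ln}: expected 3 columns")
        recs.append((parts[0], parts[1], float(parts[2])))
    df = pd.DataFrame(recs, columns=["protein", "term", "score"])
    return df.pivot(index="protein", columns="term", values="score")


# ---------------------------------------------------------------------------
# model bundle


def save_model(model, outdir) -> None:
    """Persist a fitted SBRAnnotator: JSON manifest + npz arrays."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = model.get_params()
    manifest = {
        "format": "sbrgo-model",
        "version": CONFIG_VERSION,
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in params.items()},
        "proteins": model.proteins_,
        "terms": model.terms_,
        "pairs": [list(p) for p in model.pairs_],
        "config_hash": hashlib.sha256(
            json.dumps(params, sort_keys=True, default=str).encode()
        ).hexdigest(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    arrays = {"W": model.W_, "wb": model.wb_, "Y": model._Y, "M": model._M,
              "K": model.kernel_.values, "yb": model._yb, "mb": model._mb}
    if model.pair_kernel_ is not None:
        arrays["Kp"] = model.pair_kernel_.values
    np.savez(outdir / "arrays.npz", **arrays)


def load_model(indir, dag: OntologyDAG):
    """Rebuild a fitted SBRAnnotator; predictions round-trip exactly."""
    from .model import SBRAnnotator
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    if manifest.get("format") != "sbrgo-model":
        raise FormatError(f"{indir}: not a model bundle")
    params = {k: (tuple(v) if isinstance(v, list) else v)
              for k, v in manifest["params"].items()}
    model = SBRAnnotator(**params)
    arrays = np.load(indir / "arrays.npz", allow_pickle=False)
    model.proteins_ = list(manifest["proteins"])
    model.terms_ = list(manifest["terms"])
    model.pairs_ = [tuple(p) for p in manifest["pairs"]]
    model.dag_ = dag
    model.kernel_ = KernelMatrix(model.proteins_, arrays["K"])
    model.W_ = arrays["W"]
    model.wb_ = arrays["wb"]
    model._Y = arrays["Y"]
    model._M = arrays["M"].astype(bool)
    model._yb = arrays["yb"]
    model._mb = arrays["mb"].astype(bool)
    model.pair_kernel_ = KernelMatrix(model.pairs_, arrays["Kp"]) \
        if "Kp" in arrays else None
    model.constraints_ = model._compile_constraints()
    return model


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Schema-versioned run configuration (YAML on disk)."""

    version: int = CONFIG_VERSION
    ontology: str = "ontology.obo"
    annotations: str = "annotations.tsv"
    ppi: str = "ppi.tsv"
    features_dir: str = "."
    kernel: str | None = None
    tnorm: str = "lukasiewicz"
    rules: str = "full"
    lam_l: float = 10.0
    lambda_go: float = 1.0
    lambda_ppi: float = 1.0
    go_rule_depth: int | None = None
    ppi_levels: list = field(default_factory=lambda: [1, 2, 3, 4, 5])
    ppi_namespaces: list = field(default_factory=lambda: ["BP", "CC"])
    loss: str = "squared"
    squash: str = "logistic"
    max_iter: int = 500
    coll_max_iter: int = 1000
    tol: float = 1e-6
    folds: int = 10
    mode: str = "transductive"
    full_training: bool = False
    gamma: float = 1.0
    beta: float = 1.0
    eps: float = 1e-6
    spectrum_k: int = 3
    max_depth: dict = field(default_factory=dict)
    min_annotations: int = 1
    seed: int = 0

    def validate(self, base: Path | None = None) -> None:
        if self.version != CONFIG_VERSION:
            raise FormatError(f"config version {self.version} unsupported")
        for name in ("lam_l", "lambda_go", "lambda_ppi"):
            if getattr(self, name) < 0:
                raise FormatError(f"config field {name}: must be >= 0")
        if self.mode not in ("inductive", "transductive"):
            raise FormatError("config field mode: must be inductive or "
                              "transductive")
        if base is not None:
            for name in ("ontology", "annotations", "ppi"):
                p = Path(base) / getattr(self, name)
                if not p.exists():
                    raise FormatError(f"config field {name}: {p} not found")

    def model_kwargs(self) -> dict:
        return dict(lam_l=self.lam_l, loss=self.loss, squash=self.squash,
                    tnorm=self.tnorm, rules=self.rules,
                    lambda_go=self.lambda_go, lambda_ppi=self.lambda_ppi,
                    go_rule_depth=self.go_rule_depth,
                    ppi_levels=tuple(self.ppi_levels),
                    ppi_namespaces=tuple(self.ppi_namespaces),
                    full_training=self.full_training, max_iter=self.max_iter,
                    coll_max_iter=self.coll_max_iter, tol=self.tol)


def read_config(path) -> RunConfig:
    data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(data) - known
    if unknown:
        raise FormatError(f"unknown config fields: {sorted(unknown)}")
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg


def write_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=False),
                          encoding="utf-8")


def read_kernel_file(path) -> KernelMatrix:
    from .kernels import read_kernel_tsv
    return read_kernel_tsv(Path(path).read_text(encoding="utf-8"))


def write_kernel_file(K: KernelMatrix, path) -> None:
    from .kernels import write_kernel_tsv
    Path(path).write_text(write_kernel_tsv(K), encoding="utf-8")


def read_ontology_file(path) -> OntologyDAG:
    return load_ontology(Path(path).read_text(encoding="utf-8"))


def write_ontology_file(dag: OntologyDAG, path) -> None:
    Path(path).write_text(write_obo(dag), encoding="utf-8")
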