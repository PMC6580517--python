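"""Similarity matrices feeding the kernel machines.

Five heterogeneous sources are supported: gene co-localization, diffusion over
a protein-complex graph, co-expression, shared protein domains, and a k-mer
spectrum kernel over amino-acid sequences.  Each kernel is cosine-normalized
(unit diagonal) and preconditioned by adding a small constant to the diagonal;
the aggregate is the plain average.  Interaction prediction uses the
symmetrized pairwise kernel built from the aggregate protein kernel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.linalg import expm

Pair = tuple[str, str]


@dataclass
class KernelMatrix:
    """A symmetric similarity matrix aligned to an ordered entity index."""

    index: list
    values: np.ndarray
    _pos: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.index)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match index "
                f"length {n}")
        if not np.allclose(self.values, self.values.T, atol=1e-9):
            raise ValueError("kernel matrix is not symmetric within 1e-9")
        self._pos = {e: i for i, e in enumerate(self.index)}
        if len(self._pos) != n:
            raise ValueError("duplicate entity ids in kernel index")

    def loc(self, a, b) -> float:
        return float(self.values[self._pos[a], self._pos[b]])

    def submatrix(self, entities: Sequence) -> "KernelMatrix":
        idx = [self._pos[e] for e in entities]
        return KernelMatrix(list(entities), self.values[np.ix_(idx, idx)])

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])


@dataclass
class GenomeFeatures:
    """Raw per-protein ingredients from which kernels are built.

    positions: protein -> (chromosome-id, centroid base coordinate)
    expression: protein -> expression vector over conditions
    domains: protein -> binary indicator vector over a shared domain vocabulary
    complex_graph: undirected graph of co-complex membership
    sequences: protein -> amino-acid string (optional)
    """

    proteins: list[str]
    positions: dict[str, tuple[str, float]] | None = None
    expression: dict[str, np.ndarray] | None = None
    domains: dict[str, np.ndarray] | None = None
    complex_graph: nx.Graph | None = None
    sequences: dict[str, str] | None = None


# ---------------------------------------------------------------------------
# individual kernels


def colocalization_kernel(features: GenomeFeatures, gamma: float = 1.0
                          ) -> KernelMatrix:
    """exp(-gamma * |pos - pos'|) for genes on the same chromosome, else 0.

    Distances are between gene centroids, in bases.  With the default
    ``gamma=1`` closer centroids give higher similarity and different
    chromosomes give null similarity.
    """
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if features.positions is None:
        raise ValueError("positions not available")
    prots = features.proteins
    for p in prots:
        if p not in features.positions:
            raise ValueError(f"missing gene position for protein {p!r}")
    chrom = np.array([features.positions[p][0] for p in prots], dtype=object)
    pos = np.array([features.positions[p][1] for p in prots], dtype=float)
    same = chrom[:, None] == chrom[None, :]
    K = np.where(same, np.exp(-gamma * np.abs(pos[:, None] - pos[None, :])), 0.0)
    return KernelMatrix(list(prots), K)


def diffusion_kernel(features: GenomeFeatures, beta: float = 1.0,
                     laplacian: str = "combinatorial") -> KernelMatrix:
    """Diffusion kernel exp(-beta * L) over the protein-complex graph.

    L is the combinatorial graph Laplacian D - A by default (``laplacian`` may
    be set to "normalized").  The smoothness parameter ``beta`` (default 1)
    modulates how far similarity diffuses through shared binding partners.
    Proteins absent from the graph are isolated nodes.
    """
    if beta <= 0:
        raise ValueError("beta must be positive")
    if features.complex_graph is None:
        raise ValueError("complex graph not available")
    prots = features.proteins
    g = features.complex_graph
    extra = set(g.nodes) - set(prots)
    if extra:
        raise ValueError(f"complex graph nodes outside protein index: {extra}")
    n = len(prots)
    A = np.zeros((n, n))
    pos = {p: i for i, p in enumerate(prots)}
    for a, b in g.edges:
        if a == b:
            continue
        A[pos[a], pos[b]] = A[pos[b], pos[a]] = 1.0
    deg = A.sum(axis=1)
    if laplacian == "combinatorial":
        L = np.diag(deg) - A
    elif laplacian == "normalized":
        with np.errstate(divide="ignore"):
            d = np.where(deg > 0, 1.0 / np.sqrt(deg), 0.0)
        L = np.eye(n) - d[:, None] * A * d[None, :]
        L[deg == 0, deg == 0] = 0.0
    else:
        raise ValueError(f"unknown laplacian convention {laplacian!r}")
    K = expm(-beta * L)
    K = (K + K.T) / 2.0
    return KernelMatrix(list(prots), K)


def coexpression_kernel(features: GenomeFeatures) -> KernelMatrix:
    """Inner product of raw expression vectors across conditions."""
    if features.expression is None:
        raise ValueError("expression not available")
    E = _stack(features.expression, features.proteins, "expression")
    return KernelMatrix(list(features.proteins), E @ E.T)


def domain_kernel(features: GenomeFeatures) -> KernelMatrix:
    """Linear kernel over binary domain indicators: count of shared domains."""
    if features.domains is None:
        raise ValueError("domains not available")
    D = _stack(features.domains, features.proteins, "domain")
    return KernelMatrix(list(features.proteins), D @ D.T)


def _stack(block: dict[str, np.ndarray], proteins: Sequence[str],
           what: str) -> np.ndarray:
    dims = {len(np.atleast_1d(block[p])) for p in proteins if p in block}
    missing = [p for p in proteins if p not in block]
    if missing:
        raise ValueError(f"missing {what} vector for {missing[:3]}")
    if len(dims) != 1:
        raise ValueError(f"{what} vectors have inconsistent dimensions {dims}")
    return np.vstack([np.asarray(block[p], dtype=float) for p in proteins])


def spectrum_kernel(sequences: dict[str, str], proteins: Sequence[str],
                    k: int = 3) -> KernelMatrix:
    """k-mer spectrum kernel: inner product of k-mer count vectors.

    A sequence-composition kernel used as the sequence-based similarity
    source.  Sequences shorter than k get a zero row/column (warned).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    vocab: dict[str, int] = {}
    counts = []
    for p in proteins:
        seq = sequences[p]
        if len(seq) < k:
            warnings.warn(f"sequence of {p!r} shorter than k={k}")
            counts.append({})
            continue
        c: dict[int, int] = {}
        for i in range(len(seq) - k + 1):
            kmer = seq[i:i + k]
            j = vocab.setdefault(kmer, len(vocab))
            c[j] = c.get(j, 0) + 1
        counts.append(c)
    n = len(proteins)
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            a, b = counts[i], counts[j]
            if len(b) < len(a):
                a, b = b, a
            v = sum(cnt * b.get(kmer, 0) for kmer, cnt in a.items())
            K[i, j] = K[j, i] = v
    return KernelMatrix(list(proteins), K)


# ---------------------------------------------------------------------------
# normalization / aggregation


def normalize(K: KernelMatrix, on_zero_diag: str = "error") -> KernelMatrix:
    """Cosine normalization K(a,b)/sqrt(K(a,a)K(b,b)); unit diagonal.

    A non-positive self-similarity is an error by default;
    ``on_zero_diag="isolate"`` instead gives such entities zero similarity to
    everything and unit self-similarity (e.g. a protein with no annotated
    domains under an indicator kernel).
    """
    d = np.diag(K.values).copy()
    bad = np.where(d <= 0)[0]
    if bad.size and on_zero_diag == "error":
        raise ValueError(
            f"cannot normalize: non-positive diagonal for {K.index[bad[0]]!r}")
    if on_zero_diag not in ("error", "isolate"):
        raise ValueError(f"unknown on_zero_diag policy {on_zero_diag!r}")
    s = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    V = K.values * s[:, None] * s[None, :]
    np.fill_diagonal(V, 1.0)
    return KernelMatrix(list(K.index), V)


def precondition(K: KernelMatrix, eps: float = 1e-6) -> KernelMatrix:
    """Add a small constant (default 1e-6) to the diagonal for stability."""
    V = K.values.copy()
    V[np.diag_indices_from(V)] += eps
    return KernelMatrix(list(K.index), V)


def average_kernels(kernels: Sequence[KernelMatrix]) -> KernelMatrix:
    """Entrywise mean of kernels sharing one entity index (uniform 1/n)."""
    if not kernels:
        raise ValueError("no kernels to average")
    idx = kernels[0].index
    for K in kernels[1:]:
        if K.index != idx:
            raise ValueError("kernel entity indexes do not match")
    V = np.mean([K.values for K in kernels], axis=0)
    return KernelMatrix(list(idx), V)


def pairwise_kernel(K: KernelMatrix, pairs: Sequence[Pair],
                    eps: float = 1e-6, normalized: bool = True
                    ) -> KernelMatrix:
    """Symmetrized pairwise kernel over protein pairs.

    K_pair((p,p'),(q,q')) = K(p,q) K(p',q') + K(p,q') K(p',q), which is
    invariant to swapping the members within either pair; the result is then
    cosine-normalized and preconditioned, as for the protein kernels
    (``normalized=False`` returns the raw two-product matrix).
    """
    for a, b in pairs:
        if a not in K._pos or b not in K._pos:
            raise ValueError(f"pair member missing from kernel index: {(a, b)}")
    ia = np.array([K._pos[a] for a, _ in pairs])
    ib = np.array([K._pos[b] for _, b in pairs])
    V = K.values
    M = (V[np.ix_(ia, ia)] * V[np.ix_(ib, ib)]
         + V[np.ix_(ia, ib)] * V[np.ix_(ib, ia)])
    out = KernelMatrix([tuple(p) for p in pairs], M)
    if not normalized:
        return out
    return precondition(normalize(out), eps)


def read_kernel_tsv(text: str) -> KernelMatrix:
    """Read a kernel matrix TSV (header row and column of entity ids)."""
    lines = [l for l in text.replace("\r\n", "\n").split("\n") if l.strip()]
    header = lines[0].split("\t")[1:]
    rows, ids = [], []
    for ln, line in enumerate(lines[1:], start=2):
        parts = line.split("\t")
        if len(parts) != len(header) + 1:
            raise ValueError(f"line {ln}: expected {len(header)+1} columns, "
                             f"got {len(parts)}")
        ids.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    if ids != header:
        raise ValueError("kernel TSV header and row ids disagree")
    V = np.array(rows)
    asym = np.abs(V - V.T)
    if asym.size and asym.max() > 1e-9:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ValueError(
            f"kernel TSV not symmetric at ({ids[i]!r}, {ids[j]!r}): "
            f"{V[i, j]} vs {V[j, i]}")
    return KernelMatrix(ids, V)


def write_kernel_tsv(K: KernelMatrix) -> str:
    ids = [str(e) for e in K.index]
    out = ["\t".join([""] + ids)]
    for i, e in enumerate(ids):
        out.append("\t".join([e] + [repr(float(v)) for v in K.values[i]]))
    return "\n".join(out) + "\n"
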