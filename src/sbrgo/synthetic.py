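"""Desk-scale synthetic genomes with the statistical structure the model
assumes.

Each protein carries a latent vector; term memberships are drawn top-down
through each ontology (children are subsets of their parents, so the
true-path closure holds by construction) by thresholding noisy projections of
the latents; every kernel ingredient (gene positions, expression, domains,
complex graph, sequences) is a noisy function of the same latents, so kernels
correlate with annotations; and interaction edges are drawn with probability
increasing in the number of per-level shared terms, scaled by a coupling
knob.  The generator also implements the dataset-assembly conventions:
balanced-negative pair sampling and greedy balanced cross-validation folds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np

from .kernels import GenomeFeatures
from .ontology import NEGATIVE, POSITIVE, AnnotationTable, OntologyDAG

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticGenomeSpec:
    """Generation conditions for one synthetic genome.

    levels counts the non-root depths per namespace; ``sparsity`` gives, per
    level, the fraction of each parent's positives retained by a child term.
    ``ppi_coupling`` in [0,1] scales how strongly interaction probability
    depends on shared annotations; ``kernel_noise`` is the relative noise
    scale injected into every feature block.
    """

    n_proteins: int = 200
    namespaces: tuple = ("BP", "CC", "MF")
    levels: int = 3
    branching: int = 2
    extra_parent_prob: float = 0.2
    latent_dim: int = 8
    sparsity: tuple = (0.6, 0.5, 0.4)
    ppi_coupling: float = 0.8
    kernel_noise: float = 0.5
    n_ppi_positives: int | None = None  # default 1.5 * n_proteins
    n_negative_ppi_ratio: float = 1.0
    n_conditions: int = 12
    n_domains: int = 30
    n_chromosomes: int = 4
    seq_length: int = 60
    seed: int = 0

    def __post_init__(self):
        if self.n_proteins <= 0 or self.levels <= 0 or self.branching <= 0:
            raise ValueError("counts must be positive")
        if self.n_ppi_positives is None:
            self.n_ppi_positives = int(round(1.5 * self.n_proteins))
        if self.n_ppi_positives <= 0:
            raise ValueError("counts must be positive")
        if not 0.0 <= self.ppi_coupling <= 1.0:
            raise ValueError("ppi_coupling must lie in [0,1]")
        if len(self.sparsity) != self.levels:
            raise ValueError("need one sparsity value per level")
        if any(not 0.0 < s <= 1.0 for s in self.sparsity):
            raise ValueError("sparsity values must lie in (0,1]")


def _make_dag(spec: SyntheticGenomeSpec, rng: np.random.Generator
              ) -> OntologyDAG:
    namespace: dict[str, str] = {}
    edges: dict[str, set[str]] = {}
    for ns in spec.namespaces:
        root = f"{ns}:0000"
        namespace[root] = ns
        edges[root] = set()
        prev = [root]
        counter = 1
        for l in range(1, spec.levels + 1):
            cur = []
            for parent in prev:
                for _ in range(spec.branching):
                    t = f"{ns}:{counter:04d}"
                    counter += 1
                    namespace[t] = ns
                    edges[t] = {parent}
                    if len(prev) > 1 and rng.random() < spec.extra_parent_prob:
                        other = prev[rng.integers(len(prev))]
                        edges[t].add(other)
                    cur.append(t)
            prev = cur
    return OntologyDAG(namespace, edges)


def _annotate(spec: SyntheticGenomeSpec, dag: OntologyDAG, Z: np.ndarray,
              proteins: list[str], rng: np.random.Generator
              ) -> AnnotationTable:
    """Top-down membership: a term keeps the ``sparsity[l-1]`` fraction of the
    proteins positive for all its parents, ranked by a noisy latent score."""
    table = AnnotationTable(list(proteins))
    pos: dict[str, np.ndarray] = {}
    n = len(proteins)
    for ns in dag.namespaces():
        pos[dag.roots[ns]] = np.ones(n, bool)
    for t in sorted(dag.terms, key=lambda t: (dag.depth[t], t)):
        if not dag.parents(t):
            continue
        eligible = np.ones(n, bool)
        for par in dag.parents(t):
            eligible &= pos[par]
        rate = spec.sparsity[dag.depth[t] - 1]
        k = int(round(rate * eligible.sum()))
        member = np.zeros(n, bool)
        if k > 0 and eligible.any():
            u = rng.normal(size=spec.latent_dim)
            u /= np.linalg.norm(u)
            score = Z @ u + 0.5 * rng.normal(size=n)
            idx = np.where(eligible)[0]
            member[idx[np.argsort(-score[idx], kind="stable")[:k]]] = True
        pos[t] = member
    for t, member in pos.items():
        for ip in range(n):
            table.set(proteins[ip], t, POSITIVE if member[ip] else NEGATIVE)
    return table


def _features(spec: SyntheticGenomeSpec, Z: np.ndarray,
              proteins: list[str], rng: np.random.Generator
              ) -> GenomeFeatures:
    n, d = Z.shape
    noise = spec.kernel_noise
    # positions: chromosome from a latent projection, centroid from another
    chrom_proj = Z @ rng.normal(size=d)
    chrom = np.digitize(chrom_proj, np.quantile(
        chrom_proj, np.linspace(0, 1, spec.n_chromosomes + 1)[1:-1]))
    coord = 1000.0 * (Z @ rng.normal(size=d)) + 200.0 * noise * rng.normal(size=n)
    coord = coord - coord.min() + 1.0
    positions = {p: (f"chr{chrom[i] + 1}", float(coord[i]))
                 for i, p in enumerate(proteins)}
    # expression: linear map of latents plus noise
    A = rng.normal(size=(d, spec.n_conditions))
    E = Z @ A + noise * rng.normal(size=(n, spec.n_conditions))
    expression = {p: E[i].copy() for i, p in enumerate(proteins)}
    # domains: thresholded noisy projections
    V = rng.normal(size=(d, spec.n_domains))
    D = (Z @ V + noise * rng.normal(size=(n, spec.n_domains)) > 1.0
         ).astype(float)
    domains = {p: D[i].copy() for i, p in enumerate(proteins)}
    # complex graph: edges between latently similar proteins
    sim = Z @ Z.T
    np.fill_diagonal(sim, -np.inf)
    g = nx.Graph()
    g.add_nodes_from(proteins)
    thr = np.quantile(sim[np.isfinite(sim)], 0.97)
    for i in range(n):
        for j in range(i + 1, n):
            if sim[i, j] >= thr:
                g.add_edge(proteins[i], proteins[j])
    # sequences: composition biased by the first latent coordinates
    seqs = {}
    for i, p in enumerate(proteins):
        logits = np.tile(Z[i], int(np.ceil(20 / d)))[:20] * (1.0 - noise * 0.5)
        w = np.exp(logits - logits.max())
        seqs[p] = "".join(rng.choice(list(AMINO_ACIDS), size=spec.seq_length,
                                     p=w / w.sum()))
    return GenomeFeatures(list(proteins), positions, expression, domains,
                          g, seqs)


def _shared_per_level(table: AnnotationTable, dag: OntologyDAG,
                      proteins: list[str]) -> np.ndarray:
    """Count of levels (over namespaces) at which each pair shares a term."""
    n = len(proteins)
    shared = np.zeros((n, n))
    for ns in dag.namespaces():
        for l in range(1, max(dag.depth[t] for t in dag.terms_in(ns)) + 1):
            terms = [t for t in dag.terms_in(ns) if dag.depth[t] == l]
            Mlvl = np.array([[table.get(p, t) == POSITIVE for t in terms]
                             for p in proteins])
            shared += (Mlvl @ Mlvl.T) > 0
    return shared


def generate_genome(spec: SyntheticGenomeSpec
                    ) -> tuple[OntologyDAG, AnnotationTable, GenomeFeatures,
                               list[tuple[str, str]]]:
    """Generate (ontology, closed annotation table, features, positive PPI
    edges), deterministically per ``spec.seed``.

    Edge probability is logistic in coupling * (shared-level count + latent
    similarity): at coupling 0 interactions are independent of annotations by
    construction; increasing coupling monotonically increases the shared-term
    enrichment of interacting pairs.
    """
    rng = np.random.default_rng(spec.seed)
    for l in range(1, spec.levels):
        if spec.sparsity[l] > 1.0:
            raise ValueError("infeasible sparsity")
    proteins = [f"P{i:04d}" for i in range(spec.n_proteins)]
    dag = _make_dag(spec, rng)
    Z = rng.normal(size=(spec.n_proteins, spec.latent_dim))
    table = _annotate(spec, dag, Z, proteins, rng)
    features = _features(spec, Z, proteins, rng)

    shared = _shared_per_level(table, dag, proteins)
    nlevels = spec.levels * len(spec.namespaces)
    zsim = Z @ Z.T / spec.latent_dim
    base = np.log(spec.n_ppi_positives / max(
        spec.n_proteins * (spec.n_proteins - 1) / 2, 1))
    logit = base + spec.ppi_coupling * (
        6.0 * (shared / nlevels - 0.5) + 0.5 * np.tanh(zsim))
    prob = 1.0 / (1.0 + np.exp(-logit))
    iu = np.triu_indices(spec.n_proteins, k=1)
    draws = rng.random(len(iu[0]))
    # calibrate to approximately the requested number of positives
    order = np.argsort(draws / prob[iu])
    take = order[:spec.n_ppi_positives]
    edges = [(proteins[iu[0][k]], proteins[iu[1][k]]) for k in sorted(take)]
    return dag, table, features, edges


def sample_negative_pairs(
    positives: Sequence[tuple[str, str]],
    universe: Sequence[str],
    ratio: float = 1.0,
    exclusions: Sequence[tuple[str, str]] = (),
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Uniform non-interacting pairs from the complement of the positives.

    Returns ``ratio * len(positives)`` pairs, disjoint from positives,
    exclusions and self-pairs, with the symmetric closure applied before
    sampling.  Raises when the complement is too small.
    """
    rng = np.random.default_rng(seed)
    universe = list(universe)
    pos = {tuple(sorted(e)) for e in positives}
    excl = pos | {tuple(sorted(e)) for e in exclusions}
    n = len(universe)
    want = int(round(ratio * len(pos)))
    all_pairs = n * (n - 1) // 2
    avail = all_pairs - len({e for e in excl
                             if e[0] in set(universe) and e[1] in set(universe)
                             and e[0] != e[1]})
    if want > avail:
        raise ValueError(
            f"complement exhausted: requested {want} negatives but only "
            f"{avail} candidate pairs remain of {all_pairs}")
    if want > avail // 2:
        # dense request: enumerate the complement and sample without replacement
        cand = [tuple(sorted((universe[i], universe[j])))
                for i in range(n) for j in range(i + 1, n)]
        cand = [e for e in cand if e not in excl]
        idx = rng.choice(len(cand), size=want, replace=False)
        return [cand[k] for k in sorted(idx)]
    out: list[tuple[str, str]] = []
    seen: set[tuple[str, str]] = set()
    while len(out) < want:
        i, j = rng.integers(n), rng.integers(n)
        if i == j:
            continue
        e = tuple(sorted((universe[i], universe[j])))
        if e in excl or e in seen:
            continue
        seen.add(e)
        out.append(e)
    return out


@dataclass
class FoldSplit:
    """Protein and pair fold assignments for K-fold cross-validation."""

    protein_fold: dict[str, int]
    pair_fold: dict[tuple[str, str], int] = field(default_factory=dict)
    n_folds: int = 10

    def proteins_in(self, fold: int) -> list[str]:
        return [p for p, f in self.protein_fold.items() if f == fold]

    def pairs_in(self, fold: int) -> list[tuple[str, str]]:
        return [p for p, f in self.pair_fold.items() if f == fold]


def make_folds(table: AnnotationTable,
               pairs: Sequence[tuple[str, str]] = (),
               pair_labels: Sequence[int] = (),
               K: int = 10, seed: int = 0) -> FoldSplit:
    """Greedy balanced K-fold assignment.

    Proteins are processed in decreasing annotation count (seeded shuffle
    breaks ties) and each is placed into the fold minimizing the sum of
    squared per-term count deviations after placement, with fold size as the
    tie-break.  Pairs are split similarly, balancing positive and negative
    interaction counts.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > len(table.proteins):
        raise ValueError("more folds than proteins")
    rng = np.random.default_rng(seed)
    terms = sorted(table.annotated_terms())
    t_index = {t: i for i, t in enumerate(terms)}
    vecs = {}
    for p in table.proteins:
        v = np.zeros(len(terms))
        for t in table.positive_terms(p):
            v[t_index[t]] = 1.0
        vecs[p] = v
    order = list(table.proteins)
    rng.shuffle(order)
    order = sorted(order, key=lambda p: -vecs[p].sum())
    counts = np.zeros((K, len(terms)))
    sizes = np.zeros(K, int)
    protein_fold: dict[str, int] = {}
    for p in order:
        costs = ((counts + vecs[p][None, :]) ** 2).sum(axis=1)
        best = int(np.lexsort((np.arange(K), sizes, costs))[0])
        protein_fold[p] = best
        counts[best] += vecs[p]
        sizes[best] += 1

    pair_fold: dict[tuple[str, str], int] = {}
    if pairs:
        labels = list(pair_labels) if pair_labels else [1] * len(pairs)
        pcounts = np.zeros((K, 2))
        psizes = np.zeros(K, int)
        order_idx = list(range(len(pairs)))
        rng.shuffle(order_idx)
        for i in order_idx:
            lab = int(labels[i])
            v = np.zeros(2)
            v[lab] = 1.0
            costs = ((pcounts + v[None, :]) ** 2).sum(axis=1)
            best = int(np.lexsort((np.arange(K), psizes, costs))[0])
            pair_fold[tuple(sorted(pairs[i]))] = best
            pcounts[best] += v
            psizes[best] += 1
    return FoldSplit(protein_fold, pair_fold, K)
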