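"""Graph/axiom embedding similarity: entity graphs, random walks, axiom
sentences, skip-gram training and cosine ranking.

Three corpus flavors are supported, matching the three embedding-based
similarity methods:

* ``dl2vec`` — undirected graph over classes, genes and diseases, including
  equivalence edges; uniform random walks (default 50 walks of length 30),
  edge labels interleaved as tokens, skip-gram window 10, mincount 1.
* ``owl2vec`` — directed (child→parent) graph without equivalence edges;
  walks of depth 7, 30 per node, window 5, mincount 1, 5 negatives.
* ``opa2vec`` — no walks: one sentence per axiom plus entity–annotation
  sentences repeated along the subsumption closure, optionally augmented
  with class-label word sentences; window 5, mincount 0.

All flavors share one embedding size (100) and the skip-gram with negative
sampling objective, implemented here in numpy with deterministic seeding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotations import AnnotationCorpus
from .ontology import OntologyGraph
from .similarity import SimilarityMatrix

__all__ = [
    "EntityGraph",
    "WalkCorpus",
    "EmbeddingTable",
    "axioms_to_graph",
    "generate_walks",
    "generate_axiom_sentences",
    "train_skipgram",
    "cosine_similarity_matrix",
]


@dataclass
class EntityGraph:
    """Labeled graph over phenotype classes plus gene/disease entities."""

    nodes: set[str]
    edges: list[tuple[str, str, str]]  # (u, label, v); stored once even if undirected
    directed: bool

    def adjacency(self) -> dict[str, list[tuple[str, str]]]:
        """node → sorted [(label, neighbor)]; both directions if undirected."""
        adj: dict[str, list[tuple[str, str]]] = {n: [] for n in self.nodes}
        for u, label, v in self.edges:
            adj[u].append((label, v))
            if not self.directed:
                adj[v].append((label, u))
        for n in adj:
            adj[n].sort()
        return adj


@dataclass
class WalkCorpus:
    sentences: list[list[str]]
    seed: int | None = None
    params: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sentences)


@dataclass
class EmbeddingTable:
    dim: int
    vectors: dict[str, np.ndarray]
    training_params: dict = field(default_factory=dict)

    def __getitem__(self, token: str) -> np.ndarray:
        return self.vectors[token]

    def __contains__(self, token: str) -> bool:
        return token in self.vectors


def axioms_to_graph(
    graph: OntologyGraph,
    corpora: list[AnnotationCorpus],
    flavor: str,
) -> EntityGraph:
    """Project ontology axioms and annotations onto an entity graph.

    ``dl2vec`` graphs are undirected and keep equivalence edges; ``owl2vec``
    graphs are directed child→parent and drop equivalence axioms.  Genes and
    diseases are linked to their direct annotation classes.
    """
    if flavor not in ("dl2vec", "owl2vec"):
        raise ValueError(f"unknown graph flavor {flavor!r} (expected dl2vec/owl2vec)")
    directed = flavor == "owl2vec"
    nodes: set[str] = set(graph.classes)
    edges: list[tuple[str, str, str]] = []
    for child, parent in sorted(graph.subclass_edges):
        edges.append((child, "is_a", parent))
    for s, r, o in sorted(graph.relation_edges):
        edges.append((s, r, o))
    if flavor == "dl2vec":
        for group in sorted(graph.equivalence_sets, key=sorted):
            ordered = sorted(group)
            for a, b in zip(ordered, ordered[1:]):
                edges.append((a, "equivalent_to", b))
    for corpus in corpora:
        for entity in sorted(corpus.direct):
            nodes.add(entity)
            for cid in sorted(corpus.direct[entity]):
                edges.append((entity, "has_phenotype", cid))
    return EntityGraph(nodes=nodes, edges=edges, directed=directed)


def generate_walks(
    entity_graph: EntityGraph,
    num_walks: int,
    walk_length: int,
    seed: int = 0,
) -> WalkCorpus:
    """Uniform random walks from every node, edge labels emitted as tokens.

    Each walk takes up to ``walk_length`` steps, choosing uniformly among
    (out-)neighbors and truncating at sinks; an isolated node yields the
    single-token sentence [node].  Reproducible for a fixed seed.
    """
    if num_walks < 1 or walk_length < 1:
        raise ValueError("num_walks and walk_length must be >= 1")
    if not entity_graph.nodes:
        raise ValueError("cannot walk an empty graph")
    adj = entity_graph.adjacency()
    rng = np.random.default_rng(seed)
    sentences: list[list[str]] = []
    for start in sorted(entity_graph.nodes):
        for _ in range(num_walks):
            sentence = [start]
            node = start
            for _ in range(walk_length):
                nbrs = adj[node]
                if not nbrs:
                    break
                label, nxt = nbrs[rng.integers(len(nbrs))]
                sentence.extend((label, nxt))
                node = nxt
            sentences.append(sentence)
    return WalkCorpus(
        sentences,
        seed=seed,
        params={"num_walks": num_walks, "walk_length": walk_length},
    )


def generate_axiom_sentences(
    graph: OntologyGraph,
    corpora: list[AnnotationCorpus],
    labels: bool = True,
) -> WalkCorpus:
    """Axiom and annotation sentences for the axiom-corpus embedding flavor.

    One sentence per subclass / relation / equivalence axiom, plus one
    sentence per (entity, class) annotation pair for *every* ancestor of the
    annotated class — the closure-propagated corpus.  With ``labels`` on,
    each labeled class contributes a sentence of its id followed by its
    label's words.
    """
    sentences: list[list[str]] = []
    for child, parent in sorted(graph.subclass_edges):
        sentences.append([child, "is_a", parent])
    for s, r, o in sorted(graph.relation_edges):
        sentences.append([s, r, o])
    for group in sorted(graph.equivalence_sets, key=sorted):
        ordered = sorted(group)
        for a, b in zip(ordered, ordered[1:]):
            sentences.append([a, "equivalent_to", b])
    for corpus in corpora:
        for entity in sorted(corpus.direct):
            for cid in sorted(corpus.propagated.get(entity, frozenset())):
                sentences.append([entity, "has_phenotype", cid])
    if labels:
        for cid in sorted(graph.classes):
            label = graph.classes[cid].label
            if label:
                sentences.append([cid, *label.split()])
    return WalkCorpus(sentences, params={"kind": "axiom_sentences", "labels": labels})


# ---------------------------------------------------------------------------
# Skip-gram with negative sampling (SGNS), numpy implementation


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -30, 30)))


def _scatter_mean(target: np.ndarray, idx: np.ndarray, updates: np.ndarray) -> None:
    """Add per-index mean of ``updates`` rows to ``target`` rows."""
    counts = np.bincount(idx, minlength=target.shape[0]).astype(float)
    summed = np.zeros_like(target)
    np.add.at(summed, idx, updates)
    nz = counts > 0
    target[nz] += summed[nz] / counts[nz, None]


def train_skipgram(
    corpus: WalkCorpus,
    dim: int = 100,
    window: int = 5,
    mincount: int = 1,
    negatives: int = 5,
    epochs: int = 10,
    seed: int = 0,
    learning_rate: float = 0.025,
    batch_size: int = 512,
    required_tokens: list[str] | None = None,
) -> EmbeddingTable:
    """Train skip-gram with negative sampling over a sentence corpus.

    Tokens occurring fewer than ``mincount`` times are dropped from the
    vocabulary; if any of ``required_tokens`` (typically the gene and
    disease ids that must be rankable) falls below the threshold, training
    aborts with an error listing the missing tokens.  Negative targets are
    drawn from the unigram^0.75 distribution; updates run in mini-batches
    with a linearly decaying learning rate.  Deterministic for a fixed seed.
    """
    if not corpus.sentences:
        raise ValueError("cannot train on an empty corpus")
    counts: dict[str, int] = {}
    for sentence in corpus.sentences:
        for tok in sentence:
            counts[tok] = counts.get(tok, 0) + 1
    vocab = sorted(t for t, n in counts.items() if n >= max(mincount, 1))
    if required_tokens:
        missing = sorted(set(required_tokens) - set(vocab))
        if missing:
            raise ValueError(f"required tokens below mincount={mincount}: {missing}")
    index = {t: i for i, t in enumerate(vocab)}
    nvocab = len(vocab)

    centers: list[int] = []
    contexts: list[int] = []
    for sentence in corpus.sentences:
        ids = [index[t] for t in sentence if t in index]
        for i, c in enumerate(ids):
            lo, hi = max(0, i - window), min(len(ids), i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    centers.append(c)
                    contexts.append(ids[j])
    if not centers:
        raise ValueError("corpus yields no skip-gram training pairs")
    centers_arr = np.asarray(centers, dtype=np.int64)
    contexts_arr = np.asarray(contexts, dtype=np.int64)
    npairs = len(centers_arr)

    freq = np.array([counts[t] for t in vocab], dtype=float) ** 0.75
    noise = freq / freq.sum()

    rng = np.random.default_rng(seed)
    W = (rng.random((nvocab, dim)) - 0.5) / dim  # input vectors
    C = np.zeros((nvocab, dim))  # output vectors

    total_steps = epochs * npairs
    done = 0
    for _ in range(epochs):
        order = rng.permutation(npairs)
        for lo in range(0, npairs, batch_size):
            sel = order[lo : lo + batch_size]
            b = len(sel)
            lr = learning_rate * max(1.0 - done / total_steps, 1e-4)
            ctr, pos = centers_arr[sel], contexts_arr[sel]
            neg = rng.choice(nvocab, size=(b, negatives), p=noise)
            h = W[ctr]  # (b, d)
            # positive context: label 1
            gpos = _sigmoid(np.einsum("bd,bd->b", h, C[pos])) - 1.0  # (b,)
            # negative contexts: label 0; accidental hits on the true
            # context are masked (they matter in tiny vocabularies)
            gneg = _sigmoid(np.einsum("bd,bkd->bk", h, C[neg]))  # (b, k)
            gneg = np.where(neg == pos[:, None], 0.0, gneg)
            grad_h = gpos[:, None] * C[pos] + np.einsum("bk,bkd->bd", gneg, C[neg])
            # accumulated updates are averaged per token (duplicate indices
            # within a batch would otherwise multiply the step size)
            _scatter_mean(W, ctr, -lr * grad_h)
            cidx = np.concatenate([pos, neg.reshape(-1)])
            cupd = np.concatenate(
                [-lr * gpos[:, None] * h, (-lr * gneg[..., None] * h[:, None, :]).reshape(-1, dim)]
            )
            _scatter_mean(C, cidx, cupd)
            done += b

    # expose the sum of input and output vectors: first-order co-occurrence
    # (captured by W·C) then shows up directly in cosine similarity, which
    # stabilizes small-corpus training
    vectors = {t: W[i] + C[i] for t, i in index.items()}
    return EmbeddingTable(
        dim=dim,
        vectors=vectors,
        training_params={
            "window": window,
            "mincount": mincount,
            "negatives": negatives,
            "epochs": epochs,
            "seed": seed,
            "learning_rate": learning_rate,
        },
    )


def cosine_similarity_matrix(
    embeddings: EmbeddingTable,
    gene_ids: list[str],
    disease_ids: list[str],
    method: str = "embedding",
) -> SimilarityMatrix:
    """Cosine similarity of every gene vector against every disease vector.

    A zero vector has similarity 0 against everything, by convention.
    """
    missing = sorted(t for t in list(gene_ids) + list(disease_ids) if t not in embeddings)
    if missing:
        raise KeyError(f"ids missing from embedding table: {missing[:10]}")
    G = np.stack([embeddings[g] for g in gene_ids])
    D = np.stack([embeddings[d] for d in disease_ids])
    gn = np.linalg.norm(G, axis=1, keepdims=True)
    dn = np.linalg.norm(D, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = (G @ D.T) / (gn * dn.T)
    values = np.nan_to_num(values, nan=0.0)
    return SimilarityMatrix(method, list(gene_ids), list(disease_ids), values)
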