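"""Information content, Resnik pairwise similarity and best-match-average.

The information content of a phenotype class c is

    IC(c) = -log2 p(c),      p(c) = n_prop(c) / N,

where n_prop(c) counts the entities whose *propagated* annotation set
contains c and N is the total number of entities in the supplied corpora
(each entity counted once).  Using the union of organism-gene and disease
corpora gives the cross-species ancestors that bridge human and model
vocabularies a nonzero frequency from both sides, which is what makes them
usable as most informative common ancestors (MICA).

Resnik similarity of two classes is the IC of their MICA; set-vs-set
similarity uses the symmetric best match average (BMA): each class in one
set is matched to its best Resnik partner in the other set, the per-set
means are averaged over both directions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotations import AnnotationCorpus
from .ontology import OntologyGraph

logger = logging.getLogger(__name__)

__all__ = [
    "ICTable",
    "SimilarityMatrix",
    "compute_ic",
    "resnik_pair",
    "bma_similarity",
    "similarity_matrix_resnik",
    "ResnikCalculator",
]


@dataclass
class ICTable:
    """Per-class information content, in bits, over a named corpus.

    Classes with zero propagated annotation frequency are absent (they are
    excluded from MICA candidacy rather than assigned infinite IC).
    """

    corpus_id: str
    ic: dict[str, float]
    total_entities: int

    def __getitem__(self, class_id: str) -> float:
        return self.ic[class_id]

    def get(self, class_id: str, default: float = 0.0) -> float:
        return self.ic.get(class_id, default)

    def __contains__(self, class_id: str) -> bool:
        return class_id in self.ic


@dataclass
class SimilarityMatrix:
    """Gene × disease similarity scores from one method."""

    method: str
    gene_ids: list[str]
    disease_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.disease_ids)):
            raise ValueError(
                f"matrix shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.disease_ids)} diseases"
            )

    def scores_for_disease(self, disease_id: str) -> dict[str, float]:
        j = self.disease_ids.index(disease_id)
        return {g: float(self.values[i, j]) for i, g in enumerate(self.gene_ids)}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.disease_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="gene_id")

    @classmethod
    def from_tsv(cls, path, method: str = "loaded") -> "SimilarityMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(method, list(df.index), list(df.columns), df.to_numpy(dtype=float))


def compute_ic(corpora: list[AnnotationCorpus], corpus_id: str = "union") -> ICTable:
    """Annotation-frequency information content over the union of corpora.

    p(c) = (# entities whose propagated set contains c) / (total entities);
    IC = -log2 p.  Entities appearing in several corpora are counted once.
    """
    if not corpora:
        raise ValueError("compute_ic requires at least one corpus")
    counts: dict[str, int] = {}
    entities: set[str] = set()
    for corpus in corpora:
        for entity, classes in corpus.propagated.items():
            if entity in entities:
                continue
            entities.add(entity)
            for c in classes:
                counts[c] = counts.get(c, 0) + 1
    total = len(entities)
    if total == 0:
        raise ValueError("no entities in the supplied corpora")
    ic = {c: -math.log2(n / total) for c, n in counts.items()}
    return ICTable(corpus_id=corpus_id, ic=ic, total_entities=total)


def resnik_pair(ic: ICTable, graph: OntologyGraph, c1: str, c2: str) -> float:
    """IC of the most informative common ancestor of two classes.

    Only classes present in the IC table (nonzero annotation frequency) are
    candidate ancestors; two classes sharing only never-annotated or
    universally-annotated ancestors score 0.
    """
    common = graph.ancestors(c1) & graph.ancestors(c2)
    return max((ic.ic[a] for a in common if a in ic.ic), default=0.0)


class ResnikCalculator:
    """Memoizing Resnik/BMA engine for repeated gene×disease scoring."""

    def __init__(self, ic: ICTable, graph: OntologyGraph) -> None:
        self.ic = ic
        self.graph = graph
        self._anc_ic: dict[str, dict[str, float]] = {}
        self._pair: dict[tuple[str, str], float] = {}

    def _ancestor_ic(self, c: str) -> dict[str, float]:
        got = self._anc_ic.get(c)
        if got is None:
            got = {a: self.ic.ic[a] for a in self.graph.ancestors(c) if a in self.ic.ic}
            self._anc_ic[c] = got
        return got

    def pair(self, c1: str, c2: str) -> float:
        key = (c1, c2) if c1 <= c2 else (c2, c1)
        got = self._pair.get(key)
        if got is None:
            a1, a2 = self._ancestor_ic(c1), self._ancestor_ic(c2)
            if len(a2) < len(a1):
                a1, a2 = a2, a1
            got = max((v for c, v in a1.items() if c in a2), default=0.0)
            self._pair[key] = got
        return got

    def bma(self, set_a, set_b) -> float:
        set_a, set_b = sorted(set_a), sorted(set_b)
        if not set_a or not set_b:
            logger.warning("BMA over an empty phenotype set: similarity defined as 0")
            return 0.0
        best_a = [max(self.pair(a, b) for b in set_b) for a in set_a]
        best_b = [max(self.pair(a, b) for a in set_a) for b in set_b]
        return 0.5 * (sum(best_a) / len(best_a) + sum(best_b) / len(best_b))


def bma_similarity(set_a, set_b, ic: ICTable, graph: OntologyGraph) -> float:
    """Symmetric best-match-average Resnik similarity between two class sets.

    Empty sets (entities without informative phenotypes) score 0 with a
    logged warning rather than raising.
    """
    return ResnikCalculator(ic, graph).bma(set_a, set_b)


def similarity_matrix_resnik(
    gene_corpus: AnnotationCorpus,
    disease_corpus: AnnotationCorpus,
    ic: ICTable,
    graph: OntologyGraph,
) -> SimilarityMatrix:
    """Resnik-BMA similarity of every gene against every disease.

    BMA runs over the *direct* annotation sets — ancestor lookup already
    happens inside the MICA search, so propagated sets would double-count
    the closure.
    """
    calc = ResnikCalculator(ic, graph)
    genes = gene_corpus.entities
    diseases = disease_corpus.entities
    values = np.zeros((len(genes), len(diseases)))
    for j, d in enumerate(diseases):
        dset = sorted(disease_corpus.direct[d])
        for i, g in enumerate(genes):
            values[i, j] = calc.bma(gene_corpus.direct[g], dset)
    return SimilarityMatrix("resnik_bma", genes, diseases, values)
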