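"""Annotation-bias diagnostics.

Two complementary probes explain why distance-flavored similarity methods
can rank disease genes *worse* than random on cross-species phenotype data:

* **Study bias** — genes whose (orthologs') human counterparts are already
  disease-associated tend to carry more, and more specific, phenotype
  annotations.  ``total_ic`` sums each gene's annotation IC and
  ``study_bias_test`` compares disease-associated against other genes with
  a one-tailed unpaired Student's t-test.
* **IC gap** — for a model-organism phenotype class, the difference between
  its own IC and the IC of its most informative human superclass.  Deeply
  annotated model phenotypes that connect to human classes only high up the
  hierarchy have a large gap; phenotypes bridged by an equivalence have a
  gap of zero.  ``ic_gap`` aggregates the gap per gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from scipy import stats

from .annotations import AnnotationCorpus
from .ontology import OntologyGraph
from .similarity import ICTable

logger = logging.getLogger(__name__)

__all__ = ["total_ic", "study_bias_test", "StudyBiasResult", "ic_gap", "ic_gap_table"]


def total_ic(
    gene_corpus: AnnotationCorpus,
    ic: ICTable,
    graph: OntologyGraph | None = None,
) -> dict[str, float]:
    """Per-gene sum of IC over direct annotations (0 for unannotated genes).

    The IC table is keyed by canonical class ids; pass ``graph`` so that
    annotations to non-canonical members of an equivalence set resolve to
    the merged class's IC.
    """
    def key(c: str) -> str:
        return graph.canonical(c) if graph is not None and c in graph else c

    return {
        g: sum(ic.get(key(c)) for c in classes)
        for g, classes in gene_corpus.direct.items()
    }


@dataclass
class StudyBiasResult:
    t_statistic: float
    p_value: float  # one-tailed, alternative: disease group mean greater
    mean_disease: float
    mean_other: float
    n_disease: int
    n_other: int


def study_bias_test(
    totals: dict[str, float], disease_gene_ids: set[str]
) -> StudyBiasResult:
    """One-tailed unpaired Student's t-test for annotation study bias.

    Tests whether genes in ``disease_gene_ids`` have higher mean total IC
    than the remaining genes (classic equal-variance t, alternative
    'greater').  Both groups must have at least two members.
    """
    disease_vals = [v for g, v in sorted(totals.items()) if g in disease_gene_ids]
    other_vals = [v for g, v in sorted(totals.items()) if g not in disease_gene_ids]
    if len(disease_vals) < 2 or len(other_vals) < 2:
        raise ValueError(
            f"both groups need n >= 2 (got {len(disease_vals)} disease, "
            f"{len(other_vals)} other)"
        )
    res = stats.ttest_ind(disease_vals, other_vals, equal_var=True, alternative="greater")
    return StudyBiasResult(
        t_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        mean_disease=float(sum(disease_vals) / len(disease_vals)),
        mean_other=float(sum(other_vals) / len(other_vals)),
        n_disease=len(disease_vals),
        n_other=len(other_vals),
    )


def ic_gap(
    gene_phenotypes: set[str],
    human_classes: set[str],
    ic: ICTable,
    graph: OntologyGraph,
    aggregate: str = "sum",
) -> float:
    """IC distance between a gene's model phenotypes and their best human cover.

    For each class c in ``gene_phenotypes``,
    gap(c) = | IC(c) − max{ IC(h) : h human superclass of c } |, where the
    superclass search is reflexive over canonical ids — a class bridged to a
    human class by an equivalence has gap 0 — and gap(c) = 0 when no human
    superclass exists.  Gaps are aggregated per gene by ``sum`` (default) or
    ``mean``.
    """
    if aggregate not in ("sum", "mean"):
        raise ValueError(f"aggregate must be sum/mean, got {aggregate!r}")
    if not gene_phenotypes:
        logger.warning("ic_gap over an empty phenotype set: returning 0")
        return 0.0
    human_canon = {graph.canonical(h) for h in human_classes if h in graph}
    gaps = []
    for c in sorted(gene_phenotypes):
        best = max(
            (ic.get(a) for a in graph.ancestors(c) if a in human_canon),
            default=None,
        )
        if best is None:
            gaps.append(0.0)
        else:
            gaps.append(abs(ic.get(graph.canonical(c)) - best))
    return sum(gaps) if aggregate == "sum" else sum(gaps) / len(gaps)


def ic_gap_table(
    gene_corpus: AnnotationCorpus,
    human_classes: set[str],
    ic: ICTable,
    graph: OntologyGraph,
    aggregate: str = "sum",
) -> dict[str, float]:
    """Per-gene IC gap over each gene's direct annotations."""
    table = {}
    for g in gene_corpus.entities:
        phenos = gene_corpus.direct[g]
        table[g] = ic_gap(phenos, human_classes, ic, graph, aggregate) if phenos else 0.0
    return table
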