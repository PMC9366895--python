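"""Entity→phenotype annotation corpora, orthology maps and association tables.

An :class:`AnnotationCorpus` keeps both the *direct* annotations (the class
ids asserted for each gene or disease) and the *propagated* closure (every
ancestor of every direct class, as canonical ids — the "true-path" rule).
Information content is computed from the propagated sets; best-match-average
similarity is computed over the direct sets.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field

from .ontology import OntologyGraph

logger = logging.getLogger(__name__)

__all__ = [
    "AnnotationCorpus",
    "OrthologyMap",
    "GeneDiseaseAssociations",
    "load_annotations",
    "load_orthology",
    "load_associations",
    "combine_organism_annotations",
]


def _open_text(path, mode: str = "rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode, encoding="utf-8")
    return open(path, mode.replace("t", ""), encoding="utf-8")


@dataclass
class AnnotationCorpus:
    """Entity→phenotype annotations for one species' genes, or for diseases."""

    entity_kind: str  # "gene" | "disease"
    species_tag: str
    direct: dict[str, set[str]]
    propagated: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.entity_kind not in ("gene", "disease"):
            raise ValueError(f"entity_kind must be gene/disease, got {self.entity_kind!r}")

    @classmethod
    def from_direct(
        cls,
        direct: dict[str, set[str]],
        graph: OntologyGraph,
        entity_kind: str,
        species_tag: str,
    ) -> "AnnotationCorpus":
        corpus = cls(entity_kind=entity_kind, species_tag=species_tag, direct=direct)
        corpus.propagate(graph)
        return corpus

    def propagate(self, graph: OntologyGraph) -> None:
        """(Re)compute the ancestor-closed propagated sets from the direct sets."""
        self.propagated = {
            entity: frozenset().union(*(graph.ancestors(c) for c in classes))
            if classes
            else frozenset()
            for entity, classes in self.direct.items()
        }

    @property
    def entities(self) -> list[str]:
        return sorted(self.direct)

    def __len__(self) -> int:
        return len(self.direct)

    def to_tsv(self, path) -> None:
        with _open_text(path, "wt") as fh:
            for entity in sorted(self.direct):
                for cid in sorted(self.direct[entity]):
                    fh.write(f"{entity}\t{cid}\n")


@dataclass
class OrthologyMap:
    """Pairs of orthologous genes between two species (possibly non-injective)."""

    species_a: str
    species_b: str
    pairs: set[tuple[str, str]]

    def orthologs_of(self, gene: str, species: str) -> set[str]:
        """Orthologs of ``gene``, where ``species`` names the side ``gene`` is on."""
        if species == self.species_a:
            return {b for a, b in self.pairs if a == gene}
        if species == self.species_b:
            return {a for a, b in self.pairs if b == gene}
        raise ValueError(f"species {species!r} not covered by this map")

    def to_tsv(self, path) -> None:
        with _open_text(path, "wt") as fh:
            for a, b in sorted(self.pairs):
                fh.write(f"{a}\t{b}\n")


@dataclass
class GeneDiseaseAssociations:
    """Known gene–disease association truth table."""

    positives: set[tuple[str, str]]

    def genes_for(self, disease_id: str) -> set[str]:
        return {g for g, d in self.positives if d == disease_id}

    def diseases(self) -> list[str]:
        return sorted({d for _, d in self.positives})

    def genes(self) -> list[str]:
        return sorted({g for g, _ in self.positives})

    def to_tsv(self, path) -> None:
        with _open_text(path, "wt") as fh:
            for g, d in sorted(self.positives):
                fh.write(f"{g}\t{d}\n")


# ---------------------------------------------------------------------------
# Loaders (two-column TSV, optional header, transparent gzip)


def _read_rows(path, header: bool) -> list[list[str]]:
    rows: list[list[str]] = []
    with _open_text(path) as fh:
        for i, line in enumerate(fh):
            if header and i == 0:
                continue
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            rows.append(line.split("\t"))
    return rows


def load_annotations(
    path,
    entity_kind: str,
    species_tag: str,
    graph: OntologyGraph,
    max_unknown_fraction: float = 0.05,
    header: bool = False,
) -> AnnotationCorpus:
    """Load a two-column (entity_id, class_id) TSV and propagate the closure.

    Rows whose class id is unknown to the ontology are dropped with a logged
    warning; if more than ``max_unknown_fraction`` of rows are unknown the
    load fails, listing the offending ids.
    """
    rows = _read_rows(path, header)
    if not rows:
        raise ValueError(f"annotation file {path} is empty")
    direct: dict[str, set[str]] = {}
    unknown: list[tuple[str, str]] = []
    for row in rows:
        if len(row) < 2:
            raise ValueError(f"annotation row with <2 columns in {path}: {row!r}")
        entity, cid = row[0], row[1]
        if cid not in graph:
            unknown.append((entity, cid))
            continue
        direct.setdefault(entity, set()).add(cid)
    if unknown:
        frac = len(unknown) / len(rows)
        offenders = sorted({c for _, c in unknown})
        if frac > max_unknown_fraction:
            raise ValueError(
                f"{len(unknown)}/{len(rows)} rows ({frac:.1%}) reference unknown "
                f"classes (limit {max_unknown_fraction:.0%}): {offenders[:20]}"
            )
        logger.warning(
            "dropped %d/%d annotation rows with unknown class ids: %s",
            len(unknown),
            len(rows),
            offenders[:10],
        )
    return AnnotationCorpus.from_direct(direct, graph, entity_kind, species_tag)


def load_orthology(path, species_a: str, species_b: str, header: bool = False) -> OrthologyMap:
    rows = _read_rows(path, header)
    return OrthologyMap(species_a, species_b, {(r[0], r[1]) for r in rows})


def load_associations(path, header: bool = False) -> GeneDiseaseAssociations:
    rows = _read_rows(path, header)
    return GeneDiseaseAssociations({(r[0], r[1]) for r in rows})


# ---------------------------------------------------------------------------
# Cross-organism combination


def combine_organism_annotations(
    corpora: list[AnnotationCorpus],
    orthology: list[OrthologyMap],
    anchor_species: str,
) -> AnnotationCorpus:
    """Pool each anchor-species gene's phenotypes with those of its orthologs.

    For every gene of the anchor corpus the combined direct/propagated sets
    are the union over the gene itself and *all* of its orthologs found in the
    other corpora (non-1:1 orthology unions over every ortholog).  Genes with
    no ortholog keep their own sets; the operation is commutative and
    associative over the non-anchor corpora and idempotent.
    """
    anchors = [c for c in corpora if c.species_tag == anchor_species]
    if not anchors:
        raise ValueError(f"no corpus with anchor species {anchor_species!r}")
    anchor = anchors[0]
    others = {c.species_tag: c for c in corpora if c is not anchor}

    direct: dict[str, set[str]] = {}
    propagated: dict[str, frozenset[str]] = {}
    for gene in anchor.direct:
        d = set(anchor.direct[gene])
        p = set(anchor.propagated.get(gene, frozenset()))
        for omap in orthology:
            if anchor_species == omap.species_a:
                other_tag = omap.species_b
            elif anchor_species == omap.species_b:
                other_tag = omap.species_a
            else:
                continue
            other = others.get(other_tag)
            if other is None:
                continue
            for ortho in sorted(omap.orthologs_of(gene, anchor_species)):
                d |= other.direct.get(ortho, set())
                p |= other.propagated.get(ortho, frozenset())
        direct[gene] = d
        propagated[gene] = frozenset(p)
    combined = AnnotationCorpus(
        entity_kind=anchor.entity_kind, species_tag=anchor_species, direct=direct
    )
    combined.propagated = propagated
    return combined
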