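"""Integrated cross-species phenotype ontology: classes, subclass/relation
edges, equivalence bridging, and ancestor reasoning.

The central object is :class:`OntologyGraph`, a DAG of phenotype classes in
which classes from different species-specific vocabularies may be declared
equivalent (e.g. the fly nervous system and the zebrafish nervous system).
Equivalence is handled by merging each equivalence set onto a canonical
representative, so that ancestor sets — and hence the most informative common
ancestor used by Resnik similarity — are well defined across species.

Only subclass (``is_a``) edges and equivalences contribute to the taxonomic
closure; labeled relation edges (part-of, results-from, ...) are stored for
export to the embedding graphs but never enter ``ancestors``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import obonet

__all__ = [
    "RELATION_NAMES",
    "SPECIES_TAGS",
    "PhenotypePattern",
    "PhenotypeClass",
    "OntologyGraph",
    "OntologyError",
    "parse_obo",
    "write_obo",
    "build_phenotype_class",
    "cross_species_subsumption_counts",
]

#: Relation vocabulary admitted on labeled (non-taxonomic) edges.
RELATION_NAMES = frozenset(
    {
        "part-of",
        "results-from",
        "during",
        "has-quality",
        "has-central-participant",
        "occurs-in",
        "towards",
    }
)

SPECIES_TAGS = frozenset({"human", "mouse", "fish", "fly", "yeast", "integrated"})


class OntologyError(ValueError):
    """Raised for structural problems: duplicate ids, dangling edges, cycles."""


@dataclass(frozen=True)
class PhenotypePattern:
    """Structural phenotype definition: an abnormal quality of an entity.

    ``entity`` is a class from an anatomy or process vocabulary, ``quality``
    a quality-vocabulary class (or the generic "Quality"), and the modifier
    is always "Abnormal".  ``relations`` lists the labeled relations the
    pattern traverses.
    """

    entity: str
    quality: str = "Quality"
    modifier: str = "Abnormal"
    relations: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.entity or not self.quality:
            raise ValueError("pattern entity and quality must be non-empty")
        bad = set(self.relations) - RELATION_NAMES
        if bad:
            raise ValueError(f"unknown pattern relations: {sorted(bad)}")


@dataclass
class PhenotypeClass:
    """A phenotype class: CURIE-like id, label, species tag, optional pattern."""

    id: str
    label: str | None = None
    species_tag: str = "integrated"
    definition_pattern: PhenotypePattern | None = None

    def __post_init__(self) -> None:
        if self.species_tag not in SPECIES_TAGS:
            raise ValueError(f"unknown species tag {self.species_tag!r}")


class OntologyGraph:
    """DAG of phenotype classes with subclass, relation and equivalence structure.

    Identifiers are case-sensitive CURIEs.  Equivalence sets are maintained by
    union-find; the canonical representative of a set is its lexicographically
    smallest member.  All reasoning (``ancestors``, subsumption counting) is
    done over canonical ids.
    """

    def __init__(self) -> None:
        self.classes: dict[str, PhenotypeClass] = {}
        self.subclass_edges: set[tuple[str, str]] = set()
        self.relation_edges: set[tuple[str, str, str]] = set()
        self._uf_parent: dict[str, str] = {}
        self._closure: dict[str, frozenset[str]] | None = None
        self._depths: dict[str, int] | None = None

    # -- construction -------------------------------------------------

    def add_class(self, cls: PhenotypeClass) -> PhenotypeClass:
        if cls.id in self.classes:
            raise OntologyError(f"duplicate class id {cls.id!r}")
        self.classes[cls.id] = cls
        self._uf_parent[cls.id] = cls.id
        self._closure = None
        self._depths = None
        return cls

    def has_class(self, class_id: str) -> bool:
        return class_id in self.classes

    def add_subclass_edge(self, child: str, parent: str) -> None:
        self._require(child)
        self._require(parent)
        self.subclass_edges.add((child, parent))
        self._closure = None
        self._depths = None

    def add_relation_edge(self, subject: str, relation: str, obj: str) -> None:
        if relation == "is_a":
            raise ValueError("use add_subclass_edge for taxonomic edges")
        self._require(subject)
        self._require(obj)
        self.relation_edges.add((subject, relation, obj))
        self._closure = None
        self._depths = None

    def add_equivalence(self, a: str, b: str) -> None:
        self._require(a)
        self._require(b)
        ra, rb = self._find(a), self._find(b)
        if ra != rb:
            # union by lexicographic order so canonical = smallest member
            lo, hi = sorted((ra, rb))
            self._uf_parent[hi] = lo
            self._closure = None
        self._depths = None

    def _require(self, class_id: str) -> None:
        if class_id not in self.classes:
            raise OntologyError(f"unknown class id {class_id!r}")

    def _find(self, class_id: str) -> str:
        root = class_id
        while self._uf_parent[root] != root:
            root = self._uf_parent[root]
        while self._uf_parent[class_id] != root:  # path compression
            self._uf_parent[class_id], class_id = root, self._uf_parent[class_id]
        return root

    # -- equivalence views --------------------------------------------

    def canonical(self, class_id: str) -> str:
        self._require(class_id)
        return self._find(class_id)

    @property
    def canonical_map(self) -> dict[str, str]:
        return {cid: self._find(cid) for cid in self.classes}

    @property
    def equivalence_sets(self) -> list[frozenset[str]]:
        """Non-singleton equivalence sets."""
        groups: dict[str, set[str]] = {}
        for cid in self.classes:
            groups.setdefault(self._find(cid), set()).add(cid)
        return [frozenset(g) for g in groups.values() if len(g) > 1]

    def members(self, canonical_id: str) -> frozenset[str]:
        """All class ids whose canonical representative is ``canonical_id``."""
        return frozenset(c for c in self.classes if self._find(c) == canonical_id)

    def species_of(self, canonical_id: str) -> frozenset[str]:
        """Species tags present in the equivalence group of a canonical id."""
        return frozenset(self.classes[m].species_tag for m in self.members(canonical_id))

    # -- reasoning -----------------------------------------------------

    def canonical_digraph(self) -> nx.DiGraph:
        """Child->parent digraph over canonical ids (taxonomic edges only)."""
        g = nx.DiGraph()
        g.add_nodes_from({self._find(c) for c in self.classes})
        for child, parent in self.subclass_edges:
            cc, cp = self._find(child), self._find(parent)
            if cc != cp:
                g.add_edge(cc, cp)
        return g

    def validate(self) -> None:
        """Raise :class:`OntologyError` (listing one cycle) if the canonical
        subclass relation is cyclic."""
        g = self.canonical_digraph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = [u for u, _ in nx.find_cycle(g)]
            raise OntologyError(f"subclass cycle after canonicalization: {cycle}")

    def _ensure_closure(self) -> dict[str, frozenset[str]]:
        if self._closure is None:
            g = self.canonical_digraph()
            try:
                order = list(nx.topological_sort(g))
            except nx.NetworkXUnfeasible:
                self.validate()  # raises with an explicit cycle
                raise AssertionError("unreachable")
            closure: dict[str, frozenset[str]] = {}
            for node in reversed(order):  # parents before children
                anc: set[str] = {node}
                for parent in g.successors(node):
                    anc |= closure[parent]
                closure[node] = frozenset(anc)
            self._closure = closure
        return self._closure

    def ancestors(self, class_id: str) -> frozenset[str]:
        """Reflexive-transitive superclass closure, as canonical ids.

        Equivalent classes share identical ancestor sets.
        """
        self._require(class_id)
        return self._ensure_closure()[self._find(class_id)]

    def roots(self) -> list[str]:
        """Canonical ids with no superclass."""
        g = self.canonical_digraph()
        return sorted(n for n in g.nodes if g.out_degree(n) == 0)

    def depth(self, class_id: str) -> int:
        """Length of the longest subclass path from the class to a root."""
        self._require(class_id)
        if self._depths is None:
            g = self.canonical_digraph()
            depths: dict[str, int] = {}
            # edges run child->parent, so a node's parents are its
            # successors; fill roots first by walking topological order
            # backwards
            for node in reversed(list(nx.topological_sort(g))):
                depths[node] = max(
                    (depths[p] for p in g.successors(node)), default=-1
                ) + 1
            self._depths = depths
        return self._depths[self._find(class_id)]

    # -- misc ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.classes)

    def __contains__(self, class_id: str) -> bool:
        return class_id in self.classes

    def edge_list(self) -> list[tuple[str, str, str]]:
        """(child, relation, parent) triples for debugging exports."""
        rows = [(c, "is_a", p) for c, p in self.subclass_edges]
        rows += [(s, r, o) for s, r, o in self.relation_edges]
        for group in self.equivalence_sets:
            ordered = sorted(group)
            rows += [(a, "equivalent_to", b) for a, b in zip(ordered, ordered[1:])]
        return sorted(rows)


# ---------------------------------------------------------------------------
# OBO flat-file subset I/O


_ID_LINE = re.compile(r"^id:\s*(\S+)")


def parse_obo(path, species_map: Mapping[str, str] | None = None) -> OntologyGraph:
    """Read an OBO flat-file subset into an :class:`OntologyGraph`.

    Supported tags: ``id``, ``name``, ``is_a``, ``relationship`` and the
    ``equivalent_to`` dialect tag (paired reciprocal ``is_a`` edges are also
    folded into equivalences, as a portable fallback).  ``species_map``
    assigns species tags by CURIE prefix, e.g. ``{"HP": "human"}``; unmapped
    prefixes are tagged ``integrated``.

    Raises :class:`OntologyError` on duplicate ids, edges to unknown ids, or
    a subclass cycle surviving canonicalization.
    """
    species_map = dict(species_map or {})

    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    seen: set[str] = set()
    in_term = False
    for line in text.splitlines():
        line = line.strip()
        if line.startswith("["):
            in_term = line == "[Term]"
        elif in_term:
            m = _ID_LINE.match(line)
            if m:
                if m.group(1) in seen:
                    raise OntologyError(f"duplicate class id {m.group(1)!r}")
                seen.add(m.group(1))

    nxg = obonet.read_obo(path, ignore_obsolete=True)

    def tag_for(cid: str) -> str:
        prefix = cid.split(":", 1)[0]
        return species_map.get(prefix, "integrated")

    graph = OntologyGraph()
    stanza_ids = [n for n, data in nxg.nodes(data=True) if data]
    for cid in stanza_ids:
        graph.add_class(
            PhenotypeClass(cid, label=nxg.nodes[cid].get("name"), species_tag=tag_for(cid))
        )

    for cid in stanza_ids:
        data = nxg.nodes[cid]
        for parent in data.get("is_a", []):
            if parent not in graph:
                raise OntologyError(f"is_a from {cid!r} references unknown id {parent!r}")
            graph.add_subclass_edge(cid, parent)
        for rel_line in data.get("relationship", []):
            rel, obj = rel_line.split()[:2]
            rel = rel.replace("_", "-")
            if obj not in graph:
                graph.add_class(PhenotypeClass(obj, species_tag=tag_for(obj)))
            graph.add_relation_edge(cid, rel, obj)
        for other in data.get("equivalent_to", []):
            if other not in graph:
                # referenced only via the equivalence tag: materialize it
                graph.add_class(PhenotypeClass(other, species_tag=tag_for(other)))
            graph.add_equivalence(cid, other)

    _fold_reciprocal_is_a(graph)
    graph.validate()
    return graph


def _fold_reciprocal_is_a(graph: OntologyGraph) -> None:
    """Interpret paired reciprocal is_a edges as equivalence assertions."""
    recip = {(c, p) for c, p in graph.subclass_edges if (p, c) in graph.subclass_edges and c != p}
    for child, parent in sorted(recip):
        graph.subclass_edges.discard((child, parent))
        graph.subclass_edges.discard((parent, child))
        graph.add_equivalence(child, parent)


def write_obo(graph: OntologyGraph, path) -> None:
    """Serialize in the same OBO subset ``parse_obo`` reads (round-trippable)."""
    child_parents: dict[str, list[str]] = {}
    for c, p in graph.subclass_edges:
        child_parents.setdefault(c, []).append(p)
    relations: dict[str, list[tuple[str, str]]] = {}
    for s, r, o in graph.relation_edges:
        relations.setdefault(s, []).append((r, o))
    equiv_lines: dict[str, list[str]] = {}
    for group in graph.equivalence_sets:
        ordered = sorted(group)
        for a, b in zip(ordered, ordered[1:]):
            equiv_lines.setdefault(a, []).append(b)

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        for cid in sorted(graph.classes):
            cls = graph.classes[cid]
            fh.write("\n[Term]\n")
            fh.write(f"id: {cid}\n")
            if cls.label:
                fh.write(f"name: {cls.label}\n")
            for parent in sorted(child_parents.get(cid, [])):
                fh.write(f"is_a: {parent}\n")
            for rel, obj in sorted(relations.get(cid, [])):
                fh.write(f"relationship: {rel.replace('-', '_')} {obj}\n")
            for other in sorted(equiv_lines.get(cid, [])):
                fh.write(f"equivalent_to: {other}\n")


# ---------------------------------------------------------------------------
# Abnormal-anatomy phenotype classes (the "phenotypic abnormality of X" pattern)


def build_phenotype_class(
    entity: str,
    ontology: OntologyGraph,
    species_tag: str,
    quality: str = "Quality",
) -> PhenotypeClass:
    """Create (idempotently) the abnormal-anatomy phenotype class for an entity.

    Given an anatomy class like the fly "wing", mints a class
    ``<PREFIX>AB:<local-id>`` labeled "phenotypic abnormality of wing" whose
    definition pattern records (entity, quality, Abnormal).  The new class is
    placed under the species' abnormality root (itself created on demand);
    when the entity's parent already has an abnormal counterpart, the
    abnormal classes mirror that step of the anatomy hierarchy.
    """
    if entity not in ontology:
        raise OntologyError(f"unknown entity id {entity!r}")
    prefix, _, local = entity.partition(":")
    if not local:
        prefix, local = "X", entity
    new_id = f"{prefix}AB:{local}"
    if new_id in ontology:
        return ontology.classes[new_id]

    ab_root_id = f"{prefix}AB:ROOT"
    if ab_root_id not in ontology:
        ontology.add_class(
            PhenotypeClass(
                ab_root_id,
                label=f"phenotypic abnormality ({species_tag})",
                species_tag=species_tag,
            )
        )

    entity_label = ontology.classes[entity].label or entity
    cls = ontology.add_class(
        PhenotypeClass(
            new_id,
            label=f"phenotypic abnormality of {entity_label}",
            species_tag=species_tag,
            definition_pattern=PhenotypePattern(entity=entity, quality=quality),
        )
    )
    # mirror the anatomy hierarchy where abnormal counterparts already exist
    parents = sorted(p for c, p in ontology.subclass_edges if c == entity)
    mirrored = False
    for parent in parents:
        pprefix, _, plocal = parent.partition(":")
        ab_parent = f"{pprefix}AB:{plocal}"
        if ab_parent in ontology:
            ontology.add_subclass_edge(new_id, ab_parent)
            mirrored = True
    if not mirrored:
        ontology.add_subclass_edge(new_id, ab_root_id)
    return cls


# ---------------------------------------------------------------------------
# Cross-species subsumption accounting


def cross_species_subsumption_counts(
    graph: OntologyGraph, species_a: str, species_b: str
) -> dict[str, int]:
    """Count subclass/superclass pairs linking two species' classes.

    A pair (c_a, c_b) with c_a tagged ``species_a``, c_b tagged ``species_b``
    and c_b a proper superclass of c_a counts toward ``subclass``; the
    transposed relation counts toward ``superclass``.  Each is split into
    ``direct`` (an asserted subclass edge joins the two equivalence groups)
    and ``inferred`` (reachable only through the closure).  Cross-species
    pairs made equivalent by bridging are counted under ``equivalent``.
    """
    for tag in (species_a, species_b):
        if tag not in SPECIES_TAGS:
            raise OntologyError(f"unknown species tag {tag!r}")

    by_species: dict[str, list[str]] = {species_a: [], species_b: []}
    for cid, cls in graph.classes.items():
        if cls.species_tag in by_species:
            by_species[cls.species_tag].append(cid)

    direct_pairs = {(graph.canonical(c), graph.canonical(p)) for c, p in graph.subclass_edges}

    counts = {
        "subclass_direct": 0,
        "subclass_inferred": 0,
        "superclass_direct": 0,
        "superclass_inferred": 0,
        "equivalent": 0,
    }

    def tally(src: list[str], dst: list[str], kind: str) -> None:
        dst_by_canon: dict[str, int] = {}
        for d in dst:
            dst_by_canon[graph.canonical(d)] = dst_by_canon.get(graph.canonical(d), 0) + 1
        for c in src:
            cc = graph.canonical(c)
            for a in graph.ancestors(c):
                n = dst_by_canon.get(a, 0)
                if not n:
                    continue
                if a == cc:
                    continue  # equivalence, tallied separately
                key = "direct" if (cc, a) in direct_pairs else "inferred"
                counts[f"{kind}_{key}"] += n

    tally(by_species[species_a], by_species[species_b], "subclass")
    tally(by_species[species_b], by_species[species_a], "superclass")

    for a in by_species[species_a]:
        ca = graph.canonical(a)
        for b in by_species[species_b]:
            if graph.canonical(b) == ca:
                counts["equivalent"] += 1
    return counts
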