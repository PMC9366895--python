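"""Synthetic cross-species phenotype benchmarks.

The generator emulates the statistical structure of an integrated
cross-species phenotype resource without any external download:

* two species-specific phenotype vocabularies (a "human" tree and one model
  organism tree) under a shared root, grown by seeded preferential
  branching, with a configurable fraction of model classes bridged to
  depth-matched human classes by equivalence;
* diseases annotated with human classes (depth-weighted, so specific
  classes carry information), each associated with one gene whose model
  ortholog mirrors the disease phenotypes across the species bridge with a
  controllable *fidelity* f;
* a controllable *study bias*: associated genes can receive more
  (``bias_multiplier``) and deeper (``depth_bias``) annotations than
  non-associated genes, with no change to the biological signal — this is
  the knob that lets the naive IC classifier succeed at f = 0;
* a 1:1 orthology table between human and model gene ids.

Bundles serialize to plain-text formats (OBO + TSV + YAML) and reload
through the package's own parsers, byte-identically for a fixed seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import yaml

from .annotations import (
    AnnotationCorpus,
    GeneDiseaseAssociations,
    OrthologyMap,
    load_annotations,
    load_associations,
    load_orthology,
)
from .ontology import OntologyGraph, PhenotypeClass, parse_obo, write_obo

__all__ = ["SyntheticConfig", "BenchmarkBundle", "generate_ontology", "generate_annotations", "generate_bundle"]

ROOT_ID = "PHENO:0000000"
HUMAN_ROOT = "HP:0000001"
MODEL_ROOT = "MP:0000001"


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic benchmark; defaults are the study conditions."""

    n_human_classes: int = 800
    n_model_classes: int = 800
    branching: float = 3.0  # preferential-attachment weight on already-branchy classes
    bridge_fraction: float = 0.8
    n_genes: int = 300
    n_diseases: int = 100
    pheno_per_disease: float = 6.0
    pheno_per_gene: float = 6.0
    fidelity: float = 0.9  # probability a disease phenotype is mirrored in the ortholog
    bias_multiplier: float = 1.0  # annotation-count inflation for associated genes
    # depth-bias strength s: 0/False = off; s > 0 refines each of an
    # associated gene's random annotations ~s child-steps down the tree
    # (curators of well-studied genes record more specific terms)
    depth_bias: bool | float = False
    model_species: str = "mouse"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_human_classes", "n_model_classes", "n_genes", "n_diseases"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("fidelity", "bridge_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.bias_multiplier < 1.0:
            raise ValueError("bias_multiplier must be >= 1")
        if self.n_diseases > self.n_genes:
            raise ValueError("need at least one gene per disease")


@dataclass
class BenchmarkBundle:
    """A complete synthetic (or loaded) experiment input set."""

    ontology: OntologyGraph
    gene_corpora: dict[str, AnnotationCorpus]
    disease_corpus: AnnotationCorpus
    orthology: OrthologyMap
    truth: GeneDiseaseAssociations
    config: SyntheticConfig | None = None

    @property
    def model_species(self) -> str:
        return sorted(self.gene_corpora)[0]

    @property
    def gene_corpus(self) -> AnnotationCorpus:
        """The (single) model-organism gene corpus of a default bundle."""
        return self.gene_corpora[self.model_species]

    def human_classes(self) -> set[str]:
        return {
            cid for cid, cls in self.ontology.classes.items() if cls.species_tag == "human"
        }

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_obo(self.ontology, directory / "ontology.obo")
        for species in sorted(self.gene_corpora):
            self.gene_corpora[species].to_tsv(directory / f"genes_{species}.tsv")
        self.disease_corpus.to_tsv(directory / "diseases.tsv")
        self.orthology.to_tsv(directory / "orthology.tsv")
        self.truth.to_tsv(directory / "associations.tsv")
        if self.config is not None:
            with open(directory / "config.yaml", "w", encoding="utf-8") as fh:
                yaml.safe_dump(asdict(self.config), fh, sort_keys=True)

    @classmethod
    def load(cls, directory) -> "BenchmarkBundle":
        directory = Path(directory)
        config = None
        cfg_path = directory / "config.yaml"
        if cfg_path.exists():
            with open(cfg_path, encoding="utf-8") as fh:
                config = SyntheticConfig(**yaml.safe_load(fh))
        species_map = {"HP": "human", "PHENO": "integrated"}
        if config is not None:
            species_map["MP"] = config.model_species
        graph = parse_obo(directory / "ontology.obo", species_map=species_map)
        gene_corpora = {}
        for path in sorted(directory.glob("genes_*.tsv")):
            species = path.stem.removeprefix("genes_")
            gene_corpora[species] = load_annotations(path, "gene", species, graph)
        disease_corpus = load_annotations(directory / "diseases.tsv", "disease", "human", graph)
        model = sorted(gene_corpora)[0]
        orthology = load_orthology(directory / "orthology.tsv", "human", model)
        truth = load_associations(directory / "associations.tsv")
        return cls(
            ontology=graph,
            gene_corpora=gene_corpora,
            disease_corpus=disease_corpus,
            orthology=orthology,
            truth=truth,
            config=config,
        )


# ---------------------------------------------------------------------------
# Ontology generation


def _grow_tree(
    graph: OntologyGraph,
    root: str,
    prefix: str,
    n: int,
    species: str,
    branching: float,
    rng: np.random.Generator,
) -> list[str]:
    """Grow a tree of n classes under ``root`` by preferential branching.

    A new class attaches to an existing one with probability proportional to
    (children + branching); larger ``branching`` flattens the weighting and
    yields bushier, shallower trees, smaller values produce deeper chains.
    """
    ids = [root]
    children = {root: 0}
    for i in range(n):
        weights = np.array([children[c] + branching for c in ids])
        parent = ids[rng.choice(len(ids), p=weights / weights.sum())]
        cid = f"{prefix}:{i + 2:07d}"
        graph.add_class(PhenotypeClass(cid, label=f"{species} phenotype {i + 2}", species_tag=species))
        graph.add_subclass_edge(cid, parent)
        children[parent] += 1
        children[cid] = 0
        ids.append(cid)
    return ids[1:]


def generate_ontology(config: SyntheticConfig) -> OntologyGraph:
    """Shared root, human and model subtrees, and depth-matched equivalences.

    ``bridge_fraction`` of the model classes — preferentially the shallower,
    more general ones — are made equivalent to human classes of exactly the
    same depth (classes whose depth has no human counterpart stay
    unbridged).  Equal-depth bridging keeps every subclass edge strictly
    depth-decreasing, so the merged graph is acyclic by construction.
    Total class count is n_human_classes + n_model_classes + 1 (the shared
    root; the two species roots count toward their species).
    """
    if config.bridge_fraction > 0 and config.n_human_classes == 0:
        raise ValueError("cannot bridge to human classes when there are none")
    rng = np.random.default_rng(config.seed)
    graph = OntologyGraph()
    graph.add_class(PhenotypeClass(ROOT_ID, label="phenotypic abnormality", species_tag="integrated"))
    graph.add_class(PhenotypeClass(HUMAN_ROOT, label="human phenotypic abnormality", species_tag="human"))
    graph.add_class(
        PhenotypeClass(MODEL_ROOT, label=f"{config.model_species} phenotypic abnormality", species_tag=config.model_species)
    )
    graph.add_subclass_edge(HUMAN_ROOT, ROOT_ID)
    graph.add_subclass_edge(MODEL_ROOT, ROOT_ID)
    human = _grow_tree(
        graph, HUMAN_ROOT, "HP", config.n_human_classes - 1, "human", config.branching, rng
    )
    model = _grow_tree(
        graph, MODEL_ROOT, "MP", config.n_model_classes - 1, config.model_species, config.branching, rng
    )

    if config.bridge_fraction > 0:
        # any integrated resource bridges at least the top-level phenotype
        # classes; without it, unbridged model classes would have no human
        # superclass at all
        graph.add_equivalence(HUMAN_ROOT, MODEL_ROOT)

    n_bridges = int(round(config.bridge_fraction * len(model)))
    # depths are fixed by the trees; bridging only ever joins equal-depth
    # classes, so every subclass edge keeps strictly decreasing depth and no
    # cycle can arise — no incremental validation needed
    depth = {c: graph.depth(c) for c in human + model}
    human_by_depth: dict[int, list[str]] = {}
    for h in human:
        human_by_depth.setdefault(depth[h], []).append(h)
    # Equivalences exist mostly for general, homologous structures: bridge
    # with probability decaying in depth, so deep species-specific classes
    # tend to reach the human side only through shallower bridged ancestors.
    candidates = sorted(model)
    if n_bridges < len(candidates):
        w = np.array([1.0 / (1.0 + depth[m]) for m in candidates])
        idx = rng.choice(len(candidates), size=n_bridges, replace=False, p=w / w.sum())
        candidates = [candidates[i] for i in sorted(idx)]
    candidates.sort(key=lambda m: (depth[m], m))
    for m in candidates:
        pool = human_by_depth.get(depth[m])
        if not pool:
            continue  # no human class at this depth: the class stays unbridged
        graph.add_equivalence(m, pool[rng.integers(len(pool))])
    graph.validate()
    return graph


# ---------------------------------------------------------------------------
# Annotation / truth generation


def _count(rng: np.random.Generator, mean: float) -> int:
    return max(1, int(rng.poisson(mean)))


def _depth_weights(graph: OntologyGraph, ids: list[str], power: float = 1.0) -> np.ndarray:
    w = np.maximum(np.array([graph.depth(c) for c in ids], dtype=float), 0.01) ** power
    return w / w.sum()


def _sample(
    rng: np.random.Generator,
    ids: list[str],
    k: int,
    weights: np.ndarray | None,
) -> list[str]:
    k = min(k, len(ids))
    idx = rng.choice(len(ids), size=k, replace=False, p=weights)
    return [ids[i] for i in idx]


def generate_annotations(ontology: OntologyGraph, config: SyntheticConfig) -> BenchmarkBundle:
    """Annotate diseases and genes and assemble the full benchmark bundle.

    Each disease gets depth-weighted human phenotype classes and one
    associated gene; the gene's model ortholog mirrors each disease
    phenotype across the equivalence bridge with probability ``fidelity``
    (via the deepest bridged ancestor, sometimes descending to one of its
    children), and otherwise draws random model classes.  Associated genes'
    annotation counts are inflated by ``bias_multiplier`` and, when
    ``depth_bias`` is on, their random draws are depth-weighted.
    Non-associated genes receive uniform random model classes.
    """
    if config.fidelity > 0 and config.bridge_fraction == 0:
        raise ValueError("fidelity > 0 requires bridge_fraction > 0 (no mirror possible)")
    rng = np.random.default_rng(config.seed + 1)

    human = sorted(
        c for c, cls in ontology.classes.items()
        if cls.species_tag == "human" and c != HUMAN_ROOT
    )
    model = sorted(
        c for c, cls in ontology.classes.items()
        if cls.species_tag == config.model_species and c != MODEL_ROOT
    )
    human_w = _depth_weights(ontology, human)
    bias_strength = float(config.depth_bias)

    # model counterpart of each canonical id that carries a model-tagged member
    model_of_canon: dict[str, str] = {}
    for m in model:
        model_of_canon.setdefault(ontology.canonical(m), m)
    model_children: dict[str, list[str]] = {m: [] for m in model}
    for child, parent in sorted(ontology.subclass_edges):
        if child in model_children and parent in model_children:
            model_children[parent].append(child)

    def mirror(human_class: str) -> str | None:
        """Model class for the deepest bridged ancestor-or-self of a human class."""
        bridged = [a for a in ontology.ancestors(human_class) if a in model_of_canon]
        bridged = [a for a in bridged if a != ontology.canonical(ROOT_ID)]
        if not bridged:
            return None
        deepest = max(sorted(bridged), key=ontology.depth)
        m = model_of_canon[deepest]
        kids = model_children.get(m, [])
        if kids and rng.random() < 0.5:
            return kids[rng.integers(len(kids))]
        return m

    def refine(class_id: str, strength: float) -> str:
        """Descend ~``strength`` random child steps: curators of well-studied
        genes record the more specific term for the same phenotype."""
        steps = int(strength) + (1 if rng.random() < strength - int(strength) else 0)
        node = class_id
        for _ in range(steps):
            kids = model_children.get(node, [])
            if not kids:
                break
            node = kids[rng.integers(len(kids))]
        return node

    mirrorable = [h for h in human if mirror_exists(ontology, h, model_of_canon)]

    disease_ids = [f"DIS:{i:04d}" for i in range(config.n_diseases)]
    gene_ids = [f"MG:{i:05d}" for i in range(config.n_genes)]
    human_gene_ids = [f"HG:{i:05d}" for i in range(config.n_genes)]

    disease_direct: dict[str, set[str]] = {}
    for d in disease_ids:
        k = _count(rng, config.pheno_per_disease)
        phenos = set(_sample(rng, human, k, human_w))
        if config.fidelity > 0 and mirrorable and not any(p in mirrorable for p in phenos):
            # the benchmark requires each disease to be mappable cross-species
            phenos.add(mirrorable[rng.integers(len(mirrorable))])
        disease_direct[d] = phenos

    # one associated gene per disease, chosen in order
    truth_pairs = {(gene_ids[i], disease_ids[i]) for i in range(config.n_diseases)}
    associated = {gene_ids[i]: disease_ids[i] for i in range(config.n_diseases)}

    gene_direct: dict[str, set[str]] = {}
    for g in gene_ids:
        if g in associated:
            disease_phenos = sorted(disease_direct[associated[g]])
            annotations: set[str] = set()
            for h in disease_phenos:
                if rng.random() < config.fidelity:
                    m = mirror(h)
                    if m is not None:
                        annotations.add(m)
            # top up to the target count; at f = 0 this leaves associated
            # genes statistically identical to non-associated ones
            target = _count(rng, config.bias_multiplier * config.pheno_per_gene)
            while len(annotations) < target and len(annotations) < len(model):
                need = target - len(annotations)
                drawn = _sample(rng, model, need, None)
                if bias_strength > 0:
                    drawn = [refine(c, bias_strength) for c in drawn]
                annotations.update(drawn)
            gene_direct[g] = annotations
        else:
            k = _count(rng, config.pheno_per_gene)
            gene_direct[g] = set(_sample(rng, model, k, None))

    gene_corpus = AnnotationCorpus.from_direct(gene_direct, ontology, "gene", config.model_species)
    disease_corpus = AnnotationCorpus.from_direct(disease_direct, ontology, "disease", "human")
    orthology = OrthologyMap(
        "human", config.model_species, set(zip(human_gene_ids, gene_ids))
    )
    return BenchmarkBundle(
        ontology=ontology,
        gene_corpora={config.model_species: gene_corpus},
        disease_corpus=disease_corpus,
        orthology=orthology,
        truth=GeneDiseaseAssociations(truth_pairs),
        config=config,
    )


def mirror_exists(
    ontology: OntologyGraph, human_class: str, model_of_canon: dict[str, str]
) -> bool:
    root_canon = ontology.canonical(ROOT_ID)
    return any(
        a in model_of_canon and a != root_canon for a in ontology.ancestors(human_class)
    )


def generate_bundle(config: SyntheticConfig) -> BenchmarkBundle:
    """Convenience: ontology + annotations in one call."""
    return generate_annotations(generate_ontology(config), config)
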