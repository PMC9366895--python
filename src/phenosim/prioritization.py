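"""Per-disease gene ranking: similarity-based, naive IC-sum, and supervised.

The supervised route concatenates a gene embedding with a disease embedding
and feeds the pair to a single-hidden-layer perceptron (hidden width = half
the input, logistic output) trained with Adam (learning rate 0.001, up to
300 full-batch iterations) on the known associations plus five sampled
negatives per positive.  Evaluation is 10-fold cross-validation with folds
partitioned by disease, so a held-out disease is never seen during training
(an alternative mode partitions individual associations instead).

The naive classifier scores each gene by the summed information content of
its direct phenotype annotations and predicts the *same* ranked list for
every disease; it carries no disease information at all and exists purely
as a probe for annotation bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.neural_network import MLPClassifier

from .annotations import AnnotationCorpus, GeneDiseaseAssociations
from .embedding import EmbeddingTable
from .similarity import ICTable, SimilarityMatrix

__all__ = [
    "RankingResult",
    "SupervisedConfig",
    "SupervisedResult",
    "rank_genes",
    "rank_all",
    "naive_rank",
    "supervised_scores",
]


@dataclass
class RankingResult:
    """One disease's gene ranking (best first) with the truth set attached."""

    disease_id: str
    ranked_genes: list[str]
    scores: list[float]
    truth: set[str]

    @property
    def n_genes(self) -> int:
        return len(self.ranked_genes)

    def ranks_of_truth(self) -> list[int]:
        """1-based ranks of the associated genes present in the ranking."""
        pos = {g: i + 1 for i, g in enumerate(self.ranked_genes)}
        return sorted(pos[g] for g in self.truth if g in pos)


def rank_genes(
    matrix: SimilarityMatrix, disease_id: str, truth: set[str]
) -> RankingResult:
    """Sort the gene universe by descending similarity to one disease.

    Ties are broken by ascending gene id, making the ranking deterministic.
    """
    if disease_id not in matrix.disease_ids:
        raise KeyError(f"unknown disease {disease_id!r}")
    scores = matrix.scores_for_disease(disease_id)
    ordered = sorted(scores, key=lambda g: (-scores[g], g))
    return RankingResult(
        disease_id=disease_id,
        ranked_genes=ordered,
        scores=[scores[g] for g in ordered],
        truth=set(truth),
    )


def rank_all(
    matrix: SimilarityMatrix, associations: GeneDiseaseAssociations
) -> list[RankingResult]:
    """Rankings for every disease column of a similarity matrix."""
    return [
        rank_genes(matrix, d, associations.genes_for(d)) for d in matrix.disease_ids
    ]


def naive_rank(
    ic: ICTable,
    gene_corpus: AnnotationCorpus,
    disease_ids: list[str],
    associations: GeneDiseaseAssociations | None = None,
    graph=None,
) -> list[RankingResult]:
    """Disease-independent ranking by total IC of each gene's annotations.

    score(g) = Σ IC(c) over g's direct classes (0 for classes absent from the
    IC table, and for unannotated genes).  One ranking is computed and
    replicated for every requested disease.  Pass ``graph`` so annotations
    to non-canonical members of an equivalence set resolve to the merged
    class's IC (the IC table is keyed by canonical ids).
    """
    def key(c: str) -> str:
        return graph.canonical(c) if graph is not None and c in graph else c

    totals = {
        g: sum(ic.get(key(c)) for c in classes)
        for g, classes in gene_corpus.direct.items()
    }
    ordered = sorted(totals, key=lambda g: (-totals[g], g))
    scores = [totals[g] for g in ordered]
    results = []
    for d in disease_ids:
        truth = associations.genes_for(d) if associations is not None else set()
        results.append(
            RankingResult(
                disease_id=d, ranked_genes=list(ordered), scores=list(scores), truth=truth
            )
        )
    return results


# ---------------------------------------------------------------------------
# Supervised gene-disease association scoring


@dataclass
class SupervisedConfig:
    """Hyperparameters for the MLP link predictor."""

    hidden_fraction: float = 0.5
    learning_rate: float = 0.001
    max_iterations: int = 300
    negatives_per_positive: int = 5
    folds: int = 10
    seed: int = 0
    holdout: str = "diseases"  # "diseases" | "associations"

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if min(self.hidden_fraction, self.learning_rate, self.max_iterations,
               self.negatives_per_positive) <= 0:
            raise ValueError("all supervised hyperparameters must be positive")
        if self.holdout not in ("diseases", "associations"):
            raise ValueError(f"unknown holdout mode {self.holdout!r}")


@dataclass
class SupervisedResult:
    scores: SimilarityMatrix
    fold_of_disease: dict[str, int]
    train_pairs_per_fold: dict[int, list[tuple[str, str]]]
    loss_traces: dict[int, list[float]] = field(default_factory=dict)


def _sample_negatives(
    disease: str,
    positives_of: dict[str, set[str]],
    gene_pool: list[str],
    k: int,
    rng: np.random.Generator,
) -> list[str]:
    """k genes not associated with the disease, without replacement."""
    candidates = [g for g in gene_pool if g not in positives_of.get(disease, set())]
    k = min(k, len(candidates))
    idx = rng.choice(len(candidates), size=k, replace=False)
    return [candidates[i] for i in idx]


def supervised_scores(
    embeddings: EmbeddingTable,
    associations: GeneDiseaseAssociations,
    config: SupervisedConfig,
    gene_ids: list[str] | None = None,
    disease_ids: list[str] | None = None,
) -> SupervisedResult:
    """Cross-validated MLP scores for every (gene, held-out disease) pair.

    Diseases are partitioned into ``config.folds`` groups (seeded shuffle);
    for each fold an MLP is trained on the remaining folds' positive pairs
    plus ``negatives_per_positive`` sampled negatives per positive, and every
    gene is scored against each held-out disease with the logistic output.
    In ``holdout="associations"`` mode the individual positive pairs are
    partitioned instead, and a disease's column is averaged over the folds
    that held out one of its associations.
    """
    gene_ids = sorted(gene_ids) if gene_ids is not None else associations.genes()
    disease_ids = sorted(disease_ids) if disease_ids is not None else associations.diseases()
    missing = [t for t in gene_ids + disease_ids if t not in embeddings]
    if missing:
        raise KeyError(f"ids missing from embedding table: {missing[:10]}")
    if len(disease_ids) < config.folds:
        raise ValueError(
            f"{len(disease_ids)} diseases cannot fill {config.folds} folds"
        )

    positives_of: dict[str, set[str]] = {}
    for g, d in associations.positives:
        positives_of.setdefault(d, set()).add(g)

    rng = np.random.default_rng(config.seed)
    if config.holdout == "diseases":
        shuffled = list(disease_ids)
        rng.shuffle(shuffled)
        fold_of_disease = {d: i % config.folds for i, d in enumerate(shuffled)}
        fold_test_diseases = {
            k: sorted(d for d, f in fold_of_disease.items() if f == k)
            for k in range(config.folds)
        }
    else:
        pos_list = sorted(associations.positives)
        order = list(range(len(pos_list)))
        rng.shuffle(order)
        fold_of_pair = {pos_list[i]: j % config.folds for j, i in enumerate(order)}
        fold_test_diseases = {
            k: sorted({d for (g, d), f in fold_of_pair.items() if f == k})
            for k in range(config.folds)
        }
        fold_of_disease = {}  # a disease may appear in several folds

    emb = embeddings.vectors
    n_genes = len(gene_ids)
    gmat = np.stack([emb[g] for g in gene_ids])
    score_sum = np.zeros((n_genes, len(disease_ids)))
    score_cnt = np.zeros(len(disease_ids))
    dindex = {d: j for j, d in enumerate(disease_ids)}

    train_pairs_per_fold: dict[int, list[tuple[str, str]]] = {}
    loss_traces: dict[int, list[float]] = {}
    for k in range(config.folds):
        if config.holdout == "diseases":
            test_d = set(fold_test_diseases[k])
            train_pos = sorted(
                (g, d) for g, d in associations.positives
                if d in dindex and d not in test_d and g in embeddings
            )
        else:
            test_d = set(fold_test_diseases[k])
            train_pos = sorted(
                p for p in associations.positives
                if fold_of_pair[p] != k and p[1] in dindex and p[0] in embeddings
            )
        if not train_pos:
            raise ValueError(
                f"fold {k} has no training positives; use fewer folds"
            )
        X_rows, y = [], []
        for g, d in train_pos:
            X_rows.append(np.concatenate([emb[g], emb[d]]))
            y.append(1)
            negs = _sample_negatives(
                d, positives_of, gene_ids, config.negatives_per_positive, rng
            )
            for gneg in negs:
                X_rows.append(np.concatenate([emb[gneg], emb[d]]))
                y.append(0)
        X = np.stack(X_rows)
        yarr = np.asarray(y)
        hidden = max(1, int(round(X.shape[1] * config.hidden_fraction)))
        clf = MLPClassifier(
            hidden_layer_sizes=(hidden,),
            solver="adam",
            learning_rate_init=config.learning_rate,
            max_iter=config.max_iterations,
            batch_size=len(yarr),  # full-batch
            tol=1e-8,  # use the full iteration budget; default tol stops early
            n_iter_no_change=config.max_iterations,
            random_state=int(rng.integers(2**31 - 1)),
            shuffle=True,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # convergence warnings at fixed budget
            clf.fit(X, yarr)
        pos_col = int(np.where(clf.classes_ == 1)[0][0])
        for d in sorted(test_d):
            Xtest = np.hstack([gmat, np.tile(emb[d], (n_genes, 1))])
            probs = clf.predict_proba(Xtest)[:, pos_col]
            j = dindex[d]
            score_sum[:, j] += probs
            score_cnt[j] += 1
        train_pairs_per_fold[k] = train_pos
        loss_traces[k] = list(map(float, getattr(clf, "loss_curve_", [])))

    scored = score_cnt > 0
    values = np.zeros_like(score_sum)
    values[:, scored] = score_sum[:, scored] / score_cnt[scored]
    matrix = SimilarityMatrix("supervised", gene_ids, disease_ids, values)
    return SupervisedResult(
        scores=matrix,
        fold_of_disease=fold_of_disease,
        train_pairs_per_fold=train_pairs_per_fold,
        loss_traces=loss_traces,
    )
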