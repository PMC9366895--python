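"""Rank-based ROC evaluation, macro-averaged across diseases.

For every disease the gene universe is ranked; at each rank cutoff
k ∈ {0..n} the true-positive rate (associated genes recovered in the top k,
over all associated genes) and false-positive rate (non-associated genes in
the top k, over all non-associated genes) are recorded.  The per-disease
curves share the rank grid, so the macro average is the pointwise mean of
TPR and FPR at each k; the area under the averaged curve (trapezoid rule)
is the reported ROCAUC.  A uniformly random ranking yields 0.5; on a single
disease the statistic reduces to the Mann–Whitney rank-sum AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .prioritization import RankingResult

logger = logging.getLogger(__name__)

__all__ = ["ROCResult", "roc_from_rankings", "compare_auc", "AUCComparison"]


@dataclass
class ROCResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    n_diseases: int

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("fpr\ttpr\n")
            for f, t in zip(self.fpr, self.tpr):
                fh.write(f"{f:.10g}\t{t:.10g}\n")


def _curves(ranking: RankingResult) -> tuple[np.ndarray, np.ndarray] | None:
    n = ranking.n_genes
    truth = ranking.truth & set(ranking.ranked_genes)
    n_pos = len(truth)
    n_neg = n - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    is_pos = np.fromiter(
        (g in truth for g in ranking.ranked_genes), dtype=bool, count=n
    )
    tp = np.concatenate([[0], np.cumsum(is_pos)])
    fp = np.concatenate([[0], np.cumsum(~is_pos)])
    return fp / n_neg, tp / n_pos


def roc_from_rankings(rankings: list[RankingResult]) -> ROCResult:
    """Macro-averaged ROC over per-disease rankings of one gene universe.

    Rankings without any positive (or without any negative) are excluded
    with a warning; all remaining rankings must share the universe size.
    """
    usable: list[tuple[np.ndarray, np.ndarray]] = []
    sizes: set[int] = set()
    dropped = 0
    for r in rankings:
        pair = _curves(r)
        if pair is None:
            dropped += 1
            continue
        usable.append(pair)
        sizes.add(r.n_genes)
    if dropped:
        logger.warning("excluded %d rankings without positives/negatives", dropped)
    if not usable:
        raise ValueError("no evaluable rankings (each needs >=1 positive and negative)")
    if len(sizes) != 1:
        raise ValueError(f"rankings span multiple gene-universe sizes: {sorted(sizes)}")
    fpr = np.mean([f for f, _ in usable], axis=0)
    tpr = np.mean([t for _, t in usable], axis=0)
    auc = float(np.trapezoid(tpr, fpr))
    return ROCResult(fpr=fpr, tpr=tpr, auc=auc, n_diseases=len(usable))


@dataclass
class AUCComparison:
    auc_a: float
    auc_b: float
    difference: float
    p_value: float
    n_boot: int


def compare_auc(
    rankings_a: list[RankingResult],
    rankings_b: list[RankingResult],
    n_boot: int = 1000,
    seed: int = 0,
) -> AUCComparison:
    """Paired bootstrap comparison of two methods' macro ROCAUCs.

    Both ranking lists must cover the same diseases.  Diseases are resampled
    with replacement; both macro AUCs are recomputed on each resample and the
    two-sided p-value is read off the bootstrap distribution of the
    difference (with add-one smoothing, so p is never exactly 0).
    """
    by_a = {r.disease_id: r for r in rankings_a}
    by_b = {r.disease_id: r for r in rankings_b}
    common = sorted(set(by_a) & set(by_b))
    if not common:
        raise ValueError("the two ranking sets share no diseases")
    usable = [
        d for d in common
        if _curves(by_a[d]) is not None and _curves(by_b[d]) is not None
    ]
    ca = {d: _curves(by_a[d]) for d in usable}
    cb = {d: _curves(by_b[d]) for d in usable}

    def macro_auc(curves, idx) -> float:
        fpr = np.mean([curves[usable[i]][0] for i in idx], axis=0)
        tpr = np.mean([curves[usable[i]][1] for i in idx], axis=0)
        return float(np.trapezoid(tpr, fpr))

    full = list(range(len(usable)))
    auc_a, auc_b = macro_auc(ca, full), macro_auc(cb, full)
    rng = np.random.default_rng(seed)
    diffs = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(len(usable), size=len(usable))
        diffs[i] = macro_auc(ca, idx) - macro_auc(cb, idx)
    n_le = int(np.sum(diffs <= 0))
    n_ge = int(np.sum(diffs >= 0))
    p = min(1.0, 2.0 * (min(n_le, n_ge) + 1) / (n_boot + 1))
    return AUCComparison(
        auc_a=auc_a,
        auc_b=auc_b,
        difference=auc_a - auc_b,
        p_value=p,
        n_boot=n_boot,
    )
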