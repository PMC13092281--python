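"""Discovery-mode evaluation and ranking baselines.

The evaluation protocol mimics discovery: before ranking, each dedup group
(one defense HMM cluster for positives, one functional annotation group for
controls) is collapsed to its single highest-scoring gene; precision/recall,
average precision (AP), AUROC and top-k precision are computed on the
deduplicated ranking. Tied scores are grouped into one rank block before the
precision-recall curve is stepped, so the metrics are order-independent.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import Genome

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScoredGene:
    gene_id: str
    score: float
    label: int
    dedup_group: str = ""


@dataclass
class RankedEvaluation:
    """A deduplicated ranking with its precision/recall arrays and summaries."""

    entries: list[ScoredGene]
    precision: np.ndarray
    recall: np.ndarray
    ap: float
    auroc: float


def dedup_top_per_group(scored: list[ScoredGene]) -> list[ScoredGene]:
    """Keep the maximum-score entry per dedup group (missing group = singleton).

    Score ties within a group break to the lexicographically smallest
    gene_id, so the result is deterministic.
    """
    best: dict[str, ScoredGene] = {}
    for i, e in enumerate(scored):
        key = e.dedup_group if e.dedup_group else f"__singleton__{e.gene_id}__{i}"
        cur = best.get(key)
        if cur is None or e.score > cur.score or (e.score == cur.score and e.gene_id < cur.gene_id):
            best[key] = e
    return sorted(best.values(), key=lambda e: (-e.score, e.gene_id))


def pr_curve_and_ap(deduplicated: list[ScoredGene]) -> RankedEvaluation:
    """Precision/recall at each rank, stepwise AP, and rank-statistic AUROC.

    AP is the sum over rank positions where recall increases of
    (delta recall x precision at that rank); ties share a rank block. AUROC
    is the probability a random positive outranks a random negative (ties
    count one half). Raises on single-class input.
    """
    if not deduplicated:
        raise ValueError("empty ranking")
    scores = np.array([e.score for e in deduplicated], dtype=float)
    labels = np.array([e.label for e in deduplicated], dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ranking must contain both classes")
    order = np.lexsort(([e.gene_id for e in deduplicated], -scores))
    scores, labels = scores[order], labels[order]
    entries = [deduplicated[i] for i in order]

    precision = np.empty(len(labels))
    recall = np.empty(len(labels))
    ap = 0.0
    tp = fp = 0
    prev_recall = 0.0
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and scores[j] == scores[i]:
            j += 1
        tp += int(labels[i:j].sum())
        fp += (j - i) - int(labels[i:j].sum())
        block_precision = tp / (tp + fp)
        block_recall = tp / n_pos
        precision[i:j] = block_precision
        recall[i:j] = block_recall
        ap += (block_recall - prev_recall) * block_precision
        prev_recall = block_recall
        i = j

    ranks = stats.rankdata(scores)
    auroc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return RankedEvaluation(
        entries=entries, precision=precision, recall=recall, ap=ap, auroc=float(auroc)
    )


def average_precision(scores, labels) -> float:
    """Convenience AP over raw (score, label) arrays without deduplication."""
    entries = [
        ScoredGene(gene_id=str(i), score=float(s), label=int(l))
        for i, (s, l) in enumerate(zip(scores, labels))
    ]
    return pr_curve_and_ap(entries).ap


def top_k_precision(deduplicated: list[ScoredGene], k: int) -> float:
    """Fraction of positives among the k top-ranked deduplicated entries."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(deduplicated, key=lambda e: (-e.score, e.gene_id))
    if k > len(ranked):
        logger.warning("k=%d exceeds ranking length %d; using full list", k, len(ranked))
        k = len(ranked)
    return sum(e.label for e in ranked[:k]) / k


# ---------------------------------------------------------------------------
# ranking baselines


def cosine_nn_baseline(
    queries: dict[str, np.ndarray],
    reference: dict[str, np.ndarray],
    reference_labels: dict[str, int],
) -> dict[str, float]:
    """Signed cosine-similarity nearest-neighbor ranking.

    Each query scores +cos to its nearest reference embedding if that
    neighbor is a defense protein, else -cos. Cosine ties break in favor of
    a defense-labeled neighbor, then the smallest id. Zero-vector queries
    score 0 with a warning.
    """
    if not reference:
        raise ValueError("empty reference set")
    if len(set(reference_labels.values())) < 2:
        raise ValueError("reference must contain both labels")
    ref_ids = sorted(reference)
    R = np.stack([np.asarray(reference[i], dtype=float) for i in ref_ids])
    ref_norm = np.linalg.norm(R, axis=1)
    ref_lab = np.array([reference_labels[i] for i in ref_ids])
    scores: dict[str, float] = {}
    for qid in sorted(queries):
        q = np.asarray(queries[qid], dtype=float)
        qn = np.linalg.norm(q)
        if qn == 0:
            warnings.warn(f"zero-vector query {qid!r}; scoring 0")
            scores[qid] = 0.0
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            cos = (R @ q) / (ref_norm * qn)
        cos = np.where(np.isfinite(cos), cos, -np.inf)
        best_cos = cos.max()
        tied = np.flatnonzero(cos == best_cos)
        tied_defense = tied[ref_lab[tied] == 1]
        nn = tied_defense[0] if len(tied_defense) else tied[0]
        scores[qid] = float(best_cos if ref_lab[nn] == 1 else -best_cos)
    return scores


def signed_best_hit_baseline(
    hits: pd.DataFrame,
    target_labels: dict[str, int],
    queries: list[str],
) -> dict[str, float]:
    """Signed best-bit-score ranking from a precomputed alignment-hit table.

    ``hits`` has columns query, target, score. A query scores +bit if its
    maximum-bit-score hit is defense-labeled, -bit otherwise (bit-score ties
    break defense-first); queries without hits score 0 and therefore rank
    below every scored protein.
    """
    scores = {q: 0.0 for q in queries}
    if len(hits):
        df = hits.copy()
        df["label"] = df["target"].map(target_labels).fillna(0).astype(int)
        df = df.sort_values(["query", "score", "label"], ascending=[True, False, False])
        best = df.groupby("query", sort=False).head(1)
        for row in best.itertuples(index=False):
            if row.query in scores:
                scores[row.query] = float(row.score if row.label == 1 else -row.score)
    return scores


# ---------------------------------------------------------------------------
# guilt by association


@dataclass(frozen=True)
class GuiltByAssociationResult:
    cluster_id: str
    a: int  # cluster genes near defense
    b: int  # cluster genes not near defense
    c: int  # non-cluster genes near defense
    d: int  # non-cluster genes not near defense
    p_value: float


def fisher_enrichment_p(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher exact p for a 2x2 contingency table."""
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1])


def guilt_by_association(
    genomes: list[Genome],
    cluster_map: dict[str, str],
    defense_labels: dict[str, int],
    system_map: dict[str, str] | None = None,
    fold_map: dict[str, int] | None = None,
    window: int = 10,
    exclude_same_system: bool = True,
    exclude_same_fold: bool = True,
) -> list[GuiltByAssociationResult]:
    """Rank protein clusters by enrichment of defense genes in their vicinity.

    A gene is "near defense" if at least one known defense gene lies within
    ``window`` genes of it on the same contig, not counting defensive
    neighbors from the gene's own system or (optionally) its own
    cross-validation fold. Each cluster's 2x2 table against all other genes
    is tested with a one-sided Fisher exact test; results are sorted by
    ascending p (most enriched first).
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    system_map = system_map or {}
    fold_map = fold_map or {}
    near: dict[str, bool] = {}
    for genome in genomes:
        for contig_id in genome.contigs:
            contig_genes = genome.genes_on(contig_id)
            defense_idx = [i for i, g in enumerate(contig_genes) if defense_labels.get(g.gene_id, 0) == 1]
            for i, g in enumerate(contig_genes):
                found = False
                for j in defense_idx:
                    if j == i or abs(j - i) > window:
                        continue
                    d = contig_genes[j]
                    if (
                        exclude_same_system
                        and system_map.get(g.gene_id)
                        and system_map.get(g.gene_id) == system_map.get(d.gene_id)
                    ):
                        continue
                    if (
                        exclude_same_fold
                        and g.gene_id in fold_map
                        and d.gene_id in fold_map
                        and fold_map[g.gene_id] == fold_map[d.gene_id]
                    ):
                        continue
                    found = True
                    break
                near[g.gene_id] = found
    total_near = sum(near.values())
    total = len(near)
    by_cluster: dict[str, list[str]] = {}
    for gid in near:
        cid = cluster_map.get(gid)
        if cid is not None:
            by_cluster.setdefault(cid, []).append(gid)
    results = []
    for cid in sorted(by_cluster):
        members = by_cluster[cid]
        a = sum(near[g] for g in members)
        b = len(members) - a
        c = total_near - a
        d = (total - len(members)) - c
        results.append(
            GuiltByAssociationResult(cid, a, b, c, d, fisher_enrichment_p(a, b, c, d))
        )
    results.sort(key=lambda r: (r.p_value, r.cluster_id))
    return results


# ---------------------------------------------------------------------------
# prospective system-level summary


@dataclass
class SystemSummary:
    """Per-system and per-instance roll-up of gene predictions."""

    system_max_probability: dict[str, float]
    instance_complete: dict[str, bool]
    instance_max_log_odds: dict[str, float]
    n_systems_above_p50: int
    n_systems_above_p98: int


def prospective_system_summary(
    predictions: dict[str, "object"],
    instances: pd.DataFrame,
) -> SystemSummary:
    """Summarize predictions over known system instances.

    ``instances`` is a long-form table with columns instance_id, system_id,
    gene_id. An instance is complete when every member gene has log-odds
    > 0; a system's score is the max gene probability over all its
    instances. Counts of systems whose max probability exceeds 0.5 and 0.98
    are reported.
    """
    required = {"instance_id", "system_id", "gene_id"}
    if required - set(instances.columns):
        raise ValueError(f"instances table needs columns {sorted(required)}")
    sys_max: dict[str, float] = {}
    inst_complete: dict[str, bool] = {}
    inst_max_lo: dict[str, float] = {}
    for (inst, sys_id), grp in instances.groupby(["instance_id", "system_id"]):
        los, ps = [], []
        for gid in grp["gene_id"]:
            if gid not in predictions:
                raise KeyError(f"missing prediction for gene {gid!r}")
            rec = predictions[gid]
            los.append(rec.log_odds)
            ps.append(rec.probability)
        inst_complete[inst] = all(lo > 0 for lo in los)
        inst_max_lo[inst] = max(los)
        sys_max[sys_id] = max(sys_max.get(sys_id, 0.0), max(ps))
    return SystemSummary(
        system_max_probability=sys_max,
        instance_complete=inst_complete,
        instance_max_log_odds=inst_max_lo,
        n_systems_above_p50=sum(p > 0.5 for p in sys_max.values()),
        n_systems_above_p98=sum(p > 0.98 for p in sys_max.values()),
    )
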