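"""End-to-end convenience wrappers tying the modules together.

These functions implement the canonical path: embed every protein, assemble
window feature vectors, build the homology-aware labeled dataset, train the
fold ensemble and run the held-out, deduplicated evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataset import HomologyGraph, LabeledDataset, build_labeled_dataset
from .embedding import EmbeddingBackend, embed_genes
from .evaluation import RankedEvaluation, ScoredGene, dedup_top_per_group, pr_curve_and_ap
from .features import featurize_genome, layout_length
from .genome_io import GeneLabel, Genome
from .model import EnsembleModel, predict_heldout, train_ensemble


def featurize_genomes(
    genomes: list[Genome], backend: EmbeddingBackend
) -> tuple[list[str], np.ndarray]:
    """Feature matrix for every gene of every genome, in genomic order."""
    gene_ids: list[str] = []
    rows: list[np.ndarray] = []
    for genome in genomes:
        embeddings = embed_genes(backend, genome.genes)
        fvs = featurize_genome(genome, embeddings, backend.dim)
        for g in genome.genes:
            gene_ids.append(g.gene_id)
            rows.append(fvs[g.gene_id].values)
    X = np.vstack(rows) if rows else np.empty((0, layout_length(backend.dim)))
    return gene_ids, X


def build_dataset_from_genomes(
    genomes: list[Genome],
    labels: dict[str, GeneLabel],
    graph: HomologyGraph,
    backend: EmbeddingBackend,
    k: int = 5,
    seed: int = 0,
) -> LabeledDataset:
    gene_ids, X = featurize_genomes(genomes, backend)
    return build_labeled_dataset(gene_ids, X, labels, graph, k=k, seed=seed)


@dataclass
class HeldOutResult:
    evaluation: RankedEvaluation
    dedup_prevalence: float
    raw_prevalence: float


def evaluate_heldout_dedup(model: EnsembleModel, dataset: LabeledDataset) -> HeldOutResult:
    """Held-out scoring followed by the deduplicated PR/AP protocol."""
    records = predict_heldout(model, dataset)
    scored = [
        ScoredGene(
            gene_id=r.gene_id,
            score=r.probability,
            label=int(y),
            dedup_group=grp,
        )
        for r, y, grp in zip(records, dataset.y, dataset.dedup_group)
    ]
    dedup = dedup_top_per_group(scored)
    ev = pr_curve_and_ap(dedup)
    n_pos = sum(e.label for e in dedup)
    return HeldOutResult(
        evaluation=ev,
        dedup_prevalence=n_pos / len(dedup),
        raw_prevalence=float(np.mean(dataset.y)),
    )


def train_and_evaluate(
    dataset: LabeledDataset, k: int = 5, budget: int = 0, seed: int = 0
) -> tuple[EnsembleModel, HeldOutResult]:
    model = train_ensemble(dataset, k=k, budget=budget, seed=seed)
    return model, evaluate_heldout_dedup(model, dataset)
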