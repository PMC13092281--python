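"""Labeled dataset assembly: redundancy reduction, homology-aware folds.

The fold assignment guarantees the central property of the training
protocol: proteins connected by homology edges are never split across
cross-validation folds, so a held-out fold contains no homolog of anything
the corresponding model was trained on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class HomologyGraph:
    """Undirected homology graph over protein ids (edge weight = score)."""

    graph: nx.Graph = field(default_factory=nx.Graph)

    @classmethod
    def from_pairs(cls, pairs) -> "HomologyGraph":
        """Build from an iterable of (query, target, score) rows."""
        g = nx.Graph()
        for q, t, s in pairs:
            if q == t:
                continue
            g.add_edge(q, t, weight=float(s))
        return cls(graph=g)

    def add_node(self, node: str) -> None:
        self.graph.add_node(node)

    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def edges(self):
        return self.graph.edges()


@dataclass
class LabeledDataset:
    """Aligned arrays describing one training dataset.

    ``dedup_group`` carries the discovery-mode evaluation unit (defense
    HMM-cluster id for positives, functional-group id for controls);
    ``component_id`` the homology connected component; ``fold`` the
    cross-validation fold in 1..k.
    """

    X: np.ndarray
    y: np.ndarray
    gene_ids: list[str]
    dedup_group: list[str]
    component_id: np.ndarray
    fold: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        for name in ("X", "y", "component_id", "fold"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} is not aligned with gene_ids")
        if len(self.dedup_group) != n:
            raise ValueError("dedup_group is not aligned with gene_ids")
        comp_fold: dict[int, int] = {}
        for c, f in zip(self.component_id, self.fold):
            if comp_fold.setdefault(int(c), int(f)) != int(f):
                raise ValueError(f"component {c} spans multiple folds")

    def __len__(self) -> int:
        return len(self.gene_ids)

    @property
    def folds(self) -> list[int]:
        return sorted(set(int(f) for f in self.fold))

    def subset(self, mask: np.ndarray) -> "LabeledDataset":
        mask = np.asarray(mask, dtype=bool)
        idx = np.flatnonzero(mask)
        return LabeledDataset(
            X=self.X[idx],
            y=self.y[idx],
            gene_ids=[self.gene_ids[i] for i in idx],
            dedup_group=[self.dedup_group[i] for i in idx],
            component_id=self.component_id[idx],
            fold=self.fold[idx],
        )

    def with_labels(self, y: np.ndarray) -> "LabeledDataset":
        return replace(self, y=np.asarray(y))


# ---------------------------------------------------------------------------
# redundancy reduction


def _aligner():
    from Bio import Align
    from Bio.Align import substitution_matrices

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def alignment_identity_coverage(a: str, b: str, aligner=None) -> tuple[float, float, float]:
    """Best local alignment of two proteins.

    Returns ``(identity, coverage_a, coverage_b)`` where identity is
    identical columns over all alignment columns (gaps included) and each
    coverage is the aligned span divided by that sequence's length. Returns
    zeros when no positive-scoring alignment exists.
    """
    if aligner is None:
        aligner = _aligner()
    alignments = aligner.align(a, b)
    if len(alignments) == 0 or alignments.score <= 0:
        return 0.0, 0.0, 0.0
    aln = alignments[0]
    counts = aln.counts()
    cols = counts.identities + counts.mismatches + counts.gaps
    if cols == 0:
        return 0.0, 0.0, 0.0
    identity = counts.identities / cols
    (a_blocks, b_blocks) = aln.aligned
    cov_a = (a_blocks[-1][1] - a_blocks[0][0]) / len(a)
    cov_b = (b_blocks[-1][1] - b_blocks[0][0]) / len(b)
    return identity, cov_a, cov_b


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def reduce_redundancy(
    proteins: list[tuple[str, str]],
    identity_min: float = 0.30,
    coverage_min: float = 0.80,
    seed: int = 0,
    *,
    prefilter: bool = True,
    prefilter_k: int = 4,
    prefilter_min_shared: int = 2,
) -> tuple[dict[str, str], dict[str, str]]:
    """Greedy incremental sequence clustering with random representatives.

    Proteins are processed longest-first (ties by id, so the result is
    independent of input order); each joins the first existing cluster whose
    founder it matches at ``identity_min`` identity and ``coverage_min``
    reciprocal coverage under local alignment, else founds a new cluster.
    One member per cluster is then chosen uniformly at random (seeded) as
    the representative. A shared-k-mer prefilter skips hopeless alignments,
    the same acceleration the field's standard clustering tools use; set
    ``prefilter=False`` to force exhaustive alignment against founders.

    Returns ``(id -> cluster_id, cluster_id -> representative_id)``.
    """
    if not proteins:
        raise ValueError("no proteins to cluster")
    aligner = _aligner()
    ordered = sorted(proteins, key=lambda p: (-len(p[1]), p[0]))
    founders: list[tuple[str, str]] = []  # (cluster_id, seq)
    founder_seqs: dict[str, str] = {}
    membership: dict[str, str] = {}
    kmer_index: dict[str, set[int]] = {}

    def candidates(seq: str) -> list[int]:
        if not prefilter:
            return list(range(len(founders)))
        hits: dict[int, int] = {}
        for kmer in _kmer_set(seq, prefilter_k):
            for fi in kmer_index.get(kmer, ()):
                hits[fi] = hits.get(fi, 0) + 1
        return sorted(fi for fi, n in hits.items() if n >= prefilter_min_shared)

    for pid, seq in ordered:
        assigned = None
        for fi in candidates(seq):
            cid, fseq = founders[fi]
            identity, cov_a, cov_b = alignment_identity_coverage(seq, fseq, aligner)
            if identity >= identity_min and cov_a >= coverage_min and cov_b >= coverage_min:
                assigned = cid
                break
        if assigned is None:
            cid = f"C{len(founders):06d}"
            fi = len(founders)
            founders.append((cid, seq))
            founder_seqs[cid] = seq
            for kmer in _kmer_set(seq, prefilter_k):
                kmer_index.setdefault(kmer, set()).add(fi)
            assigned = cid
        membership[pid] = assigned

    rng = np.random.default_rng(seed)
    representatives: dict[str, str] = {}
    by_cluster: dict[str, list[str]] = {}
    for pid, cid in membership.items():
        by_cluster.setdefault(cid, []).append(pid)
    for cid in sorted(by_cluster):
        members = sorted(by_cluster[cid])
        representatives[cid] = members[int(rng.integers(len(members)))]
    return membership, representatives


# ---------------------------------------------------------------------------
# fold assignment


def assign_folds(
    graph: HomologyGraph,
    labels: dict[str, int],
    k: int = 5,
    seed: int = 0,
) -> dict[str, int]:
    """Place whole homology components into k folds, balancing positives.

    Components are sorted by (positive count desc, size desc, smallest id)
    and greedily placed into the fold with the fewest positives so far (ties
    broken by smallest total count, then lowest fold index). All members of
    a component always share a fold, so no homology edge can cross folds.
    The assignment is deterministic; ``seed`` is accepted for interface
    uniformity.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    g = graph.graph.copy()
    g.add_nodes_from(labels)
    comps = []
    for comp in nx.connected_components(g):
        members = sorted(comp)
        pos = sum(labels.get(m, 0) for m in members)
        comps.append((pos, len(members), members))
    comps.sort(key=lambda c: (-c[0], -c[1], c[2][0]))
    fold_pos = [0] * k
    fold_tot = [0] * k
    assignment: dict[str, int] = {}
    for pos, size, members in comps:
        if pos > 0:
            best = min(range(k), key=lambda f: (fold_pos[f], fold_tot[f], f))
        else:
            # components without positives cannot affect positive balance;
            # spread them by total size so every fold keeps both classes
            best = min(range(k), key=lambda f: (fold_tot[f], f))
        fold_pos[best] += pos
        fold_tot[best] += size
        for m in members:
            assignment[m] = best + 1
    return assignment


def leakage_check(fold_of: dict[str, int], graph: HomologyGraph) -> list[tuple[str, str]]:
    """Homology edges whose endpoints sit in different folds (must be empty)."""
    bad = []
    for u, v in graph.edges():
        fu, fv = fold_of.get(u), fold_of.get(v)
        if fu is not None and fv is not None and fu != fv:
            bad.append((u, v))
    return bad


def make_validation_split(
    dataset: LabeledDataset,
    fraction: float = 0.1,
    seed: int = 0,
) -> tuple[LabeledDataset, LabeledDataset]:
    """Carve a stratified validation set out of whole homology components.

    Components are drawn in seeded random order and moved entirely to the
    validation side until at least ``fraction`` of positives and of controls
    are covered (so no homolog is split between train and validation). When
    stratification is unattainable — e.g. a single component holds all
    positives — the closest achievable split is returned with a logged
    warning.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    n = len(dataset)
    if fraction == 0.0:
        return dataset, dataset.subset(np.zeros(n, dtype=bool))
    comp_ids = sorted(set(int(c) for c in dataset.component_id))
    if len(comp_ids) < 2:
        raise ValueError("need at least 2 homology components to split")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(comp_ids))
    y = np.asarray(dataset.y)
    need_pos = fraction * int(y.sum())
    need_neg = fraction * int((1 - y).sum())
    got_pos = got_neg = 0.0
    chosen: set[int] = set()
    for cid in order:
        if got_pos >= need_pos and got_neg >= need_neg:
            break
        mask = dataset.component_id == cid
        cpos = int(y[mask].sum())
        cneg = int(mask.sum()) - cpos
        if (cpos > 0 and got_pos < need_pos) or (cneg > 0 and got_neg < need_neg):
            chosen.add(cid)
            got_pos += cpos
            got_neg += cneg
    if got_pos < need_pos or got_neg < need_neg:
        logger.warning(
            "validation stratification unattainable: got %d pos / %d neg, "
            "needed %.1f / %.1f",
            got_pos,
            got_neg,
            need_pos,
            need_neg,
        )
    val_mask = np.array([int(c) in chosen for c in dataset.component_id])
    if val_mask.all():
        raise ValueError("validation split would consume the whole dataset")
    return dataset.subset(~val_mask), dataset.subset(val_mask)


def build_labeled_dataset(
    gene_ids: list[str],
    X: np.ndarray,
    labels: dict[str, object],
    graph: HomologyGraph,
    k: int = 5,
    seed: int = 0,
) -> LabeledDataset:
    """Assemble a LabeledDataset from featurized genes and a label table.

    Only genes labeled defense (1) or control (0) are retained; folds come
    from :func:`assign_folds` on the homology graph restricted to those
    genes.
    """
    keep: list[int] = []
    y: list[int] = []
    groups: list[str] = []
    for i, gid in enumerate(gene_ids):
        lab = labels.get(gid)
        if lab is None or lab.label == "unlabeled":
            continue
        keep.append(i)
        y.append(1 if lab.label == "defense" else 0)
        groups.append(lab.dedup_group or gid)
    kept_ids = [gene_ids[i] for i in keep]
    label_map = dict(zip(kept_ids, y))
    sub = HomologyGraph(graph.graph.subgraph(kept_ids).copy())
    fold_of = assign_folds(sub, label_map, k=k, seed=seed)
    g = sub.graph.copy()
    g.add_nodes_from(kept_ids)
    comp_of: dict[str, int] = {}
    for ci, comp in enumerate(sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])):
        for m in comp:
            comp_of[m] = ci
    return LabeledDataset(
        X=np.asarray(X)[keep],
        y=np.array(y),
        gene_ids=kept_ids,
        dedup_group=groups,
        component_id=np.array([comp_of[g_] for g_ in kept_ids]),
        fold=np.array([fold_of[g_] for g_ in kept_ids]),
    )
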