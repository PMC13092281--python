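"""Feature construction for center genes and their 5-gene windows.

Every gene is encoded from a window of itself ("center", position 0) and up
to two neighbors on either side (positions -2, -1, +1, +2 in genomic order).
The vector concatenates, in this order:

* 5 protein blocks of ``dim`` slots each (mean-pooled embeddings, positions
  ordered [-2, -1, 0, +1, +2]) — 3,200 slots at dim=640;
* 119 genomic-context slots: per window position 22 slots (4 mononucleotide
  frequencies A/C/G/T, 16 overlapping dinucleotide frequencies, gene GC
  minus genome GC, gene length in bp), then 4 signed intergenic distances
  between consecutive window genes, 4 neighbor orientations relative to the
  center gene, and the genome-wide GC fraction.

Sequence-composition features are computed on the coding strand, so they are
intrinsic to the gene and invariant under reverse-complementing the genome.
Missing window positions at contig edges contribute zero-filled blocks.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import Genome, GeneRecord

NUCLEOTIDES = "ACGT"
DINUCLEOTIDES = [a + b for a in NUCLEOTIDES for b in NUCLEOTIDES]
WINDOW_POSITIONS = (-2, -1, 0, 1, 2)
#: consecutive window pairs whose intergenic distances are featurized; each
#: distance slot is attributed to the non-center gene of its pair.
DISTANCE_PAIRS = ((-2, -1), (-1, 0), (0, 1), (1, 2))
N_GENOMIC_FEATURES = 119


@dataclass(frozen=True)
class Block:
    """A contiguous slot range in the feature vector.

    ``position`` is the window position the block describes, or ``None`` for
    genome-level features (genome GC).
    """

    name: str
    category: str
    position: int | None
    start: int
    stop: int

    @property
    def size(self) -> int:
        return self.stop - self.start


def feature_layout(dim: int) -> list[Block]:
    """The committed slot registry for embedding width ``dim``.

    Total length is ``5 * dim + 119``; blocks are disjoint and cover every
    index exactly once.
    """
    blocks: list[Block] = []
    off = 0

    def add(name: str, category: str, position: int | None, size: int) -> None:
        nonlocal off
        blocks.append(Block(name, category, position, off, off + size))
        off += size

    for pos in WINDOW_POSITIONS:
        add(f"embedding[{pos:+d}]", "embedding", pos, dim)
    for pos in WINDOW_POSITIONS:
        add(f"nucleotide_freq[{pos:+d}]", "nucleotide_freq", pos, 4)
        add(f"dinucleotide_freq[{pos:+d}]", "dinucleotide_freq", pos, 16)
        add(f"gc_relative[{pos:+d}]", "gc_relative", pos, 1)
        add(f"gene_length[{pos:+d}]", "gene_length", pos, 1)
    for a, b in DISTANCE_PAIRS:
        owner = a if a != 0 else b
        add(f"intergenic_distance[{a:+d},{b:+d}]", "intergenic_distance", owner, 1)
    for pos in (-2, -1, 1, 2):
        add(f"orientation[{pos:+d}]", "orientation", pos, 1)
    add("genome_gc", "genome_gc", None, 1)
    assert off == 5 * dim + N_GENOMIC_FEATURES
    return blocks


def layout_length(dim: int) -> int:
    return 5 * dim + N_GENOMIC_FEATURES


def layout_to_json(blocks: list[Block]) -> list[dict]:
    return [
        {
            "name": b.name,
            "category": b.category,
            "position": b.position,
            "start": b.start,
            "stop": b.stop,
        }
        for b in blocks
    ]


def layout_from_json(data: list[dict]) -> list[Block]:
    return [Block(d["name"], d["category"], d["position"], d["start"], d["stop"]) for d in data]


@dataclass
class Neighborhood:
    """A center gene with up to two neighbors per side (nearest first)."""

    center: GeneRecord
    left: list[GeneRecord]
    right: list[GeneRecord]
    genome_gc: float

    def window(self) -> dict[int, GeneRecord | None]:
        """Genes by window position; ``None`` where the contig ends."""
        out: dict[int, GeneRecord | None] = {p: None for p in WINDOW_POSITIONS}
        out[0] = self.center
        for i, g in enumerate(self.left):
            out[-(i + 1)] = g
        for i, g in enumerate(self.right):
            out[i + 1] = g
        return out


@dataclass(frozen=True)
class FeatureVector:
    gene_id: str
    values: np.ndarray
    dim: int

    def __post_init__(self) -> None:
        if len(self.values) != layout_length(self.dim):
            raise ValueError(
                f"{self.gene_id}: feature vector length {len(self.values)} != "
                f"{layout_length(self.dim)}"
            )


def nucleotide_freqs(nt_seq: str) -> np.ndarray:
    """A/C/G/T frequencies on the coding strand; N excluded entirely."""
    if not nt_seq:
        raise ValueError("empty sequence")
    counts = np.array([nt_seq.count(b) for b in NUCLEOTIDES], dtype=float)
    total = counts.sum()
    if total == 0:
        return counts
    return counts / total


def dinucleotide_freqs(nt_seq: str) -> np.ndarray:
    """Overlapping dinucleotide frequencies in fixed AA..TT order.

    Windows containing N (or any non-ACGT character) are excluded from both
    numerator and denominator.
    """
    if len(nt_seq) < 2:
        raise ValueError("dinucleotide frequencies require length >= 2")
    index = {d: i for i, d in enumerate(DINUCLEOTIDES)}
    counts = np.zeros(16)
    for i in range(len(nt_seq) - 1):
        j = index.get(nt_seq[i : i + 2])
        if j is not None:
            counts[j] += 1
    total = counts.sum()
    if total == 0:
        return counts
    return counts / total


def gc_relative(nt_seq: str, genome_gc: float) -> float:
    """Gene GC fraction minus genome GC fraction."""
    if not nt_seq:
        raise ValueError("empty sequence")
    if not 0.0 <= genome_gc <= 1.0:
        raise ValueError("genome_gc must lie in [0, 1]")
    acgt = sum(nt_seq.count(b) for b in NUCLEOTIDES)
    if acgt == 0:
        return -genome_gc
    gc = (nt_seq.count("G") + nt_seq.count("C")) / acgt
    return gc - genome_gc


def intergenic_distance(a: GeneRecord, b: GeneRecord) -> int:
    """Signed bp gap between consecutive genes: 0 = abutting, <0 = overlap."""
    if a.contig_id != b.contig_id:
        raise ValueError("intergenic distance is undefined across contigs")
    if a.start > b.start:
        raise ValueError("gene a must precede gene b")
    return b.start - a.end


def build_neighborhood(genome: Genome, gene_id: str) -> Neighborhood:
    """Collect up to two rank-adjacent neighbors per side on the same contig."""
    center = genome.gene(gene_id)
    contig_genes = genome.genes_on(center.contig_id)
    r = center.rank
    left = [contig_genes[r - i] for i in (1, 2) if r - i >= 0]
    right = [contig_genes[r + i] for i in (1, 2) if r + i < len(contig_genes)]
    return Neighborhood(center=center, left=left, right=right, genome_gc=genome.genome_gc)


def _per_gene_block(g: GeneRecord, genome_gc: float) -> np.ndarray:
    return np.concatenate(
        [
            nucleotide_freqs(g.nt_seq),
            dinucleotide_freqs(g.nt_seq),
            [gc_relative(g.nt_seq, genome_gc)],
            [float(g.length)],
        ]
    )


def assemble_features(nb: Neighborhood, embeddings, dim: int) -> FeatureVector:
    """Assemble the full ``5*dim + 119`` vector for one center gene.

    ``embeddings`` maps gene_id to :class:`~phagedefense.embedding
    .ProteinEmbedding`; all window genes must be present. Slots belonging to
    a missing window position (contig edge) are zero, including the
    distances and orientation that would involve the missing gene.
    """
    window = nb.window()
    parts: list[np.ndarray] = []
    for pos in WINDOW_POSITIONS:
        g = window[pos]
        if g is None:
            parts.append(np.zeros(dim))
        else:
            try:
                emb = embeddings[g.gene_id]
            except KeyError:
                raise KeyError(f"missing embedding for {g.gene_id!r}") from None
            vec = np.asarray(emb.vector, dtype=float)
            if len(vec) != dim:
                raise ValueError(f"embedding dim {len(vec)} != {dim}")
            parts.append(vec)
    for pos in WINDOW_POSITIONS:
        g = window[pos]
        parts.append(np.zeros(22) if g is None else _per_gene_block(g, nb.genome_gc))
    dists = []
    for a, b in DISTANCE_PAIRS:
        ga, gb = window[a], window[b]
        if ga is None or gb is None:
            dists.append(0.0)
        else:
            first, second = (ga, gb) if ga.start <= gb.start else (gb, ga)
            dists.append(float(intergenic_distance(first, second)))
    parts.append(np.array(dists))
    orients = []
    for pos in (-2, -1, 1, 2):
        g = window[pos]
        orients.append(0.0 if g is None else float(g.strand * nb.center.strand))
    parts.append(np.array(orients))
    parts.append(np.array([nb.genome_gc]))
    values = np.concatenate(parts)
    return FeatureVector(gene_id=nb.center.gene_id, values=values, dim=dim)


def featurize_genome(genome: Genome, embeddings, dim: int) -> dict[str, FeatureVector]:
    """Feature vectors for every gene of a genome."""
    return {
        g.gene_id: assemble_features(build_neighborhood(genome, g.gene_id), embeddings, dim)
        for g in genome.genes
    }
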