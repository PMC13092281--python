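"""Genomic-context features, window assembly and layout invariants."""

import numpy as np
import pytest
from Bio.Seq import Seq

from phagedefense.embedding import embed_genes, mock_backend
from phagedefense.features import (
    DINUCLEOTIDES,
    assemble_features,
    build_neighborhood,
    dinucleotide_freqs,
    feature_layout,
    featurize_genome,
    gc_relative,
    intergenic_distance,
    layout_length,
    nucleotide_freqs,
)
from phagedefense.genome_io import GeneRecord, Genome

from conftest import make_gene, make_genome


@pytest.mark.parametrize(
    "seq, expected",
    [
        ("ATGC", [0.25, 0.25, 0.25, 0.25]),
        ("AAAA", [1, 0, 0, 0]),
        ("ANAT", [2 / 3, 0, 0, 1 / 3]),  # N excluded from both sides
    ],
)
def test_nucleotide_freqs(seq, expected):
    assert np.allclose(nucleotide_freqs(seq), expected)


def test_dinucleotide_freqs_overlapping_windows():
    f = dinucleotide_freqs("ATAT")
    assert f[DINUCLEOTIDES.index("AT")] == pytest.approx(2 / 3)
    assert f[DINUCLEOTIDES.index("TA")] == pytest.approx(1 / 3)
    assert f.sum() == pytest.approx(1.0)
    assert dinucleotide_freqs("AA")[DINUCLEOTIDES.index("AA")] == 1.0
    # windows touching N are dropped from numerator and denominator
    f2 = dinucleotide_freqs("AANTT")
    assert f2[DINUCLEOTIDES.index("AA")] == pytest.approx(0.5)
    assert f2[DINUCLEOTIDES.index("TT")] == pytest.approx(0.5)


def test_frequency_vectors_sum_to_one(rng):
    for _ in range(20):
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=int(rng.integers(2, 40))))
        assert nucleotide_freqs(seq).sum() == pytest.approx(1.0)
        assert dinucleotide_freqs(seq).sum() == pytest.approx(1.0)


@pytest.mark.parametrize(
    "seq, genome_gc, expected",
    [("GGCC", 0.5, 0.5), ("ATGC", 0.5, 0.0), ("ATAT", 0.5, -0.5)],
)
def test_gc_relative(seq, genome_gc, expected):
    assert gc_relative(seq, genome_gc) == pytest.approx(expected)


@pytest.mark.parametrize(
    "a_span, b_span, expected",
    [((0, 100), (150, 300), 50), ((0, 100), (100, 200), 0), ((0, 100), (80, 200), -20)],
)
def test_intergenic_distance(a_span, b_span, expected):
    a = make_gene("a", "c1", *a_span)
    b = make_gene("b", "c1", *b_span)
    assert intergenic_distance(a, b) == expected


def test_intergenic_distance_rejects_cross_contig():
    with pytest.raises(ValueError):
        intergenic_distance(make_gene("a", "c1", 0, 100), make_gene("b", "c2", 150, 300))


def _five_gene_genome():
    genes = [make_gene(f"g{i}", "c1", i * 200, i * 200 + 90) for i in range(5)]
    return make_genome(genes)


def test_neighborhood_middle_edge_and_degenerate():
    genome = _five_gene_genome()
    nb = build_neighborhood(genome, "g2")
    assert [g.gene_id for g in nb.left] == ["g1", "g0"]  # nearest first
    assert [g.gene_id for g in nb.right] == ["g3", "g4"]
    first = build_neighborhood(genome, "g0")
    assert first.left == [] and len(first.right) == 2
    lone = make_genome([make_gene("solo", "c9", 0, 60)])
    nb_solo = build_neighborhood(lone, "solo")
    assert nb_solo.left == [] and nb_solo.right == []


def test_unknown_gene_raises():
    with pytest.raises(KeyError):
        build_neighborhood(_five_gene_genome(), "nope")


def _featurize(genome, dim, seed=0):
    be = mock_backend(dim=dim, seed=seed)
    embeddings = embed_genes(be, genome.genes)
    return featurize_genome(genome, embeddings, dim)


def test_full_window_vector_length_is_3319_at_dim_640():
    genome = _five_gene_genome()
    fvs = _featurize(genome, 640)
    v = fvs["g2"].values
    assert len(v) == 3319
    # protein block occupies the first 3200 slots
    blocks = feature_layout(640)
    emb_blocks = [b for b in blocks if b.category == "embedding"]
    assert emb_blocks[0].start == 0 and emb_blocks[-1].stop == 3200
    assert sum(b.size for b in blocks) == 3319


def test_layout_registry_covers_indices_exactly_once():
    for dim in (8, 64, 640):
        blocks = feature_layout(dim)
        covered = []
        for b in blocks:
            covered.extend(range(b.start, b.stop))
        assert covered == list(range(layout_length(dim)))
        genomic = [b for b in blocks if b.category != "embedding"]
        assert sum(b.size for b in genomic) == 119


def test_contig_edge_gene_has_zeroed_left_blocks():
    dim = 8
    genome = _five_gene_genome()
    fvs = _featurize(genome, dim)
    v = fvs["g0"].values
    assert len(v) == 5 * dim + 119
    blocks = {b.name: b for b in feature_layout(dim)}
    # enumerate every slot owned by positions -2/-1: embeddings, per-gene
    # genomic block, the adjacent distances and orientations must be zero
    for name in (
        "embedding[-2]", "embedding[-1]",
        "nucleotide_freq[-2]", "nucleotide_freq[-1]",
        "dinucleotide_freq[-2]", "dinucleotide_freq[-1]",
        "gc_relative[-2]", "gc_relative[-1]",
        "gene_length[-2]", "gene_length[-1]",
        "intergenic_distance[-2,-1]", "intergenic_distance[-1,+0]",
        "orientation[-2]", "orientation[-1]",
    ):
        b = blocks[name]
        assert np.all(v[b.start:b.stop] == 0.0), name
    # while the center and right-side blocks are populated
    b = blocks["embedding[+0]"]
    assert np.any(v[b.start:b.stop] != 0.0)
    assert v[blocks["gene_length[+0]"].start] == 90.0
    assert v[blocks["intergenic_distance[+0,+1]"].start] == 110.0
    assert v[blocks["genome_gc"].start] == genome.genome_gc


def test_orientation_and_distance_slots():
    genes = [
        make_gene("a", "c1", 0, 90, strand=1),
        make_gene("b", "c1", 100, 190, strand=-1),
        make_gene("c", "c1", 190, 280, strand=-1),
    ]
    genome = make_genome(genes)
    fvs = _featurize(genome, 8)
    blocks = {b.name: b for b in feature_layout(8)}
    v = fvs["b"].values  # center gene on minus strand
    assert v[blocks["orientation[-1]"].start] == -1.0  # a is opposite to b
    assert v[blocks["orientation[+1]"].start] == 1.0  # c is same as b
    assert v[blocks["intergenic_distance[-1,+0]"].start] == 10.0
    assert v[blocks["intergenic_distance[+0,+1]"].start] == 0.0  # abutting


def test_all_features_finite_and_fixed_length(small_cohort, small_backend):
    genome = small_cohort.genomes[0]
    embeddings = embed_genes(small_backend, genome.genes)
    fvs = featurize_genome(genome, embeddings, small_backend.dim)
    n = layout_length(small_backend.dim)
    for fv in fvs.values():
        assert len(fv.values) == n
        assert np.all(np.isfinite(fv.values))


def test_translation_invariance_of_features(small_cohort, small_backend):
    """Shifting a contig's coordinates by a constant changes no feature."""
    genome = small_cohort.genomes[0]
    shift = 5000
    shifted = Genome(
        genome_id=genome.genome_id,
        contigs={c: l + shift for c, l in genome.contigs.items()},
        genes=[
            GeneRecord(
                gene_id=g.gene_id, contig_id=g.contig_id, start=g.start + shift,
                end=g.end + shift, strand=g.strand, nt_seq=g.nt_seq, aa_seq=g.aa_seq,
            )
            for g in genome.genes
        ],
        genome_gc=genome.genome_gc,
    )
    embeddings = embed_genes(small_backend, genome.genes)
    a = featurize_genome(genome, embeddings, small_backend.dim)
    b = featurize_genome(shifted, embeddings, small_backend.dim)
    for gid in a:
        assert np.array_equal(a[gid].values, b[gid].values)


def test_genome_reversal_preserves_per_gene_blocks(small_cohort, small_backend):
    """Coding-strand features are strand-intrinsic under genome reversal."""
    genome = small_cohort.genomes[0]
    length = {c: l for c, l in genome.contigs.items()}
    reversed_genes = [
        GeneRecord(
            gene_id=g.gene_id, contig_id=g.contig_id,
            start=length[g.contig_id] - g.end, end=length[g.contig_id] - g.start,
            strand=-g.strand, nt_seq=g.nt_seq, aa_seq=g.aa_seq,
        )
        for g in genome.genes
    ]
    rev = Genome(
        genome_id=genome.genome_id, contigs=dict(genome.contigs),
        genes=reversed_genes, genome_gc=genome.genome_gc,
    )
    embeddings = embed_genes(small_backend, genome.genes)
    fwd_fv = featurize_genome(genome, embeddings, small_backend.dim)
    rev_fv = featurize_genome(rev, embeddings, small_backend.dim)
    per_gene = [
        b for b in feature_layout(small_backend.dim)
        if b.position == 0 and b.category in
        ("nucleotide_freq", "dinucleotide_freq", "gc_relative", "gene_length", "embedding")
    ]
    for gid in fwd_fv:
        for b in per_gene:
            assert np.array_equal(
                fwd_fv[gid].values[b.start:b.stop], rev_fv[gid].values[b.start:b.stop]
            ), (gid, b.name)


def test_missing_embedding_raises(small_cohort, small_backend):
    genome = small_cohort.genomes[0]
    nb = build_neighborhood(genome, genome.genes[2].gene_id)
    with pytest.raises(KeyError, match="missing embedding"):
        assemble_features(nb, {}, small_backend.dim)
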