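"""Shared fixtures: small synthetic cohorts and hand-built toy genomes."""

from __future__ import annotations

import numpy as np
import pytest

from phagedefense.embedding import mock_backend
from phagedefense.genome_io import GeneRecord, Genome
from phagedefense.pipeline import build_dataset_from_genomes
from phagedefense.synth import SynthConfig, generate_cohort

_NT = "ACGT"


def make_gene(
    gene_id: str,
    contig: str,
    start: int,
    end: int,
    strand: int = 1,
    nt: str | None = None,
    aa: str | None = None,
) -> GeneRecord:
    """Toy gene with deterministic filler sequences of the right length."""
    if nt is None:
        nt = "".join(_NT[i % 4] for i in range(end - start))
    if aa is None:
        aa = "M" + "A" * max(0, (end - start) // 3 - 1)
    return GeneRecord(
        gene_id=gene_id, contig_id=contig, start=start, end=end, strand=strand,
        nt_seq=nt, aa_seq=aa,
    )


def make_genome(genes: list[GeneRecord], genome_id: str = "toy", gc: float = 0.5) -> Genome:
    contigs: dict[str, int] = {}
    for g in genes:
        contigs[g.contig_id] = max(contigs.get(g.contig_id, 0), g.end + 100)
    return Genome(genome_id=genome_id, contigs=contigs, genes=list(genes), genome_gc=gc)


@pytest.fixture(scope="session")
def small_cohort():
    """160-gene cohort with planted defense structure (family cluster map)."""
    return generate_cohort(
        SynthConfig(n_genomes=4, genes_per_genome=40, seed=11), cluster=False
    )


@pytest.fixture(scope="session")
def small_backend():
    return mock_backend(dim=16, seed=3)


@pytest.fixture(scope="session")
def small_dataset(small_cohort, small_backend):
    return build_dataset_from_genomes(
        small_cohort.genomes,
        small_cohort.labels,
        small_cohort.homology,
        small_backend,
        k=3,
        seed=5,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
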