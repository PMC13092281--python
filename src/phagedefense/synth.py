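"""Synthetic genome cohorts with the statistical structure the model exploits.

The generator emulates the three signals the classifier is expected to
learn from real genomes: defense genes carry (i) a GC content shifted below
the genome baseline (lateral-transfer signature), (ii) a short amino-acid
motif detectable by any composition-sensitive embedder, and (iii) a tendency
to co-locate in islands and multi-gene operons. Homology structure is
simulated by copy-with-mutation from ancestral sequences, giving paralog
families that the homology-aware fold assignment must keep together.

Everything is seeded and deterministic; the emitted objects and files use
the exact formats the real pipeline consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .dataset import HomologyGraph, reduce_redundancy
from .genome_io import GeneLabel, Genome, GeneRecord, gc_fraction

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SynthConfig:
    """Study conditions for a synthetic cohort.

    Defaults encode a typical gamma-proteobacterial host (genome GC 0.52),
    a 10% defense-gene prevalence with a -0.10 GC shift, island co-location
    probability 0.6 and the planted motif WWHHWW.
    """

    n_genomes: int = 10
    genes_per_genome: int = 100
    genome_gc: float = 0.52
    defense_fraction: float = 0.10
    defense_gc_shift: float = -0.10
    island_probability: float = 0.6
    motif: str = "WWHHWW"
    seed: int = 0
    contigs_per_genome: int = 2
    protein_length: tuple[int, int] = (80, 220)
    mutation_rate: float = 0.10
    strand_persistence: float = 0.7
    control_family_reuse: float = 0.6
    system_sizes: tuple[int, ...] = (1, 2, 3)

    def validate(self) -> None:
        for name in ("defense_fraction", "island_probability", "control_family_reuse"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 < self.genome_gc < 1.0:
            raise ValueError("genome_gc must lie in (0, 1)")
        if not 0.0 < self.genome_gc + self.defense_gc_shift < 1.0:
            raise ValueError("genome_gc + defense_gc_shift must lie in (0, 1)")
        if self.n_genomes < 1 or self.genes_per_genome < 5:
            raise ValueError("need >= 1 genome and >= 5 genes per genome")


@dataclass
class SyntheticCohort:
    genomes: list[Genome]
    labels: dict[str, GeneLabel]
    cluster_map: dict[str, str]
    representatives: dict[str, str]
    homology: HomologyGraph
    systems: pd.DataFrame  # columns instance_id, system_id, gene_id
    family_of: dict[str, str]
    config: SynthConfig


# ---------------------------------------------------------------------------
# GC-calibrated reverse translation

_TABLE11 = CodonTable.unambiguous_dna_by_id[11]


def _codons_by_aa() -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for codon, aa in sorted(_TABLE11.forward_table.items()):
        out.setdefault(aa, []).append(codon)
    return out


_CODONS = _codons_by_aa()
_STOPS = sorted(_TABLE11.stop_codons)


def _codon_weights(codons: list[str], p: float) -> np.ndarray:
    gc = np.array([c.count("G") + c.count("C") for c in codons], dtype=float)
    w = (p**gc) * ((1 - p) ** (3 - gc))
    return w / w.sum()


def _expected_gc(p: float) -> float:
    """Expected nucleotide GC of a codon-sampled protein (uniform aa usage)."""
    total = 0.0
    for aa in AMINO_ACIDS:
        codons = _CODONS[aa]
        w = _codon_weights(codons, p)
        gc = np.array([c.count("G") + c.count("C") for c in codons], dtype=float)
        total += float((w * gc).sum()) / 3.0
    return total / len(AMINO_ACIDS)


def calibrate_codon_gc(target_gc: float) -> float:
    """Invert the codon-sampling bias so realized gene GC hits ``target_gc``.

    Returns the per-position bias p such that sampling synonymous codons
    with weight p^gc (1-p)^(3-gc) yields genes whose expected GC equals the
    target. Raises when the target is outside the genetic code's reachable
    range.
    """
    lo, hi = 1e-4, 1 - 1e-4
    if not _expected_gc(lo) - 1e-9 <= target_gc <= _expected_gc(hi) + 1e-9:
        raise ValueError(
            f"target GC {target_gc:.3f} outside achievable range "
            f"[{_expected_gc(lo):.3f}, {_expected_gc(hi):.3f}]"
        )
    for _ in range(60):
        mid = (lo + hi) / 2
        if _expected_gc(mid) < target_gc:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


_SAMPLER_CACHE: dict[float, dict[str, tuple[list[str], np.ndarray]]] = {}


def _codon_samplers(gc_bias: float) -> dict[str, tuple[list[str], np.ndarray]]:
    cache = _SAMPLER_CACHE.get(gc_bias)
    if cache is None:
        cache = {
            aa: (codons, np.cumsum(_codon_weights(codons, gc_bias)))
            for aa, codons in _CODONS.items()
        }
        cache["*"] = (_STOPS, np.cumsum(_codon_weights(_STOPS, gc_bias)))
        _SAMPLER_CACHE[gc_bias] = cache
    return cache


def reverse_translate(aa_seq: str, gc_bias: float, rng: np.random.Generator) -> str:
    """Sample a coding sequence (with stop codon) at the calibrated GC bias."""
    samplers = _codon_samplers(gc_bias)
    u = rng.random(len(aa_seq) + 1)
    parts = []
    for i, aa in enumerate(aa_seq + "*"):
        codons, cum = samplers[aa]
        parts.append(codons[int(np.searchsorted(cum, u[i] * cum[-1]))])
    return "".join(parts)


def _random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        out[i] = AMINO_ACIDS[int(rng.integers(0, 20))]
    return "".join(out)


def _random_dna(length: int, gc: float, rng: np.random.Generator) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join("ATGC"[i] for i in rng.choice(4, size=length, p=probs))


# ---------------------------------------------------------------------------
# cohort generation


def generate_cohort(config: SynthConfig, *, cluster: bool = True) -> SyntheticCohort:
    """Generate a seeded cohort of genomes with planted defense structure.

    With ``cluster=True`` the cluster map comes from
    :func:`~phagedefense.dataset.reduce_redundancy` over all proteins;
    ``cluster=False`` substitutes the generator's own family map through the
    same contract (useful when the alignment pass is not needed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    ctrl_bias = calibrate_codon_gc(config.genome_gc)
    def_bias = calibrate_codon_gc(config.genome_gc + config.defense_gc_shift)

    total_genes = config.n_genomes * config.genes_per_genome
    total_defense = int(round(total_genes * config.defense_fraction))

    # system roster: each system is a tuple of defense families sharing an
    # ancestral protein each; instances re-draw mutated copies.
    mean_size = float(np.mean(config.system_sizes))
    n_systems = max(3, int(round(total_defense / (mean_size * 3))))
    systems: list[list[str]] = []
    family_ancestor: dict[str, str] = {}
    family_motif_pos: dict[str, int] = {}
    for s in range(n_systems):
        size = int(rng.choice(config.system_sizes))
        fams = []
        for gpos in range(size):
            fam = f"defF{s:03d}_{gpos}"
            length = int(rng.integers(*config.protein_length))
            anc = _random_protein(length, rng)
            pos = int(rng.integers(0, length - len(config.motif) + 1)) if config.motif else 0
            if config.motif:
                anc = anc[:pos] + config.motif + anc[pos + len(config.motif) :]
            family_ancestor[fam] = anc
            family_motif_pos[fam] = pos
            fams.append(fam)
        systems.append(fams)

    n_ctrl_fams = max(5, (total_genes - total_defense) // 3)
    ctrl_ancestors = {
        f"ctrlF{i:04d}": _random_protein(int(rng.integers(*config.protein_length)), rng)
        for i in range(n_ctrl_fams)
    }

    genomes: list[Genome] = []
    labels: dict[str, GeneLabel] = {}
    family_of: dict[str, str] = {}
    system_rows: list[dict] = []
    fresh_fam = 0
    instance_counter = 0

    for gi in range(config.n_genomes):
        genome_id = f"G{gi:03d}"
        n_genes = config.genes_per_genome
        n_defense = int(round(n_genes * config.defense_fraction))

        # plan defense instances for this genome
        instances: list[tuple[str, list[str]]] = []
        planned = 0
        while planned < n_defense:
            si = int(rng.integers(len(systems)))
            fams = systems[si]
            take = fams if planned + len(fams) <= n_defense else fams[: n_defense - planned]
            instances.append((f"sys{si:03d}", list(take)))
            planned += len(take)

        # contig gene counts
        n_contigs = config.contigs_per_genome
        base = n_genes // n_contigs
        counts = [base + (1 if i < n_genes % n_contigs else 0) for i in range(n_contigs)]

        # layout: distribute control genes, then insert defense instances,
        # preferring positions adjacent to existing defense (islands).
        contig_lists: list[list[dict]] = [[] for _ in range(n_contigs)]
        # assign each instance to a contig (weighted by contig size)
        weights = np.array(counts, dtype=float)
        weights = weights / weights.sum()
        inst_contig = [int(rng.choice(n_contigs, p=weights)) for _ in instances]
        def_per_contig = [0] * n_contigs
        for (_, fams), ci in zip(instances, inst_contig):
            def_per_contig[ci] += len(fams)
        for ci, cnt in enumerate(counts):
            n_ctrl = max(0, cnt - def_per_contig[ci])
            contig_lists[ci] = [{"kind": "ctrl"} for _ in range(n_ctrl)]
        for (sys_id, fams), ci in zip(instances, inst_contig):
            instance_counter += 1
            inst_id = f"inst{instance_counter:05d}"
            lst = contig_lists[ci]
            def_positions = [i for i, e in enumerate(lst) if e["kind"] == "def"]
            if def_positions and rng.random() < config.island_probability:
                anchor = int(def_positions[int(rng.integers(len(def_positions)))])
                insert_at = anchor + 1
            else:
                insert_at = int(rng.integers(len(lst) + 1))
            block = [
                {"kind": "def", "family": fam, "system": sys_id, "instance": inst_id}
                for fam in fams
            ]
            contig_lists[ci] = lst[:insert_at] + block + lst[insert_at:]

        # materialize genes
        genes: list[GeneRecord] = []
        contig_seqs: dict[str, str] = {}
        gene_serial = 0
        for ci, lst in enumerate(contig_lists):
            contig_id = f"{genome_id}_c{ci}"
            pos = int(rng.integers(50, 200))
            seq_parts = [_random_dna(pos, config.genome_gc, rng)]
            prev_strand = 1 if rng.random() < 0.5 else -1
            prev_instance = None
            for e in lst:
                if e["kind"] == "def":
                    fam = e["family"]
                    aa = _mutate(family_ancestor[fam], config.mutation_rate, rng)
                    if config.motif:
                        mp = family_motif_pos[fam]
                        aa = aa[:mp] + config.motif + aa[mp + len(config.motif) :]
                    bias = def_bias
                else:
                    if rng.random() < config.control_family_reuse:
                        fam = f"ctrlF{int(rng.integers(n_ctrl_fams)):04d}"
                        aa = _mutate(ctrl_ancestors[fam], config.mutation_rate, rng)
                    else:
                        fam = f"uniqF{fresh_fam:05d}"
                        fresh_fam += 1
                        aa = _random_protein(int(rng.integers(*config.protein_length)), rng)
                    bias = ctrl_bias
                nt = reverse_translate(aa, bias, rng)
                inst = e.get("instance")
                if inst is not None and inst == prev_instance:
                    strand = prev_strand
                    gap = int(rng.integers(0, 21))  # operonic spacing <= 30 bp
                else:
                    strand = prev_strand if rng.random() < config.strand_persistence else -prev_strand
                    gap = int(rng.integers(0, 31)) if rng.random() < 0.5 else int(rng.integers(31, 200))
                if genes and genes[-1].contig_id == contig_id:
                    seq_parts.append(_random_dna(gap, config.genome_gc, rng))
                    pos += gap
                start = pos
                end = pos + len(nt)
                genomic = nt if strand == 1 else _revcomp(nt)
                seq_parts.append(genomic)
                pos = end
                gid = f"{genome_id}_g{gene_serial:04d}"
                gene_serial += 1
                genes.append(
                    GeneRecord(
                        gene_id=gid,
                        contig_id=contig_id,
                        start=start,
                        end=end,
                        strand=strand,
                        nt_seq=nt,
                        aa_seq=aa,
                        translation_provided=False,
                    )
                )
                family_of[gid] = fam
                if e["kind"] == "def":
                    labels[gid] = GeneLabel("defense", system_id=e["system"], dedup_group=fam)
                    system_rows.append(
                        {"instance_id": inst, "system_id": e["system"], "gene_id": gid}
                    )
                else:
                    labels[gid] = GeneLabel("control", system_id="", dedup_group=fam)
                prev_strand = strand
                prev_instance = inst
            tail = int(rng.integers(50, 200))
            seq_parts.append(_random_dna(tail, config.genome_gc, rng))
            contig_seqs[contig_id] = "".join(seq_parts)
        contigs = {cid: len(s) for cid, s in contig_seqs.items()}
        genomes.append(
            Genome(
                genome_id=genome_id,
                contigs=contigs,
                genes=genes,
                genome_gc=gc_fraction("".join(contig_seqs.values())),
                contig_seqs=contig_seqs,
            )
        )

    # homology graph: edges among members of each multi-member family
    members_by_family: dict[str, list[str]] = {}
    for gid, fam in family_of.items():
        members_by_family.setdefault(fam, []).append(gid)
    graph = HomologyGraph()
    for gid in family_of:
        graph.add_node(gid)
    for fam, members in sorted(members_by_family.items()):
        members.sort()
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                graph.graph.add_edge(members[i], members[j], weight=100.0)

    if cluster:
        proteins = [(g.gene_id, g.aa_seq) for genome in genomes for g in genome.genes]
        cluster_map, representatives = reduce_redundancy(
            proteins, seed=int(np.random.default_rng(config.seed + 1).integers(2**31))
        )
    else:
        cluster_map = dict(family_of)
        representatives = {fam: sorted(m)[0] for fam, m in members_by_family.items()}

    return SyntheticCohort(
        genomes=genomes,
        labels=labels,
        cluster_map=cluster_map,
        representatives=representatives,
        homology=graph,
        systems=pd.DataFrame(system_rows, columns=["instance_id", "system_id", "gene_id"]),
        family_of=family_of,
        config=config,
    )


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def generate_hit_table(
    cohort: SyntheticCohort, noise: float = 0.0, seed: int = 0
) -> pd.DataFrame:
    """Simulated best-hit alignment table (columns query, target, score).

    Each gene's best hit is another member of its family (bit-score scaled
    by sequence length and approximate identity); genes in singleton
    families hit a random same-label gene at a weak score. A ``noise``
    fraction of best hits instead point to a random opposite-label gene.
    """
    rng = np.random.default_rng(seed)
    by_family: dict[str, list[str]] = {}
    by_label: dict[int, list[str]] = {0: [], 1: []}
    gene_len: dict[str, int] = {}
    for genome in cohort.genomes:
        for g in genome.genes:
            gene_len[g.gene_id] = len(g.aa_seq)
            by_family.setdefault(cohort.family_of[g.gene_id], []).append(g.gene_id)
            by_label[1 if cohort.labels[g.gene_id].label == "defense" else 0].append(g.gene_id)
    rows = []
    for genome in cohort.genomes:
        for g in genome.genes:
            gid = g.gene_id
            label = 1 if cohort.labels[gid].label == "defense" else 0
            if rng.random() < noise:
                pool = by_label[1 - label]
                target = pool[int(rng.integers(len(pool)))]
                score = 2.0 * gene_len[gid] * float(rng.uniform(0.5, 0.95))
            else:
                fam_members = [m for m in by_family[cohort.family_of[gid]] if m != gid]
                if fam_members:
                    target = fam_members[int(rng.integers(len(fam_members)))]
                    score = 2.0 * gene_len[gid] * float(rng.uniform(0.75, 0.95))
                else:
                    pool = [m for m in by_label[label] if m != gid]
                    target = pool[int(rng.integers(len(pool)))]
                    score = 2.0 * gene_len[gid] * float(rng.uniform(0.15, 0.35))
            rows.append({"query": gid, "target": target, "score": round(score, 1)})
    return pd.DataFrame(rows, columns=["query", "target", "score"])


def generate_interval_table(
    genome: Genome, fraction: float = 0.1, seed: int = 0
) -> pd.DataFrame:
    """Random prophage/plasmid intervals covering roughly ``fraction`` of each contig."""
    rng = np.random.default_rng(seed)
    rows = []
    for contig_id, length in genome.contigs.items():
        span = max(1, int(length * fraction / 2))
        for kind in ("prophage", "plasmid"):
            start = int(rng.integers(0, max(1, length - span)))
            rows.append({"contig": contig_id, "start": start, "end": start + span, "kind": kind})
    return pd.DataFrame(rows, columns=["contig", "start", "end", "kind"])
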