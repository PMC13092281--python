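"""Genome-scale downstream analyses.

Transcriptional units (TUs) are maximal runs of consecutive same-strand
genes each separated by at most 30 bp; a TU's log-odds is the maximum over
its member genes. Defense islands are gene neighborhoods within ten genes of
a known defense gene. Pangenome structure is summarized by per-cluster
genome occupancy (accessory: <= 5 genomes; core: all genomes) and by
rarefaction/accumulation curves over resampled genome subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import intergenic_distance
from .genome_io import Genome, GeneRecord

#: TU chaining threshold; "separated by 30 bp or less" is inclusive.
TU_MAX_GAP_BP = 30
#: defense-island radius in genes.
ISLAND_WINDOW_GENES = 10


@dataclass
class TranscriptionalUnit:
    genes: list[GeneRecord]
    tu_log_odds: float = float("nan")

    @property
    def strand(self) -> int:
        return self.genes[0].strand

    @property
    def contig_id(self) -> str:
        return self.genes[0].contig_id

    @property
    def gene_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]


def call_tus(
    genome: Genome,
    predictions: dict[str, object] | None = None,
    max_gap: int = TU_MAX_GAP_BP,
) -> list[TranscriptionalUnit]:
    """Partition every contig's genes into transcriptional units.

    A new TU starts whenever the strand flips or the intergenic gap exceeds
    ``max_gap`` bp (a gap of exactly ``max_gap`` stays in the same TU). When
    ``predictions`` (gene_id -> record with ``log_odds``) is supplied, each
    TU carries the max log-odds of its members. Every gene belongs to
    exactly one TU and TU order reproduces genomic order.
    """
    tus: list[TranscriptionalUnit] = []
    for contig_id in genome.contigs:
        contig_genes = genome.genes_on(contig_id)
        current: list[GeneRecord] = []
        for g in contig_genes:
            if current and (
                g.strand != current[-1].strand
                or intergenic_distance(current[-1], g) > max_gap
            ):
                tus.append(TranscriptionalUnit(genes=current))
                current = []
            current.append(g)
        if current:
            tus.append(TranscriptionalUnit(genes=current))
    if predictions is not None:
        for tu in tus:
            tu.tu_log_odds = max(predictions[g.gene_id].log_odds for g in tu.genes)
    return tus


def write_tu_table(tus: list[TranscriptionalUnit], path) -> None:
    rows = [
        {
            "tu_id": f"TU{i:05d}",
            "contig_id": tu.contig_id,
            "strand": f"{tu.strand:+d}",
            "genes": ",".join(tu.gene_ids),
            "tu_log_odds": tu.tu_log_odds,
        }
        for i, tu in enumerate(tus)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genomic context


@dataclass
class ContextAnnotation:
    """Per-gene boolean context flags plus per-set frequencies with CIs.

    ``flags`` maps gene_id -> dict(in_island, in_prophage, in_plasmid);
    ``frequencies`` maps gene-set name -> flag -> (estimate, lo, hi) where
    the interval is a 95% percentile bootstrap over genome resamples.
    """

    flags: dict[str, dict[str, bool]]
    frequencies: dict[str, dict[str, tuple[float, float, float]]] = field(default_factory=dict)


def _island_flags(genome: Genome, defense_labels: dict[str, int], window: int) -> dict[str, bool]:
    flags: dict[str, bool] = {}
    for contig_id in genome.contigs:
        contig_genes = genome.genes_on(contig_id)
        defense_idx = [
            i for i, g in enumerate(contig_genes) if defense_labels.get(g.gene_id, 0) == 1
        ]
        for i, g in enumerate(contig_genes):
            flags[g.gene_id] = any(j != i and abs(j - i) <= window for j in defense_idx)
    return flags


def _interval_flags(genome: Genome, intervals: pd.DataFrame, kind: str) -> dict[str, bool]:
    sub = intervals[intervals["kind"] == kind]
    unknown = set(sub["contig"]) - set(genome.contigs)
    if unknown:
        raise ValueError(f"interval table names unknown contigs: {sorted(unknown)}")
    flags = {g.gene_id: False for g in genome.genes}
    for row in sub.itertuples(index=False):
        for g in genome.genes_on(row.contig):
            if g.start < row.end and row.start < g.end:  # >= 1 bp overlap
                flags[g.gene_id] = True
    return flags


def annotate_context(
    genomes: list[Genome],
    defense_labels: dict[str, int],
    interval_tables: dict[str, pd.DataFrame] | None = None,
    gene_sets: dict[str, set[str]] | None = None,
    window: int = ISLAND_WINDOW_GENES,
    boot_reps: int = 200,
    seed: int = 0,
) -> ContextAnnotation:
    """Flag island/prophage/plasmid membership and estimate set frequencies.

    ``interval_tables`` maps genome_id to a BED-like DataFrame (contig,
    start, end, kind in {prophage, plasmid}). ``gene_sets`` names the gene
    sets whose flag frequencies are estimated (default: the set of all
    genes plus the known defense genes); confidence intervals come from
    ``boot_reps`` genome-level bootstrap resamples.
    """
    interval_tables = interval_tables or {}
    flags: dict[str, dict[str, bool]] = {}
    genome_of: dict[str, str] = {}
    for genome in genomes:
        isl = _island_flags(genome, defense_labels, window)
        table = interval_tables.get(genome.genome_id, pd.DataFrame(columns=["contig", "start", "end", "kind"]))
        pro = _interval_flags(genome, table, "prophage")
        pla = _interval_flags(genome, table, "plasmid")
        for g in genome.genes:
            flags[g.gene_id] = {
                "in_island": isl[g.gene_id],
                "in_prophage": pro[g.gene_id],
                "in_plasmid": pla[g.gene_id],
            }
            genome_of[g.gene_id] = genome.genome_id
    if gene_sets is None:
        gene_sets = {
            "all": set(flags),
            "known_defense": {g for g in flags if defense_labels.get(g, 0) == 1},
        }
    rng = np.random.default_rng(seed)
    genome_ids = [g.genome_id for g in genomes]
    genes_by_genome: dict[str, list[str]] = {gid: [] for gid in genome_ids}
    for gene_id, gid in genome_of.items():
        genes_by_genome[gid].append(gene_id)

    def set_freqs(sample: list[str], members: set[str]) -> dict[str, float]:
        pool = [g for gid in sample for g in genes_by_genome[gid] if g in members]
        out = {}
        for flag in ("in_island", "in_prophage", "in_plasmid"):
            out[flag] = (
                float(np.mean([flags[g][flag] for g in pool])) if pool else float("nan")
            )
        return out

    frequencies: dict[str, dict[str, tuple[float, float, float]]] = {}
    boot_samples = [
        list(rng.choice(genome_ids, size=len(genome_ids), replace=True))
        for _ in range(boot_reps)
    ]
    for set_name, members in gene_sets.items():
        point = set_freqs(genome_ids, members)
        boots = {flag: [] for flag in point}
        for sample in boot_samples:
            f = set_freqs(sample, members)
            for flag, v in f.items():
                boots[flag].append(v)
        frequencies[set_name] = {}
        for flag, est in point.items():
            arr = np.asarray(boots[flag], dtype=float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                lo, hi = np.nanpercentile(arr, [2.5, 97.5]) if len(arr) else (np.nan, np.nan)
            frequencies[set_name][flag] = (est, float(lo), float(hi))
    return ContextAnnotation(flags=flags, frequencies=frequencies)


# ---------------------------------------------------------------------------
# pangenome


def occupancy_histogram(
    genomes: list[Genome], cluster_map: dict[str, str], accessory_max: int = 5
) -> pd.DataFrame:
    """Per-cluster genome occupancy with accessory/core flags.

    A cluster is accessory when encoded by ``accessory_max`` or fewer
    genomes and core when encoded by every genome in the collection.
    """
    genomes_of: dict[str, set[str]] = {}
    for genome in genomes:
        for g in genome.genes:
            cid = cluster_map.get(g.gene_id)
            if cid is not None:
                genomes_of.setdefault(cid, set()).add(genome.genome_id)
    n_genomes = len(genomes)
    rows = [
        {
            "cluster_id": cid,
            "n_genomes": len(gs),
            "accessory": len(gs) <= accessory_max,
            "core": len(gs) == n_genomes,
        }
        for cid, gs in sorted(genomes_of.items())
    ]
    return pd.DataFrame(rows, columns=["cluster_id", "n_genomes", "accessory", "core"])


def accumulation_curve(
    genomes: list[Genome],
    cluster_map: dict[str, str],
    category_map: dict[str, str],
    step: int = 50,
    reps: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean unique clusters per category vs number of genomes sampled.

    For each grid size n (1, then multiples of ``step``, always including
    the full collection) genomes are sampled ``reps`` times without
    replacement and the number of unique clusters of each category with at
    least one gene present is averaged. ``category_map`` maps cluster_id to
    a category name; unmapped clusters are ignored.
    """
    n_genomes = len(genomes)
    if step > n_genomes:
        grid = [n_genomes]
    else:
        grid = sorted({1, n_genomes, *range(step, n_genomes + 1, step)})
    clusters_by_genome: list[dict[str, set[str]]] = []
    categories = sorted(set(category_map.values()))
    for genome in genomes:
        per_cat: dict[str, set[str]] = {c: set() for c in categories}
        for g in genome.genes:
            cid = cluster_map.get(g.gene_id)
            cat = category_map.get(cid) if cid is not None else None
            if cat is not None:
                per_cat[cat].add(cid)
        clusters_by_genome.append(per_cat)
    rng = np.random.default_rng(seed)
    rows = []
    for n in grid:
        totals = {c: 0.0 for c in categories}
        for _ in range(reps):
            idx = rng.choice(n_genomes, size=n, replace=False)
            for c in categories:
                seen: set[str] = set()
                for i in idx:
                    seen |= clusters_by_genome[i][c]
                totals[c] += len(seen)
        for c in categories:
            rows.append({"n_genomes": n, "category": c, "mean_unique_clusters": totals[c] / reps})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# validation-rate curve


def validation_rate_curve(
    tus: list[tuple[float, bool]],
    half_window: float = 2.0,
    boot_reps: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, float]:
    """Windowed experimental validation rate vs TU log-odds.

    For each TU the rate is the mean validation outcome over all TUs within
    ``half_window`` log-odds (inclusive; the TU always includes itself).
    95% percentile confidence intervals come from resampling the TU list
    ``boot_reps`` times. Returns the per-TU table and the Pearson r between
    log-odds and estimated rate (NaN with a warning when degenerate).
    """
    if len(tus) < 2:
        raise ValueError("need at least 2 TUs")
    L = np.array([t[0] for t in tus], dtype=float)
    v = np.array([t[1] for t in tus], dtype=float)
    in_window = np.abs(L[:, None] - L[None, :]) <= half_window
    rates = (in_window @ v) / in_window.sum(axis=1)
    rng = np.random.default_rng(seed)
    n = len(tus)
    boots = np.full((boot_reps, n), np.nan)
    for b in range(boot_reps):
        idx = rng.integers(0, n, size=n)
        Lb, vb = L[idx], v[idx]
        win = np.abs(L[:, None] - Lb[None, :]) <= half_window
        counts = win.sum(axis=1)
        with np.errstate(invalid="ignore"):
            boots[b] = np.where(counts > 0, (win @ vb) / np.maximum(counts, 1), np.nan)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        lo = np.nanpercentile(boots, 2.5, axis=0)
        hi = np.nanpercentile(boots, 97.5, axis=0)
    if np.ptp(L) == 0 or np.ptp(rates) == 0:
        warnings.warn("validation rate or log-odds is constant; Pearson r undefined")
        r = float("nan")
    else:
        r = float(stats.pearsonr(L, rates)[0])
    table = pd.DataFrame(
        {"log_odds": L, "rate": rates, "ci_low": lo, "ci_high": hi}
    ).sort_values("log_odds", ignore_index=True)
    return table, r
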