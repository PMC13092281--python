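"""Genome annotation parsing and tabular artifact I/O.

All coordinates are held internally as 0-based half-open intervals on the
forward strand of the contig; ``nt_seq`` is always the coding-strand sequence
(reverse-complemented relative to the contig for strand ``-1`` genes).
GenBank and GFF3 sources, which use 1-based inclusive coordinates, are
converted on read.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

VALID_LABELS = frozenset({"defense", "control", "unlabeled"})

#: NCBI translation table used when a CDS carries no /translation qualifier.
BACTERIAL_TABLE = 11


@dataclass
class GeneRecord:
    """One protein-coding gene.

    ``rank`` is the genomic order index of the gene within its contig,
    starting at 0; neighbor relationships are defined in rank space and never
    cross contig boundaries.
    """

    gene_id: str
    contig_id: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: int  # +1 or -1
    nt_seq: str
    aa_seq: str
    rank: int = -1
    translation_provided: bool = False

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.gene_id}: end must exceed start")
        if self.strand not in (1, -1):
            raise ValueError(f"{self.gene_id}: strand must be +1 or -1")
        if len(self.nt_seq) != self.end - self.start:
            raise ValueError(
                f"{self.gene_id}: nt_seq length {len(self.nt_seq)} != span "
                f"{self.end - self.start}"
            )
        if not self.aa_seq:
            raise ValueError(f"{self.gene_id}: empty protein sequence")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def gc(self) -> float:
        """GC fraction of the coding sequence (N excluded)."""
        acgt = sum(self.nt_seq.count(b) for b in "ACGT")
        if acgt == 0:
            return math.nan
        return (self.nt_seq.count("G") + self.nt_seq.count("C")) / acgt


@dataclass
class Genome:
    """An annotated genome: contigs plus ordered gene records.

    ``genome_gc`` is the GC fraction over all contig nucleotides and is the
    baseline for the gene-level "GC relative to genome" feature.
    ``contig_seqs`` is retained when the source provides full contig sequence
    (needed to write the genome back out); it is not required downstream.
    """

    genome_id: str
    contigs: dict[str, int]
    genes: list[GeneRecord]
    genome_gc: float
    contig_seqs: dict[str, str] | None = None
    _by_id: dict[str, GeneRecord] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        order = {c: i for i, c in enumerate(self.contigs)}
        self.genes.sort(key=lambda g: (order.get(g.contig_id, 1 << 30), g.start))
        rank = 0
        prev_contig = None
        self._by_id = {}
        for g in self.genes:
            if g.contig_id != prev_contig:
                rank = 0
                prev_contig = g.contig_id
            g.rank = rank
            rank += 1
            if g.gene_id in self._by_id:
                raise ValueError(f"duplicate gene_id {g.gene_id!r}")
            self._by_id[g.gene_id] = g
        if not 0.0 <= self.genome_gc <= 1.0:
            raise ValueError("genome_gc must lie in [0, 1]")

    def gene(self, gene_id: str) -> GeneRecord:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene_id {gene_id!r}") from None

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def genes_on(self, contig_id: str) -> list[GeneRecord]:
        return [g for g in self.genes if g.contig_id == contig_id]


@dataclass(frozen=True)
class GeneLabel:
    label: str
    system_id: str = ""
    dedup_group: str = ""


def gc_fraction(seq: str) -> float:
    """GC over A/C/G/T characters only (case-insensitive)."""
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt


def _translate(nt_seq: str) -> str:
    aa = str(Seq(nt_seq).translate(table=BACTERIAL_TABLE))
    if aa.endswith("*"):
        aa = aa[:-1]
    return aa


def read_genome(
    path,
    format: str = "genbank",
    *,
    fasta_path=None,
    genome_id: str | None = None,
) -> Genome:
    """Parse a genome annotation into a :class:`Genome`.

    Parameters
    ----------
    path:
        GenBank flat file, or a GFF3 file when ``format="gff_fasta"``.
    format:
        ``"genbank"`` or ``"gff_fasta"``.
    fasta_path:
        Nucleotide FASTA with contig sequences (required for ``gff_fasta``).

    CDSs without a usable protein product (pseudogenes, internal stop codons,
    compound/origin-spanning locations) are skipped with a logged warning.
    """
    if format == "genbank":
        return _read_genbank(path, genome_id=genome_id)
    if format == "gff_fasta":
        if fasta_path is None:
            raise ValueError("gff_fasta format requires fasta_path")
        return _read_gff_fasta(path, fasta_path, genome_id=genome_id)
    raise ValueError(f"unknown format {format!r}")


def _gene_id_from_qualifiers(feat, contig_id: str, index: int) -> str:
    for key in ("locus_tag", "protein_id", "gene"):
        if key in feat.qualifiers:
            return feat.qualifiers[key][0]
    return f"{contig_id}_cds{index}"


def _read_genbank(path, genome_id: str | None) -> Genome:
    records = list(SeqIO.parse(str(path), "genbank"))
    if not records:
        raise ValueError(f"no GenBank records found in {path}")
    contigs: dict[str, int] = {}
    contig_seqs: dict[str, str] = {}
    genes: list[GeneRecord] = []
    gc_num = gc_den = 0
    for rec in records:
        seq = str(rec.seq).upper()
        contigs[rec.id] = len(seq)
        contig_seqs[rec.id] = seq
        gc_num += seq.count("G") + seq.count("C")
        gc_den += sum(seq.count(b) for b in "ACGT")
        for i, feat in enumerate(rec.features):
            if feat.type != "CDS":
                continue
            gid = _gene_id_from_qualifiers(feat, rec.id, i)
            if "pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers:
                logger.warning("skipping pseudogene CDS %s", gid)
                continue
            if len(feat.location.parts) != 1:
                logger.warning("skipping compound-location CDS %s", gid)
                continue
            start = int(feat.location.start)
            end = int(feat.location.end)
            strand = 1 if feat.location.strand in (1, None) else -1
            nt = seq[start:end]
            if strand == -1:
                nt = str(Seq(nt).reverse_complement())
            provided = "translation" in feat.qualifiers
            if provided:
                aa = feat.qualifiers["translation"][0]
            else:
                aa = _translate(nt)
            if not aa or "*" in aa:
                logger.warning("skipping CDS %s without clean protein product", gid)
                continue
            genes.append(
                GeneRecord(
                    gene_id=gid,
                    contig_id=rec.id,
                    start=start,
                    end=end,
                    strand=strand,
                    nt_seq=nt,
                    aa_seq=aa,
                    translation_provided=provided,
                )
            )
    gid = genome_id or records[0].id
    return Genome(
        genome_id=gid,
        contigs=contigs,
        genes=genes,
        genome_gc=gc_num / gc_den if gc_den else 0.0,
        contig_seqs=contig_seqs,
    )


def _read_gff_fasta(gff_path, fasta_path, genome_id: str | None) -> Genome:
    import gffutils

    contig_seqs = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")
    }
    if not contig_seqs:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    db = gffutils.create_db(
        str(gff_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    contigs = {c: len(s) for c, s in contig_seqs.items()}
    genes: list[GeneRecord] = []
    for i, feat in enumerate(db.features_of_type("CDS", order_by=("seqid", "start"))):
        if feat.seqid not in contig_seqs:
            raise ValueError(f"GFF contig {feat.seqid!r} missing from FASTA")
        gid = feat.attributes.get("ID", [f"{feat.seqid}_cds{i}"])[0]
        start = feat.start - 1  # GFF3 is 1-based inclusive
        end = feat.end
        strand = -1 if feat.strand == "-" else 1
        nt = contig_seqs[feat.seqid][start:end]
        if strand == -1:
            nt = str(Seq(nt).reverse_complement())
        provided = "translation" in feat.attributes
        aa = feat.attributes["translation"][0] if provided else _translate(nt)
        if not aa or "*" in aa:
            logger.warning("skipping CDS %s without clean protein product", gid)
            continue
        genes.append(
            GeneRecord(
                gene_id=gid,
                contig_id=feat.seqid,
                start=start,
                end=end,
                strand=strand,
                nt_seq=nt,
                aa_seq=aa,
                translation_provided=provided,
            )
        )
    seq_all = "".join(contig_seqs.values())
    return Genome(
        genome_id=genome_id or next(iter(contig_seqs)),
        contigs=contigs,
        genes=genes,
        genome_gc=gc_fraction(seq_all),
        contig_seqs=contig_seqs,
    )


def write_genbank(genome: Genome, path) -> None:
    """Write a :class:`Genome` (with contig sequences) as a GenBank flat file."""
    if genome.contig_seqs is None:
        raise ValueError("genome has no contig sequences to write")
    records = []
    for contig_id, seq in genome.contig_seqs.items():
        rec = SeqRecord(Seq(seq), id=contig_id, name=contig_id[:16], description="")
        rec.annotations["molecule_type"] = "DNA"
        for g in genome.genes_on(contig_id):
            feat = SeqFeature(
                FeatureLocation(g.start, g.end, strand=g.strand),
                type="CDS",
                qualifiers={"locus_tag": [g.gene_id], "translation": [g.aa_seq]},
            )
            rec.features.append(feat)
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "genbank")


def write_gff_fasta(genome: Genome, gff_path, fasta_path) -> None:
    """Write GFF3 + nucleotide FASTA for a genome with contig sequences."""
    if genome.contig_seqs is None:
        raise ValueError("genome has no contig sequences to write")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig_id, length in genome.contigs.items():
            fh.write(f"##sequence-region {contig_id} 1 {length}\n")
        for g in genome.genes:
            strand = "+" if g.strand == 1 else "-"
            attrs = f"ID={g.gene_id};translation={g.aa_seq}"
            fh.write(
                f"{g.contig_id}\tphagedefense\tCDS\t{g.start + 1}\t{g.end}\t.\t"
                f"{strand}\t0\t{attrs}\n"
            )
    with open(fasta_path, "w") as fh:
        for contig_id, seq in genome.contig_seqs.items():
            fh.write(f">{contig_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# tabular artifacts


def read_label_table(path) -> dict[str, GeneLabel]:
    """Read a gene label TSV (columns gene_id, label[, system_id, dedup_group]).

    Unknown gene_ids are retained (they may refer to other genomes). A label
    outside {defense, control, unlabeled} raises ``ValueError``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = {"gene_id", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"label table missing columns: {sorted(missing)}")
    bad = set(df["label"]) - VALID_LABELS
    if bad:
        raise ValueError(f"invalid labels: {sorted(bad)}")
    out: dict[str, GeneLabel] = {}
    for row in df.itertuples(index=False):
        out[row.gene_id] = GeneLabel(
            label=row.label,
            system_id=getattr(row, "system_id", ""),
            dedup_group=getattr(row, "dedup_group", ""),
        )
    return out


def write_label_table(labels: dict[str, GeneLabel], path) -> None:
    rows = [
        {
            "gene_id": gid,
            "label": lab.label,
            "system_id": lab.system_id,
            "dedup_group": lab.dedup_group,
        }
        for gid, lab in labels.items()
    ]
    pd.DataFrame(rows, columns=["gene_id", "label", "system_id", "dedup_group"]).to_csv(
        path, sep="\t", index=False
    )


PREDICTION_COLUMNS = [
    "genome_id",
    "gene_id",
    "contig_id",
    "start",
    "end",
    "strand",
    "probability",
    "log_odds",
]


def write_predictions(genome: Genome, records, path) -> None:
    """Write per-gene predictions as TSV in genomic order.

    ``records`` is an iterable of objects with ``gene_id``, ``probability``
    and ``log_odds`` attributes (see :class:`phagedefense.model
    .PredictionRecord`). Probabilities are printed with 8 significant digits.
    """
    by_id = {r.gene_id: r for r in records}
    with open(path, "w") as fh:
        fh.write("\t".join(PREDICTION_COLUMNS) + "\n")
        for g in genome.genes:
            if g.gene_id not in by_id:
                continue
            r = by_id[g.gene_id]
            fh.write(
                f"{genome.genome_id}\t{g.gene_id}\t{g.contig_id}\t{g.start}\t"
                f"{g.end}\t{g.strand:+d}\t{r.probability:.8g}\t{r.log_odds:.8g}\n"
            )


def read_predictions(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(PREDICTION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"prediction table missing columns: {sorted(missing)}")
    return df


def read_pair_table(path) -> pd.DataFrame:
    """Read a homolog/alignment-hit TSV with columns query, target, score."""
    df = pd.read_csv(path, sep="\t", dtype={"query": str, "target": str})
    missing = {"query", "target", "score"} - set(df.columns)
    if missing:
        raise ValueError(f"pair table missing columns: {sorted(missing)}")
    return df


def write_pair_table(pairs, path) -> None:
    pd.DataFrame(pairs, columns=["query", "target", "score"]).to_csv(
        path, sep="\t", index=False
    )


def read_interval_table(path) -> pd.DataFrame:
    """Read a BED-like interval table: contig, start, end, kind (0-based half-open)."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["contig", "start", "end", "kind"],
        dtype={"contig": str, "kind": str},
        comment="#",
    )
    if (df["end"] <= df["start"]).any():
        raise ValueError("interval table contains empty or inverted intervals")
    return df


def write_interval_table(df: pd.DataFrame, path) -> None:
    df[["contig", "start", "end", "kind"]].to_csv(
        path, sep="\t", header=False, index=False
    )
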