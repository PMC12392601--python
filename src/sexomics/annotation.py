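"""Gene and transcript models plus GTF/FASTA input and output.

Coordinates are 0-based half-open everywhere inside the package; the GTF
reader and writer convert to and from the 1-based inclusive convention of
the format. Chromosomes are classified as autosomal, X or Y by name, which
is how every downstream stage (dosage ratios, sexing verification, DEG
density) decides which stratum a gene belongs to.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

Interval = tuple[int, int]


def merge_intervals(intervals: list[Interval]) -> list[Interval]:
    """Sort and merge overlapping or book-ended half-open intervals."""
    if not intervals:
        return []
    ivs = sorted(intervals)
    merged = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def intervals_overlap(a: Interval, b: Interval) -> bool:
    """At least 1 bp shared between two half-open intervals."""
    return a[0] < b[1] and b[0] < a[1]


@dataclass
class TranscriptModel:
    """Exon/CDS structure of one transcript.

    ``exons`` and ``cds`` are sorted, non-overlapping half-open genomic
    intervals regardless of strand; transcription order is reversed for
    minus-strand transcripts when sequence or codon order matters.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval]
    cds: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)
        for ivs, label in ((self.exons, "exon"), (self.cds, "CDS")):
            for (s0, e0), (s1, e1) in zip(ivs, ivs[1:]):
                if s1 < e0:
                    raise ValueError(f"overlapping {label} intervals in {self.transcript_id}")
            for s, e in ivs:
                if e <= s:
                    raise ValueError(f"empty {label} interval in {self.transcript_id}")

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def length(self) -> int:
        """Spliced (exonic) length in bp."""
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def introns(self) -> list[Interval]:
        """Intron chain: half-open gaps between consecutive exons."""
        return [(self.exons[i][1], self.exons[i + 1][0]) for i in range(len(self.exons) - 1)]

    def coding_positions(self) -> list[int]:
        """Genomic positions of coding bases in translation order.

        Minus-strand transcripts read their CDS intervals from the highest
        coordinate downwards, so position 0 of the returned list is always
        the first base of the start codon.
        """
        pos: list[int] = []
        for s, e in self.cds:
            pos.extend(range(s, e))
        if self.strand == "-":
            pos.reverse()
        return pos


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    biotype: str = "protein_coding"
    name: str | None = None
    is_tf: bool = False
    is_tf_cofactor: bool = False
    is_paralog: bool = False
    is_escapee: bool = False
    transcripts: list[TranscriptModel] = field(default_factory=list)

    @property
    def span(self) -> Interval:
        return (self.start, self.end)


def chromosome_class(chrom: str) -> str:
    """Map a chromosome name to 'A' (autosome), 'X' or 'Y'."""
    base = chrom.removeprefix("chr")
    if base.upper() == "X":
        return "X"
    if base.upper() == "Y":
        return "Y"
    return "A"


@dataclass
class Annotation:
    """A gene set with optional genome sequences and chromosome lengths."""

    genes: dict[str, Gene]
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    sequences: dict[str, str] = field(default_factory=dict)

    def transcripts(self) -> list[TranscriptModel]:
        return [t for g in self.genes.values() for t in g.transcripts]

    def transcript(self, transcript_id: str) -> TranscriptModel:
        for g in self.genes.values():
            for t in g.transcripts:
                if t.transcript_id == transcript_id:
                    return t
        raise KeyError(transcript_id)

    def genes_on(self, chrom_class: str) -> list[Gene]:
        return [g for g in self.genes.values() if chromosome_class(g.chrom) == chrom_class]

    def gene_lengths(self) -> dict[str, int]:
        """Per gene, spliced length of its longest transcript (bp)."""
        return {
            gid: max(t.length for t in g.transcripts) if g.transcripts else g.end - g.start
            for gid, g in self.genes.items()
        }


# ---------------------------------------------------------------------------
# GTF I/O


def _gtf_attributes(pairs: dict[str, str]) -> str:
    return " ".join(f'{k} "{v}";' for k, v in pairs.items())


def write_gtf(annotation: Annotation, path: str | Path) -> None:
    """Write genes, transcripts, exons and CDS as GTF (1-based inclusive).

    Custom attribute tags carried: gene_biotype, paralog, tf_class, escapee.
    """
    lines = []
    for gene in annotation.genes.values():
        tf_class = "TF" if gene.is_tf else ("TF_cofactor" if gene.is_tf_cofactor else "none")
        attrs = {
            "gene_id": gene.gene_id,
            "gene_biotype": gene.biotype,
            "paralog": str(gene.is_paralog).lower(),
            "tf_class": tf_class,
            "escapee": str(gene.is_escapee).lower(),
        }
        if gene.name:
            attrs["gene_name"] = gene.name
        lines.append(
            "\t".join(
                [gene.chrom, "sexomics", "gene", str(gene.start + 1), str(gene.end),
                 ".", gene.strand, ".", _gtf_attributes(attrs)]
            )
        )
        for tx in gene.transcripts:
            tx_attrs = {"gene_id": gene.gene_id, "transcript_id": tx.transcript_id}
            s, e = tx.span
            lines.append(
                "\t".join(
                    [tx.chrom, "sexomics", "transcript", str(s + 1), str(e),
                     ".", tx.strand, ".", _gtf_attributes(tx_attrs)]
                )
            )
            for es, ee in tx.exons:
                lines.append(
                    "\t".join(
                        [tx.chrom, "sexomics", "exon", str(es + 1), str(ee),
                         ".", tx.strand, ".", _gtf_attributes(tx_attrs)]
                    )
                )
            for cs, ce in tx.cds:
                lines.append(
                    "\t".join(
                        [tx.chrom, "sexomics", "CDS", str(cs + 1), str(ce),
                         ".", tx.strand, "0", _gtf_attributes(tx_attrs)]
                    )
                )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gtf(path: str | Path, fasta: str | Path | None = None) -> Annotation:
    """Parse a GTF written by :func:`write_gtf` back into an Annotation."""
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    def attr(feat, key, default=""):
        vals = feat.attributes.get(key, [default])
        return vals[0] if vals else default

    genes: dict[str, Gene] = {}
    for gf in db.features_of_type("gene"):
        tf_class = attr(gf, "tf_class", "none")
        genes[attr(gf, "gene_id")] = Gene(
            gene_id=attr(gf, "gene_id"),
            chrom=gf.seqid,
            strand=gf.strand,
            start=gf.start - 1,
            end=gf.end,
            biotype=attr(gf, "gene_biotype", "protein_coding"),
            name=attr(gf, "gene_name", None) or None,
            is_tf=tf_class == "TF",
            is_tf_cofactor=tf_class == "TF_cofactor",
            is_paralog=attr(gf, "paralog", "false") == "true",
            is_escapee=attr(gf, "escapee", "false") == "true",
        )
    # group exon/CDS features by their transcript_id attribute; this stays
    # correct for GTFs whose gene_id and transcript_id values collide
    tx_parts: dict[str, dict] = {}
    for ftype, key in (("exon", "exons"), ("CDS", "cds")):
        for feat in db.features_of_type(ftype):
            tid = attr(feat, "transcript_id")
            part = tx_parts.setdefault(
                tid,
                {"gene_id": attr(feat, "gene_id"), "chrom": feat.seqid,
                 "strand": feat.strand, "exons": [], "cds": []},
            )
            part[key].append((feat.start - 1, feat.end))
    for tid, part in tx_parts.items():
        genes[part["gene_id"]].transcripts.append(
            TranscriptModel(tid, part["gene_id"], part["chrom"], part["strand"],
                            part["exons"], part["cds"])
        )

    sequences: dict[str, str] = {}
    if fasta is not None:
        sequences = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}
    chrom_lengths = {name: len(seq) for name, seq in sequences.items()}
    return Annotation(genes=genes, chrom_lengths=chrom_lengths, sequences=sequences)


def write_fasta(sequences: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
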