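"""CDS translation, domain-hit filtering, coordinate lift-over and
disruption calls.

A PFAM-style domain hit lives in 1-based inclusive amino-acid coordinates
on a transcript's protein. Amino acid k owns CDS nucleotides 3k-2..3k in
spliced CDS space; those nucleotides map through the exon structure
(strand-aware) to one or more genomic intervals, so a lifted domain always
covers exactly 3x its amino-acid span in genomic bases, possibly split
across exon junctions. A filtered hit is called disrupted when any of its
genomic intervals overlaps (>= 1 bp, same chromosome) a significant
skipped exon.

Hit filtering applies the five high-confidence criteria with the printed
strictness: bit score > 10 and both E-values strictly below threshold;
alignment accuracy and domain-model coverage at-or-above theirs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .annotation import Interval, TranscriptModel, intervals_overlap, merge_intervals

SCORE_MIN = 10.0  # strict >
DOMAIN_EVALUE_MAX = 0.01  # strict <
SEQ_EVALUE_MAX = 1e-5  # strict <
ACCURACY_MIN = 0.8  # inclusive >=
COVERAGE_MIN = 0.9  # inclusive >=

_METRICS = ("domain_score", "domain_evalue", "seq_evalue", "accuracy", "coverage")


@dataclass
class DomainHit:
    """One domain-to-protein alignment with hmmscan-style metrics."""

    protein_id: str  # = transcript id
    domain_name: str
    aa_start: int  # 1-based inclusive
    aa_end: int
    domain_score: float | None = None  # bits
    domain_evalue: float | None = None
    seq_evalue: float | None = None  # full-sequence E-value
    accuracy: float | None = None  # mean posterior probability
    coverage: float | None = None  # fraction of the domain model aligned

    def __post_init__(self) -> None:
        if self.aa_start < 1 or self.aa_end < self.aa_start:
            raise ValueError("need 1 <= aa_start <= aa_end")


def translate_cds(model: TranscriptModel, sequences: dict[str, str]) -> str:
    """Translate a transcript's CDS with the standard genetic code.

    CDS intervals are concatenated in transcription order (reverse
    complemented on the minus strand). A trailing stop codon is dropped
    from the protein; an internal stop raises.
    """
    if not model.cds:
        raise ValueError(f"{model.transcript_id} has no CDS")
    if model.chrom not in sequences:
        raise ValueError(f"no sequence for chromosome {model.chrom}")
    chrom_seq = sequences[model.chrom]
    cds_seq = "".join(chrom_seq[s:e] for s, e in model.cds)
    if model.strand == "-":
        cds_seq = str(Seq(cds_seq).reverse_complement())
    if len(cds_seq) % 3 != 0:
        raise ValueError(f"CDS length of {model.transcript_id} is not a multiple of 3")
    protein = str(Seq(cds_seq).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise ValueError(f"internal stop codon in {model.transcript_id}")
    return protein


def protein_length(model: TranscriptModel, sequences: dict[str, str] | None = None) -> int:
    """Residue count; the trailing stop codon is excluded when sequence is known."""
    if sequences is not None:
        return len(translate_cds(model, sequences))
    return model.cds_length // 3


def protein_to_genomic(
    aa_start: int,
    aa_end: int,
    model: TranscriptModel,
    n_residues: int | None = None,
) -> list[Interval]:
    """Map a 1-based inclusive amino-acid interval to genomic intervals.

    The returned half-open intervals are sorted, merged, and always total
    3 x (aa_end - aa_start + 1) genomic bases. ``n_residues`` bounds the
    liftable protein (pass the translated length to keep a trailing stop
    codon out of reach); it defaults to cds_length // 3.
    """
    if aa_start < 1 or aa_end < aa_start:
        raise ValueError("need 1 <= aa_start <= aa_end")
    limit = n_residues if n_residues is not None else model.cds_length // 3
    if aa_end > limit:
        raise ValueError(f"amino-acid interval [{aa_start},{aa_end}] exceeds protein length {limit}")
    positions = model.coding_positions()
    wanted = positions[3 * (aa_start - 1) : 3 * aa_end]
    return merge_intervals([(p, p + 1) for p in wanted])


def genomic_to_protein(position: int, model: TranscriptModel) -> int | None:
    """Residue index (1-based) owning a genomic coding base, else None."""
    positions = model.coding_positions()
    try:
        k = positions.index(position)
    except ValueError:
        return None
    return k // 3 + 1


def filter_domain_hits(hits: list[DomainHit]) -> tuple[list[DomainHit], pd.DataFrame]:
    """Keep high-confidence hits; report every rejection with its reason.

    A hit passes iff domain_score > 10, domain_evalue < 0.01,
    seq_evalue < 1e-5, accuracy >= 0.8 and coverage >= 0.9. A hit with
    any metric missing is rejected with reason 'incomplete'.
    """
    kept: list[DomainHit] = []
    rows = []
    for hit in hits:
        missing = [m for m in _METRICS if getattr(hit, m) is None or pd.isna(getattr(hit, m))]
        if missing:
            reason = "incomplete"
        else:
            failures = []
            if not hit.domain_score > SCORE_MIN:
                failures.append("domain_score")
            if not hit.domain_evalue < DOMAIN_EVALUE_MAX:
                failures.append("domain_evalue")
            if not hit.seq_evalue < SEQ_EVALUE_MAX:
                failures.append("seq_evalue")
            if not hit.accuracy >= ACCURACY_MIN:
                failures.append("accuracy")
            if not hit.coverage >= COVERAGE_MIN:
                failures.append("coverage")
            reason = ",".join(failures) if failures else ""
        passed = reason == ""
        if passed:
            kept.append(hit)
        rows.append(
            {
                "protein_id": hit.protein_id,
                "domain_name": hit.domain_name,
                "passed": passed,
                "reason": reason,
            }
        )
    return kept, pd.DataFrame(rows)


def call_disrupted_domains(
    hits: list[DomainHit],
    models: dict[str, TranscriptModel],
    skipped_exons: pd.DataFrame,
    n_residues: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Join filtered domain hits against significant skipped exons.

    ``skipped_exons`` needs columns event_id, chrom, start, end (0-based
    half-open) and optionally bias. A hit is affected iff any lifted
    genomic interval overlaps any skipped exon on the same chromosome by
    at least one base. One row per (hit, event) pair for affected hits
    plus one row with event_id NA for untouched hits.
    """
    rows = []
    for hit in hits:
        model = models.get(hit.protein_id)
        if model is None:
            raise KeyError(f"no transcript model for {hit.protein_id}")
        limit = n_residues.get(hit.protein_id) if n_residues else None
        intervals = protein_to_genomic(hit.aa_start, hit.aa_end, model, n_residues=limit)
        affected_any = False
        for _, ev in skipped_exons.iterrows():
            if ev["chrom"] != model.chrom:
                continue
            exon = (int(ev["start"]), int(ev["end"]))
            if any(intervals_overlap(iv, exon) for iv in intervals):
                affected_any = True
                rows.append(
                    {
                        "domain_name": hit.domain_name,
                        "transcript_id": hit.protein_id,
                        "gene_id": model.gene_id,
                        "event_id": ev["event_id"],
                        "bias": ev.get("bias", "none"),
                        "affected": True,
                    }
                )
        if not affected_any:
            rows.append(
                {
                    "domain_name": hit.domain_name,
                    "transcript_id": hit.protein_id,
                    "gene_id": model.gene_id,
                    "event_id": pd.NA,
                    "bias": "none",
                    "affected": False,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["domain_name", "transcript_id", "gene_id", "event_id", "bias", "affected"],
    )


def affected_domain_counts(affected: pd.DataFrame) -> pd.Series:
    """Distinct affected domains per bias direction (one domain may recur)."""
    sub = affected[affected["affected"]]
    return sub.groupby("bias")[["domain_name", "transcript_id"]].apply(
        lambda g: len(g.drop_duplicates())
    )


# ---------------------------------------------------------------------------
# domtblout-style I/O

DOMTBL_COLUMNS = [
    "protein_id",
    "domain_name",
    "aa_start",
    "aa_end",
    "domain_score",
    "domain_evalue",
    "seq_evalue",
    "accuracy",
    "coverage",
]


def write_domain_hits(hits: list[DomainHit], path: str | Path) -> None:
    pd.DataFrame([{c: getattr(h, c) for c in DOMTBL_COLUMNS} for h in hits]).to_csv(
        path, sep="\t", index=False
    )


def read_domain_hits(path: str | Path) -> list[DomainHit]:
    df = pd.read_csv(path, sep="\t")
    hits = []
    for _, row in df.iterrows():
        kwargs = {c: row[c] for c in DOMTBL_COLUMNS}
        for m in _METRICS:
            if pd.isna(kwargs[m]):
                kwargs[m] = None
        hits.append(DomainHit(**{**kwargs, "aa_start": int(row.aa_start), "aa_end": int(row.aa_end)}))
    return hits


def write_affected_bed(affected: pd.DataFrame, models: dict[str, TranscriptModel],
                       hits: list[DomainHit], path: str | Path) -> None:
    """BED of lifted genomic intervals for affected domains
    (name = domain|transcript|event)."""
    by_key = {(h.domain_name, h.protein_id): h for h in hits}
    lines = []
    for _, row in affected[affected["affected"]].iterrows():
        hit = by_key[(row["domain_name"], row["transcript_id"])]
        model = models[hit.protein_id]
        for s, e in protein_to_genomic(hit.aa_start, hit.aa_end, model):
            name = f"{row['domain_name']}|{row['transcript_id']}|{row['event_id']}"
            lines.append(f"{model.chrom}\t{s}\t{e}\t{name}\t0\t{model.strand}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
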