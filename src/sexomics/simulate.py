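"""Synthetic cohorts, genomes, count matrices, splicing events, domain
hits and isoform chains with known ground truth.

The generator emulates the statistical structure of a sexed bovine
blastocyst study: a cohort whose male embryos progress to later blastocyst
stages with higher probability; a toy multi-chromosome genome (autosomes,
X, Y) whose protein-coding genes carry in-frame CDS split across exons on
both strands, plus an XIST-like non-coding X gene; negative-binomial
gene counts with Y-linked male-only expression, female-only XIST-like
expression, sex-specific X dosage scaling and spiked autosomal DEGs;
binomially allocated inclusion/skipping junction reads with group-specific
PSI; PFAM-style domain hits engineered to pass or fail each filter
criterion, to straddle exon junctions and to sit inside to-be-skipped
exons; and isoform intron chains covering every classifier category.

All randomness flows from one root seed through named substreams, so each
stage is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import Annotation, Gene, Interval, TranscriptModel
from .domains import DomainHit
from .expression import CountMatrix
from .isoforms import IsoformChain
from .sexing import FEMALE, MALE, STAGES, SexRecord, call_sex_from_amplicons
from .splicing import DEFAULT_INC_LEN, DEFAULT_SKIP_LEN, SEEvent

_STREAMS = {"cohort": 0, "annotation": 1, "counts": 2, "splicing": 3, "domains": 4, "isoforms": 5}

_STOP_CODONS = {"TAA", "TAG", "TGA"}
_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in _STOP_CODONS and a + b + c != "ATG"
]
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass
class SimulationConfig:
    """Study-condition knobs for every generator.

    Defaults encode the cohort and effect structure the generators
    emulate: 444 embryos with ~7% sexing failures, 5 male and 6 female
    RNA-seq pools, female X-linked expression scaled 1.3-fold, spiked
    autosomal sex-biased genes at |log2FC| = 2 with NB noise, and
    skipped-exon events with a 0.3 PSI shift in a quarter of events.
    """

    seed: int = 0
    # cohort
    n_embryos: int = 444
    p_male: float = 0.5
    sexing_failure_rate: float = 32 / 444
    p_day7: float = 0.5
    stage_probs_female: tuple[float, float, float] = (0.60, 0.31, 0.09)
    stage_probs_male: tuple[float, float, float] = (0.20, 0.62, 0.18)
    # annotation
    n_autosomes: int = 3
    genes_per_chrom: int = 30
    paralog_fraction: float = 0.2
    tf_fraction: float = 0.08
    tf_cofactor_fraction: float = 0.05
    escapee_fraction: float = 0.1
    # counts
    n_male_samples: int = 5
    n_female_samples: int = 6
    x_dosage_factor_female: float = 1.3
    x_dosage_factor_male: float = 1.0
    frac_autosomal_deg: float = 0.1
    deg_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    depth: float = 1e6
    y_leak_rate: float = 0.0
    # splicing
    n_se_events: int = 60
    frac_differential_se: float = 0.25
    se_dpsi: float = 0.3
    junction_depth: float = 200.0
    psi_table: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        for name in ("sexing_failure_rate", "p_male", "p_day7", "frac_autosomal_deg",
                     "paralog_fraction", "tf_fraction", "tf_cofactor_fraction",
                     "escapee_fraction", "frac_differential_se", "y_leak_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in ("depth", "junction_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("x_dosage_factor_female", "x_dosage_factor_male"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be non-negative")
        if self.psi_table is not None:
            for ev, (pf, pm) in self.psi_table.items():
                if not (0 <= pf <= 1 and 0 <= pm <= 1):
                    raise ValueError(f"psi values for {ev} must lie in [0, 1]")
        for probs in (self.stage_probs_female, self.stage_probs_male):
            if len(probs) != 3 or abs(sum(probs) - 1) > 1e-9 or min(probs) < 0:
                raise ValueError("stage probabilities must be a 3-simplex point")


@dataclass
class GroundTruth:
    """What the generators actually put into the data."""

    sample_sex: dict[str, str] = field(default_factory=dict)
    deg_effects: dict[str, float] = field(default_factory=dict)  # gene -> signed log2FC (male/female)
    x_genes: list[str] = field(default_factory=list)
    y_genes: list[str] = field(default_factory=list)
    xist_like: str | None = None
    psi: dict[str, tuple[float, float]] = field(default_factory=dict)  # event -> (female, male)
    differential_events: list[str] = field(default_factory=list)
    disrupted_hits: dict[str, bool] = field(default_factory=dict)  # hit key -> disrupted
    isoform_categories: dict[str, str] = field(default_factory=dict)
    biased_isoforms: dict[str, str] = field(default_factory=dict)  # isoform -> direction


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(_STREAMS[stream],))
    )


# ---------------------------------------------------------------------------
# cohort


def generate_cohort(config: SimulationConfig) -> list[SexRecord]:
    """Embryos with Bernoulli sex, sex-dependent stage and PCR amplicons.

    Stage is drawn from a per-sex categorical over (non_expanded,
    expanded, hatched); with a male-shifted stage distribution the
    conditional sex ratio at the later stages is male-biased, which is
    the developmental-pace signal the cohort statistics measure. A
    sexing failure silences both amplicons.
    """
    if config.n_embryos <= 0:
        raise ValueError("n_embryos must be positive")
    rng = _rng(config, "cohort")
    records = []
    probs = {FEMALE: config.stage_probs_female, MALE: config.stage_probs_male}
    for i in range(config.n_embryos):
        true_sex = MALE if rng.random() < config.p_male else FEMALE
        day = 7 if rng.random() < config.p_day7 else 8
        stage = STAGES[rng.choice(3, p=probs[true_sex])]
        failed = rng.random() < config.sexing_failure_rate
        autosomal = not failed
        y_present = autosomal and (
            true_sex == MALE or rng.random() < config.y_leak_rate
        )
        rec = SexRecord(
            embryo_id=f"embryo_{i + 1:04d}",
            day=day,
            stage=stage,
            autosomal_amplicon=autosomal,
            y_amplicon=y_present,
            true_sex=true_sex,
        )
        call_sex_from_amplicons(rec)
        records.append(rec)
    return records


# ---------------------------------------------------------------------------
# annotation + genome


def _design_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + internal non-stop codons + one stop codon."""
    body = "".join(rng.choice(_CODONS) for _ in range(n_codons))
    return "ATG" + body + "TAA"


def _place_transcript(
    rng: np.random.Generator,
    chrom: str,
    strand: str,
    gene_start: int,
    gene_idx: int,
    coding: bool,
) -> tuple[TranscriptModel, str | None, int]:
    """Lay one transcript down from ``gene_start``; returns (model, cds_seq, end)."""
    n_exons = int(rng.integers(3, 6))
    if coding:
        n_codons = int(rng.integers(60, 150))
        cds_seq = _design_cds(rng, n_codons)
        cds_len = len(cds_seq)
        # split the CDS across exons; pieces need not respect codon
        # boundaries (codons split mid-exon exercise the lift-over), but
        # each exon keeps a workable minimum size
        for _ in range(100):
            cuts = np.sort(rng.choice(np.arange(12, cds_len - 11), size=n_exons - 1,
                                      replace=False))
            pieces = np.diff(np.concatenate([[0], cuts, [cds_len]])).tolist()
            if min(pieces) >= 12:
                break
    else:
        cds_seq = None
        pieces = [int(rng.integers(80, 250)) for _ in range(n_exons)]
    utr5 = int(rng.integers(20, 80))
    utr3 = int(rng.integers(20, 80))
    introns = [int(rng.integers(80, 300)) for _ in range(n_exons - 1)]

    # exon lengths in transcription order
    exon_lens = list(pieces)
    if coding:
        exon_lens[0] += utr5
        exon_lens[-1] += utr3

    # genomic order: transcription order for +, reversed for -
    g_exon_lens = exon_lens if strand == "+" else exon_lens[::-1]
    g_introns = introns if strand == "+" else introns[::-1]
    exons: list[Interval] = []
    pos = gene_start
    for k, length in enumerate(g_exon_lens):
        exons.append((pos, pos + length))
        pos += length
        if k < len(g_introns):
            pos += g_introns[k]
    gene_end = exons[-1][1]

    cds: list[Interval] = []
    if coding:
        # trim UTRs off the transcription-first and transcription-last exon
        tx_exons = exons if strand == "+" else exons[::-1]
        for k, (s, e) in enumerate(tx_exons):
            cs, ce = s, e
            if k == 0:  # transcription-first exon carries the 5' UTR
                if strand == "+":
                    cs = s + utr5
                else:
                    ce = e - utr5
            if k == len(tx_exons) - 1:  # transcription-last exon carries the 3' UTR
                if strand == "+":
                    ce = e - utr3
                else:
                    cs = s + utr3
            cds.append((cs, ce))
        cds = sorted(cds)

    model = TranscriptModel(
        transcript_id=f"{chrom}_tx_{gene_idx}",
        gene_id=f"{chrom}_gene_{gene_idx}",
        chrom=chrom,
        strand=strand,
        exons=exons,
        cds=cds,
    )
    return model, cds_seq, gene_end


def generate_annotation(config: SimulationConfig) -> Annotation:
    """Toy genome: autosome_1..N, X and Y with in-frame multi-exon genes.

    Every protein-coding gene has one transcript whose CDS starts with
    ATG, ends with a stop codon and contains no internal stop; the
    designed CDS is written into the genome sequence (complemented on the
    minus strand) so translation round-trips. One extra non-coding
    XIST-like gene sits on X. Paralog/TF/cofactor/escapee flags are
    assigned at the configured fractions.
    """
    rng = _rng(config, "annotation")
    chroms = [f"autosome_{i + 1}" for i in range(config.n_autosomes)] + ["X", "Y"]
    genes: dict[str, Gene] = {}
    sequences: dict[str, str] = {}
    chrom_lengths: dict[str, int] = {}
    for chrom in chroms:
        n_genes = config.genes_per_chrom
        cursor = 1000
        chrom_genes: list[tuple[Gene, str | None]] = []
        for gi in range(n_genes):
            strand = "+" if rng.random() < 0.5 else "-"
            model, cds_seq, end = _place_transcript(rng, chrom, strand, cursor, gi + 1, True)
            gene = Gene(
                gene_id=model.gene_id,
                chrom=chrom,
                strand=strand,
                start=model.span[0],
                end=model.span[1],
                biotype="protein_coding",
                is_tf=rng.random() < config.tf_fraction,
                is_tf_cofactor=False,
                is_paralog=rng.random() < config.paralog_fraction,
                is_escapee=chrom == "X" and rng.random() < config.escapee_fraction,
                transcripts=[model],
            )
            if not gene.is_tf and rng.random() < config.tf_cofactor_fraction:
                gene.is_tf_cofactor = True
            chrom_genes.append((gene, cds_seq))
            cursor = end + int(rng.integers(2000, 4000))
        if chrom == "X":
            model, _, end = _place_transcript(rng, chrom, "+", cursor, n_genes + 1, False)
            model.transcript_id = "XIST_like_tx"
            model.gene_id = "XIST_like"
            xist = Gene(
                gene_id="XIST_like",
                chrom=chrom,
                strand="+",
                start=model.span[0],
                end=model.span[1],
                biotype="lncRNA",
                name="XIST_like",
                is_escapee=True,
                transcripts=[model],
            )
            chrom_genes.append((xist, None))
            cursor = end + 2000
        length = cursor + 5000
        chrom_lengths[chrom] = length
        base = rng.integers(0, 4, size=length)
        arr = np.array(list("ACGT"))[base]
        for gene, cds_seq in chrom_genes:
            genes[gene.gene_id] = gene
            if cds_seq is None:
                continue
            model = gene.transcripts[0]
            positions = model.coding_positions()
            assert len(positions) == len(cds_seq)
            for p, b in zip(positions, cds_seq):
                arr[p] = b if model.strand == "+" else b.translate(_COMPLEMENT)
        sequences[chrom] = "".join(arr)
    return Annotation(genes=genes, chrom_lengths=chrom_lengths, sequences=sequences)


# ---------------------------------------------------------------------------
# counts


def _sample_labels(config: SimulationConfig) -> pd.Series:
    ids = [f"M{i + 1}" for i in range(config.n_male_samples)] + [
        f"F{i + 1}" for i in range(config.n_female_samples)
    ]
    sexes = [MALE] * config.n_male_samples + [FEMALE] * config.n_female_samples
    return pd.Series(sexes, index=ids, name="sex")


def generate_counts(
    annotation: Annotation,
    config: SimulationConfig,
    sample_sex: pd.Series | None = None,
) -> tuple[CountMatrix, GroundTruth]:
    """NB gene counts with Y-, XIST-like-, X-dosage and DEG effects.

    Per gene g and sample s the mean is depth x relative abundance x a
    lognormal library factor, multiplied by: 0 for Y-linked genes in
    females (up to ``y_leak_rate``), 0 for the XIST-like gene in males,
    the sex-specific X dosage factor for X-linked genes, and
    2^(+/- deg_log2fc) in males for the spiked autosomal DEGs (half up,
    half down). Counts are gamma-Poisson with dispersion
    ``nb_dispersion``.
    """
    if not annotation.genes:
        raise ValueError("annotation has no genes")
    rng = _rng(config, "counts")
    if sample_sex is None:
        sample_sex = _sample_labels(config)
    samples = list(sample_sex.index)
    genes = list(annotation.genes.values())
    gene_ids = [g.gene_id for g in genes]
    truth = GroundTruth(sample_sex=dict(sample_sex))

    rel = rng.lognormal(mean=0.0, sigma=1.0, size=len(genes))
    rel /= rel.sum()

    from .annotation import chromosome_class

    classes = np.array([chromosome_class(g.chrom) for g in genes])
    truth.x_genes = [g.gene_id for g in genes if chromosome_class(g.chrom) == "X"]
    truth.y_genes = [g.gene_id for g in genes if chromosome_class(g.chrom) == "Y"]
    if "XIST_like" in annotation.genes:
        truth.xist_like = "XIST_like"

    autosomal = [
        g.gene_id
        for g in genes
        if chromosome_class(g.chrom) == "A" and g.biotype == "protein_coding"
    ]
    n_deg = int(round(config.frac_autosomal_deg * len(autosomal)))
    deg_ids = list(rng.choice(autosomal, size=n_deg, replace=False)) if n_deg else []
    for k, gid in enumerate(deg_ids):
        sign = 1.0 if k % 2 == 0 else -1.0
        truth.deg_effects[gid] = sign * config.deg_log2fc

    lib = rng.lognormal(mean=0.0, sigma=0.15, size=len(samples))
    counts = np.zeros((len(genes), len(samples)), dtype=np.int64)
    for j, sid in enumerate(samples):
        sex = sample_sex[sid]
        factor = np.ones(len(genes))
        if sex == FEMALE:
            y_mask = classes == "Y"
            factor[y_mask] = np.where(
                rng.random(y_mask.sum()) < config.y_leak_rate, 0.02, 0.0
            )
            factor[classes == "X"] *= config.x_dosage_factor_female
        else:
            factor[classes == "X"] *= config.x_dosage_factor_male
            if truth.xist_like is not None:
                factor[gene_ids.index(truth.xist_like)] = 0.0
        for gid, effect in truth.deg_effects.items():
            if sex == MALE:
                factor[gene_ids.index(gid)] *= 2.0 ** effect
        mu = config.depth * rel * lib[j] * factor
        if config.nb_dispersion > 0:
            shape = 1.0 / config.nb_dispersion
            lam = rng.gamma(shape, mu * config.nb_dispersion)
        else:
            lam = mu
        counts[:, j] = rng.poisson(lam)

    lengths = pd.Series(annotation.gene_lengths()).reindex(gene_ids)
    weeks = pd.Series(
        [f"week{(k % 2) + 1}" for k in range(len(samples))], index=samples, name="batch"
    )
    cm = CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=samples),
        feature_lengths=lengths,
        sample_sex=sample_sex,
        sample_batch=weeks,
    )
    return cm, truth


# ---------------------------------------------------------------------------
# skipped-exon events


def _se_anchors(annotation: Annotation) -> list[TranscriptModel]:
    """Transcripts with >= 3 exons, eligible to host a skipped-exon event."""
    return [t for t in annotation.transcripts() if len(t.exons) >= 3]


def _default_psi_table(config: SimulationConfig, rng: np.random.Generator) -> dict:
    table = {}
    n_diff = int(round(config.frac_differential_se * config.n_se_events))
    for k in range(config.n_se_events):
        eid = f"se_{k + 1:04d}"
        base = rng.uniform(0.25, 0.75)
        if k < n_diff:
            shift = config.se_dpsi if rng.random() < 0.5 else -config.se_dpsi
            pf = float(np.clip(base - shift / 2, 0.02, 0.98))
            pm = float(np.clip(base + shift / 2, 0.02, 0.98))
        else:
            pf = pm = float(base)
        table[eid] = (pf, pm)
    return table


def inclusion_probability(psi: float, inc_len: float = DEFAULT_INC_LEN,
                          skip_len: float = DEFAULT_SKIP_LEN) -> float:
    """P(an observed junction read is an inclusion read | PSI).

    The effective-length weighting here is exactly what
    :func:`sexomics.splicing.compute_psi` inverts.
    """
    num = psi * inc_len
    return num / (num + (1 - psi) * skip_len)


def generate_se_events(
    annotation: Annotation,
    config: SimulationConfig,
    sample_sex: pd.Series | None = None,
) -> tuple[list[SEEvent], GroundTruth]:
    """Skipped-exon events with binomially allocated junction reads.

    Each event anchors to the middle exon of a real transcript. Per
    sample, total junction reads are Poisson(junction_depth) and
    inclusion reads Binomial(total, p) with
    p = psi*lI / (psi*lI + (1-psi)*lS) for the sample's sex-specific PSI.
    """
    rng = _rng(config, "splicing")
    if sample_sex is None:
        sample_sex = _sample_labels(config)
    psi_table = config.psi_table or _default_psi_table(config, rng)
    for eid, (pf, pm) in psi_table.items():
        if not (0 <= pf <= 1 and 0 <= pm <= 1):
            raise ValueError(f"psi values for {eid} must lie in [0, 1]")
    anchors = _se_anchors(annotation)
    if not anchors:
        raise ValueError("annotation has no transcript with >= 3 exons")
    truth = GroundTruth(sample_sex=dict(sample_sex))
    events = []
    for k, (eid, (pf, pm)) in enumerate(sorted(psi_table.items())):
        tx = anchors[k % len(anchors)]
        mid = len(tx.exons) // 2
        event = SEEvent(
            event_id=eid,
            gene_id=tx.gene_id,
            chrom=tx.chrom,
            strand=tx.strand,
            exon=tx.exons[mid],
            upstream_exon=tx.exons[mid - 1],
            downstream_exon=tx.exons[mid + 1],
            inclusion={},
            skipping={},
        )
        for sid, sex in sample_sex.items():
            psi = pm if sex == MALE else pf
            total = rng.poisson(config.junction_depth)
            p = inclusion_probability(psi, event.inc_len, event.skip_len)
            inc = rng.binomial(total, p) if total > 0 else 0
            event.inclusion[sid] = int(inc)
            event.skipping[sid] = int(total - inc)
        events.append(event)
        truth.psi[eid] = (pf, pm)
        if pf != pm:
            truth.differential_events.append(eid)
    return events, truth


# ---------------------------------------------------------------------------
# domain hits


_PASSING = dict(domain_score=50.0, domain_evalue=1e-6, seq_evalue=1e-12, accuracy=0.95,
                coverage=0.98)
_FAILING = dict(domain_score=10.0, domain_evalue=0.02, seq_evalue=1e-4, accuracy=0.7,
                coverage=0.8)


def _residues_fully_inside(model: TranscriptModel, interval: Interval) -> list[int]:
    """1-based residues whose three bases all fall inside a genomic interval."""
    positions = model.coding_positions()
    out = []
    for r in range(len(positions) // 3):
        triplet = positions[3 * r : 3 * r + 3]
        if all(interval[0] <= p < interval[1] for p in triplet):
            out.append(r + 1)
    return out


def _residue_spanning_junction(model: TranscriptModel) -> int | None:
    """A residue whose codon is split across two exons, if any."""
    positions = model.coding_positions()
    for r in range(len(positions) // 3):
        triplet = positions[3 * r : 3 * r + 3]
        if max(triplet) - min(triplet) > 2:
            return r + 1
    return None


def generate_domain_hits(
    annotation: Annotation,
    config: SimulationConfig,
    se_events: list[SEEvent] | None = None,
) -> tuple[list[DomainHit], GroundTruth]:
    """Domain hits with controlled filter outcomes and disruption labels.

    Emits, per eligible transcript batch: clean passing hits; for each of
    the five filter criteria one hit failing exactly that criterion; a
    passing hit whose amino-acid span crosses an exon junction; and, when
    ``se_events`` are given, passing hits placed inside the skipped exon
    of an event (labelled disrupted in the ground truth). Hit keys in the
    truth are ``protein_id:domain_name``.
    """
    rng = _rng(config, "domains")
    truth = GroundTruth()
    hits: list[DomainHit] = []

    anchors = _se_anchors(annotation)
    events = se_events or []
    event_by_tx: dict[str, SEEvent] = {}
    for k, ev in enumerate(events):
        tx = anchors[k % len(anchors)]
        event_by_tx.setdefault(tx.transcript_id, ev)

    def add(model: TranscriptModel, name: str, aa_start: int, aa_end: int,
            **metrics) -> None:
        # ground-truth disruption is the actual overlap of the hit's
        # genomic footprint with the skipped exon hosted on its transcript
        vals = {**_PASSING, **metrics}
        hit = DomainHit(model.transcript_id, name, aa_start, aa_end, **vals)
        hits.append(hit)
        truth.disrupted_hits[f"{model.transcript_id}:{name}"] = _overlaps_event(
            model, aa_start, aa_end, event_by_tx
        )

    for model in anchors[: max(5, len(event_by_tx))]:
        n_res = model.cds_length // 3 - 1  # trailing stop excluded
        if n_res < 20:
            continue
        add(model, "PF_clean", 2, min(15, n_res))
        junction_res = _residue_spanning_junction(model)
        if junction_res is not None and junction_res + 3 <= n_res:
            add(model, "PF_junction", max(1, junction_res - 3), junction_res + 3)
        ev = event_by_tx.get(model.transcript_id)
        if ev is not None:
            inside = _residues_fully_inside(model, ev.exon)
            if len(inside) >= 2:
                add(model, "PF_skipped", inside[0], inside[-1])

    # one hit failing exactly one criterion, for each of the five criteria
    fail_host = next(m for m in anchors if m.cds_length // 3 - 1 >= 20)
    for crit, bad in _FAILING.items():
        add(fail_host, f"PF_fail_{crit}", 2, 10, **{crit: bad})

    rng.shuffle(hits)
    return hits, truth


def _overlaps_event(model: TranscriptModel, aa_start: int, aa_end: int,
                    event_by_tx: dict[str, SEEvent]) -> bool:
    from .annotation import intervals_overlap
    from .domains import protein_to_genomic

    ev = event_by_tx.get(model.transcript_id)
    if ev is None:
        return False
    ivs = protein_to_genomic(aa_start, aa_end, model)
    return any(intervals_overlap(iv, ev.exon) for iv in ivs)


# ---------------------------------------------------------------------------
# isoform chains


def generate_isoform_chains(
    annotation: Annotation,
    config: SimulationConfig,
) -> tuple[list[IsoformChain], pd.DataFrame, GroundTruth]:
    """Isoform chains covering all eight classifier categories, plus counts.

    Returns (chains, per-sample isoform counts, truth). One gene's FSM /
    NIC isoform pair is generated with the male-spiked-isoform pattern:
    the gene's total output is balanced between sexes while one isoform
    is 4-fold male-biased.
    """
    rng = _rng(config, "isoforms")
    truth = GroundTruth()
    chains: list[IsoformChain] = []

    donors = [t for t in annotation.transcripts() if len(t.exons) >= 4]
    if len(donors) < 4:
        raise ValueError("need at least 4 transcripts with >= 4 exons")

    def label(chain: IsoformChain, category: str) -> IsoformChain:
        truth.isoform_categories[chain.isoform_id] = category
        chains.append(chain)
        return chain

    # FSM: exact copy of a reference chain
    t0 = donors[0]
    label(IsoformChain("iso_fsm", t0.chrom, t0.strand, *t0.span, list(t0.introns)), "FSM")

    # ISM: drop the first intron (a consecutive sub-chain)
    t1 = donors[1]
    introns = t1.introns
    label(
        IsoformChain("iso_ism", t1.chrom, t1.strand, introns[0][1], t1.span[1],
                     introns[1:]),
        "ISM",
    )

    # NIC: skip an internal exon -> known sites, novel junction pairing
    t2 = donors[2]
    introns = t2.introns
    nic_introns = [(introns[0][0], introns[1][1])] + introns[2:]
    label(IsoformChain("iso_nic", t2.chrom, t2.strand, *t2.span, nic_introns), "NIC")

    # NNC: one splice site shifted into the exon interior
    t3 = donors[3]
    introns = list(t3.introns)
    s, e = introns[0]
    introns[0] = (s - 9, e)
    label(IsoformChain("iso_nnc", t3.chrom, t3.strand, *t3.span, introns), "NNC")

    # antisense: mono-exonic chain opposite a gene
    g0 = annotation.genes[t0.gene_id]
    anti_strand = "-" if g0.strand == "+" else "+"
    label(
        IsoformChain("iso_antisense", g0.chrom, anti_strand, g0.start + 10, g0.start + 400),
        "antisense",
    )

    # intergenic: beyond every gene on the first autosome
    chrom = "autosome_1"
    last_end = max(g.end for g in annotation.genes.values() if g.chrom == chrom)
    label(
        IsoformChain("iso_intergenic", chrom, "+", last_end + 1500, last_end + 2500),
        "intergenic",
    )

    # genic_genomic: mono-exonic chain inside an intron, same strand
    t4 = donors[0]
    isv, iev = t4.introns[0]
    pad = max(2, (iev - isv) // 8)
    label(
        IsoformChain("iso_genic", t4.chrom, t4.strand, isv + pad, iev - pad),
        "genic_genomic",
    )

    # fusion: span two disjoint same-strand genes on one chromosome
    fusion = None
    by_chrom: dict[tuple[str, str], list[Gene]] = {}
    for g in annotation.genes.values():
        by_chrom.setdefault((g.chrom, g.strand), []).append(g)
    for (chrom_name, strand), gene_list in sorted(by_chrom.items()):
        gene_list = sorted(gene_list, key=lambda g: g.start)
        for a, b in zip(gene_list, gene_list[1:]):
            if a.end < b.start and a.transcripts[0].introns and b.transcripts[0].introns:
                ia = a.transcripts[0].introns[0]
                ib = b.transcripts[0].introns[-1]
                fusion = IsoformChain(
                    "iso_fusion", chrom_name, strand, a.start, b.end, [ia, ib]
                )
                break
        if fusion:
            break
    if fusion is None:
        raise ValueError("could not place a fusion chain; increase genes_per_chrom")
    label(fusion, "fusion")

    # a second isoform of the FSM gene (exon-skipping NIC) so that one gene
    # carries an isoform-switch pair for the expression test below
    i0 = t0.introns
    label(
        IsoformChain("iso_nic2", t0.chrom, t0.strand, *t0.span,
                     [(i0[0][0], i0[1][1])] + i0[2:]),
        "NIC",
    )

    # per-sample isoform counts: one male-spiked isoform within a balanced gene
    sample_sex = _sample_labels(config)
    iso_ids = [c.isoform_id for c in chains]
    base = rng.lognormal(mean=4.0, sigma=0.5, size=len(iso_ids))
    counts = np.zeros((len(iso_ids), len(sample_sex)), dtype=np.int64)
    spiked, partner = "iso_fsm", "iso_nic2"  # two isoforms of the same gene
    truth.biased_isoforms[spiked] = "male_biased"
    truth.biased_isoforms[partner] = "female_biased"
    for j, (sid, sex) in enumerate(sample_sex.items()):
        mu = base.copy()
        i_sp, i_pa = iso_ids.index(spiked), iso_ids.index(partner)
        pair_total = mu[i_sp] + mu[i_pa]
        if sex == MALE:
            mu[i_sp] = pair_total * 0.8
            mu[i_pa] = pair_total * 0.2
        else:
            mu[i_sp] = pair_total * 0.2
            mu[i_pa] = pair_total * 0.8
        shape = 1.0 / max(config.nb_dispersion, 1e-6)
        counts[:, j] = rng.poisson(rng.gamma(shape, mu / shape))
    count_df = pd.DataFrame(counts, index=iso_ids, columns=list(sample_sex.index))
    truth.sample_sex = dict(sample_sex)
    return chains, count_df, truth


# ---------------------------------------------------------------------------
# tabular I/O for the generated inputs


def write_cohort(records: list[SexRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "embryo_id": r.embryo_id,
                "day": r.day,
                "stage": r.stage,
                "autosomal_amplicon": int(r.autosomal_amplicon),
                "y_amplicon": int(r.y_amplicon),
                "called_sex": r.called_sex,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def read_cohort(path: str | Path) -> list[SexRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for _, row in df.iterrows():
        rec = SexRecord(
            embryo_id=str(row.embryo_id),
            day=int(row.day),
            stage=str(row.stage),
            autosomal_amplicon=bool(row.autosomal_amplicon),
            y_amplicon=bool(row.y_amplicon),
        )
        call_sex_from_amplicons(rec)
        records.append(rec)
    return records


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    out = cm.counts.copy()
    out.insert(0, "length", cm.feature_lengths)
    out.to_csv(path, sep="\t", index_label="feature_id")


def read_counts(path: str | Path, sample_sex: pd.Series,
                sample_batch: pd.Series | None = None) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="feature_id")
    lengths = df.pop("length")
    return CountMatrix(df, lengths, sample_sex, sample_batch)


RMATS_COLUMNS = [
    "ID", "GeneID", "chr", "strand", "exonStart_0base", "exonEnd",
    "upstreamES", "upstreamEE", "downstreamES", "downstreamEE",
    "IJC_SAMPLE_1", "SJC_SAMPLE_1", "IJC_SAMPLE_2", "SJC_SAMPLE_2",
    "IncFormLen", "SkipFormLen",
]


def write_se_events(events: list[SEEvent], sample_sex: pd.Series, path: str | Path) -> None:
    """rMATS-style SE table; SAMPLE_1 = male samples, SAMPLE_2 = female."""
    males = [s for s, sex in sample_sex.items() if sex == MALE]
    females = [s for s, sex in sample_sex.items() if sex == FEMALE]
    rows = []
    for ev in events:
        rows.append(
            {
                "ID": ev.event_id,
                "GeneID": ev.gene_id,
                "chr": ev.chrom,
                "strand": ev.strand,
                "exonStart_0base": ev.exon[0],
                "exonEnd": ev.exon[1],
                "upstreamES": ev.upstream_exon[0],
                "upstreamEE": ev.upstream_exon[1],
                "downstreamES": ev.downstream_exon[0],
                "downstreamEE": ev.downstream_exon[1],
                "IJC_SAMPLE_1": ",".join(str(ev.inclusion.get(s, 0)) for s in males),
                "SJC_SAMPLE_1": ",".join(str(ev.skipping.get(s, 0)) for s in males),
                "IJC_SAMPLE_2": ",".join(str(ev.inclusion.get(s, 0)) for s in females),
                "SJC_SAMPLE_2": ",".join(str(ev.skipping.get(s, 0)) for s in females),
                "IncFormLen": ev.inc_len,
                "SkipFormLen": ev.skip_len,
            }
        )
    pd.DataFrame(rows, columns=RMATS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_se_events(path: str | Path, male_samples: list[str],
                   female_samples: list[str]) -> list[SEEvent]:
    df = pd.read_csv(path, sep="\t")
    events = []
    for _, row in df.iterrows():
        inc1 = [int(v) for v in str(row.IJC_SAMPLE_1).split(",")]
        sjc1 = [int(v) for v in str(row.SJC_SAMPLE_1).split(",")]
        inc2 = [int(v) for v in str(row.IJC_SAMPLE_2).split(",")]
        sjc2 = [int(v) for v in str(row.SJC_SAMPLE_2).split(",")]
        inclusion = dict(zip(male_samples, inc1)) | dict(zip(female_samples, inc2))
        skipping = dict(zip(male_samples, sjc1)) | dict(zip(female_samples, sjc2))
        events.append(
            SEEvent(
                event_id=str(row.ID),
                gene_id=str(row.GeneID),
                chrom=str(row["chr"]),
                strand=str(row.strand),
                exon=(int(row.exonStart_0base), int(row.exonEnd)),
                upstream_exon=(int(row.upstreamES), int(row.upstreamEE)),
                downstream_exon=(int(row.downstreamES), int(row.downstreamEE)),
                inclusion=inclusion,
                skipping=skipping,
                inc_len=float(row.IncFormLen),
                skip_len=float(row.SkipFormLen),
            )
        )
    return events
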