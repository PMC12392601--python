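import numpy as np
import pandas as pd
import pytest

from sexomics.annotation import TranscriptModel
from sexomics.domains import (
    DomainHit,
    call_disrupted_domains,
    filter_domain_hits,
    genomic_to_protein,
    protein_to_genomic,
    translate_cds,
)
from sexomics.simulate import (
    SimulationConfig,
    generate_annotation,
    generate_domain_hits,
    generate_se_events,
)


def _model(strand, exons, cds, chrom="c", tid="t1"):
    return TranscriptModel(tid, "g1", chrom, strand, exons, cds)


# ---------------------------------------------------------------------------
# translation


def test_translate_plus_strand_codon_table():
    m = _model("+", [(0, 6)], [(0, 6)])
    assert translate_cds(m, {"c": "ATGGCC"}) == "MA"


def test_translate_minus_strand_reverse_complement():
    # genomic GGCCAT read on the minus strand is ATGGCC
    m = _model("-", [(0, 6)], [(0, 6)])
    assert translate_cds(m, {"c": "GGCCAT"}) == "MA"


def test_translate_multi_exon_split_mid_codon_matches_concatenation():
    # CDS ATG GCC AAA TGA split 4 | 8 across an intron (mid-codon break)
    seq = "ATGG" + "TTTTT" + "CCAAATGA"
    split = _model("+", [(0, 4), (9, 17)], [(0, 4), (9, 17)])
    joined = _model("+", [(0, 12)], [(0, 12)])
    assert translate_cds(split, {"c": seq}) == translate_cds(
        joined, {"c": "ATGGCCAAATGA"}
    )
    # the trailing stop is dropped
    assert translate_cds(split, {"c": seq}) == "MAK"


def test_translate_error_conditions():
    with pytest.raises(ValueError, match="multiple of 3"):
        translate_cds(_model("+", [(0, 4)], [(0, 4)]), {"c": "ATGG"})
    with pytest.raises(ValueError, match="internal stop"):
        translate_cds(_model("+", [(0, 9)], [(0, 9)]), {"c": "ATGTAAAAA"})
    with pytest.raises(ValueError, match="no sequence"):
        translate_cds(_model("+", [(0, 6)], [(0, 6)]), {})


def test_every_generated_transcript_translates(small_annotation):
    for t in small_annotation.transcripts():
        if t.cds:
            protein = translate_cds(t, small_annotation.sequences)
            assert protein.startswith("M") and "*" not in protein


# ---------------------------------------------------------------------------
# hit filtering


def _hit(**over):
    base = dict(
        protein_id="t1", domain_name="PF1", aa_start=1, aa_end=10,
        domain_score=50.0, domain_evalue=1e-6, seq_evalue=1e-12,
        accuracy=0.95, coverage=0.98,
    )
    base.update(over)
    return DomainHit(**base)


@pytest.mark.parametrize(
    "override, passes",
    [
        ({}, True),
        ({"domain_score": 10.0}, False),  # strict >
        ({"domain_score": 10.0 + 1e-9}, True),
        ({"domain_evalue": 0.01}, False),  # strict <
        ({"seq_evalue": 1e-5}, False),  # strict <
        ({"accuracy": 0.8}, True),  # inclusive >=
        ({"accuracy": 0.799}, False),
        ({"coverage": 0.9}, True),  # inclusive >=
        ({"coverage": 0.899}, False),
        ({"accuracy": None}, False),  # incomplete
    ],
)
def test_filter_boundary_semantics(override, passes):
    kept, report = filter_domain_hits([_hit(**override)])
    assert (len(kept) == 1) == passes
    if override.get("accuracy", 0.95) is None:
        assert report.iloc[0]["reason"] == "incomplete"


def test_filter_is_idempotent_and_order_independent():
    hits = [_hit(domain_name=f"PF{i}", domain_score=5.0 + 3 * i) for i in range(6)]
    kept_fwd, _ = filter_domain_hits(hits)
    kept_rev, _ = filter_domain_hits(hits[::-1])
    assert {h.domain_name for h in kept_fwd} == {h.domain_name for h in kept_rev}
    again, _ = filter_domain_hits(kept_fwd)
    assert again == kept_fwd


# ---------------------------------------------------------------------------
# coordinate lift


def test_lift_plus_strand_forced_arithmetic():
    # single-exon CDS starting at genomic 101 (1-based) = 100 internal
    m = _model("+", [(100, 160)], [(100, 160)])
    assert protein_to_genomic(1, 2, m) == [(100, 106)]


def test_lift_minus_strand_first_residue():
    # single-exon CDS ending at genomic 300 (1-based) = internal end 300
    m = _model("-", [(240, 300)], [(240, 300)])
    # residue 1 owns the three highest-coordinate bases: 298..300 (1-based)
    assert protein_to_genomic(1, 1, m) == [(297, 300)]


@pytest.mark.parametrize("strand", ["+", "-"])
def test_lift_matches_enumeration_oracle(strand):
    """Explicit per-base map agrees with the lift for random intervals."""
    m = _model(strand, [(10, 25), (40, 52), (70, 91)], [(13, 25), (40, 52), (70, 82)])
    positions = []
    for s, e in m.cds:
        positions.extend(range(s, e))
    if strand == "-":
        positions.reverse()
    n_res = len(positions) // 3
    rng = np.random.default_rng(3)
    for _ in range(25):
        a = int(rng.integers(1, n_res + 1))
        b = int(rng.integers(a, n_res + 1))
        expected = sorted(positions[3 * (a - 1) : 3 * b])
        got = protein_to_genomic(a, b, m)
        flat = [p for s, e in got for p in range(s, e)]
        assert flat == expected
        assert sum(e - s for s, e in got) == 3 * (b - a + 1)


@pytest.mark.parametrize("strand", ["+", "-"])
def test_per_base_round_trip_bijection(strand):
    m = _model(strand, [(10, 25), (40, 52), (70, 91)], [(13, 25), (40, 52), (70, 82)])
    n_res = m.cds_length // 3
    seen = []
    for r in range(1, n_res + 1):
        for s, e in protein_to_genomic(r, r, m):
            for pos in range(s, e):
                assert genomic_to_protein(pos, m) == r
                seen.append(pos)
    assert sorted(seen) == sorted(set(seen))  # every coding base exactly once
    assert len(seen) == m.cds_length


def test_lift_spanning_exon_junction_splits_interval():
    m = _model("+", [(0, 4), (10, 18)], [(0, 4), (10, 18)])
    # residue 2 owns spliced bases 4..6 -> genomic 3 and 10,11
    got = protein_to_genomic(2, 2, m)
    assert got == [(3, 4), (10, 12)]
    with pytest.raises(ValueError, match="exceeds"):
        protein_to_genomic(1, 5, m)


# ---------------------------------------------------------------------------
# disruption calls


def _skipped(rows):
    return pd.DataFrame(rows, columns=["event_id", "chrom", "start", "end"])


def test_one_bp_overlap_is_affected_adjacent_is_not():
    m = _model("+", [(100, 160)], [(100, 160)])
    hit = _hit(aa_start=1, aa_end=2)  # genomic (100, 106)
    touching = _skipped([("ev1", "c", 105, 120)])
    adjacent = _skipped([("ev2", "c", 106, 120)])
    assert call_disrupted_domains([hit], {"t1": m}, touching)["affected"].all()
    assert not call_disrupted_domains([hit], {"t1": m}, adjacent)["affected"].any()


def test_domain_spanning_junction_with_upstream_part_in_exon():
    m = _model("+", [(0, 4), (10, 18)], [(0, 4), (10, 18)])
    hit = _hit(aa_start=1, aa_end=2)  # genomic (0,4) + (10,12)
    only_upstream = _skipped([("ev", "c", 0, 4)])
    out = call_disrupted_domains([hit], {"t1": m}, only_upstream)
    assert out["affected"].all()


def test_synthetic_disruption_calls_match_ground_truth(small_annotation, small_events):
    events, _ = small_events
    cfg = SimulationConfig(seed=11, n_autosomes=2, genes_per_chrom=12)
    hits, truth = generate_domain_hits(small_annotation, cfg, se_events=events)
    kept, _ = filter_domain_hits(hits)
    models = {t.transcript_id: t for t in small_annotation.transcripts()}
    lengths = {
        tid: len(translate_cds(m, small_annotation.sequences))
        for tid, m in models.items()
        if m.cds
    }
    skipped = _skipped(
        [(e.event_id, e.chrom, e.exon[0], e.exon[1]) for e in events]
    )
    out = call_disrupted_domains(kept, models, skipped, n_residues=lengths)
    per_hit = out.groupby(["transcript_id", "domain_name"])["affected"].any()
    for (tid, name), affected in per_hit.items():
        assert truth.disrupted_hits[f"{tid}:{name}"] == affected
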