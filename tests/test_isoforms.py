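import itertools

import numpy as np
import pandas as pd
import pytest

from sexomics.annotation import Annotation, Gene, TranscriptModel
from sexomics.isoforms import (
    IsoformChain,
    classify_isoform,
    classify_isoforms,
    differential_isoform_test,
    integrate_gene_sets,
)
from sexomics.simulate import SimulationConfig, generate_isoform_chains


def _toy_reference():
    """One plus-strand 4-exon gene, one minus-strand gene, built by hand."""
    t1 = TranscriptModel(
        "t1", "gA", "c1", "+",
        exons=[(100, 200), (300, 400), (500, 600), (700, 800)],
    )
    t2 = TranscriptModel("t2", "gB", "c1", "-", exons=[(2000, 2100), (2300, 2400)])
    mono = TranscriptModel("t3", "gC", "c1", "+", exons=[(5000, 5500)])
    genes = {
        "gA": Gene("gA", "c1", "+", 100, 800, transcripts=[t1]),
        "gB": Gene("gB", "c1", "-", 2000, 2400, transcripts=[t2]),
        "gC": Gene("gC", "c1", "+", 5000, 5500, transcripts=[mono]),
    }
    return Annotation(genes=genes)


REF_INTRONS = [(200, 300), (400, 500), (600, 700)]


@pytest.mark.parametrize(
    "introns, span, strand, expected, gene",
    [
        (REF_INTRONS, (100, 800), "+", "FSM", "gA"),
        ([(600, 700)], (550, 800), "+", "ISM", "gA"),  # last intron only
        ([(400, 500), (600, 700)], (350, 800), "+", "ISM", "gA"),
        # known donor of intron 1 paired with known acceptor of intron 2
        ([(200, 500), (600, 700)], (100, 800), "+", "NIC", "gA"),
        # one shifted (novel) donor
        ([(190, 300), (400, 500), (600, 700)], (100, 800), "+", "NNC", "gA"),
        ([(200, 300), (400, 500), (600, 710)], (100, 800), "+", "NNC", "gA"),
        # non-consecutive subset of known introns is NIC, not ISM
        ([(200, 300), (600, 700)], (100, 800), "+", "NIC", "gA"),
        ((), (900_000, 900_500), "+", "intergenic", None),
        ((), (120, 180), "-", "antisense", "gA"),
        ((), (210, 290), "+", "genic_genomic", "gA"),  # mono-exonic in an intron
        ((), (5050, 5400), "+", "FSM", "gC"),  # within a mono-exonic reference
    ],
)
def test_toy_annotation_oracle(introns, span, strand, expected, gene):
    ref = _toy_reference()
    chain = IsoformChain("q", "c1", strand, span[0], span[1], list(introns))
    out = classify_isoform(chain, ref)
    assert out.category == expected
    if gene is not None:
        assert out.gene_id == gene


def test_fusion_spans_two_disjoint_genes():
    ref = _toy_reference()
    chain = IsoformChain(
        "q", "c1", "+", 150, 5300, [(200, 300), (800, 5100)]
    )
    assert classify_isoform(chain, ref).category == "fusion"


def test_fsm_invariant_under_unrelated_reference_additions():
    ref = _toy_reference()
    chain = IsoformChain("q", "c1", "+", 100, 800, REF_INTRONS)
    before = classify_isoform(chain, ref).category
    extra = TranscriptModel("tx", "gD", "c9", "+", exons=[(0, 50), (80, 120)])
    ref.genes["gD"] = Gene("gD", "c9", "+", 0, 120, transcripts=[extra])
    assert classify_isoform(chain, ref).category == before == "FSM"


def test_wobble_window_rescues_near_miss_sites():
    ref = _toy_reference()
    off = [(202, 300), (400, 500), (600, 700)]
    chain = IsoformChain("q", "c1", "+", 100, 800, off)
    assert classify_isoform(chain, ref, wobble=0).category == "NNC"
    assert classify_isoform(chain, ref, wobble=3).category == "FSM"


def test_synthetic_chains_classify_to_ground_truth(small_annotation, small_config):
    chains, _, truth = generate_isoform_chains(small_annotation, small_config)
    table = classify_isoforms(chains, small_annotation)
    assert set(truth.isoform_categories.values()) == {
        "FSM", "ISM", "NIC", "NNC", "intergenic", "antisense", "genic_genomic", "fusion"
    }
    for iso, category in truth.isoform_categories.items():
        assert table.loc[iso, "category"] == category


# ---------------------------------------------------------------------------
# differential isoform expression


def _sex(n_male=5, n_female=6):
    ids = [f"M{i}" for i in range(n_male)] + [f"F{i}" for i in range(n_female)]
    return pd.Series(["male"] * n_male + ["female"] * n_female, index=ids)


def test_null_counts_produce_no_biased_isoforms():
    rng = np.random.default_rng(5)
    sex = _sex()
    counts = pd.DataFrame(
        rng.poisson(100, size=(30, 11)),
        index=[f"iso{i}" for i in range(30)],
        columns=sex.index,
    )
    out = differential_isoform_test(counts, sex)
    assert out["biased"].sum() == 0


def test_single_isoform_q_equals_p():
    rng = np.random.default_rng(6)
    sex = _sex(3, 3)
    counts = pd.DataFrame(
        rng.poisson(80, size=(1, 6)), index=["iso"], columns=sex.index
    )
    out = differential_isoform_test(counts, sex)
    assert out.loc["iso", "q"] == out.loc["iso", "p"]


def test_spiked_isoform_detected_without_gene_level_change(
    small_annotation, small_config
):
    """Isoform switching inside a balanced gene is seen only at isoform level."""
    chains, counts, truth = generate_isoform_chains(small_annotation, small_config)
    table = classify_isoforms(chains, small_annotation)
    genes = dict(table["gene_id"].items())
    sex = pd.Series(truth.sample_sex)
    out = differential_isoform_test(counts, sex, isoform_genes=genes)
    for iso, direction in truth.biased_isoforms.items():
        assert out.loc[iso, "biased"]
        assert out.loc[iso, "direction"] == direction
    # the gene's summed output stays balanced between sexes
    pair = [i for i, g in genes.items() if g == genes["iso_fsm"]]
    gene_total = counts.loc[pair].sum(axis=0)
    male = gene_total[sex == "male"].mean()
    female = gene_total[sex == "female"].mean()
    assert abs(np.log2(male / female)) < 0.5
    # an unclassifiable isoform is excluded from testing
    assert not out.loc["iso_intergenic", "tested"]


# ---------------------------------------------------------------------------
# set integration


def test_integration_disjoint_and_identical_sets():
    out = integrate_gene_sets({"a", "b"}, {"c", "d", "e"}, {"f", "g", "h", "i"})
    assert (out["deg_only"], out["dsg_only"], out["dei_only"]) == (2, 3, 4)
    assert out["deg_dsg"] == out["deg_dei"] == out["dsg_dei"] == out["deg_dsg_dei"] == 0
    same = {"x", "y", "z"}
    out = integrate_gene_sets(same, same, same)
    assert out["deg_dsg_dei"] == 3
    assert out["deg_only"] == out["dsg_only"] == out["dei_only"] == 0


def test_integration_partition_matches_brute_force():
    rng = np.random.default_rng(9)
    ids = [f"g{i}" for i in range(60)]
    deg = set(rng.choice(ids, 25, replace=False))
    dsg = set(rng.choice(ids, 20, replace=False))
    dei = set(rng.choice(ids, 30, replace=False))
    out = integrate_gene_sets(deg, dsg, dei)
    # brute-force membership enumeration
    counts = {}
    for g in set().union(deg, dsg, dei):
        key = (g in deg, g in dsg, g in dei)
        counts[key] = counts.get(key, 0) + 1
    assert out["deg_only"] == counts.get((True, False, False), 0)
    assert out["dsg_dei"] == counts.get((False, True, True), 0)
    assert out["deg_dsg_dei"] == counts.get((True, True, True), 0)
    parts = ["deg_only", "dsg_only", "dei_only", "deg_dsg", "deg_dei", "dsg_dei",
             "deg_dsg_dei"]
    assert sum(out[p] for p in parts) == out["union_size"] == len(deg | dsg | dei)
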