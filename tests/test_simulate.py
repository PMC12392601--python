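import numpy as np
import pandas as pd
import pytest

from sexomics.annotation import chromosome_class, read_fasta, read_gtf, write_fasta, write_gtf
from sexomics.simulate import (
    SimulationConfig,
    generate_annotation,
    generate_cohort,
    generate_counts,
    generate_domain_hits,
    generate_se_events,
    read_cohort,
    read_counts,
    read_se_events,
    write_cohort,
    write_counts,
    write_se_events,
)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(frac_autosomal_deg=1.2)
    with pytest.raises(ValueError):
        SimulationConfig(depth=0)
    with pytest.raises(ValueError):
        SimulationConfig(psi_table={"e": (1.2, 0.5)})
    with pytest.raises(ValueError):
        SimulationConfig(stage_probs_male=(0.5, 0.5, 0.5))


def test_seeded_determinism_across_generators(small_config):
    cfg2 = SimulationConfig(seed=11, n_autosomes=2, genes_per_chrom=12)
    a1, a2 = generate_annotation(small_config), generate_annotation(cfg2)
    assert a1.sequences == a2.sequences
    c1, c2 = generate_cohort(small_config), generate_cohort(cfg2)
    assert [(r.embryo_id, r.day, r.stage, r.called_sex) for r in c1] == [
        (r.embryo_id, r.day, r.stage, r.called_sex) for r in c2
    ]
    m1, _ = generate_counts(a1, small_config)
    m2, _ = generate_counts(a2, cfg2)
    assert m1.counts.equals(m2.counts)
    other = SimulationConfig(seed=12, n_autosomes=2, genes_per_chrom=12)
    m3, _ = generate_counts(a1, other)
    assert not m1.counts.equals(m3.counts)


def test_cohort_null_stage_advantage_gives_balanced_ratios():
    probs = (0.4, 0.4, 0.2)
    cfg = SimulationConfig(
        seed=2, n_embryos=6000, stage_probs_female=probs, stage_probs_male=probs,
        sexing_failure_rate=0.0,
    )
    cohort = generate_cohort(cfg)
    df = pd.DataFrame(
        {"stage": [r.stage for r in cohort], "sex": [r.true_sex for r in cohort]}
    )
    for _, grp in df.groupby("stage"):
        frac_male = (grp["sex"] == "male").mean()
        se = np.sqrt(0.25 / len(grp))
        assert abs(frac_male - 0.5) < 4 * se


def test_cohort_calibrated_to_published_expanded_ratio():
    """Stage probabilities tuned to the Day-7 expanded split reproduce it."""
    target = 107 / 155  # P(male | expanded)
    pf, pm = 0.35, 0.35 * target / (1 - target)
    cfg = SimulationConfig(
        seed=3, n_embryos=20000, sexing_failure_rate=0.0,
        stage_probs_female=(1 - pf - 0.1, pf, 0.1),
        stage_probs_male=(1 - pm - 0.1, pm, 0.1),
    )
    cohort = generate_cohort(cfg)
    exp = [r for r in cohort if r.stage == "expanded"]
    frac_male = np.mean([r.true_sex == "male" for r in exp])
    se = np.sqrt(target * (1 - target) / len(exp))
    assert abs(frac_male - target) < 4 * se
    ratio = frac_male / (1 - frac_male)
    assert ratio == pytest.approx(2.23, abs=0.35)


def test_cohort_sexing_failure_rate():
    cohort = generate_cohort(SimulationConfig(seed=4, n_embryos=4000))
    frac = np.mean([r.called_sex == "undetermined" for r in cohort])
    assert frac == pytest.approx(32 / 444, abs=0.02)


def test_annotation_structure(small_annotation):
    strands = set()
    for gene in small_annotation.genes.values():
        assert chromosome_class(gene.chrom) in "AXY"
        for t in gene.transcripts:
            strands.add(t.strand)
            assert t.cds_length % 3 == 0
            for (s0, e0), (s1, e1) in zip(t.exons, t.exons[1:]):
                assert e0 <= s1  # ordered, non-overlapping
            if t.cds:
                first, last = t.cds[0], t.cds[-1]
                assert first[0] >= t.exons[0][0] and last[1] <= t.exons[-1][1]
    assert strands == {"+", "-"}
    assert small_annotation.genes["XIST_like"].biotype != "protein_coding"
    assert small_annotation.genes["XIST_like"].chrom == "X"


def test_requested_paralog_fraction_is_respected():
    cfg = SimulationConfig(seed=6, n_autosomes=6, genes_per_chrom=50, paralog_fraction=0.2)
    annot = generate_annotation(cfg)
    coding = [g for g in annot.genes.values() if g.biotype == "protein_coding"]
    frac = np.mean([g.is_paralog for g in coding])
    assert frac == pytest.approx(0.2, abs=0.05)


def test_sex_specific_count_structure(small_counts):
    cm, truth = small_counts
    females = [s for s, sex in truth.sample_sex.items() if sex == "female"]
    males = [s for s, sex in truth.sample_sex.items() if sex == "male"]
    # Y-linked genes are silent in females at zero leak
    assert (cm.counts.loc[truth.y_genes, females] == 0).all().all()
    assert (cm.counts.loc[truth.y_genes, males].sum(axis=1) > 0).all()
    # the XIST-like gene is female-only
    assert (cm.counts.loc[truth.xist_like, males] == 0).all()
    assert cm.counts.loc[truth.xist_like, females].sum() > 0


def test_truth_closure(small_annotation, small_counts, small_events):
    cm, truth = small_counts
    for gid in list(truth.deg_effects) + truth.x_genes + truth.y_genes:
        assert gid in cm.counts.index
        assert gid in small_annotation.genes
    events, etruth = small_events
    ids = {e.event_id for e in events}
    assert set(etruth.psi) == ids
    assert set(etruth.differential_events) <= ids
    for e in events:
        assert e.gene_id in small_annotation.genes


def test_psi_one_means_no_skipping_reads(small_annotation):
    cfg = SimulationConfig(
        seed=8, n_autosomes=2, genes_per_chrom=12,
        psi_table={"only": (1.0, 1.0)},
    )
    events, _ = generate_se_events(small_annotation, cfg)
    assert all(v == 0 for v in events[0].skipping.values())


def test_domain_hits_cover_each_failure_mode(small_annotation, small_events):
    events, _ = small_events
    cfg = SimulationConfig(seed=11, n_autosomes=2, genes_per_chrom=12)
    hits, truth = generate_domain_hits(small_annotation, cfg, se_events=events)
    from sexomics.domains import filter_domain_hits, protein_length

    models = {t.transcript_id: t for t in small_annotation.transcripts()}
    for h in hits:
        assert 1 <= h.aa_start <= h.aa_end <= protein_length(models[h.protein_id])
    _, report = filter_domain_hits(hits)
    rejected = report[~report["passed"]]
    for crit in ("domain_score", "domain_evalue", "seq_evalue", "accuracy", "coverage"):
        sub = rejected[rejected["domain_name"] == f"PF_fail_{crit}"]
        assert (sub["reason"] == crit).all() and len(sub) >= 1
    skipped_hits = [k for k in truth.disrupted_hits if k.endswith(":PF_skipped")]
    assert skipped_hits and all(truth.disrupted_hits[k] for k in skipped_hits)


# ---------------------------------------------------------------------------
# round trips through the on-disk formats


def test_gtf_fasta_round_trip(tmp_path, small_annotation):
    gtf, fa = tmp_path / "a.gtf", tmp_path / "a.fa"
    write_gtf(small_annotation, gtf)
    write_fasta(small_annotation.sequences, fa)
    back = read_gtf(gtf, fasta=fa)
    assert set(back.genes) == set(small_annotation.genes)
    for gid, gene in small_annotation.genes.items():
        b = back.genes[gid]
        assert (b.start, b.end, b.strand, b.biotype, b.is_paralog, b.is_tf,
                b.is_escapee) == (
            gene.start, gene.end, gene.strand, gene.biotype, gene.is_paralog,
            gene.is_tf, gene.is_escapee,
        )
        for t_in, t_out in zip(gene.transcripts, b.transcripts):
            assert t_in.exons == t_out.exons and t_in.cds == t_out.cds
    assert back.sequences == small_annotation.sequences
    assert read_fasta(fa) == small_annotation.sequences


def test_cohort_counts_se_round_trips(tmp_path, small_counts, small_events):
    cm, truth = small_counts
    cohort = generate_cohort(SimulationConfig(seed=11, n_embryos=50))
    p = tmp_path / "cohort.tsv"
    write_cohort(cohort, p)
    back = read_cohort(p)
    assert [(r.embryo_id, r.called_sex) for r in back] == [
        (r.embryo_id, r.called_sex) for r in cohort
    ]
    pc = tmp_path / "counts.tsv"
    write_counts(cm, pc)
    cm2 = read_counts(pc, cm.sample_sex)
    assert cm2.counts.equals(cm.counts)
    assert cm2.feature_lengths.equals(cm.feature_lengths)
    events, _ = small_events
    pe = tmp_path / "se.tsv"
    sex = pd.Series(truth.sample_sex)
    write_se_events(events, sex, pe)
    males = [s for s, v in sex.items() if v == "male"]
    females = [s for s, v in sex.items() if v == "female"]
    back_ev = read_se_events(pe, males, females)
    assert len(back_ev) == len(events)
    by_id = {e.event_id: e for e in events}
    for ev in back_ev:
        orig = by_id[ev.event_id]
        assert ev.inclusion == orig.inclusion and ev.skipping == orig.skipping
        assert ev.exon == orig.exon and ev.gene_id == orig.gene_id
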