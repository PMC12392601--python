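"""Intron-chain isoform classification, sex-biased isoform testing and
gene-set integration.

Long-read isoforms are classified against a reference annotation by
comparing intron chains, in the SQANTI vocabulary: FSM (full splice
match, identical chain), ISM (consecutive sub-chain, the 5'-degradation
signature), NIC (novel combination of known splice sites), NNC (at least
one novel splice site), plus the gene-overlap categories antisense,
intergenic, genic_genomic and fusion. Gene-overlap categories are
resolved before splice categories and FSM before ISM. A splice site is
"known" on an exact coordinate match on the same chromosome and strand;
an optional wobble window relaxes this.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .annotation import Annotation, Interval, intervals_overlap

CATEGORIES = (
    "FSM",
    "ISM",
    "NIC",
    "NNC",
    "intergenic",
    "antisense",
    "genic_genomic",
    "fusion",
)

Q_THRESHOLD = 0.05


@dataclass
class IsoformChain:
    """One isoform as a genomic span plus an ordered intron chain."""

    isoform_id: str
    chrom: str
    strand: str
    start: int
    end: int
    introns: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.introns = sorted(tuple(i) for i in self.introns)
        for s, e in self.introns:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"intron ({s},{e}) outside span of {self.isoform_id}")
        for (_, e0), (s1, _) in zip(self.introns, self.introns[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping introns in {self.isoform_id}")

    @property
    def span(self) -> Interval:
        return (self.start, self.end)

    @property
    def mono_exonic(self) -> bool:
        return not self.introns


@dataclass
class IsoformClassification:
    isoform_id: str
    category: str
    gene_id: str | None = None


class ReferenceIndex:
    """Reference transcripts indexed for intron-chain comparison."""

    def __init__(self, annotation: Annotation, wobble: int = 0):
        self.wobble = wobble
        self.genes = list(annotation.genes.values())
        self._chains: dict[str, list[tuple[Interval, ...]]] = {}
        self._sites: dict[str, set[tuple[str, int]]] = {}
        self._mono_spans: dict[str, list[Interval]] = {}
        for g in self.genes:
            chains, sites, mono = [], set(), []
            for t in g.transcripts:
                introns = tuple(t.introns)
                if introns:
                    chains.append(introns)
                    for s, e in introns:
                        sites.add(("start", s))
                        sites.add(("end", e))
                else:
                    mono.append(t.span)
            self._chains[g.gene_id] = chains
            self._sites[g.gene_id] = sites
            self._mono_spans[g.gene_id] = mono

    def overlapping_genes(self, chain: IsoformChain) -> tuple[list, list]:
        same, opposite = [], []
        for g in self.genes:
            if g.chrom != chain.chrom or not intervals_overlap(g.span, chain.span):
                continue
            (same if g.strand == chain.strand else opposite).append(g)
        return same, opposite

    def _site_known(self, gene_ids: list[str], kind: str, pos: int) -> bool:
        for gid in gene_ids:
            for k, p in self._sites[gid]:
                if k == kind and abs(p - pos) <= self.wobble:
                    return True
        return False

    def _chains_equal(self, a: tuple[Interval, ...], b: tuple[Interval, ...]) -> bool:
        if len(a) != len(b):
            return False
        return all(
            abs(x[0] - y[0]) <= self.wobble and abs(x[1] - y[1]) <= self.wobble
            for x, y in zip(a, b)
        )

    def _is_subchain(self, sub: tuple[Interval, ...], full: tuple[Interval, ...]) -> bool:
        if len(sub) >= len(full):
            return False
        for off in range(len(full) - len(sub) + 1):
            if self._chains_equal(sub, full[off : off + len(sub)]):
                return True
        return False

    def shares_junction(self, chain: IsoformChain, gene_id: str) -> bool:
        for ref in self._chains[gene_id]:
            for intron in ref:
                if any(self._chains_equal((intron,), (q,)) for q in chain.introns):
                    return True
        return False


def classify_isoform(chain: IsoformChain, reference: Annotation | ReferenceIndex,
                     wobble: int = 0) -> IsoformClassification:
    """Assign exactly one SQANTI-style category to an isoform chain."""
    index = reference if isinstance(reference, ReferenceIndex) else ReferenceIndex(reference, wobble)
    same, opposite = index.overlapping_genes(chain)

    if not same:
        category = "antisense" if opposite else "intergenic"
        gid = opposite[0].gene_id if opposite else None
        return IsoformClassification(chain.isoform_id, category, gid)

    # fusion: the chain spans two or more mutually non-overlapping genes
    if len(same) >= 2:
        disjoint = all(
            not intervals_overlap(a.span, b.span)
            for i, a in enumerate(same)
            for b in same[i + 1 :]
        )
        if disjoint:
            return IsoformClassification(
                chain.isoform_id, "fusion", ";".join(g.gene_id for g in same)
            )

    def overlap_len(g):
        return min(g.end, chain.end) - max(g.start, chain.start)

    gene = max(same, key=overlap_len)
    gene_ids = [g.gene_id for g in same]
    query = tuple(chain.introns)

    if chain.mono_exonic:
        for gid in gene_ids:
            for s, e in index._mono_spans[gid]:
                if s <= chain.start and chain.end <= e:
                    return IsoformClassification(chain.isoform_id, "FSM", gid)
        return IsoformClassification(chain.isoform_id, "genic_genomic", gene.gene_id)

    for gid in gene_ids:
        if any(index._chains_equal(query, ref) for ref in index._chains[gid]):
            return IsoformClassification(chain.isoform_id, "FSM", gid)
    for gid in gene_ids:
        if any(index._is_subchain(query, ref) for ref in index._chains[gid]):
            return IsoformClassification(chain.isoform_id, "ISM", gid)

    all_known = all(
        index._site_known(gene_ids, "start", s) and index._site_known(gene_ids, "end", e)
        for s, e in query
    )
    category = "NIC" if all_known else "NNC"
    return IsoformClassification(chain.isoform_id, category, gene.gene_id)


def classify_isoforms(chains: list[IsoformChain], reference: Annotation,
                      wobble: int = 0) -> pd.DataFrame:
    index = ReferenceIndex(reference, wobble)
    rows = [classify_isoform(c, index) for c in chains]
    return pd.DataFrame(
        {
            "isoform_id": [r.isoform_id for r in rows],
            "category": [r.category for r in rows],
            "gene_id": [r.gene_id for r in rows],
        }
    ).set_index("isoform_id")


def differential_isoform_test(
    isoform_counts: pd.DataFrame,
    sample_sex: pd.Series,
    isoform_genes: dict[str, str] | None = None,
    q_threshold: float = Q_THRESHOLD,
) -> pd.DataFrame:
    """Per-isoform Welch t-test of sex on log2 normalised counts.

    Counts are scaled by median-of-ratios size factors (total-count
    factors when no isoform is ubiquitously expressed) and tested on the
    log2(x + 0.5) scale; BH q-values across tested isoforms, biased at
    q < q_threshold. Isoforms without a gene in ``isoform_genes`` are
    excluded and flagged.
    """
    sample_sex = sample_sex.reindex(isoform_counts.columns)
    for sex in ("male", "female"):
        if (sample_sex == sex).sum() < 2:
            raise ValueError(f"need at least 2 {sex} samples")
    arr = isoform_counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if positive.any():
        ref = arr[positive]
        logg = np.log(ref).mean(axis=1, keepdims=True)
        sf = np.exp(np.median(np.log(ref) - logg, axis=0))
    else:
        tot = arr.sum(axis=0)
        sf = tot / tot.mean()
    norm = np.log2(arr / sf + 0.5)
    male = (sample_sex == "male").to_numpy()

    classifiable = np.ones(len(isoform_counts), dtype=bool)
    genes = []
    for iso in isoform_counts.index:
        gid = (isoform_genes or {}).get(iso) if isoform_genes is not None else iso
        genes.append(gid)
    if isoform_genes is not None:
        classifiable = np.array([g is not None for g in genes])

    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(norm[:, male], norm[:, ~male], axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    log2fc = norm[:, male].mean(axis=1) - norm[:, ~male].mean(axis=1)

    q = np.full(len(p), np.nan)
    if classifiable.any():
        q[classifiable] = multipletests(p[classifiable], method="fdr_bh")[1]
    out = pd.DataFrame(
        {
            "gene_id": genes,
            "log2_fold_change": log2fc,
            "p": p,
            "q": q,
            "tested": classifiable,
        },
        index=isoform_counts.index,
    )
    out["biased"] = out["tested"] & (out["q"] < q_threshold)
    out["direction"] = np.select(
        [out["biased"] & (out["log2_fold_change"] > 0), out["biased"] & (out["log2_fold_change"] < 0)],
        ["male_biased", "female_biased"],
        default="none",
    )
    return out


def integrate_gene_sets(
    deg_genes: set[str] | list[str],
    dsg_genes: set[str] | list[str],
    dei_genes: set[str] | list[str],
) -> dict[str, int]:
    """Exclusive-intersection (UpSet-style) partition of three gene sets.

    Returns the 7 disjoint membership-pattern counts (they sum to the
    union size) alongside the three set sizes.
    """
    deg, dsg, dei = set(deg_genes), set(dsg_genes), set(dei_genes)
    return {
        "deg_only": len(deg - dsg - dei),
        "dsg_only": len(dsg - deg - dei),
        "dei_only": len(dei - deg - dsg),
        "deg_dsg": len((deg & dsg) - dei),
        "deg_dei": len((deg & dei) - dsg),
        "dsg_dei": len((dsg & dei) - deg),
        "deg_dsg_dei": len(deg & dsg & dei),
        "deg_size": len(deg),
        "dsg_size": len(dsg),
        "dei_size": len(dei),
        "union_size": len(deg | dsg | dei),
    }
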