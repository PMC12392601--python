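"""TPM normalisation, sex-biased differential expression and enrichment.

Differential expression is a negative-binomial GLM per gene with a log
link, median-of-ratios size factors as offsets, a sex term and an optional
batch (collection-week) term; the Wald p-value on the sex coefficient is
BH-adjusted across genes. This is a deliberately simple NB-GLM — per-gene
method-of-moments dispersion, no shrinkage — and its gene-level calls are
thresholded exactly as the study design requires: a gene is sex-biased
when |fold change| > 1.5 (strict) and FDR < 0.1 (strict), male relative
to female.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

FC_THRESHOLD = 1.5
FDR_THRESHOLD = 0.1

_LOG2FC_THRESHOLD = np.log2(FC_THRESHOLD)


@dataclass
class CountMatrix:
    """Features x samples integer counts with lengths and sample labels."""

    counts: pd.DataFrame  # features x samples
    feature_lengths: pd.Series  # bp, indexed like counts
    sample_sex: pd.Series  # indexed by sample
    sample_batch: pd.Series | None = None

    def __post_init__(self) -> None:
        self.feature_lengths = self.feature_lengths.reindex(self.counts.index)
        if self.feature_lengths.isna().any():
            raise ValueError("every feature needs a length")
        if (self.feature_lengths <= 0).any():
            raise ValueError("feature lengths must be positive")
        self.sample_sex = self.sample_sex.reindex(self.counts.columns)
        if self.sample_sex.isna().any():
            raise ValueError("every sample needs a sex label")
        if self.sample_batch is not None:
            self.sample_batch = self.sample_batch.reindex(self.counts.columns)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")


@dataclass
class DEResult:
    """Per-gene differential-expression table plus bookkeeping."""

    table: pd.DataFrame  # base_mean, log2_fold_change, p, fdr, is_deg, direction
    excluded_genes: list[str] = field(default_factory=list)
    fc_threshold: float = FC_THRESHOLD
    fdr_threshold: float = FDR_THRESHOLD

    @property
    def deg_ids(self) -> list[str]:
        return list(self.table.index[self.table["is_deg"]])

    def summary(self) -> pd.Series:
        t = self.table
        return pd.Series(
            {
                "n_tested": len(t),
                "n_deg": int(t["is_deg"].sum()),
                "n_male_biased": int((t["is_deg"] & (t["direction"] == "male_biased")).sum()),
                "n_female_biased": int((t["is_deg"] & (t["direction"] == "female_biased")).sum()),
                "n_excluded_all_zero": len(self.excluded_genes),
            }
        )


def flag_degs(
    log2_fold_change,
    fdr,
    fc_threshold: float = FC_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
):
    """DEG flag: |log2FC| > log2(fc_threshold) AND fdr < fdr_threshold, both strict."""
    return (np.abs(np.asarray(log2_fold_change)) > np.log2(fc_threshold)) & (
        np.asarray(fdr) < fdr_threshold
    )


def compute_tpm(counts: pd.DataFrame, lengths: pd.Series) -> pd.DataFrame:
    """Transcripts-per-million: length-normalised rates scaled to 1e6 per sample.

    All-zero samples come back as all-zero columns rather than an error.
    """
    lengths = lengths.reindex(counts.index)
    if (lengths <= 0).any():
        raise ValueError("feature lengths must be positive")
    rate = counts.div(lengths / 1e3, axis=0)
    colsum = rate.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        tpm = rate.div(colsum, axis=1) * 1e6
    return tpm.fillna(0.0)


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over genes expressed in every sample."""
    arr = counts.to_numpy(dtype=float)
    positive = (arr > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in all samples")
    ref = arr[positive]
    log_geo_mean = np.log(ref).mean(axis=1, keepdims=True)
    sf = np.exp(np.median(np.log(ref) - log_geo_mean, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def _mom_dispersion(norm_counts: np.ndarray, groups: np.ndarray) -> float:
    """Method-of-moments NB dispersion pooled across the two sex groups."""
    mu = norm_counts.mean()
    if mu <= 0:
        return 0.0
    resid_var = 0.0
    dof = 0
    for g in np.unique(groups):
        sub = norm_counts[groups == g]
        if len(sub) >= 2:
            resid_var += sub.var(ddof=1) * (len(sub) - 1)
            dof += len(sub) - 1
    if dof == 0:
        return 0.0
    var = resid_var / dof
    return max((var - mu) / mu**2, 0.0)


def differential_expression(
    counts: pd.DataFrame | CountMatrix,
    sample_sex: pd.Series | None = None,
    sample_batch: pd.Series | None = None,
    fc_threshold: float = FC_THRESHOLD,
    fdr_threshold: float = FDR_THRESHOLD,
) -> DEResult:
    """Per-gene NB-GLM Wald test of sex, male relative to female.

    ``log2_fold_change`` is the raw (unshrunken) sex-coefficient estimate;
    a gene is flagged ``is_deg`` when ``|log2FC| > log2(fc_threshold)``
    and ``fdr < fdr_threshold``, both strict. Genes with all-zero counts
    are excluded from testing and listed in ``excluded_genes``.
    """
    if isinstance(counts, CountMatrix):
        sample_sex = counts.sample_sex
        sample_batch = counts.sample_batch
        counts = counts.counts
    if sample_sex is None:
        raise ValueError("sample_sex is required")
    sample_sex = sample_sex.reindex(counts.columns)
    sexes = sample_sex.unique()
    for sex in ("male", "female"):
        if (sample_sex == sex).sum() < 2:
            raise ValueError(f"need at least 2 {sex} samples")
    if set(sexes) - {"male", "female"}:
        raise ValueError(f"unexpected sex labels: {set(sexes) - {'male', 'female'}}")

    nonzero = counts.sum(axis=1) > 0
    excluded = list(counts.index[~nonzero])
    counts = counts.loc[nonzero]

    sf = size_factors(counts)
    offset = np.log(sf.to_numpy())
    is_male = (sample_sex == "male").to_numpy(dtype=float)
    design = [np.ones_like(is_male), is_male]
    if sample_batch is not None:
        batch = pd.get_dummies(sample_batch.reindex(counts.columns), drop_first=True)
        for col in batch.columns:
            design.append(batch[col].to_numpy(dtype=float))
    X = np.column_stack(design)

    norm = counts.to_numpy(dtype=float) / sf.to_numpy()
    groups = is_male.astype(int)

    rows = []
    ln2 = np.log(2.0)
    for gid, y in zip(counts.index, counts.to_numpy(dtype=float)):
        alpha = _mom_dispersion(norm[counts.index.get_loc(gid)], groups)
        family = (
            sm.families.NegativeBinomial(alpha=alpha) if alpha > 1e-8 else sm.families.Poisson()
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                fit = sm.GLM(y, X, family=family, offset=offset).fit(maxiter=200)
                coef = fit.params[1]
                se = fit.bse[1]
            except Exception:
                coef, se = 0.0, np.inf
        if not np.isfinite(se) or se == 0:
            p = 1.0 if coef == 0 else np.nan
        else:
            p = 2 * stats.norm.sf(abs(coef / se))
        rows.append(
            {
                "gene_id": gid,
                "base_mean": norm[counts.index.get_loc(gid)].mean(),
                "log2_fold_change": coef / ln2,
                "p": p,
            }
        )
    table = pd.DataFrame(rows).set_index("gene_id")
    pvals = table["p"].fillna(1.0).clip(0, 1)
    table["fdr"] = multipletests(pvals, method="fdr_bh")[1]
    table["is_deg"] = flag_degs(
        table["log2_fold_change"], table["fdr"], fc_threshold, fdr_threshold
    )
    table["direction"] = np.where(table["log2_fold_change"] > 0, "male_biased", "female_biased")
    table.loc[table["log2_fold_change"] == 0, "direction"] = "none"
    return DEResult(
        table=table,
        excluded_genes=excluded,
        fc_threshold=fc_threshold,
        fdr_threshold=fdr_threshold,
    )


def group_enrichment(
    deg_ids: set[str] | list[str],
    gene_groups: dict[str, set[str] | list[str]],
    background_ids: set[str] | list[str],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Two-sided Fisher exact test of DEG membership against each gene group.

    For each group the 2x2 table is (DEG vs non-DEG) x (in group vs not),
    over ``background_ids``. Direction is over/under from the sample odds
    ratio; ``significant`` at ``p < alpha`` (default 0.01). Empty groups
    are skipped with a warning.
    """
    deg = set(deg_ids)
    background = set(background_ids)
    if not deg <= background:
        raise ValueError("deg_ids must be a subset of background_ids")
    non_deg = background - deg
    rows = []
    for name, members in gene_groups.items():
        members = set(members) & background
        if not members:
            warnings.warn(f"gene group {name!r} is empty within the background; skipped")
            continue
        a = len(deg & members)
        b = len(deg - members)
        c = len(non_deg & members)
        d = len(non_deg - members)
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        direction = "over" if odds > 1 else ("under" if odds < 1 else "none")
        rows.append(
            {
                "group": name,
                "n_deg_in_group": a,
                "n_deg": a + b,
                "n_group": a + c,
                "n_background": a + b + c + d,
                "odds_ratio": odds,
                "direction": direction,
                "p": p,
                "significant": p < alpha,
            }
        )
    columns = ["group", "n_deg_in_group", "n_deg", "n_group", "n_background",
               "odds_ratio", "direction", "p", "significant"]
    return pd.DataFrame(rows, columns=columns).set_index("group")


def ddct_fold_change(
    ct_target: float,
    ct_references: list[float] | np.ndarray,
    ct_target_control: float,
    ct_references_control: list[float] | np.ndarray,
) -> float:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct(target) - mean Ct(references) within each condition; the
    returned fold change is 2^-(dCt_case - dCt_control). Reference genes
    are aggregated by the arithmetic mean of their Ct values.
    """
    ct_references = np.asarray(ct_references, dtype=float)
    ct_references_control = np.asarray(ct_references_control, dtype=float)
    for val in (ct_target, ct_target_control):
        if not np.isfinite(val):
            raise ValueError("Ct values must be finite")
    if not (np.isfinite(ct_references).all() and np.isfinite(ct_references_control).all()):
        raise ValueError("Ct values must be finite")
    dct_case = ct_target - ct_references.mean()
    dct_control = ct_target_control - ct_references_control.mean()
    return float(2.0 ** -(dct_case - dct_control))
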