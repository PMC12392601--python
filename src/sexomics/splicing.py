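"""Percent-spliced-in estimation and sex-biased skipped-exon calling.

PSI for a skipped-exon event is the effective-length-normalised fraction
of transcripts including the exon:

    PSI = (I / lI) / (I / lI + S / lS)

where I and S are inclusion- and skipping-junction read counts and lI, lS
the effective lengths (junction-count convention: two inclusion junctions
vs one skipping junction, so lI=2 and lS=1 by default). Group differences
are tested per event with a likelihood-ratio test comparing a
binomial-logit GLM with a sex term against the intercept-only model
(a beta-binomial variant is available for overdispersed data), with BH
FDR across tested events. Significance requires all of: mean read count
>= 10 per group, a non-near-constitutive PSI range, FDR <= 0.01 and
|dPSI| >= 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, special, stats
from statsmodels.stats.multitest import multipletests

DEFAULT_INC_LEN = 2.0
DEFAULT_SKIP_LEN = 1.0
FDR_THRESHOLD = 0.01
MIN_COUNT = 10.0
MIN_DPSI = 0.05
PSI_RANGE = (0.05, 0.95)


@dataclass
class SEEvent:
    """One skipped-exon event with per-sample junction counts."""

    event_id: str
    gene_id: str
    chrom: str
    strand: str
    exon: tuple[int, int]  # the skipped exon, 0-based half-open
    upstream_exon: tuple[int, int]
    downstream_exon: tuple[int, int]
    inclusion: dict[str, int]  # sample -> inclusion junction count (IJC)
    skipping: dict[str, int]  # sample -> skipping junction count (SJC)
    inc_len: float = DEFAULT_INC_LEN
    skip_len: float = DEFAULT_SKIP_LEN

    def __post_init__(self) -> None:
        if self.inc_len < 1 or self.skip_len < 1:
            raise ValueError("effective lengths must be >= 1")
        for counts in (self.inclusion, self.skipping):
            for v in counts.values():
                if v < 0:
                    raise ValueError("junction counts must be non-negative")


@dataclass
class SplicingResult:
    """Per-event table plus per-sample PSI and the thresholds applied."""

    table: pd.DataFrame
    psi: pd.DataFrame  # events x samples, NaN where I=S=0
    excluded_events: list[str] = field(default_factory=list)
    fdr_threshold: float = FDR_THRESHOLD
    min_dpsi: float = MIN_DPSI

    @property
    def significant_ids(self) -> list[str]:
        return list(self.table.index[self.table["significant"]])


def compute_psi(
    inclusion,
    skipping,
    inc_len: float = DEFAULT_INC_LEN,
    skip_len: float = DEFAULT_SKIP_LEN,
):
    """Length-normalised PSI; NaN when an observation has I = S = 0."""
    I = np.asarray(inclusion, dtype=float)
    S = np.asarray(skipping, dtype=float)
    if (I < 0).any() or (S < 0).any():
        raise ValueError("junction counts must be non-negative")
    if inc_len < 1 or skip_len < 1:
        raise ValueError("effective lengths must be >= 1")
    num = I / inc_len
    den = num + S / skip_len
    with np.errstate(invalid="ignore", divide="ignore"):
        psi = np.where(den > 0, num / den, np.nan)
    return psi if psi.ndim else float(psi)


def significance_flags(
    tested,
    fdr,
    dpsi,
    fdr_threshold: float = FDR_THRESHOLD,
    min_dpsi: float = MIN_DPSI,
):
    """Significant iff tested AND fdr <= threshold AND |dPSI| >= min_dpsi.

    Both cutoffs are inclusive; the count and PSI-range pre-filters are
    already folded into ``tested``.
    """
    return (
        np.asarray(tested, dtype=bool)
        & (np.asarray(fdr) <= fdr_threshold)
        & (np.abs(np.asarray(dpsi)) >= min_dpsi)
    )


def _event_frame(events: list[SEEvent], samples: list[str]) -> tuple[np.ndarray, np.ndarray]:
    I = np.array([[ev.inclusion.get(s, 0) for s in samples] for ev in events], dtype=float)
    S = np.array([[ev.skipping.get(s, 0) for s in samples] for ev in events], dtype=float)
    return I, S


def _binomial_lrt(I: np.ndarray, S: np.ndarray, is_male: np.ndarray) -> float:
    """LRT p-value: binomial-logit GLM with sex term vs intercept only."""
    endog = np.column_stack([I, S])
    keep = (I + S) > 0
    if keep.sum() < 2 or len(np.unique(is_male[keep])) < 2:
        return np.nan
    endog = endog[keep]
    x_full = sm.add_constant(is_male[keep], has_constant="add")
    x_null = np.ones((keep.sum(), 1))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            llf_full = sm.GLM(endog, x_full, family=sm.families.Binomial()).fit(maxiter=200).llf
            llf_null = sm.GLM(endog, x_null, family=sm.families.Binomial()).fit(maxiter=200).llf
        except Exception:
            return np.nan
    lr = max(2 * (llf_full - llf_null), 0.0)
    return float(stats.chi2.sf(lr, df=1))


def _betabinom_nll(params: np.ndarray, I: np.ndarray, n: np.ndarray, x: np.ndarray) -> float:
    beta_coefs, log_phi = params[:-1], params[-1]
    mu = special.expit(x @ beta_coefs)
    phi = np.exp(log_phi)
    a = mu * phi
    b = (1 - mu) * phi
    ll = (
        special.betaln(I + a, n - I + b)
        - special.betaln(a, b)
        + special.gammaln(n + 1)
        - special.gammaln(I + 1)
        - special.gammaln(n - I + 1)
    )
    return -float(ll.sum())


def _betabinom_lrt(I: np.ndarray, S: np.ndarray, is_male: np.ndarray) -> float:
    """LRT with a beta-binomial likelihood (logit-mean, common overdispersion)."""
    n = I + S
    keep = n > 0
    if keep.sum() < 2 or len(np.unique(is_male[keep])) < 2:
        return np.nan
    I, n, g = I[keep], n[keep], is_male[keep]
    x_full = np.column_stack([np.ones_like(g), g])
    x_null = np.ones((len(g), 1))

    def fit(x):
        k = x.shape[1]
        res = optimize.minimize(
            _betabinom_nll,
            np.concatenate([np.zeros(k), [2.0]]),
            args=(I, n, x),
            method="Nelder-Mead",
            options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-8},
        )
        return -res.fun

    lr = max(2 * (fit(x_full) - fit(x_null)), 0.0)
    return float(stats.chi2.sf(lr, df=1))


def differential_se_test(
    events: list[SEEvent],
    sample_sex: pd.Series,
    min_count: float = MIN_COUNT,
    psi_range_mode: str = "standard",
    method: str = "binomial",
    fdr_threshold: float = FDR_THRESHOLD,
    min_dpsi: float = MIN_DPSI,
) -> SplicingResult:
    """Test each skipped-exon event for a sex difference in inclusion.

    Pre-filters (mean read count and PSI range) remove events before
    testing, so they contribute neither a p-value nor to the BH FDR.
    dPSI is male minus female group-mean PSI; group means average
    per-sample PSI over samples with I + S > 0. Events with zero counts
    in every sample are excluded and reported in ``excluded_events``.
    """
    samples = list(sample_sex.index)
    for sex in ("male", "female"):
        if (sample_sex == sex).sum() < 2:
            raise ValueError(f"need at least 2 {sex} samples")
    is_male = (sample_sex == "male").to_numpy(dtype=float)
    I, S = _event_frame(events, samples)
    ids = [ev.event_id for ev in events]

    all_zero = (I + S).sum(axis=1) == 0
    excluded = [eid for eid, z in zip(ids, all_zero) if z]

    psi = np.vstack(
        [
            compute_psi(I[k], S[k], events[k].inc_len, events[k].skip_len)
            for k in range(len(events))
        ]
    ) if events else np.empty((0, len(samples)))
    psi_df = pd.DataFrame(psi, index=ids, columns=samples)

    male_mask = is_male == 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        psi_male = np.nanmean(psi[:, male_mask], axis=1) if len(events) else np.array([])
        psi_female = np.nanmean(psi[:, ~male_mask], axis=1) if len(events) else np.array([])
    dpsi = psi_male - psi_female

    mean_count_male = (I + S)[:, male_mask].mean(axis=1) if len(events) else np.array([])
    mean_count_female = (I + S)[:, ~male_mask].mean(axis=1) if len(events) else np.array([])
    count_ok = (mean_count_male >= min_count) & (mean_count_female >= min_count)

    lo, hi = PSI_RANGE
    informative_m = (psi_male > lo) & (psi_male < hi)
    informative_f = (psi_female > lo) & (psi_female < hi)
    if psi_range_mode == "standard":
        # drop near-constitutive events: group-mean PSI outside (0.05, 0.95)
        # in BOTH groups
        psi_ok = informative_m | informative_f
    elif psi_range_mode == "literal":
        psi_ok = ~(
            (psi_male >= lo) & (psi_male <= hi) & (psi_female >= lo) & (psi_female <= hi)
        )
    else:
        raise ValueError("psi_range_mode must be 'standard' or 'literal'")

    tested = count_ok & psi_ok & ~all_zero & np.isfinite(dpsi)
    test_fn = {"binomial": _binomial_lrt, "betabinomial": _betabinom_lrt}.get(method)
    if test_fn is None:
        raise ValueError("method must be 'binomial' or 'betabinomial'")
    pvals = np.full(len(events), np.nan)
    for k in np.flatnonzero(tested):
        pvals[k] = test_fn(I[k], S[k], is_male)
    tested &= np.isfinite(pvals)

    fdr = np.full(len(events), np.nan)
    if tested.any():
        fdr[tested] = multipletests(pvals[tested], method="fdr_bh")[1]

    table = pd.DataFrame(
        {
            "gene_id": [ev.gene_id for ev in events],
            "psi_male": psi_male,
            "psi_female": psi_female,
            "dpsi": dpsi,
            "mean_count_male": mean_count_male,
            "mean_count_female": mean_count_female,
            "tested": tested,
            "p": pvals,
            "fdr": fdr,
        },
        index=pd.Index(ids, name="event_id"),
    )
    table["significant"] = significance_flags(
        tested, table["fdr"], table["dpsi"], fdr_threshold, min_dpsi
    )
    table["bias"] = np.select(
        [table["significant"] & (table["dpsi"] > 0), table["significant"] & (table["dpsi"] < 0)],
        ["male_biased", "female_biased"],
        default="none",
    )
    return SplicingResult(
        table=table,
        psi=psi_df,
        excluded_events=excluded,
        fdr_threshold=fdr_threshold,
        min_dpsi=min_dpsi,
    )


def filter_significant_events(
    result: SplicingResult,
    deg_ids: set[str] | list[str] | None = None,
) -> dict:
    """Apply the four significance criteria and map events to genes.

    Returns the significant event ids, the distinct gene list they map
    to, a per-gene event mapping, and — when a DEG list is supplied — the
    overlap between splicing-affected genes and DEGs.
    """
    t = result.table
    sig = t[t["significant"]]
    gene_map: dict[str, list[str]] = {}
    for eid, gid in sig["gene_id"].items():
        gene_map.setdefault(gid, []).append(eid)
    out = {
        "significant_events": list(sig.index),
        "genes": sorted(gene_map),
        "gene_events": gene_map,
    }
    if deg_ids is not None:
        out["deg_overlap"] = sorted(set(gene_map) & set(deg_ids))
    return out
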