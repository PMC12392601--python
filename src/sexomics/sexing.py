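"""Embryo sexing from PCR amplicons and stage-wise sex-ratio statistics.

Embryos are sexed from a duplex PCR: a Y-linked amplicon and an autosomal
control amplicon. An embryo with both bands is male; an embryo with only
the autosomal band is female; an embryo missing the autosomal control is a
sexing failure (undetermined) no matter what the Y lane shows, since the
reaction itself cannot be trusted. Sex calls can be cross-checked against
Y-linked gene expression, and per-stage male:female ratios are tested
against a 1:1 null with a Pearson chi-square test (df=1, no continuity
correction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

STAGES = ("non_expanded", "expanded", "hatched")

MALE = "male"
FEMALE = "female"
UNDETERMINED = "undetermined"


@dataclass
class SexRecord:
    """One embryo: amplicon observations, collection day and stage."""

    embryo_id: str
    day: int
    stage: str
    autosomal_amplicon: bool
    y_amplicon: bool
    called_sex: str = UNDETERMINED
    true_sex: str | None = None  # known only for simulated embryos

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")


@dataclass
class SexRatioResult:
    n_male: int
    n_female: int
    ratio: float
    chi2: float
    p: float


def call_sex_from_amplicons(record: SexRecord) -> str:
    """Call sex from the two amplicons and store it on the record.

    Both present -> male; autosomal only -> female; autosomal absent ->
    undetermined (a failed reaction), regardless of the Y amplicon.
    """
    if not record.autosomal_amplicon:
        sex = UNDETERMINED
    elif record.y_amplicon:
        sex = MALE
    else:
        sex = FEMALE
    record.called_sex = sex
    return sex


def sex_ratio_test(n_male: int, n_female: int) -> SexRatioResult:
    """Pearson chi-square test of an observed sex split against 1:1.

    ``chi2 = sum (obs - exp)^2 / exp`` with ``exp = n/2`` per sex, one
    degree of freedom, upper-tail p, no Yates continuity correction.
    ``ratio`` is male:female (inf when no females).
    """
    if n_male < 0 or n_female < 0:
        raise ValueError("counts must be non-negative")
    n = n_male + n_female
    if n == 0:
        raise ValueError("need at least one sexed embryo")
    expected = n / 2.0
    chi2 = (n_male - expected) ** 2 / expected + (n_female - expected) ** 2 / expected
    p = float(stats.chi2.sf(chi2, df=1))
    ratio = float("inf") if n_female == 0 else n_male / n_female
    return SexRatioResult(n_male=n_male, n_female=n_female, ratio=ratio, chi2=float(chi2), p=p)


def stagewise_sex_ratios(records: list[SexRecord]) -> pd.DataFrame:
    """Per (day, stage) sex-ratio test over successfully sexed embryos.

    Undetermined embryos are excluded; stages with no sexed embryo are
    omitted. Returns a tidy frame with one row per (day, stage).
    """
    rows = []
    sexed = [r for r in records if r.called_sex in (MALE, FEMALE)]
    for (day, stage), group in _groupby(sexed):
        n_male = sum(1 for r in group if r.called_sex == MALE)
        n_female = len(group) - n_male
        res = sex_ratio_test(n_male, n_female)
        rows.append(
            {
                "day": day,
                "stage": stage,
                "n_male": res.n_male,
                "n_female": res.n_female,
                "n_total": res.n_male + res.n_female,
                "ratio": res.ratio,
                "chi2": res.chi2,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)


def _groupby(records: list[SexRecord]):
    keys = sorted({(r.day, r.stage) for r in records}, key=lambda k: (k[0], STAGES.index(k[1])))
    for key in keys:
        yield key, [r for r in records if (r.day, r.stage) == key]


def verify_sex_by_y_expression(
    tpm: pd.DataFrame,
    y_gene_ids: list[str],
    threshold: float = 1.0,
    amplicon_calls: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Call sample sex from mean Y-linked TPM and compare with PCR calls.

    A sample is called male iff its mean TPM over ``y_gene_ids`` exceeds
    ``threshold``. Returns a frame indexed by sample with columns
    ``mean_y_tpm``, ``expression_sex``, and — when ``amplicon_calls`` is
    given — ``amplicon_sex`` and ``concordant``.
    """
    present = [g for g in y_gene_ids if g in tpm.index]
    if not present:
        raise ValueError("none of the Y-linked genes are present in the matrix")
    mean_y = tpm.loc[present].mean(axis=0)
    calls = np.where(mean_y > threshold, MALE, FEMALE)
    out = pd.DataFrame({"mean_y_tpm": mean_y, "expression_sex": calls})
    if amplicon_calls is not None:
        out["amplicon_sex"] = [amplicon_calls.get(s, UNDETERMINED) for s in out.index]
        out["concordant"] = out["expression_sex"] == out["amplicon_sex"]
    return out
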