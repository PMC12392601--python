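"""X:autosome expression ratios with stratified bootstrap confidence intervals.

The X:A ratio is the median expression of X-linked genes divided by the
median expression of autosomal genes, computed within one sex group for a
gene category (expressed: mean TPM > 1; DEG; non-DEG), optionally after
excluding paralogous genes whose multi-mapping reads blur X-linked
quantification. A ratio near 1 is read as complete dosage compensation of
the single active X, near 0.5 as none, and intermediate values as partial
compensation. Confidence intervals come from a percentile bootstrap that
resamples genes with replacement independently within the X stratum and
the autosome stratum; Y-linked genes never enter either stratum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import Annotation, chromosome_class

CATEGORIES = ("expressed", "deg", "non_deg")


@dataclass
class DosageResult:
    group: str
    category: str
    paralogs_excluded: bool
    xa_ratio: float
    ci_low: float
    ci_high: float
    n_x: int
    n_a: int
    n_boot: int

    def interpretation(self) -> str:
        """The conventional reading of the ratio scale, for report output."""
        return (
            "1.0 or higher indicates complete compensatory upregulation of "
            "X-linked genes relative to autosomes; 0.5 suggests no "
            "compensation; values between 0.5 and 1 reflect partial compensation"
        )


def gene_info_frame(annotation: Annotation) -> pd.DataFrame:
    """Per-gene chromosome class, paralog flag and start coordinate."""
    rows = [
        {
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "chrom_class": chromosome_class(g.chrom),
            "start": g.start,
            "paralog": g.is_paralog,
        }
        for g in annotation.genes.values()
    ]
    return pd.DataFrame(rows).set_index("gene_id")


def _stratum_expression(
    tpm: pd.DataFrame,
    gene_info: pd.DataFrame,
    samples: list[str],
    category: str,
    deg_ids: set[str] | None,
    exclude_paralogs: bool,
    expressed_tpm: float = 1.0,
) -> tuple[pd.Series, pd.Series]:
    """Per-gene group-mean TPM split into the X and autosome strata."""
    if category not in CATEGORIES:
        raise ValueError(f"category must be one of {CATEGORIES}")
    expr = tpm[samples].mean(axis=1)
    info = gene_info.reindex(expr.index)
    keep = info["chrom_class"].isin(["X", "A"])
    if exclude_paralogs:
        keep &= ~info["paralog"].astype(bool)
    expressed = expr > expressed_tpm
    if category == "expressed":
        keep &= expressed
    else:
        if deg_ids is None:
            raise ValueError(f"category {category!r} needs a DEG list")
        in_deg = expr.index.isin(list(deg_ids))
        keep &= expressed & (in_deg if category == "deg" else ~in_deg)
    expr = expr[keep]
    info = info.loc[expr.index]
    x = expr[info["chrom_class"] == "X"]
    a = expr[info["chrom_class"] == "A"]
    for stratum, name in ((x, "X"), (a, "autosome")):
        if len(stratum) == 0:
            raise ValueError(f"empty {name} stratum for category {category!r}")
    return x, a


def xa_ratio(
    tpm: pd.DataFrame,
    gene_info: pd.DataFrame,
    samples: list[str],
    category: str = "expressed",
    deg_ids: set[str] | None = None,
    exclude_paralogs: bool = False,
) -> float:
    """Point estimate: median X-linked over median autosomal expression."""
    x, a = _stratum_expression(tpm, gene_info, samples, category, deg_ids, exclude_paralogs)
    return float(np.median(x) / np.median(a))


def xa_bootstrap_ci(
    tpm: pd.DataFrame,
    gene_info: pd.DataFrame,
    samples: list[str],
    category: str = "expressed",
    deg_ids: set[str] | None = None,
    exclude_paralogs: bool = False,
    n_boot: int = 1000,
    seed: int | np.random.Generator = 0,
    group: str = "",
    stratify: str = "chromosome",
) -> DosageResult:
    """Stratified percentile-bootstrap 95% CI for the X:A median ratio.

    ``stratify='chromosome'`` (default) resamples genes with replacement
    independently within the X and autosome strata. ``stratify='samples'``
    instead resamples the group's samples with replacement and recomputes
    per-gene means, an alternate reading of stratified resampling.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    x, a = _stratum_expression(tpm, gene_info, samples, category, deg_ids, exclude_paralogs)
    point = float(np.median(x) / np.median(a))
    if stratify == "chromosome":
        if len(x) < 2 or len(a) < 2:
            raise ValueError("each stratum needs at least 2 genes to bootstrap")
        xv, av = x.to_numpy(), a.to_numpy()
        xi = rng.integers(0, len(xv), size=(n_boot, len(xv)))
        ai = rng.integers(0, len(av), size=(n_boot, len(av)))
        ratios = np.median(xv[xi], axis=1) / np.median(av[ai], axis=1)
    elif stratify == "samples":
        x_ids, a_ids = list(x.index), list(a.index)
        sub = tpm.loc[x_ids + a_ids, samples].to_numpy()
        nx = len(x_ids)
        ratios = np.empty(n_boot)
        for b in range(n_boot):
            cols = rng.integers(0, sub.shape[1], size=sub.shape[1])
            means = sub[:, cols].mean(axis=1)
            ratios[b] = np.median(means[:nx]) / np.median(means[nx:])
    else:
        raise ValueError("stratify must be 'chromosome' or 'samples'")
    ci_low, ci_high = np.percentile(ratios, [2.5, 97.5])
    return DosageResult(
        group=group,
        category=category,
        paralogs_excluded=exclude_paralogs,
        xa_ratio=point,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_x=len(x),
        n_a=len(a),
        n_boot=n_boot,
    )


def deg_window_density(
    positions: list[int] | np.ndarray,
    chrom_length: int,
    window: int = 1_000_000,
) -> pd.DataFrame:
    """Gene counts per fixed-width window tiling [0, chrom_length).

    Windows are 0-based half-open; a gene belongs to the window containing
    its start coordinate. Returns one row per window with ``count`` and an
    ``empty_run`` id labelling maximal runs of consecutive empty windows
    (NA for non-empty windows).
    """
    positions = np.asarray(positions, dtype=np.int64)
    if window <= 0:
        raise ValueError("window must be positive")
    if positions.size and (positions.min() < 0 or positions.max() >= chrom_length):
        raise ValueError("positions must lie in [0, chrom_length)")
    n_windows = int(np.ceil(chrom_length / window))
    counts = np.bincount(positions // window, minlength=n_windows)
    starts = np.arange(n_windows, dtype=np.int64) * window
    ends = np.minimum(starts + window, chrom_length)
    empty_run = np.full(n_windows, -1)
    run = 0
    in_run = False
    for i, c in enumerate(counts):
        if c == 0:
            if not in_run:
                run += 1
                in_run = True
            empty_run[i] = run
        else:
            in_run = False
    df = pd.DataFrame({"start": starts, "end": ends, "count": counts})
    df["empty_run"] = pd.array(
        [r if r > 0 else pd.NA for r in empty_run], dtype="Int64"
    )
    return df
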