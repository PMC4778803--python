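"""Phenotype and genotype quality control.

Mirrors the filters commonly applied before a GxE eQTL scan: a
Shapiro–Wilk normality screen on each phenotype, an outlier-count screen
(values more than ``sd_limit`` standard deviations from the mean; the
phenotype is dropped once ``max_outliers`` such values accumulate),
variant-level MAF / Hardy–Weinberg / completeness filters, and
rank-based inverse-normal (quantile) normalization, optionally within
exposure groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .types import ExposureVector, GenotypeMatrix, PhenotypeVector

__all__ = [
    "QcReport",
    "normality_filter",
    "outlier_filter",
    "genotype_qc",
    "quantile_normalize",
]


@dataclass
class QcReport:
    """Items dropped by a filter, each with exactly one primary reason."""

    dropped: list[tuple[str, str]] = field(default_factory=list)
    thresholds: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.dropped, columns=["id", "reason"])

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)


def normality_filter(
    phenotypes: list[PhenotypeVector], alpha: float = 0.05
) -> tuple[list[PhenotypeVector], QcReport]:
    """Keep phenotypes whose Shapiro–Wilk p-value is at least ``alpha``.

    Constant phenotypes are dropped with reason ``degenerate``.
    ``alpha = 0`` retains everything testable.
    """
    report = QcReport(thresholds={"alpha": alpha})
    kept = []
    for y in phenotypes:
        vals = y.values[np.isfinite(y.values)]
        if len(vals) < 3 or np.ptp(vals) == 0:
            report.dropped.append((y.name, "degenerate"))
            continue
        p = stats.shapiro(vals).pvalue
        if p < alpha:
            report.dropped.append((y.name, "non-normal"))
        else:
            kept.append(y)
    return kept, report


def outlier_filter(
    phenotypes: list[PhenotypeVector],
    sd_limit: float = 2.0,
    max_outliers: int = 5,
) -> tuple[list[PhenotypeVector], QcReport]:
    """Drop phenotypes with ``max_outliers`` or more extreme values.

    An outlier is a value more than ``sd_limit`` standard deviations
    from the mean; mean and SD are computed in a single pass including
    the outliers themselves.
    """
    report = QcReport(thresholds={"sd_limit": sd_limit, "max_outliers": max_outliers})
    kept = []
    for y in phenotypes:
        vals = y.values[np.isfinite(y.values)]
        if len(vals) < 2 or np.ptp(vals) == 0:
            report.dropped.append((y.name, "degenerate"))
            continue
        z = np.abs(vals - vals.mean()) / vals.std(ddof=0)
        if int((z > sd_limit).sum()) >= max_outliers:
            report.dropped.append((y.name, "outliers"))
        else:
            kept.append(y)
    return kept, report


def _hwe_chi2_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Chi-square (1 df, no continuity correction) Hardy-Weinberg test."""
    n = n_aa + n_ab + n_bb
    if n == 0:
        return 1.0
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1.0 - p
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_aa, n_ab, n_bb], dtype=float)
    if (exp == 0).any():
        return 1.0
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, 1))


def _hwe_exact_p(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact Hardy-Weinberg test (sum of heterozygote-count probabilities
    no larger than the observed one; Wigginton-style)."""
    n = n_aa + n_ab + n_bb
    n_a = 2 * n_aa + n_ab
    n_a = min(n_a, 2 * n - n_a)  # work with the rarer allele
    parity = n_a % 2
    hets = np.arange(parity, n_a + 1, 2)

    def logprob(h):
        hom_rare = (n_a - h) // 2
        hom_common = n - h - hom_rare
        return (
            h * np.log(2.0)
            + gammaln(n + 1)
            - gammaln(h + 1)
            - gammaln(hom_rare + 1)
            - gammaln(hom_common + 1)
        )

    lp = np.array([logprob(int(h)) for h in hets])
    lp -= lp.max()
    probs = np.exp(lp)
    probs /= probs.sum()
    p_obs = probs[hets == n_ab][0] if (hets == n_ab).any() else 0.0
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def genotype_qc(
    G: GenotypeMatrix,
    maf: float = 0.10,
    hwe_alpha: float = 1e-4,
    max_missing: float = 0.05,
    exact_hwe: bool = False,
) -> tuple[GenotypeMatrix, QcReport]:
    """Variant filters: MAF >= ``maf``, HWE p >= ``hwe_alpha``, missing
    fraction <= ``max_missing``.

    A variant failing several filters is reported once, with reason
    priority maf > hwe > missing.
    """
    report = QcReport(
        thresholds={"maf": maf, "hwe_alpha": hwe_alpha, "max_missing": max_missing}
    )
    dos = G.dosages
    n = dos.shape[0]
    keep_mask = np.ones(dos.shape[1], dtype=bool)
    hwe_test = _hwe_exact_p if exact_hwe else _hwe_chi2_p
    for j, vid in enumerate(G.variants.index):
        col = dos[:, j]
        obs = col[np.isfinite(col)]
        miss_frac = 1.0 - len(obs) / n
        p_hat = obs.mean() / 2.0 if len(obs) else 0.0
        maf_hat = min(p_hat, 1.0 - p_hat)
        counts = [int((obs == v).sum()) for v in (2.0, 1.0, 0.0)]
        hwe_p = hwe_test(*counts) if len(obs) else 1.0
        if maf_hat < maf:
            report.dropped.append((str(vid), "maf"))
        elif hwe_p < hwe_alpha:
            report.dropped.append((str(vid), "hwe"))
        elif miss_frac > max_missing:
            report.dropped.append((str(vid), "missing"))
        else:
            continue
        keep_mask[j] = False
    filtered = GenotypeMatrix(
        G.samples,
        G.variants.loc[keep_mask],
        dos[:, keep_mask],
        validate=False,
    )
    return filtered, report


def quantile_normalize(
    y: PhenotypeVector,
    exposure: ExposureVector | None = None,
    grouping: str = "none",
) -> PhenotypeVector:
    """Rank-based inverse-normal transform, whole-sample or per group.

    Within each group, values are replaced by standard-normal quantiles
    Phi^-1((rank - 0.5) / n_group) with ties assigned their average
    rank. ``grouping='by-exposure'`` normalizes each exposure group
    separately (requires an exposure). Missing values stay missing.
    """
    if grouping not in ("none", "by-exposure"):
        raise ValueError("grouping must be none|by-exposure")
    values = y.values.copy()
    if grouping == "by-exposure":
        if exposure is None:
            raise ValueError("by-exposure normalization requires an exposure")
        if exposure.samples != y.samples:
            exposure = exposure.reindex(y.samples)
        groups = [
            (f"exposure={g:g}", exposure.values == g)
            for g in np.unique(exposure.values)
        ]
    else:
        groups = [("all", np.ones(len(values), dtype=bool))]
    for gname, mask in groups:
        obs = mask & np.isfinite(values)
        ng = int(obs.sum())
        if ng < 2:
            raise ValueError(
                f"group {gname!r} has {ng} non-missing value(s); need at least 2"
            )
        ranks = stats.rankdata(values[obs], method="average")
        values[obs] = stats.norm.ppf((ranks - 0.5) / ng)
    return PhenotypeVector(list(y.samples), values, y.name)
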