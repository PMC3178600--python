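"""Pairwise relationship classification from IBS2* and K coefficients.

The decision cascade is driven primarily by the K (Cotterman) estimates,
with the IBS2*_ratio bands observed for each relationship class recorded
as supporting rationale codes: identical pairs have K2 near 1, parent-
child K1 near 1 with K2 near 0, full siblings (k1, k2) near (0.5, 0.25),
second/half-degree pairs near (0.5, 0), third-degree near (0.25, 0), and
the practical detection floor for distant relatedness sits at
K1 = 1/32 = 0.03125 (a 1/64th relationship).  Pairs whose elevated ratio
is not backed by K1 sharing are flagged as heterozygosity artifacts;
pairs with significantly depressed ratios and low heterozygosity are
flagged as homozygosity/ancestry outliers rather than called related.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotype_io import GenotypeTable
from .ibd_kcoeff import (
    EstimationError,
    IBDModelParams,
    KCoefficients,
    estimate_k,
)
from .ibs_core import (
    NULL_RATIO,
    IBS2StarStat,
    ZeroInformativeError,
    count_pair,
    ibs2star_stat,
    iter_pairs,
)

RELATIONSHIP_CLASSES = (
    "identical", "parent_child", "full_sibling", "second_degree",
    "third_degree", "distant", "unrelated", "high_het_artifact",
    "low_het_outlier",
)

# ordering from closest to most distant (artifact classes excluded)
_CLOSENESS_RANK = {
    "identical": 0, "parent_child": 1, "full_sibling": 2,
    "second_degree": 3, "third_degree": 4, "distant": 5, "unrelated": 6,
    "high_het_artifact": 6, "low_het_outlier": 6,
}


def closeness_rank(cls: str) -> int:
    return _CLOSENESS_RANK[cls]


@dataclass(frozen=True)
class ClassThresholds:
    """All numeric class boundaries in one place (reported with output)."""

    identical_k2: float = 0.9
    parent_child_k1: float = 0.9
    parent_child_k2_max: float = 0.1
    close_ratio_min: float = 0.99        # ratio band for identical / parent-child
    sibling_ratio: tuple[float, float] = (0.90, 0.96)
    second_degree_ratio: tuple[float, float] = (0.75, 0.90)
    close_k1: float = 0.15               # enter centroid classification above this
    detection_floor_k1: float = 0.03125  # K1 of a 1/64th relationship
    flag_ratio: float = 0.70             # empirical relatedness screen
    outlier_alpha: float = 0.05

    # class centroids in (k1, k2) for nearest-expected assignment
    centroids: tuple[tuple[str, float, float], ...] = (
        ("full_sibling", 0.5, 0.25),
        ("second_degree", 0.5, 0.0),
        ("third_degree", 0.25, 0.0),
    )


def heterozygosity(table: GenotypeTable, sample: str) -> float:
    """Fraction of non-missing autosomal calls that are heterozygous."""
    calls = table.sample_calls(sample)
    called = calls >= 0
    if not called.any():
        warnings.warn(f"sample {sample}: all calls missing; heterozygosity undefined")
        return float("nan")
    return float((calls[called] == 1).mean())


@dataclass
class PairReport:
    """Everything the classifier saw for one pair, plus its decision."""

    sample_a: str
    sample_b: str
    stat: IBS2StarStat | None
    k: KCoefficients | None
    het_a: float
    het_b: float
    relationship: str
    rationale: tuple[str, ...]

    @property
    def pair_heterozygosity(self) -> float:
        return self.het_a + self.het_b


def classify(
    stat: IBS2StarStat,
    k: KCoefficients,
    pair_het: float | None = None,
    cohort_het: float | None = None,
    thresholds: ClassThresholds | None = None,
) -> tuple[str, tuple[str, ...]]:
    """Assign a relationship class; returns (class, rationale codes).

    ``pair_het`` is the summed heterozygosity of the two samples and
    ``cohort_het`` the cohort norm for such sums (used only to separate
    low-heterozygosity outliers from ordinary unrelated pairs).
    """
    th = thresholds or ClassThresholds()
    codes: list[str] = []
    ratio, k1, k2 = stat.ratio, k.k1, k.k2

    if k2 >= th.identical_k2:
        if ratio < th.close_ratio_min:
            codes.append(f"ratio_atypical:{ratio:.3f}<{th.close_ratio_min}")
        return "identical", ("k2_near_1", *codes)

    if k1 >= th.parent_child_k1 and k2 < th.parent_child_k2_max:
        if ratio < th.close_ratio_min:
            codes.append(f"ratio_atypical:{ratio:.3f}<{th.close_ratio_min}")
        return "parent_child", ("k1_near_1_k2_near_0", *codes)

    if k1 >= th.close_k1:
        names = [c[0] for c in th.centroids]
        d = [np.hypot(k1 - c1, k2 - c2) for _, c1, c2 in th.centroids]
        cls = names[int(np.argmin(d))]
        codes.append(f"nearest_centroid:{cls}")
        band = {
            "full_sibling": th.sibling_ratio,
            "second_degree": th.second_degree_ratio,
            "third_degree": (th.flag_ratio, th.second_degree_ratio[0]),
        }[cls]
        if not band[0] <= ratio <= band[1]:
            codes.append(f"ratio_atypical:{ratio:.3f}!in[{band[0]},{band[1]}]")
        return cls, tuple(codes)

    if k1 >= th.detection_floor_k1:
        return "distant", (f"k1:{k1:.4f}>=floor:{th.detection_floor_k1}",)

    if ratio > th.flag_ratio:
        return "high_het_artifact", (
            f"ratio:{ratio:.3f}>{th.flag_ratio}",
            f"k1:{k1:.4f}<floor:{th.detection_floor_k1}",
        )

    if (
        ratio < NULL_RATIO
        and stat.p_two_sided <= th.outlier_alpha
        and pair_het is not None
        and cohort_het is not None
        and pair_het < cohort_het
    ):
        return "low_het_outlier", (
            f"ratio:{ratio:.3f}<2/3_significant",
            f"pair_het:{pair_het:.3f}<cohort:{cohort_het:.3f}",
        )

    return "unrelated", ("no_evidence_of_relatedness",)


def report_pair(
    table: GenotypeTable,
    sample_a: str,
    sample_b: str,
    params: IBDModelParams | None = None,
    thresholds: ClassThresholds | None = None,
    cohort_het: float | None = None,
    n_tests: int = 1,
) -> PairReport:
    """Compute IBS2* statistic, K estimates, heterozygosity, and classify."""
    het_a = heterozygosity(table, sample_a)
    het_b = heterozygosity(table, sample_b)
    counts = count_pair(table, sample_a, sample_b)
    try:
        stat = ibs2star_stat(counts, n_tests=n_tests)
    except ZeroInformativeError:
        stat = None
    try:
        k = estimate_k(table, sample_a, sample_b, params)
    except EstimationError:
        k = None
    if stat is None or k is None:
        return PairReport(
            sample_a, sample_b, stat, k, het_a, het_b,
            relationship="unrelated", rationale=("insufficient_data",),
        )
    cls, codes = classify(
        stat, k, pair_het=het_a + het_b, cohort_het=cohort_het,
        thresholds=thresholds,
    )
    return PairReport(sample_a, sample_b, stat, k, het_a, het_b, cls, codes)


def cohort_report(
    table: GenotypeTable,
    sheet: pd.DataFrame | None = None,
    mode: str = "all",
    params: IBDModelParams | None = None,
    thresholds: ClassThresholds | None = None,
) -> pd.DataFrame:
    """Relationship report for every pair, mirroring a results-table layout.

    The low-heterozygosity cohort norm is the median pair heterozygosity
    over the emitted comparisons.
    """
    pairs = list(iter_pairs(table.samples, sheet, mode))
    het = {s: heterozygosity(table, s) for s in table.samples}
    pair_hets = [het[a] + het[b] for a, b, _, _ in pairs]
    cohort_het = float(np.nanmedian(pair_hets)) if pair_hets else None
    rows = []
    for (a, b, ga, gb) in pairs:
        rep = report_pair(
            table, a, b, params=params, thresholds=thresholds,
            cohort_het=cohort_het, n_tests=len(pairs),
        )
        rows.append(
            {
                "sample_a": a, "sample_b": b,
                "ratio": rep.stat.ratio if rep.stat else np.nan,
                "group": ga if ga == gb else f"{ga}-{gb}",
                "k0": rep.k.k0 if rep.k else np.nan,
                "k1": rep.k.k1 if rep.k else np.nan,
                "k2": rep.k.k2 if rep.k else np.nan,
                "het_a": rep.het_a, "het_b": rep.het_b,
                "rel": rep.relationship,
                "rationale": ";".join(rep.rationale),
            }
        )
    return pd.DataFrame(rows)
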