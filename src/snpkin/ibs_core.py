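"""Per-locus IBS classification and the IBS2* ratio statistic.

For a pair of individuals at a biallelic SNP the identity-by-state count
is 0, 1 or 2 shared alleles.  Two sub-states of IBS2 are distinguished:
IBS2* (both heterozygous, AB/AB) and concordant homozygotes (AA/AA or
BB/BB).  IBS0 (discordant homozygotes, AA/BB) and IBS2* are the
"informative" states: under Hardy-Weinberg equilibrium and the null
hypothesis that the pair is unrelated members of one population,

    E[ IBS2* / (IBS0 + IBS2*) ] = 2/3

independent of the per-SNP allele frequencies.  Relatedness pushes this
IBS2*_ratio above 2/3 (IBS0 requires an IBD0 locus); differing allele
frequencies or reduced heterozygosity push it below.  The companion
y-axis quantity, the fraction of informative SNPs
(IBS0 + IBS2*)/(IBS0 + IBS1 + IBS2), tracks pair heterozygosity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenotypeTable

# IBS state codes
IBS0, IBS1, IBS2_STAR, IBS2_HOM, MISSING = 0, 1, 2, 3, 4
STATE_LABELS = {IBS0: "IBS0", IBS1: "IBS1", IBS2_STAR: "IBS2*", IBS2_HOM: "IBS2", MISSING: "NC"}

NULL_RATIO = 2.0 / 3.0
DEFAULT_FLAG_THRESHOLD = 0.70  # empirical relatedness screen on the ratio


class ZeroInformativeError(ValueError):
    """The pair has no IBS0 or IBS2* loci; the ratio statistic is undefined."""


def ibs_state(call_a: int, call_b: int) -> int:
    """IBS state of one locus (scalar convenience wrapper)."""
    return int(pair_states(np.array([call_a], np.int8), np.array([call_b], np.int8))[0])


def pair_states(calls_a: np.ndarray, calls_b: np.ndarray) -> np.ndarray:
    """Vector of IBS state codes for two aligned call vectors.

    MISSING if either call is NC; AB/AB -> IBS2*; identical homozygotes ->
    IBS2 (concordant hom); AA/BB -> IBS0; any hom/het mix -> IBS1.
    """
    a = np.asarray(calls_a, dtype=np.int8)
    b = np.asarray(calls_b, dtype=np.int8)
    st = np.full(a.shape, IBS1, dtype=np.int8)
    st[(a == 1) & (b == 1)] = IBS2_STAR
    st[(a == b) & (a != 1)] = IBS2_HOM
    st[np.abs(a.astype(np.int16) - b) == 2] = IBS0
    st[(a < 0) | (b < 0)] = MISSING
    return st


@dataclass(frozen=True)
class PairIBSCounts:
    """Genome-wide IBS tallies for one sample pair."""

    n_ibs0: int
    n_ibs1: int
    n_ibs2_star: int
    n_ibs2_hom: int
    n_missing: int

    @property
    def n_total(self) -> int:
        return self.n_ibs0 + self.n_ibs1 + self.n_ibs2_star + self.n_ibs2_hom + self.n_missing

    @property
    def n_ibs2(self) -> int:
        return self.n_ibs2_star + self.n_ibs2_hom

    @property
    def m_informative(self) -> int:
        """Number of informative loci (IBS0 + IBS2*)."""
        return self.n_ibs0 + self.n_ibs2_star


def counts_from_states(states: np.ndarray) -> PairIBSCounts:
    tallies = np.bincount(states, minlength=5)
    return PairIBSCounts(
        n_ibs0=int(tallies[IBS0]),
        n_ibs1=int(tallies[IBS1]),
        n_ibs2_star=int(tallies[IBS2_STAR]),
        n_ibs2_hom=int(tallies[IBS2_HOM]),
        n_missing=int(tallies[MISSING]),
    )


def count_pair(table: GenotypeTable, sample_a: str, sample_b: str) -> PairIBSCounts:
    """Tally IBS states for one pair over all markers in the table."""
    states = pair_states(table.sample_calls(sample_a), table.sample_calls(sample_b))
    return counts_from_states(states)


@dataclass(frozen=True)
class IBS2StarStat:
    """The (x, y) point of an IBS2* plot plus its test against ratio = 2/3."""

    ratio: float            # IBS2* / (IBS0 + IBS2*)
    pct_informative: float  # (IBS0 + IBS2*) / (IBS0 + IBS1 + IBS2)
    z: float
    p_two_sided: float
    flagged_related: bool   # empirical screen, ratio > 0.70 by default
    significant: bool       # after Bonferroni over n_tests
    m: int                  # informative marker count


def ibs2star_stat(
    counts: PairIBSCounts,
    n_tests: int = 1,
    alpha: float = 0.05,
    flag_threshold: float = DEFAULT_FLAG_THRESHOLD,
) -> IBS2StarStat:
    """IBS2*_ratio, percent-informative, and the Z-test of ratio = 2/3.

    The Z statistic is the one-sample binomial-proportion form on the
    informative-marker count m = IBS0 + IBS2*:
    z = (ratio - 2/3) / sqrt((2/3)(1/3)/m).  Significance is reported at
    the Bonferroni-corrected level alpha / n_tests.
    """
    m = counts.m_informative
    if m == 0:
        raise ZeroInformativeError("no informative (IBS0 or IBS2*) loci for this pair")
    ratio = counts.n_ibs2_star / m
    denom = counts.n_ibs0 + counts.n_ibs1 + counts.n_ibs2_star + counts.n_ibs2_hom
    pct_informative = m / denom if denom else float("nan")
    z = (ratio - NULL_RATIO) / np.sqrt(NULL_RATIO * (1 - NULL_RATIO) / m)
    p = float(2.0 * stats.norm.sf(abs(z)))
    p = min(p, 1.0) if p > 0 else float(np.nextafter(0, 1))
    return IBS2StarStat(
        ratio=float(ratio),
        pct_informative=float(pct_informative),
        z=float(z),
        p_two_sided=p,
        flagged_related=bool(ratio > flag_threshold),
        significant=bool(p <= alpha / max(n_tests, 1)),
        m=m,
    )


def exact_binom_p(counts: PairIBSCounts) -> float:
    """Two-sided exact binomial p-value for IBS2* successes in m trials at p = 2/3."""
    m = counts.m_informative
    if m == 0:
        raise ZeroInformativeError("no informative loci")
    return float(stats.binomtest(counts.n_ibs2_star, m, NULL_RATIO).pvalue)


# ---------------------------------------------------------------------------
# Cohort-level pairwise scans

def iter_pairs(samples: list[str], sheet: pd.DataFrame | None, mode: str):
    """Yield (a, b, group_a, group_b) per the within/between/all pairing mode."""
    if mode not in {"within", "between", "all"}:
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "all":
        groups = {}
        if sheet is not None:
            groups = dict(zip(sheet["sample_id"], sheet["group"]))
        for a, b in itertools.combinations(samples, 2):
            yield a, b, groups.get(a, ""), groups.get(b, "")
        return
    if sheet is None:
        raise ValueError(f"mode {mode!r} requires a sample sheet with group labels")
    groups = dict(zip(sheet["sample_id"], sheet["group"]))
    missing = [s for s in samples if s not in groups]
    if missing:
        raise ValueError(f"samples missing from sheet: {missing[:5]}")
    for a, b in itertools.combinations(samples, 2):
        same = groups[a] == groups[b]
        if (mode == "within" and same) or (mode == "between" and not same):
            yield a, b, groups[a], groups[b]


def all_pairs(
    table: GenotypeTable,
    sheet: pd.DataFrame | None = None,
    mode: str = "all",
    alpha: float = 0.05,
    n_tests: int | None = None,
    flag_threshold: float = DEFAULT_FLAG_THRESHOLD,
) -> pd.DataFrame:
    """IBS2* statistics for every pair under the given pairing mode.

    Bonferroni n_tests defaults to the number of emitted pairs.  Pairs
    with zero informative loci are reported with NaN statistics rather
    than dropped.
    """
    pairs = list(iter_pairs(table.samples, sheet, mode))
    if n_tests is None:
        n_tests = len(pairs)
    rows = []
    for a, b, ga, gb in pairs:
        c = count_pair(table, a, b)
        row = {
            "sample_a": a, "sample_b": b, "group_a": ga, "group_b": gb,
            "n_ibs0": c.n_ibs0, "n_ibs1": c.n_ibs1, "n_ibs2": c.n_ibs2,
            "n_ibs2_star": c.n_ibs2_star, "n_missing": c.n_missing,
        }
        try:
            s = ibs2star_stat(c, n_tests=n_tests, alpha=alpha, flag_threshold=flag_threshold)
            row.update(
                ratio=s.ratio, pct_informative=s.pct_informative, z=s.z,
                p=s.p_two_sided, significant=s.significant, flagged=s.flagged_related,
            )
        except ZeroInformativeError:
            row.update(
                ratio=np.nan, pct_informative=np.nan, z=np.nan,
                p=np.nan, significant=False, flagged=False,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def ibs_track(
    table: GenotypeTable, sample_a: str, sample_b: str, chromosome: str
) -> pd.DataFrame:
    """Per-marker (position, IBS state) track for one chromosome.

    MISSING loci are included (labelled NC) so plots can distinguish
    no-data from no-sharing.
    """
    from .genotype_io import is_autosome, normalize_chromosome

    mask = (table.markers["chromosome"] == chromosome).to_numpy()
    if not mask.any():
        # allow a recognized-but-markerless chromosome (empty track)
        norm = normalize_chromosome(chromosome)
        if not (is_autosome(norm) or norm in {"X", "Y", "MT"}):
            raise KeyError(f"unknown chromosome {chromosome!r}")
    states = pair_states(
        table.sample_calls(sample_a)[mask], table.sample_calls(sample_b)[mask]
    )
    pos = table.markers["position"].to_numpy()[mask]
    order = np.argsort(pos, kind="stable")
    return pd.DataFrame(
        {
            "chromosome": chromosome,
            "position": pos[order],
            "state": states[order],
            "state_label": [STATE_LABELS[int(s)] for s in states[order]],
        }
    )
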