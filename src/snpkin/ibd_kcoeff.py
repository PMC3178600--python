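"""Windowed Bayesian estimation of Cotterman coefficients (K0, K1, K2).

The estimator scans a pair's informative loci in overlapping fixed-size
windows and infers the IBD state of each genomic region from binomial
likelihoods of the observed IBS composition:

* **d0 track** — loci that are IBS0 or IBS2* (concordant homozygotes and
  no-calls removed).  Within a window of n such loci with k IBS0 events,
  the IBS0 fraction has expectation 1/3 under IBD0 (an allele-frequency-
  free consequence of Hardy-Weinberg genotype probabilities) and ~0 under
  IBD1/IBD2, where IBS0 arises only through genotyping error.  The
  posterior P(D0|S) compares Binom(k; n, 1/3) against Binom(k; n, error).

* **d12 track** — loci that are IBS1 or IBS2*.  Conditional on not-IBD0,
  the IBS1 fraction has expectation c (default 0.518, the allele-
  frequency-integrated value; see :func:`compute_c`) under IBD1 and ~0
  under IBD2.  P(not-D0|S) is split into P(D1|S) and P(D2|S) by the
  binomial likelihood ratio Binom(k; n, c) vs Binom(k; n, error) with
  equal sub-priors.

Because the two tracks have different marker densities (hence window
spans), window posteriors are reconciled on the genome coordinate: the
per-position P(D0) profile from the d0 track and the conditional D1/D2
split from the d12 track are averaged over overlapping windows, combined
per position, and integrated genome-length-weighted into

    K_j = sum_w P_w(D_j | S) * l_w / sum_w l_w,  j = 0, 1, 2.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.integrate import quad

from .genotype_io import GenotypeTable
from .ibs_core import IBS0, IBS1, IBS2_STAR, pair_states

DEFAULT_C = 0.518


class EstimationError(RuntimeError):
    """No usable windows: pair/marker set too sparse for IBD estimation."""


@dataclass(frozen=True)
class IBDModelParams:
    """Tunable parameters of the windowed estimator.

    window_size is in track-SNPs (informative loci), not all markers; the
    default 300 balances noise suppression against boundary resolution.
    ``error`` is the per-genotype error rate absorbed by the not-D0 (and
    D2) likelihoods.  ``c`` is the expected IBS1/(IBS1+IBS2*) fraction in
    IBD1 regions after integrating out the allele frequency.
    """

    window_size: int = 300
    step: int | None = None  # default window_size // 3
    error: float = 0.01
    c: float = DEFAULT_C
    prior_d0: float = 1.0 / 3.0
    prior_d1: float = 1.0 / 3.0
    prior_d2: float = 1.0 / 3.0
    prior_d1_given_not_d0: float = 0.5
    refine_boundaries: bool = True  # ML changepoint refinement between window runs

    def __post_init__(self):
        if not math.isclose(self.prior_d0 + self.prior_d1 + self.prior_d2, 1.0):
            raise ValueError("priors must sum to 1")
        if not (0.0 < self.error < self.c <= 2.0 / 3.0):
            raise ValueError("require 0 < error < c <= 2/3")
        if self.window_size < 2:
            raise ValueError("window_size must be >= 2")
        if self.step is not None and self.step < 1:
            raise ValueError("step must be >= 1")

    @property
    def effective_step(self) -> int:
        return self.step if self.step is not None else max(self.window_size // 3, 1)

    def fingerprint(self) -> str:
        return (
            f"window_size={self.window_size};step={self.effective_step};"
            f"error={self.error};c={self.c};priors={self.prior_d0},"
            f"{self.prior_d1},{self.prior_d2};refine={self.refine_boundaries}"
        )


@dataclass
class ChromTrack:
    """One informative track on one chromosome."""

    index: np.ndarray      # marker indices into the full table
    position: np.ndarray   # bp positions, ascending
    event: np.ndarray      # bool: IBS0 on the d0 track, IBS1 on the d12 track


@dataclass
class InformativeTracks:
    """Informative loci for one pair, split by chromosome and track.

    d0: loci with state in {IBS0, IBS2*} (event = IBS0)
    d12: loci with state in {IBS1, IBS2*} (event = IBS1)
    Concordant homozygous and missing loci appear on neither; every IBS2*
    locus appears on both.
    """

    d0: dict[str, ChromTrack]
    d12: dict[str, ChromTrack]

    @property
    def n_d0_snps(self) -> int:
        return sum(len(t.position) for t in self.d0.values())

    @property
    def n_d12_snps(self) -> int:
        return sum(len(t.position) for t in self.d12.values())


def build_tracks(table: GenotypeTable, sample_a: str, sample_b: str) -> InformativeTracks:
    """Split a pair's loci into the d0 and d12 informative tracks."""
    states = pair_states(table.sample_calls(sample_a), table.sample_calls(sample_b))
    chroms = table.markers["chromosome"].to_numpy()
    pos = table.markers["position"].to_numpy()
    d0: dict[str, ChromTrack] = {}
    d12: dict[str, ChromTrack] = {}
    on_d0 = (states == IBS0) | (states == IBS2_STAR)
    on_d12 = (states == IBS1) | (states == IBS2_STAR)
    for chrom in dict.fromkeys(chroms):  # preserve order
        cmask = chroms == chrom
        for store, on, event_state in ((d0, on_d0, IBS0), (d12, on_d12, IBS1)):
            sel = cmask & on
            idx = np.flatnonzero(sel)
            store[str(chrom)] = ChromTrack(
                index=idx, position=pos[idx], event=(states[idx] == event_state)
            )
    tracks = InformativeTracks(d0=d0, d12=d12)
    if tracks.n_d0_snps == 0 and tracks.n_d12_snps == 0:
        warnings.warn(f"pair {sample_a}/{sample_b}: no informative loci on either track")
    return tracks


@dataclass(frozen=True)
class Window:
    """One window of track-SNPs on one chromosome (indices half-open)."""

    track: str        # "d0" or "d12"
    chromosome: str
    start_index: int
    end_index: int
    start_bp: int
    end_bp: int       # position of the last SNP in the window
    n_snps: int
    n_events: int

    @property
    def span_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


def _windows_for_chrom(
    track_name: str, chrom: str, ct: ChromTrack, params: IBDModelParams
) -> list[Window]:
    n = len(ct.position)
    w, step = params.window_size, params.effective_step
    if n < w / 2:
        if n:
            warnings.warn(
                f"{track_name} track, chromosome {chrom}: only {n} SNPs "
                f"(< window_size/2 = {w / 2:g}); skipped"
            )
        return []
    cum = np.concatenate([[0], np.cumsum(ct.event)])
    out: list[Window] = []

    def make(i: int, j: int) -> Window:
        return Window(
            track=track_name, chromosome=chrom, start_index=i, end_index=j,
            start_bp=int(ct.position[i]), end_bp=int(ct.position[j - 1]),
            n_snps=j - i, n_events=int(cum[j] - cum[i]),
        )

    for start in range(0, n, step):
        end = min(start + w, n)
        if end - start < w / 2:
            # short tail: merge into the previous window rather than drop it
            out[-1] = make(out[-1].start_index, n)
            break
        out.append(make(start, end))
        if end == n:
            break
    return out


def iter_windows(tracks: InformativeTracks, params: IBDModelParams) -> list[Window]:
    """All windows over both tracks, chromosome by chromosome."""
    out: list[Window] = []
    for name, store in (("d0", tracks.d0), ("d12", tracks.d12)):
        for chrom, ct in store.items():
            out.extend(_windows_for_chrom(name, chrom, ct, params))
    return out


# ---------------------------------------------------------------------------
# Window posteriors (log-space binomial likelihood ratios)

def _log_posterior_ratio(k: int, n: int, p_alt: float, p_null: float,
                         log_prior_odds: float) -> float:
    """log[ P(alt|S) / P(null|S) ] for Binom(k; n, p_alt) vs Binom(k; n, p_null)."""
    la = stats.binom.logpmf(k, n, p_alt)
    ln = stats.binom.logpmf(k, n, p_null)
    return float(la - ln + log_prior_odds)


def _sigmoid(log_odds: float) -> float:
    if log_odds >= 0:
        return 1.0 / (1.0 + math.exp(-log_odds))
    e = math.exp(log_odds)
    return e / (1.0 + e)


def posterior_d0(window: Window, params: IBDModelParams) -> float:
    """P(D0 | S) for a d0-track window.

    Likelihoods: Binom(n_events; n_snps, 1/3) under IBD0 and
    Binom(n_events; n_snps, error) under not-IBD0; prior P(D0) against
    P(not-D0) = 1 - P(D0).
    """
    if window.track != "d0":
        raise ValueError("posterior_d0 expects a d0-track window")
    log_odds = _log_posterior_ratio(
        window.n_events, window.n_snps, 1.0 / 3.0, params.error,
        math.log(params.prior_d0) - math.log1p(-params.prior_d0),
    )
    return min(max(_sigmoid(log_odds), 0.0), 1.0)


def posterior_split_d1_d2(
    window: Window, params: IBDModelParams, p_not_d0: float
) -> tuple[float, float]:
    """(P(D1|S), P(D2|S)) for a d12-track window, conditioned on not-IBD0.

    Likelihoods: Binom(n_events; n_snps, c) under IBD1 and
    Binom(n_events; n_snps, error) under IBD2, with the equal sub-priors
    P(D1|not-D0) = P(D2|not-D0) = 1/2 unless overridden.  The returned
    probabilities sum to p_not_d0.
    """
    if window.track != "d12":
        raise ValueError("posterior_split_d1_d2 expects a d12-track window")
    q1 = params.prior_d1_given_not_d0
    log_odds = _log_posterior_ratio(
        window.n_events, window.n_snps, params.c, params.error,
        math.log(q1) - math.log1p(-q1),
    )
    r1 = _sigmoid(log_odds)
    return p_not_d0 * r1, p_not_d0 * (1.0 - r1)


@dataclass(frozen=True)
class KCoefficients:
    """Genome-wide estimates of Cotterman k0, k1, k2 (sum to 1)."""

    k0: float
    k1: float
    k2: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.k0, self.k1, self.k2)


# ---------------------------------------------------------------------------
# Per-position reconciliation of the two tracks

@dataclass
class _Intervals:
    """Contiguous piecewise-constant profile of one track on one chromosome."""

    starts: np.ndarray  # bp, ascending; interval i = [starts[i], starts[i+1]) ...
    end: int            # ... and the last interval ends at `end` (exclusive)
    values: np.ndarray

    def lookup(self, x: np.ndarray) -> np.ndarray:
        i = np.clip(np.searchsorted(self.starts, x, side="right") - 1, 0, len(self.values) - 1)
        return self.values[i]

    def covers(self, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
        return (lo >= self.starts[0]) & (hi <= self.end)


def _averaged_intervals(wins: list[Window], vals: np.ndarray) -> _Intervals:
    """Overlap-averaging aggregation: mean window posterior per position."""
    edges = np.unique(
        np.concatenate([[w.start_bp for w in wins], [w.end_bp + 1 for w in wins]])
    )
    nseg = len(edges) - 1
    cnt = np.zeros(nseg)
    tot = np.zeros(nseg)
    for w, v in zip(wins, vals):
        i = np.searchsorted(edges, w.start_bp, side="right") - 1
        j = np.searchsorted(edges, w.end_bp + 1, side="left")
        cnt[i:j] += 1.0
        tot[i:j] += v
    # window spans are nested in the chromosome extent: every segment is covered
    vals_seg = tot / np.maximum(cnt, 1)
    keep = cnt > 0
    return _Intervals(starts=edges[:-1][keep], end=int(edges[-1]), values=vals_seg[keep])


def _refined_intervals(
    wins: list[Window], vals: np.ndarray, ct: ChromTrack,
    rate_hi: float, rate_lo: float,
) -> _Intervals:
    """Run-call aggregation with ML changepoint refinement.

    Windows are hard-called (posterior > 1/2); runs of equal calls form
    segments whose boundaries are re-located at the maximum-likelihood
    split of the per-SNP events within the two straddling windows.  This
    removes the boundary smearing inherent in whole-window voting (a
    window is called "high-rate" once a modest fraction of it lies in
    the high-rate state, because the two binomial rates are far apart).
    """
    calls = vals > 0.5
    run_starts = [0] + [i for i in range(1, len(wins)) if calls[i] != calls[i - 1]]
    run_ends = run_starts[1:] + [len(wins)]
    run_values = np.array(
        [float(np.median(vals[a:b])) for a, b in zip(run_starts, run_ends)]
    )
    if len(run_starts) == 1:
        return _Intervals(
            starts=np.array([wins[0].start_bp]), end=wins[-1].end_bp + 1,
            values=run_values,
        )
    ev = ct.event
    with np.errstate(divide="ignore"):
        per_hi = np.where(ev, math.log(rate_hi), math.log1p(-rate_hi))
        per_lo = np.where(ev, math.log(rate_lo), math.log1p(-rate_lo))
    cum_hi = np.concatenate([[0.0], np.cumsum(per_hi)])
    cum_lo = np.concatenate([[0.0], np.cumsum(per_lo)])
    cps: list[int] = []  # changepoint bp positions
    prev_t = 1
    for b in range(1, len(run_starts)):
        left_win = wins[run_ends[b - 1] - 1]   # last window of the left run
        right_win = wins[run_starts[b]]        # first window of the right run
        lo = left_win.start_index
        hi = right_win.end_index
        lo = max(lo, prev_t)
        left_cum = cum_hi if calls[run_starts[b - 1]] else cum_lo
        right_cum = cum_hi if calls[run_starts[b]] else cum_lo
        t_range = np.arange(max(lo + 1, 1), max(hi, lo + 2))
        t_range = t_range[t_range < len(ct.position)]
        if len(t_range) == 0:
            t = min(prev_t + 1, len(ct.position) - 1)
        else:
            score = (left_cum[t_range] - left_cum[lo]) + (right_cum[hi] - right_cum[t_range])
            t = int(t_range[np.argmax(score)])
        t = max(t, prev_t + 1) if cps else t
        t = min(t, len(ct.position) - 1)
        prev_t = t
        cp = int(ct.position[t - 1] + ct.position[t]) // 2
        cps.append(cp)
    starts = np.concatenate([[wins[0].start_bp], np.maximum.accumulate(cps)])
    # guard against degenerate (non-increasing) boundaries
    starts = np.maximum.accumulate(starts)
    return _Intervals(starts=starts, end=wins[-1].end_bp + 1, values=run_values)


_EMPTY_TRACK = ChromTrack(
    np.empty(0, dtype=int), np.empty(0, dtype=int), np.empty(0, dtype=bool)
)


def _track_profile(
    name: str, chrom: str, ct: ChromTrack, params: IBDModelParams
) -> _Intervals | None:
    wins = _windows_for_chrom(name, chrom, ct, params)
    if not wins:
        return None
    if name == "d0":
        vals = np.array([posterior_d0(w, params) for w in wins])
        rate_hi, rate_lo = 1.0 / 3.0, params.error
    else:
        vals = np.array([posterior_split_d1_d2(w, params, 1.0)[0] for w in wins])
        rate_hi, rate_lo = params.c, params.error
    if params.refine_boundaries:
        return _refined_intervals(wins, vals, ct, rate_hi, rate_lo)
    return _averaged_intervals(wins, vals)


def ibd_profile(
    tracks: InformativeTracks, params: IBDModelParams
) -> pd.DataFrame:
    """Piecewise-constant genomic profile of (P(D0), P(D1), P(D2)).

    Returns one row per elementary segment (chromosome, start, end in
    0-based half-open bp) covered by the d0-track windows.  The d0 track
    supplies P(D0); the d12 track supplies the conditional D1/D2 split
    of the not-D0 mass (equal sub-priors where it has no coverage); the
    two are combined per position.
    """
    rows = []
    for chrom in tracks.d0:
        prof0 = _track_profile("d0", chrom, tracks.d0[chrom], params)
        if prof0 is None:
            continue
        prof12 = _track_profile(
            "d12", chrom, tracks.d12.get(chrom, _EMPTY_TRACK), params
        )
        edge_set = set(prof0.starts.tolist()) | {prof0.end}
        if prof12 is not None:
            edge_set |= set(prof12.starts.tolist()) | {prof12.end}
        edges = np.array(sorted(e for e in edge_set if prof0.starts[0] <= e <= prof0.end))
        lo, hi = edges[:-1], edges[1:]
        mids = (lo + hi) // 2
        p0 = prof0.lookup(mids)
        if prof12 is not None:
            cov12 = prof12.covers(lo, hi)
            r1 = np.where(cov12, prof12.lookup(mids), params.prior_d1_given_not_d0)
        else:
            cov12 = np.zeros(len(mids), dtype=bool)
            r1 = np.full(len(mids), params.prior_d1_given_not_d0)
        for i in range(len(mids)):
            rows.append(
                (chrom, int(lo[i]) - 1, int(hi[i]) - 1, float(p0[i]),
                 float((1 - p0[i]) * r1[i]), float((1 - p0[i]) * (1 - r1[i])),
                 bool(cov12[i]))
            )
    return pd.DataFrame(
        rows, columns=["chromosome", "start", "end", "p_d0", "p_d1", "p_d2", "d12_covered"]
    )


def estimate_k(
    table: GenotypeTable,
    sample_a: str,
    sample_b: str,
    params: IBDModelParams | None = None,
) -> KCoefficients:
    """Genome-length-weighted K0/K1/K2 for one pair."""
    params = params or IBDModelParams()
    tracks = build_tracks(table, sample_a, sample_b)
    return estimate_k_from_tracks(tracks, params, pair=(sample_a, sample_b))


def estimate_k_from_tracks(
    tracks: InformativeTracks,
    params: IBDModelParams,
    pair: tuple[str, str] | None = None,
) -> KCoefficients:
    prof = ibd_profile(tracks, params)
    if prof.empty:
        raise EstimationError(
            f"no usable windows for pair {pair}: "
            f"{tracks.n_d0_snps} d0-track SNPs, {tracks.n_d12_snps} d12-track SNPs, "
            f"window_size={params.window_size}"
        )
    length = (prof["end"] - prof["start"]).to_numpy(float)
    total = length.sum()
    k0 = float((length * prof["p_d0"]).sum() / total)
    k1 = float((length * prof["p_d1"]).sum() / total)
    k2 = float((length * prof["p_d2"]).sum() / total)
    return KCoefficients(k0=k0, k1=k1, k2=k2)


def kcoeff_table(
    table: GenotypeTable,
    pairs: list[tuple[str, str]],
    params: IBDModelParams | None = None,
) -> pd.DataFrame:
    """K estimates for a list of pairs (one TSV-ready row per pair)."""
    params = params or IBDModelParams()
    rows = []
    for a, b in pairs:
        tracks = build_tracks(table, a, b)
        n_windows = len(iter_windows(tracks, params))
        try:
            k = estimate_k_from_tracks(tracks, params, pair=(a, b))
            k0, k1, k2 = k.as_tuple()
        except EstimationError:
            k0 = k1 = k2 = np.nan
        rows.append(
            {
                "sample_a": a, "sample_b": b, "k0": k0, "k1": k1, "k2": k2,
                "n_d0_snps": tracks.n_d0_snps, "n_d12_snps": tracks.n_d12_snps,
                "n_windows": n_windows, "params": params.fingerprint(),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# The allele-frequency parameter c

def ibs_given_ibd(p: float) -> pd.DataFrame:
    """P(IBS state | IBD state) at allele frequency p under Hardy-Weinberg.

    Rows IBS0/IBS1/IBS2*, columns IBD0/IBD1/IBD2.  Columns do not sum to
    1 because concordant homozygotes are excluded (they carry no
    information about IBD once allele frequencies are unknown).
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    q = 1.0 - p
    return pd.DataFrame(
        {
            "IBD0": [2 * p**2 * q**2, 4 * p**3 * q + 4 * p * q**3, 4 * p**2 * q**2],
            "IBD1": [0.0, 2 * p * q, 0.5 - p * q],
            "IBD2": [0.0, 0.0, 2 * p * q],
        },
        index=["IBS0", "IBS1", "IBS2*"],
    )


def ibs1_fraction_given_ibd1(p: float) -> float:
    """f(p) = P(IBS1 | IBS1 or IBS2*, IBD1) = 2pq / (2pq + 1/2 - pq)."""
    pq = p * (1.0 - p)
    return 2.0 * pq / (2.0 * pq + 0.5 - pq)


def _p_obs_given_p(p: float) -> float:
    """P(O | p) in an IBD1 region: complement of the concordant-homozygote
    probability 1/2 - pq, i.e. 1/2 + pq."""
    return 0.5 + p * (1.0 - p)


def compute_c(prior: str = "empirical_bayes") -> float:
    """Expected IBS1 fraction within IBD1 regions, integrating over p.

    ``uniform``: c = integral of f(p) dp over (0, 1) with a flat prior
    (~0.479).  ``empirical_bayes``: the flat prior is updated twice by
    the observation event O (a SNP showing variation in the pair), giving
    a weight proportional to P(O|p)^2; this yields c = 0.518, the
    default used by the estimator.
    """
    if prior == "uniform":
        weight = lambda p: 1.0
    elif prior == "empirical_bayes":
        weight = lambda p: _p_obs_given_p(p) ** 2
    else:
        raise ValueError(f"unknown prior {prior!r}; use 'uniform' or 'empirical_bayes'")
    num, _ = quad(lambda p: ibs1_fraction_given_ibd1(p) * weight(p), 0.0, 1.0)
    den, _ = quad(weight, 0.0, 1.0)
    return num / den
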