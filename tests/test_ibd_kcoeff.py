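"""Windowed Bayesian K-coefficient estimator and the c parameter."""

import math
import warnings

import numpy as np
import pytest
from scipy.integrate import quad

from snpkin import (
    GenomeModel,
    NoiseModel,
    build_tracks,
    compute_c,
    estimate_k,
    ibs_given_ibd,
    iter_windows,
    scenario,
)
from snpkin.ibd_kcoeff import (
    ChromTrack,
    EstimationError,
    IBDModelParams,
    InformativeTracks,
    Window,
    ibd_profile,
    posterior_d0,
    posterior_split_d1_d2,
)

from conftest import make_table


# ---------------------------------------------------------------------------
# Tracks

class TestBuildTracks:
    def test_hand_enumerated_membership(self):
        # loci: AA/AA (neither), AB/AB (both), AA/BB (d0), AA/AB (d12), AB/NC (neither)
        t = make_table(
            [
                ("m1", "1", 10, "AA", "AA"),
                ("m2", "1", 20, "AB", "AB"),
                ("m3", "1", 30, "AA", "BB"),
                ("m4", "1", 40, "AA", "AB"),
                ("m5", "1", 50, "AB", "NC"),
            ],
            ["a", "b"],
        )
        tr = build_tracks(t, "a", "b")
        assert tr.d0["1"].index.tolist() == [1, 2]
        assert tr.d12["1"].index.tolist() == [1, 3]
        assert tr.d0["1"].event.tolist() == [False, True]   # IBS0 at m3
        assert tr.d12["1"].event.tolist() == [False, True]  # IBS1 at m4

    def test_identical_pair_has_no_d0_events(self, desk_genome):
        p = scenario("identical", desk_genome, NoiseModel(0.0, 0.0), seed=1)
        tr = build_tracks(p.table, p.sample_a, p.sample_b)
        assert not any(ct.event.any() for ct in tr.d0.values())

    def test_empty_pair_warns(self):
        t = make_table([("m1", "1", 10, "AA", "AA")], ["a", "b"])
        with pytest.warns(UserWarning, match="no informative"):
            build_tracks(t, "a", "b")


# ---------------------------------------------------------------------------
# Windows

def track_of(n, chrom="1", spacing=1000):
    pos = np.arange(1, n + 1) * spacing
    return InformativeTracks(
        d0={chrom: ChromTrack(np.arange(n), pos, np.zeros(n, dtype=bool))},
        d12={},
    )


class TestWindows:
    def test_exact_size_track_gives_one_window(self):
        wins = iter_windows(track_of(300), IBDModelParams())
        assert len(wins) == 1 and wins[0].n_snps == 300

    def test_overlap_arithmetic(self):
        wins = iter_windows(track_of(600), IBDModelParams())
        assert [w.start_index for w in wins] == [0, 100, 200, 300]
        assert all(w.end_index - w.start_index == 300 for w in wins)

    def test_trailing_partial_window_emitted_when_large(self):
        wins = iter_windows(track_of(650), IBDModelParams())
        assert wins[-1].start_index == 400 and wins[-1].n_snps == 250

    def test_short_tail_merges_into_previous(self):
        # non-overlapping windows: the 120-SNP tail is under half-size
        wins = iter_windows(track_of(420), IBDModelParams(step=300))
        assert len(wins) == 1 and wins[0].n_snps == 420

    def test_small_chromosome_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="skipped"):
            wins = iter_windows(track_of(100), IBDModelParams())
        assert wins == []

    def test_windows_do_not_cross_chromosomes(self, sib_pairs):
        p = sib_pairs[0]
        tracks = build_tracks(p.table, p.sample_a, p.sample_b)
        for w in iter_windows(tracks, IBDModelParams()):
            ct = (tracks.d0 if w.track == "d0" else tracks.d12)[w.chromosome]
            assert 0 <= w.start_index < w.end_index <= len(ct.position)


# ---------------------------------------------------------------------------
# Posteriors: brute-force oracle equivalence

def brute_posterior_d0(k, n, error, prior_d0):
    """Direct Bayes' rule with explicitly enumerated binomial pmfs."""
    def pmf(k, n, p):
        return math.comb(n, k) * p**k * (1 - p) ** (n - k)

    l0 = pmf(k, n, 1 / 3)
    ln0 = pmf(k, n, error)
    return l0 * prior_d0 / (l0 * prior_d0 + ln0 * (1 - prior_d0))


def brute_split(k, n, c, error, q1):
    def pmf(k, n, p):
        return math.comb(n, k) * p**k * (1 - p) ** (n - k)

    l1, l2 = pmf(k, n, c), pmf(k, n, error)
    return l1 * q1 / (l1 * q1 + l2 * (1 - q1))


def w(track, n, k):
    return Window(track=track, chromosome="1", start_index=0, end_index=n,
                  start_bp=1, end_bp=n, n_snps=n, n_events=k)


class TestPosteriorOracle:
    @pytest.mark.parametrize("n", [5, 10, 20])
    def test_small_window_equivalence_d0(self, n):
        params = IBDModelParams()
        for k in range(n + 1):
            expected = brute_posterior_d0(k, n, params.error, params.prior_d0)
            got = posterior_d0(w("d0", n, k), params)
            assert got == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("n", [5, 10, 20])
    def test_small_window_equivalence_d12(self, n):
        params = IBDModelParams()
        for k in range(n + 1):
            expected = brute_split(k, n, params.c, params.error, 0.5)
            p1, p2 = posterior_split_d1_d2(w("d12", n, k), params, 1.0)
            assert p1 == pytest.approx(expected, rel=1e-12)
            assert p1 + p2 == pytest.approx(1.0, abs=1e-12)

    def test_one_third_event_rate_is_confident_d0(self):
        assert posterior_d0(w("d0", 300, 100), IBDModelParams()) > 1 - 1e-9

    def test_zero_events_is_confident_not_d0(self):
        assert posterior_d0(w("d0", 300, 0), IBDModelParams()) < 1e-9

    def test_all_events_is_d0_despite_extremity(self):
        # error model makes the not-D0 explanation vanishingly unlikely
        assert posterior_d0(w("d0", 300, 300), IBDModelParams()) > 1 - 1e-9

    def test_event_rate_c_is_confident_d1(self):
        params = IBDModelParams()
        p1, _ = posterior_split_d1_d2(w("d12", 300, 155), params, 1.0)
        assert p1 > 1 - 1e-9

    def test_no_ibs1_means_ibd2(self):
        params = IBDModelParams()
        p1, p2 = posterior_split_d1_d2(w("d12", 300, 0), params, 1.0)
        assert p2 > 1 - 1e-9

    def test_conditioning_on_zero_mass(self):
        assert posterior_split_d1_d2(w("d12", 300, 0), IBDModelParams(), 0.0) == (0.0, 0.0)


class TestParamsValidation:
    def test_priors_must_sum_to_one(self):
        with pytest.raises(ValueError, match="priors"):
            IBDModelParams(prior_d0=0.5, prior_d1=0.5, prior_d2=0.5)

    def test_c_bounds(self):
        with pytest.raises(ValueError):
            IBDModelParams(c=0.7)
        with pytest.raises(ValueError):
            IBDModelParams(c=0.005)  # below the error rate


# ---------------------------------------------------------------------------
# Genome-wide estimation

class TestEstimateK:
    def test_duplicate_sample_recovers_k2(self, desk_genome):
        p = scenario("identical", desk_genome, NoiseModel(0.001, 0.005), seed=11)
        k = estimate_k(p.table, p.sample_a, p.sample_b)
        assert k.k2 > 0.999

    def test_parent_child_recovers_k1(self, desk_genome):
        p = scenario("parent_child", desk_genome, seed=12)
        k = estimate_k(p.table, p.sample_a, p.sample_b)
        assert k.k1 > 0.995 and k.k2 < 0.005

    def test_unrelated_recovers_k0_with_low_background(self, desk_genome):
        p = scenario("unrelated", desk_genome, seed=13)
        k = estimate_k(p.table, p.sample_a, p.sample_b)
        assert k.k0 > 0.95 and k.k1 <= 0.03

    def test_posterior_and_k_normalization(self, sib_pairs):
        params = IBDModelParams()
        p = sib_pairs[0]
        tracks = build_tracks(p.table, p.sample_a, p.sample_b)
        prof = ibd_profile(tracks, params)
        total = prof[["p_d0", "p_d1", "p_d2"]].sum(axis=1)
        assert np.allclose(total, 1.0, atol=1e-9)
        k = estimate_k(p.table, p.sample_a, p.sample_b, params)
        assert k.k0 + k.k1 + k.k2 == pytest.approx(1.0, abs=1e-9)

    def test_mean_recovery_matches_realized_truth(self, sib_pairs):
        """Replicate-mean estimates track the realized Cotterman coefficients."""
        est = np.array(
            [estimate_k(p.table, p.sample_a, p.sample_b).as_tuple() for p in sib_pairs]
        )
        real = np.array([p.realized_k for p in sib_pairs])
        assert np.abs(est.mean(0) - real.mean(0)).max() < 0.03

    def test_c_robustness_for_sib_and_parent_child(self, desk_genome, sib_pairs):
        """K1/K2 are insensitive to c across the recommended range c >= 0.25."""
        pairs = [sib_pairs[0], scenario("parent_child", desk_genome, seed=21)]
        for p in pairs:
            ks = [
                estimate_k(p.table, p.sample_a, p.sample_b, IBDModelParams(c=c))
                for c in (0.25, 0.4, 0.518, 0.6)
            ]
            k1s = [k.k1 for k in ks]
            k2s = [k.k2 for k in ks]
            assert max(k1s) - min(k1s) < 0.02
            assert max(k2s) - min(k2s) < 0.02

    def test_window_size_sensitivity(self, sib_pairs):
        """Sibling K2 stays near 0.25 for window sizes 150-600."""
        subset = sib_pairs[:10]
        for ws in (150, 300, 600):
            params = IBDModelParams(window_size=ws)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                k2 = np.mean(
                    [estimate_k(p.table, p.sample_a, p.sample_b, params).k2 for p in subset]
                )
            assert k2 == pytest.approx(0.25, abs=0.05)

    def test_sparse_input_raises_estimation_error(self):
        t = make_table(
            [("m1", "1", 10, "AB", "AB"), ("m2", "1", 20, "AA", "BB")], ["a", "b"]
        )
        with pytest.raises(EstimationError), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            estimate_k(t, "a", "b")

    def test_parameter_recovery_across_relationship_classes(self, desk_genome):
        """Mean (K0,K1,K2) over 20 pairs per class is within 0.03 of the
        realized truth from the simulator's IBD tracks."""
        for name in ("parent_child", "full_sib", "half_sib", "first_cousin"):
            est, real = [], []
            for i in range(20):
                p = scenario(name, desk_genome, seed=1000 + 37 * i)
                est.append(estimate_k(p.table, p.sample_a, p.sample_b).as_tuple())
                real.append(p.realized_k)
            diff = np.abs(np.mean(est, 0) - np.mean(real, 0))
            assert diff.max() < 0.03, f"{name}: {diff}"


# ---------------------------------------------------------------------------
# The c parameter and the conditional IBS table

class TestCParameter:
    def test_empirical_bayes_value(self):
        assert compute_c("empirical_bayes") == pytest.approx(0.518, abs=0.002)

    def test_uniform_prior_against_quadrature_oracle(self):
        # closed-form integrand: f(p) = 2pq/(pq + 1/2)
        oracle, _ = quad(lambda p: 2 * p * (1 - p) / (p * (1 - p) + 0.5), 0, 1)
        assert compute_c("uniform") == pytest.approx(oracle, rel=1e-9)
        assert oracle == pytest.approx(0.479, abs=0.001)

    def test_point_prior_at_half_gives_maximum(self):
        from snpkin.ibd_kcoeff import ibs1_fraction_given_ibd1

        assert ibs1_fraction_given_ibd1(0.5) == pytest.approx(2 / 3)

    def test_unknown_prior_rejected(self):
        with pytest.raises(ValueError):
            compute_c("jeffreys")


class TestIBSGivenIBD:
    @pytest.mark.parametrize("p", [0.1, 0.3, 0.5])
    def test_ibs0_is_one_third_of_informative_under_ibd0(self, p):
        tab = ibs_given_ibd(p)
        frac = tab.loc["IBS0", "IBD0"] / (tab.loc["IBS0", "IBD0"] + tab.loc["IBS2*", "IBD0"])
        assert frac == pytest.approx(1 / 3)

    @pytest.mark.parametrize("p", [0.01, 0.25, 0.8])
    def test_no_ibs0_under_ibd1_or_ibd2(self, p):
        tab = ibs_given_ibd(p)
        assert tab.loc["IBS0", "IBD1"] == 0.0
        assert tab.loc["IBS0", "IBD2"] == 0.0

    def test_values_at_half(self):
        tab = ibs_given_ibd(0.5)
        assert tab.loc["IBS0", "IBD0"] == pytest.approx(0.125)
        assert tab.loc["IBS2*", "IBD2"] == pytest.approx(0.5)

    def test_p_out_of_range(self):
        with pytest.raises(ValueError):
            ibs_given_ibd(1.0)
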