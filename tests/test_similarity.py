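import math

import numpy as np
import pytest

from peptwin.chem import PeptideIon
from peptwin.prediction import FallbackPredictor
from peptwin.similarity import (
    METRICS,
    SimilarityConfig,
    WEIGHT_PRESETS,
    greedy_cosine,
    join_peaks,
    ndotproduct,
    nspectraangle,
)
from peptwin.spectra import PeakList
from peptwin.synth import perturb_spectrum

from conftest import random_peaklist
from oracles import (
    brute_greedy_cosine,
    brute_join_peaks,
    brute_ndotproduct,
    brute_nspectraangle,
)

DA = SimilarityConfig(match_tolerance=0.01, match_ppm=0.0)
UNWEIGHTED = SimilarityConfig(match_tolerance=0.01, match_ppm=0.0,
                              weight_m=1.0, weight_n=0.0)


def random_config(rng):
    return SimilarityConfig(
        match_tolerance=float(rng.uniform(0, 0.5)),
        match_ppm=float(rng.uniform(0, 50)),
        weight_m=float(rng.choice([0.5, 0.6, 1.0])),
        weight_n=float(rng.choice([0.0, 2.0, 3.0])),
    )


class TestJoinPeaks:
    def test_two_close_peaks_matched_extra_unmatched(self):
        a = PeakList([100.000, 150.000], [1, 1])
        b = PeakList([100.001, 149.999, 200.0], [1, 1, 1])
        match = join_peaks(a, b, DA)
        assert match.pairs == ((0, 0), (1, 1))
        assert match.unmatched_a == ()
        assert match.unmatched_b == (2,)

    def test_identical_spectra_fully_matched(self, rng):
        a = random_peaklist(rng)
        match = join_peaks(a, a, DA)
        assert match.pairs == tuple((i, i) for i in range(len(a)))
        assert match.unmatched_a == match.unmatched_b == ()

    def test_closest_candidate_wins(self):
        a = PeakList([100.000], [1])
        b = PeakList([99.996, 100.003], [1, 1])
        match = join_peaks(a, b, SimilarityConfig(match_tolerance=0.005, match_ppm=0.0))
        assert match.pairs == ((0, 1),)

    def test_empty_spectra_allowed(self):
        empty = PeakList([], [])
        match = join_peaks(empty, empty, DA)
        assert match.pairs == ()

    def test_matches_quadratic_oracle_on_random_instances(self, rng):
        """1000 random instances: identical matching, nothing matched twice,
        every match inside the additive tolerance."""
        for _ in range(1000):
            a = random_peaklist(rng)
            b = random_peaklist(rng)
            cfg = random_config(rng)
            match = join_peaks(a, b, cfg)
            expected = brute_join_peaks(a, b, cfg.match_tolerance, cfg.match_ppm)
            assert (match.pairs, match.unmatched_a, match.unmatched_b) == expected
            seen_a = [i for i, _ in match.pairs]
            seen_b = [j for _, j in match.pairs]
            assert len(seen_a) == len(set(seen_a))
            assert len(seen_b) == len(set(seen_b))
            for i, j in match.pairs:
                allowed = cfg.match_tolerance + cfg.match_ppm * 1e-6 * min(a.mz[i], b.mz[j])
                assert abs(a.mz[i] - b.mz[j]) <= allowed


class TestWorkedExamples:
    def test_ndotproduct_hand_value(self):
        a = PeakList([100.0, 200.0], [1, 2])
        b = PeakList([100.0, 200.0], [2, 1])
        assert ndotproduct(a, b, UNWEIGHTED) == pytest.approx(0.64, abs=1e-12)

    def test_nspectraangle_hand_value(self):
        a = PeakList([100.0, 200.0], [1, 2])
        b = PeakList([100.0, 200.0], [2, 1])
        expected = 1 - 2 * math.acos(0.8) / math.pi
        assert nspectraangle(a, b, UNWEIGHTED) == pytest.approx(expected, abs=1e-12)
        assert nspectraangle(a, b, UNWEIGHTED) == pytest.approx(0.5903, abs=1e-4)

    def test_greedy_cosine_one_shared_peak(self):
        a = PeakList([100.0, 200.0], [1, 1])
        b = PeakList([100.0, 300.0], [1, 1])
        assert greedy_cosine(a, b, DA) == pytest.approx(0.5, abs=1e-12)

    @pytest.mark.parametrize("metric", sorted(METRICS))
    def test_identical_spectra_score_one(self, metric, rng):
        s = random_peaklist(rng)
        assert METRICS[metric](s, s, DA) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("metric", sorted(METRICS))
    def test_disjoint_spectra_score_zero(self, metric):
        a = PeakList([100.0, 150.0], [1, 1])
        b = PeakList([300.0, 350.0], [1, 1])
        assert METRICS[metric](a, b, DA) == 0.0

    @pytest.mark.parametrize("metric", sorted(METRICS))
    def test_empty_spectrum_scores_zero(self, metric, rng):
        s = random_peaklist(rng)
        assert METRICS[metric](s, PeakList([], []), DA) == 0.0


class TestOracleEquivalence:
    def test_all_three_metrics_match_bruteforce(self, rng):
        """1000 random spectrum pairs: each metric equals an independently
        coded transcription of its formula to 1e-12."""
        for _ in range(1000):
            a = random_peaklist(rng)
            b = random_peaklist(rng)
            cfg = random_config(rng)
            t, p, m, n = cfg.match_tolerance, cfg.match_ppm, cfg.weight_m, cfg.weight_n
            assert ndotproduct(a, b, cfg) == pytest.approx(
                brute_ndotproduct(a, b, t, p, m, n), abs=1e-12)
            assert nspectraangle(a, b, cfg) == pytest.approx(
                brute_nspectraangle(a, b, t, p, m, n), abs=1e-12)
            assert greedy_cosine(a, b, cfg) == pytest.approx(
                brute_greedy_cosine(a, b, t, p), abs=1e-12)


class TestScoreProperties:
    def test_symmetry_and_bounds(self, rng):
        for _ in range(1000):
            a = random_peaklist(rng, max_peaks=15)
            b = random_peaklist(rng, max_peaks=15)
            cfg = random_config(rng)
            for metric, func in METRICS.items():
                ab = func(a, b, cfg)
                ba = func(b, a, cfg)
                assert abs(ab - ba) < 1e-12, metric
                assert 0.0 <= ab <= 1.0, metric

    def test_weight_presets_known_values(self):
        assert WEIGHT_PRESETS["massbank"] == (0.5, 2.0)
        assert WEIGHT_PRESETS["stein-scott"] == (0.6, 3.0)
        cfg = SimilarityConfig().with_preset("massbank")
        assert (cfg.weight_m, cfg.weight_n) == (0.5, 2.0)

    def test_perturbation_continuity_on_fallback_corpus(self, rng):
        """Jitter every m/z by <= half the 10 ppm tolerance and intensities
        by ~1%: the spectral angle moves by < 0.05 (regression guard)."""
        fp = FallbackPredictor()
        cfg = SimilarityConfig()  # 10 ppm matching
        peptides = ["ELVISLIVESK", "ACDEFGHIKR", "PEPTIDESAMPLER", "WQNYVTSMK"]
        for k, pep in enumerate(peptides):
            spec = fp.predict_spectrum(PeptideIon(pep, 2))
            jittered = perturb_spectrum(spec, mz_jitter_ppm=5.0, intensity_cv=0.01,
                                        seed=1000 + k)
            nsa = nspectraangle(spec.peaks, jittered.peaks, cfg)
            assert nsa > 0.95
            assert abs(1.0 - nsa) < 0.05

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ValueError):
            SimilarityConfig(match_tolerance=-1)

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="metric"):
            SimilarityConfig(metric="euclidean")


class TestMatchmsCrossCheck:
    """matchms implements its own greedy cosine (matched by descending
    intensity product).  On well-separated peaks the matchings coincide, so
    the scores must agree — an independent implementation check."""

    def test_agrees_on_unambiguous_spectra(self, rng):
        matchms = pytest.importorskip("matchms")
        from matchms.similarity import CosineGreedy

        for seed in range(20):
            local = np.random.default_rng(seed)
            # peaks >= 1 Da apart with 0.01 Da tolerance: matching is unambiguous
            mz_a = np.sort(local.choice(np.arange(100, 900), size=12, replace=False)
                           + local.uniform(-0.002, 0.002, 12))
            mz_b = mz_a.copy()
            swap = local.random(12) < 0.4
            mz_b[swap] += 0.5  # move some peaks out of tolerance
            ia = local.uniform(0.1, 1.0, 12)
            ib = local.uniform(0.1, 1.0, 12)
            a = PeakList(mz_a, ia)
            b = PeakList(np.sort(mz_b), ib)
            spec_a = matchms.Spectrum(mz=a.mz.copy(), intensities=a.intensity.copy(),
                                      metadata={"precursor_mz": 500.0})
            spec_b = matchms.Spectrum(mz=b.mz.copy(), intensities=b.intensity.copy(),
                                      metadata={"precursor_mz": 500.0})
            reference = float(CosineGreedy(tolerance=0.01).pair(spec_a, spec_b)["score"])
            ours = greedy_cosine(a, b, DA)
            assert ours == pytest.approx(reference, abs=1e-9)
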