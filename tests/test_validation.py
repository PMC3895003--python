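"""Randomization, baselines, splits, reduced prediction, extrapolation."""

import numpy as np
import pytest

import akernel as ak
from akernel.validation import (alteration_model_overlap, permutation_trials,
                                random_baseline, reduced_classifier_prediction,
                                split_validate, subsample_extrapolation,
                                _classifier, _overlap_fraction)


class TestPermutationTrials:
    def test_reference_overlaps_itself_fully(self, planted):
        m, _ = planted
        ref = _classifier(m.symbols, m.disease_mask, 2.4)
        assert _overlap_fraction(ref, ref) == 1.0

    def test_permuted_labels_lose_most_overlap(self, planted):
        m, _ = planted
        rep = permutation_trials(m, 2.4, n_trials=10, seed=3)
        assert rep.n_trials == 10
        assert ((rep.overlap_fractions >= 0) & (rep.overlap_fractions <= 1)).all()
        # planted signal vanishes under permutation: far below self-overlap
        assert rep.mean < 0.5

    def test_reproducible_given_seed(self, planted):
        m, _ = planted
        a = permutation_trials(m, 2.4, n_trials=5, seed=17)
        b = permutation_trials(m, 2.4, n_trials=5, seed=17)
        assert np.array_equal(a.overlap_fractions, b.overlap_fractions)

    def test_trial_count_validated(self, planted):
        m, _ = planted
        with pytest.raises(ValueError):
            permutation_trials(m, 2.4, n_trials=0)


class TestAlterationModel:
    def test_mean_overlap_one_eighth(self):
        """Three independent equiprobable alterations -> overlap 1/8."""
        rep = alteration_model_overlap(n_loci=10_000, n_trials=50, seed=1)
        se = np.sqrt(0.125 * 0.875 / (10_000 * 50))
        assert abs(rep.mean - 0.125) < 3 * se

    def test_null_permutation_consistent_with_alteration_model(self):
        """Labels independent of genotypes: permutation overlaps match the
        alteration-model distribution within 3 SD."""
        spec = ak.SyntheticSpec(n_cases=100, n_controls=100, n_snps=400,
                                seed=23, missing_rate=0.0,
                                null_p=("uniform", 0.35, 0.65))
        m, _ = ak.generate(spec)
        # low Lambda so the null reference set is populated
        rep = permutation_trials(m, 1.3, n_trials=50, seed=23)
        model = alteration_model_overlap(n_loci=rep.reference_size,
                                         n_trials=50, seed=24)
        # the alteration model idealizes each locus as three fair coins;
        # agreement is expected only within the trial-to-trial spread
        assert abs(rep.mean - model.mean) < 3 * max(rep.sd, model.sd)


class TestRandomBaseline:
    def test_locus_overlap_expectation(self, planted):
        m, _ = planted
        rep = random_baseline(m, 2.4, mode="random-loci-modal",
                              n_trials=200, seed=5)
        L, total = rep.reference_size, m.n_loci
        # modal symbols mostly agree with the reference word, so the matched
        # overlap sits near the hypergeometric locus expectation L/(2M)
        expect = L / total
        se = np.sqrt(expect * (1 - expect) / (L * 200))
        assert abs(rep.mean - expect) < max(5 * se, 0.3 * expect)

    def test_random_symbols_halve_overlap(self):
        spec = ak.SyntheticSpec(n_cases=100, n_controls=100, n_snps=300,
                                seed=31, missing_rate=0.0,
                                null_p=("uniform", 0.45, 0.55))
        m, _ = ak.generate(spec)
        modal = random_baseline(m, 1.2, mode="random-loci-modal",
                                n_trials=150, seed=6)
        rand = random_baseline(m, 1.2, mode="random-loci-random-symbol",
                               n_trials=150, seed=6)
        assert rand.mean == pytest.approx(modal.mean / 2, rel=0.35)

    def test_full_universe_draw_overlaps_on_loci(self, null_matrix):
        # Lambda low enough that every locus is selected: L = 2M, random draw
        # must hit every reference locus; modal symbols then match fully.
        rep = random_baseline(null_matrix, 1.0 + 1e-9, mode="random-loci-modal",
                              n_trials=3, seed=2)
        if rep.reference_size == null_matrix.n_loci:
            assert rep.mean == pytest.approx(1.0, abs=0.05)


class TestSplitValidate:
    def test_planted_signal_predicts_held_out(self, planted):
        m, _ = planted
        rep = split_validate(m, 2.4, train_fraction=0.85, seed=9)
        assert rep.test_error <= 0.25  # planted separation carries over
        assert rep.n_train_d + rep.n_test_d == int(m.disease_mask.sum())

    def test_null_data_test_error_near_half(self):
        spec = ak.SyntheticSpec(n_cases=90, n_controls=90, n_snps=300,
                                seed=41, missing_rate=0.0)
        m, _ = ak.generate(spec)
        rep = split_validate(m, 1.5, train_fraction=0.7, seed=10)
        # binomial band around 0.5 for ~54 held-out samples
        assert 0.25 <= rep.test_error <= 0.75

    def test_degenerate_split_rejected(self, planted):
        m, _ = planted
        with pytest.raises(ValueError):
            split_validate(m, 2.4, train_fraction=1.0)


@pytest.fixture(scope="module")
def strong_planted():
    """Every selected locus carries real signal, so even the bottom-ranked
    subset predicts held-out samples."""
    rng = np.random.default_rng(77)
    risk = ak.synthetic.uniform_risk_loci(rng, 600, 40, 6.0,
                                          p_control_range=(0.35, 0.65))
    spec = ak.SyntheticSpec(n_cases=150, n_controls=150, n_snps=600,
                            risk_loci=risk, seed=77, missing_rate=0.0,
                            null_p=("uniform", 0.3, 0.7))
    m, _ = ak.generate(spec)
    return m


class TestReducedPrediction:
    def test_planted_signal_beats_chance(self, strong_planted):
        rep = reduced_classifier_prediction(strong_planted, 3.0, n_bottom=10,
                                            n_trials=100, seed=13)
        assert rep.rate > 0.5
        assert rep.p_value < 0.05

    def test_null_rate_within_binomial_band(self):
        spec = ak.SyntheticSpec(n_cases=60, n_controls=60, n_snps=150,
                                seed=55, missing_rate=0.0)
        m, _ = ak.generate(spec)
        rep = reduced_classifier_prediction(m, 1.4, n_bottom=20,
                                            n_trials=60, seed=14)
        half_width = 1.96 * np.sqrt(0.25 / 60) + rep.n_ties / 60
        assert abs(rep.rate - 0.5) <= half_width + 0.15

    def test_zero_trials_rejected(self, planted):
        m, _ = planted
        with pytest.raises(ValueError):
            reduced_classifier_prediction(m, 2.4, n_bottom=5, n_trials=0)


class TestSubsampleExtrapolation:
    def test_flat_curve_recovers_plateau(self):
        """Strong planted loci selected at every cohort size: beta ~ 0 and
        L_inf ~ L."""
        rng = np.random.default_rng(61)
        risk = ak.synthetic.uniform_risk_loci(rng, 200, 20, 8.0,
                                              p_control_range=(0.4, 0.6))
        spec = ak.SyntheticSpec(n_cases=150, n_controls=150, n_snps=200,
                                risk_loci=risk, seed=61, missing_rate=0.0,
                                null_p=("uniform", 0.45, 0.55))
        m, _ = ak.generate(spec)
        curve = subsample_extrapolation(m, 3.0, n_repeats=4, seed=15)
        assert curve.mean_L[-1] == pytest.approx(20, abs=3)
        assert curve.L_inf == pytest.approx(curve.mean_L[-1], abs=5)

    def test_asymptote_near_planted_count_when_powered(self):
        """With cohorts large enough that planted loci are selected at
        every fraction, L_inf approaches the planted count."""
        rng = np.random.default_rng(62)
        risk = ak.synthetic.uniform_risk_loci(rng, 800, 40, 4.0,
                                              p_control_range=(0.3, 0.7))
        spec = ak.SyntheticSpec(n_cases=400, n_controls=400, n_snps=800,
                                risk_loci=risk, seed=62, missing_rate=0.0,
                                null_p=("uniform", 0.3, 0.7))
        m, truth = ak.generate(spec)
        curve = subsample_extrapolation(m, 2.4, n_repeats=4, seed=16)
        n_risk = int(truth.is_risk.sum())
        assert curve.rel_residual < 0.1
        assert curve.L_inf == pytest.approx(n_risk, rel=0.5)

    def test_full_fraction_equals_reference(self, planted):
        m, _ = planted
        curve = subsample_extrapolation(m, 2.4, fractions=(1.0,),
                                        n_repeats=2, seed=17)
        ref = _classifier(m.symbols, m.disease_mask, 2.4)
        assert curve.mean_L[0] == ref.selection.size

    def test_invalid_fraction_rejected(self, planted):
        m, _ = planted
        with pytest.raises(ValueError):
            subsample_extrapolation(m, 2.4, fractions=(0.0, 1.0))

    def test_seeded_reproducibility(self, planted):
        m, _ = planted
        a = subsample_extrapolation(m, 2.4, n_repeats=3, seed=8)
        b = subsample_extrapolation(m, 2.4, n_repeats=3, seed=8)
        assert np.array_equal(a.mean_L, b.mean_L) and a.L_inf == b.L_inf
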