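"""Unit and property tests for the pileup simulator and the two classifiers."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest

from hapsomatic import simcore as sc


def exact_posteriors(a, r, success, priors):
    """Exact rational evaluation of the three-class binomial posterior.

    Entirely independent of the log-space implementation: probabilities are
    converted to exact fractions and the posterior is computed with integer
    arithmetic.
    """
    n = a + r
    terms = []
    for p, w in zip(success, priors):
        fp, fw = Fraction(p), Fraction(w)
        terms.append(fw * comb(n, a) * fp**a * (1 - fp) ** (n - a))
    total = sum(terms)
    return [float(t / total) for t in terms]


def exact_unphased(a, r, alpha, epsilon, mu, pi):
    fa, fe = Fraction(alpha), Fraction(epsilon)
    success = ((1 - fe) * fa / 2 + fe * (1 - fa / 2), Fraction(1, 2), fe)
    return exact_posteriors(a, r, success, (mu, pi, 1 - Fraction(mu) - Fraction(pi)))


def exact_phased(a, r, alpha, epsilon, mu, pi):
    fa, fe = Fraction(alpha), Fraction(epsilon)
    success = ((1 - fe) * fa + fe * (1 - fa), 1 - fe, fe)
    return exact_posteriors(a, r, success, (mu, pi, 1 - Fraction(mu) - Fraction(pi)))


class TestClassifiers:
    def test_parameter_validation(self):
        with pytest.raises(sc.ParameterError):
            sc.classify_unphased(1, 1, alpha=1.5, epsilon=0.01, mu=1e-5, pi=1e-3)
        with pytest.raises(sc.ParameterError):
            sc.classify_phased(1, 1, alpha=0.5, epsilon=1.0, mu=1e-5, pi=1e-3)
        with pytest.raises(sc.UndefinedSiteError):
            sc.classify_unphased(0, 0, 0.5, 0.01, 1e-5, 1e-3)

    def test_matches_exact_rational_oracle(self, rng):
        """Log-space posteriors agree with exact integer arithmetic."""
        for _ in range(150):
            n = int(rng.integers(1, 300))
            a = int(rng.integers(0, n + 1))
            alpha = float(rng.uniform(0.05, 0.95))
            eps = float(rng.uniform(1e-4, 0.05))
            got = sc.classify_unphased(a, n - a, alpha, eps, 1e-5, 1e-3)
            want = exact_unphased(a, n - a, alpha, eps, 1e-5, 1e-3)
            np.testing.assert_allclose(
                [got.p_somatic, got.p_het, got.p_reference], want, rtol=1e-6
            )
            got = sc.classify_phased(a, n - a, alpha, eps, 1e-5, 1e-3)
            want = exact_phased(a, n - a, alpha, eps, 1e-5, 1e-3)
            np.testing.assert_allclose(
                [got.p_somatic, got.p_het, got.p_reference], want, rtol=1e-6
            )

    def test_het_success_probability_is_half_for_any_epsilon(self):
        # the error terms cancel: (1-eps)/2 + eps/2 == 1/2
        for eps in (0.0, 1e-3, 0.02, 0.3):
            assert sc.unphased_success_probabilities(0.37, eps)[1] == 0.5

    def test_unphased_worked_example_is_ambiguous(self):
        """12 alt / 17 ref total reads: unphased evidence favours het."""
        post = sc.classify_unphased(12, 17, 0.5, 0.01, 5e-6, 1e-3)
        want = exact_unphased(12, 17, 0.5, 0.01, 5e-6, 1e-3)
        np.testing.assert_allclose(
            [post.p_somatic, post.p_het, post.p_reference], want, rtol=1e-9
        )
        assert post.label == "het"

    def test_phased_worked_example_is_somatic(self):
        """The same site phased: 11 alt / 5 ref on one haplotype is somatic."""
        post = sc.classify_phased(11, 5, 0.5, 0.01, 5e-6, 1e-3)
        assert post.label == "somatic"
        ref_hap = sc.classify_phased(1, 12, 0.5, 0.01, 5e-6, 1e-3)
        assert ref_hap.label == "reference"

    def test_no_alternate_support_is_reference(self):
        assert sc.classify_unphased(0, 50, 0.5, 0.01, 1e-5, 1e-3).label == "reference"

    def test_pure_alternate_haplotype_is_het(self):
        assert sc.classify_phased(30, 0, 0.5, 0.01, 1e-5, 1e-3).label == "het"

    def test_normalization_over_count_grid(self):
        for n in (1, 2, 5, 17, 60, 200, 500):
            a = np.arange(n + 1)
            for alpha, eps in ((0.1, 0.001), (0.5, 0.01), (0.9, 0.05)):
                for fn in (sc.unphased_posteriors, sc.phased_posteriors):
                    post = fn(a, n - a, alpha, eps, 1e-5, 1e-3)
                    np.testing.assert_allclose(post.sum(axis=-1), 1.0, atol=1e-9)

    def test_phased_alpha_one_reduces_to_prior_odds(self):
        """At purity 1 somatic and het likelihoods coincide: odds = mu : pi."""
        mu, pi = 5e-6, 1e-3
        for a, r in ((10, 5), (0, 30), (40, 0)):
            post = sc.classify_phased(a, r, 1.0, 0.01, mu, pi)
            np.testing.assert_allclose(post.p_somatic / post.p_het, mu / pi, rtol=1e-9)

    def test_phased_somatic_posterior_unimodal_in_alt_count(self):
        r = 20
        a = np.arange(0, 120)
        post = sc.phased_posteriors(a, r, 0.5, 0.01, 1e-5, 1e-3)
        p_som = post[:, 0]
        p_ref = post[:, 2]
        assert np.all(np.diff(p_ref) <= 1e-12)
        d = np.diff(p_som)
        peak = int(np.argmax(p_som))
        assert np.all(d[:peak] >= -1e-12)  # rising out of the reference regime
        assert np.all(d[peak:] <= 1e-12)  # falling into the het regime


class TestSimulation:
    def test_rejects_invalid_parameters(self):
        with pytest.raises(sc.ParameterError):
            sc.SimParams(G=0, lam=30, alpha=0.5, epsilon=0.01)
        with pytest.raises(sc.ParameterError):
            sc.SimParams(G=100, lam=30, alpha=0.5, epsilon=0.01, mu=0.6, pi=0.5)

    def test_noise_free_simulation_is_all_reference(self):
        params = sc.SimParams(G=2000, lam=30, alpha=0.7, epsilon=0.0, mu=0.0, pi=0.0, seed=5)
        arrays = sc.simulate_pileup(params)
        assert np.all(arrays.a == 0)
        assert np.all(arrays.label == sc.REF)
        assert arrays.r.sum() > 0

    def test_het_site_count_in_binomial_interval(self):
        params = sc.SimParams(G=1_000_000, lam=30, alpha=0.5, epsilon=0.01, mu=0.0, pi=1e-3, seed=9)
        arrays = sc.simulate_pileup(params)
        n_het = int((arrays.label == sc.HET).sum())
        # Binomial(1e6, 1e-3): 99% interval ~ mean +- 2.58 sd
        assert 1000 - 2.58 * 31.6 < n_het < 1000 + 2.58 * 31.6

    def test_fixed_seed_reproduces_stream(self):
        params = sc.SimParams(G=500, lam=20, alpha=0.5, epsilon=0.02, mu=1e-3, pi=5e-3, seed=42)
        first = list(sc.sim_pileup(params))
        second = list(sc.sim_pileup(params))
        assert first == second

    def test_reference_string_too_short_rejected(self):
        params = sc.SimParams(G=100, lam=20, alpha=0.5, epsilon=0.01)
        with pytest.raises(sc.ParameterError):
            list(sc.sim_pileup(params, reference="ACGT"))

    def test_phased_counts_decompose_unphased_depth(self):
        params = sc.SimParams(G=5000, lam=40, alpha=0.5, epsilon=0.02, mu=1e-3, pi=2e-3, seed=3)
        arrays = sc.simulate_pileup(params)
        # reference-supporting reads split exactly across haplotypes
        np.testing.assert_array_equal(arrays.r, arrays.r0 + arrays.r1)
        # combined modal-alt count is bracketed by the per-haplotype counts
        assert np.all(arrays.a >= np.maximum(arrays.a0, arrays.a1))
        assert np.all(arrays.a <= arrays.a0 + arrays.a1)


class TestEvaluation:
    @pytest.mark.parametrize(
        "truth,pred,expect",
        [
            (["somatic", "het"], ["somatic", "het"], (1.0, 1.0, 1.0)),
            (["reference"] * 4, ["reference"] * 4, (1.0, 1.0, 1.0)),
            (
                ["somatic", "somatic", "somatic", "reference", "het"],
                ["somatic", "somatic", "reference", "somatic", "reference"],
                (2 / 3, 2 / 3, 2 / 3),
            ),
            (["somatic", "reference"], ["reference", "reference"], (0.0, 0.0, 0.0)),
        ],
    )
    def test_precision_recall_f1(self, truth, pred, expect):
        got = sc.evaluate_calls(truth, pred)
        np.testing.assert_allclose(
            (got["precision"], got["recall"], got["f1"]), expect
        )

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sc.evaluate_calls(["het"], ["het", "somatic"])

    def test_f1_interval(self):
        purities = [0.1, 0.2, 0.3, 0.4, 0.5]
        f1s = [0.1, 0.95, 0.99, 0.92, 0.3]
        assert sc.f1_interval(purities, f1s) == (0.2, 0.4)
        assert sc.f1_interval(purities, [0.1] * 5) is None


class TestSweep:
    def test_phased_dominates_unphased_small_sweep(self):
        params = sc.SimParams(
            G=1_000_000, lam=40, alpha=0.5, epsilon=0.01, mu=2e-5, pi=1e-3, seed=17
        )
        table = sc.purity_sweep([40], [0.01], [0.3, 0.5, 0.7], params)
        wide = table.pivot_table(
            index=["depth", "error_rate", "purity"], columns="mode", values="f1"
        )
        assert np.all(wide["phased"] >= wide["unphased"] - 0.02)

    def test_sweep_reports_requested_grid(self):
        params = sc.SimParams(G=50_000, lam=30, alpha=0.5, epsilon=0.01, mu=1e-4, seed=2)
        table = sc.purity_sweep([20, 30], [0.01], [0.4, 0.6], params)
        assert len(table) == 2 * 1 * 2 * 2
        assert set(table.columns) >= {
            "depth", "error_rate", "purity", "mode",
            "precision", "recall", "f1", "n_truth_somatic",
        }

    def test_invalid_purity_grid_rejected(self):
        params = sc.SimParams(G=1000, lam=30, alpha=0.5, epsilon=0.01)
        with pytest.raises(sc.ParameterError):
            sc.purity_sweep([30], [0.01], [0.5, 1.2], params)
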