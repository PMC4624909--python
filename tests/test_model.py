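"""Unit and property tests for the five-stage probability model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, stats

from ednasens import (AssayCalibration, ExtractionModel, SamplingProtocol,
                      StageState, BIGHEAD_CARP, SILVER_CARP, capture_pmf,
                      detection_curve_prob, event_sensitivity,
                      replicate_positive_prob, sample_positive_prob)
from ednasens.model import SurveyModel

GAMMA_PAIRS = [
    ("bighead fluorescence", 1.885, 1.486),
    ("silver fluorescence", 2.092, 2.238),
    ("bighead sequencing", 0.877, 41.631),
    ("silver sequencing", 0.289, 6.968),
]


class TestCapturePmf:
    @pytest.mark.parametrize("n, conc, vol, expected", [
        (0, 10.0, 2.0, np.exp(-20.0)),
        (2, 0.5, 2.0, np.exp(-1.0) / 2.0),   # mu = 1
        (1, 1.0, 1.0, np.exp(-1.0)),
    ])
    def test_closed_forms(self, n, conc, vol, expected):
        assert capture_pmf(n, conc, vol) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("mu", [0.1, 1.0, 10.0, 1000.0])
    def test_sums_to_one(self, mu):
        """Total mass over the 1 - 1e-12 quantile window is 1 to 1e-10."""
        hi = int(stats.poisson.ppf(1 - 1e-12, mu)) + 1
        total = capture_pmf(np.arange(hi + 1), mu, 1.0).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            capture_pmf(0, -1.0, 2.0)
        with pytest.raises(ValueError):
            capture_pmf(-1, 1.0, 2.0)
        with pytest.raises(ValueError):
            capture_pmf(0, 1.0, 0.0)


class TestDetectionCurve:
    @pytest.mark.parametrize("name, alpha, beta", GAMMA_PAIRS)
    @pytest.mark.parametrize("n", [1, 2, 5, 10, 50, 100])
    def test_matches_density_quadrature(self, name, alpha, beta, n):
        """The curve equals the integral of the gamma density on [0, n]."""
        dens = lambda x: stats.gamma.pdf(x, alpha, scale=beta)
        expected, err = integrate.quad(dens, 0.0, n, limit=500,
                                       epsabs=1e-10, epsrel=1e-10,
                                       points=[0.0] if alpha < 1 else None)
        assert err < 1e-7
        assert detection_curve_prob(n, alpha, beta) == pytest.approx(
            expected, abs=1e-6)

    def test_zero_copies_zero_probability(self):
        for _, a, b in GAMMA_PAIRS:
            assert detection_curve_prob(0, a, b) == 0.0

    @pytest.mark.parametrize("name, alpha, beta", GAMMA_PAIRS)
    def test_nondecreasing_and_saturating(self, name, alpha, beta):
        n = np.arange(0, 500)
        p = detection_curve_prob(n, alpha, beta)
        assert np.all(np.diff(p) >= 0)
        assert 0 <= p[0] and p[-1] <= 1
        assert detection_curve_prob(1e6, alpha, beta) == pytest.approx(1.0, abs=1e-9)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            detection_curve_prob(1, -1.0, 2.0)
        with pytest.raises(ValueError):
            detection_curve_prob(1, 1.0, 0.0)
        with pytest.raises(ValueError):
            detection_curve_prob(-1, 1.0, 1.0)


class TestReplicatePositiveProb:
    def test_zero_concentration(self, bighead):
        assert replicate_positive_prob(0.0, 1.0, bighead) == 0.0

    def test_matches_brute_force_sum(self, bighead):
        """Truncated sum agrees with an extended sum to n = 200."""
        mu = 2.0
        n = np.arange(201)
        brute = float(stats.poisson.pmf(n, mu)
                      @ (bighead.fluorescence_prob(n) * bighead.sequencing_prob(n)))
        assert replicate_positive_prob(2.0, 1.0, bighead) == pytest.approx(
            brute, abs=1e-10)

    def test_monotone_in_concentration(self, bighead):
        assert (replicate_positive_prob(1.0, 1.0, bighead)
                <= replicate_positive_prob(2.0, 1.0, bighead))

    def test_expected_basis_is_curve_product(self, silver):
        mu = 3.7
        val = replicate_positive_prob(mu, 1.0, silver, basis="expected")
        assert val == pytest.approx(
            float(silver.fluorescence_prob(mu) * silver.sequencing_prob(mu)),
            rel=1e-12)

    def test_aliquot_volume_scales_mean(self, bighead):
        assert replicate_positive_prob(1.0, 2.0, bighead) == pytest.approx(
            replicate_positive_prob(2.0, 1.0, bighead), rel=1e-9)


class TestSamplePositiveProb:
    def test_zero_concentration(self, baseline, bighead, extraction):
        for mode in ("expected", "realized", "independent"):
            assert sample_positive_prob(0.0, baseline, bighead, extraction,
                                        mode=mode) == 0.0

    def test_degenerate_extraction_closed_form(self, bighead):
        """With a point-mass efficiency and k=1 the model collapses to
        a single Poisson mixture over the capture count."""
        phi0 = 0.15
        proto = SamplingProtocol(n_samples=1, sample_volume_l=2.0,
                                 elution_volume_ul=100.0, n_replicates=1)
        degen = ExtractionModel(phi0, phi0, phi0)
        conc = 500.0
        mu_ns = conc * proto.sample_volume_l
        ns = np.arange(int(stats.poisson.ppf(1 - 1e-14, mu_ns)) + 2)
        closed = float(stats.poisson.pmf(ns, mu_ns)
                       @ replicate_positive_prob(phi0 * ns / 100.0, 1.0, bighead))
        got = sample_positive_prob(conc, proto, bighead, degen, mode="realized")
        assert got == pytest.approx(closed, abs=1e-8)

    def test_k1_realized_equals_independent(self, bighead, extraction):
        """With one replicate the hierarchical and independent compositions
        are algebraically identical."""
        proto = SamplingProtocol(n_replicates=1)
        a = sample_positive_prob(300.0, proto, bighead, extraction, mode="realized")
        b = sample_positive_prob(300.0, proto, bighead, extraction, mode="independent")
        assert a == pytest.approx(b, rel=1e-10)

    def test_independent_exceeds_hierarchical(self, baseline, bighead, extraction):
        """Ignoring within-sample correlation overstates sensitivity."""
        c = 400.0
        hier = sample_positive_prob(c, baseline, bighead, extraction, mode="realized")
        indep = sample_positive_prob(c, baseline, bighead, extraction,
                                     mode="independent")
        assert indep >= hier

    @pytest.mark.parametrize("mode", ["expected", "realized"])
    def test_monotone_in_concentration_k_and_volume(self, bighead, extraction, mode):
        base = SamplingProtocol.baseline()
        p1 = sample_positive_prob(200.0, base, bighead, extraction, mode=mode)
        p2 = sample_positive_prob(400.0, base, bighead, extraction, mode=mode)
        assert p2 >= p1
        more_reps = base.replace(n_replicates=12)
        assert sample_positive_prob(200.0, more_reps, bighead, extraction,
                                    mode=mode) >= p1
        more_volume = base.replace(sample_volume_l=3.0)
        assert sample_positive_prob(200.0, more_volume, bighead, extraction,
                                    mode=mode) >= p1

    def test_inhibition_reduces_sensitivity(self, baseline, silver, extraction):
        full = sample_positive_prob(200.0, baseline, silver, extraction)
        inhibited = sample_positive_prob(200.0, baseline, silver, extraction,
                                         inhibition_factor=0.5)
        assert 0 < inhibited < full

    def test_probabilities_in_unit_interval(self, baseline, silver, extraction):
        for c in (0.01, 1.0, 100.0, 1e4, 1e6):
            for mode in ("expected", "realized", "independent"):
                p = sample_positive_prob(c, baseline, silver, extraction, mode=mode)
                assert 0.0 <= p <= 1.0


class TestEventSensitivity:
    @pytest.mark.parametrize("p, n, expected", [
        (0.0, 10, 0.0),
        (0.5, 2, 0.75),
        (0.258, 10, 1.0 - 0.742 ** 10),
        (1.0, 3, 1.0),
    ])
    def test_closed_forms(self, p, n, expected):
        assert event_sensitivity(p, n) == pytest.approx(expected, rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            event_sensitivity(1.5, 10)
        with pytest.raises(ValueError):
            event_sensitivity(0.5, 0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(p=st.floats(0.0, 1.0), n=st.integers(1, 200), m=st.integers(0, 50))
    def test_monotone_in_both_arguments(self, p, n, m):
        s = event_sensitivity(p, n)
        assert 0.0 <= s <= 1.0
        assert event_sensitivity(p, n + m) >= s
        assert event_sensitivity(min(1.0, p + 0.1), n) >= s


class TestDomainTypes:
    def test_assay_validation(self):
        with pytest.raises(ValueError):
            AssayCalibration("bad", 0.0, 1.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            AssayCalibration("bad", 1.0, 1.0, 1.0, -2.0)

    def test_default_assays(self):
        assert (BIGHEAD_CARP.alpha_f, BIGHEAD_CARP.beta_f) == (1.885, 1.486)
        assert (SILVER_CARP.alpha_s, SILVER_CARP.beta_s) == (0.289, 6.968)

    def test_protocol_invariants(self):
        base = SamplingProtocol.baseline()
        assert (base.n_samples, base.sample_volume_l) == (10, 2.0)
        assert (base.elution_volume_ul, base.aliquot_volume_ul,
                base.n_replicates) == (100.0, 1.0, 8)
        with pytest.raises(ValueError):
            SamplingProtocol(n_samples=0)
        with pytest.raises(ValueError):
            SamplingProtocol(aliquot_volume_ul=20.0, n_replicates=8,
                             elution_volume_ul=100.0)

    def test_extraction_validation_and_quadrature(self):
        with pytest.raises(ValueError):
            ExtractionModel(0.2, 0.1, 0.3)
        ex = ExtractionModel()
        nodes, weights = ex.quadrature()
        assert weights.sum() == pytest.approx(1.0, abs=1e-12)
        assert nodes @ weights == pytest.approx(ex.mean, abs=1e-12)
        degen = ExtractionModel(0.1, 0.1, 0.1)
        n, w = degen.quadrature()
        assert (n.tolist(), w.tolist()) == ([0.1], [1.0])

    def test_stage_state_chain(self):
        s = StageState(n_captured=40, efficiency=0.15)
        assert s.n_eluted == pytest.approx(6.0)
        assert s.elution_conc == pytest.approx(0.06)
        with pytest.raises(ValueError):
            StageState(n_captured=-1, efficiency=0.5)

    def test_survey_model_facade(self, bighead):
        m = SurveyModel(assay=bighead)
        assert 0.0 <= m.sensitivity(100.0) <= 1.0
        m2 = m.with_protocol(n_samples=20)
        assert m2.protocol.n_samples == 20
        assert m2.sensitivity(100.0) >= m.sensitivity(100.0)
        with pytest.raises(ValueError):
            SurveyModel(assay=bighead, mode="bogus")
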