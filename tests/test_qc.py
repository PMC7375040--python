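import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crseawater import (GeneratorConfig, SeawaterSample, aggregate_diel,
                        detect_diel_cycle, generate_survey,
                        modified_thompson_tau)
from crseawater.qc import DielGroup, thompson_tau_critical


def _sample(v, t=None, station="S1", depth=10.0):
    return SeawaterSample(station_id=station, depth=depth, cr_total=3.0,
                          cr3=v, time_local=t)


class TestModifiedThompsonTau:
    def test_zero_variance_keeps_everything(self):
        assert not modified_thompson_tau([0.10] * 4).any()

    def test_flags_single_gross_outlier(self):
        """Hand check: n=4, t(0.975, 2)=4.303 gives tau=1.425; the 0.45
        deviates 0.2625 > tau*sd = 0.250, and the remaining three are
        clean at the n=3 threshold."""
        mask = modified_thompson_tau([0.10, 0.11, 0.09, 0.45], alpha=0.05)
        assert list(mask) == [False, False, False, True]

    def test_critical_value_formula(self):
        """Textbook calibration, n=4: t(0.975, 2) = 4.30265 gives
        tau = t*3 / (2*sqrt(2+t^2)) = 1.4250; the default Bonferroni
        calibration for the group maximum is strictly larger."""
        assert thompson_tau_critical(4, 0.05, bonferroni=False) == \
            pytest.approx(1.4250, abs=2e-4)
        assert thompson_tau_critical(4, 0.05) > \
            thompson_tau_critical(4, 0.05, bonferroni=False)

    def test_too_few_points_rejects_nothing(self):
        assert not modified_thompson_tau([0.1, 9.9]).any()

    # values rounded to a sane granularity so the affine transform does
    # not collapse distinct inputs through float rounding
    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.floats(-1e3, 1e3).map(lambda v: round(v, 4)),
                    min_size=3, max_size=20),
           st.floats(0.01, 100).map(lambda v: round(v, 3)),
           st.floats(-50, 50).map(lambda v: round(v, 3)),
           st.randoms(use_true_random=False))
    def test_scale_and_permutation_equivariance(self, xs, a, b, rnd):
        """The outlier mask is unchanged by affine transforms and follows
        a permutation of the input."""
        base = modified_thompson_tau(xs)
        assert list(modified_thompson_tau([a * x + b for x in xs])) == list(base)
        idx = list(range(len(xs)))
        rnd.shuffle(idx)
        perm = modified_thompson_tau([xs[i] for i in idx])
        assert [perm[k] for k in range(len(xs))] == [base[i] for i in idx]

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=25))
    def test_rejects_at_most_half(self, xs):
        assert modified_thompson_tau(xs).sum() <= math.ceil(len(xs) / 2)

    def test_clean_gaussian_rejection_rate_below_alpha(self, rng):
        """On uncontaminated Gaussian replicate sets the fraction of
        rejected points stays below the test's significance level."""
        flagged = total = 0
        for _ in range(400):
            x = rng.normal(0.2, 0.02, 10)
            flagged += modified_thompson_tau(x, alpha=0.05).sum()
            total += x.size
        assert flagged / total <= 0.05

    def test_contaminated_generator_rate_matches_contamination(
            self, default_config, survey):
        """Rejection rate on generator defaults tracks the 10% one-sided
        contamination rate."""
        samples, _, _ = survey
        groups = aggregate_diel([s for s in samples], alpha=0.05)
        big = [g for g in groups if g.n >= 5]
        flagged = sum(sum(g.outlier_mask) for g in big)
        total = sum(g.n for g in big)
        assert flagged / total == pytest.approx(
            default_config.contamination_rate, abs=0.04)


class TestAggregateDiel:
    def test_identical_values(self):
        (g,) = aggregate_diel([_sample(0.2) for _ in range(4)])
        assert g.mean == 0.2 and g.sd == 0.0

    def test_single_value_gets_default_relative_uncertainty(self):
        (g,) = aggregate_diel([_sample(0.20)])
        assert g.mean == 0.20
        assert g.sd == pytest.approx(0.020)

    def test_mean_recovers_generator_truth(self, survey):
        samples, _, truths = survey
        truth = {(t.station_id, d): c for t in truths
                 for d, c in zip(t.depths, t.cr3)}
        groups = aggregate_diel(list(samples))
        for g in groups:
            if g.n >= 5:
                assert abs(g.mean - truth[(g.station_id, g.depth)]) <= \
                    max(g.sd, 1e-6) * 1.5

    def test_replicated_samples_get_flag(self):
        samples = [_sample(0.2), _sample(0.21)]
        aggregate_diel(samples)
        assert all("diel_replicated" in s.flags for s in samples)

    def test_by_day_splits_groups(self):
        samples = [_sample(0.2), _sample(0.3)]
        samples[0].day, samples[1].day = 1, 2
        assert len(aggregate_diel(samples, by_day=True)) == 2


class TestDetectDielCycle:
    def _group(self, values, times):
        g = DielGroup(station_id="S", depth=10.0, values=list(values),
                      times=list(times), outlier_mask=[False] * len(values))
        return g

    def test_flat_series_not_significant(self, rng):
        t = np.linspace(0, 48, 12)
        g = self._group(0.2 + rng.normal(0, 0.02, 12), t)
        fit = detect_diel_cycle(g)
        assert not fit.significant and fit.p_value > 0.05

    def test_injected_sinusoid_recovered(self, rng):
        t = np.linspace(0, 48, 16)
        x = 0.3 + 0.2 * np.cos(2 * np.pi * t / 24.0) + rng.normal(0, 0.02, 16)
        fit = detect_diel_cycle(self._group(x, t))
        assert fit.significant and fit.p_value < 0.01
        assert fit.amplitude == pytest.approx(0.2, abs=0.05)

    def test_insufficient_coverage_raises(self):
        with pytest.raises(ValueError):
            detect_diel_cycle(self._group([1, 2, 3], [0, 6, 12]))

    def test_null_false_positive_rate_near_alpha(self, rng):
        """Monte-Carlo calibration: on a flat truth the F-test fires at
        roughly its nominal level."""
        hits = 0
        n_sim = 300
        t = np.linspace(0, 48, 12)
        for _ in range(n_sim):
            g = self._group(0.2 + rng.normal(0, 0.02, 12), t)
            if detect_diel_cycle(g).p_value < 0.05:
                hits += 1
        assert hits / n_sim == pytest.approx(0.05, abs=0.035)
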