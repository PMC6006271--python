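import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from barrelsim import StimulusSpec
from barrelsim.discrimination import (
    DirectionClassifier,
    UnfittableError,
    accuracy_report,
    classify_direction,
    classify_velocity,
    direction_quotient,
    fit_direction_classifier,
    fit_velocity_classifier,
)
from barrelsim.dynamics import TrialResult


def _trial(rs_spikes, n_rs=160):
    return TrialResult(
        fs_spikes={},
        rs_spikes={c: np.asarray(ts, dtype=float) for c, ts in rs_spikes.items()},
        peak_tc_current=np.zeros(n_rs),
        peak_fs_current=np.zeros(n_rs),
        stimulus=StimulusSpec(0, 1.0),
        adapted=False,
        seed=0,
        n_rs=n_rs,
    )


class TestVelocityClassifier:
    def test_midpoint_cutoffs(self):
        clf = fit_velocity_classifier({1.0: [100], 1.25: [80]})
        np.testing.assert_allclose(clf.cutoffs, [90.0])

    def test_five_classes_four_cutoffs(self):
        clf = fit_velocity_classifier({s: [m] for s, m in
                                       zip([1.0, 1.25, 1.5, 1.75, 2.0], [100, 80, 60, 40, 20])})
        assert len(clf.cutoffs) == 4
        assert clf.monotone

    def test_degenerate_means_flagged(self):
        clf = fit_velocity_classifier({1.0: [50], 1.25: [50]})
        assert not clf.monotone
        np.testing.assert_allclose(clf.cutoffs, [50.0])

    def test_extremes_and_tie_rule(self):
        clf = fit_velocity_classifier({s: [m] for s, m in
                                       zip([1.0, 1.25, 1.5, 1.75, 2.0], [100, 80, 60, 40, 20])})
        assert classify_velocity(500, clf) == 1.0  # above all cutoffs
        assert classify_velocity(0, clf) == 2.0  # below all cutoffs
        # a count exactly on a cutoff goes to the lower-velocity side
        assert classify_velocity(90, clf) == 1.25

    def test_hand_enumerated_accuracy(self):
        """Counts {A: 10, 10; B: 20, 20} give cutoff 15 and accuracy 1."""
        clf = fit_velocity_classifier({1.0: [20, 20], 2.0: [10, 10]})
        np.testing.assert_allclose(clf.cutoffs, [15.0])
        outcomes = [classify_velocity(c, clf) == s
                    for s, counts in {1.0: [20, 20], 2.0: [10, 10]}.items()
                    for c in counts]
        assert all(outcomes)

    @given(st.integers(0, 200))
    @settings(max_examples=50, derandomize=True)
    def test_every_count_maps_to_exactly_one_class(self, count):
        clf = fit_velocity_classifier({s: [m] for s, m in
                                       zip([1.0, 1.25, 1.5, 1.75, 2.0], [100, 80, 60, 40, 20])})
        assert classify_velocity(count, clf) in clf.sigmas


class TestDirectionQuotient:
    def test_all_spikes_in_target_domain_score_eight(self, wiring):
        for n in (1, 3):
            cells = wiring.rs_cells_in_domain(0)[:n]
            t = _trial({int(c): [10.0] for c in cells})
            assert direction_quotient(t, wiring, (0,)) == pytest.approx(8.0)

    def test_uniform_spikes_score_one(self, wiring):
        t = _trial({c: [10.0] for c in range(160)})
        assert direction_quotient(t, wiring, (0,)) == pytest.approx(1.0)

    def test_silent_cortex_is_undefined(self, wiring):
        assert math.isnan(direction_quotient(_trial({}), wiring, (0,)))

    def test_competitor_pool_uses_both_domains(self, wiring):
        cells = list(wiring.rs_cells_in_domain(45)[:2]) + list(
            wiring.rs_cells_in_domain(315)[:2]
        )
        t = _trial({int(c): [10.0] for c in cells})
        assert direction_quotient(t, wiring, (45, 315)) == pytest.approx(4.0)


class TestDirectionClassifier:
    def test_cutoff_is_midpoint(self, wiring):
        target = _trial({int(c): [10.0] for c in wiring.rs_cells_in_domain(0)[:4]})
        mixed = _trial({c: [10.0] for c in range(160)})
        clf = fit_direction_classifier([target, mixed], wiring)
        assert clf.cutoff == pytest.approx((clf.target_mean + clf.competitor_mean) / 2)
        assert clf.competitor_mean < clf.cutoff < clf.target_mean

    def test_undefined_training_trials_excluded(self, wiring):
        target = _trial({int(c): [10.0] for c in wiring.rs_cells_in_domain(0)[:4]})
        clf_with = fit_direction_classifier([target, _trial({})], wiring)
        clf_without = fit_direction_classifier([target], wiring)
        assert clf_with.cutoff == pytest.approx(clf_without.cutoff)

    def test_unfittable_on_silent_training_set(self, wiring):
        with pytest.raises(UnfittableError):
            fit_direction_classifier([_trial({}), _trial({})], wiring)

    def test_strict_exceedance_rule(self, wiring):
        clf = DirectionClassifier(0, (45, 315), cutoff=8.0)
        target_only = _trial({int(wiring.rs_cells_in_domain(0)[0]): [10.0]})
        assert classify_direction(target_only, clf, wiring) is False  # quotient == cutoff
        clf_low = DirectionClassifier(0, (45, 315), cutoff=3.0)
        assert classify_direction(target_only, clf_low, wiring) is True

    def test_silent_trial_returns_none(self, wiring):
        clf = DirectionClassifier(0, (45, 315), cutoff=3.0)
        assert classify_direction(_trial({}), clf, wiring) is None


class TestAccuracyReport:
    def test_aggregate_is_weighted_mean(self):
        rep = accuracy_report({1.0: 0.5, 2.0: 1.0}, {1.0: 100, 2.0: 300})
        assert rep["aggregate"] == pytest.approx((0.5 * 100 + 1.0 * 300) / 400)
        assert rep["n_trials"] == 400

    @given(
        accs=st.lists(st.floats(0, 1), min_size=2, max_size=5),
        ns=st.lists(st.integers(1, 500), min_size=5, max_size=5),
    )
    @settings(max_examples=30, derandomize=True)
    def test_aggregate_bounded_by_class_extremes(self, accs, ns):
        per = {i: a for i, a in enumerate(accs)}
        n = {i: ns[i] for i in per}
        rep = accuracy_report(per, n)
        assert min(accs) - 1e-12 <= rep["aggregate"] <= max(accs) + 1e-12
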