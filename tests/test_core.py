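"""Unit and property tests for the learning/performance equations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heidi import (
    AssociativeState,
    ConfigurationError,
    DegenerateInputError,
    LinkMatrix,
    SubjectParams,
    ValidationError,
    combine,
    decay_alpha,
    distribute,
    learning_update,
    response_vector,
)
from conftest import closed_form_backward, closed_form_forward, iterate_acquisition

unit = st.floats(0.0, 1.0, allow_nan=False)
salience = st.floats(0.01, 1.0, allow_nan=False)


class TestLearningUpdate:
    def test_first_reinforced_trial_updates_both_directions(self):
        params = SubjectParams(alpha={"CS": 0.3}, beta={"US": 0.5})
        state = learning_update(
            AssociativeState.zeros(("CS", "US")), {"CS", "US"}, params
        )
        assert state.v("CS", "US") == pytest.approx(0.15)
        assert state.v("US", "CS") == pytest.approx(0.15)

    def test_cs_alone_extinguishes_forward_but_freezes_backward(self):
        params = SubjectParams(alpha={"CS": 0.3}, beta={"US": 0.5})
        state = AssociativeState(("CS", "US"), {("CS", "US"): 0.5, ("US", "CS"): 0.2})
        out = learning_update(state, {"CS"}, params)
        assert out.v("CS", "US") == pytest.approx(0.5 + 0.3 * (0.0 - 0.5))
        assert out.v("US", "CS") == 0.2  # US absent: rate term zeroed

    def test_us_alone_extinguishes_backward(self):
        params = SubjectParams(alpha={"CS": 0.3}, beta={"US": 0.5})
        state = AssociativeState(("CS", "US"), {("US", "CS"): 0.2})
        out = learning_update(state, {"US"}, params)
        # CS absent: its asymptote term c*alpha*[present] is 0
        assert out.v("US", "CS") == pytest.approx(0.2 + 0.5 * (0.0 - 0.2))

    def test_empty_present_set_is_noop(self):
        params = SubjectParams(alpha={"CS": 0.3}, beta={"US": 0.5})
        state = AssociativeState(("CS", "US"), {("CS", "US"): 0.4})
        assert learning_update(state, set(), params) == state

    def test_updates_applied_simultaneously_from_pretrial_state(self):
        # compound A+B with US: both elements see the same pooled error
        params = SubjectParams(alpha={"A": 0.4, "B": 0.4}, beta={"US": 0.5})
        state = AssociativeState.zeros(("A", "B", "US"))
        out = learning_update(state, {"A", "B", "US"}, params)
        assert out.v("A", "US") == pytest.approx(out.v("B", "US"))
        assert out.v("A", "US") == pytest.approx(0.4 * 0.5)

    def test_compound_converges_to_shared_asymptote(self):
        params = SubjectParams(alpha={"A": 0.4, "B": 0.4}, beta={"US": 0.5})
        state = AssociativeState.zeros(("A", "B", "US"))
        for _ in range(300):
            state = learning_update(state, {"A", "B", "US"}, params)
        total = state.v("A", "US") + state.v("B", "US")
        assert total == pytest.approx(0.5, abs=1e-9)

    def test_overshadowing_halves_each_element(self):
        # brute-force oracle: single-CS training reaches c*beta; each
        # element of an equal-salience compound reaches half of that
        params = SubjectParams(alpha={"A": 0.4, "B": 0.4}, beta={"US": 0.5})
        state = AssociativeState.zeros(("A", "B", "US"))
        for _ in range(500):
            state = learning_update(state, {"A", "B", "US"}, params)
        single, _ = iterate_acquisition(0.4, 0.5, 1.0, 500)
        assert state.v("A", "US") == pytest.approx(single.v("CS", "US") / 2, abs=1e-9)

    def test_unknown_stimulus_raises(self):
        params = SubjectParams(alpha={"CS": 0.3}, beta={"US": 0.5})
        with pytest.raises(ConfigurationError):
            learning_update(
                AssociativeState.zeros(("CS", "US")), {"CS", "NOISE"}, params
            )

    def test_terminal_alpha_overrides_rate_and_backward_asymptote(self):
        params = SubjectParams(alpha={"CS": 0.5}, beta={"US": 0.5})
        out = learning_update(
            AssociativeState.zeros(("CS", "US")),
            {"CS", "US"},
            params,
            alpha_terminal={"CS": 0.25},
        )
        assert out.v("CS", "US") == pytest.approx(0.25 * 0.5)
        assert out.v("US", "CS") == pytest.approx(0.5 * 0.25)


class TestClosedFormOracle:
    @pytest.mark.parametrize("alpha", [0.1, 0.3, 0.5, 0.7, 0.9])
    @pytest.mark.parametrize("beta", [0.1, 0.3, 0.5, 0.7, 0.9])
    def test_iterates_match_closed_form_every_trial(self, alpha, beta):
        _, history = iterate_acquisition(alpha, beta, 1.0, 100)
        for n, (vf, vb) in enumerate(history, start=1):
            assert vf == pytest.approx(
                closed_form_forward(alpha, beta, 1.0, n), abs=1e-12
            )
            assert vb == pytest.approx(
                closed_form_backward(alpha, beta, 1.0, n), abs=1e-12
            )

    @pytest.mark.parametrize("alpha,beta", [(0.3, 0.5), (0.7, 0.5), (0.5, 0.7)])
    def test_asymptotes_are_c_beta_and_c_alpha(self, alpha, beta):
        c = 2.0
        state, _ = iterate_acquisition(alpha, beta, c, 600)
        assert state.v("CS", "US") == pytest.approx(c * beta, abs=1e-6)
        assert state.v("US", "CS") == pytest.approx(c * alpha, abs=1e-6)

    def test_acquisition_strictly_increasing_and_bounded(self):
        _, history = iterate_acquisition(0.3, 0.5, 1.0, 50)
        vf = [v for v, _ in history]
        assert all(b > a for a, b in zip(vf, vf[1:]))
        assert all(v <= 0.5 for v in vf)


class TestCombine:
    def test_hand_example(self):
        assert combine(0.5, 0.5, 1.0) == pytest.approx(0.75)

    def test_zero_forward_gates_backward(self):
        assert combine(0.0, 0.9) == 0.0

    def test_zero_backward_reduces_to_forward(self):
        assert combine(0.5, 0.0, 1.0) == 0.5

    @given(vf=st.floats(-1, 1), vb=st.floats(-1, 1), c=st.floats(0.5, 3))
    @settings(deadline=None)
    def test_c_scales_only_the_interaction(self, vf, vb, c):
        assert combine(vf, vb, c) == pytest.approx(vf + vf * vb / c)


class TestDistribute:
    def test_symmetric_split_when_alpha_matches_retrieved_salience(self):
        r_cs, r_us = distribute(0.75, 0.5, 0.5, 1.0)
        assert r_cs == pytest.approx(r_us) == pytest.approx(0.375)

    def test_hand_example(self):
        r_cs, r_us = distribute(0.75, 0.7, 0.5, 1.0)
        assert r_cs == pytest.approx(0.4375)
        assert r_us == pytest.approx(0.3125)

    def test_degenerate_zero_zero_raises(self):
        with pytest.raises(DegenerateInputError):
            distribute(0.0, 0.0, 0.0)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValidationError):
            distribute(0.5, -0.1, 0.5)

    @given(
        vcomb=st.floats(-2, 2, allow_nan=False),
        alpha=unit,
        vf=st.floats(-1, 1, allow_nan=False),
        c=st.floats(0.5, 3),
    )
    @settings(deadline=None, max_examples=300)
    def test_conservation_and_sign(self, vcomb, alpha, vf, c):
        if alpha == 0 and vf == 0:
            return
        r_cs, r_us = distribute(vcomb, alpha, vf, c)
        assert r_cs + r_us == pytest.approx(vcomb, abs=1e-12)
        # both components share V_COMB's sign (or are zero)
        assert r_cs * vcomb >= 0 and r_us * vcomb >= 0

    def test_absolute_value_used_for_negative_forward_strength(self):
        # a net inhibitory forward link still yields proportions in [0, 1]
        r_cs, r_us = distribute(-0.2, 0.5, -0.5, 1.0)
        assert r_cs == pytest.approx(-0.1)
        assert r_us == pytest.approx(-0.1)


class TestResponseVector:
    def test_zero_components_give_zero_vigor(self):
        assert np.all(response_vector(0.0, 0.0, LinkMatrix()) == 0)

    def test_identity_link(self):
        links = LinkMatrix(cs_links=(1, 0, 0, 0, 0, 0), us_links=(0,) * 6)
        assert response_vector(1.0, 0.0, links, 1.0)[0] == 1.0

    def test_hand_example(self):
        links = LinkMatrix(cs_links=(0.9,) * 6, us_links=(0.3,) * 6)
        r = response_vector(0.4, 0.2, links, 1.0)
        assert r[0] == pytest.approx(0.42)

    def test_default_links_make_r1_sign_dominant_and_r4_goal_dominant(self):
        links = LinkMatrix()
        assert links.cs_links[0] > links.us_links[0]
        assert links.us_links[3] > links.cs_links[3]

    def test_invalid_links_rejected(self):
        with pytest.raises(ValidationError):
            LinkMatrix(cs_links=(1, 2, 3), us_links=(0,) * 6)
        with pytest.raises(ValidationError):
            LinkMatrix(cs_links=(-1, 0, 0, 0, 0, 0), us_links=(0,) * 6)


class TestDecayAlpha:
    def test_epoch_one_is_reset_value(self):
        assert decay_alpha(0.5, 1, 0.81) == 0.5

    def test_hand_example(self):
        assert decay_alpha(0.5, 2, 0.81) == pytest.approx(0.405)

    def test_no_decay_limit(self):
        assert decay_alpha(0.5, 7, 1.0) == 0.5

    def test_invalid_epoch_rejected(self):
        with pytest.raises(ValidationError):
            decay_alpha(0.5, 0)

    @given(alpha=unit, epoch=st.integers(1, 10))
    @settings(deadline=None)
    def test_monotone_in_epoch(self, alpha, epoch):
        assert decay_alpha(alpha, epoch + 1, 0.81) <= decay_alpha(alpha, epoch, 0.81)


class TestParamsValidation:
    def test_salience_outside_unit_interval_rejected(self):
        with pytest.raises(ValidationError):
            SubjectParams(alpha={"CS": 1.2}, beta={"US": 0.5})
        with pytest.raises(ValidationError):
            SubjectParams(alpha={"CS": 0.5}, beta={"US": -0.1})

    def test_nonpositive_c_rejected(self):
        with pytest.raises(ValidationError):
            SubjectParams(alpha={"CS": 0.5}, beta={"US": 0.5}, c=0.0)

    def test_decay_outside_half_open_interval_rejected(self):
        for bad in (0.0, 1.5):
            with pytest.raises(ValidationError):
                SubjectParams(alpha={"CS": 0.5}, beta={"US": 0.5}, decay_per_epoch=bad)

    def test_stimulus_cannot_be_both_cs_and_us(self):
        with pytest.raises(ConfigurationError):
            SubjectParams(alpha={"X": 0.5}, beta={"X": 0.5})


class TestExtinctionAsymmetry:
    def test_cs_oriented_share_grows_as_forward_strength_extinguishes(self):
        # from asymptote, extinction lowers net V_CS-US while alpha is
        # fixed, so the R_CS share of V_COMB is non-decreasing: the basis
        # for sign-tracking's greater resistance to extinction
        params = SubjectParams(alpha={"CS": 0.3}, beta={"US": 0.5})
        state, _ = iterate_acquisition(0.3, 0.5, 1.0, 400)
        shares = []
        for _ in range(30):
            vf, vb = state.v("CS", "US"), state.v("US", "CS")
            vcomb = combine(vf, vb)
            r_cs, _ = distribute(vcomb, 0.3, vf)
            shares.append(r_cs / vcomb)
            state = learning_update(state, {"CS"}, params)
        assert all(b >= a for a, b in zip(shares, shares[1:]))
        assert shares[-1] > shares[0]
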