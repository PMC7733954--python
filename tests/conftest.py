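import numpy as np
import pytest

from heidi import AssociativeState, SubjectParams, learning_update

#: The four canonical (alpha_CS, beta_US) salience settings: beta fixed
#: at .5 with alpha .3/.7, and alpha fixed at .5 with beta .3/.7.
CANONICAL = {
    "A": (0.30, 0.50),
    "B": (0.70, 0.50),
    "C": (0.50, 0.30),
    "D": (0.50, 0.70),
}


def closed_form_forward(alpha: float, beta: float, c: float, n: int) -> float:
    """Independent oracle: V_CS-US after n continuously reinforced trials.

    The single-CS pooled error reduces to the linear recurrence
    V' = V + alpha (c beta - V), whose solution is
    c beta (1 - (1 - alpha)^n).
    """
    return c * beta * (1.0 - (1.0 - alpha) ** n)


def closed_form_backward(alpha: float, beta: float, c: float, n: int) -> float:
    """Oracle for V_US-CS: c alpha (1 - (1 - beta)^n)."""
    return c * alpha * (1.0 - (1.0 - beta) ** n)


def iterate_acquisition(alpha: float, beta: float, c: float, n: int):
    """Run n reinforced CS+US trials through the model's own update."""
    params = SubjectParams(alpha={"CS": alpha}, beta={"US": beta}, c=c)
    state = AssociativeState.zeros(("CS", "US"))
    history = []
    for _ in range(n):
        state = learning_update(state, {"CS", "US"}, params)
        history.append((state.v("CS", "US"), state.v("US", "CS")))
    return state, history


@pytest.fixture
def rng():
    return np.random.default_rng(20260101)
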