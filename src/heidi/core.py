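"""Core HeiDI model equations.

HeiDI is a trial-level model of Pavlovian conditioning in which CS-US
pairings form *reciprocal* associations: a forward CS->US link and a
backward US->CS link.  Both develop under a pooled-error rule of the
Rescorla-Wagner family, with the perceived salience of the target setting
the asymptote and the perceived salience of the source setting the rate:

    dV[i->j] = s_i * (c * s_j - sum_k V[k->j])        (k, i present)

where s is alpha for a CS and beta for a US, and c is the scaling
constant (maximum associative strength, in units of V).  When a stimulus
is absent its salience terms are zero, so the forward association
extinguishes on CS-alone trials and the backward association on US-alone
trials.

On CS presentation the reciprocal strengths are combined,

    V_COMB = V_CS-US + (1/c) * V_CS-US * V_US-CS,

and distributed into a CS-oriented component R_CS and a US-oriented
component R_US according to the salience of the CS relative to the
(retrieved) strength of the US representation:

    R_CS = alpha / (alpha + |V_CS-US|/c) * V_COMB
    R_US = (|V_CS-US|/c) / (alpha + |V_CS-US|/c) * V_COMB

R_CS drives sign-tracking (CS-directed) behaviour and R_US goal-tracking
(US-directed) behaviour; a fixed link matrix maps the pair onto six
response-generating units r1..r6.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np

__all__ = [
    "HeidiError",
    "ConfigurationError",
    "ValidationError",
    "DegenerateInputError",
    "LinkMatrix",
    "SubjectParams",
    "AssociativeState",
    "learning_update",
    "combine",
    "distribute",
    "response_vector",
    "decay_alpha",
    "DEFAULT_DECAY",
    "SIGN_RESPONSE",
    "GOAL_RESPONSE",
]


class HeidiError(Exception):
    """Base class for model errors."""


class ConfigurationError(HeidiError):
    """An input refers to an unknown stimulus or is structurally invalid."""


class ValidationError(HeidiError):
    """A numeric parameter is outside its admissible range."""


class DegenerateInputError(HeidiError):
    """Performance rule called with alpha = 0 and V_forward = 0 (0/0)."""


#: Default per-epoch multiplicative decay of alpha within a trial,
#: (1 - 0.10)^2.  Epoch e uses alpha * DEFAULT_DECAY**(e-1).
DEFAULT_DECAY = 0.81

#: Indices into the r1..r6 response vector of the canonical sign-tracking
#: (lever-press-like, r1) and goal-tracking (food-well-entry-like, r4)
#: responses.
SIGN_RESPONSE = 0
GOAL_RESPONSE = 3


def _check_unit_interval(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ValidationError(f"{name} must lie in [0, 1], got {value!r}")


@dataclass(frozen=True)
class LinkMatrix:
    """Fixed, unconditioned links from the CS and US nodes to the six
    response units r1..r6.

    r1-r3 are CS-oriented responses (orienting, lever approach, rearing)
    and are more strongly driven by R_CS; r4-r6 are US-oriented responses
    (food-well approach, chewing, swallowing) and are more strongly
    driven by R_US.  The default weights are a configurable convention
    honouring that ordering; r1 is the canonical sign-tracking response
    and r4 the canonical goal-tracking response.
    """

    cs_links: Tuple[float, ...] = (0.9, 0.6, 0.3, 0.3, 0.2, 0.1)
    us_links: Tuple[float, ...] = (0.3, 0.2, 0.1, 0.9, 0.6, 0.3)

    def __post_init__(self) -> None:
        for name, links in (("cs_links", self.cs_links), ("us_links", self.us_links)):
            if len(links) != 6:
                raise ValidationError(f"{name} must have length 6, got {len(links)}")
            if any(w < 0 for w in links):
                raise ValidationError(f"{name} weights must be nonnegative")
        object.__setattr__(self, "cs_links", tuple(float(w) for w in self.cs_links))
        object.__setattr__(self, "us_links", tuple(float(w) for w in self.us_links))


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject model parameters.

    Parameters
    ----------
    alpha
        Perceived salience of each CS, in [0, 1].  Joint learning-rate
        (for the forward association) and asymptote (for the backward
        association) parameter.
    beta
        Perceived salience of each US, in [0, 1].  Joint learning-rate
        (backward) and asymptote (forward) parameter.
    c
        Scaling constant: the maximum associative strength, in units of
        V.  Defaults to 1.
    decay_per_epoch
        Multiplicative within-trial decay of alpha per epoch, in (0, 1].
        1.0 (default) means no decay; the within-trial simulation
        protocol uses ``DEFAULT_DECAY`` = 0.81.
    links
        Link matrix mapping (R_CS, R_US) onto response units r1..r6.
    """

    alpha: Mapping[str, float]
    beta: Mapping[str, float]
    c: float = 1.0
    decay_per_epoch: float = 1.0
    links: LinkMatrix = field(default_factory=LinkMatrix)

    def __post_init__(self) -> None:
        object.__setattr__(self, "alpha", dict(self.alpha))
        object.__setattr__(self, "beta", dict(self.beta))
        overlap = set(self.alpha) & set(self.beta)
        if overlap:
            raise ConfigurationError(
                f"stimuli cannot be both CS and US: {sorted(overlap)}"
            )
        for sid, a in self.alpha.items():
            _check_unit_interval(f"alpha[{sid!r}]", a)
        for sid, b in self.beta.items():
            _check_unit_interval(f"beta[{sid!r}]", b)
        if not self.c > 0:
            raise ValidationError(f"c must be positive, got {self.c!r}")
        if not (0.0 < self.decay_per_epoch <= 1.0):
            raise ValidationError(
                f"decay_per_epoch must lie in (0, 1], got {self.decay_per_epoch!r}"
            )

    @property
    def stimuli(self) -> Tuple[str, ...]:
        return tuple(self.alpha) + tuple(self.beta)

    def salience(self, stimulus: str) -> float:
        if stimulus in self.alpha:
            return self.alpha[stimulus]
        if stimulus in self.beta:
            return self.beta[stimulus]
        raise ConfigurationError(f"unknown stimulus id {stimulus!r}")


class AssociativeState:
    """Directed associative strengths V[source -> target], in units of V.

    Defined for every ordered pair of distinct stimuli in the stimulus
    set; all strengths start at 0 (no pre-training associations).
    """

    __slots__ = ("stimuli", "_v")

    def __init__(self, stimuli: Iterable[str], strengths: Optional[Dict[Tuple[str, str], float]] = None):
        self.stimuli: Tuple[str, ...] = tuple(stimuli)
        if len(set(self.stimuli)) != len(self.stimuli):
            raise ConfigurationError("duplicate stimulus ids in stimulus set")
        self._v: Dict[Tuple[str, str], float] = {
            (i, j): 0.0 for i in self.stimuli for j in self.stimuli if i != j
        }
        if strengths is not None:
            for pair, value in strengths.items():
                if pair not in self._v:
                    raise ConfigurationError(f"unknown stimulus pair {pair!r}")
                self._v[pair] = float(value)

    @classmethod
    def zeros(cls, stimuli: Iterable[str]) -> "AssociativeState":
        return cls(stimuli)

    def v(self, source: str, target: str) -> float:
        try:
            return self._v[(source, target)]
        except KeyError:
            raise ConfigurationError(
                f"unknown stimulus pair ({source!r}, {target!r})"
            ) from None

    def copy(self) -> "AssociativeState":
        return AssociativeState(self.stimuli, dict(self._v))

    def items(self):
        return self._v.items()

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AssociativeState)
            and self.stimuli == other.stimuli
            and self._v == other._v
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        nonzero = {k: v for k, v in self._v.items() if v != 0.0}
        return f"AssociativeState(stimuli={self.stimuli}, nonzero={nonzero})"


def learning_update(
    state: AssociativeState,
    present: Iterable[str],
    params: SubjectParams,
    alpha_terminal: Optional[Mapping[str, float]] = None,
) -> AssociativeState:
    """One trial of pooled-error learning; returns the post-trial state.

    For every ordered pair (i, j) with i present::

        dV[i->j] = s_i * (c * s_j * [j present] - sum_{k present} V[k->j])

    where s is the stimulus salience (alpha for CSs -- optionally the
    decayed *terminal* value supplied via ``alpha_terminal`` -- and beta
    for USs).  Pairs whose source is absent are unchanged (their rate
    term is zero).  All updates are computed from the pre-trial state and
    applied simultaneously, so there are no within-trial ordering
    effects.
    """
    present = set(present)
    for sid in present:
        if sid not in state._v and sid not in state.stimuli:
            raise ConfigurationError(f"unknown stimulus id {sid!r}")
        if sid not in state.stimuli:
            raise ConfigurationError(f"stimulus {sid!r} not in state")
    salience = {sid: params.salience(sid) for sid in present}
    if alpha_terminal is not None:
        for sid, a in alpha_terminal.items():
            if sid not in params.alpha:
                raise ConfigurationError(
                    f"alpha_terminal given for non-CS stimulus {sid!r}"
                )
            _check_unit_interval(f"alpha_terminal[{sid!r}]", a)
            if sid in salience:
                salience[sid] = float(a)

    new = state.copy()
    if not present:
        return new
    for j in state.stimuli:
        pooled = sum(state.v(k, j) for k in present if k != j)
        # terminal alpha (when supplied) sets the backward asymptote too
        asymptote = params.c * salience[j] if j in present else 0.0
        error = asymptote - pooled
        for i in present:
            if i == j:
                continue
            new._v[(i, j)] = state.v(i, j) + salience[i] * error
    return new


def combine(v_forward: float, v_backward: float, c: float = 1.0) -> float:
    """Combined associative strength V_COMB on CS presentation.

    The backward (US->CS) association contributes only to the degree the
    US representation is itself activated by the forward association:
    ``V_COMB = V_f + (1/c) * V_f * V_b``.  Signed values are used as-is.
    """
    return v_forward + (v_forward * v_backward) / c


def distribute(
    v_comb: float,
    alpha_effective: float,
    v_forward: float,
    c: float = 1.0,
) -> Tuple[float, float]:
    """Split V_COMB into the CS-oriented (R_CS) and US-oriented (R_US)
    performance components.

    The split weighs the current (possibly within-trial decayed) CS
    salience against the retrieved US salience ``|V_forward|/c``; the
    absolute value keeps both proportions in [0, 1] even when the net
    forward association is negative.  R_CS + R_US = V_COMB exactly.

    Raises
    ------
    DegenerateInputError
        If ``alpha_effective == 0`` and ``v_forward == 0`` (0/0).  Callers
        short-circuit the V_COMB = 0 case to (0, 0) before calling.
    """
    if alpha_effective < 0:
        raise ValidationError(
            f"alpha_effective must be nonnegative, got {alpha_effective!r}"
        )
    w = abs(v_forward) / c
    denom = alpha_effective + w
    if denom == 0.0:
        raise DegenerateInputError(
            "distribute() undefined for alpha_effective = 0 and V_forward = 0"
        )
    r_cs = (alpha_effective / denom) * v_comb
    r_us = (w / denom) * v_comb
    return r_cs, r_us


def response_vector(
    r_cs: float,
    r_us: float,
    links: LinkMatrix,
    c: float = 1.0,
) -> np.ndarray:
    """Map (R_CS, R_US) onto the six response units:
    ``r_i = (1/c) * (R_CS * cs_links_i + R_US * us_links_i)``.

    The value of each unit, in units of V, is read as the vigor of the
    corresponding response form.
    """
    cs = np.asarray(links.cs_links, dtype=float)
    us = np.asarray(links.us_links, dtype=float)
    return (r_cs * cs + r_us * us) / c


def decay_alpha(
    alpha_start: float,
    epoch_index: int,
    decay_per_epoch: float = DEFAULT_DECAY,
) -> float:
    """Within-trial exponential decay of CS salience.

    Alpha is reset to ``alpha_start`` at the start of each trial (epoch 1)
    and multiplied by ``decay_per_epoch`` each subsequent epoch:
    ``alpha_start * decay_per_epoch**(epoch_index - 1)``.  The default
    factor 0.81 = (1 - 0.10)^2 reproduces the within-trial decline of
    sign-tracking and rise of goal-tracking (inhibition of delay).
    """
    if epoch_index < 1:
        raise ValidationError(f"epoch_index must be >= 1, got {epoch_index!r}")
    if not (0.0 < decay_per_epoch <= 1.0):
        raise ValidationError(
            f"decay_per_epoch must lie in (0, 1], got {decay_per_epoch!r}"
        )
    return alpha_start * decay_per_epoch ** (epoch_index - 1)
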