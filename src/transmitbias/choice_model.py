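"""Probabilistic variant-choice model for two-variant cultural transmission.

A participant has learned two alternative variants of the same behaviour —
one from an expert and one from a peer, one first and one last, one per
strategy content — and must produce exactly one of them in a given onward
transmission context (teaching a novice, or showing a peer).  Three bias
parameters, each in [-1, 1], tilt that choice:

``expert_bias``
    preference for the variant learned from the expert (negative values
    favour the peer's variant);
``congruent_bias``
    preference for the variant learned in a context matching the current
    production context (the context-congruence bias);
``primacy_bias``
    order preference; by the field's sign convention used here, positive
    values favour the *last*-learned variant, negative the first.

Each bias ``b`` maps affinely to a weight ``(1 + b) / 2`` in [0, 1]; a
variant's weight is the product of its source, congruence and order factors;
the produced variant is drawn by the Luce choice rule (probability
proportional to weight).  At ``b = 0`` every factor is 1/2 and the choice is
unbiased.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Source",
    "Content",
    "Order",
    "TransmissionContext",
    "BiasParameters",
    "ChoiceWeights",
    "VariantAttributes",
    "bias_to_weight",
    "variant_weight",
    "choice_probability",
    "expert_production_probability",
]


class Source(enum.Enum):
    """Who demonstrated the variant to the participant."""

    EXPERT = "expert"
    PEER = "peer"

    @property
    def opposite(self) -> "Source":
        return Source.PEER if self is Source.EXPERT else Source.EXPERT


class Content(enum.Enum):
    """The two alternative strategies for the gear-direction task."""

    PARITY = "parity"
    SKIPPING = "skipping"

    @property
    def opposite(self) -> "Content":
        return Content.SKIPPING if self is Content.PARITY else Content.PARITY


class Order(enum.Enum):
    """Whether the variant was the first or the last one learned."""

    FIRST = "first"
    LAST = "last"

    @property
    def opposite(self) -> "Order":
        return Order.LAST if self is Order.FIRST else Order.FIRST


class TransmissionContext(enum.Enum):
    """The onward transmission context the participant produces in."""

    EXPERT_TO_NOVICE = "expert_to_novice"
    PEER_TO_PEER = "peer_to_peer"

    @property
    def congruent_source(self) -> Source:
        """The source whose variant is context-congruent here.

        Teaching a novice mirrors having been taught by the expert; showing
        a peer mirrors the peer demonstration.
        """
        if self is TransmissionContext.EXPERT_TO_NOVICE:
            return Source.EXPERT
        return Source.PEER


def bias_to_weight(bias: float) -> float:
    """Map a bias in [-1, 1] to a choice weight in [0, 1] via ``(1 + b) / 2``.

    Strictly increasing; 0 maps to the neutral weight 1/2.

    Raises
    ------
    ValueError
        If ``bias`` lies outside [-1, 1].
    """
    if not -1.0 <= bias <= 1.0:
        raise ValueError(f"bias must lie in [-1, 1], got {bias!r}")
    return (1.0 + bias) / 2.0


@dataclass(frozen=True)
class BiasParameters:
    """The three transmission biases, each in [-1, 1].

    The complementary biases are fixed by construction: the peer bias is
    ``-expert_bias``, the incongruence bias is ``-congruent_bias`` and the
    recency bias is ``-primacy_bias``.
    """

    expert_bias: float
    congruent_bias: float
    primacy_bias: float = 0.0

    def __post_init__(self) -> None:
        for name in ("expert_bias", "congruent_bias", "primacy_bias"):
            value = getattr(self, name)
            if not -1.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [-1, 1], got {value!r}")

    @property
    def peer_bias(self) -> float:
        return -self.expert_bias

    @property
    def incongruent_bias(self) -> float:
        return -self.congruent_bias

    @property
    def recency_bias(self) -> float:
        return -self.primacy_bias

    @property
    def weights(self) -> "ChoiceWeights":
        return ChoiceWeights(
            p_expert=bias_to_weight(self.expert_bias),
            p_congruent=bias_to_weight(self.congruent_bias),
            p_last=bias_to_weight(self.primacy_bias),
        )


@dataclass(frozen=True)
class ChoiceWeights:
    """Per-attribute choice weights, each ``(1 + bias) / 2`` in [0, 1]."""

    p_expert: float
    p_congruent: float
    p_last: float


@dataclass(frozen=True)
class VariantAttributes:
    """The attributes of one learned variant relevant to the choice model."""

    source: Source
    content: Content
    order: Order

    def opposite(self) -> "VariantAttributes":
        """The other variant the same participant holds (all attributes flipped)."""
        return VariantAttributes(
            source=self.source.opposite,
            content=self.content.opposite,
            order=self.order.opposite,
        )

    def is_opposite_of(self, other: "VariantAttributes") -> bool:
        return (
            self.source is not other.source
            and self.content is not other.content
            and self.order is not other.order
        )


def variant_weight(
    params: BiasParameters,
    context: TransmissionContext,
    variant: VariantAttributes,
) -> float:
    """Unnormalized production weight of one variant in one context.

    The product of three factors: the source factor (``p_expert`` for the
    expert's variant, its complement for the peer's), the congruence factor
    (``p_congruent`` if the variant's source is the context-congruent one)
    and the order factor (``p_last`` for the last-learned variant).
    """
    w = params.weights
    f_source = w.p_expert if variant.source is Source.EXPERT else 1.0 - w.p_expert
    f_congruence = (
        w.p_congruent
        if variant.source is context.congruent_source
        else 1.0 - w.p_congruent
    )
    f_order = w.p_last if variant.order is Order.LAST else 1.0 - w.p_last
    return f_source * f_congruence * f_order


def choice_probability(
    params: BiasParameters,
    context: TransmissionContext,
    produced: VariantAttributes,
    alternative: VariantAttributes,
) -> float:
    """Probability of producing ``produced`` rather than ``alternative``.

    Luce choice rule over the two variant weights.  When both weights vanish
    (only possible at the boundary of the parameter cube, e.g. a maximal
    expert bias against a maximal congruence bias) the choice is defined as
    unbiased, 1/2.

    Raises
    ------
    ValueError
        If the two variants are not attribute-wise opposite — a participant
        always holds one variant per source, content and order level.
    """
    if not produced.is_opposite_of(alternative):
        raise ValueError(
            "produced and alternative must have opposite source, content and order"
        )
    w_produced = variant_weight(params, context, produced)
    w_alternative = variant_weight(params, context, alternative)
    total = w_produced + w_alternative
    if total == 0.0:
        return 0.5
    # guard against p > 1 by one ulp; downstream binomial pmfs reject it
    return min(w_produced / total, 1.0)


def expert_production_probability(
    expert_bias,
    congruent_bias,
    primacy_bias=0.0,
    *,
    context: TransmissionContext,
    expert_order: Order | None = None,
):
    """Vectorized probability that the *expert-sourced* variant is produced.

    Accepts scalars or broadcastable numpy arrays for the three biases and
    evaluates the normalized choice model in one pass — the workhorse behind
    grid simulation and the analytic match-probability oracle.

    ``expert_order`` states whether the expert's variant was learned first
    or last for the participants being modelled.  With ``None`` the order
    factor is the neutral 1/2 for both variants, which is exact whenever
    ``primacy_bias`` is 0 (the factor cancels under normalization).
    """
    eb = np.asarray(expert_bias, dtype=float)
    cb = np.asarray(congruent_bias, dtype=float)
    pb = np.asarray(primacy_bias, dtype=float)
    if np.any((eb < -1) | (eb > 1) | (cb < -1) | (cb > 1) | (pb < -1) | (pb > 1)):
        raise ValueError("all biases must lie in [-1, 1]")

    p_expert = (1.0 + eb) / 2.0
    p_congruent = (1.0 + cb) / 2.0
    p_last = (1.0 + pb) / 2.0

    if context.congruent_source is Source.EXPERT:
        f_c_expert, f_c_peer = p_congruent, 1.0 - p_congruent
    else:
        f_c_expert, f_c_peer = 1.0 - p_congruent, p_congruent

    if expert_order is None:
        f_o_expert = f_o_peer = 0.5
    elif expert_order is Order.LAST:
        f_o_expert, f_o_peer = p_last, 1.0 - p_last
    else:
        f_o_expert, f_o_peer = 1.0 - p_last, p_last

    w_expert = p_expert * f_c_expert * f_o_expert
    w_peer = (1.0 - p_expert) * f_c_peer * f_o_peer
    total = w_expert + w_peer
    prob = np.divide(
        w_expert,
        total,
        out=np.full(np.broadcast(w_expert, w_peer).shape, 0.5),
        where=total > 0,
    )
    # roundoff can push the ratio past 1 by ~1e-13 at the cube edge; binomial
    # pmfs require p in [0, 1] exactly
    prob = np.clip(prob, 0.0, 1.0)
    if prob.ndim == 0:
        return float(prob)
    return prob
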