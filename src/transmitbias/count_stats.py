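"""Chi-squared hypothesis tests on production counts.

Three planned hypotheses are tested on the experiment's count data with
equal-expectation goodness-of-fit chi-squared tests under a Bonferroni-
corrected threshold: an overall expert-variant preference, a preference in
the expert-to-novice condition, and (the null expectation) no preference in
the peer-to-peer condition.  Independence tests check that the produced
variant is unrelated to the counterbalanced order factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simulator import CountTable, TransmissionContext

__all__ = [
    "TestResult",
    "chisq_goodness_of_fit",
    "chisq_independence",
    "bonferroni_alpha",
    "analyze_counts",
    "analyze_participants",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    alpha: float | None = None

    @property
    def significant(self) -> bool | None:
        if self.alpha is None:
            return None
        return self.p_value < self.alpha

    def to_dict(self) -> dict:
        out = {"statistic": self.statistic, "df": self.df, "p_value": self.p_value}
        if self.alpha is not None:
            out["alpha"] = self.alpha
            out["significant"] = self.significant
        return out


def chisq_goodness_of_fit(
    count_a: int, count_b: int, alpha: float | None = None
) -> TestResult:
    """Pearson chi-squared test of two counts against equal expectation.

    Equivalent to the closed form ``(a - b)^2 / (a + b)`` on one degree of
    freedom.
    """
    if count_a < 0 or count_b < 0:
        raise ValueError("counts must be non-negative")
    if count_a == 0 and count_b == 0:
        raise ValueError("goodness-of-fit test undefined for two zero counts")
    statistic, p_value = stats.chisquare([count_a, count_b])
    return TestResult(float(statistic), 1, float(p_value), alpha)


def chisq_independence(
    table, correction: bool = False, alpha: float | None = None
) -> TestResult:
    """Pearson chi-squared test of independence on a contingency table.

    Yates continuity correction is off by default; pass ``correction=True``
    to enable it.
    """
    table = np.asarray(table)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("independence test undefined with a zero marginal")
    result = stats.chi2_contingency(table, correction=correction)
    return TestResult(float(result.statistic), int(result.dof), float(result.pvalue), alpha)


def bonferroni_alpha(base_alpha: float, m: int) -> float:
    """Per-test threshold ``base_alpha / m`` for ``m`` planned tests."""
    if not 0 < base_alpha <= 1:
        raise ValueError("base_alpha must lie in (0, 1]")
    if m < 1:
        raise ValueError("m must be >= 1")
    return base_alpha / m


def analyze_counts(
    observed: CountTable, base_alpha: float = 0.05, n_tests: int = 3
) -> dict:
    """Run the planned hypothesis tests on a four-cell production table.

    Tests, each at the Bonferroni-corrected threshold: the pooled expert
    vs peer production counts; the within-condition counts in the
    expert-to-novice condition; and the within-condition counts in the
    peer-to-peer condition.
    """
    table = observed.as_four_cell()
    alpha = bonferroni_alpha(base_alpha, n_tests)
    expert_total, peer_total = table.source_totals()
    e2n = TransmissionContext.EXPERT_TO_NOVICE
    p2p = TransmissionContext.PEER_TO_PEER
    report = {
        "alpha": alpha,
        "counts": table.to_dict(),
        "tests": {
            "overall_expert_vs_peer": chisq_goodness_of_fit(
                expert_total, peer_total, alpha
            ).to_dict(),
            "e2n_expert_vs_peer": chisq_goodness_of_fit(
                table.expert_count(e2n),
                table.context_total(e2n) - table.expert_count(e2n),
                alpha,
            ).to_dict(),
            "p2p_expert_vs_peer": chisq_goodness_of_fit(
                table.expert_count(p2p),
                table.context_total(p2p) - table.expert_count(p2p),
                alpha,
            ).to_dict(),
        },
    }
    return report


def _independence_or_undefined(table, alpha: float) -> dict:
    try:
        return chisq_independence(table, alpha=alpha).to_dict()
    except ValueError as exc:
        return {"undefined": str(exc)}


def analyze_participants(records, base_alpha: float = 0.05, n_tests: int = 3) -> dict:
    """Full count analysis of a participant cohort.

    Extends :func:`analyze_counts` with the control checks that need
    participant-level coding: the strategy-content production counts, and
    independence of the produced variant from the two counterbalanced order
    factors.  An independence test whose table has a zero marginal is
    reported as undefined rather than as a number.
    """
    from .choice_model import Content, Source
    from .synthetic_data import LearningOrder, StrategyOrder, tabulate

    alpha = bonferroni_alpha(base_alpha, n_tests)
    active = [r for r in records if not r.excluded]
    report = analyze_counts(tabulate(records), base_alpha, n_tests)

    parity = sum(r.produced_strategy is Content.PARITY for r in active)
    skipping = len(active) - parity
    report["tests"]["strategy_parity_vs_skipping"] = chisq_goodness_of_fit(
        parity, skipping, alpha
    ).to_dict()

    def cross(factor, level) -> list[list[int]]:
        rows = []
        for source in (Source.EXPERT, Source.PEER):
            rows.append(
                [
                    sum(
                        r.produced_source is source and getattr(r, factor) is lev
                        for r in active
                    )
                    for lev in level
                ]
            )
        return rows

    report["tests"]["variant_vs_learning_order"] = _independence_or_undefined(
        cross("learning_order", tuple(LearningOrder)), alpha
    )
    report["tests"]["variant_vs_strategy_order"] = _independence_or_undefined(
        cross("strategy_order", tuple(StrategyOrder)), alpha
    )
    return report
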