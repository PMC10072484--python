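"""Synthetic participant cohorts with the experiment's design structure.

Generates participant-level records for a two-condition transmission study:
each participant learns one variant from an expert and one from a peer (in
counterbalanced learning and strategy order), then produces one of them in
their condition's onward context, drawn under the choice model at known
true bias values.  Cohorts make every downstream stage — count tabulation,
hypothesis tests, rejection estimation, parameter recovery — testable
without any external data.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .choice_model import (
    BiasParameters,
    Content,
    Order,
    Source,
    TransmissionContext,
    VariantAttributes,
)
from .simulator import CONTEXTS, ORDERS, SOURCES, CountTable, TableLayout, simulate_participant

__all__ = [
    "LearningOrder",
    "StrategyOrder",
    "ParticipantRecord",
    "generate_participants",
    "tabulate",
    "records_to_frame",
    "frame_to_records",
    "write_participants_csv",
    "read_participants_csv",
]


class LearningOrder(enum.Enum):
    """Which acquisition context came first for the participant."""

    EXPERT_FIRST = "expert_first"
    PEER_FIRST = "peer_first"


class StrategyOrder(enum.Enum):
    """Which strategy content was taught first."""

    PARITY_FIRST = "parity_first"
    SKIPPING_FIRST = "skipping_first"


@dataclass(frozen=True)
class ParticipantRecord:
    participant_id: str
    condition: TransmissionContext
    learning_order: LearningOrder
    strategy_order: StrategyOrder
    expert_strategy: Content
    produced_source: Source
    produced_strategy: Content
    excluded: bool = False

    def __post_init__(self) -> None:
        expected = (
            self.expert_strategy
            if self.produced_source is Source.EXPERT
            else self.expert_strategy.opposite
        )
        if self.produced_strategy is not expected:
            raise ValueError(
                "produced_strategy inconsistent with produced_source and expert_strategy"
            )

    @property
    def expert_variant(self) -> VariantAttributes:
        order = (
            Order.FIRST
            if self.learning_order is LearningOrder.EXPERT_FIRST
            else Order.LAST
        )
        return VariantAttributes(Source.EXPERT, self.expert_strategy, order)

    @property
    def produced_variant(self) -> VariantAttributes:
        expert = self.expert_variant
        return expert if self.produced_source is Source.EXPERT else expert.opposite()


def _expert_strategy(learning_order: LearningOrder, strategy_order: StrategyOrder) -> Content:
    """The content the expert taught, implied by the two order factors."""
    first_strategy = (
        Content.PARITY
        if strategy_order is StrategyOrder.PARITY_FIRST
        else Content.SKIPPING
    )
    if learning_order is LearningOrder.EXPERT_FIRST:
        return first_strategy
    return first_strategy.opposite


def generate_participants(
    true_params: BiasParameters,
    n_per_condition: int = 32,
    n_excluded_e2n: int = 0,
    seed: int | None = 0,
) -> list[ParticipantRecord]:
    """Generate one fully counterbalanced cohort.

    Each condition holds ``n_per_condition`` participants split equally over
    the four (learning order x strategy order) cells, which requires
    divisibility by 4.  ``n_excluded_e2n`` participants of the
    expert-to-novice condition are flagged excluded, chosen uniformly at
    random (exclusion in the real design was questionnaire-based; random
    flagging is the neutral emulation).  Deterministic under ``seed``.
    """
    if n_per_condition % 4 != 0:
        raise ValueError("n_per_condition must be divisible by 4 for counterbalancing")
    if not 0 <= n_excluded_e2n <= n_per_condition:
        raise ValueError("n_excluded_e2n must lie in [0, n_per_condition]")
    rng = np.random.default_rng(seed)

    cells = [(lo, so) for lo in LearningOrder for so in StrategyOrder]
    records: list[ParticipantRecord] = []
    pid = 0
    for condition in CONTEXTS:
        for learning_order, strategy_order in cells:
            for _ in range(n_per_condition // 4):
                pid += 1
                expert_strategy = _expert_strategy(learning_order, strategy_order)
                expert_order = (
                    Order.FIRST
                    if learning_order is LearningOrder.EXPERT_FIRST
                    else Order.LAST
                )
                expert_variant = VariantAttributes(
                    Source.EXPERT, expert_strategy, expert_order
                )
                produced = simulate_participant(
                    true_params,
                    condition,
                    (expert_variant, expert_variant.opposite()),
                    rng,
                )
                records.append(
                    ParticipantRecord(
                        participant_id=f"p{pid:03d}",
                        condition=condition,
                        learning_order=learning_order,
                        strategy_order=strategy_order,
                        expert_strategy=expert_strategy,
                        produced_source=produced.source,
                        produced_strategy=produced.content,
                        excluded=False,
                    )
                )
    if n_excluded_e2n:
        e2n_indices = [
            i
            for i, r in enumerate(records)
            if r.condition is TransmissionContext.EXPERT_TO_NOVICE
        ]
        chosen = rng.choice(e2n_indices, size=n_excluded_e2n, replace=False)
        for i in chosen:
            r = records[i]
            records[i] = ParticipantRecord(
                r.participant_id,
                r.condition,
                r.learning_order,
                r.strategy_order,
                r.expert_strategy,
                r.produced_source,
                r.produced_strategy,
                excluded=True,
            )
    return records


def tabulate(
    records: list[ParticipantRecord], layout: TableLayout = TableLayout.FOUR_CELL
) -> CountTable:
    """Tabulate unexcluded productions into a count table.

    Raises
    ------
    ValueError
        Duplicate participant ids — the records span more than one cohort.
    """
    ids = [r.participant_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate participant ids: records mix cohorts")
    shape = (2, 2) if layout is TableLayout.FOUR_CELL else (2, 2, 2)
    cells = np.zeros(shape, dtype=np.int64)
    for r in records:
        if r.excluded:
            continue
        i = CONTEXTS.index(r.condition)
        j = SOURCES.index(r.produced_source)
        if layout is TableLayout.FOUR_CELL:
            cells[i, j] += 1
        else:
            cells[i, j, ORDERS.index(r.produced_variant.order)] += 1
    return CountTable(layout, cells)


_COLUMNS = [
    "participant_id",
    "condition",
    "learning_order",
    "strategy_order",
    "expert_strategy",
    "produced_source",
    "produced_strategy",
    "excluded",
]


def records_to_frame(records: list[ParticipantRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "condition": r.condition.value,
                "learning_order": r.learning_order.value,
                "strategy_order": r.strategy_order.value,
                "expert_strategy": r.expert_strategy.value,
                "produced_source": r.produced_source.value,
                "produced_strategy": r.produced_strategy.value,
                "excluded": r.excluded,
            }
            for r in records
        ],
        columns=_COLUMNS,
    )


def frame_to_records(df: pd.DataFrame) -> list[ParticipantRecord]:
    missing = set(_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"participant table missing columns: {sorted(missing)}")
    return [
        ParticipantRecord(
            participant_id=str(row.participant_id),
            condition=TransmissionContext(row.condition),
            learning_order=LearningOrder(row.learning_order),
            strategy_order=StrategyOrder(row.strategy_order),
            expert_strategy=Content(row.expert_strategy),
            produced_source=Source(row.produced_source),
            produced_strategy=Content(row.produced_strategy),
            excluded=bool(row.excluded),
        )
        for row in df.itertuples(index=False)
    ]


def write_participants_csv(records: list[ParticipantRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_participants_csv(path: str | Path) -> list[ParticipantRecord]:
    return frame_to_records(pd.read_csv(path))
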