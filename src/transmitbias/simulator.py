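"""Forward simulation of the two-condition transmission experiment.

Each simulated participant holds two opposite variants and produces one of
them, drawn under :mod:`transmitbias.choice_model`.  Productions are
aggregated into count tables: four cells (context x produced source) or
eight cells (context x produced source x produced order).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .choice_model import (
    BiasParameters,
    Content,
    Order,
    Source,
    TransmissionContext,
    VariantAttributes,
    choice_probability,
    expert_production_probability,
)

__all__ = [
    "TableLayout",
    "ExperimentDesign",
    "CountTable",
    "counterbalanced_assignments",
    "simulate_participant",
    "simulate_experiment",
    "simulate_counts_batch",
    "cell_rng",
]

CONTEXTS = (TransmissionContext.EXPERT_TO_NOVICE, TransmissionContext.PEER_TO_PEER)
SOURCES = (Source.EXPERT, Source.PEER)
ORDERS = (Order.FIRST, Order.LAST)


class TableLayout(enum.Enum):
    FOUR_CELL = "four_cell"
    EIGHT_CELL = "eight_cell"


@dataclass(frozen=True)
class ExperimentDesign:
    """Condition sizes of the experiment.

    Defaults are the post-exclusion cohort (30 expert-to-novice, 32
    peer-to-peer); the pre-exclusion 32/32 design is available by passing it
    explicitly.
    """

    n_e2n: int = 30
    n_p2p: int = 32

    def __post_init__(self) -> None:
        if self.n_e2n < 0 or self.n_p2p < 0:
            raise ValueError("condition sizes must be non-negative")

    def n(self, context: TransmissionContext) -> int:
        return self.n_e2n if context is TransmissionContext.EXPERT_TO_NOVICE else self.n_p2p

    def order_split(self, context: TransmissionContext) -> tuple[int, int]:
        """(n with expert's variant learned first, n with it learned last).

        Full counterbalancing splits each condition half and half; an odd
        condition size places the extra participant in the expert-first
        stratum, deterministically.
        """
        n = self.n(context)
        n_first = (n + 1) // 2
        return n_first, n - n_first


@dataclass(frozen=True)
class CountTable:
    """Production counts per condition.

    ``cells`` is indexed ``[context, source]`` for the four-cell layout and
    ``[context, source, produced order]`` for the eight-cell layout, with
    axis order (expert-to-novice, peer-to-peer) x (expert, peer) x (first,
    last).
    """

    layout: TableLayout
    cells: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        expected = (2, 2) if self.layout is TableLayout.FOUR_CELL else (2, 2, 2)
        cells = np.asarray(self.cells, dtype=np.int64)
        if cells.shape != expected:
            raise ValueError(f"cells must have shape {expected} for {self.layout}")
        if np.any(cells < 0):
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "cells", cells)

    # -- constructors -----------------------------------------------------
    @classmethod
    def from_four_counts(
        cls, e2n_expert: int, e2n_peer: int, p2p_expert: int, p2p_peer: int
    ) -> "CountTable":
        return cls(
            TableLayout.FOUR_CELL,
            np.array([[e2n_expert, e2n_peer], [p2p_expert, p2p_peer]]),
        )

    @classmethod
    def zeros(cls, layout: TableLayout) -> "CountTable":
        shape = (2, 2) if layout is TableLayout.FOUR_CELL else (2, 2, 2)
        return cls(layout, np.zeros(shape, dtype=np.int64))

    # -- accessors --------------------------------------------------------
    def context_total(self, context: TransmissionContext) -> int:
        return int(self.cells[CONTEXTS.index(context)].sum())

    def expert_count(self, context: TransmissionContext) -> int:
        return int(self.cells[CONTEXTS.index(context), 0].sum())

    def source_totals(self) -> tuple[int, int]:
        """(total expert-variant productions, total peer-variant productions)."""
        expert = int(self.cells[:, 0].sum())
        peer = int(self.cells[:, 1].sum())
        return expert, peer

    def as_four_cell(self) -> "CountTable":
        if self.layout is TableLayout.FOUR_CELL:
            return self
        return CountTable(TableLayout.FOUR_CELL, self.cells.sum(axis=2))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.layout is other.layout and np.array_equal(self.cells, other.cells)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        out: dict = {}
        for i, context in enumerate(CONTEXTS):
            ckey = "e2n" if context is TransmissionContext.EXPERT_TO_NOVICE else "p2p"
            if self.layout is TableLayout.FOUR_CELL:
                out[ckey] = {
                    source.value: int(self.cells[i, j])
                    for j, source in enumerate(SOURCES)
                }
            else:
                out[ckey] = {
                    source.value: {
                        order.value: int(self.cells[i, j, k])
                        for k, order in enumerate(ORDERS)
                    }
                    for j, source in enumerate(SOURCES)
                }
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "CountTable":
        try:
            sample = data["e2n"]["expert"]
        except (KeyError, TypeError) as exc:
            raise ValueError(
                "counts document must nest as {'e2n': {'expert': ...}, 'p2p': ...}"
            ) from exc
        layout = TableLayout.EIGHT_CELL if isinstance(sample, dict) else TableLayout.FOUR_CELL
        shape = (2, 2) if layout is TableLayout.FOUR_CELL else (2, 2, 2)
        cells = np.zeros(shape, dtype=np.int64)
        for i, ckey in enumerate(("e2n", "p2p")):
            for j, source in enumerate(SOURCES):
                if layout is TableLayout.FOUR_CELL:
                    cells[i, j] = int(data[ckey][source.value])
                else:
                    for k, order in enumerate(ORDERS):
                        cells[i, j, k] = int(data[ckey][source.value][order.value])
        return cls(layout, cells)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CountTable":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, context in enumerate(CONTEXTS):
            for j, source in enumerate(SOURCES):
                if self.layout is TableLayout.FOUR_CELL:
                    rows.append(
                        {
                            "context": context.value,
                            "produced_source": source.value,
                            "count": int(self.cells[i, j]),
                        }
                    )
                else:
                    for k, order in enumerate(ORDERS):
                        rows.append(
                            {
                                "context": context.value,
                                "produced_source": source.value,
                                "produced_order": order.value,
                                "count": int(self.cells[i, j, k]),
                            }
                        )
        return pd.DataFrame(rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CountTable":
        df = pd.read_csv(path)
        layout = (
            TableLayout.EIGHT_CELL
            if "produced_order" in df.columns
            else TableLayout.FOUR_CELL
        )
        shape = (2, 2) if layout is TableLayout.FOUR_CELL else (2, 2, 2)
        cells = np.zeros(shape, dtype=np.int64)
        for _, row in df.iterrows():
            i = [c.value for c in CONTEXTS].index(row["context"])
            j = [s.value for s in SOURCES].index(row["produced_source"])
            if layout is TableLayout.FOUR_CELL:
                cells[i, j] = int(row["count"])
            else:
                k = [o.value for o in ORDERS].index(row["produced_order"])
                cells[i, j, k] = int(row["count"])
        return cls(layout, cells)


def counterbalanced_assignments(
    n: int, context: TransmissionContext, design: ExperimentDesign
) -> list[tuple[VariantAttributes, VariantAttributes]]:
    """Deterministic (expert variant, peer variant) pairs for one condition.

    The expert-first/expert-last split follows ``design.order_split``;
    within each order stratum the expert's strategy content alternates
    parity/skipping, mirroring full counterbalancing of both order factors.
    """
    n_first, _ = design.order_split(context)
    pairs = []
    for i in range(n):
        order = Order.FIRST if i < n_first else Order.LAST
        content = Content.PARITY if i % 2 == 0 else Content.SKIPPING
        expert_variant = VariantAttributes(Source.EXPERT, content, order)
        pairs.append((expert_variant, expert_variant.opposite()))
    return pairs


def simulate_participant(
    params: BiasParameters,
    context: TransmissionContext,
    assignment: tuple[VariantAttributes, VariantAttributes],
    rng: np.random.Generator,
) -> VariantAttributes:
    """Draw one participant's produced variant; consumes one uniform draw."""
    first, second = assignment
    p_first = choice_probability(params, context, first, second)
    return first if rng.random() < p_first else second


def simulate_experiment(
    params: BiasParameters,
    design: ExperimentDesign,
    layout: TableLayout = TableLayout.FOUR_CELL,
    rng: np.random.Generator | int | None = None,
) -> CountTable:
    """Simulate one full experiment participant by participant."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    table = CountTable.zeros(layout)
    cells = table.cells.copy()
    for i, context in enumerate(CONTEXTS):
        for assignment in counterbalanced_assignments(design.n(context), context, design):
            produced = simulate_participant(params, context, assignment, rng)
            j = SOURCES.index(produced.source)
            if layout is TableLayout.FOUR_CELL:
                cells[i, j] += 1
            else:
                cells[i, j, ORDERS.index(produced.order)] += 1
    return CountTable(layout, cells)


def cell_rng(seed: int, cell_index: int) -> np.random.Generator:
    """The deterministic RNG substream for one parameter-grid cell.

    Derived from ``(seed, cell_index)`` so batch results do not depend on
    execution order or chunking.
    """
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(cell_index,)))


def _stratum_probabilities(
    params: BiasParameters, context: TransmissionContext
) -> tuple[float, float]:
    """P(expert variant) for the expert-first and expert-last strata."""
    p_first = expert_production_probability(
        params.expert_bias,
        params.congruent_bias,
        params.primacy_bias,
        context=context,
        expert_order=Order.FIRST,
    )
    p_last = expert_production_probability(
        params.expert_bias,
        params.congruent_bias,
        params.primacy_bias,
        context=context,
        expert_order=Order.LAST,
    )
    return float(p_first), float(p_last)


def simulate_counts_batch(
    params_cells: Sequence[BiasParameters],
    design: ExperimentDesign,
    n_sims: int,
    layout: TableLayout = TableLayout.FOUR_CELL,
    seed: int = 0,
    cell_offset: int = 0,
    method: str = "binomial",
) -> np.ndarray:
    """Simulate ``n_sims`` experiments for each parameter cell.

    Returns an integer array of shape ``(n_cells, n_sims, 2, 2)`` for the
    four-cell layout or ``(n_cells, n_sims, 2, 2, 2)`` for the eight-cell
    layout, indexed like :class:`CountTable.cells`.

    ``method="binomial"`` draws each order stratum's expert count directly
    from its binomial law (distributionally identical to per-participant
    simulation, and the default); ``method="participant"`` replays
    :func:`simulate_experiment` draw by draw on the same substream, so a
    single-simulation call reproduces it bit for bit.

    Substream ``cell_offset + i`` drives cell ``i``, making chunked and
    whole-grid invocations agree.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if method not in ("binomial", "participant"):
        raise ValueError(f"unknown method {method!r}")

    n_cells = len(params_cells)
    shape = (2, 2) if layout is TableLayout.FOUR_CELL else (2, 2, 2)
    out = np.empty((n_cells, n_sims) + shape, dtype=np.int16)

    for i, params in enumerate(params_cells):
        rng = cell_rng(seed, cell_offset + i)
        if method == "participant":
            for s in range(n_sims):
                out[i, s] = simulate_experiment(params, design, layout, rng).cells
            continue
        for ci, context in enumerate(CONTEXTS):
            n = design.n(context)
            if layout is TableLayout.FOUR_CELL and params.primacy_bias == 0.0:
                # order factor cancels: the expert count is one binomial
                p = expert_production_probability(
                    params.expert_bias, params.congruent_bias, context=context
                )
                expert = rng.binomial(n, p, size=n_sims)
                out[i, :, ci, 0] = expert
                out[i, :, ci, 1] = n - expert
                continue
            n_first, n_last = design.order_split(context)
            p_first, p_last = _stratum_probabilities(params, context)
            k_first = rng.binomial(n_first, p_first, size=n_sims)
            k_last = rng.binomial(n_last, p_last, size=n_sims)
            if layout is TableLayout.FOUR_CELL:
                expert = k_first + k_last
                out[i, :, ci, 0] = expert
                out[i, :, ci, 1] = design.n(context) - expert
            else:
                # expert-first stratum produces (expert, first) or (peer, last)
                out[i, :, ci, 0, 0] = k_first
                out[i, :, ci, 0, 1] = k_last
                out[i, :, ci, 1, 0] = n_last - k_last
                out[i, :, ci, 1, 1] = n_first - k_first
    return out
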