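"""Grid-search rejection estimation of transmission-bias magnitudes.

For every parameter combination on a lattice over the bias cube, the
experiment is simulated many times; a simulation *matches* when every cell
of its count table equals the observed table (within an integer tolerance).
The multiset of parameter values attached to all matching runs — the match
distribution — is summarized by its per-parameter weighted mean, SD and
t statistics.  This is rejection sampling over a uniform lattice, i.e. a
grid-based approximate Bayesian computation with a 0/1 kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import stats

from .choice_model import BiasParameters
from .simulator import CountTable, ExperimentDesign, simulate_counts_batch

__all__ = [
    "GridAxis",
    "GridSpec",
    "MatchGrid",
    "ParameterSummary",
    "TwoSampleComparison",
    "MatchSummary",
    "InsufficientMatchesError",
    "is_match",
    "run_grid",
    "summarize_matches",
    "export_grid",
]

PARAM_NAMES = ("expert_bias", "congruent_bias", "primacy_bias")


class InsufficientMatchesError(RuntimeError):
    """Raised when a match distribution is too small to summarize."""


@dataclass(frozen=True)
class GridAxis:
    """One inclusive parameter axis ``start, start+step, ..., stop``."""

    start: float = -1.0
    stop: float = 1.0
    step: float = 0.01

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.start > self.stop:
            raise ValueError("start must not exceed stop")

    @property
    def n_points(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    def values(self) -> np.ndarray:
        return np.linspace(self.start, self.stop, self.n_points)


@dataclass(frozen=True)
class GridSpec:
    """Lattice + simulation settings for one rejection-estimation run."""

    expert_axis: GridAxis = GridAxis()
    congruent_axis: GridAxis = GridAxis()
    primacy_axis: GridAxis | None = None
    n_sims: int = 5000
    match_tolerance: int = 0

    def __post_init__(self) -> None:
        if self.n_sims < 1:
            raise ValueError("n_sims must be >= 1")
        if self.match_tolerance < 0:
            raise ValueError("match_tolerance must be >= 0")

    @classmethod
    def two_parameter(
        cls, step: float = 0.01, n_sims: int = 5000, match_tolerance: int = 0
    ) -> "GridSpec":
        """The two-bias run: steps of 0.01, 5000 simulations, exact matching."""
        axis = GridAxis(step=step)
        return cls(axis, axis, None, n_sims, match_tolerance)

    @classmethod
    def three_parameter(
        cls,
        step: float = 0.1,
        primacy_step: float = 0.05,
        n_sims: int = 5000,
        match_tolerance: int = 1,
    ) -> "GridSpec":
        """The three-bias run: coarser 0.1/0.1/0.05 lattice, +/-1 matching."""
        axis = GridAxis(step=step)
        return cls(axis, axis, GridAxis(step=primacy_step), n_sims, match_tolerance)

    @property
    def param_names(self) -> tuple[str, ...]:
        return PARAM_NAMES[: 3 if self.primacy_axis is not None else 2]

    @property
    def shape(self) -> tuple[int, ...]:
        shape = (self.expert_axis.n_points, self.congruent_axis.n_points)
        if self.primacy_axis is not None:
            shape += (self.primacy_axis.n_points,)
        return shape

    @property
    def n_cells(self) -> int:
        return int(np.prod(self.shape))

    def axis_values(self) -> dict[str, np.ndarray]:
        out = {
            "expert_bias": self.expert_axis.values(),
            "congruent_bias": self.congruent_axis.values(),
        }
        if self.primacy_axis is not None:
            out["primacy_bias"] = self.primacy_axis.values()
        return out

    def param_meshes(self) -> dict[str, np.ndarray]:
        """Per-parameter value arrays of shape ``self.shape`` (ij indexing)."""
        values = self.axis_values()
        meshes = np.meshgrid(*values.values(), indexing="ij")
        return dict(zip(values.keys(), meshes))

    def iter_cells(self) -> Iterator[BiasParameters]:
        """Cells in row-major order; the iteration index is the substream index."""
        meshes = self.param_meshes()
        eb = meshes["expert_bias"].ravel()
        cb = meshes["congruent_bias"].ravel()
        pb = (
            meshes["primacy_bias"].ravel()
            if self.primacy_axis is not None
            else np.zeros(self.n_cells)
        )
        # clip ulp-level linspace overshoot at the cube edge
        for e, c, p in zip(eb, cb, pb):
            yield BiasParameters(
                float(np.clip(e, -1, 1)), float(np.clip(c, -1, 1)), float(np.clip(p, -1, 1))
            )


@dataclass(frozen=True)
class MatchGrid:
    """Per-cell match counts from one grid-search run."""

    spec: GridSpec
    matches: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        matches = np.asarray(self.matches, dtype=np.int64)
        if matches.shape != self.spec.shape:
            raise ValueError(f"matches must have shape {self.spec.shape}")
        if np.any(matches < 0) or np.any(matches > self.spec.n_sims):
            raise ValueError("match counts must lie in [0, n_sims]")
        object.__setattr__(self, "matches", matches)

    @property
    def total_matches(self) -> int:
        return int(self.matches.sum())

    def to_frame(self) -> pd.DataFrame:
        meshes = self.spec.param_meshes()
        data = {name: mesh.ravel() for name, mesh in meshes.items()}
        data["matches"] = self.matches.ravel()
        data["n_sims"] = np.full(self.spec.n_cells, self.spec.n_sims)
        return pd.DataFrame(data)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, match_tolerance: int = 0) -> "MatchGrid":
        df = pd.read_csv(path)
        names = [n for n in PARAM_NAMES if n in df.columns]
        axes = {}
        for name in names:
            vals = np.sort(df[name].unique())
            step = float(vals[1] - vals[0]) if len(vals) > 1 else 1.0
            axes[name] = GridAxis(float(vals[0]), float(vals[-1]), round(step, 12))
        spec = GridSpec(
            expert_axis=axes["expert_bias"],
            congruent_axis=axes["congruent_bias"],
            primacy_axis=axes.get("primacy_bias"),
            n_sims=int(df["n_sims"].iloc[0]),
            match_tolerance=match_tolerance,
        )
        df = df.sort_values(names, kind="stable")
        matches = df["matches"].to_numpy().reshape(spec.shape)
        return cls(spec, matches)


def is_match(simulated: CountTable, observed: CountTable, tolerance: int = 0) -> bool:
    """True iff every cell deviates from the observed count by at most ``tolerance``."""
    if simulated.layout is not observed.layout:
        raise ValueError(
            f"layout mismatch: {simulated.layout} vs {observed.layout}"
        )
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    return bool(np.all(np.abs(simulated.cells - observed.cells) <= tolerance))


def _validate_observed(observed: CountTable, design: ExperimentDesign) -> None:
    from .simulator import CONTEXTS

    for context in CONTEXTS:
        if observed.context_total(context) != design.n(context):
            raise ValueError(
                f"observed counts sum to {observed.context_total(context)} in "
                f"{context.value} but the design has {design.n(context)} participants"
            )


def run_grid(
    observed: CountTable,
    design: ExperimentDesign,
    grid: GridSpec,
    seed: int = 0,
    chunk_size: int = 1024,
) -> MatchGrid:
    """Simulate every lattice cell and count its matching runs.

    Reproducible: cell ``i`` (row-major) always consumes RNG substream
    ``(seed, i)`` regardless of ``chunk_size``.
    """
    _validate_observed(observed, design)
    layout = observed.layout
    matches = np.empty(grid.n_cells, dtype=np.int64)
    obs = observed.cells
    cells = list(grid.iter_cells())
    for lo in range(0, grid.n_cells, chunk_size):
        chunk = cells[lo : lo + chunk_size]
        sims = simulate_counts_batch(
            chunk, design, grid.n_sims, layout, seed=seed, cell_offset=lo
        )
        dev = np.abs(sims.astype(np.int64) - obs)
        flat = dev.reshape(dev.shape[0], dev.shape[1], -1)
        matches[lo : lo + len(chunk)] = (
            (flat <= grid.match_tolerance).all(axis=2).sum(axis=1)
        )
    return MatchGrid(grid, matches.reshape(grid.shape))


@dataclass(frozen=True)
class ParameterSummary:
    """Weighted summary of one parameter's match distribution."""

    name: str
    mean: float
    sd: float
    n: int
    t_statistic: float
    df: int
    p_value: float


@dataclass(frozen=True)
class TwoSampleComparison:
    """Two-sample t comparison between two parameters' match distributions."""

    name_a: str
    name_b: str
    t_statistic: float
    df: float
    p_value: float
    welch: bool


@dataclass(frozen=True)
class MatchSummary:
    parameters: dict[str, ParameterSummary]
    comparisons: tuple[TwoSampleComparison, ...]
    total_matches: int

    def to_dict(self) -> dict:
        return {
            "total_matches": self.total_matches,
            "parameters": {
                name: {
                    "mean": p.mean,
                    "sd": p.sd,
                    "n": p.n,
                    "t_statistic": p.t_statistic,
                    "df": p.df,
                    "p_value": p.p_value,
                }
                for name, p in self.parameters.items()
            },
            "comparisons": [
                {
                    "a": c.name_a,
                    "b": c.name_b,
                    "t_statistic": c.t_statistic,
                    "df": c.df,
                    "p_value": c.p_value,
                    "welch": c.welch,
                }
                for c in self.comparisons
            ],
        }


def _weighted_moments(values: np.ndarray, weights: np.ndarray) -> tuple[float, float, int]:
    """Mean and sample SD of the multiset repeating ``values`` ``weights`` times."""
    n = int(weights.sum())
    mean = float((values * weights).sum() / n)
    ss = float((weights * (values - mean) ** 2).sum())
    sd = float(np.sqrt(ss / (n - 1)))
    return mean, sd, n


def summarize_matches(grid: MatchGrid, welch: bool = True) -> MatchSummary:
    """Summarize the match distribution of every searched parameter.

    The match distribution of a parameter is the multiset holding, for each
    matching simulation run, the parameter value of that run's grid cell;
    its size is the grid's total match count.  Means, SDs and t statistics
    are computed on this multiset in closed form from the weighted moments.

    Raises
    ------
    InsufficientMatchesError
        Fewer than two matching runs: the SD and t are undefined.
    """
    total = grid.total_matches
    if total < 2:
        raise InsufficientMatchesError(
            f"only {total} matching run(s); mean/SD/t undefined"
        )
    weights = grid.matches.ravel().astype(float)
    meshes = grid.spec.param_meshes()

    parameters: dict[str, ParameterSummary] = {}
    for name in grid.spec.param_names:
        values = meshes[name].ravel()
        mean, sd, n = _weighted_moments(values, weights)
        if sd > 0:
            t = mean / (sd / np.sqrt(n))
            p = float(2 * stats.t.sf(abs(t), n - 1))
        else:
            t, p = (np.inf if mean > 0 else (-np.inf if mean < 0 else 0.0)), (
                0.0 if mean != 0 else 1.0
            )
        parameters[name] = ParameterSummary(name, mean, sd, n, float(t), n - 1, p)

    comparisons = []
    names = list(parameters)
    for ia in range(len(names)):
        for ib in range(ia + 1, len(names)):
            a, b = parameters[names[ia]], parameters[names[ib]]
            va, vb = a.sd**2, b.sd**2
            if va == 0.0 and vb == 0.0:
                # all matches in one cell per parameter: comparison degenerates
                diff = a.mean - b.mean
                t = 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
                df = float(a.n + b.n - 2)
                comparisons.append(
                    TwoSampleComparison(
                        a.name, b.name, t, df, 1.0 if diff == 0 else 0.0, welch
                    )
                )
                continue
            if welch:
                se2 = va / a.n + vb / b.n
                t = (a.mean - b.mean) / np.sqrt(se2)
                df = se2**2 / (
                    (va / a.n) ** 2 / (a.n - 1) + (vb / b.n) ** 2 / (b.n - 1)
                )
            else:
                sp2 = ((a.n - 1) * va + (b.n - 1) * vb) / (a.n + b.n - 2)
                t = (a.mean - b.mean) / np.sqrt(sp2 * (1 / a.n + 1 / b.n))
                df = a.n + b.n - 2
            p = float(2 * stats.t.sf(abs(t), df))
            comparisons.append(
                TwoSampleComparison(a.name, b.name, float(t), float(df), p, welch)
            )
    return MatchSummary(parameters, tuple(comparisons), total)


def export_grid(
    grid: MatchGrid, path: str | Path, heatmap: str | Path | None = None
) -> None:
    """Write the grid as long-format CSV; optionally render a match heatmap.

    The heatmap (lighter = more matches) is available for two-parameter
    grids; three-parameter grids are exported as CSV only.
    """
    grid.to_csv(path)
    if heatmap is None:
        return
    if grid.spec.primacy_axis is not None:
        raise ValueError("heatmap rendering supports two-parameter grids only")
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.imshow(
        grid.matches.T,
        origin="lower",
        extent=(
            grid.spec.expert_axis.start,
            grid.spec.expert_axis.stop,
            grid.spec.congruent_axis.start,
            grid.spec.congruent_axis.stop,
        ),
        aspect="auto",
        cmap="viridis",
    )
    ax.set_xlabel("expert bias")
    ax.set_ylabel("congruence bias")
    ax.set_title(f"matches out of {grid.spec.n_sims} per cell")
    fig.tight_layout()
    fig.savefig(heatmap, dpi=150)
    plt.close(fig)
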