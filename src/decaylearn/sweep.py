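"""Parameter sweep over (learning rate, decay) for Hebbian learning.

For every grid cell (k, d) the sweep regenerates the task ``n_replicates``
times (common replicate seeds across cells, so cells differ only in their
parameters), trains a Hebbian learner from zero weights, and records two
summaries:

* the Pearson (optionally Spearman) correlation between the per-trial |PE|
  and |dW| series, averaged over replicates whose correlation is defined;
* the mean post-training classification error E.

A replicate's correlation is *undefined* — flagged, excluded from the mean —
when either series is constant (e.g. k = 0 gives |dW| identically zero from
a zero start) or when fewer than 3 usable trials remain.

By default, trials whose prediction is degenerate (a cue that has never been
presented leaves the normalized prediction's denominator at zero, so a
uniform fallback is substituted) are *excluded* from the correlation: the
prediction-error of the model is undefined there, and the fallback value
reflects the fallback convention rather than the learning dynamics.  Set
``include_degenerate=True`` to keep them.

Note an exact structural property of a zero-weight start: Hebbian weights
are linear in k, and both the normalized prediction and the Pearson
correlation are invariant to a positive rescaling of one series, so the
correlation and classification-error maps are constant along the k axis.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import classification_error, record_session
from .rules import HEBBIAN, LearningParams
from .tasks import ConfigError, TaskConfig, generate_task

PEARSON = "pearson"
SPEARMAN = "spearman"

__all__ = [
    "SweepConfig",
    "CellResult",
    "SweepResult",
    "default_grid",
    "replicate_seed",
    "run_cell",
    "run_sweep",
]


def default_grid(n: int = 10, low: float = 0.05, high: float = 0.95) -> tuple[float, ...]:
    """Uniform parameter grid, by default 10 points over [0.05, 0.95].

    The same grid serves k and d.  The upper end stops short of d = 1
    because a full-decay network is memoryless — it retains only the
    immediately preceding trial, leaving every other cue's prediction
    degenerate — which falls outside plausible learning dynamics.
    """
    return tuple(np.linspace(low, high, n).tolist())


def _validate_grid(name: str, grid, low: float, high: float, inclusive_low: bool) -> None:
    grid = list(grid)
    if not grid:
        raise ConfigError(name, "grid must be non-empty")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ConfigError(name, "grid must be strictly increasing")
    lo_ok = grid[0] >= low if inclusive_low else grid[0] > low
    if not (lo_ok and grid[-1] <= high):
        bracket = "[" if inclusive_low else "("
        raise ConfigError(name, f"grid values must lie in {bracket}{low}, {high}], got {grid}")


@dataclass(frozen=True)
class SweepConfig:
    """Grid, task, replicate count and seed for one sweep."""

    k_grid: tuple = field(default_factory=default_grid)
    d_grid: tuple = field(default_factory=default_grid)
    task: TaskConfig = field(default_factory=TaskConfig)
    n_replicates: int = 20
    seed: int = 0
    method: str = PEARSON
    include_degenerate: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "k_grid", tuple(float(k) for k in self.k_grid))
        object.__setattr__(self, "d_grid", tuple(float(d) for d in self.d_grid))
        _validate_grid("k_grid", self.k_grid, 0.0, 1.0 - 1e-12, inclusive_low=True)
        _validate_grid("d_grid", self.d_grid, 0.0, 1.0, inclusive_low=False)
        if self.n_replicates < 1:
            raise ConfigError("n_replicates", f"must be positive, got {self.n_replicates!r}")
        if self.method not in (PEARSON, SPEARMAN):
            raise ConfigError("method", f"must be {PEARSON!r} or {SPEARMAN!r}")


@dataclass(frozen=True)
class CellResult:
    """Mean correlation / error for one (k, d) cell."""

    correlation: float  # NaN when undefined in every replicate
    error: float
    n_defined: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.correlation)


def replicate_seed(seed: int, rep: int) -> int:
    """Derive a child seed (< 2**31) for one replicate from the root seed."""
    state = np.random.SeedSequence([int(seed), int(rep)]).generate_state(1)[0]
    return int(state & 0x7FFFFFFF)


def _series_correlation(pe: np.ndarray, dw: np.ndarray, method: str) -> float:
    if len(pe) < 3 or np.ptp(pe) == 0.0 or np.ptp(dw) == 0.0:
        return float("nan")
    if method == SPEARMAN:
        return float(stats.spearmanr(pe, dw).statistic)
    return float(stats.pearsonr(pe, dw).statistic)


def run_cell(
    k: float,
    d: float,
    task_config: TaskConfig,
    n_replicates: int = 20,
    seed: int = 0,
    method: str = PEARSON,
    include_degenerate: bool = False,
) -> CellResult:
    """Correlation between |PE| and |dW|, and mean E, at one (k, d) point."""
    params = LearningParams(HEBBIAN, k, d)
    correlations = []
    errors = []
    for rep in range(n_replicates):
        config = replace(task_config, seed=replicate_seed(seed, rep))
        sequence = generate_task(config)
        trace = record_session(sequence, params)
        pe, dw = trace.series(include_degenerate=include_degenerate)
        correlations.append(_series_correlation(pe, dw, method))
        errors.append(classification_error(trace.final_state, config))
    defined = [r for r in correlations if not math.isnan(r)]
    correlation = float(np.mean(defined)) if defined else float("nan")
    return CellResult(correlation=correlation, error=float(np.mean(errors)), n_defined=len(defined))


@dataclass(frozen=True, eq=False)
class SweepResult:
    """Correlation and error grids (k along rows, d along columns)."""

    correlation: np.ndarray
    error: np.ndarray
    n_defined: np.ndarray
    config: SweepConfig

    @property
    def n_trials_used(self) -> int:
        return self.config.task.n_trials

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for a, k in enumerate(self.config.k_grid):
            for b, d in enumerate(self.config.d_grid):
                rows.append(
                    {
                        "k": k,
                        "d": d,
                        "correlation": self.correlation[a, b],
                        "error": self.error[a, b],
                        "n_defined_replicates": int(self.n_defined[a, b]),
                    }
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def to_json(self, path) -> None:
        payload = {
            "config": {
                "k_grid": list(self.config.k_grid),
                "d_grid": list(self.config.d_grid),
                "task": asdict(self.config.task),
                "n_replicates": self.config.n_replicates,
                "seed": self.config.seed,
                "method": self.config.method,
                "include_degenerate": self.config.include_degenerate,
            },
            "n_trials_used": self.n_trials_used,
            "correlation": [
                [None if math.isnan(v) else v for v in row] for row in self.correlation.tolist()
            ],
            "error": self.error.tolist(),
            "n_defined": self.n_defined.astype(int).tolist(),
        }
        with open(path, "w") as handle:
            json.dump(payload, handle, indent=2)

    def plot_heatmaps(self, path=None):
        """Side-by-side heatmaps: correlation (left) and classification error (right)."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, (ax_corr, ax_err) = plt.subplots(1, 2, figsize=(11, 4.5), constrained_layout=True)
        extent = (
            self.config.d_grid[0],
            self.config.d_grid[-1],
            self.config.k_grid[0],
            self.config.k_grid[-1],
        )
        im0 = ax_corr.imshow(
            self.correlation, origin="lower", aspect="auto", extent=extent,
            vmin=-1, vmax=1, cmap="RdBu_r",
        )
        ax_corr.set_title("corr(|PE|, |dW|)")
        im1 = ax_err.imshow(
            self.error, origin="lower", aspect="auto", extent=extent, cmap="viridis"
        )
        ax_err.set_title("classification error E")
        for ax in (ax_corr, ax_err):
            ax.set_xlabel("decay rate d")
            ax.set_ylabel("learning rate k")
        fig.colorbar(im0, ax=ax_corr)
        fig.colorbar(im1, ax=ax_err)
        if path is not None:
            fig.savefig(path, dpi=150)
            plt.close(fig)
        return fig


def run_sweep(config: SweepConfig) -> SweepResult:
    """Evaluate :func:`run_cell` on every (k, d) grid point.

    Replicate seeds depend only on the root seed, so all cells see the same
    task realizations (common random numbers across the grid).
    """
    shape = (len(config.k_grid), len(config.d_grid))
    correlation = np.full(shape, np.nan)
    error = np.zeros(shape)
    n_defined = np.zeros(shape, dtype=int)
    for a, k in enumerate(config.k_grid):
        for b, d in enumerate(config.d_grid):
            cell = run_cell(
                k,
                d,
                config.task,
                n_replicates=config.n_replicates,
                seed=config.seed,
                method=config.method,
                include_degenerate=config.include_degenerate,
            )
            correlation[a, b] = cell.correlation
            error[a, b] = cell.error
            n_defined[a, b] = cell.n_defined
    return SweepResult(correlation=correlation, error=error, n_defined=n_defined, config=config)
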