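"""Factorial experiment grid: judge counts x item counts x replicates.

The default grid crosses panel sizes {5, 10, 15, 20, 30, 50, 80} with test
lengths {5, 10, 15, 20, 30, 50, 80} and simulates each of the 49
combinations 100 times, for 4900 independent panels.  Results are
materialised as a long-format table, one row per panel, written and read
as plain CSV.

Seeding: each panel's stream is spawned from
``SeedSequence(master_seed, spawn_key=(n_judges, n_items, replicate_id))``,
so the spawning scheme is collision-free by construction and any subset of
the grid reproduces exactly the panels of the full run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .config import DEFAULT_CONFIG, SimulationConfig
from .engine import PanelConfig, simulate_panel

__all__ = [
    "DEFAULT_JUDGE_COUNTS",
    "DEFAULT_ITEM_COUNTS",
    "GridSpec",
    "RESULT_COLUMNS",
    "run_grid",
    "write_results",
    "read_results",
    "validate_results",
]

logger = logging.getLogger(__name__)

DEFAULT_JUDGE_COUNTS = (5, 10, 15, 20, 30, 50, 80)
DEFAULT_ITEM_COUNTS = (5, 10, 15, 20, 30, 50, 80)

#: Fixed column order of the long-format results table.
RESULT_COLUMNS = [
    "n_judges",
    "n_items",
    "replicate_id",
    "seed",
    "score1",
    "score2",
    "abs_score1",
    "abs_score2",
    "within_panel_sd",
    "mean_accuracy",
    "mean_stringency",
    "mean_leadership",
]

_KEY = ["n_judges", "n_items", "replicate_id"]


@dataclass(frozen=True)
class GridSpec:
    """Definition of a factorial simulation experiment."""

    judge_counts: tuple[int, ...] = DEFAULT_JUDGE_COUNTS
    item_counts: tuple[int, ...] = DEFAULT_ITEM_COUNTS
    replicates: int = 100
    master_seed: int = 0

    def __post_init__(self) -> None:
        for name, counts in (
            ("judge_counts", self.judge_counts),
            ("item_counts", self.item_counts),
        ):
            counts = tuple(int(c) for c in counts)
            object.__setattr__(self, name, counts)
            if not counts:
                raise ValueError(f"{name} must be non-empty")
            if any(c < 1 for c in counts):
                raise ValueError(f"{name} must be positive")
            if any(b <= a for a, b in zip(counts, counts[1:])):
                raise ValueError(f"{name} must be strictly increasing")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @property
    def n_combinations(self) -> int:
        return len(self.judge_counts) * len(self.item_counts)

    @property
    def n_panels(self) -> int:
        return self.n_combinations * self.replicates


def run_grid(
    spec: GridSpec = GridSpec(),
    config: SimulationConfig = DEFAULT_CONFIG,
    progress: bool = False,
) -> pd.DataFrame:
    """Simulate every (combination, replicate) panel of the grid.

    Returns the long-format results table in lexicographic
    (n_judges, n_items, replicate_id) order; fully deterministic given
    ``spec.master_seed`` and ``config``.
    """
    rows = []
    for n_judges in spec.judge_counts:
        for n_items in spec.item_counts:
            if progress:
                logger.info(
                    "simulating %d panels of %d judges x %d items",
                    spec.replicates, n_judges, n_items,
                )
            for rep in range(spec.replicates):
                pc = PanelConfig(
                    n_judges=n_judges,
                    n_items=n_items,
                    replicate_id=rep,
                    seed=spec.master_seed,
                )
                res = simulate_panel(pc, config)
                rows.append(
                    (
                        n_judges,
                        n_items,
                        rep,
                        spec.master_seed,
                        res.score1,
                        res.score2,
                        abs(res.score1),
                        abs(res.score2),
                        res.within_panel_sd,
                        res.mean_accuracy,
                        res.mean_stringency,
                        res.mean_leadership,
                    )
                )
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    return table


def validate_results(table: pd.DataFrame) -> pd.DataFrame:
    """Check the results-table schema and invariants; returns the table."""
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"results table is missing columns: {missing}")
    if table.duplicated(subset=_KEY).any():
        raise ValueError("duplicate (n_judges, n_items, replicate_id) keys")
    numeric = table[RESULT_COLUMNS].to_numpy(dtype=float)
    if not np.isfinite(numeric).all():
        raise ValueError("results table contains non-finite values")
    return table[RESULT_COLUMNS]


def write_results(table: pd.DataFrame, path: str | Path) -> Path:
    """Write the results table as CSV with the documented column order."""
    path = Path(path)
    if not path.suffix:
        raise ValueError(f"output path {path} needs a file extension")
    validate_results(table)
    table.to_csv(path, index=False, columns=RESULT_COLUMNS)
    return path


def read_results(path: str | Path) -> pd.DataFrame:
    """Read and validate a results CSV written by :func:`write_results`."""
    table = pd.read_csv(path)
    return validate_results(table)
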