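"""Two-round Angoff scoring engine.

A panel of n judges rates k items.  Each (judge, item) cell receives the
score

    score_ji = (Ji * Wa + mean(Sji, Sa) * Ws) / (Wa + Ws)

i.e. a weight-mixed combination of the judge's random error component and
their stringency component, where mean(.,.) is the plain arithmetic mean
of the two item-level stringency draws.  The round-1 panel cut-score is
the grand mean of the n*k cell scores.  In round 2 each cell is multiplied
by that judge's leadership weight

    w_ji = (mean(Lji, La) + 3) / 3

and the grand mean is taken again with the same n*k divisor (weights are
not renormalised; `round2_normalize` switches to a proper weighted
average).  The true cut-score is 0 by construction, so a panel's precision
is simply |cut-score|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DEFAULT_CONFIG, SimulationConfig
from .judges import (
    ItemDraws,
    JudgeAttributes,
    PanelAttributes,
    sample_item_draws,
    sample_panel_attributes,
)

__all__ = [
    "PanelConfig",
    "PanelResult",
    "item_score",
    "item_score_matrix",
    "leadership_weight",
    "leadership_weight_matrix",
    "panel_round1",
    "panel_round2",
    "within_panel_sd",
    "simulate_panel",
]


@dataclass(frozen=True)
class PanelConfig:
    """Identity of one simulated panel within the experiment grid.

    ``seed`` is the experiment's master seed; the panel's private random
    stream is spawned from ``(seed, n_judges, n_items, replicate_id)``, so
    any panel is reproducible in isolation from its table row alone.
    """

    n_judges: int
    n_items: int
    replicate_id: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_judges < 1:
            raise ValueError("n_judges must be >= 1")
        if self.n_items < 1:
            raise ValueError("n_items must be >= 1")
        if self.replicate_id < 0:
            raise ValueError("replicate_id must be >= 0")

    def spawn_rng(self) -> np.random.Generator:
        ss = np.random.SeedSequence(
            entropy=self.seed,
            spawn_key=(self.n_judges, self.n_items, self.replicate_id),
        )
        return np.random.default_rng(ss)


@dataclass(frozen=True)
class PanelResult:
    """One panel's cut-scores and summary attributes."""

    score1: float
    score2: float
    within_panel_sd: float
    mean_accuracy: float
    mean_stringency: float
    mean_leadership: float
    config: PanelConfig


def item_score(judge: JudgeAttributes, draws: ItemDraws) -> float:
    """Score of one (judge, item) cell: weighted mix of error and stringency."""
    wa, ws = judge.weight_accuracy, judge.weight_stringency
    total = wa + ws
    if total <= 0:
        raise ValueError("Wa + Ws must be positive")
    stringency_part = 0.5 * (draws.stringency_draw + draws.stringency_accuracy_draw)
    return (draws.raw_score * wa + stringency_part * ws) / total


def item_score_matrix(
    panel: PanelAttributes, draws: dict[str, np.ndarray]
) -> np.ndarray:
    """All n*k cell scores as an (n_judges, n_items) matrix."""
    wa = panel.weight_accuracy[:, None]
    ws = panel.weight_stringency[:, None]
    total = wa + ws
    if np.any(total <= 0):
        raise ValueError("Wa + Ws must be positive for every judge")
    stringency_part = 0.5 * (
        draws["stringency_draw"] + draws["stringency_accuracy_draw"]
    )
    return (draws["raw_score"] * wa + stringency_part * ws) / total


def leadership_weight(judge: JudgeAttributes, draws: ItemDraws) -> float:
    """Round-2 multiplicative weight of one cell, mean ~= 1."""
    return (0.5 * (draws.leadership_draw + draws.leadership_accuracy_draw) + 3.0) / 3.0


def leadership_weight_matrix(draws: dict[str, np.ndarray]) -> np.ndarray:
    return (
        0.5 * (draws["leadership_draw"] + draws["leadership_accuracy_draw"]) + 3.0
    ) / 3.0


def panel_round1(per_item_scores: np.ndarray) -> float:
    """Round-1 cut-score: grand mean of the n*k cell scores."""
    scores = np.asarray(per_item_scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score matrix")
    return float(scores.mean())


def panel_round2(
    per_item_scores: np.ndarray,
    weights: np.ndarray,
    normalize: bool = False,
) -> float:
    """Round-2 cut-score: leadership-weighted cells, divided by n*k.

    With ``normalize=True`` the divisor is the sum of the weights instead,
    turning the statistic into a proper weighted average.
    """
    scores = np.asarray(per_item_scores, dtype=float)
    w = np.asarray(weights, dtype=float)
    if scores.shape != w.shape:
        raise ValueError(f"shape mismatch: scores {scores.shape} vs weights {w.shape}")
    if scores.size == 0:
        raise ValueError("empty score matrix")
    weighted = scores * w
    if normalize:
        return float(weighted.sum() / w.sum())
    return float(weighted.mean())


def within_panel_sd(per_item_scores: np.ndarray) -> float:
    """Sample SD (ddof=1) across judges of each judge's mean item score.

    Measures judge agreement: 0 for a single judge or identical judge
    means.
    """
    scores = np.asarray(per_item_scores, dtype=float)
    if scores.ndim != 2 or scores.size == 0:
        raise ValueError("expected a non-empty (n_judges, n_items) matrix")
    judge_means = scores.mean(axis=1)
    if judge_means.shape[0] == 1:
        return 0.0
    return float(judge_means.std(ddof=1))


def simulate_panel(
    config: PanelConfig, sim_config: SimulationConfig = DEFAULT_CONFIG
) -> PanelResult:
    """Simulate one complete two-round panel from its seed."""
    rng = config.spawn_rng()
    panel = sample_panel_attributes(config.n_judges, rng, sim_config)
    draws = sample_item_draws(panel, config.n_items, rng, sim_config)
    scores = item_score_matrix(panel, draws)
    weights = leadership_weight_matrix(draws)
    return PanelResult(
        score1=panel_round1(scores),
        score2=panel_round2(scores, weights, normalize=sim_config.round2_normalize),
        within_panel_sd=within_panel_sd(scores),
        mean_accuracy=float(panel.accuracy.mean()),
        mean_stringency=float(panel.stringency.mean()),
        mean_leadership=float(panel.leadership.mean()),
        config=config,
    )
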