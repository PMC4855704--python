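"""Judge-attribute sampler: the data-generating process of the study.

Every judge is described by five constants drawn once per judge --
accuracy A (dispersion of their random item error; smaller = more expert),
stringency S (systematic harshness/leniency), leadership L (influence on
the second round), and the two relative weights Wa, Ws mixing the accuracy
and stringency components of each item judgement.  Item-level quantities
are then drawn conditionally on those constants, independently per
(judge, item) cell:

===========  =========================  =======================
quantity     distribution               role
===========  =========================  =======================
A            |N(0,1)| (default)         error dispersion
S            N(0,1)                     stringency location
L            N(0,1)                     leadership location
Wa, Ws       (N(0,1)+3)/3, floored      component weights
Ji           N(0, A)                    raw item error
Sji          N(S, 1)                    item stringency
Sa           N(1-A, 1)                  accuracy->stringency
Lji          N(L, 1)                    item leadership (round 2)
La           N(1-A, 1)                  accuracy->leadership
===========  =========================  =======================

The ``1 - A`` means encode the assumption that experts (small A) are both
more stringent and more influential.  All scales are standardised; the true
cut-score is 0 by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import DEFAULT_CONFIG, SimulationConfig

__all__ = [
    "JudgeAttributes",
    "ItemDraws",
    "PanelAttributes",
    "draw_judge",
    "draw_panel",
    "draw_item",
    "sample_panel_attributes",
    "sample_item_draws",
]


@dataclass(frozen=True)
class JudgeAttributes:
    """One judge's constant determinants, fixed across all items."""

    accuracy: float
    stringency: float
    leadership: float
    weight_accuracy: float
    weight_stringency: float

    def __post_init__(self) -> None:
        if self.accuracy < 0:
            raise ValueError("accuracy is a dispersion and must be >= 0")
        if self.weight_accuracy + self.weight_stringency <= 0:
            raise ValueError("weight_accuracy + weight_stringency must be > 0")


@dataclass(frozen=True)
class ItemDraws:
    """Item-level random components for one (judge, item) cell."""

    raw_score: float
    stringency_draw: float
    stringency_accuracy_draw: float
    leadership_draw: float
    leadership_accuracy_draw: float


@dataclass(frozen=True)
class PanelAttributes:
    """Column-vector view of a whole panel's judge attributes."""

    accuracy: np.ndarray
    stringency: np.ndarray
    leadership: np.ndarray
    weight_accuracy: np.ndarray
    weight_stringency: np.ndarray

    @property
    def n_judges(self) -> int:
        return self.accuracy.shape[0]

    def judge(self, j: int) -> JudgeAttributes:
        return JudgeAttributes(
            accuracy=float(self.accuracy[j]),
            stringency=float(self.stringency[j]),
            leadership=float(self.leadership[j]),
            weight_accuracy=float(self.weight_accuracy[j]),
            weight_stringency=float(self.weight_stringency[j]),
        )


def _transform_accuracy(z: np.ndarray, transform: str) -> np.ndarray:
    if transform == "abs":
        return np.abs(z)
    if transform == "square":
        return np.square(z)
    if transform == "truncate":
        return np.maximum(z, 0.0)
    raise ValueError(f"unknown accuracy transform {transform!r}")


def sample_panel_attributes(
    n_judges: int,
    rng: np.random.Generator,
    config: SimulationConfig = DEFAULT_CONFIG,
) -> PanelAttributes:
    """Draw the constant attributes for a whole panel at once.

    Attributes are drawn column-wise (all accuracies, then all
    stringencies, ...) so panel generation is a fixed, reproducible
    function of the generator state.
    """
    if n_judges < 1:
        raise ValueError("a panel needs at least one judge")
    z_a = rng.standard_normal(n_judges)
    stringency = rng.standard_normal(n_judges)
    leadership = rng.standard_normal(n_judges)
    w_a = (rng.standard_normal(n_judges) + 3.0) / 3.0
    w_s = (rng.standard_normal(n_judges) + 3.0) / 3.0
    floor = config.weight_floor
    return PanelAttributes(
        accuracy=_transform_accuracy(z_a, config.accuracy_transform),
        stringency=stringency,
        leadership=leadership,
        weight_accuracy=np.maximum(w_a, floor),
        weight_stringency=np.maximum(w_s, floor),
    )


def draw_judge(
    rng: np.random.Generator, config: SimulationConfig = DEFAULT_CONFIG
) -> JudgeAttributes:
    """Draw one judge's constant attributes from a seeded stream."""
    return sample_panel_attributes(1, rng, config).judge(0)


def draw_panel(
    n_judges: int,
    rng: np.random.Generator,
    config: SimulationConfig = DEFAULT_CONFIG,
) -> list[JudgeAttributes]:
    """Draw ``n_judges`` independent judges as a list."""
    panel = sample_panel_attributes(n_judges, rng, config)
    return [panel.judge(j) for j in range(panel.n_judges)]


def sample_item_draws(
    panel: PanelAttributes,
    n_items: int,
    rng: np.random.Generator,
    config: SimulationConfig = DEFAULT_CONFIG,
) -> dict[str, np.ndarray]:
    """Draw all item-level components for a panel; arrays are (n_judges, n_items).

    Each cell is independent given the judge attributes.  In the
    ``zero_stringency`` diagnostic the accuracy->stringency coupling Sa is
    centred at 0 instead of ``1 - A``, which removes the only biased
    component from the round-1 score.
    """
    if n_items < 1:
        raise ValueError("need at least one item")
    n = panel.n_judges
    shape = (n, n_items)
    a = panel.accuracy[:, None]
    sa_mean = np.zeros_like(a) if config.zero_stringency else 1.0 - a
    return {
        "raw_score": rng.standard_normal(shape) * a,
        "stringency_draw": rng.standard_normal(shape) + panel.stringency[:, None],
        "stringency_accuracy_draw": rng.standard_normal(shape) + sa_mean,
        "leadership_draw": rng.standard_normal(shape) + panel.leadership[:, None],
        "leadership_accuracy_draw": rng.standard_normal(shape) + (1.0 - a),
    }


def draw_item(
    judge: JudgeAttributes,
    rng: np.random.Generator,
    config: SimulationConfig = DEFAULT_CONFIG,
) -> ItemDraws:
    """Draw the five item-level components for a single (judge, item) cell."""
    if judge.accuracy < 0:
        raise ValueError("judge accuracy must be >= 0")
    panel = PanelAttributes(
        accuracy=np.array([judge.accuracy]),
        stringency=np.array([judge.stringency]),
        leadership=np.array([judge.leadership]),
        weight_accuracy=np.array([judge.weight_accuracy]),
        weight_stringency=np.array([judge.weight_stringency]),
    )
    draws = sample_item_draws(panel, 1, rng, config)
    return ItemDraws(
        raw_score=float(draws["raw_score"][0, 0]),
        stringency_draw=float(draws["stringency_draw"][0, 0]),
        stringency_accuracy_draw=float(draws["stringency_accuracy_draw"][0, 0]),
        leadership_draw=float(draws["leadership_draw"][0, 0]),
        leadership_accuracy_draw=float(draws["leadership_accuracy_draw"][0, 0]),
    )
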