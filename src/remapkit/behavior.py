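"""Behavioral scoring and design-derived chance levels.

The swapped-city design makes naive chance levels wrong: because a known
fraction of trials have a different correct response in City 1 than in City
2, a participant relying purely on the other similar city's layout is capped
well below ceiling, and one who guesses only on the conflicting trials has
an elevated "chance" level.  Both bounds follow from trial counting and are
computed exactly here.  Also provided: per-city retrieval scoring, and the
map-drawing learning metrics (per-round slopes and city-transition costs).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd

from .core import CITIES, TrialSpec

__all__ = [
    "StrategyBounds",
    "score_retrieval",
    "swap_strategy_bounds",
    "map_transition_cost",
    "learning_slope",
]


def score_retrieval(log: pd.DataFrame | list[TrialSpec]) -> dict[int, float]:
    """Proportion correct per city, pooled over both retrieval blocks.

    ``log`` is either a response table with ``city`` plus either a
    ``correct`` column or ``chosen_side``/``correct_side`` columns, or a
    list of :class:`TrialSpec`.
    """
    if isinstance(log, list):
        df = pd.DataFrame({"city": [t.city for t in log],
                           "correct": [t.correct for t in log]})
    else:
        df = log.copy()
        if "correct" not in df.columns:
            df["correct"] = df["chosen_side"] == df["correct_side"]
    if len(df) == 0:
        raise ValueError("empty response log")
    unknown = set(df["city"].unique()) - set(CITIES)
    if unknown:
        raise ValueError(f"unknown city codes: {sorted(unknown)}")
    return {int(c): float(g["correct"].mean()) for c, g in df.groupby("city")}


@dataclass(frozen=True)
class StrategyBounds:
    """Analytic accuracy bounds for response strategies on the swapped cities.

    ``max_transfer``: ceiling when answering City 2 purely from City 1
    knowledge (conflicting-response trials are all missed).
    ``guess_strategy``: expected accuracy when shared-response trials are
    all answered correctly and conflicting trials are guessed — the
    appropriate chance level for the similar cities.
    """

    max_transfer: Fraction
    guess_strategy: Fraction

    @property
    def max_transfer_accuracy(self) -> float:
        return float(self.max_transfer)

    @property
    def guess_strategy_accuracy(self) -> float:
        return float(self.guess_strategy)


def swap_strategy_bounds(n_trials: int, n_flipped: int) -> StrategyBounds:
    """Exact strategy bounds given the number of conflicting-response trials.

    With ``n_flipped`` of ``n_trials`` trials having a different correct
    response in the two similar cities: max transfer accuracy is
    (n - f) / n and the guess-on-conflicts chance level (n - f + f/2) / n.
    For the study design (20 trials, 9 flipped) these are 55% and 77.5%.
    """
    if n_trials <= 0 or n_flipped < 0:
        raise ValueError("counts must be positive (n_trials) and nonnegative (n_flipped)")
    if n_flipped > n_trials:
        raise ValueError("n_flipped cannot exceed n_trials")
    max_transfer = Fraction(n_trials - n_flipped, n_trials)
    guess = Fraction(n_trials - n_flipped, n_trials) + Fraction(n_flipped, 2 * n_trials)
    return StrategyBounds(max_transfer=max_transfer, guess_strategy=guess)


def map_transition_cost(
    rounds: list[tuple[int, list[float]]]
) -> list[tuple[int, int, float]]:
    """Learning cost at each city-to-city transition during encoding.

    ``rounds`` lists, in encounter order, each city with its per-round map
    scores.  The cost of a transition is the first map score of the new city
    minus the last map score of the previous city; negative values mean the
    switch set learning back.
    Returns (from_city, to_city, cost) per transition.
    """
    if len(rounds) < 2:
        raise ValueError("need at least one completed city before a transition")
    costs = []
    for (prev_city, prev_scores), (new_city, new_scores) in zip(rounds, rounds[1:]):
        if not prev_scores or not new_scores:
            raise ValueError("missing rounds: every city needs at least one map score")
        costs.append((prev_city, new_city, float(new_scores[0] - prev_scores[-1])))
    return costs


def learning_slope(scores: list[float] | np.ndarray) -> float:
    """OLS slope of map score on round index (0-based); needs >= 3 rounds."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or len(scores) < 3:
        raise ValueError("need at least 3 rounds to estimate a learning slope")
    slope, _ = np.polyfit(np.arange(len(scores)), scores, 1)
    return float(slope)
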