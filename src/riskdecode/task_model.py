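"""Two-card guessing task and its normative reward/risk model.

On each trial two cards are drawn sequentially, without replacement, from a
ten-card deck (ace counted as 1). The player first guesses whether the second
card will be higher or lower than the first, sees card 1, sees card 2, and
finally reports whether they won. Correct guesses earn +10 points (−10 if
wrong); correct reports +5 (−5 if wrong).

Because the deck is small and reshuffled every trial, every model quantity is
an exact finite expectation over the deck:

* ``EV``            — P(win | guess, card1), the reward probability,
* ``P0``            — P(win | guess) before card 1, a constant 1/2,
* ``E.Risk_card1``  — Var(EV) over the ten possible first cards,
* ``RiPE_card1``    — (EV − P0)² − E.Risk_card1,
* ``E.Risk_card2``  — Var(outcome | guess, card1) = EV(1 − EV),
* ``RePE``          — outcome − EV, the reward prediction error,
* ``O.Risk``        — RePE², the observed (realized) risk,
* ``RiPE_card2``    — O.Risk − E.Risk_card2, the risk prediction error.

Closed forms exist for all of these; :func:`enumerate_expected_value` and
friends provide the brute-force deck enumerations used as oracles in tests.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields
from typing import Callable

import numpy as np
import pandas as pd

DECK = tuple(range(1, 11))
GUESS_POINTS = 10
REPORT_POINTS = 5


class Guess(enum.Enum):
    HIGHER = "HIGHER"
    LOWER = "LOWER"


class Report(enum.Enum):
    WIN = "WIN"
    LOSS = "LOSS"


def _check_card(card: int) -> None:
    if card not in DECK:
        raise ValueError(f"card must be in 1..10, got {card!r}")


def _consistent(guess: Guess, card1: int, card2: int) -> bool:
    return (guess is Guess.LOWER and card2 < card1) or (
        guess is Guess.HIGHER and card2 > card1
    )


# ---------------------------------------------------------------------------
# Enumeration oracles: literal sums over the deck, no algebraic shortcuts.
# ---------------------------------------------------------------------------

def enumerate_expected_value(guess: Guess, card1: int) -> float:
    """EV by counting the remaining nine cards consistent with the guess."""
    _check_card(card1)
    remaining = [c for c in DECK if c != card1]
    return sum(_consistent(guess, card1, c) for c in remaining) / len(remaining)


def enumerate_p0(guess: Guess) -> float:
    """P0 by enumerating all 90 ordered (card1, card2) pairs."""
    wins = total = 0
    for c1 in DECK:
        for c2 in DECK:
            if c2 == c1:
                continue
            total += 1
            wins += _consistent(guess, c1, c2)
    return wins / total


def enumerate_expected_risk_card1(guess: Guess) -> float:
    """Variance of EV over the ten equally likely first cards."""
    p0_ = enumerate_p0(guess)
    return sum((enumerate_expected_value(guess, c) - p0_) ** 2 for c in DECK) / len(DECK)


def enumerate_expected_risk_card2(guess: Guess, card1: int) -> float:
    """E[(OUT − EV)²] by enumerating the nine possible second cards."""
    ev = enumerate_expected_value(guess, card1)
    remaining = [c for c in DECK if c != card1]
    return sum((float(_consistent(guess, card1, c)) - ev) ** 2 for c in remaining) / len(
        remaining
    )


# ---------------------------------------------------------------------------
# Model quantities.
# ---------------------------------------------------------------------------

def expected_value(guess: Guess, card1: int) -> float:
    """Reward probability after card 1: fraction of remaining cards that win."""
    _check_card(card1)
    if guess is Guess.LOWER:
        return (card1 - 1) / 9
    return (10 - card1) / 9


def p0(guess: Guess) -> float:
    """Reward probability before card 1: mean EV over the ten first cards."""
    return sum(expected_value(guess, c) for c in DECK) / len(DECK)


def expected_risk_card1(guess: Guess) -> float:
    """Anticipated variance of the upcoming EV around P0 (card-1 risk)."""
    p0_ = p0(guess)
    return sum((expected_value(guess, c) - p0_) ** 2 for c in DECK) / len(DECK)


def risk_prediction_error_card1(guess: Guess, card1: int) -> float:
    """Squared EV deviation from P0 minus the expected card-1 risk."""
    return (expected_value(guess, card1) - p0(guess)) ** 2 - expected_risk_card1(guess)


def expected_risk_card2(guess: Guess, card1: int) -> float:
    """Bernoulli outcome variance around EV: EV·(1 − EV)."""
    ev = expected_value(guess, card1)
    return ev * (1.0 - ev)


def reward_prediction_error(outcome: int, ev: float) -> float:
    """Outcome minus expected value."""
    if not 0.0 <= ev <= 1.0:
        raise ValueError(f"ev must lie in [0, 1], got {ev}")
    return float(outcome) - ev


def risk_prediction_error_card2(repe: float, erisk2: float) -> float:
    """Observed risk (RePE²) minus the expected card-2 risk."""
    return repe**2 - erisk2


@dataclass(frozen=True)
class TrialVariables:
    """All normative model quantities for one trial."""

    p0: float
    ev: float
    erisk_card1: float
    ripe_card1: float
    erisk_card2: float
    repe: float
    orisk: float
    ripe_card2: float


@dataclass(frozen=True)
class Trial:
    """One card-game trial, including behavior and earned points."""

    guess: Guess
    card1: int
    card2: int
    outcome: int
    report: Report
    report_correct: bool
    guess_points: int
    report_points: int

    def __post_init__(self) -> None:
        _check_card(self.card1)
        _check_card(self.card2)
        if self.card2 == self.card1:
            raise ValueError("cards are drawn without replacement: card2 != card1")
        if self.outcome != int(_consistent(self.guess, self.card1, self.card2)):
            raise ValueError("outcome inconsistent with guess and cards")


def compute_variables(guess: Guess, card1: int, card2: int) -> TrialVariables:
    """Evaluate the full normative cascade for a realized trial."""
    ev = expected_value(guess, card1)
    out = int(_consistent(guess, card1, card2))
    repe = reward_prediction_error(out, ev)
    erisk2 = expected_risk_card2(guess, card1)
    return TrialVariables(
        p0=p0(guess),
        ev=ev,
        erisk_card1=expected_risk_card1(guess),
        ripe_card1=risk_prediction_error_card1(guess, card1),
        erisk_card2=erisk2,
        repe=repe,
        orisk=repe**2,
        ripe_card2=risk_prediction_error_card2(repe, erisk2),
    )


def simulate_trial(
    rng: np.random.Generator,
    guess_policy: Callable[[np.random.Generator], Guess] | Guess | None = None,
    report_accuracy: float = 1.0,
) -> tuple[Trial, TrialVariables]:
    """Draw one i.i.d. trial: uniform cards without replacement.

    ``guess_policy`` may be a fixed :class:`Guess`, a callable receiving the
    rng, or ``None`` for a uniformly random guess. The report matches the true
    outcome with probability ``report_accuracy``, independently of everything
    else.
    """
    if guess_policy is None:
        guess = Guess.LOWER if rng.random() < 0.5 else Guess.HIGHER
    elif isinstance(guess_policy, Guess):
        guess = guess_policy
    else:
        guess = guess_policy(rng)
        if not isinstance(guess, Guess):
            raise TypeError(f"guess_policy must return a Guess, got {guess!r}")
    card1 = int(rng.integers(1, 11))
    remaining = [c for c in DECK if c != card1]
    card2 = int(remaining[rng.integers(0, 9)])
    outcome = int(_consistent(guess, card1, card2))
    report_correct = bool(rng.random() < report_accuracy)
    won = outcome == 1
    reported_win = won if report_correct else not won
    trial = Trial(
        guess=guess,
        card1=card1,
        card2=card2,
        outcome=outcome,
        report=Report.WIN if reported_win else Report.LOSS,
        report_correct=report_correct,
        guess_points=GUESS_POINTS if outcome else -GUESS_POINTS,
        report_points=REPORT_POINTS if report_correct else -REPORT_POINTS,
    )
    return trial, compute_variables(guess, card1, card2)


def simulate_trials(
    n: int,
    rng: np.random.Generator,
    guess_policy: Callable[[np.random.Generator], Guess] | Guess | None = None,
    report_accuracy: float = 1.0,
) -> list[tuple[Trial, TrialVariables]]:
    return [simulate_trial(rng, guess_policy, report_accuracy) for _ in range(n)]


VARIABLE_COLUMNS = [f.name for f in fields(TrialVariables)]


def trials_to_frame(trials: list[tuple[Trial, TrialVariables]]) -> pd.DataFrame:
    """Tabulate trials with one column per behavioral field and model variable."""
    rows = []
    for i, (t, v) in enumerate(trials):
        row = {
            "trial": i,
            "guess": t.guess.value,
            "card1": t.card1,
            "card2": t.card2,
            "outcome": t.outcome,
            "report": t.report.value,
            "report_correct": t.report_correct,
            "guess_points": t.guess_points,
            "report_points": t.report_points,
        }
        row.update({name: getattr(v, name) for name in VARIABLE_COLUMNS})
        rows.append(row)
    return pd.DataFrame(rows)


def trials_to_tsv(trials: list[tuple[Trial, TrialVariables]], path) -> None:
    trials_to_frame(trials).to_csv(path, sep="\t", index=False)


def trials_from_tsv(path) -> list[tuple[Trial, TrialVariables]]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        trial = Trial(
            guess=Guess(r["guess"]),
            card1=int(r["card1"]),
            card2=int(r["card2"]),
            outcome=int(r["outcome"]),
            report=Report(r["report"]),
            report_correct=bool(r["report_correct"]),
            guess_points=int(r["guess_points"]),
            report_points=int(r["report_points"]),
        )
        out.append((trial, compute_variables(trial.guess, trial.card1, trial.card2)))
    return out
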