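"""Backward-counting task scoring.

Performance is the number of subtractions achieved in the task window:
(start - reported final) / decrement.  Counting frequency divides by the
task duration.  "Correctness" of a report is operationalized as the
achieved difference being divisible by the decrement — a proxy for
staying on the arithmetic sequence, labeled as such in outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CountingReport:
    start: int
    decrement: int
    reported_final: float
    duration_s: float = 60.0

    def __post_init__(self) -> None:
        if self.decrement < 1:
            raise ValueError("decrement must be >= 1")
        if not self.duration_s > 0:
            raise ValueError("duration must be positive")


#: the two task presets used in the study
EASY_TASK = dict(start=100, decrement=1)
HARD_TASK = dict(start=300, decrement=7)


def performance(r: CountingReport) -> float:
    """Subtractions achieved: (start - reported_final) / decrement."""
    score = (r.start - r.reported_final) / r.decrement
    if score < 0:
        logger.warning(
            "reported final %s exceeds start %s: negative performance %s",
            r.reported_final, r.start, score,
        )
    return score


def counting_frequency(r: CountingReport) -> float:
    """Average subtractions per second over the task duration."""
    return performance(r) / r.duration_s


def correctness(r: CountingReport) -> tuple[bool, float]:
    """Divisibility proxy for a correct end report.

    Returns (correct_path, n_steps) where correct_path is True when the
    achieved difference start - reported_final is an integer multiple of
    the decrement.
    """
    diff = r.start - r.reported_final
    steps = diff / r.decrement
    correct = abs(diff % r.decrement) < 1e-9 and float(diff).is_integer()
    return bool(correct), steps


def summarize_cohort(reports) -> dict:
    """Counts and percentages of correct-path reports in a cohort.

    Percentages are rounded to 2 decimal places and sum to 100 exactly.
    """
    flags = [correctness(r)[0] for r in reports]
    n = len(flags)
    if n == 0:
        raise ValueError("empty cohort")
    n_correct = sum(flags)
    pct_correct = round(100.0 * n_correct / n, 2)
    return {
        "n": n,
        "n_correct": n_correct,
        "n_incorrect": n - n_correct,
        "pct_correct": pct_correct,
        "pct_incorrect": round(100.0 - pct_correct, 2),
    }


def percentage_correct(n_correct: int, n_total: int) -> float:
    """Cohort percentage correct, 2 decimal places."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * n_correct / n_total, 2)
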