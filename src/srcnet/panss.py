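"""PANSS scoring: subscales, the five-factor model, and median-split subtyping.

The Positive and Negative Syndrome Scale has 30 items (P1-P7, N1-N7, G1-G16),
each rated 1-7. Besides the standard positive/negative/general subscales, the
five-factor model regroups items into positive, negative,
cognitive/disorganization, excitement and depression/anxiety factors. Cohorts
are dichotomized into high/low severity groups at the cohort median of a
chosen score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

P_ITEMS = tuple(f"P{i}" for i in range(1, 8))
N_ITEMS = tuple(f"N{i}" for i in range(1, 8))
G_ITEMS = tuple(f"G{i}" for i in range(1, 17))
ALL_ITEMS = P_ITEMS + N_ITEMS + G_ITEMS

#: Five-factor model item assignments.
FIVE_FACTORS: dict[str, tuple[str, ...]] = {
    "positive": ("P1", "P3", "P5", "P6"),
    "negative": ("N1", "N2", "N3", "N4", "N6", "G7", "G16"),
    "cognitive_disorganization": ("P2", "N5", "G9", "G10", "G11", "G13", "G15"),
    "excitement": ("P4", "P7", "G8", "G12", "G14"),
    "depression_anxiety": ("G2", "G3", "G4", "G6"),
}


@dataclass
class PanssRecord:
    """All 30 PANSS item scores for one subject, each an integer in [1, 7]."""

    items: dict[str, int]

    def __post_init__(self) -> None:
        missing = [k for k in ALL_ITEMS if k not in self.items]
        if missing:
            raise ValueError(f"missing PANSS items: {missing}")
        extra = [k for k in self.items if k not in ALL_ITEMS]
        if extra:
            raise ValueError(f"unknown PANSS items: {extra}")
        for k, v in self.items.items():
            if not (isinstance(v, (int, np.integer)) and 1 <= v <= 7):
                raise ValueError(f"item {k} = {v!r}: scores are integers in [1, 7]")
        self.items = {k: int(self.items[k]) for k in ALL_ITEMS}


@dataclass(frozen=True)
class FactorScores:
    """Five-factor sums plus the standard subscale and total sums."""

    positive: int
    negative: int
    cognitive_disorganization: int
    excitement: int
    depression_anxiety: int
    panss_positive: int
    panss_negative: int
    panss_general: int
    panss_total: int


def score_factors(record: PanssRecord) -> FactorScores:
    """Compute five-factor and subscale sums from one PANSS record."""
    items = record.items
    factor = {name: sum(items[i] for i in lst) for name, lst in FIVE_FACTORS.items()}
    p = sum(items[i] for i in P_ITEMS)
    n = sum(items[i] for i in N_ITEMS)
    g = sum(items[i] for i in G_ITEMS)
    return FactorScores(
        positive=factor["positive"],
        negative=factor["negative"],
        cognitive_disorganization=factor["cognitive_disorganization"],
        excitement=factor["excitement"],
        depression_anxiety=factor["depression_anxiety"],
        panss_positive=p,
        panss_negative=n,
        panss_general=g,
        panss_total=p + n + g,
    )


def median_split(scores, rule: str = ">") -> tuple[list[str], float]:
    """Label each subject 'high' or 'low' relative to the cohort median.

    ``rule=">"`` (default) assigns 'high' strictly above the median;
    ``rule=">="`` assigns median-valued subjects to 'high'. Returns the labels
    (in input order) and the median. A constant cohort is all 'low' with a
    warning.
    """
    scores = np.asarray(list(scores), dtype=float)
    if scores.size < 2:
        raise ValueError("median split needs at least 2 subjects")
    if rule not in (">", ">="):
        raise ValueError("rule must be '>' or '>='")
    med = float(np.median(scores))
    if np.ptp(scores) == 0:
        warnings.warn("all scores identical: every subject labelled 'low'", stacklevel=2)
        return ["low"] * scores.size, med
    high = scores > med if rule == ">" else scores >= med
    return ["high" if h else "low" for h in high], med
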