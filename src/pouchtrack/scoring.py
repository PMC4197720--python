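"""Phenotype scoring rubrics for pharyngeal pouches and ceratobranchials.

Pouches p1–p5 are scored per embryo side on a 0/1 rubric: a pouch that is
missing or reduced by more than half relative to wild type scores 0; a
mis-shapen or normal pouch scores 1.  Wild-type larvae invariably show
five pouches per side, so the wild-type total is 5.

Ceratobranchial (CB) cartilages, five per side, are scored on a graded
rubric: normal 1.0, reduced 0.5, absent 0, and a fused pair of two
adjacent elements contributes 1.5 in total (so a side with one fusion and
three normal elements totals 4.5, and the wild-type maximum stays 5.0).

Group summaries report mean ± s.e.m. with the embryo as the unit of
analysis: left and right sides of the same embryo are averaged before the
group mean is taken (a per-side mode is available).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import InputValidationError

__all__ = [
    "POUCH_STATES",
    "CB_STATES",
    "PhenotypeRecord",
    "ScoreSummary",
    "score_pouch_state",
    "score_cb_elements",
    "score_record",
    "summarize_scores",
]

POUCH_STATES = ("normal", "misshapen", "reduced_gt50", "missing")
CB_STATES = ("normal", "reduced", "absent")
FUSED = "fused"  # CB state reserved for positions covered by a fused pair

POUCH_KEYS = ("p1", "p2", "p3", "p4", "p5")

_POUCH_SCORE = {"normal": 1, "misshapen": 1, "reduced_gt50": 0, "missing": 0}
_CB_SCORE = {"normal": 1.0, "reduced": 0.5, "absent": 0.0}
_FUSED_PAIR_SCORE = 1.5


@dataclass
class PhenotypeRecord:
    """Scored anatomy of one embryo side.

    ``cb_elements`` lists the state of the five CB positions (anterior to
    posterior, 1-indexed in ``fused_pairs``).  Positions covered by a
    fused pair carry the reserved state ``"fused"`` and contribute only
    through the pair's 1.5 score.
    """

    embryo_id: str
    genotype: str
    side: Literal["left", "right"]
    pouch_states: dict[str, str]
    cb_elements: tuple[str, ...]
    fused_pairs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        self.pouch_states = dict(self.pouch_states)
        self.cb_elements = tuple(self.cb_elements)
        self.fused_pairs = tuple(tuple(p) for p in self.fused_pairs)
        if self.side not in ("left", "right"):
            raise InputValidationError(f"side must be left/right, got {self.side!r}")
        if tuple(sorted(self.pouch_states)) != tuple(sorted(POUCH_KEYS)):
            raise InputValidationError(
                f"pouch_states must have exactly keys p1..p5, got "
                f"{sorted(self.pouch_states)}"
            )
        for key, state in self.pouch_states.items():
            if state not in POUCH_STATES:
                raise InputValidationError(
                    f"unknown pouch state {state!r} for {key}"
                )
        if len(self.cb_elements) != 5:
            raise InputValidationError(
                f"cb_elements must have 5 positions, got {len(self.cb_elements)}"
            )
        _validate_fusions(self.cb_elements, self.fused_pairs)


def _validate_fusions(
    cb_elements: Sequence[str], fused_pairs: Sequence[tuple[int, int]]
) -> None:
    covered: set[int] = set()
    for pair in fused_pairs:
        i, j = pair
        if j != i + 1 or not (1 <= i <= len(cb_elements) - 1):
            raise InputValidationError(
                f"fused pair {pair} is not an adjacent 1-indexed position pair"
            )
        if covered & {i, j}:
            raise InputValidationError(
                f"fused pair {pair} overlaps another fused pair"
            )
        covered |= {i, j}
    for pos, state in enumerate(cb_elements, start=1):
        if pos in covered:
            if state != FUSED:
                raise InputValidationError(
                    f"CB position {pos} is in a fused pair but carries "
                    f"independent state {state!r}"
                )
        elif state == FUSED:
            raise InputValidationError(
                f"CB position {pos} marked fused without a covering fused pair"
            )
        elif state not in CB_STATES:
            raise InputValidationError(f"unknown CB state {state!r} at {pos}")


@dataclass
class ScoreSummary:
    """Group summary of one score metric."""

    genotype: str
    metric: Literal["pouch_score", "cb_score"]
    mean: float
    sem: float
    n: int


def score_pouch_state(state: str) -> int:
    """0/1 rubric: missing or >50%-reduced pouches score 0, others 1."""
    try:
        return _POUCH_SCORE[state]
    except KeyError:
        raise InputValidationError(f"unknown pouch state {state!r}") from None


def score_cb_elements(
    cb_elements: Sequence[str],
    fused_pairs: Sequence[tuple[int, int]] = (),
) -> float:
    """Graded CB rubric total for one side.

    Normal 1.0, reduced 0.5, absent 0; each fused adjacent pair contributes
    1.5 in place of its two positions.
    """
    _validate_fusions(cb_elements, fused_pairs)
    covered = {pos for pair in fused_pairs for pos in pair}
    total = _FUSED_PAIR_SCORE * len(fused_pairs)
    for pos, state in enumerate(cb_elements, start=1):
        if pos not in covered:
            total += _CB_SCORE[state]
    return total


def score_record(record: PhenotypeRecord) -> tuple[int, float]:
    """(pouch total, CB total) for one embryo side."""
    pouch_total = sum(
        score_pouch_state(record.pouch_states[k]) for k in POUCH_KEYS
    )
    cb_total = score_cb_elements(record.cb_elements, record.fused_pairs)
    return pouch_total, cb_total


def summarize_scores(
    records: Iterable[PhenotypeRecord],
    unit: Literal["embryo", "side"] = "embryo",
) -> list[ScoreSummary]:
    """Per-genotype mean ± s.e.m. of pouch and CB scores.

    With ``unit="embryo"`` (default) the two sides of an embryo are
    averaged first and n counts embryos; with ``unit="side"`` every record
    is an observation.
    """
    if unit not in ("embryo", "side"):
        raise InputValidationError(f"unit must be 'embryo' or 'side', got {unit!r}")
    per_genotype: dict[str, dict[str, list[tuple[float, float]]]] = {}
    for rec in records:
        p, c = score_record(rec)
        key = rec.embryo_id if unit == "embryo" else f"{rec.embryo_id}/{rec.side}"
        per_genotype.setdefault(rec.genotype, {}).setdefault(key, []).append((p, c))

    summaries: list[ScoreSummary] = []
    for genotype in sorted(per_genotype):
        units = per_genotype[genotype]
        pouch = np.array([np.mean([p for p, _ in obs]) for obs in units.values()])
        cb = np.array([np.mean([c for _, c in obs]) for obs in units.values()])
        for metric, vals in (("pouch_score", pouch), ("cb_score", cb)):
            n = vals.size
            mean = float(vals.mean())
            sem = (
                float(np.std(vals, ddof=1) / math.sqrt(n)) if n >= 2 else math.nan
            )
            summaries.append(ScoreSummary(genotype, metric, mean, sem, n))
    return summaries


def scores_by_genotype(
    records: Iterable[PhenotypeRecord],
    metric: Literal["pouch_score", "cb_score"] = "pouch_score",
    unit: Literal["embryo", "side"] = "embryo",
) -> dict[str, np.ndarray]:
    """Raw per-unit score vectors keyed by genotype (input to Tukey–Kramer)."""
    idx = 0 if metric == "pouch_score" else 1
    per_genotype: dict[str, dict[str, list[float]]] = {}
    for rec in records:
        val = score_record(rec)[idx]
        key = rec.embryo_id if unit == "embryo" else f"{rec.embryo_id}/{rec.side}"
        per_genotype.setdefault(rec.genotype, {}).setdefault(key, []).append(val)
    return {
        g: np.array([np.mean(v) for v in units.values()])
        for g, units in sorted(per_genotype.items())
    }
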