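"""Seeded synthetic-data generators for the pouch-morphogenesis pipeline.

Four generators emulate the statistical structure of the experimental
data so the downstream metrics, rubrics and statistics are fully testable
without any imaging:

tracks
    A biased persistent random walk.  At each 10-min step the heading is
    drawn from a von Mises-type circular law whose log-density is
    ``kappa_persist * cos(theta - theta_prev) + kappa_bias * cos(theta -
    goal)``: ``kappa_persist`` makes cells keep their previous heading,
    ``kappa_bias`` pulls them toward a global goal direction (the
    mesodermal guidance cue).  Step length is a zero-truncated normal
    speed times the sampling interval.  A dropout fraction of cells is
    truncated at a random interior time so the complete-track filter has
    something to reject.

phenotypes
    Per-embryo-side pouch (p1–p5) and ceratobranchial states drawn from
    per-class categorical distributions.  Shipped class defaults
    reproduce the printed group means: wild type scores 5/5.0
    invariantly, a tbx1-like class keeps only p1 and loses every CB, a
    single-mutant class averages 4 pouches and a double-mutant class 2.

timelines
    The deterministic wild-type pouch-formation schedule — p1 and p2 in
    place by 20 hpf, then one new pouch every 4 h through p6 at 36 hpf —
    and the tbx1-like arrest in which no outpocketing ever follows p1.

contribution tables
    2×2 counts of marker-positive/negative cells contributing or not to a
    pouch, as binomial draws, for Fisher's exact test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .scoring import CB_STATES, FUSED, POUCH_KEYS, POUCH_STATES, PhenotypeRecord
from .tracks import Track

__all__ = [
    "SimulationConfig",
    "PhenotypeClassParams",
    "TimelineEvent",
    "simulate_tracks",
    "simulate_phenotypes",
    "simulate_pouch_timeline",
    "simulate_contribution_table",
    "default_class_params",
    "DEFAULT_TIMELINES",
    "PHENOTYPE_CLASS_NAMES",
]


# ---------------------------------------------------------------------------
# tracks


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the biased persistent random-walk track generator.

    Defaults follow the recording protocol: one frame every 10 min over a
    6-h window.  Speed defaults are free parameters of the generator (the
    imaging literature gives no canonical value for pouch cells); 0.3 ±
    0.1 μm/min puts net displacements in the tens of microns over 6 h,
    the scale of a forming pouch.
    """

    class_name: str
    n_cells: int
    dt_min: float = 10.0
    duration_min: float = 360.0
    speed_mean: float = 0.3
    speed_sd: float = 0.1
    kappa_bias: float = 0.0
    kappa_persist: float = 0.0
    goal_angle_deg: float = 0.0
    dropout_prob: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.class_name:
            raise ConfigurationError("class_name: must be a non-empty label")
        if self.n_cells < 1:
            raise ConfigurationError(f"n_cells: must be >= 1, got {self.n_cells}")
        if self.dt_min <= 0:
            raise ConfigurationError(f"dt_min: must be > 0, got {self.dt_min}")
        if self.duration_min < 2 * self.dt_min:
            raise ConfigurationError(
                f"duration_min: must be >= 2*dt_min, got {self.duration_min}"
            )
        if self.speed_mean <= 0:
            raise ConfigurationError(
                f"speed_mean: must be > 0, got {self.speed_mean}"
            )
        if self.speed_sd < 0:
            raise ConfigurationError(f"speed_sd: must be >= 0, got {self.speed_sd}")
        if self.kappa_bias < 0:
            raise ConfigurationError(
                f"kappa_bias: must be >= 0, got {self.kappa_bias}"
            )
        if self.kappa_persist < 0:
            raise ConfigurationError(
                f"kappa_persist: must be >= 0, got {self.kappa_persist}"
            )
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ConfigurationError(
                f"dropout_prob: must be in [0, 1], got {self.dropout_prob}"
            )


def simulate_tracks(config: SimulationConfig) -> list[Track]:
    """Generate ``config.n_cells`` tracks of a biased persistent random walk.

    The first heading of each cell is uniform on the circle.  Each later
    heading is a von Mises draw around the resultant of the persistence
    pull (toward the previous heading) and the bias pull (toward the goal
    direction); the resultant length is the effective concentration, so
    the two pulls reinforce when aligned and cancel when opposed.  Step
    length is ``max(0, Normal(speed_mean, speed_sd)) * dt_min``.  A
    dropout cell is truncated at a uniformly random interior sample.
    Output is bit-identical for identical config (including seed).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cells
    n_steps = int(round(config.duration_min / config.dt_min))
    goal = math.radians(config.goal_angle_deg)
    t = np.arange(n_steps + 1) * config.dt_min

    # initial positions scattered over a 50-μm field; irrelevant to the
    # metrics (all are translation invariant) but keeps plots legible
    x = np.empty((n, n_steps + 1))
    y = np.empty((n, n_steps + 1))
    x[:, 0] = rng.uniform(0.0, 50.0, n)
    y[:, 0] = rng.uniform(0.0, 50.0, n)

    headings = rng.uniform(-math.pi, math.pi, n)
    bias_x = config.kappa_bias * math.cos(goal)
    bias_y = config.kappa_bias * math.sin(goal)
    for k in range(n_steps):
        if k > 0:
            cx = config.kappa_persist * np.cos(headings) + bias_x
            cy = config.kappa_persist * np.sin(headings) + bias_y
            kappa_eff = np.hypot(cx, cy)
            mu = np.arctan2(cy, cx)
            headings = rng.vonmises(mu, kappa_eff)
        speeds = np.maximum(0.0, rng.normal(config.speed_mean, config.speed_sd, n))
        step = speeds * config.dt_min
        x[:, k + 1] = x[:, k] + step * np.cos(headings)
        y[:, k + 1] = y[:, k] + step * np.sin(headings)

    dropout = rng.random(n) < config.dropout_prob
    # number of points kept by a dropped-out cell: uniform on [2, n_steps]
    cut = rng.integers(2, n_steps + 1, n)

    tracks: list[Track] = []
    width = len(str(n - 1))
    for i in range(n):
        stop = int(cut[i]) if dropout[i] else n_steps + 1
        tracks.append(
            Track(
                track_id=f"{config.class_name}_{i:0{width}d}",
                group=config.class_name,
                t_min=t[:stop],
                x_um=x[i, :stop],
                y_um=y[i, :stop],
            )
        )
    return tracks


# ---------------------------------------------------------------------------
# phenotypes


_PROB_TOL = 1e-12


def _uniform_state(state: str, states: Sequence[str]) -> dict[str, float]:
    return {s: (1.0 if s == state else 0.0) for s in states}


def _mostly(state: str, p: float, fallback: str, states: Sequence[str]) -> dict[str, float]:
    out = {s: 0.0 for s in states}
    out[state] = p
    out[fallback] = 1.0 - p
    return out


@dataclass(frozen=True)
class PhenotypeClassParams:
    """Per-genotype-class sampling distributions for phenotype records.

    ``pouch_probs`` maps p1..p5 to a probability vector over the pouch
    states, ``cb_probs`` gives one vector per CB position over the CB
    states, and ``fusion_prob`` is the chance that an adjacent pair of
    normal CBs is drawn as fused.  Every probability vector must sum to 1
    within 1e-12.
    """

    class_name: str
    pouch_probs: Mapping[str, Mapping[str, float]]
    cb_probs: Sequence[Mapping[str, float]]
    fusion_prob: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if sorted(self.pouch_probs) != sorted(POUCH_KEYS):
            raise ConfigurationError(
                f"pouch_probs: must have exactly keys p1..p5, got "
                f"{sorted(self.pouch_probs)}"
            )
        for key, probs in self.pouch_probs.items():
            _check_prob_vector(f"pouch_probs[{key}]", probs, POUCH_STATES)
        if len(self.cb_probs) != 5:
            raise ConfigurationError(
                f"cb_probs: must have 5 entries, got {len(self.cb_probs)}"
            )
        for i, probs in enumerate(self.cb_probs, start=1):
            _check_prob_vector(f"cb_probs[{i}]", probs, CB_STATES)
        if not 0.0 <= self.fusion_prob <= 1.0:
            raise ConfigurationError(
                f"fusion_prob: must be in [0, 1], got {self.fusion_prob}"
            )

    def expected_pouch_score(self) -> float:
        """Closed-form mean per-side pouch score: sum of P(score 1)."""
        return sum(
            probs.get("normal", 0.0) + probs.get("misshapen", 0.0)
            for probs in self.pouch_probs.values()
        )


def _check_prob_vector(
    name: str, probs: Mapping[str, float], states: Sequence[str]
) -> None:
    unknown = set(probs) - set(states)
    if unknown:
        raise ConfigurationError(f"{name}: unknown states {sorted(unknown)}")
    if any(p < 0 for p in probs.values()):
        raise ConfigurationError(f"{name}: negative probability")
    total = sum(probs.values())
    if abs(total - 1.0) > _PROB_TOL:
        raise ConfigurationError(f"{name}: probabilities sum to {total}, not 1")


def _params(
    class_name: str,
    pouch_normal: Sequence[float],
    cb_normal: Sequence[float],
    fusion_prob: float = 0.0,
    seed: int = 0,
) -> PhenotypeClassParams:
    return PhenotypeClassParams(
        class_name=class_name,
        pouch_probs={
            key: _mostly("normal", p, "missing", POUCH_STATES)
            for key, p in zip(POUCH_KEYS, pouch_normal)
        },
        cb_probs=[
            _mostly("normal", p, "absent", CB_STATES) for p in cb_normal
        ],
        fusion_prob=fusion_prob,
        seed=seed,
    )


def default_class_params(class_name: str, seed: int = 0) -> PhenotypeClassParams:
    """Shipped genotype classes.

    * ``wild_type`` — every pouch and CB normal with probability 1
      (means 5 and 5.0).
    * ``tbx1`` — only p1 forms; every CB absent (means 1 and 0.0).
    * ``single_mutant`` — p1 always normal, p2–p5 survive with
      probability 0.75 (mean pouch score 1 + 4·0.75 = 4); CBs analogous
      with cb1 normal and cb2–cb5 surviving at 0.75 (mean 4.0).
    * ``double_mutant`` — p2–p5 survive at 0.25 (mean 2); cb2–cb5 survive
      at 0.375 (mean 2.5, the "two to three ceratobranchials" class).

    Fusions default off in every class so the closed-form means above are
    exact; pass a custom :class:`PhenotypeClassParams` to sample fusions.
    """
    ones = [1.0] * 5
    table = {
        "wild_type": dict(pouch_normal=ones, cb_normal=ones),
        "tbx1": dict(pouch_normal=[1, 0, 0, 0, 0], cb_normal=[0.0] * 5),
        "single_mutant": dict(
            pouch_normal=[1.0, 0.75, 0.75, 0.75, 0.75],
            cb_normal=[1.0, 0.75, 0.75, 0.75, 0.75],
        ),
        "double_mutant": dict(
            pouch_normal=[1.0, 0.25, 0.25, 0.25, 0.25],
            cb_normal=[1.0, 0.375, 0.375, 0.375, 0.375],
        ),
    }
    if class_name not in table:
        raise ConfigurationError(
            f"class_name: unknown genotype class {class_name!r}; "
            f"known: {sorted(table)}"
        )
    return _params(class_name, seed=seed, **table[class_name])


PHENOTYPE_CLASS_NAMES = ("wild_type", "tbx1", "single_mutant", "double_mutant")


def _draw_states(
    rng: np.random.Generator, probs: Mapping[str, float], states: Sequence[str]
) -> str:
    p = np.array([probs.get(s, 0.0) for s in states])
    return states[rng.choice(len(states), p=p / p.sum())]


def simulate_phenotypes(
    params: PhenotypeClassParams,
    n_embryos: int,
    sides: Sequence[str] = ("left",),
) -> list[PhenotypeRecord]:
    """Draw ``n_embryos`` × ``len(sides)`` phenotype records for one class.

    States are drawn independently per pouch/element; afterwards each
    adjacent pair of normal CBs (scanned anterior to posterior, skipping
    positions already fused) becomes fused with probability
    ``fusion_prob``.  Deterministic under ``params.seed``.
    """
    params.validate()
    if n_embryos < 1:
        raise ConfigurationError(f"n_embryos: must be >= 1, got {n_embryos}")
    rng = np.random.default_rng(params.seed)
    records: list[PhenotypeRecord] = []
    width = len(str(n_embryos - 1))
    for i in range(n_embryos):
        for side in sides:
            pouch_states = {
                key: _draw_states(rng, params.pouch_probs[key], POUCH_STATES)
                for key in POUCH_KEYS
            }
            cb = [
                _draw_states(rng, probs, CB_STATES) for probs in params.cb_probs
            ]
            fused_pairs: list[tuple[int, int]] = []
            if params.fusion_prob > 0.0:
                pos = 1
                while pos <= 4:
                    if (
                        cb[pos - 1] == "normal"
                        and cb[pos] == "normal"
                        and rng.random() < params.fusion_prob
                    ):
                        fused_pairs.append((pos, pos + 1))
                        cb[pos - 1] = FUSED
                        cb[pos] = FUSED
                        pos += 2
                    else:
                        pos += 1
            records.append(
                PhenotypeRecord(
                    embryo_id=f"{params.class_name}_{i:0{width}d}",
                    genotype=params.class_name,
                    side=side,
                    pouch_states=pouch_states,
                    cb_elements=tuple(cb),
                    fused_pairs=tuple(fused_pairs),
                )
            )
    return records


# ---------------------------------------------------------------------------
# pouch-formation timelines


@dataclass(frozen=True)
class TimelineEvent:
    """Formation of one pouch at a developmental time (hpf)."""

    pouch_index: int
    formation_time_hpf: float


# Wild type: p1 and p2 are in place by 20 hpf and later pouches follow at
# one per 4 h; the 4-h spacing is extended backward to put p1 at 16 hpf.
# The tbx1-like class forms only p1 and never outpockets again.
DEFAULT_TIMELINES: dict[str, dict[int, float]] = {
    "wild_type": {1: 16.0, 2: 20.0, 3: 24.0, 4: 28.0, 5: 32.0, 6: 36.0},
    "tbx1": {1: 16.0},
}


def simulate_pouch_timeline(
    class_name: str,
    start_hpf: float = 26.0,
    window_h: float = 10.0,
    schedule: Mapping[int, float] | None = None,
    jitter_sd_h: float = 0.0,
    seed: int = 0,
) -> list[TimelineEvent]:
    """Pouch-formation events falling inside ``[start_hpf, start_hpf+window_h]``.

    The default schedules are deterministic (``jitter_sd_h = 0``); a
    positive jitter adds seeded Gaussian noise to each formation time.
    Any window that starts at or after 26 hpf is empty for the ``tbx1``
    class, whose only pouch (p1) formed long before.
    """
    if window_h <= 0:
        raise ConfigurationError(f"window_h: must be > 0, got {window_h}")
    if schedule is None:
        if class_name not in DEFAULT_TIMELINES:
            raise ConfigurationError(
                f"class_name: no default timeline for {class_name!r}; "
                f"known: {sorted(DEFAULT_TIMELINES)}; pass schedule="
            )
        schedule = DEFAULT_TIMELINES[class_name]
    times = dict(schedule)
    if jitter_sd_h > 0.0:
        rng = np.random.default_rng(seed)
        times = {
            idx: t + rng.normal(0.0, jitter_sd_h)
            for idx, t in sorted(times.items())
        }
    end = start_hpf + window_h
    events = [
        TimelineEvent(idx, t)
        for idx, t in times.items()
        if start_hpf <= t <= end
    ]
    events.sort(key=lambda e: (e.formation_time_hpf, e.pouch_index))
    return events


# ---------------------------------------------------------------------------
# contribution tables


def simulate_contribution_table(
    n_pos: int,
    n_neg: int,
    p_pos: float,
    p_neg: float,
    seed: int = 0,
) -> np.ndarray:
    """2×2 table of marker-positive/negative cells vs pouch contribution.

    Row 0 is marker-positive cells, row 1 marker-negative; column 0 counts
    cells contributing to a pouch (binomial draw at the row's contribution
    probability), column 1 the remainder.
    """
    if n_pos < 0 or n_neg < 0:
        raise ConfigurationError("n_pos/n_neg: counts must be >= 0")
    for name, p in (("p_pos", p_pos), ("p_neg", p_neg)):
        if not 0.0 <= p <= 1.0:
            raise ConfigurationError(f"{name}: must be in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    k_pos = int(rng.binomial(n_pos, p_pos)) if n_pos else 0
    k_neg = int(rng.binomial(n_neg, p_neg)) if n_neg else 0
    return np.array([[k_pos, n_pos - k_pos], [k_neg, n_neg - k_neg]])
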