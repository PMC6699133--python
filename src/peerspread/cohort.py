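"""Synthetic school-class cohort generator and measurement transforms.

The generator emulates a sociometric cohort of school classes in which every
pupil wore an accelerometer for four one-week waves and nominated classmates
on six peer-nomination questions per wave.  It produces two tables:

* participant records with raw daily step entries and family-affluence item
  scores, and
* nomination records (nominator, nominee, question, wave).

The measurement transforms that turn raw records into simulation inputs are
also here: day-validity filtering, wave-level step averaging, the step-to-PAL
(physical activity level) rescaling, and the family-affluence-to-environment
score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import truncnorm

__all__ = [
    "CohortSpec",
    "DayRecord",
    "ParticipantRecord",
    "NominationRecord",
    "filter_valid_days",
    "wave_mean_steps",
    "steps_to_pal",
    "fas_to_env",
    "baseline_pal_table",
    "generate_cohort",
    "cohort_tables",
    "write_cohort",
]

N_QUESTIONS = 6
N_WAVES = 4
DAYS_PER_WAVE = 7
MINUTES_FULL_DAY = 1440
MIN_VALID_STEPS = 1000
MIN_VALID_DAYS = 3
FAS_MAX = 13
#: divisor that maps the reflected affluence sum (0..13) onto the [0, 2]
#: environment scale
FAS_DIVISOR = 6.5
STEPS_PER_PAL_UNIT = 10_000 / 1.53


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic cohort.

    Defaults reproduce the target sample: 26 classes of 10-30 pupils,
    class network densities spanning roughly 0.46-0.90, individual PAL
    centred on 1.50 within [0.45, 4.27], and daily steps centred on
    10,505 with a between-pupil SD of 5,730 (the PAL draw, truncated to
    its bounds, is the primary quantity; steps are derived from it).
    """

    n_classes: int = 26
    class_size_range: tuple[int, int] = (10, 30)
    density_range: tuple[float, float] = (0.46, 0.90)
    pal_mean: float = 1.50
    pal_sd: float = 0.55
    pal_min: float = 0.45
    pal_max: float = 4.27
    steps_mean: float = 10_505.0
    steps_sd: float = 5_730.0
    fas_mean: float = 4.01
    fas_sd: float = 1.52
    n_fas_items: int = 5
    #: within-pupil day-to-day step SD as a fraction of the population SD
    day_noise_frac: float = 0.30
    #: probability that a non-boundary day is invalid (nonwear / low steps)
    invalid_day_prob: float = 0.10
    #: probability that a whole wave is lost (fewer than 3 valid days)
    missing_wave_prob: float = 0.05
    #: probability that a recorded nomination is duplicated in a second wave
    duplicate_prob: float = 0.25
    #: gamma-shape range of the latent popularity weights; small shapes give
    #: dispersed popularity and hence high in-degree centralization
    popularity_shape_range: tuple[float, float] = (0.3, 3.0)
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.class_size_range
        if not (2 <= lo <= hi):
            raise ValueError(f"invalid class_size_range {self.class_size_range}")
        dlo, dhi = self.density_range
        if not (0.0 < dlo <= dhi <= 1.0):
            raise ValueError(f"invalid density_range {self.density_range}")
        # a class of size n realises densities on a grid of step 1/(n(n-1));
        # below 4 pupils the grid is too coarse to hit a target range this wide
        if lo < 4:
            raise ValueError(
                f"density targets in {self.density_range} are infeasible for "
                f"classes of fewer than 4 pupils (class_size_range={self.class_size_range})"
            )
        if not (self.pal_min < self.pal_mean < self.pal_max):
            raise ValueError("pal_mean must lie inside (pal_min, pal_max)")
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")


@dataclass(frozen=True)
class DayRecord:
    wave: int
    day: int
    minutes_worn: int
    steps: int


@dataclass
class ParticipantRecord:
    participant_id: str
    class_id: str
    sex: str
    age: float
    daily_steps: list[DayRecord] = field(default_factory=list)
    fas_items: list[int] = field(default_factory=list)


@dataclass(frozen=True)
class NominationRecord:
    nominator_id: str
    nominee_id: str
    question_id: int
    wave: int

    def __post_init__(self) -> None:
        if self.nominator_id == self.nominee_id:
            raise ValueError("self-nominations are impossible")
        if self.question_id not in range(1, N_QUESTIONS + 1):
            raise ValueError(f"question_id must be in 1..{N_QUESTIONS}")
        if self.wave not in range(1, N_WAVES + 1):
            raise ValueError(f"wave must be in 1..{N_WAVES}")


# ---------------------------------------------------------------------------
# measurement transforms
# ---------------------------------------------------------------------------

def filter_valid_days(record: ParticipantRecord) -> ParticipantRecord:
    """Return a copy keeping only complete, plausibly-worn days.

    The first and last day of each wave are dropped (partial days at device
    hand-out and return), then only days with a full 1440 minutes of wear and
    at least 1000 steps are retained.
    """
    by_wave: dict[int, list[DayRecord]] = {}
    for d in record.daily_steps:
        by_wave.setdefault(d.wave, []).append(d)
    kept: list[DayRecord] = []
    for wave_days in by_wave.values():
        days = sorted(d.day for d in wave_days)
        first, last = days[0], days[-1]
        for d in sorted(wave_days, key=lambda r: r.day):
            if d.day in (first, last):
                continue
            if d.minutes_worn == MINUTES_FULL_DAY and d.steps >= MIN_VALID_STEPS:
                kept.append(d)
    out = ParticipantRecord(
        participant_id=record.participant_id,
        class_id=record.class_id,
        sex=record.sex,
        age=record.age,
        daily_steps=kept,
        fas_items=list(record.fas_items),
    )
    return out


def wave_mean_steps(record: ParticipantRecord, wave: int) -> float | None:
    """Mean daily steps in a wave, or None with fewer than 3 valid days.

    ``record`` must already be filtered by :func:`filter_valid_days`.
    """
    steps = [d.steps for d in record.daily_steps if d.wave == wave]
    if len(steps) < MIN_VALID_DAYS:
        return None
    return float(np.mean(steps))


def steps_to_pal(steps):
    """Rescale steps/day to a physical activity level: steps/10,000 x 1.53."""
    steps = np.asarray(steps, dtype=float)
    if np.any(steps < 0):
        raise ValueError("steps must be non-negative")
    out = steps / 10_000.0 * 1.53
    return float(out) if out.ndim == 0 else out


def fas_to_env(fas_items) -> float:
    """Map family-affluence item scores to the environment score in [0, 2].

    The item scores are summed (0..13), reflected so that low affluence maps
    high, and divided by 6.5; higher env therefore means lower affluence.
    """
    total = float(np.sum(fas_items))
    if not (0 <= total <= FAS_MAX):
        raise ValueError(f"FAS item sum {total} outside [0, {FAS_MAX}]")
    env = (FAS_MAX - total) / FAS_DIVISOR
    return float(min(2.0, max(0.0, env)))


def _participant_wave_pals(record: ParticipantRecord) -> list[float | None]:
    filtered = filter_valid_days(record)
    pals: list[float | None] = []
    for w in range(1, N_WAVES + 1):
        m = wave_mean_steps(filtered, w)
        pals.append(None if m is None else steps_to_pal(m))
    return pals


def baseline_pal_table(records: list[ParticipantRecord],
                       pal_min: float = 0.45,
                       pal_max: float = 4.27) -> pd.DataFrame:
    """One baseline PAL per pupil: mean over valid waves, missing waves
    imputed with the pupil's own mean (class mean if no wave is valid).

    Returns a frame indexed by participant_id with columns class_id,
    baseline_pal, n_valid_waves.
    """
    rows = []
    for rec in records:
        pals = _participant_wave_pals(rec)
        observed = [p for p in pals if p is not None]
        rows.append(
            {
                "participant_id": rec.participant_id,
                "class_id": rec.class_id,
                "own_mean": float(np.mean(observed)) if observed else np.nan,
                "n_valid_waves": len(observed),
            }
        )
    df = pd.DataFrame(rows).set_index("participant_id")
    class_means = df.groupby("class_id")["own_mean"].transform("mean")
    df["baseline_pal"] = df["own_mean"].fillna(class_means)
    # a fully unobserved cohort has no anchor at all; fail loudly
    if df["baseline_pal"].isna().any():
        raise ValueError("no valid step data in an entire class; cannot impute")
    df["baseline_pal"] = df["baseline_pal"].clip(pal_min, pal_max)
    return df[["class_id", "baseline_pal", "n_valid_waves"]]


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _truncnorm_draw(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _edge_prob(beta: float, pop: np.ndarray) -> np.ndarray:
    """Probability that at least one of 6 questions nominates pupil v."""
    pi = np.minimum(1.0, beta * pop)
    return 1.0 - (1.0 - pi) ** N_QUESTIONS


def _calibrate_beta(pop: np.ndarray, density: float) -> float:
    """Solve for the per-question rate giving the target expected density."""
    f = lambda b: float(np.mean(_edge_prob(b, pop))) - density
    hi = 1.0 / max(pop.min(), 1e-12)
    if f(hi) < 0:  # pragma: no cover - mean edge prob is 1 at beta=hi
        return hi
    return brentq(f, 0.0, hi, xtol=1e-12)


def _generate_class_nominations(rng: np.random.Generator,
                                ids: list[str],
                                density: float,
                                pop_shape: float,
                                duplicate_prob: float) -> list[NominationRecord]:
    n = len(ids)
    pop = rng.gamma(pop_shape, 1.0, size=n) + 0.05
    beta = _calibrate_beta(pop, density)
    pi = np.minimum(1.0, beta * pop)  # per-question prob of nominating v
    noms: list[NominationRecord] = []
    # hits[u, v, q] ~ Bernoulli(pi[v]) for ordered pairs u != v
    hits = rng.random((n, n, N_QUESTIONS)) < pi[None, :, None]
    hits[np.arange(n), np.arange(n), :] = False
    for u, v, q in zip(*np.nonzero(hits)):
        wave = int(rng.integers(1, N_WAVES + 1))
        noms.append(NominationRecord(ids[u], ids[v], int(q) + 1, wave))
        if rng.random() < duplicate_prob:
            other = int(rng.integers(1, N_WAVES + 1))
            if other != wave:
                noms.append(NominationRecord(ids[u], ids[v], int(q) + 1, other))
    # every pupil was required to nominate at least one classmate
    nominators = {nm.nominator_id for nm in noms}
    for u, uid in enumerate(ids):
        if uid not in nominators:
            v = int(rng.integers(0, n - 1))
            v = v if v < u else v + 1
            noms.append(NominationRecord(uid, ids[v], 1, int(rng.integers(1, N_WAVES + 1))))
    return noms


def _generate_participant(rng: np.random.Generator,
                          pid: str,
                          class_id: str,
                          spec: CohortSpec) -> tuple[ParticipantRecord, float]:
    true_pal = float(
        _truncnorm_draw(rng, spec.pal_mean, spec.pal_sd, spec.pal_min, spec.pal_max, None)
    )
    true_steps = true_pal * STEPS_PER_PAL_UNIT
    day_sd = spec.day_noise_frac * spec.steps_sd
    days: list[DayRecord] = []
    for wave in range(1, N_WAVES + 1):
        # a lost wave (device failure) yields no valid days and is imputed later
        wave_lost = rng.random() < spec.missing_wave_prob
        for day in range(1, DAYS_PER_WAVE + 1):
            boundary = day in (1, DAYS_PER_WAVE)
            invalid = wave_lost or (rng.random() < spec.invalid_day_prob)
            steps = max(0.0, rng.normal(true_steps, day_sd))
            if boundary:
                minutes = int(rng.integers(400, 1200))
                steps *= minutes / MINUTES_FULL_DAY
            elif invalid:
                # nonwear or device failure: short wear or implausibly few steps
                if rng.random() < 0.5:
                    minutes = int(rng.integers(600, MINUTES_FULL_DAY))
                    steps *= minutes / MINUTES_FULL_DAY
                else:
                    minutes = MINUTES_FULL_DAY
                    steps = float(rng.integers(0, MIN_VALID_STEPS))
            else:
                minutes = MINUTES_FULL_DAY
            days.append(DayRecord(wave, day, minutes, int(round(steps))))
    # family affluence: integer item scores whose sum lies in 0..13
    total = int(np.clip(round(rng.normal(spec.fas_mean, spec.fas_sd)), 0, FAS_MAX))
    items = [0] * spec.n_fas_items
    cap = math.ceil(FAS_MAX / spec.n_fas_items) + 1
    remaining = total
    while remaining > 0:
        j = int(rng.integers(spec.n_fas_items))
        if items[j] < cap:
            items[j] += 1
            remaining -= 1
    rec = ParticipantRecord(
        participant_id=pid,
        class_id=class_id,
        sex="m" if rng.random() < 0.515 else "f",
        age=float(np.clip(rng.normal(10.8, 1.3), 8.0, 15.0)),
        daily_steps=days,
        fas_items=items,
    )
    return rec, true_pal


def generate_cohort(spec: CohortSpec) -> tuple[list[ParticipantRecord], list[NominationRecord]]:
    """Generate participant and nomination records for the whole cohort.

    Deterministic for a fixed ``spec.seed``.  Class densities are drawn from
    ``spec.density_range`` and realised in expectation through a latent
    popularity model: each pupil carries a gamma-distributed popularity
    weight, and the per-question probability of being nominated is
    proportional to it.  The gamma shape (drawn per class) controls how
    concentrated incoming nominations are, and with them the in-degree
    centralization of the resulting network.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    participants: list[ParticipantRecord] = []
    nominations: list[NominationRecord] = []
    lo, hi = spec.class_size_range
    slo, shi = spec.popularity_shape_range
    for c in range(spec.n_classes):
        class_id = f"C{c + 1:03d}"
        n = int(rng.integers(lo, hi + 1))
        ids = [f"{class_id}P{i + 1:02d}" for i in range(n)]
        density = rng.uniform(*spec.density_range)
        pop_shape = float(np.exp(rng.uniform(np.log(slo), np.log(shi))))
        nominations.extend(
            _generate_class_nominations(rng, ids, density, pop_shape, spec.duplicate_prob)
        )
        for pid in ids:
            rec, _ = _generate_participant(rng, pid, class_id, spec)
            participants.append(rec)
    return participants, nominations


def cohort_tables(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the cohort and apply all measurement transforms.

    Returns ``(participants, nominations)`` frames.  Participants carry one
    row per pupil with baseline_pal (filtered, averaged, imputed, rescaled)
    and env (from family affluence).
    """
    records, noms = generate_cohort(spec)
    base = baseline_pal_table(records, spec.pal_min, spec.pal_max)
    rows = []
    for rec in records:
        rows.append(
            {
                "participant_id": rec.participant_id,
                "class_id": rec.class_id,
                "sex": rec.sex,
                "age": round(rec.age, 2),
                "baseline_pal": float(base.loc[rec.participant_id, "baseline_pal"]),
                "env": fas_to_env(rec.fas_items),
            }
        )
    participants = pd.DataFrame(rows)
    nominations = pd.DataFrame(
        [
            {
                "nominator_id": nm.nominator_id,
                "nominee_id": nm.nominee_id,
                "question_id": nm.question_id,
                "wave": nm.wave,
            }
            for nm in noms
        ]
    )
    return participants, nominations


def write_cohort(spec: CohortSpec, out_dir) -> dict[str, str]:
    """Write participants.csv and nominations.csv; returns the paths."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    participants, nominations = cohort_tables(spec)
    paths = {
        "participants": str(out / "participants.csv"),
        "nominations": str(out / "nominations.csv"),
    }
    participants.to_csv(paths["participants"], index=False)
    nominations.to_csv(paths["nominations"], index=False)
    return paths
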