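"""Generational sex-ratio dynamics under male-pheromone fertility suppression.

The core bookkeeping: a cohort of N0 males mates over a fixed window of adult
days (Day 1-6 by default) with an equal chance of mating each day; the
expected cross progeny a condition produces is sum_d N0 * f_d * k_d, where
f_d is the fraction of males fertile on day d and k_d the progeny per
successful mating. The ratio of treated to control totals is the relative
progeny factor r (~0.768 for pheromone-exposed males). Because cross progeny
are 50% male while selfed progeny are ~0.2% male (X nondisjunction), the male
fraction then decays geometrically across generations, m_X = m0 * r**X, and
the population returns to a "primarily hermaphroditic" state (default
threshold: 1% males) in ~15 generations when r = 0.768.

A stochastic agent-free extension draws matings, brood sexes and carrying-
capacity downsampling per generation; its mean-field companion
(`expected_trajectory`) is the deterministic recursion the simulation is
validated against, and it reduces to the geometric form in the scarce-male
limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from androdyn.errors import DataError, ParameterError

__all__ = [
    "FertilitySchedule", "BookkeepingConfig", "MatingSystemParams",
    "PopulationState", "SexRatioTrajectory", "BenchmarkResult",
    "relative_progeny_factor", "male_fraction_trajectory",
    "generations_to_threshold", "simulate_sex_ratio", "expected_trajectory",
    "compare_to_benchmark",
]


@dataclass(frozen=True)
class FertilitySchedule:
    """Per-day male fertility over the mating window.

    ``fraction_fertile[i]`` is the probability a male sires progeny on
    ``days[i]``; ``progeny_per_mating[i]`` the expected progeny per
    successful mating that day. Days must be contiguous.
    """

    days: tuple[int, ...]
    fraction_fertile: tuple[float, ...]
    progeny_per_mating: tuple[float, ...]

    def __post_init__(self) -> None:
        days = tuple(int(d) for d in self.days)
        if len(days) == 0:
            raise ParameterError("schedule must cover at least one day")
        if any(b - a != 1 for a, b in zip(days, days[1:])):
            raise ParameterError(f"days must be contiguous, got {days}")
        if len(self.fraction_fertile) != len(days) or \
                len(self.progeny_per_mating) != len(days):
            raise ParameterError("schedule arrays must have one entry per day")
        if any(not 0.0 <= f <= 1.0 for f in self.fraction_fertile):
            raise ParameterError("fraction_fertile values must lie in [0, 1]")
        if any(k < 0 for k in self.progeny_per_mating):
            raise ParameterError("progeny_per_mating values must be >= 0")
        object.__setattr__(self, "days", days)
        object.__setattr__(self, "fraction_fertile",
                           tuple(float(f) for f in self.fraction_fertile))
        object.__setattr__(self, "progeny_per_mating",
                           tuple(float(k) for k in self.progeny_per_mating))

    def subset(self, days: Sequence[int]) -> "FertilitySchedule":
        """Restrict the schedule to the given (contiguous) days."""
        want = tuple(int(d) for d in days)
        missing = [d for d in want if d not in self.days]
        if missing:
            raise ParameterError(f"schedule does not cover days {missing}")
        idx = [self.days.index(d) for d in want]
        return FertilitySchedule(
            days=want,
            fraction_fertile=tuple(self.fraction_fertile[i] for i in idx),
            progeny_per_mating=tuple(self.progeny_per_mating[i] for i in idx),
        )


@dataclass(frozen=True)
class BookkeepingConfig:
    """Starting male count and mating window for the progeny bookkeeping."""

    n_males: int = 60
    days: tuple[int, ...] = (1, 2, 3, 4, 5, 6)

    def __post_init__(self) -> None:
        if self.n_males < 1:
            raise ParameterError("n_males must be >= 1")
        if len(self.days) == 0:
            raise ParameterError("mating window must be non-empty")
        object.__setattr__(self, "days", tuple(int(d) for d in self.days))


@dataclass(frozen=True)
class MatingSystemParams:
    """Parameters of the mating system and the male-fraction recursion.

    relative_progeny_factor
        r: treated/control ratio of expected cross progeny (0.768 for
        pheromone-exposed males; 1.0 for controls).
    selfing_male_rate
        Probability a selfed offspring is male via X nondisjunction (0.002).
    cross_male_rate
        Probability a cross offspring is male (0.5: X or nullo-X sperm).
    encounter_efficacy
        c in the per-hermaphrodite mating probability min(1, c*M/H); a free
        parameter of the stochastic extension, near-saturating at c=10 when
        males are common and male-limited when they are scarce.
    initial_male_fraction
        m0, the male fraction after a male population explosion (0.5).
    """

    relative_progeny_factor: float = 0.768
    selfing_male_rate: float = 0.002
    cross_male_rate: float = 0.5
    encounter_efficacy: float = 10.0
    initial_male_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.relative_progeny_factor <= 1.0:
            raise ParameterError("relative_progeny_factor must be in (0, 1]")
        for name in ("selfing_male_rate", "cross_male_rate",
                     "initial_male_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        if self.encounter_efficacy < 0:
            raise ParameterError("encounter_efficacy must be >= 0")


@dataclass(frozen=True)
class PopulationState:
    n_hermaphrodites: int
    n_males: int

    def __post_init__(self) -> None:
        if self.n_hermaphrodites < 0 or self.n_males < 0:
            raise ParameterError("population counts must be >= 0")

    @property
    def total(self) -> int:
        return self.n_hermaphrodites + self.n_males

    @property
    def male_fraction(self) -> float:
        return self.n_males / self.total if self.total else math.nan


@dataclass(frozen=True)
class SexRatioTrajectory:
    """Male fraction per generation; stochastic runs carry counts too."""

    generation: np.ndarray
    male_fraction: np.ndarray
    n_males: np.ndarray | None = None
    n_hermaphrodites: np.ndarray | None = None
    extinct: bool = False

    def __len__(self) -> int:
        return len(self.generation)

    def first_below(self, threshold: float) -> int | None:
        """Smallest generation index with male fraction < threshold."""
        hits = np.nonzero(self.male_fraction < threshold)[0]
        return int(self.generation[hits[0]]) if hits.size else None


@dataclass(frozen=True)
class BenchmarkResult:
    """Days to reach a male-fraction threshold, for comparison with the
    observed 12-20 days for males to disappear from wild-type populations."""

    reached: bool
    generations: int | None
    days: float | None


def relative_progeny_factor(ctrl: FertilitySchedule, trt: FertilitySchedule,
                            cfg: BookkeepingConfig | None = None) -> float:
    """Relative progeny factor r from per-day fertility schedules.

    Expected total progeny per condition over the mating window is
    sum_d N0 * f_d * k_d (every male has an equal chance of mating each day;
    no attrition within the window), and r = total_treated / total_control.
    r is invariant to N0 and to any common rescaling of progeny counts.
    """
    cfg = cfg or BookkeepingConfig()
    c = ctrl.subset(cfg.days)
    t = trt.subset(cfg.days)
    total_ctrl = cfg.n_males * sum(
        f * k for f, k in zip(c.fraction_fertile, c.progeny_per_mating))
    total_trt = cfg.n_males * sum(
        f * k for f, k in zip(t.fraction_fertile, t.progeny_per_mating))
    if total_ctrl == 0:
        raise DataError("control schedule yields zero progeny; r undefined")
    return total_trt / total_ctrl


def male_fraction_trajectory(params: MatingSystemParams,
                             generations: int) -> SexRatioTrajectory:
    """Deterministic recursion m_X = m0 * r**X for X = 0..generations."""
    if generations < 0:
        raise ParameterError("generations must be >= 0")
    x = np.arange(generations + 1)
    m = params.initial_male_fraction * params.relative_progeny_factor ** x
    return SexRatioTrajectory(generation=x, male_fraction=m)


def generations_to_threshold(params: MatingSystemParams,
                             threshold: float = 0.01) -> int:
    """Smallest generation X at which m0 * r**X first drops below threshold.

    With r = 0.768, m0 = 0.5 and the default 1% threshold this is 15
    generations — the model's time scale for the population's return to a
    primarily hermaphroditic state.
    """
    m0 = params.initial_male_fraction
    r = params.relative_progeny_factor
    if not 0.0 < threshold < m0:
        raise ParameterError(
            f"threshold must lie in (0, m0={m0}), got {threshold}")
    if r >= 1.0:
        raise ParameterError("male fraction never declines when r >= 1")
    x = 0
    m = m0
    while m >= threshold:
        m *= r
        x += 1
    return x


def _mean_field_step(m: float, params: MatingSystemParams,
                     treated: bool = True) -> float:
    """Expected next-generation male fraction of the stochastic model."""
    if m >= 1.0:
        return math.nan  # no hermaphrodites: no offspring
    r = params.relative_progeny_factor if treated else 1.0
    p_mate = min(1.0, params.encounter_efficacy * m / (1.0 - m)) * r
    return (p_mate * params.cross_male_rate
            + (1.0 - p_mate) * params.selfing_male_rate)


def expected_trajectory(params: MatingSystemParams, init: PopulationState,
                        generations: int, treated: bool = True
                        ) -> SexRatioTrajectory:
    """Mean-field companion of `simulate_sex_ratio`.

    Iterates the expected one-generation map
    m' = p * q_cross + (1 - p) * q_self with p = min(1, c*m/(1-m)) * r.
    In the scarce-male, zero-selfing limit this is geometric with effective
    ratio c*r*q_cross, matching the m0 * r**X form of the printed model.
    """
    m = init.male_fraction
    out = [m]
    for _ in range(generations):
        m = _mean_field_step(m, params, treated=treated)
        out.append(m)
    return SexRatioTrajectory(generation=np.arange(generations + 1),
                              male_fraction=np.array(out))


def simulate_sex_ratio(params: MatingSystemParams, init: PopulationState,
                       generations: int, seed: int, cap: int,
                       brood_size: int = 238, treated: bool = True
                       ) -> SexRatioTrajectory:
    """Stochastic generational simulation of the mating system.

    Each discrete, non-overlapping generation: every hermaphrodite mates with
    probability min(1, c*M/H) scaled by male fertility (r for treated runs,
    1 for controls). Mated hermaphrodites produce a full brood of cross
    offspring (male with probability ``cross_male_rate``); unmated
    hermaphrodites self the same brood (male with probability
    ``selfing_male_rate`` — pheromone does not change self brood size). If
    the offspring pool exceeds ``cap`` it is downsampled without replacement.
    A population with no hermaphrodites (or no individuals) cannot continue:
    the trajectory is truncated with ``extinct=True``.

    Deterministic given ``seed``.
    """
    if init.total == 0:
        raise DataError("initial population is empty")
    if cap < init.total:
        raise ParameterError("cap must be >= the initial population size")
    if brood_size < 1:
        raise ParameterError("brood_size must be >= 1")
    rng = np.random.default_rng(seed)
    r = params.relative_progeny_factor if treated else 1.0

    H, M = init.n_hermaphrodites, init.n_males
    gens = [0]
    fracs = [M / (H + M)]
    males = [M]
    herms = [H]
    extinct = False
    for g in range(1, generations + 1):
        if H == 0:  # males alone cannot reproduce
            extinct = True
            break
        p_mate = min(1.0, params.encounter_efficacy * M / H) * r
        n_mated = int(rng.binomial(H, p_mate))
        n_cross = n_mated * brood_size
        n_self = (H - n_mated) * brood_size
        m_off = int(rng.binomial(n_cross, params.cross_male_rate)) + \
            int(rng.binomial(n_self, params.selfing_male_rate))
        total_off = n_cross + n_self
        if total_off == 0:
            extinct = True
            break
        if total_off > cap:
            m_off = int(rng.hypergeometric(m_off, total_off - m_off, cap))
            total_off = cap
        M, H = m_off, total_off - m_off
        gens.append(g)
        fracs.append(M / (H + M))
        males.append(M)
        herms.append(H)
    return SexRatioTrajectory(generation=np.array(gens),
                              male_fraction=np.array(fracs),
                              n_males=np.array(males),
                              n_hermaphrodites=np.array(herms),
                              extinct=extinct)


def compare_to_benchmark(trajectory: SexRatioTrajectory,
                         threshold: float = 0.01,
                         days_per_generation: float = 3.0) -> BenchmarkResult:
    """Convert generations-to-threshold into days for field comparison.

    The benchmark: males disappear from wild-type populations in 12-20 days,
    i.e. 4-7 generations at ~3 days per generation. A trajectory that never
    crosses the threshold yields an explicit not-reached result.
    """
    if days_per_generation <= 0:
        raise ParameterError("days_per_generation must be > 0")
    gen = trajectory.first_below(threshold)
    if gen is None:
        return BenchmarkResult(reached=False, generations=None, days=None)
    return BenchmarkResult(reached=True, generations=gen,
                           days=gen * days_per_generation)
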