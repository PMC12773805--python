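"""Forward simulator of a bottlenecked cooperative life cycle.

The model follows a clonal population of *Myxococcus xanthus*-like cells
through repeated cycles of

    sporulation -> germination -> bottleneck -> regrowth with mutation,

the synthetic life cycle imposed during laboratory evolution experiments.
Each cell carries two heritable abilities in [0, 1]: a sporulation ability
``s`` and a germination ability ``g``.

Sporulation is social.  Cells with ``s`` at or above a threshold (0.5 by
default) are *cooperators*; the rest are *exploiters*.  From the second
cycle onward cells are paired at random and resolve a public-goods game:

* C-C pairs: each cooperator sporulates with probability ``gamma * s``,
  where ``gamma`` is the cost-of-cooperation discount (``gamma = 1`` means
  cost-free cooperation).  The bookkeeping payoff is
  ``K = gamma * 1/2 * sum(s)`` over the paired cooperators.
* C-E pairs: exploiters siphon public goods from cooperators.  With ``D``
  the difference between the mean sporulation abilities of the paired
  cooperators and exploiters, every paired exploiter gains ``D / n`` and
  every paired cooperator loses the same amount (``n`` is the sharing
  divisor; ``n = 1`` reproduces total expropriation).  Cells whose
  post-transfer ability clears the threshold become spores.  Payoffs
  ``L`` (cooperators) and ``M`` (exploiters) are the post-transfer ability
  sums over the retained cells.
* E-E pairs never sporulate (payoff ``N = 0``).

Germination draws on a communal pool of diffusible goods: in the default
"communal" mode every spore germinates with probability
``epsilon * mean(g)``, where ``epsilon`` is the privatization factor.  The
bottleneck retains a random fraction ``beta`` of germinated cells, and
regrowth doubles the survivors until the carrying capacity is restored.
Each daughter cell mutates its germination ability by a uniform step and
its sporulation ability by the negatively coupled trade-off step; cells
pushed outside [0, 1] die (lethal mutation).

The headline outputs are the relative spore productivity and relative
germination efficiency: base-10 log ratios of the realized per-phase
retention rates in a readout cycle against the realized rates of the
ancestral (first) cycle.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from numpy.random import Generator, SeedSequence, default_rng
from scipy import stats

__all__ = [
    "ConfigurationError",
    "ExtinctionError",
    "SimConfig",
    "TraitPopulation",
    "StrategySplit",
    "InteractionAssignment",
    "InteractionSummary",
    "CEOutcome",
    "CycleRecord",
    "RelativeMetrics",
    "SimResult",
    "SweepResult",
    "init_population",
    "classify_strategies",
    "assign_interactions",
    "resolve_cc",
    "resolve_ce",
    "resolve_ee",
    "sporulation_phase",
    "germination_phase",
    "bottleneck_phase",
    "growth_phase",
    "relative_metrics",
    "run_simulation",
    "sweep",
    "derive_child_seeds",
]

logger = logging.getLogger(__name__)

#: Explicit floor used when a realized rate is zero and the log ratio
#: would be -inf.  The flag on :class:`RelativeMetrics` records the event.
METRIC_FLOOR = -12.0

GERMINATION_MODES = ("communal", "mixed")


class ConfigurationError(ValueError):
    """A simulation parameter is outside its admissible range."""


class ExtinctionError(RuntimeError):
    """Raised when a life-cycle phase leaves no cells alive."""

    def __init__(self, phase: str, cycle: int | None = None):
        self.phase = phase
        self.cycle = cycle
        where = f" in cycle {cycle}" if cycle is not None else ""
        super().__init__(f"population went extinct during {phase}{where}")


# ---------------------------------------------------------------------------
# configuration and containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """All parameters of the life-cycle model.

    Parameters
    ----------
    beta:
        Bottleneck fraction in (0, 1]; 0.01 is the stringent regimen,
        0.15 the relaxed one.
    gamma:
        Cost-of-cooperation discount in [0, 1] applied to C-C sporulation.
    epsilon:
        Privatization factor in [0, 1] scaling communal germination.
    epsilon_first_cycle:
        Privatization used in cycle 1 only (0.8: liberal sharing before
        the regimens diverge).
    n_sharing:
        Public-good sharing divisor ``n`` (>= 1).  ``n = 1`` lets
        exploiters take everything cooperators produced.
    n_max:
        Carrying capacity; regrowth restores exactly this census.
    n_cycles:
        Number of life cycles to simulate.
    readout_cycles:
        Cycles at which the relative metrics are recorded.
    coop_threshold:
        Sporulation ability at or above which a cell is a cooperator.
    mutation_halfwidth:
        Half-width of the uniform mutation step on germination ability.
    tradeoff_slope:
        Coupling of the sporulation step to the germination step
        (``ds = tradeoff_slope * dg``); negative, reflecting the
        sporulation-germination trade-off.
    mutation_prob:
        Per-daughter, per-division probability of mutating.
    init_mean, init_sd:
        Mean / sd of the truncated normal used to initialize both traits.
    germination_mode:
        "communal" (probability ``epsilon * mean(g)`` for every spore) or
        "mixed" (``epsilon * mean(g) + (1 - epsilon) * g_i``).
    seed:
        Root RNG seed; every stream in a run derives from it.
    """

    beta: float = 0.01
    gamma: float = 0.98
    epsilon: float = 0.5
    epsilon_first_cycle: float = 0.8
    n_sharing: float = 50.0
    n_max: int = 1_000_000
    n_cycles: int = 50
    readout_cycles: tuple[int, ...] = (10, 50)
    coop_threshold: float = 0.5
    mutation_halfwidth: float = 0.1
    tradeoff_slope: float = -1.15
    mutation_prob: float = 1.0
    init_mean: float = 0.5
    init_sd: float = 0.15
    germination_mode: str = "communal"
    seed: int | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        """Raise :class:`ConfigurationError` naming the offending field."""
        checks = [
            ("beta", 0.0 < self.beta <= 1.0, "must lie in (0, 1]"),
            ("gamma", 0.0 <= self.gamma <= 1.0, "must lie in [0, 1]"),
            ("epsilon", 0.0 <= self.epsilon <= 1.0, "must lie in [0, 1]"),
            (
                "epsilon_first_cycle",
                0.0 <= self.epsilon_first_cycle <= 1.0,
                "must lie in [0, 1]",
            ),
            ("n_sharing", self.n_sharing >= 1.0, "must be >= 1"),
            ("n_max", self.n_max >= 2, "must be >= 2"),
            ("n_cycles", self.n_cycles >= 0, "must be >= 0"),
            (
                "coop_threshold",
                0.0 < self.coop_threshold < 1.0,
                "must lie in (0, 1)",
            ),
            (
                "mutation_halfwidth",
                self.mutation_halfwidth >= 0.0,
                "must be >= 0",
            ),
            (
                "mutation_prob",
                0.0 <= self.mutation_prob <= 1.0,
                "must lie in [0, 1]",
            ),
            ("init_sd", self.init_sd >= 0.0, "must be >= 0"),
            (
                "init_mean",
                0.0 <= self.init_mean <= 1.0,
                "must lie in [0, 1]",
            ),
            (
                "germination_mode",
                self.germination_mode in GERMINATION_MODES,
                f"must be one of {GERMINATION_MODES}",
            ),
        ]
        for name, ok, msg in checks:
            if not ok:
                raise ConfigurationError(
                    f"{name}={getattr(self, name)!r} {msg}"
                )


@dataclass
class TraitPopulation:
    """Per-cell sporulation (``s``) and germination (``g``) abilities."""

    s: np.ndarray
    g: np.ndarray

    def __post_init__(self) -> None:
        self.s = np.asarray(self.s, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if self.s.shape != self.g.shape or self.s.ndim != 1:
            raise ValueError("s and g must be 1-d arrays of equal length")

    def __len__(self) -> int:
        return self.s.size

    def subset(self, idx: np.ndarray) -> "TraitPopulation":
        return TraitPopulation(self.s[idx], self.g[idx])

    @classmethod
    def empty(cls) -> "TraitPopulation":
        return cls(np.empty(0), np.empty(0))

    @classmethod
    def concat(cls, pops: Sequence["TraitPopulation"]) -> "TraitPopulation":
        if not pops:
            return cls.empty()
        return cls(
            np.concatenate([p.s for p in pops]),
            np.concatenate([p.g for p in pops]),
        )

    def in_bounds(self) -> bool:
        if len(self) == 0:
            return True
        return bool(
            (self.s.min() >= 0.0)
            and (self.s.max() <= 1.0)
            and (self.g.min() >= 0.0)
            and (self.g.max() <= 1.0)
        )


@dataclass(frozen=True)
class StrategySplit:
    """Cooperator / exploiter partition of a population."""

    cooperators: np.ndarray
    exploiters: np.ndarray
    p_c: float
    p_e: float


@dataclass(frozen=True)
class InteractionAssignment:
    """Random pairing of cells for the sporulation game.

    ``cc_pairs`` has shape (n_cc, 2) of cooperator indices, ``ce_pairs``
    shape (n_ce, 2) with columns (cooperator, exploiter), ``ee_pairs``
    shape (n_ee, 2) of exploiter indices.  ``unpaired`` holds at most one
    leftover cell per strategy class.
    """

    cc_pairs: np.ndarray
    ce_pairs: np.ndarray
    ee_pairs: np.ndarray
    unpaired: np.ndarray


@dataclass(frozen=True)
class InteractionSummary:
    """Payoff bookkeeping for one sporulation phase."""

    p_c: float
    p_e: float
    m: int  # cells engaged in C-C pairs
    p: int  # cooperators engaged in C-E pairs
    q: int  # exploiters engaged in C-E pairs
    K: float
    L: float
    M: float
    N: float
    D: float


@dataclass(frozen=True)
class CEOutcome:
    """Result of resolving the cooperator-exploiter interactions."""

    coop_idx: np.ndarray
    expl_idx: np.ndarray
    s_coop: np.ndarray  # post-transfer, clipped
    s_expl: np.ndarray
    coop_retained: np.ndarray  # boolean masks
    expl_retained: np.ndarray
    L: float
    M: float
    D: float
    clipped: bool


@dataclass(frozen=True)
class CycleRecord:
    """Census and payoff bookkeeping for one full life cycle."""

    cycle: int
    n_start: int
    n_spores: int
    n_germinated: int
    n_after_bottleneck: int
    n_after_growth: int
    mean_s_start: float
    mean_g_start: float
    mean_s_spores: float
    mean_g_spores: float
    spor_rate: float
    germ_rate: float
    interactions: InteractionSummary


@dataclass(frozen=True)
class RelativeMetrics:
    """Log10 ratios of evolved vs ancestral per-phase retention rates."""

    cycle: int
    rel_spore_productivity: float
    rel_germination_efficiency: float
    spore_floored: bool = False
    germ_floored: bool = False


@dataclass
class SimResult:
    """Trajectory, readout metrics and final state of one simulation."""

    config: SimConfig
    records: list[CycleRecord]
    metrics: dict[int, RelativeMetrics]
    ancestral_rates: tuple[float, float] | None
    pc_series: list[tuple[int, float]]
    final_population: TraitPopulation | None
    extinct: bool = False
    extinct_cycle: int | None = None

    def trajectory_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "cycle": r.cycle,
                    "n_start": r.n_start,
                    "n_spores": r.n_spores,
                    "n_germinated": r.n_germinated,
                    "n_after_bottleneck": r.n_after_bottleneck,
                    "n_after_growth": r.n_after_growth,
                    "mean_s_start": r.mean_s_start,
                    "mean_g_start": r.mean_g_start,
                    "spor_rate": r.spor_rate,
                    "germ_rate": r.germ_rate,
                    "p_c": r.interactions.p_c,
                    "p_e": r.interactions.p_e,
                    "K": r.interactions.K,
                    "L": r.interactions.L,
                    "M": r.interactions.M,
                    "N": r.interactions.N,
                    "D": r.interactions.D,
                }
            )
        return pd.DataFrame(rows)

    def metrics_frame(self) -> pd.DataFrame:
        rows = [
            {
                "cycle": m.cycle,
                "rel_spore_productivity": m.rel_spore_productivity,
                "rel_germination_efficiency": m.rel_germination_efficiency,
                "spore_floored": m.spore_floored,
                "germ_floored": m.germ_floored,
            }
            for m in sorted(self.metrics.values(), key=lambda m: m.cycle)
        ]
        return pd.DataFrame(rows)


@dataclass
class SweepResult:
    """Tidy per-replicate table and per-grid-point summary of a sweep."""

    table: pd.DataFrame
    summary: pd.DataFrame
    seeds: dict[tuple[float, float, int], int]


# ---------------------------------------------------------------------------
# phase operations
# ---------------------------------------------------------------------------


def derive_child_seeds(root_seed: int | None, n: int) -> list[int]:
    """Deterministically derive ``n`` independent child seeds (< 2**31)."""
    ss = SeedSequence(root_seed)
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def init_population(config: SimConfig, rng: Generator) -> TraitPopulation:
    """Draw the ancestral population.

    Both abilities are sampled independently from a normal
    (``init_mean``, ``init_sd``) truncated to [0, 1] (exact truncated
    sampling; no clipping, so no probability mass piles up at the bounds).
    """
    config.validate()
    n = config.n_max
    if config.init_sd == 0.0:
        vals = np.full(n, config.init_mean)
        return TraitPopulation(vals.copy(), vals.copy())
    a = (0.0 - config.init_mean) / config.init_sd
    b = (1.0 - config.init_mean) / config.init_sd
    dist = stats.truncnorm(a, b, loc=config.init_mean, scale=config.init_sd)
    s = dist.rvs(size=n, random_state=rng)
    g = dist.rvs(size=n, random_state=rng)
    return TraitPopulation(s, g)


def classify_strategies(
    pop: TraitPopulation, threshold: float = 0.5
) -> StrategySplit:
    """Split cells into cooperators (``s >= threshold``) and exploiters."""
    n = len(pop)
    if n == 0:
        raise ValueError("cannot classify an empty population")
    coop_mask = pop.s >= threshold
    cooperators = np.flatnonzero(coop_mask)
    exploiters = np.flatnonzero(~coop_mask)
    p_c = cooperators.size / n
    return StrategySplit(cooperators, exploiters, p_c, 1.0 - p_c)


def _repair_pair_counts(
    n_cc: int, n_ce: int, n_ee: int, n_coop: int, n_expl: int
) -> tuple[int, int, int]:
    """Reallocate multinomial pair counts so both classes can supply them.

    Keeps the total number of pairs fixed.  At most one side can be in
    deficit.  Deficits are repaired primarily by swapping same-type
    pairs between classes (cc <-> ee), which frees two cells of the
    exhausted class at a time without disturbing the C-E pair count and
    so keeps the expected pair-type frequencies unbiased; a C-E
    conversion is used only for an odd remainder or when the same-type
    pool is exhausted.
    """

    def fix_deficit(n_same, n_mixed, n_other, supply):
        # demand on the exhausted class: 2*n_same + n_mixed > supply
        d = 2 * n_same + n_mixed - supply
        if d <= 0:
            return n_same, n_mixed, n_other
        t = min(n_same, d // 2)  # same -> other frees 2 cells apiece
        n_same -= t
        n_other += t
        d -= 2 * t
        if d > 0 and n_same > 0:  # odd remainder: same -> mixed
            n_same -= 1
            n_mixed += 1
            d -= 1
        while d > 0 and n_mixed > 0:  # mixed -> other frees 1 apiece
            n_mixed -= 1
            n_other += 1
            d -= 1
        return n_same, n_mixed, n_other

    n_cc, n_ce, n_ee = fix_deficit(n_cc, n_ce, n_ee, n_coop)
    n_ee, n_ce, n_cc = fix_deficit(n_ee, n_ce, n_cc, n_expl)
    return n_cc, n_ce, n_ee


def assign_interactions(
    pop: TraitPopulation, split: StrategySplit, rng: Generator
) -> InteractionAssignment:
    """Pair cells at random for the sporulation game.

    ``floor(N/2)`` pairs are formed; pair-type counts are a multinomial
    draw with probabilities (p_c^2, 2 p_c p_e, p_e^2), then members are
    sampled without replacement from the matching strategy class.  Each
    cell joins at most one pair; at most one cell per class is left over.
    """
    n = len(pop)
    n_pairs = n // 2
    if n_pairs == 0:
        return InteractionAssignment(
            np.empty((0, 2), int),
            np.empty((0, 2), int),
            np.empty((0, 2), int),
            np.arange(n),
        )
    probs = np.array(
        [split.p_c**2, 2.0 * split.p_c * split.p_e, split.p_e**2]
    )
    probs = probs / probs.sum()
    n_cc, n_ce, n_ee = rng.multinomial(n_pairs, probs)
    n_cc, n_ce, n_ee = _repair_pair_counts(
        int(n_cc), int(n_ce), int(n_ee),
        split.cooperators.size, split.exploiters.size,
    )
    coop_perm = rng.permutation(split.cooperators)
    expl_perm = rng.permutation(split.exploiters)
    cc_pairs = coop_perm[: 2 * n_cc].reshape(n_cc, 2)
    ce_coop = coop_perm[2 * n_cc : 2 * n_cc + n_ce]
    ee_pairs = expl_perm[: 2 * n_ee].reshape(n_ee, 2)
    ce_expl = expl_perm[2 * n_ee : 2 * n_ee + n_ce]
    ce_pairs = np.column_stack([ce_coop, ce_expl]) if n_ce else np.empty(
        (0, 2), int
    )
    unpaired = np.concatenate(
        [coop_perm[2 * n_cc + n_ce :], expl_perm[2 * n_ee + n_ce :]]
    )
    return InteractionAssignment(cc_pairs, ce_pairs, ee_pairs, unpaired)


def resolve_cc(
    pop: TraitPopulation,
    cc_cells: np.ndarray,
    gamma: float,
    rng: Generator | None = None,
    *,
    threshold: float = 0.5,
    u: np.ndarray | None = None,
) -> tuple[np.ndarray, float]:
    """Resolve cooperator-cooperator interactions.

    Each of the ``m`` paired cooperators sporulates independently with
    probability ``gamma * s``; the bookkeeping payoff is
    ``K = gamma * 1/2 * sum(s)``.  ``u`` may supply the uniform draws
    (one per cell) for oracle-equivalence testing.

    Returns (indices of retained spores, K).
    """
    cc_cells = np.asarray(cc_cells, dtype=int)
    if cc_cells.size == 0:
        return cc_cells, 0.0
    s = pop.s[cc_cells]
    if np.any(s < threshold):
        raise ValueError(
            "internal consistency error: non-cooperator in a C-C pair"
        )
    K = gamma * 0.5 * float(s.sum())
    if u is None:
        if rng is None:
            raise ValueError("resolve_cc needs either rng or u")
        u = rng.random(cc_cells.size)
    keep = np.asarray(u) < gamma * s
    return cc_cells[keep], K


def resolve_ce(
    pop: TraitPopulation,
    coop_idx: np.ndarray,
    expl_idx: np.ndarray,
    n_sharing: float,
    threshold: float = 0.5,
) -> CEOutcome:
    """Resolve cooperator-exploiter interactions (deterministic).

    With ``D`` the difference of the mean sporulation abilities
    (cooperators minus exploiters), every paired exploiter gains
    ``D / n_sharing`` and every paired cooperator loses the total
    transfer divided by the cooperator count (equal shares both ways;
    ability is conserved up to clipping at [0, 1]).  Cells whose
    post-transfer ability clears ``threshold`` are retained as spores.
    """
    coop_idx = np.asarray(coop_idx, dtype=int)
    expl_idx = np.asarray(expl_idx, dtype=int)
    if coop_idx.size == 0 and expl_idx.size == 0:
        empty = np.empty(0, dtype=bool)
        return CEOutcome(
            coop_idx, expl_idx, np.empty(0), np.empty(0), empty, empty,
            0.0, 0.0, 0.0, False,
        )
    if coop_idx.size == 0 or expl_idx.size == 0:
        raise ValueError(
            "internal consistency error: C-E set with an empty side"
        )
    s_c = pop.s[coop_idx]
    s_e = pop.s[expl_idx]
    if np.any(s_c < threshold) or np.any(s_e >= threshold):
        raise ValueError(
            "internal consistency error: misclassified cell in a C-E pair"
        )
    D = float(s_c.mean() - s_e.mean())
    gain = D / n_sharing
    total = expl_idx.size * gain
    loss = total / coop_idx.size
    new_c = s_c - loss
    new_e = s_e + gain
    clipped = bool(
        (new_c < 0).any() or (new_c > 1).any()
        or (new_e < 0).any() or (new_e > 1).any()
    )
    new_c = np.clip(new_c, 0.0, 1.0)
    new_e = np.clip(new_e, 0.0, 1.0)
    coop_ret = new_c >= threshold
    expl_ret = new_e >= threshold
    L = float(new_c[coop_ret].sum())
    M = float(new_e[expl_ret].sum())
    return CEOutcome(
        coop_idx, expl_idx, new_c, new_e, coop_ret, expl_ret, L, M, D,
        clipped,
    )


def resolve_ee(ee_pairs: np.ndarray) -> tuple[np.ndarray, float]:
    """Exploiter-exploiter interactions never yield spores; N = 0."""
    return np.empty(0, dtype=int), 0.0


def sporulation_phase(
    pop: TraitPopulation,
    config: SimConfig,
    cycle_index: int,
    rng: Generator,
    *,
    u: np.ndarray | None = None,
) -> tuple[TraitPopulation, InteractionSummary]:
    """Run one sporulation phase and return (spores, payoff summary).

    Cycle 1: every cell sporulates independently with probability equal
    to its own ability ``s``.  Cycles >= 2: cells are classified, paired
    and the C-C / C-E / E-E interactions are resolved; unpaired leftovers
    do not sporulate.  ``u`` may inject the cycle-1 uniform draws for
    oracle testing.
    """
    if len(pop) == 0:
        raise ExtinctionError("sporulation", cycle_index)
    split = classify_strategies(pop, config.coop_threshold)
    if cycle_index <= 1:
        draws = rng.random(len(pop)) if u is None else np.asarray(u)
        keep = np.flatnonzero(draws < pop.s)
        spores = pop.subset(keep)
        summary = InteractionSummary(
            split.p_c, split.p_e, 0, 0, 0, 0.0, 0.0, 0.0, 0.0, 0.0
        )
        return spores, summary

    assign = assign_interactions(pop, split, rng)
    cc_cells = assign.cc_pairs.ravel()
    cc_keep, K = resolve_cc(
        pop, cc_cells, config.gamma, rng, threshold=config.coop_threshold
    )
    ce = resolve_ce(
        pop,
        assign.ce_pairs[:, 0],
        assign.ce_pairs[:, 1],
        config.n_sharing,
        config.coop_threshold,
    )
    resolve_ee(assign.ee_pairs)  # no spores, N = 0 by definition
    parts = [pop.subset(cc_keep)]
    if ce.coop_idx.size:
        parts.append(
            TraitPopulation(
                ce.s_coop[ce.coop_retained],
                pop.g[ce.coop_idx][ce.coop_retained],
            )
        )
        parts.append(
            TraitPopulation(
                ce.s_expl[ce.expl_retained],
                pop.g[ce.expl_idx][ce.expl_retained],
            )
        )
    spores = TraitPopulation.concat(parts)
    summary = InteractionSummary(
        split.p_c,
        split.p_e,
        int(cc_cells.size),
        int(ce.coop_idx.size),
        int(ce.expl_idx.size),
        K,
        ce.L,
        ce.M,
        0.0,
        ce.D,
    )
    return spores, summary


def germination_phase(
    spores: TraitPopulation,
    epsilon: float,
    mode: str = "communal",
    rng: Generator | None = None,
    *,
    u: np.ndarray | None = None,
) -> TraitPopulation:
    """Select germinating spores.

    "communal": every spore germinates with probability
    ``epsilon * mean(g)`` — germination runs entirely on the shared pool
    of diffusible goods.  "mixed": probability
    ``epsilon * mean(g) + (1 - epsilon) * g_i``.  Probabilities are
    clipped to [0, 1]; germinated cells keep their traits.
    """
    if len(spores) == 0:
        raise ExtinctionError("germination")
    if mode not in GERMINATION_MODES:
        raise ConfigurationError(
            f"germination_mode={mode!r} must be one of {GERMINATION_MODES}"
        )
    mean_g = float(spores.g.mean())
    if mode == "communal":
        probs = np.full(len(spores), epsilon * mean_g)
    else:
        probs = epsilon * mean_g + (1.0 - epsilon) * spores.g
    probs = np.clip(probs, 0.0, 1.0)
    if u is None:
        if rng is None:
            raise ValueError("germination_phase needs either rng or u")
        u = rng.random(len(spores))
    keep = np.flatnonzero(np.asarray(u) < probs)
    return spores.subset(keep)


def bottleneck_phase(
    pop: TraitPopulation, beta: float, rng: Generator
) -> TraitPopulation:
    """Trait-blind uniform subsampling of round(beta * N) cells (min 1)."""
    if len(pop) == 0:
        raise ExtinctionError("bottleneck")
    n = len(pop)
    k = int(math.floor(beta * n + 0.5))  # round half up, stable across n
    k = max(k, 1)
    k = min(k, n)
    keep = rng.choice(n, size=k, replace=False)
    return pop.subset(keep)


def growth_phase(
    pop: TraitPopulation, config: SimConfig, rng: Generator
) -> TraitPopulation:
    """Synchronous binary fission with mutation until carrying capacity.

    Every division round doubles the census.  Each daughter mutates with
    probability ``mutation_prob``: the germination step is uniform on
    [-mutation_halfwidth, +mutation_halfwidth] and the sporulation step
    is ``tradeoff_slope`` times the germination step.  Daughters pushed
    outside [0, 1] in either trait are removed (lethal mutation).  Once
    the census reaches ``n_max`` a uniform random subset of exactly
    ``n_max`` cells is kept.
    """
    if len(pop) == 0:
        raise ExtinctionError("growth")
    s, g = pop.s, pop.g
    rounds = 0
    while s.size < config.n_max:
        s = np.repeat(s, 2)
        g = np.repeat(g, 2)
        if config.mutation_prob > 0 and config.mutation_halfwidth > 0:
            if config.mutation_prob >= 1.0:
                mutate = slice(None)
                n_mut = s.size
            else:
                mask = rng.random(s.size) < config.mutation_prob
                mutate = mask
                n_mut = int(mask.sum())
            dg = rng.uniform(
                -config.mutation_halfwidth,
                config.mutation_halfwidth,
                size=n_mut,
            )
            g[mutate] = g[mutate] + dg
            s[mutate] = s[mutate] + config.tradeoff_slope * dg
            alive = (s >= 0.0) & (s <= 1.0) & (g >= 0.0) & (g <= 1.0)
            s, g = s[alive], g[alive]
            if s.size == 0:
                raise ExtinctionError("growth")
        rounds += 1
        if rounds > 10_000:  # defensive: census must eventually move
            raise RuntimeError("growth phase failed to reach n_max")
    if s.size > config.n_max:
        keep = rng.choice(s.size, size=config.n_max, replace=False)
        s, g = s[keep], g[keep]
    return TraitPopulation(s, g)


def relative_metrics(
    evolved_rates: tuple[float, float],
    ancestral_rates: tuple[float, float],
    cycle: int = 0,
) -> RelativeMetrics:
    """Log10 ratio of evolved vs ancestral per-phase retention rates.

    ``rates`` are (sporulation rate, germination rate): the retained
    fraction at each phase of the focal cycle.  A zero evolved rate is
    reported as an explicit floor (:data:`METRIC_FLOOR`) with a flag, not
    as a silent -inf.
    """
    anc_sp, anc_ge = ancestral_rates
    if anc_sp <= 0 or anc_ge <= 0:
        raise ValueError("ancestral rates must be positive")
    ev_sp, ev_ge = evolved_rates

    def _log_ratio(ev: float, anc: float) -> tuple[float, bool]:
        if ev <= 0:
            return METRIC_FLOOR, True
        return math.log10(ev / anc), False

    rel_sp, sp_fl = _log_ratio(ev_sp, anc_sp)
    rel_ge, ge_fl = _log_ratio(ev_ge, anc_ge)
    return RelativeMetrics(cycle, rel_sp, rel_ge, sp_fl, ge_fl)


# ---------------------------------------------------------------------------
# whole runs
# ---------------------------------------------------------------------------


def run_simulation(config: SimConfig) -> SimResult:
    """Run the configured number of life cycles from a fresh population.

    Cycle 1 runs without a preceding bottleneck (individual-ability
    sporulation, ``epsilon_first_cycle`` germination) and defines the
    ancestral reference rates.  Cycles 2..n are
    sporulation -> germination -> bottleneck -> growth.  Relative metrics
    are recorded at every configured readout cycle that is reached.
    Extinction ends the run gracefully with the failing cycle flagged.
    """
    config.validate()
    rng = default_rng(SeedSequence(config.seed))
    logger.info("starting simulation: %s", config)
    pop = init_population(config, rng)
    records: list[CycleRecord] = []
    metrics: dict[int, RelativeMetrics] = {}
    pc_series: list[tuple[int, float]] = []
    ancestral: tuple[float, float] | None = None

    if config.n_cycles == 0:
        metrics[0] = RelativeMetrics(0, 0.0, 0.0)
        return SimResult(config, records, metrics, None, pc_series, pop)

    for cycle in range(1, config.n_cycles + 1):
        n_start = len(pop)
        mean_s_start = float(pop.s.mean())
        mean_g_start = float(pop.g.mean())
        try:
            spores, summary = sporulation_phase(pop, config, cycle, rng)
            pc_series.append((cycle, summary.p_c))
            spor_rate = len(spores) / n_start
            eps = (
                config.epsilon_first_cycle
                if cycle == 1
                else config.epsilon
            )
            germinated = germination_phase(
                spores, eps, config.germination_mode, rng
            )
            germ_rate = len(germinated) / len(spores)
            if cycle == 1:
                ancestral = (spor_rate, germ_rate)
            if cycle in config.readout_cycles and ancestral is not None:
                metrics[cycle] = relative_metrics(
                    (spor_rate, germ_rate), ancestral, cycle
                )
            survivors = bottleneck_phase(germinated, config.beta, rng)
            pop_next = growth_phase(survivors, config, rng)
        except ExtinctionError as exc:
            logger.warning("extinction at cycle %d (%s)", cycle, exc.phase)
            return SimResult(
                config, records, metrics, ancestral, pc_series, None,
                extinct=True, extinct_cycle=cycle,
            )
        records.append(
            CycleRecord(
                cycle=cycle,
                n_start=n_start,
                n_spores=len(spores),
                n_germinated=len(germinated),
                n_after_bottleneck=len(survivors),
                n_after_growth=len(pop_next),
                mean_s_start=mean_s_start,
                mean_g_start=mean_g_start,
                mean_s_spores=float(spores.s.mean()) if len(spores) else
                float("nan"),
                mean_g_spores=float(spores.g.mean()) if len(spores) else
                float("nan"),
                spor_rate=spor_rate,
                germ_rate=germ_rate,
                interactions=summary,
            )
        )
        logger.info(
            "cycle %d: %d -> %d spores -> %d germinated (p_c=%.3f)",
            cycle, n_start, len(spores), len(germinated), summary.p_c,
        )
        pop = pop_next
    return SimResult(config, records, metrics, ancestral, pc_series, pop)


def sweep(
    config: SimConfig,
    gamma_grid: Sequence[float],
    epsilon_grid: Sequence[float],
    replicates: int = 1,
) -> SweepResult:
    """Run the simulation over a (gamma, epsilon) grid.

    Per-point child seeds derive deterministically from ``config.seed``,
    so a sweep is reproducible and parallelizable.  Extinction at a grid
    point is propagated as a flagged row, not an abort.
    """
    gamma_grid = list(gamma_grid)
    epsilon_grid = list(epsilon_grid)
    if not gamma_grid or not epsilon_grid:
        raise ConfigurationError("gamma/epsilon grids must be nonempty")
    if replicates < 1:
        raise ConfigurationError("replicates must be >= 1")
    n_points = len(gamma_grid) * len(epsilon_grid) * replicates
    child_seeds = derive_child_seeds(config.seed, n_points)
    rows = []
    seeds: dict[tuple[float, float, int], int] = {}
    i = 0
    for gamma in gamma_grid:
        for epsilon in epsilon_grid:
            for rep in range(replicates):
                seed = child_seeds[i]
                i += 1
                seeds[(gamma, epsilon, rep)] = seed
                cfg = replace(
                    config, gamma=gamma, epsilon=epsilon, seed=seed
                )
                result = run_simulation(cfg)
                if result.metrics:
                    for m in result.metrics.values():
                        rows.append(
                            {
                                "gamma": gamma,
                                "epsilon": epsilon,
                                "replicate": rep,
                                "seed": seed,
                                "cycle": m.cycle,
                                "rel_spore_productivity":
                                    m.rel_spore_productivity,
                                "rel_germination_efficiency":
                                    m.rel_germination_efficiency,
                                "extinct": result.extinct,
                            }
                        )
                else:
                    rows.append(
                        {
                            "gamma": gamma,
                            "epsilon": epsilon,
                            "replicate": rep,
                            "seed": seed,
                            "cycle": np.nan,
                            "rel_spore_productivity": np.nan,
                            "rel_germination_efficiency": np.nan,
                            "extinct": result.extinct,
                        }
                    )
    table = pd.DataFrame(rows)
    grouped = table.dropna(subset=["cycle"]).groupby(
        ["gamma", "epsilon", "cycle"], as_index=False
    )
    summary = grouped.agg(
        mean_rel_spore=("rel_spore_productivity", "mean"),
        sd_rel_spore=("rel_spore_productivity", "std"),
        mean_rel_germ=("rel_germination_efficiency", "mean"),
        sd_rel_germ=("rel_germination_efficiency", "std"),
        n=("rel_spore_productivity", "size"),
    )
    return SweepResult(table, summary, seeds)


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Min-max rescale to [-1, 1] for surface plotting only.

    The sign and ordering of the raw log ratios are the scientific
    output; this helper just eases cross-panel display.
    """
    values = np.asarray(values, dtype=float)
    lo, hi = np.nanmin(values), np.nanmax(values)
    if hi == lo:
        return np.zeros_like(values)
    return 2.0 * (values - lo) / (hi - lo) - 1.0
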