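"""Synthetic assay datasets with known ground truth.

Wet-lab measurements in this pipeline are dilution-plating CFU counts,
density-series trait responses, and paired trait values for natural
isolates.  The generators here emulate those designs with the standard
plating noise model — log-normal biological variation on the true
abundances, Poisson sampling of colonies on the plate — so every
statistic in :mod:`myxolife.assay_stats` can be exercised end-to-end and
its parameter recovery calibrated without any external download.

Every generator embeds its ground truth in the returned metadata, is
deterministic under a fixed seed, and emits the same tidy schema the
analysis functions ingest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from numpy.random import Generator

from .assay_stats import COMPETITION_COLUMNS

__all__ = [
    "AssayDesign",
    "TraitPairDesign",
    "synth_competition",
    "synth_density_assay",
    "synth_trait_pairs",
    "synth_lifecycle_competition",
    "synth_two_group",
]

#: Standard inoculum of a monoculture development assay: 100 uL of a
#: 5e9 cells/mL suspension.
DEFAULT_T0 = 5e8
#: Plated volume (mL) in the 10-fold dilution series.
PLATED_VOLUME_ML = 0.1
#: Target upper bound for countable colonies on a plate.
MAX_COUNTABLE = 300.0


@dataclass
class AssayDesign:
    """Design of a mono-/co-culture development competition experiment.

    ``strains`` maps strain id to its true monoculture log10 productivity
    (Di); ``cij`` maps ordered pairs to the true one-way mixing effect on
    the first strain.  ``marker_strains`` carry the resistance marker
    used to deconvolve co-culture plates (exactly one per pair).
    """

    strains: Mapping[str, float]
    cij: Mapping[tuple[str, str], float] = field(default_factory=dict)
    pairs: Sequence[tuple[str, str]] = ()
    marker_strains: frozenset[str] = frozenset()
    replicates: int = 4
    t0_total: float = DEFAULT_T0
    bio_sd_log10: float = 0.1
    poisson_plating: bool = True

    def validate(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.bio_sd_log10 < 0:
            raise ValueError("bio_sd_log10 must be >= 0")
        if self.t0_total <= 0:
            raise ValueError("t0_total must be > 0")
        for i, j in self.pairs:
            if i not in self.strains or j not in self.strains:
                raise ValueError(f"pair ({i}, {j}) references unknown strain")
            n_marked = (i in self.marker_strains) + (j in self.marker_strains)
            if n_marked != 1:
                raise ValueError(
                    f"pair ({i}, {j}) must contain exactly one marker strain"
                )


@dataclass
class TraitPairDesign:
    """Design of a natural-isolate trait-pair survey.

    Defaults mirror a survey of 13 soil isolates whose sporulation and
    germination abilities are negatively correlated (target r = -0.6).
    """

    n_isolates: int = 13
    target_r: float = -0.6
    mean_x: float = -1.5  # log10 sporulation efficiency (%)
    sd_x: float = 1.0
    range_x: tuple[float, float] = (-6.0, 2.0)
    mean_y: float = 50.0  # germination efficiency (%)
    sd_y: float = 20.0
    range_y: tuple[float, float] = (0.0, 100.0)

    def validate(self) -> None:
        if self.n_isolates < 3:
            raise ValueError("n_isolates must be >= 3")
        if not -1.0 < self.target_r < 1.0:
            raise ValueError("target_r must lie strictly inside (-1, 1)")
        for lo, hi, m in (
            (*self.range_x, self.mean_x),
            (*self.range_y, self.mean_y),
        ):
            if not lo < hi:
                raise ValueError("trait range must be nonempty")
            if not lo <= m <= hi:
                raise ValueError("trait mean must lie inside its range")


def _plate(true_count: float, rng: Generator, poisson: bool) -> float:
    """Simulate dilution plating of a harvest containing ``true_count``.

    Picks the 10-fold dilution that brings the expected colony number
    under :data:`MAX_COUNTABLE`, draws the Poisson colony count, and
    back-calculates the reported CFU.
    """
    if true_count <= 0:
        return 0.0
    if not poisson:
        return true_count
    lam = true_count * PLATED_VOLUME_ML
    dilution = 1.0
    if lam > MAX_COUNTABLE:
        dilution = 10.0 ** math.ceil(math.log10(lam / MAX_COUNTABLE))
        lam = true_count * PLATED_VOLUME_ML / dilution
    colonies = rng.poisson(lam)
    return colonies * dilution / PLATED_VOLUME_ML


def synth_competition(
    design: AssayDesign, rng: Generator
) -> tuple[pd.DataFrame, dict]:
    """Generate a tidy competition count table plus its ground truth.

    Monocultures start at ``t0_total`` cells, co-cultures split the same
    inoculum 1:1.  True spore yields are
    ``t0 * 10^(Di + Cij + biological noise)``; observed counts pass
    through the Poisson plating model.  Co-culture rows carry the
    nonselective total in ``count`` and the marker strain's selective
    count in ``marker_count``.
    """
    design.validate()
    rows: list[dict] = []

    def emit(strain, partner, context, rep, t0, t3_obs, marker_t0=None,
             marker_t3=None):
        rows.append(
            {
                "strain": strain,
                "partner": partner,
                "context": context,
                "timepoint": "t0",
                "replicate": rep,
                "count": t0,
                "marker_count": marker_t0,
            }
        )
        rows.append(
            {
                "strain": strain,
                "partner": partner,
                "context": context,
                "timepoint": "t3",
                "replicate": rep,
                "count": t3_obs,
                "marker_count": marker_t3,
            }
        )

    for strain, di in design.strains.items():
        for rep in range(1, design.replicates + 1):
            noise = rng.normal(0.0, design.bio_sd_log10)
            true_t3 = design.t0_total * 10.0 ** (di + noise)
            emit(
                strain, "", "mono", rep, design.t0_total,
                _plate(true_t3, rng, design.poisson_plating),
            )

    for i, j in design.pairs:
        marker = i if i in design.marker_strains else j
        other = j if marker == i else i
        t0_each = design.t0_total / 2.0
        for rep in range(1, design.replicates + 1):
            true = {}
            for a, b in ((i, j), (j, i)):
                noise = rng.normal(0.0, design.bio_sd_log10)
                eff = design.strains[a] + design.cij.get((a, b), 0.0)
                true[a] = t0_each * 10.0 ** (eff + noise)
            total_t3 = _plate(
                true[marker] + true[other], rng, design.poisson_plating
            )
            marker_t3 = _plate(true[marker], rng, design.poisson_plating)
            emit(
                marker, other, "co", rep,
                design.t0_total, total_t3,
                marker_t0=t0_each, marker_t3=marker_t3,
            )

    df = pd.DataFrame(rows, columns=list(COMPETITION_COLUMNS))
    truth = {
        "Di": dict(design.strains),
        "Cij": {f"{i}|{j}": v for (i, j), v in design.cij.items()},
        "replicates": design.replicates,
        "t0_total": design.t0_total,
        "bio_sd_log10": design.bio_sd_log10,
    }
    return df, truth


def synth_density_assay(
    slope: float,
    intercept: float,
    noise_sd: float,
    densities: Sequence[float],
    rng: Generator,
    *,
    group: str = "ancestor",
    trait: str = "growth",
) -> tuple[pd.DataFrame, dict]:
    """Density-series assay: per-capita response linear in density."""
    densities = np.asarray(densities, dtype=float)
    if densities.size < 3:
        raise ValueError("need >= 3 densities")
    responses = (
        intercept + slope * densities + rng.normal(0.0, noise_sd,
                                                   densities.size)
    )
    df = pd.DataFrame(
        {
            "trait": trait,
            "group": group,
            "density": densities,
            "response": responses,
        }
    )
    truth = {
        "slope": slope,
        "intercept": intercept,
        "noise_sd": noise_sd,
        "group": group,
        "trait": trait,
    }
    return df, truth


def _truncated_pairs(
    latent_r: float, design: TraitPairDesign, z: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Map standard-normal draws to truncated correlated trait pairs."""
    x = design.mean_x + design.sd_x * z[:, 0]
    y = design.mean_y + design.sd_y * (
        latent_r * z[:, 0] + math.sqrt(1.0 - latent_r**2) * z[:, 1]
    )
    ok = (
        (x >= design.range_x[0])
        & (x <= design.range_x[1])
        & (y >= design.range_y[0])
        & (y <= design.range_y[1])
    )
    return x[ok], y[ok]


def _calibrated_latent_r(design: TraitPairDesign) -> float:
    """Latent correlation whose truncated distribution hits target_r.

    Rejection at the range boundaries attenuates correlation, so the
    latent bivariate-normal correlation is solved (deterministically, on
    a fixed large calibration sample) such that the *truncated* pairs
    carry the design's target Pearson correlation.  Targets beyond what
    the truncation admits are clamped to the closest achievable value.
    """
    if design.target_r == 0.0:
        return 0.0
    z = np.random.default_rng(987654321).standard_normal((200_000, 2))

    def realized(rho: float) -> float:
        x, y = _truncated_pairs(rho, design, z)
        if x.size < 2:
            raise ValueError("truncation region unreachable for this design")
        return float(np.corrcoef(x, y)[0, 1])

    lo, hi = -0.9999, 0.9999
    if realized(hi) <= design.target_r:
        return hi
    if realized(lo) >= design.target_r:
        return lo
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if realized(mid) < design.target_r:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


_LATENT_R_CACHE: dict[tuple, float] = {}


def synth_trait_pairs(
    design: TraitPairDesign, rng: Generator
) -> tuple[pd.DataFrame, dict]:
    """Trait pairs at a specified Pearson correlation.

    Pairs are bivariate normal, rejected and redrawn outside the
    plausible assay ranges; the latent correlation is pre-calibrated so
    the truncated pairs carry the design's target correlation.  An
    acceptance region that cannot be reached raises a ValueError.
    """
    design.validate()
    n = design.n_isolates
    key = (
        design.target_r, design.mean_x, design.sd_x, *design.range_x,
        design.mean_y, design.sd_y, *design.range_y,
    )
    if key not in _LATENT_R_CACHE:
        _LATENT_R_CACHE[key] = _calibrated_latent_r(design)
    latent_r = _LATENT_R_CACHE[key]
    xs = np.empty(0)
    ys = np.empty(0)
    for _ in range(1000):
        z = rng.standard_normal((4 * n, 2))
        x, y = _truncated_pairs(latent_r, design, z)
        xs = np.concatenate([xs, x])
        ys = np.concatenate([ys, y])
        if xs.size >= n:
            break
    else:
        raise ValueError("truncation region unreachable for this design")
    df = pd.DataFrame(
        {
            "isolate": [f"X{k + 1}" for k in range(n)],
            "log10_sporulation_efficiency": xs[:n],
            "germination_efficiency": ys[:n],
        }
    )
    truth = {
        "target_r": design.target_r,
        "n_isolates": n,
    }
    return df, truth


def synth_lifecycle_competition(
    true_logfold: float,
    reps: int,
    noise_sd: float,
    rng: Generator,
) -> tuple[pd.DataFrame, dict]:
    """Per-replicate evolved-vs-ancestor life-cycle log-fold differences."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    diffs = true_logfold + rng.normal(0.0, noise_sd, reps)
    df = pd.DataFrame(
        {"replicate": np.arange(1, reps + 1), "logfold_diff": diffs}
    )
    truth = {"true_logfold": true_logfold, "noise_sd": noise_sd,
             "reps": reps}
    return df, truth


def synth_two_group(
    mean_a: float,
    mean_b: float,
    sd: float,
    n_per_group: int,
    rng: Generator,
    *,
    labels: tuple[str, str] = ("stringent", "relaxed"),
    value_name: str = "value",
) -> tuple[pd.DataFrame, dict]:
    """Two-group replicate measurements with a known mean contrast.

    Synthetic stand-in for the paired clone assays (growth, sporulation,
    predation, germination contrasts between regimens).
    """
    if n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if sd < 0:
        raise ValueError("sd must be >= 0")
    a = mean_a + rng.normal(0.0, sd, n_per_group)
    b = mean_b + rng.normal(0.0, sd, n_per_group)
    df = pd.DataFrame(
        {
            "group": [labels[0]] * n_per_group + [labels[1]] * n_per_group,
            value_name: np.concatenate([a, b]),
        }
    )
    truth = {"contrast": mean_a - mean_b, "sd": sd, "n": n_per_group}
    return df, truth
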