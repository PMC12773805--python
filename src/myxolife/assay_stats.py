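"""Statistics for sporulation, germination and competition assays.

This module implements the empirical side of the analysis: CFU accounting
from dilution plating, sporulation/germination efficiencies, mono- versus
co-culture development-competition metrics, life-cycle relative fitness,
density-dependence regressions, trait correlations, and a gated,
FDR-corrected testing pipeline.

The central competition quantities, for strains *i* and *j* with viable
counts ``N(t0)`` (vegetative cells before starvation) and ``N(t3)``
(viable spores after three days of starvation):

    Di  = log10[Ni(t3) / Ni(t0)]          (monoculture log productivity)
    Dij = log10[Ni(j,t3) / Ni(j,t0)]      (same, in co-culture with j)
    Wij = Dij - Dji                       (relative performance in the mix)
    Cij = Dij - Di                        (one-way mixing effect on i)

Positive ``Cij`` means strain *i* benefits from the presence of *j*;
negative means *j* suppresses it.  Co-culture plate counts are
deconvolved with a resistance marker: colonies on the selective plate are
the marker-bearing strain, the difference from the nonselective plate is
the partner.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "COMPETITION_COLUMNS",
    "CompetitionResult",
    "DensityFit",
    "TestReport",
    "sporulation_efficiency",
    "germination_efficiency",
    "cfu_from_plate",
    "log_productivity",
    "competition_metrics",
    "lifecycle_relative_fitness",
    "density_dependence",
    "trait_correlation",
    "fdr_adjust",
    "signed_sqrt",
    "test_suite",
    "read_table",
]

#: Canonical tidy schema for competition count tables.
COMPETITION_COLUMNS = (
    "strain",
    "partner",
    "context",
    "timepoint",
    "replicate",
    "count",
    "marker_count",
)


# ---------------------------------------------------------------------------
# elementary assay arithmetic
# ---------------------------------------------------------------------------


def sporulation_efficiency(initial_cells: float, spore_count: float) -> float:
    """Percentage of input vegetative cells recovered as viable spores."""
    if initial_cells <= 0:
        raise ValueError("initial_cells must be > 0")
    if spore_count < 0:
        raise ValueError("spore_count must be >= 0")
    return 100.0 * spore_count / initial_cells


def germination_efficiency(
    initial_spores: float, final_ungerminated: float
) -> float:
    """Percentage of spores that exited dormancy in the assay window.

    ``100 * (initial - final) / initial``.  A final count above the
    initial one (plating noise) is floored at 0% with a warning.
    """
    if initial_spores <= 0:
        raise ValueError("initial_spores must be > 0")
    if final_ungerminated < 0:
        raise ValueError("final_ungerminated must be >= 0")
    if final_ungerminated > initial_spores:
        warnings.warn(
            "final spore count exceeds initial count; germination "
            "efficiency floored at 0%",
            stacklevel=2,
        )
        return 0.0
    return 100.0 * (initial_spores - final_ungerminated) / initial_spores


def cfu_from_plate(
    colonies: float, dilution_factor: float, plated_volume_ml: float
) -> float:
    """CFU per mL from a colony count on a diluted plate."""
    if plated_volume_ml <= 0:
        raise ValueError("plated_volume_ml must be > 0")
    if dilution_factor < 1:
        raise ValueError("dilution_factor must be >= 1")
    if colonies < 0:
        raise ValueError("colonies must be >= 0")
    return colonies * dilution_factor / plated_volume_ml


def log_productivity(n_t0: float, n_t3: float) -> float:
    """Log10 ratio of spore output to vegetative input (``D``).

    A zero ``n_t3`` returns ``-inf`` with a warning so callers can flag
    or exclude it explicitly.
    """
    if n_t0 <= 0:
        raise ValueError("n_t0 must be > 0")
    if n_t3 < 0:
        raise ValueError("n_t3 must be >= 0")
    if n_t3 == 0:
        warnings.warn(
            "zero t3 count: log productivity is -inf", stacklevel=2
        )
        return float("-inf")
    return math.log10(n_t3 / n_t0)


def signed_sqrt(x):
    """Signed square-root transform, ``sign(x) * sqrt(|x|)``."""
    x = np.asarray(x, dtype=float)
    out = np.sign(x) * np.sqrt(np.abs(x))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# competition metrics
# ---------------------------------------------------------------------------


@dataclass
class CompetitionResult:
    """Per-replicate and summary competition metrics for a strain pair."""

    strain_i: str
    strain_j: str
    per_replicate: pd.DataFrame
    summary: dict[str, float]
    flags: list[str] = field(default_factory=list)


def _pivot_counts(
    df: pd.DataFrame, mask: pd.Series, value_col: str
) -> pd.DataFrame:
    sub = df.loc[mask, ["replicate", "timepoint", value_col]]
    wide = sub.pivot_table(
        index="replicate", columns="timepoint", values=value_col,
        aggfunc="first",
    )
    missing = {"t0", "t3"} - set(wide.columns)
    if missing:
        raise ValueError(f"missing timepoints {sorted(missing)} in records")
    return wide


def _log_ratio_series(t0: pd.Series, t3: pd.Series) -> pd.Series:
    if (t0 <= 0).any():
        raise ValueError("t0 counts must be > 0 for log ratios")
    with np.errstate(divide="ignore"):
        return np.log10(t3.astype(float) / t0.astype(float))


def competition_metrics(
    records: pd.DataFrame,
    strain_i: str,
    strain_j: str,
    *,
    pseudo_half_min: bool = False,
) -> CompetitionResult:
    """Compute Di, Dj, Dij, Dji, Wij, Cij, Cji from a tidy count table.

    ``records`` follows :data:`COMPETITION_COLUMNS`.  Monoculture rows
    carry the plain viable count; co-culture rows represent one harvest
    plated with and without the selection marker: ``strain`` is the
    marker-bearing strain, ``count`` the nonselective (total) CFU and
    ``marker_count`` the selective-plate CFU.  The partner's count is the
    difference, floored at zero and flagged when plating noise makes it
    negative.

    Zero counts produce ``-inf`` log ratios which are excluded from the
    replicate means with a warning; ``pseudo_half_min=True`` instead
    substitutes half of the smallest positive count observed in the same
    column.
    """
    df = records.copy()
    missing_cols = set(COMPETITION_COLUMNS[:6]) - set(df.columns)
    if missing_cols:
        raise ValueError(f"records lack columns {sorted(missing_cols)}")
    flags: list[str] = []

    def mono(strain: str) -> pd.DataFrame:
        mask = (df["context"] == "mono") & (df["strain"] == strain)
        if not mask.any():
            raise ValueError(f"no monoculture records for strain {strain!r}")
        return _pivot_counts(df, mask, "count")

    mono_i = mono(strain_i)
    mono_j = mono(strain_j)

    co_mask = (df["context"] == "co") & (
        ((df["strain"] == strain_i) & (df["partner"] == strain_j))
        | ((df["strain"] == strain_j) & (df["partner"] == strain_i))
    )
    if not co_mask.any():
        raise ValueError(
            f"no co-culture records for pair ({strain_i!r}, {strain_j!r})"
        )
    marker_strain = df.loc[co_mask, "strain"].iloc[0]
    if df.loc[co_mask, "strain"].nunique() != 1:
        raise ValueError("co-culture rows must share one marker strain")
    other = strain_j if marker_strain == strain_i else strain_i

    co_total = _pivot_counts(df, co_mask, "count")
    co_marker = _pivot_counts(df, co_mask, "marker_count")
    co_partner = co_total - co_marker
    if (co_partner < 0).any().any():
        flags.append("negative deconvolved partner count floored at 0")
        co_partner = co_partner.clip(lower=0.0)

    co_counts = {marker_strain: co_marker, other: co_partner}

    def maybe_pseudo(frame: pd.DataFrame) -> pd.DataFrame:
        if not pseudo_half_min:
            return frame
        out = frame.copy()
        for col in out.columns:
            pos = out[col][out[col] > 0]
            if len(pos) and (out[col] == 0).any():
                out.loc[out[col] == 0, col] = pos.min() / 2.0
                flags.append(f"pseudo-count applied in column {col}")
        return out

    d_i = _log_ratio_series(mono_i["t0"], maybe_pseudo(mono_i)["t3"])
    d_j = _log_ratio_series(mono_j["t0"], maybe_pseudo(mono_j)["t3"])
    ci = maybe_pseudo(co_counts[strain_i])
    cj = maybe_pseudo(co_counts[strain_j])
    d_ij = _log_ratio_series(ci["t0"], ci["t3"])
    d_ji = _log_ratio_series(cj["t0"], cj["t3"])

    per = pd.DataFrame(
        {
            "Di": d_i,
            "Dj": d_j,
            "Dij": d_ij,
            "Dji": d_ji,
        }
    )
    per["Wij"] = per["Dij"] - per["Dji"]
    per["Cij"] = per["Dij"] - per["Di"]
    per["Cji"] = per["Dji"] - per["Dj"]
    per = per.reset_index()

    summary = {}
    for col in ("Di", "Dj", "Dij", "Dji", "Wij", "Cij", "Cji"):
        vals = per[col].to_numpy(dtype=float)
        finite = np.isfinite(vals)
        if not finite.all():
            warnings.warn(
                f"non-finite {col} values excluded from the replicate mean",
                stacklevel=2,
            )
            flags.append(f"non-finite {col} excluded from mean")
        summary[col] = float(vals[finite].mean()) if finite.any() else (
            float("nan")
        )
    return CompetitionResult(strain_i, strain_j, per, summary, flags)


# ---------------------------------------------------------------------------
# regressions, correlations, tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DensityFit:
    """Simple linear regression of a per-capita response on density."""

    trait: str
    group: str
    slope: float
    intercept: float
    r_squared: float
    r_squared_adj: float
    p_value: float
    n: int
    density_dependent: bool
    direction: str  # "positive" | "negative" | "none"


def density_dependence(
    densities: Sequence[float],
    responses: Sequence[float],
    group: str = "",
    *,
    trait: str = "",
    alpha: float = 0.05,
) -> DensityFit:
    """OLS fit of per-capita response against initial density.

    Reports both plain and adjusted R-squared (the adjusted value can go
    slightly negative on null data, matching how weak fits are usually
    reported for these assays) and the two-sided p-value for a nonzero
    slope.  For predation-style assays where the response is prey CFU, a
    significant *negative* slope indicates density-dependent predation.
    """
    x = np.asarray(densities, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("constant density vector: cannot fit")
    if np.ptp(y) == 0:
        # degenerate flat response: slope 0, no evidence of dependence
        return DensityFit(
            trait, group, 0.0, float(y[0]), 0.0,
            0.0, 1.0, x.size, False, "none",
        )
    fit = stats.linregress(x, y)
    n = x.size
    r2 = fit.rvalue**2
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2)
    significant = fit.pvalue < alpha
    direction = "none"
    if significant:
        direction = "positive" if fit.slope > 0 else "negative"
    return DensityFit(
        trait, group, float(fit.slope), float(fit.intercept), float(r2),
        float(r2_adj), float(fit.pvalue), n, significant, direction,
    )


def trait_correlation(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float, int, float]:
    """Pearson correlation with its t statistic.

    Returns ``(r, t, df, p)`` with ``t = r * sqrt(df / (1 - r^2))`` and
    ``df = n - 2``; the two-sided p-value comes from the t distribution.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    r = float(np.corrcoef(x, y)[0, 1])
    df = x.size - 2
    if abs(r) >= 1.0:
        t = math.inf if r > 0 else -math.inf
        return r, t, df, 0.0
    t = r * math.sqrt(df / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(t), df, float(p)


def fdr_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class TestReport:
    """One hypothesis test: gates, statistic, raw and FDR-adjusted p."""

    name: str
    family: str
    test_used: str
    statistic: float
    df: float
    p_raw: float
    p_adj: float
    transform: str
    shapiro_p: float
    levene_p: float
    effect: float
    n: int


def lifecycle_relative_fitness(
    differences: Sequence[float],
    transform: str = "signed_sqrt",
) -> tuple[TestReport, float]:
    """Test per-replicate life-cycle log-fold fitness differences vs 0.

    ``differences`` are evolved-minus-ancestor log10-fold productivity
    differences across the full life-cycle competition.  The signed
    square-root transform tames heavy tails while preserving sign; the
    effect size reported is the raw-scale mean.  With fewer than two
    replicates no test is possible and only the effect is returned.
    """
    diffs = np.asarray(differences, dtype=float)
    if diffs.size == 0:
        raise ValueError("no replicate differences supplied")
    effect = float(diffs.mean())
    if transform == "signed_sqrt":
        vals = signed_sqrt(diffs)
    elif transform in ("none", None):
        vals = diffs
    else:
        raise ValueError(f"unknown transform {transform!r}")
    shapiro_p = float("nan")
    if diffs.size >= 3 and np.ptp(vals) > 0:
        shapiro_p = float(stats.shapiro(vals).pvalue)
    if diffs.size < 2:
        report = TestReport(
            "lifecycle_relative_fitness", "lifecycle", "none",
            float("nan"), float("nan"), float("nan"), float("nan"),
            transform or "none", shapiro_p, float("nan"), effect,
            int(diffs.size),
        )
        return report, effect
    if np.ptp(vals) == 0:
        stat, p = (0.0, 1.0) if vals[0] == 0 else (math.inf, 0.0)
    else:
        res = stats.ttest_1samp(vals, 0.0)
        stat, p = float(res.statistic), float(res.pvalue)
    report = TestReport(
        "lifecycle_relative_fitness", "lifecycle", "one_sample_t",
        stat, float(diffs.size - 1), p, p, transform or "none",
        shapiro_p, float("nan"), effect, int(diffs.size),
    )
    return report, effect


def _gate_shapiro(groups: list[np.ndarray]) -> float:
    ps = []
    for grp in groups:
        if grp.size >= 3 and np.ptp(grp) > 0:
            ps.append(float(stats.shapiro(grp).pvalue))
    return min(ps) if ps else float("nan")


def test_suite(
    dataset: pd.DataFrame,
    design: Sequence[dict],
    *,
    gate_alpha: float = 0.05,
) -> list[TestReport]:
    """Run a declared family of gated, FDR-corrected tests.

    Each design entry is a dict with keys:

    ``name``; ``kind`` ("one_sample" | "two_sample"); ``value_col``;
    optional ``group_col`` and ``groups`` (pair) for two-sample tests;
    ``null_value`` (default 0); ``transform`` ("none" | "signed_sqrt");
    ``family`` (FDR family label, default "default"); ``equal_var``
    (pooled-variance t, default True).

    Normality is gated with Shapiro-Wilk and two-sample variance
    homogeneity with Levene; when the normality gate fails the
    rank-based fallback (Wilcoxon signed-rank / Mann-Whitney U) is used,
    and when only the variance gate fails Welch's t is used.
    Benjamini-Hochberg correction is applied within each family.
    """
    reports: list[TestReport] = []
    for spec_entry in design:
        unknown = set(spec_entry) - {
            "name", "kind", "value_col", "group_col", "groups",
            "null_value", "transform", "family", "equal_var",
        }
        if unknown:
            raise ValueError(f"unknown design keys: {sorted(unknown)}")
        name = spec_entry["name"]
        kind = spec_entry["kind"]
        value_col = spec_entry["value_col"]
        null_value = float(spec_entry.get("null_value", 0.0))
        transform = spec_entry.get("transform", "none")
        family = spec_entry.get("family", "default")
        equal_var = bool(spec_entry.get("equal_var", True))
        if kind not in ("one_sample", "two_sample"):
            raise ValueError(f"unknown test kind {kind!r}")

        def xf(a: np.ndarray) -> np.ndarray:
            if transform == "signed_sqrt":
                return signed_sqrt(a)
            if transform in ("none", None):
                return a
            raise ValueError(f"unknown transform {transform!r}")

        if kind == "one_sample":
            x = dataset[value_col].dropna().to_numpy(dtype=float)
            vals = xf(x - null_value)
            shapiro_p = _gate_shapiro([vals])
            levene_p = float("nan")
            normal = not (shapiro_p == shapiro_p and shapiro_p < gate_alpha)
            if np.ptp(vals) == 0:
                test_used, stat, dfree, p = (
                    "one_sample_t", 0.0 if vals[0] == 0 else math.inf,
                    float(x.size - 1), 1.0 if vals[0] == 0 else 0.0,
                )
            elif normal:
                res = stats.ttest_1samp(vals, 0.0)
                test_used = "one_sample_t"
                stat, dfree, p = (
                    float(res.statistic), float(x.size - 1),
                    float(res.pvalue),
                )
            else:
                res = stats.wilcoxon(vals)
                test_used = "wilcoxon_signed_rank"
                stat, dfree, p = (
                    float(res.statistic), float("nan"), float(res.pvalue)
                )
            effect = float(np.mean(x) - null_value)
            n = int(x.size)
        else:
            group_col = spec_entry["group_col"]
            if "groups" in spec_entry:
                g1_label, g2_label = spec_entry["groups"]
            else:
                labels = list(pd.unique(dataset[group_col]))
                if len(labels) != 2:
                    raise ValueError(
                        "two_sample design needs exactly two groups"
                    )
                g1_label, g2_label = labels
            g1 = dataset.loc[
                dataset[group_col] == g1_label, value_col
            ].dropna().to_numpy(dtype=float)
            g2 = dataset.loc[
                dataset[group_col] == g2_label, value_col
            ].dropna().to_numpy(dtype=float)
            v1, v2 = xf(g1), xf(g2)
            shapiro_p = _gate_shapiro([v1, v2])
            levene_p = (
                float(stats.levene(v1, v2).pvalue)
                if min(v1.size, v2.size) >= 2
                and (np.ptp(v1) > 0 or np.ptp(v2) > 0)
                else float("nan")
            )
            normal = not (shapiro_p == shapiro_p and shapiro_p < gate_alpha)
            homoscedastic = not (
                levene_p == levene_p and levene_p < gate_alpha
            )
            if np.ptp(np.concatenate([v1, v2])) == 0:
                test_used, stat, dfree, p = (
                    "two_sample_t", 0.0, float(v1.size + v2.size - 2), 1.0
                )
            elif normal:
                pooled = equal_var and homoscedastic
                res = stats.ttest_ind(v1, v2, equal_var=pooled)
                test_used = "two_sample_t" if pooled else "welch_t"
                dfree = (
                    float(v1.size + v2.size - 2)
                    if pooled
                    else float(res.df)
                )
                stat, p = float(res.statistic), float(res.pvalue)
            else:
                res = stats.mannwhitneyu(v1, v2, alternative="two-sided")
                test_used = "mann_whitney_u"
                stat, dfree, p = (
                    float(res.statistic), float("nan"), float(res.pvalue)
                )
            effect = float(np.mean(g1) - np.mean(g2))
            n = int(g1.size + g2.size)
        reports.append(
            TestReport(
                name, family, test_used, stat, dfree, p, p,
                transform or "none", shapiro_p, levene_p, effect, n,
            )
        )
    # FDR correction within each declared family
    by_family: dict[str, list[int]] = {}
    for idx, rep in enumerate(reports):
        by_family.setdefault(rep.family, []).append(idx)
    for indices in by_family.values():
        raw = [reports[i].p_raw for i in indices]
        if any(not np.isfinite(p) for p in raw):
            continue
        adj = fdr_adjust(raw)
        for i, a in zip(indices, adj):
            reports[i].p_adj = float(a)
    return reports


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_table(
    path: str | Path,
    *,
    sheet: str | int | None = 0,
    column_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read a delimited table or a spreadsheet into a tidy DataFrame.

    ``column_map`` renames raw column headers to the canonical roles
    (useful for spreadsheet exports whose layout is not standardized).
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls", ".xlsm"):
        df = pd.read_excel(path, sheet_name=sheet)
    elif path.suffix.lower() == ".tsv":
        df = pd.read_csv(path, sep="\t")
    else:
        df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    return df
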