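"""Reference normalization, Nile-red RFU, and the screening statistics battery.

Normalization follows screening convention: fitness on an SCFA medium is
expressed as a percentage of the same strain's fitness on glucose (relative
fitness), and candidate-vs-reference comparisons use fold change
(value / reference - 1). Lipid signal is quantified as RFU =
(stained - background fluorescence) / OD595.

The statistical battery mirrors nonparametric screening practice: a
Shapiro-Wilk / Levene gate at alpha = 0.05 decides the nonparametric path,
candidate strains are compared to the reference with a two-sided
Mann-Whitney U test (exact when group sizes permit and there are no ties),
p-values are Benjamini-Hochberg adjusted within each (variable, medium)
family, and lipid content across groups is assessed with one-way ANOVA and
Kruskal-Wallis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.preprocessing import MaxAbsScaler
from statsmodels.stats.multitest import multipletests

__all__ = [
    "relative_fitness",
    "fold_change",
    "compute_rfu",
    "rfu_table",
    "max_abs_scale",
    "GateReport",
    "normality_variance_gate",
    "mann_whitney_u",
    "bh_adjust",
    "lipid_content_tests",
    "compare_to_reference",
]

#: Largest n1*n2 for which the exact Mann-Whitney null is enumerated.
EXACT_MW_LIMIT = 400


def relative_fitness(fitness_scfa: float, fitness_glucose: float) -> float:
    """Fitness on an SCFA medium as % of the same strain's glucose fitness.

    Returns NaN (an explicit missing result, not an error) when the glucose
    fitness is missing or non-positive.
    """
    if not np.isfinite(fitness_glucose) or fitness_glucose <= 0:
        return np.nan
    return 100.0 * fitness_scfa / fitness_glucose


def fold_change(value: float, reference_value: float) -> float:
    """value / reference - 1; NaN when the reference is missing or <= 0."""
    if not np.isfinite(reference_value) or reference_value <= 0:
        return np.nan
    return value / reference_value - 1.0


def compute_rfu(f_stained: float, f_background: float, od595: float) -> float:
    """Background-subtracted fluorescence per unit OD595, clamped at zero."""
    od595 = np.asarray(od595, dtype=float)
    if np.any(od595 <= 0):
        raise ValueError(f"od595 must be > 0, got {od595}")
    diff = np.maximum(np.asarray(f_stained, float) - np.asarray(f_background, float), 0.0)
    out = diff / od595
    return float(out) if out.ndim == 0 else out


def rfu_table(assay: pd.DataFrame) -> pd.DataFrame:
    """Add an ``rfu`` column to a lipid-assay table.

    Expects columns f_stained, f_background, od595.
    """
    out = assay.copy()
    out["rfu"] = compute_rfu(
        out["f_stained"].to_numpy(),
        out["f_background"].to_numpy(),
        out["od595"].to_numpy(),
    )
    return out


def max_abs_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Scale each column by its maximum absolute value (outputs in [-1, 1]).

    All-zero columns are left as zeros with a warning. NaNs pass through.
    """
    if matrix.empty:
        raise ValueError("cannot scale an empty matrix")
    zero_cols = [c for c in matrix.columns if not (matrix[c].abs().max() > 0)]
    if zero_cols:
        warnings.warn(f"all-zero variables left unscaled: {zero_cols}", stacklevel=2)
    scaled = MaxAbsScaler().fit_transform(matrix.to_numpy(dtype=float))
    return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns)


@dataclass(frozen=True)
class GateReport:
    """Outcome of the normality/variance-homogeneity gate."""

    shapiro_p: dict[str, float | None]
    levene_p: float | None
    nonparametric: bool
    skipped: dict[str, str]


def normality_variance_gate(
    groups: dict[str, np.ndarray], alpha: float = 0.05
) -> GateReport:
    """Shapiro-Wilk per group plus Levene across groups at ``alpha``.

    Flags the nonparametric path if any performed test rejects. Groups that
    are too small (< 3) or constant are skipped with the reason recorded
    rather than fabricating a p-value.
    """
    shapiro_p: dict[str, float | None] = {}
    skipped: dict[str, str] = {}
    for name, values in groups.items():
        values = np.asarray(values, dtype=float)
        if values.size < 3:
            shapiro_p[name] = None
            skipped[name] = f"n={values.size} < 3, Shapiro-Wilk skipped"
        elif np.ptp(values) == 0:
            shapiro_p[name] = None
            skipped[name] = "constant sample, Shapiro-Wilk undefined"
        else:
            shapiro_p[name] = float(sps.shapiro(values).pvalue)
    usable = [
        np.asarray(v, float) for v in groups.values() if np.asarray(v).size >= 2
    ]
    levene_p = float(sps.levene(*usable).pvalue) if len(usable) >= 2 else None
    performed = [p for p in shapiro_p.values() if p is not None]
    if levene_p is not None:
        performed.append(levene_p)
    return GateReport(
        shapiro_p=shapiro_p,
        levene_p=levene_p,
        nonparametric=any(p < alpha for p in performed),
        skipped=skipped,
    )


def mann_whitney_u(
    group_a: np.ndarray, group_b: np.ndarray
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; returns (U for group_a, p).

    The exact permutation null is used when n1*n2 <= 400 and the pooled
    sample has no ties; otherwise the normal approximation with tie and
    continuity corrections.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size * b.size <= EXACT_MW_LIMIT and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in the input order."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1-D array")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def lipid_content_tests(
    groups: list[np.ndarray],
) -> dict[str, float]:
    """One-way ANOVA (F) and Kruskal-Wallis (H) across lipid-content groups.

    Degenerate all-equal data yields F = 0, H = 0 with p = 1 instead of an
    exception. Returns keys anova_f, anova_p, kruskal_h, kruskal_p.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return {"anova_f": 0.0, "anova_p": 1.0, "kruskal_h": 0.0, "kruskal_p": 1.0}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p_f = sps.f_oneway(*arrays)
        h, p_h = sps.kruskal(*arrays)
    if not np.isfinite(f):
        f, p_f = 0.0, 1.0
    return {
        "anova_f": float(f),
        "anova_p": float(p_f),
        "kruskal_h": float(h),
        "kruskal_p": float(p_h),
    }


def compare_to_reference(
    values: pd.DataFrame,
    reference_strain: str,
    family: tuple[str, ...] = ("variable", "medium_id"),
) -> pd.DataFrame:
    """Candidate-vs-reference comparison table (fold change, U, p, BH p).

    ``values`` is long-format replicate data with columns strain_id,
    medium_id, variable, value. For every candidate strain x variable x
    medium, the fold change of medians vs the reference and a two-sided
    Mann-Whitney U test on the replicate values are computed; BH adjustment
    is applied within each ``family`` (by default one family per
    (variable, medium) across all candidate strains, recorded in the output).
    """
    required = {"strain_id", "medium_id", "variable", "value"}
    if not required.issubset(values.columns):
        raise ValueError(f"values must have columns {sorted(required)}")
    if reference_strain not in set(values["strain_id"]):
        raise ValueError(f"reference strain {reference_strain!r} not in table")
    rows = []
    for (variable, medium), group in values.groupby(["variable", "medium_id"]):
        ref = group.loc[
            group["strain_id"] == reference_strain, "value"
        ].dropna().to_numpy()
        for strain, sub in group.groupby("strain_id"):
            if strain == reference_strain:
                continue
            cand = sub["value"].dropna().to_numpy()
            if cand.size == 0 or ref.size == 0:
                u = p = np.nan
                fc = np.nan
            else:
                u, p = mann_whitney_u(cand, ref)
                fc = fold_change(float(np.median(cand)), float(np.median(ref)))
            rows.append(
                {
                    "strain_id": strain,
                    "variable": variable,
                    "medium_id": medium,
                    "fold_change": fc,
                    "u_stat": u,
                    "p_value": p,
                    "n_candidate": int(cand.size),
                    "n_reference": int(ref.size),
                }
            )
    table = pd.DataFrame(rows)
    if table.empty:
        return table.assign(p_adj_bh=[], bh_family=[])
    table["bh_family"] = table[list(family)].astype(str).agg("|".join, axis=1)
    table["p_adj_bh"] = np.nan
    for _, idx in table.groupby("bh_family").groups.items():
        p = table.loc[idx, "p_value"]
        mask = p.notna()
        if mask.any():
            table.loc[p.index[mask], "p_adj_bh"] = bh_adjust(p[mask].to_numpy())
    return table
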