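"""Colony growth phenotyping: fitness, lag and t_max from size time courses.

Three variables summarise each colony, following standard colony-fitness
screening practice:

* **fitness** — the smoothed endpoint colony size (arbitrary pixel-intensity
  units);
* **t_max** — the time at which the growth slope (size vs time) is maximal,
  estimated from sliding-window least-squares slopes on the smoothed signal;
* **lag** — the first time the smoothed signal exceeds a small fraction of
  its dynamic range above the baseline.

A growth call combines a relative threshold over the baseline size with an
optional absolute floor. Replicates are aggregated by medians, and
per-medium growth calls are summarised into UpSet-style intersection counts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "GrowthConfig",
    "GrowthParameters",
    "fit_growth_curve",
    "call_growth",
    "sliding_slopes",
    "growth_intersections",
    "as_percent",
    "summarize_replicates",
    "phenotype_screen",
    "summarize_screen",
]


@dataclass(frozen=True)
class GrowthConfig:
    """Tunables of the curve analysis.

    smooth_window   centered rolling-median width in points (odd); damps
                    scanner noise before any derived quantity.
    slope_window_h  span (hours) of the sliding least-squares slope window.
    refine_h        half-width (hours) of the quadratic-vertex refinement of
                    the slope-profile peak; None reports the raw center of
                    the earliest maximizing window.
    lag_fraction    f in the lag threshold s0 + f * (s_max - s0).
    threshold_rel   growth call requires fitness >= threshold_rel * s0.
    threshold_abs   and fitness >= threshold_abs (a.u.; 0 disables).
    """

    smooth_window: int = 9
    slope_window_h: float = 4.0
    refine_h: float | None = 8.0
    lag_fraction: float = 0.05
    threshold_rel: float = 1.5
    threshold_abs: float = 0.0

    def __post_init__(self) -> None:
        if self.smooth_window < 1:
            raise ValueError("smooth_window must be >= 1")
        if self.slope_window_h <= 0:
            raise ValueError("slope_window_h must be > 0")
        if not (0 < self.lag_fraction < 1):
            raise ValueError("lag_fraction must be in (0, 1)")


@dataclass(frozen=True)
class GrowthParameters:
    """Per-colony growth summary.

    ``lag`` and ``t_max`` are NaN for colonies called as non-growers: they
    are undefined for a flat signal and are never fabricated.
    """

    fitness: float
    lag: float
    t_max: float
    max_slope: float
    s0: float
    growth_call: bool


def _smooth(sizes: np.ndarray, window: int) -> np.ndarray:
    return (
        pd.Series(sizes)
        .rolling(window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )


def sliding_slopes(
    times: np.ndarray, values: np.ndarray, window_pts: int
) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares slope of every contiguous window of ``window_pts`` points.

    Returns ``(window_center_times, slopes)``.
    """
    if window_pts < 2:
        raise ValueError("window_pts must be >= 2")
    if len(times) < window_pts:
        raise ValueError(
            f"need at least {window_pts} points for a {window_pts}-point window, "
            f"got {len(times)}"
        )
    X = sliding_window_view(np.asarray(times, dtype=float), window_pts)
    Y = sliding_window_view(np.asarray(values, dtype=float), window_pts)
    xm = X.mean(axis=1, keepdims=True)
    ym = Y.mean(axis=1, keepdims=True)
    denom = ((X - xm) ** 2).sum(axis=1)
    slopes = ((X - xm) * (Y - ym)).sum(axis=1) / denom
    return X.mean(axis=1), slopes


def call_growth(
    fitness: float, s0: float, threshold_rel: float = 1.5, threshold_abs: float = 0.0
) -> bool:
    """Deterministic growth call: endpoint must clear both thresholds."""
    return bool(fitness >= threshold_rel * s0 and fitness >= threshold_abs)


def fit_growth_curve(
    times: np.ndarray, sizes: np.ndarray, config: GrowthConfig | None = None
) -> GrowthParameters:
    """Extract fitness, lag, t_max and max slope from one colony time course.

    The signal is median-smoothed, the baseline s0 taken as the median of the
    first three smoothed points, and the slope profile computed over sliding
    least-squares windows spanning ``config.slope_window_h`` hours. t_max is
    the earliest maximizing window center, optionally refined by fitting a
    quadratic to the slope profile within ``refine_h`` hours of the peak and
    taking its vertex (clipped to the refinement span) — this suppresses
    noise-driven wander of the argmax across the broad slope maximum.
    """
    config = config or GrowthConfig()
    times = np.asarray(times, dtype=float)
    sizes = np.asarray(sizes, dtype=float)
    if times.ndim != 1 or times.shape != sizes.shape:
        raise ValueError("times and sizes must be 1-D arrays of equal length")
    if len(times) < 3:
        raise ValueError(f"need >= 3 time points, got {len(times)}")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")

    smoothed = _smooth(sizes, config.smooth_window)
    dt = float(np.median(np.diff(times)))
    window_pts = max(3, int(round(config.slope_window_h / dt)) + 1)
    if len(times) < window_pts:
        raise ValueError(
            f"series of {len(times)} points is shorter than the "
            f"{window_pts}-point slope window ({config.slope_window_h} h)"
        )

    s0 = float(np.median(smoothed[:3]))
    fitness = float(smoothed[-1])
    centers, slopes = sliding_slopes(times, smoothed, window_pts)
    i_best = int(np.argmax(slopes))  # earliest maximizing window wins
    max_slope = float(slopes[i_best])
    t_max = float(centers[i_best])
    if config.refine_h is not None:
        near = np.abs(centers - centers[i_best]) <= config.refine_h
        if near.sum() >= 5:
            coef = np.polyfit(centers[near] - centers[i_best], slopes[near], 2)
            if coef[0] < 0:
                vertex = float(-coef[1] / (2 * coef[0]) + centers[i_best])
                t_max = float(
                    np.clip(vertex, centers[near].min(), centers[near].max())
                )

    grows = call_growth(fitness, s0, config.threshold_rel, config.threshold_abs)
    if not grows:
        return GrowthParameters(
            fitness=fitness,
            lag=np.nan,
            t_max=np.nan,
            max_slope=max_slope,
            s0=s0,
            growth_call=False,
        )

    s_max = float(np.max(smoothed))
    threshold = s0 + config.lag_fraction * (s_max - s0)
    above = np.nonzero(smoothed > threshold)[0]
    lag = float(times[above[0]]) if above.size else np.nan
    return GrowthParameters(
        fitness=fitness,
        lag=lag,
        t_max=t_max,
        max_slope=max_slope,
        s0=s0,
        growth_call=True,
    )


def as_percent(count: int, total: int, decimals: int = 2) -> float:
    """Share of the panel as a percentage, rounded for table-style reporting."""
    if total <= 0:
        raise ValueError("total must be > 0")
    return round(100.0 * count / total, decimals)


def growth_intersections(
    calls: pd.DataFrame, decimals: int = 2
) -> dict[str, dict[str, float | int]]:
    """UpSet-style intersection counts over a strains x media boolean table.

    ``calls`` must be a complete boolean DataFrame (index: strain id,
    columns: media). Returns a dict keyed by region name — ``any``, ``all``,
    and one exclusive key per non-empty media combination (media names joined
    by ``&``) — each holding ``{"count": int, "percent": float}`` with the
    percentage of the full panel.
    """
    if calls.isna().any().any():
        missing = [
            f"{calls.index[i]}x{calls.columns[j]}"
            for i, j in zip(*np.nonzero(calls.isna().to_numpy()))
        ]
        raise ValueError(f"missing strain x medium growth calls: {missing}")
    table = calls.astype(bool)
    total = len(table)
    media = list(table.columns)
    out: dict[str, dict[str, float | int]] = {}

    def region(count: int) -> dict[str, float | int]:
        return {"count": int(count), "percent": as_percent(count, total, decimals)}

    out["any"] = region(table.any(axis=1).sum())
    out["all"] = region(table.all(axis=1).sum())
    for k in range(1, len(media) + 1):
        for combo in itertools.combinations(media, k):
            in_combo = table[list(combo)].all(axis=1)
            outside = [m for m in media if m not in combo]
            exclusive = in_combo & ~table[outside].any(axis=1) if outside else in_combo
            out["&".join(combo)] = region(exclusive.sum())
    return out


def summarize_replicates(replicates: list[GrowthParameters]) -> dict[str, float | int]:
    """Median fitness/lag/t_max across replicates.

    Fitness is summarised over all replicates; lag and t_max only over
    replicates called as growers (they are undefined otherwise). An even
    number of values yields the mean of the two central ones (numpy median).
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    growers = [p for p in replicates if p.growth_call]
    return {
        "fitness": float(np.median([p.fitness for p in replicates])),
        "lag": float(np.median([p.lag for p in growers])) if growers else np.nan,
        "t_max": float(np.median([p.t_max for p in growers])) if growers else np.nan,
        "n_replicates": len(replicates),
        "n_growing": len(growers),
    }


def phenotype_screen(
    layout: pd.DataFrame,
    timecourses: pd.DataFrame,
    config: GrowthConfig | None = None,
) -> pd.DataFrame:
    """Fit every colony in a screen; returns one row per well.

    ``layout`` columns: plate_id, row, col, strain_id, replicate, medium_id.
    ``timecourses`` columns: plate_id, row, col, time_h, size.
    Output adds fitness, lag, t_max, max_slope, s0, growth_call per well.
    """
    config = config or GrowthConfig()
    key = ["plate_id", "row", "col"]
    indexed = layout.set_index(key)
    rows = []
    for well, group in timecourses.groupby(key, sort=False):
        group = group.sort_values("time_h")
        params = fit_growth_curve(
            group["time_h"].to_numpy(), group["size"].to_numpy(), config
        )
        meta = indexed.loc[well]
        rows.append(
            {
                "plate_id": well[0],
                "row": well[1],
                "col": well[2],
                "strain_id": meta["strain_id"],
                "replicate": meta["replicate"],
                "medium_id": meta["medium_id"],
                "fitness": params.fitness,
                "lag": params.lag,
                "t_max": params.t_max,
                "max_slope": params.max_slope,
                "s0": params.s0,
                "growth_call": params.growth_call,
            }
        )
    return pd.DataFrame(rows)


def summarize_screen(colony_params: pd.DataFrame) -> pd.DataFrame:
    """Per strain x medium medians from the per-colony parameter table."""
    rows = []
    for (strain, medium), group in colony_params.groupby(
        ["strain_id", "medium_id"], sort=False
    ):
        growers = group[group["growth_call"]]
        rows.append(
            {
                "strain_id": strain,
                "medium_id": medium,
                "fitness": float(group["fitness"].median()),
                "lag": float(growers["lag"].median()) if len(growers) else np.nan,
                "t_max": float(growers["t_max"].median()) if len(growers) else np.nan,
                "n_replicates": int(len(group)),
                "n_growing": int(len(growers)),
                "growth_call": bool(len(growers) > len(group) / 2),
            }
        )
    return pd.DataFrame(rows)
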