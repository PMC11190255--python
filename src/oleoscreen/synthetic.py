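"""Synthetic screening, lipid-assay and fermentation data with known ground truth.

The generators emulate the structure of a high-throughput yeast screen on
short-chain fatty acid (SCFA) media: arrayed agar plates scanned as
colony-size time courses, a Nile-red plate assay for neutral lipids, and
shake-flask fermentation time courses with sequential SCFA consumption
(acetic before propionic before butyric under default preferences).

Every generator is driven by an explicit integer seed and returns plain
pandas DataFrames with documented, stable column names, so the downstream
phenotyping/statistics/ranking stages can be tested against planted truth
without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LogisticParams",
    "SyntheticTruth",
    "ScreenDesign",
    "logistic_size",
    "generate_screen",
    "generate_lipid_assay",
    "generate_fermentation",
    "make_demo_truths",
    "truth_table",
    "fermentation_truth_table",
]

ACIDS = ("acetic", "propionic", "butyric")

#: Plate density -> (n_rows, n_cols), standard microplate geometries.
PLATE_SHAPES = {96: (8, 12), 384: (16, 24), 1536: (32, 48)}


def row_label(i: int) -> str:
    """0-based row index -> spreadsheet-style letters (A..Z, AA..AF for 1536)."""
    label = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        label = chr(ord("A") + rem) + label
    return label


@dataclass(frozen=True)
class LogisticParams:
    """Offset-logistic colony growth: s(t) = s0 + (K - s0)/(1 + exp(-r (t - t_mid))).

    K is the carrying capacity (a.u.), s0 the initial colony size (a.u.),
    r the rate (1/h) and t_mid the inflection time (h) at which the growth
    slope is maximal.
    """

    K: float
    s0: float
    r: float
    t_mid: float

    def __post_init__(self) -> None:
        if not (self.K > self.s0 >= 0):
            raise ValueError(f"require K > s0 >= 0, got K={self.K}, s0={self.s0}")
        if self.r <= 0:
            raise ValueError(f"require r > 0, got r={self.r}")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth for one strain.

    ``media`` maps medium id -> LogisticParams (or None for a non-viable
    strain x medium combination, which yields a flat signal at ``flat_s0``).
    ``lipid_content`` is the true neutral-lipid fraction of cell dry weight.
    ``uptake_rates`` are per-acid consumption rates in g/(L*h), applied
    sequentially following ``preference``; ``biomass_yield`` is g CDW per g
    SCFA consumed.
    """

    strain_id: str
    media: dict[str, LogisticParams | None]
    lipid_content: float
    uptake_rates: dict[str, float] = field(
        default_factory=lambda: {"acetic": 0.12, "propionic": 0.05, "butyric": 0.03}
    )
    preference: tuple[str, ...] = ACIDS
    biomass_yield: float = 0.4
    flat_s0: float = 100.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.lipid_content < 1.0):
            raise ValueError(
                f"lipid_content must be in [0, 1), got {self.lipid_content}"
            )
        for acid, rate in self.uptake_rates.items():
            if rate < 0:
                raise ValueError(f"uptake rate for {acid} must be >= 0, got {rate}")
        if sorted(self.preference) != sorted(set(self.preference)):
            raise ValueError("preference must not repeat acids")

    def params_for(self, medium_id: str) -> LogisticParams | None:
        if medium_id not in self.media:
            raise KeyError(
                f"strain {self.strain_id!r} has no growth parameters for "
                f"medium {medium_id!r}"
            )
        return self.media[medium_id]


@dataclass(frozen=True)
class ScreenDesign:
    """Layout and acquisition settings of a synthetic colony screen.

    Defaults mirror the study conditions: time-lapse scanning every 15 min
    (0.25 h) for 4 days (96 h), at least three biological replicates, a
    glucose control plus three SCFA compositions, and a reference strain
    present on every plate.
    """

    media: tuple[str, ...] = ("glucose", "A2P1B2", "A3P1B1", "A1P1B3")
    plate_density: int = 96
    n_replicates: int = 3
    sampling_interval_h: float = 0.25
    duration_h: float = 96.0
    noise_cv: float = 0.05
    noise_floor: float = 1.0
    seed: int = 0
    reference_strain: str = "REF"

    def __post_init__(self) -> None:
        if self.plate_density not in PLATE_SHAPES:
            raise ValueError(
                f"plate_density must be one of {sorted(PLATE_SHAPES)}, "
                f"got {self.plate_density}"
            )
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.sampling_interval_h <= 0:
            raise ValueError("sampling_interval_h must be > 0")
        if self.duration_h <= self.sampling_interval_h:
            raise ValueError("duration_h must exceed sampling_interval_h")
        if self.noise_cv < 0 or self.noise_floor < 0:
            raise ValueError("noise parameters must be >= 0")

    @property
    def times(self) -> np.ndarray:
        return np.arange(
            0.0, self.duration_h + self.sampling_interval_h / 2, self.sampling_interval_h
        )


def logistic_size(t: np.ndarray, p: LogisticParams) -> np.ndarray:
    """Closed-form offset logistic; inflection (maximal slope) at t = t_mid."""
    t = np.asarray(t, dtype=float)
    return p.s0 + (p.K - p.s0) / (1.0 + np.exp(-p.r * (t - p.t_mid)))


def _apply_noise(
    clean: np.ndarray, cv: float, floor: float, rng: np.random.Generator
) -> np.ndarray:
    sizes = clean.copy()
    if cv > 0:
        sizes = sizes * (1.0 + cv * rng.standard_normal(sizes.shape))
    if floor > 0:
        sizes = sizes + floor * rng.standard_normal(sizes.shape)
    return np.clip(sizes, 0.0, None)


def generate_screen(
    design: ScreenDesign, truths: list[SyntheticTruth]
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a colony screen: one plate per medium x replicate.

    Returns ``(layout, timecourses, truth)``:

    * layout — plate_id, row, col, strain_id, replicate, medium_id
    * timecourses — plate_id, row, col, time_h, size
    * truth — strain_id, medium_id, viable, K, s0, r, t_mid, lipid_content

    Viable strain x medium wells follow the offset logistic; non-viable wells
    stay flat at the strain's baseline size. Noise is multiplicative Gaussian
    (CV ``design.noise_cv``) plus an additive floor, truncated at zero.
    Identical (seed, design, truths) yield identical output; per-plate RNG
    streams are derived from (seed, plate index) so plates are independent.
    """
    ids = [t.strain_id for t in truths]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate strain ids in truths")
    if design.reference_strain not in ids:
        raise ValueError(
            f"reference strain {design.reference_strain!r} must be present "
            "in the truth panel (it is pinned to every plate)"
        )
    n_rows, n_cols = PLATE_SHAPES[design.plate_density]
    if len(truths) > n_rows * n_cols:
        raise ValueError(
            f"{len(truths)} strains do not fit a {design.plate_density}-density plate"
        )
    for truth in truths:
        for medium in design.media:
            truth.params_for(medium)  # raises naming strain and medium

    times = design.times
    nt = times.size
    layout_rows = []
    tc_parts = []
    plate_idx = 0
    for medium in design.media:
        for rep in range(1, design.n_replicates + 1):
            plate_id = f"{medium}-r{rep}"
            rng = np.random.default_rng([design.seed, plate_idx])
            plate_idx += 1
            for k, truth in enumerate(truths):
                row, col = divmod(k, n_cols)
                layout_rows.append(
                    (plate_id, row_label(row), col + 1, truth.strain_id, rep, medium)
                )
                p = truth.media[medium]
                clean = (
                    logistic_size(times, p)
                    if p is not None
                    else np.full(nt, truth.flat_s0)
                )
                sizes = _apply_noise(clean, design.noise_cv, design.noise_floor, rng)
                tc_parts.append(
                    pd.DataFrame(
                        {
                            "plate_id": plate_id,
                            "row": row_label(row),
                            "col": col + 1,
                            "time_h": times,
                            "size": sizes,
                        }
                    )
                )
    layout = pd.DataFrame(
        layout_rows,
        columns=["plate_id", "row", "col", "strain_id", "replicate", "medium_id"],
    )
    timecourses = pd.concat(tc_parts, ignore_index=True)
    return layout, timecourses, truth_table(truths, design.media)


def truth_table(
    truths: list[SyntheticTruth], media: tuple[str, ...]
) -> pd.DataFrame:
    """Flat per strain x medium truth table (delimited-text friendly)."""
    rows = []
    for truth in truths:
        for medium in media:
            p = truth.params_for(medium)
            rows.append(
                {
                    "strain_id": truth.strain_id,
                    "medium_id": medium,
                    "viable": p is not None,
                    "K": p.K if p else np.nan,
                    "s0": p.s0 if p else truth.flat_s0,
                    "r": p.r if p else np.nan,
                    "t_mid": p.t_mid if p else np.nan,
                    "lipid_content": truth.lipid_content,
                }
            )
    return pd.DataFrame(rows)


def fermentation_truth_table(truths: list[SyntheticTruth]) -> pd.DataFrame:
    rows = []
    for t in truths:
        rows.append(
            {
                "strain_id": t.strain_id,
                "lipid_content": t.lipid_content,
                "biomass_yield": t.biomass_yield,
                **{f"uptake_{a}": t.uptake_rates.get(a, 0.0) for a in ACIDS},
            }
        )
    return pd.DataFrame(rows)


def generate_lipid_assay(
    truths: list[SyntheticTruth],
    seed: int,
    n_replicates: int = 3,
    gain: float = 1e4,
    background: float = 50.0,
    od595: float = 0.6,
    od_cv: float = 0.05,
    noise_cv: float = 0.05,
) -> pd.DataFrame:
    """Nile-red style plate readings: background, stained fluorescence, OD595.

    stained = background + gain * lipid_content * od595 * (1 + noise).
    Because RFU = (stained - background)/od595, the recovered RFU is exactly
    gain * lipid_content * (1 + noise): linear in the planted lipid fraction.

    Columns: strain_id, replicate, f_background, f_stained, od595.
    """
    rng = np.random.default_rng([seed, 7])
    rows = []
    for truth in truths:
        for rep in range(1, n_replicates + 1):
            od = od595 * (1.0 + od_cv * rng.standard_normal()) if od_cv > 0 else od595
            od = max(od, 0.05)
            noise = noise_cv * rng.standard_normal() if noise_cv > 0 else 0.0
            stained = background + gain * truth.lipid_content * od * (1.0 + noise)
            rows.append(
                {
                    "strain_id": truth.strain_id,
                    "replicate": rep,
                    "f_background": background,
                    "f_stained": max(stained, 0.0),
                    "od595": od,
                }
            )
    return pd.DataFrame(rows)


def generate_fermentation(
    truth: SyntheticTruth,
    initial_g_per_l: dict[str, float],
    duration_h: float,
    seed: int = 0,
    dt_h: float = 0.5,
    od0: float = 1.0,
    suppression: float = 0.15,
    od_per_g_cdw: float = 1.0 / 0.45,
    noise_cv: float = 0.0,
) -> pd.DataFrame:
    """Sequential piecewise-linear SCFA consumption with growth coupling.

    Each acid is consumed at its uptake rate, scaled by ``suppression`` for
    every higher-preference acid still present — under default parameters
    acetic is depleted first, then propionic, then butyric, matching the
    acetic-first preference and the butyric > propionic > acetic toxicity
    ordering seen in yeast SCFA fermentations. OD600 rises in proportion to
    cumulative substrate consumed times the biomass yield (OD 1 ~ 0.45 g
    CDW/L). Concentrations never go below zero and decline monotonically
    (with the default noise_cv = 0).

    Columns: time_h, acetic_gL, propionic_gL, butyric_gL, od600.
    """
    if duration_h < 0:
        raise ValueError(f"duration_h must be >= 0, got {duration_h}")
    if dt_h <= 0:
        raise ValueError("dt_h must be > 0")
    rng = np.random.default_rng([seed, 11])
    conc = {a: float(initial_g_per_l.get(a, 0.0)) for a in ACIDS}
    for a, c0 in conc.items():
        if c0 < 0:
            raise ValueError(f"initial {a} concentration must be >= 0")
    pref = [a for a in truth.preference if a in ACIDS]
    times = np.arange(0.0, duration_h + dt_h / 2, dt_h)
    records = []
    od = od0
    eps = 1e-9
    for i, t in enumerate(times):
        records.append(
            {"time_h": t, **{f"{a}_gL": conc[a] for a in ACIDS}, "od600": od}
        )
        if i == len(times) - 1:
            break
        consumed_step = 0.0
        n_blockers = 0
        for a in pref:
            rate = truth.uptake_rates.get(a, 0.0) * (suppression**n_blockers)
            if conc[a] > eps:
                n_blockers += 1
            take = min(conc[a], rate * dt_h)
            conc[a] -= take
            consumed_step += take
        od += truth.biomass_yield * consumed_step * od_per_g_cdw
    df = pd.DataFrame.from_records(records)
    if noise_cv > 0:
        for col in ("acetic_gL", "propionic_gL", "butyric_gL", "od600"):
            df[col] = np.clip(
                df[col] * (1.0 + noise_cv * rng.standard_normal(len(df))), 0.0, None
            )
    return df


def make_demo_truths(
    n_strains: int = 24,
    seed: int = 0,
    media: tuple[str, ...] = ("glucose", "A2P1B2", "A3P1B1", "A1P1B3"),
    frac_viable: float = 0.4,
    reference_strain: str = "REF",
    dominant_strain: str | None = None,
) -> list[SyntheticTruth]:
    """Random but reproducible truth panel for demos and tests.

    All strains grow on glucose; on each SCFA medium a strain is viable with
    probability ``frac_viable``. The reference strain is always viable
    everywhere. If ``dominant_strain`` is given, that strain is planted to
    weakly dominate the panel: highest carrying capacity and lipid content,
    earliest inflection, on every medium.
    """
    rng = np.random.default_rng([seed, 3])
    names = [reference_strain] + [f"S{i:03d}" for i in range(1, n_strains)]
    if dominant_strain is not None and dominant_strain not in names:
        names[-1] = dominant_strain
    truths = []
    for name in names:
        params: dict[str, LogisticParams | None] = {}
        for medium in media:
            always = medium == "glucose" or name == reference_strain
            if dominant_strain is not None and name == dominant_strain:
                params[medium] = LogisticParams(K=2600.0, s0=100.0, r=0.25, t_mid=25.0)
                continue
            if always or rng.random() < frac_viable:
                params[medium] = LogisticParams(
                    K=rng.uniform(1200.0, 2500.0),
                    s0=rng.uniform(80.0, 120.0),
                    r=rng.uniform(0.12, 0.30),
                    t_mid=rng.uniform(25.0, 55.0),
                )
            else:
                params[medium] = None
        lipid = rng.uniform(0.05, 0.35)
        if dominant_strain is not None and name == dominant_strain:
            lipid = 0.45
        truths.append(
            SyntheticTruth(
                strain_id=name,
                media=params,
                lipid_content=lipid,
                uptake_rates={
                    "acetic": rng.uniform(0.10, 0.18),
                    "propionic": rng.uniform(0.04, 0.08),
                    "butyric": rng.uniform(0.02, 0.05),
                },
                biomass_yield=rng.uniform(0.3, 0.5),
            )
        )
    return truths
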