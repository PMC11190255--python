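"""SCFA media design and fermentation accounting.

Media are specified by a total SCFA concentration (g/L) and an
acetic : propionic : butyric (A:P:B) ratio. The ratio is interpreted on the
carbon basis by default — the per-acid carbon masses, not the per-acid
masses, stand in the stated proportion — with a mass basis available for
sensitivity checks. Nitrogen (ammonium sulphate) is dosed to hit a target
C/N mass ratio counting SCFA carbon only.

Endpoint accounting mirrors fermentation-table convention: per-acid
consumption percentages from initial and final concentrations, a
carbon-ratio-weighted total consumption, maximum OD600, lipid content
(% w/w of cell dry weight), lipid yield Y_L/S (g lipid per g SCFA
consumed), and mean volumetric consumption rate (g/(L*h)).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MediumSpec",
    "FermentationSummary",
    "CARBON_FRACTION",
    "design_medium",
    "ammonium_sulphate_for_cn",
    "consumption_percent",
    "format_consumption",
    "total_consumption",
    "lipid_yield",
    "biomass_for_yield",
    "consumption_rate",
    "summarize_fermentation",
]

ACIDS = ("acetic", "propionic", "butyric")

_M_C = 12.011
#: Carbon mass fraction of each acid: (n_C * M_C) / M_acid.
CARBON_FRACTION = {
    "acetic": 2 * _M_C / 60.052,
    "propionic": 3 * _M_C / 74.079,
    "butyric": 4 * _M_C / 88.106,
}
#: Nitrogen mass fraction of ammonium sulphate (NH4)2SO4.
N_FRACTION_AMS = 2 * 14.007 / 132.14


@dataclass(frozen=True)
class MediumSpec:
    """An SCFA medium: per-acid masses, ratio bookkeeping, C/N dosing."""

    total_scfa: float
    carbon_ratio: tuple[float, float, float]
    acetic: float
    propionic: float
    butyric: float
    ratio_mode: str = "carbon"
    cn_ratio: float | None = None
    ammonium_sulphate: float | None = None
    ph: float | None = None

    @property
    def masses(self) -> dict[str, float]:
        return {"acetic": self.acetic, "propionic": self.propionic, "butyric": self.butyric}

    @property
    def carbon_g_per_l(self) -> float:
        """Total SCFA-derived carbon, g/L."""
        return sum(CARBON_FRACTION[a] * m for a, m in self.masses.items())

    def observed_carbon_ratio(self) -> tuple[float, ...]:
        """Per-acid carbon masses rescaled so the smallest nonzero entry is its ratio value."""
        carbons = np.array([CARBON_FRACTION[a] * self.masses[a] for a in ACIDS])
        ref = np.array(self.carbon_ratio, dtype=float)
        nz = ref > 0
        scale = (carbons[nz] / ref[nz]).mean() if nz.any() else 1.0
        return tuple(carbons / scale if scale > 0 else carbons)


def design_medium(
    total_scfa: float,
    carbon_ratio: tuple[float, float, float],
    ratio_mode: str = "carbon",
    ph: float | None = None,
) -> MediumSpec:
    """Split a total SCFA concentration into per-acid masses.

    In ``carbon`` mode the per-acid carbon masses are in the stated
    A:P:B proportion and the per-acid masses sum to ``total_scfa``; in
    ``mass`` mode the masses themselves follow the ratio.
    """
    if total_scfa <= 0:
        raise ValueError("total_scfa must be > 0")
    ratio = np.asarray(carbon_ratio, dtype=float)
    if ratio.shape != (3,) or np.any(ratio < 0) or ratio.sum() == 0:
        raise ValueError("carbon_ratio must be three values >= 0, not all zero")
    if ratio_mode == "carbon":
        # m_i proportional to ratio_i / carbon_fraction_i, normalised to total mass.
        shares = np.array(
            [ratio[i] / CARBON_FRACTION[a] for i, a in enumerate(ACIDS)]
        )
    elif ratio_mode == "mass":
        shares = ratio
    else:
        raise ValueError(f"ratio_mode must be 'carbon' or 'mass', got {ratio_mode!r}")
    masses = total_scfa * shares / shares.sum()
    return MediumSpec(
        total_scfa=float(total_scfa),
        carbon_ratio=tuple(float(x) for x in carbon_ratio),
        acetic=float(masses[0]),
        propionic=float(masses[1]),
        butyric=float(masses[2]),
        ratio_mode=ratio_mode,
        ph=ph,
    )


def ammonium_sulphate_for_cn(medium: MediumSpec, target_cn: float) -> float:
    """Ammonium sulphate dose (g/L) that sets the C/N mass ratio to ``target_cn``.

    Carbon counts SCFA carbon only; N comes from (NH4)2SO4 at its nitrogen
    mass fraction (~0.212).
    """
    if target_cn <= 0:
        raise ValueError("target_cn must be > 0")
    carbon = medium.carbon_g_per_l
    if carbon <= 0:
        raise ValueError("medium contains no SCFA carbon")
    return (carbon / target_cn) / N_FRACTION_AMS


def consumption_percent(initial: float, final: float) -> float:
    """Percent of a substrate consumed between two samples, clamped to [0, 100].

    A final concentration above the initial one (measurement noise) clamps
    to 0 with a warning.
    """
    if initial <= 0:
        raise ValueError(f"initial concentration must be > 0, got {initial}")
    if final < 0:
        raise ValueError(f"final concentration must be >= 0, got {final}")
    if final > initial:
        warnings.warn(
            f"final ({final}) exceeds initial ({initial}); consumption clamped to 0",
            stacklevel=2,
        )
    return float(np.clip(100.0 * (initial - final) / initial, 0.0, 100.0))


def format_consumption(pct: float, censor_below: float = 10.0) -> str:
    """Table-style rendering: values under the reporting threshold print '<10'."""
    if pct < censor_below:
        return f"<{censor_below:g}"
    return f"{_round_half_up(pct):d}"


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def _decensor(value: float | str, censored_as: float) -> float:
    if isinstance(value, str):
        if value.strip().startswith("<"):
            return censored_as
        return float(value)
    return float(value)


def total_consumption(
    per_acid_pct: tuple[float | str, float | str, float | str],
    carbon_ratio: tuple[float, float, float],
    censored_as: float = 0.0,
    rounded: bool = True,
) -> float:
    """Carbon-ratio-weighted mean of per-acid consumption percentages.

    Weights are ratio_i / sum(ratio). Censored entries like ``"<10"`` are
    treated as ``censored_as`` (0 by default; use 5.0 for interval
    midpoints). ``rounded`` applies half-up integer rounding for
    table-style reporting; full precision is returned otherwise.
    """
    ratio = np.asarray(carbon_ratio, dtype=float)
    if np.any(ratio < 0) or ratio.sum() == 0:
        raise ValueError("carbon_ratio must be >= 0 and not all zero")
    pct = np.array([_decensor(v, censored_as) for v in per_acid_pct])
    if np.any((pct < 0) | (pct > 100)):
        raise ValueError("percentages must lie in [0, 100]")
    weights = ratio / ratio.sum()
    total = float(np.dot(weights, pct))
    return float(_round_half_up(total)) if rounded else total


def lipid_yield(lipid_content: float, biomass: float, scfa_consumed: float) -> float:
    """Y_L/S: g lipid per g SCFA consumed.

    lipid_content in % w/w of CDW, biomass in g CDW/L, scfa_consumed in g/L.
    Returns NaN when nothing was consumed (the yield is undefined).
    """
    if lipid_content < 0 or biomass < 0:
        raise ValueError("lipid_content and biomass must be >= 0")
    if scfa_consumed <= 0:
        return np.nan
    return (lipid_content / 100.0) * biomass / scfa_consumed


def biomass_for_yield(
    lipid_content: float, scfa_consumed: float, yield_ls: float
) -> float:
    """Inverse-consistency utility: biomass (g/L) implied by a printed
    (lipid %, consumed g/L, Y_L/S) triplet."""
    if lipid_content <= 0:
        raise ValueError("lipid_content must be > 0")
    return yield_ls * scfa_consumed / (lipid_content / 100.0)


def consumption_rate(scfa_consumed: float, duration_h: float) -> float:
    """Mean volumetric consumption rate, g/(L*h)."""
    if duration_h <= 0:
        raise ValueError(f"duration_h must be > 0, got {duration_h}")
    if scfa_consumed < 0:
        raise ValueError("scfa_consumed must be >= 0")
    return scfa_consumed / duration_h


@dataclass(frozen=True)
class FermentationSummary:
    """Endpoint accounting of one fermentation run."""

    consumption_pct: dict[str, float]
    total_pct: float
    max_od600: float
    lipid_content: float
    biomass: float | None
    yield_ls: float
    rate_g_per_l_h: float
    scfa_consumed_g_per_l: float
    duration_h: float


def summarize_fermentation(
    timecourse: pd.DataFrame,
    medium: MediumSpec,
    lipid_content: float,
    biomass: float | None = None,
    initial_tolerance: float = 0.10,
) -> FermentationSummary:
    """Summarise a fermentation time course against its medium specification.

    ``timecourse`` columns: time_h, acetic_gL, propionic_gL, butyric_gL,
    od600. Per-acid consumption uses the first and last samples; the total
    is the carbon-ratio-weighted mean; OD600 is the series maximum; yield
    and rate follow :func:`lipid_yield` and :func:`consumption_rate`. The
    run ends at the last sample — deciding when to stop is the
    experimentalist's call, not the summariser's. Initial concentrations
    deviating from the medium spec by more than ``initial_tolerance``
    (relative) raise a warning.
    """
    if len(timecourse) < 2:
        raise ValueError("need at least two time points")
    tc = timecourse.sort_values("time_h")
    first, last = tc.iloc[0], tc.iloc[-1]
    duration = float(last["time_h"] - first["time_h"])
    per_acid: dict[str, float] = {}
    consumed_total = 0.0
    for acid in ACIDS:
        col = f"{acid}_gL"
        init, fin = float(first[col]), float(last[col])
        expected = medium.masses[acid]
        if expected > 0 and abs(init - expected) > initial_tolerance * expected:
            warnings.warn(
                f"initial {acid} concentration {init:.3g} g/L deviates from "
                f"medium spec {expected:.3g} g/L",
                stacklevel=2,
            )
        if init > 0:
            per_acid[acid] = consumption_percent(init, fin)
            consumed_total += max(init - fin, 0.0)
        else:
            per_acid[acid] = np.nan
    pct_tuple = tuple(0.0 if np.isnan(per_acid[a]) else per_acid[a] for a in ACIDS)
    total = total_consumption(pct_tuple, medium.carbon_ratio, rounded=False)
    y = lipid_yield(lipid_content, biomass, consumed_total) if biomass else np.nan
    return FermentationSummary(
        consumption_pct=per_acid,
        total_pct=total,
        max_od600=float(tc["od600"].max()),
        lipid_content=float(lipid_content),
        biomass=biomass,
        yield_ls=y,
        rate_g_per_l_h=consumption_rate(consumed_total, duration) if duration > 0 else 0.0,
        scfa_consumed_g_per_l=consumed_total,
        duration_h=duration,
    )
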