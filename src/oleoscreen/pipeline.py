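"""End-to-end orchestration: simulate -> phenotype -> lipids -> stats -> rank -> ferment.

Each stage reads and writes delimited text tables under a single output
directory and drops a small JSON provenance sidecar (stage name, config
hash, seed, package version, row counts) next to its outputs. Stages form a
DAG; running a stage whose inputs are missing raises an error naming the
stage to run first. Deterministic stages are byte-identical under identical
config and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .fermentation import (
    ammonium_sulphate_for_cn,
    design_medium,
    summarize_fermentation,
)
from .growth import GrowthConfig, growth_intersections, phenotype_screen, summarize_screen
from .ranking import WeightConfig, select_top, weighted_rank
from .stats import compare_to_reference, max_abs_scale, rfu_table
from .synthetic import (
    ScreenDesign,
    fermentation_truth_table,
    generate_fermentation,
    generate_lipid_assay,
    make_demo_truths,
    SyntheticTruth,
    LogisticParams,
    generate_screen,
)

log = logging.getLogger("oleoscreen")

STAGES = ("simulate", "phenotype", "lipids", "stats", "rank", "ferment")

#: stage -> (required input files, producing stage)
_REQUIRES = {
    "simulate": ([], None),
    "phenotype": (["layout.csv", "timecourses.csv"], "simulate"),
    "lipids": (["lipid_assay.csv"], "simulate"),
    "stats": (["colony_params.csv", "lipid_rfu.csv"], "phenotype"),
    "rank": (["strain_summary.csv", "lipid_rfu.csv"], "phenotype"),
    "ferment": (["selected.csv", "fermentation_truth.csv"], "rank"),
}


@dataclass
class PipelineConfig:
    """Validated configuration of a full pipeline run."""

    outdir: str = "out"
    seed: int = 0
    n_strains: int = 24
    frac_viable: float = 0.4
    media: tuple[str, ...] = ("glucose", "A2P1B2", "A3P1B1", "A1P1B3")
    plate_density: int = 96
    n_replicates: int = 3
    sampling_interval_h: float = 0.25
    duration_h: float = 96.0
    noise_cv: float = 0.05
    reference_strain: str = "REF"
    growth: GrowthConfig = field(default_factory=GrowthConfig)
    weights: WeightConfig = field(default_factory=WeightConfig)
    n_select: int = 11
    alpha: float = 0.05
    ferment_total_scfa: float = 15.0
    ferment_carbon_ratio: tuple[float, float, float] = (3.0, 1.0, 1.0)
    ferment_cn_ratio: float | None = None
    ferment_duration_h: float = 120.0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_select < 1:
            raise ValueError("n_select must be >= 1")
        if self.n_strains < 2:
            raise ValueError("n_strains must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        growth = GrowthConfig(**raw.pop("growth", {}))
        weights = WeightConfig(**raw.pop("weights", {}))
        for key in ("media", "ferment_carbon_ratio"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(growth=growth, weights=weights, **raw)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("outdir")  # output location is not part of the analysis
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def _write_provenance(outdir: Path, stage: str, config: PipelineConfig, **extra) -> None:
    record = {
        "stage": stage,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": __version__,
        **extra,
    }
    (outdir / f"{stage}.provenance.json").write_text(
        json.dumps(record, indent=2, sort_keys=True) + "\n"
    )


def _check_inputs(stage: str, outdir: Path) -> None:
    required, producer = _REQUIRES[stage]
    missing = [f for f in required if not (outdir / f).exists()]
    if missing:
        raise FileNotFoundError(
            f"stage {stage!r} is missing inputs {missing}; "
            f"run stage {producer!r} first"
        )


def _truths_for(config: PipelineConfig) -> list[SyntheticTruth]:
    return make_demo_truths(
        n_strains=config.n_strains,
        seed=config.seed,
        media=config.media,
        frac_viable=config.frac_viable,
        reference_strain=config.reference_strain,
    )


def run_stage(stage: str, config: PipelineConfig) -> dict[str, Path]:
    """Execute one pipeline stage; returns the paths it wrote."""
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _check_inputs(stage, outdir)
    t0 = time.monotonic()
    written = getattr(_StageRunner(config, outdir), stage)()
    log.info("stage %s finished in %.1fs -> %s", stage, time.monotonic() - t0,
             [p.name for p in written.values()])
    return written


class _StageRunner:
    def __init__(self, config: PipelineConfig, outdir: Path) -> None:
        self.config = config
        self.outdir = outdir

    def _save(self, stage: str, tables: dict[str, pd.DataFrame]) -> dict[str, Path]:
        paths = {}
        rows = {}
        for name, df in tables.items():
            path = self.outdir / f"{name}.csv"
            df.to_csv(path, index=False)
            paths[name] = path
            rows[name] = len(df)
        _write_provenance(self.outdir, stage, self.config, rows_out=rows)
        return paths

    def simulate(self) -> dict[str, Path]:
        cfg = self.config
        design = ScreenDesign(
            media=cfg.media,
            plate_density=cfg.plate_density,
            n_replicates=cfg.n_replicates,
            sampling_interval_h=cfg.sampling_interval_h,
            duration_h=cfg.duration_h,
            noise_cv=cfg.noise_cv,
            seed=cfg.seed,
            reference_strain=cfg.reference_strain,
        )
        truths = _truths_for(cfg)
        layout, timecourses, truth = generate_screen(design, truths)
        assay = generate_lipid_assay(truths, seed=cfg.seed, n_replicates=cfg.n_replicates)
        return self._save(
            "simulate",
            {
                "layout": layout,
                "timecourses": timecourses,
                "truth": truth,
                "lipid_assay": assay,
                "fermentation_truth": fermentation_truth_table(truths),
            },
        )

    def phenotype(self) -> dict[str, Path]:
        layout = pd.read_csv(self.outdir / "layout.csv")
        timecourses = pd.read_csv(self.outdir / "timecourses.csv")
        colony = phenotype_screen(layout, timecourses, self.config.growth)
        summary = summarize_screen(colony)
        scfa_media = [m for m in self.config.media if m != "glucose"]
        calls = (
            summary[summary["medium_id"].isin(scfa_media)]
            .pivot(index="strain_id", columns="medium_id", values="growth_call")
        )
        intersections = growth_intersections(calls)
        (self.outdir / "intersections.json").write_text(
            json.dumps(intersections, indent=2, sort_keys=True) + "\n"
        )
        paths = self._save(
            "phenotype", {"colony_params": colony, "strain_summary": summary}
        )
        paths["intersections"] = self.outdir / "intersections.json"
        return paths

    def lipids(self) -> dict[str, Path]:
        assay = pd.read_csv(self.outdir / "lipid_assay.csv")
        rfu = rfu_table(assay)
        median = (
            rfu.groupby("strain_id", as_index=False)["rfu"].median()
            .rename(columns={"rfu": "rfu_median"})
        )
        return self._save("lipids", {"lipid_rfu": rfu, "lipid_rfu_median": median})

    def stats(self) -> dict[str, Path]:
        colony = pd.read_csv(self.outdir / "colony_params.csv")
        rfu = pd.read_csv(self.outdir / "lipid_rfu.csv")
        long = colony.melt(
            id_vars=["strain_id", "medium_id"],
            value_vars=["fitness", "t_max"],
            var_name="variable",
            value_name="value",
        ).dropna(subset=["value"])
        lipid_long = rfu.rename(columns={"rfu": "value"})[["strain_id", "value"]]
        lipid_long["variable"] = "lipid"
        lipid_long["medium_id"] = "assay"
        comparison = compare_to_reference(
            pd.concat([long, lipid_long], ignore_index=True),
            reference_strain=self.config.reference_strain,
        )
        return self._save("stats", {"comparison": comparison})

    def rank(self) -> dict[str, Path]:
        summary = pd.read_csv(self.outdir / "strain_summary.csv")
        rfu = pd.read_csv(self.outdir / "lipid_rfu.csv")
        scfa_media = [m for m in self.config.media if m != "glucose"]
        wide = {}
        kinds = {}
        sub = summary[summary["medium_id"].isin(scfa_media)]
        for var in ("fitness", "t_max"):
            pivot = sub.pivot(index="strain_id", columns="medium_id", values=var)
            for medium in scfa_media:
                col = f"{var}@{medium}"
                wide[col] = pivot[medium]
                kinds[col] = var
        lipid = rfu.groupby("strain_id")["rfu"].median()
        wide["lipid_rfu"] = lipid
        kinds["lipid_rfu"] = "lipid"
        matrix = pd.DataFrame(wide)
        scaled = max_abs_scale(matrix)
        scaled.columns = [f"scaled_{c}" for c in scaled.columns]
        table = weighted_rank(matrix, kinds, self.config.weights)
        n_select = min(self.config.n_select, len(table))
        chosen = select_top(table, n_select)
        rank_out = table.join(scaled).reset_index(names="strain_id")
        selected = pd.DataFrame(
            {"strain_id": chosen, "selection_order": range(1, len(chosen) + 1)}
        )
        return self._save("rank", {"rank_table": rank_out, "selected": selected})

    def ferment(self) -> dict[str, Path]:
        cfg = self.config
        selected = pd.read_csv(self.outdir / "selected.csv")
        ferm_truth = pd.read_csv(self.outdir / "fermentation_truth.csv").set_index(
            "strain_id"
        )
        medium = design_medium(cfg.ferment_total_scfa, cfg.ferment_carbon_ratio)
        if cfg.ferment_cn_ratio:
            ams = ammonium_sulphate_for_cn(medium, cfg.ferment_cn_ratio)
            medium = replace(medium, cn_ratio=cfg.ferment_cn_ratio, ammonium_sulphate=ams)
        rows = []
        tc_parts = []
        for strain in selected["strain_id"]:
            t = ferm_truth.loc[strain]
            truth = SyntheticTruth(
                strain_id=strain,
                media={},
                lipid_content=float(t["lipid_content"]),
                uptake_rates={
                    a: float(t[f"uptake_{a}"]) for a in ("acetic", "propionic", "butyric")
                },
                biomass_yield=float(t["biomass_yield"]),
            )
            tc = generate_fermentation(
                truth, medium.masses, cfg.ferment_duration_h, seed=cfg.seed
            )
            tc_parts.append(tc.assign(strain_id=strain))
            biomass = 0.45 * float(tc["od600"].iloc[-1])  # OD 1 ~ 0.45 g CDW/L
            s = summarize_fermentation(
                tc, medium, lipid_content=100 * truth.lipid_content, biomass=biomass
            )
            rows.append(
                {
                    "strain_id": strain,
                    "acetic_pct": s.consumption_pct["acetic"],
                    "propionic_pct": s.consumption_pct["propionic"],
                    "butyric_pct": s.consumption_pct["butyric"],
                    "total_pct": s.total_pct,
                    "max_od600": s.max_od600,
                    "lipid_content_pct": s.lipid_content,
                    "yield_ls": s.yield_ls,
                    "rate_g_per_l_h": s.rate_g_per_l_h,
                }
            )
        return self._save(
            "ferment",
            {
                "fermentation_summary": pd.DataFrame(rows),
                "fermentation_timecourses": pd.concat(tc_parts, ignore_index=True),
            },
        )


def run_all(config: PipelineConfig) -> dict[str, Path]:
    """Run every stage in dependency order; returns all written paths."""
    written: dict[str, Path] = {}
    for stage in STAGES:
        written.update(run_stage(stage, config))
    return written
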