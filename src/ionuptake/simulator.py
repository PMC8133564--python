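"""Seeded synthetic experiments with known ground truth.

The simulator emulates a diversity-panel uptake experiment: G genotypes ×
r replicates × two macronutrient concentration levels, phenotyped in
250-mL chambers sampled on the standard schedule (0, 0.5, 1, 2, 3, 4, 6,
8 h), 48 plants per run (two 24-chamber modules). Per genotype it draws
Michaelis–Menten parameters (I_max, K_m) for each focal ion from lognormal
distributions with a configurable genetic coefficient of variation and a
Gaussian-copula cross-ion correlation of the genetic effects; per plant it
draws a gamma-distributed root length, applies a multiplicative run effect
to uptake capacity, integrates the depletion forward model and corrupts the
sampled concentrations with multiplicative Gaussian noise (instrument-like
relative error, floored at zero).

Default population parameters place fractional depletion in the regime the
interval-selection rule is designed for: roughly 10–40% by 4 h in the high
solution and 10–50% by 1 h in the low solution, so the rule lands on the
4 h and 1 h samples respectively.

Everything is driven by one integer seed; identical seeds give identical
draws and byte-identical fixture files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import (
    ChamberInfo,
    ChamberMap,
    ExperimentConfig,
    RawConcentrationTable,
    write_chamber_map,
    write_experiment_config,
    write_ic_export,
)
from .mm_kinetics import MMParams, mm_depletion_conc
from .solution_chemistry import FOCAL_IONS, focal_composition, load_recipes
from .uptake_core import DepletionSeries, PlantRecord

_WELLS_24 = [f"{row}{col}" for row in "AB" for col in range(1, 13)]


@dataclass
class IonPopulationParams:
    """Population distribution of one ion's kinetic parameters."""

    mean_imax: float = 0.019  # µmol cm^-1 h^-1
    cv_imax: float = 0.30  # genetic CV of I_max
    mean_km: float = 100.0  # µM
    cv_km: float = 0.20  # genetic CV of K_m


def default_ion_params() -> dict[str, IonPopulationParams]:
    return {ion: IonPopulationParams() for ion in FOCAL_IONS}


@dataclass
class SimulationConfig:
    """Full specification of a synthetic experiment."""

    seed: int = 0
    genotypes: int = 26
    replicates: int = 6
    levels: dict[str, dict[str, float]] = field(default_factory=dict)
    ion_params: dict[str, IonPopulationParams] = field(
        default_factory=default_ion_params
    )
    cross_ion_corr: float = 0.5  # correlation of genetic effects across ions
    root_length_mean_cm: float = 400.0
    root_length_cv: float = 0.25
    noise_cv: float = 0.02  # multiplicative measurement noise on concentrations
    run_effect_sd: float = 0.05  # SD of run effects on log uptake capacity
    schedule_h: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0)
    chamber_volume_ml: float = 250.0
    sample_volume_ml: float = 1.5
    plants_per_run: int = 48
    specific_respiration_mean: float = 0.5  # nmol CO2 m^-1 s^-1
    specific_respiration_cv: float = 0.25
    specific_root_length_mean: float = 5000.0  # cm g^-1
    specific_root_length_cv: float = 0.15

    def __post_init__(self) -> None:
        if self.genotypes < 2:
            raise ValidationError("need at least 2 genotypes")
        if self.replicates < 1:
            raise ValidationError("need at least 1 replicate")
        for name in ("root_length_cv", "noise_cv", "run_effect_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.schedule_h[0] != 0:
            raise ValidationError("sampling schedule must start at 0")
        if not self.levels:
            recipes = load_recipes()
            self.levels = {
                "high": focal_composition(recipes["high"]),
                "low": focal_composition(recipes["low"]),
            }


def plan_runs(n_plants: int, plants_per_run: int = 48) -> int:
    """Number of experimental runs needed for ``n_plants``."""
    if plants_per_run <= 0:
        raise ValidationError("plants_per_run must be > 0")
    return math.ceil(n_plants / plants_per_run)


def _lognormal_params(mean: float, cv: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given mean and CV."""
    sigma2 = math.log(1.0 + cv**2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _equicorrelated(n: int, rho: float) -> np.ndarray:
    corr = np.full((n, n), rho)
    np.fill_diagonal(corr, 1.0)
    if np.linalg.eigvalsh(corr).min() <= 0:
        raise ValidationError(
            f"cross-ion correlation {rho} gives a non-positive-definite matrix"
        )
    return corr


def draw_population(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw genotype-level kinetic parameters and plant-level covariates.

    Returns ``(genotype_truth, plant_truth)``. Genotype truth has one row
    per (genotype, ion) with the true I_max and K_m; plant truth has one row
    per plant with its genotype, treatment, run, block, root length,
    structural traits and the run effect applied to its uptake capacity.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    ions = sorted(config.ion_params)
    n_ions = len(ions)
    corr = _equicorrelated(n_ions, config.cross_ion_corr)
    chol = np.linalg.cholesky(corr)

    geno_rows = []
    genos = [f"G{i + 1:03d}" for i in range(config.genotypes)]
    for geno in genos:
        z_imax = chol @ rng.standard_normal(n_ions)
        z_km = chol @ rng.standard_normal(n_ions)
        for j, ion in enumerate(ions):
            p = config.ion_params[ion]
            mu_i, sd_i = _lognormal_params(p.mean_imax, p.cv_imax)
            mu_k, sd_k = _lognormal_params(p.mean_km, p.cv_km)
            geno_rows.append(
                {
                    "genotype": geno,
                    "ion": ion,
                    "i_max": math.exp(mu_i + sd_i * z_imax[j]),
                    "k_m": math.exp(mu_k + sd_k * z_km[j]),
                }
            )
    genotype_truth = pd.DataFrame(geno_rows)

    levels = sorted(config.levels)
    n_plants = config.genotypes * config.replicates * len(levels)
    n_runs = plan_runs(n_plants, config.plants_per_run)
    run_effects = rng.normal(0.0, config.run_effect_sd, size=n_runs)

    # interleave genotypes and levels across chambers so every run mixes both
    assignments = [
        (geno, rep, level)
        for rep in range(1, config.replicates + 1)
        for geno in genos
        for level in levels
    ]
    shape_l = 1.0 / config.root_length_cv**2
    mu_r, sd_r = _lognormal_params(
        config.specific_respiration_mean, config.specific_respiration_cv
    )
    mu_s, sd_s = _lognormal_params(
        config.specific_root_length_mean, config.specific_root_length_cv
    )

    plant_rows = []
    for i, (geno, rep, level) in enumerate(assignments):
        run = i // config.plants_per_run + 1
        within = i % config.plants_per_run
        module = within // 24 + 1
        well = _WELLS_24[within % 24]
        length = rng.gamma(shape_l, config.root_length_mean_cm / shape_l)
        spec_resp = math.exp(rng.normal(mu_r, sd_r))
        srl = math.exp(rng.normal(mu_s, sd_s))
        frac = rng.dirichlet([5.0, 11.0, 4.0])  # seminal, lateral, secondary
        root_dw = length / srl
        leaf_dw = root_dw * math.exp(rng.normal(math.log(1.8), 0.15))
        stem_dw = root_dw * math.exp(rng.normal(math.log(0.9), 0.15))
        plant_rows.append(
            {
                "plant": f"PL{i + 1:04d}",
                "chamber": f"CH{i + 1:04d}",
                "genotype": geno,
                "replicate": rep,
                "treatment": level,
                "run": f"R{run}",
                "block": f"R{run}",
                "module": f"M{module}",
                "well": well,
                "root_length_cm": length,
                "seminal_length_cm": length * frac[0],
                "lateral_length_cm": length * frac[1],
                "secondary_lateral_length_cm": length * frac[2],
                "root_dw_g": root_dw,
                "leaf_dw_g": leaf_dw,
                "stem_dw_g": stem_dw,
                "respiration_nmol_s": spec_resp * length / 100.0,
                "leaf_area_cm2": leaf_dw * math.exp(rng.normal(math.log(550.0), 0.1)),
                "leaf_length_cm": 12.0 * (leaf_dw * 550.0) ** 0.5 / 10.0,
                "run_effect": math.exp(run_effects[run - 1]),
            }
        )
    return genotype_truth, pd.DataFrame(plant_rows)


def simulate_depletion(
    params: MMParams,
    c0: float,
    length_cm: float,
    schedule_h,
    volume_ml: float = 250.0,
    noise_cv: float = 0.0,
    rng: np.random.Generator | None = None,
    chamber: str = "",
) -> DepletionSeries:
    """One noisy depletion series from the closed-form forward model."""
    if c0 <= 0:
        raise ValidationError(f"starting concentration must be > 0, got {c0}")
    t = np.asarray(schedule_h, dtype=float)
    conc = np.atleast_1d(mm_depletion_conc(t, c0, params, length_cm, volume_ml))
    if noise_cv > 0:
        if rng is None:
            raise ValidationError("noisy simulation requires an rng")
        conc = conc * (1.0 + noise_cv * rng.standard_normal(conc.shape))
        conc = np.maximum(conc, 0.0)
    return DepletionSeries(
        chamber=chamber,
        ion=params.ion,
        times=t,
        concentrations=conc,
        volume=volume_ml,
        sample_volume=1.5,
    )


@dataclass
class SimulatedExperiment:
    """In-memory synthetic experiment with its generating truth."""

    config: SimulationConfig
    chamber_map: ChamberMap
    concentrations: RawConcentrationTable
    plants: dict[str, PlantRecord]
    genotype_truth: pd.DataFrame
    plant_truth: pd.DataFrame

    def series_for_chamber(self, chamber: str) -> dict[str, DepletionSeries]:
        sub = self.concentrations.data[
            self.concentrations.data["chamber"] == chamber
        ]
        out = {}
        for ion, grp in sub.groupby("ion"):
            grp = grp.sort_values("time_h")
            out[str(ion)] = DepletionSeries(
                chamber=chamber,
                ion=str(ion),
                times=grp["time_h"].to_numpy(),
                concentrations=grp["conc_um"].to_numpy(),
                volume=self.config.chamber_volume_ml,
                sample_volume=self.config.sample_volume_ml,
            )
        return out


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate a full experiment: chamber map, depletion data, plant records."""
    rng = np.random.default_rng(config.seed)
    genotype_truth, plant_truth = draw_population(config, rng)
    gt = genotype_truth.set_index(["genotype", "ion"])

    conc_rows = []
    entries: dict[str, ChamberInfo] = {}
    plants: dict[str, PlantRecord] = {}
    for _, row in plant_truth.iterrows():
        chamber = row["chamber"]
        entries[chamber] = ChamberInfo(
            chamber=chamber,
            plant=row["plant"],
            genotype=row["genotype"],
            treatment=row["treatment"],
            run=row["run"],
            block=row["block"],
            well=row["well"],
            plate=row["module"],
        )
        plants[row["plant"]] = PlantRecord(
            plant=row["plant"],
            genotype=row["genotype"],
            treatment=row["treatment"],
            run=row["run"],
            block=row["block"],
            seminal_length=row["seminal_length_cm"],
            lateral_length=row["lateral_length_cm"],
            secondary_lateral_length=row["secondary_lateral_length_cm"],
            root_dw=row["root_dw_g"],
            leaf_dw=row["leaf_dw_g"],
            stem_dw=row["stem_dw_g"],
            total_respiration=row["respiration_nmol_s"],
            leaf_area=row["leaf_area_cm2"],
            leaf_length=row["leaf_length_cm"],
        )
        composition = config.levels[row["treatment"]]
        for ion in sorted(config.ion_params):
            truth = gt.loc[(row["genotype"], ion)]
            params = MMParams(
                ion=ion,
                i_max=float(truth["i_max"]) * float(row["run_effect"]),
                k_m=float(truth["k_m"]),
            )
            series = simulate_depletion(
                params,
                c0=float(composition[ion]),
                length_cm=float(row["root_length_cm"]),
                schedule_h=config.schedule_h,
                volume_ml=config.chamber_volume_ml,
                noise_cv=config.noise_cv,
                rng=rng,
                chamber=chamber,
            )
            for t, c in zip(series.times, series.concentrations):
                conc_rows.append(
                    {"chamber": chamber, "time_h": t, "ion": ion, "conc_um": c}
                )
    table = RawConcentrationTable(
        data=pd.DataFrame(conc_rows), source="simulated", instrument="simulator"
    )
    return SimulatedExperiment(
        config=config,
        chamber_map=ChamberMap(entries),
        concentrations=table,
        plants=plants,
        genotype_truth=genotype_truth,
        plant_truth=plant_truth,
    )


def simulate_genotype_trait(
    sigma_g2: float,
    sigma_e2: float,
    genotypes: int,
    replicates: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Direct draw of a genotype-structured trait (simulation-study engine).

    y_ij = g_i + e_ij with g_i ~ N(0, σ_g²), e_ij ~ N(0, σ_e²); used for
    calibration-style recovery studies of the variance-component estimator.
    """
    g = rng.normal(0.0, math.sqrt(sigma_g2), size=genotypes)
    rows = []
    for i in range(genotypes):
        e = rng.normal(0.0, math.sqrt(sigma_e2), size=replicates)
        for j in range(replicates):
            rows.append({"genotype": f"G{i + 1:03d}", "value": g[i] + e[j]})
    return pd.DataFrame(rows)


def make_fixture_experiment(
    config: SimulationConfig, outdir: str | Path, force: bool = False
) -> SimulatedExperiment:
    """Write a complete, immediately-runnable synthetic input set to disk.

    Emits ``chamber_map.csv``, ``ic_export.csv`` (long dialect),
    ``root_traits.csv`` (classified mode with dry weights and leaf
    measurements), ``config.yaml`` and ``ground_truth.json``. Refuses a
    non-empty directory unless ``force``.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise ValidationError(
            f"output directory {outdir} is not empty (use force=True)"
        )
    outdir.mkdir(parents=True, exist_ok=True)
    exp = simulate_experiment(config)

    write_chamber_map(exp.chamber_map, outdir / "chamber_map.csv")
    write_ic_export(exp.concentrations, outdir / "ic_export.csv")

    root_rows = []
    for plant in exp.plants.values():
        root_rows.append(
            {
                "plant": plant.plant,
                "genotype": plant.genotype,
                "treatment": plant.treatment,
                "run": plant.run,
                "block": plant.block,
                "seminal_length_cm": plant.seminal_length,
                "lateral_length_cm": plant.lateral_length,
                "secondary_lateral_length_cm": plant.secondary_lateral_length,
                "root_dw_g": plant.root_dw,
                "leaf_dw_g": plant.leaf_dw,
                "stem_dw_g": plant.stem_dw,
                "respiration_nmol_s": plant.total_respiration,
                "leaf_area_cm2": plant.leaf_area,
                "leaf_length_cm": plant.leaf_length,
            }
        )
    pd.DataFrame(root_rows).to_csv(outdir / "root_traits.csv", index=False)

    write_experiment_config(
        ExperimentConfig(
            schedule_h=config.schedule_h,
            chamber_volume_ml=config.chamber_volume_ml,
            sample_volume_ml=config.sample_volume_ml,
        ),
        outdir / "config.yaml",
    )

    truth = {
        "seed": config.seed,
        "genotypes": config.genotypes,
        "replicates": config.replicates,
        "levels": {k: dict(sorted(v.items())) for k, v in sorted(config.levels.items())},
        "noise_cv": config.noise_cv,
        "cross_ion_corr": config.cross_ion_corr,
        "ion_params": {k: asdict(v) for k, v in sorted(config.ion_params.items())},
        "genotype_truth": exp.genotype_truth.to_dict("records"),
        "plant_truth": exp.plant_truth.to_dict("records"),
    }
    (outdir / "ground_truth.json").write_text(
        json.dumps(truth, indent=1, sort_keys=True)
    )
    return exp
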