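"""Tabular I/O: ion-chromatography exports, root-trait tables, chamber maps.

Everything tabular is CSV; experiment-level settings (sampling schedule,
chamber volume, runs) live in a YAML config. Canonical internal units are µM
(concentration), h (time), cm (length) and g (mass); unit conversions happen
only at these boundaries. Long format is the canonical in-memory layout for
concentration data; wide instrument exports are melted on read.

Number parsing is strict: decimal commas and thousands separators are
rejected with a row-level error rather than guessed at.
"""

from __future__ import annotations

import json
import logging
import re
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError, ValidationError
from .trait_battery import (
    METADATA_COLUMNS,
    SCHEMA_VERSION,
    TRAIT_COLUMNS,
    TRAIT_UNITS,
)
from .uptake_core import PlantRecord, classify_root_lengths

logger = logging.getLogger("ionuptake")

_WELL_RE = re.compile(r"^[A-H](?:[1-9]|1[0-2])$")


def well_index(well: str) -> int:
    """Row-major index of a 96-well plate position (A1=0 ... H12=95)."""
    if not _WELL_RE.match(well):
        raise ValidationError(f"invalid 96-well position {well!r}")
    row = string.ascii_uppercase.index(well[0])
    col = int(well[1:]) - 1
    return row * 12 + col


@dataclass
class ChamberInfo:
    chamber: str
    plant: str
    genotype: str
    treatment: str
    run: str
    block: str
    well: str
    plate: str = "P1"


@dataclass
class ChamberMap:
    """chamber id -> plant/genotype/treatment/run/block/collection well."""

    entries: dict[str, ChamberInfo]

    def __post_init__(self) -> None:
        seen_wells: set[tuple[str, str, str]] = set()
        for cid, info in self.entries.items():
            if cid != info.chamber:
                raise ValidationError(
                    f"chamber key {cid!r} != entry id {info.chamber!r}"
                )
            well_index(info.well)  # validates
            key = (info.run, info.plate, info.well)
            if key in seen_wells:
                raise ValidationError(
                    f"well {info.well} duplicated on plate {info.plate} "
                    f"of run {info.run}"
                )
            seen_wells.add(key)

    def by_well(self, run: str, plate: str, well: str) -> ChamberInfo | None:
        for info in self.entries.values():
            if (info.run, info.plate, info.well) == (run, plate, well):
                return info
        return None

    def __len__(self) -> int:
        return len(self.entries)


_CHAMBER_MAP_COLUMNS = (
    "chamber", "plant", "genotype", "treatment", "run", "block", "well",
)


def read_chamber_map(path: str | Path) -> ChamberMap:
    df = _read_csv(path)
    _require_columns(df, _CHAMBER_MAP_COLUMNS, path)
    if "plate" not in df.columns:
        df = df.assign(plate="P1")
    entries = {}
    for _, row in df.iterrows():
        cid = str(row["chamber"])
        if cid in entries:
            raise ValidationError(f"duplicate chamber id {cid!r} in {path}")
        entries[cid] = ChamberInfo(
            chamber=cid,
            plant=str(row["plant"]),
            genotype=str(row["genotype"]),
            treatment=str(row["treatment"]),
            run=str(row["run"]),
            block=str(row["block"]),
            well=str(row["well"]),
            plate=str(row["plate"]),
        )
    return ChamberMap(entries)


def write_chamber_map(cmap: ChamberMap, path: str | Path) -> None:
    rows = [vars(info) for info in cmap.entries.values()]
    pd.DataFrame(rows).to_csv(path, index=False)


@dataclass
class RawConcentrationTable:
    """Long-format (chamber, time_h, ion, conc_um) concentration records."""

    data: pd.DataFrame
    source: str = ""
    instrument: str = ""
    orphan_wells: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        required = {"chamber", "time_h", "ion", "conc_um"}
        missing = required - set(self.data.columns)
        if missing:
            raise FormatError(f"concentration table missing columns {sorted(missing)}")
        if (self.data["time_h"] < 0).any():
            raise ValidationError("negative sampling time")
        if (self.data["conc_um"] < 0).any():
            raise ValidationError("negative concentration")
        if self.data.duplicated(["chamber", "time_h", "ion"]).any():
            dupes = self.data[
                self.data.duplicated(["chamber", "time_h", "ion"], keep=False)
            ]
            raise ValidationError(
                "duplicate (chamber, time, ion) rows: "
                f"{dupes[['chamber', 'time_h', 'ion']].head().to_dict('records')}"
            )


def _read_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"file not found: {path}")
    return pd.read_csv(path, dtype=str, keep_default_na=True)


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


_STRICT_NUMBER_RE = re.compile(r"^[+-]?(\d+(\.\d*)?|\.\d+)([eE][+-]?\d+)?$")


def _parse_numeric(series: pd.Series, column: str, path) -> pd.Series:
    """Strict float parsing with row-level errors (header is line 1)."""
    out = np.full(len(series), np.nan)
    for i, (idx, raw) in enumerate(series.items()):
        if raw is None or (isinstance(raw, float) and np.isnan(raw)):
            continue
        text = str(raw).strip()
        if text == "" or text.lower() == "nan":
            continue
        if not _STRICT_NUMBER_RE.match(text):
            raise FormatError(
                f"{path}, line {int(idx) + 2}, column {column!r}: "
                f"non-numeric value {text!r} (decimal commas and thousands "
                "separators are not accepted)"
            )
        out[i] = float(text)
    return pd.Series(out, index=series.index)


def read_ic_export(
    path: str | Path,
    dialect: str,
    chamber_map: ChamberMap | None = None,
    run: str | None = None,
    plate: str = "P1",
    instrument: str = "",
) -> RawConcentrationTable:
    """Parse an ion-chromatography concentration export into long format.

    ``dialect='long'`` expects columns (chamber | well), time_h, ion,
    conc_um; ``dialect='wide'`` expects (chamber | well), time_h and one
    column per ion. Files keyed by collection-plate well require a
    ``chamber_map`` (and ``run`` when the map spans several runs); wells
    absent from the map are excluded and reported in ``orphan_wells``.
    """
    df = _read_csv(path)
    if dialect not in ("wide", "long"):
        raise FormatError(f"unknown IC export dialect {dialect!r}")

    key_col = "chamber" if "chamber" in df.columns else "well"
    if key_col == "well" and "well" not in df.columns:
        raise FormatError(f"{path}: need a 'chamber' or 'well' column")

    if dialect == "long":
        _require_columns(df, (key_col, "time_h", "ion", "conc_um"), path)
        long = df[[key_col, "time_h", "ion", "conc_um"]].copy()
    else:
        _require_columns(df, (key_col, "time_h"), path)
        ion_cols = [c for c in df.columns if c not in (key_col, "time_h", "well", "chamber")]
        if not ion_cols:
            raise FormatError(f"{path}: wide export has no ion columns")
        long = df.melt(
            id_vars=[key_col, "time_h"],
            value_vars=ion_cols,
            var_name="ion",
            value_name="conc_um",
        )

    long["time_h"] = _parse_numeric(long["time_h"], "time_h", path)
    long["conc_um"] = _parse_numeric(long["conc_um"], "conc_um", path)

    orphans: list[str] = []
    if key_col == "well":
        if chamber_map is None:
            raise FormatError(f"{path}: well-keyed export requires a chamber map")
        mapped = []
        for well in long["well"].unique():
            info = chamber_map.by_well(run or "1", plate, str(well))
            if info is None:
                orphans.append(str(well))
            else:
                mapped.append((str(well), info.chamber))
        well_to_chamber = dict(mapped)
        if orphans:
            logger.warning(
                "%s: wells not in chamber map, excluded: %s", path, sorted(orphans)
            )
        long = long[long["well"].isin(well_to_chamber)].copy()
        long["chamber"] = long["well"].map(well_to_chamber)
        long = long.drop(columns=["well"])

    long = long.dropna(subset=["conc_um"]).reset_index(drop=True)
    long = long[["chamber", "time_h", "ion", "conc_um"]]
    long["chamber"] = long["chamber"].astype(str)
    long["ion"] = long["ion"].astype(str)
    return RawConcentrationTable(
        data=long,
        source=str(path),
        instrument=instrument,
        orphan_wells=sorted(orphans),
    )


def write_ic_export(table: RawConcentrationTable, path: str | Path) -> None:
    """Write a concentration table back out in the canonical long dialect."""
    table.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Root trait tables
# ---------------------------------------------------------------------------

_CLASSIFIED_LENGTH_COLUMNS = (
    "seminal_length_cm",
    "lateral_length_cm",
    "secondary_lateral_length_cm",
)
_OPTIONAL_PLANT_COLUMNS = {
    "root_dw_g": "root_dw",
    "leaf_dw_g": "leaf_dw",
    "stem_dw_g": "stem_dw",
    "respiration_nmol_s": "total_respiration",
    "leaf_area_cm2": "leaf_area",
    "leaf_length_cm": "leaf_length",
}
_META_PLANT_COLUMNS = ("genotype", "treatment", "run", "block")


def read_root_traits(
    path: str | Path, mode: str = "classified"
) -> dict[str, PlantRecord]:
    """Read per-plant root measurements.

    ``mode='classified'`` expects one row per plant with the three class
    lengths (WinRhizo-style post-classification); ``mode='binned'`` expects
    (plant, diameter_mm, length_cm) rows which are aggregated through the
    diameter-threshold classifier. Dry weights and the other plant
    measurements are read when their columns are present.
    """
    df = _read_csv(path)
    if df.empty:
        logger.warning("%s: empty root-trait file", path)
        return {}
    records: dict[str, PlantRecord] = {}

    if mode == "classified":
        _require_columns(df, ("plant",) + _CLASSIFIED_LENGTH_COLUMNS, path)
        for col in _CLASSIFIED_LENGTH_COLUMNS:
            df[col] = _parse_numeric(df[col], col, path)
        for col in _OPTIONAL_PLANT_COLUMNS:
            if col in df.columns:
                df[col] = _parse_numeric(df[col], col, path)
        if (df[list(_CLASSIFIED_LENGTH_COLUMNS)].fillna(0) < 0).any().any():
            raise ValidationError(f"{path}: negative root length")
        for _, row in df.iterrows():
            kwargs = {}
            for col, attr in _OPTIONAL_PLANT_COLUMNS.items():
                if col in df.columns and not pd.isna(row[col]):
                    kwargs[attr] = float(row[col])
            for col in _META_PLANT_COLUMNS:
                if col in df.columns and not pd.isna(row[col]):
                    kwargs[col] = str(row[col])
            records[str(row["plant"])] = PlantRecord(
                plant=str(row["plant"]),
                seminal_length=float(row["seminal_length_cm"]),
                lateral_length=float(row["lateral_length_cm"]),
                secondary_lateral_length=float(row["secondary_lateral_length_cm"]),
                **kwargs,
            )
    elif mode == "binned":
        _require_columns(df, ("plant", "diameter_mm", "length_cm"), path)
        df["diameter_mm"] = _parse_numeric(df["diameter_mm"], "diameter_mm", path)
        df["length_cm"] = _parse_numeric(df["length_cm"], "length_cm", path)
        if (df["length_cm"].fillna(0) < 0).any():
            raise ValidationError(f"{path}: negative root length")
        for plant, group in df.groupby("plant", sort=True):
            histogram = dict(zip(group["diameter_mm"], group["length_cm"]))
            classes = classify_root_lengths(histogram)
            records[str(plant)] = PlantRecord(
                plant=str(plant),
                seminal_length=classes.seminal,
                lateral_length=classes.lateral,
                secondary_lateral_length=classes.secondary_lateral,
            )
    else:
        raise FormatError(f"unknown root-trait mode {mode!r}")
    return records


# ---------------------------------------------------------------------------
# Trait table
# ---------------------------------------------------------------------------

_TRAIT_TABLE_COLUMNS = list(METADATA_COLUMNS) + list(TRAIT_COLUMNS) + ["qc_flags"]


def write_trait_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the standardized trait table plus a JSON schema sidecar.

    Column order is canonical and stable; a ``<path>.schema.json`` sidecar
    documents units and the schema version so the file round-trips exactly.
    """
    path = Path(path)
    extra = [c for c in table.columns if c not in _TRAIT_TABLE_COLUMNS]
    missing = [c for c in _TRAIT_TABLE_COLUMNS if c not in table.columns]
    if extra or missing:
        raise FormatError(
            f"trait table schema mismatch: unexpected {extra}, missing {missing}"
        )
    # %.17g guarantees exact float64 round-trips
    table[_TRAIT_TABLE_COLUMNS].to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "metadata_columns": list(METADATA_COLUMNS),
        "trait_columns": list(TRAIT_COLUMNS),
        "units": TRAIT_UNITS,
    }
    Path(f"{path}.schema.json").write_text(json.dumps(sidecar, indent=1))


def read_trait_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        dtype={c: str for c in METADATA_COLUMNS},
        float_precision="round_trip",
    )
    missing = [c for c in _TRAIT_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing trait column(s) {missing}")
    return df[_TRAIT_TABLE_COLUMNS]


# ---------------------------------------------------------------------------
# Experiment config
# ---------------------------------------------------------------------------


@dataclass
class ExperimentConfig:
    """Experiment block: sampling schedule, chamber geometry, capacity."""

    schedule_h: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0, 3.0, 4.0, 6.0, 8.0)
    chamber_volume_ml: float = 250.0
    sample_volume_ml: float = 1.5
    modules: int = 2
    chambers_per_module: int = 24
    depletion_threshold: float = 0.10

    @property
    def plants_per_run(self) -> int:
        return self.modules * self.chambers_per_module


def read_experiment_config(path: str | Path) -> ExperimentConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    exp = doc.get("experiment", doc)
    return ExperimentConfig(
        schedule_h=tuple(float(t) for t in exp.get("schedule_h", ExperimentConfig.schedule_h)),
        chamber_volume_ml=float(exp.get("chamber_volume_ml", 250.0)),
        sample_volume_ml=float(exp.get("sample_volume_ml", 1.5)),
        modules=int(exp.get("modules", 2)),
        chambers_per_module=int(exp.get("chambers_per_module", 24)),
        depletion_threshold=float(exp.get("depletion_threshold", 0.10)),
    )


def write_experiment_config(cfg: ExperimentConfig, path: str | Path) -> None:
    doc = {
        "experiment": {
            "schedule_h": list(cfg.schedule_h),
            "chamber_volume_ml": cfg.chamber_volume_ml,
            "sample_volume_ml": cfg.sample_volume_ml,
            "modules": cfg.modules,
            "chambers_per_module": cfg.chambers_per_module,
            "depletion_threshold": cfg.depletion_threshold,
        }
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
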