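"""Net influx, specific uptake rates and depletion-interval selection.

The depletion method treats the fall of a nutrient's concentration in a
closed, stirred chamber as equal to the root system's net uptake (influx
minus efflux). For a chamber of volume ``V`` sampled at times ``t_0`` and
``t`` the net influx is

    I_n = (C_0 - C_t) * V / (t - t_0)        [µmol h⁻¹]

which, divided by total root length (cm) or root dry weight (g), gives the
specific uptake rate (SUR) in µmol cm⁻¹ h⁻¹ or µmol g⁻¹ h⁻¹.

The sampling interval is chosen by the measurable-depletion rule: the
earliest scheduled time at which *every* focal ion has been depleted by at
least a threshold fraction (default 10%) of its starting concentration.
Under the standard high/low treatment design this rule lands on the 1 h
sample for the low solution and the 4 h sample for the high solution.

Internal units throughout: µM, h, cm, g, mL, µmol (respiration in nmol CO₂).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: QC flag vocabulary
FLAG_EFFLUX = "efflux"
FLAG_FALLBACK_INTERVAL = "fallback_interval"
FLAG_OVERSIZE_DIAMETER = "oversize_diameter"


@dataclass
class DepletionSeries:
    """Concentration-vs-time record for one (chamber, ion).

    ``times`` must be strictly increasing (h); ``volume`` is the initial
    chamber volume (mL) and ``sample_volume`` the volume withdrawn per draw.
    """

    chamber: str
    ion: str
    times: np.ndarray
    concentrations: np.ndarray
    volume: float = 250.0
    sample_volume: float = 1.5

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.concentrations.shape:
            raise ValidationError(
                f"{self.chamber}/{self.ion}: times and concentrations must be "
                "1-D and equally long"
            )
        if len(self.times) < 2:
            raise ValidationError(
                f"{self.chamber}/{self.ion}: need at least 2 timepoints"
            )
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError(
                f"{self.chamber}/{self.ion}: times must be strictly increasing"
            )
        if np.any(self.times < 0):
            raise ValidationError(f"{self.chamber}/{self.ion}: negative time")
        if np.any(self.concentrations < 0):
            raise ValidationError(
                f"{self.chamber}/{self.ion}: negative concentration"
            )
        if self.volume <= 0:
            raise ValidationError(f"{self.chamber}/{self.ion}: volume must be > 0")

    @property
    def c0(self) -> float:
        """Concentration at the first sampling time (µM)."""
        return float(self.concentrations[0])

    def at(self, t: float) -> float | None:
        """Concentration at time ``t`` or None if not sampled then."""
        idx = np.nonzero(np.isclose(self.times, t))[0]
        return float(self.concentrations[idx[0]]) if idx.size else None


@dataclass
class PlantRecord:
    """One plant's structural and physiological measurements.

    Root class lengths follow the diameter-threshold classification
    (seminal: coarsest, secondary-lateral: finest); ``total_root_length``
    defaults to the sum of the classes.
    """

    plant: str
    genotype: str = ""
    treatment: str = ""
    run: str = ""
    block: str = ""
    seminal_length: float = 0.0
    lateral_length: float = 0.0
    secondary_lateral_length: float = 0.0
    total_root_length: float | None = None
    root_dw: float | None = None
    leaf_dw: float | None = None
    stem_dw: float | None = None
    total_respiration: float | None = None  # nmol CO2 s^-1
    leaf_area: float | None = None  # cm^2
    leaf_length: float | None = None  # cm

    def __post_init__(self) -> None:
        for name in ("seminal_length", "lateral_length", "secondary_lateral_length"):
            if getattr(self, name) < 0:
                raise ValidationError(f"plant {self.plant}: negative {name}")
        class_sum = (
            self.seminal_length + self.lateral_length + self.secondary_lateral_length
        )
        if self.total_root_length is None:
            self.total_root_length = class_sum
        elif not math.isclose(self.total_root_length, class_sum, rel_tol=1e-6, abs_tol=1e-6):
            raise ValidationError(
                f"plant {self.plant}: total root length {self.total_root_length} "
                f"!= sum of classes {class_sum}"
            )
        for name in ("root_dw", "leaf_dw", "stem_dw"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"plant {self.plant}: negative {name}")


@dataclass
class Interval:
    """Selected uptake interval with its selection status."""

    t0: float
    t1: float
    fallback: bool = False


@dataclass
class UptakeRecord:
    """Per-plant, per-ion uptake quantities over one interval."""

    plant: str
    ion: str
    t0: float
    t1: float
    net_influx: float  # µmol h^-1
    sur_length: float | None  # µmol cm^-1 h^-1
    sur_mass: float | None  # µmol g^-1 h^-1
    fractional_depletion: float
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Interval selection
# ---------------------------------------------------------------------------


def select_interval(
    series_by_ion: dict[str, DepletionSeries], threshold: float = 0.10
) -> Interval:
    """Earliest time at which every ion is depleted by >= ``threshold``.

    Evaluates the fractional depletion ``(C_0 - C_t) / C_0`` of each series
    at each scheduled time after the start; a time qualifies only if every
    ion was sampled there and every ion's depletion meets the threshold.
    If no time qualifies the last sampled time is returned with the
    ``fallback`` flag set so downstream QC can report it.
    """
    if not series_by_ion:
        raise ValidationError("no depletion series supplied")
    for ion, s in series_by_ion.items():
        if s.c0 == 0:
            raise ValidationError(
                f"ion {ion!r}: starting concentration is 0, depletion "
                "fraction undefined"
            )
    t_start = max(s.times[0] for s in series_by_ion.values())
    candidates = sorted(
        {float(t) for s in series_by_ion.values() for t in s.times if t > t_start}
    )
    for t in candidates:
        ok = True
        for s in series_by_ion.values():
            ct = s.at(t)
            if ct is None or (s.c0 - ct) / s.c0 < threshold:
                ok = False
                break
        if ok:
            return Interval(t0=float(t_start), t1=t, fallback=False)
    return Interval(t0=float(t_start), t1=candidates[-1], fallback=True)


# ---------------------------------------------------------------------------
# Rate arithmetic
# ---------------------------------------------------------------------------


def net_influx(
    c0: float, ct: float, t0: float, t: float, volume: float = 250.0
) -> float:
    """Net influx in µmol h⁻¹ from a two-point concentration difference.

    Positive when the solution is depleted (net uptake); negative values
    indicate net efflux and are retained, flagged by callers.
    """
    if t <= t0:
        raise ValidationError(f"interval must be positive, got t0={t0}, t={t}")
    if volume <= 0:
        raise ValidationError(f"volume must be > 0, got {volume}")
    return (c0 - ct) * (volume / 1000.0) / (t - t0)


def specific_rate(influx: float, denominator: float) -> float:
    """Specific uptake rate: influx divided by root length (cm) or mass (g)."""
    if denominator <= 0:
        raise ValidationError(
            f"normalization denominator must be > 0, got {denominator}"
        )
    return influx / denominator


def specific_respiration(total_resp: float, total_root_length: float) -> float:
    """Specific root respiration in nmol CO₂ m⁻¹ s⁻¹ (length given in cm)."""
    if total_root_length <= 0:
        raise ValidationError(
            f"total root length must be > 0, got {total_root_length}"
        )
    return total_resp / (total_root_length / 100.0)


def specific_root_length(total_root_length: float, root_dw: float) -> float:
    """Specific root length in cm g⁻¹."""
    if root_dw <= 0:
        raise ValidationError(f"root dry weight must be > 0, got {root_dw}")
    return total_root_length / root_dw


# ---------------------------------------------------------------------------
# Root diameter classification
# ---------------------------------------------------------------------------

#: class name -> (low, high) diameter interval in mm; half-open [low, high)
#: except the coarsest class which is closed at the top. A bin landing
#: exactly on a threshold goes to the coarser class.
DIAMETER_CLASSES: dict[str, tuple[float, float]] = {
    "secondary_lateral": (0.0, 0.15),
    "lateral": (0.15, 0.8),
    "seminal": (0.8, 4.25),
}


@dataclass
class ClassifiedRootLengths:
    seminal: float
    lateral: float
    secondary_lateral: float
    oversize: float = 0.0
    flags: list[str] = field(default_factory=list)

    @property
    def total(self) -> float:
        return self.seminal + self.lateral + self.secondary_lateral


def classify_root_lengths(
    histogram: dict[float, float]
) -> ClassifiedRootLengths:
    """Sum diameter-binned root lengths into the three order classes.

    ``histogram`` maps bin diameter (mm) to length (cm). Bins with diameter
    above 4.25 mm are excluded from all classes and flagged.
    """
    sums = {"seminal": 0.0, "lateral": 0.0, "secondary_lateral": 0.0}
    oversize = 0.0
    for diameter, length in histogram.items():
        if diameter < 0:
            raise ValidationError(f"negative diameter {diameter}")
        if length < 0:
            raise ValidationError(f"negative length {length} at {diameter} mm")
        if diameter > DIAMETER_CLASSES["seminal"][1]:
            oversize += length
            continue
        if diameter >= DIAMETER_CLASSES["seminal"][0]:
            sums["seminal"] += length
        elif diameter >= DIAMETER_CLASSES["lateral"][0]:
            sums["lateral"] += length
        else:
            sums["secondary_lateral"] += length
    flags = [FLAG_OVERSIZE_DIAMETER] if oversize > 0 else []
    return ClassifiedRootLengths(
        seminal=sums["seminal"],
        lateral=sums["lateral"],
        secondary_lateral=sums["secondary_lateral"],
        oversize=oversize,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# Chamber-level orchestration
# ---------------------------------------------------------------------------


def _ledger_influx(series: DepletionSeries, t0: float, t1: float) -> float:
    """Net influx with an explicit volume ledger for sample withdrawal.

    Each draw permanently removes ``sample_volume`` mL at the concentration
    prevailing at the draw; the chamber volume shrinks accordingly. The
    plant's uptake over (t0, t1] is the amount no longer accounted for by
    the remaining solution plus the withdrawn samples.
    """
    times, concs = series.times, series.concentrations
    i0 = int(np.nonzero(np.isclose(times, t0))[0][0])
    i1 = int(np.nonzero(np.isclose(times, t1))[0][0])
    vs = series.sample_volume / 1000.0  # L
    v0 = series.volume / 1000.0 - i0 * vs  # L remaining just after draw at t0
    sampled = sum(concs[j] * vs for j in range(i0 + 1, i1))
    v1 = series.volume / 1000.0 - i1 * vs  # just before accounting draw at t1
    taken_up = concs[i0] * v0 - concs[i1] * (v1 + vs) - sampled
    return taken_up / (t1 - t0)


def compute_uptake(
    series_by_ion: dict[str, DepletionSeries],
    plant: PlantRecord,
    threshold: float = 0.10,
    volume_ledger: bool = False,
    interval: Interval | None = None,
) -> list[UptakeRecord]:
    """Uptake records for every ion of one chamber over the selected interval.

    The interval is chosen once per chamber across all focal-ion series
    (pass ``interval`` to override). ``volume_ledger=True`` switches from the
    constant-volume two-point rate to the sample-withdrawal-corrected
    amount balance.
    """
    if interval is None:
        interval = select_interval(series_by_ion, threshold=threshold)
    records: list[UptakeRecord] = []
    for ion in sorted(series_by_ion):
        s = series_by_ion[ion]
        ct = s.at(interval.t1)
        if ct is None:
            continue  # ion not sampled at the selected time; QC upstream
        if volume_ledger:
            influx = _ledger_influx(s, interval.t0, interval.t1)
        else:
            influx = net_influx(s.c0, ct, interval.t0, interval.t1, s.volume)
        flags: list[str] = []
        if influx < 0:
            flags.append(FLAG_EFFLUX)
        if interval.fallback:
            flags.append(FLAG_FALLBACK_INTERVAL)
        sur_l = (
            specific_rate(influx, plant.total_root_length)
            if plant.total_root_length and plant.total_root_length > 0
            else None
        )
        sur_m = (
            specific_rate(influx, plant.root_dw)
            if plant.root_dw and plant.root_dw > 0
            else None
        )
        records.append(
            UptakeRecord(
                plant=plant.plant,
                ion=ion,
                t0=interval.t0,
                t1=interval.t1,
                net_influx=influx,
                sur_length=sur_l,
                sur_mass=sur_m,
                fractional_depletion=(s.c0 - ct) / s.c0 if s.c0 > 0 else float("nan"),
                flags=flags,
            )
        )
    return records
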