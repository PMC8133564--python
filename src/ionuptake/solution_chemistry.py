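"""Salt-based nutrient recipes resolved to ionic compositions.

A hydroponic uptake experiment is designed around solution recipes: lists of
salts at molar concentrations. Uptake arithmetic, however, runs on *ions* —
the starting concentration ``C_0`` of nitrate, ammonium, potassium, phosphate
(dihydrogen phosphate, reported as "phosphate") and sulfate in each chamber.
This module expands recipes into ionic compositions by stoichiometry and
verifies the design constraints the experiment relies on: calcium held
constant across treatment solutions (membrane-potential control) and a fixed
fold-difference in macronutrients between the high and low solutions
(high- vs low-affinity transport contrast).

Hydration water in salt formulas is ignored; charge balance is reported
informationally, never enforced (buffers and pH adjustment are not part of
the stoichiometry).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import yaml

from .errors import ConfigurationError, ValidationError

#: The five macronutrient ions analysed by the uptake pipeline.
FOCAL_IONS: tuple[str, ...] = (
    "ammonium",
    "nitrate",
    "phosphate",
    "potassium",
    "sulfate",
)

#: Ions subject to the high:low fold-difference design rule (the focal five
#: plus magnesium, which is also stepped 10-fold between the solutions).
MACRONUTRIENT_IONS: tuple[str, ...] = FOCAL_IONS + ("magnesium",)

#: Elementary charge per ion, for the informational charge-balance report.
ION_CHARGE: dict[str, int] = {
    "ammonium": +1,
    "potassium": +1,
    "calcium": +2,
    "magnesium": +2,
    "zinc": +2,
    "manganese": +2,
    "copper": +2,
    "iron": +3,
    "nitrate": -1,
    "chloride": -1,
    "phosphate": -1,  # dihydrogen phosphate, H2PO4-
    "sulfate": -2,
    "borate": 0,  # boric acid is essentially undissociated at pH 6
    "molybdate": -6,  # heptamolybdate carries -6 per formula unit; per-Mo share
    "edta": -3,
    "mes": 0,
}


@dataclass(frozen=True)
class SaltSpec:
    """One salt in a recipe.

    Parameters
    ----------
    name:
        Formula label, unique within a recipe.
    concentration:
        Salt concentration in µM.
    ions:
        Ion identifier -> stoichiometric count per formula unit
        (e.g. ``{"calcium": 1, "phosphate": 2}`` for Ca(H2PO4)2·H2O).
    trace:
        Micronutrient flag; trace salts are excluded from focal-ion totals.
    """

    name: str
    concentration: float
    ions: Mapping[str, float]
    trace: bool = False

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValidationError(
                f"salt {self.name!r}: concentration must be >= 0, "
                f"got {self.concentration}"
            )
        if not self.ions or not any(n >= 1 for n in self.ions.values()):
            raise ValidationError(
                f"salt {self.name!r}: needs at least one ion with count >= 1"
            )
        if any(n < 0 for n in self.ions.values()):
            raise ValidationError(f"salt {self.name!r}: negative stoichiometry")


@dataclass
class SolutionRecipe:
    """A labelled nutrient solution: salts, pH and an optional buffer."""

    label: str
    salts: list[SaltSpec]
    ph: float = 6.0
    buffer: SaltSpec | None = None

    def __post_init__(self) -> None:
        names = [s.name for s in self.salts]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(
                f"recipe {self.label!r}: duplicate salt names {dupes}"
            )


#: ion identifier -> total concentration in µM
IonComposition = dict[str, float]


def compose_ions(
    recipe: SolutionRecipe, *, include_trace: bool = True
) -> IonComposition:
    """Total molar concentration per ion, additive over salts.

    With ``include_trace=False`` micronutrient salts are skipped, which is
    the convention for focal-ion starting concentrations (the trace ammonium
    carried by ammonium heptamolybdate is recorded in the recipe but does not
    count as macronutrient supply).
    """
    comp: IonComposition = {}
    for salt in recipe.salts:
        if salt.trace and not include_trace:
            continue
        for ion, count in salt.ions.items():
            comp[ion] = comp.get(ion, 0.0) + salt.concentration * count
    return comp


def focal_composition(recipe: SolutionRecipe) -> IonComposition:
    """Starting concentrations of the five focal ions (trace salts excluded)."""
    comp = compose_ions(recipe, include_trace=False)
    return {ion: comp.get(ion, 0.0) for ion in FOCAL_IONS}


def fold_difference(
    a: IonComposition, b: IonComposition, ions: Iterable[str]
) -> dict[str, float]:
    """Per-ion concentration ratio ``a[ion] / b[ion]``.

    Raises
    ------
    ValidationError
        If an ion is missing from either composition or has zero
        concentration in the denominator.
    """
    out: dict[str, float] = {}
    for ion in ions:
        if ion not in a or ion not in b:
            raise ValidationError(f"ion {ion!r} missing from a composition")
        if b[ion] == 0:
            raise ValidationError(
                f"ion {ion!r}: zero concentration in denominator composition"
            )
        out[ion] = a[ion] / b[ion]
    return out


def charge_balance(comp: IonComposition) -> float:
    """Net charge of a composition in µeq/L (informational only)."""
    return sum(conc * ION_CHARGE.get(ion, 0) for ion, conc in comp.items())


# ---------------------------------------------------------------------------
# Design rules
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConstantIonRule:
    """An ion must sit at a fixed concentration in every listed recipe."""

    ion: str
    labels: tuple[str, ...]
    expected_um: float
    rel_tol: float = 1e-9

    @property
    def name(self) -> str:
        return f"{self.ion} constant at {self.expected_um:g} µM"


@dataclass(frozen=True)
class FoldRule:
    """Listed ions must differ by a fixed fold between two recipes."""

    numerator_label: str
    denominator_label: str
    ions: tuple[str, ...]
    expected_fold: float
    rel_tol: float = 1e-9

    @property
    def name(self) -> str:
        return (
            f"{self.expected_fold:g}x {self.numerator_label}:"
            f"{self.denominator_label} for {', '.join(self.ions)}"
        )


@dataclass
class RuleResult:
    rule: str
    passed: bool
    values: dict[str, float]
    message: str = ""


def check_design(
    recipes: Iterable[SolutionRecipe],
    rules: Iterable[ConstantIonRule | FoldRule],
) -> list[RuleResult]:
    """Evaluate design rules against a set of recipes.

    Returns one :class:`RuleResult` per rule, pass/fail with the computed
    concentrations or ratios. An unknown recipe label in a rule is a
    configuration error, not a failed rule.
    """
    by_label = {r.label: r for r in recipes}
    comps = {label: compose_ions(r) for label, r in by_label.items()}
    results: list[RuleResult] = []
    for rule in rules:
        if isinstance(rule, ConstantIonRule):
            missing = [lab for lab in rule.labels if lab not in by_label]
            if missing:
                raise ConfigurationError(
                    f"rule {rule.name!r}: unknown recipe label(s) {missing}"
                )
            values = {
                lab: comps[lab].get(rule.ion, 0.0) for lab in rule.labels
            }
            ok = all(
                abs(v - rule.expected_um)
                <= rule.rel_tol * max(1.0, abs(rule.expected_um))
                for v in values.values()
            )
            msg = "" if ok else (
                f"expected {rule.expected_um:g} µM, got "
                + ", ".join(f"{lab}={v:g}" for lab, v in values.items())
            )
            results.append(RuleResult(rule.name, ok, values, msg))
        elif isinstance(rule, FoldRule):
            for lab in (rule.numerator_label, rule.denominator_label):
                if lab not in by_label:
                    raise ConfigurationError(
                        f"rule {rule.name!r}: unknown recipe label {lab!r}"
                    )
            ratios = fold_difference(
                comps[rule.numerator_label],
                comps[rule.denominator_label],
                rule.ions,
            )
            ok = all(
                abs(v - rule.expected_fold) <= rule.rel_tol * rule.expected_fold
                for v in ratios.values()
            )
            msg = "" if ok else (
                f"expected {rule.expected_fold:g}x, got "
                + ", ".join(f"{ion}={v:g}" for ion, v in ratios.items())
            )
            results.append(RuleResult(rule.name, ok, ratios, msg))
        else:  # pragma: no cover - defensive
            raise ConfigurationError(f"unknown rule type {type(rule)!r}")
    return results


def default_design_rules() -> list[ConstantIonRule | FoldRule]:
    """The two constraints the treatment solutions are built around."""
    return [
        ConstantIonRule(ion="calcium", labels=("high", "low"), expected_um=500.0),
        FoldRule(
            numerator_label="high",
            denominator_label="low",
            ions=MACRONUTRIENT_IONS,
            expected_fold=10.0,
        ),
    ]


# ---------------------------------------------------------------------------
# Recipe file I/O
# ---------------------------------------------------------------------------


def _salt_from_dict(d: Mapping) -> SaltSpec:
    try:
        return SaltSpec(
            name=str(d["name"]),
            concentration=float(d["umol_per_l"]),
            ions={str(k): float(v) for k, v in d["ions"].items()},
            trace=bool(d.get("trace", False)),
        )
    except KeyError as exc:
        raise ConfigurationError(f"salt entry missing field {exc}") from exc


def load_recipes(path: str | None = None) -> dict[str, SolutionRecipe]:
    """Load recipes from a YAML file; defaults to the packaged recipe set.

    The packaged set carries the four standard solutions: ``growth``
    (modified half-strength complete solution), ``deprivation``
    (macronutrient-free), and the ``high`` / ``low`` treatment solutions.
    """
    if path is None:
        text = (
            resources.files("ionuptake.data").joinpath("recipes.yaml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "recipes" not in doc:
        raise ConfigurationError("recipe file must have a top-level 'recipes' list")
    out: dict[str, SolutionRecipe] = {}
    for entry in doc["recipes"]:
        label = str(entry["label"])
        if label in out:
            raise ConfigurationError(f"duplicate recipe label {label!r}")
        buffer = (
            _salt_from_dict(entry["buffer"]) if entry.get("buffer") else None
        )
        out[label] = SolutionRecipe(
            label=label,
            salts=[_salt_from_dict(s) for s in entry.get("salts", [])],
            ph=float(entry.get("ph", 6.0)),
            buffer=buffer,
        )
    return out
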