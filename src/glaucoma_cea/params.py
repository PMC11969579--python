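"""Parameter registry: definition, validation, loading and serving of model inputs.

Every quantity consumed anywhere in the model resolves to exactly one named
entry here.  Each entry is a :class:`ParameterSpec` carrying a point value, an
optional plausible range for deterministic sensitivity analysis, and a
probabilistic-sensitivity distribution family (beta for probabilities and
utilities, gamma for costs and other non-negative quantities) parameterised by
a standard error.

Parameter files are hierarchical YAML; a life table (CSV with columns
``age,qx``, one-year ages) rides alongside and is referenced from the YAML via
``mortality.life_table_file``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .states import DISEASED_STAGES, stage_param_key

__all__ = [
    "ParameterSpec",
    "ParameterSet",
    "SchemaError",
    "ValidationError",
    "InfeasibleMomentsError",
    "load_parameters",
    "save_parameters",
    "dsa_range",
    "psa_distribution",
    "PARAM_SCHEMA",
]


class SchemaError(KeyError):
    """A mandatory parameter is missing or unknown keys are present."""


class ValidationError(ValueError):
    """A parameter value violates its bounds or a cross-parameter invariant."""


class InfeasibleMomentsError(ValueError):
    """A beta distribution was requested with se**2 >= value*(1-value)."""


# ---------------------------------------------------------------------------
# Schema
# ---------------------------------------------------------------------------

# kind -> (bounds, default PSA family, default DSA half-width as a fraction)
_KIND_RULES: dict[str, tuple[tuple[float, float], str, float]] = {
    "probability": ((0.0, 1.0), "beta", 0.10),
    "utility": ((0.0, 1.0), "beta", 0.10),
    "cost": ((0.0, math.inf), "gamma", 0.50),
    "positive": ((0.0, math.inf), "gamma", 0.10),
    "fixed": ((-math.inf, math.inf), "fixed", 0.0),
}


@dataclass(frozen=True)
class ParamDef:
    kind: str
    provenance: str = "synthetic"


def _schema() -> dict[str, ParamDef]:
    main = "paper_main_text"
    placeholder = "paper_supplementary_placeholder"
    s: dict[str, ParamDef] = {
        # demographics / economics (held fixed in PSA)
        "demographics.start_age": ParamDef("fixed", main),
        "demographics.max_age": ParamDef("fixed"),
        "demographics.cohort_size": ParamDef("fixed", main),
        "economics.discount_rate": ParamDef("fixed", main),
        "economics.wtp": ParamDef("fixed", main),
        "economics.wtp_high": ParamDef("fixed", main),
        # screening cascade
        "screening.coverage": ParamDef("probability", main),
        "screening.ltfu_diagnosis": ParamDef("probability", main),
        "screening.ltfu_treatment": ParamDef("probability", main),
        "screening.ungradable_rate": ParamDef("probability", main),
        "screening.sens_tonometry": ParamDef("probability", placeholder),
        "screening.spec_tonometry": ParamDef("probability", placeholder),
        "screening.sens_fundus_f2f": ParamDef("probability", placeholder),
        "screening.spec_fundus_f2f": ParamDef("probability", placeholder),
        "screening.sens_fundus_ai": ParamDef("probability", placeholder),
        "screening.spec_fundus_ai": ParamDef("probability", placeholder),
        "screening.sens_flashlight": ParamDef("probability", placeholder),
        "screening.spec_flashlight": ParamDef("probability", placeholder),
        # usual-care (opportunistic) pathway
        "usual_care.consult_prob": ParamDef("probability", main),
        "usual_care.treat_prob": ParamDef("probability", main),
        # epidemiology
        "epi.incidence_oht": ParamDef("probability", main),
        "epi.incidence_poag": ParamDef("probability", main),
        "epi.incidence_pacs": ParamDef("probability", main),
        "epi.treatment_rr_poag": ParamDef("positive", placeholder),
        "epi.treatment_rr_pacd": ParamDef("positive", placeholder),
        "epi.high_risk_fraction": ParamDef("probability", placeholder),
        "epi.high_risk_rr": ParamDef("positive", placeholder),
        # mortality
        "mortality.blindness_multiplier_unilateral": ParamDef("positive", main),
        "mortality.blindness_multiplier_bilateral": ParamDef("positive", main),
        # screening-programme costs
        "cost.screening.variable_f2f": ParamDef("cost", placeholder),
        "cost.screening.ai_scan": ParamDef("cost", placeholder),
        "cost.screening.overhead_per_phc_year": ParamDef("cost", placeholder),
        "cost.screening.screened_per_phc_year": ParamDef("fixed", placeholder),
        # confirmatory work-up (outpatient, at higher centres)
        "cost.workup.public_hs": ParamDef("cost", placeholder),
        "cost.workup.public_oope": ParamDef("cost", placeholder),
        "cost.workup.private_oope": ParamDef("cost", placeholder),
        # annual management of a treated patient
        "cost.annual.consult_public_hs": ParamDef("cost", placeholder),
        "cost.annual.consult_public_oope": ParamDef("cost", placeholder),
        "cost.annual.consult_private_oope": ParamDef("cost", placeholder),
        "cost.annual.diagnostics_public_hs": ParamDef("cost", placeholder),
        "cost.annual.diagnostics_public_oope": ParamDef("cost", placeholder),
        "cost.annual.diagnostics_private_oope": ParamDef("cost", placeholder),
        "cost.annual.medicines": ParamDef("cost", placeholder),
        "cost.annual.non_medical": ParamDef("cost", placeholder),
        # one-time surgery at treatment initiation
        "cost.surgery.trabeculectomy_public_hs": ParamDef("cost", placeholder),
        "cost.surgery.trabeculectomy_public_oope": ParamDef("cost", placeholder),
        "cost.surgery.trabeculectomy_private_oope": ParamDef("cost", placeholder),
        "cost.surgery.iridotomy_public_hs": ParamDef("cost", placeholder),
        "cost.surgery.iridotomy_public_oope": ParamDef("cost", placeholder),
        "cost.surgery.iridotomy_private_oope": ParamDef("cost", placeholder),
        "cost.medicine_availability": ParamDef("probability", main),
        # care seeking (sector mix)
        "care_seeking.public_share_outpatient": ParamDef("probability", main),
        "care_seeking.public_share_inpatient": ParamDef("probability", main),
        # comorbidity utilities and population mix
        "utility.comorbidity_none": ParamDef("fixed"),
        "utility.comorbidity_hypertension": ParamDef("utility", placeholder),
        "utility.comorbidity_diabetes": ParamDef("utility", placeholder),
        "utility.comorbidity_both": ParamDef("utility", placeholder),
        "utility.share_none": ParamDef("fixed"),
        "utility.share_hypertension": ParamDef("fixed"),
        "utility.share_diabetes": ParamDef("fixed"),
        "utility.share_both": ParamDef("fixed"),
        "utility.disease_free": ParamDef("utility", placeholder),
    }
    for arm, stage in DISEASED_STAGES:
        key = stage_param_key(arm, stage)
        s[f"epi.prevalence.{key}"] = ParamDef("probability", placeholder)
        s[f"utility.{key}"] = ParamDef("utility", placeholder)
    # annual progression, untreated (stage -> successor)
    for key in (
        "oht_to_mild",
        "mild_to_moderate",
        "moderate_to_severe",
        "severe_to_unilateral",
        "poag_unilateral_to_bilateral",
        "pacs_to_pac",
        "pac_to_pacg",
        "pacg_to_unilateral",
        "pacd_unilateral_to_bilateral",
    ):
        s[f"epi.progression.{key}"] = ParamDef("probability", placeholder)
    return s


PARAM_SCHEMA: dict[str, ParamDef] = _schema()


# ---------------------------------------------------------------------------
# ParameterSpec
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterSpec:
    """One named model input with its uncertainty specification."""

    name: str
    value: float
    kind: str = "fixed"
    low: float | None = None
    high: float | None = None
    se: float | None = None
    dist_family: str = "fixed"
    provenance: str = "synthetic"

    def __post_init__(self) -> None:
        if self.kind not in _KIND_RULES:
            raise ValidationError(f"{self.name}: unknown kind {self.kind!r}")
        (lo, hi), _, _ = _KIND_RULES[self.kind]
        if not (lo <= self.value <= hi):
            raise ValidationError(
                f"{self.name}: value {self.value} outside [{lo}, {hi}] for kind {self.kind}"
            )
        if self.low is not None and self.high is not None:
            if not (self.low <= self.value <= self.high):
                raise ValidationError(
                    f"{self.name}: value {self.value} outside range "
                    f"[{self.low}, {self.high}]"
                )
        if self.se is not None and self.se < 0:
            raise ValidationError(f"{self.name}: se must be >= 0")
        if self.dist_family not in ("beta", "gamma", "fixed"):
            raise ValidationError(f"{self.name}: unknown dist_family {self.dist_family!r}")
        if self.dist_family == "beta" and not (0.0 <= self.value <= 1.0):
            raise ValidationError(f"{self.name}: beta requires a [0,1] value")
        if self.dist_family == "gamma" and self.value < 0:
            raise ValidationError(f"{self.name}: gamma requires a non-negative value")

    @property
    def uncertain(self) -> bool:
        return self.dist_family != "fixed" and (self.se or 0.0) > 0.0


def dsa_range(spec: ParameterSpec) -> tuple[float, float]:
    """Deterministic-sensitivity range for one parameter.

    Explicit ``low``/``high`` win; otherwise the value is varied by +/-10%
    (+/-50% for cost parameters), with probabilities and utilities clipped
    to [0, 1].
    """
    if spec.low is not None and spec.high is not None:
        return spec.low, spec.high
    (lo_bound, hi_bound), _, frac = _KIND_RULES[spec.kind]
    low = spec.value * (1.0 - frac)
    high = spec.value * (1.0 + frac)
    return max(low, lo_bound), min(high, hi_bound)


def psa_distribution(spec: ParameterSpec):
    """Frozen scipy distribution matched to the spec's mean and sd by moments.

    gamma: shape = (value/se)^2, scale = se^2/value.
    beta:  alpha = value * (value*(1-value)/se^2 - 1), beta = alpha*(1-value)/value.
    """
    if spec.dist_family == "fixed" or not spec.se:
        raise ValueError(f"{spec.name}: no PSA distribution (fixed or se missing)")
    m, s = spec.value, spec.se
    if spec.dist_family == "gamma":
        if m <= 0:
            raise ValueError(f"{spec.name}: gamma moment matching needs value > 0")
        shape = (m / s) ** 2
        scale = s * s / m
        return stats.gamma(a=shape, scale=scale)
    # beta
    if not (0.0 < m < 1.0):
        raise InfeasibleMomentsError(f"{spec.name}: beta needs value strictly in (0,1)")
    if s * s >= m * (1.0 - m):
        raise InfeasibleMomentsError(
            f"{spec.name}: se^2={s*s:.4g} >= value*(1-value)={m*(1-m):.4g}"
        )
    nu = m * (1.0 - m) / (s * s) - 1.0
    alpha = m * nu
    beta = (1.0 - m) * nu
    return stats.beta(a=alpha, b=beta)


# ---------------------------------------------------------------------------
# ParameterSet
# ---------------------------------------------------------------------------


@dataclass
class ParameterSet:
    """Validated bundle of every model input plus the life table."""

    specs: dict[str, ParameterSpec]
    life_table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.validate()

    # -- access ------------------------------------------------------------

    def __getitem__(self, name: str) -> float:
        return self.value(name)

    def value(self, name: str) -> float:
        try:
            return self.specs[name].value
        except KeyError:
            raise SchemaError(f"unknown parameter {name!r}") from None

    def spec(self, name: str) -> ParameterSpec:
        try:
            return self.specs[name]
        except KeyError:
            raise SchemaError(f"unknown parameter {name!r}") from None

    def qx(self, age: float) -> float:
        """Annual background death probability at integer age."""
        row = self._qx_map.get(int(age))
        if row is None:
            raise ValidationError(f"age {age} outside life-table range")
        return row

    def uncertain_specs(self) -> Iterator[ParameterSpec]:
        for spec in self.specs.values():
            if spec.uncertain:
                yield spec

    def with_values(self, overrides: Mapping[str, float]) -> "ParameterSet":
        """New set with point values replaced (ranges/uncertainty retained)."""
        specs = dict(self.specs)
        for name, value in overrides.items():
            old = self.spec(name)
            low = min(old.low, value) if old.low is not None else None
            high = max(old.high, value) if old.high is not None else None
            specs[name] = replace(old, value=float(value), low=low, high=high)
        return ParameterSet(specs, self.life_table)

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        missing = sorted(set(PARAM_SCHEMA) - set(self.specs))
        if missing:
            raise SchemaError(f"missing mandatory parameter(s): {', '.join(missing)}")
        unknown = sorted(set(self.specs) - set(PARAM_SCHEMA))
        if unknown:
            raise SchemaError(f"unknown parameter(s): {', '.join(unknown)}")
        lt = self.life_table
        if list(lt.columns) != ["age", "qx"]:
            raise ValidationError("life table must have columns age,qx")
        if lt["age"].duplicated().any():
            raise ValidationError("life table has duplicate ages")
        if ((lt["qx"] < 0) | (lt["qx"] > 1)).any():
            raise ValidationError("life-table qx outside [0,1]")
        self._qx_map = dict(zip(lt["age"].astype(int), lt["qx"].astype(float)))
        start = int(self.value("demographics.start_age"))
        stop = int(self.value("demographics.max_age"))
        if start >= stop:
            raise ValidationError("start_age must be below max_age")
        for age in range(start, stop + 1):
            if age not in self._qx_map:
                raise ValidationError(f"life table does not cover age {age}")
        prev = sum(
            self.value(f"epi.prevalence.{stage_param_key(arm, stage)}")
            for arm, stage in DISEASED_STAGES
        )
        if prev > 1.0 + 1e-9:
            raise ValidationError(f"baseline prevalences sum to {prev:.6f} > 1")
        shares = sum(
            self.value(f"utility.share_{k}")
            for k in ("none", "hypertension", "diabetes", "both")
        )
        if abs(shares - 1.0) > 1e-9:
            raise ValidationError(f"comorbidity shares sum to {shares:.6f}, expected 1")

    @property
    def disease_free_share(self) -> float:
        """Baseline disease-free occupancy, the residual of the prevalences."""
        return 1.0 - sum(
            self.value(f"epi.prevalence.{stage_param_key(arm, stage)}")
            for arm, stage in DISEASED_STAGES
        )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def _nest(flat: Mapping[str, object]) -> dict:
    tree: dict = {}
    for dotted, leaf in flat.items():
        node = tree
        *parents, last = dotted.split(".")
        for p in parents:
            node = node.setdefault(p, {})
        node[last] = leaf
    return tree


def _flatten(tree: Mapping, prefix: str = "") -> Iterator[tuple[str, object]]:
    for key, val in tree.items():
        dotted = f"{prefix}{key}"
        if isinstance(val, Mapping) and not ("value" in val):
            yield from _flatten(val, dotted + ".")
        else:
            yield dotted, val


def _spec_to_leaf(spec: ParameterSpec) -> object:
    leaf: dict[str, object] = {"value": float(spec.value)}
    if spec.low is not None:
        leaf["low"] = float(spec.low)
    if spec.high is not None:
        leaf["high"] = float(spec.high)
    if spec.se is not None:
        leaf["se"] = float(spec.se)
    if spec.dist_family != "fixed":
        leaf["dist"] = spec.dist_family
    leaf["provenance"] = spec.provenance
    return leaf


def _leaf_to_spec(name: str, leaf: object) -> ParameterSpec:
    definition = PARAM_SCHEMA.get(name)
    if definition is None:
        raise SchemaError(f"unknown parameter {name!r}")
    kind = definition.kind
    if isinstance(leaf, Mapping):
        if "value" not in leaf:
            raise SchemaError(f"{name}: missing 'value'")
        se = leaf.get("se")
        dist = leaf.get("dist")
        if dist is None:
            dist = _KIND_RULES[kind][1] if se is not None else "fixed"
        return ParameterSpec(
            name=name,
            value=float(leaf["value"]),
            kind=kind,
            low=None if leaf.get("low") is None else float(leaf["low"]),
            high=None if leaf.get("high") is None else float(leaf["high"]),
            se=None if se is None else float(se),
            dist_family=dist,
            provenance=str(leaf.get("provenance", definition.provenance)),
        )
    return ParameterSpec(
        name=name, value=float(leaf), kind=kind, provenance=definition.provenance
    )


def load_parameters(path: str | Path, life_table: str | Path | None = None) -> ParameterSet:
    """Load and validate a parameter file (YAML) plus its life table (CSV).

    The YAML may name its life table via ``mortality.life_table_file``
    (resolved relative to the YAML's directory); an explicit ``life_table``
    argument overrides it.
    """
    path = Path(path)
    with open(path) as fh:
        tree = yaml.safe_load(fh)
    if not isinstance(tree, Mapping):
        raise SchemaError(f"{path}: not a mapping")
    flat = dict(_flatten(tree))
    lt_ref = flat.pop("mortality.life_table_file", None)
    if life_table is None:
        if lt_ref is None:
            raise SchemaError("no life table given (mortality.life_table_file missing)")
        life_table = path.parent / str(lt_ref)
    lt = pd.read_csv(life_table)
    specs = {name: _leaf_to_spec(name, leaf) for name, leaf in flat.items()}
    return ParameterSet(specs, lt)


def save_parameters(
    params: ParameterSet, path: str | Path, life_table_name: str | None = None
) -> None:
    """Write the YAML file and its life-table CSV next to each other."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if life_table_name is None:
        life_table_name = path.stem + "_life_table.csv"
    flat: dict[str, object] = {n: _spec_to_leaf(s) for n, s in sorted(params.specs.items())}
    flat["mortality.life_table_file"] = life_table_name
    with open(path, "w") as fh:
        yaml.safe_dump(_nest(flat), fh, sort_keys=False)
    params.life_table.to_csv(path.parent / life_table_name, index=False)
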