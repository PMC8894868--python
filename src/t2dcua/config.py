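"""Run configuration: schema, YAML loading, validation and path access.

A run is fully described by one YAML document (see
``t2dcua/data/reference_config.yaml``, whose every default is annotated with
its source). Risk-equation coefficients live in a separate parameter file
referenced by the config (``risk_equations_file``) or inline
(``risk_equations``); the fixture shipped with the package is synthetic.

Dotted paths ("economics.complications.mi.subsequent_cost") address
individual scalars for the sensitivity machinery; :func:`set_path` mutates a
deep copy, never the original.
"""

from __future__ import annotations

import copy
import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Optional, Sequence

import yaml

from .cohort import BaselineProfile, EfficacySpec
from .economics import (
    ComplicationCost,
    ComplicationUtility,
    CostSchedule,
    EconomicParams,
    UtilityCatalog,
    annual_acquisition_cost,
    semaglutide_escalation_cost,
)
from .exceptions import ConfigurationError
from .risk_engine import COMPLICATIONS, ParameterSet, load_parameter_set
from .cua import Threshold

THERAPY_KINDS = ("fixed_box", "semaglutide_escalation")


@dataclass
class TherapyConfig:
    """Drug pricing inputs for one arm."""

    kind: str
    price_cny: float  # per box (fixed_box) or per pen (semaglutide_escalation)
    doses_per_box: int = 1
    usable_mg_per_pen: float = 2.0
    price_scale: float = 1.0  # uniform scale knob used by the price search

    def __post_init__(self) -> None:
        if self.kind not in THERAPY_KINDS:
            raise ConfigurationError(
                f"therapy.kind: must be one of {THERAPY_KINDS}, got {self.kind!r}"
            )
        if self.price_cny < 0:
            raise ConfigurationError("therapy.price_cny: must be >= 0")
        if self.doses_per_box <= 0:
            raise ConfigurationError("therapy.doses_per_box: must be > 0")
        if self.price_scale < 0:
            raise ConfigurationError("therapy.price_scale: must be >= 0")


@dataclass
class ArmConfig:
    name: str
    hba1c_md: float
    ci_lower: float
    ci_upper: float
    therapy: TherapyConfig

    def efficacy_spec(self) -> EfficacySpec:
        return EfficacySpec(self.name, self.hba1c_md, self.ci_lower, self.ci_upper)


@dataclass
class ComplicationParams:
    """Per-complication costs ($) and utility-decrement magnitudes."""

    fatal_cost: float = 0.0
    nonfatal_cost: float = 0.0
    event_decrement: float = 0.0
    subsequent_cost: float = 0.0
    subsequent_decrement: float = 0.0

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ConfigurationError(f"{f.name}: must be >= 0")


@dataclass
class EconomicsConfig:
    discount_rate: float = 0.05
    horizon_years: int = 40
    fx_cny_per_usd: float = 6.8974
    dosing_weeks_per_year: int = 48
    treatment_duration_years: int = 5
    post_switch_annual_cost: float = 400.0  # basal insulin, placeholder (unpublished)
    management_annual_cost: float = 1463.01
    initial_utility: float = 0.876
    hba1c_rebound_at_switch: bool = True
    complications: dict[str, ComplicationParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.discount_rate < 0:
            raise ConfigurationError("economics.discount_rate: must be >= 0")
        if self.horizon_years < 1:
            raise ConfigurationError("economics.horizon_years: must be >= 1")
        if self.treatment_duration_years < 1:
            raise ConfigurationError("economics.treatment_duration_years: must be >= 1")
        for f in ("post_switch_annual_cost", "management_annual_cost"):
            if getattr(self, f) < 0:
                raise ConfigurationError(f"economics.{f}: must be >= 0")
        if not 0.0 < self.initial_utility <= 1.0:
            raise ConfigurationError("economics.initial_utility: must be in (0, 1]")


@dataclass
class SAParameter:
    """One one-way-sensitivity input: dotted config paths plus low/high values."""

    name: str
    paths: tuple[str, ...]
    low: float
    high: float
    kind: str = "cost"  # {"cost", "utility", "rate", "years"}

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ConfigurationError(f"sensitivity {self.name!r}: low must be <= high")


@dataclass
class PSAConfig:
    n_iter: int = 1000
    resample_kinds: tuple[str, ...] = ("cost", "utility")  # of the SA battery
    resample_effects: bool = True

    def __post_init__(self) -> None:
        if self.n_iter < 1:
            raise ConfigurationError("psa.n_iter: must be >= 1")
        self.resample_kinds = tuple(self.resample_kinds)


@dataclass
class PricingConfig:
    tol_icur: float = 0.01  # $/QALY
    tol_price: float = 0.01  # $/year
    max_iter: int = 60


@dataclass
class RunConfig:
    seed: int
    cohort: BaselineProfile
    arms: list[ArmConfig]
    risk_equations: ParameterSet
    economics: EconomicsConfig
    threshold: Threshold
    sensitivity: list[SAParameter] = field(default_factory=list)
    psa: PSAConfig = field(default_factory=PSAConfig)
    pricing: PricingConfig = field(default_factory=PricingConfig)
    raw: dict = field(default_factory=dict, repr=False)

    def arm(self, name: str) -> ArmConfig:
        for a in self.arms:
            if a.name == name:
                return a
        raise ConfigurationError(f"unknown arm {name!r}")


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------


def _require(mapping: Mapping, key: str, where: str) -> Any:
    if key not in mapping:
        raise ConfigurationError(f"{where}.{key}: required field is missing")
    return mapping[key]


def _load_cohort(section: Mapping) -> BaselineProfile:
    kwargs = {}
    for f in dataclasses.fields(BaselineProfile):
        if f.name in section:
            v = section[f.name]
            if f.name == "race_props":
                v = dict(v)
            elif f.name == "hba1c_range":
                v = tuple(v)
            kwargs[f.name] = v
    try:
        return BaselineProfile(**kwargs)
    except ValueError as exc:
        raise ConfigurationError(f"cohort: {exc}") from None


def _load_arm(section: Mapping) -> ArmConfig:
    name = _require(section, "name", "arms[]")
    therapy = _require(section, "therapy", f"arms[{name}]")
    return ArmConfig(
        name=name,
        hba1c_md=float(_require(section, "hba1c_md", f"arms[{name}]")),
        ci_lower=float(_require(section, "ci_lower", f"arms[{name}]")),
        ci_upper=float(_require(section, "ci_upper", f"arms[{name}]")),
        therapy=TherapyConfig(
            kind=_require(therapy, "kind", f"arms[{name}].therapy"),
            price_cny=float(_require(therapy, "price_cny", f"arms[{name}].therapy")),
            doses_per_box=int(therapy.get("doses_per_box", 1)),
            usable_mg_per_pen=float(therapy.get("usable_mg_per_pen", 2.0)),
            price_scale=float(therapy.get("price_scale", 1.0)),
        ),
    )


def _load_economics(section: Mapping) -> EconomicsConfig:
    comps = {}
    for comp, spec in (section.get("complications") or {}).items():
        if comp not in COMPLICATIONS:
            raise ConfigurationError(
                f"economics.complications.{comp}: unknown complication "
                f"(expected one of {COMPLICATIONS})"
            )
        try:
            comps[comp] = ComplicationParams(
                fatal_cost=float(spec.get("fatal_cost", 0.0)),
                nonfatal_cost=float(spec.get("nonfatal_cost", 0.0)),
                event_decrement=float(spec.get("event_decrement", 0.0)),
                subsequent_cost=float(spec.get("subsequent_cost", 0.0)),
                subsequent_decrement=float(spec.get("subsequent_decrement", 0.0)),
            )
        except ValueError as exc:
            raise ConfigurationError(f"economics.complications.{comp}.{exc}") from None
    scalar = {
        f.name: section[f.name]
        for f in dataclasses.fields(EconomicsConfig)
        if f.name != "complications" and f.name in section
    }
    return EconomicsConfig(complications=comps, **scalar)


def _load_sensitivity(entries: Sequence[Mapping]) -> list[SAParameter]:
    out = []
    for e in entries or []:
        paths = e.get("paths") or [e["path"]]
        out.append(
            SAParameter(
                name=_require(e, "name", "sensitivity[]"),
                paths=tuple(paths),
                low=float(_require(e, "low", f"sensitivity[{e.get('name')}]")),
                high=float(_require(e, "high", f"sensitivity[{e.get('name')}]")),
                kind=e.get("kind", "cost"),
            )
        )
    return out


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration; defaults fill absent fields."""
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ConfigurationError(f"{path}: config must be a mapping")
    return config_from_dict(doc, base_dir=path.parent)


def config_from_dict(doc: Mapping, base_dir: Optional[Path] = None) -> RunConfig:
    if "risk_equations" in doc:
        params = load_parameter_set(doc["risk_equations"])
    elif "risk_equations_file" in doc:
        ref = Path(doc["risk_equations_file"])
        if not ref.is_absolute() and base_dir is not None:
            ref = base_dir / ref
        if not ref.exists():
            raise ConfigurationError(f"risk_equations_file: {ref} does not exist")
        with open(ref) as fh:
            params = load_parameter_set(yaml.safe_load(fh))
    else:
        raise ConfigurationError("risk_equations or risk_equations_file: required")

    arms = [_load_arm(a) for a in _require(doc, "arms", "config")]
    thr = doc.get("threshold") or {}
    cfg = RunConfig(
        seed=int(doc.get("seed", 0)),
        cohort=_load_cohort(doc.get("cohort") or {}),
        arms=arms,
        risk_equations=params,
        economics=_load_economics(doc.get("economics") or {}),
        threshold=Threshold(
            gdp_per_capita_cny=float(thr.get("gdp_per_capita_cny", 72447.0)),
            multiplier=float(thr.get("multiplier", 3.0)),
            fx=float(thr.get("fx", doc.get("economics", {}).get("fx_cny_per_usd", 6.8974))),
        ),
        sensitivity=_load_sensitivity(doc.get("sensitivity") or []),
        psa=PSAConfig(**(doc.get("psa") or {})),
        pricing=PricingConfig(**(doc.get("pricing") or {})),
        raw=dict(doc),
    )
    return cfg


def reference_config_path() -> Path:
    """Path of the annotated reference configuration shipped with the package."""
    return Path(resources.files("t2dcua").joinpath("data/reference_config.yaml"))


def load_reference_config() -> RunConfig:
    return load_config(reference_config_path())


# ---------------------------------------------------------------------------
# dotted-path access and hashing
# ---------------------------------------------------------------------------


def get_path(cfg: RunConfig, dotted: str) -> Any:
    obj: Any = cfg
    for part in dotted.split("."):
        if isinstance(obj, Mapping):
            if part not in obj:
                raise ConfigurationError(f"path {dotted!r}: no key {part!r}")
            obj = obj[part]
        elif hasattr(obj, part):
            obj = getattr(obj, part)
        else:
            raise ConfigurationError(f"path {dotted!r}: no attribute {part!r}")
    return obj


def set_path(cfg: RunConfig, dotted: str, value: Any) -> RunConfig:
    """Return a deep copy of the config with one dotted path replaced.

    Integer-valued fields (horizons, durations) accept float inputs and are
    rounded, so the sensitivity battery can treat every parameter uniformly.
    """
    new = copy.deepcopy(cfg)
    parts = dotted.split(".")
    obj: Any = new
    for part in parts[:-1]:
        if isinstance(obj, Mapping):
            if part not in obj:
                raise ConfigurationError(f"path {dotted!r}: no key {part!r}")
            obj = obj[part]
        elif hasattr(obj, part):
            obj = getattr(obj, part)
        else:
            raise ConfigurationError(f"path {dotted!r}: no attribute {part!r}")
    leaf = parts[-1]
    if isinstance(obj, dict):
        if leaf not in obj:
            raise ConfigurationError(f"path {dotted!r}: no key {leaf!r}")
        current = obj[leaf]
        obj[leaf] = round(value) if isinstance(current, int) and not isinstance(value, int) else value
    else:
        if not hasattr(obj, leaf):
            raise ConfigurationError(f"path {dotted!r}: no attribute {leaf!r}")
        current = getattr(obj, leaf)
        if isinstance(current, int) and not isinstance(current, bool) and not isinstance(value, int):
            value = round(value)
        object.__setattr__(obj, leaf, value) if _is_frozen(obj) else setattr(obj, leaf, value)
    return new


def _is_frozen(obj: Any) -> bool:
    return dataclasses.is_dataclass(obj) and obj.__dataclass_params__.frozen  # type: ignore[attr-defined]


def config_hash(cfg: RunConfig) -> str:
    """SHA-256 over a canonical JSON rendering of the effective configuration."""

    def default(o: Any):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            d = dataclasses.asdict(o)
            d.pop("raw", None)
            return d
        if isinstance(o, (set, tuple)):
            return list(o)
        return str(o)

    payload = {
        "seed": cfg.seed,
        "cohort": cfg.cohort,
        "arms": cfg.arms,
        "economics": cfg.economics,
        "threshold": cfg.threshold,
        "risk_equations": {
            "complications": cfg.risk_equations.complications,
            "mortality": cfg.risk_equations.mortality,
            "riskfactor_paths": cfg.risk_equations.riskfactor_paths,
        },
        "sensitivity": cfg.sensitivity,
        "psa": cfg.psa,
        "pricing": cfg.pricing,
    }
    canonical = json.dumps(payload, default=default, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


# ---------------------------------------------------------------------------
# builders bridging config -> economics objects
# ---------------------------------------------------------------------------


def build_cost_schedule(arm: ArmConfig, econ: EconomicsConfig) -> CostSchedule:
    """Materialise the arm's cost schedule from prices and the dosing-weeks
    convention; ``therapy.price_scale`` rescales the drug price uniformly
    (used by the threshold price search)."""
    t = arm.therapy
    if t.kind == "fixed_box":
        annual = annual_acquisition_cost(
            t.price_cny * t.price_scale, t.doses_per_box,
            econ.dosing_weeks_per_year, econ.fx_cny_per_usd,
        )
        first, maintenance = annual, annual
    elif t.price_cny * t.price_scale == 0:
        first, maintenance = 0.0, 0.0
    else:
        first, maintenance = semaglutide_escalation_cost(
            t.price_cny * t.price_scale, t.usable_mg_per_pen, econ.fx_cny_per_usd
        )
    comps = {
        name: ComplicationCost(
            fatal_cost=p.fatal_cost,
            nonfatal_cost=p.nonfatal_cost,
            subsequent_cost=p.subsequent_cost,
        )
        for name, p in econ.complications.items()
    }
    return CostSchedule(
        therapy_first_year=first,
        therapy_maintenance=maintenance,
        treatment_duration=econ.treatment_duration_years,
        post_switch_annual_cost=econ.post_switch_annual_cost,
        management_annual_cost=econ.management_annual_cost,
        complications=comps,
    )


def build_utility_catalog(econ: EconomicsConfig) -> UtilityCatalog:
    return UtilityCatalog(
        initial_utility=econ.initial_utility,
        decrements={
            name: ComplicationUtility(
                event_decrement=p.event_decrement,
                subsequent_decrement=p.subsequent_decrement,
            )
            for name, p in econ.complications.items()
        },
    )


def build_economic_params(econ: EconomicsConfig) -> EconomicParams:
    return EconomicParams(
        discount_rate=econ.discount_rate,
        horizon=econ.horizon_years,
        fx_rate=econ.fx_cny_per_usd,
        dosing_weeks_per_year=econ.dosing_weeks_per_year,
    )
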