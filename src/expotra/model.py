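"""Modified ECETOC-TRA worker inhalation-exposure model.

The modelled exposure of an operator handling a volatile substance is

    modelled = initial_exposure(vapor pressure) * A * B * C * D

where the initial exposure (ppm) is read off a monotone curve of vapor
pressure (mbar) and the four multiplicative correction coefficients reduce
it for

* **A** — exposure duration (time the substance is outside its container),
* **B** — fraction of the substance in the handled composition,
* **C** — collective protection (local exhaust ventilation),
* **D** — personal protection (filtering respiratory mask).

Two substances are special-cased: ethanol's initial exposure is fixed at
200 ppm with its own duration-coefficient table, and benzene — handled only
under laboratory hoods — uses C = 0.03 when LEV is present.  A second,
independently configured curve/coefficient set represents the unmodified
ECETOC-TRA v3 worker model for side-by-side comparison.

The vapor-pressure curve and most band values are shipped as configurable
defaults in the TRA-v3 style (the published model binds them to figures, not
tables); the three constants above are the model's hard defaults.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from .substances import BENZENE_CAS, ETHANOL_CAS, Substance

logger = logging.getLogger(__name__)

OPERATIONS = ("weighing_mixing", "packaging", "reconditioning_transferring")

PROPOSED_TAG = "proposed"
BASELINE_TAG = "ecetoc_tra_v3"


class ConfigurationError(ValueError):
    """Raised when a model configuration violates its invariants."""


# ---------------------------------------------------------------------------
# Configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InitialExposureCurve:
    """Monotone map from vapor pressure (mbar) to initial exposure (ppm).

    Piecewise log-linear between anchors (linear in ln(vapor pressure)),
    clamped to the first/last ordinate outside the anchor range.  CAS
    numbers in ``overrides`` bypass the curve entirely.
    """

    anchors: tuple[tuple[float, float], ...]
    overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.anchors:
            raise ConfigurationError("initial-exposure curve needs >= 1 anchor")
        vps = [a[0] for a in self.anchors]
        ppms = [a[1] for a in self.anchors]
        if any(v <= 0 for v in vps) or any(p < 0 for p in ppms):
            raise ConfigurationError("curve anchors must be positive/non-negative")
        if any(b <= a for a, b in zip(vps, vps[1:])):
            raise ConfigurationError("anchor vapor pressures must strictly increase")
        if any(b < a for a, b in zip(ppms, ppms[1:])):
            raise ConfigurationError("initial exposure must be non-decreasing")
        if any(v < 0 for v in self.overrides.values()):
            raise ConfigurationError("override exposures must be >= 0")
        object.__setattr__(self, "anchors", tuple(tuple(a) for a in self.anchors))

    def evaluate(self, vapor_pressure: float) -> float:
        """Interpolate the curve at ``vapor_pressure`` (mbar)."""
        (vp0, e0), (vpn, en) = self.anchors[0], self.anchors[-1]
        if vapor_pressure <= vp0:
            return e0
        if vapor_pressure >= vpn:
            return en
        for (va, ea), (vb, eb) in zip(self.anchors, self.anchors[1:]):
            if va <= vapor_pressure <= vb:
                t = (math.log(vapor_pressure) - math.log(va)) / (
                    math.log(vb) - math.log(va)
                )
                return ea + t * (eb - ea)
        raise AssertionError("unreachable: anchors cover the clamped range")


Bands = tuple[tuple[float, float], ...]  # ((upper bound, coefficient), ...)


def _check_bands(bands: Bands, label: str) -> Bands:
    if not bands:
        raise ConfigurationError(f"{label}: at least one band required")
    uppers = [b[0] for b in bands]
    coeffs = [b[1] for b in bands]
    if any(b <= a for a, b in zip(uppers, uppers[1:])):
        raise ConfigurationError(f"{label}: band bounds must strictly increase")
    if any(not 0 < c <= 1 for c in coeffs):
        raise ConfigurationError(f"{label}: coefficients must lie in (0, 1]")
    if any(b < a for a, b in zip(coeffs, coeffs[1:])):
        raise ConfigurationError(f"{label}: coefficients must be non-decreasing")
    if coeffs[-1] != 1.0:
        raise ConfigurationError(f"{label}: top band coefficient must be 1")
    return tuple(tuple(b) for b in bands)


@dataclass(frozen=True)
class CoefficientTable:
    """Banded correction coefficients A-D.

    Duration/fraction bands are half-open below and closed above: a value
    exactly on a bound takes that band's (smaller) coefficient.  ``None``
    for ``ethanol_duration_bands`` means ethanol uses the standard bands.
    """

    duration_bands: Bands
    fraction_bands: Bands
    lev_factor: float
    rpe_factor: float
    ethanol_duration_bands: Optional[Bands] = None
    lev_overrides: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "duration_bands", _check_bands(self.duration_bands, "duration")
        )
        object.__setattr__(
            self, "fraction_bands", _check_bands(self.fraction_bands, "fraction")
        )
        if self.ethanol_duration_bands is not None:
            object.__setattr__(
                self,
                "ethanol_duration_bands",
                _check_bands(self.ethanol_duration_bands, "ethanol duration"),
            )
        for name, value in (
            ("lev_factor", self.lev_factor),
            ("rpe_factor", self.rpe_factor),
            *((f"lev_overrides[{k}]", v) for k, v in self.lev_overrides.items()),
        ):
            if not 0 < value <= 1:
                raise ConfigurationError(f"{name} must lie in (0, 1]")


@dataclass(frozen=True)
class ModelConfig:
    """One complete model parameterisation: curve + coefficient table + tag."""

    curve: InitialExposureCurve
    coefficients: CoefficientTable
    tag: str = PROPOSED_TAG

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        co = self.coefficients
        return {
            "tag": self.tag,
            "curve": {
                "anchors": [list(a) for a in self.curve.anchors],
                "overrides": dict(self.curve.overrides),
            },
            "coefficients": {
                "duration_bands": [list(b) for b in co.duration_bands],
                "ethanol_duration_bands": (
                    None
                    if co.ethanol_duration_bands is None
                    else [list(b) for b in co.ethanol_duration_bands]
                ),
                "fraction_bands": [list(b) for b in co.fraction_bands],
                "lev_factor": co.lev_factor,
                "lev_overrides": dict(co.lev_overrides),
                "rpe_factor": co.rpe_factor,
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ModelConfig":
        cu = data["curve"]
        co = data["coefficients"]
        return cls(
            curve=InitialExposureCurve(
                anchors=tuple(tuple(a) for a in cu["anchors"]),
                overrides={str(k): float(v) for k, v in cu.get("overrides", {}).items()},
            ),
            coefficients=CoefficientTable(
                duration_bands=tuple(tuple(b) for b in co["duration_bands"]),
                ethanol_duration_bands=(
                    None
                    if co.get("ethanol_duration_bands") is None
                    else tuple(tuple(b) for b in co["ethanol_duration_bands"])
                ),
                fraction_bands=tuple(tuple(b) for b in co["fraction_bands"]),
                lev_factor=float(co["lev_factor"]),
                lev_overrides={
                    str(k): float(v) for k, v in co.get("lev_overrides", {}).items()
                },
                rpe_factor=float(co["rpe_factor"]),
            ),
            tag=data.get("tag", PROPOSED_TAG),
        )


def default_config() -> ModelConfig:
    """Proposed-model defaults.

    Ethanol initial exposure 200 ppm, benzene LEV coefficient 0.03 and mask
    coefficient 0.001 are the model's published constants.  Curve anchors and
    band coefficients are TRA-v3-style placeholders (the reference values are
    figure-bound) and should be replaced by site calibration.
    """
    inf = math.inf
    bands_duration: Bands = ((15.0, 0.1), (60.0, 0.2), (240.0, 0.6), (inf, 1.0))
    bands_fraction: Bands = ((1.0, 0.1), (5.0, 0.2), (25.0, 0.6), (inf, 1.0))
    return ModelConfig(
        curve=InitialExposureCurve(
            anchors=((0.2, 10.0), (20.0, 50.0), (300.0, 100.0)),
            overrides={ETHANOL_CAS: 200.0},
        ),
        coefficients=CoefficientTable(
            duration_bands=bands_duration,
            ethanol_duration_bands=bands_duration,
            fraction_bands=bands_fraction,
            lev_factor=0.1,
            lev_overrides={BENZENE_CAS: 0.03},
            rpe_factor=0.001,
        ),
        tag=PROPOSED_TAG,
    )


def default_baseline_config() -> ModelConfig:
    """Unmodified ECETOC-TRA v3 worker parameterisation for comparison.

    No substance-specific overrides; the mask factor is TRA's generic 90%
    reduction (0.1) rather than the proposed model's 0.001.
    """
    inf = math.inf
    return ModelConfig(
        curve=InitialExposureCurve(
            anchors=((0.2, 10.0), (20.0, 50.0), (300.0, 100.0)), overrides={}
        ),
        coefficients=CoefficientTable(
            duration_bands=((15.0, 0.1), (60.0, 0.2), (240.0, 0.6), (inf, 1.0)),
            ethanol_duration_bands=None,
            fraction_bands=((1.0, 0.1), (5.0, 0.2), (25.0, 0.6), (inf, 1.0)),
            lev_factor=0.1,
            lev_overrides={},
            rpe_factor=0.1,
        ),
        tag=BASELINE_TAG,
    )


def save_configs(path: str | Path, configs: dict[str, ModelConfig]) -> None:
    """Write a tag-keyed set of model configurations to one YAML file."""
    payload = {"models": {tag: cfg.to_dict() for tag, cfg in configs.items()}}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))


def load_configs(path: str | Path) -> dict[str, ModelConfig]:
    payload = yaml.safe_load(Path(path).read_text())
    return {
        tag: ModelConfig.from_dict(data) for tag, data in payload["models"].items()
    }


# ---------------------------------------------------------------------------
# Scenario and estimate types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ExposureScenario:
    """One handling operation of one substance by one operator."""

    scenario_id: str
    operator_id: str
    date: _dt.date
    substance: Substance
    operation: str
    duration: float  # minutes the substance is outside its container
    fraction: float  # % of the substance in the composition (100 = pure)
    lev_present: bool
    rpe_worn: bool

    def __post_init__(self) -> None:
        if self.operation not in OPERATIONS:
            raise ValueError(
                f"{self.scenario_id}: operation must be one of {OPERATIONS}"
            )
        if self.duration <= 0:
            raise ValueError(f"{self.scenario_id}: duration must be > 0")
        if not 0 < self.fraction <= 100:
            raise ValueError(f"{self.scenario_id}: fraction must lie in (0, 100]")


@dataclass(frozen=True)
class ExposureEstimate:
    """Model output for one scenario, with every factor recorded."""

    scenario_id: str
    cas: str
    operation: str
    initial_exposure: float
    coeff_a: float
    coeff_b: float
    coeff_c: float
    coeff_d: float
    modelled_exposure: float
    model_tag: str


# ---------------------------------------------------------------------------
# Model evaluation
# ---------------------------------------------------------------------------

def initial_exposure(substance: Substance, curve: InitialExposureCurve) -> float:
    """Initial (unmitigated) exposure in ppm for a substance.

    Overrides win over the curve; a substance lacking both a vapor pressure
    and an override cannot be modelled.
    """
    if substance.cas in curve.overrides:
        return curve.overrides[substance.cas]
    if substance.vapor_pressure is None:
        raise ValueError(
            f"substance {substance.name} ({substance.cas}) has no vapor "
            "pressure and no initial-exposure override"
        )
    return curve.evaluate(substance.vapor_pressure)


def _band_coefficient(value: float, bands: Bands, label: str) -> float:
    for upper, coeff in bands:
        if value <= upper:
            return coeff
    logger.warning(
        "%s value %.3g above all configured bands; using coefficient 1", label, value
    )
    return 1.0


def lookup_coefficients(
    scenario: ExposureScenario, table: CoefficientTable
) -> tuple[float, float, float, float]:
    """Return (A, B, C, D) for a scenario.

    Ethanol uses its dedicated duration table when one is configured; a
    substance with a LEV override (benzene by default) uses it in place of
    the generic LEV factor.  Absent protection means a coefficient of 1.
    """
    duration_bands = table.duration_bands
    if (
        scenario.substance.special_case == "ethanol"
        and table.ethanol_duration_bands is not None
    ):
        duration_bands = table.ethanol_duration_bands
    coeff_a = _band_coefficient(scenario.duration, duration_bands, "duration")
    coeff_b = _band_coefficient(scenario.fraction, table.fraction_bands, "fraction")
    if scenario.lev_present:
        coeff_c = table.lev_overrides.get(scenario.substance.cas, table.lev_factor)
    else:
        coeff_c = 1.0
    coeff_d = table.rpe_factor if scenario.rpe_worn else 1.0
    return coeff_a, coeff_b, coeff_c, coeff_d


def modelled_exposure(
    scenario: ExposureScenario, config: ModelConfig
) -> ExposureEstimate:
    """Evaluate the multiplicative model for one scenario."""
    init = initial_exposure(scenario.substance, config.curve)
    a, b, c, d = lookup_coefficients(scenario, config.coefficients)
    return ExposureEstimate(
        scenario_id=scenario.scenario_id,
        cas=scenario.substance.cas,
        operation=scenario.operation,
        initial_exposure=init,
        coeff_a=a,
        coeff_b=b,
        coeff_c=c,
        coeff_d=d,
        modelled_exposure=init * a * b * c * d,
        model_tag=config.tag,
    )


def ecetoc_tra_baseline(
    scenario: ExposureScenario, tra_config: Optional[ModelConfig] = None
) -> ExposureEstimate:
    """Evaluate the classic ECETOC-TRA v3 parameterisation for one scenario."""
    if tra_config is None:
        tra_config = default_baseline_config()
    return modelled_exposure(scenario, tra_config)


# ---------------------------------------------------------------------------
# Scenario / estimate I/O
# ---------------------------------------------------------------------------

_SCENARIO_COLUMNS = [
    "scenario_id", "operator_id", "date", "cas", "operation",
    "duration_min", "fraction_percent", "lev_present", "rpe_worn",
]


def load_scenarios(
    path: str | Path, registry: dict[str, Substance]
) -> list[ExposureScenario]:
    """Read a scenario table CSV; substances are resolved via ``registry``."""
    frame = pd.read_csv(path, dtype={"cas": str, "scenario_id": str,
                                     "operator_id": str})
    scenarios = []
    for row in frame.itertuples(index=False):
        if row.cas not in registry:
            raise KeyError(f"scenario {row.scenario_id}: unknown CAS {row.cas}")
        scenarios.append(
            ExposureScenario(
                scenario_id=row.scenario_id,
                operator_id=row.operator_id,
                date=_dt.date.fromisoformat(str(row.date)),
                substance=registry[row.cas],
                operation=row.operation,
                duration=float(row.duration_min),
                fraction=float(row.fraction_percent),
                lev_present=bool(row.lev_present),
                rpe_worn=bool(row.rpe_worn),
            )
        )
    return scenarios


def scenarios_to_frame(scenarios: list[ExposureScenario]) -> pd.DataFrame:
    rows = [
        {
            "scenario_id": s.scenario_id,
            "operator_id": s.operator_id,
            "date": s.date.isoformat(),
            "cas": s.substance.cas,
            "operation": s.operation,
            "duration_min": s.duration,
            "fraction_percent": s.fraction,
            "lev_present": s.lev_present,
            "rpe_worn": s.rpe_worn,
        }
        for s in scenarios
    ]
    return pd.DataFrame(rows, columns=_SCENARIO_COLUMNS)


def estimates_to_frame(estimates: list[ExposureEstimate]) -> pd.DataFrame:
    rows = [
        {
            "scenario_id": e.scenario_id,
            "cas": e.cas,
            "operation": e.operation,
            "initial_exposure_ppm": e.initial_exposure,
            "coeff_a": e.coeff_a,
            "coeff_b": e.coeff_b,
            "coeff_c": e.coeff_c,
            "coeff_d": e.coeff_d,
            "modelled_exposure_ppm": e.modelled_exposure,
            "model_tag": e.model_tag,
        }
        for e in estimates
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "scenario_id", "cas", "operation", "initial_exposure_ppm",
            "coeff_a", "coeff_b", "coeff_c", "coeff_d",
            "modelled_exposure_ppm", "model_tag",
        ],
    )
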