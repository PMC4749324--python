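"""Air-sampling quality control.

Workplace air is sampled on three sorbent tubes in series and quantified by
thermal desorption GC/MS.  Before a measurement may validate the exposure
model it must pass four acceptance rules:

* **breakthrough** — the analyte mass on the second tube must not exceed 5%
  of the total recovered mass (strictly above 5% invalidates);
* **humidity_range** — relative humidity within 10-80%;
* **temperature_range** — temperature within 18-25 degC, the window over
  which the sampling method is validated;
* **shelf_life** — analysis at most 16 days after sampling.

Failed samples are flagged, never dropped: every record keeps its QC result.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

BREAKTHROUGH = "breakthrough"
HUMIDITY_RANGE = "humidity_range"
TEMPERATURE_RANGE = "temperature_range"
SHELF_LIFE = "shelf_life"
RULE_CODES = (BREAKTHROUGH, HUMIDITY_RANGE, TEMPERATURE_RANGE, SHELF_LIFE)

BREAKTHROUGH_LIMIT_PCT = 5.0
HUMIDITY_WINDOW = (10.0, 80.0)  # % RH
TEMPERATURE_WINDOW = (18.0, 25.0)  # degC
SHELF_LIFE_DAYS = 16


@dataclass(frozen=True)
class Measurement:
    """One personal air sample taken during an exposure scenario."""

    measurement_id: str
    scenario_id: str
    measured_concentration: float  # ppm
    tube_masses: tuple[float, float, float]  # ng, tubes in series order
    relative_humidity: float  # %
    temperature: float  # degC
    sampling_date: _dt.date
    analysis_date: _dt.date

    def __post_init__(self) -> None:
        if len(self.tube_masses) != 3:
            raise ValueError(f"{self.measurement_id}: exactly three tube masses")
        if any(m < 0 for m in self.tube_masses):
            raise ValueError(f"{self.measurement_id}: tube masses must be >= 0")
        if self.measured_concentration < 0:
            raise ValueError(f"{self.measurement_id}: concentration must be >= 0")
        if self.analysis_date < self.sampling_date:
            raise ValueError(
                f"{self.measurement_id}: analysis date precedes sampling date"
            )
        object.__setattr__(self, "tube_masses", tuple(self.tube_masses))


@dataclass(frozen=True)
class QcResult:
    measurement_id: str
    valid: bool
    failures: tuple[str, ...]
    breakthrough_fraction: float  # % of total mass on tube 2


def check_breakthrough(
    tube_masses: tuple[float, float, float]
) -> tuple[float, bool]:
    """Second-tube share of total recovered mass, and whether it passes.

    The sample is invalidated when tube 2 holds strictly more than 5% of
    the total over all three tubes; a zero total mass passes with 0%.
    """
    if any(m < 0 for m in tube_masses):
        raise ValueError("tube masses must be >= 0")
    total = sum(tube_masses)
    if total == 0:
        return 0.0, True
    fraction = 100.0 * tube_masses[1] / total
    return fraction, fraction <= BREAKTHROUGH_LIMIT_PCT


def check_environment(measurement: Measurement) -> list[str]:
    """Rule codes violated by the sample's humidity/temperature, if any."""
    failures = []
    lo, hi = HUMIDITY_WINDOW
    if not lo <= measurement.relative_humidity <= hi:
        failures.append(HUMIDITY_RANGE)
    lo, hi = TEMPERATURE_WINDOW
    if not lo <= measurement.temperature <= hi:
        failures.append(TEMPERATURE_RANGE)
    return failures


def check_shelf_life(sampling_date: _dt.date, analysis_date: _dt.date) -> bool:
    """True iff the tube was analysed within 16 days of sampling."""
    if analysis_date < sampling_date:
        raise ValueError("analysis date precedes sampling date")
    return (analysis_date - sampling_date).days <= SHELF_LIFE_DAYS


def qc_measurement(measurement: Measurement) -> QcResult:
    """Apply all acceptance rules to one measurement."""
    failures: list[str] = []
    fraction, bt_pass = check_breakthrough(measurement.tube_masses)
    if not bt_pass:
        failures.append(BREAKTHROUGH)
    failures.extend(check_environment(measurement))
    if not check_shelf_life(measurement.sampling_date, measurement.analysis_date):
        failures.append(SHELF_LIFE)
    if measurement.tube_masses[2] > 0:
        # the third tube is a sentinel only; load there is suspicious but
        # not, by itself, invalidating
        logger.warning(
            "%s: non-zero mass on third tube (%.3g ng)",
            measurement.measurement_id,
            measurement.tube_masses[2],
        )
    return QcResult(
        measurement_id=measurement.measurement_id,
        valid=not failures,
        failures=tuple(failures),
        breakthrough_fraction=fraction,
    )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_MEASUREMENT_COLUMNS = [
    "measurement_id", "scenario_id", "concentration_ppm",
    "tube1_ng", "tube2_ng", "tube3_ng",
    "rh_percent", "temp_c", "sampling_date", "analysis_date",
]


def load_measurements(path: str | Path) -> list[Measurement]:
    frame = pd.read_csv(
        path, dtype={"measurement_id": str, "scenario_id": str}
    )
    out = []
    for row in frame.itertuples(index=False):
        out.append(
            Measurement(
                measurement_id=row.measurement_id,
                scenario_id=row.scenario_id,
                measured_concentration=float(row.concentration_ppm),
                tube_masses=(
                    float(row.tube1_ng), float(row.tube2_ng), float(row.tube3_ng)
                ),
                relative_humidity=float(row.rh_percent),
                temperature=float(row.temp_c),
                sampling_date=_dt.date.fromisoformat(str(row.sampling_date)),
                analysis_date=_dt.date.fromisoformat(str(row.analysis_date)),
            )
        )
    return out


def measurements_to_frame(measurements: list[Measurement]) -> pd.DataFrame:
    rows = [
        {
            "measurement_id": m.measurement_id,
            "scenario_id": m.scenario_id,
            "concentration_ppm": m.measured_concentration,
            "tube1_ng": m.tube_masses[0],
            "tube2_ng": m.tube_masses[1],
            "tube3_ng": m.tube_masses[2],
            "rh_percent": m.relative_humidity,
            "temp_c": m.temperature,
            "sampling_date": m.sampling_date.isoformat(),
            "analysis_date": m.analysis_date.isoformat(),
        }
        for m in measurements
    ]
    return pd.DataFrame(rows, columns=_MEASUREMENT_COLUMNS)


def qc_results_to_frame(results: list[QcResult]) -> pd.DataFrame:
    rows = [
        {
            "measurement_id": r.measurement_id,
            "valid": r.valid,
            "failures": ";".join(r.failures),
            "breakthrough_pct": r.breakthrough_fraction,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["measurement_id", "valid", "failures", "breakthrough_pct"]
    )


def qc_failure_counts(results: list[QcResult]) -> dict[str, int]:
    """Number of invalidated samples per rule (a sample may count twice)."""
    counts = {code: 0 for code in RULE_CODES}
    for r in results:
        for code in r.failures:
            counts[code] += 1
    return counts
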