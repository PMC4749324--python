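"""Annual personal exposure record cards.

French regulation requires an annual record per operator listing every
handling operation of a substance hazardous by inhalation: the chemical,
the operation type, how many times it was performed, the unit duration, the
substance content of the composition, the protective measures in place and
the assessed exposure.

Scenarios are aggregated by (substance, operation, duration band, fraction
band, protection flags) so that the thousands of near-identical weighing
operations a blender performs in a year collapse into countable entries;
raw duration extremes are retained per entry for audit.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .model import (
    Bands,
    CoefficientTable,
    ExposureEstimate,
    ExposureScenario,
    default_config,
)
from .substances import DEFAULT_INHALATION_PHRASES, Substance, is_inhalation_hazard


@dataclass(frozen=True)
class RecordEntry:
    substance_name: str
    cas: str
    operation: str
    n_operations: int
    duration_band_min: float  # raw minimum over grouped scenarios (audit)
    duration_band_max: float  # raw maximum over grouped scenarios (audit)
    fraction_percent: float  # maximum fraction in the group (conservative)
    lev_present: bool
    rpe_worn: bool
    modelled_exposure: float  # ppm, per single operation (maximum in group)


@dataclass(frozen=True)
class RecordCard:
    operator_id: str
    year: int
    entries: tuple[RecordEntry, ...]


def _band_index(value: float, bands: Bands) -> int:
    for i, (upper, _) in enumerate(bands):
        if value <= upper:
            return i
    return len(bands)


def build_record_cards(
    scenarios: Iterable[ExposureScenario],
    estimates: Iterable[ExposureEstimate],
    year: int,
    hazard_phrases: Iterable[str] = DEFAULT_INHALATION_PHRASES,
    table: Optional[CoefficientTable] = None,
) -> list[RecordCard]:
    """One card per operator for ``year``.

    Only substances passing the inhalation-hazard gate appear.  Every
    in-year scenario must have an estimate; a missing one is an error
    naming the scenario.  Output ordering is deterministic: cards by
    operator, entries by (CAS, operation, bands, protection).
    """
    if table is None:
        table = default_config().coefficients
    est_by_id = {e.scenario_id: e for e in estimates}

    groups: dict[tuple, dict] = {}
    for sc in scenarios:
        if sc.date.year != year:
            continue
        if sc.scenario_id not in est_by_id:
            raise KeyError(f"no estimate for scenario {sc.scenario_id}")
        if not is_inhalation_hazard(sc.substance, hazard_phrases):
            continue
        est = est_by_id[sc.scenario_id]
        key = (
            sc.operator_id,
            sc.substance.cas,
            sc.operation,
            _band_index(sc.duration, table.duration_bands),
            _band_index(sc.fraction, table.fraction_bands),
            sc.lev_present,
            sc.rpe_worn,
        )
        g = groups.setdefault(
            key,
            {
                "substance": sc.substance,
                "count": 0,
                "dur_min": sc.duration,
                "dur_max": sc.duration,
                "fraction": sc.fraction,
                "exposure": est.modelled_exposure,
            },
        )
        g["count"] += 1
        g["dur_min"] = min(g["dur_min"], sc.duration)
        g["dur_max"] = max(g["dur_max"], sc.duration)
        g["fraction"] = max(g["fraction"], sc.fraction)
        g["exposure"] = max(g["exposure"], est.modelled_exposure)

    by_operator: dict[str, list[RecordEntry]] = {}
    for key in sorted(groups, key=lambda k: tuple(map(str, k))):
        operator, cas, operation, _, _, lev, rpe = key
        g = groups[key]
        substance: Substance = g["substance"]
        by_operator.setdefault(operator, []).append(
            RecordEntry(
                substance_name=substance.name,
                cas=cas,
                operation=operation,
                n_operations=g["count"],
                duration_band_min=g["dur_min"],
                duration_band_max=g["dur_max"],
                fraction_percent=g["fraction"],
                lev_present=lev,
                rpe_worn=rpe,
                modelled_exposure=g["exposure"],
            )
        )
    return [
        RecordCard(operator_id=op, year=year, entries=tuple(entries))
        for op, entries in sorted(by_operator.items())
    ]


_CARD_COLUMNS = [
    "operator_id", "year", "substance_name", "cas", "operation",
    "n_operations", "duration_min_minutes", "duration_max_minutes",
    "fraction_percent", "lev_present", "rpe_worn", "modelled_exposure_ppm",
]


def cards_to_frame(cards: Iterable[RecordCard]) -> pd.DataFrame:
    """Flatten cards into one table, stable column order."""
    rows = []
    for card in cards:
        for e in card.entries:
            rows.append(
                {
                    "operator_id": card.operator_id,
                    "year": card.year,
                    "substance_name": e.substance_name,
                    "cas": e.cas,
                    "operation": e.operation,
                    "n_operations": e.n_operations,
                    "duration_min_minutes": e.duration_band_min,
                    "duration_max_minutes": e.duration_band_max,
                    "fraction_percent": e.fraction_percent,
                    "lev_present": e.lev_present,
                    "rpe_worn": e.rpe_worn,
                    "modelled_exposure_ppm": e.modelled_exposure,
                }
            )
    return pd.DataFrame(rows, columns=_CARD_COLUMNS)


def write_cards(cards: Iterable[RecordCard], out_dir: str | Path) -> Path:
    """Write one CSV per operator-year plus a combined CSV; returns out_dir."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cards = list(cards)
    for card in cards:
        cards_to_frame([card]).to_csv(
            out / f"record_card_{card.operator_id}_{card.year}.csv", index=False
        )
    cards_to_frame(cards).to_csv(out / "record_cards_combined.csv", index=False)
    return out
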