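"""Validation of model estimates against QC-passing field measurements.

The acceptance statistic is deliberately one-sided: the fraction of
scenario/measurement pairs whose modelled value is at or above the measured
airborne concentration.  The model's design goal is never to underestimate
exposure, so ties count in the model's favour and a strict-inequality count
is reported alongside for the stricter reading.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .model import ExposureEstimate
from .qc import Measurement, QcResult

Pair = tuple[ExposureEstimate, Measurement]


@dataclass(frozen=True)
class PairingReport:
    """Records excluded while joining estimates to measurements."""

    qc_invalid: tuple[str, ...]  # measurement_ids failing QC
    unmatched_measurements: tuple[str, ...]  # valid but no estimate
    unmatched_estimates: tuple[str, ...]  # scenario_ids with no valid sample


@dataclass(frozen=True)
class ValidationSummary:
    model_tag: str
    n_pairs: int
    n_overestimated: int  # modelled >= measured
    n_strictly_over: int  # modelled > measured
    fraction_overestimated: Optional[float]  # %, None when n_pairs == 0
    per_substance: dict[str, tuple[int, float]] = field(default_factory=dict)
    per_operation: dict[str, tuple[int, float]] = field(default_factory=dict)


def pair_scenarios(
    estimates: list[ExposureEstimate],
    measurements: list[Measurement],
    qc_results: list[QcResult],
) -> tuple[list[Pair], PairingReport]:
    """Join estimates to QC-valid measurements on scenario_id.

    Each valid measurement with a matching estimate yields one pair (several
    measurements may share one scenario).  Everything excluded is named in
    the report rather than silently dropped.
    """
    by_scenario: dict[str, ExposureEstimate] = {}
    for est in estimates:
        if est.scenario_id in by_scenario:
            raise ValueError(f"duplicate scenario_id among estimates: "
                             f"{est.scenario_id}")
        by_scenario[est.scenario_id] = est
    validity = {r.measurement_id: r.valid for r in qc_results}

    pairs: list[Pair] = []
    qc_invalid: list[str] = []
    unmatched_measurements: list[str] = []
    matched_scenarios: set[str] = set()
    for m in measurements:
        if not validity.get(m.measurement_id, False):
            qc_invalid.append(m.measurement_id)
            continue
        est = by_scenario.get(m.scenario_id)
        if est is None:
            unmatched_measurements.append(m.measurement_id)
            continue
        pairs.append((est, m))
        matched_scenarios.add(m.scenario_id)
    unmatched_estimates = tuple(
        sid for sid in by_scenario if sid not in matched_scenarios
    )
    return pairs, PairingReport(
        qc_invalid=tuple(qc_invalid),
        unmatched_measurements=tuple(unmatched_measurements),
        unmatched_estimates=unmatched_estimates,
    )


def _group_fractions(
    pairs: list[Pair], key
) -> dict[str, tuple[int, float]]:
    groups: dict[str, list[Pair]] = {}
    for pair in pairs:
        groups.setdefault(key(pair[0]), []).append(pair)
    return {
        k: (
            len(v),
            100.0
            * sum(e.modelled_exposure >= m.measured_concentration for e, m in v)
            / len(v),
        )
        for k, v in groups.items()
    }


def overestimation_summary(pairs: list[Pair], model_tag: str) -> ValidationSummary:
    """Fraction of pairs with modelled >= measured, overall and by group.

    Both values are in ppm (pairing keeps them in the model's unit); mixed
    model tags among the estimates are rejected.
    """
    if any(e.model_tag != model_tag for e, _ in pairs):
        raise ValueError("pairs contain estimates from a different model tag")
    n = len(pairs)
    n_over = sum(e.modelled_exposure >= m.measured_concentration for e, m in pairs)
    n_strict = sum(e.modelled_exposure > m.measured_concentration for e, m in pairs)
    return ValidationSummary(
        model_tag=model_tag,
        n_pairs=n,
        n_overestimated=n_over,
        n_strictly_over=n_strict,
        fraction_overestimated=(100.0 * n_over / n) if n else None,
        per_substance=_group_fractions(pairs, key=lambda e: e.cas),
        per_operation=_group_fractions(pairs, key=lambda e: e.operation),
    )


@dataclass(frozen=True)
class ModelComparison:
    tag_a: str
    tag_b: str
    fraction_a: float
    fraction_b: float
    difference: float  # percentage points, a - b
    per_substance_delta: dict[str, float] = field(default_factory=dict)


def compare_models(
    summary_a: ValidationSummary, summary_b: ValidationSummary
) -> ModelComparison:
    """Side-by-side overestimation fractions of two models on the same pairs."""
    if summary_a.n_pairs != summary_b.n_pairs:
        raise ValueError(
            f"summaries cover different pair sets "
            f"({summary_a.n_pairs} vs {summary_b.n_pairs} pairs)"
        )
    if summary_a.n_pairs == 0:
        raise ValueError("cannot compare empty summaries")
    deltas = {
        cas: summary_a.per_substance[cas][1] - summary_b.per_substance[cas][1]
        for cas in summary_a.per_substance
        if cas in summary_b.per_substance
    }
    return ModelComparison(
        tag_a=summary_a.model_tag,
        tag_b=summary_b.model_tag,
        fraction_a=summary_a.fraction_overestimated,
        fraction_b=summary_b.fraction_overestimated,
        difference=summary_a.fraction_overestimated - summary_b.fraction_overestimated,
        per_substance_delta=deltas,
    )


def summary_to_frame(summary: ValidationSummary) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "model_tag": summary.model_tag,
                "n_pairs": summary.n_pairs,
                "n_overestimated": summary.n_overestimated,
                "n_strictly_over": summary.n_strictly_over,
                "fraction_overestimated_pct": summary.fraction_overestimated,
            }
        ]
    )


def per_substance_frame(summary: ValidationSummary) -> pd.DataFrame:
    rows = [
        {"cas": cas, "n_pairs": n, "fraction_overestimated_pct": frac}
        for cas, (n, frac) in sorted(summary.per_substance.items())
    ]
    return pd.DataFrame(
        rows, columns=["cas", "n_pairs", "fraction_overestimated_pct"]
    )
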