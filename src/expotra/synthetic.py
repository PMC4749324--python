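"""Seeded synthetic measurement campaigns.

Emulates the statistical structure of a flavor/fragrance-factory monitoring
campaign: 27 volatile substances, 430 personal air samples split over three
operation classes (weighing-mixing 54.5%, packaging 32.5%,
reconditioning-transferring 11.6%), with measured concentrations dispersed
log-normally around a generating model's prediction and a small configurable
fraction of samples violating each sampling-QC rule.

The generating model is the proposed exposure model scaled by a configurable
distortion, so tests can create regimes where the model over- or
under-estimates at will; with the default distortion 1 and geometric-mean-1
noise, the model over-estimates exactly half the samples in expectation.

A separate, hand-computable `known_answer_campaign` (six scenarios, five
measurements, expectations derived by hand) supports end-to-end golden tests.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .model import (
    ExposureScenario,
    ModelConfig,
    OPERATIONS,
    default_config,
    modelled_exposure,
)
from .qc import Measurement
from .substances import BENZENE_CAS, ETHANOL_CAS, Substance

_INHALATION_PHRASE_POOL = ("H335", "H332", "H336", "R20", "R37", "R65")


@dataclass(frozen=True)
class CampaignSpec:
    """Parameters of one synthetic campaign.

    Defaults reproduce the reference campaign's structure: sample count,
    substance count and operation mix.  ``mu_g``/``sigma_g`` are the
    geometric mean and geometric SD of the multiplicative lognormal
    measurement noise (``sigma_g`` = 1 means no dispersion);
    ``model_distortion`` scales the generating model's predictions so the
    campaign can be made systematically over- or under-estimated.
    """

    n_substances: int = 27
    n_measurements: int = 430
    # reference shares 54.5 / 32.5 / 11.6 % sum to 98.6 (rounding in the
    # source); they are renormalised here so the mix is a true distribution
    operation_mix: tuple[float, float, float] = (
        0.545 / 0.986, 0.325 / 0.986, 0.116 / 0.986
    )
    vp_bounds: tuple[float, float] = (0.05, 500.0)  # mbar, log-uniform
    mu_g: float = 1.0
    sigma_g: float = 2.5
    model_distortion: float = 1.0
    qc_failure_rates: dict[str, float] = field(
        default_factory=lambda: {
            "breakthrough": 0.05,
            "humidity_range": 0.02,
            "temperature_range": 0.02,
            "shelf_life": 0.02,
        }
    )
    n_operators: int = 20
    year: int = 2015
    pure_handling_prob: float = 0.5
    lev_prob: float = 0.4
    rpe_prob: float = 0.25
    include_special_cases: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.operation_mix) - 1.0) > 1e-9:
            raise ValueError("operation mix proportions must sum to 1")
        if min(self.operation_mix) < 0:
            raise ValueError("operation mix proportions must be >= 0")
        if self.n_substances <= 0 or self.n_measurements <= 0:
            raise ValueError("counts must be positive")
        if self.sigma_g < 1.0:
            raise ValueError("geometric SD must be >= 1")


def _synthetic_cas(rng: np.random.Generator, taken: set[str]) -> str:
    """A syntactically valid CAS number with a correct check digit."""
    while True:
        body = f"{rng.integers(100000, 999999)}{rng.integers(10, 99)}"
        check = sum(i * int(d) for i, d in enumerate(reversed(body), 1)) % 10
        cas = f"{body[:-2]}-{body[-2:]}-{check}"
        if cas not in taken:
            taken.add(cas)
            return cas


def _make_substances(spec: CampaignSpec, rng: np.random.Generator) -> list[Substance]:
    subs: list[Substance] = []
    taken: set[str] = set()
    if spec.include_special_cases:
        subs.append(
            Substance(ETHANOL_CAS, "ethanol", 59.0, 46.07,
                      phrases=frozenset({"H335"}))
        )
        subs.append(
            Substance(BENZENE_CAS, "benzene", 127.0, 78.11,
                      phrases=frozenset({"H350"}))
        )
        taken |= {ETHANOL_CAS, BENZENE_CAS}
    lo, hi = spec.vp_bounds
    while len(subs) < spec.n_substances:
        vp = float(np.exp(rng.uniform(math.log(lo), math.log(hi))))
        subs.append(
            Substance(
                cas=_synthetic_cas(rng, taken),
                name=f"substance_{len(subs) + 1:02d}",
                vapor_pressure=round(vp, 4),
                molecular_weight=round(float(rng.uniform(46, 180)), 2),
                phrases=frozenset({str(rng.choice(_INHALATION_PHRASE_POOL))}),
            )
        )
    return subs[: spec.n_substances]


def _make_scenarios(
    spec: CampaignSpec, rng: np.random.Generator, substances: list[Substance]
) -> list[ExposureScenario]:
    n = spec.n_measurements
    # guarantee every substance appears at least once, then draw uniformly
    sub_idx = list(range(min(spec.n_substances, n)))
    sub_idx += list(rng.integers(0, len(substances), size=n - len(sub_idx)))
    rng.shuffle(sub_idx)
    operations = rng.choice(len(OPERATIONS), size=n, p=list(spec.operation_mix))
    start = _dt.date(spec.year, 1, 1)
    scenarios = []
    for i in range(n):
        duration = float(
            np.clip(rng.lognormal(math.log(20.0), math.log(3.0)), 1.0, 480.0)
        )
        if rng.random() < spec.pure_handling_prob:
            fraction = 100.0
        else:
            fraction = float(10 ** rng.uniform(math.log10(0.5), 2.0))
        scenarios.append(
            ExposureScenario(
                scenario_id=f"S{i + 1:05d}",
                operator_id=f"OP{rng.integers(1, spec.n_operators + 1):03d}",
                date=start + _dt.timedelta(days=int(rng.integers(0, 340))),
                substance=substances[sub_idx[i]],
                operation=OPERATIONS[int(operations[i])],
                duration=round(duration, 1),
                fraction=round(min(fraction, 100.0), 3),
                lev_present=bool(rng.random() < spec.lev_prob),
                rpe_worn=bool(rng.random() < spec.rpe_prob),
            )
        )
    return scenarios


def _make_measurement(
    spec: CampaignSpec,
    rng: np.random.Generator,
    scenario: ExposureScenario,
    prediction: float,
) -> Measurement:
    noise = rng.lognormal(math.log(spec.mu_g), math.log(spec.sigma_g))
    measured = prediction * spec.model_distortion * noise
    rates = spec.qc_failure_rates

    total_ng = max(measured, 1e-6) * 1000.0
    if rng.random() < rates.get("breakthrough", 0.0):
        share2 = rng.uniform(0.06, 0.25)
    else:
        share2 = rng.uniform(0.0, 0.04)
    m2 = share2 * total_ng
    m3 = 0.0  # sentinel tube stays below detection in generated campaigns
    m1 = total_ng - m2 - m3

    if rng.random() < rates.get("humidity_range", 0.0):
        rh = float(rng.uniform(81.0, 95.0))
    else:
        rh = float(rng.uniform(30.0, 70.0))
    if rng.random() < rates.get("temperature_range", 0.0):
        temp = float(rng.uniform(26.0, 32.0))
    else:
        temp = float(rng.uniform(19.0, 24.0))
    if rng.random() < rates.get("shelf_life", 0.0):
        delay = int(rng.integers(17, 26))
    else:
        delay = int(rng.integers(1, 15))

    return Measurement(
        measurement_id="M" + scenario.scenario_id[1:],
        scenario_id=scenario.scenario_id,
        measured_concentration=float(measured),
        tube_masses=(float(m1), float(m2), float(m3)),
        relative_humidity=rh,
        temperature=temp,
        sampling_date=scenario.date,
        analysis_date=scenario.date + _dt.timedelta(days=delay),
    )


def generate_campaign(
    spec: CampaignSpec, config: Optional[ModelConfig] = None
) -> tuple[list[Substance], list[ExposureScenario], list[Measurement]]:
    """Draw one full campaign (substances, scenarios, measurements).

    Deterministic given ``spec`` (including its seed).  ``config`` is the
    generating model; it defaults to the proposed-model configuration.
    """
    if config is None:
        config = default_config()
    rng = np.random.default_rng(spec.seed)
    substances = _make_substances(spec, rng)
    scenarios = _make_scenarios(spec, rng, substances)
    measurements = [
        _make_measurement(
            spec, rng, sc, modelled_exposure(sc, config).modelled_exposure
        )
        for sc in scenarios
    ]
    return substances, scenarios, measurements


# ---------------------------------------------------------------------------
# Hand-computed golden fixture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KnownAnswerBundle:
    substances: dict[str, Substance]
    scenarios: list[ExposureScenario]
    measurements: list[Measurement]
    #: expected modelled exposure (ppm) per scenario under the default config
    expected_modelled: dict[str, float]
    #: measurement ids expected to pass all QC rules
    expected_valid_measurements: tuple[str, ...]
    #: expected overall overestimation fraction (%) over the valid pairs
    expected_fraction_overestimated: float
    #: expected (n_cards, total entry operation count) for the record cards
    expected_card_counts: tuple[int, int]
    year: int


def known_answer_campaign() -> KnownAnswerBundle:
    """A six-scenario synthetic campaign with hand-derived expectations.

    Vapor pressures are synthetic round values placed on or between the
    default curve anchors (0.2, 10) - (20, 50) - (300, 100) so every modelled
    exposure is computable by hand:

    * s1 ethanol  30 min pure, no protection: 200 x 0.2        =  40 ppm
    * s2 benzene  10 min pure under LEV:      100 x 0.1 x 0.03 =  0.3 ppm
    * s3 solvent A 120 min at 5% with mask:   50 x 0.6 x 0.2 x 0.001 = 0.006
    * s4 solvent B 300 min at 50%:            30 x 1           =  30 ppm
      (vp 2 mbar is the geometric midpoint of anchors 0.2 and 20, so the
      log-linear curve gives (10 + 50) / 2 = 30 ppm)
    * s5 ethanol  10 min pure:                200 x 0.1        =  20 ppm
    * s6 ethanol  45 min pure (same band as s1, same operator)  =  40 ppm

    Measurements cover s1-s5; m5 fails breakthrough (10% on tube 2), so
    validation uses four pairs of which three are overestimated: 75%.
    Solvent B carries only an eye-irritation phrase, so s4 never reaches a
    record card; cards hold the five other scenarios, s1+s6 aggregated.
    """
    year = 2015
    subs = {
        "ethanol": Substance(ETHANOL_CAS, "ethanol", 59.0, 46.07,
                             phrases=frozenset({"H335"})),
        "benzene": Substance(BENZENE_CAS, "benzene", 300.0, 78.11,
                             phrases=frozenset({"H350"})),
        "solvent_a": Substance("123456-78-0", "solvent A", 20.0, 88.0,
                               phrases=frozenset({"H335"})),
        "solvent_b": Substance("200001-01-0", "solvent B", 2.0, 100.0,
                               phrases=frozenset({"H319"})),
    }
    d = _dt.date

    def sc(sid, op, day, sub, operation, dur, frac, lev, rpe):
        return ExposureScenario(sid, op, day, subs[sub], operation,
                                dur, frac, lev, rpe)

    scenarios = [
        sc("s1", "OP1", d(year, 3, 2), "ethanol", "weighing_mixing",
           30.0, 100.0, False, False),
        sc("s2", "OP1", d(year, 3, 3), "benzene", "packaging",
           10.0, 100.0, True, False),
        sc("s3", "OP2", d(year, 4, 10), "solvent_a", "weighing_mixing",
           120.0, 5.0, False, True),
        sc("s4", "OP2", d(year, 5, 20), "solvent_b",
           "reconditioning_transferring", 300.0, 50.0, False, False),
        sc("s5", "OP1", d(year, 6, 15), "ethanol", "weighing_mixing",
           10.0, 100.0, False, False),
        sc("s6", "OP1", d(year, 9, 1), "ethanol", "weighing_mixing",
           45.0, 100.0, False, False),
    ]

    def me(mid, sid, conc, tubes, rh, t, day, delay):
        return Measurement(mid, sid, conc, tubes, rh, t, day,
                           day + _dt.timedelta(days=delay))

    measurements = [
        me("m1", "s1", 30.0, (95.0, 4.0, 1.0), 50.0, 20.0, d(year, 3, 2), 5),
        me("m2", "s2", 0.2, (99.0, 1.0, 0.0), 45.0, 22.0, d(year, 3, 3), 3),
        me("m3", "s3", 0.01, (97.0, 3.0, 0.0), 60.0, 21.0, d(year, 4, 10), 10),
        me("m4", "s4", 25.0, (100.0, 5.0, 0.0), 35.0, 19.0, d(year, 5, 20), 16),
        me("m5", "s5", 50.0, (90.0, 10.0, 0.0), 55.0, 20.0, d(year, 6, 15), 4),
    ]

    return KnownAnswerBundle(
        substances=subs,
        scenarios=scenarios,
        measurements=measurements,
        expected_modelled={
            "s1": 40.0, "s2": 0.3, "s3": 0.006, "s4": 30.0,
            "s5": 20.0, "s6": 40.0,
        },
        expected_valid_measurements=("m1", "m2", "m3", "m4"),
        # pairs s1 (40 >= 30), s2 (0.3 >= 0.2), s4 (30 >= 25) over;
        # s3 (0.006 < 0.01) under -> 3/4
        expected_fraction_overestimated=75.0,
        # OP1: ethanol band-2 entry (s1+s6, count 2), ethanol band-1 entry
        # (s5), benzene entry (s2); OP2: solvent A entry (s3) -> 2 cards,
        # 5 counted operations
        expected_card_counts=(2, 5),
        year=year,
    )
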