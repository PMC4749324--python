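"""Substance registry, inhalation-hazard gating and gas-concentration units.

A substance is described by its CAS registry number, its vapor pressure at
room temperature (mbar) — the single driver of the model's initial exposure —
its molecular weight, and the DSD risk phrases / CLP hazard statements from
its classification.  A substance enters the exposure-record workflow only if
at least one of its phrases is on the configurable inhalation-hazard list.

Two CAS numbers receive special model treatment: ethanol (64-17-5), whose
initial exposure is fixed rather than read off the vapor-pressure curve, and
benzene (71-43-2), which carries its own local-exhaust-ventilation
coefficient because it is handled only under laboratory hoods.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

ETHANOL_CAS = "64-17-5"
BENZENE_CAS = "71-43-2"

#: Default inhalation-route hazard gate.  The DSD risk phrases and CLP hazard
#: statements below cover acute/chronic inhalation toxicity, respiratory
#: irritation/sensitisation, carcinogenicity/mutagenicity by inhalation and
#: aspiration hazard.  This list is a configurable placeholder: a site
#: deploying the model should replace it with its own regulatory gate list.
DEFAULT_INHALATION_PHRASES: frozenset[str] = frozenset(
    {
        "R20", "R23", "R26", "R29", "R31", "R32", "R37", "R39", "R40",
        "R42", "R48", "R49", "R65", "R68",
        "H304", "H330", "H331", "H332", "H333", "H334", "H335", "H336",
        "H340", "H350", "H350i", "H351", "H370", "H371", "H372", "H373",
    }
)

_CAS_RE = re.compile(r"^(\d{2,7})-(\d{2})-(\d)$")
# One R/H code, optionally a DSD combination such as R23/25 or R48/20/22.
_PHRASE_RE = re.compile(r"^[RH]\d{2,3}[a-zA-Z]{0,2}(/\d{2,3})*$")

# Ideal-gas constant and reference pressure for ppm <-> mg/m3 conversion.
_R_GAS = 8.314462618  # J / (mol K)
_P_REF = 101325.0  # Pa (1013.25 mbar)


def validate_cas(cas: str) -> bool:
    """True iff ``cas`` has valid NNN...-NN-N format and check digit.

    The CAS check digit is ``sum(i * d_i) mod 10`` where ``d_i`` is the
    i-th digit counted from the right of the body (hyphens removed,
    check digit excluded).
    """
    if not isinstance(cas, str):
        return False
    m = _CAS_RE.match(cas.strip())
    if m is None:
        return False
    body = m.group(1) + m.group(2)
    check = int(m.group(3))
    total = sum(i * int(d) for i, d in enumerate(reversed(body), start=1))
    return total % 10 == check


def _validate_phrase(code: str) -> str:
    code = code.strip()
    if not _PHRASE_RE.match(code):
        raise ValueError(f"unparseable risk/hazard phrase code: {code!r}")
    return code


def _expand_phrase(code: str) -> set[str]:
    """Expand a DSD combination phrase: R23/25 -> {R23, R25}."""
    if "/" not in code:
        return {code}
    head, *rest = code.split("/")
    return {head} | {head[0] + part for part in rest}


@dataclass(frozen=True)
class Substance:
    """One volatile substance in the site registry.

    ``vapor_pressure`` is in mbar at room temperature (the model is
    validated only over 18-25 degC, so no temperature correction is
    applied); ``molecular_weight`` in g/mol; ``phrases`` holds the raw
    classification codes.  ``special_case`` is derived from the CAS number
    and never set by callers.
    """

    cas: str
    name: str
    vapor_pressure: Optional[float]
    molecular_weight: float
    phrases: frozenset[str] = field(default_factory=frozenset)
    special_case: Optional[str] = field(default=None)

    def __post_init__(self) -> None:
        if not validate_cas(self.cas):
            raise ValueError(f"invalid CAS registry number: {self.cas!r}")
        if self.vapor_pressure is not None and self.vapor_pressure < 0:
            raise ValueError(f"{self.name}: vapor pressure must be >= 0")
        if self.molecular_weight <= 0:
            raise ValueError(f"{self.name}: molecular weight must be > 0")
        object.__setattr__(
            self, "phrases", frozenset(_validate_phrase(p) for p in self.phrases)
        )
        if self.cas == ETHANOL_CAS:
            tag = "ethanol"
        elif self.cas == BENZENE_CAS:
            tag = "benzene"
        else:
            tag = None
        object.__setattr__(self, "special_case", tag)


def is_inhalation_hazard(
    substance: Substance, phrase_list: Iterable[str] = DEFAULT_INHALATION_PHRASES
) -> bool:
    """True iff the substance carries at least one phrase from the gate list.

    Combination phrases on either side are expanded (R23/25 matches a gate
    containing R23).  Raises ``ValueError`` on an unparseable code in the
    gate list; the substance's own phrases were validated at construction.
    """
    gate = set()
    for code in phrase_list:
        gate |= _expand_phrase(_validate_phrase(code))
    if not gate:
        raise ValueError("inhalation-hazard phrase list must be non-empty")
    carried: set[str] = set()
    for code in substance.phrases:
        carried |= _expand_phrase(code)
    return bool(carried & gate)


def molar_volume(temperature: float) -> float:
    """Ideal-gas molar volume in L/mol at `temperature` degC and 1013.25 mbar."""
    return _R_GAS * (temperature + 273.15) / _P_REF * 1000.0


def convert_concentration(
    value: float,
    from_unit: str,
    to_unit: str,
    molecular_weight: float,
    temperature: float = 25.0,
) -> float:
    """Convert a gas-phase concentration between ppm and mg/m3.

    Uses the ideal-gas molar volume at ``temperature`` (degC, must lie in
    0-40) and 1013.25 mbar:  C[mg/m3] = C[ppm] * MW / Vm.
    """
    units = {"ppm", "mg_per_m3"}
    if from_unit not in units or to_unit not in units:
        raise ValueError(f"units must be one of {sorted(units)}")
    if molecular_weight <= 0:
        raise ValueError("molecular weight must be > 0")
    if not 0.0 <= temperature <= 40.0:
        raise ValueError("temperature must lie within 0-40 degC")
    if from_unit == to_unit:
        return value
    vm = molar_volume(temperature)
    if from_unit == "ppm":
        return value * molecular_weight / vm
    return value * vm / molecular_weight


# ---------------------------------------------------------------------------
# Registry I/O
# ---------------------------------------------------------------------------

def load_substances(path: str | Path) -> dict[str, Substance]:
    """Read a substance table CSV into a CAS-keyed registry.

    Expected columns: cas, name, vapor_pressure_mbar, molecular_weight,
    phrases (semicolon-joined codes; empty allowed).
    """
    frame = pd.read_csv(path, dtype={"cas": str})
    registry: dict[str, Substance] = {}
    for row in frame.itertuples(index=False):
        raw_phrases = getattr(row, "phrases", "")
        if raw_phrases is None or pd.isna(raw_phrases):
            raw_phrases = ""
        phrases = frozenset(p for p in str(raw_phrases).split(";") if p)
        vp = getattr(row, "vapor_pressure_mbar")
        sub = Substance(
            cas=row.cas,
            name=row.name,
            vapor_pressure=None if pd.isna(vp) else float(vp),
            molecular_weight=float(row.molecular_weight),
            phrases=phrases,
        )
        if sub.cas in registry:
            raise ValueError(f"duplicate CAS in substance table: {sub.cas}")
        registry[sub.cas] = sub
    return registry


def substances_to_frame(registry: dict[str, Substance]) -> pd.DataFrame:
    rows = [
        {
            "cas": s.cas,
            "name": s.name,
            "vapor_pressure_mbar": s.vapor_pressure,
            "molecular_weight": s.molecular_weight,
            "phrases": ";".join(sorted(s.phrases)),
        }
        for s in registry.values()
    ]
    return pd.DataFrame(rows, columns=["cas", "name", "vapor_pressure_mbar",
                                       "molecular_weight", "phrases"])
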