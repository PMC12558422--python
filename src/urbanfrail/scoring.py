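"""Clinical scoring: FTS-5 frailty and CONUT nutritional status.

FTS-5 (Frailty Trait Scale 5) rates five domains — nutrition, physical
activity, nervous system, strength, gait speed — each on 0-10 points. The
total (0-50) classifies a participant as frail when it is strictly above 25.
FTS-3 is a shortened subscale summing a configurable subset of three domains.

CONUT (Controlling Nutritional Status) combines graded subscores for serum
albumin (0/2/4/6), total lymphocyte count (0/1/2/3) and total cholesterol
(0/1/2/3); the total 0-12 maps to categories normal (0-1), light (2-4),
moderate (5-8) and severe (>= 9). Band edges are configurable so simplified
single-cutoff variants can be reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Optional

import numpy as np

FRAILTY_THRESHOLD = 25.0
FTS_DOMAINS = ("nutrition", "physical_activity", "nervous_system", "strength", "gait_speed")
#: Default FTS-3 composition (functional triad); configurable assumption.
DEFAULT_FTS3_SUBSET = ("physical_activity", "strength", "gait_speed")


@dataclass(frozen=True)
class FTS5Domains:
    nutrition: float
    physical_activity: float
    nervous_system: float
    strength: float
    gait_speed: float

    def __post_init__(self) -> None:
        for name in FTS_DOMAINS:
            v = getattr(self, name)
            if not (np.isfinite(v) and 0 <= v <= 10):
                raise ValueError(f"domain {name!r} must be in [0, 10], got {v}")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FTS_DOMAINS}


@dataclass(frozen=True)
class FTS5Result:
    domains: FTS5Domains
    total: float
    frail: bool


def fts5_result(domains: FTS5Domains, threshold: float = FRAILTY_THRESHOLD) -> FTS5Result:
    """Sum the five domain scores; frail iff total strictly exceeds ``threshold``."""
    total = float(sum(domains.as_dict().values()))
    return FTS5Result(domains=domains, total=total, frail=total > threshold)


def fts_subscale(domains: FTS5Domains, subset: Iterable[str] = DEFAULT_FTS3_SUBSET) -> float:
    """Sum over a named subset of domains (e.g. FTS-3). No classification."""
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    if len(set(subset)) != len(subset):
        raise ValueError("duplicate domain name in subset")
    unknown = [s for s in subset if s not in FTS_DOMAINS]
    if unknown:
        raise ValueError(f"unknown domain name(s): {unknown}")
    return float(sum(getattr(domains, s) for s in subset))


@dataclass(frozen=True)
class LabPanel:
    """Laboratory analytes. CONUT needs albumin (g/dL), lymphocytes
    (cells/mm^3) and total cholesterol (mg/dL); the rest are optional markers
    carried for correlation panels."""

    albumin: Optional[float] = None
    lymphocytes: Optional[float] = None
    total_cholesterol: Optional[float] = None
    bilirubin: Optional[float] = None
    serum_iron: Optional[float] = None
    transferrin_saturation: Optional[float] = None
    rbc_count: Optional[float] = None
    rdw: Optional[float] = None

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if v is None:
                continue
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"analyte {f.name!r} must be finite and >= 0, got {v}")
        if self.transferrin_saturation is not None and self.transferrin_saturation > 100:
            raise ValueError("transferrin_saturation must be <= 100%")


@dataclass(frozen=True)
class ConutBands:
    """Band edges for the graded CONUT subscores.

    Each tuple lists descending lower bounds paired with ascending subscores:
    the first bound b with value >= b gives the subscore. The trailing
    implicit band (< last bound) takes the final subscore.
    """

    albumin_bounds: tuple[float, ...] = (3.50, 3.00, 2.50)
    albumin_scores: tuple[int, ...] = (0, 2, 4, 6)
    lymphocyte_bounds: tuple[float, ...] = (1600, 1200, 800)
    lymphocyte_scores: tuple[int, ...] = (0, 1, 2, 3)
    cholesterol_bounds: tuple[float, ...] = (180, 140, 100)
    cholesterol_scores: tuple[int, ...] = (0, 1, 2, 3)


DEFAULT_CONUT_BANDS = ConutBands()

CONUT_CATEGORIES = ("normal", "light", "moderate", "severe")


def conut_category(total: float) -> str:
    """Map a CONUT total to its malnutrition category."""
    if total <= 1:
        return "normal"
    if total <= 4:
        return "light"
    if total <= 8:
        return "moderate"
    return "severe"


def _banded_score(value: float, bounds: tuple[float, ...], scores: tuple[int, ...]) -> int:
    for b, s in zip(bounds, scores):
        if value >= b:
            return s
    return scores[-1]


@dataclass(frozen=True)
class CONUTResult:
    albumin_sub: int
    lymphocyte_sub: int
    cholesterol_sub: int
    total: int
    category: str


def score_conut(panel: LabPanel, bands: ConutBands = DEFAULT_CONUT_BANDS) -> CONUTResult:
    """Compute the CONUT score from albumin, lymphocytes and cholesterol."""
    missing = [
        name
        for name in ("albumin", "lymphocytes", "total_cholesterol")
        if getattr(panel, name) is None
    ]
    if missing:
        raise ValueError(f"missing required analyte(s) for CONUT: {missing}")
    a = _banded_score(panel.albumin, bands.albumin_bounds, bands.albumin_scores)
    l = _banded_score(panel.lymphocytes, bands.lymphocyte_bounds, bands.lymphocyte_scores)
    c = _banded_score(panel.total_cholesterol, bands.cholesterol_bounds, bands.cholesterol_scores)
    total = a + l + c
    return CONUTResult(a, l, c, total, conut_category(total))


@dataclass
class ScoringConfig:
    """Configurable clinical-scoring knobs."""

    frailty_threshold: float = FRAILTY_THRESHOLD
    fts3_subset: tuple[str, ...] = DEFAULT_FTS3_SUBSET
    conut_bands: ConutBands = field(default_factory=ConutBands)
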