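"""Risk quotient and synthetic risk factor computation.

The traditional screen for a single pollutant is the risk quotient

    RQ = MEC / PNEC

where MEC is the measured environmental concentration and PNEC the predicted
no-effect concentration (an acute EC50/LC50 divided by 1000, or a chronic
value divided by 100). RQ ignores how long the compound survives in the
compartment. The synthetic risk factor weights the quotient by the
environmental persistence coefficient

    C = T_CV / T_half          SRF = MEC / (PNEC * C) = RQ * T_half / T_CV

with T_CV the Stockholm Convention persistence boundary value of the
compartment (60 d water, 180 d soil/sediment). A compound whose half-life
exceeds the boundary value has C < 1 and its assessed risk is raised;
short-lived compounds are discounted. Both scores share the same four
hazard bands (negligible / minimal / medium / high).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Optional, Sequence

from .core import (
    CompoundRecord,
    Direction,
    RiskClass,
    SrfToxError,
    ToxicityEndpoint,
    ValidationError,
)

__all__ = [
    "persistence_coefficient",
    "pnec",
    "risk_quotient",
    "synthetic_risk_factor",
    "classify",
    "assess",
    "compare_batch",
    "RiskResult",
    "BatchComparison",
    "BAND_EDGES",
    "round_sig",
    "RoundingMode",
]

RoundingMode = Literal["full_precision", "table_rounded"]

#: Band edges shared by RQ and SRF: value <= 0.01 negligible; < 0.1 minimal;
#: < 1 medium; >= 1 high. Each interior boundary goes to the HIGHER band
#: except 0.01, which is explicitly negligible — the conservative reading of
#: bands that leave the boundary points unassigned.
BAND_EDGES = (0.01, 0.1, 1.0)


def _require_positive(value: float, label: str) -> float:
    value = float(value)
    if not (value > 0) or not math.isfinite(value):
        raise ValidationError(f"{label} must be positive, got {value!r}")
    return value


def persistence_coefficient(half_life_days: float, t_cv_days: float) -> float:
    """Environmental persistence coefficient C = T_CV / T_half (dimensionless).

    Smaller C means the compound outlasts the compartment's persistence
    boundary value, i.e. is more persistent. Full floating precision.
    """
    half_life_days = _require_positive(half_life_days, "half-life")
    t_cv_days = _require_positive(t_cv_days, "persistence boundary value")
    return t_cv_days / half_life_days


def pnec(endpoint: ToxicityEndpoint) -> float:
    """Predicted no-effect concentration: endpoint / assessment factor, ng/L."""
    return endpoint.value_ng_per_l / endpoint.assessment_factor


def risk_quotient(mec_ng_per_l: float, pnec_ng_per_l: float) -> float:
    """RQ = MEC / PNEC (dimensionless)."""
    mec = float(mec_ng_per_l)
    if mec < 0 or not math.isfinite(mec):
        raise ValidationError(f"MEC must be non-negative, got {mec!r}")
    return mec / _require_positive(pnec_ng_per_l, "PNEC")


def synthetic_risk_factor(
    mec_ng_per_l: float, pnec_ng_per_l: float, c: float
) -> float:
    """SRF = MEC / (PNEC * C); identically RQ / C."""
    c = _require_positive(c, "persistence coefficient")
    return risk_quotient(mec_ng_per_l, pnec_ng_per_l) / c


def classify(value: float) -> RiskClass:
    """Map an RQ or SRF value to its hazard band (monotone in the value)."""
    value = float(value)
    if value < 0 or math.isnan(value):
        raise ValidationError(f"risk value must be non-negative, got {value!r}")
    if value <= BAND_EDGES[0]:
        return RiskClass.NEGLIGIBLE
    if value < BAND_EDGES[1]:
        return RiskClass.MINIMAL
    if value < BAND_EDGES[2]:
        return RiskClass.MEDIUM
    return RiskClass.HIGH


def round_sig(value: float, sig: int) -> float:
    """Round to ``sig`` significant figures (0 passes through)."""
    if value == 0 or not math.isfinite(value):
        return value
    return round(value, sig - 1 - math.floor(math.log10(abs(value))))


@dataclass
class RiskResult:
    """Full screen for one compound: C, PNEC, RQ, SRF and both bands."""

    compound: CompoundRecord
    c: float
    pnec_ng_per_l: float
    rq: float
    srf: float
    rq_class: RiskClass
    srf_class: RiskClass

    @property
    def reclassified(self) -> bool:
        return self.rq_class != self.srf_class

    @property
    def direction(self) -> Direction:
        if self.srf_class > self.rq_class:
            return Direction.UP
        if self.srf_class < self.rq_class:
            return Direction.DOWN
        return Direction.UNCHANGED


def assess(
    record: CompoundRecord,
    rounding_mode: RoundingMode = "full_precision",
) -> RiskResult:
    """Run the full screen for one compound record.

    ``rounding_mode`` controls the persistence coefficient entering the SRF:

    - ``full_precision`` (default, recommended): C = T_CV / T_half exactly.
    - ``table_rounded``: use the record's externally tabulated rounded C when
      present (``c_reference``), else round the computed C to 2 significant
      figures. This reproduces arithmetic done on published rounded tables.
    """
    if rounding_mode not in ("full_precision", "table_rounded"):
        raise ValidationError(f"unknown rounding mode {rounding_mode!r}")
    c_exact = persistence_coefficient(
        record.half_life_days, record.medium.t_cv_days
    )
    if rounding_mode == "table_rounded":
        c = record.c_reference if record.c_reference is not None else round_sig(c_exact, 2)
    else:
        c = c_exact
    pnec_value = (
        record.pnec_ng_per_l
        if record.pnec_ng_per_l is not None
        else pnec(record.toxicity)
    )
    rq = risk_quotient(record.mec_ng_per_l, pnec_value)
    srf = synthetic_risk_factor(record.mec_ng_per_l, pnec_value, c)
    return RiskResult(
        compound=record,
        c=c,
        pnec_ng_per_l=pnec_value,
        rq=rq,
        srf=srf,
        rq_class=classify(rq),
        srf_class=classify(srf),
    )


@dataclass
class BatchComparison:
    """Per-record results plus the RQ-vs-SRF summary for a compound table."""

    results: list[RiskResult]
    rq_class_counts: dict[RiskClass, int] = field(default_factory=dict)
    srf_class_counts: dict[RiskClass, int] = field(default_factory=dict)
    n_reclassified_up: int = 0
    n_reclassified_down: int = 0

    @property
    def reclassified(self) -> list[RiskResult]:
        return [r for r in self.results if r.reclassified]


def compare_batch(
    records: Sequence[CompoundRecord] | Iterable[CompoundRecord],
    rounding_mode: RoundingMode = "full_precision",
) -> BatchComparison:
    """Assess every record (input order preserved) and tally band movements."""
    records = list(records)
    if not records:
        raise SrfToxError("no valid records to assess", code="empty-after-validation")
    results = [assess(r, rounding_mode) for r in records]
    rq_counts = {band: 0 for band in RiskClass}
    srf_counts = {band: 0 for band in RiskClass}
    n_up = n_down = 0
    for res in results:
        rq_counts[res.rq_class] += 1
        srf_counts[res.srf_class] += 1
        if res.direction is Direction.UP:
            n_up += 1
        elif res.direction is Direction.DOWN:
            n_down += 1
    return BatchComparison(
        results=results,
        rq_class_counts=rq_counts,
        srf_class_counts=srf_counts,
        n_reclassified_up=n_up,
        n_reclassified_down=n_down,
    )
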