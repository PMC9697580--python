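"""Domain model for persistence-weighted aquatic risk screening.

Every symbol used by the screening equations lives here: the environmental
compartment with its persistence boundary value (T_CV), the toxicity endpoint
with its assessment factor, the per-compound input record, and the ordered
four-band risk class. Validation is strict and errors carry short machine
codes so batch readers can report row-level problems without string matching.

Concentrations are ng/L throughout, the unit used for surface-water
micropollutant monitoring. Inputs tagged with an explicit unit suffix
(``µg/L``, ``mg/L``) are converted on entry.
"""

from __future__ import annotations

import enum
import math
import re
import warnings
from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Optional

__all__ = [
    "SrfToxError",
    "ValidationError",
    "MediumKind",
    "Medium",
    "EndpointKind",
    "ToxicityEndpoint",
    "CompoundRecord",
    "RiskClass",
    "Direction",
    "DEFAULT_T_CV_DAYS",
    "DEFAULT_ASSESSMENT_FACTORS",
    "parse_concentration_ng_per_l",
    "parse_number",
    "validate_record",
    "cas_checksum_ok",
]


class SrfToxError(Exception):
    """Base error; ``code`` is a short stable identifier for the failure."""

    code = "error"

    def __init__(self, message: str, code: Optional[str] = None):
        super().__init__(message)
        if code is not None:
            self.code = code


class ValidationError(SrfToxError):
    code = "invalid-value"


class MediumKind(str, enum.Enum):
    WATER = "water"
    SOIL = "soil"
    SEDIMENT = "sediment"


#: Stockholm Convention Annex D persistence boundary values, days.
DEFAULT_T_CV_DAYS: dict[MediumKind, float] = {
    MediumKind.WATER: 60.0,
    MediumKind.SOIL: 180.0,
    MediumKind.SEDIMENT: 180.0,
}


@dataclass(frozen=True)
class Medium:
    """Environmental compartment carrying its persistence boundary value.

    ``t_cv_days`` defaults to the Stockholm Convention Annex D cut-off for the
    compartment (60 d water, 180 d soil/sediment) but may be overridden, e.g.
    from a config file, for jurisdictions using different boundary values.
    """

    kind: MediumKind
    t_cv_days: float = None  # type: ignore[assignment]

    def __post_init__(self):
        kind = MediumKind(self.kind)
        object.__setattr__(self, "kind", kind)
        t_cv = self.t_cv_days
        if t_cv is None:
            t_cv = DEFAULT_T_CV_DAYS[kind]
        t_cv = float(t_cv)
        if not (t_cv > 0) or not math.isfinite(t_cv):
            raise ValidationError(
                f"persistence boundary value must be positive, got {t_cv!r}"
            )
        object.__setattr__(self, "t_cv_days", t_cv)


class EndpointKind(str, enum.Enum):
    ACUTE_EC50 = "acute_ec50"
    ACUTE_LC50 = "acute_lc50"
    CHRONIC_CHV = "chronic_chv"

    @property
    def is_chronic(self) -> bool:
        return self is EndpointKind.CHRONIC_CHV


#: Assessment factors dividing the endpoint to a PNEC: 1000 for acute
#: EC50/LC50, 100 for a chronic value (ChV).
DEFAULT_ASSESSMENT_FACTORS: dict[EndpointKind, float] = {
    EndpointKind.ACUTE_EC50: 1000.0,
    EndpointKind.ACUTE_LC50: 1000.0,
    EndpointKind.CHRONIC_CHV: 100.0,
}


@dataclass(frozen=True)
class ToxicityEndpoint:
    """Acute or chronic toxicity endpoint with its assessment factor."""

    kind: EndpointKind
    value_ng_per_l: float
    assessment_factor: float = None  # type: ignore[assignment]

    def __post_init__(self):
        kind = EndpointKind(self.kind)
        object.__setattr__(self, "kind", kind)
        value = float(self.value_ng_per_l)
        if not (value > 0) or not math.isfinite(value):
            raise ValidationError(
                f"endpoint value must be positive, got {value!r}"
            )
        object.__setattr__(self, "value_ng_per_l", value)
        af = self.assessment_factor
        if af is None:
            af = DEFAULT_ASSESSMENT_FACTORS[kind]
        af = float(af)
        if not (af > 0) or not math.isfinite(af):
            raise ValidationError(f"assessment factor must be positive, got {af!r}")
        object.__setattr__(self, "assessment_factor", af)


class RiskClass(enum.IntEnum):
    """Ordered four-band hazard classification shared by RQ and SRF."""

    NEGLIGIBLE = 0
    MINIMAL = 1
    MEDIUM = 2
    HIGH = 3

    def __str__(self) -> str:
        return self.name.lower()

    @classmethod
    def from_name(cls, name: str) -> "RiskClass":
        return cls[name.strip().upper()]


class Direction(str, enum.Enum):
    UP = "up"
    DOWN = "down"
    UNCHANGED = "unchanged"


_CAS_RE = re.compile(r"^\d{2,7}-\d{2}-\d$")


def cas_checksum_ok(cas: str) -> bool:
    """Check the CAS registry check digit (weighted sum mod 10)."""
    digits = cas.replace("-", "")
    body, check = digits[:-1], int(digits[-1])
    total = sum(int(d) * w for w, d in enumerate(reversed(body), start=1))
    return total % 10 == check


@dataclass
class CompoundRecord:
    """One pollutant's identity, persistence, exposure and toxicity inputs.

    Exactly one of ``pnec_ng_per_l`` (a pre-derived no-effect concentration)
    or ``toxicity`` (a raw endpoint to be divided by its assessment factor)
    must be supplied. ``c_reference`` optionally carries an externally tabulated
    (rounded) persistence coefficient used by the table-rounded computation
    mode; ``extra`` holds passthrough metadata columns.
    """

    name: str
    half_life_days: float
    medium: Medium
    mec_ng_per_l: float
    cas: Optional[str] = None
    formula: Optional[str] = None  # display metadata only, never parsed
    pnec_ng_per_l: Optional[float] = None
    toxicity: Optional[ToxicityEndpoint] = None
    c_reference: Optional[float] = None
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if self.half_life_days is None:
            raise ValidationError("half-life is required", code="missing-half-life")
        self.half_life_days = float(self.half_life_days)
        if not (self.half_life_days > 0) or not math.isfinite(self.half_life_days):
            raise ValidationError(
                f"{self.name}: half-life must be positive, got {self.half_life_days!r}"
            )
        self.mec_ng_per_l = float(self.mec_ng_per_l)
        if self.mec_ng_per_l < 0 or not math.isfinite(self.mec_ng_per_l):
            raise ValidationError(
                f"{self.name}: MEC must be non-negative, got {self.mec_ng_per_l!r}"
            )
        if (self.pnec_ng_per_l is None) == (self.toxicity is None):
            raise ValidationError(
                f"{self.name}: exactly one of a direct PNEC or a toxicity "
                "endpoint must be supplied",
                code="ambiguous-toxicity",
            )
        if self.pnec_ng_per_l is not None:
            self.pnec_ng_per_l = float(self.pnec_ng_per_l)
            if not (self.pnec_ng_per_l > 0) or not math.isfinite(self.pnec_ng_per_l):
                raise ValidationError(
                    f"{self.name}: PNEC must be positive, got {self.pnec_ng_per_l!r}"
                )
        if self.c_reference is not None:
            self.c_reference = float(self.c_reference)
            if not (self.c_reference > 0):
                raise ValidationError(
                    f"{self.name}: reference persistence coefficient must be positive"
                )
        if self.cas is not None and str(self.cas).strip():
            self.cas = str(self.cas).strip()
            if not _CAS_RE.match(self.cas) or not cas_checksum_ok(self.cas):
                if not self.extra.get("suppress_cas_warning"):
                    warnings.warn(
                        f"{self.name}: CAS number {self.cas!r} fails format/checksum "
                        "validation; kept as-is",
                        stacklevel=2,
                    )
        else:
            self.cas = None

    def with_medium(self, medium: Medium) -> "CompoundRecord":
        return replace(self, medium=medium)

    def to_dict(self) -> dict[str, Any]:
        """Flat serialization; inverse of :func:`validate_record`."""
        out: dict[str, Any] = {
            "name": self.name,
            "cas": self.cas,
            "formula": self.formula,
            "half_life_days": self.half_life_days,
            "medium": self.medium.kind.value,
            "t_cv_days": self.medium.t_cv_days,
            "mec_ng_per_l": self.mec_ng_per_l,
            "pnec_ng_per_l": self.pnec_ng_per_l,
            "endpoint_kind": self.toxicity.kind.value if self.toxicity else None,
            "endpoint_value_ng_per_l": (
                self.toxicity.value_ng_per_l if self.toxicity else None
            ),
            "c_reference": self.c_reference,
        }
        out.update({k: v for k, v in self.extra.items()})
        return out


# -- raw field parsing -------------------------------------------------------

_UNIT_FACTORS_TO_NG = {"ng/l": 1.0, "ug/l": 1e3, "µg/l": 1e3, "μg/l": 1e3, "mg/l": 1e6}

# "1.48 × 10^4^", "1.48×10^4", "1.48 x 10^-3"
_CARET_SCI_RE = re.compile(
    r"^\s*([0-9.]+)\s*[×x]\s*10\s*\^?\s*([+-]?\d+)\s*\^?\s*$"
)


def parse_number(value: Any) -> float:
    """Parse a numeric cell: plain, ``1.48e4`` or ``1.48 × 10^4`` notation."""
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip().replace(",", "")
    if not text:
        raise ValidationError("empty numeric field")
    m = _CARET_SCI_RE.match(text)
    if m:
        return float(m.group(1)) * 10.0 ** int(m.group(2))
    try:
        return float(text)
    except ValueError as exc:
        raise ValidationError(f"cannot parse number from {value!r}") from exc


def parse_concentration_ng_per_l(value: Any) -> float:
    """Parse a concentration, defaulting to ng/L; µg/L and mg/L suffixes convert."""
    if isinstance(value, (int, float)):
        return float(value)
    text = str(value).strip()
    lowered = text.lower()
    for unit, factor in _UNIT_FACTORS_TO_NG.items():
        if lowered.endswith(unit):
            return parse_number(text[: -len(unit)]) * factor
    return parse_number(text)


_FIELD_ALIASES = {
    "half_life": "half_life_days",
    "half_life_d": "half_life_days",
    "mec": "mec_ng_per_l",
    "pnec": "pnec_ng_per_l",
    "endpoint_value": "endpoint_value_ng_per_l",
}

_KNOWN_FIELDS = {
    "name",
    "cas",
    "formula",
    "half_life_days",
    "medium",
    "t_cv_days",
    "mec_ng_per_l",
    "pnec_ng_per_l",
    "endpoint_kind",
    "endpoint_value_ng_per_l",
    "c_reference",
}


def _is_missing(value: Any) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return isinstance(value, str) and not value.strip()


def validate_record(
    raw_fields: Mapping[str, Any],
    medium_default: Optional[Medium] = None,
    suppress_cas_warning: bool = False,
) -> CompoundRecord:
    """Build a validated :class:`CompoundRecord` from one table row's raw fields.

    Numeric cells may be plain, ``e``-notation or ``× 10^k`` text; concentration
    fields default to ng/L unless carrying an explicit µg/L or mg/L suffix.
    When both acute and chronic endpoints are present the chronic one is used
    (long-term assessment preference). Raises :class:`ValidationError` with
    codes ``missing-half-life``, ``invalid-value`` or ``ambiguous-toxicity``.
    """
    fields_in: dict[str, Any] = {}
    extra: dict[str, Any] = {}
    for key, value in raw_fields.items():
        canon = _FIELD_ALIASES.get(key, key)
        if canon in _KNOWN_FIELDS:
            fields_in[canon] = value
        else:
            extra[key] = value

    name = str(fields_in.get("name") or "").strip()
    if not name:
        raise ValidationError("record has no compound name")

    hl_raw = fields_in.get("half_life_days")
    if _is_missing(hl_raw):
        raise ValidationError(f"{name}: missing half-life", code="missing-half-life")
    half_life = parse_number(hl_raw)

    medium_raw = fields_in.get("medium")
    if _is_missing(medium_raw):
        medium = medium_default or Medium(MediumKind.WATER)
    else:
        try:
            kind = MediumKind(str(medium_raw).strip().lower())
        except ValueError as exc:
            raise ValidationError(f"{name}: unknown medium {medium_raw!r}") from exc
        t_cv_raw = fields_in.get("t_cv_days")
        if not _is_missing(t_cv_raw):
            medium = Medium(kind, parse_number(t_cv_raw))
        elif medium_default is not None and medium_default.kind == kind:
            medium = medium_default
        else:
            medium = Medium(kind)

    mec_raw = fields_in.get("mec_ng_per_l")
    if _is_missing(mec_raw):
        raise ValidationError(f"{name}: missing MEC")
    mec = parse_concentration_ng_per_l(mec_raw)

    pnec_raw = fields_in.get("pnec_ng_per_l")
    ep_kind_raw = fields_in.get("endpoint_kind")
    ep_value_raw = fields_in.get("endpoint_value_ng_per_l")
    has_pnec = not _is_missing(pnec_raw)
    has_endpoint = not _is_missing(ep_kind_raw) and not _is_missing(ep_value_raw)
    if has_pnec == has_endpoint:
        raise ValidationError(
            f"{name}: need exactly one of a direct PNEC or a toxicity endpoint",
            code="ambiguous-toxicity",
        )

    pnec = parse_concentration_ng_per_l(pnec_raw) if has_pnec else None
    toxicity = None
    if has_endpoint:
        kinds = [k.strip().lower() for k in str(ep_kind_raw).split("|")]
        values = [v.strip() for v in str(ep_value_raw).split("|")]
        if len(kinds) != len(values):
            raise ValidationError(
                f"{name}: endpoint kinds and values do not pair up"
            )
        endpoints = [
            ToxicityEndpoint(EndpointKind(k), parse_concentration_ng_per_l(v))
            for k, v in zip(kinds, values)
        ]
        # chronic data preferred over short-term EC50/LC50 when both exist
        chronic = [e for e in endpoints if e.kind.is_chronic]
        toxicity = chronic[0] if chronic else endpoints[0]

    c_ref_raw = fields_in.get("c_reference")
    c_ref = None
    if not _is_missing(c_ref_raw):
        c_ref = parse_number(c_ref_raw)
        extra.setdefault("c_reference_text", str(c_ref_raw).strip())

    if suppress_cas_warning:
        extra["suppress_cas_warning"] = True

    cas = fields_in.get("cas")
    formula = fields_in.get("formula")
    return CompoundRecord(
        name=name,
        cas=None if _is_missing(cas) else str(cas).strip(),
        formula=None if _is_missing(formula) else str(formula).strip(),
        half_life_days=half_life,
        medium=medium,
        mec_ng_per_l=mec,
        pnec_ng_per_l=pnec,
        toxicity=toxicity,
        c_reference=c_ref,
        extra=extra,
    )
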