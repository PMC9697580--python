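"""CSV/JSON readers and writers for compound tables and screening reports.

The input schema mirrors a typical monitoring table: one row per compound
with name, optional CAS and formula, half-life (days), medium, MEC (ng/L)
and either a direct PNEC or a raw toxicity endpoint (kind + value). Unknown
columns ride along as passthrough metadata. Numeric cells may use plain,
``1.48e4`` or ``1.48 × 10^4`` notation; concentrations default to ng/L.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from os import PathLike
from pathlib import Path
from typing import Literal, Optional, Sequence, Union

import pandas as pd

from .core import CompoundRecord, Medium, SrfToxError, ValidationError, validate_record
from .engine import RiskResult, round_sig

__all__ = [
    "REQUIRED_COLUMNS",
    "RowIssue",
    "read_compound_table",
    "write_results",
    "results_to_frame",
    "read_results",
]

REQUIRED_COLUMNS = ("name", "half_life_days", "mec_ng_per_l")
_TOXICITY_COLUMNS = ("pnec_ng_per_l", "endpoint_kind", "endpoint_value_ng_per_l")


@dataclass(frozen=True)
class RowIssue:
    """A rejected input row: 1-based data row number, error code and message."""

    row: int
    code: str
    message: str


def read_compound_table(
    path: Union[str, PathLike],
    medium_default: Optional[Medium] = None,
    suppress_cas_warning: bool = False,
) -> tuple[list[CompoundRecord], list[RowIssue]]:
    """Read a compound CSV into validated records plus row-level issues.

    Invalid rows are reported (row number + reason), never silently dropped.
    Raises ``io-error`` for an unreadable file and ``schema-error`` when a
    required column is absent from the header.
    """
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise SrfToxError(f"cannot read {path}: {exc}", code="io-error") from exc

    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SrfToxError(
            f"{path}: missing required column(s) {', '.join(missing)}",
            code="schema-error",
        )
    if not any(c in frame.columns for c in _TOXICITY_COLUMNS):
        raise SrfToxError(
            f"{path}: need a pnec_ng_per_l column or endpoint_kind/"
            "endpoint_value_ng_per_l columns",
            code="schema-error",
        )

    records: list[CompoundRecord] = []
    issues: list[RowIssue] = []
    for i, row in enumerate(frame.to_dict(orient="records"), start=1):
        try:
            records.append(
                validate_record(
                    row,
                    medium_default=medium_default,
                    suppress_cas_warning=suppress_cas_warning,
                )
            )
        except ValidationError as exc:
            issues.append(RowIssue(row=i, code=exc.code, message=str(exc)))
    return records, issues


_RESULT_COLUMNS = (
    "name",
    "cas",
    "c",
    "pnec_ng_per_l",
    "rq",
    "srf",
    "rq_class",
    "srf_class",
    "reclassified",
    "direction",
)


def results_to_frame(results: Sequence[RiskResult]) -> pd.DataFrame:
    """Flatten results to a DataFrame: full-precision numerics plus 4-sig-fig twins."""
    rows = []
    for res in results:
        row = {
            "name": res.compound.name,
            "cas": res.compound.cas,
            "c": res.c,
            "pnec_ng_per_l": res.pnec_ng_per_l,
            "rq": res.rq,
            "srf": res.srf,
            "rq_class": str(res.rq_class),
            "srf_class": str(res.srf_class),
            "reclassified": res.reclassified,
            "direction": res.direction.value,
        }
        for col in ("c", "pnec_ng_per_l", "rq", "srf"):
            row[f"{col}_4sf"] = round_sig(row[col], 4)
        rows.append(row)
    return pd.DataFrame(rows)


def write_results(
    results: Sequence[RiskResult],
    path: Union[str, PathLike],
    format: Literal["csv", "json"] = "csv",
) -> Path:
    """Write the screening report as CSV or a JSON array of flat objects."""
    if not results:
        raise SrfToxError("no results to write", code="empty-after-validation")
    frame = results_to_frame(results)
    path = Path(path)
    try:
        if format == "csv":
            frame.to_csv(path, index=False)
        elif format == "json":
            records = frame.to_dict(orient="records")
            for rec in records:  # NaN (missing CAS) is not valid JSON
                for key, value in rec.items():
                    if isinstance(value, float) and math.isnan(value):
                        rec[key] = None
            path.write_text(json.dumps(records, indent=1), encoding="utf-8")
        else:
            raise ValidationError(f"unknown output format {format!r}")
        return path
    except OSError as exc:
        raise SrfToxError(f"cannot write {path}: {exc}", code="io-error") from exc


def read_results(path: Union[str, PathLike]) -> pd.DataFrame:
    """Read back a results file written by :func:`write_results`."""
    path = Path(path)
    try:
        if path.suffix.lower() == ".json":
            return pd.DataFrame(json.loads(path.read_text(encoding="utf-8")))
        return pd.read_csv(path)
    except (OSError, ValueError, pd.errors.ParserError) as exc:
        raise SrfToxError(f"cannot read results {path}: {exc}", code="io-error") from exc
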