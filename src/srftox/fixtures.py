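"""Bundled case-study compound tables.

Three published surface-water monitoring tables ship with the package as CSV
resources, one per case-study family:

- ``ebro_pesticides`` — 8 pesticide residues, Ebro River (Spain);
- ``tianjin_bohai_pfc_ope`` — 2 perfluorinated compounds (Tianjin surface
  water) and 5 organophosphate esters (Bohai Sea), China;
- ``xiangjiang_eds`` — 5 endocrine disruptors, Xiangjiang River, China.

Each row carries the source table's printed (rounded) persistence
coefficient as ``c_reference``, retained so the table-rounded computation
mode can reproduce arithmetic done on the published rounded values; the
full-precision mode ignores it. A few CAS strings are malformed in the
source tables and are stored verbatim with the checksum warning suppressed.
"""

from __future__ import annotations

import math
import re
from importlib import resources

from .core import CompoundRecord, SrfToxError
from .engine import round_sig
from .table_io import read_compound_table

__all__ = ["FIXTURE_NAMES", "load_fixture", "fixture_path", "matches_printed"]

FIXTURE_NAMES = ("ebro_pesticides", "tianjin_bohai_pfc_ope", "xiangjiang_eds")


def fixture_path(which: str):
    """Filesystem path to a bundled fixture CSV."""
    if which not in FIXTURE_NAMES:
        raise SrfToxError(
            f"unknown fixture {which!r}; available: {', '.join(FIXTURE_NAMES)}",
            code="unknown-fixture",
        )
    return resources.files("srftox.data").joinpath(f"{which}.csv")


def load_fixture(which: str) -> list[CompoundRecord]:
    """Load one bundled table as validated records, in published row order."""
    with resources.as_file(fixture_path(which)) as path:
        records, issues = read_compound_table(path, suppress_cas_warning=True)
    if issues:  # bundled data must be clean; anything else is a packaging bug
        raise SrfToxError(f"fixture {which} failed validation: {issues}")
    return records


_CARET_RE = re.compile(r"^\s*([0-9.]+)\s*[×x]\s*10\s*\^?\s*([+-]?\d+)\s*\^?\s*$")


def matches_printed(value: float, printed: str) -> bool:
    """True when ``value`` rounds to the tabulated string at its own precision.

    Plain decimals compare at their printed decimal places ("0.70" → 2);
    scientific entries ("5.1e-3", "5.1 × 10^-3") at the mantissa's significant
    figures. Used to check recomputed persistence coefficients against the
    published rounded column.
    """
    printed = printed.strip()
    m = _CARET_RE.match(printed)
    if m:
        mantissa, exponent = m.group(1), int(m.group(2))
        printed_value = float(mantissa) * 10.0**exponent
        sig = len(mantissa.replace(".", "").lstrip("0"))
        return math.isclose(round_sig(value, sig), printed_value, rel_tol=1e-9)
    if "e" in printed.lower():
        mantissa = printed.lower().split("e")[0]
        sig = len(mantissa.replace(".", "").replace("-", "").lstrip("0"))
        return math.isclose(round_sig(value, sig), float(printed), rel_tol=1e-9)
    decimals = len(printed.split(".")[1]) if "." in printed else 0
    return math.isclose(round(value, decimals), float(printed), rel_tol=1e-9)
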