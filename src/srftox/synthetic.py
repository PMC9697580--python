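"""Random compound-table generator for property-based testing.

Draws half-life, exposure concentration and PNEC log-uniformly, mirroring the
many-orders-of-magnitude spread of real monitoring tables (half-lives from a
few days for readily hydrolysed organophosphate esters up to millions of days
for bisphenol A; PNECs from sub-ng/L hormone endpoints to mg/L levels).
Deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import CompoundRecord, Medium, MediumKind, SrfToxError

__all__ = ["SyntheticSpec", "generate_synthetic_table"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic compound table.

    Ranges are (low, high) bounds of log-uniform draws; all bounds must be
    positive with low < high (equal bounds pin the value, used to construct
    degenerate cases such as every half-life equal to the boundary value).
    """

    n_compounds: int
    half_life_range_days: tuple[float, float] = (1e-1, 1e7)
    mec_range_ng_per_l: tuple[float, float] = (1e-2, 1e3)
    pnec_range_ng_per_l: tuple[float, float] = (1e-1, 1e6)
    medium: Medium = field(default_factory=lambda: Medium(MediumKind.WATER))
    seed: int = 0

    def __post_init__(self):
        if self.n_compounds < 1:
            raise SrfToxError("n_compounds must be >= 1", code="invalid-spec")
        for label, (lo, hi) in (
            ("half_life_range_days", self.half_life_range_days),
            ("mec_range_ng_per_l", self.mec_range_ng_per_l),
            ("pnec_range_ng_per_l", self.pnec_range_ng_per_l),
        ):
            if not (0 < lo <= hi):
                raise SrfToxError(
                    f"{label} bounds must be positive with low <= high, got {(lo, hi)}",
                    code="invalid-spec",
                )


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, n: int) -> np.ndarray:
    if lo == hi:  # pinned value: avoid exp∘log round-off
        return np.full(n, lo)
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))


def generate_synthetic_table(spec: SyntheticSpec) -> list[CompoundRecord]:
    """Generate ``spec.n_compounds`` valid records; identical spec ⇒ identical table."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_compounds
    half_lives = _log_uniform(rng, *spec.half_life_range_days, n)
    mecs = _log_uniform(rng, *spec.mec_range_ng_per_l, n)
    pnecs = _log_uniform(rng, *spec.pnec_range_ng_per_l, n)
    return [
        CompoundRecord(
            name=f"SYN-{i + 1:04d}",
            half_life_days=float(half_lives[i]),
            medium=spec.medium,
            mec_ng_per_l=float(mecs[i]),
            pnec_ng_per_l=float(pnecs[i]),
        )
        for i in range(n)
    ]
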