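# Methods

## Model

For one compound in one environmental compartment the package computes

- persistence coefficient `C = T_CV / T_1/2` (dimensionless),
- predicted no-effect concentration `PNEC = endpoint / AF` with `AF = 1000`
  for acute EC50/LC50 and `AF = 100` for a chronic value, unless a PNEC is
  supplied directly,
- risk quotient `RQ = MEC / PNEC`,
- synthetic risk factor `SRF = MEC / (PNEC · C) = RQ · T_1/2 / T_CV`,

and classifies RQ and SRF into four ordered hazard bands. The SRF is an
algebraic reweighting of the RQ: compounds whose half-life exceeds the
compartment's persistence boundary value (`C < 1`) are promoted, short-lived
ones demoted, and `T_1/2 = T_CV` leaves the score unchanged. The method
assumes one MEC per compound (aggregation across samples — mean, median,
worst case — is the caller's choice upstream), assesses compounds
individually (no mixture/concentration-addition effects), and treats
half-life and toxicity values as given inputs, never estimated from
structure.

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `T_CV` water | 60 | d | Stockholm Convention Annex D stability cut-off |
| `T_CV` soil, sediment | 180 | d | idem |
| acute assessment factor | 1000 | — | EC50/LC50 → PNEC divisor |
| chronic assessment factor | 100 | — | ChV → PNEC divisor |
| band edges | 0.01, 0.1, 1 | — | negligible / minimal / medium / high |

All concentrations are ng/L internally; µg/L and mg/L suffixes convert on
input (×10³, ×10⁶). `T_CV` and the assessment factors are defaults, not
universal law, and can be overridden per run from a YAML config.

## Numerical and design choices

**Band boundaries.** The band definitions in common use leave the points
0.1 and 1 formally unassigned ("0.01 < x < 0.1", "0.1 < x < 1"). Each
interior boundary is assigned here to the *higher* band — the conservative,
protective reading — except 0.01, which is conventionally inclusive in
negligible. `classify` is therefore monotone and total on [0, ∞).

**Rounding modes.** `full_precision` (default) carries `C = T_CV/T_1/2`
exactly; recommended for real use. `table_rounded` reproduces arithmetic
performed on published rounded tables: the rounded `C` printed in a source
table (carried by fixtures as `c_reference`) enters the SRF division, e.g.
imazalil's SRF prints as 1.66 with the tabulated C = 0.40 but 1.67 at full
precision. Records without a tabulated C fall back to rounding the computed
C to 2 significant figures, the modal precision of such columns. Rounding
error is never propagated unless this mode is explicitly requested.

**Endpoint precedence.** If both acute and chronic endpoints are supplied
for a compound, the chronic one is used — chronic data are the preferred
basis for long-term risk, acute endpoints a fallback.

**Degenerate inputs.** Zero MEC is valid (RQ = SRF = 0, negligible);
non-positive half-life, PNEC, endpoint, `T_CV` or `C` are rejected with the
error code `invalid-value`. Malformed CAS numbers (which occur verbatim in
published tables) warn but do not reject the record; CAS is identity
metadata, not an input to the equations. Molecular formulas are display-only
and never parsed.

**Known discrepancies in the bundled tables.** Two endocrine-disruptor
narrative claims do not survive their own table's arithmetic, and the
regression tests assert the computed outcome: progesterone
(8.1/415/0.09 ≈ 0.22) lands at medium under SRF, not high; androstenedione's
RQ (4.4/14 ≈ 0.31) starts at medium, not a low band, before rising to high
under SRF. Both still move *up*, which is the substantive claim.

## Synthetic data generator

`generate_synthetic_table` draws half-life, MEC and PNEC log-uniformly
(defaults 10⁻¹–10⁷ d, 10⁻²–10³ ng/L, 10⁻¹–10⁶ ng/L), spanning the orders of
magnitude seen in real monitoring tables — from organophosphate esters that
hydrolyse in about four days to bisphenol A's 4×10⁶-day half-life, and from
sub-ng/L hormone PNECs to mg/L levels. It emulates the *ranges and spread*
of monitoring data, not their structure: real tables have correlated
exposure and toxicity within compound families, heavy-tailed MEC
distributions, censored values and inter-site variance, none of which are
modelled. Property tests on synthetic tables therefore certify the algebra,
the classification and the I/O contract, not field performance of the
screen. Generation is deterministic for a fixed seed (numpy `default_rng`);
a degenerate (pinned) range returns the exact value rather than
`exp(log(x))` to keep identities such as `SRF = RQ` at `T_1/2 = T_CV` exact.

## Problem sizes

The bundled case studies are 8, 7 and 5 compounds; bulk property tests run
on 10⁴ synthetic compounds and the acceptance script self-checks on 10³,
sizes at which every identity can be checked exhaustively in seconds.

## Limitations

- Screening-level point estimates only: no species sensitivity
  distributions, no probabilistic exposure, no uncertainty propagation.
- One compartment per record; multi-media fate modelling is out of scope.
- The persistence weighting is linear in half-life by construction; very
  long half-lives can push SRF orders of magnitude above RQ, which is the
  intended alarm behaviour but means SRF is not bounded by the exposure
  margin alone.
- The log-axis comparison plot clamps values below 10⁻⁸ to a floor with an
  annotation; zero is unplottable on a log scale.
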