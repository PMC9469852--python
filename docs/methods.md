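# Methods

## Quantitation model

Amounts are obtained by single-point internal-standard (IS) calibration
with a unit mass-response assumption: for analyte *i* with peak area *Aᵢ*
and an IS of spiked mass *m_IS* (mg) and area *A_IS* in a sample of mass
*m* (g),

    amountᵢ [mg/100 g] = (Aᵢ / A_IS) · m_IS · 100 / m .

The model assumes (i) the detector response per unit mass is the same for
every FAME and the C19:0 IS (response factors are configurable per FA but
default to 1), (ii) IS and analytes share the vial from extraction onward,
so dilution and injection-volume factors multiply both areas and cancel —
the configured `dilution_factor` is bookkeeping and provably never changes
a result — and (iii) the IS species (C19:0, odd-chain) is absent from the
sample; an analyte parsed as straight-chain C19:0 is rejected as a
collision. A missing or zero-area IS peak is an error, never a division
producing infinity.

The spiked mass is `stock concentration (mg/ml) × volume (µl) / 1000`. By
default the full spike mass is used. An optional *acyl correction*
multiplies by the fatty-acid mass fraction of the standard (0.959 for
trinonadecanoin, 0.730 for di-C19:0 phosphatidylcholine, 1 for the free
acid), accounting for the glycerol/head-group overhead when the spike is a
TAG or phospholipid; it is off by default, matching the common shortcut of
quoting the spike as weighed.

## Composition and aggregation

Composition is `amountᵢ / Σ amounts × 100`; it is undefined (an error) for
an empty profile. Replicates aggregate in two stages: technical replicates
are averaged within each fish, then the mean and sample SD (n−1) are taken
across fish. A pooled single-stage option exists because published tables
do not always state which convention was used. An FA missing from a
replicate contributes 0 to that replicate; an FA absent from every
replicate of a group is reported as "n.d." rather than 0 ± 0.

## Nutritional indices

Class sums partition every FA by double-bond count (SFA 0, MUFA 1, PUFA
≥ 2); omega sums cover exactly the FAs of that n-series, so minor families
(n-4, n-7, …) appear in ΣPUFA but in neither Σn-3 nor Σn-6. The
Ulbricht–Southgate indices are

    AI = (C12:0 + 4·C14:0 + C16:0) / (ΣMUFA + Σn-6 + Σn-3)
    TI = (C14:0 + C16:0 + C18:0) / (0.5·ΣMUFA + 0.5·Σn-6 + 3·Σn-3 + Σn-3/Σn-6)

with the named saturates taken as straight-chain species only; branched
isomers count toward ΣSFA but never toward a numerator. Both indices are
defined on the composition (% of total) basis. This is not cosmetic for
TI: its last denominator term is a dimensionless quotient while the other
terms carry the profile's scale, so the same formula applied to raw
mg/100 g amounts gives a different number. The implementation therefore
normalizes any input profile to percent of total before applying either
formula, which (a) reproduces the published wild/farmed/feed values
(TI 0.22/0.18/0.21) and (b) makes AI, TI and n-6/n-3 exactly invariant
under uniform scaling, so amount and composition inputs agree to 1e-12
relative. Indices are computed on group-mean profiles by default (one
value per group), with per-fish values available by aggregating first.

When verifying against printed tables, the amount columns are used as
input: they carry more significant figures than the two-decimal
composition percentages, whose independent rounding can shift a borderline
index (wild AI is 0.4252 from amounts but 0.4249 from the rounded
percentages — the printed value, 0.43, matches the former).

## SPE fractions

Blank subtraction targets a configurable contaminated set (default C14:0,
C16:0, C18:0, the known aminopropyl-column bleed in the FFA eluent): the
mean blank area per SPE column type is subtracted from matching
FFA-fraction peaks; negative results clip to 0 and are flagged. A marker
column guards against double correction — re-subtracting nonzero blanks
into an already corrected table raises. Fraction profiles are percentages
of each fraction's total peak area and fraction shares are each fraction's
percentage of the summed NL+FFA+PL area, both computed per replicate on
the raw-area basis (no cross-fraction response correction) with IS peaks
excluded, then aggregated two-stage like amounts. Shares sum to exactly
100 per replicate before aggregation.

## Dietary assessment

Per-portion intakes scale linearly: `intake = amount × portion/100` (200 g
default portion). The EPA+DHA sufficiency inverts this against the EFSA
recommendation (250–500 mg/day; weekly 1.75–3.50 g), reporting the fillet
grams to meet the daily target rounded to the nearest gram for display
while retaining the exact value. The erucic-acid check compares
C22:1n-9c intake from a consumed mass against 7 mg/kg body weight/day.

## Synthetic data generator

The generator emulates the targeted study design: n fish per group
(default 3), technical replicates split over two series (default 4), IS
spikes with the reference volumes (e.g. 100 µl of 10 mg/ml C19:0 TAG for
wild salmon), per-group dilution, SPE fractionation over two column types,
and FFA blank contamination with matching blank runs. Areas follow a
proportional response: `area = R · mass_in_vial / dilution · F_fish · ε`,
with a per-fish lognormal multiplier (CV `fish_cv`, default 0.15, the
order of the between-fish spread in the reference amounts) and i.i.d.
lognormal measurement noise (CV `cv`, default 0.05). All lognormal factors
are parameterized to mean 1; multiplicative lognormal noise keeps areas
positive and right-skewed, as detector areas are. The same response and
dilution apply to the IS, so at zero CV quantitation inverts the generator
exactly — a property the tests exploit — and at nonzero CV the ratio
estimator carries only the small lognormal ratio bias (≈ cv², 0.25% at
cv = 0.05).

What the generator does *not* emulate: peak overlap and integration error,
retention-time drift, per-FAME response differences, SPE recovery losses
and cross-fraction carryover, and FA-specific fraction partitioning (the
preset partitions apply one NL/FFA/PL split, the group's published
fraction shares, uniformly to all FAs). Passing round-trip tests therefore
validate the arithmetic and its inversion, not robustness to those
instrument effects.

## Numerical and display choices

Display rounding is half-up (ties away from zero, matching printed
tables): amounts 0 decimals ≥ 1000, 1 decimal ≥ 100, else 2; compositions
and indices 2 decimals. Rounding affects rendering only. Composition
closure is asserted to ±0.1 (accumulated rounding); reconstruction of
printed subtotal rows from printed per-FA rows is asserted to ±0.05
percentage points (rounding of the addends); recomputed products/sums of
printed values are compared to one unit in the printed last digit.

## Problem sizes

The test suite runs the Monte-Carlo recovery study at 200 simulations of
3 fish × 8 replicates (≈ 15 s), checking that each FA's mean recovered
amount lies within 2 standard errors of truth; all other tests are
sub-second. The acceptance script uses a noiseless 3-fish × 4-replicate
run, which is exact by construction.

## Known limitations

Single-point calibration cannot capture detector nonlinearity;
multi-point curves are out of scope. Indices beyond AI/TI/n-6/n-3
(h/H ratio, PUFA/SFA) are not implemented. Provisional identifications
(library-search-only FAs) are carried like confirmed ones, with an
optional report flag.
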