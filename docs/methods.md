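# Methods

This note records the models, conventions, and numerical choices behind
`waxmrm`, and what the synthetic-data tests do and do not demonstrate.

## Mass model

All masses are monoisotopic sums over IUPAC atomic masses (C 12.000000,
H 1.0078250319, O 15.9949146221, N 14.0030740052, D 2.0141017780). Isotope
envelopes are not modeled: a unit-resolution triple quadrupole selects the
monoisotopic peak, and every quantity the package reports is either an exact
*m/z* or a nominal (integer) *m/z*.

Charge carriers: the proton mass 1.00728 Da for [M+H]⁺ and 18.03383 Da for
[M+NH₄]⁺; the electron mass is ignored, which is standard at unit
resolution and three orders of magnitude below the matching tolerances used
here. **Nominal m/z** is round-half-up of the monoisotopic *m/z*. This
convention reproduces the published integer anchors for ten of the eleven
worked examples; the eleventh (the C40:1 diol-FA fragment, computed
589.5918, printed 589) shows that unit-resolution rounding in the
literature is not consistent, so *comparisons against literature integers*
use |Δ| ≤ 1 while the package's own outputs stay exact.

## Chain-block chemistry

Each moiety's formula is forced by its kind and its C*n*:*d* shorthand
(*n* carbons, *d* double bonds):

| kind | formula |
|---|---|
| fatty acid (FA) | CₙH₂ₙ₋₂dO₂ |
| fatty alcohol (FAl) | CₙH₂ₙ₊₂₋₂dO |
| 1,α- / 1,ω-fatty diol | CₙH₂ₙ₊₂₋₂dO₂ |
| α- / ω-hydroxy FA | CₙH₂ₙ₋₂dO₃ |
| diol-FA conjugate (derived) | CₙH₂ₙ₋₂dO₃ |
| OAHFA (derived) | CₙH₂ₙ₋₂₋₂dO₄ |

A species' formula is the sum of its component formulas (plus cholesterol
C₂₇H₄₆O for the cholesteryl classes) minus one H₂O per newly formed ester
bond; derived conjugates already embed one ester. Two consequences are
tested as invariants: every wax diester of total C*n*:*d* is
CₙH₂ₙ₋₂₋₂dO₄ regardless of type (1α/1ω/2α/2ω — they are constitutional
isomers, which is exactly why MRM is needed), and every wax monoester is
CₙH₂ₙ₋₂dO₂.

Type 2 WdiE species can be built from full components (diol + FA + FA) or
from the two-part readout an MRM transition actually identifies (one FA +
the diol-FA conjugate); both give the same molecule, and the shorthand
(`2ω-WdiE 20:1/54:2`) encodes only the two-part readout. Iso/anteiso
branching is a bookkeeping flag that never alters a formula; the LC layer
sees branched species as an earlier retention peak, handled by doublet
merging in the quantify module.

## Fragment rules

- acylium [FA − OH]⁺: FA + H⁺ − H₂O (the FA-diagnostic cluster).
- dehydrated diol-FA [M + H − (FA − OH) − H₂O]⁺: diol-FA + H⁺ − H₂O.
  Algebraic identity, tested grid-wide: acylium + diol-FA fragment =
  [M+H]⁺ + 1.00728 − 18.01056.
- cholestadienyl C₂₇H₄₅⁺ = cholesterol + H⁺ − H₂O = 369.3516 (both
  cholesteryl classes).
- ω-OH-FA channel for Chol-OAHFA: dehydrated protonated ω-OH FA. The true
  diagnostic ion for this class is not firmly established, so this rule is
  a registry default users can replace.
- WmE: one FA-derived ion whose species depends on FA saturation. Default
  mapping: saturated FA → protonated FA, mono-unsaturated FA → acylium
  (water loss is facile for unsaturated acyl cations). Both directions are
  configurable (`FragmentConfig`) because the literature does not pin the
  saturated-FA product ion down.
- Type 1 WdiEs ship with **no** default channels — their diagnostic
  fragments are not established and the package does not invent chemistry;
  `FragmentConfig.with_extra` registers user-supplied rules.

Chol-OAHFA species enumerated at the OAHFA level (total C:d only) emit only
the split-independent cholestadienyl channel; species built with an
explicit (ω-OH FA, FA) split get all three channels.

## MRM method generation

One transition per (species × fragment channel); Q1 uses the class adduct
rule (ammonium for Chol-E, proton otherwise). Collision energies are
per-class defaults — 30 eV for wax diesters and 15 eV for Chol-OAHFA (the
product-ion-scan settings), 25 eV placeholders for WmE and Chol-E whose
per-species tuning values are instrument-dependent — all overridable per
row. Dwell time defaults to 0.03 s. Ion-source parameters and the LC
gradient are carried as metadata only. Method CSV output is byte-stable:
fixed header, *m/z* at 4 decimals, deterministic (class, compound, Q3)
ordering.

`validate_method` reports three things and raises on none: co-measured
(Q1, Q3) pairs within 0.5 Da, Q3 ≥ Q1 rows, and compound pairs that share
Q1 within 0.5 Da but differ in Q3 — the isobars MRM can resolve and LC-MS
cannot.

## Spectrum annotation

For a type 2 WdiE precursor of total C:d, all FA/diol-FA splits compatible
with the FA constraint are enumerated; each centroid is assigned to the
nearest theoretical fragment within the matching tolerance (default 0.5 Da,
the unit-resolution instrument class; configurable). Ties go to the smaller
|mass error|, then the smaller FA carbon count, and losing candidates are
recorded as alternatives rather than dropped, because real scans of
co-isobaric species have heavily overlapping clusters. Peaks with no
candidate are labeled unassigned. The dominant split is the one with the
highest summed assigned intensity (ties broken lexicographically). A
precursor inconsistent with the hypothesis beyond tolerance is an error
stating both values.

## Quantification and statistics

External calibration is unweighted OLS with intercept by default; 1/x
weighting is available and is the appropriate choice when a series spans
multiple decades (it keeps the intercept variance at the scale of the
lowest standards instead of the highest). The reported linear range is the
amount span of the longest contiguous run of points whose relative residual
is within 15% (configurable). Amounts are dilution × (area − intercept) /
slope, clipped at zero with a flag; areas outside the calibrated range are
flagged extrapolated. Internal-standard quantification uses a single-point
unit response factor, reflecting a semi-quantitative profiling design where
class-matched standards are unavailable; within-class comparisons remain
valid, absolute cross-class totals should not be over-read.

Group comparison: two groups → two-sided Welch's *t* per category; more
than two → Tukey's HSD over all pairs. Significance is starred at 0.05 (\*)
and 0.01 (\*\*). No multiple-testing correction is applied by default —
per-species testing without correction mirrors common practice in this
assay class — and Benjamini–Hochberg can be layered on by the user. Amounts
are normalized per basis (per 10 mg hair for sebum, per eyelid pair for
meibum) carried as table metadata.

## Synthetic-data generator

The generator emulates the *structure* of the measurement, not real sebum:

- **WT-like truth template.** Per-class totals (pmol per 10 mg hair) are
  order-of-magnitude choices: WmE 2000, 2α-WdiE 400, 2ω-WdiE 600,
  Chol-OAHFA 150, Chol-E 3000. Within a class, weights encode the reported
  qualitative orderings: C16:0 the dominant WmE FA (then C18:1, C16:1);
  saturated FAls bimodal at C16 and C26 and mono-unsaturated FAls near
  C31–C34; mono-unsaturated diol-FAs dominant in 2α-WdiEs peaking near
  C40; di-unsaturated diol-FAs dominant in 2ω-WdiEs peaking at C52/C54/C56
  for the C18:1/C20:1/C22:1 FAs; di-unsaturated OAHFAs peaking at C56; an
  even-carbon bonus reflects biosynthesis. Gaussian carbon profiles and the
  weight numbers are smooth stand-ins, not measured values.
- **Knockout scenarios** are exact multiplicative edits of the WT template,
  so effect sizes hold exactly at truth level: the very-long-chain-FAl
  scenario multiplies species whose FAl/diol backbone is ≥ C21 by 0.12;
  the long-chain-FA scenario multiplies WmE and 2ω-WdiE species with
  saturated FAs ≤ C17 or mono-unsaturated FAs ≤ C19 by per-chain factors
  (C16:1 → 0.22, C18:1 → 0.09, otherwise 0.15). For a WdiE known only as
  (FA, diol-FA), the diol chain length is taken as diol-FA carbons minus
  the observed FA's carbons (symmetric-split assumption).
- **Noise.** Replicate areas are slope × amount × LN(cv) + baseline with a
  mean-one lognormal (keeps areas positive); the biological replicate CV
  defaults to 0.2, a typical n = 3 spread, stated as an assumption —
  replicate-level dispersion is not published for this assay. Calibration
  series use a separate technical injection CV of 0.05: standards are
  repeated injections of pure dilutions, not independent animals.
- **Cage mixing.** Observed profile = (1 − α)·own + α·(mean of cage-mates).
  This redistributes material within a cage and exactly conserves the cage
  total; α = 0.5 reproduces a knockout animal appearing at 50% of its
  cage-mate's level while co-housed, α → 0 the separated design.
- **Product-ion scans** place centroids at the exact theoretical fragment
  *m/z* of each injected split with weight-proportional intensities (the
  diol-FA channel scaled by 0.8) and seeded lognormal intensity noise.
  Peak-position jitter is not simulated, so annotation round-trip tests
  demonstrate correct assignment logic, not robustness to mass-axis error.

All generators are deterministic given one integer seed.

## Monte-Carlo recovery experiment

`far2_recovery_experiment` runs, per seeded replicate: WT and knockout
truth over the C16:0-FA WmE family (C16–C40 FAls, 50 species — the
single-FA panel design the knockout analysis uses, which keeps every
aggregated species at a quantifiable amount), n = 3 samples per group at
CV 0.2, a ten-point calibration at technical CV 0.05 fitted with 1/x
weighting, external quantification, and two summary statistics: the
recovered total WT amount and the knockout percent-of-reference for the
very-long-chain-FAl aggregate. Defaults: 500 runs (< 1 s). The headline
checks are that recovery is unbiased within 3× the standard error of the
run mean and that the percent-of-reference lands in [8%, 18%] (truth 12%)
in ≥ 80% of runs. The 1/x weighting matters here: an unweighted intercept
on a 2.5–1280 pmol doubling series carries ±0.3 pmol of noise that, applied
as a common offset across dozens of species, would dominate aggregate
ratios — the same reason practitioners weight wide-range calibrations.

## Degenerate inputs and tie-breaks

Empty grids enumerate to empty lists (not errors); zero-area LC doublets
merge to zero with an undefined branched fraction (NaN); calibration with
fewer than two distinct amounts, non-positive fitted slopes, and zero
internal-standard areas are errors; groups with fewer than two replicates
skip the test with a warning but still report means; all-zero composition
scopes are errors. Annotation ties and dominant-split ties break
deterministically (smaller |error|, smaller FA carbons; lexicographic).

## Known limitations

Double-bond positions, iso vs anteiso discrimination, sn-position
regiochemistry, isotope envelopes, retention-time scheduling, and vendor
raw files are all out of scope. The preset grids encode the chain ranges
reported for mouse sebum in the main literature source of each class;
ranges beyond those explicitly printed (Chol-E, Chol-OAHFA) are marked
`extrapolated` and every preset is user-overridable. Passing synthetic
tests demonstrates internal consistency of the chemistry and pipeline, not
agreement with any particular biological sample.
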