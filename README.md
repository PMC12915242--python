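# waxmrm

Targeted lipidomics of sebum and meibum **wax esters** on a triple-quadrupole
mass spectrometer, as a reusable Python library plus a small CLI.

Sebaceous-gland lipidomes are dominated by ester lipids built from
interchangeable chain blocks: wax monoesters (WmE, a fatty acid esterified to
a fatty alcohol), type 1 and type 2 wax diesters (WdiE, three chains around a
hydroxy-FA or fatty-diol core, with the hydroxyl at the α or ω position),
cholesteryl esters (Chol-E), and cholesteryl (*O*-acyl)-ω-hydroxy fatty acids
(Chol-OAHFA). Species of one class with the same total carbons and double
bonds are constitutional isomers — identical precursor *m/z*, often identical
LC behavior — so distinguishing them requires multiple-reaction-monitoring
(MRM): select the precursor in Q1, fragment it, and select a
moiety-diagnostic product ion in Q3. `waxmrm` implements the chemistry and
bookkeeping this workflow needs:

- **chem** — elemental-formula arithmetic, monoisotopic masses, proton /
  ammonium adduct *m/z*, deuterium-labeled internal standards.
- **species** — chain moieties (FA, FAl, fatty diols, hydroxy-FAs, derived
  diol-FA / OAHFA conjugates), species assembly with per-class recipes, grid
  enumeration, shorthand names (`2α-WdiE 16:1/40:1`) with round-trip parsing.
- **fragments** — product-ion rules: the acylium [FA − OH]⁺, the dehydrated
  diol-FA conjugate [M + H − (FA − OH) − H₂O]⁺, the cholestadienyl cation
  C₂₇H₄₅⁺ (369.3516), and a configurable WmE channel keyed on FA saturation.
- **method** — instrument-ready MRM transition tables (Q1/Q3, collision
  energy, 0.03 s dwell) with validation for co-measured channels and
  MRM-resolvable isobars.
- **annotate** — product-ion-scan interpretation: enumerate the co-isobaric
  FA/diol-FA splits of a precursor, assign centroids to the FA or diol-FA
  fragment cluster, report the dominant split. Reads MGF, two-column CSV and
  (read-only) mzML.
- **quantify** — calibration-curve fitting (OLS, optional 1/x weighting),
  external and internal-standard quantification, LC-doublet (iso/anteiso)
  merging, compositional profiles, and Welch *t* / Tukey HSD group
  comparisons with percent-of-reference.
- **simulate** — a seeded synthetic-data generator for the whole design:
  ground-truth compositional profiles, knockout scenarios (loss of
  very-long-chain fatty alcohols; loss of long-chain-FA esters), replicate
  peak tables, ten-point calibration series, product-ion scans, and cage
  co-housing cross-contamination.

## Worked example

The most abundant 2α-wax-diester in mouse sebum pairs a C16:1 FA with a
C40:1 diol-FA conjugate:

```python
from waxmrm import LipidClass, build_species, fragment_set
from waxmrm.species import ChainKind, ChainMoiety

fa  = ChainMoiety(ChainKind.FA, 16, 1)
dfa = ChainMoiety(ChainKind.DIOL_FA, 40, 1)
sp = build_species(LipidClass.WDIE_2A, (fa, dfa))
print(sp.shorthand, sp.formula, f"{sp.precursor_mz:.4f}", sp.nominal_precursor_mz)
for f in fragment_set(sp):
    print(f.rule, f.moiety, f"{f.mz:.4f}", f.nominal_mz)
```

prints

```
2α-WdiE 16:1/40:1 C56H106O4 843.8164 844
acylium 16:1 237.2213 237
diolFA_dehydrated 40:1 589.5918 590
```

i.e. the protonated precursor is measured at nominal *m/z* 844 and its two
diagnostic MRM channels at 237 (the FA) and ~590 (the dehydrated diol-FA;
unit-resolution reports round this inconsistently, so literature comparisons
use a documented |Δ| ≤ 1 tolerance). Annotating a product-ion scan of that
precursor recovers the split:

```python
from waxmrm import Spectrum, SpeciesHypothesis, annotate_spectrum

scan = Spectrum.from_peaks(844.0, [(237.22, 80.0), (589.59, 60.0)])
res = annotate_spectrum(scan, SpeciesHypothesis(LipidClass.WDIE_2A, 56, 2),
                        tolerance=0.5)
res.dominant_split()   # -> '16:1/40:1'
```

The full synthetic pipeline — species grids → MRM method → simulated
knockout cohorts → calibration → quantification → Welch tests — runs from
the shell:

```sh
waxmrm demo --seed 1 --out-dir demo_out
waxmrm build-method --preset WmE --preset "2α-WdiE" --out method.csv
waxmrm simulate --scenario Far2KO --seed 5 --out-dir ko_run
```

`demo` verifies eleven worked-example *m/z* anchors and writes a transition
table, quantification table, and group-comparison report.

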