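# Methods

This note documents the models implemented in `rendr`, the defaults they
use, and the design decisions taken where more than one reasonable choice
existed. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Construct model and splice-site rule

A sensor construct is modelled as `exon1 + intron + exon2`, where the
intron is the splicing ribozyme. Two facts of group I intron biochemistry
are encoded as hard rules: the 5' exon must end in a uracil (the 5'
splice site lies immediately after a U), and splicing is exon ligation
with exact excision of the intron. Everything downstream of those rules —
whether a given split site yields a *catalytically* competent ribozyme,
3'-splice-site chemistry, protein folding — is out of scope; the library
screen exists precisely because competence cannot be predicted from
sequence.

Coordinates are 1-based throughout, matching how split sites are labelled
on construct maps: split index `s` is the cut between ribozyme positions
`s` and `s+1`, so a ribozyme of length L has L−1 candidate sites. Guides
are attached with guide1 at the 3' end of the 5' fragment and guide2 at
the 5' end of the 3' fragment, so both guides face the input between the
fragment ends; the linker-free attachment is a simplification of
schematic construct drawings, and removing the guides and re-joining the
cores must reproduce the ribozyme exactly (a tested invariant).

Mismatch scans substitute `round(fraction · L_interaction)` uniformly
drawn guide positions with bases that can pair the facing input base
neither canonically nor by GU wobble, so a designed mismatch stays a
mismatch under both energy backends.

## Thermodynamic expression model

The predictor compares the initial state (guides and input folded
independently) with the extended duplex (both guides fully hybridised to
their windows):

    ΔG_Predicted = ΔG_guide1 + ΔG_guide2 + ΔG_input − ΔG_ED

Only the two guides and the input enter the calculation; the ribozyme
cores are excluded. The ED is evaluated as a single fully-constrained
complex: every non-mismatch guide position pairs its window position,
mismatch positions stay unpaired, and input regions outside the windows
may still fold. With zero-length guides the ED therefore reduces to the
input's own MFE and the predictor is 0. An ensemble/partition-function
treatment (test-tube concentrations, suboptimal complexes) was the main
open alternative; the single-complex reading was chosen because the
predictor only ever enters a linear regression, where the constrained
complex energy and an ensemble energy differ mostly by an affine
rescaling absorbed into the fitted slope.

Expression is modelled as `ln(FL/OD) = a + b·ΔG_Predicted + ε`, fitted by
ordinary least squares (statsmodels). FL/OD values at or below the
blank-cell autofluorescence are floored there before the log and excluded
from the fit by default: an off-state well measures autofluorescence, not
splicing output, and `ln 0` is undefined. The no-guide (length-0) control
lands on the floor by construction and is excluded the same way.

### Energy backends

Two implementations of the backend contract (`mfe`, constrained `mfe`,
constrained duplex energy; 37 °C, deterministic):

* **internal** — Watson–Crick nearest-neighbour model with the Turner-rule
  duplex stack set (Xia et al. 1998 values, 1 M NaCl-equivalent) shipped
  as a TSV. Duplex energy is the stack sum per contiguous helix block
  plus one initiation penalty and terminal-AU penalties *per block*;
  per-block initiation makes the energy exactly additive over
  mismatch-separated blocks and guarantees that adding a mismatch never
  stabilises the duplex (both tested invariants). Monomer folding is a
  single-hairpin approximation: best single helix closing a loop ≥ 3 nt,
  scored with hairpin-loop initiation penalties (loops > 9 extrapolated
  with 1.75·RT·ln(n/9)); GU pairs and multi-helix structures are ignored.
  This is deliberately minimal — it exists so that every qualitative
  property of the model (monotonicity in interaction length, mismatch
  penalties, sign conventions) is testable with no external software.
* **vienna** — adapter over the ViennaRNA python bindings: full
  secondary-structure MFE for monomer terms (hard constraints for the
  ED-blocked input), and two-strand complex evaluation with the designed
  pairing imposed for duplex terms (includes ViennaRNA's intermolecular
  initiation). This is the backend for quantitative work. Treating the
  trimolecular ED as two independent bimolecular duplexes plus the
  constrained input double-counts one association penalty relative to a
  true three-strand complex; as above, an affine offset absorbed by the
  regression.

## FACS-seq enrichment

Reads are assigned to split sites by locating the junction between the 5'
ribozyme fragment and guide1: the last `min_anchor` bases of
`upstream + ribozyme[1..s]` followed by the first `min_anchor` of guide1.
Defaults `min_anchor = 12`, `max_mismatches = 1`: a 24-nt exact match is
essentially unique in a 420-nt reference, and one tolerated substitution
recovers the bulk of reads at amplicon-sequencing error rates (at 0.5%
per-base error, ~99.3% of junction windows carry ≤ 1 error). Matching is
exact-first with a pigeonhole half-anchor fallback, searches both
orientations, and requires a unique site across all matching windows
(ambiguous or unmatched reads are tallied with reason codes; assigned +
unassigned always equals input reads). The `upstream` context models the
vector sequence 5' of the ribozyme in the real amplicon and makes sites
`s < min_anchor` assignable.

Relative enrichment of a site is its mean sorted-library frequency over
its mean unsorted-library frequency, with a pseudocount of 0.5 reads
(scaled by the mean library total) in numerator and denominator to keep
zero-count sites finite; log2 enrichment is also emitted. Frequencies are
computed per library and averaged across replicates *before* the ratio.
Significance per site is a homoscedastic two-sample two-tailed t-test on
the replicate frequencies (α = 0.05 downstream), with the zero-variance
degenerate case mapped to p = 1 for identical groups. Sites with zero
sorted reads are flagged as lost during selection (a frequency threshold
can be supplied instead; the rule used is recorded in the output
metadata).

Spliced- versus unspliced-product fractions classify each read by exact
central-2k-mer junction probes with precedence spliced → unspliced →
other.

## Colony screen scoring

FL and OD are corrected by subtracting media-blank means (per condition
when per-condition blanks exist, plate-wide otherwise); blank-cell wells
measure autofluorescence and are reported, not subtracted. The on/off
separation of a variant is `(FL/OD_on − FL/OD_off)/√2` — its distance
from the x = y diagonal of an on-vs-off scatter. Variants are split into
rank-based tertiles per replicate (sizes differ by ≤ 1; ties broken by
variant id so the labelling is order-independent — the boundary rule is a
package choice, as tertiles could also be cut by value), and a variant is
called functional when it lands in the top two tertiles in both
replicates.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure* the analysis relies
on, not the biology:

* **References** — the ribozyme (420 nt, hence 419 split sites), reporter
  CDS (U-initial codon at position 66, emulating insertion within a
  tyrosine codon) and RNA inputs are seeded uniform-composition synthetic
  stand-ins, not natural sequences. Nothing in the pipeline depends on
  the natural sequence identity except the splice-site uracil rule, which
  the CDS stand-in encodes.
* **Library** — site proportions are symmetric-Dirichlet
  (concentration 1/skew; skew 0 = exactly uniform); a planted subset
  (default 20 of 419) is functional with on-activity lognormal around
  30,000 FL/OD (CV 0.25); everything else sits at the autofluorescence
  level 200. The on/off levels are round numbers in the range typical of
  bacterial fluorescent-reporter assays, chosen once.
* **Sorting** — per-cell fluorescence is lognormal with CV 0.3 around the
  site's activity (typical width for bacterial reporter distributions);
  rounds default to top-14% (on), bottom-85% (off, inhibitor present),
  top-14% (on). Gate thresholds are the exact mixture quantiles and
  retention is binomial per site, so the realised retained fraction
  matches the gate fraction to within sampling error; growth between
  rounds is unbiased multinomial resampling. Sorter optics, doublets and
  growth-rate differences are not modelled.
* **Reads** — substitution-only errors (typical of the amplicon-service
  class of data; indels are not modelled) at a default 0.5% per base,
  constant Phred+33 qualities consistent with the rate.
* **Plates** — `FL/OD = exp(a + b·ΔG + N(0, σ²))` floored at
  autofluorescence, decomposed into raw FL/OD with media-blank offsets so
  blank correction inverts the decomposition exactly at σ = 0. Defaults
  `a = ln 200` (the floor at zero predictor), `b = 0.008 (kcal/mol)⁻¹`
  (spans autofluorescence to ~3·10⁴ FL/OD over the ~1000 kcal/mol
  predictor range of the guide-length panel), `σ = 0.4` ln-units
  (40%-level well-to-well CV).

Passing tests on these data show the *algorithms* are correct and the
statistics calibrated (type-I error, parameter recovery, enrichment
ranking); they cannot show that real libraries are as well-separated or
that real expression follows the ln-linear model as cleanly.

## Problem sizes and numerical choices

The simulation-backed checks run at: 200,000 cells per sorting round,
100,000 reads per sequenced library (counts-level multinomial sequencing
for the 20-replicate recovery study; full FASTQ text for the read-matching
validations at ≤ 10⁴ reads), 1,000 null replicates for t-test
calibration, and 200 replicates for regression-recovery coverage. The
brute-force read-scan oracle bounds its fixtures at 10⁴ reads. All
generators accept explicit seeds and are bit-reproducible; `hypothesis`
is not used — randomised property tests draw from seeded numpy
generators. Frequencies per library must sum to 1 within 1e−9; OLS
recovery at σ = 0 is asserted to ~1e−12.

## Known limitations

* The internal backend's monomer folder is hairpin-only and WC-only; it
  under-folds structured inputs relative to ViennaRNA and is unsuitable
  for quantitative prediction.
* The ED model fixes the designed pairing; competing registers,
  partial hybrids and strand-displacement kinetics (relevant to the
  toehold inhibitor) are not modelled.
* Junction assignment assumes the amplicon design places guide1 directly
  after the 5' fragment; other amplicon layouts need a different junction
  definition.
* The quantitative benchmark against externally characterised guide-length
  / input-length / mismatch panels requires the original measurement data,
  which are not redistributed here; the corresponding acceptance test
  fails by design rather than skipping (see the test docstring).
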