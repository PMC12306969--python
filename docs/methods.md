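# Methods

This note documents the models, parameters and design choices behind the
`isbh` toolkit: what each module computes, which defaults matter, what the
synthetic data emulates, and where the limits are.

## The hairpin switch

A native sgRNA is spacer (20 nt) + scaffold. An inducible
spacer-blocking hairpin sgRNA (iSBH-sgRNA) prepends, 5'→3':

```
GC clamp | backfold | loop | [extension] | spacer | scaffold
```

The backfold is a partially complementary copy of the 3' arm
(spacer, or extension+spacer), so the cassette folds into a long stem
closed by the loop and the spacer is sterically blocked. A trigger RNA
complementary to backfold+loop forms a longer, fully Watson-Crick duplex
than the mismatched stem, so trigger binding is thermodynamically
favoured and opens the switch. The GC clamp exists for expression
chemistry (the G promotes Pol III initiation; the C pairs the first
scaffold G) and is excluded from all fold targets, as is the scaffold.

Three generations:

* **first**: backfold = spacer\* (20 nt), loop 14 nt → cassette 54 nt,
  trigger core 34 nt, engineered addition 36 nt;
* **second**: a 10 nt extension between loop and spacer, its complement
  extending the backfold to 30 nt → cassette 74 nt, trigger core 44 nt,
  addition 56 nt;
* **modular**: same 74-nt-class cassette, but only the loop-proximal
  15 backfold nt + loop come from the trigger (see MODesign below).

**Mismatch rule.** Designed mismatches sit at stem positions 11-12 and
16-17 of spacer\* and 1-2 and 6-7 of extension\* (1-based along each
starred segment). At a mismatch position the complementary base is
replaced by *the base identical to its partner* (A·A, C·C, G·G, U·U).
This is deterministic and maximally disruptive: an identical-base
apposition can form neither a Watson-Crick nor a G·U wobble pair, so a
"mismatch" can never silently re-pair. Mismatch positions are recorded
per design so alternative rules can be configured downstream.

**Target structures** are constructed programmatically: fully nested
pairing of position *i* with *N*+1−*i* across the cassette, dots at the
designed mismatch positions and their partners, loop unpaired. For the
first generation this renders the canonical 54-symbol string
`((((((((((..(((..(((…14 dots…)))..)))..))))))))))`.

**Loops and extensions** are sampled uniformly with GC content
constrained to 40-60% (rejection sampling, seeded). Auto-sampled loops
are additionally screened so that ≥90% of loop positions are unpaired in
the cassette MFE structure (up to 50 seeded draws; the most open
candidate is kept otherwise).

## The folding engine

The built-in engine replaces an external thermodynamics package with a
self-contained simplified nearest-neighbour model:

* tabulated stack free energies for all WC and G·U stacks (kcal/mol,
  37 °C, published-style two-decimal values);
* hairpin loops: 5.40 + 1.08·ln(L/3) kcal/mol, minimum loop 3 nt;
* internal loops/bulges: 1.70 + 0.35·(n₁+n₂) + 0.30·|n₁−n₂|, loops with
  more than 30 unpaired nt disallowed;
* multibranch loops: 3.40 + 0.40/branch + 0.10/unpaired nt;
* exterior bases free; RT = 0.61633 kcal/mol at 37 °C.

MFE structures come from a Zuker-style O(n³) dynamic programme;
ensemble quantities (ln Z, base-pair probabilities, unpaired profiles,
structure probabilities exp(−E(s)/RT)/Z) from McCaskill-style
inside-outside recursions. Both evaluate the *same unambiguous grammar*
(exterior F/P, paired V, multiloop segments M/M1 split at the start of
the last branch), so min-plus and sum-product results are mutually
consistent by construction; the test suite verifies both against
exhaustive enumeration on hundreds of short random sequences to 1e−9.
Partition sums are accumulated in double precision and overflow is
detected and reported; at the sequence lengths this toolkit folds
(≤ ~300 nt) the dynamic range is ample. MFE traceback ties break
deterministically (hairpin, then stack/internal by increasing loop size,
then multiloop, first match wins).

On this model, the first-generation cassette's MFE structure equals its
constructed target for roughly 55-60% of random GC-bounded spacers, and
the target typically carries ~30-60% of the Boltzmann ensemble. That is
a diagnostic of the simplified parameters, not a design gate: the
adapter contract (`sequence → MFE, ln Z, structure probability, unpaired
profile`) lets ViennaRNA substitute for production parameter quality,
with material/temperature/dangle settings exposed and defaults left at
the adapter's own (RNA, 37 °C, dangles 2).

## MODesign

Inputs: trigger RNA, spacer (20 nt), loop size L (≥4; window = L+15).

1. **Windows**: all contiguous trigger sub-sequences of length L+15,
   left to right (count |T|−(L+15)+1).
2. **Assembly**: backfold 16..30 + loop = reverse complement of the
   window (one contiguous sensing stretch); backfold 1..15 = mismatched
   reverse complement of spacer 6..20 (spacer\* convention, mismatches
   11-12 in range); extension = mismatched reverse complement of
   backfold 21..30 (extension\* convention, stem bulges at backfold
   21-22 and 26-27); spacer positions 4..20 keep the input spacer (17 nt
   of CTS complementarity) while positions 1..3 are set to pair their
   trigger-determined backfold partners 18..20. Backfold 16-17 stay
   unpaired in the target, freeing spacer 4..5 for the CTS — this is the
   mechanical reason designs sometimes show >17 CTS matches "by chance".
3. **Fold check**: candidates whose cassette adopts the target with
   probability N below the floor (default 0.10) are dropped.
4. **Scoring**: `total = N³·M·P·Q` with
   N = structure probability of the target;
   M = mean unpaired probability over the window when the whole trigger
   is folded alone (ensemble base-pair probabilities, not MFE — a
   window can be half-open);
   P = fraction of the 30 backfold nt whose ungapped antiparallel
   trigger partner (extending the seed duplex both directions) is
   WC-complementary — ≥15/30 by construction when the extended register
   stays on the trigger;
   Q = fraction of spacer nt matching the CTS protospacer (≥17/20).
5. **Ranking**: by total, descending; ties by window start. The whole
   pipeline is deterministic for fixed inputs. Bonus flags mark chance
   extra complementarity (distal backfold, >17 CTS matches).

Two interpretation choices were genuinely open and are fixed as
follows. "First 15 nt of the backfold" is read as *loop-proximal*, so
the trigger-complementary region is one contiguous stretch — required
for an uninterrupted RNA-RNA duplex, and consistent with chance "extra"
complementarity arising in the distal 15 nt from trigger sequence just
outside the window. And the modular spacer stays 20 nt with 17 enforced
matches rather than being truncated to 17 nt, keeping guide length
native while satisfying the 17 nt complementarity requirement. The
qualitative selection criteria ("high fold probability", "open
window") are operationalised as the composite score; the floor of 0.10
reflects that no quantitative threshold is prescribed.

## Orthogonality screen

Cross-activation cannot be predicted mechanistically from sequence
alone, so the screen is a hybridisation-potential surrogate: the longest
contiguous antiparallel WC run between trigger and sensing region
(computed as the longest common substring with the trigger's reverse
complement), normalised by sensing length. Cognate pairs score exactly
1.0; independent random pairs concentrate near the expected longest
common run of random sequences (≈5-6 nt for these lengths, i.e. scores
≈0.15), far under the 0.5 call threshold. The matrix is a pre-screen
with a documented threshold, not an activation model — no two-strand
partition functions or strand-displacement kinetics.

## Cytometry quantification

Event tables carry FSC-A, SSC-A, SSC-H, iBlue (transfection marker,
640-670 nm proxy) and ECFP (reporter, 405-450 nm proxy). The synthetic
generator draws log-normal mixtures of three archetypes — untransfected
(iBlue⁻/ECFP⁻), transfected-OFF (iBlue⁺/ECFP⁻), transfected-ON
(iBlue⁺/ECFP⁺) — with shared scatter distributions, 5% planted doublets
(depressed SSC-H/SSC-A ratio) and seeded determinism. Defaults: 100,000
events per condition, fluorescence log-location 4.0 (negative) vs 8.5
(positive) with log-scale 0.8, 60% transfection.

Gating: rectangular cell gate on FSC-A/SSC-A (25-150k × 12-120k, set in
the generator's own coordinate system since real scatter gates are drawn
by eye), singlet gate SSC-H/SSC-A ≥ 0.75, then fluorescence thresholds.
Each threshold is calibrated on its control as an exact empirical
quantile: the value with round(n·fraction) control events strictly above
it, fraction defaulting to 0.1%; the realised fraction is within 1/n of
the request, which is the documented tolerance of "around 0.1%". The
reported quantity is a/(a+b) with a = ECFP⁺iBlue⁺ and b = ECFP⁻iBlue⁺
among gated singlets; an empty transfected population yields a missing
value, never 0. With archetypes this well separated the planted ON
fraction is recovered within binomial error at n = 100,000; real data
with spectral spillover, autofluorescence tails or weak reporters will
not behave this cleanly, so passing tests certify the arithmetic and
calibration contracts, not instrument-level accuracy. The t-test/χ²
helpers are reporting conveniences only.

## Circularisation-assay predictor

The assay ligates RNA into circles, reverse transcribes across the
junction and sizes a nested PCR product. Primers sit in constant
sequence, so the native/truncated product size is an assay calibration
constant (81 bp for the sgRNA assay, 220 bp for the trigger assay)
rather than computed from primer coordinates — the model owns only the
delta: full-length engineered species = baseline + engineered addition
(clamp+backfold+loop+extension; 56 nt for second-generation, giving
137 bp). The exact cleavage boundary is inferred from that additivity
(137 − 81 = 56 matches clamp-through-extension removal); alternative
boundaries within a few nt are not distinguishable from band sizes. The
dCas9-independent intermediate truncation product is out of scope.

## Synthetic data and what the tests show

Fixture triggers emulate published input *shapes* — lengths 146/267/268
nt and the contrast between unstructured and structured transcripts
(the latter planted as GC-rich 16 nt inverted repeats) — not biological
sequences; panel spacers are independent GC-bounded 20-mers. Test and
acceptance problem sizes (200 oracle sequences ≤14 nt, one 146 nt
MODesign run, 5×5 panels, 100,000-event tables) were chosen so the whole
suite completes in a few minutes on one CPU while still exercising every
code path at realistic scale. Protector hairpins on expressed triggers
are annotation placeholders; their published sequences live in
supplementary material we deliberately do not reproduce. Flanked-trigger
lengths are reported as assembled (core+flanks); cloned constructs carry
extra vector-derived sequence, so plasmid-level sizes will exceed the
assembled length — the tool reports its own arithmetic rather than
guessing linker composition.

## Known limitations

* The built-in energy model has coarse loop parameters and no dangles,
  coaxial stacking or special hairpin corrections; rankings are robust,
  absolute fold probabilities are model-dependent.
* No pseudoknots, no suboptimal structure lists, no two-strand complex
  partition functions, no temperature scans.
* No genomic off-target scanning for spacers and no expression-level
  modelling of Pol III triggers.
* Chemical-modification strategies are carried as annotations, not
  optimised.
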