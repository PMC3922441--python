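# Methods

## The assay being modelled

Multiplex SNaPshot minisequencing genotypes a set of biallelic SNVs in two
in-vitro steps that this package reproduces in silico:

1. **Multiplex PCR.** Short flanking primer pairs co-amplify the regions
   containing the targets, split across reactions (A, B, ...) so that
   cross-reacting primers never share a tube.
2. **Single-base extension.** One extension primer per SNP anneals with its
   3' end immediately adjacent to the interrogated base and is extended by
   exactly one dye-labelled ddNTP.  Products are sized by capillary
   electrophoresis against an internal standard spanning roughly
   15-120 nt; the dye channel identifies the incorporated base and the
   product size identifies the SNP.  A heterozygote shows two peaks of
   different colour at (nearly) the same size, a homozygote one peak.

The package implements the designer for both primer tiers, an
electropherogram simulator and decoder, an independent panel checker, and
an in-silico PCR-RFLP predictor for orthogonal verification.  The two
published panels it ships as fixtures — a 12-plex (BCL11A intron 2) and a
16-plex (HBS1L-MYB intergenic region), both targeting variants that
modulate fetal haemoglobin levels — serve as the reference surface the
test-suite checks against.

## Conventions

* Coordinates are 1-based with inclusive intervals everywhere; conversion
  to half-open offsets happens only inside sequence slicing.
* All genotype output is reported on the genome plus strand as given by a
  target's ref/alt alleles.  The strand an extension primer anneals to is
  internal: a plus-strand primer incorporates the plus-strand allele base,
  a minus-strand primer its complement, and the dye follows the
  incorporated base (A green, C black, G blue, T red in the default map).
  Published assay sheets are inconsistent about which strand their
  "detected alleles" column refers to, so one biochemical convention is
  the only safe contract.
* Serialized primers keep the neutral tail lower-case and the genomic core
  upper-case, which makes the tail/core split recoverable from the string.

## Design rules and their defaults

| parameter | default | role |
|---|---|---|
| PCR primer length | 17-29 nt | amplification primer bounds |
| PCR primer Tm | 57-64 degC | scoring window (see below) |
| same-dye length gap | >= 4 nt | stagger between products that can share a dye |
| empirical resolution floor | 3 nt | minimum separation the instrument resolves |
| readable window | 15-120 nt | sizing-standard span for extension products |
| master tail | 40-mer `aactgact...tgacaa` | neutral 5' padding, used suffix-first |
| pad base | C | poly(C) padding once the master tail is exhausted |
| extension core length | 17-24 nt (>= 14 floor) | genomic portion searched by the designer |
| hairpin stem threshold | fail at >= 7 bp | combinatorial screen |
| 3'-anchored dimer run | fail at >= 7 bp | self- and cross-dimer screen |
| size tolerance (decoder) | 1.0 nt | peak-to-allele matching half-width |
| het ratio minimum | 0.15 | minor/major height for a het call |

Notes on the choices:

* **Tm method.** The original assays were designed with a web calculator
  whose formula is not stated, so the 57-64 degC window cannot be
  reproduced bit-exactly.  The package defaults to the unified
  nearest-neighbour model (Allawi & SantaLucia parameters, entropy salt
  correction `0.368 (N-1) ln[Na+]`, 50 mM monovalent salt, 250 nM oligo)
  via Biopython, with the Wallace rule (`2(A+T) + 4(G+C)`) as a cheap
  closed-form mode.  Panel checking therefore reports Tm-window findings
  as warnings, never errors.
* **Secondary-structure screens** are exact complementary-run scans
  (longest hairpin stem with a loop of >= 3; longest ungapped antiparallel
  Watson-Crick run, overall and anchored at a 3' terminus), not
  free-energy folds.  The failure thresholds (7 bp stem, 7 bp 3'-anchored
  run) are the tightest values that all 44 published PCR primers pass, on
  the argument that a published, validated panel defines what acceptable
  primers look like under this scoring.
* **Reaction partitioning.** No algorithm for the published A/B split is
  documented; the package uses deterministic greedy colouring of the
  cross-dimer conflict graph (descending conflict degree, ties by input
  order), which a test holds to within +1 of the exact chromatic number.
* **Decoder thresholds.** The source assays report no numeric size
  tolerance or allele-balance cutoff; 1.0 nt and 0.15 are package choices
  that make the simulated noise model comfortably decodable and are
  exposed in the configuration.

## The length-staggering solver

Products that can appear in the same dye channel must differ in size;
products in different channels may coincide.  Given per-primer core
lengths and dye pairs, the solver assigns total primer lengths such that
(a) every total is at least its core length, (b) any two primers sharing a
dye differ by at least the same-dye gap, (c) every product (total + 1)
fits the readable window, and (d) the maximum total is minimal, with the
lexicographically smallest assignment in input order among
minimal-makespan solutions.  The search is exact: makespan candidates are
tried in ascending order starting from three lower bounds (the per-colour
clique schedule, a disjoint-pairing token bound — any two primers closer
than the gap must carry disjoint dye pairs — and a sorted-cores capacity
bound), feasibility at each makespan is decided by depth-first search over
bitmask value domains with most-constrained-first ordering, and the
lexicographic representative is then recovered by a second input-ordered
pass.  A node budget turns pathological instances into an explicit
capacity error rather than an open-ended search; panels of the sizes this
chemistry supports (a few dozen primers, four dyes) solve in milliseconds.

Tails are deterministic: a total length k above the core is realised as
the length-k suffix of the master tail, with poly(C) padding prepended
once k exceeds 40.  Two of the 28 published primers deviate from this
suffix rule by a two-base transposition at the tail 5' end; the fixture
tests flag exactly those two as documented data, not as a rule.

## Flanking-variant conflicts

A known variant inside a primer footprint compromises annealing.  The
footprint includes the interrogated base itself, so an indel overlapping
the SNP blocks both strands.  A target whose plus footprint
`[pos - L, pos]` and minus footprint `[pos, pos + L]` are both hit is
reported undesignable by a single extension primer — the situation that
forced one HBS1L-MYB variant (rs7775698, flanked by two 3 bp deletions
and a 2 bp insertion) out of the published panel.  The packaged
reconstruction of that neighbourhood is synthetic: the variant identities
and types are published but not their exact coordinates, so the fixture
places them in the published window with the published geometry.

## Electropherogram model and decoder

Nominal product size is total primer length + 1.  Observed size is an
affine per-dye function of nominal size (offset + slope x nominal,
identity by default), capturing dye-mass and polymer mobility shifts; the
model is fitted per dye by least squares from control observations, with
offset-only fallback for single observations and identity plus a warning
for unobserved dyes.  Simulation places one peak per carried allele with
Gaussian size jitter, optional uniform low-height non-specific peaks, and
deterministic output per seed.

Decoding assigns a peak to an allele when the dye matches and the
observed size is within the tolerance of the predicted size.  Both
alleles supported at an adequate height ratio gives a heterozygote; a
single supported allele a homozygote; both supported below the ratio a
homozygote for the taller peak with an imbalance flag; none a no-call.
Peaks supporting no allele anywhere are flagged non-specific and never
alter calls, and calls are invariant to peak-table row order.

A structural caveat the tests make explicit: the published 16-plex
contains three 32 nt primers whose products nominally coincide within
shared dye channels.  The real instrument separated them through
sequence-dependent mobility, which a per-dye affine model cannot express,
so zero-noise round-trip decoding is only guaranteed for panels that
honour the 4 nt stagger (everything the designer emits, and the published
12-plex).  The checker accordingly treats sub-gap same-dye spacing as an
error in `design` mode and as a warning in `import` mode.

## RFLP prediction

Restriction sites are matched on the plus strand with IUPAC expansion
(reverse-strand scanning is added automatically for non-palindromic
patterns; the seven shipped enzymes — AvaII, AatII, BstXI, RsaI, MspI,
HinfI, Hpy188III — are all palindromic).  Cuts default to the 5' end of
each match; the offset is configurable because the verification logic
only uses whether the two allele fragment profiles differ (informative)
and fragment boundaries do not change that.  Fragments always partition
the amplicon.

## The toy genome

No reference genome is packaged.  The generator synthesises each
published amplicon as `forward primer + seeded random filler + reverse
complement of reverse primer` at the printed product length, embeds the
amplicons in seeded random background (150-300 bp gaps), and plants one
toy SNV per covered target inside its amplicon's filler.  This preserves
exactly what the fixtures can verify — primer sequences, product lengths,
uniqueness, end-to-end design/simulate/decode — while the amplicon
interiors, and hence any extension-primer core re-derived from the toy
genome, are synthetic.  Fixture extension-primer cores therefore come
from the published table verbatim, never from the toy genome.  Real
genomic FASTA is fully supported through the same interfaces but never
required by the tests.

## Problem sizes used by the test-suite and acceptance script

Fixture-level checks run on the full published tables (28 targets, 22
primer pairs, 28 extension primers).  Behavioural suites use: 1,000
seeded simulations of the 12-plex for decode concordance (jitter
sd = tolerance/3, two non-specific peaks per run); 100 zero-noise
simulations for the exact round trip; exhaustive-search cross-checks of
the spacing solver on seeded instances of up to 4 primers inside a
narrowed window; 1,000 random amplicon/pattern draws for digest
conservation; 100 seeded 6-node graphs for reaction colouring; and
synthetic mobility observations for fit recovery.  The whole suite runs
in well under a minute on one CPU.

## Known limitations

* Biallelic SNVs only; no tri-allelic dye logic, no indel genotyping.
* Thermodynamics is screening-grade: no ΔG ensembles, mismatch or
  dangling-end corrections, and the Tm scale is calculator-dependent.
* The genome-uniqueness screen is an exact-match scan over user-supplied
  sequences, standing behind a pluggable interface where a full aligner
  (e.g. BLAST) can be substituted; it does not model near-matches.
* Sequence-dependent mobility is not modelled beyond per-dye affine
  shifts, with the decoding consequence described above.
* Primer concentrations are carried as metadata; no titration modelling.
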