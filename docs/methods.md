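# Methods

## The model

A circular chromosome of length `L` is replicated by two forks leaving a
single origin, *oriC*. We call the fork moving in increasing coordinates
the clockwise (cw) fork, the other the anticlockwise (ccw) fork; the
"clockwise replichore" is the half-circle the cw fork replicates. A
Tus-bound 23-bp *ter* site is a polar barrier: a fork hitting its
non-permissive face is arrested, a fork arriving from the other side
displaces Tus and passes. Which fork a site arrests is a pure function
of the strand its query matches on; the mapping is a configuration
switch (`plus-blocks-cw` by default) because the motif itself does not
dictate an absolute direction — the default is fixed so that the
canonical template reproduces the textbook arrangement (terC/B/F/G/J
arresting the cw fork, terA/D/E/I/H the ccw fork).

The architecture of a genome is reconstructed by a **fork walk**: from
*oriC*, walk each fork in its direction and stop at the first site that
blocks it. The two stopping sites are the trap boundaries; the arc
between them that does not contain *oriC* is the **inner termination
area** where forks must fuse. The trap is *intact* if both walks find a
boundary. *dif* is inside the trap if its start lies strictly inside
that arc. Secondary sites (terK/L/Y/Z, whose fork-arrest activity is
very low) and sites called `likely_inactive` (critical-position mutants)
are excluded from the walk but kept in all reports; both exclusions are
configurable. The arithmetic midpoint is
`(oriC + floor(L/2)) mod L`; replichore-relative positions are scaled so
*oriC* maps to 100 % and the midpoint to 0 %.

## Motif search

The scanner is an exhaustive Hamming scan: every start position on the
circle, on both strands, including windows wrapping the coordinate
origin (implemented by scanning the sequence concatenated with its first
`k−1` bases and accumulating per-offset mismatch counts in numpy).
Indels are not modelled — the sites are fixed-length, non-palindromic
motifs. `N` never matches anything. Minus-strand hits are reported at
the leftmost forward-strand coordinate with mismatch positions in query
coordinates (position 1 = 5′ end of the query as written). At 5 Mbp × 14
queries a scan takes a few seconds on one CPU; no index is needed.

Candidate handling is two-tier, because genomes demonstrably carry
*detectable* sites whose critical base is mutated:

1. **Detection**: Hamming distance ≤ `max_mismatch` (default 4, i.e.
   "fewer than 5"; 5 for the relaxed secondary-site search).
2. **Annotation**: a hit *passes* the filter if the critical position 6
   is intact and at most `core_mismatch_budget` (default 1) mismatches
   fall in the strict core (positions 8–18 except the tolerant
   position 7). Failing hits are flagged with a reason, never dropped.

Per genome, each query is assigned a single site: the detected hit with
the fewest mismatches (ties: smallest start, then `+` strand), subject
to two rules. First, overlapping same-query hits are collapsed to the
best one. Second, when best hits of *different* queries overlap, only
the best claim keeps the locus — one genomic locus is one site — and the
losing query is reported absent. This matters when a site is genuinely
missing: its query otherwise tends to match, within the relaxed budget,
inside the most similar present site. Third, a best hit whose strict
core is degenerate beyond the budget is not accepted as a located site
at all; a hit failing only at the critical position is located but
annotated `likely_inactive` (it no longer arrests forks efficiently,
yet it exists and is reported).

The *dif* site (27 bp, `GGTGCCATAATGTATATTATGTTAAAT` on the `+` strand)
is located as the single best hit within a 2-mismatch budget; absence is
reported, not fatal.

## Variation analysis

Positions 1–5, 7 and 19–23 of a *ter* query are *variable* (tolerant of
substitution; they make little or no contact with Tus); 6 and 8–18 are
the conserved *core*. SNPs are counted per position per genome against
the reference genome's own site sequences (consensus comparison is a
user option, not the default). Functional calls are the qualitative
rules: critical position mutated → `likely_inactive`; any other core
change (position 7 excepted) → `reduced`; otherwise `active`. The
summary reports the variable/core split and the innermost (terA–D by
default) versus outer split; `fraction_variable` is defined as 0 when
there are no SNPs at all. CDS overlap of sites is taken from
user-supplied GFF3 or BED annotations (gene prediction is out of scope);
a site is `contained` only if its whole 23-bp span lies within a single
CDS interval, and CDS strand is ignored.

## Protein comparison

Tus proteins across strains are near-identical over ~309 residues, so
global alignment with match +1 / mismatch −1 / linear gap −2 is
sufficient and an affine penalty would change nothing on realistic
inputs. The Needleman–Wunsch implementation pins the traceback
(diagonal > up > left) so reported coordinates are reproducible;
optimality is verified in the tests against exhaustive enumeration of
alignments for short sequences and against Biopython's aligner scores
for longer ones. Across more than two strains, changes are aggregated
as the union of changed reference positions over all pairwise diffs
against the reference (the headline count), with (position, strain)
events reported alongside.

## Synthetic data: what it emulates, and what it does not

The generator produces the study conditions end to end: circular
chromosomes with i.i.d. background sequence (GC fraction 0.5 by
default), *oriC* placed away from coordinate zero so that fork walks
and site spans exercise the wrap, ten primary *ter* implants in two
opposed groups plus the four secondary sites, *dif* between the
innermost opposing pair on the `−` strand, per-site substitutions taken
from an explicit plan, and optional segment inversions with exact
coordinate/strand remapping in the manifest. Geometry defaults (as
fractions of `L`, clockwise from *oriC*) reproduce the canonical
proportions: the ten primary sites span 45 % of the chromosome, the
innermost four ≈ 8 %, and the terA–terC fusion area 5.76 % — so a
4.641-Mbp canonical genome has a 267-kb inner termination area.

Five templates cover the architectures the pipeline must distinguish:
`mg1655_like` (canonical), `inner_inverted` (the terA..dif..terC segment
reverse-complemented; the trap survives because both flipped sites swap
roles), `flipped_terC` (terC moved origin-proximal of *dif* in reversed
orientation: the trap becomes terC–terB, *dif* stays inside, and terC
comes to share *dif*'s strand), `broken_trap` (no cw-blocking group at
all), and `shigella_missing_site` (terC absent, terD carrying the
critical G6>A change; the trap falls back to terB/terA).

The five-genome panel fixes a cross-phylogroup comparison: four variant
genomes (4.8–5.5 Mbp by default) carry 21 planted SNPs — 18 at variable
positions, 3 in the core (one critical G6>A in terJ, the position-15
A>T of terF in two genomes), 11 of the 21 in the innermost terA–D sites,
none in terE or terH. The Tus panel is a synthetic 309-residue
reference (a random sequence with Thr fixed at 136 — a labelled
stand-in, not the natural protein) with four variants differing at
seven distinct positions (one to three per strain, including the
conservative Thr136Ser).

The shipped *ter* reference queries are likewise constructed, not
copied from any strain: all share the canonical conserved core (G at 6,
`ATGTTGTAACT` at 8–18; terY carries two deliberate core deviations
mirroring its naturally weak site) while the variable flanks were chosen
so that every pair of queries — including reverse complements and any
window of *dif* — differs at ≥ 6 positions. Natural *ter* sites are
less cleanly separated in their variable flanks; what passing tests
show is therefore that the *algorithms* are exact (scanner ≡ brute
force, recovery ≡ manifest), not that site assignment is unambiguous on
arbitrary real genomes. Other idealisations: i.i.d. background (no
repeats, skews or real gene content — spurious ≤4-mismatch matches are
possible in principle and the scanner-vs-oracle tests treat them as
correct output, not errors), no indels, no rearrangement histories
beyond single inversions.

## Numerical and convention choices

- Coordinates 0-based half-open internally; all written tables 1-based.
- Trap span is measured between boundary-site *start* coordinates; at
  whole-kb reporting precision the ±23 bp alternative choices are
  immaterial, but the choice is fixed and documented here.
- Human-readable tables round percentages to 2 decimals and kb to
  integers; JSON keeps full precision.
- Tie-breaks are pinned everywhere (fewest mismatches → smallest start
  → `+` strand for hits; diagonal → up → left in alignment traceback);
  two sites at the same coordinate are impossible after dedupe and
  asserted against.
- *oriC* is a required per-genome input (point anchor); the package does
  not predict it (no DnaA-box or GC-skew analysis).
- All randomness flows from a single integer seed per generated object;
  the same seed reproduces byte-identical FASTA.

## Problem sizes used in the packaged runs

The acceptance script runs the template sweep at 500 kb (architecture
and recovery are geometry-scaled, so results are identical across the
100 kb–5 Mbp range, which the test suite verifies at two lengths), the
canonical-architecture measurement at the realistic 4.641 Mbp, and the
variation panel at its realistic default lengths (4.6–5.5 Mbp). The test
suite uses 100–500 kb genomes and ≤ 5 kb scanner-oracle fixtures.

## Known limitations

- Hamming-only matching: a *ter* variant with an indel would be missed.
- The strand→blocking convention must be supplied correctly for real
  genomes whose orientation convention differs from the packaged one.
- `inner_span_percent` of rearranged genomes compares site *starts*;
  for genomes where boundary sites wrap the origin the span is still
  the oriC-free arc, but positions printed in tables are genome-local.
- Functional calls are qualitative rules, not binding-energy estimates.
- The six-frame translated search for Tus genes is out of scope; users
  supply protein or CDS FASTA.
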