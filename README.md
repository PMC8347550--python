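# forktrap

Analysis of the **replication fork trap** on circular bacterial
chromosomes — the arrangement of polar *ter*/Tus barriers that lets the
two replication forks enter the terminus region but not leave it.

Enterobacterial chromosomes such as *E. coli*'s are replicated
bidirectionally from a single origin (*oriC*). Ten non-palindromic 23-bp
*ter* sites, arranged as two opposed groups flanking the terminus, each
arrest a fork arriving at the non-permissive face of a Tus-bound site:
one group blocks the clockwise fork, the other the anticlockwise fork.
Forks are therefore forced to fuse between the *innermost* pair of
opposing sites, and the *dif* chromosome dimer resolution site (acted on
by the XerCD recombinase) sits inside that innermost area. This package
provides, for anyone comparing such architectures across genomes:

- **Approximate motif search** (`forktrap.motif_scan`): exhaustive
  both-strand Hamming scan of 23-bp *ter* queries and the *dif* sequence
  on circular genomes, wrap-aware, with the two-tier candidate filter —
  a detection mismatch budget (≤ 4 by default, relaxable to 5), and a
  functional annotation requiring the critical position 6 and the
  conserved core (positions 6, 8–18) to be intact.
- **Architecture reconstruction** (`forktrap.architecture`): fork walks
  from *oriC* to the first blocking site in each direction, the inner
  termination area in bp and % of genome, the arithmetic midpoint,
  replichore-relative site positions (oriC = 100 %, midpoint = 0 %),
  *dif* placement, and architecture diffing (orientation flips, rank
  changes, candidate block inversions, *dif* neighbour/strand changes).
- **Sequence variation** (`forktrap.variation`): per-site partition of
  mismatches into conserved-core vs variable positions, qualitative
  functional calls (active / reduced / likely_inactive), cross-genome
  SNP summaries, flank identity, and CDS-overlap calls from GFF3/BED.
- **Tus protein comparison** (`forktrap.protein_compare`):
  Needleman–Wunsch global alignment with deterministic traceback and
  residue-difference reports in reference coordinates.
- **Synthetic genomes with ground truth** (`forktrap.synthetic_data`):
  circular genomes (100 kb – 5.5 Mbp) with implanted *ter*/*dif*
  architectures, controlled per-position mutations, segment inversions,
  and a manifest recording exactly what was implanted where.

## Worked example

Generate a canonical-architecture genome and reconstruct its termination
area:

```sh
forktrap simulate --template mg1655_like --length 500000 --seed 1 --out sim/
forktrap architecture --genome sim/genome.fa --oric 425001 --out arch/
```

which reports on stderr

```
trap intact; inner span 28800 bp (5.76%), dif_in_trap=True
```

meaning: both fork walks found a blocking site (the trap is intact), the
innermost termination area between those two boundary sites covers
28 800 bp = 5.76 % of the genome, and the located *dif* site lies inside
it. `arch/trap_report.json` holds the full report and
`arch/site_table.tsv` one row per site, e.g. strand, which fork it
blocks, and its replichore-relative position.

The same pipeline is packaged as numbered drivers under `analysis/`
(simulation → scan → architecture → variation → protein diff), which
write their tables under `results/`. Running them end to end prints,
among other things:

```
mg1655_like: trap intact between terA and terC; inner area 28800 bp (5.76%), dif_in_trap=True
flipped_terC: trap intact between terC and terB; inner area 26000 bp (5.20%), dif_in_trap=True
broken_trap: trap NOT intact (cw boundary: none, ccw: terA)
total 21 SNPs: 18 variable / 3 core; 11 in the innermost terA-D sites
reference Tus: 309 aa; 7 distinct changed positions (8 events) across 4 strains
```

The `flipped_terC` line shows the rearranged architecture in which the
innermost trap is formed by terC and terB instead of terA and terC, with
*dif* still inside it — the diff against the canonical genome flags
exactly the terC orientation flip and the changed *dif* neighbours.

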