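#!/usr/bin/env python
"""Generate the synthetic genome set used throughout the analysis.

Builds one 500-kb genome per architecture template (canonical, inner-area
inverted, flipped terC, broken trap, missing terC) plus the five-genome
cross-phylogroup panel carrying the fixed 21-SNP plan, and writes FASTA,
ground-truth manifests and implant BED files under results/simulated/.
"""

import argparse
import json
from pathlib import Path

from forktrap.genome_io import write_genome
from forktrap.synthetic_data import TEMPLATE_NAMES, build_phylogroup_panel, build_template

RESULTS = Path(__file__).resolve().parent.parent / "results" / "simulated"


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--length", type=int, default=500_000)
    parser.add_argument("--panel-length", type=int, default=500_000,
                        help="panel genome length (pass 0 for the realistic 4.6-5.5 Mbp set)")
    args = parser.parse_args()

    RESULTS.mkdir(parents=True, exist_ok=True)
    for i, template in enumerate(TEMPLATE_NAMES):
        genome, manifest = build_template(template, length=args.length, seed=args.seed + i)
        d = RESULTS / template
        d.mkdir(exist_ok=True)
        write_genome(genome, d / "genome.fa")
        (d / "manifest.json").write_text(manifest.to_json() + "\n")
        print(f"{template}: {genome.length} bp, oriC at {genome.oric_position + 1} (1-based), "
              f"{len(manifest.implants)} ter implants, dif at {manifest.dif.position + 1}")

    lengths = None if args.panel_length == 0 else {
        k: args.panel_length for k in
        ("panelA_ref", "panelB1", "panelB2", "panelD", "panelE")
    }
    panel = build_phylogroup_panel(seed=args.seed, lengths=lengths)
    manifest_rows = []
    for name, (genome, manifest) in panel.items():
        d = RESULTS / "panel"
        d.mkdir(exist_ok=True)
        write_genome(genome, d / f"{name}.fa")
        (d / f"{name}.manifest.json").write_text(manifest.to_json() + "\n")
        manifest_rows.append(f"{name}\t{d / f'{name}.fa'}\t{manifest.oric_position + 1}")
        n_snps = sum(len(s.mutations) for s in manifest.implants)
        print(f"panel {name}: {genome.length} bp, {n_snps} planted SNPs")
    (RESULTS / "panel" / "genomes.tsv").write_text("\n".join(manifest_rows) + "\n")
    print(f"wrote {RESULTS}")


if __name__ == "__main__":
    main()
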