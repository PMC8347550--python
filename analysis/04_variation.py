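#!/usr/bin/env python
"""Cross-genome ter sequence variation on the phylogroup panel.

Scans the four non-reference panel genomes, partitions every site's
mismatches into conserved-core versus variable positions, makes the
qualitative functional call per site, and summarises: total SNPs, the
variable/core split, and the innermost (terA-D) versus outer split.
Writes summary.json and the sites x genomes matrix under
results/variation/.
"""

import json
from pathlib import Path

from forktrap.genome_io import read_genome
from forktrap.pipeline import analyze_genome
from forktrap.queries import reference_ter_queries
from forktrap.synthetic_data import ImplantManifest
from forktrap.variation import summarize_variation, variation_matrix

ROOT = Path(__file__).resolve().parent.parent / "results"
PANEL = ROOT / "simulated" / "panel"


def main():
    queries = reference_ter_queries()
    out = ROOT / "variation"
    out.mkdir(parents=True, exist_ok=True)

    variations = []
    for manifest_path in sorted(PANEL.glob("*.manifest.json")):
        manifest = ImplantManifest.from_json(manifest_path.read_text())
        if manifest.genome_name == "panelA_ref":
            continue
        genome = read_genome(manifest_path.with_name(f"{manifest.genome_name}.fa"),
                             manifest.oric_position, name=manifest.genome_name)
        analysis = analyze_genome(genome, queries)
        variations.extend(analysis.variations.values())
        calls = {n: v.functional_call for n, v in analysis.variations.items()
                 if v.functional_call != "active"}
        print(f"{manifest.genome_name}: "
              f"{sum(len(v.mismatch_positions) for v in analysis.variations.values())} SNPs"
              + (f", non-active calls: {calls}" if calls else ""))

    s = summarize_variation(variations)
    summary = {
        "total_snps": s.total_snps, "variable_snps": s.variable_snps,
        "core_snps": s.core_snps, "fraction_variable": round(s.fraction_variable, 4),
        "innermost_snps": s.innermost_snps, "outer_snps": s.outer_snps,
        "per_site": s.per_site, "per_genome": s.per_genome,
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    variation_matrix(variations).to_csv(out / "matrix.tsv", sep="\t")
    print(f"total {s.total_snps} SNPs: {s.variable_snps} variable / {s.core_snps} core; "
          f"{s.innermost_snps} in the innermost terA-D sites")


if __name__ == "__main__":
    main()
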