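#!/usr/bin/env python
"""Reconstruct and compare fork-trap architectures.

For each simulated template genome: fork-walk from oriC to the first
blocking site in each direction, measure the inner termination area,
place dif, and write the trap report (JSON) and the per-site table
(TSV, with replichore-relative percentages).  Every non-canonical
template is then diffed against the canonical one, flagging orientation
flips, dif neighbour changes and candidate block inversions.
"""

import json
from pathlib import Path

from forktrap.architecture import compare_to_reference
from forktrap.genome_io import read_genome
from forktrap.pipeline import analyze_genome
from forktrap.queries import reference_ter_queries
from forktrap.synthetic_data import TEMPLATE_NAMES, ImplantManifest

ROOT = Path(__file__).resolve().parent.parent / "results"
SIM = ROOT / "simulated"


def load(template):
    manifest = ImplantManifest.from_json((SIM / template / "manifest.json").read_text())
    genome = read_genome(SIM / template / "genome.fa", manifest.oric_position,
                         name=manifest.genome_name)
    return genome, manifest


def main():
    queries = reference_ter_queries()
    outroot = ROOT / "architecture"
    outroot.mkdir(parents=True, exist_ok=True)

    traps = {}
    for template in TEMPLATE_NAMES:
        genome, manifest = load(template)
        trap = analyze_genome(genome, queries).trap
        traps[template] = trap
        out = outroot / template
        out.mkdir(exist_ok=True)
        (out / "trap_report.json").write_text(trap.to_json(sort_keys=True) + "\n")
        rows = ["name\tstart_1based\tstrand\tblocks\tfunctional\tmismatch_count"
                "\treplichore\treplichore_percent"]
        for r in trap.site_table(genome):
            rows.append("\t".join(str(r[k]) for k in (
                "name", "start_1based", "strand", "blocks", "functional",
                "mismatch_count", "replichore", "replichore_percent")))
        (out / "site_table.tsv").write_text("\n".join(rows) + "\n")
        if trap.trap_intact:
            print(f"{template}: trap intact between {trap.ccw_boundary.name} and "
                  f"{trap.cw_boundary.name}; inner area {trap.inner_span_bp} bp "
                  f"({trap.inner_span_percent:.2f}%), dif_in_trap={trap.dif_in_trap}")
        else:
            print(f"{template}: trap NOT intact (cw boundary: "
                  f"{trap.cw_boundary.name if trap.cw_boundary else 'none'}, ccw: "
                  f"{trap.ccw_boundary.name if trap.ccw_boundary else 'none'})")

    reference = traps["mg1655_like"]
    for template in TEMPLATE_NAMES:
        if template == "mg1655_like":
            continue
        diff = compare_to_reference(traps[template], reference)
        (outroot / template / "diff_vs_canonical.json").write_text(
            json.dumps(diff.to_dict(), indent=2) + "\n")
        flips = [d.name for d in diff.site_diffs if d.orientation_flipped]
        print(f"{template} vs canonical: flipped={flips or 'none'}, "
              f"block_inversions={diff.block_inversions or 'none'}, "
              f"dif neighbours {diff.dif_neighbours_reference} -> {diff.dif_neighbours_target}")


if __name__ == "__main__":
    main()
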