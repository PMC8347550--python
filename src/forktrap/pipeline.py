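"""End-to-end orchestration: scan -> filter -> architecture -> variation.

This is the layer the command line, the analysis drivers and the
acceptance script all call; each stage stays individually importable.
"""

from __future__ import annotations

from dataclasses import dataclass

from forktrap.architecture import (
    TrapReport,
    find_innermost_trap,
    sites_from_hits,
)
from forktrap.genome_io import CircularGenome
from forktrap.motif_scan import (
    MotifHit,
    best_hit_per_query,
    dedupe_hits,
    filter_candidates,
    locate_dif,
    scan_circular,
)
from forktrap.queries import DIF_SEQUENCE, TerQuery
from forktrap.variation import SiteVariation, partition_mismatches


@dataclass
class GenomeAnalysis:
    """Everything the pipeline derives for one genome."""

    genome: CircularGenome
    hits: list[MotifHit]  # deduped + filter-annotated, all queries
    site_hits: dict[str, MotifHit]  # best passing hit per query
    variations: dict[str, SiteVariation]
    dif: MotifHit | None
    trap: TrapReport


def scan_genome(
    genome: CircularGenome,
    queries: list[TerQuery],
    max_mismatch: int = 4,
    require_critical: bool = True,
    core_mismatch_budget: int = 1,
) -> list[MotifHit]:
    """Scan all queries, dedupe overlapping matches, annotate the filter."""
    hits: list[MotifHit] = []
    for q in queries:
        hits.extend(scan_circular(genome, q, max_mismatch))
    hits = dedupe_hits(hits, genome.length)
    return filter_candidates(
        hits,
        queries,
        max_mismatch=max_mismatch,
        require_critical=require_critical,
        core_mismatch_budget=core_mismatch_budget,
    )


def _core_retained(hit: MotifHit, query: TerQuery, core_mismatch_budget: int) -> bool:
    strict_core = set(query.core_positions) - {query.critical_position, 7}
    return len(hit.mismatch_positions & strict_core) <= core_mismatch_budget


def resolve_cross_query_overlaps(
    site_hits: dict[str, MotifHit], genome_length: int
) -> dict[str, MotifHit]:
    """One genomic locus is one site: drop the weaker of overlapping claims.

    When the best hits of two different queries overlap on the circle
    (an absent site's query matching inside a related present site),
    the hit with fewer mismatches keeps the locus; ties break to the
    smaller start, then the (+) strand.  The losing query is reported
    absent rather than duplicating the site.
    """

    def overlap(a: MotifHit, b: MotifHit) -> bool:
        for d in (-genome_length, 0, genome_length):
            if a.start + d < b.start + b.span and b.start < a.start + d + a.span:
                return True
        return False

    def rank(h: MotifHit):
        return (h.mismatch_count, h.start, 0 if h.strand == "+" else 1)

    winners: dict[str, MotifHit] = {}
    for name, h in sorted(site_hits.items(), key=lambda kv: rank(kv[1])):
        if any(overlap(h, w) for w in winners.values()):
            continue
        winners[name] = h
    return winners


def analyze_genome(
    genome: CircularGenome,
    queries: list[TerQuery],
    dif_sequence: str = DIF_SEQUENCE,
    max_mismatch: int = 4,
    dif_max_mismatch: int = 2,
    convention: str = "plus-blocks-cw",
    require_critical: bool = True,
    core_mismatch_budget: int = 1,
) -> GenomeAnalysis:
    """Full single-genome analysis.

    The site table keeps one best hit per query.  Detection is separate
    from functional annotation: a site whose critical position is mutated
    is still located and reported, but marked ``likely_inactive`` and
    excluded from the fork walk.
    """
    qmap = {q.name: q for q in queries}
    # Detection tier: mismatch budget only, so critical-position mutants
    # are still located; annotation happens on the retained hits.
    raw = scan_genome(
        genome,
        queries,
        max_mismatch=max_mismatch,
        require_critical=require_critical,
        core_mismatch_budget=core_mismatch_budget,
    )
    site_hits = best_hit_per_query(raw)
    site_hits = resolve_cross_query_overlaps(site_hits, genome.length)
    # Location tier: a located site must keep its conserved core (the
    # critical position alone may vary -- such sites are reported but
    # annotated likely_inactive).  Hits with a degenerate core are not
    # sites; their query is reported absent.
    site_hits = {
        name: h
        for name, h in site_hits.items()
        if _core_retained(h, qmap[name], core_mismatch_budget)
    }

    variations = {
        name: partition_mismatches(h, qmap[name], genome_name=genome.name)
        for name, h in site_hits.items()
    }
    functional = {name: v.functional_call for name, v in variations.items()}

    dif = locate_dif(genome, dif_sequence, max_mismatch=dif_max_mismatch)
    sites = sites_from_hits(site_hits, functional=functional, convention=convention)
    trap = find_innermost_trap(sites, genome, dif=dif)
    return GenomeAnalysis(
        genome=genome,
        hits=raw,
        site_hits=site_hits,
        variations=variations,
        dif=dif,
        trap=trap,
    )


def hits_to_bed(hits: list[MotifHit], chrom: str, genome_length: int) -> str:
    """BED6 text for a hit list (start 0-based, score = mismatch count)."""
    lines = []
    for h in sorted(hits, key=lambda h: (h.start, h.query_name)):
        # wrap-around spans keep end > genome_length, flagging the wrap
        lines.append(
            "\t".join(
                [chrom, str(h.start), str(h.start + h.span),
                 h.query_name, str(h.mismatch_count), h.strand]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")


def hits_to_tsv(hits: list[MotifHit]) -> str:
    """TSV with 1-based coordinates, mismatch positions and filter status."""
    header = "query\tstart_1based\tstrand\tmismatch_count\tmismatch_positions\tfilter_status\tfail_reason"
    rows = [header]
    for h in sorted(hits, key=lambda h: (h.query_name, h.start)):
        rows.append(
            "\t".join(
                [
                    h.query_name,
                    str(h.start + 1),
                    h.strand,
                    str(h.mismatch_count),
                    ";".join(str(p) for p in sorted(h.mismatch_positions)) or ".",
                    h.filter_status,
                    h.fail_reason or ".",
                ]
            )
        )
    return "\n".join(rows) + "\n"
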