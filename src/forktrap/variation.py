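"""Per-site sequence-variation analysis.

Mismatches of a located site against its reference query are partitioned
into the conserved core (positions 6, 8-18 of the 23-mer) and the
variable positions (1-5, 7, 19-23).  The qualitative functional call
follows the Tus-binding biology: a mutated critical position 6 largely
inactivates fork blocking; any other core change (position 7 excepted)
is expected to reduce binding; variable-only changes leave the site
active.  Cross-genome summaries count per-position differences (a SNP is
one mismatched query position in one genome) and split them into the
innermost primary-trap sites versus the outer sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from forktrap.motif_scan import MotifHit
from forktrap.queries import TerQuery, INNERMOST_SITE_NAMES


@dataclass(frozen=True)
class SiteVariation:
    genome_name: str
    site_name: str
    mismatch_positions: frozenset[int]
    core_mismatches: frozenset[int]
    variable_mismatches: frozenset[int]
    critical_hit: bool
    functional_call: str

    def __post_init__(self) -> None:
        assert self.core_mismatches | self.variable_mismatches == self.mismatch_positions
        assert not (self.core_mismatches & self.variable_mismatches)


@dataclass
class VariationSummary:
    total_snps: int
    variable_snps: int
    core_snps: int
    fraction_variable: float
    innermost_snps: int
    outer_snps: int
    per_site: dict[str, int]
    per_genome: dict[str, int]


def partition_mismatches(
    hit: MotifHit, query: TerQuery, genome_name: str = ""
) -> SiteVariation:
    """Split a hit's mismatches into core and variable positions."""
    n = len(query.sequence)
    for p in hit.mismatch_positions:
        if not (1 <= p <= n):
            raise ValueError(f"mismatch position {p} outside 1..{n}")
    core = frozenset(hit.mismatch_positions & query.core_positions)
    variable = frozenset(hit.mismatch_positions & query.variable_positions)
    critical = query.critical_position in hit.mismatch_positions
    variation = SiteVariation(
        genome_name=genome_name,
        site_name=hit.query_name,
        mismatch_positions=frozenset(hit.mismatch_positions),
        core_mismatches=core,
        variable_mismatches=variable,
        critical_hit=critical,
        functional_call=_functional_call(core, critical, query),
    )
    return variation


def _functional_call(core: frozenset[int], critical: bool, query: TerQuery) -> str:
    if critical:
        return "likely_inactive"
    if core - {query.critical_position}:
        return "reduced"
    return "active"


def functional_call(variation: SiteVariation) -> str:
    """Qualitative fork-blocking call from the mismatch partition."""
    return variation.functional_call


def summarize_variation(
    variations: list[SiteVariation],
    innermost_set: tuple[str, ...] = INNERMOST_SITE_NAMES,
) -> VariationSummary:
    """Totals and splits across genomes (reference genome excluded upstream).

    SNPs are counted per position: each mismatched query position in each
    genome contributes one.  ``fraction_variable`` is defined as 0 when
    there are no SNPs at all (degenerate but well-defined).
    """
    if variations is None:
        raise ValueError("no variations given")
    total = sum(len(v.mismatch_positions) for v in variations)
    variable = sum(len(v.variable_mismatches) for v in variations)
    core = sum(len(v.core_mismatches) for v in variations)
    innermost = sum(
        len(v.mismatch_positions) for v in variations if v.site_name in innermost_set
    )
    per_site: dict[str, int] = {}
    per_genome: dict[str, int] = {}
    for v in variations:
        per_site[v.site_name] = per_site.get(v.site_name, 0) + len(v.mismatch_positions)
        per_genome[v.genome_name] = per_genome.get(v.genome_name, 0) + len(v.mismatch_positions)
    return VariationSummary(
        total_snps=total,
        variable_snps=variable,
        core_snps=core,
        fraction_variable=(variable / total) if total else 0.0,
        innermost_snps=innermost,
        outer_snps=total - innermost,
        per_site=per_site,
        per_genome=per_genome,
    )


def flank_identity(flank_a: str, flank_b: str) -> float:
    """Fraction of identical positions between two equal-length flanks."""
    if len(flank_a) != len(flank_b):
        raise ValueError(f"length mismatch: {len(flank_a)} vs {len(flank_b)}")
    if not flank_a:
        raise ValueError("empty flanks")
    same = sum(1 for a, b in zip(flank_a, flank_b) if a == b and a != "N" and b != "N")
    return same / len(flank_a)


# ---------------------------------------------------------------- annotations


def read_bed_intervals(path: str | Path) -> list[tuple[int, int]]:
    """CDS/feature intervals from BED (0-based half-open, as in the format)."""
    intervals: list[tuple[int, int]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            warnings.warn(f"{path}:{lineno}: skipping malformed BED record", stacklevel=2)
            continue
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError:
            warnings.warn(f"{path}:{lineno}: skipping malformed BED record", stacklevel=2)
            continue
        if end <= start:
            warnings.warn(f"{path}:{lineno}: skipping empty/reversed interval", stacklevel=2)
            continue
        intervals.append((start, end))
    return intervals


def read_gff_cds_intervals(path: str | Path) -> list[tuple[int, int]]:
    """CDS intervals from GFF3, converted to 0-based half-open."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    intervals = []
    for feat in db.features_of_type("CDS"):
        intervals.append((feat.start - 1, feat.end))  # GFF is 1-based inclusive
    return intervals


def orf_overlap(
    hits: list[MotifHit],
    intervals: list[tuple[int, int]],
    genome_length: int,
) -> dict[tuple[str, int], str]:
    """Per-hit overlap call against CDS intervals: none / partial / contained.

    'contained' requires the full site span inside a single interval;
    wrap-around site spans are handled by also testing the +L image.
    CDS strand is ignored (overlap is recorded, not reading frame).
    """
    calls: dict[tuple[str, int], str] = {}
    for h in hits:
        call = "none"
        for s0 in (h.start, h.start - genome_length):
            s1 = s0 + h.span
            for a, b in intervals:
                if s0 >= a and s1 <= b:
                    call = "contained"
                    break
                if s0 < b and a < s1:
                    call = "partial" if call == "none" else call
            if call == "contained":
                break
        calls[(h.query_name, h.start)] = call
    return calls


def variation_matrix(variations: list[SiteVariation]) -> pd.DataFrame:
    """Sites x genomes matrix of mismatch descriptors ('15;21' style)."""
    sites = sorted({v.site_name for v in variations})
    genomes = sorted({v.genome_name for v in variations})
    data = {g: {s: "" for s in sites} for g in genomes}
    for v in variations:
        data[v.genome_name][v.site_name] = ";".join(str(p) for p in sorted(v.mismatch_positions))
    return pd.DataFrame(data, index=sites)
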