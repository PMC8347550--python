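"""Fork-trap geometry on the circular chromosome.

Two replication forks leave *oriC* in opposite directions.  The clockwise
(cw) fork moves in increasing coordinates; the anticlockwise (ccw) fork in
decreasing coordinates.  A Tus-bound terminator arrests exactly one of
them, depending on its orientation.  Walking each fork from *oriC* to the
first site that blocks it yields the innermost trap; the arc between the
two boundary sites that does not contain *oriC* is the inner termination
area where forks must fuse, and the *dif* dimer-resolution site is
expected inside it.

The mapping from query strand to blocked fork is not dictated by the
sequence itself, so it is a configuration switch.  The default,
``plus-blocks-cw``, is chosen so that the packaged MG1655-like template
reproduces the canonical architecture (terC/B/F/G/J arrest the clockwise
fork, terA/D/E/I/H the anticlockwise one).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

from forktrap.genome_io import CircularGenome
from forktrap.motif_scan import MotifHit

CONVENTIONS = ("plus-blocks-cw", "plus-blocks-ccw")

FUNCTIONAL_LEVELS = ("active", "reduced", "likely_inactive")


class TrapUndefinedError(Exception):
    """Raised when a trap-dependent quantity is requested without an intact trap."""


@dataclass(frozen=True)
class OrientedSite:
    """A located terminator with its fork-blocking orientation."""

    name: str
    start: int
    strand: str  # '+' / '-'
    blocks: str  # 'cw' / 'ccw'
    functional: str = "active"
    mismatch_count: int = 0

    def __post_init__(self) -> None:
        assert self.strand in "+-"
        assert self.blocks in ("cw", "ccw")
        assert self.functional in FUNCTIONAL_LEVELS


@dataclass
class TrapReport:
    """Reconstructed termination-area architecture of one genome."""

    genome_name: str
    length: int
    oric_position: int
    midpoint: int
    sites: list[OrientedSite]
    cw_boundary: OrientedSite | None
    ccw_boundary: OrientedSite | None
    trap_intact: bool
    inner_span_bp: int | None
    dif_position: int | None = None
    dif_strand: str | None = None
    dif_in_trap: bool | None = None

    @property
    def inner_span_percent(self) -> float | None:
        if self.inner_span_bp is None:
            return None
        return 100.0 * self.inner_span_bp / self.length

    def site_table(self, genome: CircularGenome) -> list[dict]:
        rows = []
        for s in sorted(self.sites, key=lambda s: cw_distance(genome, s.start)):
            repl, pct = replichore_percent(s.start, genome)
            rows.append(
                {
                    "name": s.name,
                    "start_1based": s.start + 1,
                    "strand": s.strand,
                    "blocks": s.blocks,
                    "functional": s.functional,
                    "mismatch_count": s.mismatch_count,
                    "replichore": repl,
                    "replichore_percent": round(pct, 2),
                }
            )
        return rows

    def to_dict(self) -> dict:
        d = asdict(self)
        d["inner_span_percent"] = self.inner_span_percent
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)


def arithmetic_midpoint(genome: CircularGenome) -> int:
    """The point diametrically opposite *oriC* (floor for odd lengths)."""
    return (genome.oric_position + genome.length // 2) % genome.length


def cw_distance(genome: CircularGenome, position: int) -> int:
    """Clockwise (increasing-coordinate) distance from oriC to position."""
    return (position - genome.oric_position) % genome.length


def replichore_percent(position: int, genome: CircularGenome) -> tuple[str, float]:
    """Replichore assignment and position as percent of the replichore.

    *oriC* maps to 100%, the arithmetic midpoint to 0%; a site halfway
    along the clockwise replichore maps to ('cw', 50.0).
    """
    L = genome.length
    half = L / 2.0
    d = cw_distance(genome, position)
    if d <= half:
        return "cw", 100.0 * (half - d) / half
    return "ccw", 100.0 * (d - half) / half


def blocking_direction(strand: str, convention: str = "plus-blocks-cw") -> str:
    """Which fork a Tus-bound site with this query strand arrests."""
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}")
    if strand not in "+-":
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    plus_blocks = "cw" if convention == "plus-blocks-cw" else "ccw"
    other = "ccw" if plus_blocks == "cw" else "cw"
    return plus_blocks if strand == "+" else other


def sites_from_hits(
    hits: dict[str, MotifHit],
    functional: dict[str, str] | None = None,
    convention: str = "plus-blocks-cw",
) -> list[OrientedSite]:
    """Build oriented sites from one best hit per query."""
    functional = functional or {}
    sites = []
    for name, h in sorted(hits.items()):
        sites.append(
            OrientedSite(
                name=name,
                start=h.start,
                strand=h.strand,
                blocks=blocking_direction(h.strand, convention),
                functional=functional.get(name, "active"),
                mismatch_count=h.mismatch_count,
            )
        )
    return sites


def _inner_arc(genome: CircularGenome, a: int, b: int) -> tuple[int, int]:
    """Start and length of the arc between a and b not containing oriC.

    Returns (arc_start, arc_len) with the arc running clockwise from
    arc_start.  Requires oriC to coincide with neither endpoint.
    """
    L = genome.length
    fwd = (b - a) % L  # arc a -> b clockwise
    oric_in_fwd = (genome.oric_position - a) % L < fwd
    if not oric_in_fwd:
        return a, fwd
    return b, (a - b) % L


def find_innermost_trap(
    sites: list[OrientedSite],
    genome: CircularGenome,
    dif: MotifHit | None = None,
    exclude_inactive: bool = True,
    exclude_names: tuple[str, ...] = ("terY", "terZ", "terK", "terL"),
) -> TrapReport:
    """Walk each fork from *oriC* to its first blocking site.

    ``likely_inactive`` sites (critical-position mutants) and secondary
    sites are excluded from the walk by default but stay in the report.
    """
    L = genome.length
    walkable = [
        s
        for s in sites
        if s.name not in exclude_names
        and not (exclude_inactive and s.functional == "likely_inactive")
    ]
    starts = [s.start for s in walkable]
    assert len(starts) == len(set(starts)), "duplicate site coordinates after dedupe"

    cw_order = sorted(walkable, key=lambda s: cw_distance(genome, s.start))
    cw_boundary = next((s for s in cw_order if s.blocks == "cw"), None)
    ccw_order = sorted(walkable, key=lambda s: (genome.oric_position - s.start) % L)
    ccw_boundary = next((s for s in ccw_order if s.blocks == "ccw"), None)

    trap_intact = cw_boundary is not None and ccw_boundary is not None
    inner_span_bp: int | None = None
    dif_inside: bool | None = None
    if trap_intact:
        arc_start, arc_len = _inner_arc(genome, cw_boundary.start, ccw_boundary.start)
        inner_span_bp = arc_len
        if dif is not None:
            off = (dif.start - arc_start) % L
            dif_inside = 0 < off < arc_len

    return TrapReport(
        genome_name=genome.name,
        length=L,
        oric_position=genome.oric_position,
        midpoint=arithmetic_midpoint(genome),
        sites=list(sites),
        cw_boundary=cw_boundary,
        ccw_boundary=ccw_boundary,
        trap_intact=trap_intact,
        inner_span_bp=inner_span_bp,
        dif_position=dif.start if dif is not None else None,
        dif_strand=dif.strand if dif is not None else None,
        dif_in_trap=dif_inside,
    )


def dif_in_trap(trap: TrapReport, dif: MotifHit, genome: CircularGenome) -> bool:
    """True iff dif lies strictly inside the inner termination area."""
    if not trap.trap_intact:
        raise TrapUndefinedError("dif_in_trap undefined: trap is not intact")
    arc_start, arc_len = _inner_arc(genome, trap.cw_boundary.start, trap.ccw_boundary.start)
    off = (dif.start - arc_start) % genome.length
    return 0 < off < arc_len


def inner_span_percent(inner_span_bp: int | TrapReport, length: int | None = None) -> float:
    """Inner termination area as percent of total genome size.

    Accepts either (span_bp, genome_length) or an intact TrapReport.
    """
    if isinstance(inner_span_bp, TrapReport):
        trap = inner_span_bp
        if not trap.trap_intact or trap.inner_span_bp is None:
            raise TrapUndefinedError("inner_span_percent undefined: trap not intact")
        return 100.0 * trap.inner_span_bp / trap.length
    if length is None or length <= 0 or not (0 <= inner_span_bp <= length):
        raise ValueError("need 0 <= span <= length with length > 0")
    return 100.0 * inner_span_bp / length


@dataclass
class SiteDiff:
    name: str
    orientation_flipped: bool
    replichore_changed: bool
    rank_reference: int
    rank_target: int


@dataclass
class ArchitectureDiff:
    """Differences between two trap reports sharing site names."""

    shared_sites: list[str]
    site_diffs: list[SiteDiff]
    dif_strand_changed: bool | None
    dif_neighbours_reference: tuple[str, str] | None
    dif_neighbours_target: tuple[str, str] | None
    dif_neighbours_changed: bool | None
    block_inversions: list[list[str]]

    @property
    def is_empty(self) -> bool:
        return (
            not any(d.orientation_flipped or d.rank_reference != d.rank_target
                    for d in self.site_diffs)
            and not self.block_inversions
            and not (self.dif_strand_changed or False)
            and not (self.dif_neighbours_changed or False)
        )

    def to_dict(self) -> dict:
        return {
            "shared_sites": self.shared_sites,
            "site_diffs": [asdict(d) for d in self.site_diffs],
            "dif_strand_changed": self.dif_strand_changed,
            "dif_neighbours_reference": self.dif_neighbours_reference,
            "dif_neighbours_target": self.dif_neighbours_target,
            "dif_neighbours_changed": self.dif_neighbours_changed,
            "block_inversions": self.block_inversions,
        }


def _clockwise_site_order(report: TrapReport, genome_like: CircularGenome | None = None) -> list[str]:
    L = report.length
    oric = report.oric_position
    return [
        s.name
        for s in sorted(report.sites, key=lambda s: (s.start - oric) % L)
    ]


def _dif_neighbours(report: TrapReport) -> tuple[str, str] | None:
    """Names of the nearest ter sites flanking dif (ccw side, cw side)."""
    if report.dif_position is None or not report.sites:
        return None
    L = report.length
    before = min(report.sites, key=lambda s: (report.dif_position - s.start) % L)
    after = min(report.sites, key=lambda s: (s.start - report.dif_position) % L)
    return (before.name, after.name)


def compare_to_reference(report: TrapReport, reference: TrapReport) -> ArchitectureDiff:
    """Diff a reconstructed architecture against a reference one.

    Flags per-site orientation flips, replichore changes and rank-order
    changes (order read clockwise from *oriC*), dif strand/neighbour
    changes, and candidate block inversions: maximal contiguous runs of
    >= 2 shared sites that are both order-reversed and orientation-flipped
    relative to the reference.
    """
    ref_sites = {s.name: s for s in reference.sites}
    tgt_sites = {s.name: s for s in report.sites}
    shared = sorted(set(ref_sites) & set(tgt_sites))
    if not shared:
        raise ValueError("no shared sites between reports")

    ref_order = [n for n in _clockwise_site_order(reference) if n in shared]
    tgt_order = [n for n in _clockwise_site_order(report) if n in shared]
    ref_rank = {n: i for i, n in enumerate(ref_order)}
    tgt_rank = {n: i for i, n in enumerate(tgt_order)}

    ref_genome_geom = CircularGenome(
        name="_ref", sequence="A" * reference.length, oric_position=reference.oric_position
    )
    tgt_genome_geom = CircularGenome(
        name="_tgt", sequence="A" * report.length, oric_position=report.oric_position
    )

    site_diffs = []
    for name in shared:
        r, t = ref_sites[name], tgt_sites[name]
        repl_r, _ = replichore_percent(r.start, ref_genome_geom)
        repl_t, _ = replichore_percent(t.start, tgt_genome_geom)
        site_diffs.append(
            SiteDiff(
                name=name,
                orientation_flipped=r.strand != t.strand,
                replichore_changed=repl_r != repl_t,
                rank_reference=ref_rank[name],
                rank_target=tgt_rank[name],
            )
        )

    # Candidate block inversions: contiguous in the reference clockwise
    # order, contiguous and reversed in the target order, all flipped.
    flipped = {d.name for d in site_diffs if d.orientation_flipped}
    inversions: list[list[str]] = []
    n = len(ref_order)
    used: set[tuple[str, ...]] = set()
    for i in range(n):
        for j in range(n, i + 1, -1):  # longest first -> maximal runs
            run = ref_order[i:j]
            if len(run) < 2 or not all(name in flipped for name in run):
                continue
            ranks = [tgt_rank[name] for name in run]
            contiguous_reversed = ranks == list(range(ranks[0], ranks[0] - len(run), -1))
            if contiguous_reversed:
                if not any(set(run) <= set(prev) for prev in used):
                    inversions.append(run)
                    used.add(tuple(run))
                break

    dif_strand_changed = None
    if report.dif_strand is not None and reference.dif_strand is not None:
        dif_strand_changed = report.dif_strand != reference.dif_strand
    nb_ref = _dif_neighbours(reference)
    nb_tgt = _dif_neighbours(report)
    nb_changed = None
    if nb_ref is not None and nb_tgt is not None:
        nb_changed = set(nb_ref) != set(nb_tgt)

    return ArchitectureDiff(
        shared_sites=shared,
        site_diffs=site_diffs,
        dif_strand_changed=dif_strand_changed,
        dif_neighbours_reference=nb_ref,
        dif_neighbours_target=nb_tgt,
        dif_neighbours_changed=nb_changed,
        block_inversions=inversions,
    )
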