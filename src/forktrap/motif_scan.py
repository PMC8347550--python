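"""Both-strand, wrap-aware approximate motif search on circular genomes.

The scanner is an exhaustive Hamming scan (no indels): every rotation of
the circle on both strands is tested against the fixed-length query.
Internally the doubled-sequence trick is used -- the genome concatenated
with its own first ``k-1`` bases turns every wrap-around window into an
ordinary substring -- and window mismatch counts are accumulated with
numpy, so a 5-Mbp chromosome scans in well under a second per query.

Candidate filtering is two-tiered: *detection* is governed only by the
mismatch budget, while *functional annotation* additionally requires the
critical position (6) to be intact and limits mismatches in the conserved
core.  Failing hits are flagged, never discarded, because genomes do carry
detectable sites whose critical base is mutated.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from forktrap.genome_io import CircularGenome, circular_subsequence, reverse_complement
from forktrap.queries import TerQuery

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
_N_CODE = 4


_ENCODE_TABLE = np.full(256, _N_CODE, dtype=np.uint8)
for _base, _code in _CODE.items():
    _ENCODE_TABLE[ord(_base)] = _code


def _encode_fast(seq: str) -> np.ndarray:
    # ASCII bytes -> small base codes via a 256-entry lookup table.
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENCODE_TABLE[raw]


@dataclass(frozen=True)
class MotifHit:
    """One genomic match of a query.

    ``start`` is always the leftmost forward-strand coordinate of the
    matched span (0-based), regardless of strand.  ``mismatch_positions``
    are 1-based query coordinates (position 1 = 5' end of the query as
    written); for (-) strand hits the genomic span is oriented into query
    orientation before comparison.  ``matched_sequence`` is likewise in
    query orientation.
    """

    query_name: str
    start: int
    strand: str  # '+' or '-'
    mismatch_count: int
    mismatch_positions: frozenset[int]
    matched_sequence: str
    span: int
    filter_status: str = "unfiltered"  # 'pass' / 'fail' / 'unfiltered'
    fail_reason: str | None = None

    def __post_init__(self) -> None:
        assert self.strand in "+-"
        assert self.mismatch_count == len(self.mismatch_positions)

    def end(self, genome_length: int | None = None) -> int:
        """Exclusive end coordinate (may exceed the genome length on wrap)."""
        return self.start + self.span


def _window_mismatch_counts(doubled: np.ndarray, qcodes: np.ndarray, n_windows: int) -> np.ndarray:
    """Mismatch count of the query at every window start in [0, n_windows)."""
    k = len(qcodes)
    counts = np.zeros(n_windows, dtype=np.int32)
    for j in range(k):
        col = doubled[j : j + n_windows]
        qc = qcodes[j]
        if qc == _N_CODE:
            counts += 1  # N in the query matches nothing
        else:
            counts += (col != qc) | (col == _N_CODE)
    return counts


def _hit_from_window(
    genome: CircularGenome, query_name: str, qseq: str, start: int, strand: str
) -> MotifHit:
    k = len(qseq)
    span_seq = circular_subsequence(genome, start, k)
    oriented = span_seq if strand == "+" else reverse_complement(span_seq)
    mism = frozenset(
        i + 1
        for i, (a, b) in enumerate(zip(qseq, oriented))
        if a != b or a == "N" or b == "N"
    )
    return MotifHit(
        query_name=query_name,
        start=start,
        strand=strand,
        mismatch_count=len(mism),
        mismatch_positions=mism,
        matched_sequence=oriented,
        span=k,
    )


def scan_circular(genome: CircularGenome, query: TerQuery, max_mismatch: int) -> list[MotifHit]:
    """All positions on either strand with Hamming distance <= ``max_mismatch``.

    Wrap-around windows are included; an N anywhere counts as a mismatch.
    Hits are ordered by (start, strand).
    """
    if max_mismatch < 0:
        raise ValueError("max_mismatch must be >= 0")
    k = len(query.sequence)
    L = genome.length
    if k > L:
        raise ValueError(f"query {query.name!r} ({k} bp) longer than genome ({L} bp)")

    doubled = _encode_fast(genome.sequence + genome.sequence[: k - 1])
    hits: list[MotifHit] = []
    for strand, qseq in (("+", query.sequence), ("-", reverse_complement(query.sequence))):
        qcodes = _encode_fast(qseq)
        counts = _window_mismatch_counts(doubled, qcodes, L)
        for start in np.flatnonzero(counts <= max_mismatch):
            hits.append(_hit_from_window(genome, query.name, query.sequence, int(start), strand))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def _circular_overlap(a: MotifHit, b: MotifHit, length: int) -> bool:
    """Do two spans on the circle share at least one base?"""
    # Compare on the doubled line: each span occupies [start, start+span).
    for sa in (a.start, a.start + length):
        sb = b.start
        if sa < sb + b.span and sb < sa + a.span:
            return True
    for sb in (b.start + length,):
        sa = a.start
        if sa < sb + b.span and sb < sa + a.span:
            return True
    return False


def dedupe_hits(hits: list[MotifHit], genome_length: int) -> list[MotifHit]:
    """Collapse overlapping hits of the same query to the best one.

    Among hits of one query whose spans overlap on the circle, the hit
    with the fewest mismatches wins; ties break to the smallest start,
    then to the (+) strand.  Hits of different queries are never merged.
    """
    by_query: dict[str, list[MotifHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_name, []).append(h)

    kept: list[MotifHit] = []
    for _, group in sorted(by_query.items()):
        # Union overlapping spans into clusters (transitive closure).
        n = len(group)
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if _circular_overlap(group[i], group[j], genome_length):
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[rj] = ri
        clusters: dict[int, list[MotifHit]] = {}
        for i, h in enumerate(group):
            clusters.setdefault(find(i), []).append(h)
        for members in clusters.values():
            best = min(
                members,
                key=lambda h: (h.mismatch_count, h.start, 0 if h.strand == "+" else 1),
            )
            kept.append(best)
    kept.sort(key=lambda h: (h.start, h.strand, h.query_name))
    return kept


def filter_candidates(
    hits: list[MotifHit],
    queries: dict[str, TerQuery] | list[TerQuery],
    max_mismatch: int = 4,
    require_critical: bool = True,
    core_mismatch_budget: int = 1,
) -> list[MotifHit]:
    """Annotate hits with the candidate filter; nothing is dropped.

    A hit passes when its mismatch count is within ``max_mismatch``
    ("fewer than 5" at the default), its critical position is intact
    (when ``require_critical``), and at most ``core_mismatch_budget``
    mismatches fall in the conserved core outside the critical position
    and the tolerant position 7.
    """
    if isinstance(queries, list):
        queries = {q.name: q for q in queries}
    out: list[MotifHit] = []
    for h in hits:
        q = queries[h.query_name]
        reasons: list[str] = []
        if h.mismatch_count > max_mismatch:
            reasons.append(f"mismatch count {h.mismatch_count} > {max_mismatch}")
        if require_critical and q.critical_position in h.mismatch_positions:
            reasons.append("critical position")
        strict_core = set(q.core_positions) - {q.critical_position, 7}
        core_mm = h.mismatch_positions & strict_core
        if len(core_mm) > core_mismatch_budget:
            reasons.append(
                f"{len(core_mm)} core mismatches > budget {core_mismatch_budget}"
            )
        if reasons:
            out.append(replace(h, filter_status="fail", fail_reason="; ".join(reasons)))
        else:
            out.append(replace(h, filter_status="pass", fail_reason=None))
    return out


def locate_dif(
    genome: CircularGenome, dif_sequence: str, max_mismatch: int = 2
) -> MotifHit | None:
    """Best single dif hit on either strand, or None within the budget.

    Strand '+' means the given dif sequence lies on the forward strand.
    Ties resolve as in dedupe_hits (fewest mismatches, smallest start,
    then '+').
    """
    if not dif_sequence:
        raise ValueError("empty dif sequence")
    query = TerQuery(
        name="dif",
        sequence=dif_sequence,
        critical_position=1,
        core_positions=frozenset(range(1, len(dif_sequence) + 1)),
        variable_positions=frozenset(),
    )
    hits = scan_circular(genome, query, max_mismatch)
    if not hits:
        return None
    return min(hits, key=lambda h: (h.mismatch_count, h.start, 0 if h.strand == "+" else 1))


def extract_flanks(genome: CircularGenome, hit: MotifHit, flank: int = 25) -> str:
    """The hit span extended by ``flank`` bp each side, in query orientation."""
    total = hit.span + 2 * flank
    if total > genome.length:
        raise ValueError(f"flanked span {total} exceeds genome length {genome.length}")
    start = (hit.start - flank) % genome.length
    seq = circular_subsequence(genome, start, total)
    return seq if hit.strand == "+" else reverse_complement(seq)


def best_hit_per_query(hits: list[MotifHit]) -> dict[str, MotifHit]:
    """The single best hit for each query name.

    Used for per-genome site tables: a chromosome carries one copy of each
    terminator, so the lowest-mismatch (then leftmost, then '+') hit is
    taken as *the* site.
    """
    best: dict[str, MotifHit] = {}
    for h in hits:
        cur = best.get(h.query_name)
        key = (h.mismatch_count, h.start, 0 if h.strand == "+" else 1)
        if cur is None or key < (cur.mismatch_count, cur.start, 0 if cur.strand == "+" else 1):
            best[h.query_name] = h
    return best
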