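"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive: plain-Python position-by-position
comparison on the doubled string, exhaustive recursion over alignment
moves, and explicit enumeration of alignment paths.  None of it shares
code with the package implementations it checks.
"""

from __future__ import annotations

from functools import lru_cache

_COMP = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def brute_force_scan(sequence: str, query: str, max_mismatch: int) -> set[tuple[int, str, int]]:
    """All (start, strand, mismatch_count) with Hamming distance <= budget.

    Tests every rotation of the circle on both strands via the doubled
    string; N on either side counts as a mismatch.
    """
    L, k = len(sequence), len(query)
    doubled = sequence + sequence[: k - 1]
    out: set[tuple[int, str, int]] = set()
    for strand, q in (("+", query), ("-", rc(query))):
        for s in range(L):
            w = doubled[s : s + k]
            mm = sum(1 for a, b in zip(q, w) if a != b or a == "N" or b == "N")
            if mm <= max_mismatch:
                out.add((s, strand, mm))
    return out


def brute_force_cluster_best(
    hits: list, genome_length: int
) -> set[tuple[str, int, str]]:
    """Expected surviving (query, start, strand) after overlap dedupe.

    Exhaustive: builds the full overlap graph per query, takes connected
    components, keeps the best hit of each component.
    """
    from collections import defaultdict

    def overlap(a, b) -> bool:
        for d in (-genome_length, 0, genome_length):
            if a.start + d < b.start + b.span and b.start < a.start + d + a.span:
                return True
        return False

    survivors: set[tuple[str, int, str]] = set()
    by_query = defaultdict(list)
    for h in hits:
        by_query[h.query_name].append(h)
    for group in by_query.values():
        unassigned = list(group)
        while unassigned:
            comp = [unassigned.pop()]
            changed = True
            while changed:
                changed = False
                for h in list(unassigned):
                    if any(overlap(h, c) for c in comp):
                        comp.append(h)
                        unassigned.remove(h)
                        changed = True
            best = min(comp, key=lambda h: (h.mismatch_count, h.start, h.strand != "+"))
            survivors.add((best.query_name, best.start, best.strand))
    return survivors


def optimal_alignment_score(
    a: str, b: str, match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0
) -> float:
    """Optimum over all global alignments, by exhaustive recursion.

    The recursion maximises over the three possible final columns
    (substitution, gap in b, gap in a); memoisation only shares repeated
    subproblems and cannot change the optimum.
    """

    @lru_cache(maxsize=None)
    def best(i: int, j: int) -> float:
        if i == 0 and j == 0:
            return 0.0
        options = []
        if i > 0 and j > 0:
            options.append(best(i - 1, j - 1) + (match if a[i - 1] == b[j - 1] else mismatch))
        if i > 0:
            options.append(best(i - 1, j) + gap)
        if j > 0:
            options.append(best(i, j - 1) + gap)
        return max(options)

    return best(len(a), len(b))


def enumerate_alignment_scores(
    a: str, b: str, match: float = 1.0, mismatch: float = -1.0, gap: float = -2.0
) -> list[float]:
    """Scores of literally every global alignment path (tiny inputs only)."""
    scores: list[float] = []

    def walk(i: int, j: int, acc: float) -> None:
        if i == len(a) and j == len(b):
            scores.append(acc)
            return
        if i < len(a) and j < len(b):
            walk(i + 1, j + 1, acc + (match if a[i] == b[j] else mismatch))
        if i < len(a):
            walk(i + 1, j, acc + gap)
        if j < len(b):
            walk(i, j + 1, acc + gap)

    walk(0, 0, 0.0)
    return scores


def fork_walk_expected(
    manifest, exclude: tuple[str, ...] = ("terY", "terZ", "terK", "terL")
) -> dict:
    """Exhaustive fork-walk over a ground-truth manifest.

    Walks every coordinate step by step from oriC in each direction until
    a blocking implant start is reached (O(L) per fork) -- slower and
    entirely separate from the package's sorted-order walk.
    """
    L = manifest.length
    oric = manifest.oric_position
    blockers_cw = {}
    blockers_ccw = {}
    for s in manifest.implants:
        if s.name in exclude:
            continue
        if any(pos == 6 for pos, _ in s.mutations):  # critical-position mutants
            continue
        if s.strand == "+":
            blockers_cw[s.position] = s.name
        else:
            blockers_ccw[s.position] = s.name

    cw_boundary = ccw_boundary = None
    for step in range(1, L):
        pos = (oric + step) % L
        if pos in blockers_cw:
            cw_boundary = blockers_cw[pos]
            break
    for step in range(1, L):
        pos = (oric - step) % L
        if pos in blockers_ccw:
            ccw_boundary = blockers_ccw[pos]
            break
    return {"cw_boundary": cw_boundary, "ccw_boundary": ccw_boundary,
            "trap_intact": cw_boundary is not None and ccw_boundary is not None}
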