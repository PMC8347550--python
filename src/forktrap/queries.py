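"""Ter and dif query definitions.

A *ter* site is a 23-bp non-palindromic terminator.  Positions are
numbered 1..23 from the 5' end of the query as written.  Position 6 (the
strictly conserved G whose flipped-out base locks the arrest-competent
Tus complex) plus positions 8-18 form the conserved core; positions
1-5, 7 and 19-23 tolerate substitution.

The shipped reference query set is synthetic: every site shares the
canonical conserved core (G at 6, ATGTTGTAACT at 8-18) while the variable
positions carry fixed per-site flanks, so the set reproduces the
core/variable structure of the natural terA-J and secondary terK/L/Y/Z
sites without copying any strain's genome sequence.  terY deliberately
carries two core deviations (positions 9 and 17), mirroring its weak
fork-blocking activity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from forktrap.genome_io import VALID_BASES, InvalidSequenceError

#: The dif chromosome dimer resolution site recognised by XerCD,
#: written on the (+) strand.
DIF_SEQUENCE = "GGTGCCATAATGTATATTATGTTAAAT"

DEFAULT_CORE_POSITIONS = frozenset({6} | set(range(8, 19)))
DEFAULT_VARIABLE_POSITIONS = frozenset(set(range(1, 6)) | {7} | set(range(19, 24)))

#: Conserved core written at positions 6..18 of every reference query.
_CORE_6_TO_18 = "G" + "T" + "ATGTTGTAACT"  # pos 6, pos 7 placeholder, pos 8-18

PRIMARY_SITE_NAMES = ("terA", "terB", "terC", "terD", "terE",
                      "terF", "terG", "terH", "terI", "terJ")
SECONDARY_SITE_NAMES = ("terK", "terL", "terY", "terZ")
INNERMOST_SITE_NAMES = ("terA", "terB", "terC", "terD")


@dataclass(frozen=True)
class TerQuery:
    """A fixed-length terminator query with its core/variable partition."""

    name: str
    sequence: str
    critical_position: int = 6
    core_positions: frozenset[int] = DEFAULT_CORE_POSITIONS
    variable_positions: frozenset[int] = DEFAULT_VARIABLE_POSITIONS

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if n == 0:
            raise ValueError("empty query sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise InvalidSequenceError(f"query {self.name!r}: invalid characters {sorted(bad)!r}")
        allpos = set(range(1, n + 1))
        if set(self.core_positions) | set(self.variable_positions) != allpos:
            raise ValueError(f"query {self.name!r}: core u variable must cover 1..{n}")
        if set(self.core_positions) & set(self.variable_positions):
            raise ValueError(f"query {self.name!r}: core and variable overlap")
        if self.critical_position not in self.core_positions:
            raise ValueError(f"query {self.name!r}: critical position must be in the core")

    def __len__(self) -> int:
        return len(self.sequence)


# Per-site variable flanks: (positions 1-5, position 7, positions 19-23).
# Chosen so that every pair of queries -- including reverse complements
# and any window of the dif site -- differs at >= 6 positions, keeping
# sites mutually distinguishable at the default 4-mismatch scan budget.
_SITE_FLANKS: dict[str, tuple[str, str, str]] = {
    "terA": ("GACGA", "T", "TCATA"),
    "terB": ("CAACT", "G", "ATACG"),
    "terC": ("TAGAT", "G", "CGGGA"),
    "terD": ("CCGAA", "T", "GCCTG"),
    "terE": ("TGGAA", "A", "TTGTG"),
    "terF": ("GCCCG", "T", "CCTGT"),
    "terG": ("GTTGT", "G", "GCCGG"),
    "terH": ("ACAGA", "G", "TATAC"),
    "terI": ("TGGTC", "C", "TAGAC"),
    "terJ": ("TTACT", "A", "TCGGA"),
    "terK": ("GGATT", "A", "GTTCA"),
    "terL": ("CGTTA", "C", "CTAAT"),
    "terY": ("ACCGA", "C", "GGCGC"),
    "terZ": ("CCCCT", "A", "CGCCC"),
}

# terY carries core deviations at positions 9 and 17 (1-based), mirroring
# its naturally degenerate core and weak blocking activity.
_TERY_CORE_EDITS = {9: "C", 17: "G"}


def _build_site_sequence(name: str) -> str:
    left, p7, right = _SITE_FLANKS[name]
    core = list(_CORE_6_TO_18)
    core[1] = p7  # index 1 of the core string is position 7
    seq = list(left + "".join(core) + right)
    if name == "terY":
        for pos, base in _TERY_CORE_EDITS.items():
            seq[pos - 1] = base
    assert len(seq) == 23
    return "".join(seq)


def reference_ter_queries(include_secondary: bool = True) -> list[TerQuery]:
    """The synthetic reference query set (terA-J, optionally terK/L/Y/Z)."""
    names = PRIMARY_SITE_NAMES + (SECONDARY_SITE_NAMES if include_secondary else ())
    return [TerQuery(name=n, sequence=_build_site_sequence(n)) for n in names]


def read_queries(path: str | Path) -> list[TerQuery]:
    """Read a query set from FASTA (record id = site name)."""
    queries = []
    for rec in SeqIO.parse(str(path), "fasta"):
        queries.append(TerQuery(name=rec.id, sequence=str(rec.seq).upper()))
    if not queries:
        raise ValueError(f"no FASTA records in {path}")
    return queries


def write_queries(queries: list[TerQuery], path: str | Path) -> None:
    with open(path, "w") as fh:
        for q in queries:
            fh.write(f">{q.name}\n{q.sequence}\n")
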