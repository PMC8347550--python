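"""Pairwise global alignment and residue-difference reporting for Tus.

Tus terminator proteins are near-identical between strains (a handful of
substitutions over ~309 residues), so a simple global alignment with
linear gap penalty is sufficient; the analytical content is the list of
changed positions against a reference strain.  The Needleman-Wunsch DP
is implemented here with a pinned deterministic traceback (ties prefer
diagonal, then up, then left) so that diff coordinates are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

GAP = "-"


@dataclass(frozen=True)
class ProteinRecord:
    name: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"protein {self.name!r} is empty")
        bad = set(self.residues) - AA_ALPHABET
        if bad:
            raise ValueError(f"protein {self.name!r}: invalid residues {sorted(bad)!r}")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Alignment:
    name_a: str
    name_b: str
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        assert len(self.aligned_a) == len(self.aligned_b)


@dataclass(frozen=True)
class ProteinDiff:
    pair: tuple[str, str]
    aligned_length: int
    changed_positions: tuple[tuple[int, str, str], ...]  # (ref pos 1-based, ref aa, other aa)
    gap_count: int

    @property
    def change_count(self) -> int:
        return len(self.changed_positions)


@dataclass(frozen=True)
class Scoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0


def global_align(a: ProteinRecord, b: ProteinRecord, scoring: Scoring = Scoring()) -> Alignment:
    """Optimal global alignment under match/mismatch/linear-gap scoring.

    Traceback ties resolve diagonal > up (gap in b) > left (gap in a),
    making the reported alignment deterministic.
    """
    ra, rb = a.residues, b.residues
    m, n = len(ra), len(rb)
    F = np.empty((m + 1, n + 1), dtype=np.float64)
    F[0, :] = np.arange(n + 1) * scoring.gap
    F[:, 0] = np.arange(m + 1) * scoring.gap
    sa = np.frombuffer(ra.encode("ascii"), dtype=np.uint8)
    sb = np.frombuffer(rb.encode("ascii"), dtype=np.uint8)
    sub = np.where(sa[:, None] == sb[None, :], scoring.match, scoring.mismatch)
    for i in range(1, m + 1):
        row_prev = F[i - 1]
        row = F[i]
        diag = row_prev[:-1] + sub[i - 1]
        up = row_prev[1:] + scoring.gap
        # left depends on the running row, so fill sequentially
        best = np.maximum(diag, up)
        acc = row[0]
        for j in range(1, n + 1):
            acc = max(best[j - 1], acc + scoring.gap)
            row[j] = acc

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = m, n
    while i > 0 or j > 0:
        if i > 0 and j > 0 and F[i, j] == F[i - 1, j - 1] + sub[i - 1, j - 1]:
            out_a.append(ra[i - 1])
            out_b.append(rb[j - 1])
            i -= 1
            j -= 1
        elif i > 0 and F[i, j] == F[i - 1, j] + scoring.gap:
            out_a.append(ra[i - 1])
            out_b.append(GAP)
            i -= 1
        else:
            out_a.append(GAP)
            out_b.append(rb[j - 1])
            j -= 1
    return Alignment(
        name_a=a.name,
        name_b=b.name,
        aligned_a="".join(reversed(out_a)),
        aligned_b="".join(reversed(out_b)),
        score=float(F[m, n]),
    )


def diff_positions(alignment: Alignment, reference: str) -> ProteinDiff:
    """Substitution columns in reference coordinates; gaps counted separately."""
    if reference == alignment.name_a:
        ref_seq, other_seq = alignment.aligned_a, alignment.aligned_b
        other_name = alignment.name_b
    elif reference == alignment.name_b:
        ref_seq, other_seq = alignment.aligned_b, alignment.aligned_a
        other_name = alignment.name_a
    else:
        raise ValueError(f"reference {reference!r} not in alignment")

    changed: list[tuple[int, str, str]] = []
    gap_count = 0
    ref_pos = 0
    for r, o in zip(ref_seq, other_seq):
        if r != GAP:
            ref_pos += 1
        if r == GAP or o == GAP:
            gap_count += 1
        elif r != o:
            changed.append((ref_pos, r, o))
    return ProteinDiff(
        pair=(reference, other_name),
        aligned_length=len(ref_seq),
        changed_positions=tuple(changed),
        gap_count=gap_count,
    )


def aggregate_changes(diffs: list[ProteinDiff]) -> dict:
    """Union of changed reference positions over pairwise diffs vs one reference.

    The headline number is the count of distinct changed positions; the
    count of (position, strain) events is reported alongside.
    """
    positions: set[int] = set()
    events = 0
    per_strain: dict[str, int] = {}
    for d in diffs:
        positions |= {p for p, _, _ in d.changed_positions}
        events += d.change_count
        per_strain[d.pair[1]] = d.change_count
    return {
        "changed_positions": sorted(positions),
        "n_changed_positions": len(positions),
        "n_change_events": events,
        "per_strain_changes": per_strain,
    }


def read_proteins(path) -> list[ProteinRecord]:
    from Bio import SeqIO

    records = [
        ProteinRecord(name=rec.id, residues=str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records
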