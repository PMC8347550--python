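"""Synthetic circular genomes with implanted ter/dif architecture.

The generator emulates the chromosomes the pipeline is aimed at:
4.6-5.5 Mbp circular genomes carrying ten primary terminator sites in two
opposed orientation groups flanking the terminus, the *dif* site between
the innermost opposing pair, secondary terK/L/Y/Z sites, controlled
per-position mismatches, and optional segment inversions reproducing the
rearranged architectures seen in nature (inner-area inversion; terC
flipped next to *dif*; a missing terC).  Background sequence is i.i.d.
with a configurable GC fraction -- no repeats, no indels, no
rearrangement history -- so every implant is recoverable exactly and the
manifest is complete ground truth.

Template geometry constants are fractions of genome length measured
clockwise from *oriC*; the defaults reproduce the canonical proportions:
the ten primary sites span 45% of the chromosome, the innermost four
about 8%, and the innermost fork-fusion area (terA-terC) 5.76%.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from forktrap.genome_io import CircularGenome, reverse_complement
from forktrap.queries import (
    TerQuery,
    DIF_SEQUENCE,
    reference_ter_queries,
    PRIMARY_SITE_NAMES,
    SECONDARY_SITE_NAMES,
)

TEMPLATE_NAMES = (
    "mg1655_like",
    "inner_inverted",
    "flipped_terC",
    "broken_trap",
    "shigella_missing_site",
)

#: Site geometry, clockwise fraction of genome length from oriC, with the
#: fork each site blocks under the plus-blocks-cw convention.
_BASE_GEOMETRY: dict[str, tuple[float, str]] = {
    # anticlockwise-blocking group (query on '-')
    "terH": (0.275, "ccw"),
    "terI": (0.320, "ccw"),
    "terE": (0.450, "ccw"),
    "terD": (0.462, "ccw"),
    "terA": (0.4712, "ccw"),
    # clockwise-blocking group (query on '+')
    "terC": (0.5288, "cw"),
    "terB": (0.542, "cw"),
    "terF": (0.600, "cw"),
    "terG": (0.640, "cw"),
    "terJ": (0.725, "cw"),
    # secondary sites: K/L share the direction of the C/B/F/G/J group;
    # Y/Z are origin-proximal and block forks coming from oriC.
    "terK": (0.560, "cw"),
    "terL": (0.580, "cw"),
    "terZ": (0.900, "ccw"),
    "terY": (0.930, "ccw"),
}

_DIF_FRACTION = 0.50
_ORIC_FRACTION = 0.85  # oriC away from coordinate 0 so fork walks wrap


@dataclass
class ImplantSpec:
    """One implanted motif: what was written where, with what mutations."""

    name: str
    sequence: str  # query sequence as written (mutations NOT applied)
    position: int  # 0-based leftmost coordinate of the implanted span
    strand: str  # '+' or '-'
    mutations: list[tuple[int, str]] = field(default_factory=list)  # (query pos 1-based, new base)

    @property
    def span(self) -> int:
        return len(self.sequence)

    def implanted_sequence(self) -> str:
        """The bases actually written on the forward strand."""
        seq = list(self.sequence)
        for pos, base in self.mutations:
            if seq[pos - 1] == base:
                raise ValueError(f"{self.name}: mutation at {pos} does not change the base")
            seq[pos - 1] = base
        s = "".join(seq)
        return s if self.strand == "+" else reverse_complement(s)


@dataclass
class ImplantManifest:
    """Ground truth for one synthetic genome."""

    genome_name: str
    template: str
    length: int
    oric_position: int
    gc_fraction: float
    seed: int
    implants: list[ImplantSpec]
    dif: ImplantSpec | None
    inversions: list[tuple[int, int]] = field(default_factory=list)
    expected: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ImplantManifest":
        d = json.loads(text)
        d["implants"] = [
            ImplantSpec(
                name=i["name"], sequence=i["sequence"], position=i["position"],
                strand=i["strand"], mutations=[tuple(m) for m in i["mutations"]],
            )
            for i in d["implants"]
        ]
        if d["dif"] is not None:
            i = d["dif"]
            d["dif"] = ImplantSpec(
                name=i["name"], sequence=i["sequence"], position=i["position"],
                strand=i["strand"], mutations=[tuple(m) for m in i["mutations"]],
            )
        d["inversions"] = [tuple(x) for x in d["inversions"]]
        return cls(**d)


def generate_background(
    length: int, gc_fraction: float, seed: int, name: str = "synthetic"
) -> CircularGenome:
    """i.i.d. background sequence with P(G)=P(C)=gc/2, deterministic in seed."""
    if not (0.0 < gc_fraction < 1.0):
        raise ValueError(f"gc_fraction must be in (0, 1), got {gc_fraction}")
    if length < 1000:
        raise ValueError("length must be >= 1000")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_fraction) / 2.0
    gc = gc_fraction / 2.0
    codes = rng.choice(4, size=length, p=[at, gc, gc, at])
    seq = np.array([ord(c) for c in "ACGT"], dtype=np.uint8)[codes].tobytes().decode("ascii")
    return CircularGenome(name=name, sequence=seq, oric_position=0)


def _spans_overlap_circular(p1: int, k1: int, p2: int, k2: int, L: int) -> bool:
    for s1 in (p1, p1 + L):
        if s1 < p2 + k2 and p2 < s1 + k1:
            return True
    if p1 < (p2 + L) + k2 and (p2 + L) < p1 + k1:
        return True
    return False


def implant(genome: CircularGenome, spec: ImplantSpec,
            existing: list[ImplantSpec] | None = None) -> CircularGenome:
    """Overwrite the span at ``spec.position`` with the implant (wrap-aware)."""
    L = genome.length
    if not (0 <= spec.position < L):
        raise ValueError(f"implant position {spec.position} outside [0, {L})")
    for other in existing or []:
        if _spans_overlap_circular(spec.position, spec.span, other.position, other.span, L):
            raise ValueError(f"implant {spec.name} overlaps {other.name}")
    payload = spec.implanted_sequence()
    buf = bytearray(genome.sequence, "ascii")
    for i, ch in enumerate(payload):
        buf[(spec.position + i) % L] = ord(ch)
    return CircularGenome(
        name=genome.name, sequence=buf.decode("ascii"), oric_position=genome.oric_position
    )


def apply_inversion(
    genome: CircularGenome, start: int, end: int, manifest: ImplantManifest
) -> CircularGenome:
    """Reverse-complement [start, end) in place and remap the manifest.

    Implants inside the segment move to ``start + end - position - span``
    with their strand flipped; an implant bisected by a boundary is an
    error.  Applying the same inversion twice restores the original.
    """
    L = genome.length
    if not (0 <= start < end <= L):
        raise ValueError(f"invalid inversion [{start}, {end}) on length {L}")

    specs = list(manifest.implants) + ([manifest.dif] if manifest.dif else [])
    for spec in specs:
        s, e = spec.position, spec.position + spec.span
        if e <= L:
            inside = start <= s and e <= end
            outside = e <= start or s >= end
        else:  # wraps the coordinate origin; inversion segments never wrap
            inside = False
            outside = (s >= end) and (e - L <= start)
        if not (inside or outside):
            raise ValueError(f"inversion [{start},{end}) bisects implant {spec.name}")

    seq = genome.sequence
    new_seq = seq[:start] + reverse_complement(seq[start:end]) + seq[end:]
    for spec in specs:
        if start <= spec.position and spec.position + spec.span <= end:
            spec.position = start + end - spec.position - spec.span
            spec.strand = "+" if spec.strand == "-" else "-"
    manifest.inversions.append((start, end))
    return CircularGenome(name=genome.name, sequence=new_seq, oric_position=genome.oric_position)


def _resolve_mutations(
    query_seq: str, muts: list[tuple[int, str | None]]
) -> list[tuple[int, str]]:
    """Replace ``None`` targets with the next base in the ACGT cycle."""
    bases = "ACGT"
    out: list[tuple[int, str]] = []
    for pos, base in muts:
        if base is None:
            orig = query_seq[pos - 1]
            base = bases[(bases.index(orig) + 1) % 4]
        out.append((pos, base))
    return out


def _default_mutation_plan(rng: np.random.Generator, queries: dict[str, TerQuery]) -> dict[str, list[tuple[int, str]]]:
    """0-2 variable-position substitutions per primary site, seeded."""
    plan: dict[str, list[tuple[int, str]]] = {}
    bases = "ACGT"
    for name in PRIMARY_SITE_NAMES:
        q = queries[name]
        k = int(rng.choice([0, 1, 2], p=[0.4, 0.4, 0.2]))
        positions = rng.choice(sorted(q.variable_positions), size=k, replace=False)
        muts = []
        for p in sorted(int(x) for x in positions):
            orig = q.sequence[p - 1]
            alt = bases[(bases.index(orig) + 1 + int(rng.integers(3))) % 4]
            if alt == orig:
                alt = bases[(bases.index(orig) + 1) % 4]
            muts.append((p, alt))
        if muts:
            plan[name] = muts
    return plan


def build_template(
    template: str,
    length: int = 4_641_000,
    seed: int = 0,
    gc_fraction: float = 0.5,
    mutation_plan: dict[str, list[tuple[int, str]]] | None = None,
    include_secondary: bool = True,
    name: str | None = None,
) -> tuple[CircularGenome, ImplantManifest]:
    """Generate a genome for one architecture template, with ground truth.

    Templates:

    - ``mg1655_like``: the canonical two-opposed-groups arrangement; forks
      fuse between terA and terC, *dif* in between on the (-) strand.
    - ``inner_inverted``: mg1655_like with the terA..terC segment
      (including *dif*) reverse-complemented; the trap stays intact.
    - ``flipped_terC``: terC sits origin-proximal of *dif* in reversed
      orientation, so forks are trapped between terC and terB and *dif*
      shares terC's strand.
    - ``broken_trap``: the clockwise-blocking group is absent; the
      clockwise fork is never arrested.
    - ``shigella_missing_site``: terC absent and terD carrying the
      critical G6>A change; the trap falls back to terB/terA.
    """
    if template not in TEMPLATE_NAMES:
        raise ValueError(f"unknown template {template!r}; choose from {TEMPLATE_NAMES}")
    if length < 100_000:
        raise ValueError("length must be >= 100000 to honour site spacing")

    rng = np.random.default_rng(seed)
    queries = {q.name: q for q in reference_ter_queries(include_secondary=True)}
    genome = generate_background(
        length, gc_fraction, seed=int(rng.integers(2**31 - 1)),
        name=name or f"{template}_L{length}_s{seed}",
    )
    oric = int(_ORIC_FRACTION * length) % length
    genome = CircularGenome(name=genome.name, sequence=genome.sequence, oric_position=oric)

    geometry = dict(_BASE_GEOMETRY)
    dif_fraction = _DIF_FRACTION
    dif_strand = "-"
    dropped: set[str] = set()
    forced_mutations: dict[str, list[tuple[int, str]]] = {}

    if template == "flipped_terC":
        geometry["terC"] = (0.490, "ccw")
        dif_fraction = 0.505
    elif template == "broken_trap":
        dropped = {"terC", "terB", "terF", "terG", "terJ", "terK", "terL"}
    elif template == "shigella_missing_site":
        dropped = {"terC"}
        forced_mutations["terD"] = [(6, "A")]

    if not include_secondary:
        dropped |= set(SECONDARY_SITE_NAMES)

    if mutation_plan is None:
        mutation_plan = _default_mutation_plan(rng, queries)
    mutation_plan = {**mutation_plan, **forced_mutations}

    implants: list[ImplantSpec] = []
    for site, (frac, blocks) in geometry.items():
        if site in dropped:
            continue
        pos = (oric + int(frac * length)) % length
        strand = "+" if blocks == "cw" else "-"
        spec = ImplantSpec(
            name=site,
            sequence=queries[site].sequence,
            position=pos,
            strand=strand,
            mutations=_resolve_mutations(queries[site].sequence, mutation_plan.get(site, [])),
        )
        genome = implant(genome, spec, existing=implants)
        implants.append(spec)

    dif_spec = ImplantSpec(
        name="dif",
        sequence=DIF_SEQUENCE,
        position=(oric + int(dif_fraction * length)) % length,
        strand=dif_strand,
        mutations=[],
    )
    genome = implant(genome, dif_spec, existing=implants)

    manifest = ImplantManifest(
        genome_name=genome.name,
        template=template,
        length=length,
        oric_position=oric,
        gc_fraction=gc_fraction,
        seed=seed,
        implants=implants,
        dif=dif_spec,
    )

    if template == "inner_inverted":
        by_name = {s.name: s for s in implants}
        seg_start = by_name["terA"].position - 500
        seg_end = by_name["terC"].position + by_name["terC"].span + 500
        genome = apply_inversion(genome, seg_start, seg_end, manifest)

    manifest.expected = _expected_architecture(template, manifest)
    return genome, manifest


_EXPECTED_BOUNDARIES = {
    # template -> (cw boundary site, ccw boundary site, trap intact,
    #              dif in trap, dif strand after generation)
    "mg1655_like": ("terC", "terA", True, True, "-"),
    "inner_inverted": ("terA", "terC", True, True, "+"),
    "flipped_terC": ("terB", "terC", True, True, "-"),
    "broken_trap": (None, "terA", False, None, "-"),
    "shigella_missing_site": ("terB", "terA", True, True, "-"),
}


def _expected_architecture(template: str, manifest: ImplantManifest) -> dict:
    """Ground-truth architecture, fixed per template at generation time."""
    cw_name, ccw_name, intact, dif_inside, dif_strand = _EXPECTED_BOUNDARIES[template]
    by_name = {s.name: s for s in manifest.implants}
    expected: dict = {
        "cw_boundary": cw_name,
        "ccw_boundary": ccw_name,
        "trap_intact": intact,
        "dif_in_trap": dif_inside,
        "dif_strand": dif_strand,
        "dif_position": manifest.dif.position if manifest.dif else None,
    }
    if intact:
        L = manifest.length
        a, b = by_name[cw_name].position, by_name[ccw_name].position
        fwd = (b - a) % L
        oric_in_fwd = (manifest.oric_position - a) % L < fwd
        expected["inner_span_bp"] = (a - b) % L if oric_in_fwd else fwd
    else:
        expected["inner_span_bp"] = None
    return expected


# --------------------------------------------------------------- study panel

#: Fixed per-position substitution plan for the five-genome panel:
#: 21 SNPs in total, 18 at variable positions, 11 in the innermost
#: terA-D sites; terE and terH carry none.  The three core changes are
#: the critical G6>A of terJ in the D-group genome and the position-15
#: A>T of terF in the D- and E-group genomes.  A ``None`` replacement
#: means "the next base in the ACGT cycle", resolved at build time.
PANEL_SNP_PLAN: dict[str, dict[str, list[tuple[int, str | None]]]] = {
    "panelB1": {
        "terA": [(2, None)],
        "terB": [(22, None)],
        "terC": [(1, None)],
        "terI": [(1, None)],
    },
    "panelB2": {
        "terA": [(4, None)],
        "terC": [(21, None)],
        "terD": [(3, None)],
        "terJ": [(21, None)],
    },
    "panelD": {
        "terA": [(1, None)],
        "terB": [(19, None)],
        "terD": [(23, None)],
        "terJ": [(6, "A")],
        "terF": [(15, "T")],
        "terG": [(5, None)],
        "terI": [(20, None)],
    },
    "panelE": {
        "terB": [(5, None)],
        "terC": [(20, None)],
        "terF": [(15, "T")],
        "terJ": [(7, None)],
        "terG": [(19, None)],
        "terI": [(22, None)],
    },
}

#: Genome lengths of the five panel chromosomes (reference first).
PANEL_LENGTHS = {
    "panelA_ref": 4_641_000,
    "panelB1": 4_798_000,
    "panelB2": 5_032_000,
    "panelD": 5_202_000,
    "panelE": 5_528_000,
}


def build_phylogroup_panel(
    seed: int, lengths: dict[str, int] | None = None
) -> dict[str, tuple[CircularGenome, ImplantManifest]]:
    """Five mg1655_like genomes emulating a cross-phylogroup comparison.

    The reference genome carries unmutated sites; the four others carry
    the fixed substitution plan (21 SNPs: 18 variable / 3 core, 11 in the
    innermost four sites).  Genome lengths default to the 4.6-5.5 Mbp
    range of real chromosomes; smaller lengths may be passed for quick
    runs without changing the SNP plan.
    """
    lengths = lengths or PANEL_LENGTHS
    rng = np.random.default_rng(seed)
    panel: dict[str, tuple[CircularGenome, ImplantManifest]] = {}
    for name in PANEL_LENGTHS:
        plan = PANEL_SNP_PLAN.get(name, {})
        genome, manifest = build_template(
            "mg1655_like",
            length=lengths[name],
            seed=int(rng.integers(2**31 - 1)),
            mutation_plan=plan,
            name=name,
        )
        panel[name] = (genome, manifest)
    return panel


# ----------------------------------------------------------------- Tus panel

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: Substitution plan for the Tus panel: seven distinct changed positions
#: across the four non-reference strains, each strain carrying one to
#: three changes; position 136 is the conservative Thr->Ser.
TUS_SNP_PLAN: dict[str, list[tuple[int, str]]] = {
    "tusB1": [(47, None)],
    "tusB2": [(99, None), (136, "S")],
    "tusD": [(15, None), (201, None), (258, None)],
    "tusE": [(47, None), (300, None)],
}

TUS_LENGTH = 309


def build_tus_panel(seed: int) -> dict[str, str]:
    """A synthetic 309-residue reference Tus plus four variant sequences.

    The reference is a seeded random amino-acid sequence (a synthetic
    stand-in, not the natural protein) with Thr fixed at position 136;
    variants differ at the planned positions only.
    """
    rng = np.random.default_rng(seed)
    ref = [_AA20[int(i)] for i in rng.integers(len(_AA20), size=TUS_LENGTH)]
    ref[136 - 1] = "T"
    panel = {"tusA_ref": "".join(ref)}
    for strain, changes in TUS_SNP_PLAN.items():
        seq = list(ref)
        for pos, new in changes:
            if new is None:
                orig = seq[pos - 1]
                new = _AA20[(_AA20.index(orig) + 1) % len(_AA20)]
            assert new != seq[pos - 1]
            seq[pos - 1] = new
        panel[strain] = "".join(seq)
    return panel


def rotate_genome(genome: CircularGenome, r: int) -> CircularGenome:
    """Rotate coordinates so old position r becomes new position 0."""
    L = genome.length
    r %= L
    return CircularGenome(
        name=genome.name,
        sequence=genome.sequence[r:] + genome.sequence[:r],
        oric_position=(genome.oric_position - r) % L,
    )


def mirror_genome(genome: CircularGenome) -> CircularGenome:
    """Reverse-complement the whole circle (cw and ccw swap roles)."""
    L = genome.length
    return CircularGenome(
        name=genome.name,
        sequence=reverse_complement(genome.sequence),
        oric_position=(L - genome.oric_position) % L,
    )
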