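"""Seeded synthetic fixtures: toy references, motif trees and queries.

Everything here is deterministic under a seed and serializes to the same
FASTA/TSV dialects the real pipeline reads, so every module is testable
without downloads.  The generators emulate the *structure* of mtDNA data
(sparse diagnostic motifs on a rooted tree, private mutations, point
heteroplasmies, homopolymer length variants) without attempting realistic
mutation-rate spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .motifs import Motif, MotifDB
from .notation import (
    IUPAC,
    RCRS_LENGTH,
    Haplotype,
    ReadingRange,
    RefSequence,
    Variant,
    make_haplotype,
)

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}

#: minimal IUPAC code covering a base set
_CODE_OF = {v: k for k, v in IUPAC.items()}


def code_for(bases) -> str:
    return _CODE_OF[frozenset(bases)]


# ---------------------------------------------------------------------------
# Synthetic rCRS stand-in
# ---------------------------------------------------------------------------

# Bases of the real reference that the published worked examples constrain
# (C-stretches around 309 and 16189, the AC repeat at 515-524, and the
# individual positions appearing in the example motifs and transcripts).
_PINNED = {
    41: "C", 42: "T", 43: "C",
    61: "C", 62: "A", 63: "G", 64: "C", 65: "T", 66: "A", 67: "T",
    72: "T", 73: "A",
    145: "G", 146: "T", 147: "A", 152: "T", 153: "A", 195: "T",
    235: "A", 263: "A",
    301: "A", 302: "A", 310: "T", 316: "G", 317: "T",
    454: "A", 455: "T", 460: "T",
    513: "G", 514: "C", 525: "C", 526: "C",
    3338: "T", 5460: "G", 9843: "A", 12561: "G", 12613: "G",
    13500: "T", 15499: "T",
    16092: "T", 16110: "G", 16111: "C", 16112: "C", 16172: "T", 16176: "C",
    16181: "A", 16182: "A", 16183: "A", 16189: "T", 16194: "A",
    16216: "A", 16217: "T", 16222: "A", 16223: "C", 16246: "A", 16247: "A",
    16248: "C", 16261: "C", 16278: "C", 16290: "C", 16295: "C",
    16304: "T", 16311: "T", 16318: "A", 16319: "G", 16362: "T",
    16519: "T",
}
for _p in range(303, 310):
    _PINNED[_p] = "C"          # poly-C tract 303-309
for _p in range(311, 316):
    _PINNED[_p] = "C"          # poly-C tract 311-315
for _p in range(456, 460):
    _PINNED[_p] = "C"
for _i, _p in enumerate(range(515, 525)):
    _PINNED[_p] = "AC"[_i % 2]  # AC repeat 515-524
for _p in range(16184, 16189):
    _PINNED[_p] = "C"          # poly-C tract 16184-16193, T at 16189
for _p in range(16190, 16194):
    _PINNED[_p] = "C"


def _filler(n: int, rng: np.random.Generator) -> list[str]:
    """Random bases with no homopolymer longer than three."""
    out: list[str] = []
    for _ in range(n):
        choices = _BASES
        if len(out) >= 3 and out[-1] == out[-2] == out[-3]:
            choices = choices.replace(out[-1], "")
        out.append(choices[rng.integers(len(choices))])
    return out


def synthetic_rcrs() -> RefSequence:
    """Synthetic 16,569 bp stand-in for the rCRS.

    The real reference sequence is not redistributed here; this synthetic
    surrogate pins only the bases that the published control-region
    examples constrain (poly-C tracts, the AC repeat, and the positions
    named in example motifs and transcripts) and fills the remainder with
    fixed-seed random bases free of long homopolymers.
    """
    rng = np.random.default_rng(16569)
    seq = _filler(RCRS_LENGTH, rng)
    for pos, base in _PINNED.items():
        seq[pos - 1] = base
    return RefSequence("rCRS-synthetic", "".join(seq))


#: the control region, wrapping across the circular origin
CONTROL_REGION = ReadingRange(16024, 576)


# ---------------------------------------------------------------------------
# Published worked-example inputs (control-region sequences and motifs)
# ---------------------------------------------------------------------------

WORKED_EXAMPLES = {
    # hypothetical motif/query pair exercising every application step
    "theoretical": {
        "range": "16024-576",
        "motif": "42.1A 64del 65del 73G 309.1C",
        "query": "42A 65C 303del",
    },
    # Navajo control-region sequence vs the A2+(64)+16189 motif
    "navajo": {
        "range": "16024-576",
        "motif": ("16111T 16182M 16183M 16189C 16192Y 16223T 16290T 16319A "
                  "16362C 16519Y 64Y 73G 146C 153G 235G 263G 315.1c"),
        "query": ("16111T 16189C 16192.1T 16223T 16290T 16319A 16362C 73G "
                  "146C 153G 235G 263G 309.1C 315.1C"),
    },
    # East Asian control-region sequence vs the B4a1a1 motif
    "b4a1a1": {
        "range": "16024-576",
        "motif": ("16182M 16183M 16189C 16217C 16247R 16261T 16519Y 73G "
                  "146C 263G 315.1c"),
        "query": ("16182C 16183C 16189C 16217C 16247G 16261T 16519C 73G "
                  "146C 263G 308T 310d 523d 524d"),
    },
    # mitogenome whose most parsimonious alignment (456T) differs from the
    # phylogenetic one (455.1T 459del) relative to the I1a1 motif fragment
    "i1a1": {
        "range": "16024-576",
        "motif": "455.1T",
        "query": "456T",
    },
}


def worked_example(name: str, ref: RefSequence | None = None):
    """Return ``(query, motif_haplotype, range)`` for a named example."""
    from .notation import parse_haplotype

    ex = WORKED_EXAMPLES[name]
    rng = ReadingRange.parse(ex["range"])
    length = ref.length if ref else RCRS_LENGTH
    query = parse_haplotype(ex["query"], rng, name, length)
    motif = parse_haplotype(ex["motif"], rng, name + "-motif", length)
    return query, motif, rng


# ---------------------------------------------------------------------------
# Toy fixture generators
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a synthetic study fixture.

    ``motif_separation`` is the number of new diagnostic substitutions on
    every tree edge; recovery of planted queries is guaranteed when it
    exceeds twice the number of planted privates.  Rates are expected
    counts per query.
    """

    seed: int = 0
    ref_length: int = 1000
    n_haplogroups: int = 12
    tree_depth: int = 3
    motif_separation: int = 3
    private_rate: float = 1.0
    heteroplasmy_rate: float = 0.0
    length_variant_rate: float = 0.0

    def __post_init__(self):
        if self.ref_length < 100:
            raise ValueError("ref_length must be at least 100")
        if self.motif_separation < 1:
            raise ValueError("motif_separation must be positive")

    @property
    def homopolymer(self) -> tuple[int, int]:
        """1-based inclusive span of the planted C-stretch."""
        start = self.ref_length // 2
        return (start, start + 7)

    @property
    def lv_regions(self) -> tuple[tuple[int, int], ...]:
        hs, he = self.homopolymer
        return ((hs - 2, he + 2),)


def make_reference(spec: FixtureSpec) -> RefSequence:
    """Deterministic circular toy reference with one C-homopolymer stretch."""
    rng = np.random.default_rng(spec.seed)
    seq = _filler(spec.ref_length, rng)
    hs, he = spec.homopolymer
    for p in range(hs, he + 1):
        seq[p - 1] = "C"
    seq[hs - 2] = "A"
    seq[he % spec.ref_length] = "T"  # break the run 3' of the stretch
    return RefSequence(f"toy-ref-{spec.seed}", "".join(seq), circular=True)


def _position_pool(spec: FixtureSpec, rng: np.random.Generator) -> list[int]:
    hs, he = spec.homopolymer
    blocked = set(range(hs - 3, he + 4))
    pool = [p for p in range(1, spec.ref_length + 1) if p not in blocked]
    rng.shuffle(pool)
    return pool


def _take_positions(pool: list[int], used: set[int], n: int) -> list[int]:
    out = []
    while len(out) < n:
        if not pool:
            raise ValueError("toy reference too short for requested motif tree")
        p = pool.pop()
        if p in used or p - 1 in used or p + 1 in used:
            continue
        used.add(p)
        out.append(p)
    return out


def make_motif_tree(spec: FixtureSpec, ref: RefSequence) -> MotifDB:
    """Rooted toy haplogroup tree over ``ref``.

    Every child motif extends its parent by ``motif_separation`` new
    transition-style substitutions; the tree includes one starred subclade
    and one motif with an ambiguity-widened diagnostic position.
    """
    rng = np.random.default_rng(spec.seed + 1)
    full = ReadingRange(1, ref.length)
    pool = _position_pool(spec, rng)
    used: set[int] = set()

    def new_variants(n: int) -> list[Variant]:
        return [
            Variant("sub", p, 0, _TRANSITION[ref.base(p)])
            for p in _take_positions(pool, used, n)
        ]

    motifs = [Motif("MT", None, make_haplotype("MT", full, [], ref.length))]
    frontier = [motifs[0]]
    labels = iter("ABCDEFGHJKLMNPQRSTUVWXYZ")
    while len(motifs) < spec.n_haplogroups and frontier:
        parent = frontier.pop(0)
        n_children = 2 if len(motifs) + 2 <= spec.n_haplogroups else 1
        for _ in range(n_children):
            if len(motifs) >= spec.n_haplogroups:
                break
            if parent.haplogroup == "MT":
                name = next(labels)
            else:
                kids = sum(m.parent == parent.haplogroup for m in motifs)
                name = f"{parent.haplogroup}{kids + 1}"
            variants = list(parent.haplotype.variants) + new_variants(
                spec.motif_separation)
            child = Motif(name, parent.haplogroup,
                          make_haplotype(name, full, variants, ref.length))
            motifs.append(child)
            frontier.append(child)

    # one starred (unnamed) subclade under the deepest motif
    base = motifs[-1]
    star_vars = list(base.haplotype.variants) + new_variants(
        max(3, spec.motif_separation))
    star_name = base.haplogroup + "*"
    motifs.append(Motif(star_name, base.haplogroup,
                        make_haplotype(star_name, full, star_vars, ref.length)))

    # widen one diagnostic position of the first non-root motif to an
    # ambiguity code covering both the reference and the derived state
    target = motifs[1]
    v = target.haplotype.variants[0]
    widened = Variant("sub", v.position, 0,
                      code_for(IUPAC[v.observed] | {ref.base(v.position)}))
    repl = [widened if w.coord == v.coord else w
            for w in target.haplotype.variants]
    motifs[1] = Motif(target.haplogroup, target.parent,
                      make_haplotype(target.haplogroup, full, repl, ref.length))

    return MotifDB(motifs)


@dataclass(frozen=True)
class GroundTruth:
    haplogroup: str
    planted: tuple[Variant, ...] = field(default_factory=tuple)


def sample_query(
    motif: Motif,
    spec: FixtureSpec,
    ref: RefSequence,
    rng: np.random.Generator,
    sample_id: str | None = None,
    n_private: int | None = None,
) -> tuple[Haplotype, GroundTruth]:
    """Simulate one query from a motif: planted essential privates plus
    optional heteroplasmies and homopolymer length variants."""
    taken = {v.position for v in motif.haplotype.variants}
    hs, he = spec.homopolymer

    def fresh_position() -> int:
        while True:
            p = int(rng.integers(1, ref.length + 1))
            if p in taken or hs - 3 <= p <= he + 3:
                continue
            taken.add(p)
            return p

    planted: list[Variant] = []
    n_priv = n_private if n_private is not None else rng.poisson(spec.private_rate)
    for _ in range(n_priv):
        p = fresh_position()
        planted.append(Variant("sub", p, 0, _TRANSITION[ref.base(p)]))
    if rng.random() < spec.heteroplasmy_rate:
        p = fresh_position()
        b = ref.base(p)
        planted.append(Variant("sub", p, 0, code_for({b, _TRANSITION[b]})))
    if rng.random() < spec.length_variant_rate:
        planted.append(Variant("ins", he, 1, "C"))

    variants = list(motif.haplotype.variants) + planted
    sid = sample_id or f"{motif.haplogroup}-sim"
    h = make_haplotype(sid, motif.haplotype.range, variants, ref.length)
    return h, GroundTruth(motif.haplogroup, tuple(planted))


def write_reference_fasta(ref: RefSequence, path) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    SeqIO.write([SeqRecord(Seq(ref.seq), id=ref.name, description="")],
                str(path), "fasta")


def read_reference_fasta(path) -> RefSequence:
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"))
    return RefSequence(rec.id, str(rec.seq))
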