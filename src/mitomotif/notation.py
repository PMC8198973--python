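"""Reference-relative variant notation on a circular mtDNA reference.

Human mtDNA haplotypes are conventionally reported as differences to the
revised Cambridge Reference Sequence (rCRS): ``73G`` is a substitution,
``309.1C`` an insertion after position 309, ``524del`` (or ``524d``) a
deletion.  Lowercase symbols (``315.1c``) mark *optional* states that may be
present or absent, and IUPAC ambiguity codes (``16093Y``) encode point
heteroplasmies or motif widenings.  This module provides the data types for
references, reading ranges, variants and haplotypes, plus parsing,
serialization, expansion to plain symbol strings, condensation to
sub-ranges, and the essential / heteroplasmy / length-variant
classification of private mutations.

Positions are 1-based and inclusive throughout; reading ranges may wrap
around the circular origin (the control region is 16024-576).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

RCRS_LENGTH = 16569

#: IUPAC nucleotide codes mapped to the set of bases they cover.
IUPAC = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}

#: mtDNA stretches where indels are conventionally treated as length
#: variants rather than phylogenetically informative mutations (the poly-C
#: tracts around 16189 and 309/315, the AC repeat at 515-524, and the
#: shorter homopolymers at 960, 5899 and the 9-bp repeat region).
DEFAULT_LENGTH_VARIANT_REGIONS = (
    (16180, 16195), (302, 316), (513, 526), (955, 966),
    (5895, 5900), (8270, 8289),
)

GAP = "-"


class NotationError(ValueError):
    """Malformed token or inconsistent variant list."""


class RangeError(NotationError):
    """Position or range outside the reference / enclosing range."""


@dataclass(frozen=True)
class RefSequence:
    """A circular (by default) reference sequence with 1-based positions."""

    name: str
    seq: str
    circular: bool = True

    def __post_init__(self):
        bad = set(self.seq.upper()) - set("ACGTN")
        if bad:
            raise NotationError(f"non-ACGTN symbols in reference: {sorted(bad)}")
        if len(self.seq) < 1:
            raise NotationError("empty reference")
        object.__setattr__(self, "seq", self.seq.upper())

    @property
    def length(self) -> int:
        return len(self.seq)

    def base(self, pos: int) -> str:
        if not 1 <= pos <= self.length:
            if not self.circular:
                raise RangeError(f"position {pos} outside reference of length {self.length}")
            pos = (pos - 1) % self.length + 1
        return self.seq[pos - 1]


@dataclass(frozen=True, order=True)
class ReadingRange:
    """1-based inclusive range; start > end wraps around the circular origin."""

    start: int
    end: int

    def validate(self, length: int) -> None:
        for p in (self.start, self.end):
            if not 1 <= p <= length:
                raise RangeError(f"range endpoint {p} outside [1, {length}]")

    def length(self, ref_length: int) -> int:
        return (self.end - self.start) % ref_length + 1

    def index(self, pos: int, ref_length: int) -> int:
        """0-based offset of ``pos`` along the range (may exceed the range)."""
        return (pos - self.start) % ref_length

    def contains(self, pos: int, ref_length: int) -> bool:
        return self.index(pos, ref_length) < self.length(ref_length)

    def contains_range(self, sub: "ReadingRange", ref_length: int) -> bool:
        n = self.length(ref_length)
        sublen = sub.length(ref_length)
        i = self.index(sub.start, ref_length)
        if i >= n or sublen > n:
            return False
        if i + sublen <= ref_length:
            return i + sublen <= n
        # the sub-range's index run wraps modulo the reference length,
        # which stays inside only a full-circle parent
        return n == ref_length

    def positions(self, ref_length: int):
        p = self.start
        for _ in range(self.length(ref_length)):
            yield p
            p = p % ref_length + 1

    def __str__(self) -> str:
        return f"{self.start}-{self.end}"

    @classmethod
    def parse(cls, text: str) -> "ReadingRange":
        m = re.fullmatch(r"(\d+)\s*-\s*(\d+)", text.strip())
        if not m:
            raise NotationError(f"malformed range {text!r}")
        return cls(int(m.group(1)), int(m.group(2)))


@dataclass(frozen=True)
class Variant:
    """One rCRS-relative difference.

    ``kind`` is ``"sub"``, ``"ins"`` or ``"del"``; insertions carry a
    positive ``insertion_index`` (``309.1C`` has anchor 309, index 1);
    deletions observe the gap symbol.  ``optional`` records lowercase
    notation (symbol may also be absent at no cost).
    """

    kind: str
    position: int
    insertion_index: int = 0
    observed: str = GAP
    optional: bool = False

    def __post_init__(self):
        if self.kind not in ("sub", "ins", "del"):
            raise NotationError(f"bad variant kind {self.kind!r}")
        if (self.insertion_index > 0) != (self.kind == "ins"):
            raise NotationError("insertion_index > 0 iff kind is 'ins'")
        if self.kind == "del":
            if self.observed != GAP:
                raise NotationError("deletion must observe the gap symbol")
        elif self.observed not in IUPAC:
            raise NotationError(f"observed symbol {self.observed!r} is not IUPAC")
        if self.optional and self.observed == "D":
            # lowercase "d" is the deletion shorthand; an optional D symbol
            # would be unparseable
            raise NotationError("optional flag on symbol D is ambiguous with "
                                "the 'd' deletion shorthand")

    @property
    def coord(self) -> tuple[int, int]:
        return (self.position, self.insertion_index)

    @property
    def is_indel(self) -> bool:
        return self.kind in ("ins", "del")


_VARIANT_RE = re.compile(
    r"(?P<pos>\d+)(?:\.(?P<idx>\d+))?(?P<tail>del|d|[A-Za-z])"
)


def parse_variant_token(token: str, ref_length: int = RCRS_LENGTH) -> Variant:
    """Parse one variant token such as ``73G``, ``309.1C``, ``315.1c``, ``524d``."""
    m = _VARIANT_RE.fullmatch(token.strip())
    if not m:
        raise NotationError(f"malformed variant token {token!r}")
    pos = int(m.group("pos"))
    if not 1 <= pos <= ref_length:
        raise RangeError(f"position {pos} of token {token!r} outside [1, {ref_length}]")
    idx = int(m.group("idx")) if m.group("idx") else 0
    tail = m.group("tail")
    if tail in ("del", "d"):
        if idx:
            _inserted_deletion(pos, idx)
        return Variant("del", pos, 0, GAP)
    sym = tail.upper()
    if sym not in IUPAC:
        raise NotationError(f"symbol {tail!r} in token {token!r} is not IUPAC")
    optional = tail.islower()
    if idx:
        return Variant("ins", pos, idx, sym, optional)
    return Variant("sub", pos, 0, sym, optional)


def _inserted_deletion(pos: int, idx: int) -> Variant:
    # "8289.5d"-style tokens delete a previously inserted symbol; they are
    # representable only as edit ops, not as rCRS-relative variants.
    raise NotationError(
        f"deletion of inserted coordinate {pos}.{idx} is an edit operation, "
        "not an rCRS-relative variant"
    )


def serialize_variant(v: Variant) -> str:
    """Inverse of :func:`parse_variant_token`; ``d`` normalizes to ``del``."""
    pos = f"{v.position}.{v.insertion_index}" if v.insertion_index else str(v.position)
    if v.kind == "del":
        return f"{pos}del"
    sym = v.observed.lower() if v.optional else v.observed
    return f"{pos}{sym}"


def variant_sort_key(v: Variant, rng: ReadingRange, ref_length: int):
    return (rng.index(v.position, ref_length), v.insertion_index)


@dataclass(frozen=True)
class Haplotype:
    """A reading range plus an ordered variant list (an rCRS-relative alignment)."""

    sample_id: str
    range: ReadingRange
    variants: tuple[Variant, ...] = field(default_factory=tuple)

    def tokens(self) -> list[str]:
        return [serialize_variant(v) for v in self.variants]

    def __str__(self) -> str:
        return " ".join(self.tokens())


def make_haplotype(
    sample_id: str,
    rng: ReadingRange,
    variants,
    ref_length: int = RCRS_LENGTH,
) -> Haplotype:
    """Build a haplotype, sorting variants in range order and validating them."""
    rng.validate(ref_length)
    vs = sorted(variants, key=lambda v: variant_sort_key(v, rng, ref_length))
    seen: set[tuple[int, int]] = set()
    for v in vs:
        if not rng.contains(v.position, ref_length):
            raise RangeError(
                f"variant {serialize_variant(v)} outside reading range {rng}"
            )
        if v.coord in seen:
            raise NotationError(f"duplicate variant coordinate {v.position}"
                                + (f".{v.insertion_index}" if v.insertion_index else ""))
        seen.add(v.coord)
    return Haplotype(sample_id, rng, tuple(vs))


def parse_haplotype(
    line: str,
    rng: ReadingRange,
    sample_id: str = "",
    ref_length: int = RCRS_LENGTH,
) -> Haplotype:
    """Parse a whitespace-separated variant list into a :class:`Haplotype`."""
    variants = [parse_variant_token(t, ref_length) for t in line.split()]
    return make_haplotype(sample_id, rng, variants, ref_length)


def expand_coords(h: Haplotype, ref: RefSequence):
    """Expand a haplotype to ``[(position, insertion_index, symbol, optional)]``.

    Substitutions replace the reference base, deletions drop it, insertions
    follow their anchor; ambiguity codes are kept verbatim and optional
    symbols are rendered in their present state.
    """
    by_pos: dict[int, Variant] = {}
    ins: dict[int, list[Variant]] = {}
    for v in h.variants:
        if v.kind == "ins":
            ins.setdefault(v.position, []).append(v)
        else:
            by_pos[v.position] = v
    out = []
    for p in h.range.positions(ref.length):
        v = by_pos.get(p)
        if v is None:
            out.append((p, 0, ref.base(p), False))
        elif v.kind == "sub":
            out.append((p, 0, v.observed, v.optional))
        # deletions emit nothing
        for iv in sorted(ins.get(p, ()), key=lambda x: x.insertion_index):
            out.append((p, iv.insertion_index, iv.observed, iv.optional))
    return out


def expand_haplotype(h: Haplotype, ref: RefSequence) -> str:
    return "".join(sym for _, _, sym, _ in expand_coords(h, ref))


def condense_haplotype(h: Haplotype, sub: ReadingRange, ref_length: int = RCRS_LENGTH) -> Haplotype:
    """Restrict the variant list to ``sub`` (which must lie inside ``h.range``)."""
    if not h.range.contains_range(sub, ref_length):
        raise RangeError(f"range {sub} not contained in {h.range}")
    kept = [v for v in h.variants if sub.contains(v.position, ref_length)]
    return make_haplotype(h.sample_id, sub, kept, ref_length)


def classify_variant(
    v: Variant,
    length_variant_regions=DEFAULT_LENGTH_VARIANT_REGIONS,
    ref_length: int = RCRS_LENGTH,
) -> str:
    """Classify a private mutation as essential, heteroplasmy or length variant.

    A point heteroplasmy is any variant observing an IUPAC-ambiguous symbol;
    a length variant is an indel anchored inside one of the configured
    length-variable stretches; everything else is essential.
    """
    if v.observed != GAP and len(IUPAC[v.observed]) > 1:
        return "heteroplasmy"
    if v.is_indel:
        for s, e in length_variant_regions:
            if ReadingRange(s, e).contains(v.position, ref_length):
                return "length_variant"
    return "essential"


def in_length_variant_region(
    pos: int,
    regions=DEFAULT_LENGTH_VARIANT_REGIONS,
    ref_length: int = RCRS_LENGTH,
) -> bool:
    return any(ReadingRange(s, e).contains(pos, ref_length) for s, e in regions)


def read_query_table(path, ref_length: int = RCRS_LENGTH) -> list[Haplotype]:
    """Read an EMPOP-style query TSV: sample_id, range, space-separated variants."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"sample_id", "range", "variants"}
    if not required.issubset(df.columns):
        raise NotationError(f"query table must have columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        rng = ReadingRange.parse(row["range"])
        out.append(parse_haplotype(row["variants"], rng, row["sample_id"], ref_length))
    return out


def write_query_table(haplotypes, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "sample_id": [h.sample_id for h in haplotypes],
            "range": [str(h.range) for h in haplotypes],
            "variants": [str(h) for h in haplotypes],
        }
    ).to_csv(path, sep="\t", index=False)
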