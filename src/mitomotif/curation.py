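"""Automatable parts of the motif-revision procedure: mitogenome vetting,
motif widening, and detection of unnamed subclades.

Vetting excludes mitogenomes that are too short (more than 30 bp below the
standard 16,569 bp length) or carry more than nine IUPAC-ambiguous symbols.
Widening replaces a motif symbol by the minimal IUPAC code covering an
alternative base observed in a sufficient fraction of the haplogroup's
members.  Subclade detection finds maximal sets of at least three shared
essential extra variants carried by at least two members, allowing nested
sub-subclades, and proposes starred names for them.
"""

from __future__ import annotations

from dataclasses import dataclass

from .motifs import Motif
from .notation import (
    DEFAULT_LENGTH_VARIANT_REGIONS,
    IUPAC,
    Haplotype,
    NotationError,
    RefSequence,
    Variant,
    classify_variant,
    make_haplotype,
    serialize_variant,
)

STANDARD_MITOGENOME_LENGTH = 16569
MIN_VETTED_LENGTH = STANDARD_MITOGENOME_LENGTH - 30
MAX_AMBIGUOUS = 9

_CODE_OF = {v: k for k, v in IUPAC.items()}


@dataclass(frozen=True)
class VettingReport:
    sample_id: str
    length: int
    ambiguous_count: int
    passed: bool
    reasons: tuple[str, ...] = ()


def vet_mitogenome(seq: str, sample_id: str) -> VettingReport:
    """Check one mitogenome against the length and ambiguity rules.

    Both rules are evaluated even if the first fails; a non-IUPAC symbol
    raises a validation error.
    """
    seq = seq.upper()
    bad = set(seq) - set(IUPAC)
    if bad:
        raise NotationError(
            f"mitogenome {sample_id!r} carries non-IUPAC symbols {sorted(bad)}")
    ambiguous = sum(len(IUPAC[s]) > 1 for s in seq)
    reasons = []
    if len(seq) < MIN_VETTED_LENGTH:
        reasons.append(f"length {len(seq)} < {MIN_VETTED_LENGTH}")
    if ambiguous > MAX_AMBIGUOUS:
        reasons.append(f"{ambiguous} ambiguous symbols > {MAX_AMBIGUOUS}")
    return VettingReport(sample_id, len(seq), ambiguous,
                         not reasons, tuple(reasons))


def vet_batch(records) -> list[VettingReport]:
    """Vet ``(sample_id, sequence)`` pairs; deterministic and order-independent."""
    return [vet_mitogenome(seq, sid) for sid, seq in records]


def write_vetting_table(reports, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in reports],
            "length": [r.length for r in reports],
            "ambiguous": [r.ambiguous_count for r in reports],
            "passed": [r.passed for r in reports],
            "reasons": ["; ".join(r.reasons) for r in reports],
        }
    ).to_csv(path, sep="\t", index=False)


def _symbol_at(h: Haplotype, pos: int, ref: RefSequence) -> str:
    for v in h.variants:
        if v.kind == "sub" and v.position == pos:
            return v.observed
    return ref.base(pos)


def widen_motif(
    motif: Motif,
    members,
    ref: RefSequence,
    min_freq: float = 0.25,
    min_members: int = 2,
) -> Motif:
    """Widen motif positions to IUPAC codes covering frequent member states.

    For every position where an alternative base occurs in at least
    ``min_freq`` of the members (and at least ``min_members`` of them), the
    motif symbol is replaced by the minimal IUPAC code covering both the
    motif state and the alternative.
    """
    members = list(members)
    if not members:
        return motif
    positions = {v.position for m in members for v in m.variants if v.kind == "sub"}
    positions |= {v.position for v in motif.haplotype.variants if v.kind == "sub"}
    new_by_pos: dict[int, str] = {}
    for pos in positions:
        expected = _symbol_at(motif.haplotype, pos, ref)
        counts: dict[str, int] = {}
        for m in members:
            s = _symbol_at(m, pos, ref)
            if s != expected and s in "ACGT":
                counts[s] = counts.get(s, 0) + 1
        covered = IUPAC[expected]
        for alt, n in counts.items():
            if n >= min_members and n / len(members) >= min_freq:
                covered = covered | {alt}
        if covered != IUPAC[expected]:
            new_by_pos[pos] = _CODE_OF[frozenset(covered)]
    if not new_by_pos:
        return motif
    h = motif.haplotype
    variants = [v for v in h.variants
                if not (v.kind == "sub" and v.position in new_by_pos)]
    variants += [Variant("sub", p, 0, code) for p, code in new_by_pos.items()]
    widened = make_haplotype(h.sample_id, h.range, variants, ref.length)
    return Motif(motif.haplogroup, motif.parent, widened)


@dataclass(frozen=True)
class SubcladeCandidate:
    base_haplogroup: str
    extra_variants: tuple[Variant, ...]
    carriers: tuple[str, ...]
    proposed_name: str

    def variant_tokens(self) -> list[str]:
        return [serialize_variant(v) for v in self.extra_variants]


def _essential_extras(member: Haplotype, motif: Motif, ref: RefSequence,
                      lv_regions) -> frozenset[Variant]:
    motif_set = set(motif.haplotype.variants)
    return frozenset(
        v for v in member.variants
        if v not in motif_set
        and classify_variant(v, lv_regions, ref.length) == "essential"
    )


def detect_subclades(
    base: Motif,
    members,
    ref: RefSequence,
    min_variants: int = 3,
    min_carriers: int = 2,
    lv_regions=DEFAULT_LENGTH_VARIANT_REGIONS,
    allow_single_carrier: bool = False,
) -> list[SubcladeCandidate]:
    """Detect apparent unnamed subclades among a haplogroup's members.

    Candidates are the closed intersections of the members' essential
    extra-variant sets with at least ``min_variants`` variants shared by at
    least ``min_carriers`` members (one, behind the explicit override
    flag).  Nested candidates (sub-subclades) are allowed; names follow the
    starred convention: ``*`` (or ``*1``, ``*2`` for several siblings),
    with letters and digits alternating at deeper nesting levels.
    """
    members = list(members)
    extras = {m.sample_id: _essential_extras(m, base, ref, lv_regions)
              for m in members}
    min_c = 1 if allow_single_carrier else min_carriers

    # closure of the member extra-sets under intersection
    closed: set[frozenset[Variant]] = set(extras.values())
    frontier = set(closed)
    while frontier:
        nxt = set()
        for s in frontier:
            for t in list(closed):
                inter = s & t
                if len(inter) >= min_variants and inter not in closed:
                    nxt.add(inter)
        closed |= nxt
        frontier = nxt

    candidates = []
    for s in closed:
        if len(s) < min_variants:
            continue
        carriers = tuple(sorted(
            sid for sid, e in extras.items() if s <= e))
        if len(carriers) < min_c:
            continue
        candidates.append((s, carriers))
    # keep only closed sets: s must equal the intersection of its carriers
    kept = []
    for s, carriers in candidates:
        inter = frozenset.intersection(*(extras[c] for c in carriers))
        if s == inter:
            kept.append((s, carriers))

    # nesting forest by strict inclusion of extra sets
    kept.sort(key=lambda sc: (len(sc[0]), sorted(serialize_variant(v) for v in sc[0])))
    parents: dict[int, int | None] = {}
    for i, (s, _) in enumerate(kept):
        parent = None
        for j, (t, _) in enumerate(kept):
            if t < s and (parent is None or len(kept[parent][0]) < len(t)):
                parent = j
        parents[i] = parent

    names: dict[int, str] = {}

    def name_for(i: int) -> str:
        if i in names:
            return names[i]
        parent = parents[i]
        siblings = [j for j in parents if parents[j] == parent]
        rank = siblings.index(i)
        if parent is None:
            prefix = base.haplogroup + "*"
            suffix = "" if len(siblings) == 1 else str(rank + 1)
        else:
            prefix = name_for(parent)
            suffix = "abcdefghij"[rank] if prefix[-1].isdigit() else str(rank + 1)
        names[i] = prefix + suffix
        return names[i]

    out = []
    for i, (s, carriers) in enumerate(kept):
        variants = tuple(sorted(
            s, key=lambda v: (v.position, v.insertion_index)))
        out.append(SubcladeCandidate(base.haplogroup, variants, carriers,
                                     name_for(i)))
    return out


def subclade_motif_rows(base: Motif, candidates) -> list[dict]:
    """Motif-table rows (haplogroup, parent, variants) for candidates."""
    rows = []
    for c in candidates:
        variants = sorted(
            list(base.haplotype.variants) + list(c.extra_variants),
            key=lambda v: (v.position, v.insertion_index))
        tokens = " ".join(serialize_variant(v) for v in variants)
        rows.append({"haplogroup": c.proposed_name,
                     "parent": base.haplogroup, "variants": tokens})
    return rows
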