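"""Haplogroup motif database: loading, tree maintenance, completion,
condensation and MRCA queries.

A *motif* is the variant list (relative to the rCRS) that defines a named
haplogroup; starred names (``HV*``, ``L2a5*1a``) denote yet unnamed
subclades and are ordinary children of their base haplogroup in the tree.
Condensing the database to a reading range restricts every motif to that
range and merges motifs whose restricted variant lists coincide, which for
the control region almost halves the database searched.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx

from .notation import (
    RCRS_LENGTH,
    Haplotype,
    NotationError,
    ReadingRange,
    Variant,
    condense_haplotype,
    make_haplotype,
    parse_haplotype,
)

logger = logging.getLogger(__name__)

ROOT_MARKER = ""  # empty parent column marks the root

FULL_RANGE = ReadingRange(1, RCRS_LENGTH)


class MotifDBError(ValueError):
    """Structural problem in a motif table (unknown parent, cycle, ...)."""


@dataclass(frozen=True)
class Motif:
    haplogroup: str
    parent: str | None
    haplotype: Haplotype

    @property
    def starred(self) -> bool:
        return "*" in self.haplogroup


class MotifDB:
    """Named motifs plus the rooted haplogroup tree they imply."""

    def __init__(self, motifs: list[Motif]):
        self.motifs: dict[str, Motif] = {}
        for m in motifs:
            if m.haplogroup in self.motifs:
                raise MotifDBError(f"duplicate haplogroup name {m.haplogroup!r}")
            self.motifs[m.haplogroup] = m
        self._validate_tree()
        self._depth: dict[str, int] = {}
        for name in self.motifs:
            self._depth[name] = self._compute_depth(name)

    def _validate_tree(self) -> None:
        roots = []
        graph = nx.DiGraph()
        missing = []
        for m in self.motifs.values():
            graph.add_node(m.haplogroup)
            if m.parent is None:
                roots.append(m.haplogroup)
            elif m.parent not in self.motifs:
                missing.append((m.haplogroup, m.parent))
            else:
                graph.add_edge(m.parent, m.haplogroup)
        if missing:
            raise MotifDBError(f"unknown parents: {missing}")
        if len(roots) != 1:
            raise MotifDBError(f"expected exactly one root, found {roots}")
        try:
            cycle = nx.find_cycle(graph)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            raise MotifDBError(f"cycle in haplogroup tree: {cycle}")
        self.root = roots[0]
        self.tree = graph

    def _compute_depth(self, name: str) -> int:
        d = 0
        while self.motifs[name].parent is not None:
            name = self.motifs[name].parent
            d += 1
        return d

    def __len__(self) -> int:
        return len(self.motifs)

    def __contains__(self, name: str) -> bool:
        return name in self.motifs

    def __getitem__(self, name: str) -> Motif:
        return self.motifs[name]

    def names(self) -> list[str]:
        return list(self.motifs)

    def ancestors(self, name: str) -> list[str]:
        """Ancestor-or-self chain from ``name`` up to the root."""
        chain = [name]
        while self.motifs[chain[-1]].parent is not None:
            chain.append(self.motifs[chain[-1]].parent)
        return chain

    def mrca(self, names) -> str:
        """Deepest node that is ancestor-or-equal of every given haplogroup."""
        names = list(names)
        if not names:
            raise ValueError("mrca of an empty haplogroup set")
        for n in names:
            if n not in self.motifs:
                raise KeyError(f"unknown haplogroup {n!r}")
        common = set(self.ancestors(names[0]))
        for n in names[1:]:
            common &= set(self.ancestors(n))
        return max(common, key=lambda n: self._depth[n])


def load_motif_table(path, ref_length: int = RCRS_LENGTH) -> MotifDB:
    """Load a motif TSV with columns haplogroup, parent, variants.

    An empty parent cell marks the root.  Logs the motif and
    starred-subclade counts after validation.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"haplogroup", "parent", "variants"}
    if not required.issubset(df.columns):
        raise MotifDBError(f"motif table must have columns {sorted(required)}")
    rng = ReadingRange(1, ref_length)
    motifs = []
    for _, row in df.iterrows():
        try:
            h = parse_haplotype(row["variants"], rng, row["haplogroup"], ref_length)
        except NotationError as exc:
            raise MotifDBError(f"motif {row['haplogroup']!r}: {exc}") from exc
        parent = row["parent"] or None
        motifs.append(Motif(row["haplogroup"], parent, h))
    db = MotifDB(motifs)
    n_star = sum(m.starred for m in db.motifs.values())
    logger.info("loaded %d motifs (%d starred subclades)", len(db), n_star)
    return db


def write_motif_table(db: MotifDB, path) -> None:
    import pandas as pd

    rows = [
        {"haplogroup": m.haplogroup, "parent": m.parent or ROOT_MARKER,
         "variants": str(m.haplotype)}
        for m in db.motifs.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _has_variant_at(h: Haplotype, pos: int, idx: int = 0) -> bool:
    return any(v.position == pos and v.insertion_index == idx for v in h.variants)


def complete_motif(m: Motif, ref_length: int = RCRS_LENGTH) -> Motif:
    """Apply the Phylotree-to-full-haplotype completion rules to a raw motif.

    Phylotree disregards the frequent T16519C transition, the 315.1C
    insertion and the A/C state at 16182/16183; a raw Phylotree motif is
    therefore supplemented with 16519Y (except B2m, which carries 16519A),
    the optional insertion 315.1c, and 16182M 16183M (B4a1a1a16, which
    carries 16182T, only gains 16183M).  Variants already present at a
    coordinate are never duplicated; the operation is idempotent.
    """
    h = m.haplotype
    extra = []
    if m.haplogroup != "B2m" and not _has_variant_at(h, 16519):
        extra.append(Variant("sub", 16519, 0, "Y"))
    if not _has_variant_at(h, 315, 1):
        extra.append(Variant("ins", 315, 1, "C", optional=True))
    if m.haplogroup != "B4a1a1a16" and not _has_variant_at(h, 16182):
        extra.append(Variant("sub", 16182, 0, "M"))
    if not _has_variant_at(h, 16183):
        extra.append(Variant("sub", 16183, 0, "M"))
    if not extra:
        return m
    completed = make_haplotype(
        h.sample_id, h.range, list(h.variants) + extra, ref_length
    )
    return Motif(m.haplogroup, m.parent, completed)


def complete_db(db: MotifDB, ref_length: int = RCRS_LENGTH) -> MotifDB:
    return MotifDB([complete_motif(m, ref_length) for m in db.motifs.values()])


@dataclass(frozen=True)
class CondensedDB:
    """Distinct range-restricted motifs, each mapped to the haplogroups sharing it."""

    range: ReadingRange
    entries: tuple[tuple[Haplotype, frozenset[str]], ...]

    def __len__(self) -> int:
        return len(self.entries)


def _variant_key(h: Haplotype):
    return tuple(
        (v.kind, v.position, v.insertion_index, v.observed, v.optional)
        for v in h.variants
    )


def condense_db(db: MotifDB, rng: ReadingRange, ref_length: int = RCRS_LENGTH) -> CondensedDB:
    """Condense every motif to ``rng`` and merge identical restricted variant lists."""
    groups: dict[tuple, tuple[Haplotype, set[str]]] = {}
    for m in db.motifs.values():
        c = condense_haplotype(m.haplotype, rng, ref_length)
        key = _variant_key(c)
        if key in groups:
            groups[key][1].add(m.haplogroup)
        else:
            groups[key] = (c, {m.haplogroup})
    entries = tuple(
        (h, frozenset(names)) for h, names in groups.values()
    )
    logger.info("condensed %d motifs to %d distinct entries in %s",
                len(db), len(entries), rng)
    return CondensedDB(rng, entries)


def write_condensed_table(cdb: CondensedDB, path) -> None:
    import pandas as pd

    rows = [
        {"haplogroups": ",".join(sorted(names)), "range": str(cdb.range),
         "variants": str(h)}
        for h, names in cdb.entries
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
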