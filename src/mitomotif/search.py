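"""Weighted nearest-motif haplogroup search and rank clustering.

Every condensed motif entry is costed against the query via the best
transcript: the cost is the summed weight of the query's *essential*
private mutations, while point heteroplasmies, length variants in the
configured stretches, and resolutions of motif ambiguity codes or optional
symbols contribute nothing.  Neighbors are clustered by a cost margin
(default 0.5) into rank-1 and rank-2 sets, and the most recent common
ancestor of each rank's haplogroups provides a single-haplogroup estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

from .motifs import CondensedDB, MotifDB, condense_db
from .notation import (
    DEFAULT_LENGTH_VARIANT_REGIONS,
    Haplotype,
    ReadingRange,
    RefSequence,
    Variant,
    classify_variant,
)
from .transcripts import (
    UNIT_WEIGHTS,
    Transcript,
    WeightTable,
    load_weight_table,
    transcribe,
)

__all__ = [
    "CostedNeighbor", "SearchResult", "WeightTable", "load_weight_table",
    "neighbor_cost", "search_neighbors", "rank_neighbors",
    "count_essential_privates",
]


@dataclass(frozen=True)
class CostedNeighbor:
    """One condensed motif entry with its cost against a query."""

    names: frozenset[str]
    cost: float
    privates: tuple[Variant, ...]
    entry: Haplotype
    transcript: Transcript

    def sort_key(self):
        return (self.cost, sorted(self.names)[0])


@dataclass(frozen=True)
class SearchResult:
    """Rank-1/rank-2 neighbor clusters with their MRCA estimates."""

    rank1: tuple[CostedNeighbor, ...]
    rank2: tuple[CostedNeighbor, ...]
    mrca_rank1: str | None
    mrca_rank2: str | None

    def rank1_names(self) -> set[str]:
        return set().union(*(nb.names for nb in self.rank1))

    def rank2_names(self) -> set[str]:
        return set().union(*(nb.names for nb in self.rank2)) if self.rank2 else set()


def neighbor_cost(
    query: Haplotype,
    entry: Haplotype,
    ref: RefSequence,
    rng: ReadingRange | None = None,
    weights: WeightTable = UNIT_WEIGHTS,
    lv_regions=DEFAULT_LENGTH_VARIANT_REGIONS,
    names: frozenset[str] | None = None,
) -> CostedNeighbor:
    """Cost and private-variant list of a query against one condensed motif."""
    res = transcribe(query, entry, ref, rng, weights, lv_regions)
    return CostedNeighbor(
        names or frozenset({entry.sample_id}),
        res.cost, res.privates, entry, res.transcript,
    )


def search_neighbors(
    query: Haplotype,
    db,
    ref: RefSequence,
    rng: ReadingRange | None = None,
    weights: WeightTable = UNIT_WEIGHTS,
    lv_regions=DEFAULT_LENGTH_VARIANT_REGIONS,
) -> list[CostedNeighbor]:
    """Cost every condensed entry against the query, cheapest first.

    ``db`` may be a :class:`MotifDB` (condensed to the query's range on the
    fly) or an already condensed :class:`CondensedDB` over that range.
    """
    rng = rng or query.range
    if isinstance(db, MotifDB):
        cdb = condense_db(db, rng, ref.length)
    elif isinstance(db, CondensedDB):
        if db.range != rng:
            raise ValueError(f"condensed DB range {db.range} != query range {rng}")
        cdb = db
    else:
        raise TypeError(f"expected MotifDB or CondensedDB, got {type(db)!r}")
    if not cdb.entries:
        raise ValueError("empty motif database")
    neighbors = [
        neighbor_cost(query, entry, ref, rng, weights, lv_regions, names)
        for entry, names in cdb.entries
    ]
    neighbors.sort(key=CostedNeighbor.sort_key)
    return neighbors


def rank_neighbors(
    neighbors,
    db: MotifDB | None = None,
    margin: float = 0.5,
) -> SearchResult:
    """Cluster costed neighbors into rank-1/rank-2 sets by a cost margin.

    Rank 1 holds all neighbors within ``margin`` of the global minimum
    cost; rank 2 all remaining neighbors within ``margin`` of the
    remainder's minimum.  MRCAs are computed over the union of haplogroup
    names of each rank when a motif tree is supplied.
    """
    neighbors = sorted(neighbors, key=CostedNeighbor.sort_key)
    if not neighbors:
        raise ValueError("rank_neighbors needs at least one neighbor")
    cmin = neighbors[0].cost
    rank1 = tuple(nb for nb in neighbors if nb.cost <= cmin + margin)
    rest = [nb for nb in neighbors if nb.cost > cmin + margin]
    if rest:
        c2 = rest[0].cost
        rank2 = tuple(nb for nb in rest if nb.cost <= c2 + margin)
    else:
        rank2 = ()

    def mrca_of(rank):
        if db is None or not rank:
            return None
        return db.mrca(set().union(*(nb.names for nb in rank)))

    return SearchResult(rank1, rank2, mrca_of(rank1), mrca_of(rank2))


def count_essential_privates(
    query: Haplotype,
    motif_h: Haplotype,
    ref: RefSequence,
    rng: ReadingRange | None = None,
    lv_regions=DEFAULT_LENGTH_VARIANT_REGIONS,
) -> int:
    """Number of the query's private mutations (vs one motif) that are
    neither point heteroplasmies nor length variants."""
    res = transcribe(query, motif_h, ref, rng, UNIT_WEIGHTS, lv_regions)
    return sum(
        classify_variant(v, lv_regions, ref.length) == "essential"
        for v in res.privates
    )
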