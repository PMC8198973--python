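"""Phylogenetic alignment: applying a best transcript to the nearest
haplogroup motif's rCRS-relative alignment.

Instead of aligning a query directly to the rCRS (which yields the most
parsimonious but often phylogenetically implausible variant list), the
query is aligned by *modifying the alignment of its nearest haplogroup
motif* with the best transcript.  The application algorithm runs in five
steps:

1. the transcript is normalized to single-symbol ops;
2. substitutions and deletions are applied to the alignment and removed
   from the op list;
3. insertions of the current alignment are moved into the op list;
4. op-list insertions are moved 5' over gaps caused by deletions;
5. same-position insertions are combined and either emitted as insertions
   or reconciled with the immediately following deletion block via an
   auxiliary unit-cost alignment (matches cancel deletions, mismatches
   turn deletions into substitutions, leftovers stay insertions or
   deletions).

Variants of the motif untouched by the transcript survive verbatim, which
is what makes the resulting alignment phylogenetic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .motifs import MotifDB, condense_db
from .notation import (
    DEFAULT_LENGTH_VARIANT_REGIONS,
    GAP,
    Haplotype,
    NotationError,
    ReadingRange,
    RefSequence,
    Variant,
    make_haplotype,
    serialize_variant,
    variant_sort_key,
)
from .search import SearchResult, rank_neighbors, search_neighbors
from .transcripts import (
    _INS,
    _MATCH,
    _SUB,
    UNIT_WEIGHTS,
    EditOp,
    Transcript,
    WeightTable,
    normalize_transcript,
    serialize_op,
    unit_align,
)


class TranscriptApplicationError(NotationError):
    """Transcript op inconsistent with the current alignment."""


def _next_pos(pos: int, length: int) -> int:
    return pos % length + 1


def _prev_pos(pos: int, length: int) -> int:
    return (pos - 2) % length + 1


class _State:
    """Mutable per-position alignment state during transcript application."""

    def __init__(self, alignment: Haplotype, ref: RefSequence):
        self.rng = alignment.range
        self.ref = ref
        self.subs: dict[int, Variant] = {}
        self.inss: dict[tuple[int, int], Variant] = {}
        self.deleted_sym: dict[int, str] = {}
        for v in alignment.variants:
            if v.kind == "ins":
                self.inss[v.coord] = v
            else:
                self.subs[v.position] = v
                if v.kind == "del":
                    self.deleted_sym[v.position] = ref.base(v.position)

    def is_deleted(self, pos: int) -> bool:
        v = self.subs.get(pos)
        return v is not None and v.kind == "del"

    def symbol_at(self, pos: int) -> str:
        v = self.subs.get(pos)
        if v is None:
            return self.ref.base(pos)
        if v.kind == "del":
            raise TranscriptApplicationError(f"position {pos} is deleted")
        return v.observed

    def variants(self) -> list[Variant]:
        vs = list(self.subs.values()) + list(self.inss.values())
        return sorted(vs, key=lambda v: variant_sort_key(v, self.rng, self.ref.length))

    def tokens(self) -> list[str]:
        return [serialize_variant(v) for v in self.variants()]


def _apply_sub_del(state: _State, op: EditOp) -> None:
    pos, k = op.position, op.insertion_index
    name = serialize_op(op)
    if k:  # op on an inserted coordinate
        iv = state.inss.get((pos, k))
        if iv is None:
            raise TranscriptApplicationError(
                f"op {name}: no insertion at coordinate {pos}.{k}")
        if op.from_symbol and iv.observed != op.from_symbol:
            raise TranscriptApplicationError(
                f"op {name}: inserted symbol is {iv.observed}, not {op.from_symbol}")
        if op.kind == "del":
            del state.inss[(pos, k)]
        else:
            state.inss[(pos, k)] = Variant("ins", pos, k, op.to_symbol)
        return
    if state.is_deleted(pos):
        raise TranscriptApplicationError(f"op {name}: position {pos} already deleted")
    cur = state.symbol_at(pos)
    if op.from_symbol and cur != op.from_symbol:
        raise TranscriptApplicationError(
            f"op {name}: alignment carries {cur} at {pos}, not {op.from_symbol}")
    if op.kind == "del":
        state.deleted_sym[pos] = cur
        state.subs[pos] = Variant("del", pos, 0, GAP)
    elif op.to_symbol == state.ref.base(pos):
        state.subs.pop(pos, None)
    else:
        state.subs[pos] = Variant("sub", pos, 0, op.to_symbol)


def apply_transcript(
    motif_alignment: Haplotype,
    t: Transcript,
    ref: RefSequence,
    trace: bool = False,
):
    """Rewrite a motif's rCRS-relative alignment by an edit transcript.

    Returns the final alignment, or ``(alignment, steps)`` with the
    intermediate alignment/op-list snapshots after steps 2-4 when
    ``trace`` is set.
    """
    rng = motif_alignment.range
    L = ref.length
    state = _State(motif_alignment, ref)
    steps: dict[str, dict] = {}

    # step 1: single-symbol ops in reading-range order
    ops = list(normalize_transcript(t, rng, L).ops)

    # step 2: apply substitutions and deletions
    pending = []
    for op in ops:
        if op.kind == "ins":
            pending.append(op)
        else:
            _apply_sub_del(state, op)
    if trace:
        steps["step2"] = {"alignment": state.tokens(),
                          "list": [serialize_op(o) for o in pending]}

    # step 3: move alignment insertions into the op list
    for (pos, k), iv in sorted(
        state.inss.items(), key=lambda c: (rng.index(c[0][0], L), c[0][1])
    ):
        pending.append(EditOp("ins", pos, k, to_symbol=iv.observed,
                              from_optional=iv.optional, from_alignment=True))
    state.inss.clear()
    pending.sort(key=lambda op: (
        rng.index(op.position, L),
        2 * op.insertion_index + (0 if op.from_alignment else 1),
    ))
    if trace:
        steps["step3"] = {"alignment": state.tokens(),
                          "list": [serialize_op(o) for o in pending]}

    # step 4: move insertions 5' over gaps caused by deletions.  An
    # insertion can end up 5' of every surviving position (range index -1);
    # step 5 then reconciles it with the leading deletion block.
    rlen = rng.length(L)
    positions = list(rng.positions(L))
    moved: list[tuple[int, EditOp]] = []
    for op in pending:
        pos = op.position
        idx = rng.index(pos, L)
        while idx >= 0 and state.is_deleted(pos):
            pos = _prev_pos(pos, L)
            idx -= 1
        if pos != op.position:
            op = replace(op, position=pos, insertion_index=0, from_alignment=True)
        moved.append((idx, op))
    moved = [t for _, t in sorted(enumerate(moved), key=lambda e: (e[1][0], e[0]))]
    if trace:
        steps["step4"] = {"alignment": state.tokens(),
                          "list": [serialize_op(o) for _, o in moved]}

    # step 5: combine same-position insertions and reconcile them with the
    # deletion block that immediately follows, if any
    groups: dict[int, list[EditOp]] = {}
    for idx, op in moved:
        groups.setdefault(idx, []).append(op)
    next_k: dict[int, int] = {}

    def emit_insertion(anchor_idx: int, sym: str, optional: bool = False) -> None:
        if anchor_idx < 0:
            raise TranscriptApplicationError(
                f"insertion of {sym} falls before the reading range start")
        anchor = positions[anchor_idx]
        k = next_k.get(anchor, 0) + 1
        next_k[anchor] = k
        state.inss[(anchor, k)] = Variant("ins", anchor, k, sym, optional)

    for idx in sorted(groups):
        ops_g = groups[idx]
        block: list[int] = []
        pidx = idx + 1
        while pidx < rlen and state.is_deleted(positions[pidx]):
            block.append(positions[pidx])
            pidx += 1
        if not block:
            for op in ops_g:
                emit_insertion(idx, op.to_symbol, op.from_optional)
            continue
        deleted = "".join(state.deleted_sym[b] for b in block)
        inserted = "".join(op.to_symbol for op in ops_g)
        anchor_idx = idx
        di = 0
        for tag, d_sym, i_sym in unit_align(deleted, inserted):
            if tag == _INS:
                emit_insertion(anchor_idx, i_sym)
                continue
            b = block[di]
            di += 1
            if tag == _MATCH:
                # insertion cancels the deletion; the position reverts to
                # its pre-deletion symbol
                if d_sym == ref.base(b):
                    state.subs.pop(b, None)
                else:
                    state.subs[b] = Variant("sub", b, 0, d_sym)
            elif tag == _SUB:
                state.subs[b] = Variant("sub", b, 0, i_sym)
            anchor_idx = rng.index(b, L)

    final = make_haplotype(motif_alignment.sample_id, rng, state.variants(), L)
    if trace:
        return final, steps
    return final


@dataclass(frozen=True)
class QueryAlignment:
    """Search result plus the phylogenetic alignment of one query."""

    search: SearchResult
    nearest: str
    transcript: Transcript
    alignment: Haplotype


def align_query(
    query: Haplotype,
    db: MotifDB,
    ref: RefSequence,
    rng: ReadingRange | None = None,
    weights: WeightTable = UNIT_WEIGHTS,
    margin: float = 0.5,
    lv_regions=DEFAULT_LENGTH_VARIANT_REGIONS,
) -> QueryAlignment:
    """Haplogroup search plus phylogenetic alignment for one query.

    The motif database is condensed to the query's reading range, neighbors
    are costed and rank-clustered, and the alignment of the nearest motif
    (alphabetically first haplogroup on ex-aequo cost) is modified by the
    best transcript.
    """
    if len(db) == 0:
        raise ValueError("empty motif database")
    rng = rng or query.range
    cdb = condense_db(db, rng, ref.length)
    neighbors = search_neighbors(query, cdb, ref, rng, weights, lv_regions)
    result = rank_neighbors(neighbors, db, margin)
    cmin = result.rank1[0].cost
    nearest_nb = min(
        (nb for nb in result.rank1 if nb.cost == cmin),
        key=lambda nb: sorted(nb.names)[0],
    )
    nearest = sorted(nearest_nb.names)[0]
    alignment = apply_transcript(
        replace(nearest_nb.entry, sample_id=query.sample_id),
        nearest_nb.transcript, ref,
    )
    return QueryAlignment(result, nearest, nearest_nb.transcript, alignment)
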