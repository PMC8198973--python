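"""Edit transcripts: parsing, normalization, and best-transcript computation.

A *transcript* is an ordered edit script converting the sequence implied by
a haplogroup motif into a query sequence.  Tokens follow the forensic
notation printed by EMPOP-style tools: ``G73A`` (substitution of the motif
symbol G at 73 by A), ``63insC`` (insertion after coordinate 63),
``42delT`` (deletion), ``308-309delCC`` (multi-symbol range deletion, kept
intact until normalization), ``Y64C`` / ``M16182A`` (zero-cost resolution
of a motif ambiguity code) and ``c315.1C`` (resolution of an optional
lowercase symbol to its present state).

The best transcript between a query and a motif is computed by weighted
global alignment of the two expanded symbol strings.  Because both strings
are expansions of sparse variant lists against the same reference, the
alignment is anchored: dynamic programming runs only in windows around
variant anchors and the flanks align as identity.  Resolutions of motif
ambiguity codes and optional symbols cost zero; point heteroplasmies and
indels inside configured length-variant stretches also contribute zero
cost; every other edit costs its weight.  Among equal-cost scripts the one
with fewest operations is chosen and indel blocks are placed 3'-most.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .notation import (
    DEFAULT_LENGTH_VARIANT_REGIONS,
    GAP,
    IUPAC,
    RCRS_LENGTH,
    Haplotype,
    NotationError,
    ReadingRange,
    RefSequence,
    Variant,
    classify_variant,
    condense_haplotype,
    expand_coords,
)

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")


# ---------------------------------------------------------------------------
# Weight tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeightTable:
    """Positive mutation weights with a default for unlisted mutations.

    Entries are keyed by mutation descriptor: an exact ``A13500G`` form
    (reference base, position, observed base; both orientations are tried),
    a bare position, or the classes ``transition``, ``transversion``,
    ``insertion`` and ``deletion``.
    """

    entries: dict = field(default_factory=dict)
    default: float = 1.0

    def __post_init__(self):
        if self.default <= 0 or any(w <= 0 for w in self.entries.values()):
            raise ValueError("all weights must be positive")

    def substitution(self, pos: int, ref_base: str | None, to: str) -> float:
        keys = []
        if ref_base is not None:
            keys += [f"{ref_base}{pos}{to}", f"{to}{pos}{ref_base}"]
        keys.append(str(pos))
        if ref_base in _PURINES and to in _PURINES or \
           ref_base in _PYRIMIDINES and to in _PYRIMIDINES:
            keys.append("transition")
        elif ref_base is not None and to in "ACGT":
            keys.append("transversion")
        for k in keys:
            if k in self.entries:
                return self.entries[k]
        return self.default

    def indel(self, kind: str, pos: int, sym: str) -> float:
        for k in (f"{pos}{kind}{sym}", str(pos),
                  "insertion" if kind == "ins" else "deletion"):
            if k in self.entries:
                return self.entries[k]
        return self.default


UNIT_WEIGHTS = WeightTable()


def load_weight_table(path) -> WeightTable:
    """Read a weight TSV with columns position, mutation, weight."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"mutation": str}, comment="#")
    entries = {str(row["mutation"]): float(row["weight"]) for _, row in df.iterrows()}
    return WeightTable(entries)


# ---------------------------------------------------------------------------
# Edit operations and transcripts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EditOp:
    """A single edit: substitute / insert / delete, plus pre-normalization
    multi-symbol range deletions (kind ``rdel``)."""

    kind: str
    position: int
    insertion_index: int = 0
    from_symbol: str | None = None
    to_symbol: str | None = None
    from_optional: bool = False
    end_position: int | None = None
    end_insertion_index: int = 0
    #: insertion ops created from alignment insertions during transcript
    #: application; they sit *at* their coordinate rather than after it.
    from_alignment: bool = False

    @property
    def coord(self) -> tuple[int, int]:
        return (self.position, self.insertion_index)


def _coord_str(pos: int, k: int) -> str:
    return f"{pos}.{k}" if k else str(pos)


def serialize_op(op: EditOp) -> str:
    c = _coord_str(op.position, op.insertion_index)
    if op.kind == "sub":
        f = op.from_symbol.lower() if op.from_optional else op.from_symbol
        return f"{f}{c}{op.to_symbol}"
    if op.kind == "ins":
        if op.from_alignment:
            c = str(op.position)
        return f"{c}ins{op.to_symbol}"
    if op.kind == "del":
        return f"{c}del{op.from_symbol or ''}"
    if op.kind == "rdel":
        e = _coord_str(op.end_position, op.end_insertion_index)
        return f"{c}-{e}del{op.from_symbol}"
    raise NotationError(f"bad op kind {op.kind!r}")


@dataclass(frozen=True)
class Transcript:
    ops: tuple[EditOp, ...] = ()

    def tokens(self) -> list[str]:
        return [serialize_op(op) for op in self.ops]

    def __str__(self) -> str:
        return " ".join(self.tokens())

    def __len__(self) -> int:
        return len(self.ops)


_SUB_RE = re.compile(r"(?P<f>[A-Za-z])(?P<pos>\d+)(?:\.(?P<idx>\d+))?(?P<t>[A-Z])")
_INS_RE = re.compile(r"(?P<pos>\d+)(?:\.(?P<idx>\d+))?ins(?P<sym>[A-Z]+)")
_DEL_RE = re.compile(
    r"(?P<pos>\d+)(?:\.(?P<idx>\d+))?"
    r"(?:[-–](?P<epos>\d+)(?:\.(?P<eidx>\d+))?)?"
    r"del(?P<sym>[A-Za-z]*)"
)


def parse_transcript_token(token: str) -> EditOp:
    token = token.strip()
    m = _INS_RE.fullmatch(token)
    if m:
        sym = m.group("sym")
        if any(s not in IUPAC for s in sym):
            raise NotationError(f"non-IUPAC inserted symbol in {token!r}")
        return EditOp("ins", int(m.group("pos")),
                      int(m.group("idx") or 0), to_symbol=sym)
    m = _DEL_RE.fullmatch(token)
    if m:
        pos, idx = int(m.group("pos")), int(m.group("idx") or 0)
        sym = m.group("sym").upper() or None
        if m.group("epos") is None:
            if sym is not None and len(sym) > 1:
                # multi-symbol deletion without an explicit end: spans
                # consecutive coordinates starting at (pos, idx)
                if idx:
                    return EditOp("rdel", pos, idx, from_symbol=sym,
                                  end_position=pos,
                                  end_insertion_index=idx + len(sym) - 1)
                return EditOp("rdel", pos, 0, from_symbol=sym,
                              end_position=pos + len(sym) - 1)
            return EditOp("del", pos, idx, from_symbol=sym)
        epos, eidx = int(m.group("epos")), int(m.group("eidx") or 0)
        span = _range_del_span(pos, idx, epos, eidx)
        if sym is None or len(sym) != span:
            raise NotationError(
                f"range deletion {token!r}: {len(sym or '')} symbols for span {span}")
        return EditOp("rdel", pos, idx, from_symbol=sym,
                      end_position=epos, end_insertion_index=eidx)
    m = _SUB_RE.fullmatch(token)
    if m:
        f, t = m.group("f"), m.group("t")
        if f.upper() not in IUPAC or t not in IUPAC:
            raise NotationError(f"non-IUPAC symbol in {token!r}")
        return EditOp("sub", int(m.group("pos")), int(m.group("idx") or 0),
                      from_symbol=f.upper(), to_symbol=t,
                      from_optional=f.islower())
    raise NotationError(f"malformed transcript token {token!r}")


def _range_del_span(pos: int, idx: int, epos: int, eidx: int) -> int:
    if epos == pos:
        if eidx < idx:
            raise NotationError("range deletion end before start")
        return eidx - idx + 1
    if idx != 0:
        raise NotationError(
            "range deletion starting at an inserted coordinate must end on "
            "the same position")
    if epos < pos:
        raise NotationError("range deletion end before start")
    return epos - pos + 1 + eidx


def parse_transcript(text: str) -> Transcript:
    return Transcript(tuple(parse_transcript_token(t) for t in text.split()))


def _range_del_coords(op: EditOp):
    if op.end_position == op.position:
        return [(op.position, k)
                for k in range(op.insertion_index, op.end_insertion_index + 1)]
    coords = [(p, 0) for p in range(op.position, op.end_position + 1)]
    coords += [(op.end_position, k) for k in range(1, op.end_insertion_index + 1)]
    return coords


def _op_sort_key(op: EditOp, rng: ReadingRange | None, ref_length: int):
    idx = rng.index(op.position, ref_length) if rng else op.position
    slot = 2 * op.insertion_index
    if op.kind == "ins" and not op.from_alignment:
        slot += 1
    return (idx, slot)


def normalize_transcript(
    t: Transcript,
    rng: ReadingRange | None = None,
    ref_length: int = RCRS_LENGTH,
) -> Transcript:
    """Split range deletions and multi-symbol insertions into single-symbol
    ops and sort them along the reading range.

    The ops are stored in ascending reading-range order (the printed form);
    application walks the list 3' to 5'.  Idempotent.
    """
    ops: list[EditOp] = []
    for op in t.ops:
        if op.kind == "rdel":
            for (p, k), s in zip(_range_del_coords(op), op.from_symbol):
                ops.append(EditOp("del", p, k, from_symbol=s))
        elif op.kind == "ins" and len(op.to_symbol) > 1:
            for s in op.to_symbol:
                ops.append(EditOp("ins", op.position, op.insertion_index,
                                  to_symbol=s, from_alignment=op.from_alignment))
        else:
            ops.append(op)
    ops.sort(key=lambda op: _op_sort_key(op, rng, ref_length))
    return Transcript(tuple(ops))


# ---------------------------------------------------------------------------
# Weighted anchored alignment
# ---------------------------------------------------------------------------

#: path element tags: '=' identity, 'sub' aligned with differing raw symbols,
#: 'del' motif symbol deleted, 'ins' query symbol inserted.
_MATCH, _SUB, _DEL, _INS = "=", "sub", "del", "ins"

_WINDOW_PAD = 8


@dataclass(frozen=True)
class TranscriptionResult:
    """Best transcript plus its cost and the query's private mutations."""

    transcript: Transcript
    cost: float
    privates: tuple[Variant, ...]
    n_ops: int


def _sym_set(raw: str, optional: bool, pos: int, k: int, ref: RefSequence):
    s = IUPAC[raw]
    if optional and k == 0:
        s = s | {ref.base(pos)}
    return s


class _Coster:
    """Shared (cost, op-count) bookkeeping for alignment and canonicalization."""

    def __init__(self, ref, weights, lv_regions):
        self.ref = ref
        self.weights = weights
        self.lv_regions = lv_regions
        self._lv = frozenset(
            p
            for s, e in lv_regions
            for p in ReadingRange(s, e).positions(ref.length)
        )

    def diag(self, m_item, q):
        pos, k, raw, optional = m_item
        if raw == q and not optional:
            return (0.0, 0)
        if _sym_set(raw, optional, pos, k, self.ref) & IUPAC[q]:
            return (0.0, 1)  # resolution of an ambiguity/optional symbol
        if len(IUPAC[q]) > 1:
            return (0.0, 1)  # point heteroplasmy in the query
        ref_base = self.ref.base(pos) if k == 0 else None
        return (self.weights.substitution(pos, ref_base, q), 1)

    def dele(self, m_item):
        pos, k, raw, optional = m_item
        if optional or pos in self._lv:
            return (0.0, 1)
        return (self.weights.indel("del", pos, raw), 1)

    def ins(self, anchor_pos, q):
        if anchor_pos in self._lv:
            return (0.0, 1)
        return (self.weights.indel("ins", anchor_pos, q), 1)


def _add(a, b):
    return (a[0] + b[0], a[1] + b[1])


def _align_window(ms, qs, prev_pos, coster, band_pad: int = 16,
                  allow_lead_ins: bool = True):
    """Tuple-cost global alignment of motif items vs query symbols.

    ``ms``: list of (pos, k, raw, optional); ``qs``: list of raw symbols.
    The DP is banded around the main diagonal (both strings are expansions
    of near-identical variant lists, so optimal paths stay close to it).
    When the window starts at the reading-range boundary, insertions before
    the first motif symbol are forbidden (an insertion before the range
    start has no rCRS-relative coordinate).  Returns a path of
    (tag, m_item, q_sym) with deterministic traceback (diagonal preferred,
    then deletion, then insertion, resolved from the 3' end); indel
    placement is canonicalized afterwards.
    """
    n, m = len(ms), len(qs)
    band = abs(n - m) + band_pad
    INF = (float("inf"), 0)

    del_costs = [coster.dele(it) for it in ms]
    anchor = [prev_pos] + [it[0] for it in ms]
    diag_cache: list[dict] = [{} for _ in range(n)]
    ins_cache: list[dict] = [{} for _ in range(n + 1)]

    def diag_cost(i, j):
        q = qs[j]
        c = diag_cache[i].get(q)
        if c is None:
            c = diag_cache[i][q] = coster.diag(ms[i], q)
        return c

    def ins_cost(i, j):
        if i == 0 and not allow_lead_ins:
            return INF
        q = qs[j]
        c = ins_cache[i].get(q)
        if c is None:
            c = ins_cache[i][q] = coster.ins(anchor[i], q)
        return c

    D = [dict() for _ in range(n + 1)]
    D[0][0] = (0.0, 0)
    for i in range(1, min(n, band) + 1):
        D[i][0] = _add(D[i - 1][0], del_costs[i - 1])
    for i in range(n + 1):
        row = D[i]
        lo = max(1, i - band)
        hi = min(m, i + band)
        for j in range(lo, hi + 1):
            best = INF
            left = row.get(j - 1)
            if left is not None:
                c = ins_cost(i, j - 1)
                best = (left[0] + c[0], left[1] + c[1])
            if i:
                up_row = D[i - 1]
                diag = up_row.get(j - 1)
                if diag is not None:
                    c = diag_cost(i - 1, j - 1)
                    cand = (diag[0] + c[0], diag[1] + c[1])
                    if cand < best:
                        best = cand
                up = up_row.get(j)
                if up is not None:
                    c = del_costs[i - 1]
                    cand = (up[0] + c[0], up[1] + c[1])
                    if cand < best:
                        best = cand
            row[j] = best

    path = []
    i, j = n, m
    while i or j:
        cur = D[i][j]
        if i and j and D[i - 1].get(j - 1) is not None and \
                _add(D[i - 1][j - 1], diag_cost(i - 1, j - 1)) == cur:
            i, j = i - 1, j - 1
            tag = _MATCH if diag_cost(i, j)[1] == 0 else _SUB
            path.append((tag, ms[i], qs[j]))
        elif i and D[i - 1].get(j) is not None and \
                _add(D[i - 1][j], del_costs[i - 1]) == cur:
            i -= 1
            path.append((_DEL, ms[i], None))
        else:
            j -= 1
            path.append((_INS, None, qs[j]))
    path.reverse()
    return path


def _block_total(coster, tag, items, anchor_pos, diag_pair):
    """(cost, ops) of an indel block plus the aligned element following it."""
    total = coster.diag(*diag_pair)
    for it in items:
        total = _add(total, coster.dele(it) if tag == _DEL
                     else coster.ins(anchor_pos, it))
    return total


def _canonicalize_path(path, coster, start_prev_pos=None):
    """Shift indel blocks 3'-most.

    A block of consecutive insertions or deletions followed by an aligned
    element rotates one step 3' whenever the rotated form has identical
    (cost, op-count): identity matches shift freely through homopolymers
    and repeats, and zero-cost resolutions (ambiguity codes, optional
    symbols) let a block pass when the resolved state is interchangeable.
    """
    path = list(path)
    changed = True
    while changed:
        changed = False
        i = 0
        last_m_pos = start_prev_pos
        while i < len(path):
            tag = path[i][0]
            if tag not in (_DEL, _INS):
                if path[i][1] is not None:
                    last_m_pos = path[i][1][0]
                i += 1
                continue
            j = i
            while j < len(path) and path[j][0] == tag:
                j += 1
            if j >= len(path) or path[j][0] not in (_MATCH, _SUB):
                i = j
                continue
            nxt_m, nxt_q = path[j][1], path[j][2]
            if tag == _DEL:
                old_items = [el[1] for el in path[i:j]]
                new_items = old_items[1:] + [nxt_m]
                old = _block_total(coster, _DEL, old_items, None, (nxt_m, nxt_q))
                new = _block_total(coster, _DEL, new_items, None,
                                   (old_items[0], nxt_q))
                # through an op-emitting element only op-preserving shifts
                # (identical deleted symbol) are canonical
                preserving = path[j][0] == _MATCH or \
                    old_items[0][2] == nxt_m[2]
                if old == new and preserving:
                    head_tag = _MATCH if coster.diag(old_items[0], nxt_q)[1] == 0 \
                        else _SUB
                    path[i] = (head_tag, old_items[0], nxt_q)
                    path[i + 1:j + 1] = [(_DEL, it, None) for it in new_items]
                    changed = True
                    continue
            else:
                old_syms = [el[2] for el in path[i:j]]
                new_syms = old_syms[1:] + [nxt_q]
                old = _block_total(coster, _INS, old_syms, last_m_pos,
                                   (nxt_m, nxt_q))
                new = _block_total(coster, _INS, new_syms, nxt_m[0],
                                   (nxt_m, old_syms[0]))
                # an op-changing rotation through a resolution is canonical
                # only when it carries the block into a homopolymer run
                # whose base matches the rotated block (the inserted symbol
                # stays the run base; it never jumps past the run's 3' end)
                if path[j][0] == _MATCH or old_syms[0] == nxt_q:
                    allowed = True
                else:
                    allowed = (j + 1 < len(path)
                               and path[j + 1][0] == _MATCH
                               and path[j + 1][1][2] == new_syms[0])
                if old == new and allowed:
                    head_tag = _MATCH if coster.diag(nxt_m, old_syms[0])[1] == 0 \
                        else _SUB
                    path[i] = (head_tag, nxt_m, old_syms[0])
                    path[i + 1:j + 1] = [(_INS, None, s) for s in new_syms]
                    changed = True
                    continue
            i = j
    return path


def _windows(anchor_idxs, rlen, pad=_WINDOW_PAD):
    if not anchor_idxs:
        return []
    spans = []
    for i in sorted(anchor_idxs):
        lo, hi = max(0, i - pad), min(rlen - 1, i + pad)
        if spans and lo <= spans[-1][1] + 1:
            spans[-1][1] = max(spans[-1][1], hi)
        else:
            spans.append([lo, hi])
    return [tuple(s) for s in spans]


def _aligned_path(query, motif_h, ref, rng, weights, lv_regions):
    """Global alignment path of the expanded motif against the expanded query."""
    coster = _Coster(ref, weights, lv_regions)
    rlen = rng.length(ref.length)
    anchor_idxs = {rng.index(v.position, ref.length)
                   for v in list(motif_h.variants) + list(query.variants)}
    spans = _windows(anchor_idxs, rlen)

    mexp = expand_coords(motif_h, ref)
    qexp = expand_coords(query, ref)

    def split(items):
        inside = {s: [] for s in range(len(spans))}
        outside = []
        for it in items:
            idx = rng.index(it[0], ref.length)
            for s, (lo, hi) in enumerate(spans):
                if lo <= idx <= hi:
                    inside[s].append(it)
                    break
            else:
                outside.append(it)
        return inside, outside

    m_in, m_out = split(mexp)
    q_in, _ = split(qexp)

    positions = list(rng.positions(ref.length))
    path = []
    cursor = 0
    for s, (lo, hi) in enumerate(spans):
        for idx in range(cursor, lo):
            p = positions[idx]
            b = ref.base(p)
            path.append((_MATCH, (p, 0, b, False), b))
        prev_pos = positions[lo - 1] if lo > 0 else positions[0] - 1 or ref.length
        qs = [it[2] for it in q_in[s]]
        path.extend(_align_window(m_in[s], qs, prev_pos, coster,
                                  allow_lead_ins=lo > 0))
        cursor = hi + 1
    for idx in range(cursor, rlen):
        p = positions[idx]
        b = ref.base(p)
        path.append((_MATCH, (p, 0, b, False), b))
    start_prev = positions[0] - 1 or ref.length
    return _canonicalize_path(path, coster, start_prev)


def _op_variant(op: EditOp) -> Variant:
    """Private-mutation view of a sub/ins op, for classification purposes."""
    if op.kind == "sub":
        if op.insertion_index:
            return Variant("ins", op.position, op.insertion_index, op.to_symbol)
        return Variant("sub", op.position, 0, op.to_symbol)
    return Variant("ins", op.position, op.insertion_index + 1, op.to_symbol)


def transcribe(
    query: Haplotype,
    motif_h: Haplotype,
    ref: RefSequence,
    rng: ReadingRange | None = None,
    weights: WeightTable = UNIT_WEIGHTS,
    lv_regions=DEFAULT_LENGTH_VARIANT_REGIONS,
) -> TranscriptionResult:
    """Best transcript from a motif to a query, with cost and privates.

    Both haplotypes are condensed to ``rng`` (default: the query's range)
    first.  The returned transcript keeps multi-symbol deletions merged in
    range form (``308-309delCC``); :func:`normalize_transcript` splits them.
    """
    rng = rng or query.range
    if query.range != rng:
        query = condense_haplotype(query, rng, ref.length)
    if motif_h.range != rng:
        motif_h = condense_haplotype(motif_h, rng, ref.length)

    path = _aligned_path(query, motif_h, ref, rng, weights, lv_regions)

    ops: list[EditOp] = []
    cost = 0.0
    privates: list[Variant] = []
    n_ops = 0
    last_m = None  # last motif item seen (anchor for insertions)
    i = 0
    while i < len(path):
        tag, m_item, q = path[i]
        if tag == _MATCH:
            last_m = m_item
            i += 1
            continue
        if tag == _SUB:
            pos, k, raw, optional = m_item
            op = EditOp("sub", pos, k, from_symbol=raw, to_symbol=q,
                        from_optional=optional)
            resolution = (optional or len(IUPAC[raw]) > 1) and \
                q in _sym_set(raw, optional, pos, k, ref)
            if not resolution:
                v = _op_variant(op)
                cls = classify_variant(v, lv_regions, ref.length)
                if cls == "essential":
                    ref_base = ref.base(pos) if k == 0 else None
                    cost += weights.substitution(pos, ref_base, q)
                privates.append(v)
            ops.append(op)
            n_ops += 1
            last_m = m_item
            i += 1
            continue
        if tag == _DEL:
            run = []
            while i < len(path) and path[i][0] == _DEL:
                run.append(path[i][1])
                i += 1
            for pos, k, raw, optional in run:
                if optional:
                    continue  # optional symbol absent: zero-cost resolution
                pv = Variant("del", pos, 0, GAP)
                if classify_variant(pv, lv_regions, ref.length) == "essential":
                    cost += weights.indel("del", pos, raw)
                privates.append(pv)
            merged = None
            if len(run) > 1:
                cand = EditOp(
                    "rdel", run[0][0], run[0][1],
                    from_symbol="".join(r[2] for r in run),
                    end_position=run[-1][0], end_insertion_index=run[-1][1])
                # merge only when the range form re-expands to exactly the
                # deleted coordinates (it cannot express a run that starts
                # at an inserted coordinate and crosses into the next
                # reference position, or skips interior insertions)
                if _range_del_coords(cand) == [(p, k) for p, k, _, _ in run]:
                    merged = cand
            if merged is not None:
                ops.append(merged)
            else:
                for pos, k, raw, optional in run:
                    ops.append(EditOp("del", pos, k, from_symbol=raw,
                                      from_optional=optional))
            n_ops += len(run)
            last_m = run[-1]
            continue
        # insertion
        anchor = last_m if last_m is not None else None
        apos, ak = (anchor[0], anchor[1]) if anchor else (rng.start - 1 or ref.length, 0)
        op = EditOp("ins", apos, ak, to_symbol=q)
        v = _op_variant(op)
        if classify_variant(v, lv_regions, ref.length) == "essential":
            cost += weights.indel("ins", apos, q)
        privates.append(v)
        ops.append(op)
        n_ops += 1
        i += 1

    return TranscriptionResult(Transcript(tuple(ops)), cost, tuple(privates), n_ops)


def best_transcript(
    query: Haplotype,
    motif_h: Haplotype,
    ref: RefSequence,
    rng: ReadingRange | None = None,
    weights: WeightTable = UNIT_WEIGHTS,
    lv_regions=DEFAULT_LENGTH_VARIANT_REGIONS,
) -> Transcript:
    return transcribe(query, motif_h, ref, rng, weights, lv_regions).transcript


def sequence_to_haplotype(
    seq: str,
    ref: RefSequence,
    rng: ReadingRange,
    sample_id: str = "",
    band: int = 64,
) -> Haplotype:
    """Most parsimonious rCRS-relative variant list for a raw sequence.

    Banded unit-cost global alignment of ``seq`` against the reference over
    ``rng``, with indels canonicalized 3'-most.  This is only the *input*
    representation of a FASTA query; the phylogenetic alignment is produced
    later by modifying the nearest motif.  The band is doubled and the
    alignment retried if the optimal path touches the band boundary.
    """
    from .notation import make_haplotype

    seq = seq.upper().replace("-", "")
    refs = "".join(ref.base(p) for p in rng.positions(ref.length))
    positions = list(rng.positions(ref.length))
    n, m = len(refs), len(seq)
    while True:
        path = _banded_unit_align(refs, seq, band)
        if path is not None:
            break
        band *= 2
        if band > max(n, m):
            raise NotationError("alignment band exhausted")
    path2 = []
    for tag, i, j in path:
        if tag in (_MATCH, _SUB, _DEL):
            item = (positions[i], 0, refs[i], False)
        else:
            item = None
        path2.append((tag, item, seq[j] if j is not None else None))
    coster = _Coster(ref, UNIT_WEIGHTS, ())
    path2 = _canonicalize_path(path2, coster, positions[0] - 1 or ref.length)
    variants = []
    last_pos = positions[0] - 1 or ref.length
    ins_k = 0
    for tag, item, q in path2:
        if tag == _MATCH:
            last_pos, ins_k = item[0], 0
        elif tag == _SUB:
            variants.append(Variant("sub", item[0], 0, q))
            last_pos, ins_k = item[0], 0
        elif tag == _DEL:
            variants.append(Variant("del", item[0], 0, GAP))
            last_pos, ins_k = item[0], 0
        else:
            ins_k += 1
            variants.append(Variant("ins", last_pos, ins_k, q))
    return make_haplotype(sample_id, rng, variants, ref.length)


def _banded_unit_align(a: str, b: str, band: int):
    """Unit-cost global alignment within a diagonal band; returns a list of
    ``(tag, a_index | None, b_index | None)`` or None if the band was hit."""
    n, m = len(a), len(b)
    if abs(n - m) > band:
        return None
    INF = float("inf")
    D = {(0, 0): 0.0}
    for i in range(n + 1):
        lo = max(0, i - band)
        hi = min(m, i + band)
        for j in range(lo, hi + 1):
            if i == 0 and j == 0:
                continue
            best = INF
            if i and j:
                best = D.get((i - 1, j - 1), INF) + (a[i - 1] != b[j - 1])
            if i:
                best = min(best, D.get((i - 1, j), INF) + 1.0)
            if j:
                best = min(best, D.get((i, j - 1), INF) + 1.0)
            D[(i, j)] = best
    path = []
    i, j = n, m
    hit_band = False
    while i or j:
        if abs(i - j) >= band and (i, j) != (n, m):
            hit_band = True
        cur = D[(i, j)]
        if i and j and D.get((i - 1, j - 1), INF) + (a[i - 1] != b[j - 1]) == cur:
            i, j = i - 1, j - 1
            path.append((_MATCH if a[i] == b[j] else _SUB, i, j))
        elif i and D.get((i - 1, j), INF) + 1.0 == cur:
            i -= 1
            path.append((_DEL, i, None))
        else:
            j -= 1
            path.append((_INS, None, j))
    if hit_band:
        return None
    path.reverse()
    return path


def unit_align(a: str, b: str):
    """Unit-cost global alignment path of two plain strings.

    Returns a list of ``(tag, a_sym | None, b_sym | None)`` with the same
    tags as the main aligner; used for the auxiliary insertion-vs-deletion
    alignment of the transcript application algorithm.
    """
    n, m = len(a), len(b)
    INF = (float("inf"), 0)
    D = [[INF] * (m + 1) for _ in range(n + 1)]
    D[0][0] = (0.0, 0)

    def step(c, match):
        return (c[0] + (0.0 if match else 1.0), c[1] + (0 if match else 1))

    def gap(c):
        return (c[0] + 1.0, c[1] + 1)

    for i in range(1, n + 1):
        D[i][0] = gap(D[i - 1][0])
    for i in range(n + 1):
        for j in range(1, m + 1):
            best = gap(D[i][j - 1])
            if i:
                cand = step(D[i - 1][j - 1], a[i - 1] == b[j - 1])
                if cand < best:
                    best = cand
                cand = gap(D[i - 1][j])
                if cand < best:
                    best = cand
            D[i][j] = best
    path = []
    i, j = n, m
    while i or j:
        if i and j and step(D[i - 1][j - 1], a[i - 1] == b[j - 1]) == D[i][j]:
            i, j = i - 1, j - 1
            path.append((_MATCH if a[i] == b[j] else _SUB, a[i], b[j]))
        elif i and gap(D[i - 1][j]) == D[i][j]:
            i -= 1
            path.append((_DEL, a[i], None))
        else:
            j -= 1
            path.append((_INS, None, b[j]))
    path.reverse()
    return path
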