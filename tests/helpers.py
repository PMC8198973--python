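"""Independent oracles and generators shared by the test modules."""

from __future__ import annotations

import numpy as np

from mitomotif.notation import (
    ReadingRange,
    RefSequence,
    Variant,
    make_haplotype,
)

BASES = "ACGT"
AMBIG = "RYSWKM"


def levenshtein(a: str, b: str) -> int:
    """Plain unit-cost edit distance (textbook DP, no shortcuts)."""
    n, m = len(a), len(b)
    D = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(n + 1):
        D[i][0] = i
    for j in range(m + 1):
        D[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            D[i][j] = min(
                D[i - 1][j - 1] + (a[i - 1] != b[j - 1]),
                D[i - 1][j] + 1,
                D[i][j - 1] + 1,
            )
    return D[n][m]


def levenshtein_no_lead_insertion(a: str, b: str) -> int:
    """Edit distance over scripts that never insert before the first
    reference symbol (insertions before a reading range start have no
    coordinate in rCRS-relative notation)."""
    INF = 10 ** 9
    n, m = len(a), len(b)
    D = [[INF] * (m + 1) for _ in range(n + 1)]
    D[0][0] = 0
    for i in range(1, n + 1):
        D[i][0] = i
    for i in range(n + 1):
        for j in range(1, m + 1):
            c = INF
            if i:
                c = min(c, D[i - 1][j - 1] + (a[i - 1] != b[j - 1]),
                        D[i - 1][j] + 1)
                c = min(c, D[i][j - 1] + 1)
            D[i][j] = min(D[i][j], c)
    return D[n][m]


def random_reference(rng: np.random.Generator, length: int, name: str = "toy") -> RefSequence:
    return RefSequence(name, "".join(BASES[i] for i in rng.integers(4, size=length)))


def random_haplotype(
    rng: np.random.Generator,
    rr: ReadingRange,
    ref_length: int,
    max_variants: int = 4,
    ambiguity: bool = False,
    sample_id: str = "h",
    avoid_start: bool = True,
):
    """Random variant list over a reading range (subs, dels, insertions)."""
    positions = list(rr.positions(ref_length))
    if avoid_start:
        positions = positions[1:]
    vs, used = [], set()
    for _ in range(int(rng.integers(0, max_variants + 1))):
        p = positions[int(rng.integers(len(positions)))]
        if p in used:
            continue
        used.add(p)
        r = rng.random()
        if r < 0.5:
            if ambiguity and rng.random() < 0.25:
                obs = AMBIG[int(rng.integers(len(AMBIG)))]
            else:
                obs = BASES[int(rng.integers(4))]
            vs.append(Variant("sub", p, 0, obs))
        elif r < 0.75:
            vs.append(Variant("del", p))
        else:
            vs.append(Variant("ins", p, 1, BASES[int(rng.integers(4))],
                              optional=bool(ambiguity and rng.random() < 0.2)))
    return make_haplotype(sample_id, rr, vs, ref_length)
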