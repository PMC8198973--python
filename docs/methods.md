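# Methods

## Coordinate model and notation

All positions are 1-based and inclusive on a circular reference (the rCRS
numbering, length 16,569 for human mtDNA).  A reading range `start-end`
may wrap the origin (`16024-576` is the control region); positions inside
a range are ordered by their offset from `start` modulo the reference
length.  A variant is a substitution (`73G`), an insertion with anchor and
index (`309.1C`), or a deletion (`524del`; `524d` is accepted on input and
normalized to `del` on output).  IUPAC ambiguity codes denote point
heteroplasmies in queries and widened positions in motifs; lowercase
symbols are *optional* — they match both their present and absent state at
no cost (`315.1c` means "C or gap").  One deliberate grammar restriction:
an optional `D` symbol is rejected because lowercase `d` is the deletion
shorthand.

Expansion renders a haplotype as a plain symbol string over its range,
with ambiguity codes kept verbatim and optional symbols in their present
state; resolution to concrete bases happens only in transcripts.
Condensation restricts a variant list to a sub-range (variants are kept
when their anchor position lies inside it) and, at database level, merges
motifs whose restricted lists coincide — the merge key includes
optionality flags, and the merged entry remembers every haplogroup name
it represents.

## Cost model of the neighbor search

The distance between a query and a condensed motif is the cost of the best
edit transcript converting the motif-implied sequence into the query
sequence:

* aligning symbols whose IUPAC sets intersect costs 0; if the motif symbol
  is ambiguous or optional this is a *resolution* and is emitted as a
  substitution-style op (`Y64C`, `M16182A`, `c315.1C`) but is **not** a
  private mutation;
* a substitution whose query symbol is ambiguous is a point heteroplasmy:
  cost 0, recorded as a non-essential private;
* indels anchored inside the configured length-variant stretches cost 0
  and are recorded as non-essential privates.  The default stretches are
  16180–16195, 302–316, 513–526, 955–966, 5895–5900 and 8270–8289 — the
  poly-C tracts around 16189 and 309/315, the AC repeat, and the shorter
  homopolymer/9-bp-repeat regions that forensic practice treats as length
  variants.  Only 309.1C-style length variation is fixed by convention;
  the exact region list is a configurable design choice of this package;
* every other edit costs its weight.  The default weight table is unit
  (all mutations weigh 1.0); a TSV of per-mutation weights (keys like
  `T13500C`, a bare position, or the classes `transition`/`transversion`/
  `insertion`/`deletion`, tried in that order and in both orientations for
  the exact form) can be supplied.  A small excerpt of published
  transition weights ships with the package for the documented tie cases;
  the complete ranking is consumed as a config file when available, never
  derived here.

`count_essential_privates` classifies each private by the same three-way
rule (heteroplasmy / length variant / essential) and counts the essential
ones.

## The alignment engine

Both strings being compared are expansions of sparse variant lists against
the same reference, so the global alignment is *anchored*: dynamic
programming runs only inside windows of ±8 positions around variant
anchors (overlapping windows merge); between windows both strings equal
the reference and align as identity.  Within a window the DP is banded
(band = length difference + 16) and minimizes the pair
(total weight, op count) lexicographically — the op count breaks
zero-cost ties in favour of fewer operations, which matters inside the
free length-variant stretches.  Traceback prefers diagonal, then
deletion, then insertion, resolved from the 3' end.

Ties in indel placement are then canonicalized on the full path: a block
of consecutive insertions or deletions rotates one step 3' whenever the
rotated form has identical cost and op count.  Rotation through identity
matches gives the usual 3'-most placement in homopolymers and repeats
(block-wise, so an `AC` deletion walks a dinucleotide repeat correctly);
rotation through a resolution op is additionally allowed only when it
carries the block into a run whose base matches the rotated block — the
inserted symbol stays the run base and never jumps past the run's 3' end.
This reproduces, e.g., `16191insC Y16192T` (insertion at the 3' end of the
C-run, heteroplasmy resolved to T) rather than the string-equivalent
`Y16192C 16192insT`.

Insertions *before* the first position of the reading range have no
rCRS-relative coordinate, so the DP forbids them in the window that starts
at the range boundary; the minimal *expressible* script is returned
instead.  Consecutive deletions serialize in range form
(`308-309delCC`, both hyphen and en dash are parsed) whenever the range
form re-expands to exactly the deleted coordinates; otherwise they stay
single ops.  Transcripts are stored and printed in ascending reading-range
order (the conventional printed form); applications that need 3'→5' order
walk the list backwards.

A separate banded unit-cost aligner (`sequence_to_haplotype`) converts raw
FASTA queries into most-parsimonious variant lists for input only; the
band doubles and retries if the optimal path touches its edge.

## Applying a transcript to a motif alignment

`apply_transcript` rewrites the nearest motif's alignment in five steps,
with every intermediate exposed for testing:

1. normalize the transcript to single-symbol ops;
2. apply substitutions and deletions to the alignment (a substitution to
   the reference base removes the variant; deletions remember the symbol
   they removed, including motif substitutions, so cancellation can
   restore them later).  Ops naming a symbol the alignment does not carry
   raise a consistency error naming the op;
3. move the alignment's insertion variants into the op list, ordered so
   that symbols inserted *after* coordinate `p` precede the motif's own
   `p.1`, which precedes ops anchored at `p.1`;
4. move list insertions 5' over deletion gaps; an insertion may legally
   end up before every surviving position (virtual range index −1) when
   the leading positions are all deleted;
5. combine same-anchor insertions and look at the deletion block
   immediately 3' of the anchor.  No block: the insertions become
   insertion variants.  Otherwise the inserted string is aligned to the
   deleted string by unit-cost global alignment: matches cancel deletions
   (restoring the pre-deletion state), mismatches turn deletions into
   substitutions, leftover inserted symbols become insertions anchored at
   the last consumed position, leftover deletions remain.

The master invariant, checked on randomized cases and every worked
example, is string conservation: the final alignment expands to exactly
the query sequence.  Motif variants untouched by the transcript survive
verbatim — the phylogenetic preference that keeps `455.1T 459del` instead
of the more parsimonious `456T`.

## Rank clustering and MRCA estimates

Neighbors are sorted by cost; rank 1 contains every neighbor within the
margin (default 0.5, inclusive) of the global minimum, rank 2 every
remaining neighbor within the margin of the *remainder's* minimum (the
remainder-minimum reading of the clustering rule; anchoring rank 2 at
`cmin + margin` instead is the other defensible reading).  The MRCA of
each rank's haplogroup-name union is reported as that rank's
single-haplogroup estimate; starred subclades are ordinary children of
their base haplogroup, so MRCAs fold them in naturally.  When several
rank-1 entries tie at minimal cost, all names are reported but the
alphabetically first haplogroup deterministically supplies the alignment.

## Curation operations

* **Vetting**: a mitogenome passes if its length is at least 16,539 bp
  (30 bp below the standard length) and it carries at most nine
  IUPAC-ambiguous symbols; both rules are always evaluated and reported.
* **Widening**: a motif position is replaced by the minimal IUPAC code
  covering an alternative base observed in ≥ `min_freq` of the
  haplogroup's members and ≥ 2 members.  `min_freq` defaults to 0.25 — the
  published procedure says only "frequent", so the threshold is an
  explicit, configurable choice.  Widening can only remove cost, never add
  it (checked as a property).
* **Subclade detection**: candidates are the closed intersections of the
  members' essential extra-variant sets with ≥ 3 variants shared by ≥ 2
  carriers (a single carrier only behind an explicit override, mirroring
  the two documented exceptions).  The closure is computed by pairwise
  intersection of member sets, which is exact but exponential in the
  worst case — intended for per-haplogroup member lists (tens of
  sequences), not whole databases.  Nested candidates are allowed; names
  follow the starred convention: a single top-level candidate is `base*`
  (several are `*1`, `*2`, …) and nesting alternates digits and letters
  (`*1`, `*1a`).

## Synthetic fixtures

The generators produce, deterministically under a seed: a circular toy
reference with a planted 8-bp C-homopolymer (its ±2 bp neighbourhood is
the fixture's length-variant region) and no accidental run longer than
three elsewhere; a rooted motif tree in which every child adds
`motif_separation` fresh transition-style substitutions (default 3),
including one starred subclade and one ambiguity-widened motif; and
queries built from a motif's expansion plus planted essential privates,
heteroplasmies (codes covering the reference base) and homopolymer
C-insertions at configured rates.  Defaults (600–1000 bp reference, ~10
haplogroups, separation 3) keep the property suites fast while leaving
recovery provably unambiguous: with one planted private and separation 3,
the source motif is the unique rank-1 neighbor at margin 0.5.

What the fixtures do **not** emulate: realistic mutation-rate spectra,
recurrent mutation, the size and depth of the real haplogroup tree
(thousands of motifs, names like `A2+(64)+16189`), population frequencies
behind motif widening, or sequencing artefacts beyond IUPAC calls.
Passing the synthetic suites therefore demonstrates the correctness of
the machinery (notation, search, clustering, alignment rewriting), not
classification accuracy on real population data.

The bundled `synthetic_rcrs()` reference is a stand-in, not the real
rCRS: it pins the bases that the published worked examples constrain (the
C-stretches at 303–315 and 16184–16193, the AC repeat at 515–524, the
455–459 region, and the individual positions named in example motifs,
transcripts and weight anecdotes) and fills everything else with
fixed-seed random bases free of long homopolymers.  Analyses of real data
should pass a real reference FASTA.

## Known limitations

* Unit or per-mutation weights only; no affine-gap or codon-aware scoring.
* An insertion before the reading-range start is inexpressible in
  rCRS-relative notation; the search returns the best expressible script,
  and transcript application raises a named error if an applied transcript
  still forces one.
* Anchored windows assume variants are sparse relative to the ±8 pad;
  pathological references with repeats longer than the pad could in
  principle detach the optimum from the anchors (the window pad and band
  are verified against a full DP oracle in the tests).
* The condensed-database search recomputes one banded alignment per entry
  and query (~0.1 s per control-region query against ~15 condensed toy
  motifs in pure Python); real-database scale would want memoized window
  decomposition or a compiled inner loop.
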