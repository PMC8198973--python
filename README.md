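# mitomotif

Alignment-immune haplogrouping and phylogenetic alignment of human
mitochondrial DNA (mtDNA) sequences.

## The problem

Human mtDNA haplotypes are reported as differences to the revised Cambridge
Reference Sequence (rCRS) — tokens like `73G`, `309.1C`, `524del` — and are
classified into *haplogroups*, the named clades of the mtDNA phylogeny.
Each haplogroup is defined by a *motif*: the variant list that separates it
from the rCRS.  Two problems make this harder than it sounds:

1. **Notation is not unique.**  The same molecule can be written as `456T`
   or as `455.1T 459del`; indels inside homopolymer tracts and repeats can
   be placed in many equivalent ways.  Tools that compare variant lists
   token-by-token therefore disagree across laboratories.
2. **The most parsimonious alignment is often phylogenetically wrong.**
   The minimal edit script from the rCRS hides mutations that are actually
   shared with the haplotype's clade.

`mitomotif` implements an alignment-immune approach used in forensic and
population genetics: queries are compared with motifs at the **sequence
level** (so the notation of the input does not matter), and the query's
final rCRS-relative alignment is obtained by **modifying the alignment of
its nearest haplogroup motif** with a minimal edit transcript — a
*phylogenetic alignment* that keeps the motif's variants verbatim wherever
the sequence allows.  It is aimed at forensic geneticists, population
geneticists and tool builders who need reproducible haplogroup estimates
and harmonized variant notation for control-region (CR, 16024–576) or
full-mitogenome data.

## The method

For a query with reading range *R* (weights *w*, clustering margin *m* =
0.5):

1. **Condense** every motif to *R* and merge identical restricted variant
   lists (for the CR this almost halves the database searched).
2. **Search**: for each condensed motif, compute the best edit transcript
   from the motif-implied sequence to the query sequence by weighted
   global alignment.  The cost is the summed weight of the query's
   *essential* private mutations; point heteroplasmies (IUPAC codes such
   as `16093Y`), length variants in the known unstable stretches (e.g. the
   309/16189 poly-C tracts), and resolutions of motif ambiguity codes or
   optional lowercase symbols (`315.1c` = C or gap) cost nothing.
3. **Cluster** neighbor costs by the margin into rank-1 and rank-2 sets and
   report the most recent common ancestor (MRCA) of each rank's
   haplogroups as single-haplogroup estimates.
4. **Align**: normalize the best transcript to single-symbol operations
   and apply it to the nearest motif's alignment in five steps
   (substitutions/deletions first, then the motif's insertions, then 5'
   moves over deletion gaps, then an auxiliary alignment that reconciles
   combined insertions with adjacent deletion blocks).  The result is the
   query's phylogenetic alignment relative to the rCRS, with indels placed
   3'-most.

The package also implements the automatable curation steps used to revise
a motif database against collections of sequenced mitogenomes: vetting
(length ≥ 16,539 bp, at most nine ambiguous symbols), widening motif
positions to IUPAC codes that cover frequent alternative bases, and
detection of unnamed subclades (≥ 3 shared essential extra variants in ≥ 2
carriers, starred names like `HV*`, `L2a5*1a`).

Because the true rCRS sequence is not redistributed here, the package
ships a clearly labelled synthetic stand-in
(`mitomotif.synthetic_rcrs()`) that pins only the bases the published
worked examples constrain; any real reference FASTA can be supplied
instead.

## Worked example

The hypothetical motif `42.1A 64del 65del 73G 309.1C` against the query
written (in 5' form) as `42A 65C 303del`:

```python
import mitomotif as mm

ref = mm.synthetic_rcrs()
cr = mm.ReadingRange(16024, 576)
motif = mm.parse_haplotype("42.1A 64del 65del 73G 309.1C", cr, "motif")
query = mm.parse_haplotype("42A 65C 303del", cr, "query")

res = mm.transcribe(query, motif, ref, cr)
print("best transcript :", res.transcript)
print("cost            :", res.cost)

final, steps = mm.apply_transcript(motif, res.transcript, ref, trace=True)
for step in ("step2", "step3", "step4"):
    print(f"{step}: alignment = {' '.join(steps[step]['alignment'])!r}"
          f"  list = {' '.join(steps[step]['list'])!r}")
print("phylogenetic alignment:", final)
```

prints

```
best transcript : 42delT 63insC 63insC G73A 309-309.1delCC
cost            : 4.0
step2: alignment = '42del 42.1A 64del 65del 309del'  list = '63insC 63insC'
step3: alignment = '42del 64del 65del 309del'        list = '42insA 63insC 63insC'
step4: alignment = '42del 64del 65del 309del'        list = '41insA 63insC 63insC'
phylogenetic alignment: 42A 65C 309del
```

The transcript deletes the motif's T at 42, re-inserts the two symbols the
motif had deleted at 64–65, reverts the motif's `73G`, and removes two C's
from the 303–309 C-stretch (3'-most, hence `309–309.1delCC`).  Applying it
step by step turns the motif's alignment into `42A 65C 309del` — the 3'
version of the query's own notation, at a search cost of 4 unit-weight
private mutations.  A batch interface is available from the shell:

```bash
mitomotif fixtures --seed 11 --out-dir demo      # synthetic toy study
mitomotif haplogroup demo/queries.tsv --motifs demo/motifs.tsv \
    --reference demo/reference.fasta --out demo/report.tsv
mitomotif condense --motifs demo/motifs.tsv --reference demo/reference.fasta \
    --range 1-333
```

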