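# Methods

This note documents the statistical definitions, the synthetic-data model,
and the design decisions behind `plastome-compare`.

## Quadripartite partitioning

The inverted repeat is defined as the **longest pair of disjoint intervals**
(i, j) on the circular genome with `seq[j] == revcomp(seq[i])` and length at
least `min_ir_len` (default 1000 bp). Matching is exact (0 mismatches) and
extension stops at the first mismatch: plastome IR copies are near-identical
in practice and are treated as duplicated copies of a single locus
throughout the package. Detection is seed-and-extend (31-mers of the genome
against its reverse complement, on doubled strings so origin-spanning
repeats are found), with ties between equal-length candidates broken by
leftmost start. The longer single-copy arc is LSC, the shorter SSC; genomes
whose arcs tie, or that lack a qualifying repeat, raise a
"no quadripartite structure" error (IR-lacking plastomes are out of scope).

The sequence is rotated to a **canonical orientation**: position 0 is the
first LSC base downstream of IRa (the *trnH* side), so the genome reads
LSC · IRb · SSC · IRa. The strand of the input is preserved. The partition
identity `LSC + SSC + 2·IR == genome length` is asserted on every partition
the package produces.

Junction profiling reports, for each of J_LB/J_SB/J_SA/J_LA, the gene whose
span covers the junction with the bp it contributes on each side (the two
sides always sum to the gene span), or otherwise the nearest flanking genes
and gaps. Genes named with an `_like` suffix are treated as incomplete IR
duplicates: they are reported with their within-IR lengths and excluded from
the gene census and start-codon scan.

In the census, "duplicated in the IR" means a gene name with at least two
occurrences whose parts lie entirely inside the IR intervals; such genes
count once. A gene annotated with *k* exon parts has *k* − 1 introns.

## Regions and divergence statistics

Regions are delimited on the genome with the **IRa copy removed**, so every
single-copy locus and one IR copy contribute exactly once:

* coding regions: exon-concatenated CDS per unique gene (sequences come from
  the full annotation, so a CDS running through J_SA keeps its IRa tail);
* introns: gaps between consecutive exon parts of the same gene, numbered
  5′→3′ (`rps16 intron`, `ycf3 intron1`, …). When another gene is nested
  inside an intron (*matK* inside the *trnK* intron), the flanking gaps
  become spacers (`trnK (UUU)-matK`, `matK-trnK (UUU)`) instead;
* spacers: gaps between consecutive exon parts of different features, named
  `upstream-downstream` in genome order on the plus strand.

Regions are matched across genomes by name; a region absent from any genome
is excluded with a warning. Overlapping annotations yielding non-positive
gaps are skipped with a notice. Each region is aligned across taxa (mafft
when available, otherwise the built-in progressive aligner) and summarised:

* **S**, substitutions: columns with no gap and ≥2 distinct bases;
* **I**, indel events: distinct maximal gap runs keyed by (start, end)
  column coordinates — a run shared by several taxa at identical coordinates
  counts once; runs at shifted coordinates count separately;
* **G**, total indel length: sum of distinct event lengths;
* **V**, variable positions: S + number of columns containing ≥1 gap;
* **P**, percent variability: `100·(S + I)/L`, rounded **half-up** to two
  decimals (aligned length L).

Columns containing any gap are excluded from substitution counting, so a
substitution adjacent to or inside a gap contributes only through the gap
term. These conventions are locked by a regression test that reproduces the
printed "Percent variability" and "Variable positions" of **all 128 rows**
of the bundled published divergence tables for the eleven *Schima*
plastomes, including the half-up rounding case 2.857 → 2.86 (where the
source's prose says 2.85, the tabulated 2.86 is taken as authoritative).
Whether the original computation counted a shifted shared indel as one event
or two is not documented there; the distinct-coordinates rule above is this
package's fixed convention.

The **hotspot screen** keeps regions with P strictly above the threshold
("exceeding" 2.0% by default), sorted by P descending with input (genome)
order breaking ties. The aligned-length filter (> 150 bp) is applied to the
**aligned** length, after alignment. Only regions passing it are tabulated.

Whole-genome identity is the mean over unordered taxon pairs of identical
gap-free columns divided by gap-free columns for that pair, ×100, one
decimal.

## cpSSR detection

Perfect tandem repeats only, units 1–6 bp, with minimum unit counts
{1: 10, 2: 6, 3: 4, 4: 4, 5: 3, 6: 3}. A run generated by a smaller unit is
reported only under its smallest unit (the motif must be primitive), the
motif label keeps the observed phase (ATT ≠ TTA), runs are broken at N, and
a trailing partial unit is included in the locus length but not the unit
count. Overlaps between surviving candidates are resolved for the longer
run, then the smaller unit, then the leftmost — the same policy the
test-suite's independent enumeration oracle applies. Scanning is on the plus
strand of the canonical orientation with the IRa copy dropped, so an IR
locus appears exactly once.

Classification assigns region (LSC/IR/SSC by the interval containing the
locus start) and context (containing gene body, named intron, or named
spacer); loci are matched across species by (context, motif), since
coordinates shift between genomes. Summary proportions are reported over
**all** loci and therefore sum to 100%; note that the published source's
region percentages (89.09/14.55%) use the mononucleotide count as the
denominator and do not, and its printed T-share (56.36%) is inconsistent
with its own table (30/55 = 54.55%) — the package reports counts derived
from the table.

## Concatenation and trees

The concatenation is the whole-genome alignment of the IRa-stripped
sequences. Its summary adds parsimony-informative sites: columns with ≥2
base states each present in ≥2 taxa, with gaps ignored (a column {A, A, –, –}
is not informative); the source literature rarely states its PI convention,
so this one is documented here and used consistently. Gaps are a countable
state for V/I/G (matching the per-region tables) but are pairwise-deleted
for distances.

Distances are Jukes–Cantor, `d = −(3/4)·ln(1 − (4/3)p)`, with p the
mismatch proportion over gap-free pair columns; p ≥ 3/4 raises an error
naming the pair. Tree search is standard neighbor-joining: Q-criterion
agglomeration, ties broken by the lowest index pair, negative branch
lengths clamped to zero with the deficit shifted to the sibling edge.
NJ recovers additive matrices exactly (property-tested on random additive
trees up to 12 taxa, and cross-checked against an independent NJ
implementation). Bootstrap resamples columns with replacement under a fixed
seed; support for an internal edge is the percentage of completed replicate
trees containing its bipartition (replicates whose distances saturate are
dropped from the denominator). Maximum-likelihood search is deliberately
not reimplemented; the relaxed-PHYLIP export feeds external ML software.

## The synthetic-data generator

`simulate()` is the package's test bed: it emulates the *structure* of a
quadripartite plastome and the *processes* the pipeline must measure, not
any particular species' sequence.

**Ancestor.** A fixed gene map (52 unique genes: 35 CDS, 13 tRNA, 4 rRNA)
laid out as LSC ≈ 26 kb, IRb ≈ 6.5 kb, SSC ≈ 6.9 kb at the default scale
(~46 kb genome, about 0.3× a real plastome so the end-to-end suite runs in
seconds; `full_size_config()` scales to ~155 kb). The map includes seven
IR-duplicated genes, thirteen intron-containing genes (two with two
introns), *matK* nested inside the *trnK* intron, *rps19* spanning J_LB and
*ycf1* spanning J_SA with their `rps19_like`/`ycf1_like` incomplete IR
duplicates, four planted non-ATG start codons (*ndhD* ACG, *psbI* ATC,
*psbT* ATT, *rps19* GTG), fourteen planted SSR tracts, and eight designated
hotspot spacers. Base composition is drawn at plastome-like frequencies
(GC ≈ 37%). IRa is generated as the reverse complement of IRb, and guard
bases at the four junction-flanking positions keep the planted repeat
maximal in the ancestor.

**Evolution.** The IRa-stripped genome evolves along the configured newick
tree; IRa is regenerated from IRb at every node, so IR mutations are
perfectly mirrored (ideal IR homogenization — real IRs are near-ideal, and
this keeps exact-match detection valid). Per branch and segment,
substitution counts are Poisson(branch length × segment length ×
multiplier) with uniform positions and Jukes–Cantor base changes. Default
multipliers: CDS exons 0.5, tRNA/rRNA 0.15, IR noncoding 0.25,
background single-copy spacers/introns 0.5–2.0 (graded), hotspot spacers
4.0–8.0. Indels (Poisson at `indel_rate` = 0.1 of the substitution rate;
geometric lengths, mean 2 bp) are confined to noncoding segments — coding
indels exist in real data but are not needed by any recovery metric, and
excluding them keeps reading frames and start codons intact. Planted SSR
tracts mutate only by unit slippage (±1 unit per event,
Poisson(`slip_rate` × units) per branch, default 0.02/unit); substitutions
and indels skip them so that slippage is their sole process. Start codons
are substitution-protected so planted unusual starts are recoverable facts
rather than transient states.

**Defaults as study conditions.** The default tree mirrors the published
clade structure for the genus (one early-diverging lineage plus two
five-taxon clades) with branch lengths of 1–4 × 10⁻³ substitutions/site.
That is deeper than the empirical divergence of the source genus (whose
genome-wide P is ~0.5%); the elevation is deliberate, giving per-region
signal that is resolvable at the reduced genome scale (the simulated
concatenation shows P ≈ 3% and mean pairwise identity ≈ 99.2%). What the
generator does **not** model: IR expansion/contraction, rearrangements,
codon-aware selection, rate heterogeneity within a region, imperfect or
compound SSRs, and trans-splicing (*rps12* is simulated as an ordinary
gene). Passing recovery tests therefore demonstrates correctness of the
measurement pipeline under these processes, not robustness to structural
variation the generator never produces.

**Ground truth.** The manifest records the generating tree, per-region
multipliers, per-branch event counts, and for every leaf the realized
partition (if a chance mutation extends the maximal repeat past a planted
boundary, the recorded truth is the realized maximal repeat — that is what
an exact-match detector must find), planted SSR loci, junction side
lengths, and every region's sequence. The pipeline-closure tests require
exact partition recovery on all leaves, ≥95% planted-SSR recovery by
(context, motif), Robinson–Foulds distance 0 to the generating topology,
and Spearman rank correlation ≥0.8 between configured multipliers and
recovered P across noncoding regions.

## Numerical and interface choices

* Internal coordinates are 0-based half-open; GenBank I/O converts from/to
  1-based inclusive. Sequences are uppercased on read, U → T.
* Built-in aligner scores: match +1, mismatch −1, gap open −4, gap extend
  −1; deterministic tie-breaks (diagonal, then vertical). It is quadratic
  and intended for region-scale inputs; mafft, when present, is used for
  everything and is the recommended path.
* Rounding: percent variability half-up to 2 decimals; GC content and
  identity to 2 and 1 decimals respectively.
* All tabular outputs are TSV with a header row; trees are Newick with
  supports as internal node labels.
* The pipeline aborts on the first failing stage, naming it; reruns with
  identical configuration and seeds are byte-identical.

## Problem sizes

The bundled regression fixtures are the published tables themselves (128
divergence rows, 58 SSR loci, 11 partition rows). Simulated analyses use
the ~46 kb default scale with 11 taxa, ~100 extracted regions, and 200
bootstrap replicates; the full test suite and the acceptance script each
complete in a few minutes on one CPU.
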