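# Methods

`ligsel` implements the computational core of an early B cell activation
analysis: resting splenic B cells are compared with cells stimulated for
2 h through the B cell receptor (BCR, anti-IgM) or through TLR4 (LPS),
and the transcriptional and chromatin readouts are reduced to a small
set of statistics — gene-set classification by fold change, TSS-anchored
coverage summaries, the Pol II traveling ratio, promoter motif
enrichment, miRNA categorization, and CpG-island proximity.  This note
records the models, the parameters that matter, and the choices made
where the procedure was genuinely open.

## Gene-set classification

Input is a normalized abundance table (FPKM-like, one column per
condition; `rest`, `BCR120`, `LPS120` required — classification uses the
120-min time point only).  For each gene and stimulation the linear fold
change is

    f = (stim + c) / (rest + c)

with pseudocount `c = 1.0` abundance unit (configurable; the source
procedure is silent on zero handling).  A condition is called changed
when `f >= t` or `f <= 1/t` with `t = 2` ("minimal twofold", boundary
inclusive; identical to |log2 f| >= 1).  Labels:

* changed in exactly one response → preferential to that response;
* changed in both, same direction: preferential to the stronger response
  when the weaker response's fold lies in `[t, t^2]` (two- to fourfold)
  and the stronger fold is at least `t` times the weaker; otherwise
  shared;
* changed in neither: `unchanged` when resting abundance ≥ `min_expr`
  (default 1.0; no cutoff is stated for "substantial but unchanged
  transcription"), else `low_expressed`.

Opposing calls (up in one stimulus, down in the other) are outside the
stated rule and have no label of their own; the side with the larger
|log2 f| wins, and on an exact tie the induced side, which keeps the
classification symmetric under swapping the two stimulations.  The
labels partition the gene universe; all downstream modules consume
these sets.

## Coverage profiling

Coverage tracks are dense per-base counts normalized to reads per
million (RPM = count × 10⁶ / library size).  Metagene profiles extract,
for each anchor TSS, the per-base RPM vector over a window (inclusive
at both ends; offset 0 is the TSS base), reverse minus-strand vectors
so positive offsets point downstream, and average across anchors.
Anchoring is either every transcript TSS (`all_tss`; "average TSS"
profiles are implemented as per-transcript anchoring then averaging)
or the one TSS per gene with maximal Pol II RPM in ±300 bp
(`max_polII_tss`).  Anchors whose window would overrun a chromosome
edge are dropped and counted rather than zero-padded, avoiding
artificial boundary dips.  Default windows: ±2000 bp for Pol II and
H3K4me3, ±4000 bp for the broad H3K27me3 domains, ±1000 bp for the
per-gene summed scores compared across conditions.

Condition comparisons of the ±1 kb sums use the Wilcoxon–Mann–Whitney
rank-sum test: exact null enumeration when the pooled sample has ≤ 12
tie-free observations, otherwise the normal approximation with
midranks, tie correction and continuity correction (delegated to
`scipy.stats.mannwhitneyu`; an independent enumeration oracle backs it
in the tests).

## Traveling ratio

TR = (mean body RPM) / (mean promoter RPM), with promoter −300..+300
(601 bp) and body +301..+2250 (1950 bp) so the windows partition at
+300 (the boundary base is stated ambiguously in the source windows;
this convention is fixed here).  Both means are set-level: transcript
window sums are averaged per gene, then over the gene set, and the
ratio of the two set means is taken — not a mean of per-gene ratios.
TR is invariant to library size and to any rescaling of the counts;
uniform coverage gives exactly 1950/601.  Genes shorter than 2250 bp
have the body window truncated at the annotated gene end (flagged and
counted; configurable).  Per-condition TRs are reported raw and
normalized to rest, where promoter-paused recruitment (BCR) drives the
normalized TR below 1 and enhanced elongation (LPS) above 1.

## Motif enrichment

A self-contained stand-in for an external enrichment tool.  Promoters
are the strand-oriented −1000..+1000 sequences around each gene's
representative TSS.  PWMs (JASPAR-style count text, probabilities
floored at 10⁻³ then renormalized) are scanned on both strands with a
log-odds score against a uniform 0.25 background; a window scoring at
least `score_fraction = 0.8` of the motif's maximum attainable score is
a hit (an openly stated tunable with no counterpart in the source
procedure).  Enrichment of a foreground gene set against the
unchanged-gene background uses ZOOPS counting (a promoter counts once)
and the upper-tail hypergeometric probability P(X ≥ fg_hits).  Per set,
the 30 motifs with the lowest p (ties broken by more foreground hits,
then id) are intersected pairwise.  Equivalence with any external
tool's scoring is not claimed.

## miRNA categorization and CpG proximity

miRNAs reuse the same fold-change primitive at threshold 2 against the
resting column, but with no preferential two-to-fourfold refinement:
the (BCR, LPS) direction pair directly names one of nine categories,
including the two opposing-direction sets.  No minimum-abundance filter
is applied by default (none is stated); `min_expr` is available.

A promoter is CpG-associated when its TSS lies inside a CpG island or
within 200 bp of the nearest island edge (boundary inclusive; islands
are half-open BED intervals, merged before querying; the distance from
a TSS at or past an island end is `tss − end`).  Association is a
TSS-point criterion, not whole-promoter overlap.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not the sequencing process: coverage is drawn directly as per-base
Poisson counts around an expected RPM profile (alignment, fragment
lengths, duplicates and replicates are not modeled — the design has a
single track per signal and condition).  Expected profiles per gene
class and condition:

* Pol II: Gaussian promoter peak (height 30 RPM at rest, sd 100 bp) at
  each TSS — secondary TSSs at 0.3× — plus a uniform body density
  (0.3 RPM/bp at rest) from the primary TSS to the gene end.  Per-class
  condition scalings encode the observed signature: BCR multiplies
  promoter peaks (up to 2.5× at BCR-preferential genes), LPS multiplies
  body density (2× at LPS-preferential genes).
* H3K4me3: two Gaussians flanking the TSS (offsets −250/+500 bp,
  sd 150, 20 RPM), scaled up by both stimuli and most by LPS.
* H3K27me3: a uniform ±4 kb domain (3 RPM), halved during BCR
  activation at responsive genes.
* No background coverage term by default: the stated model is peak +
  body only, and a background floor would bias planted body:promoter
  ratios.

Genes occupy deterministic non-overlapping slots (4 kb gene, 5 kb
flanks) on one synthetic chromosome, alternating strand within each
class; each gene carries 1–3 transcripts with alternative-TSS offsets
drawn from 100–200 bp.  The lower bound is deliberate: below ~100 bp
the ±300 bp occupancy windows of primary and alternative TSSs are
nearly identical and the body density deterministically favors a
slightly-downstream alternative, making a "dominant TSS" unidentifiable.
Because closely stacked alternative peaks can still shift the true
occupancy maximum, the ground truth records the TSS with maximal
*expected* resting Pol II occupancy, not blindly the primary.

Expression and miRNA tables are negative binomial around planted
per-class fold changes (dispersion 0.2; dispersion 0 gives noise-free
means for exact-recovery tests), with resting means log-uniform over
20–500 (genes) and 50–2000 (miRNAs).  Promoter sequences are iid
uniform ACGT with one exact consensus occurrence planted per selected
promoter at a uniform offset and strand; each responsive class has its
own 10-mer motif (plant rate 0.5 in its class, 0.05 elsewhere), and 30
decoy motifs model generally activation-associated sites (rate 0.3 in
every responsive class, 0.05 in unchanged) so that top-30 lists are
populated the way the real promoter grammar populates them.  CpG
islands (±300 bp) cover 70% of TSSs; half of the remaining genes get a
decoy island 1.5 kb downstream, safely beyond the 200 bp bound.

A fixed seed yields byte-identical output files.  What a green recovery
test establishes is therefore that the pipeline inverts *this* model —
Poisson counts around piecewise-smooth profiles, exact planted motifs,
clean class structure.  It does not establish performance on real
chromatin: mappability, copy-number and GC biases, peak-shape
heterogeneity, overlapping genes and degenerate motif matches are all
absent.

## Numerical and interface conventions

Internal coordinates are 0-based; BED/bedGraph output is 0-based
half-open, GTF 1-based closed.  All analysis windows are inclusive at
both ends (±1 kb spans 2001 bases).  bedGraph files merge equal-value
runs, omit zero runs, and carry the RPM denominator and chromosome
lengths as `#` comments so normalization survives a disk round trip.
Empty gene sets, zero promoter means (TR undefined), invalid windows
and missing columns raise typed errors (`ConfigError` → CLI exit 2,
`DataError` → exit 3) rather than propagating NaNs.  All pipeline
randomness flows from one seed, and the JSON summary is written with
sorted keys so identical runs are byte-identical.

## Known limitations

* Single-replicate design throughout: no statistical DE testing with
  replicates, no p-values on fold-change classification.
* The motif stage is a documented approximation, not a re-implementation
  of any specific external tool; its score threshold is a free
  parameter.
* H3K27me3×CpG interactions are exposed only as joined tables, untested.
* Genome-scale concerns (multiple chromosomes work, but overlapping
  genes are not placed by the generator and are not specially handled
  by the profilers beyond their window logic).
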