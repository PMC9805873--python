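# Methods

## Off-target site model

A guide is represented by its spacer *g* (18–25 nt over {A,C,G,T}; 20 nt is
the SpCas9 standard). A genomic window *w* of the same length, on either
strand, is a candidate binding site when

* the 3-mer immediately 3′ of *w* on the scanned strand matches the PAM
  pattern (default `NGG`, any IUPAC string) with zero flaws, and
* the Hamming mismatches between *g* and *w*, split into the
  `seed_length` PAM-proximal positions (the *seed*) and the remainder
  (*non-seed*), satisfy all three caps of the flaw budget:
  seed ≤ 2, non-seed ≤ 2, total ≤ 4 by default. The total cap is
  independent of the regional caps, not their sum.

Only substitutions are modelled — "flaws" are read as point mismatches;
bulge/indel-tolerant search and cleavage-likelihood scoring (CFD/MIT-style)
are out of scope. Coordinates are 0-based half-open on the forward strand;
an overlapping site on the opposite strand is a distinct record. Output is
sorted by (chromosome, start, strand, guide id) for determinism.

**Parameter choices.** The seed length defaults to 12 PAM-proximal
nucleotides, the conventional Cas9 seed, and is exposed as a parameter
because it is a convention, not a law. The PAM must match exactly — PAM
positions never consume budget — and the pattern is configurable so
non-NGG enzymes can be scanned without modelling them. An `N` in the genome
always counts as a mismatch at a protospacer position and never satisfies a
PAM position (not even pattern `N`): an unknown base is never credited as a
match. Spacers themselves must be unambiguous; IUPAC codes in a spacer are
rejected.

**Two implementations.** `enumerate_sites` compares numpy sliding windows
of the encoded genome against the (reverse-complemented, for the − strand)
encoded spacer and counts regional mismatches by column sums;
`brute_force_sites` is the most literal per-position, per-strand string
comparison, guarded to genomes ≤ 1 Mb. The two are checked for exact set
equality on randomized inputs; the oracle also backs `--verify-oracle` in
the CLI and the post-planting collision check in the generators.

**On-target flagging and pooling.** A site within 500 bp of the guide's
declared intended TSS is flagged on-target and excluded from
"potential off-target" accounting downstream. Pooled-guide analyses take
the union of the member guides' site lists, de-duplicated per
(guide, chromosome, start, strand) — a locus shared by two guides keeps one
record per guide. Union semantics is an inference from pooled proximal-gene
counts exceeding individual ones; it is the only defensible reading but is
noted here as a choice.

## TSS proximity

Distance between a site and a TSS is the minimum over the site's bases of
the absolute separation to the TSS point: 0 if the TSS falls inside the
interval, else the gap to the nearer edge. A gene is proximal when any of
its TSSs is within the window (default 500 bp, boundary inclusive — the
most permissive literal reading of "within 500 bp"; whether the original
window was measured from the start, midpoint or nearest edge is not
documented anywhere, so nearest-edge inclusive is this package's recorded
default, not a claim about other scripts). TSS strand is carried through
but does not enter the distance. The neighbourhood query anchors at the
site midpoint and returns genes with any TSS within ±1 Mb (inclusive),
excluding the intended target gene. Queries use per-chromosome sorted
position arrays with binary search; tests compare against a quadratic
all-pairs computation.

## Significance calling and attribution

A gene is significant when |log2FC| > 1.5 **and** p < 0.05, both strict, on
the adjusted p-value by default. The raw-p mode exists because published
descriptions of this style of analysis are inconsistent about raw versus
adjusted p at the 0.05 cut; adjusted is the more conservative default and
the flag surfaces the ambiguity instead of hiding it. If a table carries no
adjusted p-values at all, the caller is warned and raw p is used.

Candidates = significant ∩ proximal. The orthogonal attribution exploits
the fact that an siRNA against the same target shares the knockdown's
pathway consequences but none of the guide's DNA-binding off-targets:
candidates also significant in the siRNA comparison are attributed to the
pathway, the remainder stay possible off-target effects — a disjoint
partition by construction. The spreading check intersects the significant
set with the ±1 Mb neighbourhood genes; an empty result is the
"no spreading" outcome. The specificity correlation is Pearson's *r* on
log2(TPM + 1) (pseudocount 1) across genes shared by both TPM vectors,
excluding the target gene; it requires ≥ 3 shared genes and returns NaN
with a warning when either vector is constant.

## Readout arithmetic

Relative expression is 2^−ΔΔCq with
ΔΔCq = (Cq_target,sample − Cq_HK,sample) − (Cq_target,NTC − Cq_HK,NTC).
Technical replicates are averaged on the Cq scale before the formula
(aggregation order is otherwise unspecified in common practice; Cq-scale
averaging is the recorded default). The housekeeping gene (e.g. GAPDH or
ACTB) is a column selection, never hard-coded. Normalised readouts are
value / control with control > 0; percent knockdown is 1 − normalised.
qPCR efficiency correction (Pfaffl) and amplification-curve processing are
out of scope.

## Synthetic data: what it emulates and what it does not

The generators exist so that every stage runs against exact planted truth.

* `make_genome` draws i.i.d. bases at a target GC fraction (default 0.41,
  the human average).
* `plant_sites` edits protospacer+PAM copies into the genome with mismatch
  positions drawn inside the designated region and substituted to a
  different base, then re-scans the whole genome with the brute-force
  oracle: if an accidental in-budget site exists (possible in the random
  background), `make_planted_genome` regenerates with an incremented
  derived seed. Planted truth is therefore exhaustive, not just sufficient.
* `make_de_tables` emulates the *output distribution* of a DE test rather
  than simulating reads: null genes get log2FC ~ Normal(0, 0.2) and uniform
  p-values, planted genes get |log2FC| in [2, 3] (target −5, the siRNA
  target 0.8× that) at p = 10⁻⁸, and adjusted p-values are
  Benjamini–Hochberg over each table. Pathway genes share one effect draw
  between the CRISPRi and siRNA tables; off-target genes are planted only
  in the CRISPRi table. TPM columns come from a log-normal baseline with
  treated = control · 2^log2FC.
* `make_study` assembles the standard study: a 4 kb chromosome carrying the
  exact on-target site (intended TSS 150 bp away) and null neighbourhood
  genes, a 16 kb chromosome carrying the full 3×3 in-budget flaw-partition
  grid plus three over-budget decoys, TSSs for two pathway genes and one
  off-target gene 150 bp from distinct planted sites, a non-proximal decoy
  gene, and a 500/501 bp boundary pair; the DE universe holds 1000 genes.
  The on-target and planted off-target sites live on different chromosomes
  so the ±1 Mb spreading neighbourhood contains only null genes, matching
  the no-spreading configuration the analysis is meant to detect.

What passing on these fixtures does **not** show: behaviour on repetitive
or GC-skewed real genomes (i.i.d. background has no repeats, so the
accidental-site rejection step almost never fires at desk scale), DE-test
miscalibration (p-values are uniform by construction), isoform-level TSS
ambiguity, or any count-level property of real RNA-seq. Fixture sizes
(≤ 20 kb genomes, 1000-gene universes, 20–50 replicates) were chosen so
the whole suite runs in well under a minute; they are scale models of the
analysis, not of a mammalian genome.

## Numerical and degenerate-input choices

Empty chromosomes and chromosomes shorter than spacer+PAM yield no sites
rather than errors; a seed length longer than the spacer is a parameter
error. Site/TSS chromosome-name mismatches are logged once per chromosome
and produce no hits. Gene-universe mismatches between proximal sets and DE
tables are logged; proximal genes missing from the DE table simply cannot
become candidates. Ties in TSS distance keep the minimum per (gene, site)
pair. All generators are deterministic functions of an integer seed.

## Known limitations

No genome index is built — the scanner is linear per (guide, genome) and
meant for desk-scale genomes, not hg38-scale screens. No bulges, no PAM
flaws, no chromatin accessibility, no cleavage scoring. The DE test,
normalisation and multiple-testing correction are consumed, never
recomputed.
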