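# Methods

## Site models

Splice-site sequence composition is modelled by an inhomogeneous Markov
chain of order 2 over a fixed window: 9 nt for donors (relative positions
−2..+7; the relative scale has no zero, so −2,−1 are the last exonic bases
and +1..+7 the first intronic, with the GT dinucleotide at +1,+2) and
27 nt for acceptors (−24..+3, covering the polypyrimidine tract and the AG
at −2,−1). Each window position carries conditional probabilities of the
base given its preceding k-mer (k = min(position, order): the first
positions condition on shorter contexts, the standard inhomogeneous-chain
convention). The log-odds splicing score sums, over positions, the log
ratio of the site conditional to a background conditional.

The background is a single position-independent order-2 model estimated
from user-supplied background sequences (the fixture uses uniform random
sequence; on real data, annotation-wide flanks are the intended input).
A positional background would require far more data than the site windows
themselves; position independence is the usual choice for signal sensors
in gene finders.

Scores are natural-log units; an optional `log_base` re-expresses them
(e.g. bits). Since the classification thresholds are calibrated in the
same units the choice is self-consistent.

**Functionality.** The model records which (position, context, base)
triples were actually observed (pre-pseudocount) in the site training set.
A window that uses an unobserved triple is flagged non-functional: it has
never been seen among real sites, so it is assumed not to act as one.
This is the basis of the disrupting/activating classes, and it is why the
default training pseudocount is 0 — smoothing would still be applied to
the probability tables if requested, but seen-ness always reflects raw
counts. Zero-probability lookups fall back to a configurable log floor
(ln 1e−12) so scores stay finite.

**PWM.** The comparison model is an ordinary per-position log-odds PWM
against a fixed background composition (uniform by default, pseudocount
0.5). It is deliberately context-free: agreement between the two models
then genuinely reflects the sequence, not shared modelling assumptions.

## Variant classification

Variants are intersected with site windows; each variant is applied to
the genomic sequence and the fixed-length window re-extracted anchored at
the intron boundary, so indels draw replacement bases from the flanking
sequence. A deletion that removes the anchoring boundary base makes the
window unscorable and is reported as disrupting with a distinct
`boundary_loss` flag. Default classification is per-variant (each variant
applied alone); a haplotype selector applies genotype-phased combinations
for per-individual analyses.

The decision table (README) uses τ = 1.5 for donors and 1.0 for
acceptors. Both windows non-functional is reported as a distinct
`neutral-nonfunctional` category rather than folded into a named class,
since no principled assignment exists for that case.

`calibrate_threshold` reproduces the τ calibration: Markov score
differences are swept over a τ grid (0–2.5, the procedure's stated
range), cross-tabulated against the fixed PWM three-class call (band ±6)
and scored by the chi-square statistic; agreement per cell is reported as
standardized residuals (observed − expected over its standard deviation,
the adjusted-residual form). Ties in the argmax break toward the smallest
τ. On synthetic data the Markov and PWM deltas share a scale (both are
log-probability ratios of the same generator), so the argmax reflects
that scale relation and can pin at the grid edge; the absolute τ values
from the original calibration depend on the external PWM database's score
scale and are not desk-reproducible.

**PSI.** Percent-spliced-in of an alternative exon uses the mean of the
two flanking inclusion-junction counts, ī, giving PSI = ī/(ī + e) with e
the exclusion-junction count; PSI is undefined below a minimum total
coverage of 10.

**Population summaries.** Per-class derived-allele-frequency histograms
are compared to the neutral class by two-sample Kolmogorov–Smirnov tests;
classes with fewer than two observations are skipped with a warning.
Variant burden tabulates sites by number of overlapping variants and the
indel fraction inside windows vs overall (Fisher exact test on the 2×2).

## Novel introns

Split mappings are filtered on mapping quality ≥ 150 (the original
mapper's scale — mapper-dependent and configurable), edit distance ≤ 6,
proper pairing and insert size ≤ 10⁶ nt. Junctions identical to annotated
introns are dropped; the rest are grouped into PNIs with read, individual
and population support (an individual counts at ≥ 1 read; "all
populations" means every distinct label present). Each novel side must
lie within 30 nt of an annotated exon boundary; for junctions with both
sides novel, one side within range suffices. Events are *internal* when
the junction lies inside an annotated transcript span, otherwise
*extensions* (upstream of the TSS or downstream of the annotated 3′ end,
in transcription direction); patterns count novel sides
(novel-combination / one-novel-donor / one-novel-acceptor / two-novel).
Only GT/AG junctions are scored for variant effects; non-canonical PNIs
are retained but flagged. PNI-derived sites feed back through the same
window extraction and classifier as annotated sites.

## Cleavage sites and poly-A signals

Unmapped reads ending in AAAA (or starting with TTTT — opposite-strand
evidence, reverse-complemented before anchoring) are trimmed of their
terminal run (≥ 5 nt, at most one internal non-A interruption, never
terminal on either side of the run), kept when the remainder is > 25 nt
with A+T content < 80%, and their unique anchorings collapsed into PCSs
keyed by exact (chrom, strand, last templated base) — no positional
merging, since none is specified; a merge radius exists but defaults
to 0. Support ≥ 2 defines the conservative subset. Cross-dataset
confirmation uses a ±50 nt window on the same chromosome (strand
matching optional, off by default to mirror the windowed-intersection
convention).

The poly-A signal scan tests the 13 CPSF hexamers in frequency rank
order within ±50 nt of the PCS on the transcribed strand ("around" is
read as ±50; an upstream-only mode is available via the scan window
choice). The first-ranked hexamer present wins; among its occurrences
the one closest to the PCS is recorded, upstream breaking ties. A SNP in
a motif yields *altered* when the variant hexamer is still in the list,
*degraded* otherwise; distances of altered vs degraded motifs to the PCS
are compared by a two-sided Mann–Whitney test.

## RNA editing

RNA-side calls are candidates when absent from the genomic variant set,
A>G on their gene's strand (T>C in genomic coordinates for minus-strand
genes; positions under genes of both strands are ambiguous and dropped),
and passing median per-sample coverage ≥ 10, ≥ 10 samples showing the
non-reference base, and call quality ≥ 100 (all boundaries inclusive on
the pass side). Editing efficiency is the overall non-reference fraction;
*exhaustive* means strictly > 0.9. The editing/intron-retention
association compares normalized intron coverage between exhaustively and
partially edited disrupted sites by Mann–Whitney; the normalization is
pluggable (default: reads per intronic base scaled by flanking-exon
coverage), since no single convention is canonical.

## Synthetic data

The generator emulates the study conditions at desk scale: 16 genes of 4
exons on two contigs (alternating strands), exons 60–120 nt, introns
70–160 nt, canonical GT..AG boundaries, and site windows drawn from a
known generative model — per-position base probabilities with a
0.7-probability consensus and 0.1 alternatives, dinucleotides fixed.
Position independence makes planted effect sizes exact (a
consensus↔alternative swap moves the true score by ±ln 7 ≈ 1.95, clear of
both τ bands; a swap between alternatives moves it by 0) while the
trained order-2 model still has to estimate full conditional tables.
Classification models train on 4,000 sampled windows so that rare
contexts are well-populated; the parameter-recovery checks use the stated
n = 1000. Planted variants per class: 30 disrupting / 30 weakening / 30
neutral / 30 enhancing / 16 activating, the latter as variants restoring
sites written broken into the reference genome (the reference-allele-bias
mechanism behind real activating calls). Per-class DAFs are Beta-
distributed (disrupting and weakening low, enhancing and activating
high, neutral uniform) and genotypes Hardy–Weinberg at the DAF.

Read-level designs: junction evidence for annotated introns plus planted
novel junctions of every pattern with low-quality decoys; a logistic PSI
response (slope 0.8 per log-odds unit, sequencing depth 100 per
junction) to summed per-allele score deltas across 100 individuals;
poly-A reads with 12–17 nt tails at planted cleavage positions whose
±50 nt scan windows are scrubbed of chance hexamers so the planted motif
is unambiguous; editing calls at acceptor adenosines with planted
efficiencies (0.95/0.4) plus one decoy per filter. The generator does
not model sequencing error, base quality, mapping ambiguity, expression
variation or linkage — passing tests demonstrate correctness of the
method's logic and calibration under its own model assumptions, not
performance on real reads.

All randomness flows from one integer-seeded numpy generator; identical
specs give byte-identical outputs.

## Numerical and testing choices

Parameter recovery at n = 1000 is asserted two ways: every count-weighted
per-(position, base) marginal within ±0.05 of the generating value, and
the mean per-context conditional error below 0.05 over contexts with ≥ 50
observations — individual rare-context conditionals at n = 1000 carry
binomial noise comparable to the tolerance, so a per-cell bound is only
asserted where the context count (≥ 200) makes it meaningful. Degenerate
inputs (empty training sets, window-length mismatches, non-ACGT symbols,
single-class calibration marginals, zero-coverage efficiency, sub-2
association groups) raise typed errors; ambiguity codes in lenient mode
mark a window unscorable, distinct from non-functional. Problem sizes
throughout (dataset scale above; 1,000-variant symmetry sweeps; 200–300
window oracle comparisons) keep the full suite and the acceptance script
within seconds on one CPU.

## Known limitations

- The mapping-quality filter default (150) is tied to a specific
  mapper's scale and must be adapted for BWA/minimap2-style MAPQ.
- The constitutive/alternative call uses a simple span-based definition
  (a site is alternative if any same-gene transcript spanning its
  boundary does not use it).
- The background model is position-independent; gene finders sometimes
  use richer backgrounds.
- Variant calling, read mapping and the external PWM database are out of
  scope: the package consumes their outputs (VCF, SAM/TSV) and
  re-implements PWM scoring as standard log-odds rather than wrapping an
  external scanner.
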