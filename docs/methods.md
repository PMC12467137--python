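# Methods

This note documents the models, parameter choices and numerical
conventions behind `cernet`, and what the synthetic experiments do and do
not demonstrate about real data.

## Coordinates and alphabets

All in-memory coordinates are 0-based half-open; GTF output is converted
to 1-based closed on write, BED stays 0-based half-open. miRNAs are stored
in the DNA alphabet (U→T) so a single alphabet serves the genome, reads
and miRNAs.

## Synthetic study generator

The generator emulates a two-group design (control C vs treatment G, five
biological replicates each) small enough to run in seconds but carrying
every signal the analysis chain filters for.

**Reference.** Random ACGT chromosomes (default 2 × 60 kb); 30 genes of
3–6 exons (150–300 bp, introns 150–300 bp) placed without overlap, each
with a 3′UTR ≥ 200 nt (default 300) inside its terminal exon; 15 mature
miRNAs of 21–24 nt with pairwise-distinct seeds; 12 circRNAs placed
according to a structural type mix dominated by multi-exon circles with
annotated boundaries (annot-exon 0.79, exon-intron 0.12, one-exon /
intron / intergenic 0.03 each), mirroring the class proportions typical of
muscle circRNA surveys. Mature miRNA lengths start at 21 nt because a
perfect duplex of a 20-mer scores 5·20 + 5·7 = 135 under the alignment
constants below and could never clear the score threshold of 140; 21–24 nt
matches the 21–23 nt mode of real small-RNA libraries.

**Junction identifiability.** When the genome base before a planted
acceptor equals the base before the donor, the circle has an equivalent
junction shifted one base left, and any caller with a deterministic
tie-break would report that shifted form. The generator rewrites the
(intronic/intergenic) base before the acceptor in such cases, so every
planted junction is its own leftmost representation and exact-coordinate
recovery is well defined.

**Planted regulation.** Each of the eight default triples picks a distinct
circRNA, miRNA and gene. The exact reverse complement of the full mature
miRNA is embedded both in the gene's 3′UTR and in one exon of the circRNA
(collision-checked against all previous embeddings), so both target
predictors can recover the pair from sequence alone. True log₂ fold
changes of ±3 are assigned with the sponge sign structure
sign(circ) = sign(mRNA) = −sign(miRNA); directions alternate between
triples so that neither direction dominates any count matrix — real DE
tallies in such designs are near-balanced, and majority one-way DE in a
12-feature matrix would defeat median-of-ratios normalization by
construction. A quarter of the remaining features receive ±3 fold changes
as distractors.

**Counts.** NB(m, α) with variance m + α·m², the standard RNA-seq
parameterization; base means log-uniform in [100, 1000], default
dispersion α = 0.05 (typical of controlled animal cohorts). For each
triple one latent log-normal factor per sample (σ = 0.8) multiplies the
circRNA and mRNA means and divides the miRNA mean, imprinting the
within-group covariance the correlation filters need; the log factors are
centred within each group so they create covariance without perturbing
group-mean fold changes. Mapped-read totals are the panel's column sums
plus a constant background of 20× the panel mass: the simulated features
stand for a sliver of a real library, and per-million scaling against the
panel alone would couple every feature to every other feature's noise
through the shared denominator — an artifact real libraries do not show.
The defaults (|log₂FC| = 3, α = 0.05, σ = 0.8) were fixed by a one-time
design study so that each filter of the chain passes planted structure
with margin (planted-triple recall ≈ 0.96, precision ≈ 0.99 over 20
seeds); they are the package's definition of "strong planted effects" and
are not tuned per run.

**Reads.** Junction reads straddle the back-splice with ≥ 20 nt on each
side: a suffix of the genomic circle span followed by a prefix, reverse
complemented for minus-strand circles; linear reads are contiguous genome
substrings. Reads are error-free by default — an optional uniform
substitution rate exists, but the caller is exact-match, so errors reduce
recall by design. `plant_regulation` edits the genome (it embeds binding
sites), so reads must be simulated after planting.

## Back-splice caller

Terminal 20-mers of each read are exact-matched against a k-mer index of
both genome strands; anchors with more than one placement are discarded
(no rescue). For uniquely anchored pairs on one chromosome and strand,
head-to-tail orientation (right anchor upstream of the left) triggers
breakpoint extension: the read prefix is extended rightward from the left
anchor, the suffix leftward from the right anchor, and a candidate is
emitted only if the two extensions cover the read. Repeats at the junction
make the breakpoint ambiguous; the maximal suffix is used, which places
the acceptor leftmost (tie-stable). Every candidate is verified by exact
containment of the read in the doubled circular segment. Support counts
*distinct read sequences* per sample — duplicates of one sequence count
once — and a call is kept iff some single sample reaches the threshold
(default 2); pooled counting across samples is available behind a flag.
Splice-signal checks (GT–AG) and statistical read-assignment models of
full circRNA quantifiers are intentionally out of scope: support-count
filtering alone defines a call.

Structural classes are assigned against the annotation with precedence
one-exon > annot-exon > exon-intron > intron > antisense > intergenic;
exonic/intronic classes require a same-strand gene, antisense means
containment in an opposite-strand gene.

## Differential expression

The DE engine is a deliberately simple, calibrated NB stand-in, isolated
behind `de_test` so a DESeq2-class engine can be swapped in:

- size factors by median-of-ratios against the geometric-mean reference
  (library-size ratios when no feature is counted in every sample);
- per-feature pooled method-of-moments dispersion
  α = [(v_C − m_C) + (v_G − m_G)] / (m_C² + m_G²), floored at 10⁻⁸;
- log₂FC from size-factor-normalized group means with pseudo-count 0.5;
- Wald statistic on the log difference of group means with variance
  m·Σ(1/s_i)/(n²·m) + α/n per group, referred to a **t distribution with
  n₁+n₂−2 df**. With five replicates per group the plug-in dispersion
  makes the plain normal reference anticonservative (measured null type-I
  error 0.088 at α = 0.05 versus 0.051 under t₈), so the t reference is
  used.

Calling uses |log₂FC| ≥ 1 (inclusive) and raw p < 0.05 (strict); a BH
column is reported for information but not used for calling. Features with
all-zero counts get p = 1, log₂FC = 0. miRNA "TPM" is counts-per-million
over counted miRNAs: mature miRNAs are near-constant length, so no length
term is applied.

## Target prediction

**Seed scan.** The seed is miRNA positions 2–8 (1-based, 5′→3′). Every
occurrence of its reverse complement in the target is a 7mer-m8 site,
upgraded to 8mer when the target base facing miRNA position 1 is an A;
overlapping occurrences are all reported.

**Duplex alignment.** Local (Gotoh) alignment of the miRNA threaded
antiparallel against a target window: Watson–Crick pairs +5, G:U wobbles
+1, mismatches −3, with pair scores doubled at miRNA positions 2–8
(5′ weighting); affine gaps cost −4.0 for the first gapped position and
−9.0 per additional position, on either strand, with cross transitions
between gap states allowed. Alignment starts and ends on a pair (terminal
gaps are never counted). Duplex energy is a per-pair stacking proxy —
GC −3, AU −2, GU −1 kcal/mol — monotone in duplex stability and calibrated
so a perfect duplex of any ≥ 21-nt miRNA clears both printed thresholds
(score 5L + 35 ≥ 140, energy ≤ −2L ≤ −42). Nearest-neighbour
thermodynamics is a non-goal. A site is reported iff score ≥ 140, energy
≤ −10 kcal/mol and the seed is paired Watson–Crick, gap-free ("strict 5′
seed pairing").

Because a strict-seed site necessarily contains the literal
reverse-complement 7-mer of the seed, alignment windows are anchored on
those occurrences (window = site ± 10 nt); this is an optimization that
cannot lose a reportable site, and the DP itself is validated against
exhaustive alignment enumeration in the tests. circRNA targets are scanned
on the doubled circular sequence — windows are cut in the middle copy of a
tripled sequence so junction-crossing sites have full flanking context —
and positions are reported modulo the circle length.

**Intersection.** The two predictors are intersected at the
(miRNA, target) *pair* level: a pair survives iff each predictor reports
at least one site for it, in which case the duplex sites (which carry
score and energy) are emitted with source `both`. Site-level intersection
would be ill-defined across predictors with different coordinate
conventions.

## Network assembly

Correlations are computed across all ten samples of both groups pooled, on
normalized expression (RPM for circRNA and mRNA, counts-per-million for
miRNA); pooling is what makes group-driven co-expression detectable.
Sponge legs are candidate-restricted to predicted target pairs and kept
iff Spearman ρ < −0.5; circRNA–mRNA candidates are pairs sharing ≥ 1
candidate miRNA, kept iff Pearson r > 0.7. All coefficient thresholds are
strict, and by default every leg must also reach two-sided p < 0.05
(`p_scope="pcc"` restricts the p clause to the Pearson leg — the reading
where significance is demanded only of the final co-regulation filter).
Spearman uses average ranks with the t-approximation p; an
exact rank-permutation p (enumerated null of Σd², cached per n, feasible
for n ≤ 10, tie-free data) is provided as a small-sample oracle. Constant
expression vectors make correlation undefined; such pairs are skipped.

A triple is emitted when its three edges all exist, deduplicated, in
lexicographic (circ, miRNA, mRNA) order, and re-checked by an independent
validator pass against the thresholds and target-pair membership. Export
writes an edge-list TSV, GraphML, and a Sankey-ready JSON with nodes in
three columns (circRNA → miRNA → mRNA) and link weights |correlation|;
rendering the figure itself is out of scope.

## Enrichment

Generic over-representation: p = upper hypergeometric tail
P(X ≥ k | N, K, n) per term, BH adjustment across tested terms,
significance on adjusted p < 0.05 by default (raw-p mode available, as the
convention differs between tools). Term maps are user-supplied GMT; GO DAG
propagation and pathway topology are out of scope. The default universe is
the expressed-gene set supplied by the caller.

## What the synthetic experiments do and do not show

The generator plants unambiguous, strong structure: error-free reads,
unique anchors, perfect-complement binding sites, |log₂FC| = 3 effects and
a dominant shared latent factor. Passing tests therefore demonstrate the
*correctness of the filtering logic* — exact junction recovery,
calibration of the DE test under the null, threshold boundary semantics,
agreement of each statistic with independent oracles, and end-to-end
recovery of structure that is detectable by design. They do not
demonstrate performance on real libraries, where reads carry errors and
adapters, anchors map ambiguously to repeats, binding sites are partial,
effect sizes are small, and dispersions vary per feature. Problem sizes
(30 genes, 15 miRNAs, 12 circRNAs, 10 samples, 20 seeds for the recovery
experiments) are the package's chosen desk-scale defaults; all stages
accept larger inputs.

## Known limitations

- The caller is exact-match by design; a single read error in an anchor or
  junction region drops the read.
- Multi-exon junction reads are reconstructed against the unspliced
  genomic circle span; spliced-read reconstruction across introns is a
  non-goal, and the read simulator emits unspliced junction reads
  accordingly.
- The DE stand-in shares no code with DESeq2 and does not attempt
  bit-compatibility; shrunken fold changes are not implemented
  (thresholding uses raw fold changes).
- The duplex energy model is a three-level proxy, not a thermodynamic
  folding energy.
- Sequencing-depth variation between samples is not simulated; mapped
  totals differ only through the panel's own counts.
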