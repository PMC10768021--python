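# Methods

## The discrimination problem

CD4 and LAG-3 arose from a tandem gene duplication and still sit head-to-tail
(LAG-3 upstream, CD4 downstream, same strand) in sharks, bichirs, and
tetrapods. Because neither binds MHC class II with high affinity, their
ectodomain sequences drift fast, and across large evolutionary distances
whole-sequence similarity and tree topology are only weakly informative of
which paralog a gene is. The pipeline therefore scores a gene on independent
discriminating features and resolves the label from the combined evidence.
Ray-finned fish additionally carry two CD4 lineages from a second early
duplication: CD4-1 (marked by a conserved C-terminal tail motif) and CD4-2
(often a reduced V-C2 or V-C2-V ectodomain, frequently with a linker CxxC).

## Motif model

A motif is an ordered list of allowed-residue sets over the 20-letter
alphabet (`x` = wildcard, `[..]` = class). Scanning is exhaustive: every
offset is tested, overlapping hits are all reported, and the unknown residue
X satisfies no position — including the wildcard — so partially determined
sequences can only lose evidence, never gain it. Inhibitory tail motifs are
ranked canonical ITIM `(I/V/L)xYxx(L/V)` > ITIM-like `(F/Y)xxL(D/E)` > `YxxM`;
the first class that matches anywhere in the tail is reported. The FxxL
4-mer core is catalogued separately from the 5-mer because the functional
contribution of the acidic fifth residue is unresolved; the classifier uses
the 5-mer.

The Kozak rule is operationalized as a disjunction: a start context
`NNN-ATG-N` is favorable iff position −3 is a purine **or** position +4 is G.
Either strong position suffices; this reproduces both reference verdicts
(`cagATGt` unfavorable, `cccATGg` favorable) and depends on no other
characters of the heptamer.

## Gene structure

All internal coordinates are 0-based half-open in transcription order;
GFF3's 1-based closed coordinates are converted at the parse boundary and
minus-strand features are reordered there, so phase arithmetic is
strand-free. Intron phase is defined on coding nucleotides only: an intron
after `n` coding nucleotides has phase `n mod 3` and interrupts residue
`n // 3`. An intron counts as "within" an Ig domain only in the domain's
strict interior (boundary residues excluded) — the discriminating introns
are internal to D1. The tail-exon criterion counts coding exons strictly
after the transmembrane-encoding exon; the CD4 baseline is 2, and `extra_exon`
(the chondrichthyan CD4 state) triggers at ≥ 3, making the shark feature
binary. A CDS whose total length is not divisible by 3 sets a warning flag
rather than failing; phases remain computable.

## Domain detection

An Ig-like domain candidate is a cysteine pair (β-strands B and F) spaced
40–80 residues; the window is a design choice spanning observed B–F
distances, since no numeric window is canonical. Detection is greedy left to
right with the closest admissible partner (deterministic smallest-spacing
tie-break) and non-overlapping pairs. Category: C2 when the F-strand
cysteine carries the WxC signature (tryptophan two residues before it — a
hallmark of family domains D2/D4); otherwise V when at least 3 of the 6
V-start consensus residues — (I/V)4, (F/Y)5, G9, (A/V)12, L14, P15 relative
to a domain start placed 15 residues before the B cysteine — are present;
otherwise degenerate (rendered `V*`). The 3-of-6 threshold tolerates the
degenerated V domains seen in LAG-3 D3 without losing the call. Domains are
labeled D1–D4, then `extra` (covering five-domain CD4-2.2-like cases). The
linker CxxC is searched only between the last domain end and the TM start,
so a domain-internal CxxC never counts as a hinge motif.

## Transmembrane span and tail features

The TM segment is the 19-residue window maximizing mean Kyte–Doolittle
hydropathy, accepted when that mean is ≥ 1.5, ties broken toward the C
terminus (the tail is defined downstream of the span). The zinc-clasp call
has class precedence CxC > CxH > CxF regardless of position — histidine
substitutes for cysteine in tetrahedral Zn²⁺ coordination, and CxF marks the
sturgeon CD4-2f variant — with a flag for the conserved tyrosine immediately
preceding the motif. The EP-repeat count is the maximal `n` with `(EP)^n` a
contiguous substring. The acidic fraction is `#(D,E)/w` over the final
`w = min(17, len)` residues; 17 is the length of the reference mammalian
EP-repeat stretch, anchoring the feature to its one concrete exemplar. The
CD4-1 C-terminal motif `P(K/Q)P(K/R)(A/G)FY(H/K/R)` is searched only in the
last 12 tail residues, where it is length-conserved.

The amphipathic score is the maximal helical hydrophobic moment over
11-residue windows at 100°/residue using the Eisenberg consensus scale,
normalized by window length, computed on hydrophobicities centered on the
window mean. Centering makes the score a measure of periodic *variation*:
a homopolymer scores exactly 0 however hydrophobic it is, which is the
property of interest (amphipathy), whereas the uncentered moment retains a
spurious nonzero residue for uniform windows because 11 steps of 100° do not
close a full turn. Moments below 1e-12 are clamped to zero.

## Expression criteria

TPM columns are length-corrected read rates rescaled to sum to 10⁶. The
dominance criterion is `test / (ref + 0.01) ≥ 5`: the five-fold default
reflects the observed thymus:spleen contrast of CD4, and the 0.01-TPM
pseudocount keeps ratios finite at the near-zero reference values that real
tables contain. The threshold is configurable and reported with each result,
since the five-fold figure is an operationalization of an observed contrast,
not an established cutoff. qPCR tables are reduced per replicate as
target/housekeeping amount, averaged per tissue, and scaled so the
calibrator tissue is exactly 1 — invariant under any global rescaling of
either amount column. Failure of dominance contributes nothing to the LAG-3
score: LAG-3 is merely *not consistently* thymus-high, so non-dominance is
absence of a pattern, not an anti-pattern.

## Synteny

Head-to-tail tandemness requires the same sequence, same strand, the
downstream gene starting at or after the upstream gene's end in
transcription orientation, and at most 2 intervening annotated genes — a
tolerance that accommodates the lungfish hybrid gene sitting between LAG-3
and CD4, and pseudogene fragments near intact shark CD4. A gene absent from
the table yields "not evaluable", which the classifier treats as unknown
(no points either way), never as negative evidence. A gene flanked
head-to-tail on both sides is positionally uninformative and scores no
synteny points.

## Classifier

Scores are additive per lineage. CD4: clasp CxC/CxH +3 (CxF +2), ≥2 tail
exons +2, phase-1 D1 intron +2, CD4-1 C-terminal motif +1, thymus dominance
+1, downstream tandem role +1. LAG-3: canonical ITIM or ITIM-like +3 (YxxM
+2), single tail exon +2, phase-2 D1 intron +2, EP-repeat (n ≥ 3) +1,
upstream tandem role +1. The 3/2/1 weighting encodes the qualitative ranking
of the evidence (tail motifs and exon organization sharp; intron phase sharp
but bony-vertebrate-only; expression and synteny supportive); the numbers
themselves are a design choice of this package. A label requires the winner
to reach 5 points with a margin of 3, so no single weak feature can decide a
call. HYBRID is checked first: an inhibitory motif on a single-exon tail
(≥ 3 LAG-3 tail points) combined with ≥ 3 CD4 ectodomain-side points
(phase-1 D1 intron 2, four-domain V-C2-V-C2 architecture 1, CD4-1-type C
terminus 1). Within a CD4 call, CD4-1 requires the C-terminal motif and
CD4-2 a reduced (< 4 domain) architecture or linker CxxC; without such a
ray-finned-fish-specific cue the gene is plain CD4, matching chondrichthyan
and tetrapod usage. Frog-type LAG-3, which lost the inhibitory motif, still
resolves as LAG-3 from the single-exon tail, phase-2 intron, and upstream
role (5 points). Everything else is AMBIGUOUS — the honest output for
conflicting or insufficient evidence. The classifier contains no randomness;
identical inputs give identical reports.

## Synthetic data

The generator emulates the comparative picture, not any real genome. Each
gene is leader + Ig domains (cysteine pairs spaced 55±10; WxC planted in C2
domains, V-start consensus in V domains) + linker + 19-residue hydrophobic
TM + a class-specific tail, with background residues drawn uniformly from
alphabets that exclude exactly the letters that could fake a feature (no
C/W in ectodomain filler; no C/F/Y/M/I/L/V in tail filler). Gene models
place the D1-internal intron so the cumulative coding length mod 3 is 1
(CD4 classes, 20 residues into D1) or 2 (LAG-3 classes, 30 residues in —
a different position), and split the tail over 1/2/3 coding exons for
LAG-3-type, CD4-type, and shark-CD4 templates respectively. Each locus gets
a same-strand tandem neighbor (upstream LAG-3-family for CD4-type genes,
downstream CD4-family for LAG-3-type, both for the hybrid), with the locus
strand randomized. Expression rows draw spleen TPM lognormally (σ = 0.5
around 1) and thymus as spleen × ratio × lognormal(σ = 0.2), ratio 6 for
CD4-type and 1 for LAG-3-type genes — reproducing the qualitative
thymus-dominance pattern without claiming any real table's exact values.
Under this noise model a CD4-type gene passes the five-fold criterion with
probability ≈ 0.8 (the normal-CDF integral the tests verify by Monte Carlo);
classification does not depend on it, since CD4-type genes carry ≥ 8 points
of other evidence. Mutation is i.i.d. residue substitution at a given rate,
optionally sparing protected spans for ablation studies; it alters only the
protein, so structural features (phases, exon counts, synteny) are noise-free
by construction — a deliberate idealization.

What the generator does **not** emulate: indels and length variation,
realistic substitution processes or phylogenetic correlation, UTR exons,
assembly artifacts, and partially degenerated real motifs. Passing at
mutation 0 therefore shows the pipeline is self-consistent (every planted
feature is re-detected and every label recovered), and the mutation sweep
shows graceful degradation — neither is a claim about recall on real
divergent genomes.

## Problem sizes and numerics

Default verification cohorts are 100 genes (4 classes × 25) for exact
recovery and 4 mutation rates × 10 seeds × 20 genes for the degradation
sweep — sizes chosen so the full suite runs in seconds on one core while
estimates stay stable. Reported floats are exact arithmetic on the inputs
except the hydrophobic moment (clamped below 1e-12) and the Monte-Carlo
expression checks (binomial tolerance in the tests). Degenerate inputs have
defined behavior: empty FASTA yields an empty list, sequences without a
hydrophobic window raise "no TM segment" and the pipeline records the
failure in the gene's report notes and continues, zero-valued references are
handled by the ratio pseudocount, and an all-zero count vector is an error.

## Known limitations

The domain detector assumes intact cysteine pairs; tetrapod LAG-3 domains
that rearranged the F-strand disulfide appear degenerate or are missed
rather than specially handled. The V/C2 call is sequence-rule based, not
structural. The classifier's weights are heuristic encodings of a
qualitative ranking; borderline real genes (pseudogene fragments, partially
sequenced tails) are expected to land in AMBIGUOUS, and the thresholds are
exposed as parameters for sensitivity analysis.
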