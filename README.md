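# cd4lag3 — discriminating CD4, CD4-1, CD4-2, and LAG-3 genes across jawed vertebrates

CD4 (an activating T-cell co-receptor) and LAG-3 (an inhibitory immune-checkpoint
receptor) are tandem-duplicated relatives that both bind MHC class II. Their
ectodomains have diverged so much over ~450 My of jawed-vertebrate evolution —
often below 20 % identity between distant orthologs — that whole-sequence
phylogenetics alone frequently cannot say which family member a newly found
gene is. What *does* discriminate them is a small set of sharp, largely
independent features:

| feature | CD4 lineage | LAG-3 lineage |
|---|---|---|
| cytoplasmic-tail motif | Cx(C/H) zinc-clasp for LCK binding (CxF in one sturgeon CD4-2 variant) | ITIM-like (F/Y)xxL(D/E); canonical ITIM (I/V/L)xYxx(L/V) or YxxM in some teleosts |
| post-TM tail exons | ≥ 2 (3 in sharks — an extra exon) | exactly 1 |
| D1-internal intron (bony vertebrates) | phase 1 | phase 2, different position |
| ectodomain | V-C2-V-C2 Ig-like domains (CD4-2 often reduced, with a linker CxxC) | V-C2-V-C2 |
| synteny | downstream of LAG-3, head-to-tail | upstream of CD4 |
| expression | thymus-dominant (≥ 5× spleen) | not consistently thymus-high |

This package implements each criterion as a tested module — a degenerate-motif
scanner with a Kozak-context rule, intron-phase/tail-exon analysis from GFF3,
rule-based Ig V/C2 domain annotation, TM and tail profiling (clasp, ITIM-like,
EP-repeat, acidic end, helical hydrophobic moment), TPM/qPCR expression
criteria, and a head-to-tail synteny check — and combines them in an additive
evidence-weighted classifier (sharp features 3/2 points, supportive features
1 point; winner needs ≥ 5 points with a margin ≥ 3) that emits transparent
per-feature evidence reports. A CD4-type gene body carrying a LAG-3-type tail
is called HYBRID (the lungfish situation); insufficient evidence is AMBIGUOUS,
never a guess.

A synthetic-data generator plants all of these features class-correctly
(proteins, gene models, synteny tables, expression tables, truth labels), so
the whole pipeline is testable at desk scale without downloads.

## Worked example

Simulate one CD4-1-type and one LAG-3-type gene and classify them with all
evidence sources:

```bash
cd4lag3 simulate --classes CD4-1,LAG-3 --n 1 --seed 7 --outdir demo
cd4lag3 classify --fasta demo/cohort.fasta --gff3 demo/cohort.gff3 \
    --synteny demo/synteny.tsv --tpm demo/expression.tsv --json demo/report.json
```

The report labels `gene_0000` CD4-1 (10 CD4 points vs 0) and `gene_0001`
LAG-3 (0 vs 9), and itemizes why; for the LAG-3 gene:

```json
{
  "gene_id": "gene_0001",
  "label": "LAG-3",
  "cd4_score": 0,
  "lag3_score": 9,
  "contributions": [
    {"feature": "inhibitory",        "points": 3, "rationale": "tail inhibitory motif (ITIM_like)"},
    {"feature": "tail_exon_count",   "points": 2, "rationale": "post-TM tail encoded by a single exon (LAG-3-type organization)"},
    {"feature": "d1_intron_phase",   "points": 2, "rationale": "phase-2 intron internal to the D1 coding sequence"},
    {"feature": "ep_repeat_n",       "points": 1, "rationale": "acidic EP-repeat near the tail end (tetrapod LAG-3 feature)"},
    {"feature": "head_to_tail_role", "points": 1, "rationale": "tandem position upstream of CD4 (ancestral organization)"}
  ]
}
```

The expression criterion on its own, on the shipped nurse-shark thymus/spleen
TPM table:

```bash
$ cd4lag3 expression --tpm tpm.tsv --gene CD4
{"dominant": true, "gene": "CD4", "ratio": 5.414414414414414, "threshold": 5.0}
```

CD4 at 6.01 TPM in thymus vs 1.10 in spleen is a 5.41-fold ratio — above the
five-fold dominance threshold; LAG-3 (0.39 vs 0.43) scores 0.89 and is not
dominant.

Other subcommands: `scan-motifs`, `gene-structure`, `annotate-domains`,
`synteny`, `qpcr`. Every subcommand is a thin wrapper over the library
(`cd4lag3.motif_engine`, `cd4lag3.classifier`, …), which is the primary API.

## Layout

```
src/cd4lag3/
  seq_io.py               FASTA/GFF3/JSON I/O, coordinate conventions
  motif_engine.py         degenerate-motif grammar, scanner, Kozak rule
  gene_structure.py       intron phases, tail exon counts
  domain_architecture.py  Ig-like V/C2 domain detection, architecture strings
  tail_analysis.py        TM location and tail feature extraction
  expression.py           TPM, thymus-dominance, qPCR relative quantification
  synteny.py              head-to-tail tandem-orientation evidence
  classifier.py           evidence weighting, labels, evidence reports
  synthetic_data.py       class-true synthetic cohorts with truth records
  data/                   motif catalogue, nurse-shark TPM table
docs/methods.md           model, parameters, and design notes
```
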