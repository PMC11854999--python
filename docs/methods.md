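# Methods

## Data model and coordinate conventions

All coordinates are 0-based half-open on the forward strand; GenBank and
GFF3 (1-based inclusive) are converted at the I/O boundary, and nothing
downstream ever re-converts. Compound (`join`) locations are collapsed to
their envelope — rhodococcal *alkB* genes are single-exon bacterial CDS, so
nothing is lost — and fuzzy location operators (`<`, `>`) set `is_partial`.
Pseudogenes and partial CDS are kept as *context* genes (their neighborhood
role still matters) but are never focal AlkB candidates.

## Motif model

Four signature histidine motifs are scanned as degenerate patterns over the
20-letter alphabet: per-position allowed sets, with true wildcards at the
`x` positions. `X` in an input sequence matches only wildcard positions; an
unknown residue never satisfies a constraint, so low-quality translations
cannot create spurious family calls.

Two profiles exist. `strict` is the literal discovered pattern set
(`HE[LM]GH[KR]`, `EHN[RHF]GHH`, `NY[LVI]EHY[AG]`, `LQRHSDHHA`);
`generalized` relaxes the interior of motifs 1, 2 and 4 and admits the
AlkB0-type deviations (`HExxH[KR]`, `EHxxGHH`, `NYxEHY[AG]`,
`LQRHxDHH[AT]`). The generalized profile is the default for typing, since
strict scanning systematically misses AlkB0-type proteins.

A protein is called `alkb` when all four motifs occur with strictly
increasing starts and every inter-motif spacing (end of one motif to start
of the next) lies within the configured gap bounds, default **[10, 160]
residues**. The literature gives motif order but not spacing; these bounds
admit any arrangement that fits the observed 349–447 aa protein lengths
while rejecting chance scatter, and the requirement of all four motifs makes
the call robust to the generous upper bound. When a motif matches more than
once, the chain maximizing the number of satisfied gap constraints is
selected, leftmost on ties. Proteins shorter than **300 aa** (default) are
never called, mirroring the standard exclusion of partial sequences.
Proteins with motifs 1, 2 and 4 in order but no HYG motif anywhere are
called `desaturase_like` — the FADS-like superfamily shares eight of the
nine histidines but lacks the HYG motif.

Variant flags are read off the selected hits: motif 1 ending in R
(`M1_terminal_R`, the AlkB0 form), the HYG motif ending in A
(`M3_terminal_A`), motif 4 ending in T (`M4_terminal_T`). Flags are
reported per sequence with no type-level assertion, because the A→T
substitution is only known to affect a fraction of sequences.

Position-frequency profiles anchor every sequence at its selected motif hit
and cover `[-flank, motif_len + flank)`. Information content per column is
`log2(20) − H` (Shannon entropy, bits) with **no small-sample correction**;
a Dirichlet pseudocount parameter is exposed (default 0) because logo
conventions differ between tools and an explicit parameter documents the
choice.

## Context model

Product strings are canonicalized by an ordered keyword lexicon
(first-match-wins) over normalized text — lowercased, with spaces and
hyphen variants removed, so "cold shock", "cold-shock" and "glutamate–tRNA
ligase"/"glutamil t-RNA synthetase" collapse to single keywords. Specific
rules precede general ones (the rubredoxin-reductase forms map to RUBB
before the bare "rubredoxin" rule maps to RUBA). Unmatched products map to
OTHER; empty products to HYPOTHETICAL. A user TSV can prepend override
rules.

Neighborhoods are expressed in the orientation of the focal gene's coding
strand (window default **6 genes per side** — every known per-type
determinant lies within 5 genes, plus slack for transporter/permease
insertions), which makes role sequences invariant under
reverse-complementation of the contig.

**Cluster detection** walks outward from the focal gene over co-directional
genes whose intergenic gap is at most **500 bp** (typical actinobacterial
operon spacing; configurable) and counts RUBA/RUBB in the chain. The walk
also stops at another ALKB-role gene: in dual-locus regions the rubredoxin
genes belong to the neighboring cluster-initiating *alkB*, and without this
stop the second, cluster-less gene would inherit them and be mistyped.
COMPLETE requires ≥2 rubA plus rubB; PARTIAL ≥2 rubA without rubB;
everything else is NONE. "≥2" rather than "exactly 2" is used because the
sources do not state exactness. A single rubA still yields NONE but is
carried in `ruba_count`, because the generalized AlkBR label keys on
rubredoxin co-localization generally (≥1 rubA). rubB without the rubA pair
is surfaced as an anomaly flag rather than forced into a cluster kind.
*alkU* is recorded when co-directional inside the chain or immediately
beyond it in convergent orientation (both layouts occur in real genomes).

**The manA–ahcY region test** requires MANA among the upstream roles and
AHCY among the downstream roles with only region/cluster genes (permease,
FieF, ABC transporter, rubA/rubB, alkU, tobH, manB, DUF3499, or a second
alkB) between the focal gene and the anchors, tolerating at most **2**
unrecognized (OTHER/HYPOTHETICAL) genes per side — unlimited tolerance
would make the region test vacuous, zero would break on the small
insertions seen in real regions.

## Typing precedence

Cluster-based rules fire first (rubredoxin co-localization is the primary
classification parameter), then the region rule for AlkB0, then the
flank-pair rules for the single-gene types; the flank-pair contexts are
mutually exclusive on conforming inputs, so their relative order
(chronological type number) is only a tie-break. AlkB0 accepts *ahcY*
within **2 genes** downstream ("immediately downstream" plus tolerance for
one small insertion; configurable). All satisfied predicates are recorded
in the evidence trail even though only the first decides. The putative
AlkBK/AlkBX groups are deliberately not output labels — they have no
reproducible context determinant — and fall to `unassigned`, which is
reported as "no context evidence", never as a novel type. Phylogenetic
placement is not used: the tool embodies the genomic-context half of the
dual (tree + context) classification criterion, and tree building is left
to standard external tools.

## Identity statistics

`pairwise_identity` uses global (Needleman–Wunsch) alignment with BLOSUM62
and affine gaps (open 10, extend 1, terminal gaps penalized) via biotite;
identity = identical aligned positions / alignment length × 100. The
denominator convention is exposed (`alignment` | `shorter`) because percent
-identity conventions differ between tools. Published within-type identity
matrices are typically computed from multiple-sequence-alignment columns;
pairwise global alignment is a documented approximation that is robust at
the 45–100% range these statistics live in. An independent Gotoh dynamic-
programming oracle in the test suite checks both optimal scores and, on
substitution-only pairs (where the optimum is gap-free and unique),
identities to 1e-9.

## Synthetic fixtures

The generator is a pure function of (label, seed, config); identical inputs
give byte-identical GenBank output (the file date is pinned for this
reason). Focal proteins are 349–447 aa with the four motifs placed at
seeded offsets; inter-motif gaps are drawn from [10, 90] — inside the
scanner's [10, 160] bounds with margin. Filler residues are uniform over 18
amino acids **excluding H and W**: every signature motif requires
histidine, so accidental motifs are impossible by construction (a re-scan
at generation time enforces exactly one hit per motif anyway). Intergenic
gaps are 50 bp within clusters and 700 bp between unrelated genes — safely
inside and outside the 500 bp chaining threshold. CDS nucleotide sequences
are back-translated with uniform synonymous codon choice under the seed
(codon bias is irrelevant to the method).

What the fixtures do **not** emulate: sequencing error, pseudogenization,
annotation noise in product strings beyond the lexicon's spelling
normalization, genuine sequence evolution, or multi-contig fragmentation of
a region. Passing the fixture suite therefore demonstrates the correctness
of the rule logic and its invariances, not robustness to noisy real-world
annotation text, which the lexicon override file exists to patch case by
case.

The dataset generator assigns one synthetic species per label and plants a
configurable fraction of deviant genomes (species name from one label,
neighborhood from another); the species-set consistency check must flag
exactly those and suggest the species whose modal set matches.

## Problem sizes

The test suite and the acceptance script run the complete pipeline on
60 truth-labeled genomes (12 assignable labels × 5 seeds), 15 decoy
genomes, 200 random 400-aa proteins for the motif-scanner oracle, and 20
random pairs for the alignment oracle — sizes at which every check is
exhaustive rather than sampled, and the whole acceptance run completes in a
few seconds on one CPU.

## Known limitations

* Typing is context-only; a genome whose *alkB* context was rearranged or
  truncated by the assembly will fall to `unassigned` even when phylogeny
  would place it.
* The region with *alkU* convergent to *alkB* and *rubB* present but no
  rubA pair (observed once in the wild) is reported as NONE with an anomaly
  flag, not reclassified.
* Product-string canonicalization is keyword-based; exotic annotation
  vocabularies need lexicon overrides.
* De-novo motif discovery is out of scope; the scanner only applies the
  published motif set and its generalized forms.
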