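# alkbtyper

Detection and genomic-context typing of AlkB family alkane monooxygenases
(alkane 1-monooxygenases, EC 1.14.15.3) in annotated *Rhodococcus*-like
bacterial genomes.

## The problem

Rhodococci and their relatives are prolific alkane degraders and often carry
several chromosomal copies of *alkB*, the gene for the membrane-bound
non-heme diiron alkane hydroxylase. New "types" of rhodococcal AlkB keep
being proposed from small sets of (often partial) sequences, which fragments
the nomenclature. Two genomic observations give a more stable basis for
classification:

* **Rubredoxin co-localization.** Many *alkB* genes sit in an operon-like
  cluster with two rubredoxin genes (*rubA*) — the electron carriers of
  alkane hydroxylation — plus, in the *complete* cluster, the rubredoxin
  reductase gene *rubB*, and usually the TetR/AraC-family regulator *alkU*.
  The *partial* cluster lacks *rubB*.
* **The conserved *manA*–*ahcY* region.** A chromosomal region bounded by
  mannose-6-phosphate isomerase (*manA*) upstream and adenosylhomocysteinase
  (*ahcY*) downstream hosts the partial cluster and, in some genomes, a
  lone *alkB* immediately upstream of *ahcY*.

`alkbtyper` turns these observations into a reproducible annotation tool. It

1. finds AlkB candidates in protein sequences through the four signature
   histidine motifs
   `HE[LM]GH[KR]`, `EHN[RHF]GHH`, `NY[LVI]EHY[AG]`, `LQRHSDHHA`
   (nine histidines coordinating the diiron active site; the third, "HYG"
   motif distinguishes alkane monooxygenases from desaturase-like proteins
   that share the other histidines), including relaxed generalized forms
   `HExxH[KR]`, `EHxxGHH`, `NYxEHY[AG]`, `LQRHxDHH[AT]` that admit the
   AlkB0-type deviations (terminal arginine in motif 1, A→T in motif 4);
2. canonicalizes the flanking gene annotations into role tokens, detects
   rubredoxin clusters and the *manA*–*ahcY* region, and assigns one of the
   types AlkB0–AlkB9, AlkB1A, AlkB2N (or `unassigned`) by a fixed rule
   precedence, plus the generalized label **AlkBR** (rubredoxin
   co-localized: AlkB1, AlkB1A, AlkB2, AlkB2N) or **AlkBS** (single);
3. aggregates calls into per-genome copy-number profiles, checks that
   genomes of one species carry the same type set (flagging likely species
   misassignments), and computes within-type pairwise identities from
   global alignments;
4. generates deterministic, truth-labeled synthetic genomes (GenBank) that
   realize every typing rule and decoy class, so the whole pipeline is
   testable without downloads.

## Worked example

Simulate a dual-locus *manA*–*ahcY* region (a partial cluster followed by a
second, cluster-less *alkB* right before *ahcY*) and type it:

```sh
alkbtyper simulate --label antrihabitans_dual --seed 7 --out demo/
alkbtyper type demo/antrihabitans_dual_s700021.gbff -o demo/report.tsv
```

The report (columns trimmed):

```text
locus_tag                        alkb_type  generalized  cluster  motif_variant_flags
antrihabitans_dual_..._g006      AlkB2      AlkBR        PARTIAL
antrihabitans_dual_..._g008      AlkB0      AlkBS        NONE     M1_terminal_R;M3_terminal_A
```

The first *alkB* heads a partial rubredoxin cluster inside the
*manA*–*ahcY* region → AlkB2, generalized AlkBR. The second has no
rubredoxin genes of its own (the walk stops at the neighboring *alkB*
cluster), sits in the region with *ahcY* immediately downstream → AlkB0,
AlkBS; its protein carries the AlkB0 motif deviations (motif 1 ends in R,
the HYG motif ends in A), which the `motif_variant_flags` column reports.

Other entry points: `alkbtyper scan` (motif screening of a protein FASTA),
`alkbtyper profile` (copy-number and species-set tables from typing
reports), `alkbtyper logo` (per-column residue frequencies and information
content around a motif). Every output begins with a comment header echoing
the resolved configuration; rerunning with the same inputs reproduces the
file byte for byte.

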