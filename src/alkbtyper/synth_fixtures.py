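"""Deterministic truth-labeled synthetic genomes and proteins.

The generator emulates the canonical per-type gene neighborhoods of
Rhodococcus-like alkB loci so the whole pipeline is testable offline:
focal proteins are 349-447 aa sequences carrying the four signature
histidine motifs in order (with the AlkB0 variant residues on request),
context genes carry product strings matching the built-in role lexicon,
and decoy classes (desaturase-like proteins lacking the HYG motif,
truncated proteins, context-less alkB genes) exercise the negative paths.

Generation is a pure function of (label, seed, config): identical inputs
give byte-identical output.  Filler protein sequence is drawn uniformly
from 18 residues excluding histidine and tryptophan, which makes
accidental signature motifs impossible (every motif requires H); planted
motifs are re-scanned after generation as a belt-and-braces check.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

from Bio.Data import CodonTable

from .core import GeneFeature, GenomeRecord, revcomp, reverse_complement_record
from .genome_io import write_genbank
from .motif_scan import MOTIF_IDS, default_patterns, evaluate_family

#: Background residue alphabet: 20 standard minus H (kills every signature
#: motif) and W (rare; keeps filler unremarkable).
BACKGROUND_AA = "ACDEFGIKLMNPQRSTVY"

ASSIGNABLE_LABELS = (
    "AlkB0", "AlkB1", "AlkB1A", "AlkB2", "AlkB2N", "AlkB3", "AlkB4",
    "AlkB5", "AlkB6", "AlkB7", "AlkB8", "AlkB9",
)
DECOY_LABELS = ("desaturase_like", "truncated", "context_less")

LENGTH_RANGE = (349, 447)

_BACK_TABLE: dict[str, list[str]] = {}
for codon, aa in CodonTable.unambiguous_dna_by_id[11].forward_table.items():
    _BACK_TABLE.setdefault(aa, []).append(codon)
for aa in _BACK_TABLE:
    _BACK_TABLE[aa].sort()
_STOP_CODONS = sorted(CodonTable.unambiguous_dna_by_id[11].stop_codons)


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for one synthetic focal protein."""

    label: str = "canonical"  # canonical | alkb0 | m4_thr | desaturase_like | truncated
    seed: int = 0
    length: int | None = None
    gap_bounds: tuple[int, int] = (10, 160)


def _motif_strings(variant: str, rng: random.Random) -> dict[str, str]:
    if variant == "alkb0":
        # strict M1 HE[LM]GH[KR] must fail: middle positions off-pattern,
        # terminal R; HYG motif ends in A.
        mid1 = rng.choice([c for c in BACKGROUND_AA if c not in "LM"])
        mid2 = rng.choice([c for c in BACKGROUND_AA if c != "G"])
        m1 = "HE" + mid1 + mid2 + "HR"
        m3 = "NY" + rng.choice("LVI") + "EHYA"
    else:
        m1 = "HE" + rng.choice("LM") + "GHK"
        m3 = "NY" + rng.choice("LVI") + "EHYG"
    m2 = "EHN" + rng.choice("RHF") + "GHH"
    m4 = "LQRHSDHHT" if variant == "m4_thr" else "LQRHSDHHA"
    return {"M1": m1, "M2": m2, "M3": m3, "M4": m4}


def _bg(rng: random.Random, n: int) -> str:
    return "".join(rng.choice(BACKGROUND_AA) for _ in range(n))


def make_alkb_protein(spec: FixtureSpec) -> str:
    """A synthetic AlkB(-like) protein per the fixture spec.

    Canonical and alkb0 variants carry all four motifs in order with gaps
    inside the configured bounds; the desaturase_like decoy omits the HYG
    motif; the truncated decoy squeezes all motifs into fewer than 300
    residues.  The generated sequence is re-scanned and regenerated (with a
    derived seed) in the unlikely event of an accidental extra hit.
    """
    for attempt in range(25):
        rng = random.Random(f"{spec.seed}|{spec.label}|{attempt}")
        seq = _assemble(spec, rng)
        if seq is not None and _verify(seq, spec):
            return seq
    raise RuntimeError(f"could not generate a clean fixture protein for {spec}")


def _assemble(spec: FixtureSpec, rng: random.Random) -> str | None:
    lo, hi = spec.gap_bounds
    if spec.label == "truncated":
        length = spec.length or 250
        gap_hi = min(hi, 55)
    else:
        length = spec.length or rng.randint(*LENGTH_RANGE)
        gap_hi = min(hi, 90)
    if gap_hi < lo:
        raise ValueError(f"infeasible gap bounds {spec.gap_bounds} for {spec.label}")
    motifs = _motif_strings(
        spec.label if spec.label in ("alkb0", "m4_thr") else "canonical", rng
    )
    order = ["M1", "M2", "M4"] if spec.label == "desaturase_like" else list(MOTIF_IDS)
    n_gaps = len(order) - 1
    gaps = [rng.randint(lo, gap_hi) for _ in range(n_gaps)]
    span = sum(len(motifs[m]) for m in order) + sum(gaps)
    rest = length - span
    if rest < 10:
        return None
    lead = rng.randint(5, rest - 5)
    parts = [_bg(rng, lead)]
    for k, m in enumerate(order):
        parts.append(motifs[m])
        if k < n_gaps:
            parts.append(_bg(rng, gaps[k]))
    parts.append(_bg(rng, rest - lead))
    return "".join(parts)


def _verify(seq: str, spec: FixtureSpec) -> bool:
    patterns = default_patterns("generalized", spec.gap_bounds)
    ev = evaluate_family(seq, patterns, min_length=300)
    if spec.label == "desaturase_like":
        return ev.family_call == "desaturase_like"
    if spec.label == "truncated":
        return ev.family_call == "none" and len(seq) < 300
    if ev.family_call != "alkb":
        return False
    # exactly one hit per motif: no accidental occurrences
    return all(len(ev.all_hits.get(m, [])) == 1 for m in MOTIF_IDS)


# --- genome fixtures ---------------------------------------------------------

#: Within-cluster intergenic gap (bp): safely inside the 500 bp chaining
#: threshold.  Unrelated genes sit 700 bp apart: safely outside it.
CLUSTER_GAP = 50
LOOSE_GAP = 700

_PRODUCTS = {
    "alkB": "alkane 1-monooxygenase",
    "rubA": "rubredoxin",
    "rubB": "rubredoxin reductase RubB",
    "alkU": "TetR family transcriptional regulator AlkU",
    "manA": "mannose-6-phosphate isomerase",
    "ahcY": "adenosylhomocysteinase",
    "permease": "amino acid permease",
    "fieF": "cation diffusion facilitator transporter FieF",
    "sortase": "class F sortase",
    "gltX": "glutamate--tRNA ligase",
    "aminotransferase": "aspartate aminotransferase",
    "coldshock": "cold-shock protein",
    "abiEi": "AbiEi family antitoxin domain-containing protein",
    "abc": "ABC transporter ATP-binding protein",
    "abhydrolase": "alpha/beta hydrolase",
    "aaa": "ATP-binding protein",
    "menH": "alpha/beta fold hydrolase MenH",
    "mshA": "inositol-3-phosphate glycosyltransferase MshA",
    "rok": "ROK family transcriptional regulator",
    "merR": "MerR family transcriptional regulator",
    "feS": "CDGSH iron-sulfur domain-containing protein",
    "hyp": "hypothetical protein",
    "gaf": "GAF and ANTAR domain-containing protein",
    "thymidylate": "thymidylate kinase",
    "desaturase": "fatty acid desaturase",
    "filler": "DUF1234 domain-containing protein",
}

# Canonical neighborhood layout per label, in genomic order.  Entries are
# (gene key, gap class) where gap class "c" means cluster spacing to the
# previous gene and "l" loose spacing.  "*" marks focal alkB genes; "*0"
# an AlkB0-variant focal; "*t" a truncated focal; "*d" a desaturase decoy.
_LAYOUTS: dict[str, list[tuple[str, str]]] = {
    "AlkB0": [("manA", "c"), ("permease", "c"), ("*", "c"), ("ahcY", "c"), ("thymidylate", "c")],
    "AlkB1": [("*", "l"), ("rubA", "c"), ("rubA", "c"), ("rubB", "c"), ("alkU", "c")],
    "AlkB1A": [
        ("manA", "c"), ("permease", "c"), ("*", "c"), ("rubA", "c"),
        ("rubA", "c"), ("rubB", "c"), ("alkU", "c"), ("ahcY", "c"),
    ],
    "AlkB2": [
        ("manA", "c"), ("rubA", "c"), ("rubA", "c"), ("*", "c"),
        ("alkU", "c"), ("ahcY", "c"),
    ],
    "AlkB2N": [("*", "l"), ("rubA", "c"), ("rubA", "c"), ("alkU", "c")],
    "AlkB3": [("*", "l"), ("sortase", "c")],
    "AlkB4": [("*", "l"), ("gltX", "c")],
    "AlkB5": [("aminotransferase", "c"), ("coldshock", "c"), ("*", "c"), ("abiEi", "c")],
    "AlkB6": [("abc", "c"), ("*", "c")],
    "AlkB7": [("abhydrolase", "c"), ("*", "c"), ("aaa", "c")],
    "AlkB8": [("menH", "c"), ("mshA", "c"), ("*", "c"), ("rok", "c")],
    "AlkB9": [("merR", "c"), ("feS", "c"), ("*", "c"), ("hyp", "c"), ("gaf", "c")],
    "antrihabitans_dual": [
        ("manA", "c"), ("rubA", "c"), ("rubA", "c"), ("*", "c"),
        ("alkU", "c"), ("*0", "c"), ("ahcY", "c"),
    ],
    "desaturase_like": [("*d", "l")],
    "truncated": [("*t", "l")],
    "context_less": [("*", "l")],
}

#: Truth labels per focal gene, in genomic order of the focal genes.
_TRUTH: dict[str, list[str]] = {
    **{lab: [lab] for lab in ASSIGNABLE_LABELS},
    "antrihabitans_dual": ["AlkB2", "AlkB0"],
    "desaturase_like": [],
    "truncated": [],
    "context_less": ["unassigned"],
}

#: Focal protein variant per label (the AlkB0 context carries the motif
#: deviations observed for that type).
_FOCAL_VARIANT = {"AlkB0": "alkb0"}


def _backtranslate(prot: str, rng: random.Random) -> str:
    nt = "".join(rng.choice(_BACK_TABLE[aa]) for aa in prot)
    return nt + rng.choice(_STOP_CODONS)


def _rand_nt(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(n))


def make_genome_fixture(
    label: str,
    seed: int,
    n_filler: int = 2,
    strand_flip: bool = False,
    alku_convergent: bool = False,
    out_path=None,
) -> tuple[GenomeRecord, list[tuple[str, str, str]]]:
    """One synthetic contig realizing a label's canonical neighborhood.

    Returns the genome and its truth table: (locus_tag, expected_type,
    label) rows for the focal genes.  ``n_filler`` unrelated genes pad each
    end; ``strand_flip`` emits the mirror-image contig (identical truth
    labels); ``alku_convergent`` flips the alkU gene to the convergent
    orientation seen in e.g. R. ruber.  With ``out_path`` set, the genome
    is also written as a GenBank file.
    """
    if label not in _LAYOUTS:
        raise ValueError(f"unknown fixture label {label!r}")
    rng = random.Random(f"{seed}|{label}|genome")
    genome_id = f"{label}_s{seed}"
    contig_id = f"{genome_id}_c1"
    layout = [("filler", "l")] * n_filler + _LAYOUTS[label] + [("filler", "l")] * n_filler

    seq_parts: list[str] = []
    feats: list[GeneFeature] = []
    pos = 0
    focal_idx = 0
    truth: list[tuple[str, str, str]] = []
    lead = _rand_nt(rng, 300)
    seq_parts.append(lead)
    pos += len(lead)
    for gi, (key, gapclass) in enumerate(layout):
        if gi > 0:
            gap = CLUSTER_GAP if gapclass == "c" else LOOSE_GAP
            seq_parts.append(_rand_nt(rng, gap))
            pos += gap
        if key.startswith("*"):
            variant = {
                "*": _FOCAL_VARIANT.get(label, "canonical"),
                "*0": "alkb0",
                "*t": "truncated",
                "*d": "desaturase_like",
            }[key]
            prot_label = variant if variant in ("truncated", "desaturase_like") else variant
            prot = make_alkb_protein(
                FixtureSpec(label=prot_label, seed=rng.randrange(2**31 - 1))
            )
            product = _PRODUCTS["desaturase" if key == "*d" else "alkB"]
            if key != "*d":
                focal_idx += 1
                if key in ("*", "*0") and label != "desaturase_like":
                    expected = _TRUTH[label]
                    if expected:
                        truth.append(
                            (f"{genome_id}_g{gi + 1:03d}", expected[focal_idx - 1], label)
                        )
        else:
            prot = _bg(rng, rng.randint(80, 200))
            product = _PRODUCTS[key]
        strand = "+"
        if alku_convergent and key == "alkU":
            strand = "-"
        nt = _backtranslate(prot, rng)
        if strand == "-":
            nt = revcomp(nt)
        feats.append(
            GeneFeature(
                contig_id=contig_id,
                start=pos,
                end=pos + len(nt),
                strand=strand,
                locus_tag=f"{genome_id}_g{gi + 1:03d}",
                product=product,
                translation=prot,
            )
        )
        seq_parts.append(nt)
        pos += len(nt)
    tail = _rand_nt(rng, 300)
    seq_parts.append(tail)
    pos += len(tail)

    genome = GenomeRecord(
        genome_id=genome_id,
        organism=f"Synthococcus {label.lower()}",
        contigs={contig_id: feats},
        contig_lengths={contig_id: pos},
        contig_sequences={contig_id: "".join(seq_parts)},
    )
    if strand_flip:
        genome = reverse_complement_record(genome)
    if out_path is not None:
        write_genbank(genome, out_path)
    return genome, truth


def make_dataset(
    n_genomes: int,
    type_mix: dict[str, float],
    seed: int,
    deviant_fraction: float = 0.0,
    out_dir=None,
) -> dict:
    """A deterministic multi-genome dataset with species labels.

    Genome counts per label follow ``type_mix`` (proportions summing to 1)
    by largest-remainder allocation.  Each label defines a synthetic
    species whose genomes carry that label's neighborhood, except a planted
    ``deviant_fraction`` of genomes which keep their species name but carry
    a different label's layout — exactly those genomes must be flagged by
    the species-set consistency check.  With ``out_dir`` set, writes one
    .gbff per genome plus truth.tsv.
    """
    total = sum(type_mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"type_mix proportions sum to {total}, expected 1")
    labels = sorted(type_mix)
    counts = {lab: int(n_genomes * type_mix[lab]) for lab in labels}
    remainders = sorted(
        labels, key=lambda l: (n_genomes * type_mix[l]) % 1, reverse=True
    )
    i = 0
    while sum(counts.values()) < n_genomes:
        counts[remainders[i % len(remainders)]] += 1
        i += 1

    assignment = [lab for lab in labels for _ in range(counts[lab])]
    rng = random.Random(f"{seed}|dataset")
    n_dev = int(round(deviant_fraction * n_genomes))
    deviant_ids = sorted(rng.sample(range(n_genomes), n_dev)) if n_dev else []

    records, truth_rows, species_map = [], [], {}
    deviant_genomes = []
    for gi, lab in enumerate(assignment):
        species = f"Synthococcus {lab.lower()}"
        layout_label = lab
        if gi in deviant_ids:
            others = [l for l in labels if l != lab] or [lab]
            layout_label = others[rng.randrange(len(others))]
        gseed = (seed * 100003 + gi) % (2**31 - 1)
        genome, truth = make_genome_fixture(layout_label, gseed)
        genome.genome_id = f"G{gi:03d}_{layout_label}"
        # re-key contig ids under the dataset-level genome id
        genome = _rename(genome)
        species_map[genome.genome_id] = species
        if gi in deviant_ids:
            deviant_genomes.append(genome.genome_id)
        for locus, expected, _ in truth:
            truth_rows.append((genome.genome_id, species, expected))
        records.append(genome)
        if out_dir is not None:
            out_dir = Path(out_dir)
            out_dir.mkdir(parents=True, exist_ok=True)
            write_genbank(genome, out_dir / f"{genome.genome_id}.gbff")
    if out_dir is not None:
        with open(Path(out_dir) / "truth.tsv", "w") as fh:
            fh.write("genome_id\tspecies\texpected_type\n")
            for row in truth_rows:
                fh.write("\t".join(row) + "\n")
    return {
        "records": records,
        "species": species_map,
        "truth": truth_rows,
        "deviants": deviant_genomes,
    }


def _rename(genome: GenomeRecord) -> GenomeRecord:
    """Rebuild contig/locus ids under the genome's (possibly changed) id."""
    from dataclasses import replace

    new_contigs, new_lengths, new_seqs = {}, {}, {}
    for old_cid, feats in genome.contigs.items():
        cid = f"{genome.genome_id}_c1"
        new_feats = [
            replace(
                f,
                contig_id=cid,
                locus_tag=f"{genome.genome_id}_g{k + 1:03d}",
            )
            for k, f in enumerate(feats)
        ]
        new_contigs[cid] = new_feats
        new_lengths[cid] = genome.contig_lengths[old_cid]
        if old_cid in genome.contig_sequences:
            new_seqs[cid] = genome.contig_sequences[old_cid]
    return GenomeRecord(
        genome_id=genome.genome_id,
        organism=genome.organism,
        contigs=new_contigs,
        contig_lengths=new_lengths,
        contig_sequences=new_seqs,
    )


def make_context_genome(
    products: list[str], seed: int = 0, genome_id: str = "ctx", spacing: int = 50
) -> tuple[GenomeRecord, GeneFeature]:
    """A one-contig genome realizing an explicit product-string context.

    ``products`` lists gene products in genomic order with ``"*"`` marking
    the focal alkB gene (which gets a generated canonical AlkB protein);
    all genes are co-directional with ``spacing`` bp between them.  Returns
    the genome and the focal feature.  Useful for encoding printed contexts
    of previously described loci.
    """
    rng = random.Random(f"{seed}|{genome_id}|context")
    contig_id = f"{genome_id}_c1"
    feats: list[GeneFeature] = []
    pos = 200
    focal: GeneFeature | None = None
    for gi, product in enumerate(products):
        if product == "*":
            prot = make_alkb_protein(FixtureSpec(seed=rng.randrange(2**31 - 1)))
            product = _PRODUCTS["alkB"]
            is_focal = True
        else:
            prot = _bg(rng, rng.randint(80, 200))
            is_focal = False
        length_nt = 3 * (len(prot) + 1)
        feat = GeneFeature(
            contig_id=contig_id,
            start=pos,
            end=pos + length_nt,
            strand="+",
            locus_tag=f"{genome_id}_g{gi + 1:03d}",
            product=product,
            translation=prot,
        )
        feats.append(feat)
        if is_focal:
            focal = feat
        pos += length_nt + spacing
    if focal is None:
        raise ValueError("products must contain one '*' focal marker")
    genome = GenomeRecord(
        genome_id=genome_id,
        contigs={contig_id: feats},
        contig_lengths={contig_id: pos + 200},
    )
    return genome, genome.find(contig_id, focal.locus_tag)
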