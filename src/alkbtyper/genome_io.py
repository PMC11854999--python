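"""Reading annotated genomes and writing typing reports.

GenBank flat files and GFF3+FASTA are converted into the internal 0-based
half-open data model at this boundary; typing results go out as TSV reports
and annotated GFF3.
"""

from __future__ import annotations

import warnings
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import (
    AfterPosition,
    BeforePosition,
    SeqFeature,
    SimpleLocation,
)
from Bio.SeqRecord import SeqRecord

from .core import AA_WITH_X, GeneFeature, GenomeRecord
from .typing_rules import TypeCall

REPORT_COLUMNS = [
    "genome_id",
    "contig_id",
    "locus_tag",
    "start",
    "end",
    "strand",
    "alkb_type",
    "generalized_type",
    "cluster_kind",
    "motif_variant_flags",
    "evidence",
]


def _clean_translation(raw: str | None, locus: str) -> tuple[str | None, bool]:
    """Uppercase a translation, mapping rare non-standard letters to X."""
    if raw is None:
        return None, False
    seq = raw.upper().replace("*", "").replace("-", "")
    cleaned = "".join(c if c in AA_WITH_X else "X" for c in seq)
    if cleaned != seq:
        warnings.warn(f"{locus}: non-standard residues replaced with X")
    return cleaned or None, cleaned != seq


def _feature_from_genbank(feat, contig_id: str, index: int) -> GeneFeature | None:
    loc = feat.location
    if loc is None:
        return None
    start = int(min(p.start for p in loc.parts))
    end = int(max(p.end for p in loc.parts))
    strand = "-" if loc.strand == -1 else "+"
    fuzzy = any(
        isinstance(p.start, BeforePosition) or isinstance(p.end, AfterPosition)
        for p in loc.parts
    )
    quals = feat.qualifiers
    locus = quals.get("locus_tag", [f"{contig_id}_cds{index}"])[0]
    product = quals.get("product", [""])[0]
    translation, _ = _clean_translation(quals.get("translation", [None])[0], locus)
    is_pseudo = "pseudo" in quals or "pseudogene" in quals
    is_partial = fuzzy or "partial" in quals
    return GeneFeature(
        contig_id=contig_id,
        start=start,
        end=end,
        strand=strand,
        locus_tag=locus,
        product=product,
        translation=translation,
        is_partial=is_partial,
        is_pseudo=is_pseudo,
    )


def read_genbank(path) -> GenomeRecord:
    """Parse a GenBank flat file into a GenomeRecord.

    GenBank 1-based inclusive coordinates become 0-based half-open (handled
    by the parser); compound (join) locations collapse to their envelope
    with ``is_partial`` set when fuzzy operators (<, >) appear.  A record
    with zero CDS yields an empty genome with a warning.
    """
    path = Path(path)
    contigs: dict[str, list[GeneFeature]] = {}
    lengths: dict[str, int] = {}
    seqs: dict[str, str] = {}
    organism = None
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise ValueError(f"unparsable GenBank file {path}: {exc}") from exc
    if not records:
        raise ValueError(f"unparsable GenBank file {path}: no LOCUS record found")
    n_cds = 0
    for rec in records:
        organism = organism or rec.annotations.get("organism")
        feats = []
        for i, f in enumerate(rec.features):
            if f.type != "CDS":
                continue
            gf = _feature_from_genbank(f, rec.id, i)
            if gf is not None:
                feats.append(gf)
                n_cds += 1
        contigs[rec.id] = feats
        lengths[rec.id] = len(rec.seq)
        try:
            seqs[rec.id] = str(rec.seq)
        except Exception:  # contig without sequence (CONTIG/skipped)
            pass
    if n_cds == 0:
        warnings.warn(f"{path}: no CDS features found")
    return GenomeRecord(
        genome_id=path.stem,
        organism=organism,
        contigs=contigs,
        contig_lengths=lengths,
        contig_sequences=seqs,
    )


def _parse_gff_attributes(text: str) -> dict[str, str]:
    out = {}
    for part in text.strip().split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def read_gff_fasta(gff_path, fasta_path) -> GenomeRecord:
    """Parse GFF3 CDS features with their genomic FASTA.

    Translations absent from the GFF are computed from the contig sequence
    with the bacterial genetic code (table 11); CDS whose length is not a
    multiple of three are flagged partial.  GFF 1-based inclusive
    coordinates become 0-based half-open.
    """
    gff_path, fasta_path = Path(gff_path), Path(fasta_path)
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    contigs: dict[str, list[GeneFeature]] = {c: [] for c in seqs}
    missing: set[str] = set()
    idx = 0
    with open(gff_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 8 or fields[2] != "CDS":
                continue
            seqid, _, _, start1, end1, _, strand, phase = fields[:8]
            attrs = _parse_gff_attributes(fields[8]) if len(fields) > 8 else {}
            if seqid not in seqs:
                missing.add(seqid)
                continue
            idx += 1
            start, end = int(start1) - 1, int(end1)
            locus = attrs.get("locus_tag") or attrs.get("ID") or f"{seqid}_cds{idx}"
            is_partial = attrs.get("partial", "").lower() == "true"
            length = end - start
            if length % 3 != 0:
                warnings.warn(f"{locus}: CDS length {length} not a multiple of 3; flagged partial")
                is_partial = True
            nt = seqs[seqid][start:end]
            if strand == "-":
                nt = str(Seq(nt).reverse_complement())
            usable = nt[: 3 * (len(nt) // 3)]
            translation = str(Seq(usable).translate(table=11)).rstrip("*")
            translation, _ = _clean_translation(translation, locus)
            contigs[seqid].append(
                GeneFeature(
                    contig_id=seqid,
                    start=start,
                    end=end,
                    strand="-" if strand == "-" else "+",
                    locus_tag=locus,
                    product=attrs.get("product", ""),
                    translation=translation,
                    is_partial=is_partial,
                    is_pseudo="pseudo" in attrs or attrs.get("pseudo", "") == "true",
                )
            )
    if missing:
        raise ValueError(
            f"GFF seqids absent from FASTA {fasta_path}: {', '.join(sorted(missing))}"
        )
    return GenomeRecord(
        genome_id=gff_path.stem,
        contigs=contigs,
        contig_lengths={c: len(s) for c, s in seqs.items()},
        contig_sequences=seqs,
    )


def write_genbank(genome: GenomeRecord, path) -> None:
    """Write a GenomeRecord back to a GenBank flat file (deterministic bytes)."""
    records = []
    for cid, feats in genome.contigs.items():
        seq = genome.contig_sequences.get(cid)
        if seq is None:
            length = genome.contig_lengths.get(
                cid, max((f.end for f in feats), default=0)
            )
            seq = "N" * length
        rec = SeqRecord(Seq(seq), id=cid, name=cid[:16], description="")
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = "linear"
        rec.annotations["date"] = "01-JAN-2025"  # fixed: byte-identical output
        if genome.organism:
            rec.annotations["organism"] = genome.organism
            rec.annotations["source"] = genome.organism
        for f in feats:
            quals = {"locus_tag": [f.locus_tag], "transl_table": ["11"]}
            if f.product:
                quals["product"] = [f.product]
            if f.translation is not None:
                quals["translation"] = [f.translation]
            if f.is_pseudo:
                quals["pseudo"] = [""]
            start = BeforePosition(f.start) if f.is_partial else f.start
            loc = SimpleLocation(start, f.end, strand=1 if f.strand == "+" else -1)
            rec.features.append(SeqFeature(loc, type="CDS", qualifiers=quals))
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "genbank")


def write_typing_report(calls: list[TypeCall], path_or_handle) -> None:
    """Tab-separated typing report, one row per call.

    Rows are ordered by (genome, contig, start); an empty call list yields a
    header-only file.
    """
    rows = sorted(
        calls, key=lambda c: (c.genome_id, c.feature.contig_id, c.feature.start)
    )
    own = not hasattr(path_or_handle, "write")
    fh = open(path_or_handle, "w") if own else path_or_handle
    try:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for c in rows:
            flags = (
                ";".join(k for k, v in sorted(c.motif_evidence.variant_flags.items()) if v)
                if c.motif_evidence is not None
                else ""
            )
            fh.write(
                "\t".join(
                    [
                        c.genome_id,
                        c.feature.contig_id,
                        c.feature.locus_tag,
                        str(c.feature.start),
                        str(c.feature.end),
                        c.feature.strand,
                        c.alkb_type,
                        c.generalized,
                        c.cluster.kind,
                        flags,
                        "; ".join(c.evidence),
                    ]
                )
                + "\n"
            )
    finally:
        if own:
            fh.close()


def write_annotated_gff(genome: GenomeRecord, calls: list[TypeCall], path) -> None:
    """GFF3 of all CDS features with alkb_type attributes on typed loci."""
    by_key = {c.feature.key: c for c in calls}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for cid, feats in genome.contigs.items():
            for f in feats:
                attrs = [f"ID={f.locus_tag}", f"locus_tag={f.locus_tag}"]
                if f.product:
                    attrs.append(f"product={f.product}")
                call = by_key.get(f.key)
                if call is not None:
                    attrs.append(f"alkb_type={call.alkb_type}")
                    attrs.append(f"generalized_type={call.generalized}")
                    attrs.append(f"cluster_kind={call.cluster.kind}")
                fh.write(
                    "\t".join(
                        [
                            cid,
                            "alkbtyper",
                            "CDS",
                            str(f.start + 1),
                            str(f.end),
                            ".",
                            f.strand,
                            "0",
                            ";".join(attrs),
                        ]
                    )
                    + "\n"
                )
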