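"""Internal data model: gene features and genome records.

All coordinates are 0-based half-open on the forward strand of the contig;
GenBank and GFF3 (1-based inclusive) are converted at the I/O boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")
AA_WITH_X = AA_ALPHABET | {"X"}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def revcomp(seq: str) -> str:
    """Reverse-complement a nucleotide string (IUPAC letters)."""
    return seq.upper().translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """One annotated CDS: the atom of genomic context.

    ``start``/``end`` are 0-based half-open genomic coordinates; ``strand``
    is ``'+'`` or ``'-'``. ``translation`` is the amino-acid sequence
    (20 standard residues plus X) or ``None`` when the annotation carries
    none. ``is_partial`` marks truncated CDS (fuzzy location operators,
    non-triplet length, or contig-edge truncation).
    """

    contig_id: str
    start: int
    end: int
    strand: str
    locus_tag: str
    product: str = ""
    translation: str | None = None
    is_partial: bool = False
    is_pseudo: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.locus_tag}: invalid coordinates {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.locus_tag}: strand must be '+' or '-', got {self.strand!r}")
        if self.translation is not None:
            bad = set(self.translation) - AA_WITH_X
            if bad:
                raise ValueError(
                    f"{self.locus_tag}: translation contains non-standard residues {sorted(bad)}"
                )

    @property
    def key(self) -> tuple[str, int, int, str]:
        return (self.contig_id, self.start, self.end, self.strand)


@dataclass
class GenomeRecord:
    """An annotated genome: ordered CDS features per contig.

    Features within a contig are kept sorted by (start, end); duplicates by
    (contig, start, end, strand) are dropped with a warning on construction.
    """

    genome_id: str
    organism: str | None = None
    contigs: dict[str, list[GeneFeature]] = field(default_factory=dict)
    contig_lengths: dict[str, int] = field(default_factory=dict)
    contig_sequences: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, feats in self.contigs.items():
            seen: set[tuple] = set()
            unique = []
            for f in sorted(feats, key=lambda f: (f.start, f.end)):
                if f.key in seen:
                    warnings.warn(
                        f"{self.genome_id}/{cid}: duplicate feature at "
                        f"{f.start}..{f.end}({f.strand}) dropped"
                    )
                    continue
                seen.add(f.key)
                unique.append(f)
            length = self.contig_lengths.get(cid)
            if length is not None:
                for f in unique:
                    if f.end > length:
                        raise ValueError(
                            f"{self.genome_id}/{cid}: feature {f.locus_tag} ends at "
                            f"{f.end} beyond contig length {length}"
                        )
            self.contigs[cid] = unique

    def features(self) -> list[GeneFeature]:
        """All features in deterministic (contig, start) order."""
        out: list[GeneFeature] = []
        for cid in self.contigs:
            out.extend(self.contigs[cid])
        return out

    def find(self, contig_id: str, locus_tag: str) -> GeneFeature:
        for f in self.contigs.get(contig_id, []):
            if f.locus_tag == locus_tag:
                return f
        raise KeyError(f"{locus_tag} not found on {contig_id}")


def reverse_complement_record(genome: GenomeRecord) -> GenomeRecord:
    """Mirror-image a genome: flip every contig's coordinates and strands.

    Useful for strand-involution checks: neighborhood role sequences and
    cluster calls must be invariant under this transformation.
    """
    contigs: dict[str, list[GeneFeature]] = {}
    lengths: dict[str, int] = {}
    seqs: dict[str, str] = {}
    for cid, feats in genome.contigs.items():
        length = genome.contig_lengths.get(cid)
        if length is None:
            length = max((f.end for f in feats), default=0)
        lengths[cid] = length
        flipped = [
            replace(
                f,
                start=length - f.end,
                end=length - f.start,
                strand="-" if f.strand == "+" else "+",
            )
            for f in feats
        ]
        contigs[cid] = flipped
        if cid in genome.contig_sequences:
            seqs[cid] = revcomp(genome.contig_sequences[cid])
    return GenomeRecord(
        genome_id=genome.genome_id,
        organism=genome.organism,
        contigs=contigs,
        contig_lengths=lengths,
        contig_sequences=seqs,
    )
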