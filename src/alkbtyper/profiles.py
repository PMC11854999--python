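"""Copy-number profiling, species-set consistency, and identity statistics.

Rhodococcus-like species carry characteristic sets of AlkB types: genomes of
one species share the same set, so a genome whose set deviates from its
species' modal set hints at misassignment.  Within-type pairwise amino-acid
identities summarize type heterogeneity (tight types like AlkB6 sit above
90%, heterogeneous ones around 60%).
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations

from biotite.sequence import ProteinSequence
from biotite.sequence.align import SubstitutionMatrix, align_optimal, get_sequence_identity

from .typing_rules import TypeCall


@dataclass
class GenomeProfile:
    genome_id: str
    species: str | None
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def type_set(self) -> frozenset[str]:
        return frozenset(t for t, c in self.counts.items() if c > 0)


@dataclass
class SpeciesSetReport:
    species: str
    modal_set: frozenset[str] | None  # None when sets tie
    all_sets: list[frozenset[str]]
    deviant_genomes: list[str]
    suggested_species: dict[str, str | None] = field(default_factory=dict)


@dataclass
class IdentityStats:
    alkb_type: str
    n_sequences: int
    min_identity: float
    mean_identity: float


def profile_genomes(
    calls_by_genome: dict[str, list[TypeCall]],
    species_map: dict[str, str] | None = None,
) -> list[GenomeProfile]:
    """One copy-number profile per genome; zero-copy genomes included."""
    species_map = species_map or {}
    profiles = []
    for genome_id in sorted(calls_by_genome):
        counts: dict[str, int] = {}
        for call in calls_by_genome[genome_id]:
            counts[call.alkb_type] = counts.get(call.alkb_type, 0) + 1
        profiles.append(
            GenomeProfile(genome_id, species_map.get(genome_id), counts)
        )
    return profiles


def species_set_check(profiles: list[GenomeProfile]) -> list[SpeciesSetReport]:
    """Per species: the modal AlkB type-set and genomes deviating from it.

    A unique modal set flags every genome with a different set; ties report
    all sets without flagging.  Flagged genomes get a suggested species when
    exactly one other species' modal set matches theirs.
    """
    by_species: dict[str, list[GenomeProfile]] = {}
    for p in profiles:
        by_species.setdefault(p.species or "unknown", []).append(p)
    modal_by_species: dict[str, frozenset[str] | None] = {}
    for sp, members in by_species.items():
        counter = Counter(p.type_set for p in members)
        top = counter.most_common()
        if len(top) > 1 and top[0][1] == top[1][1]:
            modal_by_species[sp] = None
        else:
            modal_by_species[sp] = top[0][0]
    reports = []
    for sp in sorted(by_species):
        members = by_species[sp]
        modal = modal_by_species[sp]
        deviants = (
            [p.genome_id for p in members if p.type_set != modal]
            if modal is not None
            else []
        )
        suggestions: dict[str, str | None] = {}
        for gid in deviants:
            gset = next(p.type_set for p in members if p.genome_id == gid)
            matches = [
                other
                for other, mset in modal_by_species.items()
                if other != sp and mset == gset
            ]
            suggestions[gid] = matches[0] if len(matches) == 1 else None
        reports.append(
            SpeciesSetReport(
                species=sp,
                modal_set=modal,
                all_sets=sorted({p.type_set for p in members}, key=sorted),
                deviant_genomes=deviants,
                suggested_species=suggestions,
            )
        )
    return reports


_MATRIX = SubstitutionMatrix.std_protein_matrix()  # BLOSUM62


def pairwise_identity(
    a: str, b: str, denominator: str = "alignment", gap_penalty: tuple[int, int] = (-10, -1)
) -> float:
    """Percent identity from a global (Needleman-Wunsch) protein alignment.

    BLOSUM62 scoring with affine gaps (open 10, extend 1), terminal gaps
    penalized.  ``denominator`` selects the identity convention: full
    alignment length including gap columns (default) or the shorter
    sequence's length.
    """
    if not a or not b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    mode = {"alignment": "all", "shorter": "shortest"}[denominator]
    ali = align_optimal(
        ProteinSequence(a),
        ProteinSequence(b),
        _MATRIX,
        gap_penalty=gap_penalty,
        terminal_penalty=True,
    )[0]
    return 100.0 * get_sequence_identity(ali, mode=mode)


def alignment_score(a: str, b: str, gap_penalty: tuple[int, int] = (-10, -1)) -> int:
    """Optimal global alignment score under the same scoring as pairwise_identity."""
    ali = align_optimal(
        ProteinSequence(a),
        ProteinSequence(b),
        _MATRIX,
        gap_penalty=gap_penalty,
        terminal_penalty=True,
    )[0]
    return int(ali.score)


def type_identity_stats(
    seqs_by_type: dict[str, list[str]], denominator: str = "alignment"
) -> list[IdentityStats]:
    """Min and mean pairwise identity over all unordered pairs, per type."""
    out = []
    for alkb_type in sorted(seqs_by_type):
        seqs = seqs_by_type[alkb_type]
        if len(seqs) < 2:
            warnings.warn(f"{alkb_type}: fewer than 2 sequences, skipped")
            continue
        idents = [
            pairwise_identity(a, b, denominator) for a, b in combinations(seqs, 2)
        ]
        out.append(
            IdentityStats(
                alkb_type=alkb_type,
                n_sequences=len(seqs),
                min_identity=min(idents),
                mean_identity=sum(idents) / len(idents),
            )
        )
    return out
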