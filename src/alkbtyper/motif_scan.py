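"""Signature histidine-motif scanning for AlkB family alkane monooxygenases.

AlkB alkane 1-monooxygenases carry four histidine-rich motifs whose nine
histidines coordinate the diiron active site.  The third motif (the "HYG"
motif, NYxEHY[AG]) is specific to alkane monooxygenases: membrane fatty-acid
desaturase (FADS)-like proteins share the histidines of motifs 1, 2 and 4 but
lack it.  Two pattern profiles are provided:

* ``strict`` — the literal degenerate patterns recovered by de-novo motif
  discovery on the Rhodococcus (sensu lato) AlkB set:
  HE[LM]GH[KR], EHN[RHF]GHH, NY[LVI]EHY[AG], LQRHSDHHA.
* ``generalized`` — relaxed forms admitting the AlkB0-type deviations
  (M1 terminal arginine with free middle positions, M4 terminal threonine):
  HExxH[KR], EHxxGHH, NYxEHY[AG], LQRHxDHH[AT].

A protein is called ``alkb`` when all four motifs occur in order with
plausible spacing, ``desaturase_like`` when motifs 1, 2 and 4 occur in order
but the HYG motif is absent, and ``none`` otherwise.  Sequences shorter than
300 residues are never called (they cannot span the full motif chain and
mirror the standard partial-sequence exclusion).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import AA_ALPHABET, AA_WITH_X

MOTIF_IDS = ("M1", "M2", "M3", "M4")

#: Default allowed residue spacing between the end of one motif and the
#: start of the next (M1->M2, M2->M3, M3->M4).  Wide enough to admit every
#: 349-447 aa AlkB; chance four-motif chains are already vanishingly rare.
DEFAULT_GAP_BOUNDS = (10, 160)


@dataclass(frozen=True)
class MotifPattern:
    """A degenerate amino-acid pattern.

    ``positions`` holds one entry per column: a frozenset of allowed
    residues, or ``None`` for an unconstrained wildcard.  ``X`` in a scanned
    sequence matches only wildcard columns (unknown residues never satisfy a
    constraint).
    """

    motif_id: str
    positions: tuple[frozenset[str] | None, ...]
    min_gap_to_next: int = DEFAULT_GAP_BOUNDS[0]
    max_gap_to_next: int = DEFAULT_GAP_BOUNDS[1]

    def __post_init__(self) -> None:
        if not (5 <= len(self.positions) <= 15):
            raise ValueError(f"{self.motif_id}: pattern length {len(self.positions)} outside 5..15")
        if not (0 <= self.min_gap_to_next <= self.max_gap_to_next):
            raise ValueError(f"{self.motif_id}: invalid gap bounds")

    def __len__(self) -> int:
        return len(self.positions)

    def matches_at(self, seq: str, i: int) -> bool:
        if i + len(self.positions) > len(seq):
            return False
        for pos, allowed in zip(range(i, i + len(self.positions)), self.positions):
            if allowed is not None and seq[pos] not in allowed:
                return False
        return True


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    start: int
    matched: str


@dataclass
class MotifEvidence:
    """Outcome of screening one protein against the four-motif chain."""

    hits: dict[str, MotifHit] = field(default_factory=dict)
    all_hits: dict[str, list[MotifHit]] = field(default_factory=dict)
    in_order: bool = False
    variant_flags: dict[str, bool] = field(default_factory=dict)
    family_call: str = "none"  # {"alkb", "desaturase_like", "none"}


@dataclass
class MotifProfile:
    """Per-column residue frequencies and information content (bits)."""

    motif_id: str
    offsets: list[int]
    columns: list[dict[str, float]]
    information_content: list[float]
    n_sequences: int


def _parse_pattern(motif_id: str, text: str, **gaps) -> MotifPattern:
    """Parse a PROSITE-like string: capital letters, [XY] choice sets, '.' wildcard."""
    positions: list[frozenset[str] | None] = []
    i = 0
    while i < len(text):
        c = text[i]
        if c == "[":
            j = text.index("]", i)
            positions.append(frozenset(text[i + 1 : j]))
            i = j + 1
        elif c in (".", "x"):
            positions.append(None)
            i += 1
        else:
            positions.append(frozenset(c))
            i += 1
    return MotifPattern(motif_id, tuple(positions), **gaps)


_STRICT = ("HE[LM]GH[KR]", "EHN[RHF]GHH", "NY[LVI]EHY[AG]", "LQRHSDHHA")
_GENERALIZED = ("HE..H[KR]", "EH..GHH", "NY.EHY[AG]", "LQRH.DHH[AT]")


def default_patterns(
    profile: str = "generalized",
    gap_bounds: tuple[int, int] = DEFAULT_GAP_BOUNDS,
) -> list[MotifPattern]:
    """Return the four signature-motif patterns for the given profile."""
    try:
        texts = {"strict": _STRICT, "generalized": _GENERALIZED}[profile]
    except KeyError:
        raise ValueError(
            f"unknown motif profile {profile!r}; expected 'strict' or 'generalized'"
        ) from None
    lo, hi = gap_bounds
    return [
        _parse_pattern(mid, txt, min_gap_to_next=lo, max_gap_to_next=hi)
        for mid, txt in zip(MOTIF_IDS, texts)
    ]


def _validate_seq(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - AA_WITH_X
    if bad:
        raise ValueError(f"sequence contains invalid characters {sorted(bad)}")


def scan_motifs(seq: str, patterns: list[MotifPattern]) -> list[MotifHit]:
    """All occurrences of every pattern, sorted by (start, motif_id)."""
    _validate_seq(seq)
    hits = [
        MotifHit(p.motif_id, i, seq[i : i + len(p)])
        for p in patterns
        for i in range(len(seq) - len(p) + 1)
        if p.matches_at(seq, i)
    ]
    hits.sort(key=lambda h: (h.start, h.motif_id))
    return hits


def _gap_ok(prev: MotifHit, prev_pat: MotifPattern, nxt: MotifHit) -> bool:
    gap = nxt.start - (prev.start + len(prev_pat))
    return prev_pat.min_gap_to_next <= gap <= prev_pat.max_gap_to_next


def _select_chain(
    by_motif: dict[str, list[MotifHit]], patterns: dict[str, MotifPattern]
) -> tuple[dict[str, MotifHit], int] | None:
    """Best strictly-increasing M1..M4 chain.

    Returns the chain maximizing the number of satisfied gap constraints
    (ties broken by leftmost start tuple), or None when no increasing chain
    of all four motifs exists.  Hit lists are short so exhaustive
    enumeration is fine.
    """
    lists = [by_motif.get(m, []) for m in MOTIF_IDS]
    if any(not l for l in lists):
        return None
    best: tuple[int, tuple[int, ...], dict[str, MotifHit]] | None = None
    for combo in itertools.product(*lists):
        starts = [h.start for h in combo]
        if not all(a < b for a, b in zip(starts, starts[1:])):
            continue
        score = sum(
            _gap_ok(combo[k], patterns[MOTIF_IDS[k]], combo[k + 1]) for k in range(3)
        )
        key = (-score, tuple(starts))
        if best is None or key < (-best[0], best[1]):
            best = (score, tuple(starts), dict(zip(MOTIF_IDS, combo)))
    if best is None:
        return None
    return best[2], best[0]


def _compute_variant_flags(hits: dict[str, MotifHit]) -> dict[str, bool]:
    return {
        "M1_terminal_R": hits["M1"].matched[5] == "R",
        "M3_terminal_A": hits["M3"].matched[-1] == "A",
        "M4_terminal_T": hits["M4"].matched[-1] == "T",
    }


def evaluate_family(
    seq: str,
    patterns: list[MotifPattern] | None = None,
    min_length: int = 300,
) -> MotifEvidence:
    """Screen one protein for AlkB-family membership.

    Sequences shorter than ``min_length`` residues are called ``none``
    regardless of motif content.  With all four motifs present, the
    in-order chain maximizing satisfied gap constraints is selected
    (leftmost on ties); the call is ``alkb`` only when all three gaps fall
    within bounds.  Motifs 1, 2 and 4 in order without any HYG (M3) hit
    give ``desaturase_like``.
    """
    if patterns is None:
        patterns = default_patterns()
    pat_by_id = {p.motif_id: p for p in patterns}
    ev = MotifEvidence()
    all_hits = scan_motifs(seq, patterns)
    for h in all_hits:
        ev.all_hits.setdefault(h.motif_id, []).append(h)
    if len(seq) < min_length:
        return ev
    chain = _select_chain(ev.all_hits, pat_by_id)
    if chain is not None:
        hits, n_gaps_ok = chain
        ev.hits = hits
        ev.in_order = n_gaps_ok == 3
        if ev.in_order:
            ev.family_call = "alkb"
            ev.variant_flags = _compute_variant_flags(hits)
        return ev
    # FADS-like decoy check: motifs 1, 2, 4 in increasing order, HYG absent
    if "M3" not in ev.all_hits and all(m in ev.all_hits for m in ("M1", "M2", "M4")):
        for m1, m2, m4 in itertools.product(
            ev.all_hits["M1"], ev.all_hits["M2"], ev.all_hits["M4"]
        ):
            if m1.start < m2.start < m4.start:
                ev.hits = {"M1": m1, "M2": m2, "M4": m4}
                ev.family_call = "desaturase_like"
                break
    return ev


def variant_flags(evidence: MotifEvidence) -> dict[str, bool]:
    """AlkB0-style deviation flags for an ``alkb``-called protein.

    M1_terminal_R: last motif-1 residue is R (HExxHR, the AlkB0 form).
    M3_terminal_A: HYG motif ends in A rather than G.
    M4_terminal_T: last motif-4 alanine replaced by threonine.
    """
    if evidence.family_call != "alkb":
        raise ValueError("variant_flags requires family_call == 'alkb'")
    return _compute_variant_flags(evidence.hits)


def build_profile(
    seqs: list[str],
    motif_id: str = "M1",
    flank: int = 0,
    patterns: list[MotifPattern] | None = None,
    pseudocount: float = 0.0,
) -> MotifProfile:
    """Position-frequency matrix and per-column information content.

    Sequences are anchored at their selected hit of ``motif_id``; columns
    cover offsets [-flank, motif_len + flank).  Frequencies are computed per
    column over the sequences covering that column; information content is
    log2(20) minus the column's Shannon entropy, with no small-sample
    correction (an optional Dirichlet ``pseudocount`` is exposed, default 0).
    """
    if not seqs:
        raise ValueError("build_profile requires at least one sequence")
    if flank < 0:
        raise ValueError("flank must be >= 0")
    if patterns is None:
        patterns = default_patterns()
    motif_len = len({p.motif_id: p for p in patterns}[motif_id])
    anchored: list[tuple[str, int]] = []
    for seq in seqs:
        ev = evaluate_family(seq, patterns)
        if ev.family_call != "alkb" or motif_id not in ev.hits:
            warnings.warn(f"sequence lacking an in-order {motif_id} hit excluded from profile")
            continue
        anchored.append((seq, ev.hits[motif_id].start))
    if not anchored:
        raise ValueError("no sequence carries the requested motif")
    residues = sorted(AA_ALPHABET)
    offsets = list(range(-flank, motif_len + flank))
    columns: list[dict[str, float]] = []
    ic: list[float] = []
    max_bits = math.log2(20)
    for off in offsets:
        counts = {r: pseudocount for r in residues}
        n = 20 * pseudocount
        for seq, anchor in anchored:
            pos = anchor + off
            if 0 <= pos < len(seq) and seq[pos] in counts:
                counts[seq[pos]] += 1
                n += 1
        if n == 0:
            columns.append({r: 0.0 for r in residues})
            ic.append(0.0)
            continue
        freqs = {r: c / n for r, c in counts.items()}
        entropy = -sum(f * math.log2(f) for f in freqs.values() if f > 0)
        columns.append(freqs)
        ic.append(max_bits - entropy)
    return MotifProfile(motif_id, offsets, columns, ic, len(anchored))


def profile_to_frame(profile: MotifProfile):
    """Tidy per-column table (offset, residue frequencies, IC) as a DataFrame."""
    import pandas as pd

    rows = []
    for off, col, bits in zip(profile.offsets, profile.columns, profile.information_content):
        row = {"offset": off, "information_content": bits}
        row.update(col)
        rows.append(row)
    return pd.DataFrame(rows)
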