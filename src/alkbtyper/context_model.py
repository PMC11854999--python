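"""Genomic-context canonicalization around focal alkB candidates.

Product strings are mapped to canonical role tokens through an ordered
keyword lexicon (first matching rule wins).  Neighborhoods are expressed in
the orientation of the focal gene's coding strand, so role sequences are
invariant under reverse-complementation of the contig.  Two context
determinants drive typing:

* the rubredoxin cluster — an operon-like co-directional chain around the
  focal alkB containing two rubA genes and optionally the rubredoxin
  reductase rubB (COMPLETE: >=2 rubA and rubB; PARTIAL: >=2 rubA, no rubB;
  otherwise NONE), usually with the TetR/AraC regulator alkU;
* the conserved manA-ahcY chromosomal region, bounded by
  mannose-6-phosphate isomerase (manA) upstream and adenosylhomocysteinase
  (ahcY) downstream.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

from .core import GeneFeature, GenomeRecord

ROLE_TOKENS = frozenset(
    {
        "ALKB", "RUBA", "RUBB", "ALKU", "MANA", "AHCY", "PERMEASE", "FIEF",
        "TOBH", "MANB", "DUF3499", "THYMIDYLATE_KINASE", "MTRA", "MTRB",
        "SORTASE_F", "GLTX", "AMINOTRANSFERASE", "COLD_SHOCK", "ABIEI",
        "NRPS", "ABC_TRANSPORT", "AB_HYDROLASE", "AAA_ATPASE", "MENH",
        "MSHA", "ROK", "MERR", "FE_S", "GAF_ANTAR", "HYPOTHETICAL", "OTHER",
    }
)

_DASHES = str.maketrans({"‐": "-", "‑": "-", "–": "-", "—": "-"})


def _normalize(text: str) -> str:
    """Lowercase and strip spaces/hyphens so product-string spelling variants collapse."""
    return text.translate(_DASHES).lower().replace("-", "").replace(" ", "").replace("_", "")


# Ordered (keywords, role) rules over normalized product text; every keyword in
# the set must occur as a substring.  Specific rules come first (e.g. the
# rubredoxin reductase forms before the bare "rubredoxin" -> RUBA rule).
_BUILTIN_RULES: list[tuple[frozenset[str], str]] = [
    (frozenset({"rubredoxinnad"}), "RUBB"),
    (frozenset({"rubredoxinreductase"}), "RUBB"),
    (frozenset({"rubredoxin", "reductase"}), "RUBB"),
    (frozenset({"ferredoxinreductase"}), "RUBB"),
    (frozenset({"rubredoxin"}), "RUBA"),
    (frozenset({"alkane1monooxygenase"}), "ALKB"),
    (frozenset({"alkanemonooxygenase"}), "ALKB"),
    (frozenset({"alkanehydroxylase"}), "ALKB"),
    (frozenset({"alkb"}), "ALKB"),
    (frozenset({"alku"}), "ALKU"),
    (frozenset({"tetrfamily"}), "ALKU"),
    (frozenset({"tetr/arac"}), "ALKU"),
    (frozenset({"aracfamily"}), "ALKU"),
    (frozenset({"mannose6phosphateisomerase"}), "MANA"),
    (frozenset({"adenosylhomocysteinase"}), "AHCY"),
    (frozenset({"sadenosyllhomocysteinehydrolase"}), "AHCY"),
    (frozenset({"cationdiffusion"}), "FIEF"),
    (frozenset({"cationictransporter"}), "FIEF"),
    (frozenset({"cationtransporter"}), "FIEF"),
    (frozenset({"fief"}), "FIEF"),
    (frozenset({"permease"}), "PERMEASE"),
    (frozenset({"tobh"}), "TOBH"),
    (frozenset({"phosphoglucose/phosphomannoseisomerase"}), "TOBH"),
    (frozenset({"phosphomannomutase"}), "MANB"),
    (frozenset({"duf3499"}), "DUF3499"),
    (frozenset({"thymidylatekinase"}), "THYMIDYLATE_KINASE"),
    (frozenset({"mtra"}), "MTRA"),
    (frozenset({"mtrb"}), "MTRB"),
    (frozenset({"sortase"}), "SORTASE_F"),
    (frozenset({"glutam", "trnaligase"}), "GLTX"),
    (frozenset({"glutam", "trnasynthetase"}), "GLTX"),
    (frozenset({"aminotransferase"}), "AMINOTRANSFERASE"),
    (frozenset({"coldshock"}), "COLD_SHOCK"),
    (frozenset({"abiei"}), "ABIEI"),
    (frozenset({"nonribosomalpeptidesynth"}), "NRPS"),
    (frozenset({"abctransport"}), "ABC_TRANSPORT"),
    # menH (alpha/beta FOLD hydrolase) must win over the plain alpha/beta hydrolase rule
    (frozenset({"menh"}), "MENH"),
    (frozenset({"alpha/betafoldhydrolase"}), "MENH"),
    (frozenset({"alpha/betahydrolase"}), "AB_HYDROLASE"),
    (frozenset({"msha"}), "MSHA"),
    (frozenset({"glycosyltransferase"}), "MSHA"),
    (frozenset({"rokfamily"}), "ROK"),
    (frozenset({"merr"}), "MERR"),
    (frozenset({"ironsulfur"}), "FE_S"),
    (frozenset({"cdgsh"}), "FE_S"),
    (frozenset({"antar"}), "GAF_ANTAR"),
    (frozenset({"aaa+atpase"}), "AAA_ATPASE"),
    (frozenset({"atpbindingprotein"}), "AAA_ATPASE"),
    (frozenset({"hypothetical"}), "HYPOTHETICAL"),
]


@dataclass
class RoleLexicon:
    """Ordered keyword rules mapping product strings to role tokens.

    The first rule whose keywords all occur in the normalized product wins;
    unmatched products map to OTHER; empty products map to HYPOTHETICAL.
    Extra rules (e.g. from a user TSV) take precedence over built-ins.
    """

    extra_rules: list[tuple[frozenset[str], str]] = field(default_factory=list)

    @property
    def rules(self) -> list[tuple[frozenset[str], str]]:
        return self.extra_rules + _BUILTIN_RULES

    def assign(self, product: str | None) -> str:
        if product is None or not product.strip():
            return "HYPOTHETICAL"
        text = _normalize(product)
        for keywords, role in self.rules:
            if all(k in text for k in keywords):
                return role
        return "OTHER"

    @classmethod
    def from_tsv(cls, path) -> "RoleLexicon":
        """Load override rules from a two-column TSV (keyword, role)."""
        extra = []
        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                keyword, role = row[0], row[1].strip().upper()
                if role not in ROLE_TOKENS:
                    raise ValueError(f"unknown role token {role!r} in lexicon file")
                extra.append((frozenset({_normalize(keyword)}), role))
        return cls(extra_rules=extra)


DEFAULT_LEXICON = RoleLexicon()


def assign_role(product: str | None, lexicon: RoleLexicon = DEFAULT_LEXICON) -> str:
    """Canonical role token for one product annotation."""
    return lexicon.assign(product)


@dataclass
class Neighborhood:
    """A focal alkB candidate with strand-oriented flanking genes.

    ``upstream`` lists genes 5' of the focal gene on its coding strand,
    nearest first; ``downstream`` likewise 3'.  Both carry (feature, role)
    pairs and are truncated at contig ends.
    """

    focal: GeneFeature
    upstream: list[tuple[GeneFeature, str]]
    downstream: list[tuple[GeneFeature, str]]
    window: int

    @property
    def upstream_roles(self) -> list[str]:
        return [r for _, r in self.upstream]

    @property
    def downstream_roles(self) -> list[str]:
        return [r for _, r in self.downstream]


@dataclass
class ClusterCall:
    """Shape of the rubredoxin cluster around a focal alkB gene."""

    kind: str  # {"COMPLETE", "PARTIAL", "NONE"}
    ruba_count: int = 0
    rubb_present: bool = False
    alku_present: bool = False
    alku_codirectional: bool = False
    member_loci: list[str] = field(default_factory=list)
    anomaly_flags: list[str] = field(default_factory=list)


def extract_neighborhood(
    genome: GenomeRecord,
    focal: GeneFeature,
    window: int = 6,
    lexicon: RoleLexicon = DEFAULT_LEXICON,
) -> Neighborhood:
    """Up to ``window`` genes per side of ``focal``, in focal-strand orientation."""
    feats = genome.contigs.get(focal.contig_id)
    if feats is None:
        raise ValueError(f"contig {focal.contig_id} not in genome {genome.genome_id}")
    try:
        idx = next(i for i, f in enumerate(feats) if f.key == focal.key)
    except StopIteration:
        raise ValueError(
            f"focal gene {focal.locus_tag} not found on {focal.contig_id}"
        ) from None
    left = feats[max(0, idx - window) : idx][::-1]  # nearest first
    right = feats[idx + 1 : idx + 1 + window]
    if focal.strand == "+":
        upstream, downstream = left, right
    else:
        upstream, downstream = right, left
    role = lexicon.assign
    return Neighborhood(
        focal=focal,
        upstream=[(f, role(f.product)) for f in upstream],
        downstream=[(f, role(f.product)) for f in downstream],
        window=window,
    )


def _chain_side(
    side: list[tuple[GeneFeature, str]], focal: GeneFeature, max_gap: int
) -> tuple[list[tuple[GeneFeature, str]], tuple[GeneFeature, str, int] | None]:
    """Co-directional genes chained to the focal gene by gaps <= max_gap.

    The walk stops at a strand change, an over-long intergenic gap, or
    another ALKB-role gene (rubredoxin genes belong to the nearest
    cluster-initiating alkB, which matters in dual-alkB regions).  Also
    returns the first gene beyond the chain with its gap to the chain end,
    for convergent-alkU detection.
    """
    chain: list[tuple[GeneFeature, str]] = []
    prev = focal
    for feat, role in side:
        gap = max(feat.start, prev.start) - min(feat.end, prev.end)
        if feat.strand != focal.strand or gap > max_gap or role == "ALKB":
            return chain, (feat, role, gap)
        chain.append((feat, role))
        prev = feat
    return chain, None


def detect_cluster(neigh: Neighborhood, max_gap: int = 500) -> ClusterCall:
    """Classify the rubredoxin cluster around the focal gene.

    Walks outward over co-directional genes whose intergenic gap is at most
    ``max_gap`` bp and counts rubA/rubB within the chain.  alkU is recorded
    when inside the chain (co-directional) or immediately adjacent and
    convergently oriented, a layout seen in several Rhodococcus species.
    COMPLETE requires >=2 rubA plus rubB; PARTIAL >=2 rubA without rubB;
    anything else is NONE (a lone rubA still shows in ``ruba_count`` for the
    generalized rubredoxin-co-localization label).
    """
    focal = neigh.focal
    up_chain, up_next = _chain_side(neigh.upstream, focal, max_gap)
    down_chain, down_next = _chain_side(neigh.downstream, focal, max_gap)
    chain = up_chain + down_chain
    ruba = sum(1 for _, r in chain if r == "RUBA")
    rubb = any(r == "RUBB" for _, r in chain)
    alku_in_chain = any(r == "ALKU" for _, r in chain)
    alku_convergent = False
    if not alku_in_chain:
        for beyond in (up_next, down_next):
            if beyond is not None:
                feat, role, gap = beyond
                if role == "ALKU" and feat.strand != focal.strand and gap <= max_gap:
                    alku_convergent = True
    if ruba >= 2 and rubb:
        kind = "COMPLETE"
    elif ruba >= 2:
        kind = "PARTIAL"
    else:
        kind = "NONE"
    anomalies = []
    if kind == "NONE" and rubb:
        # rubB without the rubA pair: irregular cluster remnant worth surfacing
        anomalies.append("rubB_without_rubA_pair")
    return ClusterCall(
        kind=kind,
        ruba_count=ruba,
        rubb_present=rubb,
        alku_present=alku_in_chain or alku_convergent,
        alku_codirectional=alku_in_chain,
        member_loci=[f.locus_tag for f, _ in chain],
        anomaly_flags=anomalies,
    )


#: Roles tolerated between the focal gene and the manA / ahcY anchors.  ALKB
#: is included because dual-alkB regions place a second alkane monooxygenase
#: gene between the cluster and ahcY.
_REGION_ALLOWED = frozenset(
    {"PERMEASE", "FIEF", "ABC_TRANSPORT", "RUBA", "RUBB", "ALKU", "TOBH",
     "MANB", "DUF3499", "ALKB"}
)


def in_mana_ahcy_region(
    neigh: Neighborhood, tolerance: int = 2
) -> tuple[bool, dict]:
    """Is the focal gene inside the conserved manA-ahcY region?

    True when MANA occurs among the upstream roles and AHCY among the
    downstream roles, with only cluster/region genes between the focal gene
    and the two anchors — at most ``tolerance`` OTHER/HYPOTHETICAL genes per
    side.  Evidence records the anchor offsets (1-based gene counts from the
    focal gene).
    """
    evidence: dict = {"mana_offset": None, "ahcy_offset": None}
    up = neigh.upstream_roles
    down = neigh.downstream_roles
    if "MANA" not in up or "AHCY" not in down:
        return False, evidence
    mana_i = up.index("MANA")
    ahcy_i = down.index("AHCY")
    for between in (up[:mana_i], down[:ahcy_i]):
        loose = sum(1 for r in between if r not in _REGION_ALLOWED)
        if loose > tolerance:
            return False, evidence
        if any(r not in _REGION_ALLOWED and r not in ("OTHER", "HYPOTHETICAL") for r in between):
            return False, evidence
    evidence["mana_offset"] = mana_i + 1
    evidence["ahcy_offset"] = ahcy_i + 1
    return True, evidence
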