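"""Context-based AlkB type assignment.

Each alkB candidate gets exactly one type from a fixed precedence of
neighborhood rules.  Cluster-based rules come first (rubredoxin
co-localization is the primary classification parameter), then the
manA-ahcY region rule for AlkB0, then the mutually exclusive flank-pair
rules for the single-gene types AlkB3-AlkB9:

1.  COMPLETE cluster in the manA-ahcY region            -> AlkB1A
2.  COMPLETE cluster                                    -> AlkB1
3.  PARTIAL cluster in the manA-ahcY region             -> AlkB2
4.  PARTIAL cluster elsewhere                           -> AlkB2N
5.  no cluster, in region, ahcY immediately downstream  -> AlkB0
6.  class F sortase just downstream                     -> AlkB3
7.  glutamate--tRNA ligase just downstream              -> AlkB4
8.  aminotransferase + cold-shock upstream,
    AbiEi antitoxin or NRPS downstream                  -> AlkB5
9.  ABC transporter just upstream                       -> AlkB6
10. alpha/beta hydrolase upstream, AAA ATPase downstream-> AlkB7
11. menH + mshA upstream, ROK regulator downstream      -> AlkB8
12. MerR + Fe-S upstream, hypothetical then GAF/ANTAR
    downstream                                          -> AlkB9
13. otherwise                                           -> unassigned

The generalized label is AlkBR when at least one rubA gene sits in the
cluster chain, AlkBS otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .config import RunConfig
from .context_model import (
    ClusterCall,
    Neighborhood,
    RoleLexicon,
    DEFAULT_LEXICON,
    detect_cluster,
    extract_neighborhood,
    in_mana_ahcy_region,
)
from .core import GeneFeature, GenomeRecord
from .motif_scan import MotifEvidence, default_patterns, evaluate_family

ALKB_TYPES = (
    "AlkB0", "AlkB1", "AlkB1A", "AlkB2", "AlkB2N", "AlkB3", "AlkB4",
    "AlkB5", "AlkB6", "AlkB7", "AlkB8", "AlkB9", "unassigned",
)

CLUSTER_TYPES = frozenset({"AlkB1", "AlkB1A", "AlkB2", "AlkB2N"})


@dataclass
class TypeCall:
    """One typed alkB locus with its rule-evidence trail."""

    genome_id: str
    feature: GeneFeature
    alkb_type: str
    generalized: str  # {"AlkBR", "AlkBS"}
    cluster: ClusterCall
    in_region: bool
    evidence: list[str] = field(default_factory=list)
    motif_evidence: MotifEvidence | None = None
    anomaly_flags: list[str] = field(default_factory=list)


def _roles_within(roles: list[str], token: str, k: int) -> bool:
    return token in roles[:k]


def assign_type(
    neigh: Neighborhood,
    cluster: ClusterCall,
    region: tuple[bool, dict],
    ahcy_adjacency: int = 2,
    genome_id: str = "",
    motif_evidence: MotifEvidence | None = None,
) -> TypeCall:
    """Apply the typing precedence to one focal candidate.

    All satisfied rule predicates are recorded in the evidence trail; the
    first one decides the type.  ``ahcy_adjacency`` is how many genes
    downstream ahcY may sit for the AlkB0 call (default 2: "immediately
    downstream" with tolerance for one small insertion).
    """
    if motif_evidence is not None and motif_evidence.family_call != "alkb":
        raise ValueError("assign_type requires an alkb-called focal gene")
    in_region, region_ev = region
    up = neigh.upstream_roles
    down = neigh.downstream_roles
    matched: list[tuple[str, str]] = []  # (type, predicate description)

    if cluster.kind == "COMPLETE" and in_region:
        matched.append(("AlkB1A", "complete rubredoxin cluster inside manA-ahcY region"))
    if cluster.kind == "COMPLETE":
        matched.append(("AlkB1", "complete rubredoxin cluster (2x rubA + rubB)"))
    if cluster.kind == "PARTIAL" and in_region:
        matched.append(("AlkB2", "partial rubredoxin cluster inside manA-ahcY region"))
    if cluster.kind == "PARTIAL":
        matched.append(("AlkB2N", "partial rubredoxin cluster outside manA-ahcY region"))
    if (
        cluster.kind == "NONE"
        and in_region
        and _roles_within(down, "AHCY", ahcy_adjacency)
    ):
        matched.append(("AlkB0", "no cluster; manA-ahcY region with ahcY immediately downstream"))
    if _roles_within(down, "SORTASE_F", 2):
        matched.append(("AlkB3", "class F sortase within 2 genes downstream"))
    if _roles_within(down, "GLTX", 2):
        matched.append(("AlkB4", "glutamate-tRNA ligase within 2 genes downstream"))
    if (
        "AMINOTRANSFERASE" in up
        and "COLD_SHOCK" in up
        and ("ABIEI" in down or "NRPS" in down)
    ):
        matched.append(("AlkB5", "aminotransferase + cold-shock upstream, AbiEi/NRPS downstream"))
    if _roles_within(up, "ABC_TRANSPORT", 2):
        matched.append(("AlkB6", "ABC transporter within 2 genes upstream"))
    if "AB_HYDROLASE" in up and "AAA_ATPASE" in down:
        matched.append(("AlkB7", "alpha/beta hydrolase upstream, AAA ATPase downstream"))
    if "MENH" in up and "MSHA" in up and "ROK" in down:
        matched.append(("AlkB8", "menH + mshA upstream, ROK regulator downstream"))
    if "MERR" in up and "FE_S" in up and "HYPOTHETICAL" in down and "GAF_ANTAR" in down:
        if down.index("HYPOTHETICAL") < down.index("GAF_ANTAR"):
            matched.append(
                ("AlkB9", "MerR + Fe-S upstream, hypothetical then GAF/ANTAR downstream")
            )

    if matched:
        alkb_type = matched[0][0]
        evidence = [f"{t}: {desc}" for t, desc in matched]
    else:
        alkb_type, evidence = "unassigned", []
    generalized = "AlkBR" if cluster.ruba_count >= 1 else "AlkBS"
    return TypeCall(
        genome_id=genome_id,
        feature=neigh.focal,
        alkb_type=alkb_type,
        generalized=generalized,
        cluster=cluster,
        in_region=in_region,
        evidence=evidence,
        motif_evidence=motif_evidence,
        anomaly_flags=list(cluster.anomaly_flags),
    )


def type_genome(
    genome: GenomeRecord,
    config: RunConfig | None = None,
    lexicon: RoleLexicon = DEFAULT_LEXICON,
) -> list[TypeCall]:
    """Screen every CDS translation and type each alkB candidate.

    Pseudogenes and partial CDS count as context genes but never as focal
    candidates.  Genomes with no candidate yield an empty list.
    """
    cfg = config or RunConfig()
    patterns = default_patterns(cfg.motif_profile, cfg.gap_bounds)
    calls: list[TypeCall] = []
    for feat in genome.features():
        if feat.translation is None or feat.is_pseudo or feat.is_partial:
            continue
        ev = evaluate_family(feat.translation, patterns, cfg.min_length)
        if ev.family_call != "alkb":
            continue
        neigh = extract_neighborhood(genome, feat, cfg.window, lexicon)
        cluster = detect_cluster(neigh, cfg.max_gap)
        region = in_mana_ahcy_region(neigh, cfg.mana_ahcy_tolerance)
        calls.append(
            assign_type(
                neigh,
                cluster,
                region,
                ahcy_adjacency=cfg.ahcy_adjacency,
                genome_id=genome.genome_id,
                motif_evidence=ev,
            )
        )
    calls.sort(key=lambda c: (c.feature.contig_id, c.feature.start))
    return calls
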