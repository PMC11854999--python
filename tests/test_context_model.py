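"""Role lexicon, neighborhoods, cluster detection, and the manA-ahcY region."""

import pytest

from alkbtyper.context_model import (
    RoleLexicon,
    assign_role,
    detect_cluster,
    extract_neighborhood,
    in_mana_ahcy_region,
)
from alkbtyper.core import GeneFeature, GenomeRecord, reverse_complement_record


def _genome(entries, spacing=50, contig="c1"):
    """entries: list of (product, strand) laid out left to right."""
    feats = []
    pos = 100
    for i, (product, strand) in enumerate(entries):
        feats.append(
            GeneFeature(
                contig_id=contig,
                start=pos,
                end=pos + 300,
                strand=strand,
                locus_tag=f"g{i + 1}",
                product=product,
            )
        )
        pos += 300 + spacing
    return GenomeRecord(genome_id="test", contigs={contig: feats},
                        contig_lengths={contig: pos + 100})


@pytest.mark.parametrize(
    "product,role",
    [
        ("rubredoxin reductase", "RUBB"),
        ("rubredoxin-NAD(+) reductase", "RUBB"),
        ("rubredoxin", "RUBA"),
        ("Rubredoxin RubA", "RUBA"),
        ("mannose-6-phosphate isomerase", "MANA"),
        ("adenosylhomocysteinase", "AHCY"),
        ("alkane 1-monooxygenase", "ALKB"),
        ("TetR family transcriptional regulator", "ALKU"),
        ("cation diffusion facilitator FieF", "FIEF"),
        ("amino acid permease", "PERMEASE"),
        ("glutamate--tRNA ligase", "GLTX"),
        ("glutamil t-RNA synthetase", "GLTX"),
        ("class F sortase", "SORTASE_F"),
        ("ABC transporter ATP-binding protein", "ABC_TRANSPORT"),
        ("ATP-binding protein", "AAA_ATPASE"),
        ("alpha/beta hydrolase", "AB_HYDROLASE"),
        ("alpha/beta fold hydrolase MenH", "MENH"),
        ("MerR family transcriptional regulator", "MERR"),
        ("CDGSH iron-sulfur domain-containing protein", "FE_S"),
        ("GAF and ANTAR domain-containing protein", "GAF_ANTAR"),
        ("ROK family transcriptional regulator", "ROK"),
        ("DUF9999 protein of unknown function", "OTHER"),
        ("hypothetical protein", "HYPOTHETICAL"),
        ("", "HYPOTHETICAL"),
        (None, "HYPOTHETICAL"),
    ],
)
def test_assign_role(product, role):
    """Longest-specific-first keyword rules; unmatched products fall to OTHER."""
    assert assign_role(product) == role


def test_lexicon_override_tsv(tmp_path):
    path = tmp_path / "lex.tsv"
    path.write_text("widget protein\tRUBA\n")
    lex = RoleLexicon.from_tsv(path)
    assert lex.assign("widget protein precursor") == "RUBA"
    # built-ins still apply after overrides
    assert lex.assign("rubredoxin reductase") == "RUBB"


def test_lexicon_rejects_unknown_role(tmp_path):
    path = tmp_path / "lex.tsv"
    path.write_text("x\tNOT_A_ROLE\n")
    with pytest.raises(ValueError):
        RoleLexicon.from_tsv(path)


class TestNeighborhood:
    def test_plus_strand_orientation(self):
        g = _genome([("a", "+"), ("alkane 1-monooxygenase", "+"), ("b", "+")])
        focal = g.find("c1", "g2")
        n = extract_neighborhood(g, focal, window=6)
        assert [f.locus_tag for f, _ in n.upstream] == ["g1"]
        assert [f.locus_tag for f, _ in n.downstream] == ["g3"]

    def test_minus_strand_orientation(self):
        """For a minus-strand focal gene the left genomic neighbor is downstream."""
        g = _genome([("a", "+"), ("alkane 1-monooxygenase", "-"), ("b", "+")])
        n = extract_neighborhood(g, g.find("c1", "g2"), window=6)
        assert [f.locus_tag for f, _ in n.downstream] == ["g1"]
        assert [f.locus_tag for f, _ in n.upstream] == ["g3"]

    def test_contig_edge_truncates(self):
        g = _genome([("alkane 1-monooxygenase", "+"), ("b", "+")])
        n = extract_neighborhood(g, g.find("c1", "g1"), window=6)
        assert n.upstream == []
        assert len(n.downstream) == 1

    def test_window_limits(self):
        entries = [("x", "+")] * 10 + [("alkane 1-monooxygenase", "+")] + [("y", "+")] * 10
        g = _genome(entries)
        n = extract_neighborhood(g, g.find("c1", "g11"), window=3)
        assert len(n.upstream) == 3 and len(n.downstream) == 3

    def test_missing_focal_rejected(self):
        g = _genome([("a", "+")])
        other = GeneFeature("c1", 5000, 5300, "+", "zz")
        with pytest.raises(ValueError):
            extract_neighborhood(g, other)

    def test_role_sequence_invariant_under_reverse_complement(self):
        g = _genome(
            [
                ("mannose-6-phosphate isomerase", "+"),
                ("rubredoxin", "+"),
                ("rubredoxin", "+"),
                ("alkane 1-monooxygenase", "+"),
                ("TetR family transcriptional regulator", "+"),
                ("adenosylhomocysteinase", "+"),
            ]
        )
        n1 = extract_neighborhood(g, g.find("c1", "g4"))
        g2 = reverse_complement_record(g)
        n2 = extract_neighborhood(g2, g2.find("c1", "g4"))
        assert n1.upstream_roles == n2.upstream_roles
        assert n1.downstream_roles == n2.downstream_roles
        assert n1.upstream_roles == ["RUBA", "RUBA", "MANA"]
        assert n1.downstream_roles == ["ALKU", "AHCY"]


class TestDetectCluster:
    def _neigh(self, entries, focal_tag, spacing=50):
        g = _genome(entries, spacing=spacing)
        return extract_neighborhood(g, g.find("c1", focal_tag))

    def test_complete_cluster(self):
        n = self._neigh(
            [
                ("alkane 1-monooxygenase", "+"),
                ("rubredoxin", "+"),
                ("rubredoxin", "+"),
                ("rubredoxin reductase", "+"),
                ("TetR family transcriptional regulator", "+"),
            ],
            "g1",
        )
        call = detect_cluster(n)
        assert call.kind == "COMPLETE"
        assert call.ruba_count == 2 and call.rubb_present
        assert call.alku_present and call.alku_codirectional

    def test_partial_cluster(self):
        n = self._neigh(
            [
                ("alkane 1-monooxygenase", "+"),
                ("rubredoxin", "+"),
                ("rubredoxin", "+"),
                ("TetR family transcriptional regulator", "+"),
            ],
            "g1",
        )
        call = detect_cluster(n)
        assert call.kind == "PARTIAL"
        assert not call.rubb_present

    def test_no_ruba_is_none(self):
        n = self._neigh([("alkane 1-monooxygenase", "+"), ("x", "+")], "g1")
        assert detect_cluster(n).kind == "NONE"

    def test_single_ruba_counted_but_none(self):
        n = self._neigh(
            [("alkane 1-monooxygenase", "+"), ("rubredoxin", "+")], "g1"
        )
        call = detect_cluster(n)
        assert call.kind == "NONE" and call.ruba_count == 1

    def test_gap_breaks_chain(self):
        """rubA genes beyond the max intergenic gap are not chained."""
        n = self._neigh(
            [
                ("alkane 1-monooxygenase", "+"),
                ("rubredoxin", "+"),
                ("rubredoxin", "+"),
                ("rubredoxin reductase", "+"),
            ],
            "g1",
            spacing=600,
        )
        assert detect_cluster(n, max_gap=500).kind == "NONE"
        assert detect_cluster(n, max_gap=700).kind == "COMPLETE"

    def test_strand_change_breaks_chain(self):
        n = self._neigh(
            [
                ("alkane 1-monooxygenase", "+"),
                ("rubredoxin", "-"),
                ("rubredoxin", "+"),
                ("rubredoxin reductase", "+"),
            ],
            "g1",
        )
        assert detect_cluster(n).kind == "NONE"

    def test_convergent_alku_recorded(self):
        n = self._neigh(
            [
                ("alkane 1-monooxygenase", "+"),
                ("rubredoxin", "+"),
                ("rubredoxin", "+"),
                ("rubredoxin reductase", "+"),
                ("TetR family transcriptional regulator", "-"),
            ],
            "g1",
        )
        call = detect_cluster(n)
        assert call.kind == "COMPLETE"
        assert call.alku_present and not call.alku_codirectional

    def test_chain_stops_at_second_alkb(self):
        """rubredoxins beyond another alkB gene belong to that gene's cluster."""
        n = self._neigh(
            [
                ("rubredoxin", "+"),
                ("rubredoxin", "+"),
                ("alkane 1-monooxygenase", "+"),
                ("TetR family transcriptional regulator", "+"),
                ("alkane 1-monooxygenase", "+"),
                ("adenosylhomocysteinase", "+"),
            ],
            "g5",
        )
        call = detect_cluster(n)
        assert call.kind == "NONE" and call.ruba_count == 0

    def test_rubb_without_ruba_flagged(self):
        n = self._neigh(
            [("alkane 1-monooxygenase", "+"), ("rubredoxin reductase", "+")], "g1"
        )
        call = detect_cluster(n)
        assert call.kind == "NONE"
        assert "rubB_without_rubA_pair" in call.anomaly_flags


class TestManaAhcyRegion:
    def _region(self, entries, focal_tag, **kw):
        g = _genome(entries)
        n = extract_neighborhood(g, g.find("c1", focal_tag))
        return in_mana_ahcy_region(n, **kw)

    def test_permease_between_anchor_ok(self):
        ok, ev = self._region(
            [
                ("mannose-6-phosphate isomerase", "+"),
                ("amino acid permease", "+"),
                ("alkane 1-monooxygenase", "+"),
                ("adenosylhomocysteinase", "+"),
            ],
            "g3",
        )
        assert ok
        assert ev["mana_offset"] == 2 and ev["ahcy_offset"] == 1

    def test_alku_between_focal_and_ahcy_ok(self):
        ok, _ = self._region(
            [
                ("mannose-6-phosphate isomerase", "+"),
                ("alkane 1-monooxygenase", "+"),
                ("TetR family transcriptional regulator", "+"),
                ("adenosylhomocysteinase", "+"),
            ],
            "g2",
        )
        assert ok

    def test_no_mana_false(self):
        ok, _ = self._region(
            [("x", "+"), ("alkane 1-monooxygenase", "+"), ("adenosylhomocysteinase", "+")],
            "g2",
        )
        assert not ok

    def test_unrelated_specific_gene_between_anchors_breaks_region(self):
        ok, _ = self._region(
            [
                ("mannose-6-phosphate isomerase", "+"),
                ("glutamate--tRNA ligase", "+"),
                ("alkane 1-monooxygenase", "+"),
                ("adenosylhomocysteinase", "+"),
            ],
            "g3",
        )
        assert not ok

    def test_other_gene_tolerance(self):
        entries = [
            ("mannose-6-phosphate isomerase", "+"),
            ("DUF1 protein", "+"),
            ("DUF2 protein", "+"),
            ("DUF3 protein", "+"),
            ("alkane 1-monooxygenase", "+"),
            ("adenosylhomocysteinase", "+"),
        ]
        ok2, _ = self._region(entries, "g5", tolerance=2)
        ok3, _ = self._region(entries, "g5", tolerance=3)
        assert not ok2 and ok3
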