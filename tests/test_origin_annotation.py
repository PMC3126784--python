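"""GFF loading, origin classification, and composition/size tables."""

import numpy as np
import pytest

import chlorosmall as cs
from chlorosmall import origin_annotation as oa
from chlorosmall.genome_index import MatchHit
from chlorosmall.sequence_io import CollapsedRead

GFF = """##gff-version 3
cp\tsim\ttRNA\t101\t300\t.\t+\t.\tID=trnX;Name=trnX
cp\tsim\texon\t101\t140\t.\t+\t.\tID=trnX.e1;Parent=trnX
cp\tsim\texon\t261\t300\t.\t+\t.\tID=trnX.e2;Parent=trnX
cp\tsim\trRNA\t401\t600\t.\t+\t.\tID=rrn5_a;Name=rrn5
cp\tsim\trRNA\t801\t1000\t.\t-\t.\tID=rrn5_b;Name=rrn5
cp\tsim\tmRNA\t1101\t1400\t.\t+\t.\tID=psbA;Name=psbA
"""


@pytest.fixture()
def features(tmp_path):
    p = tmp_path / "f.gff3"
    p.write_text(GFF)
    return oa.load_gff(p, 2000, "cp", circular=False)


class TestLoadGff:
    def test_exons_assembled_into_blocks(self, features):
        trn = next(f for f in features if f.name == "trnX")
        assert trn.placements[0].blocks == ((100, 140), (260, 300))
        assert trn.length == 80  # spliced

    def test_ir_copies_merged(self, features):
        rrn = next(f for f in features if f.name == "rrn5")
        assert rrn.copy_count == 2
        assert {p.strand for p in rrn.placements} == {"+", "-"}

    def test_out_of_bounds_on_linear_genome(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text("cp\ts\trRNA\t100\t900\t.\t+\t.\tID=x;Name=x\n")
        with pytest.raises(oa.GffError, match="beyond genome length"):
            oa.load_gff(p, 500, "cp", circular=False)

    def test_inverted_interval_rejected(self, tmp_path):
        p = tmp_path / "bad.gff3"
        p.write_text("cp\ts\trRNA\t300\t200\t.\t+\t.\tID=x;Name=x\n")
        with pytest.raises(oa.GffError):
            oa.load_gff(p, 500, "cp")


def hit(seq, start, strand="+"):
    return MatchHit(seq, "cp", start, start + len(seq), strand)


class TestClassifyOrigin:
    def test_read_inside_rrna(self, features):
        a = oa.classify_origin(hit("A" * 20, 450), features)
        assert (a.origin_class, a.feature_id) == ("rRNA", "rrn5_a")

    def test_spacer_read_is_igrna(self, features):
        a = oa.classify_origin(hit("A" * 20, 650), features)
        assert a.origin_class == "igRNA"
        assert a.feature_id is None

    def test_one_nt_body_overlap_binds_to_feature(self, features):
        # 1 nt on the tRNA body, 20 nt of upstream spacer
        a = oa.classify_origin(hit("A" * 21, 80), features)
        assert (a.origin_class, a.feature_id) == ("tRNA", "trnX")
        assert a.tx5 == -20

    def test_priority_trna_over_mrna(self, tmp_path):
        p = tmp_path / "f.gff3"
        p.write_text(
            "cp\ts\tmRNA\t101\t400\t.\t+\t.\tID=m;Name=m\n"
            "cp\ts\ttRNA\t181\t260\t.\t+\t.\tID=t;Name=t\n"
        )
        feats = oa.load_gff(p, 1000, "cp")
        a = oa.classify_origin(hit("A" * 20, 185), feats)
        assert a.origin_class == "tRNA"

    def test_transcript_coordinates_minus_strand(self, features):
        rrn = next(f for f in features if f.name == "rrn5")
        minus = next(p for p in rrn.placements if p.strand == "-")
        # sense read whose 5' end sits at the mature 5' end (genomic end-1)
        a = oa.classify_origin(hit("A" * 20, 980, "-"), features)
        assert (a.origin_class, a.antisense) == ("rRNA", False)
        assert a.tx5 == 0
        assert a.tx3 == 19

    def test_antisense_flag(self, features):
        a = oa.classify_origin(hit("A" * 20, 450, "-"), features)
        assert a.origin_class == "rRNA"
        assert a.antisense

    def test_spliced_coordinates_second_exon(self, features):
        # read fully inside exon 2 of the two-exon tRNA
        a = oa.classify_origin(hit("A" * 20, 265), features)
        assert a.tx5 == 40 + 5  # exon1 (40 nt) + offset into exon 2
        assert a.tx3 == 40 + 24


class TestAssignOrigins:
    def test_partition_every_read_one_class(self, default_sim):
        _, _, out = default_sim
        assert set(out.assignments) == out.csrnas
        classes = {a.origin_class for a in out.assignments.values()}
        assert classes <= {"rRNA", "tRNA", "mRNA", "igRNA"}

    def test_feature_order_invariance(self, features, rng):
        hits = {
            f"r{i}": [hit("A" * 20, int(rng.integers(0, 1300)))] for i in range(80)
        }
        hits = {h[0].sequence + str(i): h for i, h in enumerate(hits.values())}
        a1 = oa.assign_origins(hits, features)
        a2 = oa.assign_origins(hits, list(reversed(features)))
        assert {k: (v.origin_class, v.feature_id) for k, v in a1.items()} == {
            k: (v.origin_class, v.feature_id) for k, v in a2.items()
        }


class TestCompositionAndSizes:
    def test_single_read_library(self, features):
        assignments = {"A" * 20: oa.OriginAssignment("A" * 20, "rRNA", "rrn5_a")}
        collapsed = {"A" * 20: CollapsedRead("A" * 20, {"L": 4})}
        df = oa.composition_table(assignments, collapsed, ["L"])
        assert len(df) == 1
        assert df.iloc[0].unique_fraction == 1.0
        assert df.iloc[0].abundance_fraction == 1.0

    def test_fractions_sum_to_one(self, default_sim):
        _, _, out = default_sim
        for lib, grp in out.composition.groupby("library"):
            assert grp.unique_fraction.sum() == pytest.approx(1.0)
            assert grp.abundance_fraction.sum() == pytest.approx(1.0)

    def test_composition_recovery_against_planted_fractions(self):
        """Recovered class fractions match a 60/25/10/5 planted mixture."""
        cfg = cs.default_config(
            seed=5,
            class_fractions={"rRNA": 0.60, "tRNA": 0.25, "igRNA": 0.10, "mRNA": 0.05},
            shared_fraction=0.0,
            cp_only_fraction=0.0,
            shared_sites=0,
            cp_only_sites=0,
        )
        res = cs.generate_libraries(cfg)
        g = res.genome
        out = cs.run_analysis(
            res.reads, [g.chloroplast, g.other_chloroplast, g.nuclear],
            g.features, adapter=cfg.adapter,
        )
        frac = (
            out.composition[out.composition.library == "MT"]
            .set_index("class")
            .abundance_fraction
        )
        for cls, expect in cfg.class_fractions.items():
            assert frac[cls] == pytest.approx(expect, abs=0.02)
        # rRNA most abundant, mRNA least
        assert frac.idxmax() == "rRNA"
        assert frac.idxmin() == "mRNA"

    def test_size_histogram_conserves_mass(self, default_sim):
        _, _, out = default_sim
        sd = out.size_dist
        comp = out.composition
        for lib in ("MT", "HT"):
            assert (
                sd[sd.library == lib].abundance.sum()
                == comp[comp.library == lib].abundance.sum()
            )
            assert (
                sd[sd.library == lib].unique.sum()
                == comp[comp.library == lib].unique.sum()
            )

    def test_trna_size_mode(self, scenario_sim):
        """The tRNA length mixture peaks at 29 nt, as planted."""
        _, _, out = scenario_sim
        sd = out.size_dist
        trna = sd[(sd.library == "MT") & (sd["class"] == "tRNA")]
        assert trna.set_index("length").abundance.idxmax() == 29

    def test_unique_vs_abundance_modes_can_differ(self, features):
        a = {
            "A" * 20: oa.OriginAssignment("A" * 20, "rRNA", "rrn5_a"),
            "C" * 24: oa.OriginAssignment("C" * 24, "rRNA", "rrn5_a"),
            "G" * 24: oa.OriginAssignment("G" * 24, "rRNA", "rrn5_a"),
        }
        col = {
            "A" * 20: CollapsedRead("A" * 20, {"L": 100}),
            "C" * 24: CollapsedRead("C" * 24, {"L": 1}),
            "G" * 24: CollapsedRead("G" * 24, {"L": 1}),
        }
        df = oa.size_distribution(a, col, ["L"]).set_index("length")
        assert df.unique.idxmax() == 24
        assert df.abundance.idxmax() == 20
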