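"""Exact matching on circular genomes and multi-genome membership filters."""

import numpy as np
import pytest

from chlorosmall import genome_index as gi
from chlorosmall.sequence_io import CollapsedRead, Library


def naive_hits(genome: gi.GenomeRecord, read: str):
    """Independent oracle: scan the doubled forward and reverse-complement
    strings for every occurrence, reporting forward-strand coordinates."""
    n = len(genome.sequence)
    text = genome.sequence + (genome.sequence[: len(read) - 1] if genome.circular else "")
    hits = set()
    for strand, query in (("+", read), ("-", gi.revcomp(read))):
        start = text.find(query)
        while start != -1:
            if start < n:
                hits.add((start, strand))
            start = text.find(query, start + 1)
    return sorted(hits)


def rand_genome(rng, n, circular=True, gid="g"):
    seq = "".join(rng.choice(list("ACGT"), n))
    return gi.GenomeRecord(gid, gi.GenomeRole.CHLOROPLAST_PRIMARY, seq, circular)


class TestGenomeIndex:
    def test_unique_kmer_found_once(self, rng):
        g = rand_genome(rng, 500)
        read = g.sequence[100:109]
        hits = gi.GenomeIndex(g).find(read)
        assert (100, "+") in {(h.start, h.strand) for h in hits}
        assert hits == [
            gi.MatchHit(read, "g", s, s + 9, st)
            for s, st in naive_hits(g, read)
        ]

    def test_reverse_complement_on_minus_strand(self, rng):
        g = rand_genome(rng, 500)
        read = gi.revcomp(g.sequence[200:212])
        hits = gi.GenomeIndex(g).find(read)
        assert {(h.start, h.strand) for h in hits} >= {(200, "-")}

    def test_circular_wrap(self, rng):
        g = rand_genome(rng, 300, circular=True)
        read = g.sequence[-5:] + g.sequence[:7]
        hits = gi.GenomeIndex(g).find(read)
        assert {(h.start, h.strand) for h in hits} >= {(295, "+")}
        assert naive_hits(g, read) == [(h.start, h.strand) for h in hits]

    def test_no_wrap_when_linear(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 300))
        lin = gi.GenomeRecord("l", gi.GenomeRole.NUCLEAR, seq, False)
        read = seq[-5:] + seq[:7]
        # unless it occurs by chance internally, the junction read is absent
        assert gi.GenomeIndex(lin).find(read) == [
            gi.MatchHit(read, "l", s, s + 12, st) for s, st in naive_hits(lin, read)
        ]

    def test_oracle_equivalence_random(self, rng):
        """Index agrees exactly with the naive doubled-string scan."""
        for _ in range(15):
            n = int(rng.integers(60, 2000))
            g = rand_genome(rng, n, circular=bool(rng.integers(0, 2)))
            for _ in range(40):
                L = int(rng.integers(9, 37))
                if rng.random() < 0.7:  # planted read
                    s = int(rng.integers(0, n))
                    text = g.sequence + g.sequence
                    read = text[s : s + L]
                    if not g.circular and s + L > n:
                        continue
                    if rng.random() < 0.5:
                        read = gi.revcomp(read)
                else:  # random read, usually absent
                    read = "".join(rng.choice(list("ACGT"), L))
                got = [(h.start, h.strand) for h in gi.GenomeIndex(g).find(read)]
                assert got == naive_hits(g, read)

    def test_strand_symmetry(self, rng):
        g = rand_genome(rng, 400)
        flipped = gi.GenomeRecord(
            "f", gi.GenomeRole.CHLOROPLAST_PRIMARY, gi.revcomp(g.sequence), True
        )
        n = len(g.sequence)
        for _ in range(20):
            s = int(rng.integers(0, n - 20))
            read = g.sequence[s : s + 15]
            fwd = {(h.start, h.strand) for h in gi.GenomeIndex(g).find(read)}
            rev = {(h.start, h.strand) for h in gi.GenomeIndex(flipped).find(read)}
            # reverse-complementing the genome maps (s, +) <-> (n - e, -)
            assert {(n - (s + 15), "-" if st == "+" else "+") for s, st in fwd} == rev


def make_membership(**flags):
    m = gi.MembershipRecord("A" * 20)
    for k, v in flags.items():
        setattr(m, k, v)
    return m


class TestSelection:
    def test_inverted_repeat_two_hits_one_record(self, rng):
        core = "".join(rng.choice(list("ACGT"), 40))
        seq = (
            "".join(rng.choice(list("ACGT"), 100))
            + core
            + "".join(rng.choice(list("ACGT"), 80))
            + gi.revcomp(core)
            + "".join(rng.choice(list("ACGT"), 100))
        )
        g = gi.GenomeRecord("cp", gi.GenomeRole.CHLOROPLAST_PRIMARY, seq, True)
        read = core[5:30]
        collapsed = {read: CollapsedRead(read, {"L": 3})}
        hits, membership = gi.match_reads(collapsed, [g])
        assert len(hits[read]) == 2
        assert len(membership) == 1
        assert membership[read].matches_chloroplast_primary

    def test_csrna_definition_keeps_nuclear_matches(self):
        mem = {
            "a": make_membership(
                matches_chloroplast_primary=True, matches_other_chloroplast=True,
                matches_nuclear=True,
            ),
            "b": make_membership(matches_chloroplast_primary=True),
            "c": make_membership(),
        }
        cs = gi.select_csrnas(mem)
        assert cs == {"a"}  # nuclear match does NOT exclude from csRNAs
        assert gi.select_chloroplast_specific(mem) == set()
        assert gi.select_csrnas({}, True) == set()

    def test_single_species_mode(self):
        mem = {"b": make_membership(matches_chloroplast_primary=True)}
        assert gi.select_csrnas(mem, two_species=False) == {"b"}

    def test_set_algebra_and_idempotence(self, default_sim):
        _, _, out = default_sim
        cp_matched = {
            s for s, m in out.membership.items() if m.matches_chloroplast_primary
        }
        assert out.chloroplast_specific <= out.csrnas <= cp_matched
        again = gi.select_csrnas(out.membership)
        assert again == out.csrnas

    def test_specific_fraction_matches_ground_truth(self, default_sim):
        """The chloroplast-specific / csRNA unique ratio equals the
        generator's planted fraction of reads absent from the nucleus."""
        _, res, out = default_sim
        truth = res.truth
        emitted = truth[(truth.count_MT + truth.count_HT) > 0]
        cs_slots = emitted[emitted.source.isin(["anchored", "background", "intergenic", "shared"])]
        expected = 1 - (cs_slots.source == "shared").mean()
        got = len(out.chloroplast_specific) / len(out.csrnas)
        assert got == pytest.approx(expected, abs=0.02)


class TestMappingSummary:
    def test_counts_and_percentages(self):
        collapsed = {
            "A" * 20: CollapsedRead("A" * 20, {"MT": 10}),
            "C" * 20: CollapsedRead("C" * 20, {"MT": 5}),
            "G" * 20: CollapsedRead("G" * 20, {"MT": 5}),
        }
        mem = {
            "A" * 20: make_membership(
                matches_chloroplast_primary=True, matches_other_chloroplast=True
            ),
            "C" * 20: make_membership(matches_chloroplast_primary=True),
            "G" * 20: make_membership(),
        }
        df = gi.mapping_summary([Library("MT", 40)], mem, collapsed)
        row = df.iloc[0]
        assert row.chloroplast_abundance == 15
        assert row.both_genome_abundance == 10
        assert row.pct_chloroplast_of_total == pytest.approx(100 * 15 / 40)
        assert row.pct_both_of_chloroplast == pytest.approx(100 * 10 / 15)

    def test_zero_chloroplast_hits_no_division_error(self):
        collapsed = {"A" * 20: CollapsedRead("A" * 20, {"MT": 10})}
        mem = {"A" * 20: make_membership()}
        df = gi.mapping_summary([Library("MT", 10)], mem, collapsed)
        assert df.iloc[0].pct_chloroplast_of_total == 0.0
        assert df.iloc[0].pct_both_of_chloroplast == 0.0
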