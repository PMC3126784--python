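"""Core-sequence family clustering against a brute-force partition oracle."""


import numpy as np
import pytest

import chlorosmall as cs
from chlorosmall import family_clustering as fc


def member(start, end, count=1, seq=None, strand="+", lib="MT"):
    seq = seq or "A" * (end - start)
    return fc.FamilyMember(seq, start, end, strand, ((lib, count),))


def core_len(intervals):
    lo = max(s for s, _ in intervals)
    hi = min(e for _, e in intervals)
    return hi - lo


def oracle_partition(members, min_core):
    """Exhaustive oracle: among all partitions into groups whose interval
    intersections are >= min_core, return one with the fewest groups
    (branch and bound over assignment orders; ties broken by the sorted
    group-signature so the optimum is canonical)."""
    ms = sorted(members, key=lambda m: (m.start, m.end, m.sequence))
    best = {"n": len(ms) + 1, "parts": None}

    def sig(parts):
        return sorted(
            tuple(sorted((m.start, m.end, m.sequence) for m in g)) for g in parts
        )

    def rec(i, groups, cores):
        if len(groups) >= best["n"]:
            return
        if i == len(ms):
            s = sig(groups)
            if len(groups) < best["n"] or s < sig(best["parts"]):
                best["n"] = len(groups)
                best["parts"] = [list(g) for g in groups]
            return
        m = ms[i]
        for gi in range(len(groups)):
            lo = max(cores[gi][0], m.start)
            hi = min(cores[gi][1], m.end)
            if hi - lo >= min_core:
                groups[gi].append(m)
                old = cores[gi]
                cores[gi] = (lo, hi)
                rec(i + 1, groups, cores)
                cores[gi] = old
                groups[gi].pop()
        groups.append([m])
        cores.append((m.start, m.end))
        rec(i + 1, groups, cores)
        groups.pop()
        cores.pop()

    rec(0, [], [])
    return best["parts"]


def as_sets(families_or_groups):
    out = []
    for g in families_or_groups:
        ms = g.members if isinstance(g, fc.Family) else g
        out.append(frozenset((m.start, m.end, m.sequence) for m in ms))
    return sorted(out, key=sorted)


class TestClusterExamples:
    def test_interval_intersection_core(self):
        ms = [member(100, 126), member(97, 118), member(103, 126)]
        fams = fc.cluster_families(ms, min_core=9)
        assert len(fams) == 1
        assert fams[0].core_interval == (103, 118)

    def test_below_min_core_two_singletons(self):
        ms = [member(100, 120), member(112, 140)]  # overlap 8
        fams = fc.cluster_families(ms, min_core=9)
        assert len(fams) == 2
        assert all(len(f.members) == 1 for f in fams)

    def test_opposite_strands_never_merge(self):
        ms = [member(100, 126), member(100, 126, seq="C" * 26, strand="-")]
        fams = fc.cluster_families(ms, min_core=9)
        assert len(fams) == 2

    def test_core_sequence_extracted(self):
        genome = "T" * 100 + "ACGTACGTACGTACG" + "T" * 100
        ms = [member(98, 117), member(100, 120)]
        fams = fc.cluster_families(ms, genome_sequence=genome)
        assert fams[0].core_sequence == genome[100:117]

    def test_partition_property(self, rng):
        ms = [
            member(int(s), int(s) + int(L), seq=f"s{i}")
            for i, (s, L) in enumerate(
                zip(rng.integers(0, 500, 120), rng.integers(15, 35, 120))
            )
        ]
        fams = fc.cluster_families(ms, min_core=9)
        assert sum(len(f.members) for f in fams) == len(ms)
        for f in fams:
            lo = max(m.start for m in f.members)
            hi = min(m.end for m in f.members)
            assert (lo, hi) == f.core_interval
            assert hi - lo >= 9

    def test_order_invariance(self, rng):
        ms = [
            member(int(s), int(s) + int(L), count=int(c), seq=f"s{i}")
            for i, (s, L, c) in enumerate(
                zip(
                    rng.integers(0, 300, 60),
                    rng.integers(15, 35, 60),
                    rng.integers(1, 40, 60),
                )
            )
        ]
        ref = as_sets(fc.cluster_families(ms, min_core=9))
        for _ in range(5):
            perm = list(ms)
            rng.shuffle(perm)
            assert as_sets(fc.cluster_families(perm, min_core=9)) == ref


class TestOracleEquivalence:
    def make_fixture(self, rng, n_cores=3, min_core=9):
        """Planted cores far enough apart that inter-core overlap < min_core."""
        members = []
        centers = 200 + np.arange(n_cores) * 80
        n = int(rng.integers(4, 13))
        for i in range(n):
            c = centers[int(rng.integers(0, n_cores))]
            lo = c - int(rng.integers(0, 8))
            hi = c + min_core + int(rng.integers(0, 8))
            members.append(member(lo, hi, count=int(rng.integers(1, 50)), seq=f"s{i}"))
        return members

    def test_greedy_equals_exhaustive_on_random_fixtures(self):
        rng = np.random.default_rng(1234)
        for trial in range(300):
            ms = self.make_fixture(rng)
            got = as_sets(fc.cluster_families(ms, min_core=9))
            exp = as_sets(oracle_partition(ms, 9))
            assert got == exp, f"trial {trial}"


class TestSizeDistribution:
    def _family_for(self, out, genome, name):
        feat = genome.feature_by_name(name)
        pl = feat.placements[0]
        g5 = pl.blocks[0][0] if pl.strand == "+" else pl.blocks[-1][1] - 1
        for f in out.families:
            if any(m.start <= g5 < m.end for m in f.members):
                return f
        raise AssertionError(f"no family at the 5' end of {name}")

    def test_planted_bimodal_modes(self):
        """A 5'-anchored tRNA family planted with lengths {17, 29} reports
        exactly those modes."""
        cfg = cs.default_config(
            seed=21, n_reads=20_000, trna_lengths={17: 1.0, 29: 1.2}
        )
        res = cs.generate_libraries(cfg)
        g = res.genome
        out = cs.run_analysis(
            res.reads, [g.chloroplast, g.other_chloroplast, g.nuclear],
            g.features, adapter=cfg.adapter,
        )
        fam = self._family_for(out, g, "trnAla")
        _, modes = fc.family_size_distribution(fam)
        assert set(modes) == {17, 29}

    def test_planted_single_mode(self):
        cfg = cs.default_config(seed=22, n_reads=20_000, trna_lengths={23: 1.0})
        res = cs.generate_libraries(cfg)
        g = res.genome
        out = cs.run_analysis(
            res.reads, [g.chloroplast, g.other_chloroplast, g.nuclear],
            g.features, adapter=cfg.adapter,
        )
        fam = self._family_for(out, g, "trnAsp")
        _, modes = fc.family_size_distribution(fam)
        assert modes == [23]

    def test_singleton_family(self):
        fam = fc.Family("f1", "cp", 100, 126, "", "+", [member(100, 126)])
        hist, modes = fc.family_size_distribution(fam)
        assert modes == [26]
        assert hist.sum() == 1

    def test_empty_family_raises(self):
        with pytest.raises(ValueError):
            fc.family_size_distribution(fc.Family("f", "cp", 0, 9, "", "+", []))


class TestConditionShift:
    def make_family(self, lengths_counts):
        members = []
        for i, (L, mt, ht) in enumerate(lengths_counts):
            members.append(
                fc.FamilyMember(
                    "A" * L + "C" * 0, 100, 100 + L, "+", (("HT", ht), ("MT", mt))
                )
            )
        return fc.Family("f", "cp", 100, 109, "", "+", members)

    def test_uniform_halving(self):
        fam = self.make_family([(20, 100, 50), (24, 40, 20), (29, 10, 5)])
        df = fc.family_condition_shift(fam, {"MT": 1000, "HT": 1000}, "MT", "HT")
        assert df.ratio.tolist() == pytest.approx([0.5, 0.5, 0.5])

    def test_identical_libraries(self):
        fam = self.make_family([(20, 7, 7), (22, 3, 3)])
        df = fc.family_condition_shift(fam, {"MT": 500, "HT": 500}, "MT", "HT")
        assert df.ratio.tolist() == pytest.approx([1.0, 1.0])

    def test_treatment_only_length_gets_inf_sentinel(self):
        fam = self.make_family([(20, 0, 9)])
        df = fc.family_condition_shift(fam, {"MT": 100, "HT": 100}, "MT", "HT")
        assert np.isinf(df.ratio.iloc[0])
        assert df.ratio_pseudo.iloc[0] == pytest.approx(9 / 0.5)
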