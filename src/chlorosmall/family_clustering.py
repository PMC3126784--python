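"""Grouping of small RNAs into core-sequence families.

Many chloroplast small RNAs share a common genomic core (typically 9-15 nt)
and differ only in the lengths of their 5' and/or 3' extensions.  A family
is defined genomically: a set of same-strand placements whose intervals all
contain one core interval of at least ``min_core`` nt.  Working on genomic
intervals rather than strings keeps string-identical reads from merged
inverted-repeat loci in one family while separating coincidentally similar
reads from distinct loci.

Clustering is deterministic: connected components are built on pairwise
overlap >= ``min_core``; a component whose running interval intersection
collapses below ``min_core`` is split greedily, seeding families in order
of descending abundance (ties: leftmost interval, then sequence) and
joining each read to the family whose core it preserves (ties: the family
whose updated core is longest, then leftmost).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FamilyMember",
    "Family",
    "cluster_families",
    "family_size_distribution",
    "family_condition_shift",
]


@dataclass(frozen=True)
class FamilyMember:
    """One read placed at the locus under consideration."""

    sequence: str
    start: int
    end: int
    strand: str
    counts: tuple[tuple[str, int], ...]  # (library_id, count), hashable

    @property
    def total(self) -> int:
        return sum(c for _, c in self.counts)

    @property
    def interval(self) -> tuple[int, int]:
        return self.start, self.end


@dataclass
class Family:
    family_id: str
    genome_id: str
    core_start: int
    core_end: int
    core_sequence: str
    strand: str
    members: list[FamilyMember] = field(default_factory=list)

    @property
    def core_interval(self) -> tuple[int, int]:
        return self.core_start, self.core_end

    def total(self, library_id: Optional[str] = None) -> int:
        if library_id is None:
            return sum(m.total for m in self.members)
        return sum(dict(m.counts).get(library_id, 0) for m in self.members)


def _intersect(a: tuple[int, int], b: tuple[int, int]) -> tuple[int, int]:
    return max(a[0], b[0]), min(a[1], b[1])


def _ilen(iv: tuple[int, int]) -> int:
    return iv[1] - iv[0]


def _greedy_split(
    members: list[FamilyMember], min_core: int
) -> list[list[FamilyMember]]:
    """Greedy abundance-seeded partition of one connected component."""
    order = sorted(members, key=lambda m: (-m.total, m.start, m.end, m.sequence))
    groups: list[list[FamilyMember]] = []
    cores: list[tuple[int, int]] = []
    for m in order:
        best = None  # (-new_core_len, new_core_start, group_index)
        for gi, core in enumerate(cores):
            new_core = _intersect(core, m.interval)
            if _ilen(new_core) >= min_core:
                key = (-_ilen(new_core), new_core[0], gi)
                if best is None or key < best[0]:
                    best = (key, gi, new_core)
        if best is None:
            groups.append([m])
            cores.append(m.interval)
        else:
            _, gi, new_core = best
            groups[gi].append(m)
            cores[gi] = new_core
    return groups


def cluster_families(
    members: Sequence[FamilyMember],
    min_core: int = 9,
    genome_id: str = "",
    genome_sequence: Optional[str] = None,
    prefix: str = "fam",
) -> list[Family]:
    """Partition placements into core-sequence families.

    Components are connected by pairwise same-strand interval overlap of at
    least ``min_core`` nt; a component is one family when the intersection
    of all its intervals is still >= ``min_core``, and is otherwise split
    greedily (see module docstring).  Output order and family ids are
    deterministic (sorted by strand, then core start).

    ``genome_sequence``, when given, fills ``core_sequence`` (forward-strand
    sequence of the core interval; reverse-complemented cores are the
    caller's concern since families are same-strand by construction).
    """
    families: list[Family] = []
    for strand in "+-":
        sub = sorted(
            (m for m in members if m.strand == strand),
            key=lambda m: (m.start, m.end, m.sequence),
        )
        if not sub:
            continue
        # sweep: intervals sorted by start; a new component begins when the
        # overlap with the running component's max end drops below min_core
        comp: list[FamilyMember] = []
        max_end = None
        comps: list[list[FamilyMember]] = []
        for m in sub:
            if max_end is not None and min(max_end, m.end) - m.start < min_core:
                comps.append(comp)
                comp = []
                max_end = None
            comp.append(m)
            max_end = m.end if max_end is None else max(max_end, m.end)
        if comp:
            comps.append(comp)
        for c in comps:
            core = c[0].interval
            for m in c[1:]:
                core = _intersect(core, m.interval)
            groups = [c] if _ilen(core) >= min_core else _greedy_split(c, min_core)
            for g in groups:
                gcore = g[0].interval
                for m in g[1:]:
                    gcore = _intersect(gcore, m.interval)
                seq = ""
                if genome_sequence is not None:
                    seq = genome_sequence[gcore[0] : gcore[1]]
                families.append(
                    Family(
                        family_id="",
                        genome_id=genome_id,
                        core_start=gcore[0],
                        core_end=gcore[1],
                        core_sequence=seq,
                        strand=strand,
                        members=sorted(
                            g, key=lambda m: (m.start, m.end, m.sequence)
                        ),
                    )
                )
    families.sort(key=lambda f: (f.strand, f.core_start, f.core_end))
    for i, f in enumerate(families, start=1):
        f.family_id = f"{prefix}{i}"
    return families


def family_size_distribution(
    family: Family, library_id: Optional[str] = None, max_modes: int = 2
) -> tuple[pd.Series, list[int]]:
    """Length histogram of a family plus its dominant lengths.

    Modes are local maxima of the abundance-weighted length histogram,
    reported in descending mass order; at most ``max_modes`` are kept and a
    secondary mode must carry at least 10% of the primary's mass.
    """
    if not family.members:
        raise ValueError("empty family")
    hist: dict[int, float] = {}
    for m in family.members:
        c = m.total if library_id is None else dict(m.counts).get(library_id, 0)
        hist[len(m.sequence)] = hist.get(len(m.sequence), 0.0) + c
    lengths = sorted(hist)
    series = pd.Series([hist[L] for L in lengths], index=lengths, name=family.family_id)
    peaks = []
    for L in lengths:
        left = hist.get(L - 1, 0.0)
        right = hist.get(L + 1, 0.0)
        if hist[L] > 0 and hist[L] >= left and hist[L] >= right:
            peaks.append(L)
    peaks.sort(key=lambda L: (-hist[L], L))
    modes = []
    for L in peaks:
        if modes and hist[L] < 0.1 * hist[modes[0]]:
            break
        if any(abs(L - m) == 1 for m in modes):
            continue  # shoulder of an already-reported mode
        modes.append(L)
        if len(modes) == max_modes:
            break
    return series, modes


def family_condition_shift(
    family: Family,
    depths: Mapping[str, int],
    reference: str,
    treatment: str,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Per-length normalized abundance of a family in two conditions.

    Returns a table of reads-per-million per length for the reference and
    treatment libraries with their treatment/reference ratio.  A length
    present only in the treatment gets ``ratio = inf`` alongside a
    pseudocount-adjusted companion ratio that is always finite.
    """
    if reference not in depths or treatment not in depths:
        raise ValueError("depths must cover both libraries")
    per_len: dict[int, dict[str, int]] = {}
    for m in family.members:
        d = per_len.setdefault(len(m.sequence), {reference: 0, treatment: 0})
        cc = dict(m.counts)
        d[reference] += cc.get(reference, 0)
        d[treatment] += cc.get(treatment, 0)
    rows = []
    for L in sorted(per_len):
        ref_c, trt_c = per_len[L][reference], per_len[L][treatment]
        ref_rpm = 1e6 * ref_c / depths[reference]
        trt_rpm = 1e6 * trt_c / depths[treatment]
        if ref_c == 0 and trt_c == 0:
            continue
        ratio = trt_rpm / ref_rpm if ref_rpm else float("inf")
        adj_ratio = (1e6 * max(trt_c, pseudocount) / depths[treatment]) / (
            1e6 * max(ref_c, pseudocount) / depths[reference]
        )
        rows.append(
            {
                "length": L,
                f"rpm_{reference}": ref_rpm,
                f"rpm_{treatment}": trt_rpm,
                "ratio": ratio,
                "ratio_pseudo": adj_ratio,
            }
        )
    return pd.DataFrame(rows)
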