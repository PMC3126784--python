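"""Exact placement of collapsed reads on (circular) genomes.

Small RNAs are assigned to a genome only by perfect, full-length match on
either strand.  Chloroplast genomes are circular, so the indexed text is the
genome extended by its first ``MAX_LEN - 1`` bases: a read spanning the
origin appears as an ordinary substring of the extended text and is reported
with its start taken modulo the genome length.

Membership across several genomes (primary chloroplast, a second species'
chloroplast, nuclear, mitochondrial) defines the two read sets the analysis
is built on:

* csRNAs — reads perfectly matching the chloroplast genomes of *both*
  species (no nuclear exclusion: chloroplast-derived sequence shared with
  the nucleus still counts as chloroplast-related);
* chloroplast-specific small RNAs — csRNAs additionally absent from the
  nuclear and mitochondrial genomes.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .sequence_io import CollapsedRead, Library, MAX_LEN

__all__ = [
    "GenomeRole",
    "GenomeRecord",
    "MatchHit",
    "MembershipRecord",
    "GenomeIndex",
    "revcomp",
    "match_reads",
    "select_csrnas",
    "select_chloroplast_specific",
    "mapping_summary",
    "hits_to_bed",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


class GenomeRole(str, Enum):
    CHLOROPLAST_PRIMARY = "chloroplast-primary"
    CHLOROPLAST_OTHER = "chloroplast-other-species"
    NUCLEAR = "nuclear"
    MITOCHONDRIAL = "mitochondrial"


@dataclass
class GenomeRecord:
    """A reference sequence with a role in the multi-genome filter."""

    genome_id: str
    role: GenomeRole
    sequence: str
    circular: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome {self.genome_id}: empty sequence")
        seq = self.sequence.upper()
        if set(seq) - set("ACGT"):
            raise ValueError(f"genome {self.genome_id}: non-ACGT characters")
        self.sequence = seq
        self.role = GenomeRole(self.role)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MatchHit:
    """One exact placement of a read.  Coordinates are 0-based half-open on
    the forward strand; minus-strand hits are reported in forward coordinates
    with ``strand='-'``.  ``start`` is always in ``[0, genome length)``; a
    circular-origin-spanning hit has ``end > genome length`` conceptually but
    is stored as ``start + read length``.
    """

    sequence: str
    genome_id: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if self.end - self.start != len(self.sequence):
            raise ValueError("end - start must equal read length")


@dataclass
class MembershipRecord:
    """Which genome compartments a read's sequence occurs in."""

    sequence: str
    matches_chloroplast_primary: bool = False
    matches_other_chloroplast: bool = False
    matches_nuclear: bool = False
    matches_mitochondrial: bool = False


class GenomeIndex:
    """Exact substring index over both strands of one genome.

    A k-mer dictionary over seed length ``seed = 9`` (the minimum read
    length) locates candidate starts; candidates are verified against the
    extended text.  Queries must be 9-36 nt.
    """

    SEED = 9

    def __init__(self, genome: GenomeRecord):
        self.genome = genome
        ext = genome.sequence
        if genome.circular:
            ext = ext + genome.sequence[: MAX_LEN - 1]
        self._fwd = ext
        self._rc = revcomp(ext)
        self._seeds: dict[str, list[int]] = defaultdict(list)
        for text, tag in ((self._fwd, 0), (self._rc, 1)):
            for i in range(len(text) - self.SEED + 1):
                self._seeds[text[i : i + self.SEED]].append((i << 1) | tag)

    def find(self, read: str) -> list[MatchHit]:
        """All exact placements of ``read`` on either strand, deduplicated to
        one hit per (start, strand) in forward genome coordinates."""
        n = len(self.genome.sequence)
        L = len(read)
        if L < self.SEED:
            raise ValueError(f"query shorter than {self.SEED} nt")
        hits: set[tuple[int, str]] = set()
        seed = read[: self.SEED]
        for packed in self._seeds.get(seed, ()):
            i, tag = packed >> 1, packed & 1
            text = self._rc if tag else self._fwd
            if text[i : i + L] != read:
                continue
            if tag == 0:
                start = i
            else:
                # position on reverse-complemented extended text -> forward
                start = len(text) - (i + L)
            if start >= n:
                continue  # duplicate placement within the circular extension
            hits.add((start % n, "-" if tag else "+"))
        return [
            MatchHit(read, self.genome.genome_id, s, s + L, st)
            for s, st in sorted(hits)
        ]


_ROLE_FLAG = {
    GenomeRole.CHLOROPLAST_PRIMARY: "matches_chloroplast_primary",
    GenomeRole.CHLOROPLAST_OTHER: "matches_other_chloroplast",
    GenomeRole.NUCLEAR: "matches_nuclear",
    GenomeRole.MITOCHONDRIAL: "matches_mitochondrial",
}


def match_reads(
    collapsed: Mapping[str, CollapsedRead],
    genomes: Sequence[GenomeRecord] | Sequence[GenomeIndex],
) -> tuple[dict[str, list[MatchHit]], dict[str, MembershipRecord]]:
    """Place every collapsed read on every genome; report all loci.

    Returns ``(hits, membership)`` where ``hits[seq]`` lists every exact
    placement across all genomes and ``membership[seq]`` records per-role
    presence flags.  Matching is perfect (0 mismatches) on both strands.
    """
    indexes = [g if isinstance(g, GenomeIndex) else GenomeIndex(g) for g in genomes]
    roles = {ix.genome.role for ix in indexes}
    if GenomeRole.CHLOROPLAST_PRIMARY not in roles:
        raise ValueError("a chloroplast-primary genome is required")
    hits: dict[str, list[MatchHit]] = {}
    membership: dict[str, MembershipRecord] = {}
    for seq in collapsed:
        rec = MembershipRecord(seq)
        seq_hits: list[MatchHit] = []
        for ix in indexes:
            h = ix.find(seq)
            if h:
                seq_hits.extend(h)
                setattr(rec, _ROLE_FLAG[ix.genome.role], True)
        hits[seq] = seq_hits
        membership[seq] = rec
    return hits, membership


def select_csrnas(
    membership: Mapping[str, MembershipRecord], two_species: bool = True
) -> set[str]:
    """csRNA set: reads matching the primary chloroplast genome and, in
    two-species mode, also the other species' chloroplast genome.

    Reads additionally matching the nuclear or mitochondrial genome are
    *included*: the definition is chloroplast-related, not chloroplast-only.
    """
    if two_species:
        return {
            s
            for s, m in membership.items()
            if m.matches_chloroplast_primary and m.matches_other_chloroplast
        }
    return {s for s, m in membership.items() if m.matches_chloroplast_primary}


def select_chloroplast_specific(
    membership: Mapping[str, MembershipRecord], two_species: bool = True
) -> set[str]:
    """csRNAs absent from the nuclear and mitochondrial genomes."""
    return {
        s
        for s in select_csrnas(membership, two_species)
        if not membership[s].matches_nuclear
        and not membership[s].matches_mitochondrial
    }


def mapping_summary(
    libraries: Sequence[Library],
    membership: Mapping[str, MembershipRecord],
    collapsed: Mapping[str, CollapsedRead],
) -> pd.DataFrame:
    """Per-library mapping summary in the shape of the study's Table 1.

    Columns: total / chloroplast-mapped / both-genome unique and abundance
    counts, plus derived percentages (chloroplast fraction of total reads;
    both-genome fraction of chloroplast-mapped reads).  Each read is counted
    once regardless of how many loci it hits.
    """
    rows = []
    for lib in libraries:
        lid = lib.library_id
        tot_u = sum(1 for r in collapsed.values() if r.counts.get(lid, 0) > 0)
        tot_a = sum(r.counts.get(lid, 0) for r in collapsed.values())
        cp_u = cp_a = both_u = both_a = 0
        for seq, rec in collapsed.items():
            c = rec.counts.get(lid, 0)
            if c == 0:
                continue
            m = membership.get(seq)
            if m is None or not m.matches_chloroplast_primary:
                continue
            cp_u += 1
            cp_a += c
            if m.matches_other_chloroplast:
                both_u += 1
                both_a += c
        rows.append(
            {
                "library": lid,
                "total_unique": tot_u,
                "total_abundance": tot_a,
                "library_depth": lib.total_reads,
                "chloroplast_unique": cp_u,
                "chloroplast_abundance": cp_a,
                "both_genome_unique": both_u,
                "both_genome_abundance": both_a,
                "pct_chloroplast_of_total": (
                    100.0 * cp_a / lib.total_reads if lib.total_reads else 0.0
                ),
                "pct_both_of_chloroplast": (
                    100.0 * both_a / cp_a if cp_a else 0.0
                ),
            }
        )
    return pd.DataFrame(rows)


def summary_from_counts(
    library_id: str,
    total_abundance: int,
    chloroplast_abundance: int,
    both_genome_abundance: int,
    total_unique: int = 0,
    chloroplast_unique: int = 0,
    both_genome_unique: int = 0,
) -> pd.DataFrame:
    """Mapping-summary row computed directly from pre-tabulated counts.

    Lets published per-library totals be fed straight into the percentage
    arithmetic without re-running matching.
    """
    return pd.DataFrame(
        [
            {
                "library": library_id,
                "total_unique": total_unique,
                "total_abundance": total_abundance,
                "library_depth": total_abundance,
                "chloroplast_unique": chloroplast_unique,
                "chloroplast_abundance": chloroplast_abundance,
                "both_genome_unique": both_genome_unique,
                "both_genome_abundance": both_genome_abundance,
                "pct_chloroplast_of_total": (
                    100.0 * chloroplast_abundance / total_abundance
                    if total_abundance
                    else 0.0
                ),
                "pct_both_of_chloroplast": (
                    100.0 * both_genome_abundance / chloroplast_abundance
                    if chloroplast_abundance
                    else 0.0
                ),
            }
        ]
    )


def hits_to_bed(
    hits: Mapping[str, list[MatchHit]],
    collapsed: Mapping[str, CollapsedRead],
    path,
) -> None:
    """Export hits as BED6: name = read sequence, score = total count."""
    with open(path, "w") as fh:
        for seq in sorted(hits):
            score = collapsed[seq].total() if seq in collapsed else 0
            for h in hits[seq]:
                fh.write(
                    f"{h.genome_id}\t{h.start}\t{h.end}\t{seq}\t{score}\t{h.strand}\n"
                )
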