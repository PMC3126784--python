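"""Origin classification of chloroplast small RNAs.

Each csRNA is resolved to exactly one origin class — rRNA, tRNA, mRNA or
igRNA (intergenic) — by overlap with annotated features.  The chloroplast
inverted repeat carries two identical copies of every rRNA gene; the two
copies are merged into one logical feature so that the analysis works in a
single rRNA coordinate system.  Multi-exon tRNAs are handled in spliced
(exon-concatenated) transcript coordinates.

Coordinates reported per read are transcript-relative: position 0 is the
first nucleotide of the mature RNA, negative values lie in the upstream
flank, and values >= feature length lie downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence
from urllib.parse import unquote

import pandas as pd

from .genome_index import MatchHit
from .sequence_io import CollapsedRead

__all__ = [
    "Placement",
    "Feature",
    "OriginAssignment",
    "GffError",
    "load_gff",
    "classify_origin",
    "assign_origins",
    "composition_table",
    "size_distribution",
    "CLASS_PRIORITY",
]

#: resolution order when a read overlaps features of several classes
CLASS_PRIORITY = ("tRNA", "rRNA", "mRNA")


class GffError(ValueError):
    """Invalid GFF3 content (bad intervals, unknown structure)."""


@dataclass(frozen=True)
class Placement:
    """One genomic placement of a feature: ordered exon blocks on one strand.

    ``blocks`` are 0-based half-open genomic intervals sorted by start; for a
    minus-strand placement transcript order runs from the last block's end
    back to the first block's start.
    """

    blocks: tuple[tuple[int, int], ...]
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GffError("strand must be '+' or '-'")
        prev_end = None
        for s, e in self.blocks:
            if e <= s:
                raise GffError(f"inverted interval ({s}, {e})")
            if prev_end is not None and s < prev_end:
                raise GffError("overlapping exon blocks")
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        return self.blocks[0][0], self.blocks[-1][1]

    @property
    def length(self) -> int:
        """Spliced (mature) length."""
        return sum(e - s for s, e in self.blocks)

    def genome_to_transcript(self, gpos: int) -> int:
        """Map a genomic position to a spliced transcript coordinate.

        Positions upstream of the transcript 5' end map to negative values,
        downstream ones to values >= length, both measured in unspliced
        nucleotides from the mature boundary.  Intronic positions map to the
        transcript coordinate of the exon junction they sit in.
        """
        L = self.length
        if self.strand == "+":
            if gpos < self.blocks[0][0]:
                return gpos - self.blocks[0][0]
            if gpos >= self.blocks[-1][1]:
                return L + (gpos - self.blocks[-1][1])
            cum = 0
            for s, e in self.blocks:
                if gpos < s:
                    return cum  # intron: collapse onto the junction
                if gpos < e:
                    return cum + (gpos - s)
                cum += e - s
            return L  # unreachable
        # minus strand: transcript order is by descending genomic coordinate
        if gpos >= self.blocks[-1][1]:
            return self.blocks[-1][1] - 1 - gpos  # negative: upstream
        if gpos < self.blocks[0][0]:
            return L + (self.blocks[0][0] - 1 - gpos)
        cum = 0
        for s, e in reversed(self.blocks):
            if gpos >= e:
                return cum
            if gpos >= s:
                return cum + (e - 1 - gpos)
            cum += e - s
        return L  # unreachable


@dataclass
class Feature:
    """A logical annotated feature, possibly present at several genomic
    placements (the two inverted-repeat copies of an rRNA gene count as one
    feature with ``copy_count`` 2)."""

    feature_id: str
    cls: str
    name: str
    placements: list[Placement]
    genome_id: str

    @property
    def copy_count(self) -> int:
        return len(self.placements)

    @property
    def length(self) -> int:
        return self.placements[0].length


@dataclass
class OriginAssignment:
    """A read's resolved origin: one class, at most one feature, and the
    transcript-relative coordinates of its 5' and 3' termini."""

    sequence: str
    origin_class: str  # rRNA / tRNA / mRNA / igRNA
    feature_id: Optional[str] = None
    tx5: Optional[int] = None
    tx3: Optional[int] = None
    antisense: bool = False
    hit: Optional[MatchHit] = None

    @property
    def length(self) -> int:
        return len(self.sequence)


_GFF_CLASSES = {"rRNA": "rRNA", "tRNA": "tRNA", "mRNA": "mRNA", "CDS": "mRNA"}


def _attrs(col: str) -> dict[str, str]:
    out = {}
    for part in col.strip().split(";"):
        if not part:
            continue
        k, _, v = part.partition("=")
        out[k.strip()] = unquote(v.strip())
    return out


def load_gff(
    path: str | Path, genome_length: int, genome_id: str = "", circular: bool = True
) -> list[Feature]:
    """Load rRNA/tRNA/mRNA features from GFF3 and assemble logical features.

    Exon lines sharing a Parent are assembled into one multi-block placement
    (intron-containing tRNAs).  Records of the same class and Name occurring
    at several loci — the inverted-repeat rRNA copies — are merged into one
    :class:`Feature` with multiple placements.  Intervals outside the genome
    on a non-circular sequence raise :class:`GffError`.
    """
    genes: dict[str, dict] = {}
    exons: dict[str, list[tuple[int, int, str]]] = {}
    order: list[str] = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GffError(f"{path}:{lineno}: expected 9 columns")
            _, _, ftype, start, end, _, strand, _, attr_col = cols
            s, e = int(start) - 1, int(end)  # GFF is 1-based inclusive
            if e <= s:
                raise GffError(f"{path}:{lineno}: inverted interval")
            if not circular and e > genome_length:
                raise GffError(
                    f"{path}:{lineno}: interval end {e} beyond genome "
                    f"length {genome_length} on a non-circular genome"
                )
            attrs = _attrs(attr_col)
            if ftype in _GFF_CLASSES:
                fid = attrs.get("ID") or f"{ftype}:{lineno}"
                genes[fid] = {
                    "cls": _GFF_CLASSES[ftype],
                    "name": attrs.get("Name", fid),
                    "interval": (s, e, strand),
                }
                order.append(fid)
            elif ftype == "exon":
                parent = attrs.get("Parent")
                if parent:
                    exons.setdefault(parent, []).append((s, e, strand))
            # repeat_region and other types carry no origin class

    merged: dict[tuple[str, str], Feature] = {}
    out: list[Feature] = []
    for fid in order:
        g = genes[fid]
        if fid in exons:
            blocks = tuple(sorted((s, e) for s, e, _ in exons[fid]))
            strand = exons[fid][0][2]
        else:
            s, e, strand = g["interval"]
            blocks = ((s, e),)
        placement = Placement(blocks, strand)
        key = (g["cls"], g["name"])
        if key in merged:
            feat = merged[key]
            if placement.length != feat.length:
                raise GffError(
                    f"duplicate feature {g['name']!r} with differing lengths"
                )
            feat.placements.append(placement)
        else:
            feat = Feature(fid, g["cls"], g["name"], [placement], genome_id)
            merged[key] = feat
            out.append(feat)
    return out


def _overlap(hit_start: int, hit_end: int, span: tuple[int, int]) -> int:
    return max(0, min(hit_end, span[1]) - max(hit_start, span[0]))


def classify_origin(
    hit: MatchHit, features: Sequence[Feature]
) -> OriginAssignment:
    """Classify one placement of a read against the feature annotation.

    The read is assigned to the overlapping feature of highest class
    priority (tRNA > rRNA > mRNA); ties resolve to the larger overlap, then
    the leftmost feature.  Any overlap of >= 1 nt with a feature's genomic
    body (exons plus introns) binds the read to that feature; a read
    touching no feature is intergenic (igRNA).
    """
    best = None  # (priority_rank, -overlap, span_start, feature, placement)
    for feat in features:
        try:
            rank = CLASS_PRIORITY.index(feat.cls)
        except ValueError:
            continue
        for pl in feat.placements:
            ov = _overlap(hit.start, hit.end, pl.span)
            if ov < 1:
                continue
            key = (rank, -ov, pl.span[0], feat.feature_id)
            if best is None or key < best[0]:
                best = (key, feat, pl)
    if best is None:
        return OriginAssignment(hit.sequence, "igRNA", hit=hit)
    _, feat, pl = best
    # genomic positions of the read's own 5' and 3' terminal nucleotides
    read5 = hit.start if hit.strand == "+" else hit.end - 1
    read3 = hit.end - 1 if hit.strand == "+" else hit.start
    return OriginAssignment(
        hit.sequence,
        feat.cls,
        feature_id=feat.feature_id,
        tx5=pl.genome_to_transcript(read5),
        tx3=pl.genome_to_transcript(read3),
        antisense=pl.strand != hit.strand,
        hit=hit,
    )


def assign_origins(
    hits: Mapping[str, list[MatchHit]],
    features: Sequence[Feature],
    genome_id: Optional[str] = None,
    reads: Optional[Iterable[str]] = None,
) -> dict[str, OriginAssignment]:
    """Resolve each read to exactly one origin assignment.

    Every placement of the read on the annotated genome is classified; the
    winning assignment follows the same priority/overlap/leftmost rule as
    :func:`classify_origin`, so multi-locus reads (e.g. both IR copies) get
    one deterministic class.  Reads with no placement on the annotated
    genome are skipped.
    """
    out: dict[str, OriginAssignment] = {}
    pool = reads if reads is not None else hits.keys()
    for seq in pool:
        seq_hits = [
            h
            for h in hits.get(seq, [])
            if genome_id is None or h.genome_id == genome_id
        ]
        if not seq_hits:
            continue
        best_a = None
        best_key = None
        for h in seq_hits:
            a = classify_origin(h, features)
            if a.origin_class == "igRNA":
                rank = len(CLASS_PRIORITY)
                key = (rank, 0, h.start)
            else:
                rank = CLASS_PRIORITY.index(a.origin_class)
                key = (rank, 0, h.start)
            if best_key is None or key < best_key:
                best_key, best_a = key, a
        out[seq] = best_a
    return out


def composition_table(
    assignments: Mapping[str, OriginAssignment],
    collapsed: Mapping[str, CollapsedRead],
    library_ids: Sequence[str],
) -> pd.DataFrame:
    """Per-class unique and abundance fractions for each library.

    Fractions sum to 1 per library for unique and abundance separately
    (over the classes present in that library).
    """
    rows = []
    classes = ("rRNA", "tRNA", "mRNA", "igRNA")
    for lid in library_ids:
        uniq = {c: 0 for c in classes}
        abun = {c: 0 for c in classes}
        for seq, a in assignments.items():
            c = collapsed[seq].counts.get(lid, 0) if seq in collapsed else 0
            if c == 0:
                continue
            uniq[a.origin_class] += 1
            abun[a.origin_class] += c
        tu, ta = sum(uniq.values()), sum(abun.values())
        for cls in classes:
            if uniq[cls] == 0 and abun[cls] == 0:
                continue
            rows.append(
                {
                    "library": lid,
                    "class": cls,
                    "unique": uniq[cls],
                    "abundance": abun[cls],
                    "unique_fraction": uniq[cls] / tu if tu else 0.0,
                    "abundance_fraction": abun[cls] / ta if ta else 0.0,
                }
            )
    return pd.DataFrame(rows)


def size_distribution(
    assignments: Mapping[str, OriginAssignment],
    collapsed: Mapping[str, CollapsedRead],
    library_ids: Sequence[str],
    by_class: bool = False,
    min_len: int = 9,
    max_len: int = 36,
) -> pd.DataFrame:
    """Length histograms (9-36 nt) of unique and abundance mass.

    With ``by_class`` the histogram is split per origin class.  Histogram
    totals conserve the input unique/abundance totals.
    """
    rows = []
    keyfn = (lambda a: a.origin_class) if by_class else (lambda a: "all")
    groups = sorted({keyfn(a) for a in assignments.values()})
    for lid in library_ids:
        for grp in groups:
            for L in range(min_len, max_len + 1):
                uniq = abun = 0
                for seq, a in assignments.items():
                    if keyfn(a) != grp or len(seq) != L:
                        continue
                    c = collapsed[seq].counts.get(lid, 0) if seq in collapsed else 0
                    if c == 0:
                        continue
                    uniq += 1
                    abun += c
                rows.append(
                    {
                        "library": lid,
                        "class": grp,
                        "length": L,
                        "unique": uniq,
                        "abundance": abun,
                    }
                )
    return pd.DataFrame(rows)
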