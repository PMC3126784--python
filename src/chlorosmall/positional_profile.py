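"""Position-of-origin profiles along mature RNAs.

Two views establish where along a transcript small RNAs arise:

* **5% block profiles** — the transcript is divided into ``n_blocks`` equal
  blocks (default 20, i.e. 5% each) and the positions of read 5' and 3'
  ends are tallied per block, with proportionally scaled flank pseudo-blocks
  covering +/-20% of the feature length outside the mature boundaries.
* **terminus-offset histograms** — signed nucleotide distance of a read end
  from the first (5' anchor) or last (3' anchor) nucleotide of the mature
  RNA, resolving the block peaks to single-nucleotide precision.

Both tallies weight reads by abundance by default; a unique-sequence
(weight 1) mode mirrors the unique-count view.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .origin_annotation import Feature, OriginAssignment
from .sequence_io import CollapsedRead

__all__ = [
    "BlockProfile",
    "TerminusOffsetHistogram",
    "block_profile",
    "terminus_offsets",
    "end_peak_test",
    "N_FLANK_BLOCKS",
]

#: flank pseudo-blocks per side: 20% of L at 5%-of-L width
N_FLANK_BLOCKS = 4


@dataclass
class BlockProfile:
    """Per-block tallies of read 5' and 3' end positions over one feature
    (or one class of features pooled in relative coordinates).

    ``ends5``/``ends3`` have length ``2 * N_FLANK_BLOCKS + n_blocks``:
    indices ``0..3`` are the upstream flank (outermost first), ``4..4+n-1``
    the feature body, and the final four the downstream flank.
    """

    label: str
    n_blocks: int
    ends5: np.ndarray
    ends3: np.ndarray

    @property
    def body5(self) -> np.ndarray:
        return self.ends5[N_FLANK_BLOCKS : N_FLANK_BLOCKS + self.n_blocks]

    @property
    def body3(self) -> np.ndarray:
        return self.ends3[N_FLANK_BLOCKS : N_FLANK_BLOCKS + self.n_blocks]

    def total(self, end: str) -> float:
        return float((self.ends5 if end == "5" else self.ends3).sum())

    def body_fractions(self, end: str) -> np.ndarray:
        arr = self.body5 if end == "5" else self.body3
        tot = self.total(end)
        return arr / tot if tot else arr * 0.0

    def to_frame(self) -> pd.DataFrame:
        labels = (
            [f"flank5_{i}" for i in range(-N_FLANK_BLOCKS, 0)]
            + [f"block_{b}" for b in range(self.n_blocks)]
            + [f"flank3_{i}" for i in range(1, N_FLANK_BLOCKS + 1)]
        )
        rows = []
        for end, arr in (("5", self.ends5), ("3", self.ends3)):
            tot = arr.sum()
            for lab, mass in zip(labels, arr):
                rows.append(
                    {
                        "profile": self.label,
                        "end": end,
                        "block": lab,
                        "mass": float(mass),
                        "fraction": float(mass / tot) if tot else 0.0,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class TerminusOffsetHistogram:
    """Offsets of read ends from a mature-RNA boundary.

    For a 5' anchor, offset 0 is the first nucleotide of the mature RNA and
    negative offsets are upstream.  For a 3' anchor, offset 0 is the last
    nucleotide and negative offsets are inside the mature RNA.  Mass beyond
    the window is pooled under ``other``.
    """

    label: str
    anchor: str  # "5-prime" | "3-prime"
    offsets: dict[int, float] = field(default_factory=dict)
    other: float = 0.0

    def total(self) -> float:
        return sum(self.offsets.values()) + self.other

    def mass_in(self, lo: int, hi: int) -> float:
        return sum(m for o, m in self.offsets.items() if lo <= o <= hi)

    def modal_offset(self) -> Optional[int]:
        if not self.offsets or all(m == 0 for m in self.offsets.values()):
            return None
        return max(self.offsets, key=lambda o: (self.offsets[o], -abs(o)))


def _block_index(p: float, L: int, n_blocks: int) -> int:
    """Index into the flank+body+flank array for transcript position ``p``.

    Body positions use floor(p / (L / n_blocks)) clamped to the body; flank
    positions map proportionally at the same 5%-of-L width, clamped to the
    outermost pseudo-block beyond +/-20% of L.
    """
    w = L / n_blocks
    if 0 <= p < L:
        return N_FLANK_BLOCKS + min(int(p // w), n_blocks - 1)
    if p < 0:
        k = int(math.floor(p / w))  # -1 .. -inf
        return max(0, N_FLANK_BLOCKS + k)
    k = int((p - L) // w)  # 0 .. inf past the 3' boundary
    return N_FLANK_BLOCKS + n_blocks + min(k, N_FLANK_BLOCKS - 1)


def _weights(
    assignments: Mapping[str, OriginAssignment],
    collapsed: Optional[Mapping[str, CollapsedRead]],
    library_id: Optional[str],
    unique_mode: bool,
) -> dict[str, float]:
    out = {}
    for seq in assignments:
        if unique_mode or collapsed is None:
            out[seq] = 1.0
        elif library_id is None:
            out[seq] = float(collapsed[seq].total()) if seq in collapsed else 0.0
        else:
            out[seq] = float(collapsed[seq].counts.get(library_id, 0)) if seq in collapsed else 0.0
    return out


def block_profile(
    assignments: Mapping[str, OriginAssignment],
    feature: Feature | None = None,
    origin_class: str | None = None,
    features: Sequence[Feature] | None = None,
    n_blocks: int = 20,
    collapsed: Optional[Mapping[str, CollapsedRead]] = None,
    library_id: Optional[str] = None,
    unique_mode: bool = False,
) -> BlockProfile:
    """Tally read 5'/3' end positions into length-normalized blocks.

    Select reads either by ``feature`` or by ``origin_class`` (pooling the
    per-feature relative coordinates of every feature of that class, in
    which case ``features`` supplies the lengths).  Sense reads only would
    be a caller-side filter; all assigned reads are tallied here.
    """
    if feature is None and origin_class is None:
        raise ValueError("select by feature or by origin_class")
    lengths: dict[str, int] = {}
    if feature is not None:
        if feature.length < n_blocks:
            raise ValueError(
                f"feature {feature.name} length {feature.length} < {n_blocks} "
                "blocks; use fewer blocks"
            )
        lengths[feature.feature_id] = feature.length
        label = feature.name
    else:
        for f in features or ():
            if f.cls == origin_class:
                if f.length < n_blocks:
                    raise ValueError(
                        f"feature {f.name} length {f.length} < {n_blocks} "
                        "blocks; use fewer blocks"
                    )
                lengths[f.feature_id] = f.length
        label = origin_class

    size = 2 * N_FLANK_BLOCKS + n_blocks
    ends5 = np.zeros(size)
    ends3 = np.zeros(size)
    wts = _weights(assignments, collapsed, library_id, unique_mode)
    for seq, a in assignments.items():
        if a.feature_id not in lengths or a.tx5 is None:
            continue
        L = lengths[a.feature_id]
        w = wts[seq]
        if w == 0:
            continue
        ends5[_block_index(a.tx5, L, n_blocks)] += w
        ends3[_block_index(a.tx3, L, n_blocks)] += w
    return BlockProfile(label, n_blocks, ends5, ends3)


def terminus_offsets(
    assignments: Mapping[str, OriginAssignment],
    feature: Feature,
    anchor: str,
    window: int = 10,
    collapsed: Optional[Mapping[str, CollapsedRead]] = None,
    library_id: Optional[str] = None,
    unique_mode: bool = False,
) -> TerminusOffsetHistogram:
    """Histogram of read-end offsets from a mature-RNA boundary.

    ``anchor='5-prime'`` tallies read 5' ends relative to transcript
    position 0; ``anchor='3-prime'`` tallies read 3' ends relative to
    position L-1.  Offsets beyond ``+/-window`` are pooled under ``other``.
    """
    if anchor not in ("5-prime", "3-prime"):
        raise ValueError("anchor must be '5-prime' or '3-prime'")
    hist = TerminusOffsetHistogram(feature.name, anchor, {o: 0.0 for o in range(-window, window + 1)})
    wts = _weights(assignments, collapsed, library_id, unique_mode)
    L = feature.length
    for seq, a in assignments.items():
        if a.feature_id != feature.feature_id or a.tx5 is None:
            continue
        w = wts[seq]
        if w == 0:
            continue
        off = a.tx5 - 0 if anchor == "5-prime" else a.tx3 - (L - 1)
        if -window <= off <= window:
            hist.offsets[off] += w
        else:
            hist.other += w
    return hist


def end_peak_test(
    profile: BlockProfile, which_end: str, which_block: int, threshold: float = 0.5
) -> tuple[float, bool]:
    """Fraction of one end's mass falling in one body block, plus a verdict.

    The fraction is relative to the end's total mass including flanks, so a
    uniform placement over the body gives slightly less than 1/n_blocks.
    Raises on a zero-mass profile.
    """
    tot = profile.total(which_end)
    if tot == 0:
        raise ValueError("zero-mass profile")
    body = profile.body5 if which_end == "5" else profile.body3
    frac = float(body[which_block]) / tot
    return frac, frac >= threshold
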