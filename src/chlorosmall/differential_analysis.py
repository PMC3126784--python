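"""Between-condition comparison of small-RNA abundance.

Libraries are normalized to reads per million (RPM) of their total
sequencing depth; fold changes are treatment/reference RPM ratios with a
0.5-raw-read pseudocount substituted for zero counts.  Reads are called
``down`` below 1/5-fold, ``up`` above 5-fold, and ``unchanged`` between.

tRNA-derived reads get an additional size-class response typing: the
shorter (16-25 nt) and longer (29-32 nt) size classes of each tRNA are
trended separately (1.2-fold trend threshold by default) and mapped to
response groups:

* **I** — shorter increased and longer decreased;
* **II** — shorter increased and longer unchanged;
* **III** — longer decreased and shorter unchanged;
* **IV** — any other combination (feature-specific responses).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .origin_annotation import Feature, OriginAssignment
from .sequence_io import CollapsedRead

__all__ = [
    "DifferentialRecord",
    "ResponseGroup",
    "normalize",
    "fold_change",
    "differential_table",
    "class_fold_summary",
    "trna_response_groups",
    "DOWN_THRESHOLD",
    "UP_THRESHOLD",
]

DOWN_THRESHOLD = 1 / 5
UP_THRESHOLD = 5.0
SHORTER_WINDOW = (16, 25)
LONGER_WINDOW = (29, 32)


@dataclass
class DifferentialRecord:
    unit: str
    rpm_reference: float
    rpm_treatment: float
    fold_change: float
    category: str  # down | up | unchanged


@dataclass
class ResponseGroup:
    trna: str
    shorter_trend: str  # increased | decreased | unchanged
    longer_trend: str
    group: str  # I | II | III | IV


def normalize(count: float, depth: int) -> float:
    """Reads-per-million: ``count * 1e6 / depth``."""
    if depth <= 0:
        raise ValueError("library depth must be positive")
    return count * 1e6 / depth


def fold_change(
    count_reference: int,
    count_treatment: int,
    depth_reference: int,
    depth_treatment: int,
    pseudocount: float = 0.5,
    down: float = DOWN_THRESHOLD,
    up: float = UP_THRESHOLD,
) -> tuple[float, str]:
    """Treatment/reference RPM ratio and its category.

    The pseudocount replaces zero raw counts before normalization, so the
    ratio is always finite and increasing the treatment count can only move
    the unit toward ``up``.
    """
    ref = normalize(count_reference if count_reference > 0 else pseudocount, depth_reference)
    trt = normalize(count_treatment if count_treatment > 0 else pseudocount, depth_treatment)
    fc = trt / ref
    if fc < down:
        cat = "down"
    elif fc > up:
        cat = "up"
    else:
        cat = "unchanged"
    return fc, cat


def differential_table(
    collapsed: Mapping[str, CollapsedRead],
    depths: Mapping[str, int],
    reference: str,
    treatment: str,
    sequences: Optional[Sequence[str]] = None,
    pseudocount: float = 0.5,
    down: float = DOWN_THRESHOLD,
    up: float = UP_THRESHOLD,
) -> pd.DataFrame:
    """Per-sequence fold changes and categories between two libraries."""
    pool = sequences if sequences is not None else sorted(collapsed)
    rows = []
    for seq in pool:
        rec = collapsed.get(seq)
        cr = rec.counts.get(reference, 0) if rec else 0
        ct = rec.counts.get(treatment, 0) if rec else 0
        if cr == 0 and ct == 0:
            continue
        fc, cat = fold_change(
            cr, ct, depths[reference], depths[treatment], pseudocount, down, up
        )
        rows.append(
            {
                "sequence": seq,
                "count_reference": cr,
                "count_treatment": ct,
                "rpm_reference": normalize(cr, depths[reference]),
                "rpm_treatment": normalize(ct, depths[treatment]),
                "fold_change": fc,
                "category": cat,
            }
        )
    return pd.DataFrame(rows)


def class_fold_summary(
    assignments: Mapping[str, OriginAssignment],
    collapsed: Mapping[str, CollapsedRead],
    depths: Mapping[str, int],
    reference: str,
    treatment: str,
    by_length: bool = False,
) -> pd.DataFrame:
    """Per-class (optionally per-length-bin) unique and abundance ratios.

    The abundance ratio is the treatment/reference ratio of summed RPM; the
    unique ratio compares the numbers of distinct sequences observed.  Rows
    absent from both conditions are omitted.
    """
    keys: dict[tuple, dict[str, float]] = {}
    for seq, a in assignments.items():
        rec = collapsed.get(seq)
        if rec is None:
            continue
        cr = rec.counts.get(reference, 0)
        ct = rec.counts.get(treatment, 0)
        if cr == 0 and ct == 0:
            continue
        key = (a.origin_class, len(seq)) if by_length else (a.origin_class,)
        d = keys.setdefault(
            key, {"uniq_ref": 0, "uniq_trt": 0, "ab_ref": 0, "ab_trt": 0}
        )
        d["uniq_ref"] += 1 if cr > 0 else 0
        d["uniq_trt"] += 1 if ct > 0 else 0
        d["ab_ref"] += cr
        d["ab_trt"] += ct
    rows = []
    for key in sorted(keys, key=str):
        d = keys[key]
        row = {"class": key[0]}
        if by_length:
            row["length"] = key[1]
        rpm_ref = normalize(d["ab_ref"], depths[reference])
        rpm_trt = normalize(d["ab_trt"], depths[treatment])
        row.update(
            {
                "unique_reference": d["uniq_ref"],
                "unique_treatment": d["uniq_trt"],
                "rpm_reference": rpm_ref,
                "rpm_treatment": rpm_trt,
                "unique_ratio": (
                    d["uniq_trt"] / d["uniq_ref"] if d["uniq_ref"] else float("inf")
                ),
                "abundance_ratio": rpm_trt / rpm_ref if rpm_ref else float("inf"),
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)


def _trend(ratio: float, threshold: float) -> str:
    if ratio > threshold:
        return "increased"
    if ratio < 1 / threshold:
        return "decreased"
    return "unchanged"


def _group(shorter: str, longer: str) -> str:
    if shorter == "increased" and longer == "decreased":
        return "I"
    if shorter == "increased" and longer == "unchanged":
        return "II"
    if shorter == "unchanged" and longer == "decreased":
        return "III"
    return "IV"


def trna_response_groups(
    assignments: Mapping[str, OriginAssignment],
    collapsed: Mapping[str, CollapsedRead],
    features: Sequence[Feature],
    depths: Mapping[str, int],
    reference: str,
    treatment: str,
    shorter: tuple[int, int] = SHORTER_WINDOW,
    longer: tuple[int, int] = LONGER_WINDOW,
    trend_threshold: float = 1.2,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """Size-class heat-response typing of each tRNA.

    For every tRNA feature the RPM of its shorter (default 16-25 nt) and
    longer (default 29-32 nt) reads is compared between conditions; trends
    beyond ``trend_threshold`` (default 1.2-fold either way) are called
    increased/decreased and mapped to groups I-IV.  tRNAs with no reads in
    either condition are excluded.
    """
    feat_by_id = {f.feature_id: f for f in features if f.cls == "tRNA"}
    acc: dict[str, dict[str, int]] = {}
    for seq, a in assignments.items():
        if a.origin_class != "tRNA" or a.feature_id not in feat_by_id:
            continue
        rec = collapsed.get(seq)
        if rec is None:
            continue
        L = len(seq)
        if shorter[0] <= L <= shorter[1]:
            cls = "shorter"
        elif longer[0] <= L <= longer[1]:
            cls = "longer"
        else:
            continue
        d = acc.setdefault(
            a.feature_id,
            {"shorter_ref": 0, "shorter_trt": 0, "longer_ref": 0, "longer_trt": 0},
        )
        d[f"{cls}_ref"] += rec.counts.get(reference, 0)
        d[f"{cls}_trt"] += rec.counts.get(treatment, 0)
    rows = []
    for fid in sorted(acc, key=lambda i: feat_by_id[i].name):
        d = acc[fid]
        if sum(d.values()) == 0:
            continue
        trends = {}
        for cls in ("shorter", "longer"):
            fc, _ = fold_change(
                d[f"{cls}_ref"],
                d[f"{cls}_trt"],
                depths[reference],
                depths[treatment],
                pseudocount,
            )
            trends[cls] = _trend(fc, trend_threshold)
            d[f"{cls}_fc"] = fc
        rows.append(
            {
                "trna": feat_by_id[fid].name,
                "shorter_fold_change": d["shorter_fc"],
                "longer_fold_change": d["longer_fc"],
                "shorter_trend": trends["shorter"],
                "longer_trend": trends["longer"],
                "group": _group(trends["shorter"], trends["longer"]),
            }
        )
    return pd.DataFrame(rows)
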