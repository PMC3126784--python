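"""Synthetic chloroplast small-RNA data with known ground truth.

The generator builds a scaled-down circular chloroplast-like genome — two
inverted repeats each carrying a 23S/16S/5S/4.5S rRNA operon, twenty tRNAs
(one with an intron), a handful of mRNAs and intergenic spacers — together
with a nuclear decoy genome, a second-species chloroplast genome, and
condition-paired read libraries whose biogenesis parameters (terminus
anchoring, size mixtures, per-class heat-effect multipliers) are recorded
per read so every pipeline stage can be checked against ground truth.

Reads are emitted from a finite set of *slots*: an (origin, genomic start,
length, strand) combination.  Terminus-anchored slots place the designated
read end at the mature RNA boundary plus a small offset; background slots
emanate from a fixed per-feature set of processing/degradation sites with
characteristic fragment lengths, which keeps the unique-sequence universe
finite and saturable — as in real libraries, where sequencing depth far
exceeds the number of distinct processing products.

Condition effects are planted as expected reads-per-million ratios: the
treatment library is drawn so that each slot's expected RPM equals its
reference RPM times the configured multiplier, with library depth adjusted
self-consistently (organellar reads shrink or grow; decoy reads do not).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .genome_index import GenomeRecord, GenomeRole, revcomp
from .origin_annotation import Feature, Placement

__all__ = [
    "SimulationConfig",
    "SyntheticGenome",
    "SimulationResult",
    "generate_genome",
    "generate_libraries",
    "paper_scenario",
    "default_config",
]

_TRNA_NAMES = [
    "trnAla", "trnAsp", "trnPhe", "trnLys", "trnLeu", "trnGln", "trnThr",
    "trnVal", "trnCys", "trnGlu", "trnIle", "trnMet", "trnAsn", "trnPro",
    "trnSer", "trnTrp", "trnHis", "trnArg", "trnGly", "trnTyr",
]

_MRNA_NAMES = ["psbA", "rbcL", "ndhB", "ycf1"]


def _poisson_weights(mean: float, lo: int, hi: int) -> dict[int, float]:
    out = {}
    for L in range(lo, hi + 1):
        out[L] = math.exp(-mean) * mean**L / math.factorial(L)
    tot = sum(out.values())
    return {L: w / tot for L, w in out.items()}


def _default_rrna_lengths() -> dict[int, float]:
    w = {L: 3.0 for L in range(16, 31)}
    for L in (18, 19, 21, 22):
        w[L] += 8.0
    w[25] += 6.0
    return w


def _default_trna_lengths() -> dict[int, float]:
    w = {L: 0.3 for L in range(16, 33)}
    w[23] += 1.5
    w[24] += 1.5
    w[29] += 8.0
    w[32] += 3.0
    return w


@dataclass
class SimulationConfig:
    """All knobs of the generator; identical config + seed gives identical
    output.  Fractions are of the library; length-mixture dicts map read
    length (nt) to unnormalized weight."""

    seed: int = 0
    n_reads: int = 50_000  # per condition, total library depth
    genome_length: int = 40_000
    nuclear_length: int = 60_000
    cycle_length: int = 42
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    reference: str = "MT"
    treatment: str = "HT"

    organellar_fraction: float = 0.5
    class_fractions: dict = field(
        default_factory=lambda: {"rRNA": 0.62, "tRNA": 0.15, "mRNA": 0.08, "igRNA": 0.15}
    )
    rrna_weights: dict = field(
        default_factory=lambda: {"rrn4.5": 0.7, "rrn23": 0.1, "rrn16": 0.1, "rrn5": 0.1}
    )
    rrna_anchor_prob: float = 0.9  # 3'-terminus anchoring
    trna_anchor_prob: float = 0.97  # 5'-terminus anchoring
    anchor_offset_probs: dict = field(
        default_factory=lambda: {-1: 0.01, 0: 0.98, 1: 0.01}
    )
    feature_offset_probs: dict = field(default_factory=dict)  # per-feature override

    rrna_lengths: dict = field(default_factory=_default_rrna_lengths)
    trna_lengths: dict = field(default_factory=_default_trna_lengths)
    mrna_lengths: dict = field(default_factory=lambda: {21: 1.0, 22: 1.0, 23: 1.0, 24: 1.0})
    ig_lengths: dict = field(default_factory=lambda: _poisson_weights(22.0, 16, 30))
    decoy_lengths: dict = field(default_factory=lambda: {21: 1.0, 22: 1.0, 23: 1.0, 24: 1.0})

    rrna_bg_sites: int = 8
    trna_bg_sites: int = 4
    mrna_sites: int = 12
    ig_sites: int = 30
    decoy_sites: int = 200
    shared_sites: int = 4
    cp_only_sites: int = 6
    shared_fraction: float = 0.01  # of library mass; igRNA reads also in nucleus
    cp_only_fraction: float = 0.01  # reads absent from the other species' plastome

    # condition effects (expected treatment/reference RPM ratios)
    class_rpm_targets: dict = field(default_factory=dict)  # e.g. {"rRNA": 0.49}
    trna_groups: dict = field(default_factory=dict)  # feature name -> I/II/III/IV
    group_multipliers: dict = field(
        default_factory=lambda: {
            "I": {"shorter": 2.0, "longer": 0.5, "other": 0.8},
            "II": {"shorter": 2.0, "longer": 1.0, "other": 0.9},
            "III": {"shorter": 1.0, "longer": 0.5, "other": 0.9},
        }
    )
    group_iv_length: int = 18  # group IV: this length halves, others unchanged
    exempt_lengths: list = field(default_factory=list)  # e.g. [24]
    rrna_unique_mask: float = 1.0  # fraction of rRNA slots retained in treatment
    shorter_window: list = field(default_factory=lambda: [16, 25])
    longer_window: list = field(default_factory=lambda: [29, 32])
    error_rate: float = 0.0  # per-base substitution rate (default: exact reads)

    def __post_init__(self) -> None:
        tot = sum(self.class_fractions.values())
        if abs(tot - 1.0) > 1e-9:
            raise ValueError(f"class fractions sum to {tot}, expected 1")
        if not 0 <= self.organellar_fraction <= 1:
            raise ValueError("organellar_fraction must be in [0, 1]")
        for p in (self.rrna_anchor_prob, self.trna_anchor_prob, self.rrna_unique_mask):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_config(**overrides) -> SimulationConfig:
    return SimulationConfig(**overrides)


def paper_scenario(**overrides) -> SimulationConfig:
    """Preset encoding the reported heat-response directions.

    rRNA abundance drops to ~0.49x with the unique-sequence pool shrinking
    to ~0.29x; igRNA rises ~1.3x; mRNA declines; tRNAs respond by size
    class according to their planted group (most are group I: shorter reads
    up, longer reads down); 24-nt reads are exempted from all effects.
    """
    groups = {}
    for name in ("trnAla", "trnAsp", "trnPhe", "trnLys", "trnLeu", "trnGln",
                 "trnThr", "trnVal", "trnTyr"):
        groups[name] = "I"
    for name in ("trnCys", "trnGlu", "trnIle", "trnMet", "trnAsn", "trnPro",
                 "trnSer", "trnTrp"):
        groups[name] = "II"
    for name in ("trnHis", "trnArg"):
        groups[name] = "III"
    groups["trnGly"] = "IV"
    params = dict(
        n_reads=800_000,
        class_rpm_targets={"rRNA": 0.49, "igRNA": 1.3, "mRNA": 0.5},
        trna_groups=groups,
        exempt_lengths=[24],
        rrna_unique_mask=0.29,
    )
    params.update(overrides)
    return SimulationConfig(**params)


# ---------------------------------------------------------------------------
# genome construction


@dataclass
class SyntheticGenome:
    chloroplast: GenomeRecord
    other_chloroplast: GenomeRecord
    nuclear: GenomeRecord
    features: list  # Feature, IR rRNA copies merged
    spacers: list  # plain spacer intervals usable as igRNA sources
    shared_block: tuple  # chloroplast interval copied into the nuclear genome
    divergent_region: tuple  # interval mutated in the other species' plastome
    ir_a: tuple
    ir_b: tuple

    def feature_by_name(self, name: str) -> Feature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def write_fasta(self, path, which: str = "chloroplast") -> None:
        rec = getattr(self, which)
        with open(path, "w") as fh:
            fh.write(f">{rec.genome_id}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")

    def write_gff(self, path) -> None:
        gid = self.chloroplast.genome_id
        lines = ["##gff-version 3"]
        for tag, (s, e) in (("IRa", self.ir_a), ("IRb", self.ir_b)):
            lines.append(
                f"{gid}\tsim\trepeat_region\t{s + 1}\t{e}\t.\t+\t.\tID={tag};Name={tag}"
            )
        for f in self.features:
            ftype = {"rRNA": "rRNA", "tRNA": "tRNA", "mRNA": "mRNA"}[f.cls]
            for ci, pl in enumerate(f.placements):
                fid = f.feature_id if ci == 0 else f"{f.feature_id}_ir{ci}"
                s, e = pl.span
                lines.append(
                    f"{gid}\tsim\t{ftype}\t{s + 1}\t{e}\t.\t{pl.strand}\t.\t"
                    f"ID={fid};Name={f.name}"
                )
                if len(pl.blocks) > 1:
                    for bi, (bs, be) in enumerate(pl.blocks, start=1):
                        lines.append(
                            f"{gid}\tsim\texon\t{bs + 1}\t{be}\t.\t{pl.strand}\t.\t"
                            f"ID={fid}.exon{bi};Parent={fid}"
                        )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(map("ACGT".__getitem__, rng.integers(0, 4, n)))


class _Builder:
    def __init__(self, rng: np.random.Generator):
        self.rng = rng
        self.parts: list[str] = []
        self.pos = 0
        self.features: list[Feature] = []
        self.spacers: list[tuple[int, int]] = []

    def add_seq(self, seq: str) -> tuple[int, int]:
        start = self.pos
        self.parts.append(seq)
        self.pos += len(seq)
        return start, self.pos

    def add_spacer(self, n: int, record: bool = True) -> tuple[int, int]:
        iv = self.add_seq(_rand_seq(self.rng, n))
        if record:
            self.spacers.append(iv)
        return iv

    def add_gene(
        self, name: str, cls: str, exon_lens: list[int], intron_lens: list[int],
        strand: str,
    ) -> Feature:
        blocks = []
        for i, el in enumerate(exon_lens):
            s, e = self.add_seq(_rand_seq(self.rng, el))
            blocks.append((s, e))
            if i < len(intron_lens):
                self.add_seq(_rand_seq(self.rng, intron_lens[i]))
        feat = Feature(name, cls, name, [Placement(tuple(blocks), strand)], "cp")
        self.features.append(feat)
        return feat


def generate_genome(
    config: SimulationConfig, rng: Optional[np.random.Generator] = None
) -> SyntheticGenome:
    """Build the chloroplast genome, its annotation, a second-species
    chloroplast diverged only in one designated spacer, and a nuclear decoy
    carrying one designed shared block.

    Placement ambiguity of the reads the generator will emit is checked in
    :func:`generate_libraries`, which regenerates the genome in the rare
    event a read sequence recurs by chance outside the designed
    duplications (inverted repeat, shared block).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    b = _Builder(rng)
    b.add_spacer(300)
    div_outer = b.add_spacer(400, record=False)
    divergent = (div_outer[0] + 50, div_outer[1] - 50)
    b.add_spacer(200)
    sh_outer = b.add_spacer(400, record=False)
    shared = (sh_outer[0] + 100, sh_outer[1] - 100)
    b.add_spacer(150)
    for i, name in enumerate(_TRNA_NAMES):
        strand = "-" if i % 3 == 2 else "+"
        if name == "trnAla":
            b.add_gene(name, "tRNA", [38, 35], [150], strand)
        else:
            b.add_gene(name, "tRNA", [int(rng.integers(72, 82))], [], strand)
        b.add_spacer(int(rng.integers(120, 220)))
    for name in _MRNA_NAMES:
        b.add_gene(name, "mRNA", [700], [], "+")
        b.add_spacer(int(rng.integers(150, 250)))

    ira_start = b.pos
    b.add_spacer(120)
    rrna_order = [("rrn16", 1490), ("rrn23", 2800), ("rrn4.5", 100), ("rrn5", 120)]
    gaps = [250, 90, 60]
    rrna_feats = []
    for j, (name, L) in enumerate(rrna_order):
        rrna_feats.append(b.add_gene(name, "rRNA", [L], [], "+"))
        if j < len(gaps):
            b.add_spacer(gaps[j])
    b.add_spacer(130)
    ira_end = b.pos
    b.add_spacer(1000)  # small single-copy region
    ira_seq = "".join(b.parts)[ira_start:ira_end]
    irb_start = b.pos
    b.add_seq(revcomp(ira_seq))
    irb_end = b.pos
    pad = config.genome_length - b.pos
    if pad < 200:
        raise ValueError(
            f"feature roster needs {b.pos + 200} nt but genome_length is "
            f"{config.genome_length}"
        )
    b.add_spacer(pad)
    cp_seq = "".join(b.parts)

    # mirror the rRNA features into IRb (merged: same Feature, 2nd placement)
    for f in rrna_feats:
        (s, e), strand = f.placements[0].span, f.placements[0].strand
        ms, me = irb_start + (ira_end - e), irb_start + (ira_end - s)
        f.placements.append(
            Placement(((ms, me),), "-" if strand == "+" else "+")
        )

    # nuclear decoy with the designed shared block
    nuc_pad = config.nuclear_length - (shared[1] - shared[0])
    half = nuc_pad // 2
    block = cp_seq[shared[0] : shared[1]]
    nuc_seq = _rand_seq(rng, half) + block + _rand_seq(rng, nuc_pad - half)
    nuc_block = (half, half + len(block))

    # second-species chloroplast: identical except the divergent spacer
    other = (
        cp_seq[: divergent[0]]
        + _rand_seq(rng, divergent[1] - divergent[0])
        + cp_seq[divergent[1] :]
    )

    return SyntheticGenome(
        chloroplast=GenomeRecord("cp", GenomeRole.CHLOROPLAST_PRIMARY, cp_seq, True),
        other_chloroplast=GenomeRecord(
            "cp_other", GenomeRole.CHLOROPLAST_OTHER, other, True
        ),
        nuclear=GenomeRecord("nuc", GenomeRole.NUCLEAR, nuc_seq, False),
        features=b.features,
        spacers=b.spacers,
        shared_block=shared,
        divergent_region=divergent,
        ir_a=(ira_start, ira_end),
        ir_b=(irb_start, irb_end),
    )


# ---------------------------------------------------------------------------
# read generation


def _tx_interval(pl: Placement, t0: int, L: int) -> tuple[int, int]:
    """Genomic interval of transcript-relative positions [t0, t0+L), in
    unspliced coordinates along the placement."""
    if pl.strand == "+":
        g5 = pl.blocks[0][0]
        return g5 + t0, g5 + t0 + L
    gend = pl.blocks[-1][1]
    return gend - t0 - L, gend - t0


def _norm(d: dict) -> dict:
    tot = sum(d.values())
    return {k: v / tot for k, v in d.items()}


def _sites(rng, lo: int, hi: int, n: int) -> list[int]:
    if hi <= lo:
        return []
    n = min(n, hi - lo)
    return sorted(int(x) for x in rng.choice(np.arange(lo, hi), size=n, replace=False))


@dataclass
class SimulationResult:
    """Slot-level ground truth plus the emitted read sequences.

    ``truth`` has one row per slot with per-condition counts; ``reads``
    maps condition to the list of raw (adapter-bearing) read sequences, in
    which reads of slot *i* occupy a contiguous run (``truth.read_offset``
    columns give the run starts).
    """

    config: SimulationConfig
    genome: SyntheticGenome
    truth: pd.DataFrame
    reads: dict

    def expand_truth(self, condition: str) -> pd.DataFrame:
        """Per-read provenance: one row per emitted read of a condition."""
        col = f"count_{condition}"
        rep = self.truth.loc[self.truth.index.repeat(self.truth[col])]
        return rep.reset_index().rename(columns={"index": "slot"})

    def write_fastq(self, condition: str, path) -> None:
        with open(path, "w") as fh:
            for i, seq in enumerate(self.reads[condition]):
                fh.write(f"@{condition}_r{i}\n{seq}\n+\n{'I' * len(seq)}\n")


def _build_slots(config: SimulationConfig, genome: SyntheticGenome, rng) -> pd.DataFrame:
    cp = genome.chloroplast.sequence
    rows = []

    def offset_probs(fname: str) -> dict:
        return _norm(config.feature_offset_probs.get(fname, config.anchor_offset_probs))

    ig_frac = config.class_fractions["igRNA"]
    plain_ig = ig_frac - config.shared_fraction / config.organellar_fraction - (
        config.cp_only_fraction / config.organellar_fraction
    )
    if plain_ig <= 0:
        raise ValueError("shared/cp-only fractions exceed the igRNA budget")

    fo = config.organellar_fraction

    # rRNA: 3'-anchored plus background processing sites
    rl = _norm(config.rrna_lengths)
    bg_lens = _norm(
        dict(sorted(config.rrna_lengths.items(), key=lambda kv: -kv[1])[:5])
    )
    for fname, fw in _norm(config.rrna_weights).items():
        feat = genome.feature_by_name(fname)
        pl = feat.placements[0]
        Lf = pl.length
        W = fo * config.class_fractions["rRNA"] * fw
        for off, po in offset_probs(fname).items():
            for L, wl in rl.items():
                s, e = _tx_interval(pl, Lf - 1 + off - L + 1, L)
                rows.append(
                    ("anchored", "rRNA", fname, "cp", s, e, pl.strand, L, off,
                     W * config.rrna_anchor_prob * po * wl)
                )
        max_bg = max(bg_lens)
        sites = _sites(rng, 0, Lf - max_bg, config.rrna_bg_sites)
        for site in sites:
            for L, wl in bg_lens.items():
                s, e = _tx_interval(pl, site, L)
                rows.append(
                    ("background", "rRNA", fname, "cp", s, e, pl.strand, L, None,
                     W * (1 - config.rrna_anchor_prob) * wl / len(sites))
                )

    # tRNA: 5'-anchored plus background sites
    tl = _norm(config.trna_lengths)
    t_bg = _norm(dict(sorted(config.trna_lengths.items(), key=lambda kv: -kv[1])[:5]))
    n_trna = len(_TRNA_NAMES)
    for fname in _TRNA_NAMES:
        feat = genome.feature_by_name(fname)
        pl = feat.placements[0]
        span_len = pl.span[1] - pl.span[0]
        W = fo * config.class_fractions["tRNA"] / n_trna
        for off, po in offset_probs(fname).items():
            for L, wl in tl.items():
                s, e = _tx_interval(pl, off, L)
                rows.append(
                    ("anchored", "tRNA", fname, "cp", s, e, pl.strand, L, off,
                     W * config.trna_anchor_prob * po * wl)
                )
        max_bg = max(t_bg)
        sites = _sites(rng, 2, max(3, span_len - max_bg), config.trna_bg_sites)
        for site in sites:
            for L, wl in t_bg.items():
                s, e = _tx_interval(pl, site, L)
                rows.append(
                    ("background", "tRNA", fname, "cp", s, e, pl.strand, L, None,
                     W * (1 - config.trna_anchor_prob) * wl / len(sites))
                )

    # mRNA: site-based
    ml = _norm(config.mrna_lengths)
    for fname in _MRNA_NAMES:
        feat = genome.feature_by_name(fname)
        pl = feat.placements[0]
        W = fo * config.class_fractions["mRNA"] / len(_MRNA_NAMES)
        sites = _sites(rng, 0, pl.length - max(ml), config.mrna_sites)
        for site in sites:
            for L, wl in ml.items():
                s, e = _tx_interval(pl, site, L)
                rows.append(
                    ("background", "mRNA", fname, "cp", s, e, pl.strand, L, None,
                     W * wl / len(sites))
                )

    # igRNA: sites spread over plain spacers, alternating strand
    il = _norm(config.ig_lengths)
    max_ig = max(il)
    candidates = []
    for s, e in genome.spacers:
        candidates.extend(range(s, e - max_ig))
    idx = _sites(rng, 0, len(candidates), config.ig_sites)
    W = fo * plain_ig
    for j, ci in enumerate(idx):
        gs = candidates[ci]
        strand = "+" if j % 2 == 0 else "-"
        for L, wl in il.items():
            rows.append(
                ("intergenic", "igRNA", None, "cp", gs, gs + L, strand, L, None,
                 W * wl / len(idx))
            )

    # shared block: chloroplast reads whose sequence also occurs in the nucleus
    sb = genome.shared_block
    sh_sites = _sites(rng, sb[0], sb[1] - max_ig, config.shared_sites)
    for gs in sh_sites:
        for L, wl in il.items():
            rows.append(
                ("shared", "igRNA", None, "cp", gs, gs + L, "+", L, None,
                 config.shared_fraction * wl / len(sh_sites))
            )

    # primary-chloroplast-only reads (divergent in the other species)
    dv = genome.divergent_region
    dv_sites = _sites(rng, dv[0], dv[1] - max_ig, config.cp_only_sites)
    for gs in dv_sites:
        for L, wl in il.items():
            rows.append(
                ("cp_only", "igRNA", None, "cp", gs, gs + L, "+", L, None,
                 config.cp_only_fraction * wl / len(dv_sites))
            )

    # nuclear decoy reads
    dl = _norm(config.decoy_lengths)
    W = 1.0 - fo
    dc_sites = _sites(
        rng, 0, len(genome.nuclear.sequence) - max(dl), config.decoy_sites
    )
    for gs in dc_sites:
        for L, wl in dl.items():
            rows.append(
                ("decoy", None, None, "nuc", gs, gs + L, "+", L, None,
                 W * wl / len(dc_sites))
            )

    df = pd.DataFrame(
        rows,
        columns=["source", "cls", "feature", "genome", "start", "end", "strand",
                 "length", "offset", "weight"],
    )
    df = df[df["weight"] > 0].reset_index(drop=True)
    df["weight"] /= df["weight"].sum()
    return df


def _multiplier(config: SimulationConfig, row) -> float:
    if row.source == "decoy":
        return 1.0
    if row.length in config.exempt_lengths:
        return 1.0
    if row.cls == "tRNA" and config.trna_groups:
        group = config.trna_groups.get(row.feature)
        if group is None:
            return 1.0
        if group == "IV":
            return 0.5 if row.length == config.group_iv_length else 1.0
        gm = config.group_multipliers[group]
        lo, hi = config.shorter_window
        if lo <= row.length <= hi:
            return gm["shorter"]
        lo, hi = config.longer_window
        if lo <= row.length <= hi:
            return gm["longer"]
        return gm["other"]
    if row.cls in config.class_rpm_targets:
        target = config.class_rpm_targets[row.cls]
        if config.exempt_lengths:
            # solve the non-exempt multiplier so the class-level RPM ratio
            # still lands on the target despite the exempted lengths
            if row.cls == "rRNA":
                mix = _norm(config.rrna_lengths)
            elif row.cls == "mRNA":
                mix = _norm(config.mrna_lengths)
            else:
                mix = _norm(config.ig_lengths)
            w_ex = sum(mix.get(L, 0.0) for L in config.exempt_lengths)
            if w_ex < 1.0:
                return (target - w_ex) / (1.0 - w_ex)
        return target
    return 1.0


def _slots_unambiguous(genome: SyntheticGenome, slots: pd.DataFrame) -> bool:
    """Check every slot's read sequence occurs only at its designed loci.

    Reads from inverted-repeat rRNA features must hit the chloroplast
    exactly twice, shared-block reads must also occur in the nucleus, and
    everything else must be single-locus; a chance recurrence elsewhere
    (possible in random sequence) fails the check so the genome can be
    redrawn.
    """
    from .genome_index import GenomeIndex

    ix_cp = GenomeIndex(genome.chloroplast)
    ix_nuc = GenomeIndex(genome.nuclear)
    other = genome.other_chloroplast.sequence
    seqs = {"cp": genome.chloroplast.sequence, "nuc": genome.nuclear.sequence}
    for row in slots.itertuples():
        s = seqs[row.genome][row.start : row.end]
        if row.strand == "-":
            s = revcomp(s)
        n_cp = len(ix_cp.find(s))
        n_nuc = len(ix_nuc.find(s))
        if row.source == "decoy":
            if n_cp != 0 or n_nuc != 1:
                return False
        elif row.source == "shared":
            if n_cp != 1 or n_nuc != 1:
                return False
        elif row.cls == "rRNA":
            if n_cp != 2 or n_nuc != 0:
                return False
        else:
            if n_cp != 1 or n_nuc != 0:
                return False
            if row.source == "cp_only" and (s in other or revcomp(s) in other):
                return False
    return True


def generate_libraries(
    config: SimulationConfig,
    genome: Optional[SyntheticGenome] = None,
    rng: Optional[np.random.Generator] = None,
) -> SimulationResult:
    """Draw the condition-paired libraries and their ground truth.

    The reference library draws ``n_reads`` from the slot weights.  The
    treatment library re-weights organellar slots by their multipliers
    (optionally masking a fraction of rRNA slots to shrink the unique pool,
    with the masked mass redistributed within the same read length so
    per-length ratios are preserved) and adjusts its depth so each slot's
    expected RPM ratio equals its planted multiplier.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if genome is None:
        for _attempt in range(20):
            genome = generate_genome(config, rng)
            slots = _build_slots(config, genome, rng)
            if _slots_unambiguous(genome, slots):
                break
        else:
            raise RuntimeError("could not build a genome with unambiguous reads")
    else:
        slots = _build_slots(config, genome, rng)
    slots["multiplier"] = [_multiplier(config, r) for r in slots.itertuples()]

    w = slots["weight"].to_numpy()
    org = (slots["source"] != "decoy").to_numpy()
    v = w * slots["multiplier"].to_numpy()

    # optional unique-pool shrinkage for rRNA: keep a deterministic number
    # of slots (largest-remainder quotas per read length, membership drawn
    # at random), redistributing the removed mass within the same length so
    # per-length abundance ratios are untouched
    if config.rrna_unique_mask < 1.0:
        is_r = (slots["cls"] == "rRNA").to_numpy()
        keep = np.ones(len(slots), dtype=bool)
        groups = {
            L: np.flatnonzero(is_r & (slots["length"] == L).to_numpy())
            for L in sorted(slots.loc[is_r, "length"].unique())
        }
        m_total = sum(len(ix) for ix in groups.values())
        k_total = max(len(groups), int(round(config.rrna_unique_mask * m_total)))
        quotas = {L: max(1, int(config.rrna_unique_mask * len(ix))) for L, ix in groups.items()}
        remainders = sorted(
            groups,
            key=lambda L: -(config.rrna_unique_mask * len(groups[L]) - quotas[L]),
        )
        i = 0
        while sum(quotas.values()) < k_total and i < 10 * len(groups):
            L = remainders[i % len(remainders)]
            if quotas[L] < len(groups[L]):
                quotas[L] += 1
            i += 1
        for L, ix in groups.items():
            kept = rng.choice(ix, size=min(quotas[L], len(ix)), replace=False)
            drop = np.setdiff1d(ix, kept)
            keep[drop] = False
            mass = v[ix].sum()
            kept_mass = v[kept].sum()
            v[drop] = 0.0
            if kept_mass > 0:
                v[kept] *= mass / kept_mass
        slots["masked"] = ~keep
    else:
        slots["masked"] = False

    n = config.n_reads
    f_cs = w[org].sum()
    r_rel = v[org].sum() / f_cs
    n_decoy = n * (1 - f_cs)
    depth_t = n_decoy / (1 - f_cs * r_rel) if f_cs * r_rel < 1 else n
    c_org = depth_t - n_decoy

    counts_ref = rng.multinomial(n, w)
    counts_trt = np.zeros(len(slots), dtype=int)
    if org.any() and c_org > 0:
        p = v[org] / v[org].sum()
        counts_trt[org] = rng.multinomial(int(round(c_org)), p)
    if (~org).any() and n_decoy > 0:
        p = w[~org] / w[~org].sum()
        counts_trt[~org] = rng.multinomial(int(round(n_decoy)), p)
    slots[f"count_{config.reference}"] = counts_ref
    slots[f"count_{config.treatment}"] = counts_trt

    # emit adapter-bearing fixed-cycle reads
    pad_tail = "ACACTCTTTCCCTACACGACGCTCTTCCGATCT" * 3
    seqs = {"cp": genome.chloroplast.sequence, "nuc": genome.nuclear.sequence}
    inserts = []
    for row in slots.itertuples():
        s = seqs[row.genome][row.start : row.end]
        if row.strand == "-":
            s = revcomp(s)
        inserts.append(s)
    slots["insert"] = inserts

    reads = {}
    for cond in (config.reference, config.treatment):
        col = f"count_{cond}"
        out = []
        offsets = []
        for ins, c in zip(inserts, slots[col]):
            offsets.append(len(out))
            if c == 0:
                continue
            raw = (ins + config.adapter + pad_tail)[: config.cycle_length]
            if config.error_rate > 0:
                for _ in range(c):
                    chars = list(raw)
                    for i in range(len(chars)):
                        if rng.random() < config.error_rate:
                            chars[i] = "ACGT"[rng.integers(0, 4)]
                    out.append("".join(chars))
            else:
                out.extend([raw] * int(c))
        slots[f"read_offset_{cond}"] = offsets
        reads[cond] = out
    return SimulationResult(config=config, genome=genome, truth=slots, reads=reads)
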