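"""End-to-end orchestration: collapse -> match -> classify -> profile ->
families -> differential, with TSV report output.

:func:`run_analysis` is the in-memory engine used by the programmatic API
and the tests; :func:`run_pipeline` wraps it with file input/output and a
fixed set of diff-able TSV reports (mapping summary, class composition,
size distributions, positional profiles, family table, differential
tables, tRNA response groups).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, fields as dc_fields
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import sequence_io as sio
from . import genome_index as gi
from . import origin_annotation as oa
from . import positional_profile as pp
from . import family_clustering as fc
from . import differential_analysis as da

__all__ = ["PipelineConfig", "PipelineResult", "run_analysis", "run_pipeline"]

log = logging.getLogger("chlorosmall")


@dataclass
class PipelineConfig:
    """Serializable configuration of the full pipeline."""

    fastq: dict = field(default_factory=dict)  # library id -> path
    chloroplast_fasta: str = ""
    other_chloroplast_fasta: Optional[str] = None
    nuclear_fasta: Optional[str] = None
    mitochondrial_fasta: Optional[str] = None
    gff: str = ""
    out_dir: str = "chlorosmall_out"
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    min_overlap: int = 5
    min_len: int = 9
    max_len: int = 36
    keep_untrimmed: bool = False
    n_blocks: int = 20
    min_core: int = 9
    down_threshold: float = 0.2
    up_threshold: float = 5.0
    trend_threshold: float = 1.2
    pseudocount: float = 0.5
    reference: Optional[str] = None  # default: first library
    treatment: Optional[str] = None  # default: second library
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dc_fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class PipelineResult:
    collapsed: dict
    libraries: list
    hits: dict
    membership: dict
    csrnas: set
    chloroplast_specific: set
    summary: pd.DataFrame
    assignments: dict
    composition: pd.DataFrame
    size_dist: pd.DataFrame
    profiles: dict
    families: list
    family_table: pd.DataFrame
    differential: Optional[pd.DataFrame]
    class_summary: Optional[pd.DataFrame]
    class_length_summary: Optional[pd.DataFrame]
    response_groups: Optional[pd.DataFrame]
    stage_log: list


def _family_members(
    assignments: Mapping[str, oa.OriginAssignment], collapsed
) -> list[fc.FamilyMember]:
    members = []
    for seq, a in assignments.items():
        if a.hit is None:
            continue
        counts = tuple(sorted(collapsed[seq].counts.items())) if seq in collapsed else ()
        members.append(
            fc.FamilyMember(seq, a.hit.start, a.hit.end, a.hit.strand, counts)
        )
    return members


def _family_table(families: Sequence[fc.Family], library_ids: Sequence[str]) -> pd.DataFrame:
    rows = []
    for f in families:
        _, modes = fc.family_size_distribution(f)
        row = {
            "family_id": f.family_id,
            "strand": f.strand,
            "core_start": f.core_start,
            "core_end": f.core_end,
            "core_sequence": f.core_sequence,
            "n_members": len(f.members),
            "modes": ",".join(str(m) for m in modes),
        }
        for lid in library_ids:
            row[f"mass_{lid}"] = f.total(lid)
        rows.append(row)
    return pd.DataFrame(rows)


def run_analysis(
    raw_reads: Mapping[str, Iterable[str]],
    genomes: Sequence[gi.GenomeRecord],
    features: Sequence[oa.Feature],
    adapter: str,
    min_overlap: int = 5,
    min_len: int = 9,
    max_len: int = 36,
    keep_untrimmed: bool = False,
    n_blocks: int = 20,
    min_core: int = 9,
    down: float = 0.2,
    up: float = 5.0,
    trend_threshold: float = 1.2,
    pseudocount: float = 0.5,
    reference: Optional[str] = None,
    treatment: Optional[str] = None,
) -> PipelineResult:
    """Run every analysis stage on in-memory raw read sequences.

    ``raw_reads`` maps library id to an iterable of raw (adapter-bearing)
    read sequences.  Differential stages run when at least two libraries
    are present (``reference``/``treatment`` default to the first two).
    """
    stage_log = []
    collapsed: dict[str, sio.CollapsedRead] = {}
    libraries: list[sio.Library] = []
    for lid, seqs in raw_reads.items():
        trimmed = []
        for s in seqs:
            t = sio.trim_adapter(s, adapter, min_overlap)
            if t is None and keep_untrimmed:
                t = s
            trimmed.append(t)
        col, lib = sio.collapse_reads(trimmed, lid, min_len, max_len)
        libraries.append(lib)
        for seq, rec in col.items():
            tgt = collapsed.setdefault(seq, sio.CollapsedRead(seq, {}))
            tgt.counts[lid] = tgt.counts.get(lid, 0) + rec.counts[lid]
        stage_log.append(
            {
                "stage": "collapse",
                "library": lid,
                "reads_in": lib.total_reads,
                "reads_out": lib.passed_reads,
                "filtered": lib.total_reads - lib.passed_reads,
            }
        )
        log.info("collapse %s: %d reads in, %d passed", lid, lib.total_reads, lib.passed_reads)

    hits, membership = gi.match_reads(collapsed, genomes)
    roles = {g.role for g in (g.genome if isinstance(g, gi.GenomeIndex) else g for g in genomes)}
    two_species = gi.GenomeRole.CHLOROPLAST_OTHER in roles
    csrnas = gi.select_csrnas(membership, two_species)
    specific = gi.select_chloroplast_specific(membership, two_species)
    summary = gi.mapping_summary(libraries, membership, collapsed)
    stage_log.append(
        {"stage": "match", "unique_in": len(collapsed), "csrnas": len(csrnas),
         "chloroplast_specific": len(specific)}
    )

    primary_id = next(
        (g.genome if isinstance(g, gi.GenomeIndex) else g).genome_id
        for g in genomes
        if (g.genome if isinstance(g, gi.GenomeIndex) else g).role
        == gi.GenomeRole.CHLOROPLAST_PRIMARY
    )
    assignments = oa.assign_origins(hits, features, genome_id=primary_id, reads=csrnas)
    lib_ids = [l.library_id for l in libraries]
    composition = oa.composition_table(assignments, collapsed, lib_ids)
    size_dist = oa.size_distribution(assignments, collapsed, lib_ids, by_class=True)
    stage_log.append({"stage": "classify", "assigned": len(assignments)})

    profiles: dict[str, object] = {}
    for cls in ("rRNA", "tRNA"):
        if any(a.origin_class == cls for a in assignments.values()):
            profiles[cls] = pp.block_profile(
                assignments, origin_class=cls, features=features,
                n_blocks=n_blocks, collapsed=collapsed,
            )
    for f in features:
        if f.cls == "rRNA" and any(
            a.feature_id == f.feature_id for a in assignments.values()
        ):
            profiles[f"{f.name}:3-prime"] = pp.terminus_offsets(
                assignments, f, "3-prime", collapsed=collapsed
            )

    members = _family_members(assignments, collapsed)
    cp = next(
        (g.genome if isinstance(g, gi.GenomeIndex) else g)
        for g in genomes
        if (g.genome if isinstance(g, gi.GenomeIndex) else g).genome_id == primary_id
    )
    families = fc.cluster_families(
        members, min_core=min_core, genome_id=primary_id,
        genome_sequence=cp.sequence,
    )
    family_table = _family_table(families, lib_ids)
    stage_log.append({"stage": "families", "members": len(members), "families": len(families)})

    differential = class_summary = class_length_summary = response_groups = None
    if len(libraries) >= 2:
        ref = reference or lib_ids[0]
        trt = treatment or (lib_ids[1] if lib_ids[1] != ref else lib_ids[0])
        depths = {l.library_id: l.total_reads for l in libraries}
        differential = da.differential_table(
            collapsed, depths, ref, trt, sequences=sorted(csrnas),
            pseudocount=pseudocount, down=down, up=up,
        )
        class_summary = da.class_fold_summary(assignments, collapsed, depths, ref, trt)
        class_length_summary = da.class_fold_summary(
            assignments, collapsed, depths, ref, trt, by_length=True
        )
        response_groups = da.trna_response_groups(
            assignments, collapsed, features, depths, ref, trt,
            trend_threshold=trend_threshold, pseudocount=pseudocount,
        )
        stage_log.append({"stage": "differential", "units": len(differential)})

    return PipelineResult(
        collapsed=collapsed, libraries=libraries, hits=hits,
        membership=membership, csrnas=csrnas, chloroplast_specific=specific,
        summary=summary, assignments=assignments, composition=composition,
        size_dist=size_dist, profiles=profiles, families=families,
        family_table=family_table, differential=differential,
        class_summary=class_summary, class_length_summary=class_length_summary,
        response_groups=response_groups, stage_log=stage_log,
    )


def _load_genomes(config: PipelineConfig) -> list[gi.GenomeRecord]:
    from Bio import SeqIO

    specs = [
        (config.chloroplast_fasta, gi.GenomeRole.CHLOROPLAST_PRIMARY, True),
        (config.other_chloroplast_fasta, gi.GenomeRole.CHLOROPLAST_OTHER, True),
        (config.nuclear_fasta, gi.GenomeRole.NUCLEAR, False),
        (config.mitochondrial_fasta, gi.GenomeRole.MITOCHONDRIAL, True),
    ]
    genomes = []
    for path, role, circular in specs:
        if not path:
            continue
        rec = next(SeqIO.parse(path, "fasta"))
        genomes.append(gi.GenomeRecord(rec.id, role, str(rec.seq).upper(), circular))
    return genomes


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """File-based pipeline: read FASTQ + FASTA + GFF3, write TSV reports.

    Returns a mapping of report name to output path.  Any stage failure
    raises with the stage name in the message.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "input"
    try:
        if not config.fastq:
            raise FileNotFoundError("no FASTQ libraries configured")
        genomes = _load_genomes(config)
        if not genomes:
            raise FileNotFoundError("chloroplast_fasta is required")
        stage = "annotation"
        if not config.gff or not Path(config.gff).exists():
            raise FileNotFoundError(f"GFF file not found: {config.gff!r}")
        primary = genomes[0]
        features = oa.load_gff(
            config.gff, len(primary.sequence), primary.genome_id, primary.circular
        )
        stage = "analysis"
        raw = {
            lid: (r.sequence for r in sio.read_fastq(path))
            for lid, path in config.fastq.items()
        }
        res = run_analysis(
            raw, genomes, features,
            adapter=config.adapter, min_overlap=config.min_overlap,
            min_len=config.min_len, max_len=config.max_len,
            keep_untrimmed=config.keep_untrimmed, n_blocks=config.n_blocks,
            min_core=config.min_core, down=config.down_threshold,
            up=config.up_threshold, trend_threshold=config.trend_threshold,
            pseudocount=config.pseudocount, reference=config.reference,
            treatment=config.treatment,
        )
        stage = "report"
        paths = {}

        def save(name: str, df: Optional[pd.DataFrame]) -> None:
            if df is None:
                df = pd.DataFrame()
            p = out / f"{name}.tsv"
            df.to_csv(p, sep="\t", index=False, float_format="%.6g")
            paths[name] = p

        save("mapping_summary", res.summary)
        save("composition", res.composition)
        save("size_distribution", res.size_dist)
        prof_frames = [
            p.to_frame() for p in res.profiles.values() if isinstance(p, pp.BlockProfile)
        ]
        save("block_profiles", pd.concat(prof_frames) if prof_frames else None)
        offset_rows = []
        for key, p in res.profiles.items():
            if isinstance(p, pp.TerminusOffsetHistogram):
                for off, mass in sorted(p.offsets.items()):
                    offset_rows.append(
                        {"feature": p.label, "anchor": p.anchor, "offset": off, "mass": mass}
                    )
        save("terminus_offsets", pd.DataFrame(offset_rows))
        save("families", res.family_table)
        save("differential", res.differential)
        save("class_fold_summary", res.class_summary)
        save("class_length_fold_summary", res.class_length_summary)
        save("response_groups", res.response_groups)
        save("stage_log", pd.DataFrame(res.stage_log))
        gi.hits_to_bed(
            {s: res.hits[s] for s in res.csrnas}, res.collapsed, out / "csrna_hits.bed"
        )
        paths["csrna_hits"] = out / "csrna_hits.bed"
        return paths
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
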