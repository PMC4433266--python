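"""Pipeline orchestration and report tables.

Runs preprocess -> annotate -> discover -> diffexpr -> targets on two
raw libraries plus the three reference FASTA files, writing TSV reports
(read-category accounting, two-library overlap, length distribution,
ncRNA class accounting, conserved members, novel candidates,
differential expression, target hits) and a run manifest with the
configuration hash and per-stage counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import annotation, diff_expr, novel_discovery, preprocessing
from ._seq import normalize
from .preprocessing import CleaningParams, UniqueTag, round_half_up
from .novel_discovery import DiscoveryParams
from .target_prediction import scan_transcripts

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger("smallrna")

_THRESHOLD_RANGES = {
    "quality_threshold": (0, 41),
    "min_len": (10, 30),
    "max_len": (18, 50),
    "min_reads": (1, 10_000),
    "mfe_threshold": (-1000.0, 0.0),
    "flank": (20, 1000),
    "pseudo": (1e-9, 10.0),
    "fc_threshold": (0.0, 20.0),
    "p_extreme": (0.0, 1.0),
    "p_significant": (0.0, 1.0),
    "target_cutoff": (0.0, 20.0),
}


@dataclass
class PipelineConfig:
    fastq1: str = ""
    fastq2: str = ""
    mature_reference: str = ""
    ncrna_reference: str = ""
    transcripts: str = ""
    outdir: str = "smallrna_out"
    adapter: str = preprocessing.DEFAULT_ADAPTER_3P
    adapter_5p: str = preprocessing.DEFAULT_ADAPTER_5P
    quality_threshold: int = 20
    min_len: int = 18
    max_len: int = 30
    min_reads: int = 10
    require_both: bool = True
    mfe_threshold: float = -18.0
    flank: int = 150
    pseudo: float = 0.01
    sided: str = "two"
    fc_threshold: float = 1.5
    p_extreme: float = 0.01
    p_significant: float = 0.05
    exclusion_mode: str = "rpm"
    target_cutoff: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name, (lo, hi) in _THRESHOLD_RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise ValueError(f"{name}={v} outside documented range [{lo}, {hi}]")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    _PATH_FIELDS = (
        "fastq1", "fastq2", "mature_reference", "ncrna_reference",
        "transcripts", "outdir",
    )

    def config_hash(self) -> str:
        """Hash of the analysis parameters (paths excluded, so reruns of
        the same inputs into different directories stay comparable)."""
        payload = {
            k: v for k, v in dataclasses.asdict(self).items()
            if k not in self._PATH_FIELDS
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    category_counts: tuple
    tags: list[UniqueTag]
    overlap: preprocessing.OverlapSummary
    summary: annotation.AnnotationSummary
    members: list[annotation.MiRNAMember]
    conserved: dict
    candidates: list
    de_records: list
    target_hits: list
    stage_counts: dict[str, int]


def _check_inputs(config: PipelineConfig) -> None:
    for name in ("fastq1", "fastq2", "mature_reference", "ncrna_reference", "transcripts"):
        path = getattr(config, name)
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"input file for {name!r} not found: {path!r}")


def _write_table1(path: Path, c1, c2) -> None:
    rows = []
    for label, attr in [
        ("Total reads", "total_reads"),
        ("High quality", "high_quality"),
        ("Adaptor 3'-null", "adaptor3_null"),
        ("Insert-null", "insert_null"),
        ("Adaptor 5'-contaminants", "adaptor5_contaminant"),
        ("Sequences <18nt", "below_18nt"),
        ("PolyA", "polyA"),
        ("Clean reads", "clean_reads"),
    ]:
        rows.append({"Type": label, "lib1": getattr(c1, attr), "lib2": getattr(c2, attr)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _write_table2(path: Path, ov: preprocessing.OverlapSummary) -> None:
    pct = ov.percentages
    rows = [
        ("Total sRNAs", ov.total_unique, pct["total_unique"], ov.total_reads, pct["total_reads"]),
        ("Shared", ov.shared_unique, pct["shared_unique"], ov.shared_reads, pct["shared_reads"]),
        ("Lib1-specific", ov.lib1_specific_unique, pct["lib1_specific_unique"],
         ov.lib1_specific_reads, pct["lib1_specific_reads"]),
        ("Lib2-specific", ov.lib2_specific_unique, pct["lib2_specific_unique"],
         ov.lib2_specific_reads, pct["lib2_specific_reads"]),
    ]
    pd.DataFrame(
        rows, columns=["Category", "Unique", "Unique %", "Reads", "Reads %"]
    ).to_csv(path, sep="\t", index=False)


def _write_table3(path: Path, summary: annotation.AnnotationSummary) -> None:
    pct_u = summary.percentages("unique")
    pct_r = summary.percentages("reads")
    rows = []
    for cls in annotation.SUMMARY_CLASSES:
        u, r = summary.unique[cls], summary.reads[cls]
        rows.append(
            {
                "Category": cls,
                "Unique lib1": u[0], "Unique lib1 %": pct_u[cls][0],
                "Unique lib2": u[1], "Unique lib2 %": pct_u[cls][1],
                "Reads lib1": r[0], "Reads lib1 %": pct_r[cls][0],
                "Reads lib2": r[1], "Reads lib2 %": pct_r[cls][1],
            }
        )
    rows.append(
        {
            "Category": "Total",
            "Unique lib1": summary.total_unique[0], "Unique lib1 %": 100.0,
            "Unique lib2": summary.total_unique[1], "Unique lib2 %": 100.0,
            "Reads lib1": summary.total_reads[0], "Reads lib1 %": 100.0,
            "Reads lib2": summary.total_reads[1], "Reads lib2 %": 100.0,
        }
    )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute all stages; any stage failure aborts with stage context."""
    _check_inputs(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage_counts: dict[str, int] = {}
    params = CleaningParams(
        adapter_3p=config.adapter,
        adapter_5p=config.adapter_5p,
        min_quality=config.quality_threshold,
        min_len=config.min_len,
        max_len=config.max_len,
    )

    stage = "preprocess"
    try:
        logger.info("stage %s", stage)
        tags1, counts1 = preprocessing.clean_reads(config.fastq1, params, library=1)
        tags2, counts2 = preprocessing.clean_reads(config.fastq2, params, library=2)
        tags = preprocessing.merge_tag_counts(tags1, tags2)
        overlap = preprocessing.overlap_summary(tags)
        _write_table1(outdir / "read_categories.tsv", counts1, counts2)
        _write_table2(outdir / "library_overlap.tsv", overlap)
        ld = preprocessing.length_distribution(tags, "reads")
        pd.DataFrame(
            [(k, round_half_up(100 * v, 2)) for k, v in ld.items()],
            columns=["length", "percent_reads"],
        ).to_csv(outdir / "length_distribution.tsv", sep="\t", index=False)
        preprocessing.write_collapsed_fasta(tags, outdir / "clean_tags.fasta")
        stage_counts["clean_reads_lib1"] = counts1.clean_reads
        stage_counts["clean_reads_lib2"] = counts2.clean_reads
        stage_counts["unique_tags"] = len(tags)

        stage = "annotate"
        logger.info("stage %s", stage)
        ncrna_ref = annotation.load_class_reference(config.ncrna_reference)
        mature_ref = annotation.load_mature_reference(config.mature_reference)
        ncrna, conserved, unannotated, summary = annotation.annotate_tags(
            tags, ncrna_ref, mature_ref,
            config.min_reads, require_both=config.require_both,
        )
        members = annotation.collapse_members(conserved, tags)
        _write_table3(outdir / "ncrna_classes.tsv", summary)
        pd.DataFrame(
            [
                {
                    "member": m.member_id,
                    "family": m.family,
                    "isoforms": len(m.isoform_tags),
                    "representative": m.representative.sequence,
                    "count_lib1": m.count_lib1,
                    "count_lib2": m.count_lib2,
                }
                for m in members
            ]
        ).to_csv(outdir / "conserved_members.tsv", sep="\t", index=False)
        stage_counts["conserved_tags"] = len(conserved)
        stage_counts["conserved_members"] = len(members)

        stage = "discover"
        logger.info("stage %s", stage)
        transcripts = {
            rec.id: normalize(str(rec.seq))
            for rec in SeqIO.parse(config.transcripts, "fasta")
        }
        candidate_tags = [t for t in unannotated if t.total >= config.min_reads]
        tag_hits = annotation.map_to_transcripts(candidate_tags, transcripts)
        disc_params = DiscoveryParams(
            flank=config.flank,
            min_reads=config.min_reads,
            mfe_threshold=config.mfe_threshold,
        )
        candidates = novel_discovery.discover_novel(
            tag_hits, candidate_tags, transcripts, disc_params
        )
        accepted = [c for c in candidates if c.accepted]
        accepted.sort(key=lambda c: (-c.mature_tag.total, c.host))
        novel_ids = {id(c): f"miRN{i + 1:02d}" for i, c in enumerate(accepted)}
        pd.DataFrame(
            [
                {
                    "id": novel_ids[id(c)],
                    "host": c.host,
                    "start": c.precursor_interval[0],
                    "end": c.precursor_interval[1],
                    "precursor_length": len(c.precursor.sequence),
                    "mfe": c.precursor.mfe,
                    "mature": c.mature_tag.sequence,
                    "arm": c.mature_arm,
                    "count_lib1": c.mature_tag.count_lib1,
                    "count_lib2": c.mature_tag.count_lib2,
                    "star": c.star_tag.sequence if c.star_tag else "",
                    "star_count_lib1": c.star_tag.count_lib1 if c.star_tag else 0,
                    "star_count_lib2": c.star_tag.count_lib2 if c.star_tag else 0,
                    "first_nt": c.first_nt,
                }
                for c in accepted
            ]
        ).to_csv(outdir / "novel_candidates.tsv", sep="\t", index=False)
        with open(outdir / "novel_precursors.fold", "w") as out:
            for c in accepted:
                out.write(
                    f">{novel_ids[id(c)]} {c.host}:{c.precursor_interval[0]}-"
                    f"{c.precursor_interval[1]}\n{c.precursor.sequence}\n"
                    f"{c.precursor.structure} ({c.precursor.mfe:.1f})\n"
                )
        stage_counts["novel_candidates"] = len(accepted)
        stage_counts["novel_with_star"] = sum(
            1 for c in accepted if c.star_tag is not None
        )

        stage = "diffexpr"
        logger.info("stage %s", stage)
        pair = diff_expr.LibraryPair(
            max(counts1.clean_reads, 1), max(counts2.clean_reads, 1)
        )
        de_input: dict[str, tuple[int, int]] = {
            m.member_id: (m.count_lib1, m.count_lib2) for m in members
        }
        for c in accepted:
            de_input[novel_ids[id(c)]] = (
                c.mature_tag.count_lib1, c.mature_tag.count_lib2
            )
        de_records = diff_expr.diff_expr_table(
            de_input,
            pair,
            pseudo=config.pseudo,
            sided=config.sided,
            fc_threshold=config.fc_threshold,
            p_extreme=config.p_extreme,
            p_significant=config.p_significant,
            exclusion_mode=config.exclusion_mode,
        )
        pd.DataFrame(
            [
                {
                    "mirna_id": r.mirna_id,
                    "x": r.x,
                    "y": r.y,
                    "rpm1": r.rpm1,
                    "rpm2": r.rpm2,
                    "log2fc": r.log2fc,
                    "p_value": r.p_value,
                    "tier": r.tier.value,
                }
                for r in de_records
            ]
        ).to_csv(outdir / "diff_expr.tsv", sep="\t", index=False)
        stage_counts["de_significant"] = sum(
            1
            for r in de_records
            if r.tier in (diff_expr.Tier.SIGNIFICANT, diff_expr.Tier.EXTREMELY_SIGNIFICANT)
        )

        stage = "targets"
        logger.info("stage %s", stage)
        query = {m.member_id: m.representative.sequence for m in members}
        for c in accepted:
            query[novel_ids[id(c)]] = c.mature_tag.sequence
        target_hits = scan_transcripts(query, transcripts, cutoff=config.target_cutoff)
        pd.DataFrame(
            [
                {
                    "mirna": h.mirna_id,
                    "transcript": h.transcript_id,
                    "start": h.start,
                    "end": h.end,
                    "expectation": h.expectation,
                    "mode": h.inhibition_mode,
                    "mirna_aln": h.alignment[0],
                    "pairing": h.alignment[1],
                    "site_aln": h.alignment[2],
                }
                for h in target_hits
            ]
        ).to_csv(outdir / "target_hits.tsv", sep="\t", index=False)
        stage_counts["target_hits"] = len(target_hits)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    run_manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stage_counts": stage_counts,
    }
    with open(outdir / "run_manifest.json", "w") as out:
        json.dump(run_manifest, out, indent=1, sort_keys=True)

    return PipelineResult(
        config=config,
        category_counts=(counts1, counts2),
        tags=tags,
        overlap=overlap,
        summary=summary,
        members=members,
        conserved=conserved,
        candidates=candidates,
        de_records=de_records,
        target_hits=target_hits,
        stage_counts=stage_counts,
    )
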