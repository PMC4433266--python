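"""Raw-read cleaning and clean-tag accounting.

Reads are converted to unique clean tags by 3'-adapter trimming; every
discarded read is assigned to exactly one category, applied in a fixed
order (low-quality, 3'-adaptor-null, insert-null, 5'-adaptor-contaminant,
length out of bounds, polyA) so that the category counts partition the
input.  Category counts, two-library overlap and length-distribution
summaries mirror standard sequencing-report tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path

from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._seq import normalize

__all__ = [
    "ReadCategoryCounts",
    "UniqueTag",
    "OverlapSummary",
    "CleaningParams",
    "clean_reads",
    "merge_tag_counts",
    "overlap_summary",
    "length_distribution",
    "write_collapsed_fasta",
    "read_collapsed_fasta",
    "round_half_up",
]

DEFAULT_ADAPTER_3P = "TCGTATGCCGTCTTCTGCTTG"
DEFAULT_ADAPTER_5P = "GTTCAGAGTTCTACAGTCCGACGATC"


def round_half_up(value: float, ndigits: int = 2) -> float:
    """Round half away from zero, matching printed table percentages."""
    factor = 10.0**ndigits
    return math.floor(abs(value) * factor + 0.5) / factor * (1 if value >= 0 else -1)


@dataclass
class ReadCategoryCounts:
    """Per-category read accounting of one library.

    Satisfies the partition identity
    ``clean_reads = high_quality - adaptor3_null - insert_null -
    adaptor5_contaminant - below_18nt - polyA``.
    """

    total_reads: int = 0
    high_quality: int = 0
    adaptor3_null: int = 0
    insert_null: int = 0
    adaptor5_contaminant: int = 0
    below_18nt: int = 0
    polyA: int = 0
    clean_reads: int = 0

    def validate(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"negative count for {f.name}")
        if self.high_quality > self.total_reads:
            raise ValueError("high_quality exceeds total_reads")
        if self.clean_reads != self.derived_clean():
            raise ValueError("clean_reads does not satisfy the partition identity")

    def derived_clean(self) -> int:
        return (
            self.high_quality
            - self.adaptor3_null
            - self.insert_null
            - self.adaptor5_contaminant
            - self.below_18nt
            - self.polyA
        )


@dataclass
class UniqueTag:
    """A distinct clean small-RNA sequence with per-library counts."""

    sequence: str
    count_lib1: int = 0
    count_lib2: int = 0

    @property
    def total(self) -> int:
        return self.count_lib1 + self.count_lib2


@dataclass
class OverlapSummary:
    total_unique: int
    shared_unique: int
    lib1_specific_unique: int
    lib2_specific_unique: int
    total_reads: int
    shared_reads: int
    lib1_specific_reads: int
    lib2_specific_reads: int

    def percentage(self, part: int, total: int) -> float:
        if total == 0:
            return 0.0
        return round_half_up(100.0 * part / total, 2)

    @property
    def percentages(self) -> dict[str, float]:
        tu, tr = self.total_unique, self.total_reads
        return {
            "total_unique": self.percentage(self.total_unique, tu),
            "shared_unique": self.percentage(self.shared_unique, tu),
            "lib1_specific_unique": self.percentage(self.lib1_specific_unique, tu),
            "lib2_specific_unique": self.percentage(self.lib2_specific_unique, tu),
            "total_reads": self.percentage(self.total_reads, tr),
            "shared_reads": self.percentage(self.shared_reads, tr),
            "lib1_specific_reads": self.percentage(self.lib1_specific_reads, tr),
            "lib2_specific_reads": self.percentage(self.lib2_specific_reads, tr),
        }


@dataclass
class CleaningParams:
    """Tunable thresholds of the read-cleaning stage."""

    adapter_3p: str = DEFAULT_ADAPTER_3P
    adapter_5p: str = DEFAULT_ADAPTER_5P
    quality_offset: int = 33
    min_quality: int = 20
    max_low_quality_frac: float = 0.10
    min_len: int = 18
    max_len: int = 30
    max_insert_null_len: int = 0  # insert <= this => insert-null
    polya_frac: float = 0.90
    adapter_seed_len: int = 8

    def __post_init__(self) -> None:
        if len(self.adapter_3p) < 8:
            raise ValueError("3' adapter must be at least 8 nt")


def find_adapter(seq: str, adapter: str, seed_len: int = 8) -> int:
    """Leftmost 3'-adapter start, or -1.

    Exact match of the adapter's first ``seed_len`` nt, then extension of
    the remaining adapter bases allowing one mismatch.  A seed match whose
    extension fails does not mask a later valid hit.
    """
    seed = adapter[:seed_len]
    start = 0
    while True:
        pos = seq.find(seed, start)
        if pos == -1:
            return -1
        rest = seq[pos + seed_len : pos + len(adapter)]
        mism = sum(1 for a, b in zip(rest, adapter[seed_len:]) if a != b)
        if mism <= 1:
            return pos
        start = pos + 1


def _is_low_quality(seq: str, qual: str, params: CleaningParams) -> bool:
    if "N" in seq:
        return True
    cutoff = chr(params.min_quality + params.quality_offset)
    n_low = sum(1 for q in qual if q < cutoff)
    return n_low > params.max_low_quality_frac * len(qual)


def clean_reads(
    fastq_path: str | Path,
    params: CleaningParams | None = None,
    *,
    library: int = 1,
) -> tuple[dict[str, int], ReadCategoryCounts]:
    """Clean one library of raw reads.

    Returns ``(tag counts, category counts)`` where the tag counts map
    each clean insert sequence to its read count.  ``library`` is only a
    label used in error messages.

    Input may be FASTQ (raw reads: quality filter, then 3'-adapter
    trimming) or FASTA (pre-trimmed reads, optionally collapsed with
    ``_x{count}`` headers: each record is its own insert, so an
    already-clean library passes through unchanged).
    """
    params = params or CleaningParams()
    counts = ReadCategoryCounts()
    tags: dict[str, int] = {}
    path = Path(fastq_path)

    def _classify_insert(insert: str, n: int) -> None:
        if len(insert) <= params.max_insert_null_len:
            counts.insert_null += n
        elif insert.startswith(params.adapter_5p[:8]):
            counts.adaptor5_contaminant += n
        elif not (params.min_len <= len(insert) <= params.max_len):
            counts.below_18nt += n
        elif insert.count("A") >= params.polya_frac * len(insert):
            counts.polyA += n
        else:
            counts.clean_reads += n
            tags[insert] = tags.get(insert, 0) + n

    with open(path) as handle:
        first = handle.read(1)
        handle.seek(0)
        if first == ">":
            for tag in read_collapsed_fasta(path):
                n = tag.total
                counts.total_reads += n
                counts.high_quality += n
                pos = find_adapter(
                    tag.sequence, params.adapter_3p, params.adapter_seed_len
                )
                insert = tag.sequence if pos == -1 else tag.sequence[:pos]
                _classify_insert(insert, n)
        elif first == "":
            pass  # empty input: zeroed counts, no tags
        else:
            try:
                for title, seq, qual in FastqGeneralIterator(handle):
                    seq = normalize(seq)
                    counts.total_reads += 1
                    if _is_low_quality(seq, qual, params):
                        continue
                    counts.high_quality += 1
                    pos = find_adapter(
                        seq, params.adapter_3p, params.adapter_seed_len
                    )
                    if pos == -1:
                        counts.adaptor3_null += 1
                        continue
                    _classify_insert(seq[:pos], 1)
            except ValueError as exc:
                raise ValueError(
                    f"malformed FASTQ record near index {counts.total_reads} "
                    f"in library {library} ({path.name}): {exc}"
                ) from exc
    counts.validate()
    return tags, counts


def merge_tag_counts(
    lib1: dict[str, int], lib2: dict[str, int]
) -> list[UniqueTag]:
    """Merge two per-library tag-count maps into UniqueTag records,
    ordered by descending total count then sequence (deterministic)."""
    merged = [
        UniqueTag(seq, lib1.get(seq, 0), lib2.get(seq, 0))
        for seq in set(lib1) | set(lib2)
    ]
    merged.sort(key=lambda t: (-t.total, t.sequence))
    return merged


def overlap_summary(tags: list[UniqueTag]) -> OverlapSummary:
    """Two-library overlap at the unique-tag and read level.

    A tag is shared iff it has a positive count in both libraries.
    """
    shared_u = l1_u = l2_u = 0
    shared_r = l1_r = l2_r = 0
    for t in tags:
        if t.count_lib1 > 0 and t.count_lib2 > 0:
            shared_u += 1
            shared_r += t.total
        elif t.count_lib1 > 0:
            l1_u += 1
            l1_r += t.total
        elif t.count_lib2 > 0:
            l2_u += 1
            l2_r += t.total
        else:
            raise ValueError(f"tag {t.sequence} has no reads in either library")
    return OverlapSummary(
        total_unique=shared_u + l1_u + l2_u,
        shared_unique=shared_u,
        lib1_specific_unique=l1_u,
        lib2_specific_unique=l2_u,
        total_reads=shared_r + l1_r + l2_r,
        shared_reads=shared_r,
        lib1_specific_reads=l1_r,
        lib2_specific_reads=l2_r,
    )


def length_distribution(
    tags: list[UniqueTag], weighting: str = "reads"
) -> dict[int, float]:
    """Proportion of tags (``weighting='unique'``) or reads
    (``weighting='reads'``) at each insert length."""
    if weighting not in ("unique", "reads"):
        raise ValueError("weighting must be 'unique' or 'reads'")
    weights: dict[int, float] = {}
    for t in tags:
        w = 1 if weighting == "unique" else t.total
        weights[len(t.sequence)] = weights.get(len(t.sequence), 0) + w
    total = sum(weights.values())
    if total == 0:
        return {}
    return {length: w / total for length, w in sorted(weights.items())}


def write_collapsed_fasta(tags: list[UniqueTag], path: str | Path) -> None:
    """Collapsed FASTA with headers ``tag{serial}_x{count}`` (total count);
    per-library counts appended as key=value comments."""
    with open(path, "w") as out:
        for i, t in enumerate(tags, start=1):
            out.write(
                f">tag{i}_x{t.total} lib1={t.count_lib1} lib2={t.count_lib2}\n"
                f"{t.sequence}\n"
            )


def read_collapsed_fasta(path: str | Path) -> list[UniqueTag]:
    tags: list[UniqueTag] = []
    header = None
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                header = line[1:]
            else:
                if header is None:
                    raise ValueError("sequence line before header in collapsed FASTA")
                parts = dict(
                    kv.split("=") for kv in header.split()[1:] if "=" in kv
                )
                name = header.split()[0]
                if "lib1" in parts and "lib2" in parts:
                    c1, c2 = int(parts["lib1"]), int(parts["lib2"])
                else:
                    total = int(name.rsplit("_x", 1)[1]) if "_x" in name else 1
                    c1, c2 = total, 0
                tags.append(UniqueTag(normalize(line), c1, c2))
                header = None
    return tags
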