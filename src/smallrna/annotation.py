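"""Clean-tag annotation: ncRNA classes, conserved miRNAs, member collapsing.

Tags are first classified against a labelled ncRNA reference by exact
substring matching (precedence rRNA > tRNA > snRNA > snoRNA on
multi-hits), then surviving tags are compared with a mature-miRNA
reference; only full-length exact matches with sufficient read support
in both libraries are called conserved.  Conserved tags within a family
are collapsed into members by single-linkage clustering of end-variant
isoforms (total 5'/3' end length difference <= 2 nt).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from ._seq import normalize, revcomp
from .preprocessing import UniqueTag, round_half_up

__all__ = [
    "NCRNA_CLASSES",
    "AnnotationSummary",
    "MiRNAMember",
    "load_class_reference",
    "load_mature_reference",
    "classify_ncrna",
    "identify_conserved",
    "is_end_variant",
    "collapse_members",
    "map_to_transcripts",
    "annotate_tags",
]

# Precedence order for multi-hits; summary classes add miRNA and others.
NCRNA_CLASSES = ("rRNA", "tRNA", "snRNA", "snoRNA")
SUMMARY_CLASSES = ("miRNA",) + NCRNA_CLASSES + ("others",)

_FAMILY_RE = re.compile(r"(?:MIR|miR)[-]?(\d+)", re.IGNORECASE)


@dataclass
class AnnotationSummary:
    """Per-class unique/total read accounting for both libraries."""

    unique: dict[str, tuple[int, int]] = field(default_factory=dict)
    reads: dict[str, tuple[int, int]] = field(default_factory=dict)
    total_unique: tuple[int, int] = (0, 0)
    total_reads: tuple[int, int] = (0, 0)

    def percentages(self, kind: str = "reads") -> dict[str, tuple[float, float]]:
        table = self.reads if kind == "reads" else self.unique
        totals = self.total_reads if kind == "reads" else self.total_unique
        out = {}
        for cls, (a, b) in table.items():
            out[cls] = (
                round_half_up(100.0 * a / totals[0], 2) if totals[0] else 0.0,
                round_half_up(100.0 * b / totals[1], 2) if totals[1] else 0.0,
            )
        return out


@dataclass
class MiRNAMember:
    """End-variant isoform tags collapsed into one named family member."""

    family: str
    member_id: str
    isoform_tags: list[UniqueTag]
    representative: UniqueTag
    count_lib1: int
    count_lib2: int


def load_class_reference(path: str | Path) -> list[tuple[str, str, str]]:
    """Parse an ncRNA reference FASTA whose headers carry ``class=<cls>``
    (or whose id contains a known class name).  Returns
    ``(record id, class, sequence)`` triples."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        m = re.search(r"class=(\S+)", desc)
        cls = m.group(1) if m else None
        if cls is None:
            for candidate in NCRNA_CLASSES:
                if candidate.lower() in desc.lower():
                    cls = candidate
                    break
        if cls is None or cls not in NCRNA_CLASSES:
            raise ValueError(
                f"ncRNA reference record {rec.id!r} has no recognised class label"
            )
        records.append((rec.id, cls, normalize(str(rec.seq))))
    return records


def load_mature_reference(path: str | Path) -> dict[str, tuple[str, str]]:
    """Parse a mature-miRNA FASTA: ``{sequence: (name, family)}``.

    The family is extracted from the header (e.g. ``gbi-miR166a`` or an
    explicit ``MIR166`` token) and normalised to ``MIR<number>``.
    """
    out: dict[str, tuple[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        m = _FAMILY_RE.search(rec.description)
        if not m:
            raise ValueError(
                f"cannot parse a miRNA family from reference header {rec.description!r}"
            )
        family = f"MIR{m.group(1)}"
        out[normalize(str(rec.seq))] = (rec.id, family)
    return out


def classify_ncrna(
    tags: list[UniqueTag], reference: list[tuple[str, str, str]]
) -> tuple[dict[str, str], list[UniqueTag]]:
    """Assign tags to ncRNA classes by exact substring match.

    Returns ``(assignments, unannotated)`` where assignments maps tag
    sequence -> class for every tag matching at least one reference, with
    precedence rRNA > tRNA > snRNA > snoRNA; remaining tags are returned
    for downstream miRNA identification.
    """
    by_class: dict[str, list[str]] = {c: [] for c in NCRNA_CLASSES}
    for _, cls, seq in reference:
        by_class[cls].append(seq)
    assignments: dict[str, str] = {}
    unannotated: list[UniqueTag] = []
    for tag in tags:
        hit = None
        for cls in NCRNA_CLASSES:  # precedence order
            if any(tag.sequence in ref for ref in by_class[cls]):
                hit = cls
                break
        if hit is None:
            unannotated.append(tag)
        else:
            assignments[tag.sequence] = hit
    return assignments, unannotated


def identify_conserved(
    tags: list[UniqueTag],
    mature_reference: dict[str, tuple[str, str]],
    min_reads: int = 10,
    *,
    require_both: bool = True,
) -> dict[str, tuple[str, str]]:
    """Conserved-miRNA calls: ``{tag sequence: (reference name, family)}``.

    A tag is conserved iff identical (full-length, exact) to a reference
    mature sequence and its count reaches ``min_reads`` in both libraries
    (or in either, with ``require_both=False``).
    """
    out = {}
    for tag in tags:
        ref = mature_reference.get(tag.sequence)
        if ref is None:
            continue
        if require_both:
            ok = tag.count_lib1 >= min_reads and tag.count_lib2 >= min_reads
        else:
            ok = tag.count_lib1 >= min_reads or tag.count_lib2 >= min_reads
        if ok:
            out[tag.sequence] = ref
    return out


def is_end_variant(a: str, b: str, max_diff: int = 2) -> bool:
    """True iff the two sequences differ only by 5'/3' end extensions or
    truncations totalling at most ``max_diff`` nt.

    Checked by sliding one sequence over the other: some ungapped offset
    must make the overlapping cores identical with total overhang length
    (both ends, both sequences) <= ``max_diff``.
    """
    if a == b:
        return True
    la, lb = len(a), len(b)
    for shift in range(-max_diff, max_diff + 1):
        # b starts at position `shift` relative to a
        start = max(0, shift)
        end = min(la, lb + shift)
        overlap = end - start
        if overlap <= 0:
            continue
        overhang = (la - overlap) + (lb - overlap)
        if overhang > max_diff:
            continue
        if a[start:end] == b[start - shift : end - shift]:
            return True
    return False


def _single_linkage(seqs: list[str], max_diff: int = 2) -> list[list[str]]:
    n = len(seqs)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if is_end_variant(seqs[i], seqs[j], max_diff):
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    clusters: dict[int, list[str]] = {}
    for i, s in enumerate(seqs):
        clusters.setdefault(find(i), []).append(s)
    return list(clusters.values())


def collapse_members(
    conserved: dict[str, tuple[str, str]],
    tags: list[UniqueTag],
    max_diff: int = 2,
) -> list[MiRNAMember]:
    """Collapse conserved tags within each family into members.

    Single-linkage clustering under the end-variant relation; each
    cluster becomes one member named ``miR<family number><letter>-<serial>``
    by descending representative count.
    """
    tag_by_seq = {t.sequence: t for t in tags}
    by_family: dict[str, list[str]] = {}
    for seq, (_, family) in conserved.items():
        by_family.setdefault(family, []).append(seq)
    members: list[MiRNAMember] = []
    for family in sorted(by_family):
        clusters = _single_linkage(sorted(by_family[family]), max_diff)
        ranked = []
        for cluster in clusters:
            iso = sorted(
                (tag_by_seq[s] for s in cluster),
                key=lambda t: (-t.total, t.sequence),
            )
            ranked.append(iso)
        ranked.sort(key=lambda iso: (-iso[0].total, iso[0].sequence))
        num = family.replace("MIR", "")
        for idx, iso in enumerate(ranked):
            letter = chr(ord("a") + idx % 26)
            members.append(
                MiRNAMember(
                    family=family,
                    member_id=f"miR{num}{letter}-{idx + 1}",
                    isoform_tags=iso,
                    representative=iso[0],
                    count_lib1=sum(t.count_lib1 for t in iso),
                    count_lib2=sum(t.count_lib2 for t in iso),
                )
            )
    return members


def map_to_transcripts(
    tags: list[UniqueTag], transcripts: dict[str, str]
) -> dict[str, list[tuple[str, int, str]]]:
    """All exact-substring hits of each tag on either transcript strand.

    Returns ``{tag sequence: [(transcript id, offset, strand), ...]}``
    with 0-based forward-strand offsets of the match start.  Tags with no
    hits map to an empty list.
    """
    hits: dict[str, list[tuple[str, int, str]]] = {t.sequence: [] for t in tags}
    for tid in sorted(transcripts):
        seq = transcripts[tid]
        for tag in tags:
            for query, strand in ((tag.sequence, "+"), (revcomp(tag.sequence), "-")):
                start = seq.find(query)
                while start != -1:
                    hits[tag.sequence].append((tid, start, strand))
                    start = seq.find(query, start + 1)
    return hits


def annotate_tags(
    tags: list[UniqueTag],
    ncrna_reference: list[tuple[str, str, str]],
    mature_reference: dict[str, tuple[str, str]],
    min_reads: int = 10,
    *,
    require_both: bool = True,
) -> tuple[dict[str, str], dict[str, tuple[str, str]], list[UniqueTag], AnnotationSummary]:
    """Full annotation pass: ncRNA removal, then conserved-miRNA calls.

    Returns ``(ncrna assignments, conserved calls, unannotated tags,
    summary)``.  The summary partitions all input tags into miRNA, the
    four ncRNA classes and "others"; per-library unique counts include
    only tags observed in that library.
    """
    ncrna, survivors = classify_ncrna(tags, ncrna_reference)
    conserved = identify_conserved(
        survivors, mature_reference, min_reads, require_both=require_both
    )
    unannotated = [t for t in survivors if t.sequence not in conserved]

    summary = AnnotationSummary()
    uniq = {c: [0, 0] for c in SUMMARY_CLASSES}
    reads = {c: [0, 0] for c in SUMMARY_CLASSES}
    tot_u, tot_r = [0, 0], [0, 0]
    for tag in tags:
        if tag.sequence in conserved:
            cls = "miRNA"
        else:
            cls = ncrna.get(tag.sequence, "others")
        for lib, count in ((0, tag.count_lib1), (1, tag.count_lib2)):
            if count > 0:
                uniq[cls][lib] += 1
                reads[cls][lib] += count
                tot_u[lib] += 1
                tot_r[lib] += count
    summary.unique = {c: (v[0], v[1]) for c, v in uniq.items()}
    summary.reads = {c: (v[0], v[1]) for c, v in reads.items()}
    summary.total_unique = (tot_u[0], tot_u[1])
    summary.total_reads = (tot_r[0], tot_r[1])
    return ncrna, conserved, unannotated, summary
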