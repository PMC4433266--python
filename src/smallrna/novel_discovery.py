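"""Hairpin-based novel miRNA candidate discovery.

Unannotated, transcript-mapped tags seed candidate precursor windows
(tag +/- flank).  For each window, mature-anchored trial spans are
folded with the bundled engine, the stem-loop containing the mature is
located, and acceptance criteria are applied: the mature must pair a
single compact partner block on one arm (clear of the terminal loop),
with sufficient pairing or an observed star strand in 2-nt 3' overhang
geometry, a pseudo-energy at or below threshold, and minimum read
support.  Windows spanned by a long open reading frame are rejected as
likely coding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .folding import FoldResult, fold, hairpin_loops, pair_table
from .preprocessing import UniqueTag

__all__ = [
    "DiscoveryParams",
    "HairpinCandidate",
    "extract_precursors",
    "evaluate_candidate",
    "discover_novel",
    "first_nt_bias",
    "dinucleotide_shuffle",
]

_STOPS = ("TAA", "TAG", "TGA")


@dataclass
class DiscoveryParams:
    flank: int = 150
    min_reads: int = 10
    mfe_threshold: float = -18.0
    mature_len_range: tuple[int, int] = (20, 23)
    min_paired_mature: int = 17
    star_tolerance: int = 3  # nt slack when matching an observed star tag
    max_duplex_span_excess: int = 8  # partner block may exceed mature length by this
    max_precursor_len: int = 120  # trial span anchored at the mature
    max_stem_gap: int = 5  # max unpaired run tolerated while walking a stem
    orf_min_codons: int = 100
    require_star: bool = False


@dataclass
class HairpinCandidate:
    """One evaluated precursor window."""

    host: str
    window: tuple[int, int]  # transcript coords, half-open
    precursor: FoldResult | None
    precursor_interval: tuple[int, int] | None  # transcript coords
    mature_tag: UniqueTag | None
    mature_arm: str | None  # "5p" | "3p"
    mature_pos: tuple[int, int] | None  # precursor coords, half-open
    star_tag: UniqueTag | None = None
    star_pos: tuple[int, int] | None = None
    accepted: bool = False
    reasons: list[str] = field(default_factory=list)

    @property
    def first_nt(self) -> str | None:
        if self.mature_tag is None:
            return None
        return self.mature_tag.sequence[0].replace("T", "U")


def _window_intervals(
    start: int, end: int, tlen: int, flank: int
) -> list[tuple[int, int]]:
    left = (max(0, start - flank), end)
    right = (start, min(tlen, end + flank))
    return [left] if left == right else [left, right]


def extract_precursors(
    tag_hits: dict[str, list[tuple[str, int, str]]],
    transcripts: dict[str, str],
    tag_lengths: dict[str, int],
    flank: int = 150,
) -> list[tuple[str, tuple[int, int]]]:
    """Candidate precursor windows for transcript-mapped tags.

    For each forward-strand hit two windows are produced, tag start
    minus flank up to tag end, and tag start up to tag end plus flank,
    clipped to transcript bounds and deduplicated.
    """
    seen: set[tuple[str, tuple[int, int]]] = set()
    windows: list[tuple[str, tuple[int, int]]] = []
    for seq, hits in tag_hits.items():
        for tid, offset, strand in hits:
            if strand != "+":
                continue
            tlen = len(transcripts[tid])
            for iv in _window_intervals(offset, offset + tag_lengths[seq], tlen, flank):
                key = (tid, iv)
                if key not in seen:
                    seen.add(key)
                    windows.append(key)
    return windows


def _find_orf_spanning(seq: str, span: tuple[int, int], min_codons: int) -> bool:
    """Any AUG-initiated, stop-free reading frame >= min_codons codons
    covering the whole ``span``?  (Coding-potential heuristic.)"""
    need = min_codons * 3

    def _covers(run_start: int, run_end: int) -> bool:
        if run_end - run_start < need or run_start > span[0] or run_end < span[1]:
            return False
        atg = seq.find("ATG", run_start, run_end - need + 3)
        while atg != -1:
            if (atg - run_start) % 3 == 0 and run_end - atg >= need and atg <= span[0]:
                return True
            atg = seq.find("ATG", atg + 1, run_end - need + 3)
        return False

    for frame in range(3):
        run_start = frame
        pos = frame
        while pos + 3 <= len(seq):
            if seq[pos : pos + 3] in _STOPS:
                if _covers(run_start, pos):
                    return True
                run_start = pos + 3
            pos += 3
        if _covers(run_start, pos):
            return True
    return False


def _extract_stem(
    pt: np.ndarray, loop: tuple[int, int], max_gap: int
) -> tuple[int, int]:
    """Walk outward from a hairpin loop's closing pair through stacked
    and bulged pairs, stopping at a branch or a gap > max_gap.  Returns
    the half-open span of the simple stem-loop."""
    i, j = loop
    n = len(pt)
    while True:
        ni, nj = i - 1, j + 1
        while ni >= 0 and pt[ni] == -1 and i - ni <= max_gap:
            ni -= 1
        while nj < n and pt[nj] == -1 and nj - j <= max_gap:
            nj += 1
        if ni < 0 or nj >= n or i - ni > max_gap or nj - j > max_gap:
            break
        if pt[ni] != nj:  # branch or non-nesting pair: stop
            break
        i, j = ni, nj
    return i, j + 1


def _expected_star(
    pt: np.ndarray, mstart: int, mend: int
) -> tuple[int, int] | None:
    """Star interval implied by the duplex geometry: partners of the
    mature's paired bases, shifted for 2-nt 3' overhangs."""
    partners = [int(pt[p]) for p in range(mstart, mend) if pt[p] >= 0]
    if not partners:
        return None
    lo, hi = min(partners), max(partners)
    return (lo + 2, hi + 3)  # half-open; +2 shift emulates dicer overhangs


def evaluate_candidate(
    host: str,
    window: tuple[int, int],
    window_fold: FoldResult,
    overlapping: list[tuple[UniqueTag, int]],
    params: DiscoveryParams | None = None,
    transcript_seq: str | None = None,
) -> HairpinCandidate:
    """Evaluate one folded window against the acceptance criteria.

    ``overlapping`` lists (tag, offset-within-window) for tags mapped
    inside the window.  Reason codes enumerate every failed criterion.
    """
    params = params or DiscoveryParams()
    cand = HairpinCandidate(
        host=host,
        window=window,
        precursor=None,
        precursor_interval=None,
        mature_tag=None,
        mature_arm=None,
        mature_pos=None,
    )
    lo, hi = params.mature_len_range
    mature_pool = [
        (t, off) for t, off in overlapping if lo <= len(t.sequence) <= hi
    ]
    if not mature_pool:
        cand.reasons.append("no_mature_tag")
        return cand
    # Highest count; ties to the 5'-most then lexicographically smallest.
    mature, moff = min(mature_pool, key=lambda p: (-p[0].total, p[1], p[0].sequence))
    cand.mature_tag = mature
    mstart, mend = moff, moff + len(mature.sequence)

    if mature.total < params.min_reads:
        cand.reasons.append("low_abundance")

    # Mature-anchored precursor search: try both arm hypotheses with a
    # trial span extending from the mature, locate the stem-loop in the
    # isolated refold, then refold the walked stem span and apply the
    # acceptance criteria to that precursor.
    wseq = window_fold.sequence
    kmax = params.max_precursor_len
    trials = (
        ((mstart, min(len(wseq), mstart + kmax)), "5p"),
        ((max(0, mend - kmax), mend), "3p"),
    )
    best_reasons: list[str] | None = None
    best_trial: tuple[int, int] | None = None
    accepted_trial = False
    for (t0, t1), _arm in trials:
        reasons = _evaluate_span(cand, wseq, (t0, t1), mstart, mend, overlapping, params)
        if reasons is not None and not reasons:
            best_reasons, best_trial, accepted_trial = [], (t0, t1), True
            break
        if reasons is not None and (
            best_reasons is None or len(reasons) < len(best_reasons)
        ):
            best_reasons, best_trial = reasons, (t0, t1)
    if best_reasons is None:
        best_reasons = ["no_hairpin"]
    elif not accepted_trial and best_trial is not None:
        # Re-run the winning trial so the candidate fields match it.
        _evaluate_span(cand, wseq, best_trial, mstart, mend, overlapping, params)
    cand.reasons.extend(best_reasons)

    if (
        cand.precursor_interval is not None
        and transcript_seq is not None
        and _find_orf_spanning(
            transcript_seq,
            (cand.precursor_interval[0], cand.precursor_interval[1]),
            params.orf_min_codons,
        )
    ):
        cand.reasons.append("orf")

    cand.accepted = not cand.reasons
    return cand


def _evaluate_span(
    cand: HairpinCandidate,
    wseq: str,
    trial: tuple[int, int],
    mstart: int,
    mend: int,
    overlapping: list[tuple[UniqueTag, int]],
    params: DiscoveryParams,
) -> list[str] | None:
    """Evaluate one trial span; fills candidate fields and returns the
    criterion failures (empty list = accepted), or None when no hairpin
    containing the mature exists in this trial at all."""
    t0, t1 = trial
    if t1 - t0 < mend - mstart + 6:
        return None
    trial_fold = fold(wseq[t0:t1])
    pt_trial = pair_table(trial_fold.structure)
    loops = hairpin_loops(trial_fold.structure)
    if not loops:
        return None
    ms_t, me_t = mstart - t0, mend - t0
    # Loop on the correct side of the mature, nearest to it.
    side_loops = [
        (li, lj)
        for li, lj in loops
        if lj <= ms_t + 1 or li >= me_t - 1  # not strictly inside the mature
    ]
    if not side_loops:
        return None
    li, lj = min(
        side_loops,
        key=lambda L: min(abs(L[0] - me_t), abs(ms_t - L[1])),
    )
    s0, s1 = _extract_stem(pt_trial, (li, lj), params.max_stem_gap)
    # Expand to cover the mature and the 2-nt star overhang margin.
    s0 = max(0, min(s0, ms_t) - 2)
    s1 = min(t1 - t0, max(s1, me_t) + 2)
    if not (s0 <= ms_t and me_t <= s1):
        return None
    precursor = fold(wseq[t0 + s0 : t0 + s1])

    reasons: list[str] = []
    mature = cand.mature_tag
    mstart_s, mend_s = ms_t - s0, me_t - s0
    cand.precursor = precursor
    cand.precursor_interval = (cand.window[0] + t0 + s0, cand.window[0] + t0 + s1)
    cand.mature_pos = (mstart_s, mend_s)

    # Duplex geometry: the mature must pair a single compact partner
    # block entirely on one side, separated by at least a minimal loop.
    pt = pair_table(precursor.structure)
    partners = [int(pt[p]) for p in range(mstart_s, mend_s) if pt[p] >= 0]
    n_paired = len(partners)
    if n_paired < 4:
        reasons.append("no_hairpin")
        return reasons
    plo, phi = min(partners), max(partners)
    mature_len = mend_s - mstart_s
    if plo < mend_s and phi >= mstart_s:
        # Partner block overlaps the mature (or straddles it): the
        # mature runs into its own terminal loop.
        reasons.append("loop_overlap")
        return reasons
    if phi - plo + 1 > mature_len + params.max_duplex_span_excess:
        reasons.append("multiple_loops")  # fragmented, non-contiguous duplex
        return reasons
    if plo >= mend_s:  # partners downstream: mature on the 5' arm
        cand.mature_arm = "5p"
        loop_gap = plo - mend_s
    else:
        cand.mature_arm = "3p"
        loop_gap = mstart_s - phi - 1
    if loop_gap < 3:
        reasons.append("loop_overlap")
        return reasons

    if precursor.mfe > params.mfe_threshold:
        reasons.append("mfe")

    star_iv = _expected_star(pt, mstart_s, mend_s)
    cand.star_tag = None
    cand.star_pos = None
    if star_iv is not None:
        tol = params.star_tolerance
        for t, off in overlapping:
            if t is mature:
                continue
            v0, v1 = off - t0 - s0, off - t0 - s0 + len(t.sequence)
            if abs(v0 - star_iv[0]) <= tol and abs(v1 - star_iv[1]) <= tol:
                cand.star_tag = t
                cand.star_pos = (v0, v1)
                break
    if n_paired < params.min_paired_mature and cand.star_tag is None:
        reasons.append("insufficient_pairing")
    if params.require_star and cand.star_tag is None:
        reasons.append("no_star")
    return reasons


def discover_novel(
    tag_hits: dict[str, list[tuple[str, int, str]]],
    tags: list[UniqueTag],
    transcripts: dict[str, str],
    params: DiscoveryParams | None = None,
) -> list[HairpinCandidate]:
    """Run discovery over all transcript-mapped unannotated tags.

    Folds each candidate window once, evaluates it, and deduplicates
    accepted candidates by (host, precursor interval) and by mature
    sequence, keeping the lowest-energy representative.
    """
    params = params or DiscoveryParams()
    tag_by_seq = {t.sequence: t for t in tags}
    tag_lengths = {s: len(s) for s in tag_hits}
    windows = extract_precursors(tag_hits, transcripts, tag_lengths, params.flank)

    # Index forward-strand tag placements per transcript for overlap lookup.
    placements: dict[str, list[tuple[int, int, UniqueTag]]] = {}
    for seq, hits in tag_hits.items():
        tag = tag_by_seq[seq]
        for tid, offset, strand in hits:
            if strand == "+":
                placements.setdefault(tid, []).append(
                    (offset, offset + len(seq), tag)
                )

    candidates: list[HairpinCandidate] = []
    for tid, (w0, w1) in windows:
        wseq = transcripts[tid][w0:w1]
        if len(wseq) < 20:
            continue
        folded = fold(wseq)
        overlapping = [
            (tag, s - w0)
            for s, e, tag in placements.get(tid, [])
            if s >= w0 and e <= w1
        ]
        cand = evaluate_candidate(
            tid, (w0, w1), folded, overlapping, params, transcripts[tid]
        )
        candidates.append(cand)

    # Deduplicate accepted candidates.
    best: dict[tuple, HairpinCandidate] = {}
    for cand in candidates:
        if not cand.accepted:
            continue
        key = (cand.host, cand.mature_tag.sequence)
        prev = best.get(key)
        if prev is None or cand.precursor.mfe < prev.precursor.mfe:
            best[key] = cand
    rejected = [c for c in candidates if not c.accepted]
    return list(best.values()) + rejected


def first_nt_bias(candidates: list[HairpinCandidate]) -> dict[str, float]:
    """Distribution of the mature 5' first nucleotide over accepted
    candidates (RNA alphabet)."""
    accepted = [c for c in candidates if c.accepted]
    if not accepted:
        raise ValueError("no accepted candidates")
    counts: dict[str, int] = {}
    for c in accepted:
        counts[c.first_nt] = counts.get(c.first_nt, 0) + 1
    total = sum(counts.values())
    return {b: n / total for b, n in sorted(counts.items())}


def dinucleotide_shuffle(seq: str, rng: np.random.Generator) -> str:
    """Shuffle a sequence preserving dinucleotide composition (Eulerian
    edge shuffle: permute each base's successor list, keeping the last
    base's successors consistent with a valid walk)."""
    if len(seq) < 3:
        return seq
    successors: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        successors.setdefault(a, []).append(b)
    for base, succ in successors.items():
        idx = rng.permutation(len(succ))
        successors[base] = [succ[i] for i in idx]
    # Walk greedily; retry a few times if the walk stalls early.
    for _ in range(10):
        trial = {b: list(s) for b, s in successors.items()}
        out = [seq[0]]
        cur = seq[0]
        while trial.get(cur):
            cur = trial[cur].pop(0)
            out.append(cur)
        if len(out) == len(seq):
            return "".join(out)
        for base, succ in successors.items():
            idx = rng.permutation(len(succ))
            successors[base] = [succ[i] for i in idx]
    return "".join(out)
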