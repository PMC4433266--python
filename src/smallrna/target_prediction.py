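"""Complementarity-based miRNA target search with a penalty scorer.

The expectation of a miRNA/site duplex is the sum of per-position
penalties: mismatch 1.0, G:U pair 0.5, gap 2.0, each doubled within the
seed region (miRNA positions 2-13, 1-based from the 5' end).  Sites at
or below the cutoff (default 3.0) are reported; a central mismatch
(miRNA positions 9-11) switches the predicted inhibition mode from
cleavage to translational repression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import check_bases, normalize, pairs, revcomp, wobble

__all__ = ["TargetHit", "score_site", "scan_transcripts", "SEED_RANGE"]

SEED_RANGE = (2, 13)  # 1-based inclusive miRNA positions with doubled penalty
CENTRAL_RANGE = (9, 11)

MISMATCH = 1.0
GU = 0.5
GAP = 2.0


@dataclass
class TargetHit:
    mirna_id: str
    transcript_id: str
    start: int  # transcript coords, half-open
    end: int
    expectation: float
    inhibition_mode: str  # "cleavage" | "translation"
    alignment: tuple[str, str, str]  # miRNA 5'->3', symbols, site 3'->5'


def _weight(pos_1based: int) -> float:
    return 2.0 if SEED_RANGE[0] <= pos_1based <= SEED_RANGE[1] else 1.0


def _column_penalty(m: str, t: str) -> float:
    if pairs(m, t):
        return 0.0
    if wobble(m, t):
        return GU
    return MISMATCH


def score_site(mirna: str, site: str, band: int = 2) -> tuple[float, tuple[str, str, str]]:
    """Score one miRNA against one candidate site.

    ``mirna`` and ``site`` are both given 5'->3'; the duplex is
    antiparallel, so the site is reversed internally.  Lengths may
    differ by up to ``band`` nt, bridged by gaps (penalty 2, seed
    multiplier of the current miRNA position).  Returns
    ``(expectation, (miRNA 5'->3', symbols, site 3'->5'))``.
    """
    m = normalize(mirna)
    t = normalize(site)
    check_bases(m)
    check_bases(t)
    if abs(len(m) - len(t)) > band:
        raise ValueError("site length differs from miRNA by more than the gap band")
    s = t[::-1]  # site 3'->5'
    nm, ns = len(m), len(s)
    inf = float("inf")
    dp = np.full((nm + 1, ns + 1), inf)
    dp[0, 0] = 0.0
    for i in range(nm + 1):
        lo = max(0, i - band)
        hi = min(ns, i + band)
        for j in range(lo, hi + 1):
            if i == 0 and j == 0:
                continue
            best = inf
            if i > 0 and j > 0:
                best = dp[i - 1, j - 1] + _column_penalty(m[i - 1], s[j - 1]) * _weight(i)
            if i > 0:
                best = min(best, dp[i - 1, j] + GAP * _weight(i))
            if j > 0:
                best = min(best, dp[i, j - 1] + GAP * _weight(min(i + 1, nm)))
            dp[i, j] = best
    score = float(dp[nm, ns])

    # Traceback for the alignment strings.
    am, sym, asite = [], [], []
    i, j = nm, ns
    while i > 0 or j > 0:
        if i > 0 and j > 0 and np.isclose(
            dp[i, j], dp[i - 1, j - 1] + _column_penalty(m[i - 1], s[j - 1]) * _weight(i)
        ):
            am.append(m[i - 1])
            asite.append(s[j - 1])
            if pairs(m[i - 1], s[j - 1]):
                sym.append("|")
            elif wobble(m[i - 1], s[j - 1]):
                sym.append("o")
            else:
                sym.append(" ")
            i, j = i - 1, j - 1
        elif i > 0 and np.isclose(dp[i, j], dp[i - 1, j] + GAP * _weight(i)):
            am.append(m[i - 1])
            asite.append("-")
            sym.append(" ")
            i -= 1
        else:
            am.append("-")
            asite.append(s[j - 1])
            sym.append(" ")
            j -= 1
    alignment = ("".join(reversed(am)), "".join(reversed(sym)), "".join(reversed(asite)))
    return score, alignment


_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}


def _penalty_table() -> np.ndarray:
    tab = np.zeros((4, 4))
    for mb, mi in _ENC.items():
        for tb, ti in _ENC.items():
            tab[mi, ti] = _column_penalty(mb, tb)
    return tab


_PEN = _penalty_table()


def scan_transcripts(
    mirnas: dict[str, str],
    transcripts: dict[str, str],
    cutoff: float = 3.0,
) -> list[TargetHit]:
    """Scan every transcript for sites of every miRNA (ungapped windows).

    All windows of each transcript are scored against the miRNA; the
    best site per (miRNA, transcript) plus non-overlapping secondary
    sites at or below the cutoff are reported.
    """
    hits: list[TargetHit] = []
    enc_tx = {
        tid: np.array([_ENC[c] for c in normalize(seq)], dtype=np.int64)
        for tid, seq in transcripts.items()
    }
    for mid in sorted(mirnas):
        m = normalize(mirnas[mid])
        check_bases(m)
        L = len(m)
        enc_m = np.array([_ENC[c] for c in m], dtype=np.int64)
        weights = np.array([_weight(i + 1) for i in range(L)])
        central = np.array(
            [CENTRAL_RANGE[0] <= i + 1 <= CENTRAL_RANGE[1] for i in range(L)]
        )
        for tid in sorted(enc_tx):
            enc_t = enc_tx[tid]
            if len(enc_t) < L:
                continue
            windows = np.lib.stride_tricks.sliding_window_view(enc_t, L)
            rev = windows[:, ::-1]  # column i pairs miRNA position i
            pen = _PEN[enc_m[None, :], rev] * weights[None, :]
            scores = pen.sum(axis=1)
            order = np.argsort(scores, kind="stable")
            chosen: list[tuple[int, float]] = []
            for p in order:
                p = int(p)
                if scores[p] > cutoff:
                    break
                if any(p < e and p + L > s for s, e in
                       ((c, c + L) for c, _ in chosen)):
                    continue
                chosen.append((p, float(scores[p])))
            for p, score in chosen:
                site = "".join("ACGT"[b] for b in enc_t[p : p + L])
                raw = _PEN[enc_m, rev[p]]
                mode = "translation" if np.any((raw >= MISMATCH) & central) else "cleavage"
                _, alignment = score_site(m, site)
                hits.append(
                    TargetHit(
                        mirna_id=mid,
                        transcript_id=tid,
                        start=p,
                        end=p + L,
                        expectation=score,
                        inhibition_mode=mode,
                        alignment=alignment,
                    )
                )
    hits.sort(key=lambda h: (h.mirna_id, h.transcript_id, h.expectation, h.start))
    return hits
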