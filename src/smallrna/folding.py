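"""Bundled nucleic-acid secondary-structure folding engine.

A deterministic maximum-pair-score dynamic program (Nussinov-style) over
nested structures: pair scores GC=3, AU=2, GU=1, minimum hairpin loop of
3 nt.  The reported pseudo-energy is

    E = -(sum of pair scores)
        + loop_penalty * (number of hairpin loops)
        + unpaired_penalty * (number of unpaired bases enclosed by pairs)

in kcal/mol-like units; structures with E > 0 are reported as unfolded
(mfe 0, no pairs), so mfe <= 0 always holds.  An external thermodynamic
engine can replace this one behind the same ``FoldResult`` contract.

The O(n^3) DP is JIT-compiled with numba when available; the pure-Python
fallback is identical code and gives byte-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from ._seq import check_bases, normalize

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(fn):
            return fn

        return wrap if not (args and callable(args[0])) else args[0]


__all__ = ["FoldResult", "fold", "pair_table", "hairpin_loops", "structure_energy"]

MIN_LOOP = 3
LOOP_PENALTY = 3.0
UNPAIRED_PENALTY = 0.5

# Pair scores indexed by encoded bases A=0 C=1 G=2 T=3.
_PAIR_SCORE = np.zeros((4, 4), dtype=np.int64)
_PAIR_SCORE[0, 3] = _PAIR_SCORE[3, 0] = 2  # A:U
_PAIR_SCORE[2, 1] = _PAIR_SCORE[1, 2] = 3  # G:C
_PAIR_SCORE[2, 3] = _PAIR_SCORE[3, 2] = 1  # G:U wobble

# DP objective: maximize stacking (contiguous helices) first, using the
# pair weights only as a tie-break.  Each pair stacked directly on
# another earns _STACK_BONUS; a lone pair earns only its weight, so the
# optimum is stable under lone-pair removal and G:C-dense spurious
# pairs cannot displace A:U-rich genuine stems.
_STACK_BONUS = 1000

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class FoldResult:
    """A folded sequence: dot-bracket structure and pseudo-energy."""

    sequence: str
    structure: str
    mfe: float

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.structure):
            raise ValueError("structure length must equal sequence length")
        if self.structure.count("(") != self.structure.count(")"):
            raise ValueError("unbalanced brackets in structure")

    @property
    def n_pairs(self) -> int:
        return self.structure.count("(")


@njit(cache=True)
def _nussinov(enc, scores, min_loop, stack_bonus):  # pragma: no cover - numba kernel
    n = enc.shape[0]
    # m[i, j]: best score over half-open interval seq[i:j]
    # h[i, j]: best score over closed pair region (i, j-1) given that
    #          i pairs j-1; -1 if i cannot pair j-1
    m = np.zeros((n + 1, n + 1), dtype=np.int64)
    h = np.full((n + 1, n + 1), -1, dtype=np.int64)
    # cm[i, j] = 0 if i left unpaired, else k meaning i pairs k (uses h)
    cm = np.zeros((n + 1, n + 1), dtype=np.int64)
    # ch[i, j] = 1 if h[i, j] extends the inner helix pair (i+1, j-2)
    ch = np.zeros((n + 1, n + 1), dtype=np.int64)
    for span in range(min_loop + 2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span
            s = scores[enc[i], enc[j - 1]]
            if s > 0:
                best_h = s + m[i + 1, j - 1]
                stacked = 0
                if h[i + 1, j - 1] >= 0:
                    cand = s + stack_bonus + h[i + 1, j - 1]
                    if cand > best_h:
                        best_h = cand
                        stacked = 1
                h[i, j] = best_h
                ch[i, j] = stacked
            best = m[i + 1, j]
            arg = 0
            # k descending: ties prefer the distal partner, which keeps
            # long planted stems intact over equal-scoring local pairs
            for k in range(j - 1, i + min_loop, -1):
                if h[i, k + 1] < 0:
                    continue
                cand = h[i, k + 1] + m[k + 1, j]
                if cand > best:
                    best = cand
                    arg = k
            m[i, j] = best
            cm[i, j] = arg
    return m, cm, ch


def _traceback(cm: np.ndarray, ch: np.ndarray, n: int) -> list[tuple[int, int]]:
    pairs: list[tuple[int, int]] = []
    stack = [(0, n, False)]
    while stack:
        i, j, in_helix = stack.pop()
        if j - i < 2:
            continue
        if in_helix:
            # (i, j-1) is paired by construction
            pairs.append((i, j - 1))
            if ch[i, j]:
                stack.append((i + 1, j - 1, True))
            else:
                stack.append((i + 1, j - 1, False))
            continue
        k = int(cm[i, j])
        if k == 0:
            stack.append((i + 1, j, False))
        else:
            stack.append((i, k + 1, True))
            stack.append((k + 1, j, False))
    return pairs


def pair_table(structure: str) -> np.ndarray:
    """Partner index per position (-1 if unpaired) from dot-bracket."""
    pt = np.full(len(structure), -1, dtype=np.int64)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced structure")
            j = stack.pop()
            pt[i], pt[j] = j, i
    if stack:
        raise ValueError("unbalanced structure")
    return pt


def hairpin_loops(structure: str) -> list[tuple[int, int]]:
    """Closing pairs (i, j) of hairpin loops: pairs enclosing only dots."""
    pt = pair_table(structure)
    loops = []
    for i, j in enumerate(pt):
        if j > i and all(pt[k] == -1 for k in range(i + 1, j)):
            loops.append((i, int(j)))
    return loops


def structure_energy(
    sequence: str,
    structure: str,
    *,
    loop_penalty: float = LOOP_PENALTY,
    unpaired_penalty: float = UNPAIRED_PENALTY,
) -> float:
    """Pseudo-energy of a given structure under the bundled model."""
    seq = normalize(sequence)
    pt = pair_table(structure)
    score = 0
    for i, j in enumerate(pt):
        if j > i:
            score += int(_PAIR_SCORE[_ENC[seq[i]], _ENC[seq[j]]])
    if score == 0:
        return 0.0
    n_loops = len(hairpin_loops(structure))
    paired_pos = np.where(pt >= 0)[0]
    lo, hi = int(paired_pos.min()), int(paired_pos.max())
    n_unpaired_enclosed = int(np.sum(pt[lo : hi + 1] == -1))
    return -float(score) + loop_penalty * n_loops + unpaired_penalty * n_unpaired_enclosed


def _remove_lone_pairs(pairs: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Drop pairs with no stacked neighbour (helices must be >= 2 pairs),
    iterating to a fixed point, as thermodynamic folders do by default."""
    current = set(pairs)
    while True:
        lone = {
            (i, j)
            for i, j in current
            if (i - 1, j + 1) not in current and (i + 1, j - 1) not in current
        }
        if not lone:
            return sorted(current)
        current -= lone


@lru_cache(maxsize=4096)
def _fold_cached(seq: str, min_loop: int) -> tuple[str, float]:
    enc = np.array([_ENC[c] for c in seq], dtype=np.int64)
    _, cm, ch = _nussinov(enc, _PAIR_SCORE, min_loop, _STACK_BONUS)
    pairs = _remove_lone_pairs(_traceback(cm, ch, len(seq)))
    structure = ["."] * len(seq)
    for i, j in pairs:
        structure[i] = "("
        structure[j] = ")"
    db = "".join(structure)
    energy = structure_energy(seq, db)
    if energy >= 0 and pairs:
        # Folding is not favorable under the pseudo-energy model.
        return "." * len(seq), 0.0
    return db, energy


def fold(sequence: str, *, min_loop: int = MIN_LOOP) -> FoldResult:
    """Fold a sequence with the bundled engine.

    Deterministic: identical input gives identical structure and mfe.
    Raises ``ValueError`` on invalid characters or sequences shorter
    than 20 nt.
    """
    seq = normalize(sequence)
    if not seq:
        raise ValueError("cannot fold an empty sequence")
    check_bases(seq)
    structure, mfe = _fold_cached(seq, min_loop)
    return FoldResult(sequence=seq, structure=structure, mfe=mfe)
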