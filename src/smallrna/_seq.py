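"""Small sequence helpers shared across modules.

All pipeline sequences are stored as DNA-alphabet uppercase strings
(A/C/G/T); RNA input (U) is accepted at the boundaries and normalized.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

VALID_BASES = frozenset("ACGT")


def normalize(seq: str) -> str:
    """Uppercase and convert RNA (U) to the internal DNA alphabet."""
    return seq.upper().replace("U", "T")


def check_bases(seq: str, *, allow_n: bool = False) -> None:
    allowed = VALID_BASES | {"N"} if allow_n else VALID_BASES
    bad = set(seq) - allowed
    if bad:
        raise ValueError(f"invalid characters in sequence: {sorted(bad)!r}")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def pairs(a: str, b: str) -> bool:
    """Watson-Crick pair (DNA alphabet)."""
    return (a, b) in (("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"))


def wobble(a: str, b: str) -> bool:
    """G:U wobble pair (DNA alphabet: G:T)."""
    return (a, b) in (("G", "T"), ("T", "G"))
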