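"""Two-library differential expression for tag counts.

Implements reads-per-million normalization, log2 fold change with a
symmetric pseudo-count for library-specific tags, the exact conditional
probability test for comparing a tag's counts between two libraries of
known depths, and the significance-tier classification used for
reporting.

The exact test conditions on the count ``x`` observed in library 1 and
evaluates, for library-size ratio ``r = N2/N1``,

    p(y|x) = r**y * (x+y)! / (x! * y!) / (1+r)**(x+y+1)

which is a negative-binomial pmf in ``y`` (NB(x+1, 1/(1+r))).  The upper
tail ``D`` and lower tail ``C`` both include the observed ``y``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

from scipy.special import gammaln

__all__ = [
    "LibraryPair",
    "DiffExprRecord",
    "Tier",
    "normalize_rpm",
    "log2_fold_change",
    "log_pmf",
    "exact_pvalue",
    "classify_tier",
    "diff_expr_table",
]


class Tier(str, enum.Enum):
    EXTREMELY_SIGNIFICANT = "extremely_significant"
    SIGNIFICANT = "significant"
    NOT_SIGNIFICANT = "not_significant"
    EXCLUDED = "excluded"


@dataclass(frozen=True)
class LibraryPair:
    """Total clean-read depths of the two libraries being compared."""

    n1: int
    n2: int

    def __post_init__(self) -> None:
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("library totals must be positive")

    @property
    def ratio(self) -> float:
        """N2/N1."""
        return self.n2 / self.n1


@dataclass
class DiffExprRecord:
    mirna_id: str
    x: int
    y: int
    rpm1: float
    rpm2: float
    log2fc: float
    p_value: float
    d: float
    c: float
    tier: Tier | None = None


def normalize_rpm(count: int, library_total: int) -> float:
    """Reads-per-million: ``1e6 * count / library_total``."""
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return 1e6 * count / library_total


def log2_fold_change(rpm1: float, rpm2: float, pseudo: float = 0.01) -> float:
    """log2(rpm1/rpm2); a pseudo-count is added to *both* terms when
    either is zero, so library-specific tags remain reportable.
    """
    if rpm1 < 0 or rpm2 < 0:
        raise ValueError("RPM values must be non-negative")
    if rpm1 == 0 and rpm2 == 0:
        raise ValueError("fold change undefined for two zero expression values")
    if rpm1 == 0 or rpm2 == 0:
        rpm1 += pseudo
        rpm2 += pseudo
    return math.log2(rpm1 / rpm2)


def log_pmf(y: int, x: int, ratio: float) -> float:
    """log p(y|x) for library-size ratio ``ratio = N2/N1``."""
    if y < 0 or x < 0:
        raise ValueError("counts must be non-negative")
    return (
        y * math.log(ratio)
        + gammaln(x + y + 1)
        - gammaln(x + 1)
        - gammaln(y + 1)
        - (x + y + 1) * math.log1p(ratio)
    )


def _lower_tail(x: int, y: int, ratio: float) -> float:
    """C = sum_{y'=0..y} p(y'|x), summed by recurrence from y'=0."""
    log_term = log_pmf(0, x, ratio)  # p(0|x)
    term = math.exp(log_term)
    total = term
    log_r = math.log(ratio) - math.log1p(ratio)
    for yp in range(1, y + 1):
        # p(y'|x) / p(y'-1|x) = ratio/(1+ratio) * (x+y')/y'
        log_term += log_r + math.log(x + yp) - math.log(yp)
        total += math.exp(log_term)
    return min(total, 1.0)


def _upper_tail(x: int, y: int, ratio: float) -> float:
    """D = sum_{y'>=y} p(y'|x), summed upward until terms underflow."""
    log_term = log_pmf(y, x, ratio)
    term = math.exp(log_term)
    total = term
    log_r = math.log(ratio) - math.log1p(ratio)
    yp = y
    while True:
        yp += 1
        log_term += log_r + math.log(x + yp) - math.log(yp)
        term = math.exp(log_term)
        total += term
        if term < total * 1e-17 or term < 1e-300:
            break
    return min(total, 1.0)


def exact_pvalue(
    x: int, y: int, pair: LibraryPair, sided: str = "two"
) -> tuple[float, float, float]:
    """Exact conditional p-value for counts (x, y) given library depths.

    Returns ``(p_value, D, C)`` where ``D`` is the upper cumulative
    probability ``sum_{y'>=y} p(y'|x)`` and ``C`` the lower cumulative
    ``sum_{y'<=y} p(y'|x)`` (both inclusive of the observed ``y``).
    One-sided p = min(D, C); two-sided p = min(1, 2*min(D, C)).
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if sided not in ("one", "two"):
        raise ValueError("sided must be 'one' or 'two'")
    r = pair.ratio
    # Evaluate the smaller tail by direct summation; derive the other from
    # the complement plus the observed point to keep both accurate.
    mean = (x + 1) * r  # mean of the conditional distribution
    p_obs = math.exp(log_pmf(y, x, r))
    if y <= mean:
        c = _lower_tail(x, y, r)
        d = min(1.0, 1.0 - c + p_obs)
    else:
        d = _upper_tail(x, y, r)
        c = min(1.0, 1.0 - d + p_obs)
    p_min = min(d, c)
    p = p_min if sided == "one" else min(1.0, 2.0 * p_min)
    return p, d, c


def classify_tier(
    record: DiffExprRecord,
    *,
    fc_threshold: float = 1.5,
    p_extreme: float = 0.01,
    p_significant: float = 0.05,
    exclusion_mode: str = "rpm",
) -> Tier:
    """Significance tier for one record.

    Records expressed below 1 RPM in *both* libraries are excluded
    (``exclusion_mode='rpm'``, the default reading of the low-expression
    filter; ``'literal'`` disables the exclusion).  Otherwise the tier is
    extremely significant when |log2fc| > fc_threshold and p <= p_extreme,
    significant when |log2fc| > fc_threshold and p_extreme < p <
    p_significant (strict upper bound), and not significant otherwise.
    """
    if exclusion_mode not in ("rpm", "literal"):
        raise ValueError("exclusion_mode must be 'rpm' or 'literal'")
    if exclusion_mode == "rpm" and record.rpm1 < 1.0 and record.rpm2 < 1.0:
        return Tier.EXCLUDED
    if abs(record.log2fc) > fc_threshold:
        if record.p_value <= p_extreme:
            return Tier.EXTREMELY_SIGNIFICANT
        if record.p_value < p_significant:
            return Tier.SIGNIFICANT
    return Tier.NOT_SIGNIFICANT


def diff_expr_table(
    counts: dict[str, tuple[int, int]],
    pair: LibraryPair,
    *,
    pseudo: float = 0.01,
    sided: str = "two",
    fc_threshold: float = 1.5,
    p_extreme: float = 0.01,
    p_significant: float = 0.05,
    exclusion_mode: str = "rpm",
) -> list[DiffExprRecord]:
    """Full differential-expression table for ``{id: (x, y)}`` counts."""
    records = []
    for mirna_id, (x, y) in counts.items():
        rpm1 = normalize_rpm(x, pair.n1)
        rpm2 = normalize_rpm(y, pair.n2)
        log2fc = (
            log2_fold_change(rpm1, rpm2, pseudo)
            if (rpm1 > 0 or rpm2 > 0)
            else 0.0
        )
        p, d, c = exact_pvalue(x, y, pair, sided=sided)
        rec = DiffExprRecord(
            mirna_id=mirna_id,
            x=x,
            y=y,
            rpm1=rpm1,
            rpm2=rpm2,
            log2fc=log2fc,
            p_value=p,
            d=d,
            c=c,
        )
        rec.tier = classify_tier(
            rec,
            fc_threshold=fc_threshold,
            p_extreme=p_extreme,
            p_significant=p_significant,
            exclusion_mode=exclusion_mode,
        )
        records.append(rec)
    return records
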