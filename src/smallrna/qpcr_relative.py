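"""2^-ddCt relative-expression calculator for RT-qPCR validation.

dCt = Ct(target) - Ct(reference) per replicate; ddCt = mean dCt(treated)
- mean dCt(control); relative expression = 2^-ddCt, with asymmetric
bounds 2^-(ddCt +/- SE) propagated from the replicate dCt variances.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["QpcrRecord", "RelativeExpression", "relative_expression"]


@dataclass(frozen=True)
class QpcrRecord:
    gene_id: str
    condition: str
    replicate: int
    ct_target: float
    ct_reference: float

    def __post_init__(self) -> None:
        for name, ct in (("ct_target", self.ct_target), ("ct_reference", self.ct_reference)):
            if not 0.0 < ct < 50.0:
                raise ValueError(f"{name} out of range (0, 50): {ct}")

    @property
    def delta_ct(self) -> float:
        return self.ct_target - self.ct_reference


@dataclass(frozen=True)
class RelativeExpression:
    fold: float
    ddct: float
    se: float
    lower: float  # 2^-(ddCt + SE)
    upper: float  # 2^-(ddCt - SE)


def _mean_se(values: list[float]) -> tuple[float, float]:
    n = len(values)
    mean = sum(values) / n
    if n == 1:
        return mean, 0.0
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    return mean, math.sqrt(var / n)


def relative_expression(
    treated: list[QpcrRecord], control: list[QpcrRecord]
) -> RelativeExpression:
    """Fold change of the treated condition relative to control."""
    if not treated or not control:
        raise ValueError("at least one replicate required per condition")
    mt, se_t = _mean_se([r.delta_ct for r in treated])
    mc, se_c = _mean_se([r.delta_ct for r in control])
    ddct = mt - mc
    se = math.sqrt(se_t**2 + se_c**2)
    return RelativeExpression(
        fold=2.0**-ddct,
        ddct=ddct,
        se=se,
        lower=2.0 ** -(ddct + se),
        upper=2.0 ** -(ddct - se),
    )
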