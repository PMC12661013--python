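"""Shared result record for hypothesis tests.

Every test in the package — permutation tests, rank tests, t-tests —
returns a :class:`TestResult` so downstream tables can be assembled
uniformly regardless of which statistic was computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional


@dataclass
class TestResult:
    """Generic statistic / p-value record.

    Attributes
    ----------
    statistic
        The test statistic (F, U, H, t, z, r, ...).
    p_value
        Two-sided or one-sided p-value, in [0, 1].
    method
        Human-readable label of the procedure that produced the result.
    q_value
        Multiplicity-adjusted p-value, when a correction was applied.
    df
        Degrees of freedom; may be fractional (Welch) or a tuple encoded
        as a string upstream.
    effect
        Optional effect measure (e.g. R-squared for PERMANOVA/db-RDA).
    n_permutations
        Number of permutations for permutation-based p-values.
    extra
        Free-form auxiliary values (group means, tie counts, ...).
    """

    statistic: float
    p_value: float
    method: str
    q_value: Optional[float] = None
    df: Optional[float] = None
    effect: Optional[float] = None
    n_permutations: Optional[int] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (-1e-12 <= self.p_value <= 1 + 1e-12):
            raise ValueError(f"p-value outside [0, 1]: {self.p_value}")
        self.p_value = float(min(max(self.p_value, 0.0), 1.0))
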