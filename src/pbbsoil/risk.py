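"""Pesticide risk index and three-rank classification.

The risk index for a sample is the sum over its pesticides of the
predicted environmental concentration (PEC) divided by the no-effect
concentration (NEC). Samples are ranked low (index <= 1), medium
(1 < index <= 3), or high (index > 3).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Tuple

import pandas as pd

logger = logging.getLogger(__name__)

RISK_CLASSES = ("low", "medium", "high")

LOW_MAX = 1.0    # largest index still labelled low
MEDIUM_MAX = 3.0  # largest index still labelled medium


def risk_index(pairs: Iterable[Tuple[float, float]], names: Optional[Sequence[str]] = None) -> float:
    """Sum of PEC/NEC quotients over a sample's pesticides.

    PEC and NEC must share units within each pesticide; an empty list
    gives 0 (no pesticide burden). NEC <= 0 is rejected, naming the
    pesticide when names are given.
    """
    total = 0.0
    for i, (pec, nec) in enumerate(pairs):
        label = names[i] if names is not None else f"pesticide #{i + 1}"
        if nec <= 0:
            raise ValueError(f"{label}: NEC must be > 0 (got {nec})")
        if pec < 0:
            raise ValueError(f"{label}: PEC must be >= 0 (got {pec})")
        total += pec / nec
    return total


def classify_risk(ri: float) -> str:
    """Map a risk index to its rank: low (<=1), medium (1, 3], high (>3)."""
    if ri < 0:
        raise ValueError(f"risk index must be >= 0 (got {ri})")
    if ri <= LOW_MAX:
        return "low"
    if ri <= MEDIUM_MAX:
        return "medium"
    return "high"


@dataclass
class RiskAssessment:
    """Per-sample risk index and class."""

    sample_id: str
    risk_index: float
    risk_class: str = ""
    pesticides: list = field(default_factory=list)  # (name, pec, nec)

    def __post_init__(self) -> None:
        if not self.risk_class:
            self.risk_class = classify_risk(self.risk_index)


def assess_from_pairs(pairs_table: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a long-format PEC/NEC table into per-sample assessments.

    Expects columns ``sample_id``, ``pesticide``, ``pec``, ``nec``.
    Returns a frame indexed by sample with ``risk_index`` and
    ``risk_class`` columns.
    """
    required = {"sample_id", "pesticide", "pec", "nec"}
    missing = required - set(pairs_table.columns)
    if missing:
        raise ValueError(f"PEC/NEC table missing columns: {sorted(missing)}")
    rows = {}
    for sample, grp in pairs_table.groupby("sample_id"):
        ri = risk_index(
            list(zip(grp["pec"], grp["nec"])), names=list(grp["pesticide"])
        )
        rows[sample] = {"risk_index": ri, "risk_class": classify_risk(ri)}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out


def stratify_samples(metadata: pd.DataFrame) -> pd.Series:
    """Assign every sample to exactly one risk class.

    Accepts a metadata frame (indexed by sample) carrying a
    ``risk_class`` column, a ``risk_index`` column, or both. A
    precomputed class takes precedence over the index, with a logged
    warning where both are present. Samples with neither are an error.
    """
    has_class = "risk_class" in metadata.columns
    has_index = "risk_index" in metadata.columns
    if not has_class and not has_index:
        raise ValueError("metadata has neither risk_class nor risk_index")
    classes = {}
    for sample, row in metadata.iterrows():
        cls = row.get("risk_class") if has_class else None
        ri = row.get("risk_index") if has_index else None
        cls_ok = isinstance(cls, str) and cls in RISK_CLASSES
        ri_ok = ri is not None and pd.notna(ri)
        if cls_ok and ri_ok:
            derived = classify_risk(float(ri))
            if derived != cls:
                logger.warning(
                    "sample %s: precomputed class %r overrides index-derived %r",
                    sample, cls, derived,
                )
            classes[sample] = cls
        elif cls_ok:
            classes[sample] = cls
        elif ri_ok:
            classes[sample] = classify_risk(float(ri))
        else:
            raise ValueError(f"sample {sample}: no risk_class or risk_index")
    out = pd.Series(classes, name="risk_class").reindex(metadata.index)
    sizes = out.value_counts().to_dict()
    logger.info("risk stratification: %s", sizes)
    return out
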