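"""Hedges' d effect sizes and the two-way factorial interaction framework.

A single stressor's standardized effect on diversity is measured with
Hedges' d (small-sample-corrected standardized mean difference). The
joint action of pesticide risk with a second anthropogenic factor is
measured on a 2x2 factorial layout — control (C), pesticide alone (P),
factor alone (F), and both (PF) — using the factorial meta-analysis
parameterization: main effects against the pooled SD with a 2s
denominator, and the interaction contrast

    d_I = J * (Ybar_PF - Ybar_P - Ybar_F + Ybar_C) / s

whose 95% t-interval classifies the pair as additive (interval covers
zero), synergistic (excludes zero on the side of the summed main
effects), or antagonistic (excludes zero on the opposite side).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class EffectSize:
    """Hedges' d with variance and 95% t-distribution confidence interval."""

    d: float
    variance: float
    ci_low: float
    ci_high: float
    df: int
    correction: float  # small-sample factor J in (0, 1)

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.variance))

    def __post_init__(self) -> None:
        if self.variance <= 0:
            raise ValueError("effect-size variance must be > 0")
        if not (self.ci_low <= self.d <= self.ci_high):
            raise ValueError("confidence interval does not bracket d")


def hedges_d(x, y) -> EffectSize:
    """Hedges' d for two independent groups (x minus y).

    s_p is the pooled SD, df = n1 + n2 - 2, J = 1 - 3/(4 df - 1),
    d = J (mx - my)/s_p, v = (n1+n2)/(n1 n2) + d^2 / (2 (n1+n2)),
    CI = d +- t_{0.975, df} sqrt(v).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    s1, s2 = x.var(ddof=1), y.var(ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * s1 + (n2 - 1) * s2) / df
    if sp2 <= 0:
        raise ValueError("pooled variance is zero")
    J = 1.0 - 3.0 / (4.0 * df - 1.0)
    d = J * (x.mean() - y.mean()) / np.sqrt(sp2)
    v = (n1 + n2) / (n1 * n2) + d * d / (2.0 * (n1 + n2))
    half = sps.t.ppf(0.975, df) * np.sqrt(v)
    return EffectSize(d=float(d), variance=float(v),
                      ci_low=float(d - half), ci_high=float(d + half),
                      df=df, correction=float(J))


@dataclass
class InteractionResult:
    """Factorial main and interaction effects for one anthropogenic factor."""

    factor: str
    cell_means: dict            # keys C, P, F, PF
    d_pesticide: EffectSize
    d_factor: EffectSize
    d_interaction: EffectSize
    classification: str = ""    # additive | synergistic | antagonistic
    flags: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.classification:
            self.classification = classify_interaction(self)


def classify_interaction(result: "InteractionResult") -> str:
    """Additive / synergistic / antagonistic call from the d_I interval.

    Additive when the interaction CI contains zero. Otherwise the call is
    synergistic when d_I points the same way as the summed main effects
    (the joint stress exceeds the additive expectation in the direction
    the stressors already push), antagonistic when it points the other
    way. A zero main-effect sum with a non-additive interval is resolved
    by the sign of d_I alone and flagged "undirected".
    """
    eff = result.d_interaction
    if eff.ci_low <= 0.0 <= eff.ci_high:
        return "additive"
    main_sum = result.d_pesticide.d + result.d_factor.d
    if main_sum == 0.0:
        if "undirected" not in result.flags:
            result.flags.append("undirected")
        return "synergistic" if eff.d < 0 else "antagonistic"
    return "synergistic" if np.sign(eff.d) == np.sign(main_sum) else "antagonistic"


def factorial_interaction(
    cells: Mapping[str, np.ndarray],
    factor: str = "",
    interaction_denominator: str = "s",
) -> InteractionResult:
    """Main and interaction Hedges' d from a 2x2 factorial layout.

    ``cells`` maps the four cell labels C (control), P (pesticide alone),
    F (factor alone), PF (both) to response vectors. The pooled SD s uses
    all four cells, df = N - 4, J = 1 - 3/(4 df - 1); main effects use
    the 2s denominator, the interaction contrast divides by s (or 2s when
    ``interaction_denominator="2s"``), with variance
    v_I = sum_i 1/n_i + d_I^2 / (2N) and a 95% t interval.
    """
    required = ("C", "P", "F", "PF")
    missing = [k for k in required if k not in cells]
    if missing:
        raise ValueError(f"missing factorial cell(s): {missing}")
    if interaction_denominator not in ("s", "2s"):
        raise ValueError("interaction_denominator must be 's' or '2s'")
    arrs = {k: np.asarray(cells[k], dtype=float) for k in required}
    ns = {k: a.size for k, a in arrs.items()}
    if any(n < 2 for n in ns.values()):
        raise ValueError("each factorial cell needs n >= 2")
    N = sum(ns.values())
    df = N - 4
    pooled_num = sum((ns[k] - 1) * arrs[k].var(ddof=1) for k in required)
    s2 = pooled_num / sum(ns[k] - 1 for k in required)
    if s2 <= 0:
        raise ValueError("pooled SD across cells is zero")
    s = np.sqrt(s2)
    J = 1.0 - 3.0 / (4.0 * df - 1.0)
    m = {k: arrs[k].mean() for k in required}
    t975 = sps.t.ppf(0.975, df)

    def _main(plus, minus) -> EffectSize:
        d = J * (sum(m[k] for k in plus) - sum(m[k] for k in minus)) / (2.0 * s)
        # variance of a two-cell-vs-two-cell standardized contrast
        v = 0.25 * sum(1.0 / ns[k] for k in required) + d * d / (2.0 * N)
        half = t975 * np.sqrt(v)
        return EffectSize(d=float(d), variance=float(v), ci_low=float(d - half),
                          ci_high=float(d + half), df=df, correction=float(J))

    d_P = _main(("P", "PF"), ("C", "F"))
    d_F = _main(("F", "PF"), ("C", "P"))

    denom = s if interaction_denominator == "s" else 2.0 * s
    d_I = J * (m["PF"] - m["P"] - m["F"] + m["C"]) / denom
    v_I = sum(1.0 / ns[k] for k in required) + d_I * d_I / (2.0 * N)
    half = t975 * np.sqrt(v_I)
    eff_I = EffectSize(d=float(d_I), variance=float(v_I),
                       ci_low=float(d_I - half), ci_high=float(d_I + half),
                       df=df, correction=float(J))

    return InteractionResult(
        factor=factor,
        cell_means={k: float(m[k]) for k in required},
        d_pesticide=d_P, d_factor=d_F, d_interaction=eff_I,
    )


def interaction_screen(
    response: pd.Series,
    covariates: pd.DataFrame,
    risk_class: pd.Series,
    low_label: str = "low",
    high_label: str = "high",
    interaction_denominator: str = "s",
) -> pd.DataFrame:
    """Screen every anthropogenic covariate for interaction with pesticide risk.

    Samples in the medium class are dropped; the pesticide axis contrasts
    low vs high risk, and each covariate is dichotomized at its median
    within the retained samples (ties go to the low side — the split is
    invariant to any monotone rescaling of the covariate). Cells:
    C = low risk / low covariate, P = high risk / low covariate,
    F = low risk / high covariate, PF = both high.

    Returns one row per covariate sorted by |d_I| (descending), with the
    pesticide-only Hedges' d (low vs high on all retained samples)
    repeated for comparison. Covariates with fewer than two distinct
    values, or yielding a degenerate cell, are skipped.
    """
    keep = risk_class.isin([low_label, high_label])
    ids = risk_class.index[keep]
    if len(ids) == 0:
        raise ValueError("no samples in the low or high risk classes")
    y = response.loc[ids]
    rc = risk_class.loc[ids]
    low_ids = ids[rc == low_label]
    high_ids = ids[rc == high_label]
    if len(low_ids) < 4 or len(high_ids) < 4:
        raise ValueError("need >= 4 samples in both low and high risk classes")
    d_pesticide_only = hedges_d(y.loc[high_ids], y.loc[low_ids])

    rows = []
    for name in covariates.columns:
        cov = covariates[name].loc[ids].astype(float)
        if cov.nunique() < 2:
            continue
        med = cov.median()
        high_cov = cov > med  # ties assigned to the low side
        cells = {
            "C": y.loc[low_ids[~high_cov.loc[low_ids]]].values,
            "P": y.loc[high_ids[~high_cov.loc[high_ids]]].values,
            "F": y.loc[low_ids[high_cov.loc[low_ids]]].values,
            "PF": y.loc[high_ids[high_cov.loc[high_ids]]].values,
        }
        if any(v.size < 2 for v in cells.values()):
            continue
        try:
            res = factorial_interaction(
                cells, factor=name,
                interaction_denominator=interaction_denominator,
            )
        except ValueError:
            continue
        eff = res.d_interaction
        rows.append({
            "factor": name,
            "d_pesticide": res.d_pesticide.d,
            "d_factor": res.d_factor.d,
            "d_interaction": eff.d,
            "sd": eff.sd,
            "ci_low": eff.ci_low,
            "ci_high": eff.ci_high,
            "classification": res.classification,
            "d_pesticide_only": d_pesticide_only.d,
            "n_C": len(cells["C"]), "n_P": len(cells["P"]),
            "n_F": len(cells["F"]), "n_PF": len(cells["PF"]),
        })
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.reindex(
            out["d_interaction"].abs().sort_values(ascending=False).index
        ).reset_index(drop=True)
    return out
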