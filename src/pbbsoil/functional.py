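"""KO-based functional potential: pathway completeness and CNPS gene counts.

Functional annotation assigns contigs to KEGG orthology (KO) terms; per
sample, the KO counts form a profile from which growth-factor
biosynthesis capability is scored as *pathway completeness* — the
fraction of a pathway's steps with at least one detected alternative KO.
Completeness is compared across pesticide-risk classes per growth factor
(Kruskal-Wallis, BH-adjusted), and marker genes for carbon, nitrogen,
phosphorus, and sulfur cycling are tallied per class.
"""

from __future__ import annotations

import logging
from fractions import Fraction
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .catalogs import CNPSGeneMap, PathwayCatalog
from .stats import bh_fdr, kruskal_wallis

logger = logging.getLogger(__name__)


def ko_profile_from_hits(
    hits: pd.DataFrame,
    query_to_sample: Mapping[str, str],
    subject_to_ko: Mapping[str, str],
) -> pd.DataFrame:
    """Count hit contigs per KO per sample from a filtered hit table.

    ``query_to_sample`` maps contig/query ids to sample ids;
    ``subject_to_ko`` maps database subject ids to KO terms. Hits whose
    subject has no KO mapping are dropped (count logged).
    """
    if hits.empty:
        return pd.DataFrame(dtype=float)
    kos = hits["subject_id"].map(subject_to_ko)
    dropped = int(kos.isna().sum())
    if dropped:
        logger.info("ko_profile_from_hits: dropped %d unmapped hits", dropped)
    samples = hits["query_id"].map(query_to_sample)
    if samples.isna().any():
        missing = hits.loc[samples.isna(), "query_id"].unique()[:5]
        raise ValueError(f"queries with no sample assignment: {list(missing)}")
    ok = kos.notna()
    tally = (
        pd.DataFrame({"ko": kos[ok], "sample": samples[ok]})
        .groupby(["ko", "sample"])
        .size()
        .unstack(fill_value=0)
        .astype(float)
    )
    tally.index.name = "ko"
    return tally


def pathway_completeness(
    ko_profile: pd.DataFrame,
    catalog: PathwayCatalog,
    presence_threshold: float = 1.0,
) -> pd.DataFrame:
    """Completeness of each growth-factor pathway in each sample.

    A step is covered when any of its alternative KOs reaches
    ``presence_threshold`` abundance (default: one hit contig);
    completeness is covered steps over total steps, exactly rational
    with the step count as denominator. Monotone in KO abundance.

    Returns a growth-factor x sample frame of floats in [0, 1].
    """
    samples = list(ko_profile.columns)
    out = pd.DataFrame(0.0, index=[f.name for f in catalog.factors], columns=samples)
    present = ko_profile >= presence_threshold
    for f in catalog.factors:
        total = len(f.pathway)
        covered = np.zeros(len(samples), dtype=int)
        for step in f.pathway:
            kos = [k for k in step.alternatives if k in present.index]
            if kos:
                covered += present.loc[kos].any(axis=0).values
        out.loc[f.name] = covered / total
    out.index.name = "growth_factor"
    return out


def completeness_fraction(
    ko_presence: Mapping[str, bool], factor
) -> Fraction:
    """Exact rational completeness of one pathway from a KO presence map."""
    covered = sum(
        1 for step in factor.pathway
        if any(ko_presence.get(k, False) for k in step.alternatives)
    )
    return Fraction(covered, len(factor.pathway))


def detect_decreased_pathways(
    scores: pd.DataFrame,
    risk_class: pd.Series,
    catalog: Optional[PathwayCatalog] = None,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-factor Kruskal-Wallis of completeness across risk classes.

    ``scores`` is the growth-factor x sample completeness table. Factors
    with constant scores get H = 0, p = 1 and are never flagged. BH
    adjustment runs across factors; a factor is ``decreased`` when
    q < ``q_threshold`` and the median completeness in the high class is
    below the low-class median.

    Returns a per-factor table with the test, per-class medians, the
    decreased flag, and (when a catalog is given) the factor category.
    """
    classes = [c for c in ("low", "medium", "high") if (risk_class == c).any()]
    if len(classes) < 2:
        raise ValueError("need >= 2 risk classes represented")
    rows = []
    for factor in scores.index:
        vals = scores.loc[factor]
        groups = [vals[risk_class.index[risk_class == c]].values for c in classes]
        res = kruskal_wallis(groups)
        row = {
            "growth_factor": factor,
            "H": res.statistic,
            "p": res.p_value,
        }
        for c in classes:
            row[f"median_{c}"] = float(np.median(
                vals[risk_class.index[risk_class == c]]
            ))
        rows.append(row)
    out = pd.DataFrame(rows).set_index("growth_factor")
    out["q"] = bh_fdr(out["p"].values)
    med_low = out.get("median_low", pd.Series(np.nan, index=out.index))
    med_high = out.get("median_high", pd.Series(np.nan, index=out.index))
    out["decreased"] = (out["q"] < q_threshold) & (med_high < med_low)
    if catalog is not None:
        cats = {f.name: f.category for f in catalog.factors}
        out["category"] = [cats.get(f, "") for f in out.index]
    return out


def category_rollup(decreased_table: pd.DataFrame) -> pd.Series:
    """Count decreased growth factors per biosynthetic category."""
    if "category" not in decreased_table.columns:
        raise ValueError("decreased table carries no category column")
    flagged = decreased_table[decreased_table["decreased"]]
    return flagged.groupby("category").size().sort_values(ascending=False)


# ---------------------------------------------------------------------------
# CNPS cycling genes


def cnps_gene_counts(
    hits_by_class: Mapping[str, pd.DataFrame],
    gene_map: CNPSGeneMap,
    subject_to_gene: Mapping[str, str],
) -> pd.DataFrame:
    """Contig counts per CNPS marker gene per risk class.

    ``hits_by_class`` maps risk-class labels to filtered hit tables;
    ``subject_to_gene`` maps subject ids to gene keys of the CNPS map
    (e.g. ``K01601_rbcL``). Unmapped subjects and genes outside the map
    are ignored. Adds a ``cycle`` column and a ``direction`` call per
    gene (up/down from the low to the high class, flat otherwise).
    """
    counts = {}
    for cls, hits in hits_by_class.items():
        if hits.empty:
            counts[cls] = pd.Series(dtype=float)
            continue
        genes = hits["subject_id"].map(subject_to_gene)
        genes = genes[genes.notna()]
        genes = genes[genes.map(gene_map.cycle_of).notna()]
        counts[cls] = genes.value_counts().astype(float)
    table = pd.DataFrame(counts).fillna(0.0)
    all_genes = sorted(gene_map.mapping)
    table = table.reindex(all_genes, fill_value=0.0)
    table.index.name = "gene_key"
    return _annotate_cnps(table, gene_map)


def cnps_counts_from_ko_profile(
    gene_profile: pd.DataFrame,
    risk_class: pd.Series,
    gene_map: CNPSGeneMap,
) -> pd.DataFrame:
    """Per-class CNPS totals from a gene-key x sample count matrix."""
    table = {}
    for cls in pd.unique(risk_class.dropna()):
        ids = [s for s in gene_profile.columns if risk_class.get(s) == cls]
        table[cls] = gene_profile[ids].sum(axis=1)
    out = pd.DataFrame(table)
    out = out.loc[[g for g in out.index if gene_map.cycle_of(g)]]
    out.index.name = "gene_key"
    return _annotate_cnps(out, gene_map)


def _annotate_cnps(table: pd.DataFrame, gene_map: CNPSGeneMap) -> pd.DataFrame:
    table = table.copy()
    table["cycle"] = [gene_map.cycle_of(g) for g in table.index]
    if "low" in table.columns and "high" in table.columns:
        delta = table["high"] - table["low"]
        table["direction"] = np.where(
            delta > 0, "up", np.where(delta < 0, "down", "flat")
        )
    return table


def cnps_cycle_totals(table: pd.DataFrame) -> pd.DataFrame:
    """Sum gene counts within each elemental cycle (partition-conserving)."""
    value_cols = [c for c in table.columns if c not in ("cycle", "direction")]
    return table.groupby("cycle")[value_cols].sum()
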