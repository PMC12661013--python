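"""Reading taxonomic profiles and alignment hits; abundance normalization.

Community profiles are genus x sample matrices. Raw read counts come
either from a plain TSV matrix or from per-sample Kraken2-style report
files; counts are normalized to reads per million (RPM) using per-sample
library sizes from metadata, then aggregated over the trait registry to
produce per-sample PBB abundance tables.

Functional annotation hits arrive as BLAST/DIAMOND tabular files
(outfmt-6 dialect) and are filtered on e-value, query coverage, and
percent identity before any counting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import numpy as np
import pandas as pd

from .catalogs import TraitRegistry

PathLike = Union[str, Path]

#: Standard 12 columns of BLAST/DIAMOND tabular output (outfmt 6).
BLAST6_COLUMNS = [
    "query_id", "subject_id", "percent_identity", "align_length",
    "mismatches", "gap_opens", "q_start", "q_end", "s_start", "s_end",
    "evalue", "bit_score",
]

# Filtering thresholds applied to alignment hits before counting.
EVALUE_MAX = 1e-3
COVERAGE_MIN = 60.0
IDENTITY_MIN = 70.0


class ProfileError(ValueError):
    """Raised on malformed profile or alignment inputs."""


@dataclass
class CommunityProfile:
    """Genus x sample abundance matrix with an explicit unit state.

    ``matrix`` rows are genera, columns are samples. ``units`` is either
    ``"raw_counts"`` or ``"RPM"``; normalization to RPM requires per-sample
    library sizes (``total_reads``), which come from sample metadata rather
    than the matrix column sums because unassigned reads exist.
    """

    matrix: pd.DataFrame
    units: str = "raw_counts"
    total_reads: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if self.units not in ("raw_counts", "RPM"):
            raise ProfileError(f"unknown units {self.units!r}")
        if (self.matrix.values < 0).any():
            raise ProfileError("negative abundance entries")
        if self.matrix.index.duplicated().any():
            dups = self.matrix.index[self.matrix.index.duplicated()].tolist()
            raise ProfileError(f"duplicate genus rows: {dups}")
        if self.matrix.columns.duplicated().any():
            raise ProfileError("duplicate sample ids")

    @property
    def genera(self) -> list:
        return list(self.matrix.index)

    @property
    def samples(self) -> list:
        return list(self.matrix.columns)

    def subset_genera(self, genera: Iterable[str]) -> "CommunityProfile":
        keep = [g for g in self.matrix.index if g in set(genera)]
        return replace(self, matrix=self.matrix.loc[keep])


def read_profile_matrix(path: PathLike) -> CommunityProfile:
    """Read a genus x sample TSV matrix of raw counts.

    First column holds genus names; remaining columns are samples. Missing
    or non-numeric cells and duplicate genus rows are hard errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.empty:
        raise ProfileError(f"{path}: empty profile matrix")
    df.index = df.index.str.strip()
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.values.any():
        r, c = np.argwhere(bad.values)[0]
        raise ProfileError(
            f"{path}: non-numeric or missing cell at genus "
            f"{df.index[r]!r}, sample {df.columns[c]!r}"
        )
    if (numeric.values < 0).any():
        raise ProfileError(f"{path}: negative abundance value")
    return CommunityProfile(matrix=numeric.astype(float), units="raw_counts")


def read_kraken_report(path: PathLike, rank: str = "G") -> pd.Series:
    """Extract per-taxon read counts at one rank from a Kraken2 report.

    The report dialect has 6 tab-separated columns: percent of reads,
    clade read count, reads assigned directly to this taxon, rank code,
    NCBI taxid, indented taxon name. The returned counts are the directly
    assigned reads (column 3), *not* the clade totals, so sibling taxa do
    not double-count.
    """
    counts: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            if not raw.strip():
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise ProfileError(
                    f"{path}:{lineno}: expected 6 tab-separated columns, "
                    f"got {len(parts)}"
                )
            _, _, taxon_reads, rank_code, _, name = parts
            if rank_code.strip() != rank:
                continue
            counts[name.strip()] = counts.get(name.strip(), 0) + int(taxon_reads)
    return pd.Series(counts, dtype=float, name=rank)


def profile_from_kraken_reports(
    reports: Mapping[str, PathLike], rank: str = "G"
) -> CommunityProfile:
    """Assemble a CommunityProfile from per-sample Kraken2 report files."""
    columns = {s: read_kraken_report(p, rank=rank) for s, p in reports.items()}
    matrix = pd.DataFrame(columns).fillna(0.0)
    return CommunityProfile(matrix=matrix, units="raw_counts")


def rpm_normalize(
    profile: CommunityProfile, total_reads: Optional[pd.Series] = None
) -> CommunityProfile:
    """Convert raw counts to reads per million: count * 1e6 / library size.

    Library sizes come from metadata (``total_reads`` indexed by sample id),
    supplied here or already attached to the profile. Normalizing an
    RPM profile again is an error.
    """
    if profile.units == "RPM":
        raise ProfileError("profile already in RPM units")
    totals = total_reads if total_reads is not None else profile.total_reads
    if totals is None:
        raise ProfileError("total_reads required for RPM normalization")
    missing = [s for s in profile.samples if s not in totals.index]
    if missing:
        raise ProfileError(f"total_reads missing for samples: {missing}")
    totals = totals.loc[profile.samples].astype(float)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ProfileError(f"non-positive total_reads for samples: {bad}")
    matrix = profile.matrix * 1e6 / totals
    return CommunityProfile(matrix=matrix, units="RPM", total_reads=totals)


# ---------------------------------------------------------------------------
# Alignment hits


def read_alignment_hits(
    path: PathLike, query_lengths: Optional[Mapping[str, int]] = None
) -> pd.DataFrame:
    """Read a BLAST/DIAMOND tabular hit file (no header, tab-separated).

    Accepts the standard 12-column dialect, or 13 columns where the last
    is query coverage per HSP (``qcovhsp``). With 12 columns, coverage is
    computed as ``align_length / query_length`` from the supplied
    ``query_lengths`` side table.
    """
    first = None
    with open(path) as fh:
        for line in fh:
            if line.strip():
                first = line
                break
    if first is None:
        return pd.DataFrame(columns=BLAST6_COLUMNS + ["query_coverage"])
    ncols = len(first.rstrip("\n").split("\t"))
    if ncols == 13:
        names = BLAST6_COLUMNS + ["query_coverage"]
    elif ncols == 12:
        names = BLAST6_COLUMNS
    else:
        raise ProfileError(
            f"{path}: expected 12 or 13 tab-separated columns, got {ncols}"
        )
    df = pd.read_csv(path, sep="\t", names=names, header=None)
    if ncols == 12:
        if query_lengths is None:
            raise ProfileError(
                f"{path}: 12-column input carries no coverage; "
                "supply query_lengths to derive it"
            )
        qlen = df["query_id"].map(query_lengths)
        if qlen.isna().any():
            missing = df.loc[qlen.isna(), "query_id"].unique()[:5]
            raise ProfileError(f"query lengths missing for: {list(missing)}")
        df["query_coverage"] = 100.0 * df["align_length"] / qlen
    return df


def filter_alignment_hits(hits: pd.DataFrame) -> pd.DataFrame:
    """Apply the annotation filter, then keep one best hit per query.

    Rows survive when e-value <= 1e-3, query coverage >= 60%, and percent
    identity >= 70% (all boundaries inclusive); among surviving hits of
    one query, only the row with the maximum bit score is kept (first
    occurrence wins ties). Idempotent; the output is always a subset of
    the input rows.
    """
    if hits.empty:
        return hits.copy()
    mask = (
        (hits["evalue"] <= EVALUE_MAX)
        & (hits["query_coverage"] >= COVERAGE_MIN)
        & (hits["percent_identity"] >= IDENTITY_MIN)
    )
    kept = hits.loc[mask]
    if kept.empty:
        return kept.copy()
    best = kept.loc[kept.groupby("query_id")["bit_score"].idxmax()]
    return best.sort_index()


# ---------------------------------------------------------------------------
# Trait aggregation

TRAIT_COLUMNS = ["PBB_total", "PGP", "biocontrol", "stress_resistance"]


def aggregate_trait_abundance(
    profile: CommunityProfile, registry: TraitRegistry
) -> pd.DataFrame:
    """Per-sample RPM totals over PBB genera, overall and per trait group.

    ``PBB_total`` sums every registry genus present in the profile. Each
    trait column sums the genera carrying that trait; a genus with two
    traits contributes to both columns, so trait columns may exceed
    ``PBB_total`` in sum.
    """
    if profile.units != "RPM":
        raise ProfileError("trait aggregation expects an RPM profile")
    out = pd.DataFrame(0.0, index=profile.samples, columns=TRAIT_COLUMNS)
    for genus in profile.genera:
        traits = registry.traits_of(genus)
        if not traits:
            continue
        row = profile.matrix.loc[genus]
        out["PBB_total"] += row
        for t in traits:
            out[t] += row
    out.index.name = "sample_id"
    return out


def pbb_subset(profile: CommunityProfile, registry: TraitRegistry) -> CommunityProfile:
    """Restrict a profile to genera present in the trait registry."""
    keep = [g for g in profile.genera if g in registry]
    return replace(profile, matrix=profile.matrix.loc[keep])


def read_metadata(path: PathLike) -> pd.DataFrame:
    """Read the sample metadata CSV, indexed by ``sample_id``."""
    meta = pd.read_csv(path)
    if "sample_id" not in meta.columns:
        raise ProfileError(f"{path}: metadata must contain a sample_id column")
    if meta["sample_id"].duplicated().any():
        raise ProfileError(f"{path}: duplicate sample ids in metadata")
    return meta.set_index("sample_id")
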