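"""End-to-end orchestration: ingest through functional potential.

``run_pipeline`` executes the stages in the order the analysis
questions build on each other — ingest and RPM normalization, trait
aggregation, diversity, risk stratification, group tests, the
differential screen, the spatial confounding battery, the interaction
screen, and functional potential — and returns a bundle of tables that
``write_report`` serializes with a manifest recording parameters and
seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import diversity as dv
from . import effects, functional, ingest, risk, spatial, stats
from .catalogs import (
    demo_cnps_map,
    demo_pathway_catalog,
    load_cnps_map,
    load_pathway_catalog,
    load_trait_registry,
)

logger = logging.getLogger(__name__)

REPORT_FILES = (
    "diversity.tsv", "differential.tsv", "interactions.tsv",
    "spatial.tsv", "pathways.tsv", "cnps.tsv", "manifest.json",
)


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 4)."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Paths, stage toggles, and test parameters for one pipeline run."""

    profile: str = ""
    metadata: str = ""
    registry: str = ""            # empty -> bundled demo registry
    catalog: str = ""             # empty -> bundled demo catalog
    cnps_map: str = ""            # empty -> bundled demo map
    ko_profile: str = ""
    gene_profile: str = ""
    outdir: str = "pbbsoil_report"
    seed: int = 0
    n_permutations: int = 999
    q_threshold: float = 0.05
    prevalence_min: float = 0.05
    max_pcnm_axes: int = 20
    stages: dict = field(default_factory=dict)  # stage name -> bool toggle

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def validate(self) -> None:
        if self.n_permutations < 99:
            raise ConfigError("n_permutations must be >= 99")
        if not self.profile or not self.metadata:
            raise ConfigError("profile and metadata paths are required")
        for name in ("profile", "metadata", "registry", "catalog",
                     "cnps_map", "ko_profile", "gene_profile"):
            p = getattr(self, name)
            if p and not Path(p).exists():
                raise ConfigError(f"{name} path does not exist: {p}")

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))


def _region_labels(meta: pd.DataFrame) -> pd.Series:
    """Coarse site grouping: quadrants about the median coordinates."""
    lat_hi = meta["latitude"] >= meta["latitude"].median()
    lon_hi = meta["longitude"] >= meta["longitude"].median()
    labels = np.where(lat_hi, "N", "S") + np.where(lon_hi, "E", "W")
    return pd.Series(labels, index=meta.index, name="region")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all enabled stages; returns the report bundle as a dict."""
    config.validate()
    bundle: dict = {"manifest": {
        "seed": config.seed,
        "n_permutations": config.n_permutations,
        "q_threshold": config.q_threshold,
        "prevalence_min": config.prevalence_min,
        "stages": {},
    }}

    def stage(name):
        def deco(fn):
            if not config.enabled(name):
                bundle["manifest"]["stages"][name] = "skipped"
                return None
            try:
                out = fn()
            except (ConfigError, StageError):
                raise
            except Exception as exc:  # noqa: BLE001 - named stage failure
                raise StageError(name, exc) from exc
            bundle["manifest"]["stages"].setdefault(name, "ok")
            return out
        return deco

    # -- ingest -----------------------------------------------------------
    @stage("ingest")
    def _ingest():
        profile = ingest.read_profile_matrix(config.profile)
        meta = ingest.read_metadata(config.metadata)
        missing = set(profile.samples) - set(meta.index)
        if missing:
            raise ValueError(f"samples missing from metadata: {sorted(missing)[:5]}")
        if config.registry:
            registry = load_trait_registry(config.registry)
        else:
            from .catalogs import demo_trait_registry

            registry = demo_trait_registry()
        rpm = ingest.rpm_normalize(profile, meta["total_reads"])
        pbb = ingest.pbb_subset(rpm, registry)
        if not pbb.genera:
            raise ValueError(
                "no trait-registry genera found in the profile; "
                "check the registry path"
            )
        bundle.update(profile=rpm, pbb=pbb, metadata=meta, registry=registry)
        bundle["trait_abundance"] = ingest.aggregate_trait_abundance(rpm, registry)

    if "pbb" not in bundle:
        raise StageError("ingest", RuntimeError("ingest stage is mandatory"))
    meta = bundle["metadata"]
    pbb = bundle["pbb"]

    # -- diversity & risk stratification ----------------------------------
    @stage("diversity")
    def _diversity():
        table = dv.diversity_table(pbb)
        bundle["diversity"] = table.join(
            bundle["trait_abundance"], how="left"
        )

    @stage("risk")
    def _risk():
        bundle["risk_class"] = risk.stratify_samples(meta)

    risk_class = bundle.get("risk_class")
    div = bundle.get("diversity")

    # -- group tests -------------------------------------------------------
    @stage("group_tests")
    def _group_tests():
        rows = []
        classes = [c for c in ("low", "medium", "high")
                   if (risk_class == c).sum() >= 2]
        for metric in ("richness", "shannon"):
            groups = [div.loc[risk_class.index[risk_class == c], metric].values
                      for c in classes]
            kw = stats.kruskal_wallis(groups)
            rows.append({"test": f"kruskal_{metric}", "statistic": kw.statistic,
                         "p": kw.p_value, "q": ""})
            for r in stats.dunn_posthoc(groups, labels=classes):
                a, b = r.extra["pair"]
                rows.append({"test": f"dunn_{metric}_{a}_vs_{b}",
                             "statistic": r.statistic, "p": r.p_value,
                             "q": r.q_value})
        if meta["land_use"].nunique() > 1:
            ag = div.loc[meta.index[meta["land_use"] == "agricultural"], "shannon"]
            non = div.loc[meta.index[meta["land_use"] != "agricultural"], "shannon"]
            mw = stats.mann_whitney_u(ag.values, non.values)
            rows.append({"test": "mwu_shannon_land_use",
                         "statistic": mw.statistic, "p": mw.p_value, "q": ""})
        bundle["group_tests"] = pd.DataFrame(rows)

    # -- differential screen ----------------------------------------------
    @stage("differential")
    def _differential():
        bundle["differential"] = stats.differential_abundance(
            pbb, risk_class,
            q_threshold=config.q_threshold,
            prevalence_min=config.prevalence_min,
        )

    # -- spatial battery ---------------------------------------------------
    @stage("spatial")
    def _spatial():
        bc = dv.bray_curtis_matrix(pbb)
        geo = spatial.geodesic_distance_matrix(meta)
        rows = []
        factors = pd.DataFrame({"risk_class": risk_class})
        if meta["land_use"].nunique() > 1:
            factors["land_use"] = meta["land_use"]
        region = _region_labels(meta)
        if region.nunique() > 1:
            factors["region"] = region
        for r in dv.permanova(bc, factors, config.n_permutations, config.seed):
            rows.append({"test": f"permanova_{r.extra['factor']}",
                         "statistic": r.statistic, "p": r.p_value,
                         "effect": r.effect})
        mt = spatial.mantel(bc, geo, config.n_permutations, config.seed)
        rows.append({"test": "mantel_bc_geo", "statistic": mt.statistic,
                     "p": mt.p_value, "effect": ""})
        ri = meta["risk_index"].values.astype(float)
        risk_dist = pd.DataFrame(np.abs(ri[:, None] - ri[None, :]),
                                 index=meta.index, columns=meta.index)
        pm = spatial.partial_mantel(risk_dist, bc, geo,
                                    config.n_permutations, config.seed)
        rows.append({"test": "partial_mantel_risk_bc_given_geo",
                     "statistic": pm.statistic, "p": pm.p_value, "effect": ""})
        basis = spatial.pcnm(geo)
        if basis.n_axes > config.max_pcnm_axes:
            basis = spatial.PCNMBasis(
                axes=basis.axes.iloc[:, : config.max_pcnm_axes],
                eigenvalues=basis.eigenvalues[: config.max_pcnm_axes],
                truncation_threshold=basis.truncation_threshold,
            )
        dr = spatial.dbrda(bc, ri, covariates=basis,
                           n_permutations=config.n_permutations, seed=config.seed)
        rows.append({"test": "dbrda_risk_given_pcnm", "statistic": dr.statistic,
                     "p": dr.p_value, "effect": dr.effect})
        bundle["spatial"] = pd.DataFrame(rows)
        bundle["pcnm_axes"] = basis.n_axes

    # -- interaction screen ------------------------------------------------
    @stage("interactions")
    def _interactions():
        from .simulate import DEFAULT_COVARIATES

        cov_cols = [c for c in meta.columns if c in DEFAULT_COVARIATES]
        if not cov_cols:
            reserved = {"latitude", "longitude", "total_reads", "land_use",
                        "risk_index", "risk_class"}
            cov_cols = [c for c in meta.columns
                        if c not in reserved
                        and pd.api.types.is_numeric_dtype(meta[c])]
        bundle["interactions"] = effects.interaction_screen(
            div["shannon"], meta[cov_cols], risk_class,
        )

    # -- functional potential ---------------------------------------------
    @stage("functional")
    def _functional():
        if not config.ko_profile:
            bundle["manifest"]["stages"]["functional"] = "skipped (no ko_profile)"
            return
        ko = pd.read_csv(config.ko_profile, sep="\t", index_col=0)
        catalog = (load_pathway_catalog(config.catalog) if config.catalog
                   else demo_pathway_catalog())
        scores = functional.pathway_completeness(ko, catalog)
        bundle["pathway_scores"] = scores
        bundle["pathways"] = functional.detect_decreased_pathways(
            scores, risk_class, catalog=catalog, q_threshold=config.q_threshold,
        )
        if config.gene_profile:
            gene = pd.read_csv(config.gene_profile, sep="\t", index_col=0)
            gene_map = (load_cnps_map(config.cnps_map) if config.cnps_map
                        else demo_cnps_map())
            bundle["cnps"] = functional.cnps_counts_from_ko_profile(
                gene, risk_class, gene_map,
            )

    return bundle


def write_report(bundle: dict, outdir) -> dict:
    """Serialize the bundle to stable file names; returns the manifest."""
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise StageError("write_report", exc) from exc

    manifest = dict(bundle.get("manifest", {}))
    written = []

    def emit(key, fname):
        obj = bundle.get(key)
        if obj is None:
            return
        path = outdir / fname
        obj.to_csv(path, sep="\t")
        written.append(fname)

    emit("diversity", "diversity.tsv")
    emit("differential", "differential.tsv")
    emit("interactions", "interactions.tsv")
    emit("spatial", "spatial.tsv")
    emit("pathways", "pathways.tsv")
    emit("cnps", "cnps.tsv")
    if "group_tests" in bundle:
        emit("group_tests", "group_tests.tsv")

    manifest["files"] = written
    manifest["hashes"] = {
        f: hashlib.sha256((outdir / f).read_bytes()).hexdigest()
        for f in written
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str)
    )
    return manifest
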