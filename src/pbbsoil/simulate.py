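"""Synthetic soil-metagenome datasets with planted, recoverable effects.

The generator emulates the statistical structure the analysis stages
assume: a genus x sample count matrix with log-normal abundances and a
spatially autocorrelated composition (exponential-kernel Gaussian field
over sample coordinates), pesticide-risk classes with planted
suppression/enrichment of trait-labelled genera, a planted Shannon
diversity decline along the risk gradient, an optional factorial
interaction between risk and one anthropogenic covariate, and per-sample
KO content with risk-dependent pathway step coverage.

Every planted effect is recorded in a truth dictionary so recovery can
be scored, and the same seed always reproduces the same bundle.

Diversity planting works on the evenness of the PBB sub-composition: a
sample's PBB shares q are replaced by q^(1+gamma) (renormalized), with
gamma solved by bisection so the sub-community Shannon index moves by
exactly the requested multiple of its across-sample SD. This gives
direct control of effect sizes on the diversity response without
touching the rest of the community.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .catalogs import (
    PathwayCatalog,
    TraitRegistry,
    demo_cnps_map,
    demo_pathway_catalog,
)
from .ingest import CommunityProfile

#: The twelve anthropogenic covariates screened for interactions with
#: pesticide risk: climate, human-activity, and agricultural-practice factors.
DEFAULT_COVARIATES = (
    "temperature_range",
    "mean_annual_temperature",
    "annual_precipitation",
    "energy_use",
    "population_density",
    "gdp",
    "agricultural_expansion",
    "nitrogen_fertilizer",
    "phosphate_fertilizer",
    "pesticide_usage",
    "irrigation_area",
    "co2_emission",
)


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults are the standard study conditions.

    Sample sizes mirror the real survey's risk-class imbalance (many more
    high-risk than low-risk agricultural samples) at roughly quarter
    scale so permutation batteries stay fast. Effect sizes are in SD
    units: genus-level suppression/enrichment in units of the per-sample
    log-abundance noise SD, diversity and interaction offsets in units of
    the across-sample Shannon SD.
    """

    seed: int
    # community
    n_low: int = 48
    n_medium: int = 54
    n_high: int = 98
    n_genera: int = 200
    pbb_fraction: float = 0.3
    trait_probs: tuple = (0.65, 0.35, 0.30)  # PGP, biocontrol, stress_resistance
    baseline_log_mean: float = 0.0
    baseline_log_sd: float = 1.5
    sample_noise_sd: float = 1.0
    # spatial field
    lat_range: tuple = (25.0, 50.0)
    lon_range: tuple = (-120.0, -70.0)
    spatial_range_km: float = 800.0
    spatial_sd: float = 1.0
    n_spatial_fields: int = 6
    # planted genus-level risk effects
    n_suppressed: int = 20
    n_enriched: int = 8
    suppression_sd: float = 1.5
    enrichment_sd: float = 1.0
    # planted diversity effects (units of across-sample Shannon SD)
    shannon_decline_sd: float = 1.0
    interaction_factor: Optional[str] = "annual_precipitation"
    interaction_cell_sd: dict = field(
        default_factory=lambda: {"C": 0.0, "P": 0.0, "F": 0.0, "PF": -1.5}
    )
    # KO content
    base_step_coverage: float = 0.9
    decreased_step_coverage: float = 0.5
    n_decreased_pathways: int = 5
    ko_count_mean: float = 3.0
    # libraries
    library_size_mean: float = 2_000_000.0
    library_log_sd: float = 0.3
    assigned_fraction: float = 0.8
    # metadata
    non_agricultural_fraction: float = 0.0
    covariate_names: tuple = DEFAULT_COVARIATES

    def validate(self) -> None:
        if not (0 < self.pbb_fraction <= 1):
            raise ValueError("pbb_fraction must be in (0, 1]")
        if self.n_low + self.n_medium + self.n_high < 4:
            raise ValueError("too few samples")
        n_pbb = int(round(self.n_genera * self.pbb_fraction))
        if self.n_suppressed + self.n_enriched > n_pbb:
            raise ValueError("more planted genera than PBB genera")
        if self.spatial_sd < 0 or self.sample_noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not (0 <= self.base_step_coverage <= 1):
            raise ValueError("base_step_coverage must be in [0, 1]")
        if self.interaction_factor is not None and (
            self.interaction_factor not in self.covariate_names
        ):
            raise ValueError(
                f"interaction_factor {self.interaction_factor!r} not among covariates"
            )


@dataclass
class SimulatedDataset:
    """The generated bundle: inputs for every pipeline stage plus truth."""

    profile: CommunityProfile          # raw counts, total_reads attached
    metadata: pd.DataFrame             # indexed by sample_id
    registry: TraitRegistry
    ko_profile: pd.DataFrame           # KO x sample counts
    gene_profile: pd.DataFrame         # CNPS gene_key x sample counts
    catalog: PathwayCatalog
    truth: dict


def _shannon_of_shares(q: np.ndarray) -> float:
    q = q[q > 0]
    return float(-(q * np.log(q)).sum())


def _tilt_shares(q: np.ndarray, gamma: float) -> np.ndarray:
    w = np.power(np.clip(q, 1e-300, None), 1.0 + gamma)
    return w / w.sum()


def _solve_gamma(q: np.ndarray, target_H: float) -> float:
    """Bisection for gamma with H(tilt(q, gamma)) = target_H.

    H is strictly decreasing in gamma; gamma in (-1, inf) spans
    (H_max = ln S, H at concentration). Targets beyond the attainable
    range clamp to the boundary.
    """
    lo, hi = -0.999, 80.0
    H_lo = _shannon_of_shares(_tilt_shares(q, lo))
    H_hi = _shannon_of_shares(_tilt_shares(q, hi))
    if target_H >= H_lo:
        return lo
    if target_H <= H_hi:
        return hi
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _shannon_of_shares(_tilt_shares(q, mid)) > target_H:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _spatial_fields(coords_km: np.ndarray, range_km: float, sd: float,
                    n_fields: int, rng: np.random.Generator) -> np.ndarray:
    """Gaussian fields with exponential covariance over sample locations."""
    n = coords_km.shape[0]
    if sd == 0 or range_km <= 0 or n_fields == 0:
        return np.zeros((n, max(n_fields, 1)))
    d = np.sqrt(((coords_km[:, None, :] - coords_km[None, :, :]) ** 2).sum(-1))
    K = sd * sd * np.exp(-d / range_km) + 1e-8 * np.eye(n)
    L = np.linalg.cholesky(K)
    return L @ rng.standard_normal((n, n_fields))


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a full dataset bundle under the configured conditions."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_low + config.n_medium + config.n_high
    if n > 500:
        raise ValueError("generator supports at most 500 samples (dense Cholesky)")
    samples = [f"S{i + 1:04d}" for i in range(n)]
    classes = np.array(
        ["low"] * config.n_low + ["medium"] * config.n_medium + ["high"] * config.n_high
    )
    order = rng.permutation(n)
    classes = classes[order]

    # --- genus universe and trait registry -------------------------------
    n_pbb = int(round(config.n_genera * config.pbb_fraction))
    genera = [f"Genus{i + 1:04d}" for i in range(config.n_genera)]
    pbb_idx = np.arange(n_pbb)  # first block is PBB
    entries, display = {}, {}
    trait_names = ("PGP", "biocontrol", "stress_resistance")
    for i in pbb_idx:
        traits = {
            t for t, p in zip(trait_names, config.trait_probs) if rng.random() < p
        }
        if not traits:
            traits = {"PGP"}
        entries[genera[i].lower()] = frozenset(traits)
        display[genera[i].lower()] = genera[i]
    registry = TraitRegistry(entries=entries, display_names=display)

    # --- coordinates and spatial fields ----------------------------------
    lat = rng.uniform(*config.lat_range, size=n)
    lon = rng.uniform(*config.lon_range, size=n)
    # local equirectangular projection is adequate inside the box
    km_per_deg = 111.32
    coords_km = np.column_stack([
        lat * km_per_deg,
        lon * km_per_deg * np.cos(np.radians(lat.mean())),
    ])
    fields = _spatial_fields(
        coords_km, config.spatial_range_km, config.spatial_sd,
        config.n_spatial_fields, rng,
    )
    # per-genus loadings scaled so the total spatial log-variance stays
    # spatial_sd^2 regardless of how many independent fields are drawn
    loadings = rng.standard_normal(
        (config.n_genera, fields.shape[1])
    ) / np.sqrt(max(fields.shape[1], 1))

    # --- log-abundance matrix --------------------------------------------
    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd,
                          size=config.n_genera)
    noise = rng.normal(0.0, config.sample_noise_sd, size=(config.n_genera, n))
    L = baseline[:, None] + loadings @ fields.T + noise

    # planted risk effects on PBB genera (log offsets; medium gets half)
    planted = rng.choice(pbb_idx, size=config.n_suppressed + config.n_enriched,
                         replace=False)
    down_idx = planted[: config.n_suppressed]
    up_idx = planted[config.n_suppressed:]
    class_weight = np.where(classes == "high", 1.0,
                            np.where(classes == "medium", 0.5, 0.0))
    sd = config.sample_noise_sd if config.sample_noise_sd > 0 else 1.0
    L[down_idx] -= config.suppression_sd * sd * class_weight[None, :]
    L[up_idx] += config.enrichment_sd * sd * class_weight[None, :]

    shares = np.exp(L)
    shares /= shares.sum(axis=0)

    # --- covariates and interaction cells --------------------------------
    covariates = pd.DataFrame(
        rng.standard_normal((n, len(config.covariate_names))),
        index=samples, columns=list(config.covariate_names),
    )
    interacting = config.interaction_factor
    cell = np.array([""] * n, dtype=object)
    if interacting is not None:
        cov = covariates[interacting].values
        retained = np.isin(classes, ["low", "high"])
        med = np.median(cov[retained])
        hi_cov = cov > med
        cell = np.where(
            ~retained, "",
            np.where(
                classes == "low",
                np.where(hi_cov, "F", "C"),
                np.where(hi_cov, "PF", "P"),
            ),
        )

    # --- planted diversity effects on the PBB sub-community --------------
    pbb_shares = shares[pbb_idx] / shares[pbb_idx].sum(axis=0)
    H0 = np.array([_shannon_of_shares(pbb_shares[:, j]) for j in range(n)])
    sd_H = float(H0.std(ddof=1)) if n > 1 else 1.0
    delta = -config.shannon_decline_sd * sd_H * class_weight
    if interacting is not None:
        offsets = config.interaction_cell_sd
        delta = delta + sd_H * np.array(
            [offsets.get(c, 0.0) if c else 0.0 for c in cell]
        )
    if np.any(delta != 0.0) and sd_H > 0:
        for j in np.nonzero(delta)[0]:
            gamma = _solve_gamma(pbb_shares[:, j], H0[j] + delta[j])
            tilted = _tilt_shares(pbb_shares[:, j], gamma)
            pbb_total = shares[pbb_idx, j].sum()
            shares[pbb_idx, j] = tilted * pbb_total

    # --- counts ------------------------------------------------------------
    library = np.round(np.exp(
        rng.normal(np.log(config.library_size_mean), config.library_log_sd, size=n)
    )).astype(np.int64)
    assigned = (library * config.assigned_fraction).astype(np.int64)
    counts = rng.poisson(shares * assigned[None, :])
    profile = CommunityProfile(
        matrix=pd.DataFrame(counts.astype(float), index=genera, columns=samples),
        units="raw_counts",
        total_reads=pd.Series(library, index=samples, name="total_reads"),
    )

    # --- risk index consistent with the class -----------------------------
    ri = np.where(
        classes == "low", rng.uniform(0.05, 1.0, size=n),
        np.where(classes == "medium", rng.uniform(1.001, 3.0, size=n),
                 rng.uniform(3.001, 9.0, size=n)),
    )

    land_use = np.where(
        rng.random(n) < config.non_agricultural_fraction,
        "non_agricultural", "agricultural",
    )
    metadata = pd.DataFrame(
        {
            "latitude": lat,
            "longitude": lon,
            "total_reads": library,
            "land_use": land_use,
            "risk_index": ri,
            "risk_class": classes,
        },
        index=pd.Index(samples, name="sample_id"),
    ).join(covariates)

    # --- KO content --------------------------------------------------------
    catalog = demo_pathway_catalog()
    factor_names = [f.name for f in catalog.factors]
    n_dec = min(config.n_decreased_pathways, len(factor_names))
    decreased = sorted(rng.choice(factor_names, size=n_dec, replace=False).tolist())
    ko_ids = sorted(catalog.ko_ids)
    ko_counts = np.zeros((len(ko_ids), n))
    ko_pos = {k: i for i, k in enumerate(ko_ids)}
    cov_mid = 0.5 * (config.base_step_coverage + config.decreased_step_coverage)
    for j in range(n):
        for f in catalog.factors:
            if f.name in decreased:
                p = {"low": config.base_step_coverage, "medium": cov_mid,
                     "high": config.decreased_step_coverage}[classes[j]]
            else:
                p = config.base_step_coverage
            for step in f.pathway:
                if rng.random() < p:
                    ko = sorted(step.alternatives)[
                        rng.integers(len(step.alternatives))
                    ]
                    ko_counts[ko_pos[ko], j] += 1 + rng.poisson(config.ko_count_mean)
    ko_profile = pd.DataFrame(ko_counts, index=ko_ids, columns=samples)
    ko_profile.index.name = "ko"

    # --- CNPS marker-gene counts ------------------------------------------
    gene_map = demo_cnps_map()
    gene_keys = sorted(gene_map.mapping)
    base_rate = 5.0
    rate = np.full((len(gene_keys), n), base_rate)
    effect_scale = 1.0 if config.shannon_decline_sd > 0 else 0.0
    for gi, g in enumerate(gene_keys):
        if gene_map.cycle_of(g) in ("C", "N"):
            rate[gi] = base_rate * (1.0 - 0.5 * effect_scale * class_weight)
        elif gene_map.cycle_of(g) == "S":
            rate[gi] = base_rate * (1.0 + 0.4 * effect_scale * class_weight)
    gene_profile = pd.DataFrame(
        rng.poisson(rate).astype(float), index=gene_keys, columns=samples
    )
    gene_profile.index.name = "gene_key"

    truth = {
        "seed": config.seed,
        "planted_down": sorted(genera[i] for i in down_idx),
        "planted_up": sorted(genera[i] for i in up_idx),
        "suppression_sd": config.suppression_sd,
        "shannon_decline_sd": config.shannon_decline_sd,
        "shannon_sd_unit": sd_H,
        "interaction_factor": interacting,
        "interaction_cell_sd": dict(config.interaction_cell_sd),
        "decreased_pathways": decreased,
        "n_samples": {"low": int(config.n_low), "medium": int(config.n_medium),
                      "high": int(config.n_high)},
    }
    return SimulatedDataset(
        profile=profile, metadata=metadata, registry=registry,
        ko_profile=ko_profile, gene_profile=gene_profile,
        catalog=catalog, truth=truth,
    )


def null_config(config: SimulationConfig) -> SimulationConfig:
    """Copy of a config with every planted effect neutralized."""
    return replace(
        config,
        n_suppressed=0,
        n_enriched=0,
        suppression_sd=0.0,
        enrichment_sd=0.0,
        shannon_decline_sd=0.0,
        interaction_factor=None,
        n_decreased_pathways=0,
    )


def simulate_null_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Same generative process with all planted effects zeroed."""
    return simulate_dataset(null_config(config))


def write_dataset(dataset: SimulatedDataset, outdir) -> dict:
    """Write the bundle in the plain-text formats the ingest stage reads.

    Returns a manifest of the files written.
    """
    from .catalogs import write_trait_registry

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}

    profile_path = outdir / "profile.tsv"
    m = dataset.profile.matrix.copy()
    m.index.name = "genus"
    m.to_csv(profile_path, sep="\t")
    files["profile"] = str(profile_path)

    meta_path = outdir / "metadata.csv"
    dataset.metadata.to_csv(meta_path)
    files["metadata"] = str(meta_path)

    reg_path = outdir / "trait_registry.tsv"
    write_trait_registry(dataset.registry, reg_path)
    files["registry"] = str(reg_path)

    ko_path = outdir / "ko_profile.tsv"
    dataset.ko_profile.to_csv(ko_path, sep="\t")
    files["ko_profile"] = str(ko_path)

    gene_path = outdir / "gene_profile.tsv"
    dataset.gene_profile.to_csv(gene_path, sep="\t")
    files["gene_profile"] = str(gene_path)

    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(dataset.truth, indent=2, sort_keys=True))
    files["truth"] = str(truth_path)
    return files
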