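# pbbsoil

Analysis toolkit for **plant-beneficial bacteria (PBB) in soil metagenomes
under pesticide stress**: trait-annotated community profiling, pesticide-risk
stratification, diversity and differential-abundance statistics, spatial
confounding controls, factorial stressor-interaction effect sizes, and
KO-based biosynthesis-capability scoring — with a synthetic-data generator
that plants recoverable effects so the whole pipeline is testable offline.

## Who this is for

Soil-microbiome researchers who have genus-level taxonomic profiles (TSV
matrices or Kraken2-style reports), sample metadata with coordinates and
pesticide exposure, and DIAMOND/BLAST functional annotation hits — and who
want to ask: *does pesticide risk reduce the beneficial fraction of the soil
community, is that effect real after accounting for spatial autocorrelation,
and which metabolic capabilities are lost?*

## The statistics at the core

- **Trait profiling.** A curated registry maps genera to beneficial traits
  (PGP = plant growth promotion, biocontrol, stress resistance). Counts are
  normalized to reads per million, RPM = count × 10⁶ / library size, and
  summed per trait group.
- **Risk classification.** Risk index RI = Σᵢ PECᵢ/NECᵢ (predicted
  environmental concentration over no-effect concentration, summed over
  pesticides); classes: low (RI ≤ 1), medium (1 < RI ≤ 3), high (RI > 3).
- **Diversity & composition.** Richness, Shannon H′ = −Σ pᵢ ln pᵢ,
  Bray–Curtis dissimilarity, and a sequential (Type-I) multi-factor
  PERMANOVA with whole-sample label permutations.
- **Differential screen.** Per-genus two-sided Welch t (high vs low risk),
  Benjamini–Hochberg correction, PBB-up / PBB-down called at q < 0.05.
- **Spatial controls.** Haversine geographic distances; Mantel and partial
  Mantel permutation tests; PCNM spatial eigenvectors (truncation at the
  longest minimum-spanning-tree edge, beyond-threshold distances set to 4t);
  db-RDA of the community on the risk index with PCNM covariates partialled
  out, permuting reduced-model residuals.
- **Interaction effect sizes.** For each anthropogenic covariate crossed
  with risk on a 2×2 layout (C, P, F, PF cells), Hedges-corrected main
  effects and the interaction contrast
  d_I = J (Ȳ_PF − Ȳ_P − Ȳ_F + Ȳ_C)/s with a 95% t-interval; classified
  additive / synergistic / antagonistic.
- **Functional potential.** Pathway completeness = fraction of a
  biosynthesis pathway's steps with ≥1 detected alternative KO; per-factor
  Kruskal–Wallis across risk classes with BH correction flags decreased
  growth-factor biosynthesis; CNPS (carbon/nitrogen/phosphorus/sulfur)
  cycling marker genes are tallied per class.

## Worked example

```python
from pbbsoil import (SimulationConfig, simulate_dataset, rpm_normalize,
                     pbb_subset, diversity_table, stratify_samples)

ds = simulate_dataset(SimulationConfig(seed=1, n_low=30, n_medium=20, n_high=40))
pbb = pbb_subset(rpm_normalize(ds.profile), ds.registry)
div = diversity_table(pbb)
rc = stratify_samples(ds.metadata)
for cls in ("low", "medium", "high"):
    sub = div.loc[rc.index[rc == cls]]
    print(cls, round(sub["shannon"].mean(), 3))
```

prints

```
low 2.666
medium 2.322
high 1.429
```

— the planted diversity decline along the risk gradient: mean PBB Shannon
diversity falls from 2.67 in low-risk soils to 1.43 in high-risk soils.
The spatial battery on a similar dataset (`examples/03_spatial_controls.py`)
prints

```
Mantel (community vs geography): r = 0.095, p = 0.002
db-RDA (risk | PCNM): pseudo-F = 4.10, R^2 = 0.0819, p = 0.001
```

— the community is spatially structured (distance decay), yet pesticide risk
still explains composition after the PCNM spatial eigenvectors absorb that
structure. Each script in `examples/` demonstrates one capability and
explains the numbers it prints.

A thin CLI wraps the same library:

```bash
pbbsoil simulate --seed 1 --out sim/
pbbsoil run --profile sim/profile.tsv --metadata sim/metadata.csv \
        --registry sim/trait_registry.tsv --out report/
```

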