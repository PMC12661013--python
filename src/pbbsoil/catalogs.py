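"""Trait registry, biosynthesis pathway catalog, and nutrient-cycling gene map.

These three catalogs drive every downstream stage: the trait registry says
which genera count as plant-beneficial bacteria (PBB) and which beneficial
properties they carry; the pathway catalog describes growth-factor
biosynthesis routes as ordered steps with alternative KEGG orthology (KO)
terms; the CNPS map assigns marker genes to the carbon, nitrogen,
phosphorus, and sulfur cycles.

The registry and catalogs bundled under ``pbbsoil/data`` are small
demonstration versions; production analyses supply their own curated
files in the same formats.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Union

PathLike = Union[str, Path]

#: The three beneficial-trait groups: plant growth promotion (nitrogen
#: fixation, P/K solubilization, siderophore and phytohormone production),
#: biocontrol of plant pathogens, and enhancement of plant stress resistance.
TRAIT_VOCABULARY = frozenset({"PGP", "biocontrol", "stress_resistance"})

#: The six growth-factor biosynthetic categories.
FACTOR_CATEGORIES = (
    "amino_acid",
    "coenzyme",
    "fatty_acid",
    "ironophore",
    "nucleotide",
    "vitamin",
)

#: The four elemental nutrient cycles tracked by the CNPS gene map.
CNPS_CYCLES = frozenset({"C", "N", "P", "S"})

_KO_RE = re.compile(r"^K\d{5}$")


class CatalogError(ValueError):
    """Raised when a catalog file fails validation."""


def _canonical_genus(name: str) -> str:
    return " ".join(name.split()).lower()


@dataclass
class TraitRegistry:
    """Genus -> set-of-traits map defining the PBB universe.

    Genus matching is case-insensitive and whitespace-normalized; the
    original spelling of the first occurrence is kept for display.
    """

    entries: dict  # canonical genus -> frozenset of traits
    display_names: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for genus, traits in self.entries.items():
            if not traits:
                raise CatalogError(f"genus {genus!r} has no traits")
            bad = set(traits) - TRAIT_VOCABULARY
            if bad:
                raise CatalogError(
                    f"genus {genus!r} carries unknown trait(s) {sorted(bad)}"
                )

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, genus: str) -> bool:
        return _canonical_genus(genus) in self.entries

    def traits_of(self, genus: str) -> frozenset:
        """Trait set for one genus; empty set when the genus is not PBB."""
        return self.entries.get(_canonical_genus(genus), frozenset())

    @property
    def genera(self) -> list:
        return sorted(self.entries)


def load_trait_registry(path: PathLike) -> TraitRegistry:
    """Load a two-column TSV (``genus``, ``traits``) into a registry.

    Trait labels are semicolon-separated. Duplicate genus rows are merged
    by union of their trait sets. Unknown trait labels raise
    :class:`CatalogError` naming the offending line.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise CatalogError(f"{path}: empty registry file")
    header = [h.strip().lower() for h in lines[0].split("\t")]
    if header[:2] != ["genus", "traits"]:
        raise CatalogError(
            f"{path}: expected header 'genus\\ttraits', got {lines[0]!r}"
        )
    entries: dict = {}
    display: dict = {}
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        parts = raw.split("\t")
        if len(parts) < 2:
            raise CatalogError(f"{path}:{lineno}: expected 2 columns")
        genus_raw, trait_field = parts[0].strip(), parts[1].strip()
        if not genus_raw:
            raise CatalogError(f"{path}:{lineno}: empty genus name")
        traits = {t.strip() for t in trait_field.split(";") if t.strip()}
        if not traits:
            raise CatalogError(f"{path}:{lineno}: genus {genus_raw!r} has no traits")
        bad = traits - TRAIT_VOCABULARY
        if bad:
            raise CatalogError(
                f"{path}:{lineno}: unknown trait label(s) {sorted(bad)} "
                f"(allowed: {sorted(TRAIT_VOCABULARY)})"
            )
        genus = _canonical_genus(genus_raw)
        entries[genus] = frozenset(entries.get(genus, frozenset()) | traits)
        display.setdefault(genus, genus_raw)
    if not entries:
        raise CatalogError(f"{path}: registry contains no entries")
    return TraitRegistry(entries=entries, display_names=display)


def write_trait_registry(registry: TraitRegistry, path: PathLike) -> None:
    """Write a registry in canonical form: genera sorted, traits sorted."""
    lines = ["genus\ttraits"]
    for genus in registry.genera:
        name = registry.display_names.get(genus, genus)
        traits = ";".join(sorted(registry.entries[genus]))
        lines.append(f"{name}\t{traits}")
    Path(path).write_text("\n".join(lines) + "\n")


def lookup_traits(registry: TraitRegistry, genera: Iterable[str]) -> dict:
    """Map each queried genus to its trait set (empty set = not PBB)."""
    return {g: registry.traits_of(g) for g in genera}


# ---------------------------------------------------------------------------
# Growth-factor biosynthesis catalog


@dataclass(frozen=True)
class Step:
    """One reaction step; any listed alternative KO satisfies the step."""

    step_id: str
    alternatives: frozenset

    def __post_init__(self) -> None:
        if not self.alternatives:
            raise CatalogError(f"step {self.step_id!r}: empty alternatives set")
        for ko in self.alternatives:
            if not _KO_RE.match(ko):
                raise CatalogError(
                    f"step {self.step_id!r}: malformed KO id {ko!r} "
                    "(expected K followed by 5 digits)"
                )


@dataclass(frozen=True)
class GrowthFactor:
    """An essential growth factor with its ordered biosynthesis pathway."""

    name: str
    category: str
    pathway: tuple  # tuple of Step

    def __post_init__(self) -> None:
        if self.category not in FACTOR_CATEGORIES:
            raise CatalogError(
                f"factor {self.name!r}: unknown category {self.category!r} "
                f"(allowed: {list(FACTOR_CATEGORIES)})"
            )
        if not self.pathway:
            raise CatalogError(f"factor {self.name!r}: pathway has no steps")


@dataclass
class PathwayCatalog:
    factors: list  # list of GrowthFactor

    @property
    def n_factors(self) -> int:
        return len(self.factors)

    @property
    def n_steps(self) -> int:
        return sum(len(f.pathway) for f in self.factors)

    @property
    def ko_ids(self) -> frozenset:
        kos: set = set()
        for f in self.factors:
            for step in f.pathway:
                kos |= step.alternatives
        return frozenset(kos)

    @property
    def n_kos(self) -> int:
        return len(self.ko_ids)

    @property
    def categories(self) -> frozenset:
        return frozenset(f.category for f in self.factors)

    def factor(self, name: str) -> GrowthFactor:
        for f in self.factors:
            if f.name == name:
                return f
        raise KeyError(name)

    def summary(self) -> dict:
        return {
            "n_factors": self.n_factors,
            "n_steps": self.n_steps,
            "n_distinct_kos": self.n_kos,
            "n_categories": len(self.categories),
        }


def load_pathway_catalog(path: PathLike) -> PathwayCatalog:
    """Load a pathway catalog from JSON.

    Schema::

        {"factors": [
            {"name": "arginine", "category": "amino_acid",
             "pathway": [{"step_id": "argA", "alternatives": ["K14682", ...]},
                         ...]},
            ...]}
    """
    with open(path) as fh:
        doc = json.load(fh)
    if "factors" not in doc or not isinstance(doc["factors"], list):
        raise CatalogError(f"{path}: JSON must contain a 'factors' list")
    factors = []
    seen: set = set()
    for fdoc in doc["factors"]:
        name = fdoc.get("name", "")
        if not name:
            raise CatalogError(f"{path}: factor missing 'name'")
        if name in seen:
            raise CatalogError(f"{path}: duplicate factor {name!r}")
        seen.add(name)
        steps = tuple(
            Step(step_id=s.get("step_id", f"step{i}"),
                 alternatives=frozenset(s.get("alternatives", [])))
            for i, s in enumerate(fdoc.get("pathway", []), start=1)
        )
        factors.append(
            GrowthFactor(name=name, category=fdoc.get("category", ""), pathway=steps)
        )
    if not factors:
        raise CatalogError(f"{path}: catalog contains no factors")
    return PathwayCatalog(factors=factors)


# ---------------------------------------------------------------------------
# CNPS nutrient-cycling gene map


@dataclass
class CNPSGeneMap:
    """Marker gene -> elemental cycle map.

    Keys follow the ``<KO>_<gene symbol>`` convention (e.g. ``K01601_rbcL``
    for the carbon-fixation gene of RuBisCO); each key belongs to exactly
    one of the C, N, P, S cycles.
    """

    mapping: dict  # gene_key -> cycle

    def __post_init__(self) -> None:
        for key, cycle in self.mapping.items():
            if cycle not in CNPS_CYCLES:
                raise CatalogError(
                    f"gene {key!r}: unknown cycle {cycle!r} (allowed: C, N, P, S)"
                )

    def __len__(self) -> int:
        return len(self.mapping)

    def cycle_of(self, gene_key: str):
        return self.mapping.get(gene_key)

    def genes_in_cycle(self, cycle: str) -> list:
        return sorted(k for k, c in self.mapping.items() if c == cycle)


def load_cnps_map(path: PathLike) -> CNPSGeneMap:
    """Load a two-column TSV (``gene_key``, ``cycle``)."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise CatalogError(f"{path}: empty CNPS map")
    header = [h.strip().lower() for h in lines[0].split("\t")]
    if header[:2] != ["gene_key", "cycle"]:
        raise CatalogError(f"{path}: expected header 'gene_key\\tcycle'")
    mapping: dict = {}
    for lineno, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        parts = [p.strip() for p in raw.split("\t")]
        if len(parts) < 2:
            raise CatalogError(f"{path}:{lineno}: expected 2 columns")
        key, cycle = parts[0], parts[1]
        if key in mapping and mapping[key] != cycle:
            raise CatalogError(f"{path}:{lineno}: gene {key!r} mapped to two cycles")
        if cycle not in CNPS_CYCLES:
            raise CatalogError(f"{path}:{lineno}: unknown cycle {cycle!r}")
        mapping[key] = cycle
    return CNPSGeneMap(mapping=mapping)


# ---------------------------------------------------------------------------
# Bundled demonstration catalogs


def _data_path(name: str) -> Path:
    return Path(str(resources.files("pbbsoil").joinpath("data", name)))


def demo_trait_registry() -> TraitRegistry:
    """Small bundled registry covering all three trait groups."""
    return load_trait_registry(_data_path("trait_registry.tsv"))


def demo_pathway_catalog() -> PathwayCatalog:
    """Bundled growth-factor catalog covering all six categories."""
    return load_pathway_catalog(_data_path("pathway_catalog.json"))


def demo_cnps_map() -> CNPSGeneMap:
    """Bundled CNPS marker-gene map."""
    return load_cnps_map(_data_path("cnps_genes.tsv"))
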