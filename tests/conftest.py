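import numpy as np
import pandas as pd
import pytest

from pbbsoil.catalogs import TraitRegistry
from pbbsoil.ingest import CommunityProfile


@pytest.fixture
def rng():
    return np.random.default_rng(20250925)


@pytest.fixture
def toy_profile():
    """3 genera x 2 samples, raw counts, library sizes attached."""
    matrix = pd.DataFrame(
        {"s1": [10.0, 0.0, 40.0], "s2": [5.0, 25.0, 20.0]},
        index=["Bacillus", "Rhizobium", "Other"],
    )
    totals = pd.Series({"s1": 1_000_000, "s2": 2_000_000})
    return CommunityProfile(matrix=matrix, units="raw_counts", total_reads=totals)


@pytest.fixture
def small_registry():
    return TraitRegistry(
        entries={
            "bacillus": frozenset({"PGP", "biocontrol"}),
            "rhizobium": frozenset({"PGP"}),
            "serratia": frozenset({"biocontrol"}),
            "variovorax": frozenset({"stress_resistance"}),
        }
    )


def rpm_profile(matrix: pd.DataFrame) -> CommunityProfile:
    """Wrap an abundance frame directly as an RPM-unit profile."""
    return CommunityProfile(matrix=matrix.astype(float), units="RPM")
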