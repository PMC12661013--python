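from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from pbbsoil.catalogs import GrowthFactor, PathwayCatalog, Step, demo_cnps_map
from pbbsoil.functional import (
    category_rollup,
    cnps_counts_from_ko_profile,
    cnps_cycle_totals,
    cnps_gene_counts,
    completeness_fraction,
    detect_decreased_pathways,
    ko_profile_from_hits,
    pathway_completeness,
)


def _catalog():
    return PathwayCatalog(factors=[
        GrowthFactor(
            name="demo", category="vitamin",
            pathway=(
                Step("s1", frozenset({"K00001", "K00002"})),
                Step("s2", frozenset({"K00003"})),
                Step("s3", frozenset({"K00004"})),
                Step("s4", frozenset({"K00005"})),
            ),
        ),
        GrowthFactor(
            name="tiny", category="amino_acid",
            pathway=(Step("t1", frozenset({"K00010"})),),
        ),
    ])


def _hits(rows):
    return pd.DataFrame(rows, columns=["query_id", "subject_id", "bit_score"])


class TestKOProfile:
    def test_empty_hits_give_empty_profile(self):
        out = ko_profile_from_hits(_hits([]), {}, {})
        assert out.empty

    def test_hand_tally(self):
        hits = _hits([
            ["c1", "db1", 50], ["c2", "db1", 50], ["c3", "db1", 50],
            ["c4", "db2", 50], ["c5", "unknown", 50],
        ])
        q2s = {f"c{i}": ("sA" if i <= 4 else "sB") for i in range(1, 6)}
        s2k = {"db1": "K00001", "db2": "K00002"}
        out = ko_profile_from_hits(hits, q2s, s2k)
        assert out.loc["K00001", "sA"] == 3
        assert out.loc["K00002", "sA"] == 1
        assert "sB" not in out.columns or out.get("sB", pd.Series()).sum() == 0

    def test_unassigned_query_is_error(self):
        hits = _hits([["c1", "db1", 50]])
        with pytest.raises(ValueError, match="no sample assignment"):
            ko_profile_from_hits(hits, {}, {"db1": "K00001"})


class TestCompleteness:
    def test_all_and_none_present(self):
        cat = _catalog()
        ko = pd.DataFrame(
            {"full": [1, 0, 1, 1, 1, 1], "none": [0, 0, 0, 0, 0, 0]},
            index=["K00001", "K00002", "K00003", "K00004", "K00005", "K00010"],
            dtype=float,
        )
        scores = pathway_completeness(ko, cat)
        assert scores.loc["demo", "full"] == 1.0
        assert scores.loc["demo", "none"] == 0.0
        assert scores.loc["tiny", "full"] == 1.0

    def test_alternatives_rule_quarter(self):
        # only K00002 (an alternative of step s1) present -> 1 of 4 steps
        cat = _catalog()
        ko = pd.DataFrame({"s": [0, 1, 0, 0, 0, 0]},
                          index=["K00001", "K00002", "K00003", "K00004",
                                 "K00005", "K00010"], dtype=float)
        assert pathway_completeness(ko, cat).loc["demo", "s"] == 0.25

    def test_exact_rational_representation(self):
        cat = _catalog()
        frac = completeness_fraction(
            {"K00002": True, "K00003": True}, cat.factor("demo")
        )
        assert frac == Fraction(2, 4)
        assert frac.denominator in (1, 2, 4)  # reduced from step count 4

    def test_monotone_in_abundance(self, rng):
        cat = _catalog()
        kos = ["K00001", "K00002", "K00003", "K00004", "K00005", "K00010"]
        base = pd.DataFrame(
            rng.integers(0, 2, size=(6, 5)).astype(float), index=kos
        )
        more = base.copy()
        more.iloc[rng.integers(0, 6), rng.integers(0, 5)] += 3
        s1 = pathway_completeness(base, cat)
        s2 = pathway_completeness(more, cat)
        assert (s2.values >= s1.values - 1e-15).all()

    def test_presence_threshold_configurable(self):
        cat = _catalog()
        ko = pd.DataFrame({"s": [1, 0, 0, 0, 0, 0]},
                          index=["K00001", "K00002", "K00003", "K00004",
                                 "K00005", "K00010"], dtype=float)
        assert pathway_completeness(ko, cat, presence_threshold=2).loc["demo", "s"] == 0.0


class TestDecreasedPathways:
    def _scores(self, rng, n_per_class=12, decline=0.0):
        classes = ["low"] * n_per_class + ["medium"] * n_per_class + ["high"] * n_per_class
        ids = [f"s{i}" for i in range(len(classes))]
        rows = {}
        for name in ("f1", "f2", "f3"):
            base = rng.choice([0.6, 0.8, 1.0], size=len(ids))
            if name == "f1" and decline:
                base = base - decline * np.array(
                    [0, 0.5, 1.0])[np.repeat([0, 1, 2], n_per_class)]
            rows[name] = np.clip(base, 0, 1)
        scores = pd.DataFrame(rows).T
        scores.columns = ids
        return scores, pd.Series(classes, index=ids)

    def test_planted_decline_flagged(self, rng):
        scores, rc = self._scores(rng, decline=0.5)
        out = detect_decreased_pathways(scores, rc)
        assert bool(out.loc["f1", "decreased"])
        assert out.loc["f1", "median_high"] < out.loc["f1", "median_low"]

    def test_constant_scores_never_flagged(self, rng):
        scores, rc = self._scores(rng)
        scores.loc["f2"] = 0.75
        out = detect_decreased_pathways(scores, rc)
        assert out.loc["f2", "p"] == 1.0
        assert not out.loc["f2", "decreased"]

    def test_identical_samples_nothing_flagged(self):
        ids = [f"s{i}" for i in range(12)]
        scores = pd.DataFrame(0.5, index=["f1", "f2"], columns=ids)
        rc = pd.Series(["low"] * 6 + ["high"] * 6, index=ids)
        out = detect_decreased_pathways(scores, rc)
        assert not out["decreased"].any()

    def test_single_class_rejected(self, rng):
        scores, rc = self._scores(rng)
        with pytest.raises(ValueError, match="2 risk classes"):
            detect_decreased_pathways(scores, pd.Series("low", index=rc.index))

    def test_category_rollup_counts_flagged_factors(self, rng):
        scores, rc = self._scores(rng, decline=0.6)
        cat = _catalog()
        # rename planted factor to a catalogued one
        scores = scores.rename(index={"f1": "demo"})
        out = detect_decreased_pathways(scores, rc, catalog=cat)
        roll = category_rollup(out)
        if out.loc["demo", "decreased"]:
            assert roll.get("vitamin", 0) >= 1


class TestCNPS:
    def test_empty_input_zero_table(self):
        gm = demo_cnps_map()
        out = cnps_gene_counts({"low": pd.DataFrame(columns=["subject_id"])},
                               gm, {})
        assert (out.drop(columns=["cycle"]).values == 0).all()

    def test_hand_tally_and_direction(self):
        gm = demo_cnps_map()
        s2g = {"dbC": "K01601_rbcL", "dbN": "K01429_ureB", "dbS": "K02048_cysP"}
        low = pd.DataFrame({"subject_id": ["dbC", "dbC", "dbN"]})
        high = pd.DataFrame({"subject_id": ["dbC", "dbS", "dbS"]})
        out = cnps_gene_counts({"low": low, "high": high}, gm, s2g)
        assert out.loc["K01601_rbcL", "low"] == 2
        assert out.loc["K01601_rbcL", "high"] == 1
        assert out.loc["K01601_rbcL", "direction"] == "down"
        assert out.loc["K02048_cysP", "direction"] == "up"

    def test_cycle_totals_conserve_partition(self, rng):
        gm = demo_cnps_map()
        genes = sorted(gm.mapping)
        profile = pd.DataFrame(
            rng.poisson(4, size=(len(genes), 6)).astype(float),
            index=genes, columns=[f"s{i}" for i in range(6)],
        )
        rc = pd.Series(["low", "low", "low", "high", "high", "high"],
                       index=profile.columns)
        table = cnps_counts_from_ko_profile(profile, rc, gm)
        totals = cnps_cycle_totals(table)
        value_cols = [c for c in table.columns if c not in ("cycle", "direction")]
        assert totals[value_cols].values.sum() == pytest.approx(
            table[value_cols].values.sum()
        )
        for cyc in totals.index:
            member_sum = table.loc[table["cycle"] == cyc, value_cols].sum()
            np.testing.assert_allclose(totals.loc[cyc, value_cols].astype(float),
                                       member_sum.astype(float))
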