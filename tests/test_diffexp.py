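"""Size factors, the NB pairwise test, and consistency/overlap logic."""

import numpy as np
import pandas as pd
import pytest

from coldacc import diffexp, simulate
from coldacc.containers import CountMatrix, SampleDesign, SimulationConfig


class TestSizeFactors:
    def test_identical_samples_get_unit_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]}, index=["g1", "g2", "g3"])
        sf = diffexp.size_factors(counts)
        assert np.allclose(sf, [1.0, 1.0])

    def test_doubling_doubles_factor_ratio(self):
        counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]}, index=["g1", "g2", "g3"])
        sf = diffexp.size_factors(counts)
        assert sf["b"] / sf["a"] == pytest.approx(2.0, rel=1e-12)
        assert np.exp(np.log(sf).mean()) == pytest.approx(1.0, rel=1e-12)

    def test_equal_true_libraries_recovered_within_5pct(self):
        rng = np.random.default_rng(0)
        mu = rng.lognormal(3, 1.5, size=5000)
        counts = pd.DataFrame(
            {s: rng.negative_binomial(10, 10 / (10 + mu)) for s in ["a", "b", "c", "d"]}
        )
        sf = diffexp.size_factors(counts, pseudo_reference=True)
        assert np.all(np.abs(sf - 1.0) < 0.05)

    def test_no_common_gene_raises_with_hint(self):
        counts = pd.DataFrame({"a": [5, 0], "b": [0, 5]}, index=["g1", "g2"])
        with pytest.raises(ValueError, match="pseudo_reference"):
            diffexp.size_factors(counts)


class TestPairwise:
    def test_identical_groups_are_null(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(50, size=(100, 2))
        counts = pd.DataFrame(
            np.hstack([base, base]), columns=["a1", "a2", "b1", "b2"],
            index=[f"g{i}" for i in range(100)],
        )
        cm = CountMatrix(counts=counts, lengths=pd.Series(1000, index=counts.index))
        design = SampleDesign(
            pd.DataFrame(
                {"group": ["A", "A", "B", "B"], "temperature_C": [2.0] * 2 + [18.0] * 2},
                index=pd.Index(counts.columns, name="sample"),
            )
        )
        res = diffexp.test_pairwise(cm, design, "A", "B")
        assert (res.table["p_value"] > 0.999).all()
        assert not res.table["significant"].any()

    def test_all_zero_gene_gets_p_one_and_no_direction(self, tiny_counts, tiny_design):
        counts = tiny_counts.counts.copy()
        counts.loc["g2"] = 0
        cm = CountMatrix(counts=counts, lengths=tiny_counts.lengths)
        res = diffexp.test_pairwise(cm, tiny_design, "T2", "T18")
        assert res.table.loc["g2", "p_value"] == 1.0
        assert res.table.loc["g2", "direction"] == "none"

    def test_bh_adjustment_is_monotone_and_bounded(self, two_group_config):
        counts, design, _ = simulate.generate_counts(two_group_config)
        res = diffexp.test_pairwise(counts, design, "T2", "T18")
        tab = res.table.sort_values("p_value")
        assert (tab["adj_p"] >= tab["p_value"] - 1e-12).all()
        assert tab["adj_p"].max() <= 1.0
        # running max of adj_p along the p ranking never decreases
        assert (tab["adj_p"].cummax() == tab["adj_p"].cummax().cummax()).all()

    def test_significant_genes_have_direction(self, two_group_config):
        counts, design, _ = simulate.generate_counts(two_group_config)
        res = diffexp.test_pairwise(counts, design, "T2", "T18")
        sig = res.table[res.table["significant"]]
        assert len(sig) > 0
        assert (sig["direction"] != "none").all()

    def test_label_permutation_keeps_null_calibrated(self):
        """Permuting group labels in null data must not create signal."""
        cfg = SimulationConfig(
            n_genes=2000, n_samples_per_group=3, groups={"A": 2.0, "B": 18.0},
            frac_responsive=0.0, seed=21,
        )
        counts, design, _ = simulate.generate_counts(cfg)
        rng = np.random.default_rng(0)
        fracs = []
        for _ in range(3):
            perm = rng.permutation(design.table["group"].to_numpy())
            d2 = SampleDesign(design.table.assign(group=perm))
            if len(d2.samples_in("A")) == 0 or len(d2.samples_in("B")) == 0:
                continue
            res = diffexp.test_pairwise(counts, d2, "A", "B")
            fracs.append(res.table["significant"].mean())
        assert max(fracs) <= 0.05


def _fake_result(genes, sig, direction="up_in_A", comparison=("L", "H")):
    tab = pd.DataFrame(
        {
            "lfc": [1.0 if g in sig else 0.0 for g in genes],
            "p_value": [0.001 if g in sig else 0.9 for g in genes],
            "adj_p": [0.01 if g in sig else 0.95 for g in genes],
            "significant": [g in sig for g in genes],
            "direction": [direction if g in sig else "none" for g in genes],
        },
        index=genes,
    )
    return diffexp.DEResult(comparison=comparison, table=tab)


class TestConsistency:
    GENES = [f"g{i}" for i in range(8)]

    def test_gene_in_all_comparisons_included(self):
        res = {h: _fake_result(self.GENES, {"g1", "g2"}) for h in ("H1", "H2", "H3")}
        cset = diffexp.consistent_degs(res, "L")
        assert cset.gene_ids == {"g1", "g2"}
        assert all(cset.consistent_direction.values())
        assert cset.direction_of("g1") == "up_in_A"

    def test_gene_in_two_of_three_excluded(self):
        res = {
            "H1": _fake_result(self.GENES, {"g1", "g2"}),
            "H2": _fake_result(self.GENES, {"g1", "g2"}),
            "H3": _fake_result(self.GENES, {"g2"}),
        }
        cset = diffexp.consistent_degs(res, "L")
        assert cset.gene_ids == {"g2"}

    def test_mixed_direction_flagged_inconsistent(self):
        res = {
            "H1": _fake_result(self.GENES, {"g3"}, direction="up_in_A"),
            "H2": _fake_result(self.GENES, {"g3"}, direction="down_in_A"),
        }
        cset = diffexp.consistent_degs(res, "L")
        assert cset.gene_ids == {"g3"}
        assert cset.consistent_direction["g3"] is False
        assert cset.direction_of("g3") == "mixed"

    def test_empty_sets_give_empty_result(self):
        res = {h: _fake_result(self.GENES, set()) for h in ("H1", "H2")}
        cset = diffexp.consistent_degs(res, "L")
        assert cset.gene_ids == set()

    def test_mismatched_universe_rejected(self):
        res = {
            "H1": _fake_result(self.GENES, {"g1"}),
            "H2": _fake_result(self.GENES[:-1], {"g1"}),
        }
        with pytest.raises(ValueError, match="universe"):
            diffexp.consistent_degs(res, "L")

    def test_matches_bruteforce_intersection(self):
        """Randomised check against a naive per-gene loop."""
        rng = np.random.default_rng(7)
        genes = [f"g{i}" for i in range(120)]
        for _ in range(10):
            sigs = {h: {g for g in genes if rng.random() < 0.3} for h in ("H1", "H2", "H3")}
            res = {h: _fake_result(genes, s) for h, s in sigs.items()}
            cset = diffexp.consistent_degs(res, "L")
            naive = {g for g in genes if all(g in sigs[h] for h in sigs)}
            assert cset.gene_ids == naive


class TestOverlap:
    GENES = [f"g{i}" for i in range(10)]

    def _cset(self, genes, low="T2"):
        res = {h: _fake_result(self.GENES, set(genes)) for h in ("H1", "H2")}
        return diffexp.consistent_degs(res, low)

    def test_disjoint_sets(self):
        rep = diffexp.overlap_analysis(self._cset({"g1"}), self._cset({"g2"}, low="T5"))
        assert rep["n_intersection"] == 0

    def test_equal_sets(self):
        a = self._cset({"g1", "g2", "g3"})
        b = self._cset({"g1", "g2", "g3"}, low="T5")
        rep = diffexp.overlap_analysis(a, b)
        assert rep["n_intersection"] == rep["n_set1"] == 3

    def test_direct_comparison_counts(self):
        direct = _fake_result(self.GENES, {"g1", "g5"}, comparison=("T2", "T5"))
        rep = diffexp.overlap_analysis(
            self._cset({"g1", "g2"}), self._cset({"g5"}, low="T5"), direct
        )
        assert rep["n_set1_also_direct"] == 1
        assert rep["n_set2_also_direct"] == 1
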