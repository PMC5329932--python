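"""Site filtering, IUPAC genotyping, coding effects, distances and NJ."""

import io

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from coldacc import variants
from coldacc.variants import GenotypeMatrix, SiteTable


def make_sites(rows, samples=("s1", "s2")):
    """rows: (gene, pos, ref, alt, qual, qd, depths) where depths is a
    list per sample of per-allele depth lists."""
    meta = pd.DataFrame(
        [(r[0], r[1], r[2], r[3], r[4], r[5]) for r in rows],
        columns=["gene_id", "pos", "ref", "alt", "qual", "qd"],
        index=pd.Index([f"{r[0]}:{r[1]}" for r in rows], name="site_id"),
    )
    slots = max(max(len(d) for d in r[6]) for r in rows)
    depths = np.zeros((len(rows), len(samples), slots), dtype=np.int64)
    for i, r in enumerate(rows):
        for j, d in enumerate(r[6]):
            depths[i, j, : len(d)] = d
    return SiteTable(meta=meta, depths=depths, samples=list(samples))


class TestQualityFilter:
    def test_low_qual_removed_even_with_good_qd(self):
        st = make_sites([("g", 5, "A", "G", 29.9, 10.0, [[8, 8], [8, 8]])])
        assert len(variants.quality_filter(st)) == 0

    def test_boundary_values_retained(self):
        st = make_sites([("g", 5, "A", "G", 30.0, 5.0, [[8, 8], [8, 8]])])
        assert len(variants.quality_filter(st)) == 1

    def test_empty_table_passes_through(self):
        st = make_sites([("g", 5, "A", "G", 50.0, 10.0, [[8, 8], [8, 8]])])
        empty = st.subset(np.array([], dtype=int))
        assert len(variants.quality_filter(empty)) == 0

    def test_missing_scores_pass_with_warning(self):
        st = make_sites([("g", 5, "A", "G", np.nan, np.nan, [[8, 8], [8, 8]])])
        with pytest.warns(UserWarning, match="QUAL/QD"):
            assert len(variants.quality_filter(st)) == 1

    def test_idempotent(self):
        st = make_sites(
            [
                ("g", 1, "A", "G", 25.0, 10.0, [[8, 8], [8, 8]]),
                ("g", 2, "A", "G", 60.0, 10.0, [[8, 8], [8, 8]]),
            ]
        )
        once = variants.quality_filter(st)
        twice = variants.quality_filter(once)
        assert once.meta.equals(twice.meta)


class TestSelectSites:
    def test_triallelic_removed(self):
        st = make_sites([("g", 1, "A", "G,T", 50.0, 10.0, [[4, 3, 2], [5, 3, 1]])])
        assert len(variants.select_sites(st)) == 0

    def test_low_depth_sample_removes_site(self):
        st = make_sites([("g", 1, "A", "G", 50.0, 10.0, [[3, 2], [6, 6]])])
        assert len(variants.select_sites(st)) == 0

    def test_good_biallelic_kept(self):
        st = make_sites([("g", 1, "A", "G", 50.0, 10.0, [[3, 3], [6, 6]])])
        assert len(variants.select_sites(st)) == 1

    def test_relaxed_coverage_flag(self):
        st = make_sites([("g", 1, "A", "G", 50.0, 10.0, [[3, 2], [6, 6]])])
        assert len(variants.select_sites(st, min_samples_covered=1)) == 1

    def test_listed_but_unobserved_allele_not_counted(self):
        st = make_sites([("g", 1, "A", "G,T", 50.0, 10.0, [[4, 3, 0], [5, 3, 0]])])
        assert len(variants.select_sites(st)) == 1


class TestCallIupac:
    def test_balanced_heterozygote(self):
        assert variants.call_iupac("A", "G", 6, 6) == "R"

    def test_homozygote(self):
        assert variants.call_iupac("A", "G", 12, 0) == "A"

    def test_minor_fraction_below_threshold_calls_majority(self):
        assert variants.call_iupac("A", "G", 11, 1) == "A"

    def test_fraction_at_threshold_calls_het(self):
        assert variants.call_iupac("A", "G", 8, 2) == "R"  # 0.2 exactly

    def test_zero_depth_raises(self):
        with pytest.raises(ValueError, match="depth"):
            variants.call_iupac("A", "G", 0, 0)

    @pytest.mark.parametrize(
        "pair,code",
        [(("A", "G"), "R"), (("C", "T"), "Y"), (("C", "G"), "S"),
         (("A", "T"), "W"), (("G", "T"), "K"), (("A", "C"), "M")],
    )
    def test_all_ambiguity_codes(self, pair, code):
        assert variants.call_iupac(pair[0], pair[1], 5, 5) == code


class TestBuildMatrix:
    def _sites(self):
        return make_sites(
            [
                ("gB", 10, "A", "G", 50.0, 10.0, [[10, 0], [5, 5]]),
                ("gA", 3, "C", "T", 50.0, 10.0, [[0, 10], [10, 10]]),
            ]
        )

    def test_full_matrix_and_column_order(self):
        gm = variants.build_matrix(self._sites())
        assert gm.site_ids == ["gA:3", "gB:10"]  # sorted by (gene, pos)
        assert gm.table.loc["s1", "gB:10"] == "A"
        assert gm.table.loc["s2", "gB:10"] == "R"
        assert gm.table.loc["s1", "gA:3"] == "T"
        assert gm.table.loc["s2", "gA:3"] == "Y"

    def test_subsample_determinism(self):
        st = make_sites(
            [("g", p, "A", "G", 50.0, 10.0, [[6, 6], [12, 0]]) for p in range(1, 30)]
        )
        a = variants.build_matrix(st, n_subsample=10, seed=3)
        b = variants.build_matrix(st, n_subsample=10, seed=3)
        assert a.table.equals(b.table)
        with pytest.raises(ValueError, match="exceeds"):
            variants.build_matrix(st, n_subsample=100)

    def test_identical_depths_give_identical_rows(self):
        st = make_sites(
            [("g", 1, "A", "G", 50.0, 10.0, [[6, 6], [6, 6]]),
             ("g", 2, "C", "T", 50.0, 10.0, [[9, 0], [9, 0]])]
        )
        gm = variants.build_matrix(st)
        assert (gm.table.loc["s1"] == gm.table.loc["s2"]).all()

    def test_nexus_round_trip(self, tmp_path):
        gm = variants.build_matrix(self._sites())
        path = tmp_path / "m.nex"
        gm.to_nexus(path)
        back = GenotypeMatrix.from_nexus(path, site_ids=gm.site_ids)
        assert back.table.equals(gm.table)


CDS = pd.DataFrame(
    [{"gene_id": "g", "cds_id": "g.1", "start": 4, "end": 12, "strand": "+", "frame": 0}]
)
#          123 456 789 012
SEQ = {"g": "AAA" "GCT" "AAA" "TGA" "CCCC"}  # CDS: GCT AAA TGA


class TestCodingEffect:
    def test_synonymous_substitution(self):
        eff = variants.coding_effect("g", 6, "T", "C", CDS, SEQ)  # GCT -> GCC, both Ala
        assert eff.effect == "synonymous"
        assert eff.aa_before == eff.aa_after == "A"

    def test_non_synonymous_substitution(self):
        eff = variants.coding_effect("g", 7, "A", "G", CDS, SEQ)  # AAA -> GAA, Lys->Glu
        assert eff.effect == "non_synonymous"
        assert (eff.aa_before, eff.aa_after) == ("K", "E")

    def test_position_outside_cds_is_non_coding(self):
        eff = variants.coding_effect("g", 2, "A", "G", CDS, SEQ)
        assert eff.effect == "non_coding"

    def test_minus_strand_codon_lookup(self):
        cds = pd.DataFrame(
            [{"gene_id": "g", "cds_id": "g.1", "start": 1, "end": 6, "strand": "-", "frame": 0}]
        )
        seq = {"g": "TTACATGG"}  # revcomp(TTACAT) = ATGTAA : Met, stop
        eff = variants.coding_effect("g", 6, "T", "C", cds, seq)
        # pos 6 maps to first base of ATG; T->C means A->G on the CDS: GTG (Val)
        assert eff.effect == "non_synonymous"
        assert eff.aa_before == "M"

    def test_ratio_by_gene(self):
        effs = [
            variants.CodingEffect("a:1", "c", "non_synonymous"),
            variants.CodingEffect("a:2", "c", "synonymous"),
            variants.CodingEffect("a:3", "c", "synonymous"),
            variants.CodingEffect("b:1", "c", "synonymous"),
            variants.CodingEffect("b:2", "c", "synonymous"),
            variants.CodingEffect("d:1", "c", "non_synonymous"),
            variants.CodingEffect("e:1", "c", "non_coding"),
        ]
        r = variants.ratio_by_gene(effs)
        assert r["a"] == pytest.approx(0.5)
        assert r["b"] == 0.0
        assert np.isinf(r["d"])
        assert np.isnan(r["e"])


class TestDistanceAndNJ:
    def test_identical_rows_distance_zero(self):
        gm = GenotypeMatrix(pd.DataFrame({"x": ["A", "A"], "y": ["C", "C"]},
                                         index=["s1", "s2"]).T)
        gm = GenotypeMatrix(pd.DataFrame([["A", "C"], ["A", "C"]], index=["s1", "s2"],
                                         columns=["x", "y"]))
        d = variants.distance_matrix(gm)
        assert d.loc["s1", "s2"] == 0.0

    def test_ambiguity_half_mismatch(self):
        gm = GenotypeMatrix(
            pd.DataFrame([["A", "R"], ["A", "A"]], index=["s1", "s2"], columns=["x", "y"])
        )
        d = variants.distance_matrix(gm)
        assert d.loc["s1", "s2"] == pytest.approx(0.25, abs=1e-9)

    def test_disjoint_ambiguities_full_mismatch(self):
        gm = GenotypeMatrix(
            pd.DataFrame([["R"], ["Y"]], index=["s1", "s2"], columns=["x"])
        )
        assert variants.distance_matrix(gm).loc["s1", "s2"] == 1.0

    def test_missing_sites_skipped_pairwise(self):
        gm = GenotypeMatrix(
            pd.DataFrame([["A", "?"], ["G", "C"]], index=["s1", "s2"], columns=["x", "y"])
        )
        assert variants.distance_matrix(gm).loc["s1", "s2"] == 1.0  # only site x scored

    def test_nj_needs_three_samples(self):
        d = pd.DataFrame([[0.0, 0.1], [0.1, 0.0]], index=["a", "b"], columns=["a", "b"])
        with pytest.raises(ValueError, match="3"):
            variants.nj_tree(d)

    def test_nj_recovers_additive_four_taxon_topology(self):
        """Additive distances on ((A,B),(C,D)); the four-point condition
        identifies that split, and NJ must agree."""
        ids = ["A", "B", "C", "D"]
        d = pd.DataFrame(
            [
                [0.0, 0.2, 0.5, 0.5],
                [0.2, 0.0, 0.5, 0.5],
                [0.5, 0.5, 0.0, 0.2],
                [0.5, 0.5, 0.2, 0.0],
            ],
            index=ids,
            columns=ids,
        )
        # four-point condition oracle over the three possible splits
        s_ab = d.loc["A", "B"] + d.loc["C", "D"]
        s_ac = d.loc["A", "C"] + d.loc["B", "D"]
        s_ad = d.loc["A", "D"] + d.loc["B", "C"]
        assert s_ab < min(s_ac, s_ad)
        tree = TreeNode.read(io.StringIO(variants.nj_tree(d)))
        tip_sets = [
            {t.name.strip("'") for t in node.tips()} for node in tree.non_tips(include_self=False)
        ]
        assert any(s in ({"A", "B"}, {"C", "D"}) for s in tip_sets)


class TestTsvRoundTrip:
    def test_site_table_round_trip(self, tmp_path):
        st = make_sites(
            [
                ("gB", 10, "A", "G", 50.0, 10.0, [[10, 0], [5, 5]]),
                ("gA", 3, "C", "T,G", 45.0, 8.0, [[0, 10, 1], [10, 10, 0]]),
            ]
        )
        path = tmp_path / "sites.tsv"
        st.to_tsv(path)
        back = SiteTable.from_tsv(path)
        assert list(back.meta.index) == list(st.meta.index)
        assert np.array_equal(back.depths, st.depths)
        assert back.samples == st.samples
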