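import pytest

from prodomainkit.conserve import (
    ConservationParams,
    ConserveError,
    FeatureTable,
    load_feature_table,
    map_features,
    render_shading,
    scan_cysteines,
    shade_profile,
)
from prodomainkit.seqio import Alignment


def _aln(rows, ids=None):
    ids = ids or [f"r{i}" for i in range(len(rows))]
    return Alignment(ids, rows)


class TestShadeProfile:
    def test_identical_column(self):
        prof = shade_profile(_aln(list("LLLL")))
        assert prof.classes == ["identical"]
        assert prof.consensus == ["L"]

    def test_similar_via_group_count(self):
        # I/L/V group reaches 3 of 4 at the half cutoff; no residue does
        prof = shade_profile(_aln(list("LVIF")))
        assert prof.classes == ["similar"]
        assert prof.consensus == ["ILV"]

    def test_group_tie_resolves_to_listed_order(self):
        # both I/L/V and F/W/Y reach exactly 2 of 4: first listed group wins
        prof = shade_profile(_aln(list("LVFY")))
        assert prof.classes == ["similar"]
        assert prof.consensus == ["ILV"]

    def test_exactly_half_counts(self):
        # "half of the sequences" is inclusive: 2 of 4 identical L suffices
        prof = shade_profile(_aln(list("LLDP")))
        assert prof.classes == ["identical"]

    def test_unconserved_column(self):
        prof = shade_profile(_aln(list("LDPW")))
        assert prof.classes == ["none"]
        assert prof.consensus == [None]

    def test_gaps_never_count_toward_threshold(self):
        # 2 L of 5 rows (3 gaps): ceil(0.5*5)=3 not reached by L
        prof = shade_profile(_aln(["L", "L", "-", "-", "-"]))
        assert prof.classes == ["none"]

    def test_identical_needs_single_residue_not_group(self):
        # 2 L + 2 I: L alone reaches 2 = ceil(0.5*4) -> identical, not merely similar
        prof = shade_profile(_aln(list("LLII")))
        assert prof.classes == ["identical"]

    def test_row_permutation_invariance_and_duplicate_promotion(self):
        rows = ["LVD", "LID", "LFE", "LWE"]
        base = shade_profile(_aln(rows))
        perm = shade_profile(_aln(rows[::-1]))
        assert base.classes == perm.classes
        rank = {"none": 0, "similar": 1, "identical": 2}
        extra = shade_profile(_aln(rows + [rows[0]]))
        for b, e in zip(base.classes, extra.classes):
            assert rank[e] >= rank[b]

    def test_disjoint_group_validation(self):
        with pytest.raises(ConserveError):
            ConservationParams(groups=("DE", "EK"))

    def test_render_shading_marks_classes(self):
        aln = _aln(["LL", "LV", "LI", "LD"])
        text = render_shading(aln, shade_profile(aln))
        assert "L" in text  # identical column kept uppercase


class TestMapFeatures:
    def test_gapfree_reference_columns_equal_positions(self):
        aln = _aln(["MKWVLA", "MK-VLA"], ids=["ref", "o"])
        ft = FeatureTable("ref", {"helix": (2, 4)})
        fmap = map_features(aln, "ref", ft)
        assert fmap.column_ranges["helix"] == (2, 4)

    def test_leading_gaps_shift_columns(self):
        aln = _aln(["--MKWVLA", "AAMKWVLA"], ids=["ref", "o"])
        fmap = map_features(aln, "ref", FeatureTable("ref", {"helix": (2, 4)}))
        assert fmap.column_ranges["helix"] == (4, 6)

    def test_overlapping_ranges_rejected(self):
        with pytest.raises(ConserveError, match="overlap"):
            FeatureTable("ref", {"a": (1, 5), "b": (4, 8)})

    def test_absent_reference_and_out_of_bounds(self):
        aln = _aln(["MKWV", "MKWV"], ids=["a", "b"])
        with pytest.raises(ConserveError):
            map_features(aln, "zz", FeatureTable("zz", {"f": (1, 2)}))
        with pytest.raises(ConserveError, match="exceeds"):
            map_features(aln, "a", FeatureTable("a", {"f": (1, 9)}))

    def test_roundtrip_through_reference_coordinates(self, default_family):
        from prodomainkit import progressive_align, split_record
        from prodomainkit.seqio import ProteinRecord
        from prodomainkit.synth import feature_table_for

        reg, truth = default_family
        pro = [ProteinRecord(r.id, split_record(r).prodomain) for r in reg.records[:6]]
        aln = progressive_align(pro)
        ft = feature_table_for(truth, pro[0].id)
        fmap = map_features(aln, pro[0].id, ft)
        row = aln.row(pro[0].id)
        for name, (a, b) in ft.ranges.items():
            c0, c1 = fmap.column_ranges[name]
            assert row[: c0 - 1].replace("-", "") == pro[0].sequence[: a - 1]
            assert row[c0 - 1] == pro[0].sequence[a - 1]
            assert row[c1 - 1] == pro[0].sequence[b - 1]


class TestScanCysteines:
    def test_cxc_and_cxxc_share_anchor(self):
        aln = _aln(
            ["ACAC-A", "AC-AAC", "AAAAAA", "ACGGGA"],
            ids=["cxc", "cxxc", "none", "solo"],
        )
        ft = FeatureTable("none", {"region": (1, 6)})
        fmap = map_features(aln, "none", ft)
        rep = scan_cysteines(aln, fmap, "region")
        assert rep.row_motifs == {
            "cxc": "CxC", "cxxc": "CxxC", "none": "none", "solo": "solo"
        }
        # first cysteines of all motif-bearing rows sit in column 2
        assert rep.row_anchor_columns["cxc"] == 2
        assert rep.row_anchor_columns["cxxc"] == 2
        assert rep.anchor_groups == {2: ["cxc", "cxxc", "solo"]}
        assert 2 in rep.columns_with_shared_cys

    def test_gap_inside_motif_does_not_break_it(self):
        # CxxC split by an alignment gap still classifies from ungapped text
        aln = _aln(["CA-AC", "AAAAA"], ids=["m", "x"])
        fmap = map_features(aln, "x", FeatureTable("x", {"r": (1, 5)}))
        rep = scan_cysteines(aln, fmap, "r")
        assert rep.row_motifs["m"] == "CxxC"

    def test_cysteine_free_region(self):
        aln = _aln(["AAAA", "GGGG"], ids=["a", "b"])
        fmap = map_features(aln, "a", FeatureTable("a", {"r": (1, 4)}))
        rep = scan_cysteines(aln, fmap, "r")
        assert set(rep.row_motifs.values()) == {"none"}
        assert rep.anchor_groups == {}

    def test_unknown_region_is_error(self):
        aln = _aln(["AAAA", "GGGG"], ids=["a", "b"])
        fmap = map_features(aln, "a", FeatureTable("a", {"r": (1, 4)}))
        with pytest.raises(ConserveError):
            scan_cysteines(aln, fmap, "zz")

    def test_planted_motifs_recovered_with_shared_anchor(self, default_family):
        """Simulator-planted cysteine classes are recovered exactly, and the
        first cysteine aligns across subfamilies (the hallmark the scanner
        is built to detect)."""
        from prodomainkit import (
            map_features,
            progressive_align,
            scan_cysteines,
            score_recovery,
            split_record,
        )
        from prodomainkit.seqio import ProteinRecord
        from prodomainkit.synth import feature_table_for

        reg, truth = default_family
        pro = [ProteinRecord(r.id, split_record(r).prodomain) for r in reg]
        aln = progressive_align(pro)
        fmap = map_features(aln, "Activin1", feature_table_for(truth, "Activin1"))
        for region in ("ltbp", "beta8"):
            rep = scan_cysteines(aln, fmap, region)
            card = score_recovery(truth, {"motifs": {region: rep.row_motifs}})
            assert card["motif_accuracy"][region] == 1.0
        rep = scan_cysteines(aln, fmap, "beta8")
        assert len(rep.anchor_groups) == 1  # one shared first-C column


def test_load_feature_table_toml(tmp_path):
    cfgfile = tmp_path / "features.toml"
    cfgfile.write_text(
        'reference_id = "ref"\n[features]\nalpha1 = [3, 10]\nbeta8 = [20, 29]\n'
    )
    ft = load_feature_table(cfgfile)
    assert ft.reference_id == "ref"
    assert ft.ranges == {"alpha1": (3, 10), "beta8": (20, 29)}
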