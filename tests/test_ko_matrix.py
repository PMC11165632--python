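"""Taxon-KO matrix construction, CPM normalization and twofold screening."""

import pandas as pd
import pytest

from orepan import ko_matrix as km
from orepan import synthetic


def make_annotations(rows):
    return pd.DataFrame(rows, columns=["query", "KEGG_ko", "taxon_group", "dataset"])


class TestBuildMatrix:
    def test_single_cell_counts_queries(self):
        ann = make_annotations(
            [(f"q{i}", "ko:K00001", "Actinomycetota", "PMT|Actinomycetota")
             for i in range(10)])
        matrix = km.build_matrix(ann)
        assert matrix.table["raw"].tolist() == [10]

    def test_multi_ko_query_counts_once_per_ko(self):
        ann = make_annotations([
            ("q1", "ko:K00001,ko:K00002", "Actinomycetota", "D"),
            ("q2", "ko:K00001", "Actinomycetota", "D"),
        ])
        matrix = km.build_matrix(ann)
        counts = dict(zip(matrix.table["ko"], matrix.table["raw"]))
        assert counts == {"K00001": 2, "K00002": 1}

    def test_other_rows_excluded(self):
        ann = make_annotations([
            ("q1", "ko:K00001", "Other", "D"),
            ("q2", "ko:K00002", "Actinomycetota", "D"),
        ])
        matrix = km.build_matrix(ann)
        assert matrix.table["ko"].tolist() == ["K00002"]

    def test_all_other_gives_empty_matrix(self, caplog):
        ann = make_annotations([("q1", "ko:K00001", "Other", "D")])
        matrix = km.build_matrix(ann)
        assert matrix.table.empty

    def test_duplicate_query_rejected(self):
        ann = make_annotations([
            ("q1", "ko:K00001", "Actinomycetota", "D"),
            ("q1", "ko:K00002", "Actinomycetota", "D"),
        ])
        with pytest.raises(ValueError, match="duplicate query"):
            km.build_matrix(ann)

    def test_conserves_annotation_multiplicities(self, config):
        """Sum of raw counts equals the number of (query, KO) assignments."""
        datasets, _ = synthetic.generate_ko_datasets(config)
        ann = synthetic.ko_datasets_to_annotations(datasets)
        matrix = km.build_matrix(ann)
        expected = sum(len(km.parse_ko_field(f)) for f in ann["KEGG_ko"])
        assert matrix.table["raw"].sum() == expected


class TestParseKoField:
    @pytest.mark.parametrize("text, expected", [
        ("ko:K00001", ["K00001"]),
        ("ko:K00001,ko:K00002", ["K00001", "K00002"]),
        ("K12345", ["K12345"]),
        ("-", []),
        ("", []),
    ])
    def test_parses(self, text, expected):
        assert km.parse_ko_field(text) == expected

    def test_rejects_malformed(self):
        with pytest.raises(ValueError):
            km.parse_ko_field("ko:K1")


class TestCpm:
    def test_simple_arithmetic(self):
        table = pd.DataFrame({"dataset": ["D", "D"], "ko": ["K00001", "K00002"],
                              "raw": [5, 5], "cpm": [None, None]})
        out = km.normalize_cpm(km.TaxonKoMatrix(table=table), {"D": 10})
        assert out.table["cpm"].tolist() == [500000.0, 500000.0]

    def test_single_ko_full_million(self):
        table = pd.DataFrame({"dataset": ["D"], "ko": ["K00001"],
                              "raw": [3], "cpm": [None]})
        out = km.normalize_cpm(km.TaxonKoMatrix(table=table), {"D": 3})
        assert out.table["cpm"].iloc[0] == 1e6

    def test_joint_scaling_leaves_cpm_unchanged(self):
        table = pd.DataFrame({"dataset": ["D"] * 3, "ko": list("abc"),
                              "raw": [1, 2, 3], "cpm": [None] * 3})
        base = km.normalize_cpm(km.TaxonKoMatrix(table=table), {"D": 6})
        scaled_table = table.assign(raw=table["raw"] * 7)
        scaled = km.normalize_cpm(km.TaxonKoMatrix(table=scaled_table), {"D": 42})
        assert base.table["cpm"].tolist() == scaled.table["cpm"].tolist()

    def test_zero_total_with_counts_errors(self):
        table = pd.DataFrame({"dataset": ["D"], "ko": ["K00001"],
                              "raw": [3], "cpm": [None]})
        with pytest.raises(ValueError, match="mapped total"):
            km.normalize_cpm(km.TaxonKoMatrix(table=table), {"D": 0})

    def test_cpm_sums_to_one_million_on_synthetic_data(self, config):
        datasets, _ = synthetic.generate_ko_datasets(config)
        ann = synthetic.ko_datasets_to_annotations(datasets)
        matrix = km.normalize_cpm(km.build_matrix(ann))
        for _, grp in matrix.table.groupby("dataset"):
            assert abs(grp["cpm"].sum() - 1e6) <= 1e-3

    def test_raw_never_mutated(self):
        table = pd.DataFrame({"dataset": ["D"], "ko": ["K00001"],
                              "raw": [3], "cpm": [1e6]})
        out = km.normalize_cpm(km.TaxonKoMatrix(table=table), {"D": 6})
        assert out.table["raw"].tolist() == [3]
        assert out.table["cpm"].tolist() == [500000.0]


class TestTaxonProfile:
    def test_read_bracken_report(self, tmp_path, config):
        frames = synthetic.generate_taxon_profiles(config)
        path = tmp_path / "report.tsv"
        frames["PMT"].to_csv(path, sep="\t", index=False)
        profile = km.read_taxon_profile(path, sample="PMT")
        assert len(profile.rows) == len(frames["PMT"])

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "bad.tsv"
        pd.DataFrame({"name": ["x"]}).to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="taxonomy_id"):
            km.read_taxon_profile(path)

    def test_fraction_out_of_bounds_rejected(self, tmp_path):
        df = pd.DataFrame([["x", 1, "G", 10, 0, 10, 1.2]],
                          columns=km.BRACKEN_COLUMNS)
        path = tmp_path / "bad.tsv"
        df.to_csv(path, sep="\t", index=False)
        with pytest.raises(ValueError, match="fraction"):
            km.read_taxon_profile(path)


class TestRelativeAbundance:
    @staticmethod
    def profile(counts: dict[str, int]) -> km.TaxonProfile:
        total = sum(counts.values())
        rows = [[n, i, "G", c, 0, c, c / total]
                for i, (n, c) in enumerate(counts.items())]
        return km.TaxonProfile(
            sample="s", rows=pd.DataFrame(rows, columns=km.BRACKEN_COLUMNS))

    def test_no_pooling_above_threshold(self):
        out = km.relative_abundance(self.profile({"a": 80, "b": 15, "c": 5}), "G")
        assert out == {"a": 80.0, "b": 15.0, "c": 5.0}

    def test_rare_taxa_pooled(self):
        out = km.relative_abundance(self.profile({"a": 990, "b": 6, "c": 4}), "G")
        assert out == {"a": 99.0, "<1 %": 1.0}

    def test_unknown_taxa_pooled_regardless_of_abundance(self):
        out = km.relative_abundance(self.profile({"a": 50, "unknown": 50}), "G")
        assert out == {"a": 50.0, "<1 %": 50.0}

    def test_all_rare_single_bucket(self):
        counts = {f"t{i}": 1 for i in range(200)}
        out = km.relative_abundance(self.profile(counts), "G")
        assert set(out) == {"<1 %"}
        assert out["<1 %"] == pytest.approx(100.0)

    def test_percentages_sum_to_100(self, config):
        frames = synthetic.generate_taxon_profiles(config)
        prof = km.TaxonProfile(sample="PMT", rows=frames["PMT"])
        out = km.relative_abundance(prof, "G")
        assert sum(out.values()) == pytest.approx(100.0, abs=1e-6)

    def test_empty_rank_errors(self):
        with pytest.raises(ValueError, match="rank"):
            km.relative_abundance(self.profile({"a": 10}), "P")


class TestTwofoldScreen:
    def test_boundary_inclusive(self):
        res = km.twofold_screen({"f": 2.0}, {"f": 1.0})
        assert "f" in res.flagged
        assert res.flagged["f"] == (2.0, "a")

    def test_below_threshold_not_flagged(self):
        res = km.twofold_screen({"f": 1.9}, {"f": 1.0})
        assert res.flagged == {}

    def test_one_sided_is_exclusive_not_flagged(self):
        res = km.twofold_screen({"f": 0.5}, {"f": 0.0})
        assert res.flagged == {}
        assert res.exclusive_a == {"f"}

    def test_symmetric_up_to_direction(self):
        a = {"x": 4.0, "y": 1.0, "z": 3.0}
        b = {"x": 1.0, "y": 4.0, "w": 2.0}
        ab, ba = km.twofold_screen(a, b), km.twofold_screen(b, a)
        assert set(ab.flagged) == set(ba.flagged)
        assert ab.exclusive_a == ba.exclusive_b
        assert ab.exclusive_b == ba.exclusive_a

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValueError):
            km.twofold_screen({"f": -1.0}, {"f": 1.0})
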