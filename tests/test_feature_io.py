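"""Feature/report parsing, ground-truth labeling, and dataset splitting."""

import gzip

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nanocon import (BisulfiteSiteRecord, MethylInstance, attach_labels,
                     class_proportion, label_sites, read_bisulfite_report,
                     read_feature_file, split_dataset, write_bisulfite_report,
                     write_feature_file)
from nanocon.feature_io import FeatureFormatError

from conftest import make_instance


def _feature_row(motif="ACGTACCTACGTA", n_means=13, label="1"):
    means = ",".join(str(0.1 * i) for i in range(n_means))
    stds = ",".join("0.5" for _ in range(13))
    lens = ",".join("8" for _ in range(13))
    return f"chr1\t100\t+\tread0\t{motif}\t{means}\t{stds}\t{lens}\t{label}"


class TestFeatureFile:
    def test_single_row_parses(self, tmp_path):
        path = tmp_path / "f.tsv"
        path.write_text(_feature_row() + "\n")
        (inst,) = read_feature_file(path)
        assert inst.motif == "ACGTACCTACGTA"
        assert inst.label == 1
        assert len(inst.means) == 13

    def test_empty_file(self, tmp_path):
        path = tmp_path / "f.tsv"
        path.write_text("")
        assert read_feature_file(path) == []

    def test_short_track_raises_with_line_number(self, tmp_path):
        path = tmp_path / "f.tsv"
        path.write_text(_feature_row() + "\n" + _feature_row(n_means=12) + "\n")
        with pytest.raises(FeatureFormatError, match="line 2"):
            read_feature_file(path)

    def test_lenient_mode_skips_bad_rows(self, tmp_path):
        path = tmp_path / "f.tsv"
        path.write_text(_feature_row(n_means=12) + "\n" + _feature_row() + "\n")
        assert len(read_feature_file(path, strict=False)) == 1

    def test_unknown_label_raises(self, tmp_path):
        path = tmp_path / "f.tsv"
        path.write_text(_feature_row(label="2") + "\n")
        with pytest.raises(FeatureFormatError, match="label"):
            read_feature_file(path)

    def test_gzip_transparent(self, tmp_path):
        path = tmp_path / "f.tsv.gz"
        instances = [make_instance(read_id=f"r{i}") for i in range(3)]
        write_feature_file(instances, path)
        with gzip.open(path, "rt") as fh:
            assert len(fh.readlines()) == 3
        assert read_feature_file(path) == instances

    @settings(max_examples=25, deadline=None)
    @given(st.lists(
        st.tuples(
            st.text(alphabet="ACGT", min_size=6, max_size=6),
            st.text(alphabet="ACGT", min_size=6, max_size=6),
            st.lists(st.floats(-5, 5, allow_nan=False), min_size=13, max_size=13),
            st.sampled_from([0, 1, -1])),
        min_size=0, max_size=5))
    def test_write_read_round_trip(self, tmp_path_factory, rows):
        instances = [
            make_instance(motif=left + "C" + right, means=means, label=label,
                          read_id=f"r{i}", pos=10 * i)
            for i, (left, right, means, label) in enumerate(rows)]
        path = tmp_path_factory.mktemp("rt") / "f.tsv"
        write_feature_file(instances, path)
        assert read_feature_file(path) == instances


class TestInstanceInvariants:
    def test_center_must_be_cytosine(self):
        with pytest.raises(ValueError, match="center"):
            make_instance(motif="ACGTACATACGTA")

    def test_track_lengths_enforced(self):
        with pytest.raises(ValueError, match="means"):
            make_instance(means=[1.0] * 12)

    def test_lens_must_be_positive(self):
        with pytest.raises(ValueError, match="lens"):
            make_instance(lens=[0] * 13)


def _site(pos, count_meth, count_unmeth):
    return BisulfiteSiteRecord(chrom="chr1", pos=pos, strand="+",
                               count_meth=count_meth,
                               count_unmeth=count_unmeth, context="CpG")


class TestLabelSites:
    # every boundary of the coverage/rate rules
    CASES = [
        (_site(0, 6, 0), "positive"),     # cov 6 > 5, rate 1.0 > 0.9
        (_site(1, 19, 1), "positive"),    # cov 20, rate 0.95
        (_site(2, 0, 10), "negative"),    # cov 10, rate 0
        (_site(3, 5, 5), "excluded"),     # rate 0.5
        (_site(4, 4, 0), "excluded"),     # cov 4 fails coverage threshold
        (_site(5, 5, 0), "excluded"),     # cov 5 not strictly above 5
        (_site(6, 0, 4), "excluded"),     # 0% rate but cov 4 (filter applies)
        (_site(7, 9, 1), "excluded"),     # rate 0.9 not strictly over 0.9
        (_site(8, 0, 0), "excluded"),     # coverage 0: rate undefined
    ]

    def test_rule_boundaries(self):
        records = [r for r, _ in self.CASES]
        calls = label_sites(records)
        for record, expected in self.CASES:
            assert calls[record.site] == expected, record

    def test_negative_coverage_filter_can_be_disabled(self):
        calls = label_sites([_site(0, 0, 4)], coverage_filter_negatives=False)
        assert calls[("chr1", 0, "+")] == "negative"

    def test_partition_and_order_independence(self, rng):
        records = [_site(i, int(rng.integers(0, 12)), int(rng.integers(0, 12)))
                   for i in range(50)]
        calls = label_sites(records)
        assert set(calls.values()) <= {"positive", "negative", "excluded"}
        assert len(calls) == 50
        reversed_calls = label_sites(records[::-1])
        assert reversed_calls == calls
        assert label_sites(records) == calls  # idempotent


class TestAttachLabels:
    def test_instances_at_positive_site_survive(self):
        labels = {("chr1", 100, "+"): "positive", ("chr1", 200, "+"): "excluded"}
        instances = ([make_instance(pos=100, read_id=f"a{i}") for i in range(3)]
                     + [make_instance(pos=200, read_id=f"b{i}") for i in range(2)])
        labeled, counts = attach_labels(instances, labels)
        assert len(labeled) == 3
        assert all(i.label == 1 for i in labeled)
        assert counts == {"positive": 3, "negative": 0, "dropped": 2}

    def test_empty_label_map(self):
        labeled, counts = attach_labels([make_instance()], {})
        assert labeled == []
        assert counts["dropped"] == 1

    def test_six_site_example(self):
        # 2 sites meet the positive rule, 1 the negative rule, 3 neither
        records = [_site(0, 10, 0), _site(1, 19, 1), _site(2, 0, 8),
                   _site(3, 3, 3), _site(4, 2, 0), _site(5, 0, 2)]
        calls = label_sites(records)
        instances = [make_instance(pos=p, read_id=f"r{p}") for p in range(6)]
        labeled, _ = attach_labels(instances, calls)
        assert sorted(i.pos for i in labeled) == [0, 1, 2]
        assert {i.pos: i.label for i in labeled} == {0: 1, 1: 1, 2: 0}


class TestSplitDataset:
    def test_ten_instances(self):
        instances = [make_instance(read_id=f"r{i}") for i in range(10)]
        assert split_dataset(instances, seed=3).sizes == (8, 1, 1)

    def test_same_seed_identical(self):
        instances = [make_instance(read_id=f"r{i}") for i in range(50)]
        a = split_dataset(instances, seed=5)
        b = split_dataset(instances, seed=5)
        assert a.train == b.train and a.test == b.test

    @pytest.mark.parametrize("n", [3, 17, 100, 1003])
    def test_partition_properties(self, n):
        instances = [make_instance(read_id=f"r{i}") for i in range(n)]
        split = split_dataset(instances, seed=1)
        parts = [split.train, split.validation, split.test]
        assert sum(len(p) for p in parts) == n
        ids = [i.read_id for p in parts for i in p]
        assert len(set(ids)) == n  # disjoint, union equals input
        assert len(split.train) >= len(split.validation) >= 0

    def test_too_few_raises(self):
        with pytest.raises(ValueError, match="at least 3"):
            split_dataset([make_instance(), make_instance()], seed=0)


class TestClassProportion:
    def test_balanced(self):
        instances = ([make_instance(label=1, read_id=f"p{i}") for i in range(5)]
                     + [make_instance(label=0, read_id=f"n{i}") for i in range(5)])
        assert class_proportion(instances) == 1.0

    def test_explicit_counts(self):
        assert class_proportion(n_pos=1796190, n_neg=6263834) == pytest.approx(
            0.28675568, abs=5e-9)

    def test_zero_negatives_raises(self):
        with pytest.raises(ValueError, match="zero negatives"):
            class_proportion(n_pos=3, n_neg=0)
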