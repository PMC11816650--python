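import logging

import numpy as np
import pytest

from subtype_awa import (
    ClusterAssignment,
    DataValidationError,
    OmicsDataset,
    OmicsKind,
    align_and_validate,
    read_clinical_table,
    read_cluster_assignment,
    read_omics_matrix,
    write_clinical_table,
    write_cluster_assignment,
    write_omics_matrix,
)
from conftest import mk_assignment, mk_clinical, mk_matrix


def write_tsv(path, text):
    path.write_text(text, encoding="utf-8")
    return path


class TestReadOmicsMatrix:
    def test_identity_round_trip_preserves_order_and_values(self, tmp_path):
        p = write_tsv(
            tmp_path / "m.tsv",
            "sample_id\tf1\tf2\tf3\ns1\t1\t2\t3\ns2\t4\t5\t6\n",
        )
        m = read_omics_matrix(p, OmicsKind.MRNA)
        assert m.values.shape == (2, 3)
        assert m.sample_ids == ["s1", "s2"]
        assert m.feature_ids == ["f1", "f2", "f3"]
        np.testing.assert_array_equal(m.values, [[1, 2, 3], [4, 5, 6]])

    @pytest.mark.parametrize("token", ["NA", "na", "Na", ""])
    def test_missing_tokens_set_mask(self, tmp_path, token):
        p = write_tsv(
            tmp_path / "m.tsv",
            f"sample_id\tf1\tf2\ns1\t1\t{token}\ns2\t3\t4\n",
        )
        m = read_omics_matrix(p, OmicsKind.MRNA)
        assert m.missing_mask[0, 1] and m.missing_mask.sum() == 1

    def test_methylation_beta_out_of_range_names_cell(self, tmp_path):
        p = write_tsv(
            tmp_path / "m.tsv",
            "sample_id\tf1\tf2\ns1\t0.5\t1.2\ns2\t0.3\t0.4\n",
        )
        with pytest.raises(DataValidationError, match=r"s1.*f2|f2.*s1"):
            read_omics_matrix(p, OmicsKind.METHYLATION)

    def test_non_numeric_cell_names_coordinates(self, tmp_path):
        p = write_tsv(
            tmp_path / "m.tsv",
            "sample_id\tf1\tf2\ns1\t1\tx\ns2\t3\t4\n",
        )
        with pytest.raises(DataValidationError, match="f2"):
            read_omics_matrix(p, OmicsKind.MRNA)

    def test_duplicate_sample_id_rejected(self, tmp_path):
        p = write_tsv(
            tmp_path / "m.tsv",
            "sample_id\tf1\ns1\t1\ns1\t2\n",
        )
        with pytest.raises(DataValidationError, match="s1"):
            read_omics_matrix(p, OmicsKind.MRNA)

    def test_round_trip_full_precision_with_missing(self, tmp_path):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(5, 4)) * 1e-7 + 0.1
        vals[2, 1] = np.nan
        m = mk_matrix(OmicsKind.COPY_NUMBER, vals)
        write_omics_matrix(m, tmp_path / "m.tsv")
        back = read_omics_matrix(tmp_path / "m.tsv", OmicsKind.COPY_NUMBER)
        assert back.sample_ids == m.sample_ids
        assert back.feature_ids == m.feature_ids
        np.testing.assert_array_equal(back.values, m.values)  # exact, incl. NaN


class TestClinicalTable:
    TABLE = (
        "sample_id\tos_time\tos_event\tgender\tage_at_diagnosis\tpathologic_t"
        "\tpathologic_m\tpathologic_n\tpathologic_stage\n"
        "s1\t100\t1\tmale\t60\tT1\tM0\tN0\tStage I\n"
        "s2\t200\t0\tfemale\t55\tT2\tM0\tN1\tStage II\n"
        "s3\t50\t1\tmale\tNA\tT3\tM1\tN2\tStage III\n"
    )

    def test_default_schema_gives_six_covariates(self, tmp_path):
        p = write_tsv(tmp_path / "c.tsv", self.TABLE)
        c = read_clinical_table(p)
        assert len(c.covariates) == 6
        assert c.covariates["age_at_diagnosis"].kind == "numeric"
        assert np.isnan(c.covariates["age_at_diagnosis"].values[2])
        np.testing.assert_array_equal(c.event, [1, 0, 1])

    def test_missing_schema_column_warns_and_skips(self, tmp_path, caplog):
        table = "\n".join(
            "\t".join(line.split("\t")[:-1]) for line in self.TABLE.splitlines()
        )
        p = write_tsv(tmp_path / "c.tsv", table + "\n")
        with caplog.at_level(logging.WARNING, logger="subtype_awa"):
            c = read_clinical_table(p)
        assert len(c.covariates) == 5
        assert "pathologic_stage" not in c.covariates
        assert any("pathologic_stage" in m for m in caplog.messages)

    def test_bad_event_value_names_sample(self, tmp_path):
        p = write_tsv(tmp_path / "c.tsv", "sample_id\tos_time\tos_event\ns1\t10\t2\n")
        with pytest.raises(DataValidationError, match="s1"):
            read_clinical_table(p)

    def test_negative_time_rejected(self, tmp_path):
        p = write_tsv(tmp_path / "c.tsv", "sample_id\tos_time\tos_event\ns1\t-1\t0\n")
        with pytest.raises(DataValidationError, match="s1"):
            read_clinical_table(p)

    def test_round_trip(self, tmp_path):
        p = write_tsv(tmp_path / "c.tsv", self.TABLE)
        c = read_clinical_table(p)
        write_clinical_table(c, tmp_path / "c2.tsv")
        c2 = read_clinical_table(tmp_path / "c2.tsv")
        assert c2.sample_ids == c.sample_ids
        np.testing.assert_array_equal(c2.survival_time, c.survival_time)
        np.testing.assert_array_equal(c2.event, c.event)
        for name in c.covariates:
            a, b = c.covariates[name], c2.covariates[name]
            assert a.kind == b.kind
            if a.kind == "numeric":
                np.testing.assert_array_equal(a.values, b.values)
            else:
                assert list(a.values) == list(b.values)


class TestClusterAssignment:
    def test_round_trip_with_metadata(self, tmp_path):
        a = ClusterAssignment("methodX", {"s1": 1, "s2": 2, "s3": 1}, 2, runtime_s=12.5)
        write_cluster_assignment(a, tmp_path / "a.tsv")
        b = read_cluster_assignment(tmp_path / "a.tsv")
        assert (b.method_name, b.K, b.runtime_s) == ("methodX", 2, 12.5)
        assert b.labels == a.labels

    def test_label_outside_range_rejected(self):
        with pytest.raises(DataValidationError, match="outside"):
            ClusterAssignment("m", {"s1": 3}, 2)

    def test_empty_cluster_rejected_on_read(self, tmp_path):
        write_tsv(tmp_path / "a.tsv", "# K=3\nsample_id\tlabel\ns1\t1\ns2\t3\n")
        with pytest.raises(DataValidationError, match="cluster 2"):
            read_cluster_assignment(tmp_path / "a.tsv")

    def test_duplicate_sample_rejected(self, tmp_path):
        write_tsv(tmp_path / "a.tsv", "sample_id\tlabel\ns1\t1\ns1\t2\n")
        with pytest.raises(DataValidationError, match="s1"):
            read_cluster_assignment(tmp_path / "a.tsv")


class TestAlignAndValidate:
    def _inputs(self):
        m = mk_matrix(OmicsKind.MRNA, np.arange(8.0).reshape(4, 2))
        ds = OmicsDataset("d", {OmicsKind.MRNA: m})
        clin = mk_clinical([10, 20, 30, 40], [1, 0, 1, 0])
        assign = mk_assignment([1, 1, 2, 2])
        return ds, clin, assign

    def test_identical_sets_identity(self):
        ds, clin, assign = self._inputs()
        out = align_and_validate(ds, clin, [assign])
        assert out.dataset.sample_ids == ds.sample_ids
        assert out.dropped == {}
        np.testing.assert_array_equal(
            out.dataset.matrices[OmicsKind.MRNA].values, ds.matrices[OmicsKind.MRNA].values
        )

    def test_extra_clinical_sample_dropped_and_reported(self):
        ds, _, assign = self._inputs()
        clin = mk_clinical([1, 2, 3, 4, 5], [1, 1, 1, 1, 1],
                           sample_ids=["s1", "s2", "s3", "s4", "s5"])
        out = align_and_validate(ds, clin, [assign])
        assert out.clinical.sample_ids == ds.sample_ids
        assert out.dropped == {"clinical": ["s5"]}

    def test_cluster_emptied_by_intersection_errors(self):
        ds, clin, _ = self._inputs()
        assign = ClusterAssignment("mx", {"s1": 1, "s2": 1, "s3": 1, "s4": 1, "z1": 2}, 2)
        with pytest.raises(DataValidationError, match=r"mx.*cluster 2"):
            align_and_validate(ds, clin, [assign])

    def test_empty_intersection_errors(self):
        ds, clin, _ = self._inputs()
        assign = mk_assignment([1, 2], sample_ids=["z1", "z2"])
        with pytest.raises(DataValidationError, match="empty"):
            align_and_validate(ds, clin, [assign])

    def test_idempotent(self):
        ds, _, assign = self._inputs()
        clin = mk_clinical([1, 2, 3, 4, 5], [1, 1, 1, 1, 1],
                           sample_ids=["s4", "s3", "s2", "s1", "s9"])
        once = align_and_validate(ds, clin, [assign])
        twice = align_and_validate(once.dataset, once.clinical, once.assignments)
        assert twice.dataset.sample_ids == once.dataset.sample_ids
        assert twice.dropped == {}
        np.testing.assert_array_equal(twice.clinical.survival_time, once.clinical.survival_time)
        assert twice.assignments[0].labels == once.assignments[0].labels
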