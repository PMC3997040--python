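"""Containers, file round-trips and mask-indexed flattening."""

import numpy as np
import pandas as pd
import pytest

from fwmap.data import (SampleStack, StatMap, TruthMask, flatten, read_labels,
                        read_stack, read_stat_map, unflatten,
                        write_cluster_table, write_labels, write_stack,
                        write_stat_map)
from fwmap.simulate import SimulationParams, generate_dataset


class TestSampleStack:
    def test_label_count_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="label count"):
            SampleStack(data=rng.normal(size=(4, 3, 3, 3)),
                        labels=np.array([1, -1, 1]))

    def test_mask_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="mask shape"):
            SampleStack(data=rng.normal(size=(4, 3, 3, 3)),
                        labels=np.array([1, 1, -1, -1]),
                        mask=np.ones((2, 3, 3), dtype=bool))

    def test_minimum_class_size_enforced(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            SampleStack(data=rng.normal(size=(4, 3, 3, 3)),
                        labels=np.array([1, 1, 1, -1]))

    def test_default_mask_is_all_voxels(self, rng):
        st = SampleStack(data=rng.normal(size=(4, 3, 3, 3)),
                         labels=np.array([1, 1, -1, -1]))
        assert st.mask.all() and st.mask.shape == (3, 3, 3)


class TestFileRoundTrips:
    def test_stack_round_trip_identity(self, rng, tmp_path):
        st = SampleStack(data=rng.normal(size=(4, 5, 4, 3)),
                         labels=np.array([1, -1, 1, -1]),
                         mask=rng.random((5, 4, 3)) > 0.3)
        vols, labs, mask = (tmp_path / "s.nii.gz", tmp_path / "l.tsv",
                            tmp_path / "m.nii.gz")
        write_stack(st, vols, labels_path=labs, mask_path=mask)
        back = read_stack(vols, labs, mask)
        np.testing.assert_array_equal(back.data, st.data)
        np.testing.assert_array_equal(back.labels, st.labels)
        np.testing.assert_array_equal(back.mask, st.mask)

    def test_simulated_labels_are_balanced_fifteen_each(self, tmp_path):
        stack, _ = generate_dataset(SimulationParams(seed=0))
        path = tmp_path / "labels.tsv"
        write_labels(stack.labels, path)
        labels = read_labels(path)
        assert labels.size == 30
        assert (labels == 1).sum() == 15 and (labels == -1).sum() == 15

    def test_label_row_count_mismatch_rejected(self, rng, tmp_path):
        st = SampleStack(data=rng.normal(size=(4, 3, 3, 3)),
                         labels=np.array([1, -1, 1, -1]))
        vols, labs = tmp_path / "s.nii.gz", tmp_path / "l.tsv"
        write_stack(st, vols, labels_path=labs)
        # drop one row: 3 labels for 4 volumes
        lines = labs.read_text().splitlines()
        labs.write_text("\n".join(lines[:-1]) + "\n")
        with pytest.raises(ValueError, match="3 rows for 4 volumes"):
            read_stack(vols, labs)

    def test_string_labels_mapped_first_seen(self, tmp_path):
        path = tmp_path / "l.tsv"
        path.write_text("sample\tlabel\n0\ttap\n1\trest\n2\ttap\n")
        np.testing.assert_array_equal(read_labels(path), [1, -1, 1])

    def test_signed_weight_map_round_trip(self, rng, tmp_path):
        vals = rng.normal(size=(4, 4, 4))
        m = StatMap(values=vals, kind="weight")
        write_stat_map(m, tmp_path / "w.nii.gz")
        back = read_stat_map(tmp_path / "w.nii.gz", kind="weight")
        np.testing.assert_allclose(back.values, vals, rtol=0, atol=0)
        assert (back.values < 0).any()

    def test_out_of_mask_written_as_zero(self, rng, tmp_path):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        m = StatMap(values=np.full((3, 3, 3), 7.0), kind="weight", mask=mask)
        write_stat_map(m, tmp_path / "w.nii.gz")
        back = read_stat_map(tmp_path / "w.nii.gz", kind="weight").values
        assert back[1, 1, 1] == 7.0 and back[0, 0, 0] == 0.0

    def test_empty_cluster_table_is_header_only(self, tmp_path):
        write_cluster_table(pd.DataFrame(), tmp_path / "c.tsv")
        text = (tmp_path / "c.tsv").read_text().strip().splitlines()
        assert text == ["cluster\tsize\tsign\tp\tsignificant"]


class TestFlatten:
    def test_full_mask_counts(self, rng):
        st = SampleStack(data=rng.normal(size=(4, 2, 2, 2)),
                         labels=np.array([1, 1, -1, -1]))
        matrix, index = flatten(st)
        assert matrix.shape == (4, 8) and index.shape == (8, 3)

    def test_mask_restricts_columns(self, rng):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask.ravel()[[3, 11, 17, 40, 63]] = True
        st = SampleStack(data=rng.normal(size=(4, 4, 4, 4)),
                         labels=np.array([1, 1, -1, -1]), mask=mask)
        matrix, _ = flatten(st)
        assert matrix.shape[1] == 5

    def test_unflatten_inverts_flatten_on_mask(self, tiny_stack):
        matrix, index = flatten(tiny_stack)
        volumes = unflatten(matrix, index, tiny_stack.shape)
        np.testing.assert_array_equal(volumes[:, tiny_stack.mask],
                                      tiny_stack.data[:, tiny_stack.mask])
        assert (volumes[:, ~tiny_stack.mask] == 0).all()

    def test_empty_mask_rejected(self, rng):
        st = SampleStack(data=rng.normal(size=(4, 3, 3, 3)),
                         labels=np.array([1, 1, -1, -1]),
                         mask=np.zeros((3, 3, 3), dtype=bool))
        with pytest.raises(ValueError, match="empty"):
            flatten(st)


class TestStatMapInvariants:
    def test_accuracy_values_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="accuracy"):
            StatMap(values=np.full((2, 2, 2), 1.5), kind="accuracy")

    def test_truth_mask_values_restricted(self):
        with pytest.raises(ValueError):
            TruthMask(values=np.full((2, 2, 2), 3))
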