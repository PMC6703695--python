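"""Error taxonomy, metrics and the exhaustive matching oracle."""

import numpy as np
import pytest

from envseg.benchmark import (ERROR_CODES, compute_metrics, match_instances,
                              write_error_map)
from envseg.io import LabelVolume, read_label_volume


def vol(arr):
    return LabelVolume(np.asarray(arr, dtype=np.int64))


def toy(shape=(6, 20, 20)):
    return np.zeros(shape, dtype=np.int64)


def brute_force_classes(gt, test, majority=0.5):
    """Independent, loop-based implementation of the mutual-majority rule."""
    gt_ids = sorted(int(i) for i in np.unique(gt) if i > 0)
    test_ids = sorted(int(i) for i in np.unique(test) if i > 0)

    def overlap(gi, ti):
        return int(np.sum((gt == gi) & (test == ti)))

    gt_major, test_major = {}, {}
    for gi in gt_ids:
        size = int(np.sum(gt == gi))
        for ti in test_ids:
            if overlap(gi, ti) > majority * size:
                gt_major[gi] = ti
    for ti in test_ids:
        size = int(np.sum(test == ti))
        for gi in gt_ids:
            if overlap(gi, ti) > majority * size:
                test_major[ti] = gi

    mutual = {(gi, ti) for gi, ti in gt_major.items()
              if test_major.get(ti) == gi}
    merge_products = {ti for ti in test_ids
                      if sum(1 for gi in gt_ids if gt_major.get(gi) == ti) >= 2}
    split_parents = {gi for gi in gt_ids
                     if sum(1 for ti in test_ids if test_major.get(ti) == gi) >= 2}

    gt_cls, test_cls = {}, {}
    for gi in gt_ids:
        if any(g == gi for g, _ in mutual):
            gt_cls[gi] = "accurate"
        elif gt_major.get(gi) in merge_products:
            gt_cls[gi] = "merge"
        elif gi in split_parents:
            gt_cls[gi] = "split"
        else:
            gt_cls[gi] = "miss"
    for ti in test_ids:
        if any(t == ti for _, t in mutual):
            test_cls[ti] = "accurate"
        elif ti in merge_products:
            test_cls[ti] = "merge"
        elif test_major.get(ti) in split_parents:
            test_cls[ti] = "split"
        else:
            test_cls[ti] = "spurious"
    return gt_cls, test_cls


def random_toy_pair(rng, n_max=5):
    """A random GT/test pair of up to n_max blocky instances."""
    gt = toy()
    test = toy()
    n = int(rng.integers(1, n_max + 1))
    nid = 1
    for _ in range(n):
        z0 = int(rng.integers(0, 4))
        y0 = int(rng.integers(0, 14))
        x0 = int(rng.integers(0, 14))
        dz, dy, dx = (int(rng.integers(1, 3)), int(rng.integers(3, 7)),
                      int(rng.integers(3, 7)))
        gt[z0:z0 + dz, y0:y0 + dy, x0:x0 + dx] = nid
        mode = rng.integers(0, 4)
        if mode == 0:      # perfect copy
            test[z0:z0 + dz, y0:y0 + dy, x0:x0 + dx] = nid
        elif mode == 1:    # split in two
            mid = y0 + dy // 2
            test[z0:z0 + dz, y0:mid, x0:x0 + dx] = nid
            test[z0:z0 + dz, mid:y0 + dy, x0:x0 + dx] = nid + 50
        elif mode == 2:    # shifted copy (may become miss+spurious)
            test[z0:z0 + dz, y0 + 2:y0 + dy + 2, x0 + 2:x0 + dx + 2] = nid
        # mode 3: absent -> miss
        nid += 1
    return vol(gt), vol(test)


class TestMatching:
    def test_identical_labelling_all_accurate(self):
        gt = toy()
        gt[1:3, 2:8, 2:8] = 1
        gt[3:5, 10:16, 10:16] = 2
        table = match_instances(vol(gt), vol(gt.copy()))
        assert table.gt_class == {1: "accurate", 2: "accurate"}
        assert table.test_class == {1: "accurate", 2: "accurate"}

    def test_two_nuclei_covered_by_one_is_merge(self):
        gt = toy()
        gt[1:3, 2:8, 2:8] = 1
        gt[1:3, 9:15, 2:8] = 2
        test = toy()
        test[1:3, 2:15, 2:8] = 7
        table = match_instances(vol(gt), vol(test))
        assert table.gt_class == {1: "merge", 2: "merge"}
        assert table.test_class == {7: "merge"}
        report = compute_metrics(table)
        assert report.counts["accurate"] == 0

    def test_split_plus_spurious(self):
        gt = toy()
        gt[1:4, 2:10, 2:10] = 1
        test = toy()
        test[1:4, 2:6, 2:10] = 1
        test[1:4, 6:10, 2:10] = 2
        test[1:4, 14:18, 14:18] = 3  # blob in empty space
        table = match_instances(vol(gt), vol(test))
        assert table.gt_class == {1: "split"}
        assert table.test_class == {1: "split", 2: "split", 3: "spurious"}

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            match_instances(vol(toy((2, 5, 5))), vol(toy((3, 5, 5))))

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        gt, test = random_toy_pair(rng)
        table = match_instances(gt, test)
        gt_cls, test_cls = brute_force_classes(gt.data, test.data)
        assert table.gt_class == gt_cls
        assert table.test_class == test_cls

    @pytest.mark.parametrize("seed", range(10))
    def test_gt_class_conservation(self, seed):
        """accurate + merge members + split parents + misses = |GT|."""
        rng = np.random.default_rng(100 + seed)
        gt, test = random_toy_pair(rng)
        table = match_instances(gt, test)
        total = sum(table.count(c) for c in ("accurate", "merge", "split", "miss"))
        assert total == len(table.gt_class)

    @pytest.mark.parametrize("seed", range(10))
    def test_swap_symmetry(self, seed):
        """Swapping GT and test exchanges miss<->spurious, merge<->split."""
        rng = np.random.default_rng(200 + seed)
        gt, test = random_toy_pair(rng)
        fwd = match_instances(gt, test)
        rev = match_instances(test, gt)
        assert fwd.count("miss") == rev.count("spurious", side="test")
        assert fwd.count("merge") == rev.count("split")
        assert fwd.count("accurate") == rev.count("accurate")


class TestMetrics:
    def test_perfect_match(self):
        gt = toy()
        for i in range(5):
            gt[1:3, 1 + 3 * i:3 + 3 * i, 2:8] = i + 1
        report = compute_metrics(match_instances(vol(gt), vol(gt.copy())))
        assert report.precision == report.recall == report.f_measure == 1.0
        assert report.mean_ji == 1.0

    def test_nine_of_ten_recovered(self):
        gt = toy((4, 25, 25))
        test = toy((4, 25, 25))
        for i in range(10):
            y = 1 + 2 * i
            gt[1:3, y:y + 2, 2:20] = i + 1
            if i < 9:
                test[1:3, y:y + 2, 2:20] = i + 1
        report = compute_metrics(match_instances(vol(gt), vol(test)))
        assert report.recall == pytest.approx(0.9)
        assert report.precision == pytest.approx(1.0)
        assert report.f_measure == pytest.approx(2 * 0.9 / 1.9)

    def test_zero_accurate_gives_zero_f(self):
        gt = toy()
        gt[1:3, 2:8, 2:8] = 1
        report = compute_metrics(match_instances(vol(gt), vol(toy())))
        assert report.f_measure == 0.0

    def test_empty_gt_warns(self):
        test = toy()
        test[0, :3, :3] = 1
        with pytest.warns(UserWarning, match="recall"):
            report = compute_metrics(match_instances(vol(toy()), vol(test)))
        assert np.isnan(report.recall)


class TestErrorMap:
    def test_all_accurate_only_code_one(self, tmp_path):
        gt = toy()
        gt[1:3, 2:8, 2:8] = 1
        table = match_instances(vol(gt), vol(gt.copy()))
        path = write_error_map(table, vol(gt), vol(gt.copy()),
                               tmp_path / "map.tif")
        emap = read_label_volume(path)
        assert set(np.unique(emap.data)) == {0, ERROR_CODES["accurate"]}

    def test_merge_and_miss_codes(self, tmp_path):
        gt = toy()
        gt[1:3, 2:8, 2:8] = 1
        gt[1:3, 9:15, 2:8] = 2
        gt[4:6, 14:19, 14:19] = 3  # missed entirely
        test = toy()
        test[1:3, 2:15, 2:8] = 7
        table = match_instances(vol(gt), vol(test))
        path = write_error_map(table, vol(gt), vol(test), tmp_path / "map.tif")
        emap = read_label_volume(path).data
        assert set(np.unique(emap[1:3, 2:15, 2:8])) <= {0, ERROR_CODES["merge"]}
        assert np.all(emap[4:6, 14:19, 14:19] == ERROR_CODES["miss"])
        assert (path.parent / "map.legend.json").exists()
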