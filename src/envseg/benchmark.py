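"""Segmentation benchmarking against ground truth.

Instances of a test segmentation are matched to ground-truth (GT)
instances by a mutual-majority rule: a GT/test pair is a candidate match
when their overlap exceeds half of each instance's volume.  Every GT
instance is then classified as exactly one of

* ``accurate`` — one mutual match;
* ``merge`` (member) — two or more GT instances whose majority overlap
  lands on the same test instance;
* ``split`` (parent) — one GT instance majority-covered by two or more
  test instances;
* ``miss`` — no counterpart in the test image;

and every test instance involved in none of those is ``spurious``.
Precision, recall and the F-measure summarise the table: precision is the
fraction of test instances that are accurate, recall the fraction of GT
instances recovered.  An optional Jaccard dialect (``JI >= 0.5`` instead
of mutual majority) is available for comparison with other comparators.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io import LabelVolume, write_label_volume

__all__ = ["MatchTable", "BenchmarkReport", "match_instances",
           "compute_metrics", "write_error_map", "benchmark_directories",
           "ERROR_CODES"]

ERROR_CODES = {"accurate": 1, "merge": 2, "split": 3, "spurious": 4, "miss": 5}


@dataclass
class MatchTable:
    """Per-instance classification and the overlaps that produced it."""

    gt_class: dict        # gt id -> class name
    test_class: dict      # test id -> class name
    pair_ji: dict         # (gt, test) mutual matches -> Jaccard index
    gt_sizes: dict
    test_sizes: dict
    overlaps: dict        # (gt, test) -> voxel overlap

    def count(self, cls: str, side: str = "gt") -> int:
        table = self.gt_class if side == "gt" else self.test_class
        return sum(1 for v in table.values() if v == cls)


@dataclass
class BenchmarkReport:
    counts: dict
    precision: float
    recall: float
    f_measure: float
    mean_ji: float
    mean_centroid_distance: float = float("nan")

    def as_row(self) -> dict:
        row = dict(self.counts)
        row.update(precision=self.precision, recall=self.recall,
                   f_measure=self.f_measure, mean_ji=self.mean_ji)
        return row


def _overlap_table(gt: np.ndarray, test: np.ndarray):
    pairs = np.stack([gt.ravel(), test.ravel()])
    uniq, counts = np.unique(pairs, axis=1, return_counts=True)
    overlaps: dict = {}
    for (g, t), c in zip(uniq.T, counts):
        overlaps[(int(g), int(t))] = int(c)
    return overlaps


def match_instances(gt: LabelVolume, test: LabelVolume,
                    rule: str = "mutual_majority",
                    majority: float = 0.5) -> MatchTable:
    """Match and classify instances of ``test`` against ``gt``.

    ``rule`` is ``mutual_majority`` (default) or ``jaccard`` (candidate
    match when JI >= ``majority``).
    """
    if gt.data.shape != test.data.shape:
        raise ValueError("ground truth and test images are on different grids")
    g, t = np.asarray(gt.data), np.asarray(test.data)
    overlaps = _overlap_table(g, t)
    gt_ids = [int(i) for i in np.unique(g) if i > 0]
    test_ids = [int(i) for i in np.unique(t) if i > 0]
    gt_sizes = {i: 0 for i in gt_ids}
    test_sizes = {i: 0 for i in test_ids}
    for (gi, ti), c in overlaps.items():
        if gi > 0:
            gt_sizes[gi] += c
        if ti > 0:
            test_sizes[ti] += c

    def ji(gi, ti):
        ov = overlaps.get((gi, ti), 0)
        return ov / (gt_sizes[gi] + test_sizes[ti] - ov) if ov else 0.0

    # majority partners
    gt_major: dict = {}    # gt -> test holding > majority of the gt
    test_major: dict = {}  # test -> gt holding > majority of the test
    for (gi, ti), ov in overlaps.items():
        if gi <= 0 or ti <= 0:
            continue
        if ov > majority * gt_sizes[gi]:
            gt_major[gi] = ti
        if ov > majority * test_sizes[ti]:
            test_major[ti] = gi

    if rule == "jaccard":
        mutual = {(gi, ti): ji(gi, ti) for (gi, ti) in overlaps
                  if gi > 0 and ti > 0 and ji(gi, ti) >= majority}
    elif rule == "mutual_majority":
        mutual = {(gi, ti): ji(gi, ti) for gi, ti in gt_major.items()
                  if test_major.get(ti) == gi}
    else:
        raise ValueError(f"unknown matching rule {rule!r}")

    gt_class: dict = {}
    test_class: dict = {}
    mutual_gt = {gi for gi, _ in mutual}
    mutual_test = {ti for _, ti in mutual}

    # merge groups: several gt majority-mapped onto one test
    by_test: dict = {}
    for gi, ti in gt_major.items():
        by_test.setdefault(ti, []).append(gi)
    merge_products = {ti for ti, gis in by_test.items() if len(gis) >= 2}

    # split groups: several test majority-mapped onto one gt
    by_gt: dict = {}
    for ti, gi in test_major.items():
        by_gt.setdefault(gi, []).append(ti)
    split_parents = {gi for gi, tis in by_gt.items() if len(tis) >= 2}

    for gi in gt_ids:
        if gi in mutual_gt:
            gt_class[gi] = "accurate"
        elif gt_major.get(gi) in merge_products:
            gt_class[gi] = "merge"
        elif gi in split_parents:
            gt_class[gi] = "split"
        else:
            gt_class[gi] = "miss"

    for ti in test_ids:
        if ti in mutual_test:
            test_class[ti] = "accurate"
        elif ti in merge_products:
            test_class[ti] = "merge"
        elif test_major.get(ti) in split_parents:
            test_class[ti] = "split"
        else:
            test_class[ti] = "spurious"

    return MatchTable(gt_class=gt_class, test_class=test_class,
                      pair_ji=dict(mutual), gt_sizes=gt_sizes,
                      test_sizes=test_sizes, overlaps=overlaps)


def compute_metrics(table: MatchTable) -> BenchmarkReport:
    """Precision / recall / F-measure and shape agreement from a match table.

    precision = accurate / (all test instances); recall = accurate / |GT|;
    F = 2PR/(P+R), defined as 0 when P + R = 0.  The precision denominator
    counts every test instance exactly once, whatever its class.
    """
    n_gt = len(table.gt_class)
    n_test = len(table.test_class)
    accurate = table.count("accurate")
    counts = {
        "n_gt": n_gt,
        "n_test": n_test,
        "accurate": accurate,
        "merge_events": table.count("merge", side="test"),
        "merged_gt": table.count("merge"),
        "split_gt": table.count("split"),
        "miss": table.count("miss"),
        "spurious": table.count("spurious", side="test"),
    }
    precision = accurate / n_test if n_test else 0.0
    if n_gt == 0:
        warnings.warn("empty ground truth: recall undefined", stacklevel=2)
        recall = float("nan")
        f = float("nan")
    else:
        recall = accurate / n_gt
        f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    jis = list(table.pair_ji.values())
    mean_ji = float(np.mean(jis)) if jis else float("nan")
    return BenchmarkReport(counts=counts, precision=precision, recall=recall,
                           f_measure=f, mean_ji=mean_ji)


def write_error_map(table: MatchTable, gt: LabelVolume, test: LabelVolume,
                    path) -> Path:
    """Colour-coded error map: voxels carry their instance's class code
    (1 accurate, 2 merge, 3 split, 4 spurious, 5 miss; misses are rendered
    from the GT masks).  A JSON legend sidecar is written alongside."""
    out = np.zeros(test.data.shape, dtype=np.uint16)
    t = np.asarray(test.data)
    g = np.asarray(gt.data)
    for ti, cls in table.test_class.items():
        out[t == ti] = ERROR_CODES[cls]
    for gi, cls in table.gt_class.items():
        if cls == "miss":
            out[(g == gi) & (out == 0)] = ERROR_CODES["miss"]
    path = Path(path)
    write_label_volume(LabelVolume(out.astype(np.int64), test.calibration), path)
    legend = path.with_suffix(".legend.json")
    legend.write_text(json.dumps(ERROR_CODES, indent=2) + "\n")
    return path


def benchmark_directories(gt_dir, test_dir, out_dir) -> pd.DataFrame:
    """Batch comparison of two directories matched by filename.

    Writes ``Summary.tsv`` (one row of metrics per image) and one error-map
    TIFF per image into ``out_dir``; returns the summary table.
    """
    from .io import read_label_volume

    gt_dir, test_dir, out_dir = Path(gt_dir), Path(test_dir), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    names = sorted(p.name for p in gt_dir.glob("*.tif*"))
    for name in names:
        test_path = test_dir / name
        if not test_path.exists():
            continue
        gt = read_label_volume(gt_dir / name)
        test = read_label_volume(test_path)
        table = match_instances(gt, test)
        report = compute_metrics(table)
        write_error_map(table, gt, test, out_dir / f"errormap_{name}")
        rows.append(dict(image=name, **report.as_row()))
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "Summary.tsv", sep="\t", index=False)
    return df
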