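"""End-to-end segmentation: smooth, enhance, seed, trace, select, link.

Planes are processed independently (the per-plane stages commute with
plane order, so the loop may be parallelised without changing the
output), then 2D areas are linked into 3D volumes and refined.  Time
series are processed frame by frame, sequentially, so memory stays
bounded by one frame plus per-plane buffers.
"""

from __future__ import annotations

import logging
import time
from concurrent.futures import ThreadPoolExecutor
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .io import IntensityVolume, LabelVolume, SegmentationParams
from .linkage import (Area2D, build_link_graph, label_volumes,
                      merge_broken_chains, resolve_ambiguities,
                      volumes_to_label_image)
from .postprocess import refine_volumes
from .ridge import gaussian_smooth, steerable_ridge_response
from .seeds import detect_maxima, dog_filter
from .shapes import (TrainedClassifier, compute_features,
                     enumerate_candidates, plane_intensity_scale,
                     resolve_plane_conflicts, select_winners)
from .tracing import build_tree

logger = logging.getLogger(__name__)

__all__ = ["segment", "segment_plane", "segment_timelapse"]

_MAX_SEEDS_PER_PLANE = 300


def segment_plane(plane: np.ndarray, z: int, params: SegmentationParams,
                  classifier: TrainedClassifier) -> list:
    """Run the 2D stages on one plane; returns the accepted shapes.

    Seeds are visited in decreasing score order (bounded per plane); a seed
    falling inside an already accepted, confidently valid winner is skipped
    — its nucleus is taken — which keeps the output deterministic while
    avoiding redundant tracing of the same shell.
    """
    raw = np.asarray(plane, dtype=np.float64)
    work = gaussian_smooth(raw, params.smoothing_sigma) \
        if params.smoothing_sigma > 0 else raw
    response = steerable_ridge_response(work, params.ridge_scale)
    dog = dog_filter(work, params.dog_sigma_small, params.dog_sigma_large)
    seeds = detect_maxima(dog, params.seed_threshold,
                          params.seed_separation, plane_index=z)
    seeds = seeds[:_MAX_SEEDS_PER_PLANE]
    scale = plane_intensity_scale(raw)

    winners = []
    claimed: set = set()
    for seed in seeds:
        if seed.position in claimed:
            continue
        tree = build_tree(response, seed, params)
        if not tree.ridglets:
            continue
        candidates = enumerate_candidates(tree, plane_index=z)
        for cand in candidates:
            compute_features(cand, raw, response.response,
                             intensity_scale=scale)
        found = select_winners(candidates, classifier, params.posterior_cut)
        winners.extend(found)
        for w in found:
            if w.posterior_valid >= 0.99:
                claimed |= w.pixels
    return resolve_plane_conflicts(winners)


def _drop_background_volumes(volumes, intensity: IntensityVolume,
                             params: SegmentationParams):
    """Plausibility gate: an envelope-labelled nucleus is bright.

    A volume whose mean intensity barely exceeds the image background is
    noise or internuclear space; it must rise above background by
    ``min_foreground_fraction`` of the local foreground relief (the
    per-plane foreground scale over the volume's own planes, so
    depth-dependent falloff is respected).
    """
    if params.min_foreground_fraction <= 0 or not volumes:
        return volumes
    plane_stats: dict = {}

    def stats(z):
        if z not in plane_stats:
            pl = intensity.plane(z).astype(np.float64)
            plane_stats[z] = (float(np.median(pl)), plane_intensity_scale(pl))
        return plane_stats[z]

    kept = []
    for v in volumes:
        n = 0
        total = 0.0
        bg = fg = 0.0
        for z, pixels in v.areas.items():
            if not 0 <= z < intensity.n_planes:
                continue
            pl = intensity.plane(z)
            vals = [float(pl[y, x]) for x, y in pixels
                    if 0 <= y < pl.shape[0] and 0 <= x < pl.shape[1]]
            if not vals:
                continue
            total += sum(vals)
            n += len(vals)
            m, s = stats(z)
            bg += m * len(vals)
            fg += s * len(vals)
        if n == 0:
            continue
        mean, bg, fg = total / n, bg / n, fg / n
        if fg <= bg or mean >= bg + params.min_foreground_fraction * (fg - bg):
            kept.append(v)
    return kept


def _areas_by_plane(accepted_per_plane: dict) -> dict:
    out: dict = {}
    for z, shapes in accepted_per_plane.items():
        areas = []
        for i, shp in enumerate(shapes):
            areas.append(Area2D(plane=z, index=i, pixels=frozenset(shp.pixels)))
        if areas:
            out[z] = areas
    return out


def segment(volume: IntensityVolume, params: SegmentationParams,
            classifier: TrainedClassifier,
            n_workers: int = 1) -> tuple[LabelVolume, pd.DataFrame]:
    """Segment one volume into labelled nuclei.

    Returns the instance label image and a per-nucleus table (id, centroid
    in micrometres, volume, plane span, mean envelope intensity).  The
    output is deterministic and identical for any ``n_workers``.
    """
    params.validate()
    nz = volume.n_planes
    t0 = time.perf_counter()

    def run_plane(z: int):
        return segment_plane(volume.plane(z), z, params, classifier)

    if n_workers > 1:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            results = list(pool.map(run_plane, range(nz)))
    else:
        results = [run_plane(z) for z in range(nz)]
    accepted = {z: shapes for z, shapes in enumerate(results)}
    n_shapes = sum(len(s) for s in results)
    logger.info("2D stage: %d shapes in %d planes (%.1f s)",
                n_shapes, nz, time.perf_counter() - t0)

    areas = _areas_by_plane(accepted)
    graph = build_link_graph(areas, params, volume.calibration)
    graph = resolve_ambiguities(graph, params, volume.calibration)
    volumes = label_volumes(graph, params, volume.calibration)
    volumes = merge_broken_chains(volumes, params, volume.calibration)
    volumes = refine_volumes(volumes, volume, params)
    # volume constraints re-applied after refinement
    volumes = [v for v in volumes if params.min_volume <= v.volume]
    volumes = _drop_background_volumes(volumes, volume, params)
    for new_id, v in enumerate(volumes, start=1):
        v.id = new_id

    nzyx = (nz, volume.data.shape[1], volume.data.shape[2])
    labels = volumes_to_label_image(volumes, nzyx, volume.calibration)

    rows = []
    for v in volumes:
        cx, cy, cz = v.centroid
        vals = []
        for z, pixels in v.areas.items():
            if 0 <= z < nz:
                pl = volume.plane(z)
                vals.extend(float(pl[y, x]) for x, y in pixels
                            if 0 <= y < pl.shape[0] and 0 <= x < pl.shape[1])
        rows.append({
            "id": v.id, "centroid_x_um": cx, "centroid_y_um": cy,
            "centroid_z_um": cz, "volume_um3": v.volume,
            "plane_min": v.planes[0], "plane_max": v.planes[-1],
            "mean_intensity": float(np.mean(vals)) if vals else float("nan"),
        })
    table = pd.DataFrame(rows)
    logger.info("segmented %d nuclei in %.1f s", len(volumes),
                time.perf_counter() - t0)
    return labels, table


def segment_timelapse(frames: Union[Sequence[IntensityVolume], str],
                      params: SegmentationParams,
                      classifier: TrainedClassifier,
                      timepoints: Optional[Iterable[int]] = None,
                      n_workers: int = 1):
    """Segment a time series frame by frame (generator).

    ``frames`` is either a sequence of volumes or a path to a 4D/5D TIFF;
    each requested frame is loaded, segmented and yielded as
    ``(t, LabelVolume, table)`` before the next one is touched.  Frames
    are independent, so any ``timepoints`` order gives the same per-frame
    results.
    """
    from . import io as _io

    if isinstance(frames, (str, bytes)) or hasattr(frames, "__fspath__"):
        path = frames

        def get_frame(t: int) -> IntensityVolume:
            return _io.read_volume(path, timepoint=t)

        import tifffile
        with tifffile.TiffFile(path) as tf:
            axes = tf.series[0].axes.upper()
            shp = dict(zip(axes, tf.series[0].shape))
        n_frames = shp.get("T", 1)
    else:
        seq = list(frames)

        def get_frame(t: int) -> IntensityVolume:
            return seq[t]

        n_frames = len(seq)

    if timepoints is None:
        timepoints = range(n_frames)
    for t in timepoints:
        frame = get_frame(t)
        labels, table = segment(frame, params, classifier, n_workers=n_workers)
        yield t, labels, table
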